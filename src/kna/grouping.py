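"""Binning of (log-density, SNPC1, SNPC2) triples and bin grouping.

Every localisation of every image is summarised by three numbers: log10
local density and its two SNPCA scores.  A single 50x50x50 grid spanning
the pooled range of all images discretises this space; counting
localisations per 3D bin and unfolding the grid turns each image into a
row of a compositional frequency table (rows sum to one).  Bins with
similar frequency profiles across images are then merged into a small
number of "groups" — the colour key that is mapped back onto the images.

Two grouping paths are provided: a generic average-linkage hierarchical
cut, and the nine-group scheme (k-means with k=4 on bins occupied in all
images, the leftover bins split in two by density, then clusters
straddling SNPC1 = 0 split at that boundary).

Flattened bin index convention (stable, part of the file format):
``index = i_den * n_bins**2 + i_pc1 * n_bins + i_pc2`` with axis order
(log10Den, PC1, PC2).  Per-axis bins are half-open [lo, hi) except the
last bin, which is closed at the axis maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

__all__ = [
    "GridSpec",
    "FrequencyTable",
    "GroupAssignment",
    "build_grid",
    "bin_localisations",
    "assemble_frequency_table",
    "filter_common_bins",
    "cluster_bins_hierarchical",
    "nine_group_scheme",
    "assign_localisation_groups",
]

AXIS_NAMES = ("log10_density", "pc1", "pc2")


@dataclass(frozen=True)
class GridSpec:
    """Common 3D binning grid, axis order (log10Den, PC1, PC2)."""

    mins: tuple[float, float, float]
    maxs: tuple[float, float, float]
    n_bins: int = 50

    def __post_init__(self) -> None:
        for name, lo, hi in zip(AXIS_NAMES, self.mins, self.maxs):
            if not hi > lo:
                raise ValueError(f"degenerate axis {name}: [{lo}, {hi}]")

    def axis_index(self, axis: int, values: np.ndarray) -> np.ndarray:
        """Per-axis bin index with boundary clamping.

        Values exactly at the axis maximum fall in the last bin; values
        outside the range are clamped to the nearest boundary bin.
        """
        lo, hi = self.mins[axis], self.maxs[axis]
        width = (hi - lo) / self.n_bins
        idx = np.floor((np.asarray(values, float) - lo) / width).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def flat_index(self, log10_den, pc1, pc2) -> np.ndarray:
        i0 = self.axis_index(0, log10_den)
        i1 = self.axis_index(1, pc1)
        i2 = self.axis_index(2, pc2)
        return i0 * self.n_bins**2 + i1 * self.n_bins + i2

    def bin_centres(self, flat: np.ndarray) -> np.ndarray:
        """(len(flat), 3) centre coordinates of flattened bin indices."""
        flat = np.asarray(flat, int)
        idx = np.stack(
            [flat // self.n_bins**2, (flat // self.n_bins) % self.n_bins, flat % self.n_bins],
            axis=1,
        )
        centres = np.empty(idx.shape, float)
        for a in range(3):
            width = (self.maxs[a] - self.mins[a]) / self.n_bins
            centres[:, a] = self.mins[a] + (idx[:, a] + 0.5) * width
        return centres

    def to_dict(self) -> dict:
        return {"mins": list(self.mins), "maxs": list(self.maxs), "n_bins": self.n_bins}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["mins"]), tuple(d["maxs"]), int(d["n_bins"]))


def build_grid(
    coordinate_sets: list[np.ndarray], n_bins: int = 50
) -> GridSpec:
    """Grid spanning the pooled per-axis range of all images.

    ``coordinate_sets`` holds one (N_i, 3) array per image with columns
    (log10Den, PC1, PC2); non-finite rows are ignored.  Equal-width bins
    per axis.  Adding an image strictly inside the pooled range leaves
    the grid unchanged.
    """
    if not coordinate_sets:
        raise ValueError("need at least one image")
    pooled = np.vstack([np.asarray(c, float) for c in coordinate_sets])
    pooled = pooled[np.isfinite(pooled).all(axis=1)]
    if pooled.size == 0:
        raise ValueError("no finite coordinates")
    mins = tuple(pooled.min(axis=0))
    maxs = tuple(pooled.max(axis=0))
    return GridSpec(mins, maxs, n_bins)


def bin_localisations(
    coords: np.ndarray, grid: GridSpec
) -> tuple[dict[int, int], np.ndarray]:
    """Count localisations per occupied 3D bin.

    ``coords`` is (N, 3) in axis order (log10Den, PC1, PC2); non-finite
    rows (e.g. invalid-profile localisations) get bin index -1 and are
    not counted.  Out-of-range values — possible when a grid is reused on
    new data — are clamped to the boundary bin with a warning.

    Returns ``(counts, flat_index_per_localisation)`` where ``counts``
    maps occupied flattened bin index to its count.
    """
    coords = np.asarray(coords, float)
    finite = np.isfinite(coords).all(axis=1)
    out = np.full(len(coords), -1, dtype=int)
    vals = coords[finite]
    n_outside = int(
        np.sum(
            (vals < np.array(grid.mins)) | (vals > np.array(grid.maxs))
        )
    )
    if n_outside:
        warnings.warn(
            f"{n_outside} coordinate values outside the grid range were "
            "clamped to boundary bins",
            stacklevel=2,
        )
    out[finite] = grid.flat_index(vals[:, 0], vals[:, 1], vals[:, 2])
    occupied, counts = np.unique(out[out >= 0], return_counts=True)
    return dict(zip(occupied.tolist(), counts.tolist())), out


@dataclass(frozen=True)
class FrequencyTable:
    """Images x occupied-bins count matrix with a compositional view.

    ``counts`` is a pandas DataFrame: rows indexed by image id, columns by
    flattened bin index (sorted ascending, hence deterministic).
    """

    counts: pd.DataFrame

    @property
    def normalised(self) -> pd.DataFrame:
        """Row-stochastic view: each row divided by its total."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    @property
    def bin_indices(self) -> np.ndarray:
        return self.counts.columns.to_numpy(int)

    @property
    def image_ids(self) -> list:
        return list(self.counts.index)


def assemble_frequency_table(per_image_counts: dict[str, dict[int, int]]) -> FrequencyTable:
    """Stack per-image bin counts into one table.

    Columns are the union of occupied bins over all images (zero where an
    image does not occupy a bin); every image must have at least one
    counted localisation.
    """
    for image_id, counts in per_image_counts.items():
        if not counts:
            raise ValueError(f"image {image_id!r} has no binned localisations")
    frame = (
        pd.DataFrame(per_image_counts)
        .T.fillna(0)
        .astype(int)
        .sort_index(axis=1)
    )
    frame = frame.loc[list(per_image_counts)]  # preserve image order
    return FrequencyTable(frame)


def filter_common_bins(table: FrequencyTable) -> tuple[FrequencyTable, np.ndarray]:
    """Split columns into bins occupied by every image vs the rest.

    Returns the filtered table (common bins only) and the array of
    leftover bin indices.
    """
    if len(table.counts) < 2:
        raise ValueError("need at least two images")
    common = (table.counts > 0).all(axis=0)
    if not common.any():
        raise ValueError(
            "no bin is occupied in all images; the images may be too "
            "dissimilar or too sparse for a common grid"
        )
    kept = table.counts.loc[:, common]
    leftover = table.counts.columns[~common].to_numpy(int)
    return FrequencyTable(kept), leftover


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of occupied bins into labelled groups (1..m)."""

    bin_to_group: dict[int, int]
    provenance: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.bin_to_group.values()))

    def group_members(self) -> dict[int, list[int]]:
        members: dict[int, list[int]] = {}
        for b, g in self.bin_to_group.items():
            members.setdefault(g, []).append(b)
        return {g: sorted(v) for g, v in sorted(members.items())}

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "bin_to_group": {str(k): int(v) for k, v in self.bin_to_group.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupAssignment":
        return cls(
            {int(k): int(v) for k, v in d["bin_to_group"].items()},
            d.get("provenance", {}),
        )


def cluster_bins_hierarchical(
    table: FrequencyTable, n_groups: int, metric: str = "euclidean"
) -> GroupAssignment:
    """Average-linkage hierarchical clustering of bins (columns).

    Each bin is represented by its normalised-frequency profile across
    images; the dendrogram is cut to ``n_groups`` labels.
    """
    profiles = table.normalised.to_numpy().T  # bins x images
    if n_groups > len(profiles):
        raise ValueError(f"n_groups={n_groups} exceeds {len(profiles)} bins")
    if len(profiles) == 1:
        labels = np.array([1])
    else:
        z = linkage(profiles, method="average", metric=metric)
        labels = fcluster(z, t=n_groups, criterion="maxclust")
    bins = table.bin_indices
    return GroupAssignment(
        {int(b): int(g) for b, g in zip(bins, labels)},
        provenance={"method": "hierarchical-average", "n_groups": n_groups},
    )


def nine_group_scheme(
    filtered: FrequencyTable,
    leftover_bins: np.ndarray,
    grid: GridSpec,
    leftover_counts: pd.DataFrame | None = None,
    k_kmeans: int = 4,
    split_min_frac: float = 0.10,
    seed: int = 0,
) -> GroupAssignment:
    """The joint colour-key scheme: k-means, leftover split, SNPC1 split.

    1. k-means (``k_kmeans``, 50 restarts, fixed seed) on the
       normalised-frequency profiles of bins occupied in all images.
    2. Bins not occupied in all images form one extra category, split in
       two at the median bin-centre log10-density of those bins (weighted
       by pooled counts when ``leftover_counts`` is given).
    3. Every cluster from steps 1-2 whose member bins place at least
       ``split_min_frac`` of the cluster's pooled localisations on each
       side of SNPC1 = 0 (by bin centre) is split at that boundary.

    With the reference configuration (k=4, two leftover categories, three
    straddling clusters) this yields 4 + 2 = 6 clusters before splitting
    and 9 groups after.  Group labels are renumbered 1..m; provenance
    records which clusters were split.
    """
    profiles = filtered.normalised.to_numpy().T
    if k_kmeans > len(profiles):
        raise ValueError(f"k_kmeans={k_kmeans} exceeds {len(profiles)} common bins")
    km = KMeans(n_clusters=k_kmeans, n_init=50, random_state=seed)
    km_labels = km.fit_predict(profiles)

    bins = filtered.bin_indices
    clusters: list[np.ndarray] = [bins[km_labels == c] for c in range(k_kmeans)]

    leftover_bins = np.asarray(leftover_bins, int)
    if leftover_bins.size:
        centres = grid.bin_centres(leftover_bins)[:, 0]  # log10 density
        if leftover_counts is not None and len(leftover_counts):
            weights = leftover_counts.loc[:, leftover_bins].sum(axis=0).to_numpy(float)
        else:
            weights = np.ones(leftover_bins.size)
        order = np.argsort(centres, kind="stable")
        cum = np.cumsum(weights[order])
        median_pos = np.searchsorted(cum, cum[-1] / 2.0, side="right")
        low = leftover_bins[order[: max(median_pos, 1)]]
        high = leftover_bins[order[max(median_pos, 1):]]
        clusters.append(low)
        if high.size:
            clusters.append(high)

    n_before_split = len(clusters)

    # pooled per-bin totals for the straddle rule
    totals = filtered.counts.sum(axis=0)
    if leftover_counts is not None and leftover_bins.size:
        totals = pd.concat([totals, leftover_counts.loc[:, leftover_bins].sum(axis=0)])
    totals = totals.groupby(level=0).sum()

    final: list[np.ndarray] = []
    split_ids: list[int] = []
    for ci, members in enumerate(clusters):
        pc1 = grid.bin_centres(members)[:, 1]
        w = totals.reindex(members).fillna(1.0).to_numpy(float)
        wtot = w.sum()
        neg, pos = members[pc1 < 0], members[pc1 >= 0]
        frac_neg = w[pc1 < 0].sum() / wtot if wtot else 0.0
        if min(frac_neg, 1 - frac_neg) >= split_min_frac and neg.size and pos.size:
            final.extend([neg, pos])
            split_ids.append(ci)
        else:
            final.append(members)

    bin_to_group = {
        int(b): gi + 1 for gi, members in enumerate(final) for b in members
    }
    return GroupAssignment(
        bin_to_group,
        provenance={
            "method": "nine-group-scheme",
            "k_kmeans": k_kmeans,
            "split_min_frac": split_min_frac,
            "seed": seed,
            "n_clusters_before_split": n_before_split,
            "split_cluster_ids": split_ids,
            "n_groups": len(final),
        },
    )


def assign_localisation_groups(
    flat_index: np.ndarray, assignment: GroupAssignment
) -> np.ndarray:
    """Transfer bin group labels to localisations.

    ``flat_index`` is the per-localisation flattened bin index from
    :func:`bin_localisations`; entries of -1 (invalid localisations) get
    label 0.  An occupied bin missing from the assignment is an error.
    """
    flat_index = np.asarray(flat_index, int)
    labels = np.zeros(flat_index.shape, int)
    valid = flat_index >= 0
    unknown = set(np.unique(flat_index[valid]).tolist()) - set(assignment.bin_to_group)
    if unknown:
        raise KeyError(f"bins without a group assignment: {sorted(unknown)[:10]}")
    lut = assignment.bin_to_group
    labels[valid] = [lut[b] for b in flat_index[valid]]
    return labels
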