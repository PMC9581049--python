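"""Per-localisation K-nearest-neighbour distance features.

Each localisation *i* is described by the vector of Euclidean distances
``(D_i1, ..., D_iK)`` to its first K nearest neighbours (self excluded) —
its K-neighbourhood.  Dividing the vector by its own last entry ``D_iK``
yields a scale-free profile on (0, 1] whose shape encodes local topology:
for a homogeneous Poisson process the expected profile is ``sqrt(j/K)``,
while clustered or segregated points bend the curve away from it.

The same distances give a local density estimate
``Den_i = (K/2) / (pi * Dbar_i**2)`` with ``Dbar_i`` the row mean — the
intensity for which a disk of radius ``Dbar_i`` would hold ``K/2`` points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import LocalisationTable

__all__ = [
    "NNFT",
    "NormalisedNNFT",
    "compute_nnft",
    "normalise_nnft",
    "local_density",
    "kth_nn_distances",
]


class InsufficientPointsError(ValueError):
    """Fewer than K+1 points available for a K-neighbourhood."""


@dataclass(frozen=True)
class NNFT:
    """Nearest-neighbour feature table: N rows of K sorted NN distances.

    ``distances[i, j-1]`` is the distance from point *i* to its *j*-th
    nearest other point, so every row is non-decreasing.  Duplicate input
    coordinates produce zero entries; these rows are kept but should be
    flagged downstream (see :func:`normalise_nnft`).
    """

    distances: np.ndarray
    K: int
    image_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[1] != self.K:
            raise ValueError(f"distances must be (N, {self.K})")
        object.__setattr__(self, "distances", d)

    @property
    def n(self) -> int:
        return self.distances.shape[0]

    @property
    def row_means(self) -> np.ndarray:
        return self.distances.mean(axis=1)


@dataclass(frozen=True)
class NormalisedNNFT:
    """Scale-free NN feature table: each row divided by its K-th entry.

    ``values`` lie in (0, 1] with the last column identically one on valid
    rows.  ``valid`` flags rows whose K-th distance was strictly positive;
    invalid rows (all K neighbours coincident with the point) are retained
    positionally but must be excluded from statistics.
    """

    values: np.ndarray
    K: int
    valid: np.ndarray
    image_id: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


def _query_neighbours(table: LocalisationTable, k: int) -> np.ndarray:
    n = len(table)
    if n <= k:
        raise InsufficientPointsError(
            f"need at least {k + 1} points for order-{k} neighbourhoods, got {n}"
        )
    tree = cKDTree(table.coords)
    # column 0 of the query is the point itself (distance 0)
    dist, _ = tree.query(table.coords, k=k + 1)
    return dist[:, 1:]


def compute_nnft(table: LocalisationTable, K: int) -> NNFT:
    """Distances from every localisation to its K nearest neighbours.

    Self-exclusion is strict: a point is never its own neighbour, so
    coincident duplicates yield zero distances (a warning is emitted and
    the rows are kept for downstream flagging).  Ties in distance do not
    affect the retained values.

    Raises
    ------
    InsufficientPointsError
        If the table holds fewer than ``K + 1`` points.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    distances = _query_neighbours(table, K)
    n_zero = int((distances[:, 0] == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} localisations have coincident duplicates "
            "(zero nearest-neighbour distance)",
            stacklevel=2,
        )
    return NNFT(distances, K, table.image_id)


def normalise_nnft(nnft: NNFT) -> NormalisedNNFT:
    """Divide each row by its own K-th entry, mapping it onto (0, 1].

    The result is invariant to global coordinate scaling.  Rows whose K-th
    distance is zero (K coincident neighbours) cannot be normalised; they
    are flagged invalid, filled with NaN, and counted via ``n_invalid``.
    """
    last = nnft.distances[:, -1]
    valid = last > 0
    values = np.full_like(nnft.distances, np.nan)
    values[valid] = nnft.distances[valid] / last[valid, None]
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} rows with zero K-th distance flagged invalid",
            stacklevel=2,
        )
    return NormalisedNNFT(values, nnft.K, valid, nnft.image_id)


def local_density(nnft: NNFT) -> np.ndarray:
    """Per-localisation density ``(K/2) / (pi * Dbar**2)``.

    ``Dbar`` is the mean of the row's K distances.  Units are points per
    squared input unit.  Rows with zero mean distance give ``inf`` and
    should be treated as invalid.  Densities are typically examined on a
    log10 scale.
    """
    dbar = nnft.row_means
    with np.errstate(divide="ignore"):
        return (nnft.K / 2.0) / (np.pi * dbar**2)


def kth_nn_distances(table: LocalisationTable, k: int) -> np.ndarray:
    """The single k-th nearest-neighbour distance of every point.

    Used for long-range structure profiles (k of a few hundred) without
    materialising the full feature table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return _query_neighbours(table, k)[:, -1]
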