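"""End-to-end orchestration: config-driven single-image and ensemble runs.

A run takes localisation tables to per-localisation features
(density, SNPC1, SNPC2, r, theta), then — for ensembles — to the common
grid, the compositional frequency table, the nine-group colour key,
log-ratio ordination with permutation tests, and (when a second channel
is present) per-group enrichment.  Every stochastic stage is seeded from
the config, so a rerun of the same config is bit-identical; stage counts
and parameters are logged to a provenance record in the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import ensemble_stats as es
from . import grouping as grp
from .io import LocalisationTable, Window, read_localisations
from .neighbourhood import NNFT, compute_nnft, local_density, normalise_nnft
from .snpca import (
    SNPCABasis,
    default_basis,
    filter_edge_points,
    polar_coords,
    project_snpca,
    train_basis,
)
from .viz import RenderSpec, auto_hue_offset, group_colours, hue_to_rgb, render_points, theta_to_hue

__all__ = ["ImageInput", "RunConfig", "analyse_image", "run_single_image", "run_ensemble"]

log = logging.getLogger("kna.pipeline")

FEATURE_COLUMNS = ["x", "y", "den", "log10_den", "pc1", "pc2", "r", "theta", "valid"]


@dataclass(frozen=True)
class ImageInput:
    """One image of a run: a file path or an in-memory table."""

    path: str | None = None
    table: LocalisationTable | None = None
    image_id: str = ""
    condition: str | None = None
    column_map: dict | None = None
    delimiter: str = ","
    path_b: str | None = None            # optional second channel
    table_b: LocalisationTable | None = None

    def load(self) -> LocalisationTable:
        if self.table is not None:
            return self.table
        if self.path is None:
            raise ValueError("image input needs a path or a table")
        table, report = read_localisations(
            self.path, self.column_map, self.delimiter, image_id=self.image_id or None
        )
        if report.n_dropped_nonfinite:
            log.info(
                "%s: dropped %d non-finite rows", table.image_id, report.n_dropped_nonfinite
            )
        return table

    def load_b(self) -> LocalisationTable | None:
        if self.table_b is not None:
            return self.table_b
        if self.path_b is None:
            return None
        table, _ = read_localisations(self.path_b, self.column_map, self.delimiter)
        return table


@dataclass
class RunConfig:
    """Parameters of a full run; defaults follow the reference analysis.

    ``basis`` selects the universal SNPCA basis: ``"default"`` for the
    shipped artefact, a path to a basis JSON, or ``{"train": {...}}`` with
    keyword arguments for :func:`kna.snpca.train_basis`.
    """

    inputs: list[ImageInput] = field(default_factory=list)
    K: int = 100
    basis: object = "default"
    edge_filter: bool = False
    window: Window | None = None
    grid_bins: int = 50
    k_kmeans: int = 4
    split_min_frac: float = 0.10
    group_seed: int = 0
    n_perm: int = 9999
    test_seed: int = 0
    null_reps: int = 10_000
    thresholds: tuple[float, ...] = (10.0,)
    out_dir: str = "kna-out"
    render: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = [ImageInput(**item) for item in raw.pop("inputs", [])]
        window = raw.pop("window", None)
        cfg = cls(inputs=inputs, **raw)
        if window is not None:
            cfg.window = Window(**window)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("config lists no inputs")
        if self.basis is None:
            raise ValueError("config must name a basis ('default', a path, or training params)")
        for item in self.inputs:
            if item.path is not None and not Path(item.path).exists():
                raise FileNotFoundError(item.path)

    def resolve_basis(self) -> SNPCABasis:
        if isinstance(self.basis, SNPCABasis):
            basis = self.basis
            if basis.K != self.K:
                raise ValueError(
                    f"basis K={basis.K} does not match config K={self.K}"
                )
            return basis
        if self.basis == "default":
            basis = default_basis()
        elif isinstance(self.basis, dict) and "train" in self.basis:
            basis = train_basis(**self.basis["train"])
        elif isinstance(self.basis, str):
            basis = SNPCABasis.from_json(self.basis)
        else:
            raise ValueError(f"unrecognised basis specification: {self.basis!r}")
        if basis.K != self.K:
            raise ValueError(f"basis K={basis.K} does not match config K={self.K}")
        return basis

    def provenance(self) -> dict:
        return {
            "K": self.K,
            "basis": self.basis if isinstance(self.basis, (str, dict)) else "in-memory",
            "edge_filter": self.edge_filter,
            "grid_bins": self.grid_bins,
            "k_kmeans": self.k_kmeans,
            "split_min_frac": self.split_min_frac,
            "group_seed": self.group_seed,
            "n_perm": self.n_perm,
            "test_seed": self.test_seed,
            "null_reps": self.null_reps,
            "thresholds": list(self.thresholds),
            "images": [
                {"image_id": i.image_id or i.path, "condition": i.condition}
                for i in self.inputs
            ],
        }


def analyse_image(
    table: LocalisationTable,
    basis: SNPCABasis,
    K: int = 100,
    edge_filter: bool = False,
    window: Window | None = None,
) -> pd.DataFrame:
    """Per-localisation KNA features for one image.

    Computes the K-NN feature table, normalises it, projects onto the
    universal basis and converts to polar coordinates, alongside the
    local density.  With ``edge_filter`` enabled, localisations whose
    K-neighbourhood disk is truncated by the window are dropped.  Rows
    the profile normalisation flagged invalid carry NaN features and
    ``valid = False``.
    """
    nnft = compute_nnft(table, K)
    if edge_filter:
        if window is None:
            window = Window(
                float(table.x.min()), float(table.x.max()),
                float(table.y.min()), float(table.y.max()),
            )
        keep = filter_edge_points(table, nnft, window)
        table = table.select(keep)
        # neighbours were found against the full table; only rows are dropped
        nnft = NNFT(nnft.distances[keep], K, nnft.image_id)
    normalised = normalise_nnft(nnft)
    scores = project_snpca(normalised, basis)
    r, theta = polar_coords(scores[:, 0], scores[:, 1])
    den = local_density(nnft)
    with np.errstate(divide="ignore"):
        log_den = np.log10(den)
    frame = pd.DataFrame(
        {
            "x": table.x,
            "y": table.y,
            "den": den,
            "log10_den": log_den,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
            "r": r,
            "theta": theta,
            "valid": normalised.valid & np.isfinite(log_den),
        }
    )
    frame.attrs["image_id"] = table.image_id
    log.info(
        "%s: %d localisations, %d invalid", table.image_id, len(frame),
        int((~frame["valid"]).sum()),
    )
    return frame


def run_single_image(config: RunConfig) -> pd.DataFrame:
    """Feature table plus theta-hue render for a single-image config."""
    config.validate()
    if len(config.inputs) != 1:
        raise ValueError("run_single_image expects exactly one input")
    basis = config.resolve_basis()
    table = config.inputs[0].load()
    features = analyse_image(table, basis, config.K, config.edge_filter, config.window)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_id = config.inputs[0].image_id or table.image_id or "image"
    stages = [
        f"load {image_id}: {len(table)} localisations",
        f"features {image_id}: {len(features)} rows, "
        f"{int((~features['valid']).sum())} invalid",
    ]
    features.to_csv(out / f"{image_id}_features.csv", index=False)
    if config.render:
        ok = features["valid"].to_numpy()
        offset = auto_hue_offset(
            features.loc[ok, "theta"].to_numpy(), features.loc[ok, "den"].to_numpy()
        )
        hue = theta_to_hue(features["theta"].to_numpy(), offset)
        colours = hue_to_rgb(np.nan_to_num(hue))
        colours[~ok] = (80, 80, 80)
        render_points(
            table, colours, out / f"{image_id}_theta.png", RenderSpec(), config.window
        )
    (out / "provenance.json").write_text(json.dumps(config.provenance(), indent=1))
    (out / "run.log").write_text("\n".join(stages) + "\n")
    return features


def run_ensemble(config: RunConfig) -> dict:
    """Full ensemble pipeline.

    Returns a dict with the frequency table, group assignment,
    per-localisation labels, ordination and test results, and (when any
    input declares a second channel) enrichment tables.  All artefacts
    are also written to ``config.out_dir``.
    """
    config.validate()
    if len(config.inputs) < 2:
        raise ValueError("ensembles need at least two images")
    basis = config.resolve_basis()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages: list[str] = []
    tables: dict[str, LocalisationTable] = {}
    features: dict[str, pd.DataFrame] = {}
    for i, item in enumerate(config.inputs):
        table = item.load()
        image_id = item.image_id or table.image_id or f"image-{i}"
        if image_id in features:
            raise ValueError(f"duplicate image id {image_id!r}")
        tables[image_id] = table
        features[image_id] = analyse_image(
            table, basis, config.K, config.edge_filter, config.window
        )
        stages.append(f"features {image_id}: {len(features[image_id])} rows")

    coord_sets = {
        iid: f.loc[f["valid"], ["log10_den", "pc1", "pc2"]].to_numpy()
        for iid, f in features.items()
    }
    grid = grp.build_grid(list(coord_sets.values()), config.grid_bins)
    counts: dict[str, dict[int, int]] = {}
    flat: dict[str, np.ndarray] = {}
    for iid, f in features.items():
        c, idx = grp.bin_localisations(
            f[["log10_den", "pc1", "pc2"]].to_numpy(), grid
        )
        counts[iid] = c
        flat[iid] = idx
    freq = grp.assemble_frequency_table(counts)
    filtered, leftover = grp.filter_common_bins(freq)
    assignment = grp.nine_group_scheme(
        filtered,
        leftover,
        grid,
        k_kmeans=config.k_kmeans,
        split_min_frac=config.split_min_frac,
        seed=config.group_seed,
    )
    labels = {iid: grp.assign_localisation_groups(flat[iid], assignment) for iid in features}
    stages.append(
        f"grouping: {len(freq.counts.columns)} occupied bins, "
        f"{len(filtered.counts.columns)} common, {assignment.n_groups} groups"
    )

    groups = sorted(set(assignment.bin_to_group.values()))
    group_freq = pd.DataFrame(
        {
            iid: [
                (labels[iid] == g).sum() / max((labels[iid] > 0).sum(), 1)
                for g in groups
            ]
            for iid in features
        },
        index=groups,
    ).T

    results: dict = {
        "grid": grid,
        "frequency_table": freq,
        "group_assignment": assignment,
        "localisation_groups": labels,
        "group_frequencies": group_freq,
    }

    conditions = {
        (item.image_id or t.image_id or f"image-{i}"): item.condition
        for i, (item, t) in enumerate(zip(config.inputs, tables.values()))
    }
    cond = np.array([conditions[iid] for iid in features])
    if all(c is not None for c in cond):
        levels, counts_per = np.unique(cond, return_counts=True)
        if len(levels) < 2:
            raise ValueError("tests need at least two conditions")
        clr = es.logratio_transform(group_freq.to_numpy())
        ordination = es.ordinate(clr, cond)
        results["ordination"] = ordination
        results["dispersion_test"] = es.dispersion_test(
            ordination.scores[:, : max(2, len(levels) - 1)], cond,
            config.n_perm, config.test_seed,
        )
        results["mean_difference_test"] = es.mean_difference_test(
            ordination.scores[:, : max(2, len(levels) - 1)], cond,
            config.n_perm, config.test_seed,
        )
    else:
        log.warning("conditions missing for some images; permutation tests skipped")

    if any(i.path_b is not None or i.table_b is not None for i in config.inputs):
        enrich_rows = []
        for i, item in enumerate(config.inputs):
            b = item.load_b()
            if b is None:
                continue
            iid = item.image_id or list(features)[i]
            flags = enr.colocalise(tables[iid], b, config.thresholds[0])
            keep = labels[iid] > 0
            res = enr.enrichment_scores(
                labels[iid][keep], flags[keep], config.thresholds[0]
            )
            band = enr.null_enrichment(
                res.table["freq"].to_numpy(), res.n_p,
                reps=config.null_reps, seed=config.test_seed + i,
            )
            enrich_rows.append(
                res.table.assign(
                    image_id=iid,
                    null_lo=band["null_lo"].to_numpy(),
                    null_hi=band["null_hi"].to_numpy(),
                    threshold=config.thresholds[0],
                )
            )
        if enrich_rows:
            results["enrichment"] = pd.concat(enrich_rows, ignore_index=True)

    # --- persist artefacts -------------------------------------------------
    freq.counts.to_csv(out / "frequency_table.csv")
    group_freq.to_csv(out / "group_frequencies.csv")
    (out / "group_assignment.json").write_text(json.dumps(assignment.to_dict(), indent=1))
    for iid, f in features.items():
        f.assign(group=labels[iid]).to_csv(out / f"{iid}_features.csv", index=False)
        if config.render:
            render_points(
                tables[iid],
                group_colours(labels[iid]),
                out / f"{iid}_groups.png",
                RenderSpec(),
                config.window,
            )
    if "enrichment" in results:
        results["enrichment"].to_csv(out / "enrichment.csv", index=False)
    prov = config.provenance()
    prov["grid"] = grid.to_dict()
    prov["n_groups"] = assignment.n_groups
    if "dispersion_test" in results:
        prov["dispersion_p"] = results["dispersion_test"].p_value
        prov["mean_difference_p"] = results["mean_difference_test"].p_value
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    (out / "run.log").write_text("\n".join(stages) + "\n")
    return results
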