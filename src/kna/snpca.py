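"""Spatial-neighbourhood PCA: a universal basis for NN profiles.

Per-image PCA bases are incomparable between images, so the basis is fitted
once on normalised NN profiles of completely spatially random (CSR) points
— a homogeneous Poisson process — and then reused for every image.  Any
normalised feature table can be projected onto the same two leading
components (SNPC1, SNPC2), making point patterns from different images
directly comparable.  CSR data itself projects around the origin; distance
from the origin (r) measures departure from spatial randomness and the
angle (theta) the kind of departure.

The default shipped basis is trained on a Poisson process of intensity
1e5 on the unit square at K = 100, with edge points (whose K-neighbourhood
disk is truncated by the window) discarded before fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import LocalisationTable, Window
from .neighbourhood import NNFT, NormalisedNNFT, compute_nnft, normalise_nnft

__all__ = [
    "SNPCABasis",
    "simulate_csr",
    "filter_edge_points",
    "fit_snpca",
    "project_snpca",
    "polar_coords",
    "train_basis",
    "default_basis",
    "DEFAULT_BASIS_SEED",
]

BASIS_SCHEMA_VERSION = 1
#: Seed used to train the shipped universal basis (unit square, lambda=1e5, K=100).
DEFAULT_BASIS_SEED = 190346071

UNIT_SQUARE = Window(0.0, 1.0, 0.0, 1.0)


def simulate_csr(
    intensity: float, window: Window = UNIT_SQUARE, seed: int | None = None
) -> LocalisationTable:
    """Homogeneous Poisson process: CSR points in a window.

    The point count is Poisson(intensity * area) and coordinates are
    i.i.d. uniform.  Deterministic given ``seed``.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area)
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    return LocalisationTable(x, y, image_id="csr")


def filter_edge_points(
    table: LocalisationTable, nnft: NNFT, window: Window
) -> np.ndarray:
    """Keep-mask for points whose K-neighbourhood is untruncated.

    A point is discarded (mask False) when its distance to the nearest
    window boundary is smaller than its own K-th NN distance, i.e. the
    disk containing its K neighbours pokes outside the observed window and
    the profile would be biased by censoring.
    """
    if len(table) != nnft.n:
        raise ValueError("table and NNFT row counts differ")
    boundary = window.boundary_distance(table.x, table.y)
    return boundary >= nnft.distances[:, -1]


@dataclass(frozen=True)
class SNPCABasis:
    """Mean profile and orthonormal loadings of the CSR-trained PCA.

    Attributes
    ----------
    mean_vector
        Length-K column means of the training normalised NNFT.
    loadings
        (m, K) orthonormal rows, ordered by decreasing eigenvalue.  The
        sign of each loading is fixed so its largest-magnitude entry is
        positive, removing PCA's sign indeterminacy.
    eigenvalues
        Variances along the retained components, non-increasing.
    training_params
        Provenance of the CSR training draw (intensity, n_points, seed).
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    K: int
    training_params: dict = field(default_factory=dict)
    total_variance: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_vector", np.asarray(self.mean_vector, float))
        object.__setattr__(self, "loadings", np.asarray(self.loadings, float))
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, float))
        if self.mean_vector.shape != (self.K,):
            raise ValueError("mean_vector must have length K")
        if self.loadings.ndim != 2 or self.loadings.shape[1] != self.K:
            raise ValueError("loadings must be (m, K)")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(len(self.loadings)), atol=1e-10):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def variance_share(self) -> np.ndarray:
        """Fraction of training variance carried by each retained component.

        Uses the full training variance when recorded, else the retained
        eigenvalue total.
        """
        total = self.total_variance or self.eigenvalues.sum()
        return self.eigenvalues / total

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": BASIS_SCHEMA_VERSION,
            "K": self.K,
            "mean_vector": self.mean_vector.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_variance": self.total_variance,
            "training_params": self.training_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SNPCABasis":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != BASIS_SCHEMA_VERSION:
            raise ValueError(f"unsupported basis schema version {payload.get('version')}")
        return cls(
            mean_vector=np.array(payload["mean_vector"]),
            loadings=np.array(payload["loadings"]),
            eigenvalues=np.array(payload["eigenvalues"]),
            K=int(payload["K"]),
            training_params=payload.get("training_params", {}),
            total_variance=payload.get("total_variance"),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each loading so its largest-magnitude entry is positive."""
    out = loadings.copy()
    for row in out:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return out


def fit_snpca(
    normalised: NormalisedNNFT,
    n_components: int = 2,
    training_params: dict | None = None,
) -> SNPCABasis:
    """PCA of a mean-centred normalised NNFT (covariance, not correlation).

    Only valid rows enter the fit.  Intended for CSR training data, but
    the operation itself is generic.
    """
    rows = normalised.values[normalised.valid]
    if rows.shape[0] < normalised.K + 1:
        raise ValueError("need at least K+1 valid rows to fit a basis")
    mean = rows.mean(axis=0)
    centred = rows - mean
    if not np.any(np.abs(centred) > 1e-15):
        raise ValueError("degenerate training set: all rows identical")
    # economical PCA via SVD of the centred matrix
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = svals**2 / (rows.shape[0] - 1)
    loadings = _fix_signs(vt[:n_components])
    return SNPCABasis(
        mean_vector=mean,
        loadings=loadings,
        eigenvalues=eigenvalues[:n_components],
        K=normalised.K,
        training_params=dict(training_params or {}),
        total_variance=float(eigenvalues.sum()),
    )


def project_snpca(normalised: NormalisedNNFT, basis: SNPCABasis) -> np.ndarray:
    """Orthogonal projection of each profile onto the basis loadings.

    Returns an (N, m) array of component scores; invalid rows project to
    NaN.  The basis mean is subtracted first, so the training mean profile
    itself maps to the origin.
    """
    if normalised.K != basis.K:
        raise ValueError(f"K mismatch: profiles K={normalised.K}, basis K={basis.K}")
    scores = np.full((normalised.n, len(basis.loadings)), np.nan)
    rows = normalised.values[normalised.valid] - basis.mean_vector
    scores[normalised.valid] = rows @ basis.loadings.T
    return scores


def polar_coords(pc1: np.ndarray, pc2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius and angle of (PC1, PC2) scores about the basis origin.

    ``r = hypot(PC1, PC2)``; ``theta = atan2(PC2, PC1)`` in (-pi, pi],
    with theta defined as 0 at the origin.
    """
    pc1 = np.asarray(pc1, float)
    pc2 = np.asarray(pc2, float)
    r = np.hypot(pc1, pc2)
    theta = np.arctan2(pc2, pc1)
    return r, np.where(r == 0, 0.0, theta)


def train_basis(
    intensity: float = 1e5,
    K: int = 100,
    window: Window = UNIT_SQUARE,
    seed: int = DEFAULT_BASIS_SEED,
    n_components: int = 2,
) -> SNPCABasis:
    """Train a universal basis on a fresh CSR draw.

    Simulates the Poisson process, computes and normalises the NNFT,
    discards edge points, and fits the PCA.  With default arguments this
    reproduces the shipped basis bit-for-bit.
    """
    table = simulate_csr(intensity, window, seed)
    nnft = compute_nnft(table, K)
    keep = filter_edge_points(table, nnft, window)
    normalised = normalise_nnft(NNFT(nnft.distances[keep], K, nnft.image_id))
    return fit_snpca(
        normalised,
        n_components=n_components,
        training_params={
            "intensity": intensity,
            "n_points": len(table),
            "n_after_edge_filter": int(keep.sum()),
            "seed": seed,
        },
    )


def default_basis() -> SNPCABasis:
    """The shipped universal basis (K=100, CSR intensity 1e5, fixed seed)."""
    ref = resources.files("kna.data").joinpath("snpca_basis_k100.json")
    with resources.as_file(ref) as path:
        return SNPCABasis.from_json(path)
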