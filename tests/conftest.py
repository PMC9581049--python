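"""Shared fixtures: small CSR bases and simulated reference patterns.

Heavy objects (trained bases, the reference clustered simulation and the
three-condition ensemble) are session-scoped so the suite pays for them
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from kna import (
    ImageInput,
    RunConfig,
    SimulationParams,
    Window,
    analyse_image,
    default_basis,
    run_ensemble,
    simulate_clustered_pattern,
    train_basis,
)

# deliberately modest problem sizes: the small basis trades calibration
# sharpness for speed and is used wherever absolute CSR accuracy is not
# the thing under test
SMALL_BASIS_K = 30
SMALL_BASIS_INTENSITY = 2e4


@pytest.fixture(scope="session")
def small_basis():
    """CSR basis at K=30 for fast structural tests."""
    return train_basis(intensity=SMALL_BASIS_INTENSITY, K=SMALL_BASIS_K, seed=5)


@pytest.fixture(scope="session")
def shipped_basis():
    """The K=100 universal basis distributed with the package."""
    return default_basis()


@pytest.fixture(scope="session")
def reference_pattern():
    """One draw of the default clustered design (~500 clusters + noise)."""
    return simulate_clustered_pattern(seed=11)


@pytest.fixture(scope="session")
def reference_features(reference_pattern, shipped_basis):
    """KNA features of the reference pattern at K=100 on the shipped basis."""
    return analyse_image(reference_pattern.table, shipped_basis, K=100)


def _ensemble_inputs():
    conditions = {
        "A": SimulationParams(window=Window.square(6.0)),
        "B": SimulationParams(window=Window.square(6.0), noise_intensity=150.0),
        "C": SimulationParams(window=Window.square(6.0), count_min=5, count_max=30),
    }
    inputs = []
    patterns = {}
    seed = 0
    for cname, params in conditions.items():
        for rep in range(3):
            pat = simulate_clustered_pattern(params, seed=100 + seed)
            seed += 1
            image_id = f"{cname}{rep}"
            patterns[image_id] = pat
            inputs.append(ImageInput(table=pat.table, image_id=image_id, condition=cname))
    return inputs, patterns


@pytest.fixture(scope="session")
def ensemble_run(small_basis, tmp_path_factory):
    """Three synthetic conditions x three images, run end to end."""
    inputs, patterns = _ensemble_inputs()
    cfg = RunConfig(
        inputs=inputs,
        K=SMALL_BASIS_K,
        basis=small_basis,
        grid_bins=12,
        n_perm=199,
        null_reps=500,
        render=False,
        out_dir=str(tmp_path_factory.mktemp("ensemble")),
    )
    results = run_ensemble(cfg)
    return {"config": cfg, "patterns": patterns, "results": results}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
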