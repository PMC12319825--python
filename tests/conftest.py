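"""Shared fixtures: small phantoms sized for fast, deterministic tests."""

import numpy as np
import pytest

from vipgradient.phantom import (
    PhantomSpec,
    make_geometry,
    plant_design,
    simulate_run,
)
from vipgradient.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom: 4 subjects x 4 runs, ~1.9k voxels, 9 areas/hemisphere."""
    return PhantomSpec(
        n_subjects=4,
        runs_per_subject=4,
        grid_dims=(10, 16, 6),
        areas_per_region=1,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return make_geometry(small_spec)


@pytest.fixture(scope="session")
def small_truth(small_spec, small_geometry):
    geom, _, _ = small_geometry
    return plant_design(small_spec, geom)


@pytest.fixture(scope="session")
def small_run(small_spec, small_geometry, small_truth):
    geom, _, _ = small_geometry
    return simulate_run(small_spec, geom, small_truth, 0, 0)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Pure latent signal: no noise, no nuisance, no spikes."""
    return PhantomSpec(
        n_subjects=1,
        runs_per_subject=1,
        grid_dims=(10, 16, 6),
        areas_per_region=1,
        noise_sd=0.0,
        global_amp=0.0,
        wm_amp=0.0,
        csf_amp=0.0,
        spike_prob=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def null_spec():
    """All loadings zero: pure noise phantom for calibration checks."""
    design = {
        name: (0.0, 0.0, 0.0)
        for name in ["OF1", "PF1", "MOT1", "CG1", "LB1", "TMP1", "PAR1", "OCC1", "VIP"]
    }
    return PhantomSpec(
        n_subjects=10,
        runs_per_subject=8,
        grid_dims=(6, 16, 4),
        areas_per_region=1,
        area_design=design,
        rng_seed=23,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_spec, tmp_path_factory):
    """Full pipeline run on the small phantom; returns (report, out_dir)."""
    out = tmp_path_factory.mktemp("pipe")
    config = PipelineConfig(out_dir=str(out))
    report = run_pipeline(config, spec=small_spec)
    return report, out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
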