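"""Shared fixtures.

The expensive pipeline artefacts (the noise-free synthetic study, its
backward calibration, and the forward re-simulation) are built once per
session and shared across the round-trip, protocol and acceptance tests.
"""

import numpy as np
import pytest

from lumbocal import (
    SynthConfig,
    load_characteristics,
    make_synthetic_fsu,
    make_synthetic_spine,
    packaged_default_path,
    run_backward_calibration,
    run_stepwise_forward,
    simulate_eds1,
)

#: Seed of the frozen noise-free study conditions.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def default_chars():
    return load_characteristics(packaged_default_path())


@pytest.fixture(scope="session")
def noise_free_cfg():
    return SynthConfig(seed=STUDY_SEED, noise_rom_deg=0.0)


@pytest.fixture(scope="session")
def fsu_geom(noise_free_cfg):
    return make_synthetic_fsu(noise_free_cfg)


@pytest.fixture(scope="session")
def spine_geom(noise_free_cfg):
    return make_synthetic_spine(noise_free_cfg)


@pytest.fixture(scope="session")
def eds1_noise_free(fsu_geom, default_chars, noise_free_cfg):
    return simulate_eds1(fsu_geom, default_chars, noise_free_cfg)


@pytest.fixture(scope="session")
def calibrated(eds1_noise_free, fsu_geom, default_chars):
    """The backward calibration of the noise-free synthetic study."""
    return run_backward_calibration(eds1_noise_free, fsu_geom, base=default_chars)


@pytest.fixture(scope="session")
def forward_rerun(calibrated, fsu_geom):
    """Forward re-simulation of the full protocol with the calibrated model."""
    return run_stepwise_forward(calibrated, fsu_geom)


@pytest.fixture(scope="session")
def eds2_table(spine_geom, default_chars, noise_free_cfg):
    """The 49-scenario pressure table of the ground-truth chain."""
    from lumbocal import simulate_eds2

    return simulate_eds2(spine_geom, default_chars, noise_free_cfg)


def _curve_rmse(fit, truth, lo, hi, n=200):
    """RMS difference of two clamped force-strain curves over [lo, hi] %."""
    eps = np.linspace(lo, hi, n)
    f = np.maximum(fit.spring_force(eps), 0.0)
    g = np.maximum(truth.spring_force(eps), 0.0)
    return float(np.sqrt(np.mean((f - g) ** 2))), float(np.abs(g).max())


@pytest.fixture(scope="session")
def curve_rmse():
    return _curve_rmse
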