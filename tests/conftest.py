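"""Shared fixtures: small seeded synthetic scenes, generated at test time."""

import warnings

import numpy as np
import pytest

from micromot import pipeline, registration, synthetic

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def control_cell():
    return synthetic.build_cell("control", 1, cell_id="fixture_cell")


@pytest.fixture(scope="session")
def basal_gt(control_cell):
    return synthetic.simulate_basal(
        control_cell, speed_mean=2.38, territory_scale=4.18, duration=480.0, dt=45.0, rng_seed=2
    )


@pytest.fixture(scope="session")
def basal_movie(control_cell, basal_gt):
    """Rendered basal movie with a known injected drift."""
    n = len(basal_gt.tips[0].t_s)
    t = np.arange(n)
    drift = 1.5 * np.column_stack([np.sin(2 * np.pi * t / (n - 1)), t / (n - 1)])
    drift[0] = 0.0
    cfg = pipeline.field_config_for_cells(
        [control_cell], dx_nm=200.0, dt_s=45.0, drift_px=drift
    )
    series = synthetic.render(control_cell, basal_gt, cfg, rng_seed=3)
    return series, cfg, drift


@pytest.fixture(scope="session")
def lesion_gt():
    """Small lesion-response ground truth (no rendering)."""
    rng = np.random.default_rng(11)
    target = np.zeros(3)
    dist = np.array([18.0, 22.0, 26.0, 30.0, 34.0, 40.0])
    cells = synthetic.build_target_field(target, dist, rng)
    return synthetic.simulate_directed(
        cells,
        target,
        scenario="lesion",
        front_speed=3.75,
        response_radius=35.8,
        coordination=False,
        duration=720.0,
        dt=25.0,
        rng_seed=rng,
        abort_fraction=0.0,
    )


@pytest.fixture(scope="session")
def registered_mip(basal_movie):
    series, cfg, _ = basal_movie
    trace = registration.estimate_drift(series)
    return registration.mip(registration.apply_drift(series, trace)), cfg
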