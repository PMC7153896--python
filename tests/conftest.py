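"""Shared fixtures: masks, calibrated model parameters, simulated and
synthetic ensembles.  Expensive fixtures are session-scoped; everything is
seeded, so the suite is deterministic."""

import dataclasses

import numpy as np
import pytest

from microlane import (
    GeneratorParams,
    ModelParams,
    PatternSpec,
    calibrate_mcs_duration,
    generate_ensemble,
    make_mask,
    run_simulation,
)


@pytest.fixture(scope="session")
def round_mask():
    """The reference lane: 170 x 20 um, round tips, 2 um spacing."""
    return make_mask(PatternSpec(length=170.0, width=20.0, tip_shape="round"))


@pytest.fixture(scope="session")
def calibrated(round_mask):
    """Default model parameters with mcs_minutes calibrated to 0.6 um/min."""
    p = ModelParams()
    mm = calibrate_mcs_duration(round_mask, p, target_speed=0.6, seed=123)
    return dataclasses.replace(p, mcs_minutes=mm)


@pytest.fixture(scope="session")
def sim_batch_records(round_mask, calibrated):
    """32 independent 36-h simulated cells on the reference lane."""
    return [run_simulation(round_mask, calibrated, duration=2160.0, sampling=10.0,
                           seed=4000 + s) for s in range(32)]


@pytest.fixture(scope="session")
def sim_batch(sim_batch_records):
    return [rec.trajectory for rec in sim_batch_records]


@pytest.fixture(scope="session")
def sim_with_fields(round_mask, calibrated):
    """One 36-h run with polarization-field and occupancy snapshots."""
    return run_simulation(round_mask, calibrated, duration=2160.0, sampling=10.0,
                          seed=77, record_fields=True)


#: generator settings emulating the experimental kinematics: plateau speed
#: 0.62 um/min, repolarization zone 55 um, nucleus turning point 40 um from
#: the tip, and a pause such that the expected tip-region occupancy is
#: ~117 min (the value consistent with the observed period-length regression).
EXPERIMENT_LIKE = GeneratorParams(
    v_run=0.62, ramp_xi=55.0, turn_point=40.0, pause_mean=20.0, pause_shape=4.0,
    noise_sd=1.0, dt=10.0, duration=2160.0, seed=7,
)

LANE_LENGTHS = [120.0, 170.0, 220.0, 270.0]


@pytest.fixture(scope="session")
def experiment_like_ensemble():
    """50 tracks per lane length in the experiment's study design."""
    trajs, manifest, logs = generate_ensemble(EXPERIMENT_LIKE, 50, LANE_LENGTHS)
    return trajs, manifest, logs


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
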