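"""Trajectory quantification: projection, filtering, profiles, change
points, spectra, period regression, reversal events and kymographs."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from microlane import (
    GeneratorParams,
    SpatialProfile,
    Trajectory,
    detect_reversals,
    filter_tracks,
    fit_changepoints,
    generate_ensemble,
    generate_trajectory,
    instantaneous_velocity,
    kymograph,
    mean_cycle_period,
    period_vs_length,
    project_and_center,
    reversal_region,
    reversal_times,
    spatial_profiles,
    speed_distribution,
    velocity_spectrum,
)
from microlane.analysis import histogram_mode

# ---------------------------------------------------------------------------
# projection, filtering, velocities
# ---------------------------------------------------------------------------


def _traj(koor, dt=10.0, L=170.0, cid="t"):
    koor = np.asarray(koor, dtype=float)
    return Trajectory(times=np.arange(len(koor)) * dt, koor=koor, lane_length=L,
                      cell_id=cid)


def test_project_and_center_midpoint_rule(round_mask):
    """Lane center = midpoint of the two closest tip approaches."""
    x = np.concatenate([np.linspace(1, 80, 40), np.linspace(80, -78, 60),
                        np.linspace(-78, 0, 30)])
    times = np.arange(len(x)) * 10.0
    tr = project_and_center(x, round_mask, times)
    assert tr.flag == ""
    assert np.max(tr.koor) == pytest.approx(79.0)
    assert np.min(tr.koor) == pytest.approx(-79.0)


def test_project_identity_for_centered_track(round_mask):
    x = np.concatenate([np.linspace(-80, 80, 50), np.linspace(80, -80, 50)])
    tr = project_and_center(x, round_mask, np.arange(len(x)) * 10.0)
    assert tr.koor == pytest.approx(x)


def test_project_flags_track_that_never_leaves_center(round_mask):
    x = 3.0 * np.sin(np.linspace(0, 6, 40))  # purely local wiggling
    tr = project_and_center(x, round_mask, np.arange(40) * 10.0)
    assert "no-tip-approach" in tr.flag


def test_filter_rules():
    good = _traj(np.concatenate([np.linspace(0, 80, 109), np.linspace(80, -80, 108)]))
    short = _traj(np.linspace(-80, 80, 100))          # 990 min < 36 h
    half = _traj(np.abs(np.linspace(-80, 80, 217)))   # never visits the left tip
    still = _traj(np.full(217, 5.0))                  # non-moving cell
    kept, report = filter_tracks([good, short, half, still])
    assert kept == [good]
    assert report.excluded == {"short": 1, "incomplete_exploration": 1, "non_moving": 1}


def test_filter_clean_ensemble_passes():
    p = GeneratorParams(seed=1)
    trajs, _, _ = generate_ensemble(p, 10)
    kept, report = filter_tracks(trajs)
    assert report.n_retained == 10 and not any(report.excluded.values())


def test_instantaneous_velocity():
    assert instantaneous_velocity(_traj([0.0, 6.0]))[0] == pytest.approx(0.6)
    assert not instantaneous_velocity(_traj([5.0] * 10)).any()
    ramp = _traj(np.arange(20) * 3.0, L=300.0)
    assert instantaneous_velocity(ramp) == pytest.approx(np.full(19, 0.3))


def test_nonuniform_sampling_rejected():
    with pytest.raises(ValueError, match="uniform"):
        Trajectory(times=np.array([0.0, 10.0, 25.0]), koor=np.zeros(3), lane_length=170.0)


# ---------------------------------------------------------------------------
# spatial profiles and change points
# ---------------------------------------------------------------------------


def test_occupancy_normalized_exactly():
    p = GeneratorParams(seed=2)
    trajs, _, _ = generate_ensemble(p, 20)
    prof = spatial_profiles(trajs)
    assert abs(prof.occupancy.sum() - 1.0) < 1e-9


def test_single_crossing_gives_flat_profile():
    tr = _traj(np.linspace(-84, 84, 113), L=170.0)  # 1.5 um per 10-min frame
    prof = spatial_profiles([tr])
    filled = prof.counts > 0
    assert prof.mean_abs_velocity[filled] == pytest.approx(
        np.full(filled.sum(), 0.15), rel=1e-9)
    assert np.isnan(prof.mean_abs_velocity[~filled]).all()


def test_profile_plateau_matches_generator_speed():
    p = GeneratorParams(v_run=0.6, noise_sd=0.5, seed=3)
    trajs, _, _ = generate_ensemble(p, 50)
    prof = spatial_profiles(trajs)
    plateau = np.abs(prof.bin_centers) < p.lane_length / 2 - p.ramp_xi - 5
    assert np.nanmean(prof.mean_abs_velocity[plateau]) == pytest.approx(0.6, rel=0.05)


def _trapezoid_profile(L=170.0, xi=55.0, v_plateau=0.6, v_tip=0.1, noise=None, rng=None):
    n_bins = int(L / 5)
    centers = (np.arange(n_bins) - n_bins / 2 + 0.5) * 5.0
    y = np.empty(n_bins)
    for i, x in enumerate(centers):
        d = L / 2 - abs(x)  # distance to the nearer tip
        y[i] = v_plateau if d >= xi else v_tip + (v_plateau - v_tip) * d / xi
    if noise is not None:
        y = y + rng.normal(0.0, noise, n_bins)
    counts = np.full(n_bins, 100)
    return SpatialProfile(
        bin_edges=np.arange(n_bins + 1) * 5.0 - L / 2, bin_centers=centers,
        occupancy=np.full(n_bins, 1 / n_bins), mean_abs_velocity=y,
        sem=np.full(n_bins, 0.02), counts=counts, pos_counts=counts, lane_length=L)


def test_changepoint_recovers_noiseless_trapezoid():
    fit = fit_changepoints(_trapezoid_profile())
    assert fit.xi0_left == pytest.approx(55.0, abs=5.0)
    assert fit.xi0_right == pytest.approx(55.0, abs=5.0)
    assert fit.plateau_speed == pytest.approx(0.6, abs=0.02)
    assert not fit.fully_ramped


def test_changepoint_flat_profile_degenerates_to_zero_ramps():
    prof = _trapezoid_profile(v_tip=0.6)  # flat everywhere
    fit = fit_changepoints(prof)
    assert fit.sse == pytest.approx(0.0, abs=1e-18)
    # tie-break toward the smallest ramps: breakpoints sit at the outermost bins
    assert fit.xi0_left <= 5.0 and fit.xi0_right <= 5.0


def test_changepoint_noisy_recovery_rate(rng):
    """xi0 recovered within 10 um in >= 90% of 100 SEM-scaled-noise replicates."""
    hits = 0
    for _ in range(100):
        fit = fit_changepoints(_trapezoid_profile(noise=0.02, rng=rng))
        hits += (abs(fit.xi0_left - 55.0) <= 10.0 and abs(fit.xi0_right - 55.0) <= 10.0)
    assert hits >= 90


# ---------------------------------------------------------------------------
# speed distribution and spectra
# ---------------------------------------------------------------------------


def test_speed_distribution_normalized_and_degenerate():
    p = GeneratorParams(seed=4)
    trajs, _, _ = generate_ensemble(p, 10)
    edges, density = speed_distribution(trajs)
    assert np.sum(density) * (edges[1] - edges[0]) == pytest.approx(1.0)
    flat = [_traj(np.full(30, 1.0))]
    edges0, density0 = speed_distribution(flat)
    assert density0[0] * (edges0[1] - edges0[0]) == pytest.approx(1.0)


def test_spectrum_peak_of_triangle_wave():
    """Triangle-wave position of period T0: spectral peak within one bin of 1/T0."""
    T0 = 480.0
    t = np.arange(0, 2160.0 + 5, 10.0)
    saw = 2 * np.abs((t / T0) % 1.0 - 0.5) - 0.5  # triangle in [-0.5, 0.5]
    trajs = [Trajectory(times=t, koor=60 * saw, lane_length=170.0, cell_id=str(i))
             for i in range(3)]
    fit = velocity_spectrum(trajs)
    df = fit.frequencies[1] - fit.frequencies[0]
    assert fit.fit_ok
    assert abs(fit.f_max - 1 / T0) <= df


def test_spectrum_white_noise_flagged_unreliable(rng):
    trajs = [Trajectory(times=np.arange(217) * 10.0,
                        koor=np.cumsum(rng.normal(0, 2, 217)).clip(-80, 80),
                        lane_length=170.0, cell_id=str(i)) for i in range(20)]
    fit = velocity_spectrum(trajs)
    assert not fit.fit_ok


def test_spectrum_recovers_generator_cycle_period():
    """Ensemble spectral period within 15% of the generator's mean cycle.

    72-h records: the DFT needs a few full cycles per record to resolve the
    ~15.6-h default cycle (the 36-h experimental window holds only ~2.3).
    """
    p = GeneratorParams(v_run=0.6, pause_mean=100.0, duration=4320.0, seed=6)
    trajs, _, logs = generate_ensemble(p, 100)
    truth = np.mean([mean_cycle_period(ev) for ev in logs.values()
                     if len(ev) >= 3]) / 60.0  # hours
    fit = velocity_spectrum(trajs)
    assert fit.fit_ok
    assert fit.period_T == pytest.approx(truth, rel=0.15)


def test_period_regression_exact_line():
    pts = {L: 0.054 * (L - 29.4) for L in (120.0, 170.0, 220.0, 270.0)}
    fit = period_vs_length(pts)
    assert fit.slope == pytest.approx(0.054, rel=1e-12)
    assert fit.x_intercept == pytest.approx(29.4, rel=1e-9)
    assert fit.v_c == pytest.approx(2 / 0.054 / 60, rel=1e-12)  # 0.617 um/min
    resid = [T - (fit.slope * L + fit.intercept) for L, T in pts.items()]
    assert np.allclose(resid, 0.0, atol=1e-12)


def test_period_regression_jittered_line(rng):
    """Slope recovered within 10% in >= 95% of 100 5%-jitter replicates."""
    lanes = np.array([120.0, 170.0, 220.0, 270.0])
    hits = 0
    for _ in range(100):
        T = 0.054 * (lanes - 29.4) * (1 + rng.uniform(-0.05, 0.05, lanes.size))
        fit = period_vs_length(list(zip(lanes, T)))
        hits += abs(fit.slope - 0.054) <= 0.1 * 0.054
    assert hits >= 95


def test_period_regression_needs_three_points():
    with pytest.raises(ValueError):
        period_vs_length({120.0: 5.0, 170.0: 7.0})


# ---------------------------------------------------------------------------
# reversal events
# ---------------------------------------------------------------------------


def test_reversal_event_construction():
    region = reversal_region(170.0, 55.0)
    koor = np.zeros(40)
    koor[10:21] = 40.0   # enters at t=100, last inside sample t=200, exit t=210
    koor[15] = 60.0      # goes deeper mid-visit
    events = detect_reversals(_traj(koor), region)
    assert len(events) == 1
    ev = events[0]
    assert (ev.t1, ev.t2, ev.t_R) == (100.0, 210.0, 110.0)
    assert ev.tip == "right" and ev.reversed


def test_reversal_no_entry_no_events():
    region = reversal_region(170.0, 55.0)
    assert detect_reversals(_traj(np.zeros(50)), region) == []


def test_reversal_censored_intervals_dropped():
    region = reversal_region(170.0, 55.0)
    koor = np.zeros(40)
    koor[:5] = -50.0     # open at the record start
    koor[30:] = 50.0     # open at the record end
    assert detect_reversals(_traj(koor), region) == []


def test_reversal_times_match_generator_ground_truth():
    """Detected t_R on noiseless tracks equals the ground-truth region
    occupancy within one sampling interval."""
    p = GeneratorParams(noise_sd=0.0, seed=8)
    traj, events = generate_trajectory(p)
    region = reversal_region(p.lane_length, p.ramp_xi)
    detected = detect_reversals(traj, region)
    transit = p.ramp_time
    for ev in detected:
        truth = [t for t in events
                 if abs((t.t_arrive - transit) - ev.t1) <= p.dt + 1e-9]
        assert truth, f"no matching turning event for t1={ev.t1}"
        expected_tr = (truth[0].t_depart + transit) - (truth[0].t_arrive - transit)
        assert abs(ev.t_R - expected_tr) <= 2 * p.dt + 1e-9


def test_reversal_distribution_invariant_under_lane_length():
    """Length-independent pauses give length-independent t_R distributions."""
    base = GeneratorParams(seed=12)
    tA, _, _ = generate_ensemble(dataclasses.replace(base, lane_length=120.0), 60)
    tB, _, _ = generate_ensemble(dataclasses.replace(base, lane_length=270.0), 60)
    rA = reversal_times(tA, reversal_region(120.0, 55.0))
    rB = reversal_times(tB, reversal_region(270.0, 55.0))
    assert stats.ks_2samp(rA, rB).statistic < 0.1


def test_cycle_period_consistency_identity():
    """Mean cycle ~= 2 * (turning-point separation) / v + 2 * mean pause for a
    modest deceleration ramp."""
    p = GeneratorParams(v_run=0.6, ramp_xi=25.0, turn_point=15.0, pause_mean=100.0,
                        noise_sd=0.0, duration=6000.0, seed=13)
    _, logs = generate_trajectory(p)
    measured = mean_cycle_period(logs)
    d_turn = p.lane_length - 2 * p.turn_point
    identity = 2 * d_turn / p.v_run + 2 * p.pause_mean
    assert measured == pytest.approx(identity, rel=0.15)


# ---------------------------------------------------------------------------
# end-to-end parameter recovery (generator -> pipeline)
# ---------------------------------------------------------------------------


def test_end_to_end_parameter_recovery():
    """Pipeline returns v_c within 10%, mean t_R within 15% and xi0 within
    10 um of the generator ground truth (100 tracks, fixed seed)."""
    from microlane.synth import expected_region_time

    base = GeneratorParams(v_run=0.6, ramp_xi=55.0, turn_point=15.0,
                           pause_mean=100.0, noise_sd=1.0, seed=14)
    lanes = [120.0, 170.0, 220.0, 270.0]
    trajs, _, _ = generate_ensemble(base, 25, lanes)  # 100 tracks total
    by_lane = {L: [t for t in trajs if t.lane_length == L] for L in lanes}

    periods = {L: velocity_spectrum(g).period_T for L, g in by_lane.items()}
    fit = period_vs_length(periods)
    assert fit.v_c == pytest.approx(base.v_run, rel=0.10)

    tR = reversal_times(by_lane[170.0], reversal_region(170.0, 55.0))
    assert tR.mean() == pytest.approx(expected_region_time(base, 55.0), rel=0.15)

    xi = []
    for L in (170.0, 220.0, 270.0):
        cp = fit_changepoints(spatial_profiles(by_lane[L]))
        xi.extend([cp.xi0_left, cp.xi0_right])
    assert np.mean(xi) == pytest.approx(55.0, abs=10.0)


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------


def test_kymograph_stationary_and_moving_bands():
    ny, nx, nt = 4, 30, 20
    fields = np.zeros((nt, ny, nx))
    fields[:, 1, 10] = 1.0  # stationary cell: constant stripe
    mat = kymograph(fields)
    assert mat.shape == (nx, nt)
    assert (mat.argmax(axis=0) == 10).all()
    # constant-velocity band: slope equals the speed (1 column per frame)
    moving = np.zeros((nt, ny, nx))
    for t in range(nt):
        moving[t, 2, t + 3] = 1.0
    slope = np.diff(kymograph(moving).argmax(axis=0))
    assert (slope == 1).all()


def test_kymograph_of_simulated_cell_zigzags(sim_with_fields):
    """Quasi-periodic runs show a zigzag band crossing the lane center."""
    mat = kymograph(sim_with_fields.field_series)
    peak_pos = mat.argmax(axis=0).astype(float)
    centered = peak_pos - peak_pos.mean()
    crossings = np.sum(np.abs(np.diff(np.sign(centered))) > 0)
    assert crossings >= 4
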