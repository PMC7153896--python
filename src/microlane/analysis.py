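"""Quantification of 1D pole-to-pole migration trajectories.

Implements the full statistics pipeline for single-cell tracks on microlanes:

* 1D projection and per-track centering of raw positions,
* track exclusion rules (duration, whole-lane exploration, motility),
* instantaneous velocities v(t) = [x(t+dt) - x(t)] / dt,
* spatial occupancy p(x) and mean absolute speed <|v|>(x) in 5-um bins,
* change-point (trapezoid) fit locating the ramp/plateau transition xi0,
* pooled speed distribution,
* ensemble velocity spectrum with a log-normal peak fit, T = 1/f_max,
* linear regression of the migration period T on lane length L,
* reversal events (entry/exit of the tip region) and reversal times t_R,
* kymographs of the simulated polarization field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .geometry import PatternMask, ReversalRegion

#: default spatial bin width in micrometers
BIN_WIDTH_UM = 5.0
#: default distance from the lane tip to the ramp/plateau change point
XI0_UM = 55.0
#: default minimum track duration in minutes (36 h of 10-min frames)
MIN_DURATION_MIN = 36 * 60.0


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Uniformly sampled 1D track along a lane's long axis.

    ``koor`` is the distance from the lane center in micrometers; ``times``
    are minutes.  ``flag`` carries degeneracy warnings from the projection
    step ("" when clean).
    """

    times: np.ndarray
    koor: np.ndarray
    lane_length: float
    cell_id: str = ""
    flag: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.koor = np.asarray(self.koor, dtype=float)
        if self.times.shape != self.koor.shape or self.times.ndim != 1:
            raise ValueError("times and koor must be 1D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("trajectory needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.ptp(steps) > 1e-6 * steps[0] + 1e-9:
            raise ValueError("trajectory is not uniformly sampled")
        if np.max(np.abs(self.koor)) > self.lane_length / 2 + 2.0:
            raise ValueError("koor exceeds lane half-length by more than the 2 um tolerance")

    @property
    def dt(self) -> float:
        """Sampling interval in minutes."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def project_and_center(raw_track: np.ndarray, mask: PatternMask, times: np.ndarray,
                       cell_id: str = "") -> Trajectory:
    """Project a raw 2D track onto the long axis and center it per track.

    The lane center of each track is the midpoint between the two positions
    where the cell got closest to either tip (i.e. the track's extremes along
    the long axis); ``koor`` is measured from that midpoint.  Tracks that never
    leave the lane middle fall back to the mask's geometric center and are
    flagged.
    """
    raw = np.asarray(raw_track, dtype=float)
    x = raw if raw.ndim == 1 else raw[:, 0]
    L = mask.spec.length
    span = np.ptp(x)
    if span < 0.25 * L:
        # never approached the tips: per-track centering is unreliable
        return Trajectory(times=np.asarray(times, float), koor=x - 0.0,
                          lane_length=L, cell_id=cell_id,
                          flag="no-tip-approach: centered on mask geometric center")
    center = (np.max(x) + np.min(x)) / 2
    return Trajectory(times=np.asarray(times, float), koor=x - center,
                      lane_length=L, cell_id=cell_id)


@dataclass
class FilterReport:
    """Book-keeping of the track exclusion rules."""

    n_input: int = 0
    n_retained: int = 0
    excluded: dict = field(default_factory=dict)


def filter_tracks(tracks: list[Trajectory], min_duration: float = MIN_DURATION_MIN,
                  xi0: float = XI0_UM, min_range: float = 10.0,
                  ) -> tuple[list[Trajectory], FilterReport]:
    """Apply the track exclusion rules.

    Retained tracks (i) last at least ``min_duration`` minutes, (ii) explored
    the whole stripe — reached both tip regions of half-width ``xi0`` — and
    (iii) moved at all (koor range at least ``min_range`` um, excluding
    non-moving or dead cells).
    """
    report = FilterReport(n_input=len(tracks),
                          excluded={"short": 0, "incomplete_exploration": 0, "non_moving": 0})
    keep: list[Trajectory] = []
    for tr in tracks:
        if tr.duration < min_duration - 1e-9:
            report.excluded["short"] += 1
            continue
        if np.ptp(tr.koor) < min_range:
            report.excluded["non_moving"] += 1
            continue
        left_edge = -tr.lane_length / 2 + xi0
        right_edge = tr.lane_length / 2 - xi0
        if not (np.min(tr.koor) <= left_edge and np.max(tr.koor) >= right_edge):
            report.excluded["incomplete_exploration"] += 1
            continue
        keep.append(tr)
    report.n_retained = len(keep)
    if tracks and not keep:
        raise ValueError(f"all {len(tracks)} tracks excluded — configuration/data mismatch: "
                         f"{report.excluded}")
    return keep, report


def instantaneous_velocity(traj: Trajectory) -> np.ndarray:
    """Signed forward-difference velocity in um/min (length = samples - 1)."""
    return np.diff(traj.koor) / traj.dt


# ---------------------------------------------------------------------------
# Spatial profiles and the change-point fit
# ---------------------------------------------------------------------------


@dataclass
class SpatialProfile:
    """Binned occupancy and mean-speed profile along the lane."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    occupancy: np.ndarray          # fraction of position samples per bin, sums to 1
    mean_abs_velocity: np.ndarray  # um/min; NaN where no velocity started in the bin
    sem: np.ndarray                # standard error of the mean; NaN where count < 2
    counts: np.ndarray             # velocity samples per bin
    pos_counts: np.ndarray         # position samples per bin
    lane_length: float


def spatial_profiles(trajs: list[Trajectory], bin_width: float = BIN_WIDTH_UM) -> SpatialProfile:
    """Occupancy p(x) and mean absolute speed <|v|>(x) in ``bin_width`` bins.

    Velocities are assigned to the bin containing the *start* position of each
    displacement interval.  Empty bins report NaN, never zero.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    L = trajs[0].lane_length
    if any(abs(t.lane_length - L) > 1e-6 for t in trajs):
        raise ValueError("all trajectories must share one lane length")
    n_bins = int(np.ceil(L / bin_width - 1e-9))
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2

    pos_all = np.concatenate([t.koor for t in trajs])
    start_pos = np.concatenate([t.koor[:-1] for t in trajs])
    speeds = np.concatenate([np.abs(instantaneous_velocity(t)) for t in trajs])

    clip = lambda x: np.clip(x, edges[0] + 1e-9, edges[-1] - 1e-9)  # noqa: E731 — keep tip samples
    pos_counts = np.histogram(clip(pos_all), bins=edges)[0]
    counts = np.histogram(clip(start_pos), bins=edges)[0]
    sums = np.histogram(clip(start_pos), bins=edges, weights=speeds)[0]
    sq_sums = np.histogram(clip(start_pos), bins=edges, weights=speeds**2)[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = sq_sums / np.maximum(counts, 1) - mean**2
        sem = np.where(counts >= 2, np.sqrt(np.maximum(var, 0) / np.maximum(counts - 1, 1)), np.nan)
    return SpatialProfile(
        bin_edges=edges, bin_centers=centers,
        occupancy=pos_counts / pos_counts.sum(),
        mean_abs_velocity=mean, sem=sem, counts=counts, pos_counts=pos_counts,
        lane_length=L,
    )


@dataclass
class ChangePointFit:
    """Ramp–plateau–ramp (trapezoid) change-point fit of a speed profile."""

    xi0_left: float
    xi0_right: float
    plateau_speed: float
    sse: float
    fully_ramped: bool = False

    @property
    def xi0_mean(self) -> float:
        return (self.xi0_left + self.xi0_right) / 2


def fit_changepoints(profile: SpatialProfile) -> ChangePointFit:
    """Least-squares trapezoid fit of the spatial mean-speed profile.

    The model is continuous and piecewise linear: a ramp rising from the
    observed profile value at the first (last) populated bin to a free plateau
    level at the left (right) breakpoint.  Both breakpoints range over the bin
    grid; the O(bins^2) exhaustive search is exact.  xi0 is the distance from
    the lane tip to the breakpoint.  Ties are broken toward smaller xi0.
    Profiles whose best breakpoints coincide are flagged ``fully_ramped`` (the
    short-lane regime with no run phase).
    """
    ok = np.where(np.isfinite(profile.mean_abs_velocity) & (profile.counts > 0))[0]
    if len(ok) < 6:
        raise ValueError("need at least 6 populated bins for a change-point fit")
    x = profile.bin_centers[ok]
    y = profile.mean_abs_velocity[ok]
    x_l, x_r = x[0], x[-1]
    v_l, v_r = y[0], y[-1]
    half_L = profile.lane_length / 2

    best = None  # (sse, xi_sum, i, j, plateau)
    for i in range(len(x)):
        for j in range(i, len(x)):
            c_l, c_r = x[i], x[j]
            # design: y_model = a + b * plateau
            a = np.zeros_like(y)
            b = np.ones_like(y)
            if c_l > x_l:
                s = np.clip((x - x_l) / (c_l - x_l), None, 1.0)
                left = x < c_l
                a[left] = v_l * (1 - s[left])
                b[left] = s[left]
            if c_r < x_r:
                s = np.clip((x_r - x) / (x_r - c_r), None, 1.0)
                right = x > c_r
                a[right] = v_r * (1 - s[right])
                b[right] = s[right]
            denom = float(b @ b)
            plateau = float(b @ (y - a)) / denom if denom > 0 else 0.0
            resid = y - (a + b * plateau)
            sse = float(resid @ resid)
            xi_sum = (c_l + half_L) + (half_L - c_r)
            cand = (sse, xi_sum, i, j, plateau)
            if best is None or sse < best[0] - 1e-12 or (abs(sse - best[0]) <= 1e-12 and xi_sum < best[1]):
                best = cand
    sse, _, i, j, plateau = best
    return ChangePointFit(
        xi0_left=float(x[i] + half_L),
        xi0_right=float(half_L - x[j]),
        plateau_speed=max(plateau, 0.0),
        sse=sse,
        fully_ramped=bool(i == j),
    )


def speed_distribution(trajs: list[Trajectory], bin_width: float = 0.05,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (density) of pooled absolute velocities.

    Returns ``(bin_edges, density)`` with ``sum(density) * bin_width == 1``.
    """
    speeds = np.concatenate([np.abs(instantaneous_velocity(t)) for t in trajs])
    if speeds.size == 0:
        raise ValueError("no velocities to histogram")
    top = max(float(speeds.max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    density, edges = np.histogram(speeds, bins=edges, density=True)
    return edges, density


# ---------------------------------------------------------------------------
# Spectral period analysis
# ---------------------------------------------------------------------------


@dataclass
class SpectralFit:
    """Ensemble velocity spectrum with a log-normal peak fit."""

    frequencies: np.ndarray   # 1/min, zero-frequency bin excluded
    mean_amplitude: np.ndarray
    f_max: float              # 1/min, peak of the fitted curve
    lognorm_shape: float
    lognorm_scale: float
    period_T: float           # hours, 1/f_max
    fit_ok: bool


def _scaled_lognorm(f: np.ndarray, amp: float, shape: float, scale: float) -> np.ndarray:
    return amp * stats.lognorm.pdf(f, shape, loc=0, scale=scale)


def velocity_spectrum(trajs: list[Trajectory]) -> SpectralFit:
    """Ensemble-averaged DFT amplitude of signed velocities + log-normal fit.

    Cells are truncated to the shortest common length; each cell's velocity
    series is mean-removed (no window, no further detrending); the magnitude
    spectra are averaged over cells and the zero-frequency bin is dropped.
    ``f_max`` is the mode of the fitted scaled log-normal; on fit failure or a
    peakless spectrum the raw argmax is used and ``fit_ok`` is False.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    dt = trajs[0].dt
    if any(abs(t.dt - dt) > 1e-9 for t in trajs):
        raise ValueError("all trajectories must share the sampling interval")
    m = min(len(t.koor) for t in trajs) - 1
    if m < 8:
        raise ValueError("trajectories too short for spectral analysis")
    v = np.stack([instantaneous_velocity(t)[:m] for t in trajs])
    v = v - v.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(v, axis=1)).mean(axis=0)
    freqs = np.fft.rfftfreq(m, d=dt)
    freqs, amp = freqs[1:], amp[1:]

    i_raw = int(np.argmax(amp))
    fit_ok = True
    shape, scale = np.nan, np.nan
    try:
        p0 = (float(amp[i_raw] / stats.lognorm.pdf(freqs[i_raw], 0.6, scale=freqs[i_raw] * np.exp(0.36))),
              0.6, freqs[i_raw] * np.exp(0.36))
        popt, _ = optimize.curve_fit(
            _scaled_lognorm, freqs, amp, p0=p0,
            bounds=([0, 0.05, freqs[0] / 4], [np.inf, 3.0, freqs[-1] * 4]),
            maxfev=20000,
        )
        amp0, shape, scale = popt
        f_max = scale * np.exp(-shape**2)  # mode of the log-normal
        fitted = _scaled_lognorm(freqs, *popt)
        # peakless (flat) spectra: the fit is unreliable
        if not (freqs[0] <= f_max <= freqs[-1]) or fitted.max() < 1.3 * np.median(amp):
            fit_ok = False
    except (RuntimeError, ValueError):
        fit_ok = False
    if not fit_ok:
        f_max = float(freqs[i_raw])
    return SpectralFit(
        frequencies=freqs, mean_amplitude=amp, f_max=float(f_max),
        lognorm_shape=float(shape), lognorm_scale=float(scale),
        period_T=float(1.0 / f_max / 60.0), fit_ok=fit_ok,
    )


@dataclass
class PeriodLengthFit:
    """OLS of the migration period T (hours) on lane length L (um)."""

    slope: float        # dT/dL in h/um
    slope_err: float
    intercept: float    # hours
    x_intercept: float  # um
    v_c: float          # um/min, = 2/slope unit-converted
    r_value: float
    points: list[tuple[float, float]]


def period_vs_length(periods: dict[float, float] | list[tuple[float, float]]) -> PeriodLengthFit:
    """Fit T(L) = slope * (L - x_intercept) by ordinary least squares.

    ``periods`` maps lane length (um) to migration period (hours).  The
    crossing velocity follows from the slope: a cycle covers the lane twice,
    so dT/dL = 2 / v_c.
    """
    pts = sorted(periods.items()) if isinstance(periods, dict) else sorted(periods)
    if len(pts) < 3:
        raise ValueError("need at least 3 lane lengths for a period-length regression")
    L = np.array([p[0] for p in pts], dtype=float)
    T = np.array([p[1] for p in pts], dtype=float)
    res = stats.linregress(L, T)
    if res.slope <= 0:
        raise ValueError("non-positive dT/dL slope: periods do not grow with lane length")
    return PeriodLengthFit(
        slope=float(res.slope), slope_err=float(res.stderr),
        intercept=float(res.intercept),
        x_intercept=float(-res.intercept / res.slope),
        v_c=float(2.0 / res.slope / 60.0),
        r_value=float(res.rvalue),
        points=[(float(a), float(b)) for a, b in pts],
    )


# ---------------------------------------------------------------------------
# Reversal events
# ---------------------------------------------------------------------------


@dataclass
class ReversalEvent:
    """One entry/exit of a tip region: t_R = t2 - t1 (minutes)."""

    t1: float
    t2: float
    tip: str              # "left" or "right"
    reversed: bool        # approached the tip strictly deeper than at entry
    cell_id: str = ""

    @property
    def t_R(self) -> float:
        return self.t2 - self.t1


def detect_reversals(traj: Trajectory, region: ReversalRegion) -> list[ReversalEvent]:
    """Maximal in-region intervals of a track; censored intervals are dropped.

    ``t1`` is the first sample inside a tip interval and ``t2`` the first
    sample after the exit.  Intervals open at either end of the record are
    censored and discarded.  The definition is purely geometric; the
    ``reversed`` flag marks events where the cell moved strictly closer to the
    tip after entering (for sensitivity analyses).
    """
    events: list[ReversalEvent] = []
    if not region.tip_intervals:
        return events
    for tip, inside in (("left", region.in_left(traj.koor)),
                        ("right", region.in_right(traj.koor))):
        idx = np.flatnonzero(np.diff(inside.astype(int)))
        starts = [i + 1 for i in idx if not inside[i]]
        ends = [i + 1 for i in idx if inside[i]]  # first index after the run
        if inside[0]:
            ends = ends[1:] if ends else ends  # censored at record start
        for s, e in zip(starts, ends):
            depth = traj.koor[s:e]
            if tip == "left":
                went_deeper = bool(np.min(depth) < depth[0])
            else:
                went_deeper = bool(np.max(depth) > depth[0])
            events.append(ReversalEvent(
                t1=float(traj.times[s]), t2=float(traj.times[e]),
                tip=tip, reversed=went_deeper, cell_id=traj.cell_id,
            ))
        # runs still open at the record end have no matching `e` and are dropped
    events.sort(key=lambda ev: ev.t1)
    return events


def reversal_times(trajs: list[Trajectory], region: ReversalRegion) -> np.ndarray:
    """Pooled reversal times t_R (minutes) over an ensemble."""
    out = [ev.t_R for tr in trajs for ev in detect_reversals(tr, region)]
    return np.asarray(out, dtype=float)


def histogram_mode(values: np.ndarray, bin_width: float = 20.0) -> float:
    """Center of the most populated fixed-width bin (bins anchored at 0)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    edges = np.arange(0.0, values.max() + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------


def kymograph(field_series: np.ndarray) -> np.ndarray:
    """Collapse per-frame 2D fields to a (long-axis position x time) matrix.

    ``field_series`` has shape (n_frames, ny, nx); each frame is reduced by
    the maximum over the lane's short axis.  Rows are long-axis positions,
    columns are frames.
    """
    fields = np.asarray(field_series, dtype=float)
    if fields.ndim != 3:
        raise ValueError("field_series must have shape (n_frames, ny, nx)")
    return fields.max(axis=1).T


def render_kymograph(matrix: np.ndarray, times_min: np.ndarray, x_centers: np.ndarray,
                     path: str, label: str = "polarization field") -> None:
    """Render a kymograph matrix to a PNG with annotated axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.2))
    extent = (times_min[0] / 60, times_min[-1] / 60, x_centers[0], x_centers[-1])
    im = ax.imshow(matrix, aspect="auto", origin="lower", extent=extent, cmap="viridis")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("position along lane (um)")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
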