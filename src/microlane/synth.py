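"""Synthetic quasi-periodic pole-to-pole trajectories with known ground truth.

The generator emulates the phenomenology of single cells on microlanes:
constant-speed runs along the lane, a deceleration ramp near each tip, a
stochastic (gamma-distributed) repolarization pause at the turning point, and
frame-wise Gaussian position noise at a 10-min sampling interval.  Every
turning event is logged, so each analysis operation can be tested against an
exact ground truth without running the lattice simulation.

Kinematics of the ramp: the cell decelerates at constant rate from ``v_run``
(at distance ``ramp_xi`` from the tip) to zero exactly at the turning point
(distance ``turn_point`` from the tip), i.e. the speed is linear in time and
proportional to sqrt(distance-to-turn) in space.  A taper linear in *space*
down to zero would never reach the turning point (log-divergent traversal
time); the constant-deceleration ramp has the closed-form traversal time
``2 * (ramp_xi - turn_point) / v_run``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analysis import Trajectory


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth kinematic parameters of the trajectory generator.

    Distances in micrometers, times in minutes.  ``ramp_xi`` and
    ``turn_point`` are distances from the lane tip.  The pause at each
    turning point is Gamma(pause_shape, pause_mean / pause_shape).
    """

    lane_length: float = 170.0
    v_run: float = 0.6
    ramp_xi: float = 55.0
    turn_point: float = 15.0
    pause_mean: float = 100.0
    pause_shape: float = 4.0
    noise_sd: float = 1.0
    dt: float = 10.0
    duration: float = 2160.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.turn_point <= self.ramp_xi < self.lane_length / 2):
            raise ValueError("require 0 < turn_point <= ramp_xi < lane_length/2")
        if self.v_run <= 0:
            raise ValueError("v_run must be positive")
        if self.pause_mean < 0 or self.pause_shape <= 0:
            raise ValueError("pause_mean must be >= 0 and pause_shape > 0")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")

    @property
    def x_turn(self) -> float:
        """Turning-point coordinate (positive side), koor frame."""
        return self.lane_length / 2 - self.turn_point

    @property
    def ramp_time(self) -> float:
        """One-way traversal time of the deceleration ramp, minutes."""
        return 2.0 * (self.ramp_xi - self.turn_point) / self.v_run

    @property
    def ramp_length(self) -> float:
        return self.ramp_xi - self.turn_point


@dataclass(frozen=True)
class TurnEvent:
    """Ground-truth record of one turning event at a lane tip."""

    t_arrive: float   # minutes, arrival at the turning point
    t_depart: float   # minutes, departure after the pause
    tip: str          # "left" or "right"

    @property
    def pause(self) -> float:
        return self.t_depart - self.t_arrive


def region_traversal_time(params: GeneratorParams, xi0: float) -> float:
    """One-way travel time (minutes) from distance ``xi0`` to the turning point.

    Piecewise closed form: constant ``v_run`` outside the ramp, constant
    deceleration inside it (speed ~ sqrt of the remaining distance).
    """
    if xi0 <= params.turn_point:
        return 0.0
    if xi0 >= params.ramp_xi:
        return (xi0 - params.ramp_xi) / params.v_run + params.ramp_time
    # partway down the ramp: v(d) = v_run * sqrt((d - tp) / (xi - tp))
    frac = (xi0 - params.turn_point) / (params.ramp_xi - params.turn_point)
    return params.ramp_time * np.sqrt(frac)


def expected_region_time(params: GeneratorParams, xi0: float) -> float:
    """Expected tip-region occupancy time: in + out traversal plus the pause."""
    return 2.0 * region_traversal_time(params, xi0) + params.pause_mean


def pause_for_target_reversal_time(params: GeneratorParams, target_tR_mean: float,
                                   xi0: float | None = None) -> float:
    """Pause mean that makes the expected region-occupancy time equal ``target``."""
    xi0 = params.ramp_xi if xi0 is None else xi0
    transit = 2.0 * region_traversal_time(params, xi0)
    if target_tR_mean < transit - 1e-9:
        raise ValueError(
            f"target reversal time {target_tR_mean} min is below the minimum "
            f"2x ramp traversal of {transit:.1f} min"
        )
    return float(target_tR_mean - transit)


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------


def _position(seg: tuple, t: np.ndarray) -> np.ndarray:
    """Evaluate one kinematic segment (kind, t0, x0, v0, a) at times t."""
    kind, t0, x0, v0, a = seg
    tau = t - t0
    if kind == "pause":
        return np.full_like(tau, x0)
    return x0 + v0 * tau + 0.5 * a * tau**2


def _build_timeline(params: GeneratorParams, rng: np.random.Generator,
                    ) -> tuple[list[tuple], list[TurnEvent]]:
    """Event-driven exact kinematics until ``duration`` is covered."""
    p = params
    segs: list[tuple] = []       # (kind, t_start, x_start, v_start, accel)
    events: list[TurnEvent] = []
    x_ramp = p.lane_length / 2 - p.ramp_xi  # |x| where the ramp starts
    decel = (p.v_run**2 / (2 * p.ramp_length)) if p.ramp_length > 1e-12 else np.inf

    direction = 1 if rng.random() < 0.5 else -1
    x = float(rng.uniform(-x_ramp, x_ramp)) if x_ramp > 0 else 0.0
    t = 0.0
    state = "run"
    while t <= p.duration:
        if state == "run":
            target = direction * x_ramp
            dt_seg = (target - x) / (direction * p.v_run)
            if np.isfinite(decel):
                segs.append(("run", t, x, direction * p.v_run, 0.0))
                t, x, state = t + dt_seg, target, "decel"
            else:
                # degenerate ramp: run straight to the turning point
                dt_seg = (direction * p.x_turn - x) / (direction * p.v_run)
                segs.append(("run", t, x, direction * p.v_run, 0.0))
                t, x, state = t + dt_seg, direction * p.x_turn, "turn"
        elif state == "decel":
            segs.append(("decel", t, x, direction * p.v_run, -direction * decel))
            t, x, state = t + p.ramp_time, direction * p.x_turn, "turn"
        elif state == "turn":
            pause = float(rng.gamma(p.pause_shape, p.pause_mean / p.pause_shape)) \
                if p.pause_mean > 0 else 0.0
            events.append(TurnEvent(t_arrive=t, t_depart=t + pause,
                                    tip="right" if direction > 0 else "left"))
            if pause > 0:
                segs.append(("pause", t, x, 0.0, 0.0))
                t += pause
            direction = -direction
            state = "accel" if np.isfinite(decel) else "run"
        else:  # accel: mirror of the deceleration ramp, still on the old tip's side
            segs.append(("accel", t, x, 0.0, direction * decel))
            t, x, state = t + p.ramp_time, -direction * x_ramp, "run"
    return segs, events


def generate_trajectory(params: GeneratorParams,
                        rng: np.random.Generator | None = None,
                        cell_id: str = "synthetic",
                        ) -> tuple[Trajectory, list[TurnEvent]]:
    """One quasi-periodic track plus its ground-truth turning-event log."""
    p = params
    rng = np.random.default_rng(p.seed) if rng is None else rng
    segs, events = _build_timeline(p, rng)
    times = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    starts = np.array([s[1] for s in segs])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segs) - 1)
    koor = np.empty_like(times)
    for k in range(len(segs)):
        sel = idx == k
        if np.any(sel):
            koor[sel] = _position(segs[k], times[sel])
    if p.noise_sd > 0:
        koor = koor + rng.normal(0.0, p.noise_sd, size=koor.shape)
    koor = np.clip(koor, -p.lane_length / 2, p.lane_length / 2)
    traj = Trajectory(times=times, koor=koor, lane_length=p.lane_length, cell_id=cell_id)
    return traj, [ev for ev in events if ev.t_depart <= p.duration]


def generate_ensemble(params: GeneratorParams, n_cells: int,
                      lane_lengths: list[float] | None = None,
                      seed: int | None = None,
                      ) -> tuple[list[Trajectory], "pandas.DataFrame", dict[str, list[TurnEvent]]]:
    """Independent tracks for each lane length, with a manifest table.

    Per-cell RNG streams are spawned from the master seed with
    :class:`numpy.random.SeedSequence`, so each track is reproducible
    independently of generation order.
    """
    import pandas as pd

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lanes = [params.lane_length] if lane_lengths is None else list(lane_lengths)
    master = params.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(len(lanes) * n_cells)
    trajs: list[Trajectory] = []
    logs: dict[str, list[TurnEvent]] = {}
    rows = []
    k = 0
    for L in lanes:
        p = replace(params, lane_length=float(L))
        for i in range(n_cells):
            cid = f"L{int(round(L))}_c{i:03d}"
            traj, events = generate_trajectory(p, rng=np.random.default_rng(children[k]),
                                               cell_id=cid)
            trajs.append(traj)
            logs[cid] = events
            rows.append({"cell_id": cid, "lane_length": float(L), "width": 20.0,
                         "tip_shape": "round", "source": "synthetic"})
            k += 1
    return trajs, pd.DataFrame(rows), logs


def mean_cycle_period(events: list[TurnEvent]) -> float:
    """Ground-truth mean full cycle (minutes): successive same-tip departures."""
    by_tip: dict[str, list[float]] = {"left": [], "right": []}
    for ev in events:
        by_tip[ev.tip].append(ev.t_depart)
    gaps = [np.diff(v) for v in by_tip.values() if len(v) >= 2]
    gaps = np.concatenate([g for g in gaps if g.size]) if gaps else np.array([])
    if gaps.size == 0:
        raise ValueError("not enough turning events for a cycle period")
    return float(np.mean(gaps))
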