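"""Extended Cellular Potts model of a single confined, self-polarizing cell.

The cell is a 4-connected set of adhesion sites on the microlane raster with
configuration energy

    H = kappa_A * A^2 + kappa_P * P^2 - sum_x eps(x, t)

where ``A`` is the spreading area, ``P`` the contact-line perimeter, and
``eps(x, t)`` a per-site polarization field bounded to
``[eps0 - delta_eps/2, eps0 + delta_eps/2]`` that emulates local protrusive
capability (actin polymerization, contractility, adhesion).  Elementary
Metropolis moves add or remove single adhesion sites on the cell boundary;
protrusion outside the adhesive mask is forbidden (strict confinement).
After each Monte Carlo step (MCS), sites surrounded by more accepted
protrusion than retraction events within the signaling range ``R`` relax
toward the upper field bound, sites surrounded by more retractions toward the
lower bound, and all other contact sites toward the rest state ``eps0`` —
the two feedback loops that break detailed balance and generate persistent
polarity.

The public API (``hamiltonian``, ``attempt_step``, ``classify_neighborhoods``,
``update_polarization``) is a plain-NumPy reference implementation used in
tests; ``run_simulation`` drives a numba-compiled kernel implementing the
identical dynamics for production runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .analysis import Trajectory
from .geometry import PatternMask

_NBRS = ((-1, 0), (1, 0), (0, -1), (0, 1))


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """CPM parameters.  Energies are in arbitrary model units.

    ``mcs_minutes`` converts Monte Carlo steps to physical time and is set by
    :func:`calibrate_mcs_duration` so the plateau speed of migrating cells
    matches a target (0.6 um/min in the experiments this model describes).
    Defaults are implementation choices tuned to reproduce pole-to-pole
    migration statistics on a 20-um-wide lane at 2 um lattice spacing.
    """

    kappa_A: float = 0.0033      # area stiffness, energy / um^4
    kappa_P: float = 0.02        # perimeter stiffness, energy / um^2
    eps0: float = 26.0           # average polarization field, energy per site
    delta_eps: float = 50.0      # polarization range, energy per site
    mu: float = 0.12             # field relaxation rate, 1 / min
    signaling_R: float = 5.0     # signaling range, um
    kT: float = 10.0             # Metropolis temperature, energy
    mcs_minutes: float = 0.35    # minutes per MCS (~calibrated at the defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kappa_A", "kappa_P", "eps0", "mu", "signaling_R", "kT", "mcs_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be >= 0")

    @property
    def eps_lo(self) -> float:
        return self.eps0 - self.delta_eps / 2

    @property
    def eps_hi(self) -> float:
        return self.eps0 + self.delta_eps / 2


def steady_state_area(params: ModelParams, spacing: float) -> float:
    """Estimate of the steady-state spreading area in um^2.

    From the marginal energy balance of adding one site to a compact cell,
    2*kappa_A*A + 4*pi*kappa_P = eps0/spacing^2 (circle perimeter estimate);
    used to size the initial cell, the true steady state emerges dynamically.
    """
    gain = params.eps0 / spacing**2 - 4 * math.pi * params.kappa_P
    if gain <= 0:
        raise ValueError("parameters admit no finite positive steady-state area")
    return gain / (2 * params.kappa_A)


@dataclass
class CellState:
    """Lattice state: occupancy, polarization field and this-MCS event labels.

    ``labels``: 0 = unchanged, 1 = accepted protrusion, 2 = accepted
    retraction (labels may sit on now-unoccupied sites after a retraction).
    """

    mask: PatternMask
    occupied: np.ndarray    # bool (ny, nx), subset of mask.grid
    eps: np.ndarray         # float (ny, nx); meaningful on occupied sites
    labels: np.ndarray      # uint8 (ny, nx)
    time: float = 0.0

    def n_sites(self) -> int:
        return int(self.occupied.sum())


def make_initial_state(mask: PatternMask, params: ModelParams,
                       area_um2: float | None = None) -> CellState:
    """Compact cell of the steady-state size at the lane center, eps == eps0.

    The nearest-N mask sites to the lane center are occupied, which yields a
    disc clipped to the lane (a stadium when the target radius exceeds W/2).
    """
    a = mask.spacing
    target = steady_state_area(params, a) if area_um2 is None else area_um2
    n_target = max(2, int(round(target / a**2)))
    ys, xs = np.nonzero(mask.grid)
    d2 = mask.x_centers[xs] ** 2 + mask.y_centers[ys] ** 2
    order = np.argsort(d2, kind="stable")[:n_target]
    occ = np.zeros_like(mask.grid, dtype=bool)
    occ[ys[order], xs[order]] = True
    eps = np.where(occ, params.eps0, 0.0)
    return CellState(mask=mask, occupied=occ, eps=eps,
                     labels=np.zeros_like(mask.grid, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Reference (NumPy) implementation of the elementary operations
# ---------------------------------------------------------------------------


def _exposed_edges(occ: np.ndarray) -> int:
    """Number of occupied-to-unoccupied 4-neighbor edges (grid border counts)."""
    padded = np.pad(occ, 1, constant_values=False)
    total = 0
    for dy, dx in _NBRS:
        nb = padded[1 + dy : padded.shape[0] - 1 + dy, 1 + dx : padded.shape[1] - 1 + dx]
        total += int(np.sum(occ & ~nb))
    return total


def geometry_measures(state: CellState) -> tuple[float, float]:
    """(area um^2, perimeter um) of the current configuration."""
    a = state.mask.spacing
    return state.n_sites() * a**2, _exposed_edges(state.occupied) * a


def hamiltonian(state: CellState, params: ModelParams) -> float:
    """Full recomputation of H = kappa_A A^2 + kappa_P P^2 - sum eps."""
    if state.n_sites() == 0:
        raise ValueError("empty cell has no defined configuration energy")
    A, P = geometry_measures(state)
    return params.kappa_A * A**2 + params.kappa_P * P**2 - float(state.eps[state.occupied].sum())


def _occupied_neighbor_eps(state: CellState, iy: int, ix: int) -> float:
    """Polarization assigned to a newly protruded site: mean over the occupied
    4-neighbors it protruded from (copy when there is a single one)."""
    ny, nx = state.occupied.shape
    vals = [state.eps[iy + dy, ix + dx] for dy, dx in _NBRS
            if 0 <= iy + dy < ny and 0 <= ix + dx < nx and state.occupied[iy + dy, ix + dx]]
    if not vals:
        raise ValueError("protrusion site has no occupied neighbor")
    return float(np.mean(vals))


def delta_hamiltonian(state: CellState, params: ModelParams, site: tuple[int, int],
                      add: bool) -> tuple[float, float]:
    """Local energy change of adding/removing ``site``; returns (dH, eps_used).

    Exactly equals hamiltonian(after) - hamiltonian(before); property-tested
    against the full recomputation.
    """
    iy, ix = site
    a = state.mask.spacing
    ny, nx = state.occupied.shape
    k = sum(1 for dy, dx in _NBRS
            if 0 <= iy + dy < ny and 0 <= ix + dx < nx and state.occupied[iy + dy, ix + dx])
    A = state.n_sites() * a**2
    Pe = _exposed_edges(state.occupied)
    if add:
        new_Pe = Pe + 4 - 2 * k
        eps_used = _occupied_neighbor_eps(state, iy, ix)
        dH = (params.kappa_A * ((A + a**2) ** 2 - A**2)
              + params.kappa_P * a**2 * (new_Pe**2 - Pe**2)
              - eps_used)
    else:
        new_Pe = Pe + 2 * k - 4
        eps_used = float(state.eps[iy, ix])
        dH = (params.kappa_A * ((A - a**2) ** 2 - A**2)
              + params.kappa_P * a**2 * (new_Pe**2 - Pe**2)
              + eps_used)
    return float(dH), eps_used


def protrusion_candidates(state: CellState) -> list[tuple[int, int]]:
    """Unoccupied mask sites 4-adjacent to the cell."""
    ny, nx = state.occupied.shape
    out = []
    for iy, ix in zip(*np.nonzero(state.mask.grid & ~state.occupied)):
        if any(0 <= iy + dy < ny and 0 <= ix + dx < nx and state.occupied[iy + dy, ix + dx]
               for dy, dx in _NBRS):
            out.append((int(iy), int(ix)))
    return out


def retraction_candidates(state: CellState) -> list[tuple[int, int]]:
    """Occupied sites with at least one unoccupied 4-neighbor (cell boundary)."""
    ny, nx = state.occupied.shape
    out = []
    for iy, ix in zip(*np.nonzero(state.occupied)):
        if any(not (0 <= iy + dy < ny and 0 <= ix + dx < nx
                    and state.occupied[iy + dy, ix + dx]) for dy, dx in _NBRS):
            out.append((int(iy), int(ix)))
    return out


def removal_keeps_connected(occ: np.ndarray, iy: int, ix: int) -> bool:
    """Digital-topology simple-point test (4-connected foreground).

    The Yokoi connectivity number over the 8-neighborhood ring must be 1 for
    the removal to preserve a single 4-connected component.
    """
    ny, nx = occ.shape
    ring = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))
    x = [1 if (0 <= iy + dy < ny and 0 <= ix + dx < nx and occ[iy + dy, ix + dx]) else 0
         for dy, dx in ring]
    x = x + x[:2]
    c = sum(x[k] - x[k] * x[k + 1] * x[k + 2] for k in range(0, 8, 2))
    return c == 1


def attempt_step(state: CellState, params: ModelParams,
                 rng: np.random.Generator) -> bool:
    """One elementary Metropolis move; mutates ``state``; True iff accepted.

    A candidate site is drawn uniformly from the union of protrusion and
    retraction candidates.  Protrusions into non-mask sites never occur (they
    are not candidates: hard confinement).  Retractions that would disconnect
    or empty the cell are rejected outright.  Acceptance probability is
    min(1, exp(-dH/kT)); accepted moves are written to ``state.labels``.
    """
    prot = protrusion_candidates(state)
    retr = retraction_candidates(state)
    i = int(rng.integers(0, len(prot) + len(retr)))
    if i < len(prot):
        site, add = prot[i], True
    else:
        site, add = retr[i - len(prot)], False
        if state.n_sites() <= 1 or not removal_keeps_connected(state.occupied, *site):
            return False
    dH, eps_used = delta_hamiltonian(state, params, site, add)
    if dH > 0 and rng.random() >= math.exp(-dH / params.kT):
        return False
    iy, ix = site
    if add:
        state.occupied[iy, ix] = True
        state.eps[iy, ix] = eps_used
        state.labels[iy, ix] = 1
    else:
        state.occupied[iy, ix] = False
        state.labels[iy, ix] = 2
    return True


def classify_neighborhoods(state: CellState, params: ModelParams) -> np.ndarray:
    """Per-site class from this MCS's event labels: +1 protrusive, -1
    retracting, 0 neutral (ties and event-free neighborhoods are neutral).

    A site is protrusive when strictly more accepted protrusion than
    retraction events lie within Euclidean distance R of it.
    """
    ny, nx = state.occupied.shape
    a = state.mask.spacing
    classes = np.zeros((ny, nx), dtype=np.int8)
    ev = np.nonzero(state.labels)
    if len(ev[0]) == 0:
        return classes
    ev_y, ev_x = ev
    ev_kind = state.labels[ev]
    for iy, ix in zip(*np.nonzero(state.occupied)):
        d2 = ((ev_y - iy) ** 2 + (ev_x - ix) ** 2) * a**2
        near = d2 <= params.signaling_R**2 + 1e-9
        n_p = int(np.sum(near & (ev_kind == 1)))
        n_r = int(np.sum(near & (ev_kind == 2)))
        classes[iy, ix] = 1 if n_p > n_r else (-1 if n_r > n_p else 0)
    return classes


def update_polarization(state: CellState, classes: np.ndarray, params: ModelParams,
                        dt: float) -> None:
    """Exact exponential relaxation of eps over one MCS of duration ``dt``.

    eps <- target + (eps - target) * exp(-mu dt), with target eps0 +/-
    delta_eps/2 for protrusive/retracting sites and eps0 for neutral ones.
    The field bounds are preserved exactly (targets and state lie inside).
    """
    decay = math.exp(-params.mu * dt)
    target = np.where(classes > 0, params.eps_hi,
                      np.where(classes < 0, params.eps_lo, params.eps0))
    upd = target + (state.eps - target) * decay
    state.eps = np.where(state.occupied, np.clip(upd, params.eps_lo, params.eps_hi), state.eps)


def run_mcs(state: CellState, params: ModelParams, rng: np.random.Generator) -> int:
    """One Monte Carlo step at the reference-implementation level.

    Attempts as many elementary moves as there are boundary sites, then
    classifies neighborhoods, relaxes the field and clears the labels.
    Returns the number of accepted moves.  Production runs use the compiled
    kernel; this exists for tests and small demonstrations.
    """
    state.labels[:] = 0
    attempts = max(1, len(retraction_candidates(state)))
    accepted = sum(attempt_step(state, params, rng) for _ in range(attempts))
    classes = classify_neighborhoods(state, params)
    update_polarization(state, classes, params, params.mcs_minutes)
    state.time += params.mcs_minutes
    return accepted


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _occ_nbr_count(occ, iy, ix):
    ny, nx = occ.shape
    k = 0
    if iy > 0 and occ[iy - 1, ix] == 1:
        k += 1
    if iy < ny - 1 and occ[iy + 1, ix] == 1:
        k += 1
    if ix > 0 and occ[iy, ix - 1] == 1:
        k += 1
    if ix < nx - 1 and occ[iy, ix + 1] == 1:
        k += 1
    return k


@njit(cache=True)
def _is_prot_cand(mask, occ, iy, ix):
    return mask[iy, ix] == 1 and occ[iy, ix] == 0 and _occ_nbr_count(occ, iy, ix) > 0


@njit(cache=True)
def _is_ret_cand(occ, iy, ix):
    return occ[iy, ix] == 1 and _occ_nbr_count(occ, iy, ix) < 4


@njit(cache=True)
def _simple_point(occ, iy, ix):
    # Yokoi 4-connectivity number over the 8-ring == 1
    ny, nx = occ.shape
    x = np.zeros(10, dtype=np.uint8)
    dys = (0, -1, -1, -1, 0, 1, 1, 1)
    dxs = (1, 1, 0, -1, -1, -1, 0, 1)
    for k in range(8):
        yy = iy + dys[k]
        xx = ix + dxs[k]
        if 0 <= yy < ny and 0 <= xx < nx and occ[yy, xx] == 1:
            x[k] = 1
    x[8] = x[0]
    x[9] = x[1]
    c = 0
    for k in range(0, 8, 2):
        c += x[k] - x[k] * x[k + 1] * x[k + 2]
    return c == 1


@njit(cache=True)
def _upd_list(lst, pos, n, s, want):
    p = pos[s]
    if want:
        if p < 0:
            lst[n] = s
            pos[s] = n
            n += 1
    elif p >= 0:
        last = lst[n - 1]
        lst[p] = last
        pos[last] = p
        pos[s] = -1
        n -= 1
    return n


@njit(cache=True)
def _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy, ix):
    ny, nx = occ.shape
    s = iy * nx + ix
    npc = _upd_list(pc_list, pc_pos, npc, s, _is_prot_cand(mask, occ, iy, ix))
    nrc = _upd_list(rc_list, rc_pos, nrc, s, _is_ret_cand(occ, iy, ix))
    return npc, nrc


@njit(cache=True)
def _refresh_around(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy, ix):
    ny, nx = occ.shape
    npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy, ix)
    if iy > 0:
        npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy - 1, ix)
    if iy < ny - 1:
        npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy + 1, ix)
    if ix > 0:
        npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy, ix - 1)
    if ix < nx - 1:
        npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc, rc_list, rc_pos, nrc, iy, ix + 1)
    return npc, nrc


@njit(cache=True)
def _run_kernel(mask, occ, eps, xs,
                a, kappa_A, kappa_P, eps0, delta_eps, decay, kT,
                offs_y, offs_x,
                n_mcs, sample_every, seed, do_seed, record_fields):
    """Monte Carlo driver; mutates occ/eps in place.

    Returns (com, areas, fields, occs, A_sites, P_edges) where com/areas are
    sampled every ``sample_every`` MCS (index 0 = initial state).
    """
    ny, nx = occ.shape
    n = ny * nx
    if do_seed:
        np.random.seed(seed)
    pc_list = np.empty(n, np.int32)
    pc_pos = np.full(n, -1, np.int32)
    rc_list = np.empty(n, np.int32)
    rc_pos = np.full(n, -1, np.int32)
    npc = 0
    nrc = 0
    A = 0
    Pe = 0
    for iy in range(ny):
        for ix in range(nx):
            if occ[iy, ix] == 1:
                A += 1
                Pe += 4 - _occ_nbr_count(occ, iy, ix)
            npc, nrc = _refresh_site(mask, occ, pc_list, pc_pos, npc,
                                     rc_list, rc_pos, nrc, iy, ix)
    a2 = a * a
    hi = eps0 + delta_eps / 2
    lo = eps0 - delta_eps / 2
    n_samples = n_mcs // sample_every + 1
    com = np.empty(n_samples)
    areas = np.empty(n_samples, np.int64)
    if record_fields:
        fields = np.zeros((n_samples, ny, nx))
        occs = np.zeros((n_samples, ny, nx), np.uint8)
    else:
        fields = np.zeros((1, 1, 1))
        occs = np.zeros((1, 1, 1), np.uint8)
    pcnt = np.zeros((ny, nx), np.int32)
    rcnt = np.zeros((ny, nx), np.int32)
    ev_y = np.empty(n, np.int32)
    ev_x = np.empty(n, np.int32)
    ev_t = np.empty(n, np.uint8)
    n_off = offs_y.shape[0]

    si = 0
    sx = 0.0
    for iy in range(ny):
        for ix in range(nx):
            if occ[iy, ix] == 1:
                sx += xs[ix]
    com[0] = sx / A
    areas[0] = A
    if record_fields:
        for iy in range(ny):
            for ix in range(nx):
                if occ[iy, ix] == 1:
                    fields[0, iy, ix] = eps[iy, ix]
                    occs[0, iy, ix] = 1

    for step in range(1, n_mcs + 1):
        n_ev = 0
        attempts = nrc if nrc > 0 else 1
        for _ in range(attempts):
            tot = npc + nrc
            r = int(np.random.random() * tot)
            if r >= tot:
                r = tot - 1
            if r < npc:
                s = pc_list[r]
                iy = s // nx
                ix = s % nx
                tot_e = 0.0
                cnt_e = 0
                if iy > 0 and occ[iy - 1, ix] == 1:
                    tot_e += eps[iy - 1, ix]
                    cnt_e += 1
                if iy < ny - 1 and occ[iy + 1, ix] == 1:
                    tot_e += eps[iy + 1, ix]
                    cnt_e += 1
                if ix > 0 and occ[iy, ix - 1] == 1:
                    tot_e += eps[iy, ix - 1]
                    cnt_e += 1
                if ix < nx - 1 and occ[iy, ix + 1] == 1:
                    tot_e += eps[iy, ix + 1]
                    cnt_e += 1
                eps_new = tot_e / cnt_e
                A_um = A * a2
                newPe = Pe + 4 - 2 * cnt_e
                dH = (kappa_A * (2.0 * A_um * a2 + a2 * a2)
                      + kappa_P * a2 * (newPe * newPe - Pe * Pe)
                      - eps_new)
                if dH <= 0.0 or np.random.random() < math.exp(-dH / kT):
                    occ[iy, ix] = 1
                    eps[iy, ix] = eps_new
                    A += 1
                    Pe = newPe
                    ev_y[n_ev] = iy
                    ev_x[n_ev] = ix
                    ev_t[n_ev] = 1
                    n_ev += 1
                    npc, nrc = _refresh_around(mask, occ, pc_list, pc_pos, npc,
                                               rc_list, rc_pos, nrc, iy, ix)
            else:
                s = rc_list[r - npc]
                iy = s // nx
                ix = s % nx
                if A <= 1:
                    continue
                if not _simple_point(occ, iy, ix):
                    continue
                k = _occ_nbr_count(occ, iy, ix)
                A_um = A * a2
                newPe = Pe + 2 * k - 4
                dH = (kappa_A * (-2.0 * A_um * a2 + a2 * a2)
                      + kappa_P * a2 * (newPe * newPe - Pe * Pe)
                      + eps[iy, ix])
                if dH <= 0.0 or np.random.random() < math.exp(-dH / kT):
                    occ[iy, ix] = 0
                    A -= 1
                    Pe = newPe
                    ev_y[n_ev] = iy
                    ev_x[n_ev] = ix
                    ev_t[n_ev] = 2
                    n_ev += 1
                    npc, nrc = _refresh_around(mask, occ, pc_list, pc_pos, npc,
                                               rc_list, rc_pos, nrc, iy, ix)

        # neighborhood classification within the signaling range
        for e in range(n_ev):
            for o in range(n_off):
                yy = ev_y[e] + offs_y[o]
                xx = ev_x[e] + offs_x[o]
                if 0 <= yy < ny and 0 <= xx < nx:
                    if ev_t[e] == 1:
                        pcnt[yy, xx] += 1
                    else:
                        rcnt[yy, xx] += 1
        # exact exponential relaxation toward the class target
        for iy in range(ny):
            for ix in range(nx):
                if occ[iy, ix] == 1:
                    p = pcnt[iy, ix]
                    q = rcnt[iy, ix]
                    if p > q:
                        tgt = hi
                    elif q > p:
                        tgt = lo
                    else:
                        tgt = eps0
                    e1 = tgt + (eps[iy, ix] - tgt) * decay
                    if e1 > hi:
                        e1 = hi
                    elif e1 < lo:
                        e1 = lo
                    eps[iy, ix] = e1
        for e in range(n_ev):
            for o in range(n_off):
                yy = ev_y[e] + offs_y[o]
                xx = ev_x[e] + offs_x[o]
                if 0 <= yy < ny and 0 <= xx < nx:
                    if ev_t[e] == 1:
                        pcnt[yy, xx] -= 1
                    else:
                        rcnt[yy, xx] -= 1

        if step % sample_every == 0:
            si += 1
            sx = 0.0
            for iy in range(ny):
                for ix in range(nx):
                    if occ[iy, ix] == 1:
                        sx += xs[ix]
            com[si] = sx / A
            areas[si] = A
            if record_fields:
                for iy in range(ny):
                    for ix in range(nx):
                        if occ[iy, ix] == 1:
                            fields[si, iy, ix] = eps[iy, ix]
                            occs[si, iy, ix] = 1
    return com, areas, fields, occs, A, Pe


def _signaling_offsets(R: float, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.floor(R / spacing + 1e-9))
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if (dy * dy + dx * dx) * spacing**2 <= R**2 + 1e-9]
    arr = np.array(offs, dtype=np.int64)
    return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])


# ---------------------------------------------------------------------------
# Simulation driver and calibration
# ---------------------------------------------------------------------------


@dataclass
class SimulationRecord:
    """Output of one run: 10-min-sampled COM track plus optional snapshots."""

    trajectory: Trajectory
    area_series: np.ndarray                 # um^2 per sample
    field_series: np.ndarray | None         # (n_samples, ny, nx) eps, 0 outside cell
    occ_series: np.ndarray | None
    params: ModelParams
    seed: int
    sampling: float                          # actual minutes between samples


def run_simulation(mask: PatternMask, params: ModelParams,
                   duration: float = 2160.0, sampling: float = 10.0,
                   seed: int | None = None, record_fields: bool = False,
                   burn_in: float = 240.0) -> SimulationRecord:
    """Simulate one cell on ``mask`` and record its center-of-mass track.

    The sampling interval is realized as the nearest whole number of MCS, so
    the recorded interval can deviate from ``sampling`` by up to half an MCS.
    A burn-in window (default 240 min) lets the cell polarize before
    recording starts.  Identical seeds yield bit-identical records.
    """
    if duration < sampling:
        raise ValueError("duration must be at least one sampling interval")
    seed = params.seed if seed is None else int(seed)
    kseed = seed & 0x7FFFFFFF
    mm = params.mcs_minutes
    steps_per_sample = max(1, int(round(sampling / mm)))
    dt = steps_per_sample * mm
    n_samples = max(1, int(round(duration / dt)))
    n_mcs = n_samples * steps_per_sample
    burn_mcs = int(round(burn_in / mm))

    state = make_initial_state(mask, params)
    occ = np.ascontiguousarray(state.occupied.astype(np.uint8))
    eps = np.ascontiguousarray(state.eps.astype(np.float64))
    grid = np.ascontiguousarray(mask.grid.astype(np.uint8))
    xs = np.ascontiguousarray(mask.x_centers.astype(np.float64))
    offs_y, offs_x = _signaling_offsets(params.signaling_R, mask.spacing)
    decay = math.exp(-params.mu * mm)
    args = (grid, occ, eps, xs, mask.spacing, params.kappa_A, params.kappa_P,
            params.eps0, params.delta_eps, decay, params.kT, offs_y, offs_x)
    init_sites = int(occ.sum())

    if burn_mcs > 0:
        _run_kernel(*args, burn_mcs, burn_mcs, kseed, True, False)
        com, areas, fields, occs, A, Pe = _run_kernel(
            *args, n_mcs, steps_per_sample, 0, False, record_fields)
    else:
        com, areas, fields, occs, A, Pe = _run_kernel(
            *args, n_mcs, steps_per_sample, kseed, True, record_fields)

    # incremental bookkeeping must agree with a recomputation from the lattice
    occ_bool = occ.astype(bool)
    assert A == int(occ_bool.sum()), "area bookkeeping diverged"
    assert Pe == _exposed_edges(occ_bool), "perimeter bookkeeping diverged"
    if areas.min() < max(2, 0.25 * init_sites):
        raise RuntimeError(
            f"cell collapsed to {areas.min()} sites (from {init_sites}): "
            "pathological parameters (kT too high or eps0 too low?)"
        )
    times = np.arange(n_samples + 1) * dt
    traj = Trajectory(times=times, koor=com, lane_length=mask.spec.length,
                      cell_id=f"sim_seed{seed}")
    return SimulationRecord(
        trajectory=traj, area_series=areas * mask.spacing**2,
        field_series=fields if record_fields else None,
        occ_series=occs if record_fields else None,
        params=params, seed=seed, sampling=dt,
    )


def _plateau_speed_per_mcs(com: np.ndarray, sample_every: int, plateau_halfwidth: float,
                           min_run_um: float = 20.0) -> float:
    """Ballistic center-of-mass speed in um/MCS from maximal monotone runs.

    The COM series (one value per ``sample_every`` MCS) is lightly smoothed,
    split into maximal monotone segments, and the speed is the
    duration-weighted mean over segments that traverse at least ``min_run_um``
    within the plateau band.  Window-free, hence unbiased by reversals or
    frame-to-frame jitter.
    """
    kern = np.ones(3) / 3
    sm = np.convolve(com, kern, mode="valid")
    sgn = np.sign(np.diff(sm))
    sgn[sgn == 0] = 1
    breaks = np.flatnonzero(np.diff(sgn) != 0) + 1
    bounds = np.concatenate(([0], breaks, [len(sm) - 1]))
    dist = 0.0
    dur = 0.0
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        x0, x1 = sm[b0], sm[b1]
        lo, hi = sorted((x0, x1))
        # clip the segment to the plateau band
        lo_c, hi_c = max(lo, -plateau_halfwidth), min(hi, plateau_halfwidth)
        if hi_c - lo_c < min_run_um or abs(x1 - x0) < min_run_um:
            continue
        frac = (hi_c - lo_c) / (hi - lo)
        dist += hi_c - lo_c
        dur += (b1 - b0) * sample_every * frac
    if dur <= 0:
        return 0.0
    return dist / dur


def calibrate_mcs_duration(mask: PatternMask, params: ModelParams,
                           target_speed: float = 0.6, xi0: float = 55.0,
                           n_mcs: int = 60000, sample_every: int = 10,
                           seed: int | None = None) -> float:
    """Minutes per MCS so the plateau run speed matches ``target_speed`` (um/min).

    Runs the model in MCS time, measures the center-of-mass speed over
    monotone plateau-crossing runs (beyond ``xi0`` of either tip), and returns
    (speed per MCS) / target_speed.  The measurement does not depend on the
    target, so the returned value scales exactly inversely with
    ``target_speed``.
    """
    if params.delta_eps <= 0:
        raise ValueError("calibration requires delta_eps > 0 (persistent migration)")
    if target_speed <= 0:
        raise ValueError("target_speed must be positive")
    seed = params.seed if seed is None else int(seed)
    state = make_initial_state(mask, params)
    occ = np.ascontiguousarray(state.occupied.astype(np.uint8))
    eps = np.ascontiguousarray(state.eps.astype(np.float64))
    grid = np.ascontiguousarray(mask.grid.astype(np.uint8))
    xs = np.ascontiguousarray(mask.x_centers.astype(np.float64))
    offs_y, offs_x = _signaling_offsets(params.signaling_R, mask.spacing)
    decay = math.exp(-params.mu * params.mcs_minutes)
    com, _, _, _, _, _ = _run_kernel(
        grid, occ, eps, xs, mask.spacing, params.kappa_A, params.kappa_P,
        params.eps0, params.delta_eps, decay, params.kT, offs_y, offs_x,
        n_mcs, sample_every, seed & 0x7FFFFFFF, True, False)
    plateau = mask.spec.length / 2 - xi0
    speed_per_mcs = _plateau_speed_per_mcs(com, sample_every, plateau)
    if speed_per_mcs < 1e-4:
        raise ValueError("no monotone plateau crossings: non-migrating parameter set")
    return speed_per_mcs / target_speed


def calibrated_params(mask: PatternMask, params: ModelParams,
                      target_speed: float = 0.6, **kw) -> ModelParams:
    """Convenience: ``params`` with ``mcs_minutes`` set by calibration."""
    return replace(params, mcs_minutes=calibrate_mcs_duration(mask, params,
                                                              target_speed, **kw))
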