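# Methods

`microlane` simulates and quantifies quasi-periodic pole-to-pole migration of
single cells confined to stripe-shaped adhesive micropatterns ("microlanes").
It has three parts: a lattice model of a self-polarizing cell (`cpm`), a
trajectory-statistics pipeline (`analysis`), and a kinematic trajectory
generator with exact ground truth (`synth`), tied together by mask geometry
(`geometry`) and I/O (`io`, `cli`).

## Lane geometry

A microlane is parameterized by tip-to-tip length L, width W (default 20 um)
and a tip shape (round, blunt, sharp, concave).  Masks are rasterized on a
square lattice (default spacing 2 um, i.e. 10 sites across a 20-um lane) by a
center-of-site inclusion test.  `equalize_area` adjusts only the length so
that different tip shapes enclose the same adhesive area — every supported
shape has area = W·L − k(shape), so the solution is exact.  Two rasterization
caveats: the default 45-degree sharp cap aligns its edges with the lattice
diagonal, which biases the raster area by half a site per edge site (error
proportional to spacing, not spacing squared), and center-of-site errors on
curved caps can tie between spacings rather than decrease strictly.

The *reversal region* consists of the two intervals within xi0 (default
55 um) of each lane end, in the `koor` frame (micrometers from the lane
center along the long axis).  xi0 >= L/2 is rejected: the two regions then
cover the lane and no run phase exists, which is the observed regime on the
shortest (70-um) lanes.

## Cell model

The cell is a 4-connected set of occupied lattice sites with energy

    H = kappa_A A^2 + kappa_P P^2 − Σ_x eps(x, t),

with spreading area A (um^2), contact-line perimeter P (um), and a per-site
polarization field eps bounded to [eps0 − Δeps/2, eps0 + Δeps/2] that stands
in for local protrusive capability.  Elementary Metropolis moves add or
remove one boundary site, chosen uniformly from the union of protrusion
candidates (unoccupied mask sites 4-adjacent to the cell) and retraction
candidates (occupied boundary sites), accepted with min(1, exp(−ΔH/kT)).
Protrusion off the mask is impossible by construction (strict confinement);
removals that would disconnect or empty the cell are rejected via a local
simple-point (Yokoi connectivity-number) test, which provably preserves a
single 4-connected component.  A newly occupied site inherits the mean eps of
its occupied 4-neighbors (a copy when there is exactly one), preserving
spatial continuity of the field.

One Monte Carlo step (MCS) comprises as many attempted moves as there are
boundary sites.  After each MCS, every occupied site is classified by the
accepted events within the Euclidean signaling range R: more protrusions than
retractions → relax exponentially (rate mu) toward the upper field bound;
more retractions → toward the lower bound; ties and quiet neighborhoods →
toward eps0.  The relaxation uses the exact exponential update
eps ← target + (eps − target)·exp(−mu·dt), so the bounds are never violated.
These two feedback loops break detailed balance and generate persistent
polarity; with Δeps = 0 the field is inert and the cell performs an unbiased
random walk (the control used in tests).

### Parameters

| symbol | default | units | role |
|---|---|---|---|
| kappa_A | 0.0033 | energy/um^4 | area stiffness (sets cell size with eps0) |
| kappa_P | 0.02 | energy/um^2 | perimeter stiffness (contour smoothness) |
| eps0 | 26 | energy/site | mean polarization field |
| Δeps | 50 | energy/site | polarization range (front–rear contrast) |
| mu | 0.12 | 1/min | field relaxation rate (repolarization timescale) |
| R | 5 | um | signaling range (lamellipodium coherence) |
| kT | 10 | energy | Metropolis temperature (shape fluctuations) |
| mcs_minutes | 0.35 | min/MCS | physical duration of one MCS |

The defaults are implementation choices (no published parameter table is
reproduced here), selected so that the model on a 170 x 20 um round-tip lane
shows (i) a steady-state spreading area near 950 um^2 — a polarized cell
50–60 um long, matching the elongated morphology of MDA-MB-231 cells on
20-um lanes — with area fluctuations under 10%; (ii) persistent pole-to-pole
migration with a trapezoidal spatial speed profile; and (iii) a reversal-time
histogram (55-um region, 20-min bins) peaking at ~90–100 min after speed
calibration.  A larger cell makes reversals too shallow and fast; a smaller
one loses persistence.  Front–rear contrast (Δeps/eps0 ≈ 1.9) is the main
persistence knob; mu sets the repolarization dwell at the tips.

### Calibration of physical time

`calibrate_mcs_duration` runs the model in MCS time, measures the
center-of-mass speed over maximal monotone plateau-crossing runs (a
window-free estimator immune to reversal and jitter bias), and returns
(speed per MCS) / (target speed), with target 0.6 um/min by default.  The
measurement does not depend on the target, so the result scales exactly
inversely with it.  Because the per-MCS field decay exp(−mu·mcs_minutes)
couples the dynamics to the assumed step duration, the calibration is
self-consistent only at the fixed point of this map; the default
`mcs_minutes = 0.35` *is* that fixed point (recalibrating at the calibrated
parameters reproduces it within a few percent).

Simulated records start from a compact cell at the lane center with
eps ≡ eps0, discard a 240-min burn-in during which polarity establishes
itself, and then sample the center of mass every 10 min (realized as the
nearest whole number of MCS) for 36 h, mirroring the experimental protocol.

## Trajectory statistics

All statistics operate on uniformly sampled 1D tracks (`koor` vs minutes):

* **Projection/centering** — raw positions are projected on the long axis;
  each track's lane center is the midpoint of its two extreme tip approaches.
* **Filtering** — tracks shorter than 36 h, tracks that never explored both
  tip regions, and non-moving cells are excluded, with per-rule counts.
* **Velocities** — forward differences v(t) = [x(t+Δt) − x(t)]/Δt, Δt=10 min.
* **Spatial profiles** — occupancy p(x) and mean |v|(x) in 5-um bins;
  velocities are assigned to the bin of their start position; empty bins are
  NaN, never zero; SEM requires at least two samples.
* **Change points** — a continuous ramp–plateau–ramp (trapezoid) model is
  fitted to |v|(x) by exhaustive least squares over all breakpoint pairs on
  the bin grid (at most ~54 bins, so O(bins^2) search is exact).  Ramps are
  anchored at the outermost populated bins' values; the plateau level is the
  only linear parameter per candidate pair.  Ties break toward smaller xi0;
  coinciding breakpoints are flagged "fully ramped" (short-lane regime).
* **Spectra** — per-cell magnitude DFT of the signed, mean-removed velocity
  series (no window, cells truncated to the common length), averaged over the
  ensemble, zero-frequency bin dropped, and fitted with a scaled log-normal;
  f_max is the mode of the fitted curve and T = 1/f_max.  Non-convergent or
  peakless fits fall back to the raw argmax and are flagged unreliable.
* **Period vs length** — ordinary least squares of T (h) on L (um).  A full
  cycle covers the lane twice, so the crossing speed is v_c = 2/slope.
* **Reversal events** — maximal intervals of tip-region occupancy; t1 is the
  first sample inside, t2 the first sample after exit, t_R = t2 − t1.
  Intervals censored by either record end are discarded.  The definition is
  purely geometric; a `reversed` flag (the cell moved strictly deeper after
  entry) is provided for sensitivity analyses but not used in the headline
  statistics.
* **Kymographs** — per frame, the maximum of the polarization field over the
  lane's short axis at each long-axis position.

## Synthetic trajectory generator

The generator produces pole-to-pole tracks with exact ground truth: constant
run speed v_run on the plateau, a constant-deceleration ramp from distance
`ramp_xi` down to standstill exactly at the turning point (`turn_point` from
the tip), a gamma-distributed pause there, a mirrored acceleration ramp on
exit, Gaussian position noise per 10-min sample, and a logged record of every
turning event.  The ramp is linear in *time*; a taper linear in space to zero
would never reach the turning point (logarithmically divergent traversal),
whereas the constant-deceleration form has the closed-form traversal time
2(ramp_xi − turn_point)/v_run, verified against numerical quadrature of
1/v(x).  Defaults (v_run 0.6 um/min, ramp_xi 55 um, turn_point 15 um, gamma
pause with mean 100 min and shape 4, noise 1 um, 10-min sampling, 36-h
records) are fixture choices emulating the observed phenomenology.

What the generator does *not* emulate: 2D shape dynamics, cell-to-cell
parameter variability, spontaneous mid-lane reversals, tracking outliers and
track fragmentation.  Pipeline tests on synthetic ensembles therefore
demonstrate estimator correctness (parameter recovery under the generator's
assumptions), not robustness to every artifact of real microscopy data.

A note on internal consistency of the emulation used in tests: with plateau
speed v and region depth xi0, the period–length regression obeys
x_intercept = 2·xi0 − v·E[t_R].  With v = 0.62 um/min and xi0 = 55 um, an
x-intercept of ~29 um implies a mean region time of ~130 min while the
reversal-time distribution centers near 100 min — the printed values are
mutually consistent only to within their tolerances.  The emulation fixes
E[t_R] ≈ 117 min (turning point 40 um, pause mean 20 min), which satisfies
all three observables inside their stated bands simultaneously.

## Numerical and testing choices

* Problem sizes: 32 cells x 36 h for simulation statistics (about 280
  reversal events), 50 tracks per lane length for pipeline statistics, 100
  tracks for recovery properties — enough for stable modes and means at
  desk scale.
* Determinism: a single seeded generator per simulation run; per-cell streams
  spawned from a master seed (`numpy.random.SeedSequence`), so ensembles are
  reproducible cell-by-cell regardless of generation order.
* The production lattice kernel (numba) and the plain-NumPy reference
  implementation share the same move rules; energy bookkeeping is verified
  against full recomputation over >= 1e4 moves, and the kernel's incremental
  area/perimeter tallies are asserted against a from-lattice recomputation at
  the end of every run.
* Degenerate inputs: empty cells, non-uniform sampling, lanes fully covered
  by reversal regions, all-zero velocity ensembles and peakless spectra are
  rejected or flagged rather than silently processed.

## Known limitations

* The model keeps eps0 constant, so the spreading area barely changes upon
  depolarization; area regulation at the tips is deliberately not modeled.
* Cells cannot leave the adhesive pattern, unlike occasional transient
  protrusions past the pattern border seen in experiments.
* Simulated cells are clonal: ensemble variances underestimate experimental
  cell-to-cell variability.
* The spectral period estimator needs a few full cycles per record; on 36-h
  records it resolves cycles up to ~9 h well, and longer-period conditions
  require longer records (tests use 72 h where needed).
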