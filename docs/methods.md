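# Methods

## Coordinate system and genome

The chromosome is a circle of `length` bp (default 4,033,000) with *oriC*
at 0 and the terminus at ±length/2.  Map angles convert linearly
(bp = deg/360 × length); −180° and +180° are the same locus.  Internally
all positions are signed and origin-centred (negative = left replichore);
file output uses 0-based half-open linear coordinates on [0, length).
The default length is a round PY79-scale value rather than a specific
assembly: the degree/kb arithmetic used throughout (e.g. −59° ≈ 661 kb)
is only approximately linear on a real genome, and keeping the length a
config value keeps all distance bookkeeping self-consistent.

## Replisome model

Each cell carries at most one fork pair on a single-sister coordinate:
the replicated set is the interval [left_pos, right_pos], so per-cell
copy number is 1 or 2 everywhere and population MFA lies in [1, 2].
Five parameters control the population:

| parameter | default | meaning |
|---|---|---|
| `f_pre` | 0.18 | fraction of cells with a pre-existing fork pair at T=0, arm progress uniform on (0,1) |
| `t_init_mean` | 15/ln 20 ≈ 5.01 min | mean of the exponential replisome-loading delay; runs only while initiation is permitted (30 °C) |
| `v30`, `v42` | 40, 66 kb/min | elongation speed by temperature |
| `p_stall` | 0.001 /min/fork | irreversible spontaneous stalling |

A single exponential initiation clock yields both the sub-unity initiation
fraction (a 15-min permissive window at the default mean gives
1 − e^(−15/t_init_mean) = 95%) and the gradual origin-proximal rise of
mid-course MFA profiles.  `v30` and `p_stall` are not directly measured
quantities; the defaults are chosen at the scale of published replisome
speeds in slower-growth conditions and of the small late-time stalled
fraction, and both are ordinary config values.  HPUra freezes all forks in
place without removing them; there is no restart, degradation, or
re-initiation.

## SMC model

A pool of `n_smc` = 40 complexes per chromosome.  Unbound complexes load
at rate `k_load` (default 1/60 s⁻¹) while loading is active; the loading
position is a parS site with probability proportional to
`parS_weight` (default 10⁸ vs `background_weight` = 1 per bp, i.e. >95% of
loads at a single parS), otherwise uniform.  Both motors start at the
loading site and translocate apart; speed is `v_to_ter` = 71.5 kb/min when
moving away from the origin and `v_to_ori` = 49 kb/min when moving toward
it (set equal for origin-proximal parS scenarios, where the published
asymmetry does not apply).  Motors stop at the terminus; complexes
dissociate spontaneously with mean residence `tau_dissoc` = 1200 s and
return to the pool.

**Collisions.**  Encounter detection is by interval crossing between a
motor's and a fork's per-step displacements, so no tunnelling occurs at
any speed or time step (default dt = 1 s).  A blocked motor sits at, and
is carried with, the blocking fork (head-on pushback shrinks the extruded
interval; no slack is stored).  On blocking, two independent exponential
clocks start: unloading (mean `tau_unload`, removes the whole complex) and
bypassing (mean `tau_bypass`, places the motor one 1-kb lattice bin past
the fork).  The pure models are exact limits — blocking-only (both clocks
off), unloading-only, bypassing-only — and are run through the same engine
with zero/infinite means.  At the defaults (30 s, 120 s) the mean pause is
24 s with an 80%/20% unload/bypass split.  If the blocking fork disappears
(replication completes), pending clocks are discarded and the motor is
released unblocked.  Motors pass freely through other SMC complexes.

**Fork memory.**  Each cell keeps a 1-kb grid of replication times; a
motor's speed is scaled by `m = clip(age/t_memory, 0, 1)` where age is
time since the locus under the motor was replicated.  Non-finite age
(unreplicated DNA, or DNA replicated before the observation window, e.g.
behind pre-existing forks extrapolated backwards at `v42`) gives m = 1.
The linear-in-age ramp equals a linear-in-distance ramp of width
`t_memory × v_fork` (770 kb at the 700 s default and 66 kb/min) for a
constant-speed fork, and resolves on its own behind a stalled fork once
local ages exceed `t_memory` — both asserted in tests.

**Reduced fork-chasing (arc) model.**  Independent motor pairs against a
deterministic fork, no blocking/pushing/unloading/SMC–SMC interaction:
pairs load at the parS at times uniform over the window in which loading
is active *and* the parS has been replicated (the fork-chasing
subpopulation; earlier loads run ahead of the fork and belong to the
primary diagonal features, not the arc).  The memory factor applies to
both motors of a pair — in practice the ori-directed motor traverses old
DNA and is unaffected.  A motor currently behind a *moving* fork cannot
overtake it (its speed vanishes at the fork); stalled forks are crossed
freely once the local memory has aged out.

## Observables

* **MFA**: per-bin mean copy number at bin centers (10-kb default).
* **Occupancy**: histogram of bound motor positions plus loading sites,
  Gaussian-smoothed (5-kb footprint), normalized reads-per-million.
* **Contact maps**: unit-mass Gaussian-smeared density of
  (motor_ccw, motor_cw) anchor pairs, symmetrized, weighted by
  `loop_weight` (default 5) over a unit-mass background
  `(s0 + d)^(−α)` with s0 = 30 kb, α = 1 on circular distance;
  optional iterative proportional balancing preserves symmetry and total
  mass.  The loop/background mixture is a display-scale choice exposed as
  config: it controls feature visibility, not any fitted quantity.
* **Zipping extent** walks the anti-diagonal outward from the loading
  site on the observed-minus-expected map, greedily following the local
  ridge (±1 bin of tilt per step, so tilted arcs are tracked); the end is
  the last step at ≥ 20% of the proximal-segment median intensity, with
  three consecutive misses terminating the walk.  Deterministic given the
  map, so extent-based estimates are reproducible bit for bit.
* **Arc speed ratio**: least-squares slope through the origin of
  counter-clockwise versus clockwise anchor displacements from the
  loading site; 1 ⇒ perpendicular secondary diagonal, < 1 ⇒ the
  counter-clockwise arm is slower (arc tilts toward it).

## Estimators

* **Fork speed**: per arm, the boundary is the midpoint crossing between
  the ori-side and ter-side plateaus; speed is the least-squares slope of
  boundary vs time, averaged over arms.  With pre-existing forks the
  moving ramp they contribute biases this slightly low (~2% at the
  defaults) — an accepted property of the plateau-midpoint definition.
* **Pre-existing fraction**: from the T=0 ori/ter window-mean ratio with
  the exact finite-window inversion `f = (r−1)/(1 − (W/2)(r+1))`
  (windows ±5% of the genome; W = 0.1 in arm-progress units).  The naive
  `r − 1` underestimates by ~11%.
* **Initiation fraction**: on the absolute copy-number scale, at a sample
  time when every replicating cell has covered the origin window and no
  initiated fork has reached the terminus window,
  `ori_mean = 1 + f_pre + (1 − f_pre)·f_init`, inverted with `f_pre`
  estimated from the T=0 profile.  A naive difference of ori/ter ratios
  is biased once pre-existing forks begin finishing at the terminus
  (worked example at the defaults: 0.58 vs truth 0.95), hence the
  absolute-scale correction; read-count tracks are first rescaled with
  `normalize_mfa_counts` (lowest-decile baseline), which requires an
  unreplicated baseline region.
* **Motor speed**: least-squares slope of zipping extent vs time per arm.
  Valid while the extent is in a single-speed regime: the terminus caps
  the terminus-directed extent and crossing the origin switches the
  ori-directed motor to the terminus-directed speed, so sample times must
  precede those transitions.
* **Bypass delay**: extent deficit divided by motor speed, reported raw
  and rounded to the nearest minute.
* **Goodness of fit**: sum of squared residuals of unit-sum-normalized
  profiles, masked (±20 kb around parS and zero-coverage reference bins);
  scale-free and deterministic.
* **Sweeps**: the engagement sweep scores a (tau_unload, tau_bypass) grid
  (zero/infinite entries embed the pure models) and annotates the
  `tau_bypass ≥ 2 × tau_unload` region; the fork-memory sweep scores
  (t_memory, effective time) by the squared mismatch of the arc's
  terminus-directed endpoint (5% quantile, scaled by 100 kb) plus the arc
  speed ratio, and reports a curvature-based uncertainty half-width from a
  local quadratic fit of the marginal score.  Several near-equal grid
  cells are expected in the engagement sweep; the result object reports
  the best cell and the region annotation rather than claiming a unique
  optimum.

## Synthetic data

Scenario fixtures pin the study conditions: G1-arrest control, induced
loading with free-running forks, constitutive loading with moving forks
(parS −27° and −59°), two-sided head-to-tail (parS −1°, HPUra+IPTG when
the permissive window closes), one-sided head-to-tail (HPUra once the
leftward fork is ~1169 kb from the origin, past the −59° parS), head-on
with stalled forks (stall at ~450 kb, short of parS), and head-on with
moving forks.  Event times that depend on fork position are derived from
the replication parameters at scenario construction.

Read sampling is multinomial at the configured depth (Hi-C on the upper
triangle, then symmetrized); expected counts are proportional to the
forward-model intensities, with no overdispersion — at 5–10-kb bins the
counting noise is already small, and overdispersion can be layered on the
returned counts if needed.  Bundles are byte-identical for identical
arguments; the truth manifest records every parameter and seed.

What the generator does *not* emulate: restriction-fragment geometry,
read mappability and GC bias, 3D polymer contacts beyond the distance-decay
background, explicit transcription (absorbed into the direction-dependent
motor speeds), sister-chromatid resolution, or XerD-mediated unloading at
the terminus.  Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to these
real-data artefacts.

## Numerical choices

dt = 1 s for the joint simulator (motor displacement ≈ 1.2 bp/s·dt ≪ the
1-kb memory grid); fork sub-stepping aligns to protocol breakpoints so
environment switches land exactly on step boundaries.  Discrete per-step
event probabilities use `1 − exp(−rate·dt)`, giving a +dt/2 bias on
exponential means (0.04% at tau = 1200 s).  Bypass placement is one
lattice bin (1 kb) past the fork.  Simulation sizes used by the default
test suite and the acceptance script (300–5000 cells, 40 complexes each)
put Monte-Carlo errors comfortably inside the stated tolerances: ±3 kb/min
for fork speed, ±2 points for the pre-existing fraction, ±2 kb/min for
motor speed, ±3 points for the initiation fraction, ±100 s for the
fork-memory duration.

## Known limitations

* The plateau-midpoint fork-speed estimator inherits a small negative bias
  from pre-existing forks (see above); it stays within the stated
  tolerance at the default 18% fraction.
* `estimate_initiation_fraction` requires profiles on the copy-number
  scale and a sampling time inside its validity window (all origins
  covered, no initiated fork at the terminus); it raises on unscaled
  input rather than guessing.
* Occupancy forward models count motor and loading positions only — no
  footprint occupancy for the unextruded loop interior, no loader
  (ParB) spreading beyond a Gaussian footprint.
* The engagement sweep's score surface is intentionally shallow along
  `tau_bypass/tau_unload` ratios above 2; conclusions should quote the
  region, not a single cell.
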