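# Methods

`qqfit` estimates model parameters from two kinds of evidence at once:
numerical measurements and qualitative observations ("higher than control",
"stays below 8", "within error of baseline"). This note records the model
and scoring conventions, the synthetic-data conditions used by the built-in
case studies, the numerical choices, and the known limitations.

## Objective function

For parameters **x** the fitted objective is

    f_tot(x) = f_quant(x) + f_qual(x)

* `f_quant` is the plain sum of squares Σ_j (y_j,model(x) − y_j,data)².
  Residuals are unweighted: no per-point σ_j enters, so `f_tot` is a score,
  not a calibrated likelihood.
* Every qualitative observation is rewritten as an inequality g_i(x) < 0 and
  scored by a *static penalty*: `f_qual(x) = Σ_i C_i · max(0, g_i(x))`. The
  penalty is linear in the violation. A squared penalty would let one badly
  violated constraint dominate the sum; the linear form keeps constraints
  commensurate. Two exact consequences that the test suite asserts: a
  satisfied constraint contributes precisely 0, and doubling one violation
  (or scaling all C_i by λ) scales the corresponding contribution exactly.

Constraint kinds and their g:

| kind | g(x) | typical reading |
|---|---|---|
| `less_than` | value − threshold | "lower than control" |
| `greater_than` | threshold − value | "higher than control" |
| `within_band` | \|value − ref\| − ε | "within error (0 label)" |
| `never_reach` | max over windowed trajectory − threshold | "divides before V hits 8" |
| `must_reach` | threshold − max over windowed trajectory | "spindle assembly completes" |

A band constraint is a single term, not two one-sided constraints, and the
boundary |Δ| = ε scores exactly zero — "within error" is interpreted as a
strict inequality whose penalty vanishes continuously at the edge.
Observables may be differences of one output under two conditions (e.g.
A(I) − A(0)); the reference is recomputed from the model at every parameter
vector rather than frozen to a number, since it may depend on fitted
parameters in general.

Trajectory constraints are evaluated on the simulator's native time grid
with no interpolation; windows are closed intervals, and a value-triggered
window end closes at the first sample where the trigger output reaches its
level. An auxiliary `oscillation_penalty` charges `weight · max(0, p − 20)`
where p is the number of strict interior local maxima, discouraging
rapidly oscillating time courses that overfit noisy time series; exactly 20
peaks is unpenalized.

## Raf dimer–inhibitor equilibrium model

Raf monomers R dimerize and each protomer binds an inhibitor I, giving
species R, RI, RR, RIR, RIRI with association constants K1..K6 (μM⁻¹).
Thermodynamic cycles force K4 = K1·K3/K2 and K6 = K1·K3·K5/K2², so only
(K1, K2, K3, K5) are independent. K3 is assigned to the first inhibitor
binding on the dimer (RR + I ⇌ RIR) and K5 to the second (RIR + I ⇌ RIRI);
with K3 ≫ K2 ≫ K5 this yields the clinically observed *paradoxical
activation*: a low inhibitor dose increases the active pool A = RR + RIR
before higher doses suppress it.

Free inhibitor is clamped (an experimental titration), total Raf is
conserved. Free monomer solves

    2·K1·(1 + K3·I + K3·K5·I²)·R² + (1 + K2·I)·R − R_tot = 0,

taken in the cancellation-free root form `R = 2·R_tot / (b + √(b² + 4aR_tot))`,
with the linear fallback `R = R_tot/(1 + K2·I)` when the quadratic
coefficient underflows (K1 below ~1e−300). All concentrations are μM, all
constants μM⁻¹; there is no unit layer. Mass conservation holds to better
than 1e−10·R_tot and the solver matches an independent bisection on the
conservation residual to 1e−8 relative (both property-tested).

Observables: occupancy Ȳ = (RI + RIR + 2·RIRI)/R_tot and activity
A = RR + RIR. With the reference constants (K1, K2, K3, K5) =
(0.04, 20, 4000, 0.1) μM⁻¹ and R_tot = 50 μM, A(0) = 15.24 μM.

## Synthetic study conditions

The generators *are* the study conditions of the built-in case studies;
their defaults are fixed and not tuned per run.

* **Quantitative**: occupancy at 15 log-spaced I values with additive
  Gaussian noise, sd 0.1, not clipped to [0, 1] (the noise is additive on
  the measured fraction, so values slightly outside the unit interval are
  legitimate data).
* **Qualitative**: noiseless activity labels at 20 log-spaced I values —
  "0" when |A(I) − A(0)| < ε with ε = 1.5 μM, otherwise "+"/"−". Each label
  becomes one constraint on A(I) − A(0) with weight C_i = 0.03, a value that
  puts the two datasets' objective contributions on a comparable scale.
* **I range**: both grids span [1e−5, 1e2] μM. The range is dictated by the
  physics of the reference system: its occupancy runs from ≈0.01 to ≈0.97
  over exactly this window, which is what a binding-curve titration would
  cover. Under these conditions the labels read 0…0/+…+/0/−…− along
  increasing I (basal, paradoxically activated, crossover, inhibited). A
  grid starting at 1e−3 — where occupancy is already 0.32 — leaves the
  upper shoulder of the K3 profile unconstrained and makes two-sided K3
  intervals unobtainable; spanning the transition is therefore part of the
  study design, not a tuning knob.
* **Polynomial demo**: y₁ = a·x² − b·x + c and y₂ = d·x + e with ground
  truth (0.5, 3, 5, 1, 1.5); labels are the sign of y₂ − y₁ at n+1 equally
  spaced points of [0, 10]. When an intersection falls exactly on a grid
  point (|y₁ − y₂| ≤ 1e−9, which happens for the ground truth whenever 1
  and 7 are grid points, e.g. n = 10 or n = 100), the generator reports a
  tie label "0" and the interval logic treats it as an exactly located
  root. Forcing a sign onto an exact tie would claim an observation that
  was never made and systematically biases the recovered bounds half a grid
  cell to one side; with the tie convention the dense-label limit converges
  to the generating coefficients.

What the generators do **not** emulate: biological replicates or
heteroscedastic error in the binding curve, mislabelled qualitative calls,
and inhibitor depletion (free I is exact, not inferred from total). Passing
tests show the machinery recovers parameters under the stated noise model;
they do not certify robustness to label noise or systematic error.

## Optimization

* **Differential evolution** (`de_fit`) wraps
  `scipy.optimize.differential_evolution`: strategy `best1exp`, up to 1000
  iterations, population 15, seeded and fully deterministic. Default search
  range for the Raf study is [1e−4, 1e4] per parameter on a *linear* scale;
  log10 scaling is available per parameter (8 decades in linear scale biases
  sampling toward large values, but linear is the default).
* **Scatter search** (`scatter_search_fit`) is implemented natively:
  a reference set of 12 members; per iteration one child for each ordered
  pair (12 × 11), each child drawn uniformly from the box centered on the
  better parent with per-coordinate half-width equal to the parent
  separation; out-of-range coordinates reset to the boundary; a child
  replaces *its own* parent only if strictly better, judged against the
  parent's pre-iteration objective so the outcome is independent of pair
  enumeration order. A member unimproved for 5 consecutive iterations is
  presumed a local minimum and replaced from a seeded Latin-hypercube queue
  drawn without replacement (refilled with a fresh seeded batch, with a log
  message, if exhausted; default size max(1000, 100·dims) — sized to the
  desk-scale problems here rather than a cluster run). The initial refset
  is the first 12 queue entries. The current refset best is exempt from
  stagnation replacement, which keeps the refset's best objective monotone
  non-increasing — an invariant the tests assert on every run.

## Profile likelihood

One parameter is fixed at each point of a grid (log-uniform for dose–
response constants: 100 points over [1e2, 1e5] for K3, [1e−3, 1] for K5)
and the remaining parameters are re-optimized with the same evolutionary
settings as the full fit. Each curve is normalized to zero by subtracting
its minimum; the confidence interval at threshold 0.15 is the range where
the normalized curve stays ≤ 0.15. Conventions:

* endpoints are linearly interpolated (on the grid's scale) between the
  straddling grid points rather than snapped to the grid;
* a side still at or below the threshold at a grid end is *censored* —
  reported as a one-sided bound (e.g. log10(K5) "<−0.6");
* the curve is not assumed unimodal: the interval is the hull of the
  outermost crossings, and interior excursions above the threshold raise a
  disconnected-region warning;
* with replicates r > 1, each grid point keeps the best of r independently
  seeded inner minimizations;
* an inner-optimizer failure at a grid point is recorded as missing, not
  fatal.

The threshold 0.15 is illustrative. Because the objective is not a
likelihood, no χ² calibration is attached to it; intervals are comparative
(quantitative-only vs qualitative-only vs combined), and the headline
observation is that the combined interval for log10(K3) (≈1.3–1.5 decades
across noise realizations at the default conditions) is contained in, and
substantially tighter than, either single-dataset interval (≈1.8–2.0
decades).

## Numerical and design choices

* Vieta system: the two root-bound intervals are sampled at midpoints of
  `grid_n` equal subdivisions, strictly inside the open intervals, so
  boundary-degenerate systems (e.g. a root at 0 forcing c = e) never enter;
  a pinned root (tie label) collapses its interval to the single point.
  Batched 5×5 solves; isolated singular pairs are dropped as infeasible.
* Monotone shrinkage of coefficient ranges with label count is exact for
  the underlying continuum but the sampled endpoints can jitter by about a
  grid cell between non-nested grids; tests allow exactly that slack.
* Determinism: every stochastic component (noise generation, DE, scatter
  search, replicate seeds) is driven by an explicit seed; derived seeds come
  from `numpy.random.SeedSequence`.
* Best-fit K3 on noisy data varies by noise realization (roughly
  log10(K3) ∈ [3.1, 3.8] across seeds at the default conditions) — the flat
  upper shoulder of the combined objective lets unlucky realizations drift;
  the profile widths are far more stable than the point estimate, which is
  the case for combining datasets in the first place.

## Limitations

* Only equilibrium (closed-form) models ship as adapters; the trajectory
  constraint kinds are exercised against synthetic time courses. Plugging
  in an ODE simulator means implementing the small `evaluate` contract
  (plus optional `evaluate_batch` for speed).
* Penalty weights C_i are hand-chosen, inherent to static penalty methods;
  the practical recipe is to normalize C_i by the output's order of
  magnitude and adjust the qualitative/quantitative balance by optimizing
  each term alone first.
* No SBML/BNGL import; models register through the Python adapter registry.
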