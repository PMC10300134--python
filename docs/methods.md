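# Methods

## Model

Each cell's reporter is described by a linear two-compartment ODE with
step promoter activation:

    dU/dt = b + i·S(t) − (f + d)·U        (unfolded reporter)
    dF/dt = f·U − d·F                     (mature, fluorescent reporter)
    S(t)  = H(t − t_on) · H(t_end + t_off − t)

Units: minutes and maxGAL1 (1 maxGAL1 = mean stationary expression of a
single-copy GAL1 promoter reporter).  The model is deterministic per
cell; cell-to-cell variability enters through the parameters, not
through chemical noise.  Assumptions worth keeping in mind:

* promoter activity is all-or-none with sharp lags (no graded
  dose-response inside one experiment);
* maturation is first order with a rate f fixed from an independent
  measurement — the time courses alone cannot separate f from d;
* degradation-and-dilution is a single first-order loss acting equally
  on both compartments.

Before induction the cell sits in the basal steady state
(U, F) = (b/(f+d), f·b/(d(f+d))).  The exact ON solution is

    F_ON(t) = (f/d)(i+b)/(f+d) − i/(d(d+f)) · e^{−dτ} (f + d(1 − e^{−fτ})),
    τ = t − t_on,

and the OFF solution is its mirror image when induction has reached
steady state.  The implementation generalizes the OFF branch to
shutoffs from a *non*-stationary state by chaining the exact ON state
at the shutoff time into the relaxation — necessary because for slow
systems (d ~ 10⁻³ min⁻¹) a 3.5-h induction is nowhere near stationary.
Both branches are validated against direct numerical integration
(`integrate_model`, DOP853 with rtol 1e-10, split at the two switch
times) to < 1e-6 relative error over broad random parameter draws.

Degenerate rates (|d| or |f+d| below 1e-8 min⁻¹) make the closed forms
singular; those calls raise and the caller falls back to the
integrator.

## Staged fitting

Stage order: basal plateau → decay (d) → rise (i, t_on) → fall (t_off)
→ back-computed b.

* **Basal plateau** — mean fluorescence over −60..0 min, or the single
  t = 0 sample for light-induced systems imaged only from induction
  onset (blue imaging light would itself induce them earlier).
* **Decay** — nonlinear least squares of F₀·e^{−d(t−t₀)} + floor over
  270..390 min (≥ 4 maturation half-times after shutoff), floor fixed
  at the basal plateau.  d is unconstrained: d < 0 is the exclusion
  signal for cells that rise after shutoff.  The residual maturation
  transient biases d low by ~3% at the default parameters; this is an
  accepted property of the windowed single-exponential procedure, and
  it propagates into a ~1-min early bias of the fitted t_off.
* **Rise / fall** — one-sided least-squares fits with i, t_on, t_off
  bounded below by zero.  Two model bases are provided:
  * `basis="taylor"`: the classic second-order Taylor forms,
    plateau ± (i·f/2)(t − lag)².  Their truncation error grows like
    (2d+f)·τ/3, which reaches ~100% forty minutes after onset at the
    default rates — fitted this way, i is biased low severalfold
    whenever the window extends well past the lag.  The basis is kept
    because it is the standard simplification and needs no d estimate.
  * `basis="exact"` (default): the exact solutions, which are equally
    linear in i once the lag is fixed, using d from the decay stage.
    Unbiased on model-generated data at no extra cost.
* **Optimizer** — both bases are linear in the amplitude for a fixed
  lag, so the fits use variable projection: closed-form nonnegative
  amplitude inside a bounded 1-D lag search (1-min coarse grid, Brent
  refinement, xatol 1e-8).  This reaches the same least-squares optimum
  a simplex search would, deterministically and roughly 20× faster —
  which matters because the bootstrap machinery runs ~10⁵ fits.
* **Media delay** — for chemically induced systems the ~170 s transport
  time of medium to the observation chamber is subtracted from both
  fitted lags (clamped at zero).  Whether the original procedure
  corrected t_off as well as t_on is ambiguous; both are corrected
  here and the flag is per-system configuration.
* **Exclusion rules** — cells with fitted d < 0, or with fluorescence
  at induction onset strictly exceeding the level one hour after
  shutoff (read at the nearest sampled timepoints), are excluded with
  reasons; equality keeps the cell.
* **Population-average fits** — the lags are particularly sensitive to
  single-cell fluctuations, so t_on/t_off are reported from the fit of
  the pointwise mean trace, with 95% percentile-bootstrap CIs from
  resampling 100 single-cell timecourses (with replacement), averaging,
  refitting, and taking the 2.5th–97.5th percentiles over 1000
  resamples.  Resamples with undefined lags are dropped and counted.

## Synthetic experiments

The generator emulates the benchmark design: ≥ 1 h pre-induction
imaging, 3.5 h induction, 3 h post-induction, 10-min sampling
(−60..390 min), with an optogenetic variant that starts observing at
t = 0.  Per cell it draws rates lognormally (the draw's mean equals the
central value; lognormal keeps rates positive and produces the
right-skewed parameter distributions seen in real populations) and lags
from a zero-truncated normal, integrates the model exactly, then adds a
cell-constant autofluorescence offset and i.i.d. Gaussian measurement
noise per timepoint.  Everything is deterministic given the seed, and
the per-cell ground truth is returned for recovery scoring.

Defaults, chosen once as a realistic mid-range condition and then left
alone: central parameters b = 1e-4, i = 1e-3 maxGAL1·min⁻¹, f = 0.035,
d = 0.017 min⁻¹, t_on = 10, t_off = 5 min; CV 0.2 on b and i, 0.1 on d,
0.2 on the lags, f common to all cells (the fit treats it as a known
constant); measurement noise SD = 5% of the central induced steady
state.  The maturation default 0.035 min⁻¹ corresponds to a ~20-min
maturation half-time of a yellow reporter; a red reporter with an
11.8-min maturation time is carried in the preset table.

What the generator does **not** emulate: nonmonotonic mid-course
dynamics (metabolic feedback of galactose/methionine/phosphate
systems), photobleaching, segmentation artifacts, cell-cycle-coupled
expression, or correlated noise.  Passing the recovery tests therefore
shows the estimation chain is correct and well-conditioned for
step-like responders at realistic noise — not that every real system's
mid-course dynamics are fit well (they are explicitly out of the
model's scope).

Pathological-cell injection replaces a chosen fraction of cells with
the two failure modes the exclusion rules target: traces still rising
after shutoff (promoter never off → fitted d < 0) and traces brighter
at induction onset than one hour after shutoff.

## Population statistics

* **CV** — sample SD (n−1 denominator, as everywhere in the package) /
  mean, at the last induction timepoint.
* **Noise scaling** — OLS of log₁₀ CV on log₁₀ mean across systems,
  with named exclusions; the slope's 95% CI uses the t distribution on
  the OLS standard error.
* **Violin summaries** — values beyond 2 SD of the mean become outlier
  dots; the bimodality coefficient (s² + 1)/k uses plain biased sample
  moments and non-excess kurtosis (that convention is what makes the
  reference values hold: 1/3 for a normal, 5/9 for uniform and
  exponential).  Strictly above 5/9 the sample is split at the Otsu
  threshold (256 histogram bins by default, ties to the lower edge) and
  the smaller of the two sides' bandwidths 0.8·std/n^(1/5) is used;
  otherwise the unimodal bandwidth.  A side with < 2 points falls back
  to the unimodal bandwidth with a note.
* **Event alignment** — event times are snapped to the nearest sampled
  timepoint so shifted grids stay commensurate; mean/SD are reported
  only where ≥ 2 cells overlap.
* **One-tailed z test** — difference of means over pooled per-sample
  SEs, P(Z ≥ z); identical samples give 0.5.
* **Calibration** — the maxGAL1 reference is the mean of the reference
  population's stationary distribution *including* outliers; cross-batch
  factors come from a shared construct measured in both batches.

## Growth

Doubling times come from log-linear regression of colony area over the
last hour of induction (150..210 min) — exact on noiseless
exponentials for any window — with a 90% CI propagated from the slope's
standard error.  The slope-1 decomposition's intercept is the mean of
(d − growth rate) over included systems; adding c to every d moves the
intercept by exactly c, and systems far below the line (turning off
slower than growth explains) show as negative residuals.  The
reporter half-life is ln(2)/intercept.

## Problem sizes and numerical choices

The validation workloads use: 100 random parameter draws for the
oracle-equivalence bound; a 200-cell population for recovery; 100
replicate experiments × 1000 bootstrap resamples × 120-cell populations
(sample size 100) for CI coverage; 200 seeded panels for the
noise-slope coverage; 50 samples of n ≤ 200 for the Otsu check.  ODE
tolerances are rtol 1e-10/atol 1e-14 for oracle comparisons and rtol
1e-9 inside the generator.  Lag searches run on a 1-min coarse grid
with Brent refinement; ties in the Otsu scan resolve to the lower bin
edge; bootstrap and all generators consume a single root seed through
independently spawned substreams.

## Known limitations

* The Taylor-basis fit reproduces the classic simplified procedure
  including its truncation bias; quantitative recovery claims hold for
  the exact basis only.
* The decay stage's single-exponential model leaves a small,
  parameter-dependent negative bias in d (and hence an early bias in
  t_off of order a minute at defaults).
* b recovered through the basal plateau is meaningless when d ≈ 0
  (systems that do not turn off); such cells are flagged, not fixed.
* The bootstrap treats cells as exchangeable; lineage or spatial
  correlation in real colonies would shrink its effective sample size.
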