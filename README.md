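# promkin

Kinetic benchmarking of inducible transcriptional systems from
single-cell fluorescence time courses.

## The problem

Inducible promoters and optogenetic transcription systems (GAL1pr,
MET3pr, CUP1pr, tetOpr, estradiol- and light-driven systems, ...) are
the workhorses of quantitative yeast biology, but their dynamic
properties — how fast they turn on and off, how leaky they are, how
noisy the response is across cells, and how induction conditions affect
growth — are rarely characterized in comparable units.  `promkin`
implements the analysis chain for such a benchmark: a minimal kinetic
model fitted in stages to single-cell fluorescence traces from
time-lapse microscopy, plus the population statistics built on top of
the fits.  A seeded synthetic-experiment generator with known ground
truth makes every stage verifiable offline.

## The model

Per cell, unfolded reporter *U* and mature (fluorescent) reporter *F*
follow

    dU/dt = b + i·S(t) − (f + d)·U
    dF/dt = f·U − d·F
    S(t)  = 1  if  t_on ≤ t < t_end + t_off,  else 0

with basal synthesis rate *b*, induced synthesis increment *i*,
maturation rate *f* (fixed from an independent measurement), combined
degradation-and-dilution rate *d*, and activation/deactivation lags
*t_on*, *t_off*.  Because activation is a step, fluorescence rises
purely quadratically at onset — the signature that distinguishes this
second-order model from first-order relaxation.  Fitting is staged:
basal plateau from the pre-induction window, *d* from an exponential
decay fit starting four maturation half-times after shutoff, then *i*
and the lags from one-sided fits around the switches (*i*, *t_on*,
*t_off* bounded below by zero), and finally *b* back-computed from the
basal plateau.  Fluorescence is expressed in maxGAL1 units (1 = mean
stationary expression of a single-copy GAL1 promoter reporter).

On top of the fits: percentile-bootstrap confidence intervals for the
lags (resampled population averages), expression-noise scaling
(log₁₀ CV vs log₁₀ mean across systems), bimodality-aware violin
summaries (outliers beyond 2 SD, bandwidth 0.8·std/n^(1/5), bimodality
coefficient (s²+1)/k with 5/9 as the threshold, Otsu split), colony-area
doubling times, and the slope-1 decomposition of *d* into growth
dilution plus active degradation.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a
synthetic experiment (200 cells, 10-min sampling from −60 to 390 min,
induction 0–210 min, 5% measurement noise):

```sh
python analysis/01_simulate_population.py
python analysis/02_fit_kinetics.py
python analysis/03_population_statistics.py
python analysis/04_growth_turnover.py
```

Output of the fitting step (seed 1):

```
fitted 200 cells, excluded 0
population-average fit vs. generator truth:
       b: fitted 9.108e-05   true 0.0001
       i: fitted 0.00091843   true 0.001
       d: fitted 0.015949   true 0.017
    t_on: fitted 9.2326   true 10
   t_off: fitted 3.7944   true 5
```

The fitted induction speed *i* and basal rate *b* land within ~10% of
the generator's truth, the lags within ~1–2 min; *d* is a few percent
low because the single-exponential decay fit still carries a trace of
the maturation transient (see `docs/methods.md`).  The statistics step
then reports, e.g.

```
bootstrap lag CIs (95%, 1000 resamples of 100 cells): t_on [7.42, 11.05] min, ...
noise scaling across 13 systems: slope -0.305 (95% CI [-0.358, -0.251]), R^2 0.935
```

and the growth step recovers the active-degradation intercept of the
slope-1 decomposition (0.00734 min⁻¹ on this seed, truth 0.0072) and
the implied reporter half-life ln(2)/intercept ≈ 94 min.

All tables land under `results/analysis/`.

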