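# Methods

`pupmonitor` reimplements, as a tested pipeline over synthetic data, the
analysis chain used in long-term fur seal pup monitoring programmes:
mark-recapture abundance estimation, body-condition indices, linear
condition models with information-criterion selection, and smooth-trend
inference on the abundance series.

## Mark-recapture abundance

Each colony-year has one marking event (M pups marked) followed by Q
replicate recapture counts. Replicate *i* sees Ci pups of which Ri are
marked and yields the Chapman-corrected ("modified") Petersen estimate

    Pi = (M + 1)(Ci + 1) / (Ri + 1) − 1 ,

which is nearly unbiased when M·Ci comfortably exceeds 4N and stays
finite at Ri = 0. The colony-year estimate is the arithmetic mean P of
the Pi, with

    SE = sqrt( Σ (Pi − P)² / (Q (Q − 1)) ) ,

algebraically the sample standard deviation of the Pi over √Q.
Assumptions: closed population over the ~1-day marking-to-recapture
window, zero tag loss (marks are fresh), full mixing of marked and
unmarked pups between replicates, and replicates independent given N and
M. Ambiguous mark/no-mark sightings are simply absent from Ci; no
correction or imputation is applied.

**Confidence intervals.** The interval is P ± q·SE truncated below at 0.
Because SE comes from only Q (typically five) replicate estimates, q is
by default the Student-t quantile on Q − 1 degrees of freedom: with the
normal quantile the interval covers true abundance only ≈88% of the time
at Q = 5 (P(|t₄| < 1.96) ≈ 0.878), versus ≈95% with the t quantile, as
the simulation checks in the test suite measure. A z-quantile interval
remains available (`ci_method="normal"`). Single-replicate sessions
report the mean with SE and CI marked unavailable — a zero SE would
misrepresent certainty.

**Percent-change arithmetic.** Period change is 100·(end − start)/start.
Consecutive period changes compose multiplicatively
(Π(1 + cᵢ/100) − 1), and the "annual average" change over n years is the
geometric rate 100·((end/start)^{1/n} − 1); both choices reflect that
declines act multiplicatively, and the compound of printed period
declines then reproduces printed whole-study totals. Dead-pup counts are
summarised as 100·dead/(dead + live), kept out of the mark-recapture
arithmetic.

## Body condition

* **BCI1** = mass/length (kg/cm).
* **BCI2** = observed mass / expected mass, with expected mass from the
  ordinary least-squares power law fitted on the pooled reference set
  (all pups, all colonies, all years): ln ExpM = a + b·ln Length. Over
  the exact fitting set the OLS log-residuals sum to zero, so the
  geometric mean of BCI2 is identically 1 — colonies and years are
  scored against the study-wide mass-at-length relationship. The
  reference set can be restricted via the `fit` argument.

A colony-year is classified *better than expected* iff the arithmetic
mean of its pups' BCI2 strictly exceeds 1 (the mean of ratios, not the
ratio of means; a mean of exactly 1 classifies as worse). Plausibility
windows of 1–20 kg and 40–120 cm, padded outward from observed field
ranges, reject corrupt records at load time with a logged warning. Day
of measurement is counted from 1 January of the (later) season year, so
the late-January survey window sits around days 20–40 and the day
coefficient is in kg per calendar day.

## Condition models and AICc

Pan-colony models regress mass or BCI1 on Year (categorical — year
effects are not monotone), Sex, Colony and Day (numeric), with optional
pairwise interactions among included main effects; candidate structures
are capped at 60 estimated parameters. Models are ranked by

    AICc = −2 logLik + 2k + 2k(k+1)/(n − k − 1) ,

with the full Gaussian log-likelihood (variance profiled out; the
additive constant cancels in rankings) and k counting the mean
parameters plus the error variance. Exact ties go to the earlier
candidate; unfittable or oversized candidates are annotated in the
ranking rather than aborting selection; fits too small for the AICc
correction report NaN. Baselines are the alphabetically first colony,
the earliest year and female sex. Unknown-sex pups are kept for the
condition indices but excluded from any model containing a Sex term.

**Day standardisation.** Within single colonies the spread of
measurement days is too small to identify a day slope, so per-colony
models fix the Day coefficient at the pan-colony estimate: the response
is offset by −day_effect·(day − reference day) and a Year(+Sex) model is
refit — an exact constraint with no tuning. Standardised yearly means
are predictions at the reference day (default: the data-wide median
measurement day) under a 50/50 sex mix, with delta-method standard
errors; a reference day outside the observed range warns rather than
errors. Inter-survey percent change uses the ordinary period formula on
these means.

**Mass–abundance correlation.** Standardised mass at survey *t* is
paired with the abundance change from the previous survey
(abundance_t − abundance_{t−1}); each colony's first survey has no pair.
Pearson's r with the two-sided t-transform p-value is reported; raw
p-values, no multiplicity adjustment.

## Trend smoothing and turning points

Abundance-vs-year trends are penalized cubic B-spline smooths (a
one-smooth GAM) minimising ||y − Xβ||² + λ β'Sβ, where S is the exact
integrated squared second derivative of the spline,
S_ij = ∫ B_i''B_j'' dx (3-point Gauss rule per knot span, exact for the
piecewise-quadratic integrand). The null space of this penalty is
exactly the straight lines, so linear data are reproduced exactly at
*any* λ — a coefficient-difference penalty on clamped knots would not
have this property, which is why the integral penalty is used. λ is
chosen by GCV (default) or a REML-type criterion; basis dimension
defaults to 10 basis functions on the observed year range, in line with
the effective degrees of freedom (≈7–8) such series exhibit.

Families: Gaussian/identity, and gamma/log via penalized IRLS (for that
link the working weights are identically 1; λ is re-selected each
iteration, convergence at 1e-10 on the linear predictor, 100-iteration
cap with diagnostics). Gamma fits are strictly positive by construction.

Inference uses the Bayesian posterior covariance
V = (X'X + λS)⁻¹·scale with scale = RSS/(n − edf) (Pearson-based for
gamma). Intervals use the Student-t quantile on n − edf degrees of
freedom — the same small-sample argument as for the recapture CI; with
a few dozen surveys the z interval measurably undercovers. Curve
intervals are reported on the response scale (exponentiated for
gamma/log); the first derivative — the spline basis differentiated
analytically — and its interval are on the linear-predictor scale, with
an optional posterior-simulation interval (coefficient draws) as a
cross-check of the delta method.

A **turning point** is an adjacent-grid-pair sign change of the
derivative point estimate (grid step 0.25 year), reported as the
bracketing year pair rather than an interpolated crossing time, and
flagged *significant* when the derivative interval excludes zero on at
least one flank of the change. **Significant periods** are maximal grid
runs whose interval excludes zero, labelled by sign. A degenerate-input
guard ignores derivative magnitudes below 1e-8 of the coefficient scale
so that noiseless data (where the posterior scale collapses) do not
produce spurious "significant" float-level wiggle. Estimate SEs are not
used as fit weights by default (the mean estimates are smoothed
directly); weighting is out of scope.

**Basis adequacy.** Coverage statements for the pointwise intervals
presuppose the basis can represent the truth: knots must be clearly
finer than the truth's features (extrema spacing, kinks). The replicated
coverage check in the tests therefore uses 12 basis functions for a
period-14 sinusoid, and kink localization uses 18; with an undersized
basis the intervals inherit approximation bias no calibration can
absorb.

## Synthetic data generator

The generator defines the study conditions for every downstream check.
Per colony, true abundance follows

    N(t) = round( baseline · e^{−rt} · (1 + A sin(2πt/T)) · Π drops ) ,

floored at 0: a long-term exponential decline, a quasi-cyclic component
(default A = 0.25, T = 14 y), and episodic single-season multipliers
(default 0.6–0.75 at seasons 2000 and 2023). The default three-colony
world uses baselines 850/300/900 and decline rates 0.054/0.0366/0.0269,
calibrated so compound declines from each colony's recorded maximum land
near 84/71/61% over 35 seasons, with one island colony carrying 12.7%
expected pup mortality against 2.3–3% elsewhere.

Sampling: M = round(0.5·N) marked (the >50% marking aim), five
replicates with Ci ~ Binomial(N, coverage 0.3) and
Ri ~ Hypergeometric(N, M, Ci); dead ~ Binomial(round(N/(1 − m)), m) so
the expected dead fraction of total pups equals m. Biometrics: length ~
Normal(73.5 cm, 4 cm); mass = exp(a + b ln L + ε) + 0.69·I(male) +
0.04·(day − 30) + colony offset (0/−0.14/−0.75 kg) + year effect
(sd 0.3 kg), truncated positive, with log-noise sd 0.1; days uniform on
20–40, 120 pups measured per colony-year. Both sexes share one length
distribution deliberately: the 0.69 kg sex effect is a model-scale gap,
and a sex-specific length mean would leak the allometric length
difference into the fitted sex coefficient, leaving no well-defined
estimand to recover. The `coefficient_recovery_config` scenario
additionally switches year effects off so coefficient sampling
distributions match the fitted model's iid assumption exactly.

Turning-point ground truth is defined on the *drop-free* smooth
component of the trajectory: an episodic drop is a transient shock, not
a trajectory turning point, and in an annual series it produces
down/up/down sign triples no smoother can resolve. Truth points within
2 years of a drop are flagged `shock_adjacent` and excluded from the
±1-year recovery guarantee.

All randomness descends from one root seed through
`SeedSequence([seed, colony_index, year_index, stream_id])`, so any
colony-year and stream regenerates independently and identical configs
give byte-identical output tables.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no individual identity or pup growth
between replicates, no behavioural response to marking (trap-shyness),
no spatial structure or sector effects within colonies, no observer or
measurement-device error beyond the stated noise terms, no environmental
covariates driving the trajectories (the quasi-cycle is phenomenological),
and year effects independent across colonies rather than regionally
correlated. Real series also mix survey methods across decades; the
generator holds the design fixed.

## Pipeline

`run_pipeline` executes simulate → estimate → condition → models → trend,
writing every intermediate CSV plus a JSON manifest (config, versions,
seed, per-stage status); a failed stage halts downstream stages but
preserves completed outputs, and schema violations fail fast naming the
offending colony-year. `summary_report` renders estimates
integer-rounded with CIs in parentheses, percentages to one decimal, and
a period-decline table whose compound totals are recomputed from its own
period rows; every reported number traces to a CSV cell. The decline
table splits each colony's series at the recorded maximum and a split
year (default 70% through the series) to mirror two-period reporting.

## Known limitations

* The smoothing parameter is selected pointwise per series; no
  simultaneous (across-the-function) intervals, so significant-period
  boundaries are pointwise statements.
* The gamma IRLS re-selects λ each iteration (performance iteration),
  which can cycle on pathological series; the iteration cap surfaces
  this as an error rather than silently accepting a non-converged fit.
* AICc uses the Gaussian likelihood also for BCI1 (a ratio), as in the
  modelling tradition this follows.
* Mean-of-ratios colony-year BCI2 classification; the ratio-of-means
  alternative is not implemented.
* The per-colony day effect is assumed equal to the pan-colony value,
  an identifying restriction rather than a tested hypothesis.
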