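# Methods

## The question and the design

Per-gene prognostic screening asks, for each somatically mutated gene,
whether mutant and wild-type patients differ in overall survival. The
screen's yield depends on cohort size: small cohorts contain too few
mutant carriers and too few deaths to power the log-rank test, so
independent studies of the same disease recover almost disjoint gene
lists. `progsat` quantifies this with a saturation design:

1. fix a cohort (real or simulated) of N samples with D observed deaths;
2. choose a grid of subsample sizes n₁ < … < n_k (default 5%–95% of N in
   10 equal steps);
3. at each size draw R random subsamples without replacement (default
   R = 100), screen every gene in each subsample, and record the number
   of significant genes (p < 0.05, strict) and the subsample's death
   count;
4. summarise per size as mean ± standard error (SD/√R) of the
   significant-gene count, the mean events number, and the fraction of
   replicates with ≥ 1 hit;
5. fit N = a·Xᵇ to the mean count (vs. size and vs. mean events) and a
   logistic CDF to the ≥1-hit probability, and invert the logistic to
   minimum-size requirements.

Replicates are drawn independently at each size (no nesting of smaller
subsamples inside larger ones). Subsamples that happen to contain zero
deaths are retained with a count of 0 rather than redrawn — the log-rank
test is undefined there, so no gene can be significant; redrawing would
bias the small-size levels toward event-rich subsamples.

## The screening test

The two-group log-rank statistic accumulates, over distinct event times
t with d deaths among n at risk (n₁ of them mutant, d₁ mutant deaths):

* observed O = Σ d₁, expected E = Σ d·n₁/n,
* variance V = Σ d·(n₁/n)(1−n₁/n)·(n−d)/(n−1) (the hypergeometric
  variance with tie correction; a time with n = 1 contributes nothing),

giving χ² = (O−E)²/V referred to χ²(1), with direction sign(O−E): +1
means mutants die faster. Censored samples at an event time are still at
risk at that time (censoring is ordered after events). Genes mutated in
fewer than `min_mutant` samples (default 5, the conventional floor in
mutation-survival workflows and exposed as a parameter) or in every
sample are reported untested; so are genes whose comparison is
degenerate (V = 0, e.g. a subsample without deaths). The screen is
implemented as a single vectorised pass over all gene columns; tests
verify exact agreement with a naive per-event-time tally, with an exact
permutation oracle in distribution, and with lifelines. Kaplan–Meier
curves are delegated to lifelines. No multiple-testing correction is
applied: the discovery count deliberately uses the raw p < 0.05 rule,
so at large sizes part of the count is false positives at rate α per
tested gene (that is a property of the screening practice being
analysed, not a bug).

## Curve fits

**Power law.** The default fit is ordinary least squares of ln N on
ln X (a = exp(intercept), b = slope), the convention behind typical
"best-fit trendline" captions, with R² reported on the log scale and
labelled as such. Sizes with zero mean count carry no information on
the log scale and are excluded (logged), rather than offset by +1. A
nonlinear least-squares alternative on the linear scale is available
(`fit_scale="linear"`), initialised from the log-log solution.

**Logistic CDF.** F(x) = 1/(1+exp(−(x−μ)/s)) is fitted by (optionally
weighted) least squares with scipy's Levenberg–Marquardt/TRF, initialised
from the empirical median crossing (μ₀) and the 25th–75th crossing
spread (IQR of a logistic = 2s·ln 3), with s bounded positive; the fit
is deterministic given its inputs. Identical probabilities at all sizes
leave μ unidentifiable and raise an error.

**Inversion.** For a target probability p < 1 the minimum size is
⌈μ + s·ln(p/(1−p))⌉. A "100% probability" target is operationalised
empirically — the smallest grid size at which every replicate, there and
at all larger sizes, produced at least one hit — because the logistic
attains 1 only asymptotically; outputs flag this rule. Cohort sizes
convert to events numbers by the hypergeometric mean n·D/N rounded half
up (`expected_events`), the expected death count of a uniform
without-replacement subsample.

## The synthetic cohort generator

Real cohorts of this kind are not publicly deposited, so the generator
emulates their structure; its defaults are the study conditions the
analysis assumes.

* **Mutation frequencies**: truncated Pareto on [0.005, 0.9] with tail
  exponent 2.33. The exponent was calibrated analytically (closed-form
  truncated-Pareto survival function) so that a 14,000-gene exome
  yields ≈ 65 genes above 5% mutation frequency — the reported spectrum
  shape for ESCC — with rare genes dominating. Indicators are
  independent Bernoulli draws per sample and gene.
* **Survival**: exponential baseline with rate ln 2 / median, median
  `median_survival_months`; each mutated prognostic gene multiplies the
  hazard by its hazard ratio (proportional hazards). The first
  `n_prognostic` genes are prognostic (documented convention), with a
  shared HR by default and per-gene vectors accepted; their mutation
  frequency can be pinned (`prognostic_freq`, default 0.20, a realistic
  recurrently-mutated-driver frequency) so planted effects are
  detectable by design.
* **Censoring**: administrative only — censoring time = fixed follow-up
  plus a uniform accrual offset on [0, accrual]; no loss to follow-up.
  This is the simplest mechanism reproducing the target event fractions
  and median follow-up times.
* **Stage presets** (`make_fixture`): `stageII-like` (200 samples ×
  500 genes, 5 prognostic genes with HR 2.5, baseline median 158.1 mo,
  accrual 24 + follow-up 22 mo) targets an event fraction of
  77/222 ≈ 0.347 and ≈ 34 months median follow-up; `stageIII-like`
  (165 samples, baseline median 47.25 mo, follow-up 15 mo) targets
  99/165 = 0.60 and ≈ 27 months. The baseline medians were solved from
  the closed-form event-probability of the exponential/uniform-censoring
  model *marginalised over the planted drivers* (a binomial mixture over
  carrier counts), since mutated drivers shorten survival and raise the
  cohort-wide death fraction above what the baseline alone would give.
  `null-cohort` (HR = 1 everywhere) and `one-strong-gene` (one driver,
  frequency 0.25, HR 3) support calibration and power tests.
* **Reproducibility**: a cohort is a pure function of its config
  (including the seed). The saturation engine spawns one child RNG
  stream per (size, replicate) from the master seed, so tables are
  byte-identical across runs and execution orders. An optional
  rounding switch (`round_times_to`) discretises times to exercise tie
  handling.

What the generator does **not** emulate: co-mutation structure (gene
indicators are independent), non-proportional or time-varying hazards,
loss to follow-up, stage mixtures, or any nucleotide-level detail.
Passing tests therefore show that the pipeline behaves correctly under
the stated model, not that real cohorts follow an exponential hazard or
a Pareto spectrum.

## Numerical and design choices

* Strict inequality p < 0.05; a tie at exactly 0.05 is not significant.
* The size grid rounds N×fraction to integers, de-duplicates, and floors
  at 2; the run manifest records the grid actually used.
* Power-law fits use per-size means (matching the mean ± SE
  presentation), not per-replicate points.
* At the full cohort size every "subsample" is the whole cohort, so the
  ≥1-hit probability there is exactly 0 or 1.
* Degenerate inputs: empty survival vectors, non-positive times,
  one-group comparisons and unidentifiable logistic fits raise
  `ValueError`; pipeline stages re-raise with a stage label.

## Problem sizes

The shipped analyses run the design at desk scale: 200-sample ×
500-gene cohorts, 8 grid levels × 50 replicates, chosen so a full
saturation run completes in about a second while leaving the growth
curves' shapes clearly resolved (Monte-Carlo SE of the per-size mean
count ≈ 0.1–0.2). The engine itself is vectorised and handles
exome-scale gene counts (14,000) at the default 100 replicates.

## Limitations

* Scaled-down synthetic runs reproduce the *qualitative* laws (power-law
  growth, logistic discovery probability, events-number primacy), not
  the specific fitted constants of any real cohort; exponents depend on
  the planted effect structure.
* The log-log R² and the fitted exponent are sensitive to the smallest
  grid sizes, where counts are near zero and log-scale noise is large.
* The χ²(1) reference for the log-rank statistic is asymptotic; at very
  small subsample or mutant counts its p-values are approximate (the
  test suite quantifies the deviation against exact permutation nulls).
* The empirical 100% rule depends on the replicate count: with R
  replicates it certifies a discovery probability of roughly ≥ 1−1/R,
  not literally 1.
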