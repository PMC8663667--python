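# Methods

This note documents the models, conventions and design choices behind
`smglyc`, and what the synthetic cohorts do and do not emulate.

## Glycemic control: Rosendaal A1c%TIC

A patient-year of HbA1c labs is interpolated onto a daily grid: every
calendar day between two successive measurements gets the chord value
between them, and days at a measurement date get the measurement exactly.
A1c%TIC is `100 × (days with value < threshold) / (days in span)` with the
control threshold at 8.0% HbA1c. The inequality is strict: a day sitting
exactly at 8.0% is *not* in control, and in the good/poor/neither outcome
classification such days count toward neither side.

Two denominator conventions are provided. The default, `covered`, spans
the first to the last in-year measurement — the standard convention for
time-in-range statistics, which avoids inventing values outside the
observed period. `full` extends the first and last measurements outward as
constants to cover the whole calendar year. A single in-year measurement
yields a degenerate one-day span (TIC 0 or 100) rather than dropping the
patient; `n_measurements` is carried in the summary so downstream users
can filter. Leap years use their true length. The sampling classifiers use
the unweighted mean of the raw in-year labs (not the interpolated curve):
"baseline uncontrolled" is mean > 8.0 *and* TIC < 25%; outcome control is
good when TIC ≥ 75%, poor when above-threshold time ≥ 75%.

Numerically, interpolation is exact linear algebra (`np.interp`), and the
test suite checks it against an independent day-by-day enumeration oracle
to 1e-9 on hundreds of random series. A day whose chord value lands
*exactly* on the threshold is a genuine tie; constructed series in tests
avoid placing crossings precisely on day boundaries except where the tie
behaviour itself is under test.

## SM exposure

Months-with-use counts distinct calendar months with at least one
**patient-sent** message; team messages never contribute to exposure, but
they do contribute to topic coding, since a patient engages with a thread
by reading as well as writing. Thread topic flags are the OR over the
thread's messages (so they are idempotent and monotone under added
messages), and patient-level indicators are the OR over threads. The
eligibility rules are calendar-window predicates: sustained use requires
two years in 2013–2015 each satisfying refill use, view/download use and
≥ 2 messages; current use requires ≥ 4 patient-sent messages between
2016-01-01 and 2017-06-30, both endpoint days inclusive. Timestamps are
compared naively in one timezone.

## DSMQ scoring

Items are answered 0–3; negatively worded items are reverse coded
(r → 3 − r); each subscale is scaled to 0–10 as
`sum / (3 × n_answered) × 10`; the composite is the mean of the four
subscale scores. The item→subscale map and reverse flags ship as a YAML
instrument definition (15 items across four subscales, one general item,
nine reverse-coded) and can be overridden, so the scoring engine is
correct under any instrument version. Missingness is prorated: a subscale
is scored if strictly more than half its items are answered, otherwise
that subscale — and therefore the composite — is returned as missing
(NaN), never as an exception.

## Moderated mediation

The mediator model regresses M on 1, X, W, X·W and covariates; the
outcome model regresses Y on 1, X, M and covariates. The outcome model
deliberately omits W and X·W — the moderation is first-stage only — with
a flag to include them. The conditional indirect effect at moderator
value w is `(a1 + a3·w)·b`, and the index of moderated mediation is the
difference across the two W levels, `a3·b·(w1 − w0)`; both identities are
asserted on every fit. Rural is coded 0 and urban 1 by default. Software
packages differ here (some code dichotomous moderators 1/2); the index is
invariant to any unit-spacing recoding, the coding is configurable, and
reports label conditional effects ("rural"/"urban") rather than exposing
codes.

OLS fits use statsmodels with classical SEs, two-tailed t tests on
n − p df, and 95% CIs; rank-deficient designs raise an error naming the
collinear columns (QR with column pivoting). Bootstrap inference draws
`n_boot` (default 5000) case resamples at the original n, refits both
models per resample through a batched normal-equations path, and takes
percentile CIs of the resampled statistics; significance is CI-excludes-
zero. The percentile interval (not BCa) is the default deliberately — it
is the common reporting convention for indirect effects. Resamples whose
Gram matrix is ill-conditioned (condition number above 1e10) are skipped
and counted; if more than `max_unusable_fraction` (default 10%) of
resamples are unusable the run aborts with diagnostics. Tiny datasets
with the full interaction design sit above that default intrinsically —
at n = 7 with a 3/4 moderator split, enumeration shows 31.5% of all
resamples are rank-deficient — so exhaustive-oracle comparisons raise the
threshold explicitly. Missing data are handled by listwise deletion with
the analyzed n reported.

## Descriptive statistics

Group comparisons default to the pooled-variance t test and the
uncorrected Pearson chi-square (the uncorrected statistic is the one that
reproduces the published diabetes-content comparison, χ² ≈ 6.34,
p ≈ .012; Yates and Welch variants sit behind flags). χ² equals the
squared two-proportion z statistic by identity, which the tests assert.
Income enters as a binary band split at $35,000.

## The synthetic cohort generator

The generator draws, per patient: exposure X from a beta-binomial on 12
trials matched to mean 6.7 / SD 3.1 months (a plain binomial cannot reach
that dispersion; the beta-binomial stays on the 0–12 support without
claiming the true population shape); rurality W with P(rural) = 0.51;
age from a truncated normal (66.4, SD 7.5, range 34–88); visit counts
from a negative binomial (mean 10.1, SD 7.8); income ≥ $35k with
probability 0.536. Latent M and latent TIC then follow the structural
equations with defaults at the published magnitudes (a1 = 0.04 at the
rural level, a2 = 0.49, a3 = −0.08, b = 10.38, c' = 0.09; intercepts
chosen so the population means land near 7.9 for M and 52.6 for TIC) and
are clamped to the instrument ranges [0, 10] and [0, 100].

Observables are constructed measurement-first: the message log realizes X
exactly (one active month set of size X, each with ≥ 1 patient-sent
thread); DSMQ items are the integer totals per subscale closest to the
latent M with a ±1 local search across subscales to cancel rounding
(worst-case composite error ≈ 0.1, empirically ≤ 0.25 including the test
bound); the lab series is built around a single threshold crossing placed
so that the forward Rosendaal computation returns the latent TIC to day
granularity (≤ ±2 points, verified by round-trip with bounded retries).
Measurement dates are anchored near the year's ends so the covered span
is long enough for day-granularity inversion.

**Residual scales.** `sigma_m` defaults to 0.8 (the observed composite SD
of ~0.9 is mostly residual). `sigma_y` defaults to 20, *not* the ~44
marginal SD a stratified half-good/half-poor-control sample shows: that
spread comes from a bimodal sampling design piled against the 0/100
bounds, which a linear structural model cannot reproduce — pushing the
residual that high forces ~25% of latent outcomes onto the clamp bounds
and the censoring attenuates the fitted b-path, invalidating parameter
recovery. At sigma_y = 20, under 3% of latent outcomes clamp and
recovery is clean. Consequently the synthetic Y SD (~20) is deliberately
smaller than a stratified study sample's.

**What the generator does not emulate**: the stratified good/poor-control
sampling (and hence the bimodal outcome distribution); the strong
positive correlation between SM use and in-person utilization seen in
real portal users (covariates are drawn independently of exposure);
free-text message content (topic flags are generated directly, with the
diabetes-topic share differing by rurality, 0.77 rural vs 0.67 urban at
the patient level); item-level DSMQ response noise (items are a
deterministic quantization of latent M). Passing tests therefore
demonstrate correctness of the measures and estimator under the assumed
structural model, not robustness to those real-data features.

## Problem sizes

The parameter-recovery suite runs 100 replicates at n = 450 with 1000
bootstrap resamples per fit (coverage of the true index lands at 97/100;
a null-structure sweep of the same size flags significance in 0/100), and
the exhaustive bootstrap oracle enumerates all 7⁷ resamples of an n = 7
dataset through multiset weighting. The analysis drivers use one cohort
of 446 patients with 5000 bootstrap draws.

## Reproducibility

Every stochastic step takes a seed; cohort generation derives
per-stage/per-patient streams from the config seed via `SeedSequence`
(CRC-tagged, process-stable), so identical configs yield byte-identical
CSVs. The pipeline writes a manifest with SHA-256 hashes of every
artifact; re-running with the same config reproduces the hashes.
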