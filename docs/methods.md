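# Methods

## The screening procedure

Each rat in a cohort of `n` is scored on three criteria after operant
ethanol training: persistence (mean active presses over the nine signaled
no-drug unavailability periods: 3 sessions x 3 four-minute periods),
motivation (progressive-ratio breakpoint, the last completed requirement of
`ratio_i = round(5 e^{0.2 i} - 5)`, averaged over 3 sessions) and punished
responding (mean presses with every reward paired to a 0.22 mA footshock,
3 sessions). Positivity on a criterion means the score lies in the
cohort's 66th–99th percentile window for that criterion; each criterion is
thresholded on its own distribution.

Numerical conventions (pinned so results are bit-stable):

- **Quantile**: linear interpolation, the p-quantile at rank `1 + (n-1)p`
  of the sorted sample (numpy's default). A degenerate all-equal
  distribution raises rather than classifying arbitrarily.
- **Boundary**: a score exactly equal to the lower threshold counts
  positive (the window is read as inclusive).
- **Above the 99th percentile**: counted positive by default, with a
  warning naming the rats (excluding the most extreme of 59 rats would
  contradict the reference group sizes); `above_upper_policy =
  "exclude_flagged"` provides the alternative reading.
- **Addiction score**: per-criterion z-scores use the sample SD (n-1
  denominator); the score is their sum and is zero-sum over the cohort to
  1e-9 relative tolerance.
- **Groups**: vulnerable iff at least 2 criteria (configurable).
- **Breakpoint reading**: "maximal presses to reach the final ratio" is
  ambiguous between the final requirement and cumulative presses; the
  final-requirement reading is adopted because the published group means
  (23–48) sit in the range of single requirements, far below plausible
  cumulative counts. The session aggregator recovers it from the PR
  session's reward count.
- **Persistence pooling**: pooling all 9 periods versus averaging within
  sessions first is a distinction without a difference for balanced data,
  and balance (exactly 3 sessions per test) is enforced.

## The generative model

The simulator's purpose is to produce cohorts with the statistical
structure the screen assumes, calibrated to the published summary
statistics of the reference 59-rat cohort.

**Latent layer.** Rat `i` has liability `L_i ~ N(0,1)` and anxiety
`A_i ~ N(0,1)` with `corr(L, A) = 0.7` by default (the anxiety latent is
oriented so higher values mean a more anxious phenotype; vulnerable rats
are therefore more anxious, and open-arm time decreases with it).
Criterion `j`'s latent is `x_ij = l_j L_i + sqrt(1 - l_j^2) e_ij`.

**Count layer.** Conditional on `x_ij`, the criterion score is Poisson
with log-normal mean `m_ij = exp(a_j + b_j x_ij)` (negative binomial with
size `theta_j` if configured; the feasibility bound
`e^{b^2}(1 + 1/theta) = (sd^2 - mu + mu^2)/mu^2 >= 1` is validated — the
published breakpoint moments leave room only for `theta >= ~79`, which is
why the Poisson-log-normal limit is the default). `a_j, b_j` are solved
from the configured marginal mean and SD, so moments are exact by
construction, and the count-level covariance has the closed form
`cov(s_j, s_k) = mu_j mu_k (e^{b_j b_k l_j l_k} - 1)`.

**Calibration.** The published score-criterion correlations
(0.794, 0.818, 0.641) invert, via
`corr(score, z_j) = (row sum of R)_j / sqrt(1'R1)`, into the
inter-criterion matrix with off-diagonals 0.594 / 0.195 / 0.249. The
closed-form covariance then inverts into the loadings: products
`beta_j beta_k = log(1 + r_jk sd_j sd_k / (mu_j mu_k))` are solved by
triple product and divided by the total slope `b_j`, giving
`l = (0.836, 0.954, 0.341)`. Marginal moments are the pooled cohort
moments of the printed group summaries: means (8.383, 34.019, 12.412),
SDs (5.238, 14.382, 9.073). Nothing is fitted; the calibration is an
exact inversion, and `calibrate_trait_config()` reproduces it for any
other target.

**Breakpoint quantization.** Breakpoint scores are snapped to the nearest
attainable PR requirement at generation time, so a noise-free session
realizes exactly the trait value and the session round-trip is the
identity. Quantization attenuates the persistence-breakpoint correlation
by about 0.01 — inside the ±0.02 recovery band.

**Sessions.** The session simulator emits 80 baseline conditioning
sessions (saccharine then ethanol phases) plus 3 test sessions per
criterion, with per-period rows for the no-drug test. Baseline response
rates drift: the liability-linked component ramps in over training, so
early sessions are uninformative about the eventual phenotype and
low-liability rats decline late in training (the late-training-only
correlation pattern is a qualitative calibration property, not a fit).
`session_noise` (default 0.25) scales between-session variability; at 0
the 3-session averages equal the configured scores exactly. PR sessions
record cumulative presses equal to the sum of completed requirements.

**Choice test.** Ethanol preference over fading saccharine
(0.2 ... 0.00625, 0% w/v; one caption in the reference prints 0.0062, the
Methods value 0.00625 is used) follows a logistic model: baseline log-odds
rise as saccharine fades, and the liability slope grows toward the water
end (`0.08 + 0.42 (1 - c/0.2)`), so groups separate only at low
concentrations. A per-rat taste intercept (SD 0.8) keeps the
score-vs-water-choice correlation moderate. `liability_effect = 0`
removes the group difference entirely.

**Elevated plus maze.** `open% = clip(23 - 22 A_i + N(0, 13^2), 0, 100)`,
with 8 of 59 rats dropped completely at random (the mechanism the
reference attributes to a technical failure; 51 observed, df 49).
Constants were calibrated by Monte-Carlo — once, before freezing — so
screened groups reproduce open-arm means near 30 / 12-15% and an unpaired
t averaging ~2.7 across replicate cohorts (printed: 30.36 / 11.99,
t = 2.65).

**Blood alcohol.** One-compartment first-order absorption with zero-order
elimination, `C(t) = peak (1 - e^{-k_a t}) - k_0 t` floored at zero, with
`peak = 0.95 g/kg` per 1 g/kg dose (per-rat SD 0.06), `k_a = 0.15/min`,
`k_0 = 0.0038 g/kg/min`, measurement SD 0.1. BAL is reported in g/kg (the
reference assay's convention; g/L is more common — output metadata carries
the note). The elimination rate is shared across rats by default: the
reference study's conclusion is precisely that groups eliminate alcohol
identically, and per-rat random elimination slopes also measurably inflate
the mixed-ANOVA group-test type-I rate above nominal. `group_effect = 0`
makes the group distributions identical.

**Randomness.** One root seed; the pipeline derives independent per-stage
streams via `numpy` `SeedSequence.spawn`, so runs are byte-identical for
identical configs.

## The statistics layer

- One-way ANOVA is the textbook decomposition; `anova_from_summary`
  rebuilds it from means/SEs/ns (`SD = SE sqrt(n)`,
  `SS_within = sum (n_i - 1) SD_i^2`) and equals the raw-data ANOVA
  exactly for unrounded summaries.
- Tukey-Kramer post hocs use the studentized-range distribution with the
  Kramer unequal-n correction (scipy); with two groups the adjusted p
  equals the pooled t-test p.
- The mixed (split-plot) repeated-measures ANOVA uses no sphericity
  correction by default, matching how these assays are conventionally
  reported; pingouin computes the decomposition (its Greenhouse-Geisser
  output is available from the same call path), with an internal textbook
  fallback for degenerate noise-free designs where 0/0 is read as F = 0.
  Between-group contrasts at each within level are Bonferroni-adjusted
  pooled t tests, Tukey being reserved for the one-way designs.
- Factor extraction is principal-component style on the Pearson
  correlation matrix: loadings are the first eigenvector scaled by
  sqrt(eigenvalue) (signed so their sum is non-negative), retention
  follows the eigenvalue-1 rule with ties at exactly 1.0 retained, and the
  variance share is `lambda_1 / trace` — identically 100 x the mean
  squared loading, which is why the printed loadings
  (0.819, 0.818, 0.641) and the printed 58% check against each other.
- p-values are reported to 4 decimals; the text report prints "< 0.0001"
  below that.

## What the synthetic data do and do not show

The generator reproduces the reference cohort's first two moments, its
inter-criterion correlation structure, the inflated 0-/3-criteria tails,
single-factor dominance, the anxiety-group difference and the null BAL
group effect. It does **not** emulate: event-level press timing,
within-session intoxication dynamics, body-weight growth, non-random
dropout, or the exact heteroscedasticity of the published punished data
(the printed 0-criteria SD of 2.5 presses is far tighter than any shared
log-normal count model matched to the pooled moments can produce — the
punished criterion's between-group F is consequently under-generated by
roughly a quarter relative to the printed 12.53). Passing tests therefore
certify the classification and statistics machinery and the distributional
shape of the cohort, not every conditional feature of real data.

Two further caveats. First, with the implied correlation matrix
(eigenvalues 1.73 / 0.87 / 0.40), the second eigenvalue of a 59-rat sample
correlation matrix exceeds 1 in roughly 7–9% of replicate cohorts — even
for exactly multivariate-normal latents — so single-factor retention at
n = 59 occurs in ~92% of cohorts, not ~100%; a single observed cohort
retaining one factor is entirely consistent with this. Second, the
reference report's two-way RM ANOVA degrees of freedom for the choice data
are internally inconsistent with its design (n = 42, 7 concentrations);
standard split-plot dfs are computed and no matching is attempted.

## Problem sizes

Monte-Carlo checks use n = 100,000 rats for correlation recovery (±0.02
bands), 300–400 replicate 59-rat cohorts for tail-inflation, retention and
F-recovery properties, and 300 replicates for the BAL type-I check —
sizes chosen so sampling error sits well inside each asserted band.
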