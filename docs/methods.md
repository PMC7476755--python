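# Methods

This note documents the statistical model behind each stage of the package,
the defaults and why they were chosen, what the synthetic-observer generator
does and does not emulate, and the numerical choices that affect results.

## Task and measures

In a spatial temporal-order judgment (TOJ) task two brief stimuli are
presented in quick succession, one on each side, and the participant reports
which side came first. The stimulus onset asynchrony (SOA) is signed:
negative means the left stimulus led. On *bimodal* trials the two stimuli
are in different modalities (visual–auditory or visual–tactile); the SOA is
then re-signed as `soa_visual`, positive when the visual stimulus led, and
the response is recoded as `visual_first`.

Three complementary bias/resolution measures are derived per participant:

- **PSS** (point of subjective simultaneity): the SOA at which the two
  stimuli are perceived as simultaneous. Positive PSS = the visual stimulus
  must lead to be perceived as simultaneous (vision perceived as slow).
- **'Visual first' bias**: |P(visual-first response) − 0.5| pooled across
  SOAs; the criterion analogue of the PSS, robust to outlying points on the
  psychometric function.
- **JND** (just noticeable difference): the SOA supporting 75% correct
  order reports; an inverse resolution measure.

## Observer model (synthetic data)

A participant is a cumulative-Gaussian observer with symmetric lapses:

    P(visual first | soa) = λ/2 + (1 − λ) Φ((soa − pss) / σ)

with `pss` the bias, `σ` the temporal imprecision and `λ` the lapse rate
(split λ/2 per response so the asymptotes are symmetric — the standard
psychometric convention). Unimodal trials use the same form over the
side-signed SOA with `pss = 0` and their own `σ`, since left/right bias is
not the object of study.

Mean reaction time on bimodal trials is a Gaussian bump centred on the
observer's PSS — decision uncertainty, and hence RT, is maximal where
perceived order is ambiguous:

    E[rt] = rt_baseline + rt_amplitude · exp(−(soa_v − pss)² / (2 rt_width²))

with iid Gaussian trial noise; unimodal RTs draw from the baseline only.

Defaults (chosen once as representative of adult audio-visual TOJ
performance): `σ = 90 ms` (JND ≈ 61 ms), `λ = 0.02`, between-participant
PSS SD 40 ms, RT baseline 500 ms, bump amplitude 150 ms, bump width 120 ms,
RT noise SD 150 ms, unimodal `σ = 60 ms`. The default four-group study uses
10/10/9/9 participants with group-mean PSS −40 (CC), +40 (MCC), +60 (DC),
+30 (MDC) ms and larger `σ` and lapse in the clinical groups, mirroring the
qualitative pattern of a congenital-cataract-reversal design: the CC-like
group perceives vision as early (negative PSS), everyone else as delayed.
With these RT parameters the 100 ms / 2.5 SD exclusions remove ≈2% of
trials, a realistic housekeeping load.

The design is 2 modalities × 2 sides × 8 SOAs (±30, ±90, ±135, ±400 ms)
× 10 repetitions = 320 trials in 10 blocks. Data-quality nuisances are
emulated by a per-trial probability of an experimenter-entered response
(response kept, RT missing) and a per-participant completed-block count.

What the generator does **not** emulate: practice trials and feedback,
sequential effects (fatigue, drift, serial dependence), left/right response
bias on bimodal trials, RT distributions' right skew (noise is Gaussian),
and any correlation between PSS and σ across participants. Passing
recovery tests therefore certify the estimators under the assumed
observer model, not robustness to these real-data features.

Seeding: one master seed; per-participant substreams are spawned
deterministically (`numpy` `SeedSequence`), so whole-study simulations are
reproducible and participants are independent.

## Trial exclusions

Per participant and experiment, over self-entered responses only:
trials with RT < 100 ms are removed first; then trials with RT more than
2.5 *sample* SDs above that participant's mean RT, with mean and SD
computed on the remaining trials pooled across conditions. Experimenter-
entered responses are never filtered (they have no usable RT). Missing RT
on a self-entered row excludes the row with its own logged reason. The
exclusion fraction is reported over self-entered rows. Thresholds are
defined once, on the raw data; re-running the filter on filtered data can
only tighten, never resurrect, so the pipeline applies it exactly once.

## Probit-line psychometrics

Response proportions per SOA are clamped to [1/(2n), 1 − 1/(2n)] (n =
trials at that SOA) before the probit transform, keeping every point
finite with minimal bias, and an **unweighted** OLS line is fitted to
probit vs. SOA. PSS = −intercept/slope, clipped to ±150 ms with a flag;
JND = Φ⁻¹(0.75)/slope ≈ 0.6745/slope. A non-positive slope flags the fit
non-identifiable (PSS/JND reported missing).

**Asymptote rule.** If performance at the longest |SOA| has reached that at
the second longest, the ±400 ms points are dropped before fitting. This is
operationalised on proportion correct pooled over both signs, with
"reached" = `≤` by default ("equal" exactly is a config option,
`asymptote_rule="eq"`), treating both tails symmetrically.

**Known estimator property.** When an extreme SOA saturates (observed
proportion 0 or 1), the clamp compresses its probit and deterministically
attenuates the line: with σ = 90 ms and ±400 ms retained, the
population-level PSS estimate is ≈16% closer to zero than the true PSS.
This is a property of probit-line linearization, not of the
implementation; the dual-route check against a direct ML
cumulative-Gaussian fit is therefore run in a non-saturating regime
(σ = 150 ms at 10,000 trials per SOA, where the linearization is exact),
and unbiasedness under the study design is asserted on the mean error over
a symmetric PSS distribution, where the attenuation cancels.

## Permutation inference

Classical statistics (one-sample t, pooled-variance two-sample t, one-way
F, Pearson r) are computed on the observed data; their nulls are built by
sign-flipping centred values (one-sample), permuting group labels
(two-sample, ANOVA) or shuffling one variable (correlation). When the full
group is small (≤ 2¹⁵ sign patterns / assignments) it is enumerated and
p = #{T* ≥ T}/#permutations with the observed arrangement included;
otherwise 10,000 Monte-Carlo draws with the add-one convention
p = (#+1)/(n+1). Planned, directional comparisons default to one-tailed
p-values (in the direction of the observed statistic, recorded in the
result); omnibus and exploratory tests are two-tailed. Degenerate inputs
(zero variance) yield p = 1 with a flag rather than an error.

**Effect size.** `r_equivalent(p, df)` converts a one-tailed p and the
participants-based df of the underlying test into
r = t/√(t² + df) with t the one-tailed t quantile; p ≥ 0.5 clips r to 0
with a flag. For χ² likelihood-ratio tests the df is the participant-based
df of the corresponding t test (n − 1 within-group, N − 2 between-group).
For two-tailed results r is computed from p/2.

## Binomial random-intercept GLMM

Single-trial binaries ('visual first', correct) are modelled as

    y_ij ~ Bernoulli(g⁻¹(x_ij'β + b_i)),   b_i ~ N(0, τ²)

with one random intercept per participant. The marginal likelihood is
integrated by **adaptive Gauss–Hermite quadrature** (default 15 nodes; the
log-likelihood stabilises to <1e−5 between 15 and 25 nodes on typical
data): per cluster, a damped Newton search finds the posterior mode and
curvature of the random effect, and the Hermite nodes are recentred and
rescaled there. Bernoulli rows are first collapsed to binomial counts per
participant × covariate cell, which is exact and makes each likelihood
evaluation cheap. (β, log τ) are maximised with L-BFGS-B (τ bounded in
[1e−4, 50]; at the lower bound the model collapses to the plain GLM, which
is also the analytic τ → 0 limit of the implementation). Standard errors
come from the numerical Hessian. The default link is the logit — with it,
"chance level" (probability 0.5) maps to 0 on the link scale, which is how
the reported chance-level contrasts behave; a `log` link (with the mean
capped below 1) is available as a config option, and the choice is
recorded in every fit.

Group effects are tested by likelihood-ratio χ² between nested fits;
single contrasts (e.g. a group's intercept against chance) by Wald z on
the link scale. Categorical fixed effects are treatment-coded; with two
factors the interaction is included.

## RT peak

Within participant, bimodal self-entered RTs are z-scored across SOAs and
the profile rt_z vs. soa_visual is fitted by maximum likelihood with a
Gaussian-bump mean and constant residual SD — the same shape the generator
uses, chosen for identifiability and because a single uncertainty peak at
the PSS is the theoretical expectation. With Gaussian errors the ML mean
parameters are the least-squares ones and the residual SD profiles out, so
the fit is a bounded nonlinear least squares, multi-started over 7 peak
locations spanning the SOA range; the peak is constrained to [−400, 400] ms
and the width to [5, 600] ms (≈75% of the SOA span — wider bumps are not
identifiable from data confined to the design range and otherwise run away
on noisy profiles). A quadratic mean would behave similarly near the peak
but has no bounded-support interpretation and was not pursued.

A likelihood-ratio test against the constant-mean model (3 df, α = 0.05)
flags flat profiles; unreliable peaks are excluded from group comparisons
(counts logged), preventing boundary estimates from dominating the
permutation t tests.

**Precision.** The Fisher information of the peak location at residual
SD 1 with 40 trials per SOA gives a ≈22 ms standard error, and the
implementation attains that bound empirically; recovering the peak to
±15 ms in ≥90% of runs therefore requires a residual SD ≲ 0.4, and the
recovery test uses 0.35. Single-participant peaks under the generator's
default RT noise are accordingly noisy — which is why group comparisons,
not individual peaks, are the analysis endpoint.

## Bias–resolution correlation

Across participants of all groups (within experiment), Pearson r between
accuracy and |p_visual_first − 0.5|. To avoid leverage effects, a
participant is excluded when either measure lies more than 2.5 sample SDs
from their group's mean of that measure; exclusion is applied per group
per measure before pooling, and the permutation p shuffles one variable.

## Pipeline and test plan

Stages run in order: validate → recode → filter → per-participant fits and
summaries → group tests → RT analysis → correlation. The test plan is
data-driven from group labels: each group's PSS against zero, the omnibus
ANOVA, planned CC↔MCC and DC↔MDC comparisons (clinical groups are never
compared with each other — they differ in age by design), GLMM group
effects and chance contrasts, the correlation, and RT-peak comparisons.
JNDs are computed and exported but never statistically compared across
groups: JND estimates are unreliable for participants whose performance
has not saturated by ±135 ms, and that reliability differs systematically
between groups. Every stochastic stage draws its seed from one master
seed stream and records it, so a report is reproducible from config +
seed alone.

## Problem sizes used in the validation suite

Recovery and calibration checks are sized to be informative yet quick:
200 observers for PSS recovery; 10,000 trials per SOA for the dual-route
oracle; 1000 null replicates (500 for the GLMM likelihood-ratio test) with
2000 permutations each for type-I-error calibration, giving a Monte-Carlo
SE of ≈0.7 (1.0) percentage points on the rejection rate against the
[3%, 7%] acceptance band at α = 5%.

## Known limitations

- The probit-line PSS is attenuated toward 0 when saturated extreme SOAs
  are retained (see above); the ±150 ms bound further censors extreme
  observers. Both are properties of the published procedure, reproduced
  deliberately.
- The GLMM supports one random intercept (no random slopes) and one or two
  fixed factors with full interaction — the designs the analysis needs.
- The log link caps μ below 1; likelihoods near the cap are non-smooth,
  and the logit link is the default for inference.
- One-tailed permutation tests take their direction from the observed
  statistic when not specified; for confirmatory use, fix the direction
  explicitly (`tails="greater"` / `"less"`).
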