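# toj — spatial temporal-order-judgment analysis

`toj` is an analysis pipeline for spatial temporal-order-judgment (TOJ)
experiments that probe cross-modal temporal biases: which of two stimuli —
one per side, possibly in different modalities (visual–auditory,
visual–tactile) — is perceived first, as a function of the signed stimulus
onset asynchrony (SOA). It is written for psychophysicists analysing
multi-group TOJ studies (e.g. clinical groups vs. matched controls) and
ships a synthetic-observer generator so every stage can be validated by
parameter recovery without access to human data.

The pipeline implements, per participant:

- **Probit-line psychometrics.** The proportion of 'visual first' responses
  per SOA is probit-transformed (clamped to [1/(2n), 1−1/(2n)]) and fitted
  with an OLS line z = a + b·SOA. The **PSS** (point of subjective
  simultaneity) is the zero crossing −a/b, bounded to ±150 ms; the **JND**
  is Φ⁻¹(0.75)/b, the SOA supporting 75% correct order reports. If
  performance at the longest SOA has reached that at the second longest,
  the ±400 ms points are dropped first (asymptote rule).
- **RT-based bias.** Bimodal reaction times are z-scored within participant
  and the SOA at which the RT profile peaks — where perceived order is most
  uncertain — is estimated by ML under a Gaussian-bump mean.
- **Trial housekeeping.** RT < 100 ms and RT > mean + 2.5 SD exclusions
  (never applied to experimenter-entered responses), response recoding with
  the visual-first sign convention.

and, per group:

- **Permutation inference**: sign-flip one-sample t (PSS vs. 0), label-
  permutation two-sample t and one-way ANOVA, exhaustive when the
  permutation group is small; p-values carry their seed and count.
- **Binomial random-intercept GLMMs** (adaptive Gauss–Hermite quadrature)
  for the single-trial 'visual first' probability and accuracy, with
  likelihood-ratio group tests and Wald chance-level contrasts.
- **Effect sizes** as r_equivalent = t/√(t² + df), reconstructed from the
  one-tailed p and the participants-based df.
- **Bias–resolution correlation** across participants with a per-group
  2.5 SD leverage exclusion.

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

Simulate a four-group study (CC/DC cataract-reversal-like groups and
matched controls MCC/MDC, 10/10/9/9 participants, 320 trials each, with
experimenter-entered responses and incomplete sessions), then run the full
analysis:

```bash
python analysis/01_simulate_study.py --seed 2026
python analysis/02_preprocess.py
python analysis/03_psychometric_fits.py
python analysis/04_group_inference.py --seed 2026
python analysis/05_parameter_recovery.py
```

`02_preprocess.py` reports the trial exclusions:

```
12160 trials in; excluded 148 fast, 85 slow outliers, 0 missing-RT
(2.0% of self-entered trials)
```

`03_psychometric_fits.py` prints the group summary of the probit-line fits
(PSS/JND in ms):

```
        n  pss_mean  pss_sd  jnd_mean  p_visual_first  accuracy
group
CC     10    -49.69   49.91    140.66            0.57      0.78
DC      9     61.58   46.19    139.91            0.41      0.77
MCC    10     62.34   48.19    100.99            0.40      0.84
MDC     9     41.75   51.86    109.05            0.44      0.85
```

The CC-like group shows the generative reversed bias (negative PSS: vision
perceived as early; 'visual first' proportion above 0.5) while the other
groups show the typical positive PSS, and the clinical groups are less
accurate. `04_group_inference.py` then prints the test table, e.g.

```
                             id  statistic  df  p_perm tails  r_equiv
 visual-auditory:pss_vs_zero:CC     -3.148   9   0.007   one    0.714
   visual-auditory:pss:CC_vs_MCC     -5.106  18   0.000   one    0.715
visual-auditory:bias_accuracy_corr  -0.439   36   0.007   two    0.430
```

— the CC group's PSS differs from zero (one-tailed sign-flip permutation
test, t(9) = −3.15), differs from its matched controls (label-permutation
t(18)), and across all participants a larger 'visual first' bias goes with
lower accuracy (permutation Pearson r = −0.44). `05_parameter_recovery.py`
closes the loop against the simulation truth (PSS recovery r = 0.96,
RT-peak recovery r = 0.87 on this seed).

The same pipeline runs from the command line on any trial CSV in the
documented schema (`toj simulate`, `toj analyze --data trials.csv`,
`toj report`), or from a YAML config via `toj analyze --config cfg.yaml`.

## Library use

```python
from toj import ObserverParams, default_design, simulate_participant
from toj.preprocess import recode, filter_trials
from toj.psychometric import fit_condition
from toj.inference import perm_t_one_sample, r_equivalent

trials = simulate_participant(ObserverParams(pss=-40), default_design(), seed=1)
fit = fit_condition(filter_trials(recode(trials)).retained, "bimodal")
print(fit.pss, fit.jnd)          # PSS (ms, bounded ±150), JND (ms)
print(r_equivalent(0.009, 9))    # 0.693...
```

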