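# strokebci

An off-line brain–computer-interface (BCI) analysis pipeline for two-class
motor-task EEG — **filter-bank common spatial patterns (FBCSP)** feature
extraction, **marginal-relevance (MRelv)** feature ranking and **Gaussian
process classification (GPC)** — together with a synthetic EEG cohort
generator that emulates healthy and stroke-affected recordings, the
evaluation schemes used to study cross-subject and longitudinal BCI
transfer after stroke, and the group statistics of the published accuracy
tables.

It is aimed at BCI methods researchers who want a tested, deterministic
reference implementation of this classic decoding chain, and at anyone
studying how motor-related EEG features shift between healthy and
stroke-affected cortex from a machine-learning perspective.

## The method

A session is 32-channel EEG (10/20 montage, BioSemi-32 layout) recorded
during alternating 10 s *move* / *rest* trials (20 + 20 per session).
Processing steps:

1. **Sagittal mirroring** — left-hand performers have left/right homologue
   channels swapped so all sessions share the right-hand convention.
2. **Filter bank** — nine zero-phase 4th-order Butterworth band-passes,
   4–8 … 36–40 Hz (forward–backward application), then per-trial windows
   starting 2 s after trial onset, lasting 6 s.
3. **CSP per band** — with Σ₁, Σ₂ the trial-averaged, trace-normalized
   class covariances, the projection W solves Σ₁w = λ(Σ₁+Σ₂)w, so
   Wᵀ(Σ₁+Σ₂)W = I and WᵀΣ₁W = diag(λ); trials are decomposed as
   Z_{b,i} = W_bᵀE_{b,i}. Spatial patterns (scalp maps) are the columns of
   W⁻ᵀ.
4. **Features** — log proportional variance of each CSP component,
   v_{b,i} = log[ var(Z_{b,i}) / Σ_{i'} var(Z_{b,i'}) ], concatenated
   band-major into a trials × (9·32) matrix with labels y ∈ {+1, −1}.
5. **MRelv selection** — each column is scored by its between- to
   within-group sum-of-squares ratio (∝ the one-way ANOVA F); the four
   top-ranked columns are kept together with their complementary partner
   filters (component j pairs with component c−1−j of the same band).
6. **GPC** — a latent GP (squared-exponential kernel) squashed through a
   logistic sigmoid, fitted with the Laplace approximation; each trial gets
   a class probability and a 0.5 decision threshold.

Evaluation schemes: temporally-blocked 10-fold cross-validation,
one-on-one cross-session transfer matrices, grouped (pooled-trial)
training with leave-one-out, and longitudinal (early-session-trained,
late-session-tested) decoding. Group comparisons use tie- and
continuity-corrected Wilcoxon rank-sum tests with effect size
r = |Z|/√N, and paired Wilcoxon signed-rank tests.

## Worked example

```python
import strokebci as sb

# a healthy synthetic subject: beta-band (16-24 Hz) desynchronization
# over C3, move-trial band power 0.25x the rest-trial power
session = sb.generate_session(sb.make_profile("healthy", seed=11), "H1")
print(sb.kfold_cv(session))            # 10-fold CV accuracy (%)

bci = sb.train_bci(session)            # individual BCI
late = sb.generate_session(sb.make_profile("stroke_late", seed=23), "S1", "S1L")
print(sb.test_bci(bci, late))          # healthy-trained, stroke-tested
```

prints

```
100.0
55.00000000000001
```

The within-session cross-validation of the healthy session is perfect
(the rhythm is strongly class-discriminative), while the same BCI applied
to a late-stroke session — whose discriminative power sits in lower
frequency bands — drops toward chance level (50%), the transfer
degradation the package is built to study.

The published accuracy tables are packaged and their summary statistics
can be recomputed directly:

```python
stats = sb.reproduce_printed_stats()
print(stats["table5_healthy_median"], stats["table5_all_stroke_median"])
# 82.5 70.0
print(round(stats["table5_healthy_vs_all_stroke_absZ"], 2))
# 5.55
```

## Layout

- `strokebci.simulate` — cohort profiles and the synthetic session generator
- `strokebci.preprocess` — mirroring, filter bank, epoching
- `strokebci.csp` — `FilterBankCSP` (fit/transform), spatial patterns
- `strokebci.selection` — `MarginalRelevanceSelector`
- `strokebci.gpc` — `LaplaceGPClassifier`
- `strokebci.experiments` — training/testing schemes and accuracy tables
- `strokebci.stats`, `strokebci.tables` — group statistics and packaged tables

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
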