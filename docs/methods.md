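# Methods

This note documents the models, conventions and design choices behind
`salisense`, in the order data flows through the pipeline.

## 1. Synthetic cohorts

Each group's clinical markers are drawn independently from truncated
normals.  Markers reported as *mean (range)* — FBG, triglycerides, HbA1c,
2-h postprandial glucose — use the range as hard truncation bounds, an SD
of range/4 (the conventional range-based estimate), and a **moment-matched
location**: the underlying normal mean is solved (Brent's method) so the
*truncated* distribution's mean equals the reported group mean.  This
matters: the diabetic FBG range (84–287 mg/dL) is strongly asymmetric
around its mean (146.37), and a naive `loc = 146.37` parameterisation would
inflate the sampled mean by about +10 mg/dL.  Ages are reported as
mean ± SD and drawn directly with a physiological truncation to
[18, 100] years; sex is Bernoulli with the reported male fractions
(26/45 diabetic, 20/45 non-diabetic).

Daily activity hours (truncated normal, means 2.0/2.5 h, SD 2 h on
[0, 24]) are included as metadata but deliberately uncorrelated with
anything; the anecdotal activity–glycaemia link seen in the real cohort is
not modelled.

## 2. Synthetic responses

The raw per-receptor intensities of the real device are not published; the
generator reconstructs a response model from the qualitative
responsiveness pattern and the one published quantitative distribution
(group-wise Euclidean norms).  A row is assembled in three layers:

1. **Responsiveness mask.**  Spots not responsive for the participant's
   group carry |N(0, `noise_sd`)| per channel (`noise_sd` = 2.5 intensity
   units by default; exactly zero at zero noise).  The pattern: S2, S5, S9,
   S10 respond to both groups; S3 only to non-diabetic saliva; S7, S8, S12
   only to diabetic saliva; S1, S4, S6, S11 never.
2. **Magnitudes.**  Group-exclusive spots scale their `max_delta_rgb`
   triple by a logistic activation in FBG: diabetic-linked spots switch on
   around 132 mg/dL, the non-diabetic-linked spot switches off above
   ~97 mg/dL, both with scale τ = 3 mg/dL.  Borderline-glycaemia subjects
   from *either* group therefore show near-zero exclusive-receptor signal
   and become genuinely confusable — the regime reported for the device's
   misclassified subjects (FBG 100–106 mg/dL).  The two
   glucose-tracking spots are linear in a latent bivariate-normal link,
   `u = ρ·z + √(1−ρ²)·ε`, with ρ = 0.871 against standardised raw FBG for
   TMA-AgNPs (S10) and ρ = 0.726 against standardised FBG-category
   midpoints for MR+TBOH (S5).  Because each spot's three channels share
   one latent, any linear summary of the spot (e.g. its channel norm)
   carries the population correlation exactly.  Multiplicative per-receptor
   jitter (SD 5%, clipped at ±3σ) and additive per-channel jitter (SD 6)
   model within-group biological variability.
3. **Norm calibration.**  Each row is rescaled so its Euclidean norm equals
   a draw from the configured group distribution (358.31 ± 27.98 diabetic,
   328.47 ± 31.60 non-diabetic; draws truncated at ±2.5 SD).  Only the
   responsive *non-correlated* channels are scaled, so the calibration
   leaves the FBG correlations and the noise floor untouched while making
   the norm statistics exact by construction.  A per-channel cap
   (200 units) with norm-preserving redistribution guarantees that no
   calibrated shift exceeds what an 8-bit spot can render.

Replicates model device-to-device reproducibility as a single
multiplicative gain, `row · (1 + δ)`, δ ~ N(0, RSD/100), so the RSD% of
replicate norms converges to the configured 6.03% (diabetic) / 6.71%
(non-diabetic).

Random streams are split per purpose (cohort, responses, norm targets,
replicates, pixels) from one user-facing seed, so enabling or extending
one stage never perturbs another.

**What the generator does *not* emulate** — scanner colour calibration,
spatial within-spot texture, signed colour shifts in the feature view
(features are magnitudes; the shift direction exists only in rendered
images), participant exclusion, metabolite chemistry, and any
activity- or age-linked response.  Passing tests therefore validate the
*pipeline*, and the calibrated statistics above, not the device itself.

### Calibration of the discrimination difficulty

The activation midpoints/scale (132, 97, τ = 3) and the noise floor were
fixed by a one-time design scan so that the default conditions reproduce
the discrimination regime of the reference cohort: leave-one-out PCA-LDA
accuracy averages ≈ 93% over seeds (individual seeds range ≈ 88–98%),
bracketing the reported 88.9% — rather than the ~100% that a crisp,
non-overlapping activation would give.  With those values roughly a fifth
of diabetic subjects (FBG below ~115) and the high-normal tail of controls
fall in the ambiguous zone.  They are defaults of the study conditions, not
per-run tuning knobs.

## 3. Imaging conventions

Coordinates are image-style (origin top-left, x right, y down, 0-based).
A pixel belongs to a spot when its integer centre is within the disk
(distance ≤ radius): no anti-aliasing, so every mask is enumerable and the
extraction is exactly testable.  The response element is the **absolute
difference of spot means** (not the mean of per-pixel absolute
differences), which is robust to zero-mean pixel noise.  The default
layout is a 3 × 4 grid on a 300 × 200 px canvas with 20 px spot radius;
layouts are configuration, not detected — the device is printed, so its
geometry is known.  Rendering shifts each spot's colour toward the larger
8-bit headroom and rounds to integers; together with the 200-unit channel
cap this bounds the render → extract round-trip error by the 0.5-unit
quantisation limit.

## 4. Statistics

- **DAF** uses ANOVA mean squares, MSB/(k−1-df) over MSW/(n−k-df); on
  scalars it *is* the one-way F statistic (cross-checked against an
  independent ANOVA implementation in the tests).  Vector inputs use the
  scatter-trace ratio with the same df normalisation.  Zero within-group
  variance with separated means returns +inf; condition rankings break
  ties lexicographically on the condition id.
- **t-test** defaults to the pooled-variance Student form (Welch by flag);
  degenerate zero-variance inputs return t = 0, p = 1 (equal means) or an
  infinite-t flag.
- **Threshold rule**: `norm > threshold → diabetic`, ties to non-diabetic
  (the rule is strictly "greater than"); the threshold defaults to the
  grand mean of the analysed data, with an override to fix an external
  value.
- **Percentages** round half-away-from-zero to one decimal at the
  reporting layer only.  Note 39/45 = 86.67% rounds to 86.7 under this
  rule; the reference results table prints 86.6 for that cell, a
  discrepancy we record rather than imitate.
- **FBG binning** for the MR+TBOH correlation uses right-open clinical
  categories [0, 100), [100, 126), [126, 200), [200, ∞) mg/dL with bin
  midpoints (250 as the representative of the open top bin); fully
  configurable.
- **Age correlations** are reported with the package's own t-transform
  p-values; no multiple-testing correction is applied anywhere (matching
  the reference analysis protocol).

## 5. PCA-LDA

PCA mean-centres and eigendecomposes the sample covariance; components are
ordered by explained variance with the sign fixed so each loading's
largest-magnitude element is positive (reproducible score plots across
platforms).  Retention for classification keeps the smallest leading set
reaching 95% cumulative variance (configurable; plots always use PC1/PC2).
LDA solves `S_w w = μ_d − μ_nd` with a relative ridge (1e-8 · mean
eigenvalue) for singular scatter, orients diabetic-high, and places the
threshold at the equal-covariance Gaussian decision point (midpoint of
projected class means under equal priors).

Validation defaults to leave-one-out (deterministic, standard for a
90-sample chemometrics panel); stratified k-fold and resubstitution are
available.  **PCA is refit inside every training fold** so no held-out
information leaks into the decomposition — a deliberate divergence from
the common fit-once practice, which resubstitution mode reproduces for
comparison.  Note that under label permutation, leave-one-out estimates
are slightly anti-conservative (below 50%) because removing a sample tilts
the training balance against its own label; the chance-level check in the
tests therefore averages over permutations.

## 6. Degenerate inputs and numerical tolerances

Empty cohorts produce empty (0 × 36) matrices and empty CSVs; a single
replicate is returned but RSD computation rejects it; constant inputs to
Pearson raise; a confusion table with an empty truth class flags that
class's sensitivity as undefined (null with reason in the JSON report).
Oracle comparisons in the tests use 1e-10..1e-12 relative tolerances for
closed-form identities, 0.5 intensity units for image quantisation, and
3-standard-error bands for Monte-Carlo recovery checks.

## 7. Problem sizes

Defaults mirror the reference cohort scale: 45 + 45 subjects, 36 features.  The test
suite uses 200 seeded cohorts for correlation recovery, 20 seeds for the
accuracy-band property, 10 label permutations for the chance-level check,
5000 replicates for RSD convergence, and 2000/group for calibration
recovery; the acceptance script simulates 200 cohorts of 90.
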