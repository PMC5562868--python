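# Methods

`metabotype` re-implements, as a tested and reusable pipeline, a
multivariate metabolic-phenotyping workflow for untargeted LC-MS urine
profiles from a murine colitis model: pooled-QC reliability filtering
and normalization of an aligned feature table, genotype discrimination
by PLS-LDA with leave-one-out cross-validation and full confusion
statistics, regression of metabolite profiles against a colitis
severity score, a random-forest feature-permutation significance test
based on classification cross-entropy, and Bray-Curtis / PCoA /
PERMANOVA beta-diversity statistics for pathway-abundance tables. A
synthetic-data generator provides cohorts with the statistical
structure the analysis assumes, so every stage is testable without any
data download.

## Synthetic cohort model

`CohortConfig` defaults describe the study design being emulated:
65 biological samples in four groups (WT-6wk/KO-6wk/WT-18wk/KO-18wk =
18/18/17/12), 3129 aligned mass ions over four acquisition windows
(positive/negative ionisation × m/z 60–200 and 140–1250, RT 0–23.5
min), and 8 pooled-QC injections.

Intensities are log-normal per feature with baselines spanning ~3
orders of magnitude (10^5.3–10^8), so the instrument noise threshold
(100 000 counts by default) is meaningful. Group effects are
multiplicative: an age effect (fold 2.0 on 800 features) deliberately
dominates a weaker genotype effect (fold 1.5 on 150 features), which
reproduces the headline phenomenology — unsupervised PCA separates
age, while supervised PLS-LDA is needed to discriminate genotype.
Every study sample is multiplied by a log-normal dilution scalar
(CV 0.30), the dominant nuisance in urine; two internal-standard ions
(emulating endogenous creatine and histidine) have near-zero
biological variance (log-SD 0.02) and are untouched by the group
effects, so ratio normalization against them cancels dilution. Noise
ions (15% of features) sit near the noise threshold, drop out
erratically in both study and QC injections, and carry 20× inflated
retention-time jitter; they are the designated prey of the noise
threshold, QC-presence/RSD and RT-RSD filters. QC rows are the
feature-wise mean of the study rows perturbed by 5% technical noise
(noise ions excepted). Colitis scores are 0 for WT and KO-6wk and
uniform on 4–12 for KO-18wk, independent of the metabolite values by
default — the null structure under which predictive regression should
fail (Q² ≤ 0) — with an optional coupling parameter for power studies.

The generator does **not** simulate chromatograms, isotope patterns,
peak picking or alignment, batch drift, or heteroscedastic
missingness; passing tests therefore demonstrate correctness of the
statistics given an aligned table, not robustness to upstream
processing pathologies.

All randomness flows through `numpy.random.default_rng(seed)`;
identical config + seed is bit-identical, and sample generation uses
a canonical group order so the output does not depend on dict key
order.

## Preprocessing

The canonical chain is noise threshold → QC reliability → singleton
removal → correlation filter → (optional internal-standard ratio) →
Z-score. Filters only remove feature columns and report everything
they removed.

* **Noise threshold**: drop features whose maximum over study samples
  is below the threshold (100 000 default; 1 000 000 for the stricter
  re-processing variant).
* **QC reliability**: detection in ≥ 80% of pooled-QC injections,
  peak-area RSD ≤ 30%, RT RSD ≤ 5%. RSD = sd/mean (sample sd) over QC
  rows; undefined (zero-mean) RSDs are flagged, never treated as 0.
  The RT criterion needs per-sample retention times, which aligned
  export tables often lack; it is skipped (and the report says so)
  when none are supplied.
* **Singletons**: features detected in ≤ 1 study sample. This is the
  standard metabolomics reading of "singleton" removal; it is
  toggleable.
* **Correlation filter** (threshold 0.98): greedy scan in column
  order; each retained feature removes all later features with
  |Pearson r| ≥ threshold, so the survivors are provably pair-free.
  Keeping the earlier column makes the result deterministic and
  order-stable; `keep="variance"` keeps the higher-variance member
  instead, and Spearman is available behind a flag. Constant columns
  have undefined correlations and are retained with a report note.
* **Z-score**: Z = (x − µ)/σ per feature with µ, σ computed on study
  samples only, population (n) denominator — the unit-variance
  scaling convention of the multivariate software the workflow
  follows; whether QC rows entered µ, σ was not specified, and
  excluding them keeps the QC rows interpretable after transform.
  Zero-variance columns map to zero and are flagged.

## PLS-LDA and confusion statistics

"PLS-LDA" is read as PLS regression of the feature matrix on a
one-hot class encoding (latent variables extracted by iterative
deflation; the scikit-learn NIPALS implementation is used), followed
by a discriminant read-out. The default read-out is the argmax of the
predicted class responses with ties broken toward the first-listed
class — chosen because it is deterministic and the most common
reading; fitting an LDA on the latent scores is available via
`readout="lda"`. Five latent variables is the default, matching the
published model; the count is capped at min(n−1, p) with a recorded
warning. With all components on full-rank data the PLS prediction
reproduces ordinary least squares, which the tests assert.

Leave-one-out cross-validation refits the model on n−1 samples per
fold. Per-class one-vs-rest counts feed the metric formulas
(recall = TP/(TP+FN), precision = TP/(TP+FP), specificity =
TN/(TN+FP), F = harmonic mean, accuracy, and Cohen's κ from the
marginal chance agreement). Ratios with zero denominators are
returned NaN and listed in an `undefined` field. Comparisons against
printed tables use decimal half-up rounding at 2 decimals. When
features outnumber samples ten-fold the result carries an explicit
over-fitting warning.

Regression against the colitis score (PLS or random-forest, LOO)
reports per-sample cross-validated predictions, the slope/intercept
of predicted-on-observed (the identity line being perfect
calibration) and Q², the cross-validated R². On the default
(uncoupled) synthetic cohort Q² ≤ 0 in expectation — the model has
nothing to find, mirroring the negative result the workflow was built
to demonstrate.

## Permutation feature importance

Baseline: the RF classifier (500 trees, √p features per split by
default — recorded in the result, since no hyperparameters were
published) is refitted `n_repeats` times (default 100) with seeds
derived from the master seed; the classification cross-entropy
−(1/N)·Σ log p̂(true class) (natural log, probabilities floored at a
configurable ε, default 1e-15) of its class-probability estimates is
recorded each time, giving mean and σ. Cross-entropy is evaluated on
out-of-bag probabilities by default: no extra split is spent, and the
error is honest rather than resubstitution-optimistic (training-set
evaluation is a flag). Each feature column is then permuted across
samples — a fresh permutation per repeat, since repeated
randomization is the point of the loop; a fixed-permutation mode
exists — the classifier refitted, and the repeat-mean cross-entropy
compared with the baseline. A feature is **significant** when
Δ = mean permuted CE − mean baseline CE exceeds 1.96·σ.

Two statistical properties of this rule matter and are documented
rather than hidden:

1. **The σ rule is conservative.** Because Δ is a difference of two
   repeat means, its null standard deviation is σ·√(1/R_perm +
   1/R_base) ≪ σ; the null flag rate is therefore far below the
   nominal one-sided 2.5%. The calibration test accordingly checks
   that the flagged fraction does not *exceed* the exact binomial 95%
   upper bound at 2.5% — a conservative rule passes, an
   anti-conservative one fails.
2. **p-values use the proper standard error.** Reported p-values are
   P(Z > Δ/se) with se = σ·√(1/R_perm + 1/R_base), which is
   approximately uniform under the null and hence a valid input to
   Storey's estimator. Dividing by raw σ instead (available as
   `p_scale="single"`) concentrates null p-values in ~[0.2, 0.8],
   collapses the π̂0 estimate towards 1/m, and drives *every* q-value
   to ~0 — an implementation trap verified empirically during
   development.

**Storey q-values**: π̂0 is estimated on the λ grid 0.05…0.95 (step
0.05) via π̂0(λ) = #{p > λ}/(m(1−λ)) with a cubic least-squares
smoother extrapolated to λ = 1, clipped to [1/m, 1]; below 100
p-values the conservative moment fallback min(1, 2·mean p) is used.
q_j = min over p_i ≥ p_j of π̂0·m·p_i/rank(p_i). With π̂0 forced to 1
this reduces exactly to Benjamini–Hochberg, which the tests assert
against a hand-written step-up oracle; BH itself is delegated to
statsmodels.

**Power and masking.** Permutation importance measures each feature's
*unique* contribution. Redundant informative features mask one
another — permuting one leaves the rest carrying the signal — so a
set of, say, ten group-shifted features is not individually
recoverable at any shift (measured per-feature Δ ≈ 0.01, at the null
noise level), and sparse features informative for only a small sample
block are not learnable by RF at these sample sizes. This is a
property of the method, consistent with the original workflow
flagging only a handful of ions out of ~3000. The recovery test
therefore uses `generate_marker_classes`: a 10-class problem in which
feature j is the sole marker of class j, the regime where per-feature
power genuinely exists; all ten markers are then recovered both at
q < 0.05 and by the 1.96σ rule.

**Problem sizes.** The test suite and acceptance script run the
permutation machinery at reduced scale, chosen as a package default
for a single-CPU desk run: null calibration on two genotype-null
cohorts of 30 samples × 60 features with 8 repeats and 100-tree
forests (120 pooled feature decisions); recovery on 80 samples × 60
features with 5 repeats and 250-tree forests. Small ensembles make
the ε-floored OOB cross-entropy spiky (a sample whose every OOB tree
votes wrong contributes −log ε); the scaled runs therefore use ≥100
trees, and the recovery config uses ε = 0.05, which bounds a single
sample's contribution and stabilises σ without affecting ranking.

## Beta diversity

Rarefaction subsamples each row without replacement to even depth
(default: minimum row total, since no depth was published) via
multivariate hypergeometric draws; under-depth samples are dropped
and reported. Bray-Curtis d = Σ|a−b|/Σ(a+b) is computed with scipy
and checked elementwise. PCoA is classical scaling — double-centre
the squared distances, eigendecompose — with negative eigenvalues
(expected for Bray-Curtis) reported explicitly and excluded from
coordinates rather than silently corrected; explained fractions are
relative to the positive eigenvalue sum; each axis's
largest-magnitude coordinate is made positive for determinism.
PERMANOVA is the one-way (single-factor) design only, matching the
reported single-factor analyses: pseudo-F from the between/within
decomposition of squared distances, R² = SS_between/SS_total, and
p = (1 + #{F* ≥ F})/(1 + n_permutations) under seeded label
permutations. Both PCoA and PERMANOVA are cross-checked against
scikit-bio in the tests, and PERMANOVA additionally against exhaustive
enumeration of all balanced relabelings on small instances.

## Pipeline and reproducibility

`run_pipeline` executes the filter chain and requested analyses from
a single validated config (unknown keys rejected; every stochastic
stage carries an explicit seed), writes deterministic JSON artifacts
(sorted keys), and emits a manifest echoing the config, package
version, filter chain, input checksums and seeds. Two runs of one
config produce byte-identical analysis reports; the manifest's
wall-clock timestamp is the only differing field, and replaying the
manifest's config echo reproduces the original confusion statistics
exactly.

## Known limitations

* The generator's group effects are homoscedastic log-normal shifts;
  real LC-MS effects are messier (feature-specific, non-multiplicative,
  drift-confounded), so power numbers on synthetic data are
  best-case.
* LOO error estimates on p ≫ n data do not rule out over-fitting;
  the package surfaces this as a warning rather than attempting a
  nested-CV redesign, to stay faithful to the workflow it implements.
* The permutation test quantifies unique feature contributions only;
  correlated marker panels need a grouped or conditional importance
  scheme, which is out of scope.
* One-way PERMANOVA only; no interaction or stratified designs.
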