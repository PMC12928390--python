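# Methods

## Problem setting

Ex vivo drug screens on AML patient samples yield, per (sample, drug), a
dose–viability curve summarized as a normalized AUC (100 = no drug
effect; AUC < 100 calls the sample *sensitive*). The modelling task is
to predict that binary sensitivity call from bulk RNA-seq expression.
Two features of the data drive every design choice here: the sensitive
class is usually a small minority, and expression values from different
cohorts/platforms are not on a common scale (strong batch effects). The
k-Top Scoring Pairs (kTSP) classifier addresses both: its rules compare
two genes *within* one sample, so it depends only on within-sample
orderings and can be applied to a single new sample with no
normalization against a reference cohort.

## Expression normalization

Input matrices are genes × samples on one of three linear scales.
RPKM → TPM rescales each column to sum to 10⁶
(`TPM_ij = RPKM_ij / Σ_i RPKM_ij × 10⁶`); counts → TPM first divides by
effective gene length (a required user input, in bp), then rescales.
Analysis proceeds on `log2(TPM + pseudocount)` restricted to
protein-coding genes. The pseudocount defaults to 1 (keeps zeros at
zero) and is configurable. Both conversions and the log are strictly
monotone within a sample, so they never change the gene orderings the
classifier uses.

## Probit dose–response model and sensitivity scores

Viability (percent of control) over a seven-point 3-fold dilution series
(10 µM … 0.0137 µM) is modelled as `v(x) = 100·Φ(β₀ + β₁x)` with
`x = log10(concentration)`, fitted by least squares (the Gaussian MLE
for slope and intercept). All-identical viabilities use the flat-curve
closed form (slope 0; intercept Φ⁻¹(v̄/100) when 0 < v̄ < 100, else the
observed level carried directly). Non-convergence is reported, never
defaulted.

**AUC** is the mean fitted viability over the screened log10 range
(4096-point composite trapezoid), clipped to the theoretical range
[0, 300]; a flat 100 % profile scores exactly 100 and
AUC < 100 ⇒ sensitive (exactly 100 ⇒ resistant). Values above 100
(drug-enhanced growth) arise only from flat raw-anchored curves, since
the Φ-model itself is capped at 100.

**DSS.** With inhibition `r(x) = 100 − v(x)` (floored at 0), activity
threshold `Amin` (default 10 %), screened bounds `Cmin < Cmax` and the
active window `[x1, x2]` where `r > Amin` (first up-crossing to last
down-crossing, found by bisection to 1e-8 after a dense-grid scan; all
on the log10 axis so ratios are dimensionless):

- `DSS1 = (∫ r dx − Amin·(x2−x1)) / ((100−Amin)·(Cmax−Cmin))`
- `DSS2 = DSS1 / log10(Rmax)` with `Rmax` the top inhibition asymptote
  (requires Rmax > 1)
- `DSS3 = DSS2 · (x2−x1)/(Cmax−Cmin)`

`sDSS = DSS_patient − mean(DSS_controls)`. When sensitivity is called
from sDSS, the threshold is the 95th linear-interpolation percentile of
the sDSS values pooled over *all* drugs and samples, with a strict
inequality for the sensitive call. All three DSS versions are
implemented; the pipeline takes a version flag (default 2).

## kTSP classifier

A rule is an oriented gene pair: `gene_a > gene_b` in a sample casts +1
(sensitive), otherwise −1; an expression tie counts −1 (the rule's
strict inequality is not satisfied). Scoring of a candidate pair uses
Δ = |P̂(a>b | sensitive) − P̂(a>b | resistant)| (ties contribute ½ to
each fraction) with a secondary score γ, the between-class difference in
mean within-sample rank difference, as tie-break. Pairs are oriented so
the sensitive class favours `a > b`, sorted by (Δ desc, γ desc,
lexicographic), and accepted greedily subject to gene-disjointness
(each gene in at most one rule) up to k_max = 15.

k ∈ [1, 15] is chosen on training data only, by a Welch-type
standardized separation of the per-sample vote sums under the first k
rules: `|m_s − m_r| / √(v_s/n_s + v_r/n_r)`; ties resolve to the
smallest k, and zero-variance perfect separations score +∞ (so a single
perfect rule yields k = 1 — parsimony is deliberate). Prediction is the
unweighted majority vote; a vote sum of 0 defaults to *resistant*
(conservative; configurable). The continuous score for AUROC is
`(vote_sum + k) / 2k ∈ [0, 1]` — the only continuous output a voting
rule set has.

All-pairs scoring is O(G²·n); above 5000 genes (configurable) only the
most variable 5000 enter the search, with a loud log message.

Because every ingredient uses only within-sample order, predictions and
vote sums are invariant under any strictly increasing per-sample
transformation; this is property-tested with random cubic/affine/
exponential per-sample maps.

## Benchmarking harness

Comparators (linear SVM, RBF SVM, random forest, elastic-net logistic
regression; delegated to scikit-learn) are tuned by random search
(default 20 draws; cost log-uniform [1e-3, 1e3], RBF γ log-uniform
[1e-5, 1e1], forest: 500 trees with features-per-split uniform on
[1, 2√p], elastic net: mixing uniform [0, 1], penalty log-uniform
[1e-4, 1e1]), scored by mean balanced accuracy over stratified seeded
5-fold CV. SMOTE, when enabled, is applied *inside* each fold to that
fold's training portion only — never before splitting — and once to the
full training set for the final refit. SMOTE itself synthesizes
minority points as `x + u·(x_nn − x)`, `u ~ U(0,1)`, `x_nn` one of the
k = 5 nearest minority neighbours, upsampling to parity. z-scoring
(SVM, elastic net) uses training-set constants only; zero-sd genes map
to 0. Training is a pure function of (training data, seed).

## Evaluation

Sensitivity, specificity, balanced accuracy ((sens+spec)/2, asserted as
an identity), and Mann–Whitney AUROC (midranks, identical to cross-pair
counting with ties at ½). Undefined denominators are NaN, never 0.
Drugs enter the study only with ≥ 20 sensitive and ≥ 20 resistant
training samples and ≥ 10/10 in the test cohort. The sDSS group test is
a one-sided Wilcoxon rank-sum (predicted-sensitive > predicted-
resistant; exact null for small tie-free groups, else normal
approximation with tie correction) with Benjamini–Hochberg adjustment
across tested drugs; untestable drugs are flagged, not assigned p = 1.
Rule-compliance profiles summarize vote sums per subgroup; for two
groups the mean difference gets a seeded 1000-resample bootstrap
percentile CI (the source analyses show these distributions without a
formal test; the bootstrap is this package's declared quantification).
Gene recurrence counts, per gene, the number of per-drug classifiers
using it, plus the fraction of genes unique to one classifier.

## Synthetic cohort generator

The generator emulates the statistical structure the classifier
assumes, with defaults chosen as the study conditions:

- 1000 genes; 30 sensitive / 150 resistant samples (sensitive samples
  are typically the minority for single drugs);
- per-gene baseline levels ~ N(8, 2) on the log2 scale plus iid
  within-sample noise N(0, 1);
- 10 gene-disjoint truth pairs. The two genes of a pair share their
  baseline and a per-sample co-expression level ~ N(0, 3): informative
  pairs are co-regulated genes of comparable absolute expression. This
  matters for identifiability — if pair members were independent, a
  cross-pairing of genes from two different truth pairs would carry
  exactly the same expected Δ as a true pair (the class-conditional
  ordering probabilities factor), and no method could prefer the true
  pairing. Co-expression cancels exactly inside a true pair but adds
  independent variance to every cross-pair comparison, diluting its Δ;
- class signal: with probability θ = 0.9 (pair fidelity) a sensitive
  sample's a-gene is boosted by δ = 1.5 log2 units, otherwise the
  b-gene; mirrored for resistant samples. θ = 0.5 is the signal-free
  null used for calibration checks;
- drug AUC ~ U(60, 95) for sensitive and U(100, 150) for resistant
  samples, so thresholding at 100 reproduces the intended labels
  exactly (asserted at generation);
- batch effects as per-batch strictly increasing maps
  `x → α(x−c)³ + βx + γ` (α ≥ 0, β > 0), which shift distributions
  without touching any within-sample ordering;
- dose–response curves as `100·Φ(β₀ + β₁ log10 c)` on the seven-point
  series plus optional Gaussian noise, clipped to [0, 300].

Train/test cohort pairs share truth pairs and gene baselines but are
otherwise independent draws.

What the generator does **not** emulate: real AML marginal expression
distributions, gene–gene correlation beyond the pair structure,
mutation covariates, library-specific quantification artifacts, or
drug–drug correlation. Passing tests therefore demonstrate correctness
of the machinery and its claimed invariances under the assumed
structure, not clinical performance on real cohorts.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at the default
cohort scale (1000 genes, 180 samples). Replicate counts are chosen for
stable Monte-Carlo estimates at desk scale: 100 seeds for truth-pair
recovery in the test suite (25 in the acceptance script), 50 null
cohorts, 200 null replicates for the type-I-error check, 25 seeds for
the imbalance benchmark (comparator tuned with 5 random-search draws —
the harness default of 20 is for real analyses), and 10 train/test
runs for the headline performance summary.

## Numerical choices and degenerate inputs

- Probit fitting: Levenberg–Marquardt least squares from a
  probit-linearized start plus two fallback starts; best of three by
  cost. Flat curves short-circuit to the closed form.
- Integration: 4096-point composite trapezoid; crossing search:
  bisection per sign-change bracket, tolerance 1e-8.
- Percentiles: linear interpolation (NumPy default, R type 7).
- Vote ties at prediction (even k): resistant by default.
- Expression ties inside a rule: the rule does not apply (−1).
- Duplicate gene/sample ids, non-numeric cells, ragged rows, all-zero
  columns, rank gaps in rules tables: rejected with the offending
  identifiers named.

## Known limitations

- The ANOVA-style k selection is a declared Welch-type criterion; the
  literature names the approach without a formula, so other
  implementations may pick different k on the same data.
- AUROC from vote sums has at most 2k + 1 distinct score levels; with
  small k the ROC curve is coarse.
- The comparator harness fixes forest size at 500 trees and does not
  tune kernel choices beyond the declared ranges.
- sDSS-based labelling pools all drugs for one global threshold, as in
  the source protocol; per-drug thresholds are not offered.
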