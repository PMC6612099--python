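# Methods

## The discovery model

The pipeline operationalizes the classic model of epigenetic gene
silencing: a gene whose promoter CpG island gains dense methylation in
one condition while its transcript drops is a candidate for
methylation-driven silencing. The evidence is assembled as a
conjunction of per-probe and per-gene filters rather than a joint
statistical model, matching how array-era methylome/transcriptome
integrations are actually run:

- **Δβ** is the difference of arithmetic condition means per probe
  (resistant − sensitive). Replicates are averaged arithmetically; in
  the motivating design each condition is a single array, so replicate
  handling matters only for synthetic or richer data.
- **Gain/loss** calls use |Δβ| ≥ 0.20 with an inclusive boundary (the
  rule is stated as "≥"); **stringent** hyper/hypomethylation uses
  strict inequalities (β < 0.20 on one side and > 0.60 on the other),
  again following how the rule is stated. For validating against
  β values published at two decimals, `classify_stringent` takes a
  rounding guard `tol` (0.005 = half an ulp of the printed precision);
  the guard exists because a printed 0.60 may be any value in
  [0.595, 0.605).
- **Regulatory restriction**: a probe qualifies if it lies on a CpG
  island AND at least one of its (gene, region) annotations is
  promoter-class (TSS200, TSS1500, 5′UTR, 1stExon). The connective is
  configurable (`island_or_promoter`) because prose descriptions of
  "promoters and islands" do not pin it down; AND is the default as
  the more conservative reading. A multi-gene probe is assigned to
  every gene for which it has a qualifying entry, so one CpG can
  support several genes.
- **Expression filter**: per-gene fold change of condition means,
  oriented ≥ 1 with a direction flag, inclusive at the 1.5 threshold.
  A pseudocount (default 0.5) is added to both means only when either
  is zero — this guards division by zero without perturbing
  informative ratios. No dispersion model is fitted: the input is a
  normalized expression table and the filter is a plain fold change,
  which is the level of modeling the discovery design specifies.
- **Candidates** are genes with ≥ 1 stringent hypermethylated CpG and
  downregulation ≥ 1.5-fold; the **shortlist** additionally requires
  ≥ 3 supporting CpGs. Within the shortlist, ordering is
  (CpG count desc, fold change desc, symbol asc). The tie-break is a
  package convention: real final selections also weigh prior
  biology, which a sort key cannot encode.

Counting genes from multi-symbol probes is ambiguous in general (the
reference table's 46 CpGs carry 33 distinct symbols, of which 32
survive promoter-class assignment — e.g. *EXOC3L* appears only as a
gene-body annotation). The package always counts assigned genes; the
discrepancy between plausible counting rules is documented rather than
hidden.

Hierarchical clustering of the most variable CpGs uses average linkage
on Euclidean distances for both probes and samples, chosen for
determinism (scipy's implementation with stable input order); the
cluster step is descriptive and feeds no downstream filter.

Gene-set enrichment is a one-sided hypergeometric tail
P(overlap ≥ k) over a user-supplied GMT file with Benjamini–Hochberg
correction across sets. No ontology semantics are implemented.

## Validation statistics

- **Pyrosequencing**: the assay value is the arithmetic mean of the
  per-CpG percent-methylation values in the sequenced window.
- **qPCR**: 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference) per
  measurement and ΔΔCt contrasting group-mean ΔCt against a calibrator
  group (group means, not per-sample pairing, because replicate wells
  are averaged). The calibrator's relative expression is exactly 1.
- **Mann–Whitney U**: exact two-sided p by the counting recurrence for
  the U distribution when n₁+n₂ ≤ 12 and the pooled data are tie-free;
  otherwise the normal approximation with tie and continuity
  corrections. The two-sided exact convention doubles the smaller tail
  and caps at 1, matching common references. Sidedness is not stated
  in the motivating design; two-sided is the safe default.
- **Kruskal–Wallis**: H with the standard tie correction; χ² p with
  k − 1 df, or the exact permutation distribution of H when the pooled
  sample is small (≤ 10), enumerated over all group assignments.
- **Restoration** after a demethylating agent: each dose group is
  compared to untreated by Mann–Whitney; restoration requires both
  p < α (default 0.05) and a dose median above the untreated median —
  a significant *decrease* is not restoration.
- Paired pre/post comparisons default to Mann–Whitney (following the
  attribution in the motivating design's figure legends) with a
  Wilcoxon signed-rank alternative available.

## Biomarker evaluation

- **Dichotomization** of percent methylation at 20%: the boundary
  value goes to the *high* (at-risk) class, resolving the overlapping
  "low ≤ 20 / high ≥ 20" phrasing; the resolution is echoed in run
  reports.
- **ROC/AUC**: empirical curve over all observed thresholds; AUC by
  the concordance identity (ties ½), which is asserted in tests to
  equal U/(n₁n₂) from the rank-sum module on every input. The
  confidence interval uses the DeLong placement-variance estimator
  (Wald interval clipped to [0, 1]); a percentile bootstrap is
  available. Positive class for the cohort run: post-treatment
  non-responder samples; negatives: pre-treatment samples.
- **Logistic fit**: two-parameter IRLS/Newton, convergence at
  |Δ log-likelihood| < 1e-10 or 100 iterations. Complete separation is
  detected from disjoint score ranges and flagged; coefficients then
  diverge by construction and the last iterate's probabilities are
  returned for downstream use. A singular Hessian (constant
  predictor) falls back to a minimal-norm step, which converges to the
  event-rate fit.
- **Hosmer–Lemeshow**: quantile bins (deciles by default) with tied
  probabilities kept together, χ² = Σ (O−E)²/(E(1−E/n_g)), df =
  bins − 2, upper-tail p. Degenerate bins merge into a neighbour. With
  a cohort much smaller than 20, the pipeline shrinks the bin count
  rather than refusing to run.
- **Association scan**: Spearman for numeric covariates, Mann–Whitney
  for two-level factors, Kruskal–Wallis for more, plus a χ² test of
  factor × dichotomized methylation switching to Fisher's exact test
  when any expected cell is < 5. Single-level covariates are skipped
  with a log message. The scanned methylation value per patient is the
  post-treatment one when present (where resistance-associated gain
  shows), otherwise the pre-treatment value.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the biology. β values are simulated on the logit scale
(β = expit(logit(μ) + ε), ε ~ N(0, sd)), which keeps draws in (0, 1)
with controllable spread; sd defaults to 0.3. Planted genes receive
3–5 promoter-island probes with true sensitive means in (0.03, 0.15)
and resistant means in (0.65, 0.95) — the magnitude range of the
reference candidate CpGs; all other probes share one mean across
conditions. 5% of probes sit on chromosomes X/Y so the exclusion
filter always has work. Expression couples to the same manifest:
planted genes are downregulated by 1 log2 unit by default with
log-normal noise (sd 0.2 log2 units). The cohort plants a
+24-percentage-point post-treatment shift in non-responders over a 6%
baseline with sd 5 — the magnitudes of the motivating cohort's pre/post
summary statistics. Clinical covariates are drawn from configurable
categorical distributions and are independent of methylation by
construction (the association scan should find nothing).

What the synthetic data does *not* model: probe-specific biases and
spatial correlation along islands, batch/normalization artifacts,
tumor cellularity and FFPE degradation, correlated covariates, or any
dependence of expression noise on expression level. Passing recovery
tests therefore demonstrates that the pipeline's logic is correct
under its own assumptions, not that the thresholds are optimal for
real arrays.

Default problem sizes (2 000 probes, 300 genes, 10 planted, 2
replicates per condition, 20-seed recovery batches, 200-rep
calibration simulations) keep every check fast while leaving the
planted-signal margins non-trivial; they are the package's standing
study conditions and are not tuned per run.

## Numerical conventions and edge cases

- Missing β values drop the probe (no imputation); detection-p
  filtering removes a probe if any sample fails, a deliberately
  conservative reading since aggregate semantics are equally
  defensible.
- Filters are stable (input order preserved) and idempotent.
- r² is undefined for zero-variance condition means and raised as an
  error rather than returned as NaN.
- All seeded generators use `numpy.random.default_rng`; the expression
  and cohort generators derive independent streams from the same seed,
  so one config reproduces the whole bundle byte for byte.

## Known limitations

- Genome-scale quantities from the motivating design (tens of
  thousands of differential CpGs, the exact 31-gene list, a real
  cohort AUC) depend on deposited arrays and unspecified normalization
  and are out of reach by construction; the package reproduces the
  rules, not those counts.
- The DeLong interval is Wald-type and can hit the [0, 1] boundary at
  extreme AUCs with small samples, where its coverage degrades (the
  bootstrap option behaves better there).
- The exact Mann–Whitney path requires tie-free data; tied small
  samples silently use the corrected normal approximation, which can
  be liberal at very small n.
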