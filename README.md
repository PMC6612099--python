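# methsilence

Discovery and evaluation of genes silenced by promoter CpG-island
hypermethylation, built for two-condition drug-resistance studies: a
sensitive cell model versus its resistant derivative (e.g. a
trastuzumab-resistant HER2+ breast cancer line), followed by a
patient-cohort evaluation of a candidate methylation biomarker.

## What it computes

**Discovery cascade.** Starting from a 450K-style β-value matrix
(β ∈ [0, 1], probes × samples), a manifest-style probe annotation and a
normalized per-gene expression table:

1. quality filters — drop probes failing detection (p ≥ 0.01 in any
   sample), probes on chromosomes X/Y, probes with missing β;
2. Δβ = β̄(resistant) − β̄(sensitive) per probe; methylation *gained* /
   *lost* calls at |Δβ| ≥ 0.20;
3. restriction to regulatory probes: CpG-island probes with a
   promoter-class gene annotation (TSS200, TSS1500, 5′UTR, 1stExon);
4. stringent calls: *hypermethylated* iff β(sensitive) < 0.20 **and**
   β(resistant) > 0.60 (mirrored for hypomethylated);
5. gene-level aggregation, then intersection with expression:
   candidates are hypermethylated **and** downregulated at fold change
   ≥ 1.5, shortlisted at ≥ 3 supporting CpGs.

Supporting machinery: global methylome concordance (r² of condition
means), supervised average-linkage clustering of the most variable
CpGs, and an optional hypergeometric gene-set enrichment with
Benjamini–Hochberg FDR control.

**Candidate validation.** Pyrosequencing window averaging, 2^−ΔΔCt
relative expression against an endogenous control, exact small-sample
Mann–Whitney / Kruskal–Wallis tests, and a demethylating-agent
(5-aza-dC) restoration comparison.

**Biomarker evaluation.** For a cohort of pre-/post-treatment biopsies
with response annotation: low/high dichotomization at 20% methylation,
paired and unpaired pre/post comparisons, an empirical ROC curve with
the concordance-identity AUC and a DeLong confidence interval,
univariate logistic calibration with the Hosmer–Lemeshow decile test,
and an association scan against clinical covariates (Spearman,
Mann–Whitney, Kruskal–Wallis, χ²/Fisher as appropriate).

A seeded synthetic-data module generates all of these inputs with
planted signal and a ground-truth manifest, so the full pipeline runs
and can be scored at desk scale.

## Worked example

```python
import tempfile
from methsilence import SynthConfig, generate_bundle, write_fixture
from methsilence.pipeline import PipelineConfig, run_discovery, run_cohort

bundle = generate_bundle(SynthConfig(seed=42))          # 2000 probes, 10 planted genes
paths = write_fixture(bundle, tempfile.mkdtemp())
config = PipelineConfig(inputs={k: str(v) for k, v in paths.items()
                                if k not in ("truth", "config")})
report = run_discovery(config)
for stage, n in report["survivors"].items():
    print(f"{stage:>28}: {n}")
```

prints the survivor count of every filter stage:

```
                probes_input: 2000
    probes_after_detection_p: 2000
  probes_after_sex_exclusion: 1900
           probes_regulatory: 614
            probes_stringent: 40
             genes_stringent: 10
             genes_candidate: 10
           genes_shortlisted: 10
```

All 10 planted genes survive to the shortlist (at the default noise
level of this seed, recovery is typically 90–100%). The cohort side of
the same bundle:

```python
cohort = run_cohort(config)
r = cohort["results"]["roc"]
print("AUC %.3f (95%% CI %.3f-%.3f)" % (r["auc"], r["ci_low"], r["ci_high"]))
```

```
AUC 1.000 (95% CI 1.000-1.000)
```

— the planted +24 percentage-point post-treatment shift in
non-responders separates pre from post samples completely at this
noise level; the paired comparison reports p = 1.8e-4 with 100% of
pairs increased.

The same runs are available from the shell:

```sh
methsilence simulate --config cfg.yaml --out fixtures/
methsilence discover --config cfg.yaml --out discovery.json
methsilence cohort   --config cfg.yaml --out cohort.json
methsilence report   --in discovery.json
```

The package also ships the reference candidate table of 46
promoter-island CpGs (31 hypermethylated-and-downregulated genes,
including *TGFBI*, *CXCL2* and *SLC38A1*), available as
`methsilence.load_candidate_cpgs()`.

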