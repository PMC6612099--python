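"""Seeded synthetic data with the structure the discovery pipeline assumes.

Three linked generators: a two-condition methylome with planted
promoter-island hypermethylation, an expression table in which the
planted genes are downregulated in the resistant condition, and a
patient cohort in which non-responders acquire a post-treatment
methylation increase.  A ground-truth manifest accompanies every
bundle so recovery can be scored exactly.

Beta values are simulated on the logit scale: each probe has a true
per-condition mean, every replicate observes
``expit(logit(mean) + N(0, beta_noise_sd))``, which keeps draws inside
[0, 1] with a controllable spread.  Planted genes receive 3-5
promoter-island probes whose true means mimic the magnitudes seen in
stringently hypermethylated candidate CpGs (sensitive < 0.2, resistant
well above 0.6); 5% of probes sit on chromosomes X/Y so the
sex-chromosome exclusion always has work to do.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import (
    BetaMatrix,
    ExpressionTable,
    read_beta_matrix,
    read_expression_table,
    read_probe_annotation,
)

#: Default categorical covariate distributions, loosely matching the
#: clinical mix of a neoadjuvant HER2+ early breast cancer cohort.
DEFAULT_COVARIATES = {
    "menopause": {"premenopausal": 0.5, "postmenopausal": 0.5},
    "ER": {"negative": 0.2, "positive": 0.8},
    "stage": {"IIB": 0.2, "IIIA": 0.2, "IIIB": 0.6},
    "grade": {"G1-2": 0.9, "G3": 0.1},
    "surgery": {"lumpectomy": 0.3, "mastectomy": 0.7},
}

SEX_CHROMOSOME_FRACTION = 0.05  # fixed so the exclusion filter is exercised


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    The defaults emulate the conditions of the real design at desk
    scale: a couple of thousand probes, ten planted silenced genes with
    3-5 promoter-island CpGs each, logit-scale beta noise of 0.3, a
    planted expression log2 fold change of 1 (comfortably past the
    1.5-fold filter), and a cohort of 4 responders (pre-treatment
    biopsy only) plus 10 non-responders with paired biopsies whose
    post-treatment methylation is shifted by ~24 percentage points over
    a ~6% baseline.
    """

    n_probes: int = 2000
    n_genes: int = 300
    n_planted_hyper_down: int = 10
    promoter_fraction: float = 0.6
    island_fraction: float = 0.5
    replicates_per_condition: int = 2
    beta_noise_sd: float = 0.3
    expr_log2fc_planted: float = 1.0
    expr_noise_sd: float = 0.2
    n_patients_responder: int = 4
    n_patients_nonresponder: int = 10
    cohort_baseline_pct: float = 6.0
    cohort_effect_pct: float = 24.0
    cohort_noise_sd: float = 5.0
    covariate_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_genes", "replicates_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_planted_hyper_down", "n_patients_responder",
                     "n_patients_nonresponder"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_planted_hyper_down > self.n_genes:
            raise ValueError("n_planted_hyper_down exceeds n_genes")
        for name in ("promoter_fraction", "island_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("beta_noise_sd", "expr_noise_sd", "cohort_noise_sd",
                     "cohort_effect_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expr_log2fc_planted < 0:
            raise ValueError("expr_log2fc_planted must be >= 0")


@dataclass
class GroundTruth:
    """Manifest of everything the generators planted."""

    planted_genes: set
    planted_probes: set
    probe_means: pd.DataFrame  # probe x (sens_mean, res_mean)
    gene_expression: pd.DataFrame  # gene x (sens_mean, res_mean), set by expression gen
    patient_shift: dict  # patient_id -> planted post-pre shift in pct
    xy_probes: set
    n_genes: int
    seed: int


@dataclass
class FixtureBundle:
    beta: BetaMatrix
    annotation: pd.DataFrame
    expression: ExpressionTable | None
    cohort: pd.DataFrame | None
    truth: GroundTruth
    config: SynthConfig


def _gene_names(config: SynthConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(config.n_genes)]


def generate_methylome(config: SynthConfig):
    """Generate (BetaMatrix, annotation, GroundTruth) for one study.

    Planted genes each get 3-5 probes annotated Island + promoter
    region, with true sensitive-condition means drawn in (0.03, 0.15)
    and resistant means in (0.65, 0.95).  All other probes share one
    true mean across conditions.  Identical config (including seed)
    reproduces the output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    planted = list(rng.choice(genes, size=config.n_planted_hyper_down, replace=False))
    null_genes = [g for g in genes if g not in set(planted)]

    promoter_regions = ["TSS200", "TSS1500", "5'UTR", "1stExon"]
    probe_rows = []  # (gene, region, island, chrom, sens_mean, res_mean)
    for gene in planted:
        k = int(rng.integers(3, 6))
        chrom = str(int(rng.integers(1, 23)))
        for _ in range(k):
            probe_rows.append(
                (gene, promoter_regions[int(rng.integers(0, 4))], "Island",
                 chrom, float(rng.uniform(0.03, 0.15)), float(rng.uniform(0.65, 0.95)))
            )
    n_planted_probes = len(probe_rows)
    if n_planted_probes > config.n_probes:
        raise ValueError("n_probes too small for the planted genes")
    n_null = config.n_probes - n_planted_probes
    n_xy = int(round(SEX_CHROMOSOME_FRACTION * config.n_probes))
    if n_xy > n_null:
        raise ValueError("n_probes too small to allocate sex-chromosome probes")
    for i in range(n_null):
        if i < n_xy:
            chrom = "X" if rng.random() < 0.5 else "Y"
        else:
            chrom = str(int(rng.integers(1, 23)))
        island = "Island" if rng.random() < config.island_fraction else "OpenSea"
        if rng.random() < config.promoter_fraction:
            region = promoter_regions[int(rng.integers(0, 4))]
        else:
            region = "Body"
        gene = null_genes[int(rng.integers(0, len(null_genes)))] if null_genes else ""
        mean = float(rng.uniform(0.02, 0.98))
        probe_rows.append((gene, region, island, chrom, mean, mean))

    order = rng.permutation(len(probe_rows))
    probe_ids = [f"cg{i:08d}" for i in range(len(probe_rows))]
    annotation = pd.DataFrame(
        {
            "chromosome": [probe_rows[j][3] for j in order],
            "position": rng.integers(1, 200_000_000, size=len(probe_rows)),
            "gene_entries": [
                ((probe_rows[j][0], probe_rows[j][1]),) if probe_rows[j][0] else ()
                for j in order
            ],
            "island_relation": [probe_rows[j][2] for j in order],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    sens_means = np.array([probe_rows[j][4] for j in order])
    res_means = np.array([probe_rows[j][5] for j in order])

    reps = config.replicates_per_condition
    samples = [f"sens_{i + 1}" for i in range(reps)] + [
        f"res_{i + 1}" for i in range(reps)
    ]
    conditions = pd.Series(
        ["sensitive"] * reps + ["resistant"] * reps, index=samples
    )
    means = np.column_stack([sens_means] * reps + [res_means] * reps)
    noise = rng.normal(0.0, config.beta_noise_sd, size=means.shape) \
        if config.beta_noise_sd > 0 else np.zeros_like(means)
    eps = 1e-9
    betas = expit(logit(np.clip(means, eps, 1 - eps)) + noise)
    betas = np.clip(betas, 0.0, 1.0)
    matrix = BetaMatrix(
        values=pd.DataFrame(betas, index=annotation.index, columns=samples),
        conditions=conditions,
    )
    planted_mask = np.array([probe_rows[j][0] in set(planted) for j in order])
    truth = GroundTruth(
        planted_genes=set(planted),
        planted_probes=set(annotation.index[planted_mask]),
        probe_means=pd.DataFrame(
            {"sens_mean": sens_means, "res_mean": res_means}, index=annotation.index
        ),
        gene_expression=pd.DataFrame(columns=["sens_mean", "res_mean"]),
        patient_shift={},
        xy_probes=set(annotation.index[annotation["chromosome"].isin(["X", "Y"])]),
        n_genes=config.n_genes,
        seed=config.seed,
    )
    return matrix, annotation, truth


def generate_expression(truth: GroundTruth, config: SynthConfig) -> ExpressionTable:
    """Generate the expression table coupled to the planted silencing.

    Planted genes are downregulated in the resistant condition by
    ``expr_log2fc_planted`` on the log2 scale; all other genes share a
    common mean.  Per-sample values multiply the gene mean by
    ``2**N(0, expr_noise_sd)``, so everything stays positive.
    """
    if truth.n_genes != config.n_genes:
        raise ValueError("ground truth and config disagree on the gene set")
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_names(config)
    if not set(truth.planted_genes) <= set(genes):
        raise ValueError("planted genes not in configured gene set")
    base = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=len(genes))
    res_mean = base * np.where(
        np.isin(genes, list(truth.planted_genes)),
        2.0 ** (-config.expr_log2fc_planted),
        1.0,
    )
    reps = config.replicates_per_condition
    samples = [f"sens_{i + 1}" for i in range(reps)] + [
        f"res_{i + 1}" for i in range(reps)
    ]
    means = np.column_stack([base] * reps + [res_mean] * reps)
    noise = rng.normal(0.0, config.expr_noise_sd, size=means.shape) \
        if config.expr_noise_sd > 0 else np.zeros_like(means)
    values = means * 2.0 ** noise
    truth.gene_expression = pd.DataFrame(
        {"sens_mean": base, "res_mean": res_mean}, index=pd.Index(genes, name="gene")
    )
    return ExpressionTable(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                            columns=samples),
        conditions=pd.Series(["sensitive"] * reps + ["resistant"] * reps,
                             index=samples),
    )


def generate_cohort(config: SynthConfig):
    """Generate the patient table and record the planted shift.

    Responders contribute a pre-treatment biopsy only; non-responders
    contribute a pre/post pair.  Pre-treatment methylation is drawn
    near a common low baseline for both groups; non-responder
    post-treatment values are shifted upward by ``cohort_effect_pct``.
    Percentages are clipped to [0, 100].
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    shift = {}

    def covariates():
        cov = {"age": int(rng.integers(35, 76))}
        for name, dist in config.covariate_distributions.items():
            levels = list(dist)
            probs = np.array([dist[lv] for lv in levels], dtype=float)
            cov[name] = levels[int(rng.choice(len(levels), p=probs / probs.sum()))]
        return cov

    def draw_pct(mean):
        return float(np.clip(rng.normal(mean, config.cohort_noise_sd), 0.0, 100.0))

    for i in range(config.n_patients_responder):
        pid = f"R{i + 1:02d}"
        cov = covariates()
        shift[pid] = 0.0
        rows.append({"patient_id": pid, "timepoint": "pre",
                     "response": "complete",
                     "methylation_pct": draw_pct(config.cohort_baseline_pct), **cov})
    for i in range(config.n_patients_nonresponder):
        pid = f"N{i + 1:02d}"
        cov = covariates()
        shift[pid] = config.cohort_effect_pct
        rows.append({"patient_id": pid, "timepoint": "pre",
                     "response": "non_response",
                     "methylation_pct": draw_pct(config.cohort_baseline_pct), **cov})
        rows.append({"patient_id": pid, "timepoint": "post",
                     "response": "non_response",
                     "methylation_pct": draw_pct(
                         config.cohort_baseline_pct + config.cohort_effect_pct
                     ), **cov})
    columns = ["patient_id", "timepoint", "response", "methylation_pct",
               "age"] + list(config.covariate_distributions)
    cohort = pd.DataFrame(rows, columns=columns)
    return cohort, shift


def generate_bundle(config: SynthConfig) -> FixtureBundle:
    """Run all three generators with one config."""
    beta, annotation, truth = generate_methylome(config)
    expression = generate_expression(truth, config)
    cohort, shift = generate_cohort(config)
    truth.patient_shift = shift
    return FixtureBundle(beta=beta, annotation=annotation, expression=expression,
                         cohort=cohort, truth=truth, config=config)


def _annotation_to_table(annotation: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "TargetID": annotation.index,
            "Chr": annotation["chromosome"].to_numpy(),
            "Position": annotation["position"].to_numpy(),
            "Gene_Name": [";".join(g for g, _ in e) for e in annotation["gene_entries"]],
            "Gene_Region": [";".join(r for _, r in e) for e in annotation["gene_entries"]],
            "Island_Relation": annotation["island_relation"].to_numpy(),
        }
    )


def write_fixture(bundle: FixtureBundle, directory) -> dict:
    """Write the bundle as the plain-text fixture file set.

    Produces annotation/beta/expression TSVs with their sample sheets,
    the cohort CSV, a JSON ground-truth manifest and a YAML echo of the
    config; all round-trip losslessly through the package readers.
    Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("annotation", "annotation.tsv"),
        ("beta", "beta.tsv"),
        ("beta_samples", "beta_samples.csv"),
        ("expression", "expression.tsv"),
        ("expression_samples", "expression_samples.csv"),
        ("cohort", "cohort.csv"),
        ("truth", "truth.json"),
        ("config", "config.yaml"),
    ]}
    _annotation_to_table(bundle.annotation).to_csv(
        paths["annotation"], sep="\t", index=False
    )
    bundle.beta.values.to_csv(paths["beta"], sep="\t", index_label="TargetID")
    pd.DataFrame({"sample_id": bundle.beta.conditions.index,
                  "condition": bundle.beta.conditions.to_numpy()}).to_csv(
        paths["beta_samples"], index=False)
    if bundle.expression is not None:
        bundle.expression.values.to_csv(paths["expression"], sep="\t",
                                        index_label="gene")
        pd.DataFrame({"sample_id": bundle.expression.conditions.index,
                      "condition": bundle.expression.conditions.to_numpy()}).to_csv(
            paths["expression_samples"], index=False)
    if bundle.cohort is not None:
        bundle.cohort.to_csv(paths["cohort"], index=False)
    truth = bundle.truth
    manifest = {
        "planted_genes": sorted(truth.planted_genes),
        "planted_probes": sorted(truth.planted_probes),
        "xy_probes": sorted(truth.xy_probes),
        "probe_means": {
            p: [float(truth.probe_means.loc[p, "sens_mean"]),
                float(truth.probe_means.loc[p, "res_mean"])]
            for p in truth.probe_means.index
        },
        "gene_expression": {
            g: [float(truth.gene_expression.loc[g, "sens_mean"]),
                float(truth.gene_expression.loc[g, "res_mean"])]
            for g in truth.gene_expression.index
        },
        "patient_shift": {k: float(v) for k, v in truth.patient_shift.items()},
        "n_genes": truth.n_genes,
        "seed": truth.seed,
    }
    paths["truth"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    cfg = asdict(bundle.config)
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def read_fixture(directory) -> FixtureBundle:
    """Read a written fixture back through the package readers."""
    directory = Path(directory)
    annotation = read_probe_annotation(directory / "annotation.tsv")
    beta = read_beta_matrix(directory / "beta.tsv", directory / "beta_samples.csv")
    expression = None
    if (directory / "expression.tsv").exists():
        expression = read_expression_table(
            directory / "expression.tsv", directory / "expression_samples.csv"
        )
    cohort = None
    if (directory / "cohort.csv").exists():
        cohort = pd.read_csv(directory / "cohort.csv")
    manifest = json.loads((directory / "truth.json").read_text())
    probe_means = pd.DataFrame.from_dict(
        manifest["probe_means"], orient="index", columns=["sens_mean", "res_mean"]
    )
    gene_expr = pd.DataFrame.from_dict(
        manifest["gene_expression"], orient="index", columns=["sens_mean", "res_mean"]
    )
    truth = GroundTruth(
        planted_genes=set(manifest["planted_genes"]),
        planted_probes=set(manifest["planted_probes"]),
        probe_means=probe_means,
        gene_expression=gene_expr,
        patient_shift=manifest["patient_shift"],
        xy_probes=set(manifest["xy_probes"]),
        n_genes=manifest["n_genes"],
        seed=manifest["seed"],
    )
    config = SynthConfig(**yaml.safe_load((directory / "config.yaml").read_text()))
    return FixtureBundle(beta=beta, annotation=annotation, expression=expression,
                         cohort=cohort, truth=truth, config=config)
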