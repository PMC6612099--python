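"""Pipeline orchestration: discovery and cohort runs from one config.

``run_discovery`` executes the filter cascade in its canonical order
(detection-p -> sex-chromosome exclusion -> regulatory restriction ->
stringent classification -> gene summary -> expression intersection ->
ranking) and records the survivor count at every stage, so a run can be
lined up against the stage-by-stage narrative of a real analysis.
``run_cohort`` bundles the biomarker statistics for a patient table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biomarker import (
    association_scan,
    compare_pre_post,
    dichotomize,
    fit_univariate_logistic,
    hosmer_lemeshow,
    roc,
)
from .diffmeth import (
    NONE,
    diffmeth_records,
    global_concordance,
    select_regulatory,
    summarize_genes,
)
from .integration import classify_de, fold_change, intersect, rank_candidates
from .io import (
    filter_probes,
    read_beta_matrix,
    read_expression_table,
    read_probe_annotation,
)
from .synthetic import SynthConfig, generate_bundle, write_fixture

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline config is malformed."""


DEFAULT_THRESHOLDS = {
    "delta_min": 0.20,
    "stringent_low": 0.20,
    "stringent_high": 0.60,
    "fc_min": 1.5,
    "min_cpgs": 3,
    "cutoff_pct": 20.0,
    "detection_p_max": 0.01,
    "alpha": 0.05,
    "pseudocount": 0.5,
}

_THRESHOLD_RANGES = {
    "delta_min": (0.0, 1.0),
    "stringent_low": (0.0, 1.0),
    "stringent_high": (0.0, 1.0),
    "fc_min": (1.0, float("inf")),
    "min_cpgs": (1, 1000),
    "cutoff_pct": (0.0, 100.0),
    "detection_p_max": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "pseudocount": (0.0, float("inf")),
}

_INPUT_KEYS = {"annotation", "beta", "beta_samples", "expression",
               "expression_samples", "cohort", "gene_sets"}
_TOP_KEYS = {"inputs", "thresholds", "regulatory_policy",
             "exclude_chromosomes", "seed", "synthetic", "fixture_dir"}


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    regulatory_policy: str = "island_and_promoter"
    exclude_chromosomes: tuple = ("X", "Y")
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    fixture_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        merged = {**DEFAULT_THRESHOLDS, **self.thresholds}
        for key, value in merged.items():
            lo, hi = _THRESHOLD_RANGES[key]
            if not lo <= value <= hi:
                raise ConfigError(f"threshold {key}={value} outside [{lo}, {hi}]")
        if not merged["stringent_low"] < merged["stringent_high"]:
            raise ConfigError("stringent_low must be < stringent_high")
        self.thresholds = merged
        self.exclude_chromosomes = tuple(self.exclude_chromosomes)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "thresholds": dict(self.thresholds),
            "regulatory_policy": self.regulatory_policy,
            "exclude_chromosomes": list(self.exclude_chromosomes),
            "seed": self.seed,
            "synthetic": dict(self.synthetic),
            "fixture_dir": self.fixture_dir,
        }


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _base_report(config: PipelineConfig, used_inputs) -> dict:
    return {
        "version": __version__,
        "config": config.echo(),
        "input_digests": {k: _digest(config.inputs[k]) for k in used_inputs
                          if k in config.inputs},
        "skipped": [],
    }


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the discovery cascade and return the structured report."""
    thr = config.thresholds
    annotation = read_probe_annotation(config.inputs["annotation"])
    matrix = read_beta_matrix(config.inputs["beta"], config.inputs["beta_samples"])
    report = _base_report(
        config, ["annotation", "beta", "beta_samples", "expression",
                 "expression_samples"]
    )
    survivors = {"probes_input": int(len(matrix.probe_ids))}

    m_detect = filter_probes(matrix, annotation, exclude_chromosomes=(),
                             detection_p_max=thr["detection_p_max"])
    survivors["probes_after_detection_p"] = int(len(m_detect.probe_ids))
    m_auto = filter_probes(m_detect, annotation,
                           exclude_chromosomes=config.exclude_chromosomes,
                           detection_p_max=thr["detection_p_max"])
    survivors["probes_after_sex_exclusion"] = int(len(m_auto.probe_ids))

    assignments = select_regulatory(annotation.loc[m_auto.probe_ids],
                                    policy=config.regulatory_policy)
    reg_probes = [p for p in m_auto.probe_ids
                  if p in set(assignments["probe_id"])]
    survivors["probes_regulatory"] = int(len(reg_probes))

    records_all = diffmeth_records(m_auto, delta_min=thr["delta_min"],
                                   low=thr["stringent_low"],
                                   high=thr["stringent_high"])
    records = records_all.loc[reg_probes]
    survivors["probes_stringent"] = int((records["stringent_class"] != NONE).sum())

    summaries = summarize_genes(records, assignments)
    survivors["genes_stringent"] = int(len(summaries))

    try:
        r_squared = global_concordance(m_auto)
    except ValueError as exc:
        r_squared = None
        report["skipped"].append(f"global_concordance: {exc}")

    expr = read_expression_table(config.inputs["expression"],
                                 config.inputs["expression_samples"])
    if len(expr.genes) == 0:
        calls = None
        de_sets = {"up": set(), "down": set()}
        report["skipped"].append("fold_change: empty expression table")
    else:
        calls = fold_change(expr, pseudocount=thr["pseudocount"])
        de_sets = classify_de(calls, fc_min=thr["fc_min"])
    venn = intersect(summaries, de_sets, expression_calls=calls)
    survivors["genes_candidate"] = int(venn["counts"]["hyper_and_down"])
    shortlist = rank_candidates(venn["candidates"], min_cpgs=thr["min_cpgs"])
    survivors["genes_shortlisted"] = int(len(shortlist))

    report.update(
        {
            "survivors": survivors,
            "r_squared": r_squared,
            "venn_counts": venn["counts"],
            "n_de_up": len(de_sets["up"]),
            "n_de_down": len(de_sets["down"]),
            "candidates": venn["candidates"].reset_index().to_dict(orient="records"),
            "shortlist": shortlist.reset_index().to_dict(orient="records"),
            "gene_summaries": {
                g: {"n_hyper": int(summaries.loc[g, "n_hyper"]),
                    "n_hypo": int(summaries.loc[g, "n_hypo"]),
                    "probes": list(summaries.loc[g, "probes"])}
                for g in summaries.index
            },
        }
    )
    return report


def _patient_frame(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """One row per patient: covariates plus the methylation value to scan.

    Post-treatment methylation is used when a patient has a post
    sample (the timepoint at which resistance-associated gain shows),
    the pre value otherwise.
    """
    covar_cols = [c for c in cohort.columns
                  if c not in ("patient_id", "timepoint", "response",
                               "methylation_pct")]
    rows = {}
    meth = {}
    for pid, grp in cohort.groupby("patient_id"):
        post = grp[grp["timepoint"] == "post"]
        chosen = post.iloc[0] if len(post) else grp.iloc[0]
        rows[pid] = chosen[covar_cols]
        meth[pid] = float(chosen["methylation_pct"])
    frame = pd.DataFrame(rows).T.infer_objects()
    frame.index.name = "patient_id"
    return frame, pd.Series(meth, name="methylation_pct")


def run_cohort(config: PipelineConfig) -> dict:
    """Run the biomarker evaluation battery on the cohort table."""
    thr = config.thresholds
    cohort = pd.read_csv(config.inputs["cohort"])
    required = {"patient_id", "timepoint", "response", "methylation_pct"}
    if not required <= set(cohort.columns):
        raise ConfigError(f"cohort table needs columns {sorted(required)}")
    report = _base_report(config, ["cohort"])
    results: dict = {}

    try:
        unpaired = compare_pre_post(cohort)
        results["pre_post_unpaired"] = {
            "p_value": unpaired["test"].p_value,
            "statistic": unpaired["test"].statistic,
            "method": unpaired["test"].method,
            "mean_pre": unpaired["mean_pre"],
            "mean_post": unpaired["mean_post"],
        }
    except ValueError as exc:
        report["skipped"].append(f"pre_post_unpaired: {exc}")

    try:
        paired = compare_pre_post(cohort, paired_only=True)
        results["pre_post_paired"] = {
            "p_value": paired["test"].p_value,
            "method": paired["test"].method,
            "n_pairs": paired["n_pairs"],
            "fraction_increased": paired["fraction_increased"],
            "deltas": {k: float(v) for k, v in paired["deltas"].items()},
        }
    except ValueError as exc:
        report["skipped"].append(f"pre_post_paired: {exc}")

    groups = dichotomize(cohort["methylation_pct"], cutoff=thr["cutoff_pct"])
    results["dichotomized_counts"] = {
        tp: {lvl: int(((cohort["timepoint"] == tp) & (groups == lvl)).sum())
             for lvl in ("low", "high")}
        for tp in ("pre", "post")
    }
    results["dichotomize_cutoff"] = {
        "cutoff_pct": thr["cutoff_pct"],
        "boundary_rule": "a value exactly at the cutoff is classed high",
    }

    is_pos = (cohort["timepoint"] == "post") & (cohort["response"] == "non_response")
    is_neg = cohort["timepoint"] == "pre"
    roc_frame = cohort[is_pos | is_neg]
    labels = is_pos[is_pos | is_neg].map({True: "resistant", False: "baseline"})
    try:
        curve = roc(roc_frame["methylation_pct"], labels, positive_label="resistant")
        results["roc"] = {
            "auc": curve.auc, "ci_low": curve.ci_low, "ci_high": curve.ci_high,
            "ci_method": curve.ci_method,
            "youden_threshold": curve.youden_threshold,
            "n_positive": curve.n_positive, "n_negative": curve.n_negative,
            "points": [
                {"threshold": float(t), "sensitivity": float(se),
                 "specificity": float(sp)}
                for t, se, sp in zip(curve.thresholds, curve.sensitivity,
                                     curve.specificity)
            ],
        }
    except ValueError as exc:
        curve = None
        report["skipped"].append(f"roc: {exc}")

    try:
        y = (labels == "resistant").astype(float).to_numpy()
        fit = fit_univariate_logistic(roc_frame["methylation_pct"].to_numpy(), y)
        results["logistic"] = {
            "intercept": fit.intercept, "slope": fit.slope,
            "converged": fit.converged, "separation": fit.separation,
        }
        n = len(y)
        n_groups = 10 if n >= 20 else max(3, n // 2)
        cal = hosmer_lemeshow(fit.predicted, y, n_groups=n_groups)
        results["hosmer_lemeshow"] = {
            "chi_square": cal.chi_square, "df": cal.df, "p_value": cal.p_value,
            "n_groups": cal.n_groups,
            "observed": [float(v) for v in cal.observed],
            "expected": [float(v) for v in cal.expected],
            "bin_sizes": [int(v) for v in cal.bin_sizes],
        }
    except ValueError as exc:
        report["skipped"].append(f"calibration: {exc}")

    try:
        frame, meth = _patient_frame(cohort)
        scan = association_scan(frame, meth, cutoff=thr["cutoff_pct"])
        results["association_scan"] = scan.to_dict(orient="records")
    except ValueError as exc:
        report["skipped"].append(f"association_scan: {exc}")

    report["results"] = results
    return report


def make_fixtures(config: PipelineConfig, out_dir=None) -> dict:
    """Generate and write a fixture bundle per the config's synthetic block."""
    synth_kwargs = dict(config.synthetic)
    synth_kwargs.setdefault("seed", config.seed)
    try:
        synth = SynthConfig(**synth_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic block: {exc}") from exc
    bundle = generate_bundle(synth)
    target = out_dir or config.fixture_dir
    if target is None:
        raise ConfigError("no output directory for fixtures")
    return write_fixture(bundle, target)
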