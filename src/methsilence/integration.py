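"""Methylation x expression integration.

Couples the gene-level stringent methylation summaries to an expression
fold-change filter, intersects the two (hypermethylated & downregulated
vs hypomethylated & overexpressed), ranks candidates by supporting CpG
count, and offers a generic hypergeometric gene-set enrichment with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .diffmeth import HYPER, HYPO
from .io import ExpressionTable

UP, DOWN, NONE = "up_in_resistant", "down_in_resistant", "none"


def fold_change(expr: ExpressionTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene condition means and oriented fold change.

    The fold change is the ratio of condition means oriented to be
    >= 1, with a ``direction`` flag; the pseudocount is added to both
    means only when either is zero, so that informative ratios are
    untouched while division by zero is impossible.
    Requires samples in both conditions.
    """
    for cond in ("sensitive", "resistant"):
        if not expr.samples_of(cond):
            raise ValueError(f"expression table has no {cond} samples")
    means = expr.condition_means()
    sens = means["sensitive"].to_numpy(dtype=float)
    res = means["resistant"].to_numpy(dtype=float)
    guard = (sens == 0) | (res == 0)
    sens = np.where(guard, sens + pseudocount, sens)
    res = np.where(guard, res + pseudocount, res)
    fc = np.maximum(sens, res) / np.minimum(sens, res)
    direction = np.where(res > sens, UP, np.where(sens > res, DOWN, NONE))
    return pd.DataFrame(
        {
            "expr_sens": means["sensitive"],
            "expr_res": means["resistant"],
            "fold_change": fc,
            "direction": direction,
        },
        index=means.index,
    )


def classify_de(calls: pd.DataFrame, fc_min: float = 1.5) -> dict:
    """Partition genes into up/down sets at fold change >= fc_min (inclusive)."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    passed = calls["fold_change"] >= fc_min
    return {
        "up": set(calls.index[passed & (calls["direction"] == UP)]),
        "down": set(calls.index[passed & (calls["direction"] == DOWN)]),
    }


def intersect(meth_summaries: pd.DataFrame, de_sets: dict,
              expression_calls: pd.DataFrame | None = None) -> dict:
    """Venn intersection of methylation and expression gene sets.

    The concordant quadrants are hypermethylated & downregulated
    (promoter silencing) and hypomethylated & overexpressed
    (derepression).  Returns the four Venn counts and the silencing
    candidates as a DataFrame (gene, n_hyper_cpgs, fold_change,
    direction).
    """
    hyper = set(meth_summaries.index[meth_summaries["n_hyper"] >= 1]) \
        if len(meth_summaries) else set()
    hypo = set(meth_summaries.index[meth_summaries["n_hypo"] >= 1]) \
        if len(meth_summaries) else set()
    down = set(de_sets.get("down", set()))
    up = set(de_sets.get("up", set()))
    candidates_genes = sorted(hyper & down)
    rows = []
    for gene in candidates_genes:
        fc = np.nan
        if expression_calls is not None and gene in expression_calls.index:
            fc = float(expression_calls.loc[gene, "fold_change"])
        rows.append(
            {
                "gene": gene,
                "n_hyper_cpgs": int(meth_summaries.loc[gene, "n_hyper"]),
                "fold_change": fc,
                "direction": DOWN,
            }
        )
    candidates = pd.DataFrame(
        rows, columns=["gene", "n_hyper_cpgs", "fold_change", "direction"]
    ).set_index("gene")
    return {
        "counts": {
            "hyper_and_down": len(hyper & down),
            "hyper_only": len(hyper - down),
            "down_only": len(down - hyper),
            "hypo_and_up": len(hypo & up),
        },
        "candidates": candidates,
    }


def rank_candidates(candidates: pd.DataFrame, min_cpgs: int = 3) -> pd.DataFrame:
    """Shortlist candidates with >= min_cpgs supporting stringent CpGs.

    Sorted by (CpG count desc, fold change desc, gene symbol asc); the
    tie-break beyond CpG count is a convention of this package — in
    practice, final gene selection also weighs prior biological
    knowledge, which no ranking rule can encode.
    """
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    kept = candidates[candidates["n_hyper_cpgs"] >= min_cpgs]
    kept = (
        kept.rename_axis("gene")
        .reset_index()
        .sort_values(
            by=["n_hyper_cpgs", "fold_change", "gene"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("gene")
    )
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0] == "":
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich_gene_sets(candidates, universe, gene_sets) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of candidates in each gene set.

    ``gene_sets`` may be a GMT path or a mapping name -> member set.
    For each set, p = P(overlap >= observed) drawing |candidates| genes
    from the universe without replacement; q-values are
    Benjamini-Hochberg across sets.
    """
    candidates = set(candidates)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidates outside universe: {sorted(stray)[:5]}")
    if not isinstance(gene_sets, dict):
        gene_sets = read_gmt(gene_sets)
    rows = []
    for name, members in gene_sets.items():
        members_in = members & universe
        k = len(candidates & members_in)
        # P(X >= k) for X ~ Hypergeom(M=|universe|, K=|set|, n=|candidates|)
        p = float(hypergeom.sf(k - 1, len(universe), len(members_in), len(candidates)))
        rows.append({"gene_set": name, "overlap": k, "set_size": len(members_in),
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = []
    return table.set_index("gene_set")
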