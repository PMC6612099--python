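"""Differential-methylation cascade for a sensitive vs resistant contrast.

The cascade mirrors the discovery design for epigenetically silenced
genes: per-probe condition means and their difference (delta-beta,
resistant minus sensitive), gain/loss calls at |delta| >= 0.20,
restriction to regulatory probes (CpG island + promoter-class region),
a stringent hyper/hypomethylation call (beta < 0.20 on one side and
> 0.60 on the other), and gene-level aggregation of the stringent calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import PROMOTER_REGIONS, BetaMatrix

GAINED, LOST, NONE = "gained", "lost", "none"
HYPER, HYPO = "hypermethylated", "hypomethylated"

REGULATORY_POLICIES = ("island_and_promoter", "island_or_promoter")


def delta_beta(matrix: BetaMatrix) -> pd.DataFrame:
    """Per-probe condition means and delta = resistant - sensitive.

    Replicates within a condition are averaged arithmetically.
    Returns a DataFrame indexed by probe with columns ``beta_sens``,
    ``beta_res``, ``delta``.
    """
    means = matrix.condition_means()
    out = pd.DataFrame(
        {
            "beta_sens": means["sensitive"],
            "beta_res": means["resistant"],
        }
    )
    out["delta"] = out["beta_res"] - out["beta_sens"]
    return out


def classify_gain_loss(delta, threshold: float = 0.20):
    """Call methylation gain/loss at |delta| >= threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    delta_arr = np.asarray(delta, dtype=float)
    calls = np.where(
        delta_arr >= threshold, GAINED, np.where(delta_arr <= -threshold, LOST, NONE)
    )
    if np.isscalar(delta) or delta_arr.ndim == 0:
        return str(calls)
    if isinstance(delta, pd.Series):
        return pd.Series(calls, index=delta.index)
    return calls


def classify_stringent(beta_sens, beta_res, low: float = 0.20, high: float = 0.60,
                       tol: float = 0.0):
    """Stringent class: hypermethylated iff beta_sens < low and beta_res > high.

    The mirrored condition (beta_res < low and beta_sens > high) is
    hypomethylated; anything else is none.  Comparisons are strict, per
    the stringency of the rule; ``tol`` relaxes both by a rounding
    guard (useful for beta values published at two decimals, where
    tol=0.005 is half an ulp of the printed precision).
    """
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    s = np.asarray(beta_sens, dtype=float)
    r = np.asarray(beta_res, dtype=float)
    hyper = (s < low + tol) & (r > high - tol)
    hypo = (r < low + tol) & (s > high - tol)
    calls = np.where(hyper, HYPER, np.where(hypo, HYPO, NONE))
    if calls.ndim == 0:
        return str(calls)
    if isinstance(beta_sens, pd.Series):
        return pd.Series(calls, index=beta_sens.index)
    return calls


def select_regulatory(annotation: pd.DataFrame,
                      policy: str = "island_and_promoter") -> pd.DataFrame:
    """Probe -> gene assignments restricted to regulatory context.

    Default policy: the probe must sit on a CpG island AND have at
    least one gene entry in a promoter-class region (TSS200, TSS1500,
    5'UTR, 1stExon); the probe is assigned to every gene for which it
    has a qualifying promoter-class entry.  The ``island_or_promoter``
    policy accepts either condition; the gene assignment still follows
    promoter-class entries when any exist, otherwise all entries.

    Returns a DataFrame with columns ``probe_id``, ``gene``, ``region``
    (one row per assignment, input probe order preserved).
    """
    if policy not in REGULATORY_POLICIES:
        raise ValueError(f"unknown regulatory policy: {policy!r}")
    rows = []
    for probe_id, ann in annotation.iterrows():
        on_island = ann["island_relation"] == "Island"
        promoter_entries = [
            (g, r) for g, r in ann["gene_entries"] if r in PROMOTER_REGIONS
        ]
        if policy == "island_and_promoter":
            qualifying = promoter_entries if on_island else []
        else:
            if on_island:
                qualifying = promoter_entries or list(ann["gene_entries"])
            else:
                qualifying = promoter_entries
        seen = set()
        for gene, region in qualifying:
            if gene not in seen:
                seen.add(gene)
                rows.append((probe_id, gene, region))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "region"])


def diffmeth_records(matrix: BetaMatrix, delta_min: float = 0.20,
                     low: float = 0.20, high: float = 0.60) -> pd.DataFrame:
    """Full per-probe record table: means, delta, gain/loss, stringent class."""
    rec = delta_beta(matrix)
    rec["gainloss"] = classify_gain_loss(rec["delta"], threshold=delta_min)
    rec["stringent_class"] = classify_stringent(
        rec["beta_sens"], rec["beta_res"], low=low, high=high
    )
    return rec


def summarize_genes(records: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Aggregate stringent probe calls per gene.

    ``records`` is the per-probe table from :func:`diffmeth_records`
    restricted to regulatory probes; ``assignments`` maps probes to
    genes (from :func:`select_regulatory`).  Returns one row per gene
    with at least one stringent probe: ``n_hyper``, ``n_hypo``, the
    contributing probe IDs and the regions present.
    """
    merged = assignments.merge(
        records[["stringent_class"]], left_on="probe_id", right_index=True
    )
    merged = merged[merged["stringent_class"].isin([HYPER, HYPO])]
    if merged.empty:
        return pd.DataFrame(
            columns=["n_hyper", "n_hypo", "probes", "regions"],
            index=pd.Index([], name="gene"),
        )
    out = (
        merged.groupby("gene", sort=True)
        .apply(
            lambda g: pd.Series(
                {
                    "n_hyper": int((g["stringent_class"] == HYPER).sum()),
                    "n_hypo": int((g["stringent_class"] == HYPO).sum()),
                    "probes": tuple(g["probe_id"]),
                    "regions": tuple(sorted(set(g["region"]))),
                }
            ),
            include_groups=False,
        )
    )
    out["n_hyper"] = out["n_hyper"].astype(int)
    out["n_hypo"] = out["n_hypo"].astype(int)
    return out


def global_concordance(matrix: BetaMatrix) -> float:
    """Squared Pearson correlation of per-probe condition means.

    Measures how similar the two methylomes are genome-wide; a high
    r-squared with a cloud of off-diagonal probes is the expected
    signature of focal differential methylation.
    """
    means = matrix.condition_means().dropna()
    if len(means) < 2:
        raise ValueError("need at least 2 probes")
    x = means["sensitive"].to_numpy()
    y = means["resistant"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a condition; r^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def cluster_top_cpgs(matrix: BetaMatrix, records: pd.DataFrame,
                     delta_min: float = 0.20) -> dict:
    """Hierarchical clustering of the most variable CpGs (|delta| >= delta_min).

    Average-linkage agglomeration on Euclidean distances, for both
    samples and probes; scipy's deterministic tie-handling plus the
    stable input order make the result reproducible.  Returns linkage
    matrices and leaf orderings.
    """
    qualifying = records.index[records["delta"].abs() >= delta_min]
    if len(qualifying) < 2:
        raise ValueError("fewer than 2 CpGs pass the delta-beta filter")
    sub = matrix.values.loc[qualifying]
    probe_link = linkage(pdist(sub.to_numpy()), method="average")
    sample_link = linkage(pdist(sub.to_numpy().T), method="average")
    return {
        "probe_ids": list(sub.index),
        "sample_ids": list(sub.columns),
        "probe_linkage": probe_link,
        "sample_linkage": sample_link,
        "probe_order": [sub.index[i] for i in leaves_list(probe_link)],
        "sample_order": [sub.columns[i] for i in leaves_list(sample_link)],
    }
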