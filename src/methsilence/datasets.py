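"""Packaged reference data.

``candidate_cpgs.tsv`` is the worked reference example shipped with the
package: the 46 promoter-island CpGs supporting the 31 genes found both
stringently hypermethylated and downregulated in a trastuzumab-resistant
breast cancer model (SKTR) relative to its sensitive parent line (SK).
Columns carry the manifest-style probe annotation, the per-condition
beta values as published (two decimals) and the published difference
column.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import parse_gene_entries


def load_candidate_cpgs() -> pd.DataFrame:
    """The reference candidate CpG table, indexed by probe ID.

    Returns the annotation columns (``chromosome``, ``position``,
    ``gene_entries``, ``island_relation``) together with ``beta_sens``,
    ``beta_res`` and ``delta_printed`` (the published difference, which
    on a few rows differs from the subtraction of the two-decimal betas
    by one rounding ulp).
    """
    with resources.files("methsilence.data").joinpath("candidate_cpgs.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t", dtype={"Chr": str})
    out = pd.DataFrame(
        {
            "chromosome": raw["Chr"].astype(str).to_numpy(),
            "position": raw["Position"].astype(int).to_numpy(),
            "gene_entries": [
                parse_gene_entries(g, r)
                for g, r in zip(raw["Gene_Name"], raw["Gene_Region"])
            ],
            "island_relation": raw["Island_Relation"].to_numpy(),
            "beta_sens": raw["beta_sens"].astype(float).to_numpy(),
            "beta_res": raw["beta_res"].astype(float).to_numpy(),
            "delta_printed": raw["delta_printed"].astype(float).to_numpy(),
        },
        index=pd.Index(raw["TargetID"], name="probe_id"),
    )
    return out
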