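"""Readers and filters for 450K-style methylation and expression tables.

The pipeline starts from normalised data: a probe annotation table
(mimicking the Illumina 450K manifest columns), a probes x samples matrix
of beta values (methylation fractions in [0, 1]), and a per-gene
normalised expression table.  Raw IDAT handling and array normalisation
are out of scope; values are taken as deposited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gene-region groups of the 450K manifest counted as promoter-class.
PROMOTER_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon")

#: All gene-region tokens the manifest uses.
VALID_REGIONS = PROMOTER_REGIONS + ("Body", "3'UTR")

VALID_ISLAND_RELATIONS = (
    "Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea",
)

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

CONDITIONS = ("sensitive", "resistant")

# Unicode prime variants occasionally found in exported manifests.
_REGION_NORMALISE = {"5′UTR": "5'UTR", "3′UTR": "3'UTR",
                     "5’UTR": "5'UTR", "3’UTR": "3'UTR"}

ANNOTATION_COLUMNS = ["TargetID", "Chr", "Position", "Gene_Name",
                      "Gene_Region", "Island_Relation"]


class MethylomeIOError(ValueError):
    """Raised when an input table violates its documented format."""


def _normalise_region(token: str) -> str:
    token = _REGION_NORMALISE.get(token, token)
    if token not in VALID_REGIONS:
        raise MethylomeIOError(f"malformed gene-region token: {token!r}")
    return token


def parse_gene_entries(gene_field, region_field) -> tuple[tuple[str, str], ...]:
    """Zip semicolon-delimited symbol and region lists into (symbol, region) pairs.

    The manifest repeats the symbol once per transcript, so the two lists
    are zipped pairwise and then deduplicated (first occurrence wins,
    order preserved).  Lists of unequal length are an error: the pairing
    would be ambiguous.
    """
    if gene_field is None or (isinstance(gene_field, float) and np.isnan(gene_field)):
        gene_field = ""
    if region_field is None or (isinstance(region_field, float) and np.isnan(region_field)):
        region_field = ""
    genes = [g for g in str(gene_field).split(";") if g != ""]
    regions = [r for r in str(region_field).split(";") if r != ""]
    if len(genes) != len(regions):
        raise MethylomeIOError(
            f"gene list ({len(genes)}) and region list ({len(regions)}) "
            f"differ in length: {gene_field!r} vs {region_field!r}"
        )
    pairs = []
    for g, r in zip(genes, regions):
        pair = (g, _normalise_region(r))
        if pair not in pairs:
            pairs.append(pair)
    return tuple(pairs)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read a manifest-style annotation TSV.

    Returns a DataFrame indexed by probe ID with columns ``chromosome``
    (string label), ``position`` (1-based, as in the manifest MAPINFO
    column), ``gene_entries`` (tuple of deduplicated (symbol, region)
    pairs) and ``island_relation``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise MethylomeIOError(f"annotation table missing columns: {missing}")
    if raw["TargetID"].duplicated().any():
        dupes = raw["TargetID"][raw["TargetID"].duplicated()].tolist()
        raise MethylomeIOError(f"duplicate probe IDs in annotation: {dupes[:5]}")
    chrom = raw["Chr"].astype(str)
    bad_chrom = sorted(set(chrom) - set(VALID_CHROMOSOMES))
    if bad_chrom:
        raise MethylomeIOError(f"unknown chromosome labels: {bad_chrom}")
    position = pd.to_numeric(raw["Position"], errors="raise").astype(np.int64)
    if (position < 1).any():
        raise MethylomeIOError("positions must be >= 1 (1-based coordinates)")
    bad_rel = sorted(set(raw["Island_Relation"]) - set(VALID_ISLAND_RELATIONS))
    if bad_rel:
        raise MethylomeIOError(f"unknown island relation: {bad_rel}")
    entries = [
        parse_gene_entries(g, r)
        for g, r in zip(raw["Gene_Name"], raw["Gene_Region"])
    ]
    out = pd.DataFrame(
        {
            "chromosome": chrom.to_numpy(),
            "position": position.to_numpy(),
            "gene_entries": entries,
            "island_relation": raw["Island_Relation"].to_numpy(),
        },
        index=pd.Index(raw["TargetID"], name="probe_id"),
    )
    return out


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` rows are probes, columns are samples; ``conditions`` maps
    each sample to ``sensitive`` or ``resistant``.  ``detection_p`` is an
    optional same-shaped matrix of detection p-values.
    """

    values: pd.DataFrame
    conditions: pd.Series
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        unknown = sorted(set(self.conditions) - set(CONDITIONS))
        if unknown:
            raise MethylomeIOError(f"unknown condition labels: {unknown}")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise MethylomeIOError(f"samples without a condition: {missing}")
        self.conditions = self.conditions.loc[list(self.values.columns)]
        for cond in CONDITIONS:
            if not (self.conditions == cond).any():
                raise MethylomeIOError(f"no samples in condition {cond!r}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise MethylomeIOError("beta values must lie in [0, 1]")
        if self.values.index.duplicated().any():
            raise MethylomeIOError("duplicate probe IDs in beta matrix")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise MethylomeIOError("detection_p shape differs from beta matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Arithmetic mean beta per probe within each condition."""
        return pd.DataFrame(
            {c: self.values[self.samples_of(c)].mean(axis=1) for c in CONDITIONS}
        )

    def subset(self, probe_ids) -> "BetaMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return replace(self, values=self.values.loc[probe_ids], detection_p=det)


def read_sample_sheet(path) -> pd.Series:
    sheet = pd.read_csv(path, dtype=str)
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise MethylomeIOError("sample sheet needs columns sample_id, condition")
    if sheet["sample_id"].duplicated().any():
        raise MethylomeIOError("duplicate sample_id in sample sheet")
    return pd.Series(sheet["condition"].to_numpy(), index=sheet["sample_id"].to_numpy())


def read_beta_matrix(path, sample_sheet) -> BetaMatrix:
    """Read a beta-value TSV (first column TargetID) plus a sample sheet.

    ``sample_sheet`` is a path to a CSV with columns sample_id,condition
    or an equivalent mapping.  Empty cells are preserved as missing.
    """
    if not isinstance(sample_sheet, (pd.Series, dict)):
        sample_sheet = read_sample_sheet(sample_sheet)
    conditions = pd.Series(sample_sheet)
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "probe_id"
    unknown = [s for s in table.columns if s not in conditions.index]
    if unknown:
        raise MethylomeIOError(f"samples not in sample sheet: {unknown}")
    return BetaMatrix(values=table.astype(float), conditions=conditions[list(table.columns)])


def filter_probes(
    matrix: BetaMatrix,
    annotation: pd.DataFrame,
    exclude_chromosomes=("X", "Y"),
    detection_p_max: float = 0.01,
) -> BetaMatrix:
    """Apply the quality and sex-chromosome filters.

    Removes, in input order (stable): probes on excluded chromosomes
    (sex chromosomes by default, a high source of inter-sample
    methylation variation), probes whose detection p-value is >=
    ``detection_p_max`` in any sample (when a detection matrix is
    present), and probes with any missing beta.  Idempotent.
    """
    missing_ann = matrix.probe_ids.difference(annotation.index)
    if len(missing_ann):
        raise MethylomeIOError(
            f"probes absent from annotation: {list(missing_ann[:5])}"
        )
    ann = annotation.loc[matrix.probe_ids]
    keep = ~ann["chromosome"].isin(set(exclude_chromosomes))
    if matrix.detection_p is not None:
        keep &= (matrix.detection_p < detection_p_max).all(axis=1)
    keep &= matrix.values.notna().all(axis=1)
    if not keep.any():
        logger.warning("filter_probes removed every probe")
    return matrix.subset(matrix.probe_ids[keep.to_numpy()])


@dataclass
class ExpressionTable:
    """Per-gene normalised expression for two conditions (values > 0)."""

    values: pd.DataFrame  # genes x samples
    conditions: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()]
            raise MethylomeIOError(f"duplicate gene symbol: {list(dupes[:5])}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise MethylomeIOError("negative expression value")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise MethylomeIOError(f"samples without a condition: {missing}")
        self.conditions = self.conditions.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.values[self.samples_of(c)].mean(axis=1) for c in CONDITIONS}
        )


def read_expression_table(path, sample_sheet) -> ExpressionTable:
    """Read a per-gene expression TSV (first column gene symbol)."""
    if not isinstance(sample_sheet, (pd.Series, dict)):
        sample_sheet = read_sample_sheet(sample_sheet)
    conditions = pd.Series(sample_sheet)
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "gene"
    return ExpressionTable(values=table.astype(float), conditions=conditions)
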