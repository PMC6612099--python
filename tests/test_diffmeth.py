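import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsilence.datasets import load_candidate_cpgs
from methsilence.diffmeth import (
    GAINED,
    HYPER,
    HYPO,
    LOST,
    NONE,
    classify_gain_loss,
    classify_stringent,
    cluster_top_cpgs,
    delta_beta,
    diffmeth_records,
    global_concordance,
    select_regulatory,
    summarize_genes,
)
from methsilence.io import BetaMatrix


def test_delta_beta_reference_row():
    """Published candidate CpG: beta 0.06 vs 0.61 gives delta 0.55."""
    values = pd.DataFrame({"s": [0.06], "r": [0.61]},
                          index=pd.Index(["cg14120129"], name="probe_id"))
    out = delta_beta(BetaMatrix(values, pd.Series({"s": "sensitive",
                                                   "r": "resistant"})))
    assert out.loc["cg14120129", "delta"] == pytest.approx(0.55)


def test_delta_beta_replicate_means(toy_matrix):
    out = delta_beta(toy_matrix)
    assert out.loc["cg1", "beta_sens"] == pytest.approx(0.15)
    assert out.loc["cg1", "beta_res"] == pytest.approx(0.75)
    assert out.loc["cg1", "delta"] == pytest.approx(0.60)
    assert out.loc["cg2", "delta"] == pytest.approx(0.0)


@pytest.mark.parametrize(
    "delta, expected",
    [(0.55, GAINED), (-0.55, LOST), (0.1999, NONE), (0.20, GAINED), (-0.20, LOST)],
)
def test_gain_loss_boundaries(delta, expected):
    """Gain/loss is inclusive at |delta| >= 0.20; below is no call."""
    assert classify_gain_loss(delta) == expected


@pytest.mark.parametrize(
    "sens, res, expected",
    [
        (0.11, 0.61, HYPER),  # reference candidate cg21034676
        (0.61, 0.11, HYPO),
        (0.5, 0.5, NONE),
        (0.20, 0.61, NONE),  # strict boundary on the low side
        (0.19, 0.60, NONE),  # strict boundary on the high side
    ],
)
def test_stringent_rule(sens, res, expected):
    assert classify_stringent(sens, res) == expected


@settings(deadline=None, derandomize=True)
@given(
    s=st.floats(min_value=0, max_value=1, allow_nan=False),
    r=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_stringent_mirror_symmetry(s, r):
    """Swapping conditions maps hypermethylated to hypomethylated exactly."""
    forward = classify_stringent(s, r)
    backward = classify_stringent(r, s)
    mirror = {HYPER: HYPO, HYPO: HYPER, NONE: NONE}
    assert backward == mirror[forward]


@settings(deadline=None, derandomize=True)
@given(
    s=st.floats(min_value=0, max_value=1, allow_nan=False),
    r=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_stringent_call_implies_gain_loss_call(s, r):
    """A stringent call forces |delta| > 0.40, hence a gain/loss call at 0.20."""
    if classify_stringent(s, r) != NONE:
        assert classify_gain_loss(r - s) != NONE


def test_all_reference_rows_classified_hypermethylated():
    table = load_candidate_cpgs()
    calls = classify_stringent(table["beta_sens"], table["beta_res"], tol=0.005)
    assert (calls == HYPER).all()


def test_select_regulatory_promoter_island():
    ann = pd.DataFrame(
        {
            "chromosome": ["5", "16", "2"],
            "position": [135364552, 67218584, 100],
            "gene_entries": [
                (("TGFBI", "TSS200"),),
                (("KIAA0895L", "TSS1500"), ("EXOC3L", "Body")),
                (("SOMEGENE", "TSS200"),),
            ],
            "island_relation": ["Island", "Island", "OpenSea"],
        },
        index=pd.Index(["cg21034676", "cg01568244", "cgX"], name="probe_id"),
    )
    assigned = select_regulatory(ann)
    pairs = set(zip(assigned["probe_id"], assigned["gene"]))
    assert ("cg21034676", "TGFBI") in pairs
    assert ("cg01568244", "KIAA0895L") in pairs
    assert "EXOC3L" not in set(assigned["gene"])  # Body-only entry not assigned
    assert "cgX" not in set(assigned["probe_id"])  # OpenSea fails island test
    # the OR policy keeps the open-sea promoter probe
    relaxed = select_regulatory(ann, policy="island_or_promoter")
    assert "cgX" in set(relaxed["probe_id"])


def test_select_regulatory_unknown_policy():
    with pytest.raises(ValueError, match="policy"):
        select_regulatory(pd.DataFrame(), policy="everything")


def test_summarize_genes_reference_counts():
    """Gene-level aggregation of the reference table: TGFBI has 3 hyper CpGs."""
    table = load_candidate_cpgs()
    assignments = select_regulatory(table)
    records = pd.DataFrame(
        {"stringent_class": classify_stringent(table["beta_sens"],
                                               table["beta_res"], tol=0.005)},
        index=table.index,
    )
    summaries = summarize_genes(records, assignments)
    assert summaries.loc["TGFBI", "n_hyper"] == 3
    assert summaries.loc["CXCL2", "n_hyper"] == 4
    assert summaries.loc["SLC38A1", "n_hyper"] == 3
    assert summaries.loc["LRRC61", "n_hyper"] == 5
    assert (summaries["n_hypo"] == 0).all()


def test_summarize_genes_matches_manifest(zero_noise_bundle):
    bundle = zero_noise_bundle
    assignments = select_regulatory(bundle.annotation)
    records = diffmeth_records(bundle.beta)
    summaries = summarize_genes(records, assignments)
    assert set(summaries.index) == bundle.truth.planted_genes
    planted_probe_count = sum(
        summaries.loc[g, "n_hyper"] for g in summaries.index
    )
    assert planted_probe_count == len(bundle.truth.planted_probes)


def test_global_concordance_identical_conditions():
    values = pd.DataFrame(
        {"s": [0.1, 0.5, 0.9], "r": [0.1, 0.5, 0.9]},
        index=pd.Index(["a", "b", "c"], name="probe_id"),
    )
    mat = BetaMatrix(values, pd.Series({"s": "sensitive", "r": "resistant"}))
    assert global_concordance(mat) == pytest.approx(1.0)


def test_global_concordance_anticorrelated_is_one():
    """r^2 is sign-blind: perfectly anti-correlated conditions give 1."""
    values = pd.DataFrame(
        {"s": [0.1, 0.9, 0.5], "r": [0.9, 0.1, 0.5]},
        index=pd.Index(["a", "b", "c"], name="probe_id"),
    )
    mat = BetaMatrix(values, pd.Series({"s": "sensitive", "r": "resistant"}))
    assert global_concordance(mat) == pytest.approx(1.0)


def test_global_concordance_matches_textbook_formula(noisy_bundle):
    mat = noisy_bundle.beta
    means = mat.condition_means()
    x, y = means["sensitive"].to_numpy(), means["resistant"].to_numpy()
    # two-pass covariance formula, independent of np.corrcoef
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert global_concordance(mat) == pytest.approx(r * r, abs=1e-12)


def test_global_concordance_zero_variance_error():
    values = pd.DataFrame(
        {"s": [0.5, 0.5], "r": [0.2, 0.8]},
        index=pd.Index(["a", "b"], name="probe_id"),
    )
    mat = BetaMatrix(values, pd.Series({"s": "sensitive", "r": "resistant"}))
    with pytest.raises(ValueError, match="variance"):
        global_concordance(mat)


def _block_matrix():
    # two planted blocks: samples split perfectly by condition
    values = pd.DataFrame(
        {
            "s1": [0.1, 0.1, 0.9, 0.5],
            "s2": [0.12, 0.1, 0.88, 0.5],
            "r1": [0.8, 0.82, 0.2, 0.5],
            "r2": [0.82, 0.8, 0.22, 0.5],
        },
        index=pd.Index(["cg1", "cg2", "cg3", "cg4"], name="probe_id"),
    )
    conditions = pd.Series(
        ["sensitive", "sensitive", "resistant", "resistant"],
        index=["s1", "s2", "r1", "r2"],
    )
    return BetaMatrix(values, conditions)


def test_cluster_separates_conditions():
    mat = _block_matrix()
    records = diffmeth_records(mat)
    tree = cluster_top_cpgs(mat, records)
    order = tree["sample_order"]
    conds = [mat.conditions[s] for s in order]
    assert conds in (["sensitive"] * 2 + ["resistant"] * 2,
                     ["resistant"] * 2 + ["sensitive"] * 2)
    assert "cg4" not in tree["probe_ids"]  # flat probe filtered out


def test_cluster_permutation_invariance():
    mat = _block_matrix()
    records = diffmeth_records(mat)
    tree = cluster_top_cpgs(mat, records)
    perm = mat.values.iloc[::-1]
    mat2 = BetaMatrix(perm, mat.conditions)
    tree2 = cluster_top_cpgs(mat2, diffmeth_records(mat2))
    # same merge heights regardless of probe input order
    assert np.allclose(sorted(tree["probe_linkage"][:, 2]),
                       sorted(tree2["probe_linkage"][:, 2]))
    assert np.allclose(tree["sample_linkage"][:, 2], tree2["sample_linkage"][:, 2])


def test_cluster_average_linkage_hand_computed():
    """4 probes x 2+2 samples: merge heights equal hand-derived values."""
    values = pd.DataFrame(
        {
            "s1": [0.0, 0.0, 1.0, 1.0],
            "s2": [0.0, 0.1, 1.0, 0.9],
            "r1": [1.0, 1.0, 0.0, 0.0],
            "r2": [1.0, 0.9, 0.0, 0.1],
        },
        index=pd.Index(["a", "b", "c", "d"], name="probe_id"),
    )
    mat = BetaMatrix(values, pd.Series({"s1": "sensitive", "s2": "sensitive",
                                        "r1": "resistant", "r2": "resistant"}))
    tree = cluster_top_cpgs(mat, diffmeth_records(mat))
    # pairwise distances: d(a,b) = d(c,d) = sqrt(0.02); the four cross
    # distances are d(a,c) = 2, d(a,d) = d(b,c) = sqrt(3.62),
    # d(b,d) = sqrt(3.28); average linkage merges {a,b} and {c,d} at
    # sqrt(0.02) each and joins the pairs at the mean cross distance
    heights = sorted(tree["probe_linkage"][:, 2])
    assert heights[0] == pytest.approx(np.sqrt(0.02))
    assert heights[1] == pytest.approx(np.sqrt(0.02))
    expected_top = (2.0 + 2 * np.sqrt(3.62) + np.sqrt(3.28)) / 4
    assert heights[2] == pytest.approx(expected_top)


def test_cluster_too_few_probes():
    mat = _block_matrix()
    records = diffmeth_records(mat)
    with pytest.raises(ValueError, match="fewer than 2"):
        cluster_top_cpgs(mat, records, delta_min=0.95)
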