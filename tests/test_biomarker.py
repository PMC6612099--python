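import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from methsilence.biomarker import (
    association_scan,
    compare_pre_post,
    dichotomize,
    fit_univariate_logistic,
    hosmer_lemeshow,
    roc,
)
from methsilence.stats import mann_whitney


@pytest.mark.parametrize(
    "value, expected",
    [(6.08, "low"), (30.26, "high"), (20.0, "high"), (19.99, "low")],
)
def test_dichotomize_boundary(value, expected):
    """Low/high split at 20%; the boundary value goes to the high class."""
    assert dichotomize(value) == expected


def test_dichotomize_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 100\]"):
        dichotomize(120.0)


def test_dichotomize_high_counts_monotone_in_cutoff():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 100, size=200)
    highs = [np.sum(dichotomize(vals, cutoff=c) == "high")
             for c in np.linspace(0, 100, 21)]
    assert all(a >= b for a, b in zip(highs, highs[1:]))


def _cohort(pre, post, responders=()):
    rows = []
    for i, v in enumerate(pre):
        rows.append({"patient_id": f"N{i}", "timepoint": "pre",
                     "response": "non_response", "methylation_pct": v})
    for i, v in enumerate(post):
        rows.append({"patient_id": f"N{i}", "timepoint": "post",
                     "response": "non_response", "methylation_pct": v})
    for i, v in enumerate(responders):
        rows.append({"patient_id": f"R{i}", "timepoint": "pre",
                     "response": "complete", "methylation_pct": v})
    return pd.DataFrame(rows)


def test_compare_pre_post_all_deltas_zero():
    cohort = _cohort([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
    out = compare_pre_post(cohort, paired_only=True)
    assert out["fraction_increased"] == 0.0
    assert out["test"].p_value == pytest.approx(1.0)


def test_compare_pre_post_single_increasing_pair():
    out = compare_pre_post(_cohort([5.0], [30.0]), paired_only=True)
    assert out["fraction_increased"] == 1.0
    assert out["n_pairs"] == 1


def test_compare_pre_post_paired_fraction_matches_manifest(noisy_bundle):
    bundle = noisy_bundle
    out = compare_pre_post(bundle.cohort, paired_only=True)
    # direct recount against the raw table
    pre = bundle.cohort.query("timepoint == 'pre'").set_index("patient_id")
    post = bundle.cohort.query("timepoint == 'post'").set_index("patient_id")
    shared = post.index.intersection(pre.index)
    manual = float(np.mean(post.loc[shared, "methylation_pct"].to_numpy()
                           > pre.loc[shared, "methylation_pct"].to_numpy()))
    assert out["fraction_increased"] == pytest.approx(manual)
    # the planted +24 pct shift should dominate 5-pct noise in most pairs
    assert out["fraction_increased"] >= 0.8


def test_compare_pre_post_requires_pairs():
    cohort = _cohort([5.0], [], responders=[4.0])
    with pytest.raises(ValueError, match="pair"):
        compare_pre_post(cohort, paired_only=True)


def test_roc_perfect_separation():
    curve = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], positive_label=1)
    assert curve.auc == 1.0
    assert curve.ci_high == 1.0


def test_roc_pair_counting_oracle():
    """AUC equals the concordant-pair count on a hand-checkable input."""
    curve = roc([1, 2, 3, 4], [0, 1, 0, 1], positive_label=1)
    # pairs (pos, neg): (2,1)+ (2,3)- (4,1)+ (4,3)+ -> 3/4
    assert curve.auc == pytest.approx(0.75)


def test_roc_matches_pair_enumeration_random():
    rng = np.random.default_rng(9)
    scores = rng.normal(size=30)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]  # ensure both classes
    curve = roc(scores, labels, positive_label=1)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    concordant = np.mean([
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    ])
    assert curve.auc == pytest.approx(concordant)


def test_roc_complement_under_score_negation():
    rng = np.random.default_rng(21)
    scores = rng.normal(size=40)
    labels = np.r_[np.zeros(20), np.ones(20)]
    a = roc(scores, labels, positive_label=1).auc
    b = roc(-scores, labels, positive_label=1).auc
    assert a + b == pytest.approx(1.0)


def test_roc_equals_u_statistic_identity():
    """Cross-module identity: AUC = U / (n1 n2) with ties counted half."""
    rng = np.random.default_rng(33)
    pos = np.round(rng.normal(1.0, 1.0, size=15), 1)  # rounding forces ties
    neg = np.round(rng.normal(0.0, 1.0, size=12), 1)
    curve = roc(np.r_[pos, neg], np.r_[np.ones(15), np.zeros(12)], 1)
    u = mann_whitney(pos, neg).statistic
    assert curve.auc == pytest.approx(u / (15 * 12))


def test_roc_single_class_error():
    with pytest.raises(ValueError, match="both classes"):
        roc([1, 2], [1, 1], positive_label=1)


def test_roc_bootstrap_ci_contains_auc():
    rng = np.random.default_rng(4)
    scores = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]
    labels = np.r_[np.zeros(30), np.ones(30)]
    curve = roc(scores, labels, 1, ci="bootstrap", n_boot=200, seed=0)
    assert curve.ci_low <= curve.auc <= curve.ci_high


def test_logistic_symmetric_data_zero_intercept():
    x = np.array([-2.0, -1.0, 1.0, 2.0, -2.0, -1.0, 1.0, 2.0])
    y = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=float)
    fit = fit_univariate_logistic(x, y)
    assert fit.intercept == pytest.approx(0.0, abs=1e-8)


def test_logistic_flat_predictor_gives_event_rate():
    x = np.zeros(10)
    x[:5] = 0.0  # constant predictor: slope unidentifiable, prediction = rate
    y = np.r_[np.ones(3), np.zeros(7)]
    fit = fit_univariate_logistic(np.zeros(10), y)
    assert np.allclose(fit.predicted, 0.3, atol=1e-8)


def test_logistic_matches_statsmodels():
    """Coefficients agree with an independently optimised reference fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    x = rng.normal(size=60)
    y = rng.binomial(1, expit(0.3 + 0.8 * x)).astype(float)
    fit = fit_univariate_logistic(x, y)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton")
    assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
    assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)
    assert fit.converged and not fit.separation


def test_logistic_separation_flagged():
    x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    fit = fit_univariate_logistic(x, y)
    assert fit.separation
    assert not fit.converged
    assert np.all((fit.predicted >= 0) & (fit.predicted <= 1))


def test_hosmer_lemeshow_perfectly_matched_bins_zero():
    """Observed = expected in every bin gives chi-square exactly 0."""
    p = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 10)
    y = np.concatenate([
        np.r_[np.ones(int(round(pi * 10))), np.zeros(10 - int(round(pi * 10)))]
        for pi in [0.1, 0.3, 0.5, 0.7, 0.9]
    ])
    res = hosmer_lemeshow(p, y, n_groups=5)
    assert res.chi_square == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == res.n_groups - 2


def test_hosmer_lemeshow_expected_sums_to_predicted():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.05, 0.95, size=100)
    y = rng.binomial(1, p).astype(float)
    res = hosmer_lemeshow(p, y)
    assert res.expected.sum() == pytest.approx(p.sum())
    assert res.bin_sizes.sum() == 100


def test_hosmer_lemeshow_detects_miscalibration():
    """Probabilities shifted +0.3 are rejected at n=500."""
    rng = np.random.default_rng(6)
    p_true = rng.uniform(0.05, 0.6, size=500)
    y = rng.binomial(1, p_true).astype(float)
    res = hosmer_lemeshow(np.clip(p_true + 0.3, 0.01, 0.99), y)
    assert res.p_value < 0.05


def test_hosmer_lemeshow_validation():
    with pytest.raises(ValueError, match=r"\(0, 1\)"):
        hosmer_lemeshow([0.0, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    with pytest.raises(ValueError, match="fewer observations"):
        hosmer_lemeshow([0.2, 0.4, 0.6], [0, 1, 0], n_groups=10)


def _scan_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    meth = pd.Series(rng.uniform(0, 60, size=n),
                     index=[f"P{i}" for i in range(n)])
    frame = pd.DataFrame(
        {
            "age": rng.integers(35, 76, size=n),
            "ER": rng.choice(["negative", "positive"], size=n),
            "stage": rng.choice(["IIB", "IIIA", "IIIB"], size=n),
            "constant": ["x"] * n,
        },
        index=meth.index,
    )
    return frame, meth


def test_association_scan_methods_and_skips():
    frame, meth = _scan_cohort()
    table = association_scan(frame, meth)
    methods = table.groupby("covariate")["method"].apply(set)
    assert methods["age"] == {"spearman"}
    assert any(m.startswith("mann-whitney") for m in methods["ER"])
    assert any(m.startswith("kruskal-wallis") for m in methods["stage"])
    assert "constant" not in set(table["covariate"])
    # categorical covariates additionally get a contingency test
    count_rows = table[table["method"].isin(["chi-square", "fisher-exact"])]
    assert set(count_rows["covariate"]) <= {"ER", "stage"}


def test_association_scan_fisher_exact_small_table():
    """3/0 vs 0/3 contingency: two-sided Fisher p = 0.1 (C(6,3) = 20)."""
    frame = pd.DataFrame(
        {"ER": ["negative"] * 3 + ["positive"] * 3},
        index=[f"P{i}" for i in range(6)],
    )
    meth = pd.Series([5.0, 6.0, 7.0, 50.0, 60.0, 70.0], index=frame.index)
    table = association_scan(frame, meth)
    fisher = table[table["method"] == "fisher-exact"]
    assert len(fisher) == 1
    assert fisher["p_value"].iloc[0] == pytest.approx(0.1)


def test_association_scan_null_p_roughly_uniform():
    """Independent covariates: p-values should not pile up near 0."""
    ps = []
    for seed in range(40):
        frame, meth = _scan_cohort(seed=seed)
        table = association_scan(frame[["age"]], meth)
        ps.append(table["p_value"].iloc[0])
    assert 0.2 < np.mean(ps) < 0.8
    assert np.mean(np.array(ps) < 0.05) < 0.2


def test_delong_ci_width_shrinks_with_n():
    rng = np.random.default_rng(12)
    widths = []
    for n in (20, 200):
        pos = rng.normal(1, 1, n)
        neg = rng.normal(0, 1, n)
        c = roc(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)], 1)
        widths.append(c.ci_high - c.ci_low)
    assert widths[1] < widths[0]


def test_auc_closed_form_gaussian_shift():
    """AUC of a Gaussian shift delta converges to Phi(delta / sqrt(2))."""
    rng = np.random.default_rng(7)
    delta = 1.0
    pos = rng.normal(delta, 1, 2000)
    neg = rng.normal(0, 1, 2000)
    curve = roc(np.r_[pos, neg], np.r_[np.ones(2000), np.zeros(2000)], 1)
    target = norm.cdf(delta / np.sqrt(2))
    assert abs(curve.auc - target) < 3 * curve.auc_se + 1e-9
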