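"""Patient-cohort biomarker evaluation.

Evaluates a percent-methylation biomarker measured in pre- and
post-treatment biopsies: low/high dichotomization, pre/post group
comparison (unpaired or paired), empirical ROC with AUC and a DeLong
confidence interval, univariate logistic calibration with the
Hosmer-Lemeshow decile test, and an association scan against clinical
covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .stats import TestResult, kruskal_wallis, mann_whitney, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


def dichotomize(methylation_pct, cutoff: float = 20.0):
    """Split percent methylation into low (< cutoff) / high (>= cutoff).

    A value exactly at the cutoff is assigned to the high (at-risk)
    class.
    """
    vals = np.asarray(methylation_pct, dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percent methylation must lie in [0, 100]")
    out = np.where(vals >= cutoff, HIGH, LOW)
    if out.ndim == 0:
        return str(out)
    if isinstance(methylation_pct, pd.Series):
        return pd.Series(out, index=methylation_pct.index)
    return out


def compare_pre_post(cohort: pd.DataFrame, paired_only: bool = False,
                     test: str = "mann-whitney") -> dict:
    """Compare methylation before vs after treatment.

    ``cohort`` needs columns ``patient_id``, ``timepoint`` (pre/post)
    and ``methylation_pct``.  Unpaired mode tests all pre values
    against all post values; paired mode restricts to patients with
    both timepoints and reports per-patient deltas (post - pre) and
    the fraction of patients whose methylation increased.  ``test``
    selects ``mann-whitney`` (default) or ``signed-rank`` (paired
    mode only).
    """
    pre = cohort.loc[cohort["timepoint"] == "pre"]
    post = cohort.loc[cohort["timepoint"] == "post"]
    if paired_only:
        both = sorted(set(pre["patient_id"]) & set(post["patient_id"]))
        if not both:
            raise ValueError("paired mode requires at least one pre/post pair")
        pre_vals = pre.set_index("patient_id")["methylation_pct"].loc[both]
        post_vals = post.set_index("patient_id")["methylation_pct"].loc[both]
        deltas = (post_vals - pre_vals).rename("delta")
        if test == "signed-rank":
            result = wilcoxon_signed_rank(pre_vals, post_vals)
        else:
            result = mann_whitney(pre_vals, post_vals)
        return {
            "test": result,
            "deltas": deltas,
            "fraction_increased": float((deltas > 0).mean()),
            "n_pairs": len(both),
        }
    if pre.empty or post.empty:
        raise ValueError("need at least one pre and one post value")
    result = mann_whitney(pre["methylation_pct"], post["methylation_pct"])
    return {
        "test": result,
        "mean_pre": float(pre["methylation_pct"].mean()),
        "mean_post": float(post["methylation_pct"].mean()),
    }


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    youden_threshold: float
    ci_method: str = "delong"
    n_positive: int = 0
    n_negative: int = 0
    auc_se: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("AUC outside its own confidence interval")


def _auc_and_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC by pairwise concordance (ties count 1/2) plus DeLong placements."""
    # placement of each positive among negatives and vice versa
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > nval) + 0.5 * (pos == nval)) for nval in neg])
    auc = float(v10.mean())
    return auc, v10, v01


def roc(scores, labels, positive_label, ci: str = "delong",
        n_boot: int = 2000, seed: int | None = None,
        alpha: float = 0.05) -> RocCurve:
    """Empirical ROC curve of ``scores`` for detecting ``positive_label``.

    Higher scores are taken to indicate the positive class.  The AUC
    is computed by the concordance (Mann-Whitney) identity with ties
    counted one half; the confidence interval uses the DeLong
    placement-variance estimator by default, or a percentile bootstrap
    with ``ci='bootstrap'``.  The reported Youden threshold maximises
    sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    pos, neg = scores[is_pos], scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _auc_and_placements(pos, neg)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    youden = thresholds[int(np.argmax(sens + spec - 1.0))]

    z = sps.norm.ppf(1 - alpha / 2)
    if ci == "delong":
        var = 0.0
        if pos.size > 1:
            var += np.var(v10, ddof=1) / pos.size
        if neg.size > 1:
            var += np.var(v01, ddof=1) / neg.size
        se = float(np.sqrt(var))
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(pos, size=pos.size, replace=True)
            nb = rng.choice(neg, size=neg.size, replace=True)
            reps[b] = _auc_and_placements(pb, nb)[0]
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, auc), max(hi, auc)
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return RocCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, ci_low=float(lo), ci_high=float(hi),
        youden_threshold=float(youden), ci_method=ci,
        n_positive=int(pos.size), n_negative=int(neg.size), auc_se=se,
    )


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    predicted: np.ndarray
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float


def fit_univariate_logistic(x, y, tol: float = 1e-10,
                            max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression by IRLS.

    Newton-Raphson on the two-parameter log-likelihood, declaring
    convergence when the log-likelihood improves by less than ``tol``.
    Complete separation (the two outcome groups occupy disjoint score
    ranges) is detected and flagged: coefficients then diverge, a
    warning is logged, and the last stable iterate is returned so that
    predicted probabilities remain usable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcomes must be present")
    separation = (x[y == 1].min() > x[y == 0].max()) or (
        x[y == 0].min() > x[y == 1].max()
    )
    if separation:
        logger.warning(
            "complete separation detected: logistic coefficients diverge"
        )
    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    eps = 1e-12
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(design @ beta)
        p = np.clip(p, eps, 1 - eps)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        w = p * (1 - p)
        hess = design.T @ (design * w[:, None])
        grad = design.T @ (y - p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            # singular Hessian (e.g. constant predictor): minimal-norm step
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
    p = np.clip(expit(design @ beta), eps, 1 - eps)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        predicted=expit(design @ beta),
        converged=converged and not separation, separation=separation,
        n_iter=n_iter, log_likelihood=ll,
    )


@dataclass
class CalibrationResult:
    n_groups: int
    observed: np.ndarray
    expected: np.ndarray
    bin_sizes: np.ndarray
    chi_square: float
    df: int
    p_value: float


def hosmer_lemeshow(pred_prob, outcomes, n_groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit test over quantile bins.

    Subjects are sorted by predicted probability and split into
    ``n_groups`` quantile bins (deciles by default) with tied
    probabilities kept in one bin; the statistic is
    sum (O - E)^2 / (E (1 - E/n_g)) over bins, referred to chi-square
    with (bins - 2) degrees of freedom.
    """
    p = np.asarray(pred_prob, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("pred_prob and outcomes differ in length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie in (0, 1)")
    if n_groups < 3:
        raise ValueError("need at least 3 groups")
    if p.size < n_groups:
        raise ValueError("fewer observations than groups")
    bins = pd.qcut(p, q=n_groups, labels=False, duplicates="drop")
    n_bins = int(bins.max()) + 1
    if n_bins < 3:
        raise ValueError("fewer than 3 distinct bins after collapsing ties")
    observed = np.array([y[bins == b].sum() for b in range(n_bins)])
    expected = np.array([p[bins == b].sum() for b in range(n_bins)])
    sizes = np.array([(bins == b).sum() for b in range(n_bins)])
    denom = expected * (1.0 - expected / sizes)
    # a bin whose expected count is degenerate contributes nothing stable;
    # merge it into its neighbour
    while np.any(denom <= 0) and len(sizes) > 3:
        b = int(np.argmin(denom))
        m = b - 1 if b > 0 else b + 1
        observed[m] += observed[b]
        expected[m] += expected[b]
        sizes[m] += sizes[b]
        observed = np.delete(observed, b)
        expected = np.delete(expected, b)
        sizes = np.delete(sizes, b)
        denom = expected * (1.0 - expected / sizes)
    denom = np.where(denom <= 0, np.nan, denom)
    terms = (observed - expected) ** 2 / denom
    chi2 = float(np.nansum(terms))
    df = len(sizes) - 2
    return CalibrationResult(
        n_groups=len(sizes), observed=observed, expected=expected,
        bin_sizes=sizes, chi_square=chi2, df=df,
        p_value=float(sps.chi2.sf(chi2, df=df)),
    )


def association_scan(cohort: pd.DataFrame, methylation_by_patient: pd.Series,
                     cutoff: float = 20.0) -> pd.DataFrame:
    """Scan clinical covariates for association with methylation.

    For each covariate column of ``cohort`` (indexed by patient):
    numeric covariates get a Spearman correlation against methylation;
    two-level categorical covariates a Mann-Whitney comparison of
    methylation between levels plus a chi-square / Fisher-exact test on
    the covariate vs the low/high dichotomized methylation (Fisher when
    any expected cell count is < 5); covariates with more than two
    levels a Kruskal-Wallis test plus the chi-square contingency test.
    Single-level covariates are skipped with a log message.
    """
    meth = methylation_by_patient.loc[cohort.index].astype(float)
    dichot = dichotomize(meth, cutoff=cutoff)
    rows = []
    for name in cohort.columns:
        col = cohort[name]
        values = col.dropna()
        meth_sub = meth.loc[values.index]
        levels = values.unique()
        if len(levels) < 2:
            logger.info("covariate %s has a single level; skipped", name)
            continue
        if pd.api.types.is_numeric_dtype(values) and len(levels) > 2:
            rho, p = sps.spearmanr(values, meth_sub)
            rows.append({"covariate": name, "method": "spearman",
                         "statistic": float(rho), "p_value": float(p),
                         "n": len(values)})
            continue
        groups = [meth_sub[values == lv].to_numpy() for lv in sorted(levels, key=str)]
        if len(levels) == 2:
            res = mann_whitney(groups[0], groups[1])
        else:
            res = kruskal_wallis(groups)
        rows.append({"covariate": name, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n": len(values)})
        table = pd.crosstab(values, dichot.loc[values.index])
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            expected = sps.contingency.expected_freq(table)
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = sps.fisher_exact(table)
                rows.append({"covariate": name, "method": "fisher-exact",
                             "statistic": float("nan"), "p_value": float(p),
                             "n": len(values)})
            else:
                chi2, p, _, _ = sps.chi2_contingency(table)
                rows.append({"covariate": name, "method": "chi-square",
                             "statistic": float(chi2), "p_value": float(p),
                             "n": len(values)})
    return pd.DataFrame(
        rows, columns=["covariate", "method", "statistic", "p_value", "n"]
    )
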