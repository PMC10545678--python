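"""Discrimination, association and calibration statistics for a PRS.

Covers the covariate-adjusted AUC with a stratified bootstrap, paired
bootstrap AUC comparison, inverse-variance pooling across studies, per-SD
odds ratios with family-history and age stratification and an age trend
test, the model-based relative-risk percentile curve, and relative-risk
calibration in 5% PRS bins against the 40-60% reference stratum.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger("prskit")

AGE_BAND_LABELS = ["<50", "50-59", "60-69", "70-79", ">80"]


@dataclasses.dataclass
class AUCResult:
    estimate: float
    se: float
    ci95: tuple
    n_bootstrap: int
    study: str = ""


@dataclasses.dataclass
class ORResult:
    or_per_sd: float
    ci95: tuple
    p_value: float
    stratum: str = "overall"
    n_cases: int = 0
    n_controls: int = 0


# ---------------------------------------------------------------------------
# AUC

def _residualize_on_controls(prs, case, covariates):
    """Regress PRS on covariates among controls (OLS); apply to everyone.

    Removes confounder-driven PRS variation without letting the covariates
    contribute to discrimination.
    """
    prs = np.asarray(prs, float)
    if covariates is None:
        return prs
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    D = np.column_stack([np.ones(len(prs)), C])
    ctrl = np.asarray(case) == 0
    coef, _, _, _ = np.linalg.lstsq(D[ctrl], prs[ctrl], rcond=None)
    return prs - D @ coef


def _auc_mann_whitney(x_cases, x_controls) -> float:
    """AUC as the Mann-Whitney statistic, ties counted 1/2 (rank formulation)."""
    n1, n0 = len(x_cases), len(x_controls)
    ranks = stats.rankdata(np.concatenate([x_cases, x_controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def adjusted_auc(prs, case_status, covariates=None, n_bootstrap: int = 500,
                 seed: int = 0, study: str = "") -> AUCResult:
    """Covariate-adjusted AUC of a PRS with a stratified bootstrap SE.

    The PRS is residualized on the covariates (fit among controls), and the
    AUC is the Mann-Whitney statistic of the residualized PRS, cases vs
    controls. The SE comes from ``n_bootstrap`` resamples stratified by case
    status, each repeating the whole procedure including residualization;
    the CI is estimate +/- 1.96*SE, clipped to [0, 1].
    """
    case = np.asarray(case_status, int)
    if len(np.unique(case)) < 2:
        raise ValueError("both outcome classes must be present")
    if n_bootstrap < 50:
        warnings.warn("n_bootstrap < 50: bootstrap SE will be unstable")

    def estimate(idx_case, idx_ctrl):
        idx = np.concatenate([idx_case, idx_ctrl])
        r = _residualize_on_controls(np.asarray(prs, float)[idx], case[idx],
                                     None if covariates is None
                                     else np.asarray(covariates, float)[idx])
        return _auc_mann_whitney(r[: len(idx_case)], r[len(idx_case):])

    idx_case = np.where(case == 1)[0]
    idx_ctrl = np.where(case == 0)[0]
    est = estimate(idx_case, idx_ctrl)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = estimate(rng.choice(idx_case, len(idx_case)),
                            rng.choice(idx_ctrl, len(idx_ctrl)))
    se = float(boots.std(ddof=1))
    ci = (max(0.0, est - 1.96 * se), min(1.0, est + 1.96 * se))
    return AUCResult(est, se, ci, n_bootstrap, study)


def compare_auc(prs_1, prs_2, case_status, covariates=None, n_bootstrap: int = 500,
                seed: int = 0) -> float:
    """Two-sided p-value for a difference in covariate-adjusted AUCs.

    Both PRSs are evaluated on the same paired bootstrap resamples; the
    p-value is the normal approximation of the point-estimate difference
    against the bootstrap SE of the difference.
    """
    case = np.asarray(case_status, int)
    if len(np.unique(case)) < 2:
        raise ValueError("both outcome classes must be present")
    prs_1, prs_2 = np.asarray(prs_1, float), np.asarray(prs_2, float)
    cov = None if covariates is None else np.asarray(covariates, float)

    def auc_of(p, idx_case, idx_ctrl):
        idx = np.concatenate([idx_case, idx_ctrl])
        r = _residualize_on_controls(p[idx], case[idx],
                                     None if cov is None else cov[idx])
        return _auc_mann_whitney(r[: len(idx_case)], r[len(idx_case):])

    idx_case = np.where(case == 1)[0]
    idx_ctrl = np.where(case == 0)[0]
    diff = auc_of(prs_1, idx_case, idx_ctrl) - auc_of(prs_2, idx_case, idx_ctrl)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        ic = rng.choice(idx_case, len(idx_case))
        i0 = rng.choice(idx_ctrl, len(idx_ctrl))
        diffs[b] = auc_of(prs_1, ic, i0) - auc_of(prs_2, ic, i0)
    se = diffs.std(ddof=1)
    if se == 0:
        return 1.0
    z = diff / se
    return float(2.0 * stats.norm.sf(abs(z)))


def pool_ivw(estimates, ses):
    """Inverse-variance-weighted fixed-effect pooling of k estimates."""
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if est.shape != se.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and ses must be equal-length 1-d arrays")
    if not np.all(np.isfinite(est)) or not np.all(np.isfinite(se)):
        raise ValueError("non-finite input")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float((w * est).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    return pooled, pooled_se


# ---------------------------------------------------------------------------
# Odds ratios

def _logit_or(prs_scaled, case, covariates):
    X = prs_scaled[:, None]
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    res = sm.Logit(case, sm.add_constant(X)).fit(disp=0)
    b, se = res.params[1], res.bse[1]
    return (float(np.exp(b)), (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
            float(2.0 * stats.norm.sf(abs(b / se))), float(b), float(se))


def or_per_sd(prs, case_status, covariates=None, strata: dict | None = None,
              min_cases: int = 10) -> list[ORResult]:
    """Per-SD odds ratio of case status on the PRS, overall and by stratum.

    The PRS is scaled to unit SD within the analysis sample before fitting a
    logistic regression with the supplied covariates. ``strata`` maps a
    stratification name to a per-sample label array (e.g. family-history
    levels or age bands); each non-missing level is analyzed separately, with
    the PRS rescaled within the stratum. Strata with fewer than ``min_cases``
    cases (or no controls) are skipped with a warning.
    """
    prs = np.asarray(prs, float)
    case = np.asarray(case_status, int)
    cov = None if covariates is None else np.asarray(covariates, float)
    results = []

    def fit_one(mask, label):
        c = case[mask]
        if c.sum() < min_cases or (1 - c).sum() < 1 or len(np.unique(c)) < 2:
            log.warning("stratum '%s' skipped: %d cases", label, int(c.sum()))
            return
        p = prs[mask]
        sd = p.std(ddof=1)
        if sd == 0:
            log.warning("stratum '%s' skipped: constant PRS", label)
            return
        orr, ci, pval, _, _ = _logit_or((p - p.mean()) / sd, c,
                                        None if cov is None else cov[mask])
        results.append(ORResult(orr, ci, pval, label, int(c.sum()), int((1 - c).sum())))

    fit_one(np.ones(len(prs), bool), "overall")
    for name, labels in (strata or {}).items():
        labels = np.asarray(labels).astype(str)
        for lev in pd.unique(labels):
            if lev in ("missing", "nan"):
                continue
            fit_one(labels == lev, f"{name}:{lev}")
    return results


def age_bands(age) -> np.ndarray:
    """Categorize age into the bands <50, 50-59, 60-69, 70-79, >80."""
    age = np.asarray(age, float)
    out = np.empty(len(age), dtype=object)
    out[age < 50] = "<50"
    out[(age >= 50) & (age < 60)] = "50-59"
    out[(age >= 60) & (age < 70)] = "60-69"
    out[(age >= 70) & (age < 80)] = "70-79"
    out[age >= 80] = ">80"
    return out


def age_trend_test(or_results_by_age: list[ORResult]):
    """Trend of log-OR across ordered age strata.

    Inverse-variance-weighted least squares of log-OR on the stratum index;
    returns ``(slope, two-sided p)`` from a Wald test of the slope.
    """
    if len(or_results_by_age) < 3:
        raise ValueError("need >= 3 age strata with estimates")
    y = np.array([np.log(r.or_per_sd) for r in or_results_by_age])
    se = np.array([(np.log(r.ci95[1]) - np.log(r.ci95[0])) / (2 * 1.96)
                   for r in or_results_by_age])
    x = np.arange(len(y), dtype=float)
    w = 1.0 / se**2
    xbar = (w * x).sum() / w.sum()
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * y).sum() / sxx
    slope_se = 1.0 / np.sqrt(sxx)
    p = float(2.0 * stats.norm.sf(abs(slope / slope_se)))
    return float(slope), p


# ---------------------------------------------------------------------------
# Relative risk

def rr_percentile_curve(or_per_sd: float, percentiles) -> np.ndarray:
    """Model-based relative risk at PRS percentiles vs the population average.

    Under a log-linear risk model with standard-normal PRS,
    ``RR(p) = exp(beta * z_p) / E[exp(beta * Z)] = exp(beta * z_p - beta^2/2)``
    with ``beta = ln(OR per SD)`` and ``z_p`` the standard-normal quantile.
    """
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    p = np.asarray(percentiles, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentiles must lie in (0, 1)")
    beta = np.log(or_per_sd)
    return np.exp(beta * stats.norm.ppf(p) - beta**2 / 2.0)


def rr_calibration(prs, case_status, covariates=None, or_per_sd: float | None = None,
                   n_bins: int = 20) -> pd.DataFrame:
    """Relative-risk calibration of the PRS in 5% bins vs the 40-60% stratum.

    Bin edges are type-7 sample quantiles of the PRS (ties to the lower bin).
    The expected OR of a bin is the ratio of within-bin geometric means of
    individual model-based ORs, ``exp(mean_bin(PRS * beta) - mean_ref(PRS *
    beta))`` with ``beta = ln(OR per SD)``. The observed OR comes from a
    logistic regression of case status on a bin-vs-reference indicator plus
    covariates, with 95% Wald CI. The reference (two merged middle bins) has
    observed OR 1 by construction.
    """
    prs = np.asarray(prs, float)
    case = np.asarray(case_status, int)
    cov = None if covariates is None else np.asarray(covariates, float)
    if or_per_sd is None:
        sd = prs.std(ddof=1)
        _, _, _, b, _ = _logit_or((prs - prs.mean()) / sd, case, cov)
        beta = b / sd
    else:
        beta = np.log(or_per_sd) / prs.std(ddof=1)

    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(prs, qs)  # type-7 (linear) is numpy's default
    bin_idx = np.searchsorted(edges, prs, side="left")

    # merge empty bins leftward (only possible under heavy ties)
    counts = np.bincount(bin_idx, minlength=n_bins)
    for b_i in np.where(counts == 0)[0]:
        log.warning("empty PRS bin %d merged with neighbor", b_i)

    ref_bins = (n_bins // 2 - 1, n_bins // 2)  # 40-60% for 20 bins
    ref_mask = np.isin(bin_idx, ref_bins)
    ref_score = (prs[ref_mask] * beta).mean()

    all_edges = np.concatenate([[-np.inf], edges, [np.inf]])
    rows = []
    for b_i in range(n_bins):
        mask = bin_idx == b_i
        is_ref = b_i in ref_bins
        n_case = int(case[mask].sum())
        n_ctrl = int((1 - case[mask]).sum())
        if mask.sum() == 0:
            continue
        expected = float(np.exp((prs[mask] * beta).mean() - ref_score))
        if is_ref:
            observed, ci = 1.0, (1.0, 1.0)
        else:
            sub = mask | ref_mask
            ind = mask[sub].astype(float)
            X = ind[:, None]
            if cov is not None:
                C = cov[sub]
                X = np.column_stack([X, C if C.ndim == 2 else C[:, None]])
            try:
                res = sm.Logit(case[sub], sm.add_constant(X)).fit(disp=0)
                coef, cse = res.params[1], res.bse[1]
                observed = float(np.exp(coef))
                ci = (float(np.exp(coef - 1.96 * cse)), float(np.exp(coef + 1.96 * cse)))
            except Exception:
                observed, ci = np.nan, (np.nan, np.nan)
        rows.append({
            "bin": b_i, "lower": float(all_edges[b_i]), "upper": float(all_edges[b_i + 1]),
            "is_reference": is_ref, "expected_or": expected, "observed_or": observed,
            "ci_low": ci[0], "ci_high": ci[1], "n_cases": n_case, "n_controls": n_ctrl,
        })
    return pd.DataFrame(rows)
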