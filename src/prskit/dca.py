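"""Decision-curve analysis under competing risks.

Clinical utility of intervening (e.g. screening) on individuals whose
predicted 10-year colorectal-cancer risk exceeds a threshold ``rt``, with
death as a competing event. At a landmark time t, with ``p = I(t)`` the
cause-specific cumulative incidence of CRC and ``w = rt/(1-rt)`` the odds at
the threshold,

    NB  = sensitivity * p - (1 - specificity) * (1 - p) * w
    sNB = NB / p

and the true/false positive counts at each threshold are computed from the
subgroup cumulative incidences: ``TP_rt = I(t|z=1) * P(z=1) * N`` and
``FP_rt = (1 - I(t|z=1)) * P(z=1) * N``, with ``z = 1`` iff predicted risk
>= rt. Sensitivity and specificity are the Eq-count ratios against the
treat-all (rt = 0) row: TPR = TP_rt / TP_0, FPR = FP_rt / FP_0.

Cumulative incidences are Aalen-Johansen estimates; per-sample risks come
from cause-specific exponential-hazard regressions (family-history only, and
family-history + PRS), with a logistic-at-landmark fallback.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

log = logging.getLogger("prskit")


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence

def cif(time, event, t_landmark: float, cause: int = 1) -> float:
    """Aalen-Johansen estimate of the cause-specific cumulative incidence.

    ``event`` codes 0 = censored, 1 = CRC, 2 = competing death. At each
    distinct event time the increment is ``S(t-) * d_cause / n_at_risk`` with
    S the product-limit estimate of overall (any-event) survival; censoring
    enters only through the risk sets.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.shape != event.shape:
        raise ValueError("time and event length mismatch")
    n = len(time)
    if n == 0 or (event == 0).all() and np.all(time == 0):
        warnings.warn("no events and no censoring information; CIF = 0")
        return 0.0
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    inc = 0.0
    surv = 1.0
    i = 0
    while i < n and time[i] <= t_landmark:
        t = time[i]
        j = i
        d_cause = d_any = 0
        while j < n and time[j] == t:
            if event[j] == cause:
                d_cause += 1
            if event[j] != 0:
                d_any += 1
            j += 1
        at_risk = n - i
        if d_any:
            inc += surv * d_cause / at_risk
            surv *= 1.0 - d_any / at_risk
        i = j
    return float(inc)


# ---------------------------------------------------------------------------
# Risk models

class CauseSpecificExponentialRisk(BaseEstimator):
    """Cause-specific exponential-hazard regression for landmark risk.

    The CRC hazard is ``lambda_1(x) = exp(theta_0 + x @ theta)`` (fitted by
    maximum likelihood via the Poisson-likelihood equivalence for censored
    exponential data: event indicator ~ Poisson with exposure = follow-up
    time); the competing death hazard is a constant ``lambda_2`` (its MLE,
    deaths / total person-time). The predicted t-year risk is the closed-form
    cause-1 cumulative incidence of two independent exponentials,
    ``lambda_1/(lambda_1+lambda_2) * (1 - exp(-(lambda_1+lambda_2) t))``.
    """

    def fit(self, X, y):
        """Fit hazards. ``y`` is an (n, 2) array of (time, event)."""
        X = check_array(X)
        y = np.asarray(y, float)
        time, event = y[:, 0], y[:, 1].astype(int)
        if np.any(time < 0):
            raise ValueError("negative follow-up time")
        if (event == 1).sum() == 0:
            raise ValueError("no CRC events to fit on")
        D = sm.add_constant(X, has_constant="add")
        try:
            res = sm.GLM((event == 1).astype(float), D,
                         family=sm.families.Poisson(),
                         exposure=np.maximum(time, 1e-12)).fit()
        except Exception as exc:
            raise RuntimeError(f"cause-specific hazard fit failed: {exc}") from exc
        if not res.converged or not np.all(np.isfinite(res.params)):
            raise RuntimeError("cause-specific hazard fit did not converge; "
                               f"params={res.params}")
        self.coef_ = np.asarray(res.params)
        self.death_rate_ = float((event == 2).sum() / time.sum())
        return self

    def predict_risk(self, X, t_landmark: float) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        lam1 = np.exp(sm.add_constant(X, has_constant="add") @ self.coef_)
        tot = lam1 + self.death_rate_
        return lam1 / tot * -np.expm1(-tot * t_landmark)


def _landmark_logistic_risk(X, time, event, t_landmark):
    """Fallback: logistic regression of CRC-by-t among subjects with known status."""
    known = (event == 1) & (time <= t_landmark) | (time >= t_landmark) | (event == 2)
    y = ((event == 1) & (time <= t_landmark)).astype(float)
    D = sm.add_constant(X, has_constant="add")
    res = sm.Logit(y[known], D[known]).fit(disp=0)
    return res.predict(D)


def fit_risk_models(cohort: pd.DataFrame, t_landmark: float, prs=None,
                    model: str = "exponential") -> dict[str, np.ndarray]:
    """Per-sample landmark risks under the two candidate models.

    Returns ``{"famhx": risks, "famhx_prs": risks}`` for the family-history-
    only model and the family-history + PRS model. ``cohort`` must carry
    ``famhx`` (no 'missing' rows), ``time`` and ``event``; the PRS defaults
    to the cohort's ``prs`` column.
    """
    if (cohort["famhx"] == "missing").any():
        raise ValueError("cohort contains missing family history; filter first")
    fam = (cohort["famhx"] == "yes").to_numpy(float)[:, None]
    if prs is None:
        prs = cohort["prs"].to_numpy(float)
    prs = np.asarray(prs, float)
    time = cohort["time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    X2 = np.column_stack([fam, prs])
    if model == "exponential":
        y = np.column_stack([time, event])
        m1 = CauseSpecificExponentialRisk().fit(fam, y)
        m2 = CauseSpecificExponentialRisk().fit(X2, y)
        return {"famhx": m1.predict_risk(fam, t_landmark),
                "famhx_prs": m2.predict_risk(X2, t_landmark)}
    elif model == "logistic":
        return {"famhx": _landmark_logistic_risk(fam, time, event, t_landmark),
                "famhx_prs": _landmark_logistic_risk(X2, time, event, t_landmark)}
    raise ValueError(f"unknown model '{model}'")


# ---------------------------------------------------------------------------
# Net benefit

@dataclasses.dataclass
class NBRow:
    risk_threshold: float
    w: float
    p: float                      # marginal landmark cumulative incidence I(t)
    sensitivity: float
    specificity: float
    nb: float
    snb: float
    tp: float
    fp: float
    tpr: float
    fpr: float
    n_high_risk: int
    n_high_risk_events: int
    fp_reduction_per100: float = np.nan
    net_interventions_avoided_per100: float = np.nan
    model: str = ""
    flag: str = ""


def nb_treat_all(p: float, rt: float) -> float:
    """Net benefit of intervening on everyone: p - (1-p) * rt/(1-rt)."""
    return p - (1.0 - p) * rt / (1.0 - rt)


def net_benefit(risks, time, event, rt: float, t_landmark: float,
                model: str = "") -> NBRow:
    """One decision-curve row for a risk model at threshold ``rt``.

    High risk is ``z = risk >= rt``. Subgroup cumulative incidences
    ``I(t|z)`` come from the Aalen-Johansen estimator on the respective
    subgroup; TP/FP counts, sensitivity/specificity as ratios against the
    treat-all row, and NB/sNB follow the definitions in the module docstring.
    """
    if not 0 < rt < 1:
        raise ValueError("rt must lie in (0, 1)")
    risks = np.asarray(risks, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(risks)
    z = risks >= rt
    p = cif(time, event, t_landmark)
    flag = ""
    if z.all():
        i1, i0 = p, 0.0
    elif not z.any():
        i1, i0 = 0.0, p
        flag = "empty_high_risk"
        log.warning("threshold %g: no high-risk samples", rt)
    else:
        i1 = cif(time[z], event[z], t_landmark)
        i0 = cif(time[~z], event[~z], t_landmark)
    pz = z.mean()
    tp = i1 * pz * n
    fp = (1.0 - i1) * pz * n
    tp0 = p * n            # treat-all (rt -> 0) counts
    fp0 = (1.0 - p) * n
    tpr = tp / tp0 if tp0 > 0 else 0.0
    fpr = fp / fp0 if fp0 > 0 else 0.0
    sens, spec = tpr, 1.0 - fpr
    w = rt / (1.0 - rt)
    nb = sens * p - (1.0 - spec) * (1.0 - p) * w
    snb = nb / p if p > 0 else 0.0
    n_hr_events = int(((event == 1) & (time <= t_landmark) & z).sum())
    return NBRow(rt, w, p, sens, spec, nb, snb, tp, fp, tpr, fpr,
                 int(z.sum()), n_hr_events, model=model, flag=flag)


def fp_reduction_per100(nb_model: float, nb_all: float, rt: float) -> float:
    """Reduction in false positives per 100 individuals vs treating everyone:
    (NB_model - NB_treat_all) / (rt/(1-rt)) * 100."""
    if not 0 < rt < 1:
        raise ValueError("rt must lie in (0, 1)")
    return (nb_model - nb_all) / (rt / (1.0 - rt)) * 100.0


#: Table-4-style default grid plus the three clinical 10-year-risk anchors
#: (average risk at ages 45, 50, 55).
DEFAULT_THRESHOLDS = (
    0.0004, 0.0008, 0.0009, 0.0011, 0.0013, 0.0014, 0.0016, 0.0017, 0.0019,
    0.0020, 0.0022, 0.0023, 0.0025, 0.0026, 0.0028, 0.0029, 0.0031, 0.0032,
    0.0039, 0.0049,
)


def decision_table(cohort: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS,
                   t_landmark: float = 10.0, prs=None,
                   risk_model: str = "exponential",
                   risks: dict | None = None) -> pd.DataFrame:
    """Full decision-curve table for both models plus treat-all/treat-none.

    One row per (strategy, threshold); the model rows carry FP-reduction and
    net-interventions-avoided summaries (the same stated formula).
    """
    thresholds = sorted(thresholds)
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if risks is None:
        risks = fit_risk_models(cohort, t_landmark, prs=prs, model=risk_model)
    time = cohort["time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    p = cif(time, event, t_landmark)
    n = len(cohort)
    rows = []
    for rt in thresholds:
        w = rt / (1.0 - rt)
        nb_all = nb_treat_all(p, rt)
        rows.append(dataclasses.asdict(NBRow(rt, w, p, 1.0, 0.0, nb_all, nb_all / p if p else 0.0,
                                             p * n, (1 - p) * n, 1.0, 1.0, n,
                                             int(((event == 1) & (time <= t_landmark)).sum()),
                                             model="treat_all")))
        rows.append(dataclasses.asdict(NBRow(rt, w, p, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0,
                                             0.0, 0.0, 0, 0, model="treat_none")))
        for name, r in risks.items():
            row = net_benefit(r, time, event, rt, t_landmark, model=name)
            row.fp_reduction_per100 = fp_reduction_per100(row.nb, nb_all, rt)
            row.net_interventions_avoided_per100 = row.fp_reduction_per100
            rows.append(dataclasses.asdict(row))
    return pd.DataFrame(rows)


def snb_bootstrap(cohort: pd.DataFrame, rt: float, t_landmark: float = 10.0,
                  n_bootstrap: int = 500, seed: int = 0, prs=None,
                  risk_model: str = "exponential",
                  models=("famhx", "famhx_prs")) -> dict:
    """Bootstrap CIs for the sNB of both models and a paired-comparison p.

    Resamples the cohort with replacement, refits the risk models, and
    recomputes sNB at ``rt``. Returns percentile 95% CIs per model and a
    two-sided normal-approximation p-value for the paired sNB difference
    (second model minus first).
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(seed)
    time = cohort["time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)

    def snbs(df):
        risks = fit_risk_models(df, t_landmark, prs=None, model=risk_model)
        t = df["time"].to_numpy(float)
        e = df["event"].to_numpy(int)
        return {m: net_benefit(risks[m], t, e, rt, t_landmark).snb for m in models}

    base = cohort.reset_index(drop=True)
    point = snbs(base)
    boots = {m: np.empty(n_bootstrap) for m in models}
    for b in range(n_bootstrap):
        idx = rng.integers(0, len(base), len(base))
        res = snbs(base.iloc[idx])
        for m in models:
            boots[m][b] = res[m]
    out = {}
    for m in models:
        lo, hi = np.percentile(boots[m], [2.5, 97.5])
        out[m] = {"snb": point[m], "ci95": (float(lo), float(hi))}
    if len(models) == 2:
        d = boots[models[1]] - boots[models[0]]
        diff = point[models[1]] - point[models[0]]
        se = d.std(ddof=1)
        out["difference"] = {
            "estimate": float(diff),
            "ci95": tuple(float(v) for v in np.percentile(d, [2.5, 97.5])),
            "p_value": 1.0 if se == 0 else float(2.0 * stats.norm.sf(abs(diff / se))),
        }
    return out
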