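"""PRS scoring against weight files and the two-PRS logistic combination.

``score`` computes raw PRSs as weighted allele-dosage sums with allele
alignment and missing-dosage imputation. ``PRSCombiner`` learns the weighted
sum ``alpha * PRS_European + beta * PRS_Asian`` from a logistic regression of
case status on the two standardized PRSs — the combination step used to turn
two ancestry-specific scores into one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import DosageMatrix


def score(dosages: DosageMatrix, weights: pd.DataFrame) -> pd.DataFrame:
    """Score each sample against a weight table.

    For every weight-file variant present in the dosage data, the dosage of
    the weight's effect allele enters the sum (``2 - d`` when the genotype
    file counts the opposite allele). Missing dosages are imputed with
    ``2 * EAF`` when the weight file carries an ``eaf`` column, otherwise with
    the cohort mean dosage. Returns a per-sample table with the raw PRS and
    alignment/imputation counts.
    """
    cols = set(dosages.dosages.columns)
    used, flips, skipped = [], [], []
    for _, w in weights.iterrows():
        key = w["key"]
        if key not in cols:
            skipped.append((key, "not_in_genotypes"))
            continue
        m = dosages.meta.loc[key]
        if w["effect_allele"] == m["effect_allele"] and w["other_allele"] == m["other_allele"]:
            flip = False
        elif w["effect_allele"] == m["other_allele"] and w["other_allele"] == m["effect_allele"]:
            flip = True
        else:
            skipped.append((key, "allele_mismatch"))
            continue
        used.append((key, float(w["effect_weight"]), flip,
                     float(w["eaf"]) if "eaf" in w.index and np.isfinite(w.get("eaf", np.nan)) else np.nan))
        flips.append(flip)
    if not used:
        raise ValueError("no overlapping variants between weights and genotypes")

    n = len(dosages.dosages)
    prs = np.zeros(n)
    n_missing = np.zeros(n, dtype=int)
    for key, w, flip, eaf in used:
        d = dosages.dosages[key].to_numpy(float)
        miss = ~np.isfinite(d)
        if miss.any():
            fill = 2.0 * eaf if np.isfinite(eaf) else np.nanmean(d)
            if not np.isfinite(fill):
                fill = 0.0  # variant entirely missing and no EAF
            d = np.where(miss, fill, d)
            n_missing += miss.astype(int)
        if flip:
            d = 2.0 - d
        prs += w * d
    out = pd.DataFrame({
        "sample_id": dosages.dosages.index,
        "prs": prs,
        "n_variants_used": len(used),
        "n_flipped": int(sum(flips)),
        "n_missing_imputed": n_missing,
    }).reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


class PRSCombiner(BaseEstimator, TransformerMixin):
    """Logistic combination of a European and an Asian PRS.

    ``fit(X, y)`` takes a two-column array ``[PRS_European, PRS_Asian]`` and a
    binary case-status vector; both columns are standardized to unit SD on the
    training set, and a maximum-likelihood logistic regression with intercept
    supplies the combination coefficients. ``transform(X)`` returns
    ``alpha_ * PRS_Eur_std + beta_ * PRS_Asn_std`` — the intercept is omitted
    because every downstream use (AUC, per-SD OR, percentiles) is invariant to
    a monotone shift.

    Attributes
    ----------
    alpha_ : float
        Coefficient on the (standardized) European PRS.
    beta_ : float
        Coefficient on the (standardized) Asian PRS.
    intercept_ : float
    mean_, scale_ : ndarray of shape (2,)
        Training-set standardization of the two PRS columns.
    training_n_ : int
    """

    def __init__(self, min_cases: int = 50, collinearity_r: float = 0.999):
        self.min_cases = min_cases
        self.collinearity_r = collinearity_r

    def fit(self, X, y):
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly two columns: [PRS_Eur, PRS_Asn]")
        y = np.asarray(y, float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("case status must contain both classes coded 0/1")
        n_cases, n_controls = int(y.sum()), int((1 - y).sum())
        if n_cases < self.min_cases or n_controls < self.min_cases:
            raise ValueError(
                f"need >= {self.min_cases} cases and controls "
                f"(got {n_cases}/{n_controls})")
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        if abs(r) > self.collinearity_r:
            raise ValueError(f"PRS columns are collinear (|r| = {abs(r):.4f})")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("constant PRS column")
        Z = (X - self.mean_) / self.scale_
        try:
            res = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        except Exception as exc:  # includes PerfectSeparationError
            raise ValueError(
                "logistic fit failed (possible perfect separation); "
                "consider a regularized fit") from exc
        coefs = np.asarray(res.params)
        if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 50:
            raise ValueError("logistic fit diverged (possible perfect separation); "
                             "consider a regularized fit")
        self.intercept_ = float(coefs[0])
        self.alpha_ = float(coefs[1])
        self.beta_ = float(coefs[2])
        self.training_n_ = len(y)
        return self

    def transform(self, X):
        check_is_fitted(self, "alpha_")
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly two columns: [PRS_Eur, PRS_Asn]")
        Z = (X - self.mean_) / self.scale_
        return self.alpha_ * Z[:, 0] + self.beta_ * Z[:, 1]


def fit_combination(prs_eur, prs_asn, case_status, **kwargs) -> PRSCombiner:
    """Fit the two-PRS logistic combination (thin wrapper over PRSCombiner)."""
    X = np.column_stack([np.asarray(prs_eur, float), np.asarray(prs_asn, float)])
    return PRSCombiner(**kwargs).fit(X, case_status)


def apply_combination(combiner: PRSCombiner, prs_eur, prs_asn) -> np.ndarray:
    """Apply fitted combination weights: alpha*PRS_Eur + beta*PRS_Asn (standardized)."""
    prs_eur = np.asarray(prs_eur, float)
    prs_asn = np.asarray(prs_asn, float)
    if prs_eur.shape != prs_asn.shape:
        raise ValueError("PRS vectors have different lengths")
    return combiner.transform(np.column_stack([prs_eur, prs_asn]))
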