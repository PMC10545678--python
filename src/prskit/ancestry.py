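"""Trans-ancestry standardization of the PRS distribution.

Raw PRS distributions differ across ancestral groups because of allele
frequency and LD differences, not because of real risk differences. The
standardization fits, on a reference panel, two linear models predicting the
mean and the variance of the raw PRS from the top genetic principal
components, and then maps any new sample to

    adjusted = (raw - (a0 + sum_i a_i PC_i)) / sqrt(b0 + sum_i b_i PC_i)

so adjusted distributions align across groups. A per-study additive mean
offset (computed on controls) handles studies whose raw PRS is shifted by a
technical artifact such as a different imputation panel.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class AncestryPCA(BaseEstimator, TransformerMixin):
    """PCA of standardized reference dosages, for projecting new samples.

    Dosages are centered at ``2f`` and scaled by ``sqrt(2f(1-f))`` with ``f``
    the reference allele frequency (missing values mean-imputed); loadings are
    the top-k right singular vectors. Monomorphic variants are excluded at
    fit time. The sign of each loading is fixed so its largest-magnitude
    entry is positive, making serialized models reproducible.

    Attributes
    ----------
    allele_freq_ : ndarray, reference allele frequency per kept variant
    scale_ : ndarray, ``sqrt(2 f (1 - f))``
    components_ : ndarray (n_variants_kept, k), orthonormal loadings
    variant_keys_ : list of kept variant keys (when fitted on a DataFrame)
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        keys = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, ensure_all_finite="allow-nan")
        n, m = X.shape
        if self.n_components > n - 1:
            raise ValueError("n_components must be <= n_samples - 1")
        f = np.nanmean(X, axis=0) / 2.0
        keep = (f > 0) & (f < 1)
        if not keep.all():
            import logging
            logging.getLogger("prskit").warning(
                "AncestryPCA: excluding %d monomorphic variant(s)", int((~keep).sum()))
        if keep.sum() == 0:
            raise ValueError("all variants monomorphic")
        X = X[:, keep]
        f = f[keep]
        self.allele_freq_ = f
        self.scale_ = np.sqrt(2.0 * f * (1.0 - f))
        self.variant_keys_ = [k for k, ok in zip(keys, keep) if ok] if keys else None
        Z = self._standardize(X)
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        V = Vt[: self.n_components].T
        # deterministic sign: largest-|entry| of each loading positive
        for j in range(V.shape[1]):
            i = np.argmax(np.abs(V[:, j]))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        self.components_ = V
        return self

    def _standardize(self, X):
        Z = (X - 2.0 * self.allele_freq_) / self.scale_
        return np.where(np.isfinite(Z), Z, 0.0)  # mean imputation after centering

    def transform(self, X):
        check_is_fitted(self, "components_")
        if isinstance(X, pd.DataFrame):
            if self.variant_keys_ is not None:
                X = X[self.variant_keys_]
            X = X.to_numpy(float)
        X = check_array(X, ensure_all_finite="allow-nan")
        if X.shape[1] != len(self.allele_freq_):
            raise ValueError("variant count does not match the fitted model")
        return self._standardize(X) @ self.components_

    def to_json(self, path) -> None:
        d = {
            "n_components": self.n_components,
            "allele_freq": self.allele_freq_.tolist(),
            "scale": self.scale_.tolist(),
            "components": self.components_.tolist(),
            "variant_keys": self.variant_keys_,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AncestryPCA":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(n_components=d["n_components"])
        obj.allele_freq_ = np.asarray(d["allele_freq"])
        obj.scale_ = np.asarray(d["scale"])
        obj.components_ = np.asarray(d["components"])
        obj.variant_keys_ = d["variant_keys"]
        return obj


class AncestryAdjuster(BaseEstimator, TransformerMixin):
    """PC-based mean/variance standardization of a raw PRS.

    ``fit(X, y)`` takes the reference samples' PC scores ``X`` (n x k) and raw
    PRS ``y``. The mean model is ordinary least squares of PRS on the PCs;
    the variance model is least squares of the squared mean-model residuals
    on the PCs (the denominator is a conditional SD around the conditional
    mean). Predicted variances are floored at ``variance_floor_frac`` times
    the marginal PRS variance so the square root stays real and positive.

    ``transform`` expects ``[prs | pc_1..pc_k]`` column-stacked, matching the
    fit-time PC order, and returns the adjusted PRS.
    """

    def __init__(self, variance_floor_frac: float = 1e-4, min_samples_per_coef: int = 10):
        self.variance_floor_frac = variance_floor_frac
        self.min_samples_per_coef = min_samples_per_coef

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, float).ravel()
        n, k = X.shape
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if n < self.min_samples_per_coef * (k + 1):
            raise ValueError(
                f"need >= {self.min_samples_per_coef * (k + 1)} reference samples for k={k}")
        D = np.column_stack([np.ones(n), X])
        alpha, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < k + 1:
            raise ValueError("rank-deficient PC design")
        resid = y - D @ alpha
        beta, _, _, _ = np.linalg.lstsq(D, resid**2, rcond=None)
        self.n_components_ = k
        self.alpha_ = alpha
        self.beta_ = beta
        self.variance_floor_ = max(self.variance_floor_frac * float(np.var(y)),
                                   np.finfo(float).tiny)
        return self

    def adjust(self, prs, pc_scores) -> np.ndarray:
        """Adjusted PRS = (raw - predicted mean) / predicted SD."""
        check_is_fitted(self, "alpha_")
        prs = np.asarray(prs, float).ravel()
        pc_scores = check_array(pc_scores)
        if pc_scores.shape != (len(prs), self.n_components_):
            raise ValueError("pc_scores shape does not match prs/fitted model")
        D = np.column_stack([np.ones(len(prs)), pc_scores])
        mean = D @ self.alpha_
        var = np.maximum(D @ self.beta_, self.variance_floor_)
        return (prs - mean) / np.sqrt(var)

    def transform(self, X):
        X = check_array(X)
        return self.adjust(X[:, 0], X[:, 1:])

    def to_json(self, path) -> None:
        d = {
            "variance_floor_frac": self.variance_floor_frac,
            "alpha": self.alpha_.tolist(),
            "beta": self.beta_.tolist(),
            "variance_floor": self.variance_floor_,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AncestryAdjuster":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(variance_floor_frac=d["variance_floor_frac"])
        obj.alpha_ = np.asarray(d["alpha"])
        obj.beta_ = np.asarray(d["beta"])
        obj.variance_floor_ = d["variance_floor"]
        obj.n_components_ = len(obj.alpha_) - 1
        return obj


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_pc_model(reference_dosages, k: int = 4) -> AncestryPCA:
    return AncestryPCA(n_components=k).fit(reference_dosages)


def fit_adjustment(reference_prs, reference_pc_scores, **kwargs) -> AncestryAdjuster:
    return AncestryAdjuster(**kwargs).fit(np.asarray(reference_pc_scores),
                                          np.asarray(reference_prs))


def adjust(prs, pc_scores, model: AncestryAdjuster) -> np.ndarray:
    return model.adjust(prs, pc_scores)


def apply_study_offsets(adjusted_prs, study_labels, is_control, flagged_studies):
    """Shift flagged studies so their control-mean PRS matches the pooled one.

    The offset for a flagged study is (pooled control mean - study control
    mean), where the pooled mean is taken over controls of the non-flagged
    studies, and is added to all of that study's samples (cases and controls
    move by the same amount). Returns ``(shifted_prs, offsets_dict)``.
    """
    prs = np.asarray(adjusted_prs, float).copy()
    study = np.asarray(study_labels)
    ctrl = np.asarray(is_control, bool)
    if prs.shape != study.shape or prs.shape != ctrl.shape:
        raise ValueError("length mismatch")
    ref = ctrl & ~np.isin(study, list(flagged_studies))
    if not ref.any():
        raise ValueError("no controls outside the flagged studies")
    pooled = prs[ref].mean()
    offsets = {}
    for s in flagged_studies:
        in_s = study == s
        if not in_s.any():
            raise ValueError(f"flagged study '{s}' has no samples")
        if not (in_s & ctrl).any():
            raise ValueError(f"flagged study '{s}' has no controls")
        off = pooled - prs[in_s & ctrl].mean()
        prs[in_s] += off
        offsets[s] = float(off)
    return prs, offsets
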