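"""Diagonal-covariance Gaussian linear discriminant with LOO CV and permutation nulls.

The classifier fits one multivariate normal per class with class-specific
means and a single pooled *diagonal* covariance (features independent, shared
across classes), giving linear decision boundaries.  Model selection follows
the two-group decoding recipe used throughout the package:

* features are z-scored with training-fold statistics (no leakage; a
  ``zscore="global"`` option standardizes the full matrix up front instead);
* leave-one-out cross-validation: n folds, each observation held out once;
* significance via a permutation null (labels shuffled, LOO accuracy
  recomputed) and via a one-tailed t-test of per-subject accuracies
  against chance (0.5).

Because the discriminant depends on features only through
``(x - mu_c)^2 / sigma^2``, predictions and posteriors are invariant to any
per-feature affine rescaling; the vectorized LOO path exploits this to avoid
explicitly standardizing every fold (verified against the explicit
per-fold estimator loop in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "DiagLinearClassifier",
    "CVResult",
    "PermutationNull",
    "zscore_fit_apply",
    "loo_cv",
    "permutation_null",
    "accuracy_vs_chance_ttest",
]

VAR_FLOOR = 1e-12  # on pooled variances, post-standardization scale


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome."""

    predicted: np.ndarray        # per-observation predicted label
    posterior: np.ndarray        # posterior probability of the assigned class
    accuracy: float
    n_folds: int


@dataclass
class PermutationNull:
    """Empirical chance distribution of LOO accuracy under label shuffling."""

    null_accuracies: np.ndarray
    alpha: float
    threshold: float             # (1 - alpha) quantile of the null


def zscore_fit_apply(train: np.ndarray, test: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Standardize columns by training mean/SD; drop zero-variance columns.

    Returns the transformed matrices and a dict with the per-column training
    ``mean``, ``sd`` and boolean ``kept`` mask.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    kept = sd > 0
    n_dropped = int(np.sum(~kept))
    if n_dropped == train.shape[1]:
        raise ValueError("all columns have zero variance")
    if n_dropped:
        logger.warning("dropping %d zero-variance column(s)", n_dropped)
    tz = (train[:, kept] - mean[kept]) / sd[kept]
    vz = (test[:, kept] - mean[kept]) / sd[kept]
    return tz, vz, {"mean": mean, "sd": sd, "kept": kept}


class DiagLinearClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian discriminant with pooled diagonal covariance ('diaglinear').

    Parameters
    ----------
    priors : array-like of shape (2,), optional
        Class priors; empirical class frequencies when omitted.
    var_floor : float
        Lower bound applied to the pooled per-feature variances (after any
        standardization the caller performed) for numerical safety.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted).
    theta_ : (2, n_features) per-class feature means.
    var_ : (n_features,) pooled within-class diagonal variance.
    priors_ : (2,) class priors.

    Exact posterior ties are broken toward the first class in sorted label
    order.
    """

    def __init__(self, priors: Optional[Sequence[float]] = None,
                 var_floor: float = VAR_FLOOR):
        self.priors = priors
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly 2 classes required, got {len(self.classes_)}"
            )
        counts = np.bincount(y_idx, minlength=2)
        self.theta_ = np.vstack([X[y_idx == c].mean(axis=0) for c in (0, 1)])
        ss = sum(((X[y_idx == c] - self.theta_[c]) ** 2).sum(axis=0)
                 for c in (0, 1))
        dof = max(len(y) - 2, 1)
        self.var_ = np.maximum(ss / dof, self.var_floor)
        if self.priors is None:
            self.priors_ = counts / counts.sum()
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            self.priors_ = self.priors_ / self.priors_.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def _log_posterior_unnorm(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with "
                f"{self.n_features_in_}"
            )
        out = np.empty((X.shape[0], 2))
        for c in (0, 1):
            d = (X - self.theta_[c]) ** 2 / self.var_
            out[:, c] = -0.5 * d.sum(axis=1) + np.log(self.priors_[c])
        return out

    def predict_proba(self, X) -> np.ndarray:
        lp = self._log_posterior_unnorm(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        # argmax returns the first (sorted-order) class on exact ties
        return self.classes_[np.argmax(p, axis=1)]


def _loo_diag_predict(X: np.ndarray, y01: np.ndarray,
                      var_floor: float = VAR_FLOOR
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized leave-one-out diaglinear predictions.

    Returns (predicted class index per fold, posterior of the assigned
    class).  Equivalent to standardizing each training fold, fitting
    :class:`DiagLinearClassifier` and predicting the held-out row, but
    computed with O(n*p) rank-one updates.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations for LOO")
    y01 = np.asarray(y01)
    X2 = X * X

    # per-fold training variance (for zero-variance column handling and the
    # z-score-scale variance floor)
    S, Q = X.sum(0), X2.sum(0)
    tmean = (S - X) / (n - 1)
    tvar = np.maximum((Q - X2) / (n - 1) - tmean ** 2, 0.0)

    masks = [(y01 == 0), (y01 == 1)]
    mu, ssq, ncl = [], [], []
    for c, m in enumerate(masks):
        Sc, Qc = X[m].sum(0), X2[m].sum(0)
        nc = int(m.sum())
        if nc < 2:
            raise ValueError("each class needs at least 2 observations")
        inc = m.astype(float)[:, None]
        ncf = nc - inc  # (n, 1) training count of class c per fold
        mc = (Sc - X * inc) / ncf
        sc = (Qc - X2 * inc) - ncf * mc ** 2  # within-class SS per fold
        mu.append(mc)
        ssq.append(sc)
        ncl.append(ncf)

    dof = np.maximum((n - 1) - 2, 1)
    pooled = (ssq[0] + ssq[1]) / dof  # (n, p)
    # variance floor expressed on the z-scored scale; columns constant in the
    # training fold contribute nothing (dropped by the standardizer)
    keep = tvar > 1e-24 * np.maximum(1.0, tmean ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_z = np.where(keep, pooled / np.where(keep, tvar, 1.0), np.inf)
    pooled_z = np.maximum(pooled_z, var_floor)
    w = np.where(keep, 1.0 / (pooled_z * np.where(keep, tvar, 1.0)), 0.0)

    q = [np.sum(w * (X - mu[c]) ** 2, axis=1) for c in (0, 1)]
    logprior = [np.log(ncl[c][:, 0] / (n - 1)) for c in (0, 1)]
    # log odds of class 1 vs class 0
    L = (logprior[1] - logprior[0]) - 0.5 * (q[1] - q[0])
    pred = (L > 0).astype(int)
    p1 = 1.0 / (1.0 + np.exp(-np.clip(L, -700, 700)))
    posterior = np.where(pred == 1, p1, 1.0 - p1)
    return pred, posterior


def loo_cv(X: np.ndarray, y: np.ndarray, zscore: str = "fold") -> CVResult:
    """Leave-one-out cross-validation of the diaglinear classifier.

    Parameters
    ----------
    X : (n, p) feature matrix.
    y : (n,) binary labels (any two values).
    zscore : {"fold", "global", "none"}
        "fold" standardizes inside each training fold (default);
        "global" z-scores the full matrix once up front;
        predictions are identical across modes because the discriminant is
        invariant to per-feature affine maps, but "global" is provided for
        fidelity with analyses that standardized before cross-validating.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(classes)}")
    if zscore not in ("fold", "global", "none"):
        raise ValueError(f"unknown zscore mode {zscore!r}")
    if zscore == "global":
        Xz, _, _ = zscore_fit_apply(X, X)
        X = Xz
    y01 = (y == classes[1]).astype(int)
    pred_idx, post = _loo_diag_predict(X, y01)
    predicted = classes[pred_idx]
    acc = float(np.mean(predicted == y))
    return CVResult(predicted=predicted, posterior=post,
                    accuracy=acc, n_folds=len(y))


def permutation_null(X: np.ndarray, y: np.ndarray, n_perm: int = 500,
                     alpha: float = 0.05,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None
                     ) -> PermutationNull:
    """Chance distribution of LOO accuracy under uniform label shuffling.

    Labels are permuted without replacement, preserving the group balance.
    The decision threshold is the empirical (1 - alpha) quantile of the
    null accuracies.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    y01 = (y == classes[1]).astype(int)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y01)
        pred, _ = _loo_diag_predict(X, yp)
        null[i] = np.mean(pred == yp)
    return PermutationNull(null_accuracies=null, alpha=alpha,
                           threshold=float(np.quantile(null, 1.0 - alpha)))


def accuracy_vs_chance_ttest(per_subject_accuracies: Sequence[float],
                             chance: float = 0.5) -> Tuple[float, float]:
    """One-sample, one-tailed t-test of subject accuracies above chance."""
    a = np.asarray(per_subject_accuracies, dtype=float)
    if len(a) < 2:
        raise ValueError("need accuracies from at least 2 subjects")
    if np.std(a, ddof=1) == 0:
        logger.warning("zero variance across subjects; degenerate p-value")
        if np.all(a == chance):
            return 0.0, 0.5
        return (np.inf, 0.0) if a[0] > chance else (-np.inf, 1.0)
    res = sps.ttest_1samp(a, popmean=chance, alternative="greater")
    return float(res.statistic), float(res.pvalue)
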