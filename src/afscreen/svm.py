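"""Two-level SVM classifying patients by the distribution of their R-R intervals.

The estimator follows scikit-learn conventions (``fit`` / ``decision_function``
/ ``predict``, parameters in ``__init__``, fitted attributes with a trailing
underscore) and composes with sklearn model selection, but its inputs are
lists of variable-length interval vectors rather than a rectangular matrix:
each patient may contribute any number of samples, at training time and at
inference time alike.  The dual quadratic program is delegated to
``sklearn.svm.SVC`` in precomputed-kernel mode; the bespoke content is the
distributional kernel, the class-dependent misclassification costs, and
variable-length scoring from stored support samples.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .kernel import (GramMatrix, KernelParams, SelfTermCache, pairwise_sq_dist,
                     second_level_kernel)

_FORMAT_VERSION = 1


class _SupportSample:
    """Lightweight view of a stored support sample (duck-types RRiVector)."""

    __slots__ = ("values", "patient_id")

    def __init__(self, values, patient_id=""):
        self.values = values
        self.patient_id = patient_id


def _as_list(X):
    if isinstance(X, (np.ndarray, list, tuple)) and len(X) and not np.isscalar(X[0]):
        return list(X)
    raise ValueError("X must be a non-empty sequence of interval vectors")


class DistributionalSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM on empirical kernel mean embeddings of R-R intervals.

    Parameters
    ----------
    sigma : float, default=0.1
        Bandwidth of the base Gaussian kernel ``exp[-(z1-z2)^2/sigma^2]``
        acting on individual normalized intervals (which live near 1).
    gamma : float, default=0.5
        Bandwidth of the second-level Gaussian kernel
        ``exp[-dist^2/(2 gamma^2)]`` acting on embedding distances.
    C : float, default=1.0
        Base misclassification cost (the noAF class cost).
    cost_ratio : float, default=1.0
        Ratio cost_AF / cost_noAF.  Values above 1 penalize missed AF more,
        trading specificity for the screening-critical sensitivity.
    tol : float, default=1e-6
        Solver stopping tolerance.
    max_iter : int, default=1_000_000
        Hard iteration cap; hitting it raises instead of returning a silently
        partial model.

    Attributes
    ----------
    classes_ : ndarray
        ``[-1, 1]`` (noAF, AF).
    support_rri_ : list of ndarray
        The support patients' interval vectors, kept so unseen patients of
        ANY length can be scored.
    support_ids_ : list of str
        Patient ids of the support vectors (empty strings when unknown).
    dual_coef_ : ndarray
        Signed dual coefficients ``alpha_i * y_i`` of the support vectors.
    intercept_ : float
        Bias term of the decision function.
    """

    def __init__(self, sigma: float = 0.1, gamma: float = 0.5, C: float = 1.0,
                 cost_ratio: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 1_000_000):
        self.sigma = sigma
        self.gamma = gamma
        self.C = C
        self.cost_ratio = cost_ratio
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit on a list of interval vectors (RRiVector or 1-D arrays) and labels in {-1, +1}."""
        X = _as_list(X)
        y = np.asarray(y, dtype=int)
        if y.shape != (len(X),):
            raise ValueError(f"y has shape {y.shape}, expected ({len(X)},)")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +1 (AF) or -1 (noAF)")
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class; both AF "
                             "and noAF examples are required")
        params = KernelParams(self.sigma, self.gamma)
        cache = SelfTermCache()
        D = pairwise_sq_dist(X, X, params.sigma, cache)
        K = second_level_kernel(D, params.gamma)
        svc = _solve_dual(K, y, C=self.C, cost_ratio=self.cost_ratio,
                          tol=self.tol, max_iter=self.max_iter)
        self.classes_ = svc.classes_
        sv = svc.support_
        self.support_rri_ = [np.asarray(getattr(X[i], "values", X[i]), float) for i in sv]
        self.support_ids_ = [getattr(X[i], "patient_id", "") or "" for i in sv]
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self._self_cache_ = cache
        return self

    # -- scoring ------------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Signed margin for each query: sum_i (alpha_i y_i) K(mu_q, mu_sv_i) + b.

        Queries may have any length d >= 1 regardless of the lengths seen at
        training, and the score is invariant to permuting a query's entries.
        """
        self._check_fitted()
        X = _as_list(X)
        support = [_SupportSample(vals, pid)
                   for vals, pid in zip(self.support_rri_, self.support_ids_)]
        D = pairwise_sq_dist(X, support, self.sigma, getattr(self, "_self_cache_", None))
        K = second_level_kernel(D, self.gamma)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Predicted labels; a score of exactly 0 resolves to +1 (AF) —
        screening prefers false positives over false negatives."""
        scores = self.decision_function(X)
        return np.where(scores >= 0.0, 1, -1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "dual_coef_"):
            raise AttributeError("this DistributionalSVC instance is not fitted yet")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format_version": _FORMAT_VERSION,
            "params": {"sigma": self.sigma, "gamma": self.gamma, "C": self.C,
                       "cost_ratio": self.cost_ratio, "tol": self.tol,
                       "max_iter": self.max_iter},
            "support_ids": self.support_ids_,
            "support_rri": [v.tolist() for v in self.support_rri_],
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }

    def save(self, path) -> None:
        """Serialize to a single JSON archive (floats round-trip exactly)."""
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionalSVC":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {d.get('format_version')!r}")
        model = cls(**d["params"])
        model.classes_ = np.array([-1, 1])
        model.support_rri_ = [np.asarray(v, float) for v in d["support_rri"]]
        model.support_ids_ = list(d["support_ids"])
        model.dual_coef_ = np.asarray(d["dual_coef"], float)
        model.intercept_ = float(d["intercept"])
        return model

    @classmethod
    def load(cls, path) -> "DistributionalSVC":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _solve_dual(K: np.ndarray, y: np.ndarray, C: float, cost_ratio: float,
                tol: float, max_iter: int) -> SVC:
    """Solve the weighted soft-margin dual on a precomputed kernel matrix.

    Per-class box constraints scale with the misclassification costs:
    C_AF = C * cost_ratio, C_noAF = C.  Convergence failure raises."""
    if K.shape[0] != K.shape[1]:
        raise ValueError(f"Gram matrix must be square, got {K.shape}")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("Gram matrix must be symmetric")
    svc = SVC(kernel="precomputed", C=C, class_weight={1: cost_ratio, -1: 1.0},
              tol=tol, max_iter=max_iter, shrinking=True)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(K, y)
        except ConvergenceWarning as w:
            raise RuntimeError(f"SVM solver failed to converge within "
                               f"{max_iter} iterations: {w}") from w
    return svc


def fit_gram(train_gram: GramMatrix, labels, class_costs=(1.0, 1.0), tol: float = 1e-6,
             max_iter: int = 1_000_000) -> SVC:
    """Thin functional wrapper: fit a weighted SVM directly on a precomputed
    square self-Gram.  ``class_costs`` is (cost_AF, cost_noAF).  Used by the
    cross-validation loop, where Gram sub-blocks are sliced out of one matrix."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    cost_af, cost_noaf = class_costs
    if not (cost_af > 0 and cost_noaf > 0):
        raise ValueError("class costs must be positive")
    return _solve_dual(train_gram.values, y, C=cost_noaf,
                       cost_ratio=cost_af / cost_noaf, tol=tol, max_iter=max_iter)
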