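"""Quadratic discriminant analysis from per-class Gaussian fits.

Each class k is modelled as a multivariate Gaussian with its own mean and
covariance; a query point is scored by the log joint density

    score_k(x) = -1/2 log det(S_k) - 1/2 (x - m_k)' S_k^{-1} (x - m_k) + log pi_k

up to a class-independent constant, and classified to the argmax.  Priors
are the empirical class frequencies.  Covariances are the unbiased sample
covariances plus a relative ridge ``ridge * tr(S)/d`` on the diagonal; the
small default ridge keeps near-singular folds (n_k barely above d) usable
without noticeably moving well-conditioned decisions.

Scores are computed through a Cholesky factorization of each covariance
(triangular solves, never an explicit inverse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .errors import SingularCovarianceError

DEFAULT_RIDGE = 1e-6


@dataclass
class QDAModel:
    """A fitted QDA classifier.

    ``feature_indices`` records which pair-vector columns the model was fit
    on; ``property_accessions`` and ``mass_convention`` let prediction-time
    checks refuse a mismatched property table.
    """

    class_labels: list
    means: np.ndarray          # (k, d)
    covariances: np.ndarray    # (k, d, d), after regularization
    log_priors: np.ndarray     # (k,)
    ridge: float
    feature_indices: list[int] | None = None
    property_accessions: list[str] | None = None
    mass_convention: str | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def _factorize(self):
        if self._chol is None:
            k, d = self.means.shape
            chol = np.empty((k, d, d))
            logdet = np.empty(k)
            for i in range(k):
                try:
                    chol[i] = np.linalg.cholesky(self.covariances[i])
                except np.linalg.LinAlgError:
                    raise SingularCovarianceError(
                        f"covariance of class {self.class_labels[i]!r} is "
                        "not positive definite",
                        class_label=self.class_labels[i]) from None
                logdet[i] = 2.0 * np.sum(np.log(np.diag(chol[i])))
            self._chol, self._logdet = chol, logdet
        return self._chol, self._logdet

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "class_labels": list(self.class_labels),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_priors": self.log_priors.tolist(),
            "ridge": self.ridge,
            "feature_indices": self.feature_indices,
            "property_accessions": self.property_accessions,
            "mass_convention": self.mass_convention,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "QDAModel":
        d = json.loads(text)
        return cls(class_labels=d["class_labels"],
                   means=np.array(d["means"], dtype=float),
                   covariances=np.array(d["covariances"], dtype=float),
                   log_priors=np.array(d["log_priors"], dtype=float),
                   ridge=d["ridge"],
                   feature_indices=d.get("feature_indices"),
                   property_accessions=d.get("property_accessions"),
                   mass_convention=d.get("mass_convention"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "QDAModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_qda(X: np.ndarray, y: Sequence, ridge: float = DEFAULT_RIDGE,
            feature_indices: list[int] | None = None,
            property_accessions: list[str] | None = None,
            mass_convention: str | None = None) -> QDAModel:
    """Fit per-class Gaussians with empirical priors.

    Requires at least two classes and at least two samples per class.
    Class order is sorted label order; exact prediction ties break toward
    the earlier class in that order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("fit_qda requires at least 2 classes")
    n, d = X.shape
    means = np.empty((len(labels), d))
    covs = np.empty((len(labels), d, d))
    priors = np.empty(len(labels))
    for i, lab in enumerate(labels):
        Xc = X[y == lab]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        means[i] = Xc.mean(axis=0)
        cov = np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1))
        cov = cov + ridge * (np.trace(cov) / d) * np.eye(d)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise SingularCovarianceError(
                f"covariance of class {lab!r} is singular after "
                f"regularization (n={Xc.shape[0]}, d={d}, ridge={ridge})",
                class_label=lab) from None
        covs[i] = cov
        priors[i] = Xc.shape[0] / n
    return QDAModel(class_labels=labels, means=means, covariances=covs,
                    log_priors=np.log(priors), ridge=ridge,
                    feature_indices=feature_indices,
                    property_accessions=property_accessions,
                    mass_convention=mass_convention)


def qda_scores(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """Per-class scores; (k,) for a single vector, (n, k) for a matrix."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X2.shape[1]}")
    chol, logdet = model._factorize()
    scores = np.empty((X2.shape[0], model.n_classes))
    for i in range(model.n_classes):
        diff = (X2 - model.means[i]).T
        z = solve_triangular(chol[i], diff, lower=True)
        maha = np.sum(z * z, axis=0)
        scores[:, i] = -0.5 * logdet[i] - 0.5 * maha + model.log_priors[i]
    return scores[0] if single else scores


def predict(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax of scores per row; exact ties go to the earlier class label."""
    scores = np.atleast_2d(qda_scores(model, X))
    idx = np.argmax(scores, axis=1)  # argmax returns the first maximum
    return np.array([model.class_labels[i] for i in idx])
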