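"""Gaussian-kernel SVM training, scoring, LOOCV objectives, and grid search.

The kernel is parameterized by the kernel scale sigma,
``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))``, and the soft-margin box
constraint C, matching the (C; sigma) hyperparameter pairs the signatures
are reported with. Decision scores are signed hyperplane distances in
"hu": positive predicts sensitive, negative resistant.

Two cross-validated objectives are available: the leave-one-out
misclassification rate, and a bounded log-loss defined as the mean of one
minus the Platt-calibrated posterior probability of the true class, which
lies in [0, 1] (standard clipped cross-entropy is kept behind the
``"cross_entropy"`` objective for comparison).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.svm import SVC

from .core_data import ExpressionMatrix, LabelVector

OBJECTIVES = ("misclassification", "logloss", "cross_entropy")

# libsvm stopping tolerance; tightened beyond the 1e-3 default so decision
# scores are reproducible to high precision on small panels
SOLVER_TOL = 1e-8


@dataclass(frozen=True)
class SvmHyperparams:
    """Box constraint C and Gaussian kernel scale sigma (both > 0)."""

    C: float
    sigma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")

    @property
    def gamma(self) -> float:
        """Equivalent RBF gamma: ||u-v||^2 coefficient, 1 / (2 sigma^2)."""
        return 1.0 / (2.0 * self.sigma**2)

    @classmethod
    def from_gamma(cls, C: float, gamma: float) -> "SvmHyperparams":
        return cls(C, float(np.sqrt(1.0 / (2.0 * gamma))))


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between rows of ``a`` and rows of ``b``."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass
class SvmModel:
    """Trained soft-margin Gaussian SVM over a fixed ordered gene set.

    Stores enough state (support vectors, dual coefficients, bias) to score
    new samples without scikit-learn objects; positive decision score
    predicts the sensitive class.
    """

    genes: list[str]
    hyperparams: SvmHyperparams
    support_vectors: np.ndarray  # n_sv x n_genes
    dual_coef: np.ndarray  # signed alpha_i * y_i, length n_sv
    intercept: float
    training_X: np.ndarray  # n_samples x n_genes (for perturbation bounds)
    training_y: np.ndarray
    training_sample_ids: list[str]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        k = rbf_kernel(np.atleast_2d(X), self.support_vectors, self.hyperparams.sigma)
        return k @ self.dual_coef + self.intercept

    def training_predictions(self) -> np.ndarray:
        return (self.decision_scores(self.training_X) >= 0).astype(int)

    def training_checksum(self) -> str:
        """SHA-256 over the training matrix and labels, for provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.training_X).tobytes())
        h.update(np.ascontiguousarray(self.training_y).tobytes())
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "training_checksum": self.training_checksum(),
            "genes": self.genes,
            "C": self.hyperparams.C,
            "sigma": self.hyperparams.sigma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "training_X": self.training_X.tolist(),
            "training_y": self.training_y.tolist(),
            "training_sample_ids": self.training_sample_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        model = cls._from_fields(d)
        stored = d.get("training_checksum")
        if stored is not None and stored != model.training_checksum():
            raise ValueError("training-data checksum mismatch: serialized model is corrupt")
        return model

    @classmethod
    def _from_fields(cls, d: dict) -> "SvmModel":
        return cls(
            genes=list(d["genes"]),
            hyperparams=SvmHyperparams(d["C"], d["sigma"]),
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            intercept=float(d["intercept"]),
            training_X=np.asarray(d["training_X"], float),
            training_y=np.asarray(d["training_y"], int),
            training_sample_ids=list(d["training_sample_ids"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CvEstimate:
    """Cross-validated objective value with per-sample held-out predictions."""

    objective: str
    value: float
    per_fold_predictions: pd.DataFrame  # columns: sample_id, true, predicted, score

    def __post_init__(self) -> None:
        if self.objective in ("misclassification", "logloss") and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"{self.objective} must lie in [0, 1], got {self.value}")

    @property
    def held_out_scores(self) -> np.ndarray:
        return self.per_fold_predictions["score"].to_numpy()


def _as_xy(x: ExpressionMatrix, y: LabelVector, genes: Sequence[str] | None = None):
    if list(x.sample_ids) != list(y.sample_ids):
        raise ValueError("expression matrix and labels cover different samples")
    m = x if genes is None else x.subset_genes(list(genes))
    return m.values.T.copy(), y.y.copy()  # samples x genes


def train_svm(x: ExpressionMatrix, y: LabelVector, h: SvmHyperparams, genes: Sequence[str] | None = None) -> SvmModel:
    """Fit a soft-margin Gaussian SVM; deterministic for fixed input."""
    X, yv = _as_xy(x, y, genes)
    if len(np.unique(yv)) < 2:
        raise ValueError("degenerate labeling: both classes required")
    svc = SVC(C=h.C, kernel="rbf", gamma=h.gamma, tol=SOLVER_TOL)
    svc.fit(X, yv)
    used_genes = list(genes) if genes is not None else list(x.gene_ids)
    return SvmModel(
        genes=used_genes,
        hyperparams=h,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        training_X=X,
        training_y=yv,
        training_sample_ids=list(x.sample_ids),
    )


def decision_score(m: SvmModel, sample: dict[str, float] | np.ndarray) -> float:
    """Signed hyperplane distance for one sample (>= 0 -> sensitive)."""
    if isinstance(sample, dict):
        missing = [g for g in m.genes if g not in sample]
        if missing:
            raise KeyError(f"sample is missing signature genes: {', '.join(missing)}")
        vec = np.array([sample[g] for g in m.genes], float)
    else:
        vec = np.asarray(sample, float)
        if vec.shape != (len(m.genes),):
            raise ValueError(f"expected a vector of {len(m.genes)} gene values")
    return float(m.decision_scores(vec[None, :])[0])


@dataclass
class PlattCalibration:
    """Monotone sigmoid map from decision score to sensitive-class posterior.

    p(score) = 1 / (1 + exp(A * score + B)) with A <= 0 so the map is
    non-decreasing; probabilities are clipped to [1e-15, 1 - 1e-15].
    """

    A: float
    B: float

    def __call__(self, scores: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(scores, float)
        p = 1.0 / (1.0 + np.exp(np.clip(self.A * s + self.B, -500, 500)))
        p = np.clip(p, 1e-15, 1 - 1e-15)
        return float(p) if np.isscalar(scores) else p


def calibrate_posteriors(scores: np.ndarray, y: np.ndarray) -> PlattCalibration:
    """Fit Platt's sigmoid on (cross-validated) decision scores.

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    and minimizes the cross-entropy in (A, B) with A constrained <= 0 so
    higher scores never get lower posteriors.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite decision scores")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for calibration")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = np.clip(a * scores + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))
        p = np.clip(p, 1e-15, 1 - 1e-15)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="L-BFGS-B", bounds=[(None, 0.0), (None, None)])
    return PlattCalibration(float(res.x[0]), float(res.x[1]))


def _loocv_scores(X: np.ndarray, yv: np.ndarray, h: SvmHyperparams) -> np.ndarray:
    """Held-out decision score per sample via a shared precomputed Gram matrix."""
    n = len(yv)
    G = rbf_kernel(X, X, h.sigma)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        ytr = yv[tr]
        svc = SVC(C=h.C, kernel="precomputed", tol=SOLVER_TOL)
        svc.fit(G[np.ix_(tr, tr)], ytr)
        scores[i] = float(svc.decision_function(G[i, tr][None, :])[0])
    return scores


def _loocv_scores_per_fold_scaled(X: np.ndarray, yv: np.ndarray, h: SvmHyperparams) -> np.ndarray:
    """LOOCV scores with features re-standardized inside every training fold."""
    n = len(yv)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        svc = SVC(C=h.C, kernel="rbf", gamma=h.gamma, tol=SOLVER_TOL)
        svc.fit((X[tr] - mu) / sd, yv[tr])
        scores[i] = float(svc.decision_function(((X[i] - mu) / sd)[None, :])[0])
    return scores


def loocv(
    x: ExpressionMatrix,
    y: LabelVector,
    h: SvmHyperparams,
    objective: str = "misclassification",
    genes: Sequence[str] | None = None,
    rescale_per_fold: bool = False,
) -> CvEstimate:
    """Leave-one-out cross-validated objective.

    Requires n >= 3 and at least two members per class so every fold
    retains both classes. ``logloss`` is the bounded variant: the mean of
    one minus the calibrated posterior of the true class. By default
    features keep their global (whole-dataset) scaling; with
    ``rescale_per_fold`` each fold re-standardizes on its own training
    samples, removing the mild information leak of global scaling at the
    cost of noisier small-n folds.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    X, yv = _as_xy(x, y, genes)
    n = len(yv)
    if n < 3:
        raise ValueError("LOOCV requires at least 3 samples")
    if yv.sum() < 2 or (1 - yv).sum() < 2:
        raise ValueError("each class needs >= 2 members so every fold retains both classes")
    if rescale_per_fold:
        scores = _loocv_scores_per_fold_scaled(X, yv, h)
    else:
        scores = _loocv_scores(X, yv, h)
    pred = (scores >= 0).astype(int)
    if objective == "misclassification":
        value = float((pred != yv).mean())
    else:
        cal = calibrate_posteriors(scores, yv)
        p_sens = np.asarray(cal(scores))
        p_true = np.where(yv == 1, p_sens, 1 - p_sens)
        if objective == "logloss":
            value = float(np.mean(1.0 - p_true))
        else:  # cross_entropy
            value = float(-np.mean(np.log(p_true)))
    df = pd.DataFrame(
        {"sample_id": y.sample_ids, "true": yv, "predicted": pred, "score": scores}
    )
    return CvEstimate(objective, value, df)


def grid_search(
    x: ExpressionMatrix,
    y: LabelVector,
    C_grid: Sequence[float] = (10.0, 100.0, 1000.0, 1e4, 1e5),
    sigma_grid: Sequence[float] = (10.0, 100.0, 1000.0),
    objective: str = "misclassification",
    genes: Sequence[str] | None = None,
) -> tuple[SvmHyperparams, CvEstimate]:
    """Exhaustive LOOCV over the (C, sigma) grid.

    Default grids span the hyperparameter pairs the derived signatures are
    reported with. Ties are broken toward smaller C, then smaller sigma.
    """
    if not len(C_grid) or not len(sigma_grid):
        raise ValueError("grids must be non-empty")
    best: tuple[SvmHyperparams, CvEstimate] | None = None
    for C in sorted(set(float(c) for c in C_grid)):
        for s in sorted(set(float(s) for s in sigma_grid)):
            h = SvmHyperparams(C, s)
            est = loocv(x, y, h, objective, genes)
            if best is None or est.value < best[1].value:
                best = (h, est)
    assert best is not None
    return best
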