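"""Probability calibration of raw classifier scores.

Three calibrators, all trained on out-of-fold (OOF) scores so the map
from raw score to probability is estimated on data the base model did
not fit:

* ``LR``  — per class, univariable Platt-style logistic regression of
  the one-vs-rest indicator on the logit of that class's raw score.
* ``FLR`` — the same design with Firth's penalized likelihood
  l(b) + 1/2 log det I(b), whose estimates stay finite even under
  complete separation.
* ``MR``  — multinomial logistic regression with an L2 (ridge) penalty
  on the full K-column raw score matrix; the penalty is chosen by
  5-fold cross-validated multiclass log loss on a log-spaced grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import BetaMatrix, LabelVector, ProbMatrix
from .folds import stratified_fold_ids

__all__ = [
    "CalibratorModel",
    "FirthFit",
    "firth_logistic",
    "oof_scores",
    "fit_calibrator",
    "apply_calibrator",
    "LAMBDA_GRID",
]

LAMBDA_GRID = np.logspace(-4, 4, 25)
_EPS = 1e-12


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _mlogloss(P: np.ndarray, codes: np.ndarray) -> float:
    p = np.clip(P[np.arange(len(codes)), codes], 1e-15, 1 - 1e-15)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------


@dataclass
class FirthFit:
    beta: np.ndarray
    fisher_info: np.ndarray
    hat_values: np.ndarray
    converged: bool
    iterations: int
    loglik_penalized: float


def firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthFit:
    """Firth-penalized logistic regression (design X includes the intercept).

    Maximizes l(b) + 1/2 log det I(b) by Newton steps on the modified
    score U*_r = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ir, with step
    halving on the penalized likelihood.  Finite estimates are
    guaranteed on any finite dataset, including separable ones.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, d = X.shape
    beta = np.zeros(d)

    def penalized_ll(beta: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        z = X @ beta
        pi = _sigmoid(z)
        W = pi * (1.0 - pi)
        I = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(I)
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
        return ll + 0.5 * (logdet if sign > 0 else -np.inf), pi, W, I

    ll, pi, W, I = penalized_ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Ii = np.linalg.pinv(I)
        # hat values of the weighted least-squares smoother
        H = (X * W[:, None]) @ Ii * X
        h = H.sum(axis=1)
        U = X.T @ (y - pi + h * (0.5 - pi))
        if np.abs(U).max() < tol:
            converged = True
            break
        step = Ii @ U
        t = 1.0
        while t >= 1e-10:
            cand = beta + t * step
            ll_new, pi_new, W_new, I_new = penalized_ll(cand)
            if ll_new >= ll - 1e-12:
                beta, ll, pi, W, I = cand, ll_new, pi_new, W_new, I_new
                break
            t /= 2.0
        else:
            break
    Ii = np.linalg.pinv(I)
    h = ((X * W[:, None]) @ Ii * X).sum(axis=1)
    if not converged:
        U = X.T @ (y - pi + h * (0.5 - pi))
        converged = bool(np.abs(U).max() < 1e-4)
    return FirthFit(beta, I, np.clip(h, 0.0, 1.0), converged, it, ll)


def _plain_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> Tuple[np.ndarray, bool]:
    """Unpenalized logistic regression by Newton with step halving.

    Returns (beta, diverged): under complete separation the slope grows
    without bound; the fit is stopped after ``max_iter`` Newton steps
    and flagged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    beta = np.zeros(X.shape[1])

    def nll(beta: np.ndarray) -> float:
        z = X @ beta
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    val = nll(beta)
    for _ in range(max_iter):
        z = X @ beta
        pi = _sigmoid(z)
        g = X.T @ (pi - y)
        if np.abs(g).max() < tol:
            break
        W = np.maximum(pi * (1.0 - pi), 1e-12)
        Hm = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, g, rcond=None)[0]
        t = 1.0
        while t >= 1e-10:
            cand = beta - t * step
            v = nll(cand)
            if v <= val + 1e-12:
                beta, val = cand, v
                break
            t /= 2.0
        else:
            break
    z = X @ beta
    g = X.T @ (_sigmoid(z) - y)
    # under complete separation the gradient vanishes while the slope
    # blows up, so an absurd coefficient magnitude also counts as divergence
    return beta, bool(np.abs(g).max() >= 1e-6 or np.abs(beta).max() > 12.0)


# ---------------------------------------------------------------------------
# Calibrator model
# ---------------------------------------------------------------------------


@dataclass
class CalibratorModel:
    """Fitted calibration map from raw scores to probabilities."""

    method: str  # LR | FLR | MR
    class_names: List[str]
    # LR/FLR: (K, 2) intercept/slope on the logit of the class's own score
    ab: Optional[np.ndarray] = None
    diverged: Optional[List[bool]] = None
    # MR: (K, K) coefficients + (K,) intercepts on the raw probability columns
    coef: Optional[np.ndarray] = None
    intercept: Optional[np.ndarray] = None
    lam: Optional[float] = None
    cv_losses: Optional[Dict[float, float]] = None

    def to_jsonable(self) -> dict:
        out = {"method": self.method, "class_names": self.class_names}
        if self.ab is not None:
            out["ab"] = self.ab.tolist()
            out["diverged"] = self.diverged
        if self.coef is not None:
            out["coef"] = self.coef.tolist()
            out["intercept"] = self.intercept.tolist()
            out["lam"] = self.lam
        return out


def fit_calibrator(
    raw: ProbMatrix, y: LabelVector, method: str, seed: int = 0
) -> CalibratorModel:
    """Fit an LR / FLR / MR calibrator on raw OOF scores."""
    if raw.sample_ids != y.sample_ids:
        y = y.subset(raw.sample_ids)
    classes = list(raw.class_names)
    missing = [c for c in classes if c not in set(y.labels)]
    if missing:
        raise ValueError(f"classes absent from calibration data: {missing}")
    K = len(classes)
    codes = np.array([classes.index(l) for l in y.labels])
    V = raw.values

    if method in ("LR", "FLR"):
        ab = np.zeros((K, 2))
        diverged = [False] * K
        for k in range(K):
            design = np.column_stack([np.ones(len(codes)), _logit(V[:, k])])
            target = (codes == k).astype(float)
            if method == "LR":
                beta, div = _plain_logistic(design, target)
                diverged[k] = div
            else:
                fit = firth_logistic(design, target)
                beta = fit.beta
                diverged[k] = not fit.converged
            ab[k] = beta
        return CalibratorModel(method, classes, ab=ab, diverged=diverged)

    if method == "MR":
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(seed)
        fold = stratified_fold_ids(y.labels, 5, rng)
        cv_losses: Dict[float, float] = {}
        for lam in LAMBDA_GRID:
            losses = []
            for f in range(5):
                tr = fold != f
                if len(set(codes[tr])) < K:
                    continue
                est = _mr_estimator(lam)
                est.fit(V[tr], codes[tr])
                P = _mr_proba(est, V[~tr], K)
                losses.append(_mlogloss(P, codes[~tr]))
            cv_losses[float(lam)] = float(np.mean(losses)) if losses else math.inf
        lam_best = min(cv_losses, key=lambda l: (cv_losses[l], l))
        est = _mr_estimator(lam_best)
        est.fit(V, codes)
        coef = np.zeros((K, K))
        intercept = np.zeros(K)
        coef[np.asarray(est.classes_, dtype=int)] = est.coef_
        intercept[np.asarray(est.classes_, dtype=int)] = est.intercept_
        return CalibratorModel(
            "MR", classes, coef=coef, intercept=intercept, lam=lam_best,
            cv_losses=cv_losses,
        )

    raise ValueError(f"unknown calibration method {method!r}")


def _mr_estimator(lam: float):
    from sklearn.linear_model import LogisticRegression

    # sklearn minimizes loss + 1/(2C) |b|^2, so lam |b|^2 <=> C = 1/(2 lam)
    return LogisticRegression(C=1.0 / (2.0 * lam), solver="lbfgs", max_iter=2000)


def _mr_proba(est, V: np.ndarray, K: int) -> np.ndarray:
    P = np.full((len(V), K), 1e-15)
    P[:, np.asarray(est.classes_, dtype=int)] = est.predict_proba(V)
    return P / P.sum(axis=1, keepdims=True)


def apply_calibrator(cal: CalibratorModel, raw: ProbMatrix) -> ProbMatrix:
    """Map raw scores through a fitted calibrator; output is row-stochastic."""
    if list(raw.class_names) != list(cal.class_names):
        if sorted(raw.class_names) != sorted(cal.class_names):
            raise ValueError("class sets of calibrator and scores differ")
        raw = raw.reorder_classes(cal.class_names)
    V = raw.values
    K = len(cal.class_names)
    if cal.method in ("LR", "FLR"):
        out = np.empty_like(V)
        for k in range(K):
            z = cal.ab[k, 0] + cal.ab[k, 1] * _logit(V[:, k])
            out[:, k] = _sigmoid(z)
        out = np.maximum(out, 1e-300)
        out /= out.sum(axis=1, keepdims=True)
    elif cal.method == "MR":
        Z = V @ cal.coef.T + cal.intercept
        Z -= Z.max(axis=1, keepdims=True)
        out = np.exp(Z)
        out /= out.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown calibration method {cal.method!r}")
    return ProbMatrix(list(raw.sample_ids), list(cal.class_names), out)


# ---------------------------------------------------------------------------
# Out-of-fold scores
# ---------------------------------------------------------------------------


def oof_scores(
    X: BetaMatrix,
    y: LabelVector,
    model_spec: dict,
    n_folds: int = 5,
    seed: int = 0,
    fold_ids: Optional[np.ndarray] = None,
) -> ProbMatrix:
    """Raw out-of-fold scores: each sample is scored by the fold model
    that did not train on it; every sample is covered exactly once.

    ``model_spec`` is ``{"kind": ..., **hyperparameters}`` as accepted
    by :func:`methylens.classifiers.train_base`.
    """
    from . import classifiers

    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    if fold_ids is None:
        rng = np.random.default_rng(seed)
        fold_ids = stratified_fold_ids(y.labels, n_folds, rng)
    fold_ids = np.asarray(fold_ids)
    classes = sorted(set(y.labels))
    n = X.n_samples
    out = np.full((n, len(classes)), np.nan)
    spec = dict(model_spec)
    kind = spec.pop("kind")
    for f in sorted(set(fold_ids.tolist())):
        tr = fold_ids != f
        tr_ids = [s for s, m in zip(X.sample_ids, tr) if m]
        te_ids = [s for s, m in zip(X.sample_ids, tr) if not m]
        y_tr = y.subset(tr_ids)
        cnt = y_tr.counts()
        lacking = [c for c in classes if cnt.get(c, 0) < 2]
        if lacking:
            raise ValueError(
                f"inner fold {f}: classes {lacking} have < 2 training samples; "
                "use fewer folds"
            )
        model = classifiers.train_base(X.subset_samples(tr_ids), y_tr, kind, seed=seed, **spec)
        pm = model.predict_proba(X.subset_samples(te_ids))
        pm = pm.reorder_classes(classes)
        out[~tr] = pm.values
    if np.isnan(out).any():
        raise AssertionError("some samples were not covered by any fold")
    return ProbMatrix(list(X.sample_ids), classes, out)
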