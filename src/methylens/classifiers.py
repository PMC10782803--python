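"""Classification models.

The centrepiece is the ensemble SVM (eSVM): B linear-kernel SVM base
learners, each trained on all samples but on a random feature subset of
size m, with the ensemble posterior equal to the arithmetic mean of the
base posteriors.  Feature subsampling shortens the sample vectors that
enter the kernel inner products, which is what makes the ensemble cheap
on very wide methylation matrices while leaving the margin geometry —
and hence the support-vector set — essentially intact.  The same
wrapper around multilayer-perceptron bases gives the eNeural model.
Random forest / XGBoost / elastic-net logistic bases are pluggable and
delegate to their standard implementations.

Multiclass SVM probabilities follow the canonical recipe: one-vs-one
soft-margin machines, a Platt sigmoid per class pair fitted on the
training decision values, and pairwise coupling of the K(K-1)/2 pair
probabilities into a single posterior vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.svm import SVC

from .core import BetaMatrix, LabelVector, ProbMatrix

__all__ = [
    "LinearSVMModel",
    "MLPModel",
    "EnsembleModel",
    "SKLearnModel",
    "train_svm",
    "train_mlp",
    "train_ensemble",
    "train_base",
    "predict_proba",
    "support_vectors",
    "platt_fit",
    "pairwise_coupling",
]


# ---------------------------------------------------------------------------
# Platt scaling and pairwise coupling
# ---------------------------------------------------------------------------


def platt_fit(decision: np.ndarray, target: np.ndarray, max_iter: int = 100) -> Tuple[float, float]:
    """Fit P(y=1|f) = 1 / (1 + exp(A f + B)) by penalized ML (Platt's method).

    Uses the smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    and the Newton iteration with backtracking of Lin, Lu & Weng (2007).
    Deterministic.
    """
    f = np.asarray(decision, dtype=np.float64)
    t = np.where(np.asarray(target) > 0, 1.0, 0.0)
    n_pos = t.sum()
    n_neg = len(t) - n_pos
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(t > 0, hi, lo)

    A, B = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12

    def fval(A: float, B: float) -> float:
        z = A * f + B
        # -[t log p + (1-t) log(1-p)] computed stably
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1) * z + np.log1p(np.exp(z)))))

    fv = fval(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # dF/dz
        d2 = p * (1 - p)
        g1 = float(np.dot(f, d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float(np.dot(f * f, d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.dot(f, d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            An, Bn = A + step * dA, B + step * dB
            fn = fval(An, Bn)
            if fn < fv + 1e-4 * step * gd:
                A, B, fv = An, Bn, fn
                break
            step /= 2.0
        else:
            break
    return A, B


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def pairwise_coupling(R: np.ndarray) -> np.ndarray:
    """Couple pairwise probabilities into a posterior vector.

    ``R[i, j]`` is the estimated P(class i | class i or j) for one
    sample (R[j, i] = 1 - R[i, j]).  Solves the quadratic program of
    Wu, Lin & Weng (2004, second approach) via its KKT linear system,
    then clips tiny negatives and renormalizes.
    """
    K = R.shape[0]
    if K == 2:
        p = np.array([R[0, 1], R[1, 0]])
        return p / p.sum()
    Q = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i == j:
                Q[i, i] = sum(R[j2, i] ** 2 for j2 in range(K) if j2 != i)
            else:
                Q[i, j] = -R[j, i] * R[i, j]
    A = np.zeros((K + 1, K + 1))
    A[:K, :K] = Q
    A[:K, K] = 1.0
    A[K, :K] = 1.0
    b = np.zeros(K + 1)
    b[K] = 1.0
    try:
        sol = np.linalg.solve(A, b)
        p = sol[:K]
    except np.linalg.LinAlgError:
        p = np.full(K, 1.0 / K)
    p = np.maximum(p, 0.0)
    s = p.sum()
    return p / s if s > 0 else np.full(K, 1.0 / K)


# ---------------------------------------------------------------------------
# Linear one-vs-one SVM
# ---------------------------------------------------------------------------


@dataclass
class LinearSVMModel:
    """One-vs-one linear SVM with per-pair Platt sigmoids."""

    class_names: List[str]  # sorted
    feature_ids: List[str]
    weights: np.ndarray  # (n_pairs, p)
    biases: np.ndarray  # (n_pairs,)
    platt_ab: np.ndarray  # (n_pairs, 2)
    sv_indices: List[int]  # indices into the training sample order
    train_sample_ids: List[str]
    C: float = 1.0

    @property
    def kind(self) -> str:
        return "svm"

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        K = len(self.class_names)
        return [(i, j) for i in range(K) for j in range(i + 1, K)]

    def _pair_probs(self, X: np.ndarray) -> np.ndarray:
        """(n, n_pairs) matrix of P(class j beats class i) per pair (i, j)."""
        F = X @ self.weights.T + self.biases
        A = self.platt_ab[:, 0]
        B = self.platt_ab[:, 1]
        return _sigmoid(-(A * F + B))  # Platt: P(y=1|f) = sigma(-(Af+B))

    def predict_proba(self, X: BetaMatrix) -> ProbMatrix:
        Xs = _align(X, self.feature_ids)
        P1 = self._pair_probs(Xs.values)
        K = len(self.class_names)
        out = np.empty((Xs.n_samples, K))
        for s in range(Xs.n_samples):
            R = np.full((K, K), 0.5)
            for m, (i, j) in enumerate(self.pairs):
                pj = min(max(P1[s, m], 1e-12), 1 - 1e-12)
                R[j, i] = pj
                R[i, j] = 1.0 - pj
            out[s] = pairwise_coupling(R)
        return ProbMatrix(list(Xs.sample_ids), list(self.class_names), out)

    def to_state(self) -> Tuple[dict, Dict[str, np.ndarray]]:
        meta = {
            "kind": "svm",
            "class_names": self.class_names,
            "feature_ids": self.feature_ids,
            "train_sample_ids": self.train_sample_ids,
            "sv_indices": list(map(int, self.sv_indices)),
            "C": self.C,
        }
        arrays = {
            "weights": self.weights,
            "biases": self.biases,
            "platt_ab": self.platt_ab,
        }
        return meta, arrays

    @classmethod
    def from_state(cls, meta: dict, arrays: Dict[str, np.ndarray]) -> "LinearSVMModel":
        return cls(
            class_names=list(meta["class_names"]),
            feature_ids=list(meta["feature_ids"]),
            weights=arrays["weights"],
            biases=arrays["biases"].ravel(),
            platt_ab=arrays["platt_ab"],
            sv_indices=list(meta["sv_indices"]),
            train_sample_ids=list(meta["train_sample_ids"]),
            C=float(meta["C"]),
        )


def _align(X: BetaMatrix, feature_ids: Sequence[str]) -> BetaMatrix:
    have = set(X.feature_ids)
    missing = [f for f in feature_ids if f not in have]
    if missing:
        raise KeyError(
            f"matrix lacks {len(missing)} features required by the model, "
            f"e.g. {missing[:10]}"
        )
    if list(X.feature_ids) == list(feature_ids):
        return X
    return X.subset_features(feature_ids)


def _check_classes(y: LabelVector) -> List[str]:
    counts = y.counts()
    classes = sorted(c for c in counts if counts[c] > 0)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with samples")
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with a single sample cannot be fit: {small}")
    return classes


def train_svm(X: BetaMatrix, y: LabelVector, C: float = 1.0) -> LinearSVMModel:
    """One-vs-one soft-margin linear SVM with Platt posteriors.

    For each class pair a linear SVC is solved and a Platt sigmoid is
    fitted on the training decision values; multiclass posteriors come
    from pairwise coupling.  Deterministic given the input order.
    """
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    classes = _check_classes(y)
    lab = np.asarray(y.labels, dtype=object)
    K = len(classes)
    p = X.n_features
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    W = np.zeros((len(pairs), p))
    b = np.zeros(len(pairs))
    AB = np.zeros((len(pairs), 2))
    svs: Set[int] = set()
    for m, (i, j) in enumerate(pairs):
        mask = (lab == classes[i]) | (lab == classes[j])
        idx = np.flatnonzero(mask)
        Xi = X.values[idx]
        yi = (lab[idx] == classes[j]).astype(np.float64)  # 1 <-> class j
        clf = SVC(C=C, kernel="linear")
        clf.fit(Xi, yi)
        # SVC orders classes_ ascending, so decision > 0 <-> yi = 1
        W[m] = clf.coef_[0]
        b[m] = clf.intercept_[0]
        f = Xi @ W[m] + b[m]
        AB[m] = platt_fit(f, yi)
        svs.update(int(idx[s]) for s in clf.support_)
    return LinearSVMModel(
        class_names=classes,
        feature_ids=list(X.feature_ids),
        weights=W,
        biases=b,
        platt_ab=AB,
        sv_indices=sorted(svs),
        train_sample_ids=list(X.sample_ids),
        C=C,
    )


# ---------------------------------------------------------------------------
# Multilayer perceptron base (numpy, full-batch Adam)
# ---------------------------------------------------------------------------


@dataclass
class MLPModel:
    """Single-hidden-layer ReLU network with softmax output."""

    class_names: List[str]
    feature_ids: List[str]
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    seed: int = 0

    @property
    def kind(self) -> str:
        return "mlp"

    def _forward(self, X: np.ndarray) -> np.ndarray:
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        Z = H @ self.W2 + self.b2
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    def predict_proba(self, X: BetaMatrix) -> ProbMatrix:
        Xs = _align(X, self.feature_ids)
        return ProbMatrix(list(Xs.sample_ids), list(self.class_names), self._forward(Xs.values))

    def to_state(self) -> Tuple[dict, Dict[str, np.ndarray]]:
        meta = {
            "kind": "mlp",
            "class_names": self.class_names,
            "feature_ids": self.feature_ids,
            "seed": self.seed,
        }
        return meta, {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    @classmethod
    def from_state(cls, meta: dict, arrays: Dict[str, np.ndarray]) -> "MLPModel":
        return cls(
            class_names=list(meta["class_names"]),
            feature_ids=list(meta["feature_ids"]),
            W1=arrays["W1"],
            b1=arrays["b1"].ravel(),
            W2=arrays["W2"],
            b2=arrays["b2"].ravel(),
            seed=int(meta["seed"]),
        )


def train_mlp(
    X: BetaMatrix,
    y: LabelVector,
    hidden: int = 128,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
) -> MLPModel:
    """Train the MLP base learner: ReLU hidden layer, softmax output,
    cross-entropy loss, full-batch Adam for a fixed epoch budget.
    Seed controls only the weight initialization."""
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    classes = _check_classes(y)
    K = len(classes)
    codes = np.array([classes.index(l) for l in y.labels])
    n, p = X.values.shape
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, math.sqrt(2.0 / p), size=(p, hidden))
    b1 = np.zeros(hidden)
    W2 = rng.normal(0, math.sqrt(2.0 / hidden), size=(hidden, K))
    b2 = np.zeros(K)
    Y = np.zeros((n, K))
    Y[np.arange(n), codes] = 1.0

    params = [W1, b1, W2, b2]
    mom = [np.zeros_like(q) for q in params]
    vel = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    Xv = X.values
    for t in range(1, epochs + 1):
        H = np.maximum(Xv @ W1 + b1, 0.0)
        Z = H @ W2 + b2
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        G = (P - Y) / n
        gW2 = H.T @ G
        gb2 = G.sum(axis=0)
        GH = (G @ W2.T) * (H > 0)
        gW1 = Xv.T @ GH
        gb1 = GH.sum(axis=0)
        for q, g, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], mom, vel):
            m_ *= beta1
            m_ += (1 - beta1) * g
            v_ *= beta2
            v_ += (1 - beta2) * g * g
            mhat = m_ / (1 - beta1**t)
            vhat = v_ / (1 - beta2**t)
            q -= lr * mhat / (np.sqrt(vhat) + eps)
    return MLPModel(classes, list(X.feature_ids), W1, b1, W2, b2, seed)


# ---------------------------------------------------------------------------
# Feature-sampling ensembles (eSVM / eNeural)
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """B base learners on independently sampled feature subsets.

    The ensemble posterior is the arithmetic mean of the base
    posteriors (renormalized); prediction is therefore invariant to the
    order of the base learners.
    """

    base_kind: str  # "svm" or "mlp"
    learners: List[object]
    subsets: List[List[str]]
    class_names: List[str]
    feature_ids: List[str]
    seed: int = 0
    bootstrap: bool = False

    @property
    def kind(self) -> str:
        return "esvm" if self.base_kind == "svm" else "eneural"

    @property
    def B(self) -> int:
        return len(self.learners)

    def predict_proba(self, X: BetaMatrix) -> ProbMatrix:
        Xs = _align(X, self.feature_ids)
        acc = None
        for learner in self.learners:
            pm = learner.predict_proba(Xs)
            acc = pm.values if acc is None else acc + pm.values
        acc /= acc.sum(axis=1, keepdims=True)
        return ProbMatrix(list(Xs.sample_ids), list(self.class_names), acc)

    def to_state(self) -> Tuple[dict, Dict[str, np.ndarray]]:
        meta = {
            "kind": self.kind,
            "base_kind": self.base_kind,
            "class_names": self.class_names,
            "feature_ids": self.feature_ids,
            "seed": self.seed,
            "bootstrap": self.bootstrap,
            "subsets": self.subsets,
            "learners": [],
        }
        arrays: Dict[str, np.ndarray] = {}
        for i, learner in enumerate(self.learners):
            lm, la = learner.to_state()
            meta["learners"].append(lm)
            for name, arr in la.items():
                arrays[f"learner{i}_{name}"] = arr
        return meta, arrays

    @classmethod
    def from_state(cls, meta: dict, arrays: Dict[str, np.ndarray]) -> "EnsembleModel":
        learners = []
        for i, lm in enumerate(meta["learners"]):
            la = {
                name[len(f"learner{i}_"):]: arr
                for name, arr in arrays.items()
                if name.startswith(f"learner{i}_")
            }
            learners.append(model_from_state(lm, la))
        return cls(
            base_kind=meta["base_kind"],
            learners=learners,
            subsets=[list(s) for s in meta["subsets"]],
            class_names=list(meta["class_names"]),
            feature_ids=list(meta["feature_ids"]),
            seed=int(meta["seed"]),
            bootstrap=bool(meta["bootstrap"]),
        )


def train_ensemble(
    X: BetaMatrix,
    y: LabelVector,
    base_kind: str = "svm",
    B: Optional[int] = None,
    m: Optional[int] = None,
    C: float = 1.0,
    mlp_params: Optional[dict] = None,
    bootstrap: bool = False,
    seed: int = 0,
) -> EnsembleModel:
    """Train an eSVM (``base_kind="svm"``) or eNeural (``"mlp"``) ensemble.

    Learner ``b`` sees all samples (unless ``bootstrap``) restricted to
    a feature subset of size ``m`` drawn without replacement,
    independently per learner.  Defaults: ``m = min(p, 1000)`` and
    ``B = max(10, ceil(p / m))`` so that expected feature coverage is at
    least one.  With ``B=1, m=p`` the ensemble reduces exactly to the
    single base learner.
    """
    if base_kind not in ("svm", "mlp"):
        raise ValueError("base_kind must be 'svm' or 'mlp'")
    p = X.n_features
    if m is None:
        m = min(p, 1000)
    if B is None:
        B = max(10, math.ceil(p / m))
    if m <= 0 or B <= 0:
        raise ValueError("B and m must be positive")
    m = min(m, p)
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    rng = np.random.default_rng(seed)
    learners: List[object] = []
    subsets: List[List[str]] = []
    feats = np.asarray(X.feature_ids, dtype=object)
    for b in range(B):
        cols = np.sort(rng.choice(p, size=m, replace=False))
        sub_ids = [str(f) for f in feats[cols]]
        Xb = BetaMatrix(list(X.sample_ids), sub_ids, X.values[:, cols], X.value_type)
        yb = y
        if bootstrap:
            rows = np.sort(rng.choice(X.n_samples, size=X.n_samples, replace=True))
            # keep unique rows: duplicated IDs are not representable
            rows = np.unique(rows)
            Xb = Xb.subset_samples([X.sample_ids[r] for r in rows])
            yb = y.subset(Xb.sample_ids)
        if base_kind == "svm":
            learner = train_svm(Xb, yb, C=C)
        else:
            mp = dict(mlp_params or {})
            mp.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
            learner = train_mlp(Xb, yb, **mp)
        learners.append(learner)
        subsets.append(sub_ids)
    return EnsembleModel(
        base_kind=base_kind,
        learners=learners,
        subsets=subsets,
        class_names=learners[0].class_names,
        feature_ids=list(X.feature_ids),
        seed=seed,
        bootstrap=bootstrap,
    )


# ---------------------------------------------------------------------------
# Pluggable standard bases (internals delegated)
# ---------------------------------------------------------------------------


@dataclass
class SKLearnModel:
    """Wrapper around a standard estimator (RF / XGBoost / elastic net)."""

    kind: str
    estimator: object
    class_names: List[str]
    feature_ids: List[str]

    def predict_proba(self, X: BetaMatrix) -> ProbMatrix:
        Xs = _align(X, self.feature_ids)
        P = np.asarray(self.estimator.predict_proba(Xs.values), dtype=np.float64)
        P = np.maximum(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        return ProbMatrix(list(Xs.sample_ids), list(self.class_names), P)

    def to_state(self):
        raise NotImplementedError(
            f"{self.kind} models delegate to an opaque estimator; use "
            "core.save_model which stores it via joblib"
        )


def train_base(X: BetaMatrix, y: LabelVector, kind: str, seed: int = 0, **hp):
    """Fit a pluggable base learner of the given kind.

    ``svm``/``esvm``/``eneural`` use this package's own implementations;
    ``rf``, ``xgb`` and ``elnet`` delegate to scikit-learn / xgboost.
    """
    if kind == "svm":
        return train_svm(X, y, C=hp.get("C", 1.0))
    if kind == "esvm":
        return train_ensemble(X, y, base_kind="svm", seed=seed, **hp)
    if kind == "eneural":
        return train_ensemble(X, y, base_kind="mlp", seed=seed, **hp)
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    classes = _check_classes(y)
    codes = np.array([classes.index(l) for l in y.labels])
    if kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500), random_state=seed, n_jobs=1
        )
    elif kind == "xgb":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=hp.get("n_estimators", 100),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    elif kind == "elnet":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(
            solver="saga",
            l1_ratio=hp.get("l1_ratio", 0.5),
            C=hp.get("C", 1.0),
            max_iter=hp.get("max_iter", 5000),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    est.fit(X.values, codes)
    return SKLearnModel(kind, est, classes, list(X.feature_ids))


def predict_proba(model, X: BetaMatrix) -> ProbMatrix:
    """Posterior class probabilities; features re-aligned by ID.

    Extra features in ``X`` are ignored; missing ones raise with the
    list of missing IDs.
    """
    return model.predict_proba(X)


def support_vectors(model) -> Set[str]:
    """Support-vector sample IDs: the SV set for a plain linear SVM, and
    the union of the base learners' SV sets for an SVM-based ensemble."""
    if isinstance(model, LinearSVMModel):
        return {model.train_sample_ids[i] for i in model.sv_indices}
    if isinstance(model, EnsembleModel):
        if model.base_kind != "svm":
            raise ValueError("support vectors are defined only for SVM-based models")
        out: Set[str] = set()
        for learner in model.learners:
            out |= support_vectors(learner)
        return out
    raise ValueError(f"support vectors undefined for {type(model).__name__}")


def model_from_state(meta: dict, arrays: Dict[str, np.ndarray]):
    kind = meta["kind"]
    if kind == "svm":
        return LinearSVMModel.from_state(meta, arrays)
    if kind == "mlp":
        return MLPModel.from_state(meta, arrays)
    if kind in ("esvm", "eneural"):
        return EnsembleModel.from_state(meta, arrays)
    raise ValueError(f"cannot rebuild model of kind {kind!r} from blobs")
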