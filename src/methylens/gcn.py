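"""Multi-omics classification.

Two routes to a multi-omics classifier over an aligned bundle of
matrices:

* a feature-sampling ensemble (eSVM / eNeural) whose base learners each
  draw their feature subset *within* one omic, so every omic contributes
  the same number of base learners and the ensemble mean fuses them; and
* a MOGONET-style transductive model: one (or more) two-layer graph
  convolutional networks per omic on a cosine-similarity sample graph,
  fused by a small fully connected head.  The head consumes either the
  concatenated per-learner class-probability vectors (``concat``) or
  their cross-omics outer product of dimension K^M (``interaction``,
  the original design).  Because the interaction dimension explodes
  with the class count, ``auto`` mode keeps interactions only for
  binary problems (class number <= 2) and otherwise discards them,
  compensating with more than one GCN base learner per omic.

The GCN itself is a compact numpy implementation: two graph
convolutions H1 = ReLU(A_hat X W1), logits = A_hat H1 W2 with the
symmetrically normalized self-looped adjacency, cross-entropy on the
labelled (training) nodes only, full-batch Adam, fixed epoch budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classifiers import EnsembleModel, MLPModel, train_mlp, train_svm
from .core import BetaMatrix, LabelVector, OmicsBundle, ProbMatrix

__all__ = [
    "SampleGraph",
    "GCNModel",
    "MogonetModel",
    "build_sample_graph",
    "train_gcn",
    "train_mogonet",
    "train_multiomics_ensemble",
    "interaction_dimension",
]

INTERACTION_CAP = 10_000


def interaction_dimension(K: int, M: int) -> int:
    """Size of the cross-omics interaction representation: the outer
    product of M per-omic K-vectors has K**M entries."""
    return K**M


@dataclass
class SampleGraph:
    adjacency: np.ndarray  # A: non-negative, symmetric, zero diagonal
    operator: np.ndarray  # A_hat = D^{-1/2} (A + I) D^{-1/2}
    mean_degree: float
    target_degree: int


def build_sample_graph(X: np.ndarray, mean_degree: int = 10) -> SampleGraph:
    """Cosine-similarity graph thresholded to a target mean degree.

    The threshold is the similarity at the sorted position that retains
    approximately ``mean_degree * n / 2`` undirected edges; retained
    edges keep their (non-negative) cosine weight.
    """
    X = X.values if isinstance(X, BetaMatrix) else np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < mean_degree + 1:
        raise ValueError(f"need n >= mean_degree + 1 (= {mean_degree + 1})")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"sample {bad} is the zero vector; cosine undefined")
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    np.fill_diagonal(S, -np.inf)
    triu = S[np.triu_indices(n, k=1)]
    n_edges = min(int(round(mean_degree * n / 2)), len(triu))
    if n_edges < 1:
        t = np.inf
    else:
        t = np.sort(triu)[::-1][n_edges - 1]
    A = np.where(S >= t, S, 0.0)
    np.maximum(A, 0.0, out=A)  # negative cosines never form edges
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    deg = (A > 0).sum(axis=1)
    Atil = A + np.eye(n)
    d = Atil.sum(axis=1)
    Dm = 1.0 / np.sqrt(d)
    op = Atil * Dm[:, None] * Dm[None, :]
    return SampleGraph(A, op, float(deg.mean()), mean_degree)


@dataclass
class GCNModel:
    W1: np.ndarray
    W2: np.ndarray
    class_names: List[str]
    epochs: int
    lr: float
    seed: int
    loss_trace: List[float] = field(default_factory=list)

    def forward(self, X: np.ndarray, op: np.ndarray) -> np.ndarray:
        """All-node class probabilities under the given graph operator."""
        H1 = np.maximum(op @ X @ self.W1, 0.0)
        Z = op @ H1 @ self.W2
        Z = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)


def train_gcn(
    X,
    y_codes: np.ndarray,
    train_mask: np.ndarray,
    graph: SampleGraph,
    class_names: Sequence[str],
    hidden: int = 64,
    epochs: int = 300,
    lr: float = 1e-3,
    seed: int = 0,
) -> GCNModel:
    """Train a two-layer GCN transductively.

    ``X`` holds train and test rows; ``y_codes`` is only read where
    ``train_mask`` is True, and only those nodes contribute to the
    cross-entropy.  Deterministic given the seed.
    """
    X = X.values if isinstance(X, BetaMatrix) else np.asarray(X, dtype=np.float64)
    y_codes = np.asarray(y_codes)
    train_mask = np.asarray(train_mask, dtype=bool)
    K = len(class_names)
    present = set(y_codes[train_mask].tolist())
    absent = [class_names[k] for k in range(K) if k not in present]
    if absent:
        raise ValueError(f"training mask covers no sample of classes {absent}")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, math.sqrt(2.0 / p), size=(p, hidden))
    W2 = rng.normal(0.0, math.sqrt(2.0 / hidden), size=(hidden, K))
    op = graph.operator
    idx = np.flatnonzero(train_mask)
    Y = np.zeros((len(idx), K))
    Y[np.arange(len(idx)), y_codes[idx]] = 1.0

    params = [W1, W2]
    mom = [np.zeros_like(q) for q in params]
    vel = [np.zeros_like(q) for q in params]
    b1c, b2c, eps = 0.9, 0.999, 1e-8
    trace: List[float] = []
    opX = op @ X
    for t in range(1, epochs + 1):
        A1 = opX @ W1
        H1 = np.maximum(A1, 0.0)
        opH = op @ H1
        Z = opH @ W2
        Zs = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Zs)
        P = E / E.sum(axis=1, keepdims=True)
        Pm = P[idx]
        trace.append(float(-np.mean(np.log(np.clip(Pm[np.arange(len(idx)), y_codes[idx]], 1e-15, None)))))
        G = np.zeros_like(P)
        G[idx] = (Pm - Y) / len(idx)
        gW2 = opH.T @ G
        GH = (op.T @ (G @ W2.T)) * (A1 > 0)
        gW1 = opX.T @ GH
        for q, g, m_, v_ in zip(params, [gW1, gW2], mom, vel):
            m_ *= b1c
            m_ += (1 - b1c) * g
            v_ *= b2c
            v_ += (1 - b2c) * g * g
            q -= lr * (m_ / (1 - b1c**t)) / (np.sqrt(v_ / (1 - b2c**t)) + eps)
    return GCNModel(W1, W2, list(class_names), epochs, lr, seed, trace)


# ---------------------------------------------------------------------------
# Fusion head
# ---------------------------------------------------------------------------


def _fuse_inputs(
    per_learner: List[np.ndarray], omic_of: List[int], mode: str, K: int, M: int
) -> np.ndarray:
    if mode == "concat":
        return np.hstack(per_learner)
    # interaction: outer product of the per-omic mean probability vectors
    per_omic = []
    for m in range(M):
        parts = [P for P, o in zip(per_learner, omic_of) if o == m]
        per_omic.append(np.mean(parts, axis=0))
    n = per_omic[0].shape[0]
    out = per_omic[0]
    for m in range(1, M):
        out = np.einsum("ia,ib->iab", out.reshape(n, -1), per_omic[m]).reshape(n, -1)
    return out


def _train_head(
    F: np.ndarray,
    y_codes: np.ndarray,
    train_mask: np.ndarray,
    K: int,
    hidden: int = 64,
    epochs: int = 300,
    lr: float = 1e-2,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Small fully connected aggregation network on fused inputs."""
    rng = np.random.default_rng(seed)
    n, d = F.shape
    W1 = rng.normal(0, math.sqrt(2.0 / d), size=(d, hidden))
    b1 = np.zeros(hidden)
    W2 = rng.normal(0, math.sqrt(2.0 / hidden), size=(hidden, K))
    b2 = np.zeros(K)
    idx = np.flatnonzero(train_mask)
    Y = np.zeros((len(idx), K))
    Y[np.arange(len(idx)), y_codes[idx]] = 1.0
    params = [W1, b1, W2, b2]
    mom = [np.zeros_like(q) for q in params]
    vel = [np.zeros_like(q) for q in params]
    b1c, b2c, eps = 0.9, 0.999, 1e-8
    Ft = F[idx]
    for t in range(1, epochs + 1):
        H = np.maximum(Ft @ W1 + b1, 0.0)
        Z = H @ W2 + b2
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        G = (P - Y) / len(idx)
        gW2 = H.T @ G
        gb2 = G.sum(axis=0)
        GH = (G @ W2.T) * (H > 0)
        gW1 = Ft.T @ GH
        gb1 = GH.sum(axis=0)
        for q, g, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], mom, vel):
            m_ *= b1c
            m_ += (1 - b1c) * g
            v_ *= b2c
            v_ += (1 - b2c) * g * g
            q -= lr * (m_ / (1 - b1c**t)) / (np.sqrt(v_ / (1 - b2c**t)) + eps)
    return W1, b1, W2, b2


@dataclass
class MogonetModel:
    """Transductive multi-omics GCN + fusion model.

    Predictions exist for exactly the samples present at training time
    (the graph includes the unlabelled test nodes); ``predict_proba``
    looks them up by sample ID.
    """

    kind: str
    mode: str
    class_names: List[str]
    sample_ids: List[str]
    probs: np.ndarray  # fused all-node probabilities
    gcn_models: Dict[str, List[GCNModel]]
    seed: int

    def predict_proba(self, X) -> ProbMatrix:
        ids = X.sample_ids if hasattr(X, "sample_ids") else list(X)
        lut = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lut]
        if missing:
            raise KeyError(
                f"samples not part of the transductive graph: {missing[:5]}"
            )
        rows = [lut[s] for s in ids]
        return ProbMatrix([str(s) for s in ids], list(self.class_names), self.probs[rows])


def train_mogonet(
    bundle: OmicsBundle,
    y: LabelVector,
    train_sample_ids: Sequence[str],
    learners_per_omic: int = 3,
    mode: str = "auto",
    mean_degree: int = 10,
    hidden: int = 64,
    epochs: int = 300,
    lr: float = 1e-3,
    seed: int = 0,
) -> MogonetModel:
    """MOGONET-style fusion of per-omic GCNs.

    ``mode="interaction"`` reproduces the original design (outer-product
    cross-omics terms, input dimension K^M, capped at 10 000);
    ``"concat"`` is the modification that drops interaction terms and
    assigns each omic several GCN base learners; ``"auto"`` picks
    interaction iff the class number is <= 2.
    """
    sample_ids = bundle.sample_ids
    y = y.subset(sample_ids)
    classes = sorted(set(y.labels))
    K = len(classes)
    M = len(bundle)
    if mode == "auto":
        mode = "interaction" if K <= 2 else "concat"
    if mode not in ("concat", "interaction"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "interaction":
        dim = interaction_dimension(K, M)
        if dim > INTERACTION_CAP:
            raise ValueError(
                f"interaction dimension K^M = {K}^{M} = {dim} exceeds the cap "
                f"of {INTERACTION_CAP}"
            )
    if learners_per_omic < 1:
        raise ValueError("learners_per_omic must be >= 1")
    lut = {c: k for k, c in enumerate(classes)}
    codes = np.array([lut[l] for l in y.labels])
    train_set = set(train_sample_ids)
    mask = np.array([s in train_set for s in sample_ids])

    rng = np.random.default_rng(seed)
    per_learner: List[np.ndarray] = []
    omic_of: List[int] = []
    gcn_store: Dict[str, List[GCNModel]] = {}
    for m, name in enumerate(bundle.omic_names):
        X = bundle[name]
        graph = build_sample_graph(X.values, mean_degree)
        gcn_store[name] = []
        for _ in range(learners_per_omic):
            s = int(rng.integers(0, 2**31 - 1))
            gcn = train_gcn(
                X.values, codes, mask, graph, classes,
                hidden=hidden, epochs=epochs, lr=lr, seed=s,
            )
            gcn_store[name].append(gcn)
            per_learner.append(gcn.forward(X.values, graph.operator))
            omic_of.append(m)

    if M == 1 and learners_per_omic == 1:
        # nothing to fuse: the single learner's posterior is the output
        probs = per_learner[0]
    else:
        F = _fuse_inputs(per_learner, omic_of, mode, K, M)
        s = int(rng.integers(0, 2**31 - 1))
        W1, b1, W2, b2 = _train_head(F, codes, mask, K, seed=s)
        H = np.maximum(F @ W1 + b1, 0.0)
        Z = H @ W2 + b2
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        probs = E / E.sum(axis=1, keepdims=True)
    return MogonetModel("mogonet", mode, classes, list(sample_ids), probs, gcn_store, seed)


# ---------------------------------------------------------------------------
# Multi-omics feature-sampling ensemble
# ---------------------------------------------------------------------------


def train_multiomics_ensemble(
    bundle: OmicsBundle,
    y: LabelVector,
    base_kind: str = "svm",
    learners_per_omic: int = 10,
    m: Optional[int] = None,
    C: float = 1.0,
    mlp_params: Optional[dict] = None,
    seed: int = 0,
) -> EnsembleModel:
    """eSVM/eNeural over a multi-omics bundle: every omic contributes
    ``learners_per_omic`` base learners whose feature subsets are drawn
    within that omic only; the ensemble mean fuses all learners.

    With a single-omic bundle this reproduces
    :func:`methylens.classifiers.train_ensemble` exactly (same seed,
    ``B = learners_per_omic``).
    """
    if base_kind not in ("svm", "mlp"):
        raise ValueError("base_kind must be 'svm' or 'mlp'")
    sample_ids = bundle.sample_ids
    y = y.subset(sample_ids)
    rng = np.random.default_rng(seed)
    learners: List[object] = []
    subsets: List[List[str]] = []
    all_features: List[str] = []
    for name in bundle.omic_names:
        all_features.extend(bundle[name].feature_ids)
    for name in bundle.omic_names:
        X = bundle[name]
        p = X.n_features
        m_omic = min(p, 1000) if m is None else m
        if m_omic > p:
            warnings.warn(
                f"omic {name!r} has only {p} features; subset size clamped from "
                f"{m_omic} to {p}"
            )
            m_omic = p
        feats = np.asarray(X.feature_ids, dtype=object)
        for _ in range(learners_per_omic):
            cols = np.sort(rng.choice(p, size=m_omic, replace=False))
            sub_ids = [str(f) for f in feats[cols]]
            Xb = BetaMatrix(list(sample_ids), sub_ids, X.values[:, cols], X.value_type)
            if base_kind == "svm":
                learner = train_svm(Xb, y, C=C)
            else:
                mp = dict(mlp_params or {})
                mp.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
                learner = train_mlp(Xb, y, **mp)
            learners.append(learner)
            subsets.append(sub_ids)
    return EnsembleModel(
        base_kind=base_kind,
        learners=learners,
        subsets=subsets,
        class_names=learners[0].class_names,
        feature_ids=all_features,
        seed=seed,
    )
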