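"""Embeddings and the pan-cancer concordance filter.

PCA and t-SNE 2-D embeddings; a joint multi-omics t-SNE that averages
the per-omic perplexity-calibrated affinity matrices before optimizing
a single layout; grid-based clustering of an embedding (equal cells,
8-neighbour connected components of occupied cells); and the
majority-label filter that keeps only samples whose class label matches
their embedding cluster's dominant label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .core import BetaMatrix, LabelVector, OmicsBundle
from .features import _weighted_sqdist, perplexity_affinities

__all__ = [
    "Embedding",
    "GridClustering",
    "pca_embed",
    "tsne_embed",
    "joint_embed",
    "joint_affinities",
    "grid_cluster",
    "label_clusters_filter",
]


@dataclass
class Embedding:
    sample_ids: List[str]
    coords: np.ndarray  # (n, dims)
    source: str  # pca | tsne | joint
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")
        if self.coords.shape[0] != len(self.sample_ids):
            raise ValueError("coords misaligned with sample_ids")


def pca_embed(X, dims: int = 2, sample_ids: Optional[Sequence[str]] = None) -> Embedding:
    """Principal-component projection of centered data.

    Deterministic including sign: each axis is flipped so that its
    largest-magnitude loading is positive.
    """
    if isinstance(X, BetaMatrix):
        sample_ids = list(X.sample_ids)
        V = X.values
    else:
        V = np.asarray(X, dtype=np.float64)
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(V.shape[0])]
    n = V.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples")
    Vc = V - V.mean(axis=0)
    if np.allclose(Vc, 0.0):
        raise ValueError("constant matrix has no principal axes")
    U, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    comps = Vt[:dims]
    for k in range(dims):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    coords = Vc @ comps.T
    return Embedding(list(sample_ids), coords, "pca", {"dims": dims})


# ---------------------------------------------------------------------------
# t-SNE (gradient optimization on a given affinity matrix)
# ---------------------------------------------------------------------------


def _tsne_optimize(
    P: np.ndarray,
    seed: int = 0,
    n_iter: int = 500,
    learning_rate: float = 200.0,
    early_exaggeration: float = 4.0,
    exaggeration_iter: int = 100,
) -> np.ndarray:
    """Standard t-SNE gradient descent (momentum + early exaggeration)
    on a symmetric affinity matrix summing to 1."""
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    dY = np.zeros_like(Y)
    Pe = P * early_exaggeration
    for it in range(n_iter):
        Pc = Pe if it < exaggeration_iter else P
        D2 = _weighted_sqdist(Y, np.ones(2))
        W = 1.0 / (1.0 + D2)
        np.fill_diagonal(W, 0.0)
        Q = W / W.sum()
        G = (Pc - Q) * W
        grad = 4.0 * ((np.diag(G.sum(axis=1)) - G) @ Y)
        momentum = 0.5 if it < 250 else 0.8
        dY = momentum * dY - learning_rate * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)
    return Y


def tsne_embed(
    X, perplexity: float = 30.0, seed: int = 0, n_iter: int = 500
) -> Embedding:
    """t-SNE of a single matrix (convenience wrapper over the joint path)."""
    if isinstance(X, BetaMatrix):
        bundle = OmicsBundle({"x": X})
    else:
        V = np.asarray(X, dtype=np.float64)
        ids = [f"S{i + 1}" for i in range(V.shape[0])]
        bundle = OmicsBundle({"x": BetaMatrix(ids, [f"f{j}" for j in range(V.shape[1])], V, "generic")})
    emb = joint_embed(bundle, perplexity=perplexity, seed=seed, n_iter=n_iter)
    return Embedding(emb.sample_ids, emb.coords, "tsne", emb.params)


def joint_affinities(
    bundle: OmicsBundle,
    perplexity: float = 30.0,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Joint affinity matrix: weighted mean (default unweighted) of the
    per-omic symmetrized perplexity-calibrated affinities, renormalized.
    Symmetric, non-negative, zero diagonal, sums to 1."""
    names = bundle.omic_names
    if weights is None:
        weights = [1.0] * len(names)
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(names) or (weights < 0).any() or weights.sum() == 0:
        raise ValueError("invalid omic weights")
    weights = weights / weights.sum()
    P = None
    for w, name in zip(weights, names):
        V = bundle[name].values
        D2 = _weighted_sqdist(V, np.ones(V.shape[1]))
        Pm, _ = perplexity_affinities(D2, perplexity)
        P = w * Pm if P is None else P + w * Pm
    P = (P + P.T) / 2.0
    return P / P.sum()


def joint_embed(
    bundle: OmicsBundle,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 500,
    weights: Optional[Sequence[float]] = None,
) -> Embedding:
    """Joint t-SNE over all omics of an aligned bundle.

    Per-omic affinity matrices are computed at a shared perplexity,
    averaged, and a single 2-D layout is optimized against the joint
    matrix.  A single-omic bundle therefore reduces to ordinary t-SNE.
    """
    n = len(bundle.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to embed")
    perplexity = min(perplexity, max((n - 1) / 3.0, 2.0))
    P = joint_affinities(bundle, perplexity, weights)
    Y = _tsne_optimize(P, seed=seed, n_iter=n_iter)
    return Embedding(
        bundle.sample_ids,
        Y,
        "joint",
        {"perplexity": perplexity, "seed": seed, "n_iter": n_iter},
    )


# ---------------------------------------------------------------------------
# Grid clustering and concordance filtering
# ---------------------------------------------------------------------------


@dataclass
class GridClustering:
    sample_ids: List[str]
    cluster_ids: np.ndarray  # per-sample component id (1-based)
    n_clusters: int
    resolution: int


def grid_cluster(emb: Embedding, resolution: int = 30) -> GridClustering:
    """Cluster an embedding by splitting its bounding box into a
    ``resolution`` x ``resolution`` grid and merging occupied cells into
    8-neighbour connected components."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    xy = emb.coords[:, :2]
    lo = xy.min(axis=0)
    span = xy.max(axis=0) - lo
    span[span == 0] = 1.0  # degenerate axis: everything in one cell row
    cell = np.minimum((xy - lo) / span * resolution, resolution - 1).astype(int)
    occ = np.zeros((resolution, resolution), dtype=bool)
    occ[cell[:, 0], cell[:, 1]] = True
    labels, n_comp = ndimage.label(occ, structure=np.ones((3, 3), dtype=int))
    ids = labels[cell[:, 0], cell[:, 1]]
    return GridClustering(list(emb.sample_ids), ids, int(n_comp), resolution)


def label_clusters_filter(
    clusters: GridClustering, y: LabelVector
) -> Tuple[Set[str], Dict[int, Optional[str]], Dict[str, int]]:
    """Keep only samples whose label matches their cluster's dominant label.

    Each cluster's dominant label is the modal histological label among
    its samples; clusters with a tied mode are dropped entirely.
    Returns (kept sample set, per-cluster dominant label, report with
    kept/dropped counts).
    """
    if set(clusters.sample_ids) - set(y.sample_ids):
        raise ValueError("cluster samples missing from labels")
    y = y.subset(clusters.sample_ids)
    lab = dict(zip(y.sample_ids, y.labels))
    dominant: Dict[int, Optional[str]] = {}
    for cid in sorted(set(clusters.cluster_ids.tolist())):
        members = [
            s for s, c in zip(clusters.sample_ids, clusters.cluster_ids) if c == cid
        ]
        counts = Counter(lab[s] for s in members)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            dominant[cid] = None  # tie: whole cluster unassigned
        else:
            dominant[cid] = top[0][0]
    kept = {
        s
        for s, c in zip(clusters.sample_ids, clusters.cluster_ids)
        if dominant[int(c)] is not None and lab[s] == dominant[int(c)]
    }
    report = {
        "n_total": len(clusters.sample_ids),
        "n_kept": len(kept),
        "n_dropped": len(clusters.sample_ids) - len(kept),
        "n_clusters": clusters.n_clusters,
        "n_tied_clusters": sum(1 for v in dominant.values() if v is None),
    }
    return kept, dominant, report
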