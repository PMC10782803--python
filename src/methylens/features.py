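"""Feature (probe) selection.

Four selectors over a samples x probes matrix:

* ``topvar``  — the n most variable probes (unbiased variance).
* ``limma``   — one-way group-means linear model per probe with
  empirical-Bayes variance shrinkage; probes ranked by the moderated F
  statistic.  The prior (d0, s0^2) is estimated by moment matching on
  log residual variances, and the posterior variance is
  s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g).
* ``anova``   — ordinary one-way ANOVA F (identical to limma at d0 = 0).
* ``scmer``   — manifold-preserving selection: non-negative per-probe
  weights w minimizing KL(P || Q(w)) + l1 |w|_1 + l2 |w|_2^2, where P is
  the symmetrized perplexity-calibrated sample-similarity matrix on all
  probes and Q(w) is the same kernel on the reweighted data.  The l1
  penalty is tuned by bisection to hit the requested feature count.

Also: promoter-probe -> gene mapping and the promoter / gene body /
other pseudo-omics split used for pan-cancer multi-omics models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.special import digamma, polygamma

from .core import (
    PROMOTER_REGIONS,
    BetaMatrix,
    LabelVector,
    OmicsBundle,
    ProbeAnnotation,
)

__all__ = [
    "FeatureSet",
    "select_top_variable",
    "select_limma",
    "select_anova",
    "select_scmer",
    "map_probes_to_genes",
    "split_pseudo_omics",
    "moderated_variance",
    "perplexity_affinities",
]


@dataclass
class FeatureSet:
    method: str
    feature_ids: List[str]
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    warning: Optional[str] = None

    def __len__(self) -> int:
        return len(self.feature_ids)


def _ranked(
    method: str, ids: Sequence[str], scores: np.ndarray, n: int, params: dict
) -> FeatureSet:
    """Top-n by decreasing score; ties broken lexicographically by ID."""
    ids = np.asarray(ids, dtype=object)
    order = np.lexsort((ids, -scores))
    top = order[:n]
    return FeatureSet(method, [str(f) for f in ids[top]], scores[top], params)


def select_top_variable(X: BetaMatrix, n: int) -> FeatureSet:
    """The ``n`` probes with the largest sample variance."""
    if not 1 <= n <= X.n_features:
        raise ValueError(f"n={n} outside [1, {X.n_features}]")
    var = X.values.var(axis=0, ddof=1)
    return _ranked("topvar", X.feature_ids, var, n, {"n": n})


def _group_stats(X: BetaMatrix, y: LabelVector) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Per-feature between-group mean square and within-group variance."""
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    counts = y.counts()
    classes = [c for c in y.class_names if counts[c] > 0]
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with < 2 samples: {small}")
    K = len(classes)
    n = X.n_samples
    codes = np.array([classes.index(l) for l in y.labels])
    V = X.values
    grand = V.mean(axis=0)
    ss_between = np.zeros(X.n_features)
    ss_within = np.zeros(X.n_features)
    for k in range(K):
        Vk = V[codes == k]
        mk = Vk.mean(axis=0)
        ss_between += len(Vk) * (mk - grand) ** 2
        ss_within += ((Vk - mk) ** 2).sum(axis=0)
    ms_between = ss_between / (K - 1)
    s2 = ss_within / (n - K)
    return ms_between, s2, K, n


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in empirical-Bayes
    variance-shrinkage practice)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def moderated_variance(s2: np.ndarray, df: int) -> Tuple[float, float, np.ndarray]:
    """Estimate the inverse-chi-square prior (d0, s0^2) from residual
    variances and return the posterior (shrunken) variances.

    Moment matching on z = log s^2: under the hierarchical model,
    z - psi(df/2) + log(df/2) has mean log s0^2 + psi(d0/2) - log(d0/2)
    and excess variance psi'(d0/2) beyond psi'(df/2).  Features with
    non-positive s^2 are excluded from prior estimation (their posterior
    still shrinks toward s0^2).
    """
    s2 = np.asarray(s2, dtype=np.float64)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero (constant matrix?)")
    z = np.log(s2[ok])
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    m = len(e)
    if m > 1:
        evar = float(((e - emean) ** 2).sum() / (m - 1))
        evar -= float(polygamma(1, df / 2.0))
    else:
        evar = -1.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess dispersion beyond chi-square sampling noise: variances
        # are exchangeable and shrink fully to their mean
        d0 = math.inf
        s02 = float(s2[ok].mean())
    post = _posterior_var(s2, df, d0, s02)
    return d0, s02, post


def _posterior_var(s2: np.ndarray, df: int, d0: float, s02: float) -> np.ndarray:
    if math.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + df * s2) / (d0 + df)


def select_limma(
    X: BetaMatrix, y: LabelVector, n: int, d0: Optional[float] = None
) -> FeatureSet:
    """Top-n probes by moderated F (empirical-Bayes shrunken denominator).

    ``d0`` overrides the estimated prior degrees of freedom; ``d0=0``
    reduces exactly to the ordinary ANOVA F ranking.
    """
    if n > X.n_features:
        raise ValueError(f"n={n} > p={X.n_features}")
    ms_between, s2, K, nsamp = _group_stats(X, y)
    df = nsamp - K
    if d0 is None:
        d0_est, s02, post = moderated_variance(s2, df)
    elif d0 == 0:
        d0_est, s02, post = 0.0, float("nan"), s2
    else:
        _, s02, _ = moderated_variance(s2, df)
        d0_est = float(d0)
        post = _posterior_var(s2, df, d0_est, s02)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(post > 0, ms_between / post, np.where(ms_between > 0, np.inf, 0.0))
    return _ranked(
        "limma", X.feature_ids, F, n, {"n": n, "d0": d0_est, "s02": s02, "df": df}
    )


def select_anova(X: BetaMatrix, y: LabelVector, n: int) -> FeatureSet:
    """Top-n probes by ordinary one-way ANOVA F (limma with d0 = 0)."""
    fs = select_limma(X, y, n, d0=0)
    return FeatureSet("anova", fs.feature_ids, fs.scores, {"n": n})


# ---------------------------------------------------------------------------
# Manifold-preserving (SCMER-style) selection
# ---------------------------------------------------------------------------


def perplexity_affinities(
    D2: np.ndarray, perplexity: float, tol: float = 1e-5, max_iter: int = 64
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-point precision calibration and symmetrized affinities.

    Binary-searches beta_i so that each conditional distribution
    exp(-beta_i d_ij^2) / sum has the requested perplexity, then returns
    (P, beta) with P = (P_cond + P_cond^T) / (2n): symmetric,
    non-negative, zero diagonal, summing to 1.
    """
    n = D2.shape[0]
    target = math.log(perplexity)
    P = np.zeros((n, n))
    beta = np.ones(n)
    for i in range(n):
        d = np.delete(D2[i], i)
        lo, hi = 0.0, math.inf
        b = 1.0
        for _ in range(max_iter):
            w = np.exp(-b * (d - d.min()))
            sw = w.sum()
            pr = w / sw
            # Shannon entropy of the conditional distribution
            nz = pr > 0
            H = float(-(pr[nz] * np.log(pr[nz])).sum())
            if abs(H - target) < tol:
                break
            if H > target:
                lo = b
                b = b * 2.0 if math.isinf(hi) else (b + hi) / 2.0
            else:
                hi = b
                b = (lo + b) / 2.0
        beta[i] = b
        row = np.zeros(n)
        row[np.arange(n) != i] = pr
        P[i] = row
    P = (P + P.T) / (2.0 * n)
    return P, beta


def _cond_probs(D2: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Row-conditional kernel probabilities at fixed per-point precisions."""
    D2 = D2.copy()
    np.fill_diagonal(D2, np.inf)
    # shift by the off-diagonal row minimum: softmax is shift-invariant
    # and this avoids whole-row underflow
    E = np.exp(-beta[:, None] * (D2 - D2.min(axis=1, keepdims=True)))
    return E / E.sum(axis=1, keepdims=True)


def _weighted_sqdist(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w
    sq = (Xw * Xw).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Xw @ Xw.T)
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return D2


def _scmer_loss_grad(
    X: np.ndarray,
    w: np.ndarray,
    P: np.ndarray,
    beta: np.ndarray,
    lam1: float,
    lam2: float,
    want_grad: bool = True,
):
    n = X.shape[0]
    D2w = _weighted_sqdist(X, w)
    Qc = _cond_probs(D2w, beta)
    Q = (Qc + Qc.T) / (2.0 * n)
    mask = P > 0
    kl = float((P[mask] * (np.log(P[mask]) - np.log(np.maximum(Q[mask], 1e-300)))).sum())
    loss = kl + lam1 * w.sum() + lam2 * float(w @ w)
    if not want_grad:
        return loss, None
    # dKL/dw_g = 4 w_g sum_ij G_ij (x_ig - x_jg)^2 with
    # G = M - diag(rowsum(M)) Qc,  M_ij = A_ij beta_i Qc_ij,
    # A_ij = P_ij / (Qc_ij + Qc_ji)  (P zero-diagonal keeps A finite)
    denom = Qc + Qc.T
    A = np.where(mask, P / np.maximum(denom, 1e-300), 0.0)
    M = A * beta[:, None] * Qc
    r = M.sum(axis=1)
    G = M - r[:, None] * Qc
    rows = G.sum(axis=1)
    cols = G.sum(axis=0)
    X2 = X * X
    s = (rows + cols) @ X2 - 2.0 * np.sum(X * (G @ X), axis=0)
    grad = 4.0 * w * s + lam1 + 2.0 * lam2 * w
    return loss, grad


def _scmer_optimize(
    X: np.ndarray,
    P: np.ndarray,
    beta: np.ndarray,
    lam1: float,
    lam2: float,
    max_iter: int = 500,
    tol: float = 1e-6,
    w0: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, List[float]]:
    """Projected gradient descent on w >= 0 with backtracking line search."""
    p = X.shape[1]
    w = np.ones(p) if w0 is None else w0.copy()
    loss, grad = _scmer_loss_grad(X, w, P, beta, lam1, lam2)
    trace = [loss]
    step = 0.25
    for _ in range(max_iter):
        # backtracking under the proximal majorization condition: large
        # steps are rejected even if they happen to decrease the loss,
        # because w_g = 0 is an absorbing state (the KL gradient scales
        # with w_g), so a wild step can kill features irreversibly
        improved = False
        for _bt in range(40):
            w_new = np.maximum(w - step * grad, 0.0)
            d = w_new - w
            new_loss, _ = _scmer_loss_grad(X, w_new, P, beta, lam1, lam2, want_grad=False)
            if new_loss <= loss + float(grad @ d) + float(d @ d) / (2.0 * step):
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        rel = (loss - new_loss) / max(abs(loss), 1e-12)
        w = w_new
        loss = new_loss
        _, grad = _scmer_loss_grad(w=w, X=X, P=P, beta=beta, lam1=lam1, lam2=lam2)
        trace.append(loss)
        step = min(step * 1.5, 4.0)
        if 0 <= rel < tol:
            break
    return w, trace


def select_scmer(
    X: BetaMatrix,
    target_n: int,
    perplexity: float = 30.0,
    lam2: float = 0.1,
    lam1: Optional[float] = None,
    tol_frac: float = 0.1,
    max_bisect: int = 40,
    max_iter: int = 500,
) -> FeatureSet:
    """Manifold-preserving probe selection.

    Builds the perplexity-calibrated sample-similarity matrix P on all
    probes, then finds non-negative probe weights whose reweighted
    similarities Q(w) stay close to P (KL divergence) under an elastic
    net penalty.  The ridge term spreads weight across redundant
    informative probes instead of keeping an arbitrary subset of them.

    The l1 strength is tuned along a warm-started continuation path
    (increasing l1, then bisecting the bracketing interval) until the
    number of weights > 1e-6 falls within ``tol_frac`` of ``target_n``;
    if the budget of ``max_bisect`` optimizations is exhausted the
    nearest achieved count is returned with a warning flag.  Passing an
    explicit ``lam1`` skips the search and runs a single optimization.
    """
    if X.n_samples < 10:
        raise ValueError("need at least 10 samples")
    if target_n > X.n_features:
        raise ValueError(f"target_n={target_n} > p={X.n_features}")
    Xv = X.values
    perplexity = min(perplexity, (X.n_samples - 1) / 3.0)
    D2 = _weighted_sqdist(Xv, np.ones(X.n_features))
    P, beta = perplexity_affinities(D2, perplexity)

    def run(l1: float, w0=None) -> Tuple[np.ndarray, int, List[float]]:
        w, trace = _scmer_optimize(Xv, P, beta, l1, lam2, max_iter=max_iter, w0=w0)
        return w, int((w > 1e-6).sum()), trace

    if lam1 is not None:
        w, c, tr = run(lam1)
        return _finish(X, w, tr, lam1, lam2, perplexity, None)

    lo_tol = math.floor(target_n * (1 - tol_frac))
    hi_tol = math.ceil(target_n * (1 + tol_frac))

    w_lo, c_lo, tr = run(0.0)
    best = (abs(c_lo - target_n), w_lo, c_lo, 0.0, tr)
    if lo_tol <= c_lo <= hi_tol:
        return _finish(X, w_lo, tr, 0.0, lam2, perplexity, None)
    runs = 1
    lam_lo = 0.0
    lam = 1e-4
    lam_hi = None
    # continuation: raise l1 from the previous solution until the count
    # drops to (or past) the target band
    while runs < max_bisect:
        w, c, tr = run(lam, w0=w_lo)
        runs += 1
        if abs(c - target_n) < best[0]:
            best = (abs(c - target_n), w, c, lam, tr)
        if lo_tol <= c <= hi_tol:
            return _finish(X, w, tr, lam, lam2, perplexity, None)
        if c < lo_tol:
            lam_hi = lam
            break
        lam_lo, w_lo = lam, w
        lam *= 4.0
    # bisect the bracket, always warm-starting from the denser end
    while lam_hi is not None and runs < max_bisect:
        mid = math.sqrt(lam_lo * lam_hi) if lam_lo > 0 else (lam_lo + lam_hi) / 2.0
        w, c, tr = run(mid, w0=w_lo)
        runs += 1
        if abs(c - target_n) < best[0]:
            best = (abs(c - target_n), w, c, mid, tr)
        if lo_tol <= c <= hi_tol:
            return _finish(X, w, tr, mid, lam2, perplexity, None)
        if c > hi_tol:
            lam_lo, w_lo = mid, w
        else:
            lam_hi = mid
        if lam_hi / max(lam_lo, 1e-12) < 1.0 + 1e-6:
            break
    _, w, c, lam, tr = best
    return _finish(
        X, w, tr, lam, lam2, perplexity,
        f"l1 search did not reach target {target_n} within {max_bisect} "
        f"optimizations; nearest achieved count {c}",
    )


def _finish(
    X: BetaMatrix,
    w: np.ndarray,
    trace: List[float],
    lam1: float,
    lam2: float,
    perplexity: float,
    warning: Optional[str],
) -> FeatureSet:
    ids = np.asarray(X.feature_ids, dtype=object)
    keep = w > 1e-6
    order = np.lexsort((ids[keep], -w[keep]))
    sel = np.flatnonzero(keep)[order]
    return FeatureSet(
        "scmer",
        [str(f) for f in ids[sel]],
        w[sel],
        {
            "lam1": lam1,
            "lam2": lam2,
            "perplexity": perplexity,
            "loss_trace": trace,
            "weights_full": w,
        },
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Annotation-driven operations
# ---------------------------------------------------------------------------


def map_probes_to_genes(
    features: FeatureSet, ann: ProbeAnnotation
) -> Tuple[Set[str], int]:
    """Unique gene symbols of promoter probes (TSS200/TSS1500/1stExon).

    Probes absent from the annotation (or without a gene symbol) are
    skipped; the skip count is returned alongside the gene set.
    """
    genes: Set[str] = set()
    skipped = 0
    tab = ann.table
    for probe in features.feature_ids:
        if probe not in tab.index:
            skipped += 1
            continue
        row = tab.loc[probe]
        gene = str(row["gene"])
        if row["gene_region"] in PROMOTER_REGIONS and gene:
            genes.add(gene)
    return genes, skipped


def split_pseudo_omics(X: BetaMatrix, ann: ProbeAnnotation) -> OmicsBundle:
    """Partition probes into promoter / gene body / other pseudo-omics.

    Unannotated probes go to ``other``.  Raises if any group ends up
    empty, since a per-omic learner could not be trained on it.
    """
    groups: Dict[str, List[str]] = {"promoter": [], "body": [], "other": []}
    for probe in X.feature_ids:
        region = ann.gene_region(probe)
        if region in PROMOTER_REGIONS:
            groups["promoter"].append(probe)
        elif region == "Body":
            groups["body"].append(probe)
        else:
            groups["other"].append(probe)
    empty = [g for g, ids in groups.items() if not ids]
    if empty:
        raise ValueError(f"pseudo-omic group(s) empty: {empty}")
    return OmicsBundle({g: X.subset_features(ids) for g, ids in groups.items()})
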