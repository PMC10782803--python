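"""Nested cross-validation, loss metrics, aggregation and validity indices.

The central protocol is the stratified outer x inner ("5 by 5") nested
CV: feature selection and model fitting happen inside each outer
training fold only (no leakage), outer-test predictions are concatenated
into an out-of-fold probability matrix, and calibrators are trained on
the inner-fold out-of-fold scores of each outer training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from . import calibrate as _cal
from . import classifiers as _clf
from . import features as _feat
from .core import BetaMatrix, LabelVector, ProbMatrix
from .folds import FoldPlan, make_nested_folds, stratified_fold_ids

__all__ = [
    "FoldPlan",
    "make_nested_folds",
    "MetricsReport",
    "IndexReport",
    "CVResult",
    "compute_metrics",
    "run_nested_cv",
    "calibrate_and_evaluate",
    "aggregate_predictions",
    "stratify_by_confidence",
    "group_small_classes",
    "internal_indices",
    "class_enrichment",
    "DEFAULT_CONFIDENCE_BINS",
]

DEFAULT_CONFIDENCE_BINS = [(0.0, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]


@dataclass
class MetricsReport:
    error: float
    brier: float
    mlogloss: float
    n: int

    def as_dict(self) -> dict:
        return {
            "error": self.error,
            "brier": self.brier,
            "mlogloss": self.mlogloss,
            "n": self.n,
        }


@dataclass
class IndexReport:
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float


def compute_metrics(probs: ProbMatrix, y: LabelVector) -> MetricsReport:
    """Misclassification error, multiclass Brier score (sum-of-squares
    dialect, range [0, 2]) and mLogloss (clipped at 1e-15)."""
    if probs.sample_ids != y.sample_ids:
        y = y.subset(probs.sample_ids)
    extra = set(y.labels) - set(probs.class_names)
    if extra:
        raise ValueError(f"labels outside the score class set: {sorted(extra)}")
    classes = list(probs.class_names)
    codes = np.array([classes.index(l) for l in y.labels])
    pred = probs.argmax_labels()
    err = float(np.mean(np.asarray(pred.labels, dtype=object) != np.asarray(y.labels, dtype=object)))
    onehot = np.zeros_like(probs.values)
    onehot[np.arange(len(codes)), codes] = 1.0
    brier = float(np.mean(((probs.values - onehot) ** 2).sum(axis=1)))
    p_true = np.clip(probs.values[np.arange(len(codes)), codes], 1e-15, 1 - 1e-15)
    mll = float(-np.mean(np.log(p_true)))
    return MetricsReport(err, brier, mll, len(codes))


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    folds: FoldPlan
    raw: Dict[Tuple[str, str], ProbMatrix]  # (model, feature) -> OOF scores
    inner_oof: Dict[Tuple[str, str, int], ProbMatrix]  # + outer fold id
    metrics: pd.DataFrame
    selected_features: Dict[Tuple[str, int], List[str]]  # (feature, outer) -> ids


def _select(X: BetaMatrix, y: LabelVector, spec: dict) -> List[str]:
    spec = dict(spec)
    method = spec.pop("method")
    if method == "none":
        return list(X.feature_ids)
    if method == "topvar":
        return _feat.select_top_variable(X, **spec).feature_ids
    if method == "limma":
        return _feat.select_limma(X, y, **spec).feature_ids
    if method == "anova":
        return _feat.select_anova(X, y, **spec).feature_ids
    if method == "scmer":
        return _feat.select_scmer(X, **spec).feature_ids
    raise ValueError(f"unknown feature method {method!r}")


def run_nested_cv(
    X: BetaMatrix,
    y: LabelVector,
    model_specs: Dict[str, dict],
    feature_specs: Optional[Dict[str, dict]] = None,
    folds: Optional[FoldPlan] = None,
    inner_oof: bool = False,
    seed: int = 0,
) -> CVResult:
    """Leakage-free nested CV over (model, feature-selection) pairs.

    Per outer fold: features are selected on the outer training set
    only, each model is fitted on the outer training set restricted to
    them, and the outer test fold is scored.  With ``inner_oof=True``
    the inner folds additionally produce out-of-fold scores of the
    outer training samples (for calibrator training).

    ``feature_specs`` maps a name to a selector spec such as
    ``{"method": "topvar", "n": 100}``; passing a precomputed feature
    list is deliberately unsupported — selection must be refit per fold.
    """
    if feature_specs is None:
        feature_specs = {"all": {"method": "none"}}
    for name, fs in feature_specs.items():
        if not isinstance(fs, dict) or "method" not in fs:
            raise TypeError(
                f"feature spec {name!r} must be a selector spec dict; "
                "precomputed feature lists are rejected to prevent leakage"
            )
    if X.sample_ids != y.sample_ids:
        y = y.subset(X.sample_ids)
    if folds is None:
        folds = make_nested_folds(y, 5, 5, seed=seed)
    classes = sorted(set(y.labels))
    raw: Dict[Tuple[str, str], ProbMatrix] = {}
    inner_scores: Dict[Tuple[str, str, int], ProbMatrix] = {}
    sel_store: Dict[Tuple[str, int], List[str]] = {}
    parts: Dict[Tuple[str, str], List[ProbMatrix]] = {
        (mn, fn): [] for mn in model_specs for fn in feature_specs
    }
    for o in range(folds.n_outer):
        tr_ids, te_ids = folds.outer_split(o)
        X_tr, y_tr = X.subset_samples(tr_ids), y.subset(tr_ids)
        X_te = X.subset_samples(te_ids)
        for fname, fspec in feature_specs.items():
            feat_ids = _select(X_tr, y_tr, fspec)
            sel_store[(fname, o)] = feat_ids
            Xf_tr = X_tr.subset_features(feat_ids)
            Xf_te = X_te.subset_features(feat_ids)
            for mname, mspec in model_specs.items():
                spec = dict(mspec)
                kind = spec.pop("kind")
                model = _clf.train_base(Xf_tr, y_tr, kind, seed=seed + o, **spec)
                pm = model.predict_proba(Xf_te).reorder_classes(classes)
                parts[(mname, fname)].append(pm)
                if inner_oof:
                    inner_scores[(mname, fname, o)] = _cal.oof_scores(
                        Xf_tr,
                        y_tr,
                        {"kind": kind, **spec},
                        fold_ids=folds.inner[o],
                        seed=seed + o,
                    )
    rows = []
    for (mname, fname), plist in parts.items():
        pm = ProbMatrix(
            [s for p in plist for s in p.sample_ids],
            classes,
            np.vstack([p.values for p in plist]),
        ).subset(X.sample_ids)
        raw[(mname, fname)] = pm
        rep = compute_metrics(pm, y)
        rows.append({"model": mname, "feature": fname, "calibration": "Raw", **rep.as_dict()})
    return CVResult(folds, raw, inner_scores, pd.DataFrame(rows), sel_store)


def calibrate_and_evaluate(
    cv: CVResult,
    y: LabelVector,
    methods: Sequence[str] = ("LR", "FLR", "MR"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per (model, feature, calibration) metrics over the nested CV output.

    For each outer fold the calibrator is fitted on the pooled inner
    OOF scores of that fold's training set and applied to the fold's
    raw test scores; fold partitions and base models are untouched.
    The uncalibrated ("Raw") rows are included.
    """
    if not cv.inner_oof:
        raise ValueError("run_nested_cv must be called with inner_oof=True")
    if list(y.sample_ids) != list(cv.folds.sample_ids):
        y = y.subset(cv.folds.sample_ids)
    rows = list(cv.metrics.to_dict("records"))
    for (mname, fname), pm in cv.raw.items():
        for method in methods:
            parts: List[ProbMatrix] = []
            for o in range(cv.folds.n_outer):
                tr_ids, te_ids = cv.folds.outer_split(o)
                inner = cv.inner_oof[(mname, fname, o)]
                cal = _cal.fit_calibrator(inner, y.subset(tr_ids), method, seed=seed)
                parts.append(_cal.apply_calibrator(cal, pm.subset(te_ids)))
            full = ProbMatrix(
                [s for p in parts for s in p.sample_ids],
                list(parts[0].class_names),
                np.vstack([p.values for p in parts]),
            ).subset(list(y.sample_ids))
            rep = compute_metrics(full, y)
            rows.append(
                {"model": mname, "feature": fname, "calibration": method, **rep.as_dict()}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aggregation, stratification, grouping
# ---------------------------------------------------------------------------


def aggregate_predictions(prob_list: Sequence[ProbMatrix]) -> Tuple[ProbMatrix, LabelVector]:
    """Element-wise mean of probability matrices (same samples and
    classes), renormalized; labels are the argmax with lexicographic
    tie-break."""
    if not prob_list:
        raise ValueError("empty probability list")
    ref = prob_list[0]
    acc = np.zeros_like(ref.values)
    for pm in prob_list:
        if pm.sample_ids != ref.sample_ids:
            raise ValueError("sample sets differ")
        if sorted(pm.class_names) != sorted(ref.class_names):
            raise ValueError("class sets differ")
        acc += pm.reorder_classes(ref.class_names).values
    acc /= acc.sum(axis=1, keepdims=True)
    out = ProbMatrix(list(ref.sample_ids), list(ref.class_names), acc)
    return out, out.argmax_labels()


def stratify_by_confidence(
    probs: ProbMatrix,
    reference_conf: np.ndarray,
    y: LabelVector,
    bins: Sequence[Tuple[float, float]] = DEFAULT_CONFIDENCE_BINS,
) -> pd.DataFrame:
    """Metrics within reference-confidence bins.

    Bins are half-open ``(lo, hi]`` except the first, which is closed at
    0, mirroring the [0, 0.7], (0.7, 0.8], (0.8, 0.9], (0.9, 1]
    stratification of validation samples by their reference-classifier
    confidence score.
    """
    conf = np.asarray(reference_conf, dtype=np.float64)
    if conf.min() < 0 or conf.max() > 1:
        raise ValueError("confidence values must lie in [0, 1]")
    if len(conf) != len(probs.sample_ids):
        raise ValueError("one confidence value per sample required")
    rows = []
    for i, (lo, hi) in enumerate(bins):
        if i == 0:
            mask = (conf >= lo) & (conf <= hi)
        else:
            mask = (conf > lo) & (conf <= hi)
        ids = [s for s, m in zip(probs.sample_ids, mask) if m]
        row = {"bin_lo": lo, "bin_hi": hi, "n": len(ids)}
        if ids:
            rep = compute_metrics(probs.subset(ids), y.subset(ids))
            row.update(error=rep.error, brier=rep.brier, mlogloss=rep.mlogloss)
        else:
            row.update(error=np.nan, brier=np.nan, mlogloss=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def group_small_classes(labels: LabelVector, min_size: int = 11) -> LabelVector:
    """Relabel classes with fewer than ``min_size`` samples (default:
    <= 10) as ``"others"``; larger classes are untouched."""
    counts = labels.counts()
    small = {c for c, n in counts.items() if 0 < n <= min_size - 1}
    if not small:
        return LabelVector(list(labels.sample_ids), list(labels.labels))
    new = ["others" if l in small else l for l in labels.labels]
    return LabelVector(list(labels.sample_ids), new)


# ---------------------------------------------------------------------------
# Internal validity indices and enrichment
# ---------------------------------------------------------------------------


def internal_indices(X, labels: LabelVector) -> IndexReport:
    """Silhouette (maximize), Calinski-Harabasz (maximize) and
    Davies-Bouldin (minimize) on Euclidean distances.

    ``X`` is any samples x dims matrix — probe space or embedding
    coordinates; the caller chooses the space.
    """
    V = X.values if isinstance(X, BetaMatrix) else np.asarray(X, dtype=np.float64)
    lab = np.asarray(labels.labels, dtype=object)
    if len(set(lab)) < 2:
        raise ValueError("need at least 2 classes")
    if V.shape[0] != len(lab):
        raise ValueError("matrix and labels misaligned")
    return IndexReport(
        silhouette=float(silhouette_score(V, lab)),
        calinski_harabasz=float(calinski_harabasz_score(V, lab)),
        davies_bouldin=float(davies_bouldin_score(V, lab)),
    )


def class_enrichment(subset: Set[str], y: LabelVector) -> pd.DataFrame:
    """Per-class two-sided Fisher exact test of enrichment in a sample
    subset, with the sample odds ratio (inf when the off-cells vanish).
    Classes with p < 0.05 are flagged."""
    subset = set(subset)
    if not subset:
        raise ValueError("empty subset")
    unknown = subset - set(y.sample_ids)
    if unknown:
        raise ValueError(f"subset samples not in labels: {sorted(unknown)[:5]}")
    in_sub = np.array([s in subset for s in y.sample_ids])
    lab = np.asarray(y.labels, dtype=object)
    rows = []
    for cls in sorted(set(lab)):
        is_cls = lab == cls
        a = int(np.sum(in_sub & is_cls))
        b = int(np.sum(in_sub & ~is_cls))
        c = int(np.sum(~in_sub & is_cls))
        d = int(np.sum(~in_sub & ~is_cls))
        odds = math.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else math.nan
        )
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "class": cls,
                "in_subset": a,
                "out_subset": c,
                "odds_ratio": odds,
                "p_value": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows)
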