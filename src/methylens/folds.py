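"""Stratified nested cross-validation partitions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .core import LabelVector

__all__ = ["FoldPlan", "make_nested_folds", "stratified_fold_ids"]


def stratified_fold_ids(labels: List[str], k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each sample a fold in 0..k-1, stratified by class.

    Within each class, samples are shuffled and dealt round-robin over a
    shuffled fold order, so per-fold class counts deviate from exact
    proportionality by at most one sample.
    """
    labels = np.asarray(labels, dtype=object)
    out = np.empty(len(labels), dtype=np.int64)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        fold_order = rng.permutation(k)
        out[idx] = fold_order[np.arange(len(idx)) % k]
    return out


@dataclass
class FoldPlan:
    """Outer fold id per sample plus, per outer fold, inner fold ids over
    that fold's training samples.  All ids are 0-based."""

    sample_ids: List[str]
    outer: np.ndarray  # (n,) outer fold id
    inner: Dict[int, np.ndarray]  # outer fold -> inner id per outer-training sample
    n_outer: int
    n_inner: int
    seed: int

    def outer_split(self, o: int):
        """(train_sample_ids, test_sample_ids) of outer fold ``o``."""
        ids = np.asarray(self.sample_ids, dtype=object)
        test = ids[self.outer == o]
        train = ids[self.outer != o]
        return [str(s) for s in train], [str(s) for s in test]

    def inner_split(self, o: int, i: int):
        """(train, held-out) sample IDs of inner fold ``i`` within outer
        training fold ``o``."""
        train_ids, _ = self.outer_split(o)
        mask = self.inner[o] == i
        held = [s for s, m in zip(train_ids, mask) if m]
        rest = [s for s, m in zip(train_ids, mask) if not m]
        return rest, held


def make_nested_folds(y: LabelVector, outer: int, inner: int, seed: int = 0) -> FoldPlan:
    """Stratified ``outer`` x ``inner`` nested partition (e.g. 5 x 5).

    Every class must have at least ``outer`` samples so each outer
    training set contains every class.
    """
    if outer < 2 or inner < 2:
        raise ValueError("need outer >= 2 and inner >= 2")
    for cls, cnt in y.counts().items():
        if 0 < cnt < outer:
            raise ValueError(
                f"class {cls!r} has only {cnt} samples; needs >= {outer} for "
                f"{outer} outer folds"
            )
    rng = np.random.default_rng(seed)
    outer_ids = stratified_fold_ids(y.labels, outer, rng)
    inner_map: Dict[int, np.ndarray] = {}
    lab = np.asarray(y.labels, dtype=object)
    for o in range(outer):
        train_lab = lab[outer_ids != o]
        inner_map[o] = stratified_fold_ids(list(train_lab), inner, rng)
    return FoldPlan(list(y.sample_ids), outer_ids, inner_map, outer, inner, seed)
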