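"""Seeded synthetic-data generators.

Produces desk-scale stand-ins for methylation-array cohorts: a
high-dimensional (p >> n) beta matrix in which most probes are
uninformative Beta(a, b) background noise and each class owns a small
block of informative probes whose mean is shifted by +-delta.  Also
generates aligned multi-omics bundles and temperature-degraded
probability matrices used as calibration fixtures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import BetaMatrix, LabelVector, OmicsBundle, ProbMatrix

__all__ = ["SynthSpec", "gen_methyl_dataset", "gen_multiomics_dataset", "degrade_scores"]

CLIP_LO, CLIP_HI = 0.01, 0.99


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent named substream of one global integer seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class SynthSpec:
    """Parameters of one synthetic methylation cohort.

    ``delta`` is the shift applied to the mean of each class's
    informative probes (sign drawn per probe); ``beta_a``/``beta_b``
    parameterize the background Beta distribution.
    """

    n_samples: int = 200
    n_features: int = 500
    n_classes: int = 4
    n_informative: int = 20  # informative probes per class
    delta: float = 0.3
    beta_a: float = 2.0
    beta_b: float = 2.0
    class_proportions: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_informative * self.n_classes > self.n_features:
            raise ValueError(
                f"{self.n_informative} informative probes x {self.n_classes} classes "
                f"exceed {self.n_features} features"
            )
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        mean = self.beta_a / (self.beta_a + self.beta_b)
        if not (CLIP_LO <= mean - self.delta and mean + self.delta <= CLIP_HI):
            # shifted means must remain inside the clipped beta range
            raise ValueError(
                f"delta={self.delta} pushes the background mean {mean:.3f} outside "
                f"({CLIP_LO}, {CLIP_HI})"
            )
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        else:
            self.class_proportions = [float(x) for x in self.class_proportions]
            if len(self.class_proportions) != self.n_classes:
                raise ValueError("one proportion per class required")
            if abs(sum(self.class_proportions) - 1.0) > 1e-8:
                raise ValueError("class proportions must sum to 1")


def _class_sizes(spec: SynthSpec) -> np.ndarray:
    """Largest-remainder apportionment of n_samples across classes."""
    raw = np.asarray(spec.class_proportions) * spec.n_samples
    sizes = np.floor(raw).astype(int)
    rem = spec.n_samples - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:rem]] += 1
    return sizes


def gen_methyl_dataset(
    spec: SynthSpec, prefix: str = "", class_names: Optional[Sequence[str]] = None
) -> Tuple[BetaMatrix, LabelVector]:
    """Generate one (BetaMatrix, LabelVector) pair from a :class:`SynthSpec`.

    Background probes are i.i.d. Beta(a, b); class ``k`` owns probes
    ``[k * n_informative, (k + 1) * n_informative)`` whose draws are
    shifted by a per-probe sign times ``delta`` for samples of that
    class, then clipped to [0.01, 0.99].  Deterministic given
    ``spec.seed``; matrix, labels and probe signs use named substreams.
    """
    if class_names is None:
        class_names = [f"C{k + 1}" for k in range(spec.n_classes)]
    sizes = _class_sizes(spec)
    labels = np.repeat(np.arange(spec.n_classes), sizes)
    rng_lab = _substream(spec.seed, prefix + "labels")
    labels = labels[rng_lab.permutation(spec.n_samples)]

    rng_mat = _substream(spec.seed, prefix + "matrix")
    X = rng_mat.beta(spec.beta_a, spec.beta_b, size=(spec.n_samples, spec.n_features))
    signs = np.where(
        _substream(spec.seed, prefix + "signs").random(spec.n_informative * spec.n_classes)
        < 0.5,
        -1.0,
        1.0,
    )
    for k in range(spec.n_classes):
        cols = slice(k * spec.n_informative, (k + 1) * spec.n_informative)
        rows = labels == k
        X[np.ix_(rows, np.arange(spec.n_features)[cols])] += (
            spec.delta * signs[cols]
        )
    np.clip(X, CLIP_LO, CLIP_HI, out=X)

    ndig = len(str(spec.n_samples))
    sample_ids = [f"{prefix}S{i + 1:0{ndig}d}" for i in range(spec.n_samples)]
    pdig = len(str(spec.n_features))
    feature_ids = [f"{prefix}cg{j + 1:0{pdig}d}" for j in range(spec.n_features)]
    mat = BetaMatrix(sample_ids, feature_ids, X, "beta")
    y = LabelVector(sample_ids, [class_names[k] for k in labels], list(class_names))
    return mat, y


def gen_multiomics_dataset(
    specs: Dict[str, SynthSpec], labels: LabelVector
) -> OmicsBundle:
    """One matrix per omic over the shared sample set of ``labels``.

    Each omic uses its own spec (and seed), so informativeness and
    reproducibility are controlled per omic, but the class structure is
    the one fixed by ``labels``.
    """
    n = len(labels.sample_ids)
    K = labels.n_classes
    codes = labels.codes()
    omics: Dict[str, BetaMatrix] = {}
    for name, spec in specs.items():
        if spec.n_samples != n:
            raise ValueError(f"omic {name!r}: n_samples {spec.n_samples} != {n}")
        if spec.n_classes != K:
            raise ValueError(f"omic {name!r}: n_classes {spec.n_classes} != {K}")
        rng_mat = _substream(spec.seed, name + ":matrix")
        X = rng_mat.beta(spec.beta_a, spec.beta_b, size=(n, spec.n_features))
        signs = np.where(
            _substream(spec.seed, name + ":signs").random(spec.n_informative * K) < 0.5,
            -1.0,
            1.0,
        )
        for k in range(K):
            cols = np.arange(k * spec.n_informative, (k + 1) * spec.n_informative)
            X[np.ix_(codes == k, cols)] += spec.delta * signs[cols]
        np.clip(X, CLIP_LO, CLIP_HI, out=X)
        pdig = len(str(spec.n_features))
        feats = [f"{name}_f{j + 1:0{pdig}d}" for j in range(spec.n_features)]
        omics[name] = BetaMatrix(list(labels.sample_ids), feats, X, "beta")
    return OmicsBundle(omics)


def degrade_scores(probs: ProbMatrix, temperature: float, seed: int = 0) -> ProbMatrix:
    """Flatten (T > 1) or sharpen (T < 1) a probability matrix.

    Each row is raised to the power 1/T and renormalized; T = 1 is the
    identity and T -> inf drives every row to uniform 1/K.  Used as a
    miscalibration fixture.  Deterministic (``seed`` kept for interface
    symmetry with the other generators).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    v = np.power(np.maximum(probs.values, 1e-300), 1.0 / temperature)
    v /= v.sum(axis=1, keepdims=True)
    return ProbMatrix(list(probs.sample_ids), list(probs.class_names), v)
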