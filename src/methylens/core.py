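"""Core data model and I/O.

In-memory containers shared by every other module: sample-by-feature
matrices of methylation beta values (or M-values / generic omics),
class-label vectors, row-stochastic probability matrices, probe
annotations, and aligned multi-omics bundles.  Matrices are always
oriented samples-in-rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "LabelVector",
    "ProbMatrix",
    "ProbeAnnotation",
    "OmicsBundle",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_annotation",
    "save_model",
    "load_model",
]

GENE_REGIONS = ("TSS200", "TSS1500", "1stExon", "Body", "other")
ISLAND_REGIONS = ("Island", "Shore", "Shelf", "OpenSea")
PROMOTER_REGIONS = ("TSS200", "TSS1500", "1stExon")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = True
    if dups:
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))[:10]}")


@dataclass
class BetaMatrix:
    """Samples x features numeric matrix with IDs.

    ``value_type`` is one of ``beta`` (values constrained to [0, 1]),
    ``mvalue`` or ``generic`` (no range constraint).
    """

    sample_ids: List[str]
    feature_ids: List[str]
    values: np.ndarray
    value_type: str = "beta"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.value_type not in ("beta", "mvalue", "generic"):
            raise ValueError(f"unknown value_type {self.value_type!r}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.value_type == "beta":
            out = (self.values < 0) | (self.values > 1)
            if out.any():
                i, j = np.argwhere(out)[0]
                raise ValueError(
                    f"beta value {self.values[i, j]} outside [0, 1] at sample "
                    f"{self.sample_ids[i]!r} (row {i + 1}), feature "
                    f"{self.feature_ids[j]!r} (column {j + 1})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "BetaMatrix":
        """Column subset in the given order; missing IDs raise KeyError."""
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"features not present: {missing[:10]}")
        cols = [idx[f] for f in feature_ids]
        return BetaMatrix(
            list(self.sample_ids),
            list(feature_ids),
            self.values[:, cols],
            self.value_type,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return BetaMatrix(
            list(sample_ids), list(self.feature_ids), self.values[rows], self.value_type
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class LabelVector:
    """Class labels aligned 1:1 with an ordered list of sample IDs."""

    sample_ids: List[str]
    labels: List[str]
    class_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        _check_unique(self.sample_ids, "sample")
        if self.class_names is None:
            self.class_names = sorted(set(self.labels))
        else:
            self.class_names = [str(c) for c in self.class_names]
            extra = set(self.labels) - set(self.class_names)
            if extra:
                raise ValueError(f"labels outside declared class set: {sorted(extra)}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def codes(self) -> np.ndarray:
        """Integer codes in ``class_names`` order."""
        lut = {c: k for k, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def counts(self) -> Dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for l in self.labels:
            out[l] += 1
        return out

    def subset(self, sample_ids: Sequence[str]) -> "LabelVector":
        lut = dict(zip(self.sample_ids, self.labels))
        return LabelVector(
            list(sample_ids), [lut[s] for s in sample_ids], list(self.class_names)
        )


@dataclass
class ProbMatrix:
    """Samples x classes row-stochastic score matrix."""

    sample_ids: List[str]
    class_names: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_names = [str(c) for c in self.class_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.class_names)):
            raise ValueError("shape mismatch in ProbMatrix")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.class_names, "class")
        if (self.values < 0).any():
            raise ValueError("negative probability entry")
        rs = self.values.sum(axis=1)
        if np.abs(rs - 1.0).max() > 1e-8:
            i = int(np.argmax(np.abs(rs - 1.0)))
            raise ValueError(
                f"row {self.sample_ids[i]!r} sums to {rs[i]:.12f}, not 1"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def argmax_labels(self) -> LabelVector:
        """Predicted labels: argmax per row, lexicographically first class on ties."""
        order = np.argsort(np.asarray(self.class_names, dtype=object), kind="stable")
        vals = self.values[:, order]
        names = [self.class_names[i] for i in order]
        idx = np.argmax(vals, axis=1)  # first (lexicographic) max wins
        return LabelVector(
            list(self.sample_ids), [names[i] for i in idx], sorted(self.class_names)
        )

    def reorder_classes(self, class_names: Sequence[str]) -> "ProbMatrix":
        if sorted(class_names) != sorted(self.class_names):
            raise ValueError("class sets differ")
        lut = {c: k for k, c in enumerate(self.class_names)}
        cols = [lut[c] for c in class_names]
        return ProbMatrix(list(self.sample_ids), list(class_names), self.values[:, cols])

    def subset(self, sample_ids: Sequence[str]) -> "ProbMatrix":
        lut = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lut[s] for s in sample_ids]
        return ProbMatrix(list(sample_ids), list(self.class_names), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.class_names)


@dataclass
class ProbeAnnotation:
    """Per-probe gene symbol, gene region and CpG-island region.

    Gene regions follow Illumina array nomenclature (TSS200, TSS1500,
    1stExon, Body); anything else is folded into ``other``.
    """

    table: pd.DataFrame  # index probe_id; columns gene, gene_region, island_region

    def __post_init__(self) -> None:
        need = {"gene", "gene_region", "island_region"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(need)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe IDs in annotation: {dups[:10]}")
        bad = set(self.table["gene_region"]) - set(GENE_REGIONS)
        if bad:
            raise ValueError(f"unknown gene_region values: {sorted(bad)}")
        bad = set(self.table["island_region"]) - set(ISLAND_REGIONS)
        if bad:
            raise ValueError(f"unknown island_region values: {sorted(bad)}")

    def gene_region(self, probe_id: str) -> Optional[str]:
        if probe_id in self.table.index:
            return str(self.table.loc[probe_id, "gene_region"])
        return None

    def covered(self, probe_ids: Iterable[str]) -> List[str]:
        idx = set(self.table.index)
        return [p for p in probe_ids if p in idx]


@dataclass
class OmicsBundle:
    """Named matrices over one ordered sample set (multi-omics or pseudo-omics)."""

    omics: Dict[str, BetaMatrix]

    def __post_init__(self) -> None:
        if not self.omics:
            raise ValueError("empty bundle")
        names = list(self.omics)
        _check_unique(names, "omic")
        ref = self.omics[names[0]].sample_ids
        for name in names[1:]:
            if self.omics[name].sample_ids != ref:
                raise ValueError(
                    f"omic {name!r} has different sample IDs/order than {names[0]!r}"
                )

    @property
    def sample_ids(self) -> List[str]:
        return list(next(iter(self.omics.values())).sample_ids)

    @property
    def omic_names(self) -> List[str]:
        return list(self.omics)

    def __getitem__(self, name: str) -> BetaMatrix:
        return self.omics[name]

    def __len__(self) -> int:
        return len(self.omics)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsBundle":
        return OmicsBundle(
            {k: v.subset_samples(sample_ids) for k, v in self.omics.items()}
        )

    def merged(self) -> BetaMatrix:
        """Column-concatenate all omics into one generic matrix."""
        feats: List[str] = []
        blocks = []
        for name in self.omics:
            feats.extend(self.omics[name].feature_ids)
            blocks.append(self.omics[name].values)
        return BetaMatrix(self.sample_ids, feats, np.hstack(blocks), "generic")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def _sniff_delim(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_matrix(path, value_type: str = "beta") -> BetaMatrix:
    """Read a delimited matrix: first row feature IDs, first column sample IDs.

    The delimiter is auto-detected (tab or comma).  Row and column order
    are preserved; validation errors name the offending cell.
    """
    path = Path(path)
    delim = _sniff_delim(path)
    df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    return BetaMatrix(
        [str(s) for s in df.index],
        [str(f) for f in df.columns],
        df.to_numpy(dtype=np.float64),
        value_type,
    )


def write_matrix(mat: BetaMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = mat.to_frame()
    df.index.name = "sample_id"
    # repr-roundtrip precision so read_matrix reproduces values bitwise
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path) -> LabelVector:
    """Two-column delimited file (sample_id, label) with header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delim(path))
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, label")
    return LabelVector(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].astype(str).tolist())


def write_labels(y: LabelVector, path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "label": y.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> ProbeAnnotation:
    """Four-column file: probe_id, gene, gene_region, island_region."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delim(path), index_col=0, keep_default_na=False)
    df.columns = ["gene", "gene_region", "island_region"]
    df["gene_region"] = [
        g if g in GENE_REGIONS else "other" for g in df["gene_region"].astype(str)
    ]
    return ProbeAnnotation(df)


def write_probs(p: ProbMatrix, path) -> None:
    df = p.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_probs(path) -> ProbMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delim(path), index_col=0, float_precision="round_trip")
    return ProbMatrix(
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Model serialization: JSON manifest + little-endian float64 blobs
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_model(model, path) -> None:
    """Serialize a fitted model to a directory.

    Layout: ``manifest.json`` with the model kind, metadata and the shape
    and checksum of each numeric blob; one ``<name>.bin`` raw
    little-endian float64 blob per array.  Predictions of the reloaded
    model are bit-identical to the original's.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    try:
        meta, arrays = model.to_state()
    except NotImplementedError:
        # pluggable standard learners (rf/xgb/elnet) carry an opaque
        # estimator; store it via joblib next to a minimal manifest
        import joblib

        blob = path / "estimator.joblib"
        joblib.dump(model.estimator, blob)
        manifest = {
            "kind": model.kind,
            "meta": {
                "kind": model.kind,
                "class_names": model.class_names,
                "feature_ids": model.feature_ids,
            },
            "blobs": {},
            "opaque": {"file": blob.name, "sha256": _sha256(blob)},
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return
    manifest = {"kind": meta["kind"], "meta": meta, "blobs": {}}
    for name, arr in arrays.items():
        arr = np.ascontiguousarray(np.asarray(arr, dtype="<f8"))
        blob = path / f"{name}.bin"
        arr.tofile(blob)
        manifest["blobs"][name] = {
            "shape": list(arr.shape),
            "sha256": _sha256(blob),
        }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(path):
    """Inverse of :func:`save_model`; verifies blob checksums."""
    from . import classifiers  # deferred: avoid import cycle

    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if "opaque" in manifest:
        import joblib

        blob = path / manifest["opaque"]["file"]
        if not blob.exists():
            raise FileNotFoundError(f"missing blob {blob.name} for model at {path}")
        if _sha256(blob) != manifest["opaque"]["sha256"]:
            raise IOError(f"checksum mismatch for blob {blob.name} at {path}")
        est = joblib.load(blob)
        return classifiers.SKLearnModel(
            manifest["kind"],
            est,
            list(manifest["meta"]["class_names"]),
            list(manifest["meta"]["feature_ids"]),
        )
    arrays = {}
    for name, info in manifest["blobs"].items():
        blob = path / f"{name}.bin"
        if not blob.exists():
            raise FileNotFoundError(f"missing blob {blob.name} for model at {path}")
        if _sha256(blob) != info["sha256"]:
            raise IOError(f"checksum mismatch for blob {blob.name} at {path}")
        arrays[name] = np.fromfile(blob, dtype="<f8").reshape(info["shape"])
    return classifiers.model_from_state(manifest["meta"], arrays)
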