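"""Synthetic UCI-like tabular diagnosis datasets and institutional splits.

The generator draws from a class-conditional model: continuous features are
per-class Gaussians whose mean gap grows with ``class_separation``; binary
and ordinal features are per-class Bernoulli / multinomial with logits
scaled by the same knob. ``class_separation = 0`` collapses every class to
one distribution (no learnable signal); values around 5 give a task a
linear baseline solves almost perfectly. Labels can be flipped with
probability ``label_noise`` to emulate diagnostic uncertainty.

Three presets mirror the shapes (feature counts and kinds only, not the
values) of public dermatology, hepatitis-C panel, and early-stage diabetes
risk datasets commonly used for tabular diagnosis benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetSpec",
    "PartitionSpec",
    "InstitutionDataset",
    "PRESETS",
    "make_spec",
    "generate",
    "partition",
    "scale_features",
    "write_csv",
    "read_csv",
]


@dataclass
class InstitutionDataset:
    """One institution's private shard: features X, labels y."""

    institution_id: int
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[0] < 1:
            raise ValueError("institution dataset must be nonempty")

    @property
    def n_i(self) -> int:
        return self.X.shape[0]


@dataclass
class DatasetSpec:
    """Recipe for one synthetic dataset.

    feature_kinds entries are "binary", "continuous", or ("ordinal", levels).
    """

    n_samples: int
    n_features: int
    feature_kinds: list
    n_classes: int
    class_separation: float = 2.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1 or self.n_classes < 2:
            raise ValueError("counts must be positive (and >= 2 classes)")
        if len(self.feature_kinds) != self.n_features:
            raise ValueError("feature_kinds length must equal n_features")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _preset_kinds(name: str) -> tuple[list, int]:
    if name == "dermatology_like":
        # 33 clinical/histopathological ordinal scores + age; 6 diagnoses
        return [("ordinal", 4)] * 33 + ["continuous"], 6
    if name == "hcv_like":
        # 12 continuous lab-panel measurements; 5 disease stages
        return ["continuous"] * 12, 5
    if name == "diabetes_like":
        # 16 yes/no symptoms + age; 2 classes
        return ["binary"] * 16 + ["continuous"], 2
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("dermatology_like", "hcv_like", "diabetes_like")


def make_spec(preset: str, n_samples: int = 1000, class_separation: float = 2.0,
              label_noise: float = 0.0, seed: int = 0) -> DatasetSpec:
    """DatasetSpec for a named preset shape."""
    kinds, n_classes = _preset_kinds(preset)
    return DatasetSpec(
        n_samples=n_samples,
        n_features=len(kinds),
        feature_kinds=kinds,
        n_classes=n_classes,
        class_separation=class_separation,
        label_noise=label_noise,
        seed=seed,
    )


def generate(spec: DatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y) from the class-conditional model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    y = rng.integers(0, spec.n_classes, size=spec.n_samples)
    X = np.empty((spec.n_samples, spec.n_features))
    sep = spec.class_separation
    for f, kind in enumerate(spec.feature_kinds):
        if kind == "continuous":
            mus = sep * rng.normal(0.0, 1.0, size=spec.n_classes)
            X[:, f] = rng.normal(mus[y], 1.0)
        elif kind == "binary":
            logits = sep * rng.uniform(-1.0, 1.0, size=spec.n_classes)
            p = 1.0 / (1.0 + np.exp(-logits))
            X[:, f] = (rng.random(spec.n_samples) < p[y]).astype(float)
        else:
            tag, levels = kind
            if tag != "ordinal":
                raise ValueError(f"unknown feature kind {kind!r}")
            g = sep * rng.normal(0.0, 1.0, size=(spec.n_classes, levels))
            probs = np.exp(g - g.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            cdf = probs.cumsum(axis=1)
            u = rng.random(spec.n_samples)
            X[:, f] = (u[:, None] > cdf[y]).sum(axis=1)
    if spec.label_noise > 0:
        flip = rng.random(spec.n_samples) < spec.label_noise
        shift = rng.integers(1, spec.n_classes, size=spec.n_samples)
        y = np.where(flip, (y + shift) % spec.n_classes, y)
    return X, y.astype(int)


@dataclass
class PartitionSpec:
    """How to shard a dataset across simulated institutions."""

    n_institutions: int = 10
    mode: str = "iid"  # or "dirichlet_noniid"
    dirichlet_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_institutions < 1:
            raise ValueError("n_institutions must be >= 1")
        if self.mode not in ("iid", "dirichlet_noniid"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")


def partition(X: np.ndarray, y: np.ndarray,
              pspec: PartitionSpec) -> list[InstitutionDataset]:
    """Split (X, y) into disjoint, exhaustive institutional shards.

    iid mode shuffles and splits into (near-)equal parts. dirichlet_noniid
    draws each institution's class mix from Dirichlet(alpha): small alpha
    gives heavily skewed shards, large alpha approaches the iid balance.
    Every institution is guaranteed at least one row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    k = pspec.n_institutions
    if n < k:
        raise ValueError("fewer samples than institutions")
    rng = np.random.default_rng(pspec.seed)

    if pspec.mode == "iid":
        idx_parts = np.array_split(rng.permutation(n), k)
    else:
        classes = np.unique(y)
        props = rng.dirichlet([pspec.dirichlet_alpha] * k, size=len(classes))
        buckets: list[list[int]] = [[] for _ in range(k)]
        for ci, c in enumerate(classes):
            members = rng.permutation(np.flatnonzero(y == c))
            cuts = (np.cumsum(props[ci])[:-1] * len(members)).round().astype(int)
            for b, chunk in zip(buckets, np.split(members, cuts)):
                b.extend(chunk.tolist())
        # rebalance: no institution may be empty
        sizes = [len(b) for b in buckets]
        for i in range(k):
            while len(buckets[i]) == 0:
                donor = int(np.argmax([len(b) for b in buckets]))
                buckets[i].append(buckets[donor].pop())
        idx_parts = [np.array(sorted(b)) for b in buckets]

    return [
        InstitutionDataset(institution_id=i, X=X[part], y=y[part])
        for i, part in enumerate(idx_parts)
    ]


def scale_features(X: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Min-max scale columns to [0, 1] (RBM visible-unit convention).

    Pass `ref` to reuse a training split's ranges on held-out data;
    results are clipped into [0, 1]. Constant columns map to 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    base = X if ref is None else np.atleast_2d(np.asarray(ref, dtype=float))
    lo = base.min(axis=0)
    span = base.max(axis=0) - lo
    span[span == 0] = 1.0
    return np.clip((X - lo) / span, 0.0, 1.0)


def write_csv(path, X: np.ndarray, y: np.ndarray,
              feature_names: list[str] | None = None,
              label_column: str = "label") -> None:
    """Write a dataset as headered CSV with a trailing label column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    df[label_column] = np.asarray(y)
    df.to_csv(path, index=False)


def read_csv(path, label_column: str = "label",
             impute: str = "median") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a headered CSV into (X, y, feature_names).

    Accepts the generated layout and UCI-style exports (numeric features,
    one label column). Non-numeric labels are factorized to integer codes;
    missing feature values are imputed with the column median (the only
    supported `impute` policy).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {path}; "
            f"columns are {list(df.columns)}"
        )
    ydf = df[label_column]
    feats = df.drop(columns=[label_column])
    feats = feats.apply(pd.to_numeric, errors="coerce")
    if impute != "median":
        raise ValueError(f"unknown imputation policy {impute!r}")
    feats = feats.fillna(feats.median())
    if ydf.dtype == object:
        y = pd.factorize(ydf)[0]
    else:
        y = ydf.to_numpy()
    return feats.to_numpy(dtype=float), np.asarray(y, dtype=int), list(feats.columns)
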