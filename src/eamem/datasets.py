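"""Synthetic labelled feature corpora with the structure the memory assumes.

The real system encodes images into 64 real-valued latent features via a
convolutional encoder; here class-conditional Gaussian clusters emulate
those encoder outputs: one mean vector per class (drawn once per seed),
instances = mean + independent per-feature noise. `class_separation` sets
the expected distance between class means in units of the within-class
spread, so it directly controls how much the classes' quantized level sets
overlap — the regime that drives the memory's precision/recall trade-off.

Corpora are pandas DataFrames with columns ``id``, ``label``, ``split``
(once partitioned) and ``f0..f{n-1}``; missing feature values are NaN and
serialize as empty CSV fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "partition",
    "occlude",
    "feature_columns",
    "read_corpus",
    "write_corpus",
]

SPLIT_NAMES = ("train", "rem", "test")
DEFAULT_FRACTIONS = (0.57, 0.33, 0.10)


@dataclass
class GeneratorConfig:
    """Knobs of the class-conditional Gaussian corpus generator.

    Defaults emulate the desk-scale analogue of the digit task: 10 classes,
    64 features, 1,000 instances per class (so the remembered split holds
    330 per class — enough for a 32-level register to cover its class's
    level sets the way the full-size corpus does), with class means
    separated per feature by about 6 within-class standard deviations.
    """

    n_classes: int = 10
    n_features: int = 64
    n_per_class: int = 1000
    class_separation: float = 6.0
    within_spread: float = 1.0
    fractions: tuple = DEFAULT_FRACTIONS
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_features < 1 or self.n_per_class < 1:
            raise ValueError("counts must be positive")
        if self.class_separation < 0 or self.within_spread <= 0:
            raise ValueError("class_separation >= 0 and within_spread > 0 required")
        if abs(sum(self.fractions) - 1.0) > 1e-9 or len(self.fractions) != 3:
            raise ValueError("fractions must be three values summing to 1")


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]


def generate_corpus(cfg: GeneratorConfig) -> pd.DataFrame:
    """Balanced class-conditional Gaussian corpus, deterministic under seed.

    Class means are drawn once per feature from N(0, s^2) with
    ``s = class_separation * within_spread / sqrt(2)``, so the RMS
    per-feature distance between two class means is
    ``class_separation * within_spread`` — separation is on the scale of a
    single feature track, the scale quantization bins live on. Instances
    add independent N(0, within_spread^2) noise per feature.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.class_separation * cfg.within_spread / np.sqrt(2)
    means = rng.normal(0.0, s, size=(cfg.n_classes, cfg.n_features))

    labels = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    noise = rng.normal(0.0, cfg.within_spread,
                       size=(labels.size, cfg.n_features))
    X = means[labels] + noise
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(cfg.n_features)])
    df.insert(0, "label", labels)
    df.insert(0, "id", [f"s{j:05d}" for j in range(labels.size)])
    return df


def _split_sizes(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment: sizes within 1 of n*fraction, summing to n."""
    exact = np.asarray(fractions) * n
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    for k in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[k] += 1
    return sizes.tolist()


def partition(corpus: pd.DataFrame, fractions=DEFAULT_FRACTIONS, fold: int = 0,
              seed: int = 0) -> pd.DataFrame:
    """Tag every instance with a class-stratified train/rem/test split.

    Per class, instances are put in a fixed seeded shuffle order and the
    order is rotated by ``fold`` tenths; contiguous blocks then land in the
    train/rem/test splits, so rotating the fold rotates split membership the
    way a 10-fold cross-validation rotation would.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not 0 <= fold <= 9:
        raise ValueError("fold must be in [0, 9]")
    rng = np.random.default_rng(seed)
    out = corpus.copy()
    out["split"] = ""
    for lab in sorted(out["label"].unique(), key=str):
        idx = out.index[out["label"] == lab].to_numpy()
        order = rng.permutation(idx)
        shift = (fold * len(order)) // 10
        order = np.roll(order, -shift)
        sizes = _split_sizes(len(order), fractions)
        start = 0
        for name, size in zip(SPLIT_NAMES, sizes):
            out.loc[order[start:start + size], "split"] = name
            start += size
    return out


def _occluded_indices(n: int, fraction: float, pattern: str, seed: int,
                      bar_width: int = 4) -> np.ndarray:
    k = int(np.floor(fraction * n))
    if pattern == "prefix":
        return np.arange(k)
    if pattern == "bars":
        # every other block of fixed width, clipped to the first k such indices
        blocks = [np.arange(start, min(start + bar_width, n))
                  for start in range(0, n, 2 * bar_width)]
        flat = np.concatenate(blocks) if blocks else np.empty(0, dtype=int)
        return flat[:k]
    if pattern == "random":
        return np.random.default_rng(seed).choice(n, size=k, replace=False)
    raise ValueError(f"unknown pattern {pattern!r}")


def occlude(v, mode: str = "missing", fraction: float = 0.5,
            pattern: str = "prefix", seed: int = 0, pool=None) -> np.ndarray:
    """Corrupt a feature vector the way occluding pixels corrupts the encoder.

    A floor(fraction * n)-sized set of feature indices (chosen by `pattern`)
    is either marked missing (``mode="missing"``: information simply absent)
    or replaced by draws from the pooled all-class marginal
    (``mode="background"``: the encoder emits uninformative values; requires
    `pool`, a table whose column j supplies candidate values for feature j).
    ``fraction=0`` is the identity.
    """
    v = np.asarray(v, dtype=float).copy()
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if mode not in ("missing", "background"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = _occluded_indices(v.size, fraction, pattern, seed)
    if idx.size == 0:
        return v
    if mode == "missing":
        v[idx] = np.nan
    else:
        if pool is None:
            raise ValueError("mode='background' requires a pool of feature values")
        pool = np.asarray(pool, dtype=float)
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, pool.shape[0], size=idx.size)
        v[idx] = pool[rows, idx]
    return v


def write_corpus(df: pd.DataFrame, path) -> None:
    """CSV with header id,label[,split],f0,...; missing values as empty fields."""
    df.to_csv(path, index=False)


def read_corpus(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError("corpus CSV must have 'id' and 'label' columns")
    return df
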