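"""Codeword encoding and temporal pooling.

A clip's whitened patches M (n x m) are matched against the codebook D
(n x k) by F = M' D, an m x k matrix whose column i is the match-score
time series against codeword i.  Because m depends on clip duration, F
is pooled over time with a fixed set of summary statistics (mean, std,
max) per column, yielding a k*l feature vector independent of duration.

Pooling order is stat-major, codeword-minor: all means first, then all
stds, then all maxes (restricted to the requested statistics, in that
canonical order).  The standard deviation uses the population
convention (divide by m), so a single-patch clip pools to 0, not NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .learning import Codebook, PatchMatrix

STAT_ORDER = ("mean", "std", "max")

_STAT_FUNCS = {
    "mean": lambda F: F.mean(axis=0),
    "std": lambda F: F.std(axis=0),  # population (ddof=0)
    "max": lambda F: F.max(axis=0),
}


@dataclass(frozen=True)
class PoolingSpec:
    """Ordered set of summary statistics applied per codeword column."""

    stats: tuple[str, ...] = ("mean", "std")

    def __post_init__(self) -> None:
        if len(self.stats) == 0:
            raise ValueError("at least one summary statistic is required")
        unknown = set(self.stats) - set(STAT_ORDER)
        if unknown:
            raise ValueError(f"unknown summary statistics: {sorted(unknown)}")
        canonical = tuple(s for s in STAT_ORDER if s in self.stats)
        object.__setattr__(self, "stats", canonical)

    @property
    def l(self) -> int:  # noqa: E743 - the field's name for |f_stat|
        return len(self.stats)


# the three pooling sets searched over in the hyperparameter grid
POOLING_GRID = (
    PoolingSpec(("mean", "std")),
    PoolingSpec(("max",)),
    PoolingSpec(("mean", "std", "max")),
)


@dataclass
class EncodedClip:
    """Match-score matrix F = M' D for one clip (m patches x k codewords)."""

    F: np.ndarray

    @property
    def m(self) -> int:
        return self.F.shape[0]

    @property
    def k(self) -> int:
        return self.F.shape[1]


def encode_clip(codebook: Codebook, M: PatchMatrix | np.ndarray) -> EncodedClip:
    """Encode one clip's whitened patches against the codebook (F = M' D)."""
    Ma = M.X if isinstance(M, PatchMatrix) else np.asarray(M, dtype=np.float64)
    if Ma.ndim != 2 or Ma.shape[1] == 0:
        raise ValueError("M must be a non-empty 2-D matrix of column patches")
    if Ma.shape[0] != codebook.n:
        raise ValueError(f"dimension mismatch: M has {Ma.shape[0]} dims, codebook {codebook.n}")
    return EncodedClip(F=Ma.T @ codebook.D)


def pool_features(encoded: EncodedClip, spec: PoolingSpec) -> np.ndarray:
    """Pool F over time into a fixed k*l feature vector."""
    if encoded.m == 0:
        raise ValueError("cannot pool an empty encoding")
    parts = [_STAT_FUNCS[s](encoded.F) for s in spec.stats]
    return np.concatenate(parts)


def feature_names(k: int, spec: PoolingSpec) -> list[str]:
    return [f"{s}_cw{i}" for s in spec.stats for i in range(k)]


def features_to_frame(features: np.ndarray, spec: PoolingSpec, clip_ids=None) -> pd.DataFrame:
    """Tabulate pooled features (rows = clips) for CSV export."""
    features = np.atleast_2d(features)
    k = features.shape[1] // spec.l
    return pd.DataFrame(features, columns=feature_names(k, spec), index=clip_ids)


@dataclass
class Standardizer:
    """Per-dimension z-scoring with training-set mean and std.

    Zero-variance dimensions are passed through with divisor 1 (they
    are centered but not scaled).  Test-time vectors always use the
    training parameters.
    """

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, features: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if F.shape[1] != self.mean.size:
            raise ValueError(f"feature length {F.shape[1]} != standardizer dim {self.mean.size}")
        out = (F - self.mean) / self.scale
        return out if np.asarray(features).ndim > 1 else out[0]


def fit_standardizer(train_features: np.ndarray) -> Standardizer:
    F = np.asarray(train_features, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least 2 training feature vectors")
    scaler = StandardScaler().fit(F)  # scale_ is 1 where variance is 0
    return Standardizer(mean=scaler.mean_.copy(), scale=scaler.scale_.copy())


def apply_standardizer(standardizer: Standardizer, features: np.ndarray) -> np.ndarray:
    return standardizer.transform(features)
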