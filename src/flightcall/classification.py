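"""Margin classification on codebook features, plus the MFCC baseline.

The classifier is an RBF-kernel support-vector machine trained on
standardized pooled codebook features, with confidences obtained by
Platt scaling of the decision values (logistic calibration fitted via
internal cross-validation).  Hyperparameters — TF-patch duration
``d_patch``, codebook size ``k``, pooling statistics ``f_stat`` and the
SVM penalty ``C`` — are selected by grid search: nested inside 5-fold
stratified cross-validation for the N-class regime, or on a single
stratified train/validation split for the season-mismatched monitoring
regime (where the model is trained with equal weight for every datum,
since the test-season class distribution is unknown at training time).

The baseline model replaces learned features with 25 MFCCs per frame
(same window and hop) pooled with a fixed set of 11 summary statistics,
giving a 275-dimensional vector.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .encoding import (
    POOLING_GRID,
    PoolingSpec,
    Standardizer,
    encode_clip,
    fit_standardizer,
    pool_features,
)
from .frontend import (
    DEFAULT_CONFIG,
    AudioClip,
    SpectrogramConfig,
    frames_for_duration,
    logmel_spectrogram,
    slice_patches,
)
from .learning import (
    Codebook,
    WhiteningTransform,
    apply_whitening,
    fit_whitening,
    spherical_kmeans,
    subsample_patches,
)

# --------------------------------------------------------------------------
# hyperparameter grids (study-scale defaults)

D_PATCH_GRID_MS = (1.45, 5.8, 11.6, 23.2, 46.4, 92.9, 185.8)
K_GRID = (128, 256, 512, 1024, 2048)
C_GRID = (1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class HyperParams:
    d_patch_ms: float = 46.4
    k: int = 128
    f_stat: PoolingSpec = field(default_factory=lambda: PoolingSpec(("mean", "std", "max")))
    C: float = 10.0


def default_grids() -> dict:
    return {
        "d_patch_ms": D_PATCH_GRID_MS,
        "k": K_GRID,
        "f_stat": POOLING_GRID,
        "C": C_GRID,
    }


def iter_grid(grids: dict) -> list[HyperParams]:
    """Enumerate the hyperparameter grid in declared order."""
    if any(len(v) == 0 for v in grids.values()):
        raise ValueError("empty hyperparameter grid")
    return [
        HyperParams(d_patch_ms=d, k=k, f_stat=f, C=c)
        for d, k, f, c in itertools.product(
            grids["d_patch_ms"], grids["k"], grids["f_stat"], grids["C"]
        )
    ]


# --------------------------------------------------------------------------
# MFCC baseline

MFCC_N_COEFF = 25

# 11 summary statistics pooled per coefficient (declared, swappable)
BASELINE_STATS = (
    "min",
    "max",
    "median",
    "mean",
    "var",
    "skew",
    "kurtosis",
    "dmean",
    "dvar",
    "d2mean",
    "d2var",
)


def _safe_skew(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-300, (x - mu) / np.where(sd > 1e-300, sd, 1.0), 0.0)
    return (z**3).mean(axis=1)


def _safe_kurtosis(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-300, (x - mu) / np.where(sd > 1e-300, sd, 1.0), 0.0)
    return (z**4).mean(axis=1) - 3.0


def extract_mfcc_baseline(
    clip: AudioClip, config: SpectrogramConfig | None = None
) -> np.ndarray:
    """25 MFCCs per frame pooled with 11 summary statistics (length 275).

    MFCCs are the DCT-II (orthonormal) of a full-band 40-channel log-mel
    spectrogram computed with the same window and hop as the codebook
    front end.  Statistics are ordered stat-major over coefficients.
    """
    if config is None:
        config = DEFAULT_CONFIG
    mfcc_config = SpectrogramConfig(
        n_mels=40,
        fmin=0.0,
        fmax=config.sample_rate / 2,
        window_length=config.window_length,
        hop_length=config.hop_length,
        sample_rate=config.sample_rate,
        log_floor=config.log_floor,
        mel_style=config.mel_style,
        spectrum=config.spectrum,
    )
    spec = logmel_spectrogram(clip, mfcc_config)
    if spec.n_frames < 3:
        raise ValueError("clip too short for MFCC baseline (need >= 3 frames)")
    coeffs = dct(spec.values, type=2, norm="ortho", axis=0)[:MFCC_N_COEFF]  # (25, T)
    d1 = np.diff(coeffs, axis=1)
    d2 = np.diff(coeffs, n=2, axis=1)
    stats = {
        "min": coeffs.min(axis=1),
        "max": coeffs.max(axis=1),
        "median": np.median(coeffs, axis=1),
        "mean": coeffs.mean(axis=1),
        "var": coeffs.var(axis=1),
        "skew": _safe_skew(coeffs),
        "kurtosis": _safe_kurtosis(coeffs),
        "dmean": d1.mean(axis=1),
        "dvar": d1.var(axis=1),
        "d2mean": d2.mean(axis=1),
        "d2var": d2.var(axis=1),
    }
    return np.concatenate([stats[name] for name in BASELINE_STATS])


# --------------------------------------------------------------------------
# pipeline helpers


def clip_fingerprint(clip: AudioClip) -> str:
    """Stable identifier of a clip, for leakage audits."""
    if clip.clip_id is not None:
        return str(clip.clip_id)
    return hashlib.sha1(np.ascontiguousarray(clip.samples).tobytes()).hexdigest()


def _clip_patches(clip: AudioClip, config: SpectrogramConfig, patch_frames: int, stride: int):
    spec = logmel_spectrogram(clip, config)
    return slice_patches(spec, patch_frames, stride)


def collect_training_patches(
    clips,
    config: SpectrogramConfig,
    patch_frames: int,
    stride: int = 1,
    max_patches: int = 250_000,
    seed: int = 0,
) -> np.ndarray:
    """Union of TF-patches over training clips, capped by seeded subsampling."""
    blocks = [_clip_patches(c, config, patch_frames, stride).patches for c in clips]
    patches = np.concatenate(blocks, axis=1)
    return subsample_patches(patches, max_patches, seed=seed)


def pooled_stats_for_clips(
    clips,
    whitening: WhiteningTransform,
    codebook: Codebook,
    config: SpectrogramConfig,
    patch_frames: int,
    stride: int = 1,
) -> dict[str, np.ndarray]:
    """Per-clip mean/std/max over the match-score time series.

    Computing all three statistics at once lets a grid search over
    pooling sets reuse one encoding pass.
    """
    out = {"mean": [], "std": [], "max": []}
    for clip in clips:
        raw = _clip_patches(clip, config, patch_frames, stride)
        M = apply_whitening(whitening, raw)
        F = encode_clip(codebook, M).F
        out["mean"].append(F.mean(axis=0))
        out["std"].append(F.std(axis=0))
        out["max"].append(F.max(axis=0))
    return {k: np.vstack(v) for k, v in out.items()}


def assemble_features(stats: dict[str, np.ndarray], pooling: PoolingSpec) -> np.ndarray:
    return np.hstack([stats[s] for s in pooling.stats])


def compute_pooled_features(
    clips,
    whitening: WhiteningTransform,
    codebook: Codebook,
    pooling: PoolingSpec,
    config: SpectrogramConfig = DEFAULT_CONFIG,
    patch_frames: int = 32,
    stride: int = 1,
) -> np.ndarray:
    """Pooled k*l features for a sequence of clips (rows = clips)."""
    feats = []
    for clip in clips:
        raw = _clip_patches(clip, config, patch_frames, stride)
        M = apply_whitening(whitening, raw)
        feats.append(pool_features(encode_clip(codebook, M), pooling))
    return np.vstack(feats)


# --------------------------------------------------------------------------
# training / prediction


def _fit_svm_with_calibration(Z: np.ndarray, y: np.ndarray, C: float, seed: int):
    svc = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
    svc.fit(Z, y)
    _, counts = np.unique(y, return_counts=True)
    cv = int(min(3, counts.min()))
    if cv >= 2:
        calibrated = CalibratedClassifierCV(
            estimator=SVC(kernel="rbf", C=C, gamma="scale", random_state=seed),
            method="sigmoid",
            cv=cv,
        )
    else:  # too few per-class samples for CV: calibrate on the fit itself
        from sklearn.frozen import FrozenEstimator

        calibrated = CalibratedClassifierCV(FrozenEstimator(svc), method="sigmoid")
    calibrated.fit(Z, y)
    return svc, calibrated


@dataclass
class TrainedModel:
    """A fully fitted pipeline: whitening + codebook + standardizer + SVM.

    All learned components were fitted strictly on the training clips
    recorded in ``train_fingerprints``.
    """

    whitening: WhiteningTransform
    codebook: Codebook
    standardizer: Standardizer
    svc: SVC
    calibrated: CalibratedClassifierCV
    hyperparams: HyperParams
    classes_: np.ndarray
    config: SpectrogramConfig
    patch_frames: int
    encode_stride: int
    train_fingerprints: frozenset[str]
    seed: int

    def features(self, clips) -> np.ndarray:
        raw = compute_pooled_features(
            clips,
            self.whitening,
            self.codebook,
            self.hyperparams.f_stat,
            self.config,
            self.patch_frames,
            self.encode_stride,
        )
        return self.standardizer.transform(raw)

    def decision_values(self, clips) -> np.ndarray:
        """Signed distances from the separating hyperplane (binary)."""
        return self.svc.decision_function(self.features(clips))


@dataclass
class PredictionResult:
    labels: np.ndarray  # object array; None where encoding failed
    probabilities: np.ndarray  # (n_clips, n_classes); NaN rows where failed
    classes: np.ndarray
    failed: list  # (index, reason) for unencodable clips

    def positive_probability(self, positive_label) -> np.ndarray:
        j = int(np.nonzero(self.classes == positive_label)[0][0])
        return self.probabilities[:, j]


def train_model(
    clips,
    labels,
    hp: HyperParams,
    *,
    config: SpectrogramConfig = DEFAULT_CONFIG,
    seed: int = 0,
    learn_stride: int = 1,
    encode_stride: int = 1,
    max_patches: int = 250_000,
) -> TrainedModel:
    """Train the full pipeline on a labeled clip set with equal datum weights.

    Feature learning (whitening + codebook), the standardizer and the
    Platt calibration are all fitted only on ``clips``.
    """
    clips = list(clips)
    y = np.asarray(labels)
    if len(clips) != y.size:
        raise ValueError("clips and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    patch_frames = frames_for_duration(hp.d_patch_ms, config.hop_ms)
    patches = collect_training_patches(
        clips, config, patch_frames, learn_stride, max_patches, seed
    )
    whitening = fit_whitening(patches)
    X = apply_whitening(whitening, patches)
    codebook, _ = spherical_kmeans(X, k=hp.k, seed=seed)
    features = compute_pooled_features(
        clips, whitening, codebook, hp.f_stat, config, patch_frames, encode_stride
    )
    standardizer = fit_standardizer(features)
    Z = standardizer.transform(features)
    svc, calibrated = _fit_svm_with_calibration(Z, y, hp.C, seed)
    return TrainedModel(
        whitening=whitening,
        codebook=codebook,
        standardizer=standardizer,
        svc=svc,
        calibrated=calibrated,
        hyperparams=hp,
        classes_=calibrated.classes_.copy(),
        config=config,
        patch_frames=patch_frames,
        encode_stride=encode_stride,
        train_fingerprints=frozenset(clip_fingerprint(c) for c in clips),
        seed=seed,
    )


def predict(model: TrainedModel, clips) -> PredictionResult:
    """Predict labels and calibrated per-class probabilities.

    Unencodable clips (e.g. shorter than one TF-patch) are flagged in
    ``failed`` and carry a None label and NaN probabilities rather than
    being silently dropped.
    """
    clips = list(clips)
    n_classes = model.classes_.size
    labels = np.empty(len(clips), dtype=object)
    proba = np.full((len(clips), n_classes), np.nan)
    failed = []
    encodable, keep = [], []
    for i, clip in enumerate(clips):
        try:
            min_samples = (
                model.config.window_length
                + (model.patch_frames - 1) * model.config.hop_length
            )
            if clip.n_samples < min_samples:
                raise ValueError(
                    f"clip has {clip.n_samples} samples, need >= {min_samples}"
                )
            encodable.append(clip)
            keep.append(i)
        except ValueError as exc:
            failed.append((i, str(exc)))
    if encodable:
        Z = model.features(encodable)
        p = model.calibrated.predict_proba(Z)
        p = p / p.sum(axis=1, keepdims=True)
        idx = np.asarray(keep)
        proba[idx] = p
        labels[idx] = model.classes_[np.argmax(p, axis=1)]
    return PredictionResult(
        labels=labels, probabilities=proba, classes=model.classes_.copy(), failed=failed
    )


# --------------------------------------------------------------------------
# baseline model


@dataclass
class BaselineModel:
    """MFCC-statistics baseline: standardized 275-dim features + RBF SVM."""

    standardizer: Standardizer
    svc: SVC
    calibrated: CalibratedClassifierCV
    C: float
    classes_: np.ndarray
    config: SpectrogramConfig
    train_fingerprints: frozenset[str]

    def features(self, clips) -> np.ndarray:
        raw = np.vstack([extract_mfcc_baseline(c, self.config) for c in clips])
        return self.standardizer.transform(raw)

    def predict(self, clips) -> PredictionResult:
        Z = self.features(clips)
        p = self.calibrated.predict_proba(Z)
        p = p / p.sum(axis=1, keepdims=True)
        labels = self.classes_[np.argmax(p, axis=1)].astype(object)
        return PredictionResult(
            labels=labels, probabilities=p, classes=self.classes_.copy(), failed=[]
        )


def train_baseline(
    clips, labels, C: float = 10.0, *, config: SpectrogramConfig = DEFAULT_CONFIG, seed: int = 0
) -> BaselineModel:
    clips = list(clips)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    features = np.vstack([extract_mfcc_baseline(c, config) for c in clips])
    standardizer = fit_standardizer(features)
    Z = standardizer.transform(features)
    svc, calibrated = _fit_svm_with_calibration(Z, y, C, seed)
    return BaselineModel(
        standardizer=standardizer,
        svc=svc,
        calibrated=calibrated,
        C=C,
        classes_=calibrated.classes_.copy(),
        config=config,
        train_fingerprints=frozenset(clip_fingerprint(c) for c in clips),
    )


# --------------------------------------------------------------------------
# grid search


@dataclass
class GridSearchResult:
    scheme: str
    table: pd.DataFrame  # fold, d_patch_ms, k, f_stat, C, score
    best: list[HyperParams]  # one per fold (nclass) or singleton (monitoring)
    fold_test_scores: list[float]  # nclass only
    mean_score: float
    models: list[TrainedModel]
    fold_assignments: list  # (train_fingerprints, test_fingerprints) per fold

    @property
    def best_single(self) -> HyperParams:
        return self.best[0]


def _fstat_tag(pooling: PoolingSpec) -> str:
    return "+".join(pooling.stats)


def _grid_scores_for_split(
    train_clips,
    train_labels,
    val_clips,
    val_labels,
    grids: dict,
    *,
    config: SpectrogramConfig,
    seed: int,
    learn_stride: int,
    encode_stride: int,
    max_patches: int,
) -> list[tuple[HyperParams, float]]:
    """Validation accuracy for every grid point, sharing front-end work.

    Whitening is refit per patch duration, the codebook per (duration,
    k); encodings are pooled once for all three statistics, so the
    f_stat and C axes only cost an SVM fit each.
    """
    y_tr = np.asarray(train_labels)
    y_val = np.asarray(val_labels)
    rows = []
    for d_patch in grids["d_patch_ms"]:
        patch_frames = frames_for_duration(d_patch, config.hop_ms)
        patches = collect_training_patches(
            train_clips, config, patch_frames, learn_stride, max_patches, seed
        )
        whitening = fit_whitening(patches)
        X = apply_whitening(whitening, patches)
        for k in grids["k"]:
            codebook, _ = spherical_kmeans(X, k=k, seed=seed)
            tr_stats = pooled_stats_for_clips(
                train_clips, whitening, codebook, config, patch_frames, encode_stride
            )
            val_stats = pooled_stats_for_clips(
                val_clips, whitening, codebook, config, patch_frames, encode_stride
            )
            for pooling in grids["f_stat"]:
                F_tr = assemble_features(tr_stats, pooling)
                F_val = assemble_features(val_stats, pooling)
                standardizer = fit_standardizer(F_tr)
                Z_tr = standardizer.transform(F_tr)
                Z_val = standardizer.transform(F_val)
                for C in grids["C"]:
                    svc = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
                    svc.fit(Z_tr, y_tr)
                    score = float(np.mean(svc.predict(Z_val) == y_val))
                    rows.append((HyperParams(d_patch, k, pooling, C), score))
    return rows


def grid_search(
    clips,
    labels,
    grids: dict | None = None,
    scheme: str = "nclass",
    *,
    seed: int = 0,
    n_folds: int = 5,
    val_fraction: float = 0.25,
    config: SpectrogramConfig = DEFAULT_CONFIG,
    learn_stride: int = 1,
    encode_stride: int = 1,
    max_patches: int = 250_000,
) -> GridSearchResult:
    """Nested hyperparameter search for either evaluation regime.

    ``nclass``: outer stratified 5-fold CV; within each fold the fold
    training set is split 75/25 (stratified) into search-train and
    validation, the full grid is scored on the validation subset, the
    best point refits on the whole fold-train and is scored on the
    fold-test; the final score is the mean over folds.

    ``monitoring``: a single stratified 75/25 train/validation split of
    the provided (training-season) data; the best point refits on all
    of it.  Within-grid ties break toward the earliest grid point.
    """
    if grids is None:
        grids = default_grids()
    grid_points = iter_grid(grids)  # validates non-emptiness
    clips = list(clips)
    y = np.asarray(labels)
    idx = np.arange(len(clips))
    records = []
    best_per_fold: list[HyperParams] = []
    fold_test_scores: list[float] = []
    models: list[TrainedModel] = []
    fold_assignments = []
    common = dict(
        config=config,
        seed=seed,
        learn_stride=learn_stride,
        encode_stride=encode_stride,
        max_patches=max_patches,
    )

    def _search_split(fold, tr_idx, val_idx):
        scored = _grid_scores_for_split(
            [clips[i] for i in tr_idx],
            y[tr_idx],
            [clips[i] for i in val_idx],
            y[val_idx],
            grids,
            **common,
        )
        for hp, score in scored:
            records.append(
                {
                    "fold": fold,
                    "d_patch_ms": hp.d_patch_ms,
                    "k": hp.k,
                    "f_stat": _fstat_tag(hp.f_stat),
                    "C": hp.C,
                    "score": score,
                }
            )
        best_i = int(np.argmax([s for _, s in scored]))  # ties -> earliest point
        return scored[best_i][0]

    if scheme == "nclass":
        outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (train_idx, test_idx) in enumerate(outer.split(idx, y)):
            tr_idx, val_idx = train_test_split(
                train_idx,
                test_size=val_fraction,
                stratify=y[train_idx],
                random_state=seed,
            )
            best_hp = _search_split(fold, tr_idx, val_idx)
            best_per_fold.append(best_hp)
            model = train_model(
                [clips[i] for i in train_idx],
                y[train_idx],
                best_hp,
                config=config,
                seed=seed,
                learn_stride=learn_stride,
                encode_stride=encode_stride,
                max_patches=max_patches,
            )
            pred = predict(model, [clips[i] for i in test_idx])
            fold_test_scores.append(float(np.mean(pred.labels == y[test_idx])))
            models.append(model)
            fold_assignments.append(
                (
                    frozenset(clip_fingerprint(clips[i]) for i in train_idx),
                    frozenset(clip_fingerprint(clips[i]) for i in test_idx),
                )
            )
        mean_score = float(np.mean(fold_test_scores))
    elif scheme == "monitoring":
        tr_idx, val_idx = train_test_split(
            idx, test_size=val_fraction, stratify=y, random_state=seed
        )
        best_hp = _search_split(0, tr_idx, val_idx)
        best_per_fold.append(best_hp)
        model = train_model(
            clips,
            y,
            best_hp,
            config=config,
            seed=seed,
            learn_stride=learn_stride,
            encode_stride=encode_stride,
            max_patches=max_patches,
        )
        models.append(model)
        fold_assignments.append(
            (frozenset(clip_fingerprint(c) for c in clips), frozenset())
        )
        mean_score = float(max(r["score"] for r in records))  # chosen point's val score
        fold_test_scores = []
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    table = pd.DataFrame.from_records(
        records, columns=["fold", "d_patch_ms", "k", "f_stat", "C", "score"]
    )
    return GridSearchResult(
        scheme=scheme,
        table=table,
        best=best_per_fold,
        fold_test_scores=fold_test_scores,
        mean_score=mean_score,
        models=models,
        fold_assignments=fold_assignments,
    )


def sensitivity_groups(table: pd.DataFrame, param: str) -> dict:
    """Group grid-search scores by the value of one hyperparameter.

    Returns {value: np.ndarray of scores}; group sizes sum to the table
    size.  This is the grouping behind per-hyperparameter sensitivity
    box plots.
    """
    aliases = {"d_patch": "d_patch_ms", "dpatch": "d_patch_ms"}
    param = aliases.get(param, param)
    if len(table) == 0:
        raise ValueError("empty grid-score table")
    if param not in ("d_patch_ms", "k", "f_stat", "C"):
        raise ValueError(f"unknown hyperparameter {param!r}")
    return {
        value: group["score"].to_numpy()
        for value, group in table.groupby(param, sort=True)
    }
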