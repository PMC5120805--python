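"""Evaluation metrics for both study regimes.

N-class regime: overall accuracy, per-class accuracy and the confusion
matrix.  Open-set monitoring regime: ROC/AUC and precision-recall
curves over the calibrated probabilities, threshold selection (default
0.5, f1-optimal on the training set, or the "oracle" f1-optimal on the
test set), daily detection curves over a migration season, and their
Pearson correlation against the expert-labeled reference curve.

Error analysis approximates each ~1 s positive clip's signal-to-noise
ratio as

    SNR_dB = 10 log10(P_call / P_background)

where P_call is the mean band-limited (2000-11025 Hz) spectral power in
the clip's central 150 ms and P_background the mean over the rest of
the clip.  True-positive and false-negative SNR distributions are
compared with a two-sample Kolmogorov-Smirnov test, and SNR is
correlated against the model's calibrated confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve, roc_curve

from .frontend import DEFAULT_CONFIG, AudioClip, SpectrogramConfig


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows = true
    labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def per_class_accuracy(self) -> dict:
        row_sums = self.counts.sum(axis=1)
        out = {}
        for i, lab in enumerate(self.labels):
            out[lab] = float(self.counts[i, i] / row_sums[i]) if row_sums[i] else np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion_and_accuracy(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Confusion matrix with overall accuracy = trace/total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts=counts, labels=list(labels))


@dataclass
class CurveResult:
    kind: str  # "roc" | "pr"
    x: np.ndarray  # fpr (roc) or recall (pr)
    y: np.ndarray  # tpr (roc) or precision (pr)
    thresholds: np.ndarray
    auc: float | None = None

    def to_frame(self) -> pd.DataFrame:
        t = self.thresholds
        if t.size < self.x.size:  # pad to align with curve points
            t = np.concatenate([[np.nan], t])
        cols = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        return pd.DataFrame({"threshold": t[: self.x.size], cols[0]: self.x, cols[1]: self.y})


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return y


def roc(scores, y) -> CurveResult:
    """ROC curve over all distinct score thresholds; AUC by trapezoid rule."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=np.float64)
    fpr, tpr, thr = roc_curve(y, scores)
    return CurveResult(kind="roc", x=fpr, y=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


def pr(scores, y) -> CurveResult:
    """Precision-recall curve over all distinct score thresholds."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=np.float64)
    precision, recall, thr = precision_recall_curve(y, scores)
    return CurveResult(kind="pr", x=recall, y=precision, thresholds=thr)


def f1_at_threshold(scores, y, threshold: float) -> float:
    y = np.asarray(y).astype(int)
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def select_threshold(scores=None, y=None, mode: str = "default") -> float:
    """Decision threshold on calibrated probabilities.

    ``default`` returns 0.5.  ``f1_train`` / ``oracle`` return the
    exact argmax of f1 over all distinct scores plus {0, 1} — the same
    computation, named for whether training- or test-set labels are
    supplied.
    """
    if mode == "default":
        return 0.5
    if mode not in ("f1_train", "oracle"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    y = np.asarray(y).astype(int)
    if y.sum() == 0:
        raise ValueError("f1 threshold selection requires positive examples")
    scores = np.asarray(scores, dtype=np.float64)
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    f1s = np.array([f1_at_threshold(scores, y, t) for t in candidates])
    return float(candidates[int(np.argmax(f1s))])


@dataclass
class DetectionCurve:
    """Daily detection counts across a season."""

    dates: pd.DatetimeIndex
    counts: np.ndarray
    threshold: float | None = None
    source: str = "model"  # "model" | "reference"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.counts})


def detection_histogram(
    timestamps,
    probabilities=None,
    threshold: float = 0.5,
    labels=None,
    positive_label=None,
    date_range=None,
) -> DetectionCurve:
    """Daily counts of above-threshold detections (or labeled positives).

    Passing ``probabilities`` + ``threshold`` builds a model curve;
    passing ``labels`` + ``positive_label`` builds the reference curve
    from expert annotations the same way.  Days are local calendar
    dates of each clip timestamp; missing timestamps raise, naming the
    offending clip indices.
    """
    ts = pd.Series(list(timestamps))
    missing = ts.index[ts.isna() | (ts == "")].tolist()
    if missing:
        raise ValueError(f"clips with missing timestamps: {missing}")
    dates = pd.to_datetime(ts).dt.normalize()
    if probabilities is not None:
        hits = np.asarray(probabilities, dtype=np.float64) >= threshold
        source = "model"
    elif labels is not None:
        hits = np.asarray(labels) == positive_label
        source = "reference"
        threshold = None
    else:
        raise ValueError("provide probabilities or labels")
    per_day = dates[hits].value_counts().sort_index()
    if date_range is not None:
        start, end = pd.to_datetime(date_range[0]), pd.to_datetime(date_range[1])
    elif len(per_day) > 0:
        start, end = per_day.index.min(), per_day.index.max()
    else:
        start, end = dates.min(), dates.max()
    axis = pd.date_range(start, end, freq="D")
    counts = per_day.reindex(axis, fill_value=0).to_numpy()
    return DetectionCurve(dates=axis, counts=counts, threshold=threshold, source=source)


def curve_correlation(a: DetectionCurve, b: DetectionCurve) -> tuple[float, float, int]:
    """Pearson r between two detection curves, with df = n - 2."""
    if len(a.dates) != len(b.dates) or not (a.dates == b.dates).all():
        raise ValueError("detection curves must share the same date axis")
    x = np.asarray(a.counts, dtype=np.float64)
    y = np.asarray(b.counts, dtype=np.float64)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for a zero-variance curve")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), x.size - 2


# --------------------------------------------------------------------------
# SNR error analysis


@dataclass
class SNRRecord:
    clip_id: str | None
    p_call: float
    p_background: float
    snr_db: float
    confidence: float | None = None
    outcome: str | None = None  # "TP" | "FN"


def band_power_profile(
    clip: AudioClip,
    band: tuple[float, float] = (2000.0, 11025.0),
    config: SpectrogramConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame band-limited STFT power and frame-center times."""
    from numpy.lib.stride_tricks import sliding_window_view
    from scipy.signal import get_window

    win, hop = config.window_length, config.hop_length
    if clip.n_samples < win:
        raise ValueError("clip shorter than the analysis window")
    frames = sliding_window_view(clip.samples, win)[::hop]
    window = get_window("hann", win, fftbins=False)
    power = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / clip.sample_rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    profile = power[:, in_band].sum(axis=1)
    times = (np.arange(profile.size) * hop + win / 2) / clip.sample_rate
    return profile, times


def _bandpass_power_profile(clip, band, config):
    from scipy.signal import butter, sosfiltfilt

    nyq = clip.sample_rate / 2
    hi = min(band[1], nyq * 0.999)
    sos = butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    filtered = sosfiltfilt(sos, clip.samples)
    hop = config.hop_length
    n_hops = clip.n_samples // hop
    profile = (filtered[: n_hops * hop] ** 2).reshape(n_hops, hop).mean(axis=1)
    times = (np.arange(n_hops) + 0.5) * hop / clip.sample_rate
    return profile, times


def estimate_snr(
    clip: AudioClip,
    band: tuple[float, float] = (2000.0, 11025.0),
    call_ms: float = 150.0,
    config: SpectrogramConfig = DEFAULT_CONFIG,
    method: str = "stft",
    clip_id: str | None = None,
) -> SNRRecord:
    """Approximate SNR of a ~1 s monitoring clip (call centered).

    P_call is the mean band-limited power over the central ``call_ms``
    window; P_background the mean everywhere else.  ``method`` selects
    the band-limited STFT power (default) or a time-domain band-pass
    alternative.  SNR is scale-invariant: scaling the waveform leaves
    it unchanged.
    """
    if clip.duration_ms < 2 * call_ms:
        raise ValueError(
            f"clip of {clip.duration_ms:.0f} ms too short; need >= {2 * call_ms:.0f} ms "
            "so the background region is non-empty"
        )
    if method == "stft":
        profile, times = band_power_profile(clip, band, config)
    elif method == "bandpass":
        profile, times = _bandpass_power_profile(clip, band, config)
    else:
        raise ValueError(f"unknown SNR method {method!r}")
    mid = clip.n_samples / clip.sample_rate / 2
    half = call_ms / 2000.0
    in_call = (times >= mid - half) & (times < mid + half)
    if not in_call.any() or in_call.all():
        raise ValueError("degenerate call/background segmentation")
    p_call = float(profile[in_call].mean())
    p_background = float(profile[~in_call].mean())
    if p_background <= 0 or p_call <= 0:
        raise ValueError("silent region: SNR undefined")
    snr_db = 10.0 * np.log10(p_call / p_background)
    return SNRRecord(
        clip_id=clip_id if clip_id is not None else clip.clip_id,
        p_call=p_call,
        p_background=p_background,
        snr_db=float(snr_db),
    )


@dataclass
class SNRAnalysis:
    ks_statistic: float
    ks_pvalue: float
    n_tp: int
    n_fn: int
    pearson_r: float
    pearson_p: float
    df: int


def snr_error_analysis(records: list[SNRRecord]) -> SNRAnalysis:
    """Compare TP vs FN SNR distributions and correlate SNR with confidence.

    Two-sample KS (asymptotic two-sided p-value) on the SNR values of
    the true-positive vs false-negative groups, plus Pearson r between
    SNR and calibrated confidence over all positive clips (df = n - 2).
    """
    tp = np.array([r.snr_db for r in records if r.outcome == "TP"])
    fn = np.array([r.snr_db for r in records if r.outcome == "FN"])
    if tp.size == 0 or fn.size == 0:
        raise ValueError("both TP and FN groups must be non-empty")
    ks = sps.ks_2samp(tp, fn, method="asymp")
    pairs = [(r.snr_db, r.confidence) for r in records if r.confidence is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 clips with confidences for correlation")
    snr, conf = map(np.asarray, zip(*pairs))
    r, p = sps.pearsonr(snr, conf)
    return SNRAnalysis(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_tp=int(tp.size),
        n_fn=int(fn.size),
        pearson_r=float(r),
        pearson_p=float(p),
        df=len(pairs) - 2,
    )
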