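"""Audio loading and time-frequency front end.

Flight calls are short (~50-150 ms) frequency-modulated notes in the
2-11 kHz band, so the spectrogram must resolve very fine temporal
structure.  The canonical parametrization used throughout the package is
a 40-band log-scaled mel spectrogram between 2000 and 11025 Hz, computed
with an 11.6 ms (256-sample) Hann window and a 1.45 ms (32-sample) hop
at a 22050 Hz sampling rate.  The spectrogram is then sliced into
overlapping fixed-width time-frequency patches ("TF-patches") which are
the unit of both codebook learning and encoding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

DEFAULT_SAMPLE_RATE = 22050


@dataclass
class AudioClip:
    """A mono audio clip with optional dataset metadata."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    label: str | None = None
    sensor_id: str | None = None
    timestamp: str | None = None  # ISO-8601
    clip_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("AudioClip must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate

    def scaled(self, gain: float) -> "AudioClip":
        return replace(self, samples=self.samples * gain)


@dataclass(frozen=True)
class SpectrogramConfig:
    """Log-mel spectrogram parametrization.

    ``mel_style`` selects the mel-scale dialect ("slaney": linear below
    1 kHz, logarithmic above, area-normalized triangles; "htk": the
    2595*log10(1+f/700) formula) and ``spectrum`` whether filters act on
    the power or magnitude spectrum.  Defaults follow common practice
    (Slaney-style bank on power) and are recorded with every spectrogram
    so downstream consumers can reconstruct the exact bank.
    """

    n_mels: int = 40
    fmin: float = 2000.0
    fmax: float = 11025.0
    window_length: int = 256
    hop_length: int = 32
    sample_rate: int = DEFAULT_SAMPLE_RATE
    log_floor: float = 1e-10
    mel_style: str = "slaney"
    spectrum: str = "power"

    def __post_init__(self) -> None:
        if not (0 <= self.fmin < self.fmax <= self.sample_rate / 2):
            raise ValueError("require 0 <= fmin < fmax <= sample_rate/2")
        if self.hop_length > self.window_length:
            raise ValueError("hop_length must not exceed window_length")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.mel_style not in ("slaney", "htk"):
            raise ValueError(f"unknown mel_style {self.mel_style!r}")
        if self.spectrum not in ("power", "magnitude"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")

    @property
    def hop_ms(self) -> float:
        return 1000.0 * self.hop_length / self.sample_rate

    def to_dict(self) -> dict:
        return {
            "n_mels": self.n_mels,
            "fmin": self.fmin,
            "fmax": self.fmax,
            "window_length": self.window_length,
            "hop_length": self.hop_length,
            "sample_rate": self.sample_rate,
            "log_floor": self.log_floor,
            "mel_style": self.mel_style,
            "spectrum": self.spectrum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrogramConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpectrogramConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_CONFIG = SpectrogramConfig()


@dataclass
class MelSpectrogram:
    """Log-scaled mel spectrogram (n_mels x n_frames)."""

    values: np.ndarray
    frame_times: np.ndarray
    band_centers: np.ndarray
    config: SpectrogramConfig = field(default_factory=SpectrogramConfig)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_mels(self) -> int:
        return self.values.shape[0]


@dataclass
class RawPatchSet:
    """Flattened TF-patches, one per column, ordered by source time.

    Each column is a ``n_mels x patch_frames`` sub-matrix of a
    spectrogram flattened band-major (band index varies slowest).
    """

    patches: np.ndarray  # (n_mels*patch_frames, n_patches)
    patch_frames: int
    stride_frames: int
    n_mels: int = 40

    @property
    def n_patches(self) -> int:
        return self.patches.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.patches.shape[0]

    def unflatten(self, j: int) -> np.ndarray:
        """Recover patch ``j`` as an (n_mels, patch_frames) matrix."""
        return self.patches[:, j].reshape(self.n_mels, self.patch_frames)


# ---------------------------------------------------------------------------
# mel filterbank


def hz_to_mel(freq, style: str = "slaney"):
    freq = np.asarray(freq, dtype=np.float64)
    if style == "htk":
        return 2595.0 * np.log10(1.0 + freq / 700.0)
    # Slaney: linear below 1 kHz, logarithmic above
    f_sp = 200.0 / 3.0
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    mel = freq / f_sp
    log_region = freq >= min_log_hz
    mel = np.where(
        log_region,
        min_log_mel + np.log(np.maximum(freq, min_log_hz) / min_log_hz) / logstep,
        mel,
    )
    return mel


def mel_to_hz(mel, style: str = "slaney"):
    mel = np.asarray(mel, dtype=np.float64)
    if style == "htk":
        return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)
    f_sp = 200.0 / 3.0
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    freq = f_sp * mel
    log_region = mel >= min_log_mel
    freq = np.where(log_region, min_log_hz * np.exp(logstep * (mel - min_log_mel)), freq)
    return freq


def mel_filterbank(config: SpectrogramConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank.

    Returns ``(weights, centers)`` where ``weights`` has shape
    ``(n_mels, n_fft//2 + 1)``.  Slaney-style banks are area-normalized
    (each triangle scaled by 2 / bandwidth).
    """
    n_fft = config.window_length
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / config.sample_rate)
    mel_lo = hz_to_mel(config.fmin, config.mel_style)
    mel_hi = hz_to_mel(config.fmax, config.mel_style)
    mel_pts = np.linspace(mel_lo, mel_hi, config.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts, config.mel_style)

    weights = np.zeros((config.n_mels, fft_freqs.size))
    for i in range(config.n_mels):
        lower, center, upper = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - fft_freqs) / max(upper - center, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        if config.mel_style == "slaney":
            tri = tri * (2.0 / (upper - lower))
        weights[i] = tri
    centers = hz_pts[1:-1]
    return weights, centers


# ---------------------------------------------------------------------------
# operations


def load_clip(path: str | Path, target_rate: int = DEFAULT_SAMPLE_RATE) -> AudioClip:
    """Load a WAV file as a mono clip at ``target_rate``.

    Multichannel input is downmixed by channel mean; off-rate input is
    resampled with a polyphase filter.  Integer PCM is scaled to
    [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read audio file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"audio file is empty: {path}")
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit PCM is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        data = resample_poly(data, target_rate // g, rate // g)
    data = np.clip(data, -1.0, 1.0)
    return AudioClip(samples=data, sample_rate=target_rate, clip_id=path.stem)


def save_clip(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, (x * 32767.0).astype(np.int16))


def trim_center(clip: AudioClip, duration_ms: float = 150.0, pad: bool = False) -> AudioClip:
    """Trim a clip to its central ``duration_ms`` milliseconds.

    Monitoring detections are ~1 s clips centered on the detector
    trigger, so the call is assumed to sit in the middle; trimming to
    the central 150 ms discards mostly-background context.  Clips
    shorter than the target duration raise unless ``pad=True``
    (reflect-padding), which is off by default.
    """
    n_target = int(round(duration_ms * clip.sample_rate / 1000.0))
    n = clip.n_samples
    if n < n_target:
        if not pad:
            raise ValueError(
                f"clip of {clip.duration_ms:.1f} ms is shorter than {duration_ms} ms"
            )
        deficit = n_target - n
        left = deficit // 2
        x = np.pad(clip.samples, (left, deficit - left), mode="reflect")
        return replace(clip, samples=x)
    start = int(math.floor((n - n_target) / 2))
    return replace(clip, samples=clip.samples[start : start + n_target])


def logmel_spectrogram(clip: AudioClip, config: SpectrogramConfig = DEFAULT_CONFIG) -> MelSpectrogram:
    """Compute the log-scaled mel spectrogram of a clip.

    Frames are ``window_length`` samples at ``hop_length`` spacing with
    no padding, so ``n_frames = 1 + floor((N - window) / hop)``.  The
    log is natural log of (band energy + log_floor).
    """
    if clip.sample_rate != config.sample_rate:
        raise ValueError(
            f"clip rate {clip.sample_rate} != config rate {config.sample_rate}; "
            "canonicalize with load_clip first"
        )
    n = clip.n_samples
    win = config.window_length
    hop = config.hop_length
    if n < win:
        raise ValueError(f"clip of {n} samples is shorter than the {win}-sample window")
    frames = sliding_window_view(clip.samples, win)[::hop]
    window = get_window("hann", win, fftbins=False)  # symmetric taper
    spectrum = np.fft.rfft(frames * window, axis=1)
    power = np.abs(spectrum)
    if config.spectrum == "power":
        power = power**2
    weights, centers = mel_filterbank(config)
    mel = power @ weights.T  # (n_frames, n_mels)
    values = np.log(mel.T + config.log_floor)
    n_frames = values.shape[1]
    frame_times = (np.arange(n_frames) * hop + win / 2) / config.sample_rate
    return MelSpectrogram(values=values, frame_times=frame_times, band_centers=centers, config=config)


def frames_for_duration(duration_ms: float, hop_ms: float | None = None) -> int:
    """Number of spectrogram frames spanning ``duration_ms``.

    Patch durations are quoted in milliseconds but are frame-count
    multiples of the hop (e.g. 92.9 ms -> 64 frames, 23.2 ms -> 16
    frames at a 1.45 ms hop).
    """
    if hop_ms is None:
        hop_ms = DEFAULT_CONFIG.hop_ms
    if duration_ms <= 0 or hop_ms <= 0:
        raise ValueError("durations must be positive")
    return int(round(duration_ms / hop_ms))


def slice_patches(spec: MelSpectrogram, patch_frames: int, stride_frames: int = 1) -> RawPatchSet:
    """Slice a spectrogram into overlapping flattened TF-patches.

    Column ``j`` covers frames ``[j*stride, j*stride + patch_frames)``
    flattened band-major, giving ``1 + floor((n_frames - patch_frames)
    / stride)`` columns ordered by source time.
    """
    if patch_frames < 1 or stride_frames < 1:
        raise ValueError("patch_frames and stride_frames must be >= 1")
    n_frames = spec.n_frames
    if n_frames < patch_frames:
        raise ValueError(f"spectrogram has {n_frames} frames < patch_frames={patch_frames}")
    # windows: (n_patches, n_mels, patch_frames)
    windows = sliding_window_view(spec.values, patch_frames, axis=1)
    windows = windows[:, ::stride_frames, :].transpose(1, 0, 2)
    m = windows.shape[0]
    patches = windows.reshape(m, spec.n_mels * patch_frames).T.copy()
    return RawPatchSet(
        patches=patches,
        patch_frames=patch_frames,
        stride_frames=stride_frames,
        n_mels=spec.n_mels,
    )
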