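"""Synthetic flight-call audio, background scenes, and dataset builders.

Real flight calls are single-note frequency-modulated vocalizations of
~50-150 ms in the 2-11 kHz band, and species differ in contour shape:
number of frequency peaks, slope of the descending contour, terminal
modulation.  The generator ships a library of contour archetypes
(down-sweep, up-sweep, V, inverted V, two-peak, modulated tail) with
per-parameter jitter, and mixes calls into background scenes (quiet,
wind-like pink noise, insect-like AM tone cluster, and a peeper-like
repeated rising note that spectrally overlaps the target calls — the
dominant false-positive source in field monitoring).  A spectrogram
cross-correlation template detector emulates the sensor side: it scans
a long stream and emits ~1 s clips centered on above-threshold events.

Everything is deterministic under a seed.  No attempt is made at
bioacoustic realism sufficient for ecological inference; the generator
reproduces dataset *structure* (band limits, durations, class
imbalance, season-mismatched splits, confounders), not real species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, lfilter

from .evaluation import band_power_profile, estimate_snr
from .frontend import (
    DEFAULT_CONFIG,
    DEFAULT_SAMPLE_RATE,
    AudioClip,
    MelSpectrogram,
    SpectrogramConfig,
    logmel_spectrogram,
)

BAND = (2000.0, 11025.0)


@dataclass(frozen=True)
class CallArchetype:
    """A species-like contour family with jitter distributions.

    ``f_start``/``f_end`` anchor the fundamental contour (Hz);
    ``shape`` selects the contour family; ``mod_depth_hz``/``mod_rate``
    parametrize superimposed modulation (peaks, terminal FM).  Jitter
    standard deviations give within-species variation.
    """

    species: str
    shape: str  # down | up | v | inv_v | two_peak | mod_tail
    f_start: float
    f_end: float
    duration_ms: float = 100.0
    freq_jitter_hz: float = 150.0
    duration_jitter_ms: float = 10.0
    mod_depth_hz: float = 0.0
    mod_rate: float = 0.0
    n_harmonics: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("down", "up", "v", "inv_v", "two_peak", "mod_tail"):
            raise ValueError(f"unknown contour shape {self.shape!r}")
        if not (50.0 <= self.duration_ms <= 150.0):
            raise ValueError("archetype duration must lie in [50, 150] ms")
        for f in (self.f_start, self.f_end):
            if not (BAND[0] <= f <= BAND[1]):
                raise ValueError("contour anchors must lie inside 2000-11025 Hz")


# >= 6 distinct contour families; both regimes are emulated from these.
ARCHETYPES: dict[str, CallArchetype] = {
    "dsw": CallArchetype("dsw", "down", 8000.0, 5000.0, 100.0),
    "usw": CallArchetype("usw", "up", 3500.0, 6500.0, 80.0),
    "vee": CallArchetype("vee", "v", 7000.0, 4000.0, 90.0),
    "ivee": CallArchetype("ivee", "inv_v", 4500.0, 7500.0, 110.0),
    "twop": CallArchetype(
        "twop", "two_peak", 6200.0, 5400.0, 120.0, mod_depth_hz=800.0, mod_rate=2.0
    ),
    "mtail": CallArchetype(
        "mtail", "mod_tail", 8500.0, 5500.0, 130.0, mod_depth_hz=600.0, mod_rate=8.0
    ),
}


def _contour(arch: CallArchetype, t: np.ndarray, f0: float, f1: float) -> np.ndarray:
    """Fundamental frequency contour over normalized time t in [0, 1]."""
    if arch.shape == "down" or arch.shape == "up":
        f = f0 + (f1 - f0) * t
    elif arch.shape == "v":
        f = f0 + (f1 - f0) * np.sin(np.pi * t)  # f1 is the valley
    elif arch.shape == "inv_v":
        f = f0 + (f1 - f0) * np.sin(np.pi * t)  # f1 is the peak
    elif arch.shape == "two_peak":
        f = f0 + (f1 - f0) * t + arch.mod_depth_hz * np.sin(np.pi * arch.mod_rate * t) ** 2
    elif arch.shape == "mod_tail":
        f = f0 + (f1 - f0) * t
        tail = t > 0.7
        f = f + np.where(
            tail, arch.mod_depth_hz * np.sin(2 * np.pi * arch.mod_rate * (t - 0.7)), 0.0
        )
    return f


def synth_call(
    arch: CallArchetype,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    jitter_scale: float = 1.0,
) -> AudioClip:
    """Synthesize one jittered call of an archetype (deterministic per seed).

    The call is an FM sinusoid following the jittered contour with a
    raised-cosine amplitude envelope and optional weak harmonics.
    Raises if the jittered contour leaves the 2000-11025 Hz band or the
    duration leaves [50, 150] ms.
    """
    rng = np.random.default_rng(seed)
    dur = arch.duration_ms + jitter_scale * rng.normal(0.0, arch.duration_jitter_ms)
    dur = float(np.clip(dur, 50.0, 150.0))
    f0 = arch.f_start + jitter_scale * rng.normal(0.0, arch.freq_jitter_hz)
    f1 = arch.f_end + jitter_scale * rng.normal(0.0, arch.freq_jitter_hz)
    n = int(round(dur * sample_rate / 1000.0))
    t = np.arange(n) / max(n - 1, 1)
    freq = _contour(arch, t, f0, f1)
    if freq.min() < BAND[0] or freq.max() > BAND[1]:
        raise ValueError(
            f"jittered contour ({freq.min():.0f}-{freq.max():.0f} Hz) leaves the "
            f"{BAND[0]:.0f}-{BAND[1]:.0f} Hz analysis band"
        )
    phase = 2.0 * np.pi * np.cumsum(freq) / sample_rate
    x = np.sin(phase)
    for h in range(2, arch.n_harmonics + 1):
        x = x + (0.3 / h) * np.sin(h * phase)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))
    x = 0.5 * x * envelope
    return AudioClip(samples=x, sample_rate=sample_rate, label=arch.species)


# --------------------------------------------------------------------------
# background scenes


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    # Paul Kellet's economy pink filter on white noise
    b = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
    a = [1.0, -2.494956002, 2.017265875, -0.522189400]
    white = rng.standard_normal(n + 1500)
    pink = lfilter(b, a, white)[1500:]
    return pink / max(np.std(pink), 1e-12)


def _insect_background(n: int, rng: np.random.Generator, sr: int) -> np.ndarray:
    t = np.arange(n) / sr
    x = np.zeros(n)
    for carrier in (4200.0, 4900.0, 5600.0):
        fc = carrier * (1.0 + 0.01 * rng.standard_normal())
        am_rate = rng.uniform(25.0, 60.0)
        am = 0.5 * (1.0 + np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi)))
        x += am * np.sin(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    x += 0.2 * rng.standard_normal(n)
    return x / max(np.std(x), 1e-12)


def _peeper_background(n: int, rng: np.random.Generator, sr: int) -> np.ndarray:
    """Repeated short rising FM note overlapping the target-call band."""
    x = 0.08 * rng.standard_normal(n)  # faint ambience under the notes
    note_ms = 120.0
    note_n = int(note_ms * sr / 1000.0)
    period_n = int(rng.uniform(0.28, 0.4) * sr)
    start = int(rng.uniform(0, period_n))
    while start + note_n < n:
        f_lo = 4800.0 + rng.normal(0.0, 150.0)
        f_hi = f_lo + 1600.0 + rng.normal(0.0, 200.0)
        tt = np.arange(note_n) / max(note_n - 1, 1)
        freq = f_lo + (f_hi - f_lo) * tt
        phase = 2 * np.pi * np.cumsum(freq) / sr
        env = 0.5 * (1 - np.cos(2 * np.pi * tt))
        x[start : start + note_n] += 2.2 * np.sin(phase) * env
        start += period_n + int(rng.normal(0.0, 0.02 * sr))
    return x / max(np.std(x), 1e-12)


BACKGROUND_KINDS = ("quiet", "wind", "insect", "peeper")


def background_noise(
    kind: str, n: int, rng: np.random.Generator, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> np.ndarray:
    """Unit-RMS background of the requested kind (gain set by the mixer)."""
    if kind == "quiet":
        return rng.standard_normal(n)
    if kind == "wind":
        return _pink_noise(n, rng)
    if kind == "insect":
        return _insect_background(n, rng, sample_rate)
    if kind == "peeper":
        return _peeper_background(n, rng, sample_rate)
    raise ValueError(f"unknown background kind {kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """A mixing recipe: background kind, target SNR and clip geometry.

    ``snr_mode`` selects the SNR semantics: "measured" calibrates the
    background gain so the band-limited center-vs-rest power-ratio
    estimator applied to the *mix* returns ``snr_db`` (feasible only
    above ~0 dB, since the call window also contains background);
    "call" interprets ``snr_db`` as the pure call-to-background power
    ratio, which may be arbitrarily negative.
    """

    background: str = "quiet"
    snr_db: float = 10.0
    clip_ms: float = 1000.0
    seed: int = 0
    snr_mode: str = "measured"
    call_window_ms: float = 150.0

    def __post_init__(self) -> None:
        if self.background not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.background!r}")
        if self.snr_mode not in ("measured", "call"):
            raise ValueError(f"unknown snr_mode {self.snr_mode!r}")


def mix_scene(
    call: AudioClip | None,
    spec: SceneSpec,
    config: SpectrogramConfig = DEFAULT_CONFIG,
) -> AudioClip:
    """Mix a call (centered) into a background scene at the requested SNR.

    Background gain is solved in closed form from the band-limited
    power of call and background in the central call window versus the
    rest, so the realized SNR tracks the request closely.  No-call
    scenes are labeled "Reject".  Raises when the requested SNR is
    unreachable (silent background, or an "measured" target at or below the
    level floor imposed by background inside the call window).
    """
    sr = config.sample_rate
    n = int(round(spec.clip_ms * sr / 1000.0))
    rng = np.random.default_rng(spec.seed)
    bg = background_noise(spec.background, n, rng, sr)
    if call is None:
        out = 0.05 * bg
        return AudioClip(samples=out, sample_rate=sr, label="Reject")
    if call.n_samples > n:
        raise ValueError("call is longer than the requested clip")
    start = (n - call.n_samples) // 2
    padded = np.zeros(n)
    padded[start : start + call.n_samples] = call.samples

    mid = n / sr / 2
    half = spec.call_window_ms / 2000.0
    call_profile, times = band_power_profile(
        AudioClip(padded, sr), BAND, config
    )
    bg_profile, _ = band_power_profile(AudioClip(bg, sr), BAND, config)
    in_call = (times >= mid - half) & (times < mid + half)
    p_call = call_profile[in_call].mean()
    p_bg_call = bg_profile[in_call].mean()
    p_bg_else = bg_profile[~in_call].mean()
    if p_bg_else <= 1e-300 or p_call <= 1e-300:
        raise ValueError("unreachable SNR: silent background or silent call")
    ratio = 10.0 ** (spec.snr_db / 10.0)
    if spec.snr_mode == "measured":
        denom = ratio * p_bg_else - p_bg_call
        if denom <= 0:
            raise ValueError(
                f"unreachable SNR: {spec.snr_db} dB is at or below the floor set by "
                "background power inside the call window"
            )
        gain = np.sqrt(p_call / denom)
    else:  # pure call-to-background ratio
        gain = np.sqrt(p_call / (ratio * p_bg_else))
    out = padded + gain * bg
    peak = np.abs(out).max()
    if peak > 0.99:  # common rescale preserves the SNR
        out = out * (0.99 / peak)
    return AudioClip(samples=out, sample_rate=sr, label=call.label)


# --------------------------------------------------------------------------
# template detector (sensor simulation)


@dataclass
class Detection:
    clip: AudioClip
    score: float
    time_s: float


def template_detector(
    stream: AudioClip,
    template: MelSpectrogram,
    threshold: float = 0.6,
    clip_duration_s: float = 1.0,
    config: SpectrogramConfig = DEFAULT_CONFIG,
) -> list[Detection]:
    """Scan a stream by spectrogram cross-correlation against a template.

    The score at each position is the zero-mean normalized cross-
    correlation between the template and the aligned spectrogram
    window, rectified at 0 so scores lie in [0, 1].  Local score maxima
    above ``threshold`` emit ~``clip_duration_s`` clips centered on the
    event.
    """
    if stream.n_samples < clip_duration_s * stream.sample_rate:
        raise ValueError("stream must be at least one clip duration long")
    spec = logmel_spectrogram(stream, config)
    T = template.values
    tf = T.shape[1]
    if tf > spec.n_frames:
        raise ValueError("template is wider than the stream spectrogram")
    L = T.size
    t_mean = T.mean()
    t_std = T.std()
    if t_std <= 1e-300:
        raise ValueError("template has zero variance")
    S = spec.values
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(S, tf, axis=1)  # (bands, nw, tf) view
    cross = np.einsum("bwt,bt->w", windows, T)
    w_sum = np.einsum("bwt->w", windows)
    w_sq = np.einsum("bwt,bwt->w", windows, windows)
    w_mean = w_sum / L
    w_var = np.maximum(w_sq / L - w_mean**2, 0.0)
    w_std = np.sqrt(w_var)
    denom = L * w_std * t_std
    r = np.where(denom > 1e-300, (cross - L * w_mean * t_mean) / np.maximum(denom, 1e-300), 0.0)
    scores = np.clip(r, 0.0, 1.0)
    peaks, _ = find_peaks(scores, height=threshold, distance=max(tf, 1))
    # an exact match at the stream edge is a boundary plateau, not a peak
    if scores.size and scores[0] >= threshold and (scores.size == 1 or scores[0] >= scores[1]):
        if not (peaks.size and peaks[0] < tf):
            peaks = np.concatenate([[0], peaks]).astype(int)
    detections = []
    half = clip_duration_s / 2.0
    for w in peaks:
        center = spec.frame_times[int(w)] + (tf / 2) * config.hop_length / config.sample_rate
        lo = int(round((center - half) * stream.sample_rate))
        lo = int(np.clip(lo, 0, stream.n_samples - int(clip_duration_s * stream.sample_rate)))
        hi = lo + int(clip_duration_s * stream.sample_rate)
        detections.append(
            Detection(
                clip=AudioClip(stream.samples[lo:hi].copy(), stream.sample_rate),
                score=float(scores[int(w)]),
                time_s=float(center),
            )
        )
    return detections


# --------------------------------------------------------------------------
# dataset builders


@dataclass
class DatasetSpec:
    """Structural recipe for a synthetic dataset.

    ``counts`` maps split -> label -> clip count, where labels are
    archetype keys (N-class regime) or the monitoring annotation
    categories "Target" / "FlightCall" / "Reject".  Backgrounds and SNR
    ranges are per split so train/test condition shift (season
    mismatch) can be dialed in.
    """

    name: str
    counts: dict[str, dict[str, int]]
    target_species: str | None = None
    backgrounds: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"train": ("quiet", "wind"), "test": ("quiet", "wind")}
    )
    snr_range_db: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"train": (5.0, 20.0), "test": (5.0, 20.0)}
    )
    date_ranges: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "train": ("2014-09-15", "2014-11-15"),
            "test": ("2015-04-01", "2015-05-27"),
        }
    )
    clip_ms: float = 1000.0
    snr_mode: str = "measured"


def _random_timestamp(rng, start: str, end: str) -> str:
    days = pd.date_range(start, end, freq="D")
    day = days[int(rng.integers(len(days)))]
    # nocturnal migration: calls land in the night hours
    hour = int(rng.choice([21, 22, 23, 0, 1, 2, 3, 4]))
    minute, second = int(rng.integers(60)), int(rng.integers(60))
    ts = day + pd.Timedelta(hours=hour, minutes=minute, seconds=second)
    return ts.isoformat()


def _mix_with_retry(
    call: AudioClip | None,
    kinds: tuple[str, ...],
    snr_range: tuple[float, float],
    clip_ms: float,
    rng: np.random.Generator,
    snr_mode: str = "measured",
    max_tries: int = 30,
) -> AudioClip:
    """Mix a scene, redrawing background/SNR when the draw is infeasible.

    Non-stationary backgrounds (e.g. a peeper note landing inside the
    call window) can make a low measured-SNR target unreachable; redrawing
    keeps the realized SNR distribution inside the requested range
    without biasing the stationary-background case.
    """
    last_exc = None
    for _ in range(max_tries):
        scene = SceneSpec(
            background=str(rng.choice(kinds)),
            snr_db=float(rng.uniform(*snr_range)),
            clip_ms=clip_ms,
            seed=int(rng.integers(2**31)),
            snr_mode=snr_mode,
        )
        try:
            return mix_scene(call, scene)
        except ValueError as exc:
            last_exc = exc
    raise ValueError(f"could not realize a feasible scene after {max_tries} draws") from last_exc


def _scene_for_label(
    label: str, spec: DatasetSpec, split: str, rng: np.random.Generator
) -> AudioClip:
    other_keys = [
        k for k in ARCHETYPES if spec.target_species is None or k != spec.target_species
    ]
    if label == "Reject":
        arch_key = None
    elif label == "FlightCall":
        arch_key = other_keys[int(rng.integers(len(other_keys)))]
    elif label == "Target":
        arch_key = spec.target_species
    else:
        arch_key = label
    call = None
    if arch_key is not None:
        call = synth_call(ARCHETYPES[arch_key], seed=int(rng.integers(2**31)))
    clip = _mix_with_retry(
        call,
        spec.backgrounds[split],
        spec.snr_range_db[split],
        spec.clip_ms,
        rng,
        spec.snr_mode,
    )
    clip.label = label
    return clip


def build_dataset(
    spec: DatasetSpec, seed: int = 0, out_dir=None, audio: bool = True
) -> tuple[pd.DataFrame, dict[str, AudioClip]]:
    """Materialize a dataset: manifest (+ audio) with exact per-label counts.

    Returns ``(manifest, clips)`` where ``clips`` maps clip id to
    AudioClip (empty when ``audio=False``, which builds just the
    manifest for structural checks).  With ``out_dir`` set, clips are
    written as WAV files and the manifest paths point at them.
    """
    from pathlib import Path

    from .frontend import save_clip

    rng = np.random.default_rng(seed)
    rows = []
    clips: dict[str, AudioClip] = {}
    i = 0
    for split, label_counts in spec.counts.items():
        for label, count in label_counts.items():
            for _ in range(count):
                clip_id = f"{spec.name}_{split}_{label}_{i:06d}"
                ts = _random_timestamp(rng, *spec.date_ranges[split])
                sensor = f"sensor{int(rng.integers(1, 11)):02d}"
                if audio:
                    clip = _scene_for_label(label, spec, split, rng)
                    clip.clip_id = clip_id
                    clip.timestamp = ts
                    clip.sensor_id = sensor
                    clips[clip_id] = clip
                else:
                    rng.integers(2**31)  # keep the stream position stable
                path = f"{clip_id}.wav"
                rows.append(
                    {
                        "path": path,
                        "label": label,
                        "split": split,
                        "sensor": sensor,
                        "timestamp": ts,
                    }
                )
                i += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None and audio:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for clip_id, clip in clips.items():
            save_clip(clip, out / f"{clip_id}.wav")
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, clips


@dataclass
class SeasonSpec:
    """A monitoring test season with a planted migration pulse.

    Daily positive counts follow a Gaussian pulse (peak day, width);
    negatives arrive at a steady nightly rate.  The reference detection
    curve is the planted per-day positive count.
    """

    target_species: str = "dsw"
    start_date: str = "2015-04-01"
    n_days: int = 57
    pulse_peak_day: int = 28
    pulse_sd_days: float = 7.0
    total_positives: int = 150
    negatives_per_day: float = 6.0
    backgrounds: tuple[str, ...] = ("quiet", "wind", "peeper")
    # pure call-to-background ratio ("call" mode): the low end yields calls
    # buried beyond recovery, making quietness the dominant failure factor
    snr_range_db: tuple[float, float] = (-12.0, 15.0)
    snr_mode: str = "call"
    clip_ms: float = 1000.0
    unusual_fraction: float = 0.2  # jitter-doubled "unusual variant" calls


def build_monitoring_season(
    spec: SeasonSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, AudioClip], pd.Series]:
    """Generate a test season; returns (manifest, clips, planted daily counts)."""
    rng = np.random.default_rng(seed)
    days = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    d = np.arange(spec.n_days)
    weights = np.exp(-0.5 * ((d - spec.pulse_peak_day) / spec.pulse_sd_days) ** 2)
    weights /= weights.sum()
    pos_per_day = rng.multinomial(spec.total_positives, weights)
    neg_per_day = rng.poisson(spec.negatives_per_day, size=spec.n_days)

    rows = []
    clips: dict[str, AudioClip] = {}
    other_keys = [k for k in ARCHETYPES if k != spec.target_species]
    i = 0
    for day_idx, day in enumerate(days):
        n_pos, n_neg = int(pos_per_day[day_idx]), int(neg_per_day[day_idx])
        for kind in ["Target"] * n_pos + ["FlightCall", "Reject"] * (n_neg // 2) + (
            ["Reject"] * (n_neg % 2)
        ):
            clip_id = f"season_{i:06d}"
            if kind == "Target":
                jitter = 2.0 if rng.random() < spec.unusual_fraction else 1.0
                call = synth_call(
                    ARCHETYPES[spec.target_species],
                    seed=int(rng.integers(2**31)),
                    jitter_scale=jitter,
                )
            elif kind == "FlightCall":
                call = synth_call(
                    ARCHETYPES[other_keys[int(rng.integers(len(other_keys)))]],
                    seed=int(rng.integers(2**31)),
                )
            else:
                call = None
            clip = _mix_with_retry(
                call, spec.backgrounds, spec.snr_range_db, spec.clip_ms, rng, spec.snr_mode
            )
            clip.label = kind
            clip.clip_id = clip_id
            hour = int(rng.choice([21, 22, 23, 0, 1, 2, 3, 4]))
            clip.timestamp = (
                day + pd.Timedelta(hours=hour, minutes=int(rng.integers(60)))
            ).isoformat()
            clips[clip_id] = clip
            rows.append(
                {
                    "path": f"{clip_id}.wav",
                    "label": kind,
                    "split": "test",
                    "sensor": f"sensor{int(rng.integers(1, 11)):02d}",
                    "timestamp": clip.timestamp,
                }
            )
            i += 1
    manifest = pd.DataFrame(rows)
    reference = pd.Series(pos_per_day, index=days)
    return manifest, clips, reference
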