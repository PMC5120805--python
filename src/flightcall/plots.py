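"""Thin optional plotting layer (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_spectrogram(spec, ax=None):
    ax = ax or plt.gca()
    extent = [spec.frame_times[0], spec.frame_times[-1], 0, spec.n_mels]
    ax.imshow(spec.values, origin="lower", aspect="auto", extent=extent, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mel band")
    return ax


def plot_sensitivity(groups: dict, param: str, ax=None):
    """Box plot of grid-search scores grouped by one hyperparameter."""
    ax = ax or plt.gca()
    keys = list(groups)
    ax.boxplot([groups[k] for k in keys], tick_labels=[str(k) for k in keys])
    ax.set_xlabel(param)
    ax.set_ylabel("validation accuracy")
    return ax


def plot_curve(curve, ax=None, label=None):
    ax = ax or plt.gca()
    ax.plot(curve.x, curve.y, label=label)
    if curve.kind == "roc":
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
    else:
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
    if label:
        ax.legend()
    return ax


def plot_detection_curves(curves: dict, ax=None, log_y: bool = False):
    """Daily detection curves: {name: DetectionCurve}."""
    ax = ax or plt.gca()
    for name, curve in curves.items():
        ax.plot(curve.dates, curve.counts, label=name)
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("date")
    ax.set_ylabel("detections per day")
    ax.legend()
    return ax
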