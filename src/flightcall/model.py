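"""Model/Results front door over the codebook-classification pipeline.

``FlightCallModel`` binds a labeled clip set (or a manifest) to a
hyperparameter setting; ``fit`` learns the whitening transform, the
spherical-k-means codebook, the feature standardizer and the calibrated
RBF-SVM, and returns a ``FlightCallResults`` object carrying the
trained pipeline, its dimensions and diagnostics, with ``summary()``,
``predict()`` and ``evaluate()`` methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import (
    HyperParams,
    PredictionResult,
    TrainedModel,
    predict as _predict,
    train_model,
)
from .evaluation import ConfusionMatrix, confusion_and_accuracy, pr, roc
from .frontend import DEFAULT_CONFIG, SpectrogramConfig


class FlightCallModel:
    """Codebook-feature flight-call classifier.

    Parameters
    ----------
    clips, labels : the training clips and their class labels.  Two or
        more classes are required (binary for the monitoring regime,
        N species for the closed-set regime).
    hyperparams : TF-patch duration, codebook size, pooling statistics
        and SVM penalty.  Defaults suit the N-class regime; use
        ``classification.grid_search`` to select them from data.
    """

    def __init__(
        self,
        clips,
        labels,
        hyperparams: HyperParams | None = None,
        *,
        scenario: str = "nclass",
        config: SpectrogramConfig = DEFAULT_CONFIG,
        learn_stride: int = 1,
        encode_stride: int = 1,
        max_patches: int = 250_000,
    ) -> None:
        self.clips = list(clips)
        self.labels = np.asarray(labels)
        if len(self.clips) != self.labels.size:
            raise ValueError("clips and labels must have equal length")
        if scenario not in ("nclass", "monitoring"):
            raise ValueError(f"unknown scenario {scenario!r}")
        self.scenario = scenario
        self.hyperparams = hyperparams or HyperParams()
        self.config = config
        self.learn_stride = learn_stride
        self.encode_stride = encode_stride
        self.max_patches = max_patches

    @classmethod
    def from_manifest(
        cls, manifest, clips: dict, split: str = "train", **kwargs
    ) -> "FlightCallModel":
        """Build from a manifest DataFrame and an id->AudioClip mapping."""
        sub = manifest[manifest["split"] == split]
        ids = [p.rsplit(".", 1)[0] for p in sub["path"]]
        return cls([clips[i] for i in ids], sub["label"].to_numpy(), **kwargs)

    def fit(self, seed: int = 0) -> "FlightCallResults":
        trained = train_model(
            self.clips,
            self.labels,
            self.hyperparams,
            config=self.config,
            seed=seed,
            learn_stride=self.learn_stride,
            encode_stride=self.encode_stride,
            max_patches=self.max_patches,
        )
        train_pred = _predict(trained, self.clips)
        train_acc = float(np.mean(train_pred.labels == self.labels))
        return FlightCallResults(model=self, trained=trained, train_accuracy=train_acc)


@dataclass
class FlightCallResults:
    """Fitted pipeline with diagnostics."""

    model: FlightCallModel
    trained: TrainedModel
    train_accuracy: float

    @property
    def classes_(self) -> np.ndarray:
        return self.trained.classes_

    @property
    def n_whitened_dims(self) -> int:
        return self.trained.whitening.n_components

    def predict(self, clips) -> PredictionResult:
        return _predict(self.trained, clips)

    def evaluate(self, clips, labels, positive_label=None) -> dict:
        """Test-set metrics: confusion/accuracy, plus ROC-AUC and PR
        curves when a positive label is given (binary regime)."""
        y = np.asarray(labels)
        pred = self.predict(clips)
        cm = confusion_and_accuracy(y, pred.labels, labels=sorted(set(y) | set(self.classes_)))
        out = {
            "confusion": cm,
            "accuracy": cm.overall_accuracy,
            "per_class_accuracy": cm.per_class_accuracy(),
        }
        if positive_label is not None:
            scores = pred.positive_probability(positive_label)
            y_bin = (y == positive_label).astype(int)
            out["roc"] = roc(scores, y_bin)
            out["auc"] = out["roc"].auc
            out["pr"] = pr(scores, y_bin)
            out["scores"] = scores
        return out

    def summary(self) -> str:
        hp = self.trained.hyperparams
        wt = self.trained.whitening
        lines = [
            "Flight-call codebook classifier",
            "=" * 47,
            f"{'Scenario':<28}{self.model.scenario:>19}",
            f"{'Training clips':<28}{len(self.model.clips):>19}",
            f"{'Classes':<28}{self.classes_.size:>19}",
            f"{'TF-patch duration (ms)':<28}{hp.d_patch_ms:>19.2f}",
            f"{'TF-patch frames':<28}{self.trained.patch_frames:>19}",
            f"{'Whitened dims (99% var)':<28}{wt.n_components:>19}",
            f"{'Codebook size k':<28}{hp.k:>19}",
            f"{'Pooling statistics':<28}{'+'.join(hp.f_stat.stats):>19}",
            f"{'Feature length k*l':<28}{hp.k * hp.f_stat.l:>19}",
            f"{'SVM penalty C':<28}{hp.C:>19.1f}",
            f"{'Support vectors':<28}{int(self.trained.svc.n_support_.sum()):>19}",
            f"{'Training accuracy':<28}{self.train_accuracy:>19.4f}",
            "=" * 47,
        ]
        return "\n".join(lines)
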