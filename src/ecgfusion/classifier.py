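"""High-level Model/Results interface over the full pipeline.

Mirrors the fit/results convention of statistical modelling packages: a
:class:`HeartbeatClassifier` is built from data (fused image stacks and
labels, or raw beats via :meth:`from_beats`), ``fit()`` trains the
residual FCA network and returns a :class:`ClassifierResults` carrying the
trained parameters, the training history, test-set predictions and a
``summary()`` table of the per-class metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balance import SmoteConfig, oversample
from .imaging import ImagingConfig, encode_beat
from .metrics import ClassMetrics, ConfusionMatrix, confusion, metrics
from .network import (
    ModelConfig,
    ResNetFca,
    TrainConfig,
    TrainHistory,
    predict,
    train,
)
from .preprocess import resample_beat

__all__ = ["HeartbeatClassifier", "ClassifierResults"]


class HeartbeatClassifier:
    """Multimodal ECG heartbeat classifier (RP/GAF/MTF fusion + FCA CNN).

    Parameters
    ----------
    x_train, y_train : fused image stacks (N, C, S, S) and integer labels.
    x_val, y_val : validation split used for best-checkpoint selection.
    model_config, train_config : architecture / optimisation settings.
    smote : optional :class:`SmoteConfig`; when given, Borderline-SMOTE is
        applied to the *training beats* (requires ``beats_train``), never
        to validation or test data.
    """

    def __init__(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.x_train = np.asarray(x_train, dtype=np.float32)
        self.y_train = np.asarray(y_train, dtype=np.int64)
        self.x_val = np.asarray(x_val, dtype=np.float32)
        self.y_val = np.asarray(y_val, dtype=np.int64)
        if len(self.x_train) != len(self.y_train):
            raise ValueError("x_train and y_train lengths differ")
        size = self.x_train.shape[-1]
        self.model_config = model_config or ModelConfig(image_size=size)
        if self.model_config.image_size != size:
            raise ValueError(
                f"model image_size {self.model_config.image_size} != data size {size}"
            )
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_beats(
        cls,
        beats_train: np.ndarray,
        y_train: np.ndarray,
        beats_val: np.ndarray,
        y_val: np.ndarray,
        image_size: int = 64,
        imaging: ImagingConfig | None = None,
        smote: SmoteConfig | None = None,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "HeartbeatClassifier":
        """Build from 1-D beat windows, optionally oversampling the
        training beats with Borderline-SMOTE before image encoding."""
        beats_train = np.asarray(beats_train, dtype=np.float64)
        y_train = np.asarray(y_train, dtype=np.int64)
        if smote is not None:
            beats_train, y_train = oversample(beats_train, y_train, smote)
        cfg = imaging or ImagingConfig()

        def render(beats):
            return np.stack(
                [
                    encode_beat(resample_beat(b, image_size), cfg).channels
                    for b in beats
                ]
            ).astype(np.float32)

        return cls(
            render(beats_train), y_train, render(beats_val), y_val,
            model_config=model_config
            or ModelConfig(image_size=image_size),
            train_config=train_config,
        )

    def fit(self, seed: int | None = None, verbose: bool = False) -> "ClassifierResults":
        """Train the network and return a results object.

        ``seed`` overrides ``train_config.seed`` and also seeds parameter
        initialisation, so a refit with the same seed is bit-identical.
        """
        tcfg = self.train_config
        if seed is not None:
            from dataclasses import replace
            tcfg = replace(tcfg, seed=seed)
        model = ResNetFca(self.model_config, seed=tcfg.seed)
        history = train(
            model, self.x_train, self.y_train, self.x_val, self.y_val,
            tcfg, verbose=verbose,
        )
        return ClassifierResults(model=model, history=history, classifier=self)


@dataclass
class ClassifierResults:
    """Trained model + history; evaluation hangs off this object."""

    model: ResNetFca
    history: TrainHistory
    classifier: HeartbeatClassifier
    _eval_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters()

    @property
    def best_val_accuracy(self) -> float:
        return self.history.val_accuracy[self.history.best_epoch]

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, argmax labels) in evaluation mode."""
        return predict(self.model, np.asarray(x, dtype=np.float32))

    def evaluate(self, x_test: np.ndarray, y_test: np.ndarray) -> ClassMetrics:
        """Confusion matrix + per-class metrics on a held-out test set."""
        y_test = np.asarray(y_test, dtype=np.int64)
        if len(x_test) == 0:
            raise ValueError("empty test set")
        _, labels = self.predict(x_test)
        cm = confusion(y_test, labels, self.model.config.n_classes)
        self._eval_cache["confusion"] = cm
        self._eval_cache["metrics"] = metrics(cm)
        return self._eval_cache["metrics"]

    @property
    def confusion_matrix(self) -> ConfusionMatrix:
        if "confusion" not in self._eval_cache:
            raise RuntimeError("call evaluate() first")
        return self._eval_cache["confusion"]

    def summary(self, include_q: bool = True) -> str:
        """Human-readable report: fit diagnostics + per-class test metrics."""
        lines = [
            "Multimodal ECG heartbeat classifier (RP/GAF/MTF + FCA ResNet)",
            f"parameters: {self.n_parameters:,}",
            f"epochs run: {len(self.history.train_loss)}  "
            f"best epoch: {self.history.best_epoch}  "
            f"best val acc: {self.best_val_accuracy:.4f}",
        ]
        if "metrics" in self._eval_cache:
            lines.append("")
            lines.append(self._eval_cache["metrics"].summary(include_q=include_q))
        return "\n".join(lines)
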