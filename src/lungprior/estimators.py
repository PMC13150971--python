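"""scikit-learn style estimators wrapping the two pipeline stages.

``EdgePriorExtractor`` is a stateless transformer: radiographs in,
five-plane channel stacks out.  ``FusionSegmenter`` is a fit/predict
segmenter over those stacks (selection -> learnable 1x1 mixer -> U-Net
family member).  Both compose with sklearn pipelines and model selection;
the module-level functions in :mod:`lungprior.harness` remain thin
functional equivalents.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import fusion, harness, interface
from .fusion import Combination, enumerate_combinations
from .params import HeuristicParams, default_params

__all__ = ["EdgePriorExtractor", "FusionSegmenter"]


def _combo_from_label(label: str) -> Combination:
    for combo in enumerate_combinations():
        if combo.label == label:
            return combo
    raise ValueError(f"unknown channel combination {label!r}")


class EdgePriorExtractor(BaseEstimator, TransformerMixin):
    """Training-free extraction of structural prior channels.

    Parameters
    ----------
    params : HeuristicParams, optional
        Heuristic constants; defaults follow the standard configuration.
    channel_size : int
        Side of the square channel planes (default 256).

    The transformer is stateless: ``fit`` only records the input count.
    """

    def __init__(self, params: HeuristicParams | None = None,
                 channel_size: int = 256):
        self.params = params
        self.channel_size = channel_size

    def fit(self, X, y=None):
        self.n_images_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Radiographs (sequence of 2-D arrays) to (n, 5, s, s) stacks."""
        p = self.params or default_params()
        stacks = []
        for img in X:
            res = interface.run_stage1(np.asarray(img, np.float64), p,
                                       channel_size=self.channel_size)
            stacks.append(res.channels.stack())
        return np.stack(stacks)

    def transform_single(self, img) -> interface.Stage1Result:
        """Full artifact bundle for one radiograph (for QC and inspection)."""
        p = self.params or default_params()
        return interface.run_stage1(np.asarray(img, np.float64), p,
                                    channel_size=self.channel_size)


class FusionSegmenter(BaseEstimator):
    """Early-fusion lung-field segmenter with a learnable channel mixer.

    Parameters mirror the training configuration: the channel combination
    (by label, e.g. ``"Io_cn2_log_pm"``), the architecture family, depth
    and base filter count, and the optimization settings.  ``fit`` expects
    ``X`` of shape (n, 5, s, s) — the output of
    :class:`EdgePriorExtractor` — and ``y`` of shape (n, s, s) binary.

    Attributes (after fit)
    ----------------------
    model_ : the trained :class:`lungprior.nn.FusionModel`
    mixer_weights_ : (3, 5) array, the learned 1x1 mixer weights
    loss_history_ : per-step training losses
    """

    def __init__(self, combo: str = "Io", family: str = "unet",
                 depth: int = 3, base_filters: int = 8,
                 learning_rate: float = 1e-4, epochs: int = 50,
                 batch_size: int = 4, max_steps: int | None = None,
                 input_size: int = 256, threshold: float = 0.5,
                 seed: int = 0):
        self.combo = combo
        self.family = family
        self.depth = depth
        self.base_filters = base_filters
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.input_size = input_size
        self.threshold = threshold
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _config(self) -> harness.TrainConfig:
        return harness.TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, input_size=self.input_size,
            seed=self.seed, threshold=self.threshold,
            max_steps=self.max_steps,
            model=harness.ModelSpec(self.family, self.depth,
                                    self.base_filters))

    @staticmethod
    def _validate(X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[1] != 5:
            raise ValueError(
                f"X must have shape (n, 5, s, s); got {X.shape}")
        if y is not None:
            y = np.asarray(y)
            if y.shape != (X.shape[0], X.shape[2], X.shape[3]):
                raise ValueError(
                    f"y shape {y.shape} does not match X {X.shape}")
            return X, y.astype(bool)
        return X

    def _as_dataset(self, X, y):
        data = []
        for i in range(X.shape[0]):
            cs = fusion.ChannelSet(image=X[i, 0], cn1=X[i, 1], cn2=X[i, 2],
                                   log=X[i, 3], pm=X[i, 4])
            data.append((cs, y[i]))
        return data

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate(X, y)
        if X.shape[2] != self.input_size:
            raise ValueError(
                f"channel stacks are {X.shape[2]}px but input_size is "
                f"{self.input_size}")
        combo = _combo_from_label(self.combo)
        seg = harness.train_model(self._config(), self._as_dataset(X, y),
                                  combo)
        self.model_ = seg.model
        self.segmenter_ = seg
        self.combo_ = combo
        self.mixer_weights_ = seg.model.mixer_w.data[:, :, 0, 0].copy()
        self.loss_history_ = list(seg.loss_history)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate(X)
        return self.segmenter_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate(X)
        return self.segmenter_.predict(X)

    def score(self, X, y) -> float:
        """Mean dice over the given stacks and reference masks."""
        X, y = self._validate(X, y)
        preds = self.segmenter_.predict(X)
        reports = [harness.pixel_metrics(preds[i], y[i])
                   for i in range(len(preds))]
        return float(np.mean([r.dice for r in reports]))

    def _check_fitted(self):
        if not hasattr(self, "segmenter_"):
            raise RuntimeError("FusionSegmenter is not fitted yet")
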