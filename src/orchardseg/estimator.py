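"""Scikit-learn-style estimator facade over the segmentation pipeline.

``OrchardSegmenter`` wraps model construction, training and inference in
the fit/predict idiom so the pipeline composes with sklearn tooling
(``get_params``/``set_params``, ``clone``, grid search over the exposed
hyperparameters).  ``fit`` consumes labelled :class:`ImageSample` lists,
``predict`` returns per-image :class:`Detection` lists, and ``score``
reports validation box mAP@50.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import ImageSample, SplitFractions, split_dataset
from .metrics import EvalReport, evaluate
from .model import ModelSpec, SegmentationModel
from .postprocess import Detection, segment_image
from .train import TrainConfig, train


class OrchardSegmenter(BaseEstimator):
    """Two-class (fruit, stem) instance segmenter.

    Parameters mirror the model / training configuration; fitted state
    lives in attributes with a trailing underscore (``model_``,
    ``curves_``).
    """

    def __init__(self, num_classes: int = 2, input_size: int = 640,
                 width_multiple: float = 1.0, depth_multiple: float = 1.0,
                 spatial_kernel: int = 7, epochs: int = 500, patience: int = 100,
                 batch_size: int = 8, lr0: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0005, conf: float = 0.25,
                 iou: float = 0.7, seed: int = 0, verbose: bool = False):
        self.num_classes = num_classes
        self.input_size = input_size
        self.width_multiple = width_multiple
        self.depth_multiple = depth_multiple
        self.spatial_kernel = spatial_kernel
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.conf = conf
        self.iou = iou
        self.seed = seed
        self.verbose = verbose

    @classmethod
    def tiny(cls, **kw) -> "OrchardSegmenter":
        """Quarter-width desk preset (CPU-trainable)."""
        kw.setdefault("width_multiple", 0.25)
        kw.setdefault("depth_multiple", 0.34)
        kw.setdefault("input_size", 320)
        return cls(**kw)

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(num_classes=self.num_classes, input_size=self.input_size,
                         width_multiple=self.width_multiple,
                         depth_multiple=self.depth_multiple,
                         spatial_kernel=self.spatial_kernel)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, patience=self.patience,
                           batch_size=self.batch_size, lr0=self.lr0,
                           momentum=self.momentum, weight_decay=self.weight_decay,
                           seed=self.seed)

    def fit(self, X: list[ImageSample], y=None,
            validation: list[ImageSample] | None = None,
            val_fraction: float = 0.125) -> "OrchardSegmenter":
        """Train on labelled samples; ``y`` is unused (labels travel with
        the samples).  Without an explicit validation list, a fraction is
        carved off deterministically."""
        X = list(X)
        if validation is None and val_fraction > 0 and len(X) >= 8:
            n_val = max(1, int(round(len(X) * val_fraction)))
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            validation = [X[i] for i in order[:n_val]]
            X = [X[i] for i in order[n_val:]]
        self.model_ = SegmentationModel(self._model_spec(), seed=self.seed)
        best, curves = train(self.model_, X, validation or [],
                             self._train_config(), verbose=self.verbose)
        self.model_.load_state_dict(best)
        self.curves_ = curves
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() or load()")

    def predict(self, X) -> list[list[Detection]]:
        """Segment each raster / sample; returns per-image detections."""
        self._require_fitted()
        out = []
        for item in X:
            raster = item.image if isinstance(item, ImageSample) else np.asarray(item)
            out.append(segment_image(self.model_, raster, conf=self.conf,
                                     iou=self.iou))
        return out

    def evaluate(self, X: list[ImageSample], conf: float = 0.001) -> EvalReport:
        """Metric report over labelled samples.

        AP is a confidence-sweep metric, so evaluation decodes at a very
        low threshold (``conf``) rather than the deployment threshold
        used by :meth:`predict`.
        """
        self._require_fitted()
        dets = [segment_image(self.model_, s.image, conf=conf, iou=self.iou)
                for s in X]
        return evaluate(dets, X)

    def score(self, X: list[ImageSample], y=None) -> float:
        """Box mAP@50 over all classes (sklearn score contract)."""
        rep = self.evaluate(X)
        return rep.box["All"].ap50 if "All" in rep.box else 0.0

    def save(self, path) -> None:
        self._require_fitted()
        self.model_.save(path)

    def load(self, path) -> "OrchardSegmenter":
        self.model_ = SegmentationModel.load(path)
        spec = self.model_.spec
        self.input_size = spec.input_size
        self.num_classes = spec.num_classes
        self.width_multiple = spec.width_multiple
        self.depth_multiple = spec.depth_multiple
        self.spatial_kernel = spec.spatial_kernel
        return self


def train_test_val_split(samples, fractions: SplitFractions | None = None,
                         seed: int = 0):
    """Convenience re-export of the dataset splitter."""
    return split_dataset(samples, fractions, seed)
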