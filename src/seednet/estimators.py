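"""scikit-learn style estimators wrapping the network and the segmenter.

``SeedClassifier`` is the front door for classification: construct with the
architecture toggles and training hyperparameters, ``fit`` on images, then
``predict`` / ``predict_proba`` / ``score``. It follows the scikit-learn
estimator contract (get_params/set_params, clone-ability, fitted attributes
with a trailing underscore) so it composes with sklearn model selection.
Images are (N, H, W, 3) uint8 arrays; a flattened 2-D matrix of pixels is
also accepted when ``image_size`` is set, for plumbing through sklearn
utilities that insist on 2-D X.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .network_builder import (DEFAULT_PLAN, NetworkPlan, SeedNet,
                              VariantConfig, build_model, softmax)
from .segmentation import SegmentationParams, segment_scene
from .training_eval import (TrainConfig, evaluate, predict_logits, train)

__all__ = ["SeedClassifier", "SceneSegmenter"]


class SeedClassifier(ClassifierMixin, BaseEstimator):
    """Residual-network image classifier for single-seed crops.

    Parameters mirror the ablation toggles and the training protocol.
    Fitted attributes: ``model_`` (the network), ``classes_``,
    ``history_`` (per-epoch loss/accuracy), ``n_features_in_`` when fitted
    on 2-D input.
    """

    def __init__(self, resstage: bool = True, improved_block: bool = True,
                 mixed_activation: bool = True, epochs: int = 150,
                 batch_size: int = 32, learning_rate: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 0.0005,
                 image_size: Optional[int] = None,
                 plan: Optional[NetworkPlan] = None, random_state: int = 0):
        self.resstage = resstage
        self.improved_block = improved_block
        self.mixed_activation = mixed_activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.image_size = image_size
        self.plan = plan
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _as_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 4:
            return X
        if X.ndim == 2:
            if self.image_size is None:
                raise ValueError("2-D X requires image_size to reshape")
            s = self.image_size
            return X.reshape(len(X), s, s, 3)
        raise ValueError("X must be (N, H, W, 3) images or a 2-D matrix")

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           rng_seed=self.random_state)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y) -> "SeedClassifier":
        images = self._as_images(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if np.asarray(X).ndim == 2:
            self.n_features_in_ = np.asarray(X).shape[1]
        cfg = VariantConfig(use_resstage=self.resstage,
                            use_improved_block=self.improved_block,
                            use_mixed_activation=self.mixed_activation,
                            num_classes=len(self.classes_),
                            input_size=max(32, images.shape[1]))
        rng = np.random.default_rng(self.random_state)
        self.model_ = build_model(cfg, plan=self.plan or DEFAULT_PLAN, rng=rng)
        self.history_ = train(self.model_, images, y_enc,
                              self._train_config())
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_logits(self.model_, self._as_images(X),
                              batch_size=self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]

    def evaluate(self, X, y):
        """Confusion matrix and per-class precision/recall/F1."""
        check_is_fitted(self, "model_")
        y = np.asarray(y)
        y_enc = np.searchsorted(self.classes_, y)
        return evaluate(self.model_, self._as_images(X), y_enc,
                        batch_size=self.batch_size)


class SceneSegmenter(TransformerMixin, BaseEstimator):
    """Transformer: multi-seed scene images -> lists of single-seed crops."""

    def __init__(self, threshold: str = "otsu_auto", fixed_threshold: int = 128,
                 morph_open_radius: int = 3, morph_close_radius: int = 3,
                 min_area: int = 400, crop_size: int = 224,
                 background_fill: int = 0):
        self.threshold = threshold
        self.fixed_threshold = fixed_threshold
        self.morph_open_radius = morph_open_radius
        self.morph_close_radius = morph_close_radius
        self.min_area = min_area
        self.crop_size = crop_size
        self.background_fill = background_fill

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            threshold=self.threshold, fixed_threshold=self.fixed_threshold,
            morph_open_radius=self.morph_open_radius,
            morph_close_radius=self.morph_close_radius,
            min_area=self.min_area, crop_size=self.crop_size,
            background_fill=self.background_fill)

    def fit(self, X=None, y=None) -> "SceneSegmenter":
        self.params_ = self._params()   # validates
        return self

    def transform(self, X) -> List[list]:
        params = self._params()
        scenes = [X] if (isinstance(X, np.ndarray) and X.ndim == 3) else X
        return [segment_scene(np.asarray(scene), params,
                              source_id=f"scene{i:04d}")
                for i, scene in enumerate(scenes)]
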