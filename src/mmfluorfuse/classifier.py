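"""Scikit-learn estimator facade over the multimodal network.

``MmVitnNetClassifier`` exposes the gated image-text network through the
familiar fit/predict surface so it composes with sklearn model selection.
``X`` is the pair ``(images, text)``: images ``(n, S, S, 3)`` in [0, 1]
(S = model img_size) and text ``(n, k)`` reduced parameter features; ``y``
are the 1-based salt-tolerance levels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import MmVitnNet, ModelConfig
from .training import TrainConfig, class_weights, load_state, train, _predict_logits


def _unpack(X):
    if isinstance(X, dict):
        return np.asarray(X["image"], float), np.asarray(X["text"], float)
    images, text = X
    return np.asarray(images, float), np.asarray(text, float)


class MmVitnNetClassifier(ClassifierMixin, BaseEstimator):
    """Gated image-text attention classifier with an sklearn interface.

    Parameters
    ----------
    model_config : ModelConfig or None
        Architecture; defaults to the standard configuration
        (depths (1,3,3,1), widths (64,128,256,512), variant "ai", k=6).
    train_config : TrainConfig or None
        Optimization settings (batch 32, 200 epochs, cosine 1e-4 -> 1e-6).
    class_weighting : bool, default True
        Use inverse-frequency class weights in the loss.
    seed : int, default 0
        Controls weight initialization and batch shuffling.

    Attributes
    ----------
    model_ : the fitted network (best-validation weights restored)
    classes_ : sorted class levels seen in ``y``
    history_ : per-epoch log DataFrame
    class_weights_ : the loss weights used (or None)
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 class_weighting: bool = True, seed: int = 0):
        self.model_config = model_config
        self.train_config = train_config
        self.class_weighting = class_weighting
        self.seed = seed

    def fit(self, X, y, validation_data=None):
        images, text = _unpack(X)
        y = np.asarray(y, dtype=int)
        if len(images) != len(y) or len(text) != len(y):
            raise ValueError("images, text and y must have equal length")
        cfg = self.model_config or ModelConfig()
        tcfg = self.train_config or TrainConfig()
        if tcfg.seed != self.seed:
            tcfg = TrainConfig(batch_size=tcfg.batch_size, epochs=tcfg.epochs,
                               lr_max=tcfg.lr_max, lr_min=tcfg.lr_min,
                               seed=self.seed)
        self.classes_ = np.arange(1, cfg.n_classes + 1)
        weights = None
        if self.class_weighting:
            counts = np.array([(y == c).sum() for c in self.classes_])
            weights = np.where(counts > 0, 1.0, 0.0)
            present = counts > 0
            w = class_weights(counts[present])
            weights[present] = w
        self.class_weights_ = weights
        self.model_ = MmVitnNet(cfg, seed=self.seed)
        val = None
        if validation_data is not None:
            v_X, v_y = validation_data
            v_img, v_txt = _unpack(v_X)
            val = (v_img, v_txt, np.asarray(v_y, dtype=int))
        best_state, self.history_ = train(self.model_, (images, text, y), val,
                                          tcfg, weights)
        load_state(self.model_, best_state)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        images, text = _unpack(X)
        return _predict_logits(self.model_, images, text)

    def predict_proba(self, X):
        return _softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
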