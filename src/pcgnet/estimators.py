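"""scikit-learn style estimator facade.

`PCGNetSegmenter` wraps model construction and supervised training behind
the familiar ``fit(X, y) / predict(X)`` contract (X: (N, H, W) grayscale
slices, y: (N, H, W) integer label maps), so the network composes with
sklearn model-selection utilities; `ContrastivePretrainer` wraps the Siamese
pretraining stage as a ``fit(X) / transform(X)`` feature learner whose fitted
encoder weights can seed a segmenter.

These classes are thin: all of the science lives in :mod:`pcgnet.decoder`,
:mod:`pcgnet.training` and friends.
"""

from __future__ import annotations

import numpy as onp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .decoder import ModelConfig, init_model, pcgnet_forward, predict_label
from .encoder import EncoderConfig
from .metrics import dsc
from .phantoms import PhantomSample
from .training import (
    PretrainConfig,
    TrainConfig,
    _encode_pooled,
    pretrain,
    train,
    transfer,
)


def _as_image_array(X):
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], PhantomSample):
        X = onp.stack([s.image for s in X])
    X = onp.asarray(X, dtype=onp.float32)
    if X.ndim != 3:
        raise ValueError(f"expected (N, H, W) images, got shape {X.shape}")
    return X


class PCGNetSegmenter(BaseEstimator):
    """Multi-structure 2-D segmentation with the parallel-encoder graph network.

    Parameters mirror the scaled-down study conditions by default; pass
    ``level`` to build any ablation variant (baseline, level1..level5).

    Attributes (after ``fit``): ``model_params_``, ``bn_state_`` (the
    best-validation checkpoint), ``history_`` (per-epoch trace),
    ``best_val_dsc_``, ``n_classes_``.
    """

    def __init__(
        self,
        level: str = "level5",
        image_size: int = 48,
        num_classes: int = 6,
        stage_channels: tuple = (8, 16, 32, 64),
        heads: tuple = (2, 2, 2, 2),
        gat_blocks: int = 1,
        cgm_nodes: int = 2,
        cgm_rates: tuple = (1, 2),
        cgm_steps: int = 2,
        decoder_width: int = 16,
        epochs: int = 15,
        batch_size: int = 4,
        lr: float = 5e-3,
        weight_decay: float = 1e-4,
        bn_momentum: float = 0.8,
        val_fraction: float = 0.25,
        seed: int = 0,
        init_encoder_weights=None,
    ):
        self.level = level
        self.image_size = image_size
        self.num_classes = num_classes
        self.stage_channels = stage_channels
        self.heads = heads
        self.gat_blocks = gat_blocks
        self.cgm_nodes = cgm_nodes
        self.cgm_rates = cgm_rates
        self.cgm_steps = cgm_steps
        self.decoder_width = decoder_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.bn_momentum = bn_momentum
        self.val_fraction = val_fraction
        self.seed = seed
        self.init_encoder_weights = init_encoder_weights

    # -- config plumbing ----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            image_size=self.image_size,
            num_classes=self.num_classes,
            level=self.level,
            stage_channels=tuple(self.stage_channels),
            heads=tuple(self.heads),
            gat_blocks=self.gat_blocks,
            cgm_nodes=self.cgm_nodes,
            cgm_rates=tuple(self.cgm_rates),
            cgm_steps=self.cgm_steps,
            decoder_width=self.decoder_width,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            weight_decay=self.weight_decay,
            bn_momentum=self.bn_momentum,
            seed=self.seed,
        )

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (N, H, W) images and integer label maps.

        Without an explicit validation set the trailing ``val_fraction`` of
        the data is held out (the split is deterministic).
        """
        X = _as_image_array(X)
        y = onp.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"X {X.shape} and y {y.shape} must align")
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            X, X_val = X[:-n_val], X[-n_val:]
            y, y_val = y[:-n_val], y[-n_val:]
        else:
            X_val = _as_image_array(X_val)
            y_val = onp.asarray(y_val)

        mc = self._model_config()
        tr = [PhantomSample(image=X[i], label=y[i].astype(onp.int16)) for i in range(X.shape[0])]
        va = [
            PhantomSample(image=X_val[i], label=y_val[i].astype(onp.int16))
            for i in range(X_val.shape[0])
        ]
        init_params = None
        if self.init_encoder_weights is not None:
            rng = onp.random.default_rng(self.seed)
            fresh = init_model(rng, mc)
            init_params, self.transfer_manifest_ = transfer(self.init_encoder_weights, fresh)
        result = train(tr, va, self._train_config(), mc, init_params=init_params)
        self.model_params_ = result["best_params"] or result["params"]
        self.bn_state_ = result["best_bn"] or result["bn"]
        self.final_params_ = result["params"]
        self.history_ = result["trace"]
        self.best_val_dsc_ = result["best_val_dsc"]
        self.n_classes_ = self.num_classes
        return self

    def predict(self, X):
        """Predicted integer label maps, (N, H, W)."""
        check_is_fitted(self, "model_params_")
        X = _as_image_array(X)[:, None]
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            out.append(
                predict_label(self.model_params_, X[start : start + self.batch_size], self._model_config(), self.bn_state_)
            )
        return onp.concatenate(out, axis=0)

    def predict_proba(self, X):
        """Class-probability maps at full resolution, (N, M, H, W)."""
        check_is_fitted(self, "model_params_")
        X = _as_image_array(X)[:, None]
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            probs = pcgnet_forward(
                self.model_params_, X[start : start + self.batch_size], self._model_config(), self.bn_state_, training=False
            )
            out.append(onp.asarray(probs[-1]))
        return onp.concatenate(out, axis=0)

    def score(self, X, y):
        """Mean DSC over the non-background structures (macro average)."""
        pred = self.predict(X)
        y = onp.asarray(y)
        vals = []
        for m in range(1, self.num_classes):
            per = [dsc(pred[i] == m, y[i] == m)[0] for i in range(pred.shape[0])]
            vals.append(onp.mean(per))
        return float(onp.mean(vals))


class ContrastivePretrainer(BaseEstimator, TransformerMixin):
    """Siamese stop-gradient pretraining of the parallel encoder.

    ``fit`` consumes unlabeled (N, H, W) images; the fitted
    ``encoder_weights_`` can be handed to :class:`PCGNetSegmenter` via
    ``init_encoder_weights``.  ``transform`` returns pooled encoder features.
    """

    def __init__(
        self,
        image_size: int = 48,
        stage_channels: tuple = (8, 16, 32, 64),
        heads: tuple = (2, 2, 2, 2),
        gat_blocks: int = 1,
        epochs: int = 10,
        batch_size: int = 8,
        base_lr: float = 0.05,
        projector_dim: int = 32,
        seed: int = 0,
    ):
        self.image_size = image_size
        self.stage_channels = stage_channels
        self.heads = heads
        self.gat_blocks = gat_blocks
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.projector_dim = projector_dim
        self.seed = seed

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            image_size=self.image_size,
            stage_channels=tuple(self.stage_channels),
            heads=tuple(self.heads),
            gat_blocks=self.gat_blocks,
        )

    def fit(self, X, y=None):
        cfg = PretrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            base_lr=self.base_lr,
            projector_dim=self.projector_dim,
            projector_hidden=2 * self.projector_dim,
            predictor_hidden=max(8, self.projector_dim // 2),
            seed=self.seed,
        )
        weights, result = pretrain(X, cfg, self._encoder_config())
        self.encoder_weights_ = weights
        self.loss_trace_ = result["loss_trace"]
        self.embedding_std_ = result["z_std"]
        self.bn_state_ = result["bn_state"]
        return self

    def transform(self, X):
        """Pooled deepest-stage encoder features, (N, 2*C_4)."""
        check_is_fitted(self, "encoder_weights_")
        X = _as_image_array(X)[:, None]
        feats = _encode_pooled(self.encoder_weights_, X, self._encoder_config(), self.bn_state_, False)
        return onp.asarray(feats)
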