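"""Scikit-learn style estimators wrapping the two training stages.

``MaskedCytometryPretrainer`` fits the self-supervised stage (embedding +
encoder + heteroscedastic heads) on unlabelled samples;
``CytometrySetClassifier`` fits the cross-attention decoder on sample
labels, optionally on top of a fitted pretrainer whose encoder stays
frozen.  Both follow the sklearn contract: constructor arguments are
hyperparameters stored verbatim (``get_params``/``set_params`` work, the
estimators clone cleanly), fitted state lives in trailing-underscore
attributes, and ``X`` is a list of :class:`~cytoset.core.CytometrySample`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import CytometrySample, MarkerVocabulary
from .interpret import AttributionRecord, extract_attention
from .masking import MaskDistributionConfig
from .model import CytoTransformer, ModelConfig
from .train import (DownstreamConfig, PretrainConfig, PretrainLossConfig,
                    predict_proba, run_downstream, run_pretraining)

__all__ = ["MaskedCytometryPretrainer", "CytometrySetClassifier"]


def _infer_vocabulary(X: list[CytometrySample]) -> MarkerVocabulary:
    markers = sorted({m for s in X for m in s.measured_markers})
    return MarkerVocabulary(markers)


class MaskedCytometryPretrainer(BaseEstimator):
    """Self-supervised masked-prediction pretraining of the cell encoder.

    Parameters mirror the training configuration: model size, masking Beta
    parameters, loss weights, and optimisation settings.  ``fit`` ignores
    ``y``.  Fitted attributes: ``model_`` (the transformer with trained
    embedding/encoder/heads), ``vocabulary_``, ``history_``.
    """

    def __init__(self, vocabulary=None, hidden_size=128, encoder_layers=4,
                 heads=4, feedforward_multiplier=4, projection_depth=1,
                 epochs=10, lr=1e-3, weight_decay=0.01, sigma=0.05,
                 cell_cap=5000, cells_per_step=None, beta_unmasked=0.1,
                 drop_alpha=1.0, drop_beta=9.0, uniform_alpha=2.0,
                 uniform_beta=6.0, markerwise_alpha=2.0, markerwise_beta=6.0,
                 validation_fraction=0.1, cache_dir=None, random_state=0):
        self.vocabulary = vocabulary
        self.hidden_size = hidden_size
        self.encoder_layers = encoder_layers
        self.heads = heads
        self.feedforward_multiplier = feedforward_multiplier
        self.projection_depth = projection_depth
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.sigma = sigma
        self.cell_cap = cell_cap
        self.cells_per_step = cells_per_step
        self.beta_unmasked = beta_unmasked
        self.drop_alpha = drop_alpha
        self.drop_beta = drop_beta
        self.uniform_alpha = uniform_alpha
        self.uniform_beta = uniform_beta
        self.markerwise_alpha = markerwise_alpha
        self.markerwise_beta = markerwise_beta
        self.validation_fraction = validation_fraction
        self.cache_dir = cache_dir
        self.random_state = random_state

    def _model_config(self, decoder_layers: int = 0) -> ModelConfig:
        return ModelConfig(hidden_size=self.hidden_size,
                           encoder_layers=self.encoder_layers,
                           decoder_layers=decoder_layers,
                           heads=self.heads,
                           feedforward_multiplier=self.feedforward_multiplier,
                           projection_depth=self.projection_depth)

    def fit(self, X: list[CytometrySample], y=None) -> "MaskedCytometryPretrainer":
        vocab = self.vocabulary
        if vocab is None:
            vocab = _infer_vocabulary(X)
        elif not isinstance(vocab, MarkerVocabulary):
            vocab = MarkerVocabulary(vocab)
        self.vocabulary_ = vocab
        self.model_ = CytoTransformer(vocab, self._model_config(decoder_layers=0),
                                      n_outputs=1, seed=self.random_state)
        config = PretrainConfig(
            epochs=self.epochs, lr=self.lr, weight_decay=self.weight_decay,
            cell_cap=self.cell_cap, cells_per_step=self.cells_per_step,
            sigma=self.sigma, validation_fraction=self.validation_fraction,
            mask=MaskDistributionConfig(self.drop_alpha, self.drop_beta,
                                        self.uniform_alpha, self.uniform_beta,
                                        self.markerwise_alpha, self.markerwise_beta),
            loss=PretrainLossConfig(beta_unmasked=self.beta_unmasked),
        )
        self.history_ = run_pretraining(list(X), self.model_, config,
                                        seed=self.random_state,
                                        cache_dir=self.cache_dir)
        return self


class CytometrySetClassifier(BaseEstimator, ClassifierMixin):
    """Sample-level classifier: cross-attention pooling over encoded cells.

    With a fitted ``pretrainer``, the embedding/encoder (and its
    architecture) are taken from it and frozen by default; without one the
    whole network trains end-to-end from random initialisation
    ("encoder not pretrained"), or with ``encoder_layers=0`` the decoder
    pools the cell embeddings directly ("decoder only").

    Fitted attributes: ``classes_``, ``model_``, ``history_``.
    """

    def __init__(self, pretrainer=None, vocabulary=None, hidden_size=128,
                 encoder_layers=4, decoder_layers=4, heads=4,
                 feedforward_multiplier=4, projection_depth=1, epochs=150,
                 lr=1e-3, weight_decay=0.01, batch_size=10,
                 marker_dropout_rate=0.1, freeze_encoder=True,
                 standardize_latents=True, validation_fraction=0.1, patience=20,
                 cell_cap=7000, cells_per_step=None, random_state=0):
        self.pretrainer = pretrainer
        self.vocabulary = vocabulary
        self.hidden_size = hidden_size
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.heads = heads
        self.feedforward_multiplier = feedforward_multiplier
        self.projection_depth = projection_depth
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.marker_dropout_rate = marker_dropout_rate
        self.freeze_encoder = freeze_encoder
        self.standardize_latents = standardize_latents
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.cell_cap = cell_cap
        self.cells_per_step = cells_per_step
        self.random_state = random_state

    def _build_model(self, X, n_classes: int) -> CytoTransformer:
        pre = self.pretrainer
        if pre is not None:
            if not hasattr(pre, "model_"):
                raise ValueError("pretrainer must be fitted before the classifier")
            src: CytoTransformer = pre.model_
            model = CytoTransformer(src.vocabulary, ModelConfig(
                hidden_size=src.config.hidden_size,
                encoder_layers=src.config.encoder_layers,
                decoder_layers=self.decoder_layers,
                heads=src.config.heads,
                feedforward_multiplier=src.config.feedforward_multiplier,
                projection_depth=src.config.projection_depth,
            ), n_outputs=n_classes, seed=self.random_state)
            for p_dst, p_src in zip(model.pretrain_parameters(),
                                    src.pretrain_parameters()):
                p_dst.data = p_src.data.copy()
            return model
        vocab = self.vocabulary
        if vocab is None:
            vocab = _infer_vocabulary(X)
        elif not isinstance(vocab, MarkerVocabulary):
            vocab = MarkerVocabulary(vocab)
        config = ModelConfig(hidden_size=self.hidden_size,
                             encoder_layers=self.encoder_layers,
                             decoder_layers=self.decoder_layers,
                             heads=self.heads,
                             feedforward_multiplier=self.feedforward_multiplier,
                             projection_depth=self.projection_depth)
        return CytoTransformer(vocab, config, n_outputs=n_classes,
                               seed=self.random_state)

    def fit(self, X: list[CytometrySample], y) -> "CytometrySetClassifier":
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("classification requires at least two classes")
        self.model_ = self._build_model(X, len(self.classes_))
        # freezing only makes sense when there is a pretrained encoder to preserve
        freeze = self.freeze_encoder and self.pretrainer is not None
        config = DownstreamConfig(
            epochs=self.epochs, lr=self.lr, weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            marker_dropout_rate=self.marker_dropout_rate, freeze_encoder=freeze,
            standardize_latents=self.standardize_latents,
            validation_fraction=self.validation_fraction, patience=self.patience,
            cell_cap=self.cell_cap, cells_per_step=self.cells_per_step,
        )
        self.history_ = run_downstream(list(X), y_idx, self.model_, config,
                                       seed=self.random_state)
        return self

    def predict_proba(self, X: list[CytometrySample]) -> np.ndarray:
        return np.vstack([predict_proba(self.model_, s, cell_cap=self.cell_cap,
                                        seed=self.random_state) for s in X])

    def predict(self, X: list[CytometrySample]) -> np.ndarray:
        proba = self.predict_proba(X)
        if len(self.classes_) == 2:
            idx = (proba[:, 1] >= 0.5).astype(int)  # fixed 0.5 decision threshold
        else:
            idx = proba.argmax(axis=1)
        return self.classes_[idx]

    def attention(self, sample: CytometrySample) -> AttributionRecord:
        """Per-cell attention attribution for one sample (pure read-out)."""
        return extract_attention(sample, self.model_)
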