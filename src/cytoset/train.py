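"""Two-stage training: masked-prediction pretraining and downstream fitting.

Stage 1 (self-supervised) optimises the cell embedding, the encoder and the
three heteroscedastic heads with a Gaussian negative log-likelihood on the
dual masked views of each sample; masked entries carry full weight and
unmasked measured entries a regularisation weight ``beta < 1``, while
unmeasured vocabulary slots contribute nothing.

Stage 2 trains the cross-attention decoder and task head on sample labels
(cross-entropy for classification, squared error for regression) with the
embedding/encoder frozen by default and a fixed-rate marker-wise input
dropout standing in for neuron dropout.

Also here: AdamW with cosine decay, grouped/stratified split construction,
and the evaluation metrics (accuracy, macro-F1, one-vs-rest macro AUC).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedGroupKFold, StratifiedKFold

from ._autodiff import Parameter, Tensor, log_softmax
from .core import CytometrySample
from .io import sample_seed, subsample_cells
from .masking import (MARKER_WISE, UNIFORM_RANDOM, MaskDistributionConfig,
                      MaskedView, make_views)
from .model import CytoTransformer, EncoderOutput, ModelConfig, PretrainHeadOutput
from .targets import DEFAULT_SIGMA, PretrainTargets, precompute_targets

logger = logging.getLogger(__name__)

__all__ = ["PretrainLossConfig", "PretrainConfig", "DownstreamConfig", "AdamW",
           "gnll", "pretrain_loss", "cross_entropy", "run_pretraining",
           "run_downstream", "predict_proba", "compute_metrics", "make_splits",
           "cross_validate"]

LOG_2PI = math.log(2.0 * math.pi)
PRETRAIN_CELL_CAP = 5000
DOWNSTREAM_CELL_CAP = 7000


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def gnll(target, mean, variance) -> Tensor:
    """Gaussian negative log-likelihood, averaged over entries.

    ``mean over entries of 0.5*[log var + (target - mean)^2 / var] +
    0.5*log(2*pi)`` — the constant is included so the value is the actual
    negative log-density; it does not affect gradients.
    """
    if not isinstance(mean, Tensor):
        mean = Tensor(mean)
    if not isinstance(variance, Tensor):
        variance = Tensor(variance)
    target = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    if np.any(variance.data <= 0):
        raise ValueError("gnll requires strictly positive variances")
    if target.shape != mean.shape or mean.shape != variance.shape:
        raise ValueError("gnll inputs must share a shape")
    resid = Tensor(target) - mean
    per_entry = (variance.log() + resid * resid / variance) * 0.5
    return per_entry.mean() + 0.5 * LOG_2PI


@dataclass
class PretrainLossConfig:
    beta_unmasked: float = 0.1
    w_x: float = 1.0
    w_p: float = 1.0
    w_d: float = 1.0
    w_uniform: float = 0.5
    w_markerwise: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.beta_unmasked < 1.0:
            raise ValueError("beta_unmasked must be in [0, 1)")
        for name in ("w_x", "w_p", "w_d", "w_uniform", "w_markerwise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_TARGET_FIELDS = {
    "X": ("expression", "expr_mean", "expr_var"),
    "P": ("percentile", "pct_mean", "pct_var"),
    "D": ("density", "dens_mean", "dens_var"),
}


def _class_gnll(targets: PretrainTargets, head: PretrainHeadOutput,
                rows: np.ndarray, sample_cols: np.ndarray, slot_cols: np.ndarray,
                target_key: str) -> Tensor | float:
    tname, mname, vname = _TARGET_FIELDS[target_key]
    if rows.size == 0:
        return 0.0
    t = getattr(targets, tname)[rows, sample_cols]
    mean = getattr(head, mname)[rows, slot_cols]
    var = getattr(head, vname)[rows, slot_cols]
    return gnll(t, mean, var)


def pretrain_loss(sample_targets: PretrainTargets,
                  views: dict[str, MaskedView],
                  head_outputs: dict[str, PretrainHeadOutput],
                  config: PretrainLossConfig,
                  measured_slots: np.ndarray) -> tuple[Tensor, dict[str, float]]:
    """Dual-view, three-target masked GNLL objective.

    ``measured_slots[j]`` is the vocabulary slot of the sample's j-th
    measured marker; head outputs span all vocabulary slots but only
    measured, non-dropped entries ever enter a component.  Returns the
    scalar loss and the 12-component breakdown
    ``{pattern}.{target}.{masked|unmasked}``.
    """
    measured_slots = np.asarray(measured_slots)
    pattern_w = {UNIFORM_RANDOM: config.w_uniform, MARKER_WISE: config.w_markerwise}
    target_w = {"X": config.w_x, "P": config.w_p, "D": config.w_d}
    total: Tensor | float = 0.0
    breakdown: dict[str, float] = {}
    for pattern in (UNIFORM_RANDOM, MARKER_WISE):
        view = views[pattern]
        head = head_outputs[pattern]
        masked, unmasked, _dropped = view.entry_classes()
        if not masked.any():
            logger.warning("view %s has no masked entries; masked term is 0", pattern)
        for tkey in ("X", "P", "D"):
            for cls_name, cls_mask, weight in (
                ("masked", masked, 1.0),
                ("unmasked", unmasked, config.beta_unmasked),
            ):
                rows, cols = np.nonzero(cls_mask)
                comp = _class_gnll(sample_targets, head, rows, cols,
                                   measured_slots[cols], tkey)
                value = comp.data.item() if isinstance(comp, Tensor) else float(comp)
                breakdown[f"{pattern}.{tkey}.{cls_name}"] = value
                total = total + comp * (pattern_w[pattern] * target_w[tkey] * weight)
    if not isinstance(total, Tensor):
        total = Tensor(total)
    return total, breakdown


def breakdown_weights(config: PretrainLossConfig) -> dict[str, float]:
    """Weight applied to each of the 12 logged components in the total."""
    pattern_w = {UNIFORM_RANDOM: config.w_uniform, MARKER_WISE: config.w_markerwise}
    target_w = {"X": config.w_x, "P": config.w_p, "D": config.w_d}
    out = {}
    for pattern, pw in pattern_w.items():
        for tkey, tw in target_w.items():
            out[f"{pattern}.{tkey}.masked"] = pw * tw
            out[f"{pattern}.{tkey}.unmasked"] = pw * tw * config.beta_unmasked
    return out


def cross_entropy(scores: Tensor, label_index: int) -> Tensor:
    return -log_softmax(scores, axis=-1)[int(label_index)]


def squared_error(score: Tensor, target: float) -> Tensor:
    resid = score - float(target)
    return (resid * resid).mean()


# --------------------------------------------------------------------------
# Optimiser
# --------------------------------------------------------------------------

class AdamW:
    """AdamW with global-norm gradient clipping; lr may vary per step."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01, clip_norm: float = 1.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm:
            norm = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if norm > self.clip_norm:
                grads = [g * (self.clip_norm / norm) for g in grads]
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= lr * (update + self.weight_decay * p.data)


def cosine_lr(step: int, total_steps: int, base_lr: float, min_frac: float = 0.05) -> float:
    if total_steps <= 1:
        return base_lr
    frac = min(step / (total_steps - 1), 1.0)
    return base_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + math.cos(math.pi * frac)))


# --------------------------------------------------------------------------
# Pretraining
# --------------------------------------------------------------------------

@dataclass
class PretrainConfig:
    epochs: int = 10
    lr: float = 1e-3
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    cell_cap: int = PRETRAIN_CELL_CAP
    cells_per_step: int | None = None   # rows drawn per optimisation step
    sigma: float = DEFAULT_SIGMA
    validation_fraction: float = 0.1
    mask: MaskDistributionConfig = field(default_factory=MaskDistributionConfig)
    loss: PretrainLossConfig = field(default_factory=PretrainLossConfig)


def _step_rows(n: int, cells_per_step: int | None, rng: np.random.Generator) -> np.ndarray:
    if cells_per_step is None or n <= cells_per_step:
        return np.arange(n)
    return np.sort(rng.choice(n, size=cells_per_step, replace=False))


def _view_loss(model: CytoTransformer, sample: CytometrySample,
               targets: PretrainTargets, rows: np.ndarray,
               mask_cfg: MaskDistributionConfig, loss_cfg: PretrainLossConfig,
               seed: int, epoch: int) -> tuple[Tensor, dict[str, float]]:
    events = sample.events[rows]
    uni, mw = make_views(events, mask_cfg, seed, sample.sample_id, epoch)
    views = {UNIFORM_RANDOM: uni, MARKER_WISE: mw}
    sub = replace(sample, events=events)
    heads = {}
    for pattern, view in views.items():
        latent = model.encode(sub, per_cell_mask=view.mask)
        heads[pattern] = model.pretrain_heads(latent)
    row_targets = PretrainTargets(targets.expression[rows], targets.percentile[rows],
                                  targets.density[rows], targets.sigma)
    slots = model.vocabulary.slots(sample.measured_markers)
    return pretrain_loss(row_targets, views, heads, loss_cfg, slots)


def run_pretraining(samples: list[CytometrySample], model: CytoTransformer,
                    config: PretrainConfig | None = None, seed: int = 0,
                    cache_dir=None) -> dict:
    """Optimise embedding + encoder + heads on the dual-masking objective.

    Returns a history record; the model is updated in place and left at
    the parameters with the best validation loss (training loss when the
    corpus is too small for a validation split).
    """
    config = config or PretrainConfig()
    if not samples:
        raise ValueError("pretraining corpus is empty")
    prepared = []
    for s in samples:
        sub, tgt = precompute_targets(s, sigma=config.sigma, max_cells=config.cell_cap,
                                      seed=seed, cache_dir=cache_dir)
        prepared.append((sub, tgt))

    order_rng = sample_seed(seed, "pretrain-order")
    n_val = int(round(config.validation_fraction * len(prepared)))
    n_val = min(n_val, len(prepared) - 1)
    perm = order_rng.permutation(len(prepared))
    val_idx = set(perm[:n_val].tolist())
    train_set = [prepared[i] for i in range(len(prepared)) if i not in val_idx]
    val_set = [prepared[i] for i in sorted(val_idx)]

    opt = AdamW(model.pretrain_parameters(), lr=config.lr,
                weight_decay=config.weight_decay, clip_norm=config.clip_norm)
    total_steps = config.epochs * len(train_set)
    history = []
    best = (math.inf, None)
    step = 0
    for epoch in range(config.epochs):
        epoch_rng = sample_seed(seed, "pretrain-epoch", epoch)
        losses = []
        for i in epoch_rng.permutation(len(train_set)):
            sample, targets = train_set[i]
            rows = _step_rows(sample.n_cells, config.cells_per_step,
                              sample_seed(seed, "rows", sample.sample_id, epoch))
            loss, _ = _view_loss(model, sample, targets, rows, config.mask,
                                 config.loss, seed, epoch)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"pretraining diverged at epoch {epoch} "
                                   f"(sample {sample.sample_id}): non-finite loss")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=cosine_lr(step, total_steps, config.lr))
            step += 1
            losses.append(loss.data.item())
        val_losses = []
        for sample, targets in val_set:
            rows = _step_rows(sample.n_cells, config.cells_per_step,
                              sample_seed(seed, "val-rows", sample.sample_id, epoch))
            loss, _ = _view_loss(model, sample, targets, rows, config.mask,
                                 config.loss, seed, epoch)
            val_losses.append(loss.data.item())
        train_loss = float(np.mean(losses))
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("pretrain epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
        if val_loss < best[0]:
            best = (val_loss, [p.data.copy() for p in model.pretrain_parameters()])
    if best[1] is not None:
        for p, data in zip(model.pretrain_parameters(), best[1]):
            p.data = data
    return {"history": history, "best_val_loss": best[0], "n_train": len(train_set),
            "n_val": len(val_set)}


# --------------------------------------------------------------------------
# Downstream training
# --------------------------------------------------------------------------

@dataclass
class DownstreamConfig:
    epochs: int = 150
    lr: float = 1e-3
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    batch_size: int = 10                 # samples per accumulated gradient step
    marker_dropout_rate: float = 0.1
    freeze_encoder: bool = True
    standardize_latents: bool = True
    loss: str = "cross_entropy"          # or "mean_squared_error"
    validation_fraction: float = 0.1
    patience: int = 20                   # epochs without validation improvement
    cell_cap: int = DOWNSTREAM_CELL_CAP
    cells_per_step: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.marker_dropout_rate < 1.0:
            raise ValueError("marker_dropout_rate must be in [0, 1)")
        if self.loss not in ("cross_entropy", "mean_squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def marker_dropout_mask(n: int, m: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed-rate marker-wise input dropout: whole columns, round(m*rate) of them."""
    n_drop = min(int(math.floor(m * rate + 0.5)), m - 1)
    mask = np.ones((n, m), dtype=np.int8)
    if n_drop > 0:
        mask[:, rng.choice(m, size=n_drop, replace=False)] = 0
    return mask


def _score_loss(scores: Tensor, y, config: DownstreamConfig) -> Tensor:
    if config.loss == "cross_entropy":
        return cross_entropy(scores, int(y))
    return squared_error(scores, float(y))


def _dropped_columns(m: int, rate: float, rng: np.random.Generator) -> tuple[int, ...]:
    n_drop = min(int(math.floor(m * rate + 0.5)), m - 1)
    if n_drop == 0:
        return ()
    return tuple(sorted(rng.choice(m, size=n_drop, replace=False).tolist()))


def run_downstream(samples: list[CytometrySample], y: np.ndarray,
                   model: CytoTransformer, config: DownstreamConfig | None = None,
                   seed: int = 0) -> dict:
    """Train decoder + task head on labels; encoder frozen by default.

    ``y`` holds class indices (cross-entropy) or real targets (MSE).
    Marker-wise input dropout at the configured fixed rate is applied
    during training steps only; validation and inference see full panels.
    Gradients are accumulated over ``batch_size`` samples per optimiser
    step.  With a frozen encoder the (few) distinct per-sample latent
    matrices are cached, so epochs cost only the decoder; the cell subset
    used for training steps is then fixed per sample.  Before the first
    step the per-dimension latent mean/sd over the training corpus is
    frozen into the model and applied ahead of the decoder.
    """
    config = config or DownstreamConfig()
    if not samples:
        raise ValueError("downstream corpus is empty")
    y = np.asarray(y)
    if config.loss == "cross_entropy" and len(np.unique(y)) < 2:
        raise ValueError("classification requires at least two classes in the corpus")
    capped = [subsample_cells(s, config.cell_cap, seed) for s in samples]
    steps_view = []
    for s in capped:
        rows = _step_rows(s.n_cells, config.cells_per_step,
                          sample_seed(seed, "ds-rows", s.sample_id))
        steps_view.append(replace(s, events=s.events[rows]))

    params = model.decoder_parameters()
    if not config.freeze_encoder:
        params = model.pretrain_parameters() + params
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay,
                clip_norm=config.clip_norm)

    split_rng = sample_seed(seed, "downstream-split")
    n = len(capped)
    n_val = min(int(round(config.validation_fraction * n)), n - 1)
    perm = split_rng.permutation(n)
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]

    latent_cache: dict[tuple, np.ndarray] = {}

    def encoded(i: int, dropped: tuple[int, ...]):
        """Encoder output for sample i's step view under a marker-drop pattern."""
        sub = steps_view[i]
        mask = None
        if dropped:
            mask = np.ones((sub.n_cells, sub.n_markers), dtype=np.int8)
            mask[:, list(dropped)] = 0
        if not config.freeze_encoder:
            return model.encode(sub, per_cell_mask=mask)
        key = (sub.sample_id, dropped)
        if key not in latent_cache:
            latent_cache[key] = model.encode(sub, per_cell_mask=mask).latent.data
        return EncoderOutput(Tensor(latent_cache[key]))

    if config.standardize_latents:
        stack = np.vstack([np.asarray(encoded(i, ()).latent.data)
                           for i in train_idx])
        model.latent_mu = stack.mean(axis=0)
        model.latent_sd = stack.std(axis=0) + 1e-8

    total_steps = max(1, config.epochs * len(train_idx) // config.batch_size)
    history = []
    best = (math.inf, None, -1)
    step = 0
    for epoch in range(config.epochs):
        epoch_rng = sample_seed(seed, "downstream-epoch", epoch)
        losses = []
        opt.zero_grad()
        in_batch = 0
        for i in epoch_rng.permutation(train_idx):
            drop_rng = sample_seed(seed, "ds-dropout", capped[i].sample_id, epoch)
            dropped = _dropped_columns(steps_view[i].n_markers,
                                       config.marker_dropout_rate, drop_rng)
            scores, _ = model.decode_predict(encoded(i, dropped))
            loss = _score_loss(scores, y[i], config)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"downstream training diverged at epoch {epoch}")
            (loss * (1.0 / config.batch_size)).backward()
            losses.append(loss.data.item())
            in_batch += 1
            if in_batch == config.batch_size:
                opt.step(lr=cosine_lr(step, total_steps, config.lr))
                opt.zero_grad()
                in_batch = 0
                step += 1
        if in_batch:
            opt.step(lr=cosine_lr(step, total_steps, config.lr))
            opt.zero_grad()
            step += 1
        val_losses = [_score_loss(model.decode_predict(encoded(i, ()))[0],
                                  y[i], config).data.item() for i in val_idx]
        train_loss = float(np.mean(losses))
        val_loss = float(np.mean(val_losses)) if val_losses else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("downstream epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
        if val_loss < best[0] - 1e-9:
            best = (val_loss, [p.data.copy() for p in params], epoch)
        elif epoch - best[2] >= config.patience:
            logger.info("early stopping at epoch %d (best epoch %d)", epoch, best[2])
            break
    if best[1] is not None:
        for p, data in zip(params, best[1]):
            p.data = data
    return {"history": history, "best_val_loss": best[0], "best_epoch": best[2],
            "n_train": len(train_idx), "n_val": len(val_idx)}


def predict_proba(model: CytoTransformer, sample: CytometrySample,
                  cell_cap: int = DOWNSTREAM_CELL_CAP, seed: int = 0) -> np.ndarray:
    """Class probabilities for one sample (deterministic, no dropout)."""
    sub = subsample_cells(sample, cell_cap, seed)
    scores, _ = model.forward(sub)
    z = scores.data - scores.data.max()
    e = np.exp(z)
    return e / e.sum()


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, proba: np.ndarray,
                    n_classes: int | None = None) -> dict:
    """Accuracy, macro-F1, AUC and confusion matrix from class probabilities.

    Binary problems threshold the positive-class probability at 0.5;
    multiclass uses the argmax and a one-vs-rest macro-averaged AUC.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba)
    n_classes = n_classes or proba.shape[1]
    labels = np.arange(n_classes)
    if n_classes == 2:
        pred = (proba[:, 1] >= 0.5).astype(int)
        auc = roc_auc_score(y_true, proba[:, 1])
    else:
        pred = proba.argmax(axis=1)
        auc = roc_auc_score(y_true, proba, multi_class="ovr", average="macro",
                            labels=labels)
    return {
        "accuracy": float(np.mean(pred == y_true)),
        "macro_f1": float(f1_score(y_true, pred, average="macro", labels=labels,
                                   zero_division=0)),
        "auc": float(auc),
        "confusion": confusion_matrix(y_true, pred, labels=labels).tolist(),
        "n": int(len(y_true)),
    }


def make_splits(y: np.ndarray, groups: np.ndarray, spec: dict, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs for the supported split kinds.

    ``spec['kind']`` is one of ``stratified_group_kfold`` (``k`` folds,
    grouped by batch), ``leave_one_batch_out``, ``leave_one_panel_out``
    (pass panel fingerprints as ``groups``), or ``holdout``
    (``test_fraction``, stratified).
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    kind = spec["kind"]
    idx = np.arange(len(y))
    if kind in ("leave_one_batch_out", "leave_one_panel_out"):
        return list(LeaveOneGroupOut().split(idx, y, groups))
    if kind == "stratified_group_kfold":
        k = int(spec.get("k", 5))
        try:
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            return list(cv.split(idx, y, groups))
        except ValueError as e:
            warnings.warn(f"batch-grouped stratification infeasible ({e}); "
                          "falling back to ungrouped stratified folds")
            cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            return list(cv.split(idx, y))
    if kind == "holdout":
        frac = float(spec.get("test_fraction", 0.25))
        rng = np.random.default_rng(seed)
        test = []
        for cls in np.unique(y):
            members = idx[y == cls]
            n_test = max(1, int(round(frac * len(members))))
            test.extend(rng.permutation(members)[:n_test].tolist())
        test = np.sort(np.array(test))
        train = np.setdiff1d(idx, test)
        return [(train, test)]
    raise ValueError(f"unknown split kind {kind!r}")


def cross_validate(samples: list[CytometrySample], y: np.ndarray,
                   fit_predict, split_spec: dict, seed: int = 0,
                   groups: np.ndarray | None = None) -> dict:
    """Run ``fit_predict(train_samples, train_y, test_samples, fold_seed)``
    per fold, aggregate predictions, and compute pooled + per-fold metrics."""
    y = np.asarray(y)
    if groups is None:
        groups = np.array([s.batch_id or s.sample_id for s in samples])
    folds = make_splits(y, groups, split_spec, seed)
    n_classes = len(np.unique(y))
    pooled_true, pooled_proba, per_fold = [], [], []
    for f, (tr, te) in enumerate(folds):
        train_batches = {samples[i].batch_id for i in tr}
        test_batches = {samples[i].batch_id for i in te}
        if None not in train_batches and train_batches & test_batches \
                and split_spec["kind"] != "holdout":
            warnings.warn(f"fold {f}: batch appears on both sides of the split")
        proba = fit_predict([samples[i] for i in tr], y[tr],
                            [samples[i] for i in te], seed + f)
        pooled_true.append(y[te])
        pooled_proba.append(np.asarray(proba))
        per_fold.append(compute_metrics(y[te], np.asarray(proba), n_classes))
    pooled = compute_metrics(np.concatenate(pooled_true),
                             np.vstack(pooled_proba), n_classes)
    return {"pooled": pooled, "per_fold": per_fold, "n_folds": len(folds)}
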