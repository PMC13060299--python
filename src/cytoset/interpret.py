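"""Per-cell attention attribution from the decoder's cross-attention.

During inference each decoder layer's cross-attention assigns every cell a
softmax-normalised weight per head; head-averaged per layer, these weights
sum to one and quantify each cell's contribution to the sample-level
decision.  Extraction is a pure read-out of an evaluation-mode forward
pass: it never alters the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CytometrySample
from .model import AttentionMap, CytoTransformer

__all__ = ["AttributionRecord", "extract_attention", "clip_for_display",
           "export_attribution"]

DEFAULT_CLIP_FRACTION = 0.002  # top and bottom 0.2 %


@dataclass
class AttributionRecord:
    sample_id: str
    per_layer_weights: np.ndarray        # (layers, n), head-averaged
    head_weights: np.ndarray             # (layers, heads, n), pre-average
    max_weight_per_layer: np.ndarray     # (layers,)
    clipped_weights: np.ndarray          # (layers, n), winsorised for display
    cell_index: np.ndarray               # alignment to the sample's rows
    prediction: np.ndarray               # class probabilities / scalar


def clip_for_display(weights: np.ndarray,
                     clip_fraction: float = DEFAULT_CLIP_FRACTION) -> np.ndarray:
    """Winsorise at the ``clip_fraction`` / ``1 - clip_fraction`` quantiles.

    Order among unclipped entries is preserved; the result is suitable for
    power-scaled colour mapping.  ``clip_fraction = 0`` is the identity.
    """
    if not 0.0 <= clip_fraction < 0.5:
        raise ValueError("clip_fraction must be in [0, 0.5)")
    weights = np.asarray(weights, dtype=np.float64)
    if clip_fraction == 0.0:
        return weights.copy()
    lo, hi = np.quantile(weights, [clip_fraction, 1.0 - clip_fraction], axis=-1,
                         keepdims=True)
    return np.clip(weights, lo, hi)


def extract_attention(sample: CytometrySample, model: CytoTransformer,
                      clip_fraction: float = DEFAULT_CLIP_FRACTION) -> AttributionRecord:
    """Evaluation-mode forward pass capturing decoder attention per layer."""
    if not model.decoder_blocks:
        raise ValueError("model has no decoder; attribution requires a task-trained decoder")
    scores, amap = model.forward(sample)
    per_layer = amap.per_layer_mean                       # (layers, n)
    z = scores.data - scores.data.max()
    proba = np.exp(z) / np.exp(z).sum()
    return AttributionRecord(
        sample_id=sample.sample_id,
        per_layer_weights=per_layer,
        head_weights=amap.weights,
        max_weight_per_layer=per_layer.max(axis=1),
        clipped_weights=clip_for_display(per_layer, clip_fraction),
        cell_index=np.arange(sample.n_cells),
        prediction=proba,
    )


def export_attribution(record: AttributionRecord, sample: CytometrySample,
                       path, embedding: np.ndarray | None = None) -> Path:
    """Write a per-cell TSV: index, marker values, per-layer raw and clipped
    attention, and optional 2-D embedding coordinates for plotting tools."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"cell_index": record.cell_index}
    for j, m in enumerate(sample.measured_markers):
        cols[m] = sample.events[:, j]
    for layer in range(record.per_layer_weights.shape[0]):
        cols[f"attention_layer{layer}"] = record.per_layer_weights[layer]
    for layer in range(record.clipped_weights.shape[0]):
        cols[f"attention_layer{layer}_clipped"] = record.clipped_weights[layer]
    if embedding is not None:
        embedding = np.asarray(embedding)
        cols["embed_x"] = embedding[:, 0]
        cols["embed_y"] = embedding[:, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
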