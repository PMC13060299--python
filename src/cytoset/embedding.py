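"""Fixed-size per-cell embedding over a global marker vocabulary.

Every cell is lifted to a vector of length ``2|M|``: a binary availability
indicator ``a`` (1 where the marker is measured *and* not masked) is
concatenated with an expression vector ``e`` that holds the measured value
where available and a learnable per-marker mask value ``mu_j`` everywhere
else.  Masked-but-measured entries are therefore indistinguishable from
truly unmeasured ones at this stage, while a measured zero and an
unmeasured marker always differ (their availability bits differ).  The
augmented vector is projected to the transformer hidden size by a small
position-wise feed-forward map, identical for every cell.

Columns are addressed by vocabulary slot, never by per-sample position, so
any panel ordering maps deterministically onto the same embedding slots.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor, concatenate
from .core import CytometrySample, MarkerVocabulary

__all__ = ["LearnableMaskBank", "Projection", "augment_arrays", "embed_sample", "project"]


class LearnableMaskBank:
    """One trainable mask value per vocabulary marker, initialised at zero.

    Zero matches a "no signal" prior before learning; values are updated
    during pretraining only and frozen downstream.
    """

    def __init__(self, vocabulary: MarkerVocabulary):
        self.vocabulary = vocabulary
        self.mu = Parameter(np.zeros(vocabulary.size))

    @property
    def values(self) -> np.ndarray:
        return self.mu.data


def augment_arrays(sample: CytometrySample, vocabulary: MarkerVocabulary,
                   per_cell_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Availability matrix and slot-scattered expression matrix (numpy).

    Returns ``(availability, scattered)`` of shape ``n x |M|``:
    availability is 1 where measured and unmasked; ``scattered`` holds the
    raw value there and 0 elsewhere (the mask value is added by
    :func:`embed_sample`, which keeps the graph differentiable in ``mu``).
    """
    sample.validate_vocabulary(vocabulary)
    n = sample.n_cells
    size = vocabulary.size
    slots = vocabulary.slots(sample.measured_markers)
    avail = np.zeros((n, size))
    values = np.zeros((n, size))
    keep = np.ones((n, sample.n_markers), dtype=bool)
    if per_cell_mask is not None:
        per_cell_mask = np.asarray(per_cell_mask)
        if per_cell_mask.shape != (n, sample.n_markers):
            raise ValueError("per_cell_mask must have shape n_cells x n_measured_markers")
        keep = per_cell_mask.astype(bool)
    avail[:, slots] = keep
    values[:, slots] = sample.events * keep
    return avail, values


def embed_sample(sample: CytometrySample, vocabulary: MarkerVocabulary,
                 mask_bank: LearnableMaskBank,
                 per_cell_mask: np.ndarray | None = None) -> Tensor:
    """Augmented cell matrix ``[a ; e]`` of shape ``n x 2|M|`` (autodiff graph).

    Wherever availability is 0 the expression entry is the learnable
    ``mu_j``, so the output is exactly insensitive to raw values at
    unavailable entries.
    """
    avail, values = augment_arrays(sample, vocabulary, per_cell_mask)
    a = Tensor(avail)
    e = Tensor(values) + Tensor(1.0 - avail) * mask_bank.mu
    return concatenate([a, e], axis=1)


class Projection:
    """Position-wise map from augmented vectors (2|M|) to hidden size h.

    One affine layer + GELU by default; ``depth=2`` inserts a second
    hidden-to-hidden layer.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, depth: int = 1):
        if depth not in (1, 2):
            raise ValueError("projection depth must be 1 or 2")
        scale = (2.0 / (in_dim + hidden)) ** 0.5
        self.w1 = Parameter(rng.normal(0.0, scale, size=(in_dim, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.depth = depth
        if depth == 2:
            scale2 = (1.0 / hidden) ** 0.5
            self.w2 = Parameter(rng.normal(0.0, scale2, size=(hidden, hidden)))
            self.b2 = Parameter(np.zeros(hidden))

    def __call__(self, cells: Tensor) -> Tensor:
        if cells.shape[-1] != self.w1.shape[0]:
            raise ValueError(f"expected input dim {self.w1.shape[0]}, got {cells.shape[-1]}")
        out = (cells @ self.w1 + self.b1).gelu()
        if self.depth == 2:
            out = (out @ self.w2 + self.b2).gelu()
        return out


def project(cells: Tensor | np.ndarray, projection: Projection) -> Tensor:
    """Row-wise projection of augmented cells to the hidden size."""
    if not isinstance(cells, Tensor):
        cells = Tensor(cells)
    return projection(cells)
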