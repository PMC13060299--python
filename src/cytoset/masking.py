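"""Dual masking for masked-prediction pretraining.

Two complementary views of each sample are produced per step:

* **uniform_random** — an optional sample-wide marker dropout (a fraction
  ``r_drop ~ Beta(a1, b1)`` of markers is removed from the measured set
  entirely) followed by i.i.d. per-entry masking with probability
  ``r_mask ~ Beta(a2, b2)``; encourages learning inter-cell structure.
* **marker_wise** — a fraction ``r_mask ~ Beta(a3, b3)`` of whole marker
  columns is masked for every cell; mimics a missing panel marker and
  encourages learning inter-marker correlations.

Masked entries are treated exactly like unmeasured markers by the
embedding, but the loss bookkeeping keeps three disjoint entry classes
(masked / unmasked-measured / unmeasured-or-dropped): masked entries are
reconstruction targets, dropped and unmeasured ones are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import sample_seed

__all__ = ["MaskDistributionConfig", "MaskedView", "mask_uniform_random",
           "mask_marker_wise", "make_views", "view_rng"]

UNIFORM_RANDOM = "uniform_random"
MARKER_WISE = "marker_wise"


@dataclass
class MaskDistributionConfig:
    """Beta parameters for the masking ratios (all > 0)."""

    drop_alpha: float = 1.0
    drop_beta: float = 9.0        # E[r_drop] = 0.1
    uniform_alpha: float = 2.0
    uniform_beta: float = 6.0     # E[r_mask] = 0.25
    markerwise_alpha: float = 2.0
    markerwise_beta: float = 6.0

    def __post_init__(self):
        for name in ("drop_alpha", "drop_beta", "uniform_alpha",
                     "uniform_beta", "markerwise_alpha", "markerwise_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MaskedView:
    """A masked copy of a sample's event matrix.

    ``mask`` is 1 where the entry is retained; masked *and* dropped
    entries are 0, so ``mask`` doubles as the embedding's availability
    pattern.  ``dropped_markers`` records the columns removed sample-wide
    (uniform_random only); those columns are excluded from the loss
    bookkeeping entirely, which :meth:`entry_classes` makes explicit.
    """

    masked_events: np.ndarray
    mask: np.ndarray
    pattern: str
    dropped_markers: frozenset[int] = field(default_factory=frozenset)

    def entry_classes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Disjoint boolean matrices (masked, unmasked, dropped) over n x m."""
        dropped_cols = np.zeros(self.mask.shape[1], dtype=bool)
        if self.dropped_markers:
            dropped_cols[list(self.dropped_markers)] = True
        dropped = np.broadcast_to(dropped_cols, self.mask.shape)
        retained = self.mask.astype(bool) & ~dropped
        masked = ~self.mask.astype(bool) & ~dropped
        return masked, retained, dropped


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def mask_uniform_random(events: np.ndarray, config: MaskDistributionConfig,
                        rng: np.random.Generator) -> MaskedView:
    """Sample-wide marker dropout followed by i.i.d. per-entry masking."""
    events = np.asarray(events, dtype=np.float64)
    n, m = events.shape
    r_drop = rng.beta(config.drop_alpha, config.drop_beta)
    n_drop = min(_round_half_away(m * r_drop), m - 1)  # >= 1 marker survives
    dropped = frozenset(rng.choice(m, size=n_drop, replace=False).tolist()) if n_drop else frozenset()

    r_mask = rng.beta(config.uniform_alpha, config.uniform_beta)
    mask = (rng.random((n, m)) >= r_mask).astype(np.int8)
    if dropped:
        mask[:, list(dropped)] = 0
    return MaskedView(events * mask, mask, UNIFORM_RANDOM, dropped)


def mask_marker_wise(events: np.ndarray, config: MaskDistributionConfig,
                     rng: np.random.Generator) -> MaskedView:
    """Mask whole marker columns: each marker is masked for all cells or none."""
    events = np.asarray(events, dtype=np.float64)
    n, m = events.shape
    r_mask = rng.beta(config.markerwise_alpha, config.markerwise_beta)
    n_mask = min(_round_half_away(m * r_mask), m - 1)  # >= 1 marker observed
    cols = rng.choice(m, size=n_mask, replace=False) if n_mask else np.empty(0, dtype=int)
    mask = np.ones((n, m), dtype=np.int8)
    mask[:, cols] = 0
    return MaskedView(events * mask, mask, MARKER_WISE)


def view_rng(global_seed: int, sample_id: str, epoch: int, pattern: str) -> np.random.Generator:
    """Fresh rng stream per (seed, sample, epoch, pattern); masks are not cached."""
    return sample_seed(global_seed, "mask", sample_id, epoch, pattern)


def make_views(events: np.ndarray, config: MaskDistributionConfig,
               global_seed: int, sample_id: str, epoch: int) -> tuple[MaskedView, MaskedView]:
    """Both pretraining views of a sample for one epoch, independently keyed."""
    uni = mask_uniform_random(events, config,
                              view_rng(global_seed, sample_id, epoch, UNIFORM_RANDOM))
    mw = mask_marker_wise(events, config,
                          view_rng(global_seed, sample_id, epoch, MARKER_WISE))
    return uni, mw
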