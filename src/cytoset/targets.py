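"""Per-cell self-supervision targets: expression, percentile rank, log-density.

For a sample matrix ``X`` (n cells x m markers) the masked-prediction
pretraining regresses three targets per measured entry:

* the raw (transformed) expression ``X`` itself,
* the percentile matrix ``P``: ``P[i, j] = rank(X[i, j] | X[:, j]) / n``
  with average (fractional) ranks on ties, so every column of ``P`` lies in
  ``(0, 1]`` and is invariant to strictly monotone transforms of the column,
* the density matrix ``D``: the natural log of a Gaussian-kernel KDE of
  column ``j`` evaluated at each cell's own value (self-contribution
  included), bandwidth ``sigma`` (default 0.05 on the logicle-like scale).

``P`` and ``D`` summarise the sample-wide per-marker distribution at each
cell, which makes the cell-level reconstruction task carry sample-level
information and softens sensitivity to batch-wide signal shifts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .core import CytometrySample
from .io import subsample_cells

__all__ = ["PretrainTargets", "percentile_matrix", "density_matrix", "precompute_targets"]

DEFAULT_SIGMA = 0.05
DEFAULT_TARGET_CELL_CAP = 50_000


@dataclass
class PretrainTargets:
    expression: np.ndarray  # n x m
    percentile: np.ndarray  # n x m, entries in (0, 1]
    density: np.ndarray     # n x m, natural log scale
    sigma: float

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]


def percentile_matrix(events: np.ndarray) -> np.ndarray:
    """Column-wise fractional ranks divided by n (average ranks on ties)."""
    events = np.asarray(events, dtype=np.float64)
    n = events.shape[0]
    return rankdata(events, axis=0, method="average") / n


def density_matrix(events: np.ndarray, sigma: float = DEFAULT_SIGMA,
                   chunk: int = 1024) -> np.ndarray:
    """Log Gaussian-KDE of each column evaluated at each of its own entries.

    ``D[i, j] = log[(1/(n*sigma)) * sum_i' K((X[i,j] - X[i',j]) / sigma)]``
    with ``K`` the standard normal density; the sum runs over all cells
    including ``i`` itself.  Computed in log-space (log-sum-exp) and in row
    chunks so memory stays at ``chunk * n`` per column block.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    events = np.asarray(events, dtype=np.float64)
    n, m = events.shape
    log_norm = -math.log(n * sigma) - 0.5 * math.log(2.0 * math.pi)
    out = np.empty_like(events)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        # (hi-lo) x n x m standardised differences, reduced over axis 1
        diff = (events[lo:hi, None, :] - events[None, :, :]) / sigma
        out[lo:hi] = logsumexp(-0.5 * diff * diff, axis=1) + log_norm
    return out


def compute_targets(events: np.ndarray, sigma: float = DEFAULT_SIGMA) -> PretrainTargets:
    events = np.asarray(events, dtype=np.float64)
    return PretrainTargets(expression=events.copy(),
                           percentile=percentile_matrix(events),
                           density=density_matrix(events, sigma),
                           sigma=float(sigma))


def _cache_key(sample: CytometrySample, sigma: float, max_cells: int, seed: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(sample.events).tobytes())
    h.update(json.dumps([list(sample.measured_markers), sigma, max_cells, seed]).encode())
    return h.hexdigest()[:16]


def precompute_targets(sample: CytometrySample,
                       sigma: float = DEFAULT_SIGMA,
                       max_cells: int = DEFAULT_TARGET_CELL_CAP,
                       seed: int = 0,
                       cache_dir=None) -> tuple[CytometrySample, PretrainTargets]:
    """Subsample to ``max_cells`` then compute (X, P, D), with optional cache.

    Returns the (possibly subsampled) sample together with its targets so
    rows stay aligned.  Cache entries are keyed by the event bytes and by
    (sigma, max_cells, seed): changing any of them invalidates the entry.
    """
    sub = subsample_cells(sample, max_cells, seed)
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = _cache_key(sub, sigma, max_cells, seed)
        path = cache_dir / f"{sample.sample_id}.{key}.targets.npz"
        if path.exists():
            z = np.load(path)
            return sub, PretrainTargets(z["expression"], z["percentile"],
                                        z["density"], float(z["sigma"]))
        tgt = compute_targets(sub.events, sigma)
        np.savez(path, expression=tgt.expression, percentile=tgt.percentile,
                 density=tgt.density, sigma=tgt.sigma)
        return sub, tgt
    return sub, compute_targets(sub.events, sigma)
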