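"""Core containers: a cytometry sample (a set of cells) and the marker vocabulary.

A sample is an unordered set of cells, each featurised by the intensities of
the markers its panel measured.  Panels differ between samples, so every
sample carries its own ordered list of measured markers; the global
:class:`MarkerVocabulary` fixes the embedding slot each marker name maps to
for the lifetime of a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CytometrySample",
    "MarkerVocabulary",
    "CytosetError",
    "FormatError",
    "VocabularyError",
]


class CytosetError(Exception):
    """Base class for package errors."""


class FormatError(CytosetError):
    """A file could not be parsed in the expected format."""


class VocabularyError(CytosetError):
    """A marker name is not a member of the model's vocabulary."""


@dataclass(frozen=True)
class MarkerVocabulary:
    """Ordered global marker set; ordering defines embedding slot identity."""

    markers: tuple[str, ...]

    def __init__(self, markers: Sequence[str]):
        markers = tuple(markers)
        if len(set(markers)) != len(markers):
            raise ValueError("vocabulary marker names must be unique")
        object.__setattr__(self, "markers", markers)

    @property
    def size(self) -> int:
        return len(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise VocabularyError(f"marker {marker!r} is not in the vocabulary") from None

    def slots(self, markers: Sequence[str]) -> np.ndarray:
        """Vocabulary slot index for each marker name, in the given order."""
        return np.array([self.index(m) for m in markers], dtype=np.intp)


@dataclass
class CytometrySample:
    """One sample: an ``n_cells x n_markers`` event matrix plus metadata.

    Events are assumed to already be on the transformed (logicle-like)
    scale.  Row order carries no meaning; column order matches
    ``measured_markers``.
    """

    events: np.ndarray
    measured_markers: tuple[str, ...]
    sample_id: str
    label: object | None = None
    batch_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=np.float64)
        self.measured_markers = tuple(self.measured_markers)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix (cells x markers)")
        if self.events.shape[0] < 1:
            raise ValueError("a sample must contain at least one cell")
        if self.events.shape[1] != len(self.measured_markers):
            raise ValueError("events column count must match measured_markers")
        if len(set(self.measured_markers)) != len(self.measured_markers):
            raise ValueError("measured_markers must be unique")

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    @property
    def n_markers(self) -> int:
        return self.events.shape[1]

    def validate_vocabulary(self, vocabulary: MarkerVocabulary) -> None:
        for m in self.measured_markers:
            if m not in vocabulary:
                raise VocabularyError(f"marker {m!r} is not in the vocabulary")

    def permuted(self, order: np.ndarray) -> "CytometrySample":
        """Equivalent sample with rows reordered (sets are unordered)."""
        return replace(self, events=self.events[np.asarray(order)])

    def with_markers(self, keep: Sequence[str]) -> "CytometrySample":
        """Restrict to a subset of measured markers (panel projection)."""
        idx = [self.measured_markers.index(m) for m in keep]
        return replace(self, events=self.events[:, idx], measured_markers=tuple(keep))
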