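"""Reading cytometry data: FCS 3.0/3.1 files, plain matrices, and the sample store.

Preprocessing follows standard practice for sample-level modelling: the
logicle transform is applied to every kept channel, channels without a
marker annotation are discarded, and corpora can drop markers that occur
in only a single sample.  Compensation/spillover correction is *not*
applied; inputs are taken as-is after the transform.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CytometrySample, FormatError, MarkerVocabulary, VocabularyError
from .logicle import LogicleTransform

__all__ = [
    "read_fcs",
    "read_matrix",
    "subsample_cells",
    "sample_seed",
    "SampleStore",
    "rare_marker_filter",
]


# --------------------------------------------------------------------------
# FCS parsing
# --------------------------------------------------------------------------

def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of delimited tokens")
    return {parts[i].decode("utf-8", "replace").strip(): parts[i + 1].decode("utf-8", "replace").strip()
            for i in range(0, len(parts), 2)}


def _read_fcs_raw(path) -> tuple[dict[str, str], np.ndarray]:
    """Parse an FCS 3.0/3.1 file into (keywords, events-by-channel matrix)."""
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = data[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_begin = int(data[10:18])
        text_end = int(data[18:26])
        data_begin = int(data[26:34])
        data_end = int(data[34:42])
    except ValueError as e:
        raise FormatError(f"{path}: malformed HEADER offsets") from e
    kw = _parse_fcs_text(data[text_begin:text_end + 1])
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if data_begin == 0 or data_end == 0:
        raise FormatError(f"{path}: no DATA segment offsets")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE=L) FCS is supported")

    seg = data[data_begin:data_end + 1]
    if dtype_code == "F":
        arr = np.frombuffer(seg[: n_tot * n_par * 4], dtype=order + "f4")
    elif dtype_code == "D":
        arr = np.frombuffer(seg[: n_tot * n_par * 8], dtype=order + "f8")
    elif dtype_code == "I":
        bits = {int(kw.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise FormatError(f"{path}: only uniform 16/32-bit integer data supported")
        width = next(iter(bits)) // 8
        arr = np.frombuffer(seg[: n_tot * n_par * width], dtype=f"{order}u{width}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    if arr.size < n_tot * n_par:
        raise FormatError(f"{path}: DATA segment shorter than $TOT x $PAR")
    events = arr.astype(np.float64).reshape(n_tot, n_par)
    return kw, events


def _resolve_markers(kw: Mapping[str, str],
                     channel_map: Mapping[str, str | None] | None) -> list[tuple[int, str]]:
    """(channel index, marker name) for every kept channel.

    Resolution per channel: an explicit ``channel_map`` entry (by $PnN or
    $PnS; value None/"" discards) wins; otherwise a non-empty $PnS stain
    annotation is the marker name; channels with neither are discarded.
    """
    n_par = int(kw["$PAR"])
    kept: list[tuple[int, str]] = []
    for i in range(n_par):
        pnn = kw.get(f"$P{i + 1}N", "")
        pns = kw.get(f"$P{i + 1}S", "")
        marker: str | None
        if channel_map is not None and (pnn in channel_map or pns in channel_map):
            marker = channel_map.get(pnn, channel_map.get(pns))
        elif pns:
            marker = pns
        else:
            marker = None
        if marker:
            kept.append((i, marker))
    return kept


def read_fcs(path,
             channel_map: Mapping[str, str | None] | None = None,
             transform: LogicleTransform | None = None,
             vocabulary: MarkerVocabulary | None = None,
             pre_transformed: bool = False,
             sample_id: str | None = None,
             label=None,
             batch_id: str | None = None) -> CytometrySample:
    """Read one FCS file into a :class:`CytometrySample`.

    Channels without marker annotation are dropped.  Unless
    ``pre_transformed`` is set, the logicle transform (default parameters
    when ``transform`` is None) is applied to all kept channels.
    """
    kw, events = _read_fcs_raw(path)
    kept = _resolve_markers(kw, channel_map)
    if not kept:
        raise FormatError(f"{path}: no channel resolved to a marker name")
    idx = [i for i, _ in kept]
    markers = [m for _, m in kept]
    if len(set(markers)) != len(markers):
        raise FormatError(f"{path}: duplicate marker names after channel resolution")
    values = events[:, idx]
    if not pre_transformed:
        values = (transform or LogicleTransform()).scale(values)
    sample = CytometrySample(values, markers,
                             sample_id=sample_id or Path(path).stem,
                             label=label, batch_id=batch_id)
    if vocabulary is not None:
        sample.validate_vocabulary(vocabulary)
    return sample


def read_matrix(path,
                vocabulary: MarkerVocabulary | None = None,
                transform: LogicleTransform | None = None,
                pre_transformed: bool = True,
                sample_id: str | None = None,
                label=None,
                batch_id: str | None = None) -> CytometrySample:
    """Read a CSV/TSV event matrix whose header row holds marker names.

    Plain matrices are assumed already transformed (the synthetic
    generator and re-analysis path) unless ``pre_transformed=False``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    values = df.to_numpy(dtype=np.float64)
    if not pre_transformed:
        values = (transform or LogicleTransform()).scale(values)
    sample = CytometrySample(values, list(df.columns),
                             sample_id=sample_id or Path(path).stem,
                             label=label, batch_id=batch_id)
    if vocabulary is not None:
        sample.validate_vocabulary(vocabulary)
    return sample


# --------------------------------------------------------------------------
# Subsampling
# --------------------------------------------------------------------------

def sample_seed(global_seed: int, *keys) -> np.random.Generator:
    """Generator keyed by (global_seed, *keys); stable across iteration order."""
    digest = hashlib.sha256(("\x1f".join(str(k) for k in keys)).encode()).digest()
    entropy = [global_seed & 0x7FFFFFFF] + [int.from_bytes(digest[i:i + 4], "little")
                                            for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subsample_cells(sample: CytometrySample, max_cells: int, seed: int) -> CytometrySample:
    """Uniform subsample (without replacement) down to ``max_cells`` rows.

    Samples at or below the cap are returned unchanged.  The row choice is
    reproducible from ``(seed, sample_id)`` alone.
    """
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    if sample.n_cells <= max_cells:
        return sample
    rng = sample_seed(seed, "subsample", sample.sample_id)
    rows = rng.choice(sample.n_cells, size=max_cells, replace=False)
    return replace(sample, events=sample.events[np.sort(rows)])


# --------------------------------------------------------------------------
# Sample store
# --------------------------------------------------------------------------

def _panel_fingerprint(markers: Sequence[str]) -> str:
    return hashlib.sha1("|".join(markers).encode()).hexdigest()[:12]


class SampleStore:
    """On-disk corpus: one events matrix + JSON sidecar per sample, plus a
    TSV manifest (sample_id, path, label, batch_id, panel fingerprint)."""

    MANIFEST = "manifest.tsv"

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def put(self, sample: CytometrySample) -> None:
        np.save(self.root / f"{sample.sample_id}.events.npy", sample.events)
        meta = {
            "sample_id": sample.sample_id,
            "measured_markers": list(sample.measured_markers),
            "label": sample.label,
            "batch_id": sample.batch_id,
        }
        (self.root / f"{sample.sample_id}.json").write_text(json.dumps(meta, indent=1))

    def get(self, sample_id: str) -> CytometrySample:
        meta = json.loads((self.root / f"{sample_id}.json").read_text())
        events = np.load(self.root / f"{sample_id}.events.npy")
        return CytometrySample(events, meta["measured_markers"],
                               sample_id=meta["sample_id"], label=meta["label"],
                               batch_id=meta["batch_id"])

    def ids(self) -> list[str]:
        return sorted(p.stem.replace(".events", "") for p in self.root.glob("*.events.npy"))

    def __len__(self) -> int:
        return len(self.ids())

    def __iter__(self):
        for sid in self.ids():
            yield self.get(sid)

    def write_manifest(self) -> Path:
        rows = []
        for s in self:
            rows.append({"sample_id": s.sample_id,
                         "path": f"{s.sample_id}.events.npy",
                         "label": s.label,
                         "batch_id": s.batch_id,
                         "panel": _panel_fingerprint(s.measured_markers)})
        df = pd.DataFrame(rows)
        path = self.root / self.MANIFEST
        df.to_csv(path, sep="\t", index=False)
        return path

    def manifest(self) -> pd.DataFrame:
        path = self.root / self.MANIFEST
        if not path.exists():
            self.write_manifest()
        return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Corpus-level filtering
# --------------------------------------------------------------------------

def rare_marker_filter(samples: Iterable[CytometrySample],
                       min_samples: int = 2) -> tuple[list[CytometrySample], list[str]]:
    """Drop markers measured in fewer than ``min_samples`` samples.

    With the default threshold this removes exactly the markers that appear
    in one sample only; returns (filtered samples, removed marker names).
    """
    samples = list(samples)
    counts: dict[str, int] = {}
    for s in samples:
        for m in s.measured_markers:
            counts[m] = counts.get(m, 0) + 1
    rare = sorted(m for m, c in counts.items() if c < min_samples)
    if not rare:
        return samples, []
    out = []
    for s in samples:
        keep = [m for m in s.measured_markers if m not in rare]
        out.append(s.with_markers(keep) if len(keep) != s.n_markers else s)
    return out, rare
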