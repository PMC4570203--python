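"""Transmembrane-segment (TMS) annotations.

Segments come either from a precomputed table ("given", e.g. an external
HMM-based predictor) or from the built-in hydropathy-window predictor.
The predictor slides a window over the Kyte-Doolittle hydropathy scale and
reports maximal above-threshold runs as candidate membrane-spanning
segments; it is a deliberately simple stand-in whose output has the same
shape as any dedicated topology predictor, which is all the downstream
procedures consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

__all__ = ["TMSAnnotation", "predict_tms", "tms_count", "read_tms_table", "write_tms_table"]


@dataclass
class TMSAnnotation:
    """Sorted, non-overlapping 1-based inclusive membrane-segment coordinates."""

    seq_id: str
    segments: list[tuple[int, int]] = field(default_factory=list)
    source: str = "given"  # "given" | "predicted"

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping TMS segments {s1}-{e1} and {s2}-{e2} on {self.seq_id}")
        self.segments = segs

    def __len__(self) -> int:
        return len(self.segments)


def predict_tms(seq: str, seq_id: str = "", window: int = 19, threshold: float = 1.6,
                min_length: int = 15, merge_gap: int = 5) -> TMSAnnotation:
    """Predict membrane segments by sliding-window mean hydropathy.

    Window centers whose mean Kyte-Doolittle hydropathy exceeds *threshold*
    form runs; each run is emitted as the residue span its windows cover
    (run extent = half a window beyond the first and last center, clipped
    to the sequence).  Extents separated by fewer than *merge_gap*
    residues are merged, and merged extents shorter than *min_length* are
    discarded.  Returns zero segments (with a warning) for sequences
    shorter than the window.
    """
    n = len(seq)
    if n < window:
        logger.warning("sequence %s shorter than window (%d < %d); no prediction", seq_id, n, window)
        return TMSAnnotation(seq_id, [], source="predicted")
    hyd = np.array([KYTE_DOOLITTLE.get(aa.upper(), 0.0) for aa in seq])
    means = np.convolve(hyd, np.ones(window) / window, mode="valid")  # center i+window//2
    half = window // 2
    above = means > threshold
    # maximal runs of above-threshold window centers, as 1-based center spans
    runs: list[list[int]] = []
    for i, flag in enumerate(above):
        center = i + half + 1
        if flag:
            if runs and runs[-1][1] == center - 1:
                runs[-1][1] = center
            else:
                runs.append([center, center])
    extents = [[max(1, s - half), min(n, e + half)] for s, e in runs]
    merged: list[list[int]] = []
    for s, e in extents:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    segments = [(s, e) for s, e in merged if e - s + 1 >= min_length]
    return TMSAnnotation(seq_id, segments, source="predicted")


def tms_count(ann: TMSAnnotation, region: tuple[int, int] | None = None) -> int:
    """Number of segments fully contained in *region* (whole sequence if None)."""
    if region is None:
        return len(ann.segments)
    rs, re = region
    return sum(1 for s, e in ann.segments if s >= rs and e <= re)


def read_tms_table(path: str | Path) -> dict[str, TMSAnnotation]:
    """Read a TSV ``seq_id<TAB>start<TAB>end`` (one row per segment)."""
    segs: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from None
        segs.setdefault(parts[0], []).append((s, e))
    return {sid: TMSAnnotation(sid, sorted(v), source="given") for sid, v in segs.items()}


def write_tms_table(anns: Iterable[TMSAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_id\tstart\tend\n")
        for ann in anns:
            for s, e in ann.segments:
                fh.write(f"{ann.seq_id}\t{s}\t{e}\n")
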