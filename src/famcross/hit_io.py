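"""Domain-hit tables and sequence I/O.

The canonical hit-table dialect is a TSV with header
``seq_id  family  clan  start  end  evalue  bitscore`` modeled on tabular
profile-search output.  Coordinates are 1-based inclusive.  E-value
thresholds throughout the toolkit are inclusive (a hit at exactly the
threshold is kept); upstream significance filtering (per-family gathering
thresholds) is assumed to have been applied by whatever produced the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "HitTable",
    "read_hits",
    "write_hits",
    "unmatched_sequences",
    "read_fasta",
    "write_fasta",
]

_COLUMNS = ["seq_id", "family", "clan", "start", "end", "evalue", "bitscore"]


@dataclass(frozen=True)
class DomainHit:
    """One match of a family model to a sequence region."""

    seq_id: str
    family: str
    clan: str | None
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}-{self.end} for {self.seq_id}/{self.family}")
        if self.evalue <= 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")


class HitTable:
    """A list of :class:`DomainHit` with indexes by sequence id and family."""

    def __init__(self, hits: Iterable[DomainHit] = ()):  # noqa: D107
        self.hits: list[DomainHit] = list(hits)
        self._by_seq: dict[str, list[DomainHit]] = {}
        self._by_family: dict[str, list[DomainHit]] = {}
        for h in self.hits:
            self._by_seq.setdefault(h.seq_id, []).append(h)
            self._by_family.setdefault(h.family, []).append(h)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __eq__(self, other) -> bool:
        return isinstance(other, HitTable) and self.hits == other.hits

    @property
    def families(self) -> list[str]:
        return list(self._by_family)

    def for_seq(self, seq_id: str) -> list[DomainHit]:
        return sorted(self._by_seq.get(seq_id, []), key=lambda h: h.start)

    def for_family(self, family: str) -> list[DomainHit]:
        return sorted(self._by_family.get(family, []), key=lambda h: (h.seq_id, h.start))

    def query(self, seq_id: str, family: str) -> list[DomainHit]:
        """Hits of *family* on *seq_id*, sorted by start coordinate."""
        return sorted((h for h in self._by_seq.get(seq_id, []) if h.family == family),
                      key=lambda h: h.start)

    def filtered(self, evalue_max: float) -> "HitTable":
        """Hits with E-value <= *evalue_max* (inclusive)."""
        return HitTable(h for h in self.hits if h.evalue <= evalue_max)

    def has_hit(self, seq_id: str) -> bool:
        return seq_id in self._by_seq


def read_hits(path: str | Path, evalue_max: float | None = None) -> HitTable:
    """Read a hit-table TSV, optionally dropping rows above an E-value threshold.

    The threshold is inclusive: a row at exactly *evalue_max* is retained.
    The number of dropped rows is logged.
    """
    lines = Path(path).read_text().splitlines()
    data = [(i, ln) for i, ln in enumerate(lines, start=1)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not data:
        raise ValueError(f"{path}: empty hit table (no header)")
    header_no, header = data[0]
    cols = header.rstrip("\n").split("\t")
    if cols != _COLUMNS:
        missing = [c for c in _COLUMNS if c not in cols]
        raise ValueError(f"{path}:{header_no}: bad header; missing columns {missing or cols}")
    hits, dropped = [], 0
    for lineno, line in data[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(_COLUMNS)} columns, got {len(parts)}")
        rec = dict(zip(_COLUMNS, parts))
        try:
            hit = DomainHit(rec["seq_id"], rec["family"], rec["clan"] or None,
                            int(rec["start"]), int(rec["end"]),
                            float(rec["evalue"]), float(rec["bitscore"]))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
        if evalue_max is not None and hit.evalue > evalue_max:
            dropped += 1
            continue
        hits.append(hit)
    if evalue_max is not None:
        logger.info("read_hits(%s): dropped %d rows above E-value %g", path, dropped, evalue_max)
    return HitTable(hits)


def write_hits(table: HitTable, path: str | Path) -> None:
    """Write the canonical TSV; numeric fields use shortest exact representation
    (scientific notation for small E-values), so read(write(T)) == T."""
    with open(path, "w") as fh:
        fh.write("# domain hit table; coordinates 1-based inclusive\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for h in table.hits:
            fh.write(f"{h.seq_id}\t{h.family}\t{h.clan or ''}\t{h.start}\t{h.end}\t"
                     f"{h.evalue!r}\t{h.bitscore!r}\n")


def unmatched_sequences(seq_ids: Iterable[str], hits: HitTable) -> list[str]:
    """Ids with zero hits, in input order."""
    return [sid for sid in seq_ids if not hits.has_hit(sid)]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences as an id -> string mapping, preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
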