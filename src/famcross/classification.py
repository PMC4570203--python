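"""Hierarchical transporter-classification identifiers and assignment tables.

The Transporter Classification (TC) system is a five-level hierarchy:
class (1-9), subclass (a letter), family, subfamily and transport system,
written ``C.S.F.U.N`` (e.g. ``2.A.7.27.1``).  A four-token form
(``2.A.7.27``) is a subfamily-level prefix.  A single protein may carry
several TC numbers (multi-role proteins such as Tic110 homologues appear
in more than one family), so assignments are stored as rows, not as a
one-to-one mapping.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TCNumber",
    "TCParseError",
    "FamilyEntry",
    "AssignmentTable",
    "parse_tc",
    "filter_by_class",
    "dedup_representatives",
    "read_assignments",
    "write_assignments",
    "read_registry",
    "write_registry",
    "DEFAULT_CLASS_FILTER",
]

#: Classes retained by default when scanning for unclassified proteins:
#: classes 1-5 and 8.  Class 9 (systems of unknown mechanism) is excluded.
DEFAULT_CLASS_FILTER = frozenset({1, 2, 3, 4, 5, 8})


class TCParseError(ValueError):
    """Raised when a TC identifier string cannot be parsed."""


@functools.total_ordering
@dataclass(frozen=True)
class TCNumber:
    """A parsed TC identifier.

    ``system`` is ``None`` for the four-token prefix form.  Ordering is
    lexicographic on the (class, subclass, family, subfamily, system)
    tuple, with an absent system sorting before any concrete system.
    """

    cls: int
    subclass: str
    family: int
    subfamily: int
    system: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.cls <= 9):
            raise TCParseError(f"class index must be 1-9, got {self.cls!r}")
        if len(self.subclass) != 1 or not self.subclass.isalpha() or not self.subclass.isupper():
            raise TCParseError(f"subclass must be a single uppercase letter, got {self.subclass!r}")
        for name in ("family", "subfamily"):
            v = getattr(self, name)
            if v < 1:
                raise TCParseError(f"{name} must be a positive integer, got {v!r}")
        if self.system is not None and self.system < 1:
            raise TCParseError(f"system must be a positive integer, got {self.system!r}")

    def _key(self) -> tuple:
        return (self.cls, self.subclass, self.family, self.subfamily,
                -1 if self.system is None else self.system)

    def __lt__(self, other: "TCNumber") -> bool:
        if not isinstance(other, TCNumber):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        parts = [str(self.cls), self.subclass, str(self.family), str(self.subfamily)]
        if self.system is not None:
            parts.append(str(self.system))
        return ".".join(parts)

    def prefix(self, k: int) -> str:
        """Return the first *k* levels as a dotted string, k in 1..5.

        ``prefix(4)`` is the key used for representative deduplication.
        """
        if not 1 <= k <= 5:
            raise ValueError(f"prefix level must be in 1..5, got {k}")
        parts = [str(self.cls), self.subclass, str(self.family), str(self.subfamily)]
        if self.system is not None:
            parts.append(str(self.system))
        if k > len(parts):
            raise ValueError(f"prefix({k}) requested but identifier has only {len(parts)} levels")
        return ".".join(parts[:k])


def parse_tc(text: str) -> TCNumber:
    """Parse a dotted TC identifier (4 or 5 tokens) into a :class:`TCNumber`."""
    tokens = text.strip().split(".")
    if len(tokens) not in (4, 5):
        raise TCParseError(f"expected 4 or 5 dot-separated tokens, got {len(tokens)} in {text!r}")

    def _int(tok: str, name: str) -> int:
        try:
            v = int(tok)
        except ValueError:
            raise TCParseError(f"{name} token {tok!r} in {text!r} is not an integer") from None
        if v < 1:
            raise TCParseError(f"{name} token {tok!r} in {text!r} must be positive")
        return v

    cls = _int(tokens[0], "class")
    sub = tokens[1]
    if len(sub) != 1 or not sub.isalpha():
        raise TCParseError(f"subclass token {sub!r} in {text!r} must be a single letter")
    fam = _int(tokens[2], "family")
    subfam = _int(tokens[3], "subfamily")
    system = _int(tokens[4], "system") if len(tokens) == 5 else None
    return TCNumber(cls, sub.upper(), fam, subfam, system)


@dataclass(frozen=True)
class FamilyEntry:
    """One domain-family registry entry (accession, name, optional clan)."""

    accession: str
    name: str = ""
    clan: str | None = None
    is_unknown_function: bool = False

    @staticmethod
    def infer_unknown_function(name: str) -> bool:
        """DUF/UPF naming marks families of unknown function."""
        u = name.upper()
        return u.startswith("DUF") or u.startswith("UPF")


class AssignmentTable:
    """Rows of (sequence id, TCNumber), indexed by id and by every prefix level.

    A sequence id may appear in multiple rows (one per TC number).
    """

    def __init__(self, rows: Iterable[tuple[str, TCNumber]] = ()):  # noqa: D107
        self.rows: list[tuple[str, TCNumber]] = list(rows)
        self._by_seq: dict[str, list[TCNumber]] = {}
        self._by_prefix: dict[str, list[str]] = {}
        for seq_id, tc in self.rows:
            self._by_seq.setdefault(seq_id, []).append(tc)
            max_k = 5 if tc.system is not None else 4
            for k in range(1, max_k + 1):
                self._by_prefix.setdefault(tc.prefix(k), []).append(seq_id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def seq_ids(self) -> list[str]:
        """Distinct sequence ids in first-appearance order."""
        return list(self._by_seq)

    def tc_numbers(self, seq_id: str) -> list[TCNumber]:
        return list(self._by_seq.get(seq_id, []))

    def by_prefix(self, prefix: str) -> list[str]:
        """Sequence ids whose TC number starts with *prefix* (union over rows)."""
        seen: dict[str, None] = {}
        for sid in self._by_prefix.get(prefix, []):
            seen.setdefault(sid)
        return list(seen)

    def prefixes(self, k: int) -> list[str]:
        """Distinct level-*k* prefixes present, in first-appearance order."""
        seen: dict[str, None] = {}
        for _, tc in self.rows:
            seen.setdefault(tc.prefix(k))
        return list(seen)


def filter_by_class(table: AssignmentTable, keep: Iterable[int]) -> AssignmentTable:
    """Keep only rows whose TC class is in *keep*.

    A sequence carrying TC numbers in both kept and dropped classes retains
    only the kept rows.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be nonempty")
    return AssignmentTable((sid, tc) for sid, tc in table.rows if tc.cls in keep)


def dedup_representatives(table: AssignmentTable, seqs: Mapping[str, str]) -> list[str]:
    """One representative sequence id per distinct 4-level TC prefix.

    The representative is the longest sequence in the group; ties break to
    the lexicographically smallest id.  Output order follows first
    appearance of each prefix in the table.
    """
    for sid, _ in table.rows:
        if sid not in seqs:
            raise KeyError(f"sequence id {sid!r} has no sequence in the store")
    groups: dict[str, list[str]] = {}
    for sid, tc in table.rows:
        groups.setdefault(tc.prefix(4), []).append(sid)
    reps = []
    for prefix, members in groups.items():
        best = min(members, key=lambda s: (-len(seqs[s]), s))
        reps.append(best)
    return reps


# ---------------------------------------------------------------------------
# TSV interfaces

def read_assignments(path: str | Path) -> AssignmentTable:
    """Read a two-column TSV ``seq_id<TAB>tc_number``; '#' lines are comments."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        try:
            tc = parse_tc(parts[1])
        except TCParseError as e:
            raise TCParseError(f"{path}:{lineno}: {e}") from None
        rows.append((parts[0], tc))
    return AssignmentTable(rows)


def write_assignments(table: AssignmentTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_id\ttc_number\n")
        for sid, tc in table.rows:
            fh.write(f"{sid}\t{tc}\n")


def read_registry(path: str | Path) -> list[FamilyEntry]:
    """Read a family registry TSV ``accession name clan duf_flag`` (clan may be empty)."""
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        acc, name, clan, duf = parts
        entries.append(FamilyEntry(acc, name, clan or None, duf == "1"))
    seen = set()
    for e in entries:
        if e.accession in seen:
            raise ValueError(f"duplicate accession {e.accession!r} in registry {path}")
        seen.add(e.accession)
    return entries


def write_registry(entries: Iterable[FamilyEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# accession\tname\tclan\tduf_flag\n")
        for e in entries:
            fh.write(f"{e.accession}\t{e.name}\t{e.clan or ''}\t{1 if e.is_unknown_function else 0}\n")
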