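"""Subclass match-matrix construction, SVG rendering and pattern analysis.

The match matrix plots the TC families of one subclass (rows) against the
domain families that match them (columns).  Each cell holds the average
number of hits per sequence of the TC family — the fraction of the
family's sequences matched, counting multiple hits per sequence, so values
can exceed 1 (tandem repeats).  Fractions are shaded on a 10-increment
scale; fractions above 1 fall in the top (0.9-1.0) bin.

The SVG writer attaches machine-readable attributes to every cell so a
separate analysis pass — possibly after hand-editing the file to delete
irrelevant cells — can reconstruct the matrix exactly and search it for
patterns such as isolated cells (a unique 1:1 family correspondence).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .classification import AssignmentTable
from .hit_io import HitTable
from .topology import TMSAnnotation, tms_count

__all__ = [
    "MatchMatrix",
    "MatrixPattern",
    "fraction_bin",
    "build_matrix",
    "write_svg",
    "read_svg",
    "find_patterns",
    "repfam_view",
]

SVG_NS = "http://www.w3.org/2000/svg"
FC_NS = "https://famcross.invalid/scv"

CELL = 18       # cell edge, px
MARGIN_L = 120  # room for row labels
MARGIN_T = 120  # room for column labels

#: light -> dark 10-step red ramp (bin 0 .. bin 9)
RAMP = [f"#ff{v:02x}{v:02x}" for v in range(230, 230 - 10 * 23, -23)]


def fraction_bin(fraction: float) -> int:
    """10-increment shading bin: min(floor(10 f), 9); f > 1 clamps to 9."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    return min(int(10 * fraction), 9)


@dataclass
class MatchMatrix:
    """TC-family x domain-family grid of binned match fractions."""

    row_labels: list[str]                       # TC family prefixes (level 3)
    col_labels: list[str]                       # domain-family accessions
    cells: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (r, c), f in self.cells.items():
            if f <= 0:
                raise ValueError(f"nonempty cell ({r},{c}) must have fraction > 0, got {f}")

    def fraction(self, row: str, col: str) -> float | None:
        return self.cells.get((row, col))

    def bin(self, row: str, col: str) -> int | None:
        f = self.cells.get((row, col))
        return None if f is None else fraction_bin(f)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MatchMatrix):
            return NotImplemented
        return (self.row_labels == other.row_labels
                and self.col_labels == other.col_labels
                and self.cells.keys() == other.cells.keys()
                and all(abs(self.cells[k] - other.cells[k]) <= 1e-9 * max(1.0, abs(self.cells[k]))
                        for k in self.cells))


def build_matrix(subclass: tuple[int, str], assignments: AssignmentTable,
                 hits: HitTable, evalue_max: float = 1e-5) -> MatchMatrix:
    """Build the match matrix for one subclass (e.g. ``(2, "A")``).

    cell(f, p) = (hits of domain family p over sequences of TC family f,
    counting multiple hits per sequence) / (number of sequences in f).
    TC families with no matching column still appear as all-empty rows;
    columns appear only when matched by at least one row.
    """
    cls, letter = subclass
    sub_prefix = f"{cls}.{letter}"
    fams = [p for p in assignments.prefixes(3) if p.startswith(sub_prefix + ".")]
    if not fams:
        raise ValueError(f"subclass {sub_prefix} not present in assignments")
    sig = hits.filtered(evalue_max)
    cells: dict[tuple[str, str], float] = {}
    col_order: dict[str, None] = {}
    for fam in sorted(fams):
        members = assignments.by_prefix(fam)
        counts: dict[str, int] = {}
        for sid in members:
            for h in sig.for_seq(sid):
                counts[h.family] = counts.get(h.family, 0) + 1
        for acc, n in counts.items():
            cells[(fam, acc)] = n / len(members)
            col_order.setdefault(acc)
    return MatchMatrix(row_labels=sorted(fams), col_labels=sorted(col_order), cells=cells)


# ---------------------------------------------------------------------------
# SVG round-trip

def write_svg(m: MatchMatrix, path: str | Path) -> None:
    """Render the matrix as an SVG grid.

    Every nonempty cell is a <rect> filled from the 10-step red ramp and
    carries machine-readable attributes (row, col, fraction with >=6
    significant digits, bin) in a dedicated namespace; geometric positions
    correspond to row/column order, so reported coordinates locate cells
    directly in a graphics editor.
    """
    ET.register_namespace("", SVG_NS)
    ET.register_namespace("fc", FC_NS)
    width = MARGIN_L + CELL * max(1, len(m.col_labels)) + 10
    height = MARGIN_T + CELL * max(1, len(m.row_labels)) + 10
    root = ET.Element(f"{{{SVG_NS}}}svg", {
        "width": str(width), "height": str(height), "version": "1.1",
        f"{{{FC_NS}}}rows": "|".join(m.row_labels),
        f"{{{FC_NS}}}cols": "|".join(m.col_labels),
    })
    for j, col in enumerate(m.col_labels):
        x = MARGIN_L + j * CELL + CELL // 2
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "x": str(x), "y": str(MARGIN_T - 6), "font-size": "9",
            "transform": f"rotate(-60 {x} {MARGIN_T - 6})",
        })
        t.text = col
    for i, row in enumerate(m.row_labels):
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "x": str(MARGIN_L - 6), "y": str(MARGIN_T + i * CELL + CELL - 5),
            "font-size": "9", "text-anchor": "end",
        })
        t.text = row
    for (row, col), frac in sorted(m.cells.items()):
        i, j = m.row_labels.index(row), m.col_labels.index(col)
        b = fraction_bin(frac)
        ET.SubElement(root, f"{{{SVG_NS}}}rect", {
            "x": str(MARGIN_L + j * CELL), "y": str(MARGIN_T + i * CELL),
            "width": str(CELL), "height": str(CELL),
            "fill": RAMP[b], "stroke": "#999999",
            f"{{{FC_NS}}}row": row, f"{{{FC_NS}}}col": col,
            f"{{{FC_NS}}}fraction": repr(frac), f"{{{FC_NS}}}bin": str(b),
        })
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")


def read_svg(path: str | Path) -> MatchMatrix:
    """Reconstruct a matrix from an SVG produced by :func:`write_svg`.

    Cells deleted by hand-editing are simply absent from the result; row
    and column label order is preserved via root attributes.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as e:
        raise ValueError(f"{path}: not a well-formed SVG file ({e})") from None
    root = tree.getroot()
    rows_attr = root.get(f"{{{FC_NS}}}rows")
    cols_attr = root.get(f"{{{FC_NS}}}cols")
    if rows_attr is None or cols_attr is None:
        raise ValueError(f"{path}: missing matrix metadata attributes (fc:rows, fc:cols)")
    row_labels = rows_attr.split("|") if rows_attr else []
    col_labels = cols_attr.split("|") if cols_attr else []
    cells: dict[tuple[str, str], float] = {}
    for rect in root.iter(f"{{{SVG_NS}}}rect"):
        row = rect.get(f"{{{FC_NS}}}row")
        col = rect.get(f"{{{FC_NS}}}col")
        frac = rect.get(f"{{{FC_NS}}}fraction")
        if row is None and col is None and frac is None:
            continue  # decoration, not a cell
        missing = [n for n, v in (("fc:row", row), ("fc:col", col), ("fc:fraction", frac)) if v is None]
        if missing:
            raise ValueError(f"{path}: cell rect missing attributes {missing}")
        cells[(row, col)] = float(frac)
    return MatchMatrix(row_labels=row_labels, col_labels=col_labels, cells=cells)


# ---------------------------------------------------------------------------
# Pattern analysis

@dataclass
class MatrixPattern:
    """Isolated cells and multi-hit rows/columns of a match matrix."""

    isolated: list[tuple[str, str]]
    multi_hit_rows: list[str]
    multi_hit_cols: list[str]


def find_patterns(m: MatchMatrix, adjacency_only: bool = False) -> MatrixPattern:
    """Find isolated cells (candidate 1:1 family correspondences).

    Default reading: a cell is isolated when its whole row and whole
    column contain no other nonempty cell.  With *adjacency_only*, only
    the four immediate neighbors are required to be empty.
    """
    row_counts: dict[str, int] = {}
    col_counts: dict[str, int] = {}
    for (r, c) in m.cells:
        row_counts[r] = row_counts.get(r, 0) + 1
        col_counts[c] = col_counts.get(c, 0) + 1
    if adjacency_only:
        ri = {r: i for i, r in enumerate(m.row_labels)}
        ci = {c: j for j, c in enumerate(m.col_labels)}
        occupied = {(ri[r], ci[c]) for (r, c) in m.cells}
        isolated = [
            (r, c) for (r, c) in m.cells
            if not any((ri[r] + di, ci[c] + dj) in occupied
                       for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)))
        ]
    else:
        isolated = [(r, c) for (r, c) in m.cells
                    if row_counts[r] == 1 and col_counts[c] == 1]
    isolated.sort(key=lambda rc: (m.row_labels.index(rc[0]), m.col_labels.index(rc[1])))
    return MatrixPattern(
        isolated=isolated,
        multi_hit_rows=[r for r in m.row_labels if row_counts.get(r, 0) >= 2],
        multi_hit_cols=[c for c in m.col_labels if col_counts.get(c, 0) >= 2],
    )


def cell_svg_position(m: MatchMatrix, row: str, col: str) -> tuple[int, int]:
    """Pixel position of a cell in the written SVG (top-left corner)."""
    return (MARGIN_L + m.col_labels.index(col) * CELL,
            MARGIN_T + m.row_labels.index(row) * CELL)


# ---------------------------------------------------------------------------
# TMS-overlay family report

def repfam_view(tc_family: str, assignments: AssignmentTable, hits: HitTable,
                tms: dict[str, TMSAnnotation]) -> dict:
    """Report how domain hits to one TC family relate to membrane topology.

    For every (sequence, hit): the hit envelope and the number of TMSs
    fully contained in it (a partially covered TMS does not count); per
    domain family, the mean TMS count per hit.  Sequences without a TMS
    annotation are skipped and listed.
    """
    members = assignments.by_prefix(tc_family)
    if not members:
        raise ValueError(f"TC family {tc_family!r} not present in assignments")
    per_hit: list[dict] = []
    skipped: list[str] = []
    by_family: dict[str, list[int]] = {}
    for sid in members:
        ann = tms.get(sid)
        if ann is None:
            skipped.append(sid)
            continue
        for h in hits.for_seq(sid):
            inside = [(s, e) for s, e in ann.segments if s >= h.start and e <= h.end]
            per_hit.append({
                "seq_id": sid, "family": h.family, "start": h.start, "end": h.end,
                "tms_inside": inside, "n_tms": len(inside),
            })
            by_family.setdefault(h.family, []).append(len(inside))
    mean_tms = {fam: sum(v) / len(v) for fam, v in by_family.items()}
    return {
        "tc_family": tc_family,
        "containment_rule": "TMS counted only when fully inside the hit envelope",
        "hits": per_hit,
        "mean_tms_per_hit": mean_tms,
        "skipped": skipped,
    }
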