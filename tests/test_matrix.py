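"""Match-matrix construction, binning, SVG round-trip and pattern search."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famcross.classification import AssignmentTable, parse_tc
from famcross.hit_io import DomainHit, HitTable
from famcross.matrix import (FC_NS, RAMP, SVG_NS, MatchMatrix, build_matrix,
                             find_patterns, fraction_bin, read_svg,
                             repfam_view, write_svg)
from famcross.topology import TMSAnnotation


@settings(max_examples=300, deadline=None)
@given(st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
def test_binning_law(f):
    b = fraction_bin(f)
    assert b == min(int(np.floor(10 * f)), 9)
    assert 0 <= b <= 9


@pytest.mark.parametrize("f,expected", [
    (0.05, 0), (0.1, 1), (0.95, 9),
    (1.0, 9),    # the 0.9-1.0 bin is top
    (1.7, 9),    # more than one average hit per sequence clamps to top
    (2.5, 9),
])
def test_binning_examples(f, expected):
    assert fraction_bin(f) == expected


def _toy_world():
    rows = [(f"f1_s{i}", parse_tc(f"2.A.1.1.{i}")) for i in range(1, 5)]
    rows += [(f"f2_s{i}", parse_tc(f"2.A.2.1.{i}")) for i in range(1, 3)]
    rows += [("f3_s1", parse_tc("2.A.3.1.1"))]
    table = AssignmentTable(rows)
    hits = HitTable([
        # 2 of f1's 4 sequences hit PFa once -> fraction 0.5
        DomainHit("f1_s1", "PFa", None, 1, 50, 1e-10, 5.0),
        DomainHit("f1_s2", "PFa", None, 1, 50, 1e-10, 5.0),
        # both f2 sequences carry a tandem double hit -> fraction 2.0
        DomainHit("f2_s1", "PFb", None, 1, 40, 1e-10, 5.0),
        DomainHit("f2_s1", "PFb", None, 41, 80, 1e-10, 5.0),
        DomainHit("f2_s2", "PFb", None, 1, 40, 1e-10, 5.0),
        DomainHit("f2_s2", "PFb", None, 41, 80, 1e-10, 5.0),
        # a hit above the default threshold is ignored
        DomainHit("f3_s1", "PFc", None, 1, 40, 1e-3, 5.0),
    ])
    return table, hits


class TestBuildMatrix:
    def test_fraction_definition_and_tandem_hits(self):
        table, hits = _toy_world()
        m = build_matrix((2, "A"), table, hits)
        assert m.fraction("2.A.1", "PFa") == pytest.approx(0.5)
        assert m.bin("2.A.1", "PFa") == 5
        assert m.fraction("2.A.2", "PFb") == pytest.approx(2.0)
        assert m.bin("2.A.2", "PFb") == 9

    def test_unmatched_family_keeps_empty_row_and_no_empty_columns(self):
        table, hits = _toy_world()
        m = build_matrix((2, "A"), table, hits)
        assert "2.A.3" in m.row_labels        # visible all-empty row
        assert "PFc" not in m.col_labels      # its only hit fell above threshold

    def test_unknown_subclass_is_an_error(self):
        table, hits = _toy_world()
        with pytest.raises(ValueError, match="9.Z"):
            build_matrix((9, "Z"), table, hits)

    def test_matrix_equals_planted_incidence(self, bundle, manifest):
        m = build_matrix((2, "A"), bundle.assignments, bundle.hits)
        for fam in manifest["families"]:
            if not fam["tc_prefix3"].startswith("2.A."):
                continue
            got = m.fraction(fam["tc_prefix3"], fam["accession"])
            if fam["orphan"]:
                assert got is None
                assert fam["tc_prefix3"] in m.row_labels
            else:
                assert got == pytest.approx(fam["hit_fraction"])

    def test_brute_force_recount_oracle(self, bundle):
        m = build_matrix((2, "A"), bundle.assignments, bundle.hits, evalue_max=1e-5)
        sig = [h for h in bundle.hits if h.evalue <= 1e-5]
        for row in m.row_labels:
            members = bundle.assignments.by_prefix(row)
            for col in m.col_labels:
                n = sum(1 for h in sig if h.family == col and h.seq_id in set(members))
                expected = n / len(members) if n else None
                assert m.fraction(row, col) == (pytest.approx(expected) if expected else None)


class TestSvgRoundTrip:
    def test_write_read_identity(self, tmp_path, bundle):
        m = build_matrix((2, "A"), bundle.assignments, bundle.hits)
        p = tmp_path / "m.svg"
        write_svg(m, p)
        assert read_svg(p) == m

    def test_one_by_one_matrix_uses_darkest_ramp(self, tmp_path):
        m = MatchMatrix(["r"], ["c"], {("r", "c"): 1.0})
        p = tmp_path / "m.svg"
        write_svg(m, p)
        rects = [el for el in ET.parse(p).getroot().iter(f"{{{SVG_NS}}}rect")]
        assert len(rects) == 1
        assert rects[0].get("fill") == RAMP[9]
        assert RAMP[9] < RAMP[0]  # darker = smaller channel values

    def test_empty_matrix_has_labels_but_no_cells(self, tmp_path):
        m = MatchMatrix(["r1", "r2"], [], {})
        p = tmp_path / "m.svg"
        write_svg(m, p)
        root = ET.parse(p).getroot()
        assert not list(root.iter(f"{{{SVG_NS}}}rect"))
        assert read_svg(p) == m

    def test_hand_deleted_cell_is_absent_after_reread(self, tmp_path):
        m = MatchMatrix(["r1", "r2"], ["c1", "c2"],
                        {("r1", "c1"): 0.5, ("r2", "c2"): 1.0})
        p = tmp_path / "m.svg"
        write_svg(m, p)
        tree = ET.parse(p)
        root = tree.getroot()
        victim = [el for el in root.iter(f"{{{SVG_NS}}}rect")
                  if el.get(f"{{{FC_NS}}}row") == "r1"][0]
        root.remove(victim)
        tree.write(p)
        m2 = read_svg(p)
        assert ("r1", "c1") not in m2.cells
        assert m2.cells[("r2", "c2")] == 1.0
        assert m2.row_labels == m.row_labels  # labels survive the edit

    def test_unreadable_files_rejected(self, tmp_path):
        empty = tmp_path / "empty.svg"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_svg(empty)
        alien = tmp_path / "alien.svg"
        alien.write_text(f'<svg xmlns="{SVG_NS}"><rect x="0"/></svg>')
        with pytest.raises(ValueError, match="metadata"):
            read_svg(alien)


def _random_sparse(rng, n_rows=20, n_cols=30, density=0.05):
    rows = [f"r{i}" for i in range(n_rows)]
    cols = [f"c{j}" for j in range(n_cols)]
    cells = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if rng.random() < density:
                cells[(rows[i], cols[j])] = float(rng.uniform(0.05, 2.5))
    return MatchMatrix(rows, cols, cells)


def _patterns_oracle(m):
    """Exhaustive O(rows x cols) scan."""
    isolated = []
    for (r, c) in m.cells:
        row_others = any(c2 != c for (r2, c2) in m.cells if r2 == r)
        col_others = any(r2 != r for (r2, c2) in m.cells if c2 == c)
        if not row_others and not col_others:
            isolated.append((r, c))
    return set(isolated)


class TestFindPatterns:
    def test_diagonal_matrix_is_all_isolated(self):
        labels = ["a", "b", "c"]
        m = MatchMatrix(labels, labels, {(x, x): 1.0 for x in labels})
        assert len(find_patterns(m).isolated) == 3

    def test_full_matrix_has_no_isolated_cells(self):
        m = MatchMatrix(["a", "b"], ["x", "y"],
                        {(r, c): 1.0 for r in "ab" for c in "xy"})
        pat = find_patterns(m)
        assert pat.isolated == []
        assert pat.multi_hit_rows == ["a", "b"]
        assert pat.multi_hit_cols == ["x", "y"]

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            m = _random_sparse(rng)
            assert set(find_patterns(m).isolated) == _patterns_oracle(m)

    def test_isolated_cells_not_in_multi_hit_lists(self):
        rng = np.random.default_rng(99)
        m = _random_sparse(rng, density=0.15)
        pat = find_patterns(m)
        for r, c in pat.isolated:
            assert r not in pat.multi_hit_rows
            assert c not in pat.multi_hit_cols

    def test_adjacency_only_mode_differs(self):
        # two cells in one row but far apart: isolated by adjacency, not by row
        m = MatchMatrix(["r"], ["c0", "c1", "c2", "c3"],
                        {("r", "c0"): 1.0, ("r", "c3"): 1.0})
        assert find_patterns(m).isolated == []
        assert len(find_patterns(m, adjacency_only=True).isolated) == 2


class TestRepfamView:
    def test_tms_containment_per_hit(self):
        table = AssignmentTable([("s1", parse_tc("2.A.7.1.1"))])
        hits = HitTable([DomainHit("s1", "PFx", None, 1, 200, 1e-10, 5.0),
                         DomainHit("s1", "PFy", None, 40, 60, 1e-10, 5.0)])
        tms = {"s1": TMSAnnotation("s1", [(10, 30), (50, 70), (210, 230)])}
        rep = repfam_view("2.A.7", table, hits, tms)
        by_fam = {h["family"]: h for h in rep["hits"]}
        assert by_fam["PFx"]["n_tms"] == 2          # 210-230 is outside 1-200
        assert by_fam["PFy"]["n_tms"] == 0          # 50-70 only half-covered
        assert rep["mean_tms_per_hit"]["PFx"] == 2.0

    def test_missing_annotation_skips_sequence(self):
        table = AssignmentTable([("s1", parse_tc("2.A.7.1.1")),
                                 ("s2", parse_tc("2.A.7.1.2"))])
        hits = HitTable([DomainHit("s1", "PFx", None, 1, 100, 1e-10, 5.0),
                         DomainHit("s2", "PFx", None, 1, 100, 1e-10, 5.0)])
        tms = {"s1": TMSAnnotation("s1", [(10, 30)])}
        rep = repfam_view("2.A.7", table, hits, tms)
        assert rep["skipped"] == ["s2"]
        assert len(rep["hits"]) == 1

    def test_planted_four_tms_families_average_four(self, bundle, manifest):
        fam = next(f for f in manifest["families"]
                   if not f["orphan"] and not f["multi_hit"])
        rep = repfam_view(fam["tc_prefix3"], bundle.assignments, bundle.hits, bundle.tms)
        assert rep["mean_tms_per_hit"][fam["accession"]] == pytest.approx(4.0)
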