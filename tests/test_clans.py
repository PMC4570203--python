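"""Clan correspondence, majority rules and the candidate-entry pipeline."""

import pytest

from famcross.classification import AssignmentTable, FamilyEntry, parse_tc
from famcross.clans import (CANDIDATE_EVALUE_MAX, CANDIDATE_EVALUE_MIN,
                            SuperfamilyDef, candidate_pipeline,
                            candidate_verdict, karlin_altschul_evalue,
                            propose_clan_changes, superfamily_to_clans)
from famcross.hit_io import DomainHit, HitTable


def _world(clans_by_family, evalue=1e-30):
    """One superfamily whose sequences hit each listed family once."""
    rows = [("s1", parse_tc("2.A.1.1.1"))]
    table = AssignmentTable(rows)
    hits = HitTable([DomainHit("s1", fam, clan, 1, 50, evalue, 10.0)
                     for fam, clan in clans_by_family.items()])
    registry = [FamilyEntry(fam, fam, clan, False)
                for fam, clan in clans_by_family.items()]
    sf = SuperfamilyDef("SF", ("2.A.1",))
    return sf, table, hits, registry


class TestSuperfamilyToClans:
    def test_majority_with_outlier(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": "X",
                                       "P4": "X", "P5": "Y"})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert c.dominant_clan == "X"
        assert c.dominant_fraction == pytest.approx(0.8)
        assert c.outliers == ["P5"]

    def test_tie_yields_no_dominant_clan(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "Y"})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert c.dominant_clan is None
        assert c.tied_clans == ["X", "Y"]
        assert propose_clan_changes(c) == []

    def test_evalue_cutoff_applies_per_hit(self):
        sf, table, hits, reg = _world({"P1": "X"}, evalue=1e-20)
        c = superfamily_to_clans(sf, table, hits, reg, evalue_max=1e-25)
        assert c.matched_families == {}
        # inclusive at the threshold itself
        sf, table, hits, reg = _world({"P1": "X"}, evalue=1e-25)
        c = superfamily_to_clans(sf, table, hits, reg, evalue_max=1e-25)
        assert "P1" in c.matched_families

    def test_raising_cutoff_never_shrinks_matches(self, bundle):
        sf = bundle.superfamilies[0]
        prev: set = set()
        for e in (1e-30, 1e-25, 1e-10, 1e-3):
            c = superfamily_to_clans(sf, bundle.assignments, bundle.hits,
                                     bundle.registry, evalue_max=e)
            assert prev <= set(c.matched_families)
            prev = set(c.matched_families)

    def test_planted_dominant_clan_recovered(self, bundle, manifest):
        for sf in bundle.superfamilies:
            fams = [f for f in manifest["families"]
                    if f["superfamily"] == sf.name and not f["orphan"]]
            clans = [f["clan_assigned"] for f in fams]
            expected = max(set(clans), key=lambda c: (clans.count(c), c))
            counts = sorted(clans.count(c) for c in set(clans))
            if len(set(clans)) > 1 and counts[-1] == counts[-2]:
                continue  # planted tie; no unique mode to recover
            c = superfamily_to_clans(sf, bundle.assignments, bundle.hits, bundle.registry)
            assert c.dominant_clan == expected
            assert c.dominant_fraction == pytest.approx(clans.count(expected) / len(clans))


class TestProposeClanChanges:
    def test_proposes_for_each_outlier_above_threshold(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": "X",
                                       "P4": "X", "P5": "Y"})
        c = superfamily_to_clans(sf, table, hits, reg)
        props = propose_clan_changes(c)
        assert len(props) == 1
        assert props[0]["family"] == "P5" and props[0]["proposed_clan"] == "X"

    def test_below_threshold_no_proposals(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": "Y", "P4": "Z"})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert c.dominant_fraction == pytest.approx(0.5)
        assert propose_clan_changes(c) == []

    def test_exact_threshold_is_inclusive(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": "X",
                                       "P4": "Y", "P5": "Z"})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert c.dominant_fraction == pytest.approx(0.6)
        assert len(propose_clan_changes(c, min_fraction=0.6)) == 2

    def test_extreme_min_fraction_bounds(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": "Y"})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert len(propose_clan_changes(c, min_fraction=0.0)) == len(c.outliers)
        assert propose_clan_changes(c, min_fraction=1.01) == []

    def test_clanless_family_proposed_to_join_dominant(self):
        sf, table, hits, reg = _world({"P1": "X", "P2": "X", "P3": None})
        c = superfamily_to_clans(sf, table, hits, reg)
        assert c.dominant_fraction == pytest.approx(1.0)  # among labeled families
        props = propose_clan_changes(c)
        assert [p["family"] for p in props] == ["P3"]
        assert props[0]["current_clan"] is None


class TestCandidateVerdict:
    @pytest.mark.parametrize("delta,evalue,expected,failing", [
        (1, 1e-4, True, []),                       # both filters satisfied
        (-1, 1e-4, True, []),                      # +-1 is symmetric
        (2, 1e-4, False, ["tms_delta"]),
        (0, 0.1, True, []),                        # upper bound inclusive
        (0, 1e-7, True, []),                       # lower bound inclusive
        (0, 1e-8, False, ["evalue_window"]),       # too close: already in the system
        (0, 0.2, False, ["evalue_window"]),
        (2, 1e-9, False, ["tms_delta", "evalue_window"]),
    ])
    def test_boundary_cases(self, delta, evalue, expected, failing):
        ok, fails = candidate_verdict(delta, evalue)
        assert ok is expected
        assert fails == failing


def _clan_world(n_hitting, n_total):
    """A clan with n_total families of which n_hitting hit the superfamily."""
    rows = [("s1", parse_tc("2.A.1.1.1"))]
    table = AssignmentTable(rows)
    registry, hits = [], []
    for i in range(n_total):
        fam = f"P{i}"
        registry.append(FamilyEntry(fam, fam, "CLX", False))
        if i < n_hitting:
            hits.append(DomainHit("s1", fam, "CLX", 1, 50, 1e-30, 10.0))
    sf = SuperfamilyDef("SF", ("2.A.1",))
    return sf, table, HitTable(hits), registry


class TestCandidatePipeline:
    def test_clan_selected_only_above_half(self):
        # exactly half does not qualify ("more than half" is strict)
        sf, table, hits, reg = _clan_world(2, 4)
        recs = candidate_pipeline(sf, table, hits, reg, {"s1": "LLLL"}, {}, {})
        assert recs == []
        sf, table, hits, reg = _clan_world(3, 4)
        recs = candidate_pipeline(sf, table, hits, reg, {"s1": "LLLL"}, {}, {})
        assert [r.family for r in recs] == ["P3"]

    def test_family_without_representative_is_flagged(self):
        sf, table, hits, reg = _clan_world(3, 4)
        recs = candidate_pipeline(sf, table, hits, reg, {"s1": "LLLL"}, {}, {})
        assert recs[0].verdict is None
        assert recs[0].failing_filters == ["no_representative"]

    def test_verdicts_match_rule_applied_to_reported_evidence(self, bundle):
        for sf in bundle.superfamilies:
            recs = candidate_pipeline(sf, bundle.assignments, bundle.hits,
                                      bundle.registry, bundle.seqs, bundle.tms,
                                      bundle.family_reps)
            for r in recs:
                expected, fails = candidate_verdict(r.candidate_tms - r.closest_tms,
                                                    r.evalue)
                assert r.verdict is expected
                assert r.failing_filters == fails

    def test_candidate_enumeration_matches_brute_force(self, bundle, manifest):
        """Steps 1-2 recomputed independently from the raw tables."""
        reg = bundle.registry
        assigned = set(bundle.assignments.seq_ids)
        hit_anywhere = {h.family for h in bundle.hits if h.seq_id in assigned}
        for sf in bundle.superfamilies:
            sf_seqs = {s for p in sf.members for s in bundle.assignments.by_prefix(p)}
            sf_fams = {h.family for h in bundle.hits if h.seq_id in sf_seqs}
            expected = set()
            for clan in {e.clan for e in reg if e.clan}:
                members = [e.accession for e in reg if e.clan == clan]
                if sum(f in sf_fams for f in members) / len(members) > 0.5:
                    expected |= {f for f in members if f not in hit_anywhere}
            recs = candidate_pipeline(sf, bundle.assignments, bundle.hits, reg,
                                      bundle.seqs, bundle.tms, bundle.family_reps)
            assert {r.family for r in recs} == expected

    def test_pipeline_surfaces_pass_and_fail_plantings(self, bundle):
        """Across the planted universe, some candidates pass and others are
        rejected by each filter."""
        all_recs = [r for sf in bundle.superfamilies
                    for r in candidate_pipeline(sf, bundle.assignments, bundle.hits,
                                                bundle.registry, bundle.seqs,
                                                bundle.tms, bundle.family_reps)]
        assert any(r.verdict for r in all_recs)
        assert any("tms_delta" in r.failing_filters for r in all_recs)
        assert any("evalue_window" in r.failing_filters for r in all_recs)

    def test_verdicts_invariant_to_database_order(self):
        sf, table, hits, reg = _clan_world(3, 4)
        seqs = {"s1": "MKLLIVAFGGDE" * 10, "rep": "MKLLIVAFGGDE" * 10}
        from famcross.topology import TMSAnnotation
        tms = {"s1": TMSAnnotation("s1", [(5, 25)]), "rep": TMSAnnotation("rep", [(5, 25)])}
        r1 = candidate_pipeline(sf, table, hits, reg, seqs, tms, {"P3": "rep"})
        r2 = candidate_pipeline(sf, table, hits, reg, dict(reversed(list(seqs.items()))),
                                tms, {"P3": "rep"})
        assert r1 == r2


def test_karlin_altschul_monotone_in_score():
    e1 = karlin_altschul_evalue(50, 300, 30000)
    e2 = karlin_altschul_evalue(100, 300, 30000)
    assert e2 < e1
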