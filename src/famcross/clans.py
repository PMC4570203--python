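"""Clan <-> superfamily correspondence and the candidate-entry pipeline.

A TC superfamily is a curated grouping of TC families outside the
five-level hierarchy.  Its counterpart in a domain database is the clan.
Correspondence is established by majority rule over the domain families
matching the superfamily's sequences: when at least 60% of matching
families share one clan, that clan is the superfamily's counterpart, and
families outside it become proposals for clan reclassification.

The candidate pipeline runs the other direction — finding domain families
that plausibly belong in the transporter database but are absent from it:
clans where more than half the member families hit the superfamily are
scanned for families with no hit to any classified sequence; each such
family's representative is aligned against the classified sequences, and
a candidate passes when its TMS count is within +-1 of its closest match
and the alignment E-value lies in [1e-7, 0.1] — distant enough to be a
novel subfamily, close enough to be credibly related.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .classification import AssignmentTable, FamilyEntry
from .hit_io import HitTable
from .homology import AlignParams, align_score
from .topology import TMSAnnotation

__all__ = [
    "SuperfamilyDef",
    "ClanCorrespondence",
    "CandidateRecord",
    "superfamily_to_clans",
    "propose_clan_changes",
    "candidate_verdict",
    "candidate_pipeline",
    "karlin_altschul_evalue",
    "CANDIDATE_EVALUE_MIN",
    "CANDIDATE_EVALUE_MAX",
    "CANDIDATE_TMS_DELTA",
]

#: Candidate filters: |delta TMS| <= 1 and E-value in [1e-7, 0.1], both ends
#: inclusive.  The lower bound deliberately excludes near-identical matches:
#: the pipeline looks for distant relatives representing novel subfamilies.
CANDIDATE_EVALUE_MIN = 1e-7
CANDIDATE_EVALUE_MAX = 0.1
CANDIDATE_TMS_DELTA = 1


@dataclass(frozen=True)
class SuperfamilyDef:
    """A named set of member TC family prefixes (level 2 or 3)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"superfamily {self.name!r} has no members")


@dataclass
class ClanCorrespondence:
    superfamily: str
    matched_families: dict[str, str | None]   # accession -> clan (None = clanless)
    dominant_clan: str | None
    dominant_fraction: float                  # |dominant| / |matched with any clan|
    tied_clans: list[str] = field(default_factory=list)
    outliers: list[str] = field(default_factory=list)  # matched, not in dominant clan


def superfamily_to_clans(sf: SuperfamilyDef, assignments: AssignmentTable,
                         hits: HitTable, registry: Sequence[FamilyEntry],
                         evalue_max: float = 1e-25) -> ClanCorrespondence:
    """Majority-rule clan correspondence for one superfamily.

    Matched families are those with at least one hit at E <= *evalue_max*
    (applied per hit) to any sequence of any member TC family.  The
    dominant clan is the mode of clan labels among matched families;
    a tie yields no dominant clan.  Clanless matched families count as
    outliers (candidates to join the dominant clan) but not in the
    majority denominator.
    """
    member_seqs: dict[str, None] = {}
    for prefix in sf.members:
        for sid in assignments.by_prefix(prefix):
            member_seqs.setdefault(sid)
    clan_of = {e.accession: e.clan for e in registry}
    sig = hits.filtered(evalue_max)
    matched: dict[str, str | None] = {}
    for sid in member_seqs:
        for h in sig.for_seq(sid):
            matched.setdefault(h.family, clan_of.get(h.family, h.clan))
    labeled = [c for c in matched.values() if c]
    if not labeled:
        return ClanCorrespondence(sf.name, matched, None, 0.0)
    counts = Counter(labeled)
    top = max(counts.values())
    modes = sorted(c for c, n in counts.items() if n == top)
    if len(modes) > 1:
        return ClanCorrespondence(sf.name, matched, None, top / len(labeled),
                                  tied_clans=modes,
                                  outliers=sorted(a for a, c in matched.items() if c not in modes))
    dominant = modes[0]
    return ClanCorrespondence(
        sf.name, matched, dominant, top / len(labeled),
        outliers=sorted(a for a, c in matched.items() if c != dominant),
    )


def propose_clan_changes(c: ClanCorrespondence, min_fraction: float = 0.6) -> list[dict]:
    """Clan-membership proposals for outlier families.

    Emitted only when a dominant clan exists and its fraction reaches
    *min_fraction* (inclusive); one proposal per outlier, including
    clanless families (proposed to join the dominant clan).
    """
    if c.dominant_clan is None or c.dominant_fraction < min_fraction:
        return []
    return [{
        "superfamily": c.superfamily,
        "family": acc,
        "current_clan": c.matched_families.get(acc),
        "proposed_clan": c.dominant_clan,
        "dominant_fraction": c.dominant_fraction,
    } for acc in c.outliers]


# ---------------------------------------------------------------------------
# Candidate pipeline

@dataclass
class CandidateRecord:
    """A domain family proposed for entry into the transporter database."""

    family: str
    clan: str | None
    rep_seq_id: str | None
    candidate_tms: int | None
    closest_seq_id: str | None
    closest_tms: int | None
    align_score: float | None
    evalue: float | None
    verdict: bool | None            # None when no representative was available
    failing_filters: list[str] = field(default_factory=list)


def karlin_altschul_evalue(score: float, query_len: int, db_residues: int,
                           lam: float = 0.267, k: float = 0.041) -> float:
    """Convert a raw alignment score to an extreme-value expectation.

    E = K * m * n * exp(-lambda * S) with gapped BLOSUM62 defaults
    (lambda = 0.267, K = 0.041); m is the query length and n the total
    residue count of the searched database.
    """
    return k * query_len * db_residues * math.exp(-lam * score)


def candidate_verdict(delta_tms: int, evalue: float,
                      tms_delta_max: int = CANDIDATE_TMS_DELTA,
                      evalue_min: float = CANDIDATE_EVALUE_MIN,
                      evalue_max: float = CANDIDATE_EVALUE_MAX) -> tuple[bool, list[str]]:
    """Apply the candidate filters; returns (pass, failing filter names)."""
    failing = []
    if abs(delta_tms) > tms_delta_max:
        failing.append("tms_delta")
    if not (evalue_min <= evalue <= evalue_max):
        failing.append("evalue_window")
    return (not failing, failing)


def candidate_pipeline(sf: SuperfamilyDef, assignments: AssignmentTable,
                       hits: HitTable, registry: Sequence[FamilyEntry],
                       seqs: Mapping[str, str], tms: Mapping[str, TMSAnnotation],
                       family_reps: Mapping[str, str],
                       aligner: Callable[[str, str], float] | None = None,
                       params: AlignParams | None = None,
                       exclude_prefixes: Sequence[str] = (),
                       evalue_min: float = CANDIDATE_EVALUE_MIN,
                       evalue_max: float = CANDIDATE_EVALUE_MAX,
                       tms_delta_max: int = CANDIDATE_TMS_DELTA) -> list[CandidateRecord]:
    """Find domain families that may warrant new transporter-database entries.

    Steps: (1) select clans where strictly more than half of the clan's
    families hit the superfamily's sequences; (2) within those clans, take
    families with zero hits to any classified sequence; (3) align each
    family's representative (from *family_reps*) against every classified
    sequence, keeping the best score (ties: smaller E-value, then smaller
    id); (4) apply the TMS-difference and E-value-window filters.  Every
    record carries its full evidence trail.  *exclude_prefixes* removes
    multi-component systems the caller wants pre-filtered.
    """
    align = aligner or (lambda a, b: align_score(a, b, params))

    def _excluded(sid: str) -> bool:
        for tc in assignments.tc_numbers(sid):
            s = str(tc)
            if any(s == p or s.startswith(p + ".") for p in exclude_prefixes):
                return True
        return False

    sf_seqs: dict[str, None] = {}
    for prefix in sf.members:
        for sid in assignments.by_prefix(prefix):
            if exclude_prefixes and _excluded(sid):
                continue
            sf_seqs.setdefault(sid)
    clan_families: dict[str, list[str]] = {}
    for e in registry:
        if e.clan:
            clan_families.setdefault(e.clan, []).append(e.accession)
    hit_families_sf = {h.family for sid in sf_seqs for h in hits.for_seq(sid)}
    # step 1: clans with > 1/2 of member families hitting the superfamily
    selected_clans = [clan for clan, fams in clan_families.items()
                      if sum(1 for f in fams if f in hit_families_sf) / len(fams) > 0.5]
    # step 2: their families with zero hits to ANY classified sequence
    assigned = set(assignments.seq_ids)
    hit_anywhere = {h.family for h in hits if h.seq_id in assigned}
    candidates = sorted(f for clan in selected_clans for f in clan_families[clan]
                        if f not in hit_anywhere)
    clan_of = {e.accession: e.clan for e in registry}

    db_ids = sorted(sf_seqs)
    db_residues = sum(len(seqs[sid]) for sid in db_ids if sid in seqs)
    records: list[CandidateRecord] = []
    for fam in candidates:
        rep = family_reps.get(fam)
        if rep is None or rep not in seqs:
            records.append(CandidateRecord(fam, clan_of.get(fam), rep, None, None,
                                           None, None, None, None, ["no_representative"]))
            continue
        rep_seq = seqs[rep]
        # step 3: best match among classified sequences, deterministic tie-break
        best: tuple[float, float, str] | None = None  # (-score, evalue, id)
        for sid in db_ids:
            if sid not in seqs:
                continue
            s = align(rep_seq, seqs[sid])
            e = karlin_altschul_evalue(s, len(rep_seq), db_residues)
            key = (-s, e, sid)
            if best is None or key < best:
                best = key
        if best is None:
            records.append(CandidateRecord(fam, clan_of.get(fam), rep, None, None,
                                           None, None, None, None, ["empty_database"]))
            continue
        score, evalue, closest = -best[0], best[1], best[2]
        cand_tms = len(tms[rep]) if rep in tms else None
        closest_tms = len(tms[closest]) if closest in tms else None
        if cand_tms is None or closest_tms is None:
            records.append(CandidateRecord(fam, clan_of.get(fam), rep, cand_tms, closest,
                                           closest_tms, score, evalue, None, ["missing_tms"]))
            continue
        ok, failing = candidate_verdict(cand_tms - closest_tms, evalue,
                                        tms_delta_max, evalue_min, evalue_max)
        records.append(CandidateRecord(fam, clan_of.get(fam), rep, cand_tms, closest,
                                       closest_tms, score, evalue, ok, failing))
    return records
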