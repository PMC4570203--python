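"""Missing-family discovery: the orphan -> representative -> expansion funnel.

Classified sequences with no domain-family hit are candidates for founding
new families in the other system.  The procedure: filter to the classes of
interest, take the unmatched sequences, collapse to one representative per
4-level TC prefix, then expand each representative through an iterative
search of a reference database — representatives whose expansion reaches
the retention threshold (>=100 matches after two iterations by default)
are the ones most likely to seed large families.  After new families are
adopted, the scan can be repeated: sequences skipped earlier (e.g. the
second, nonhomologous subunit of a multi-component system sharing the same
4-level prefix) surface in the next iteration, until a fixed point.

The search backend is pluggable; an external iterative profile search can
be wired in.  The shipped stand-in is a transitive pairwise-alignment
search thresholded on fractional edit distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import edlib

from .classification import (DEFAULT_CLASS_FILTER, AssignmentTable, FamilyEntry,
                             dedup_representatives, filter_by_class)
from .hit_io import DomainHit, HitTable, unmatched_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "SearchBackend",
    "EdlibSearchBackend",
    "CandidateFamilySeed",
    "find_missing",
    "expand_and_retain",
    "rescan_iteration",
    "match_unknown_function",
    "NEW_FAMILY_EVALUE",
]

#: Sentinel E-value for synthetic hits of newly adopted families: far below
#: every threshold in the toolkit, so augmented hits always count as matched.
NEW_FAMILY_EVALUE = 1e-30


class SearchBackend(Protocol):
    """Contract: (query sequence, reference store, iterations) -> matched ids.

    Must be deterministic given its configuration; the query always
    matches itself when present in the reference store.
    """

    def __call__(self, query: str, refdb: Mapping[str, str], iterations: int) -> set[str]: ...


@dataclass
class EdlibSearchBackend:
    """Transitive pairwise search thresholded on fractional edit distance.

    Each "iteration" aligns the current query set against the reference
    store and admits sequences whose global edit distance is at most
    *max_dist_frac* of the longer sequence; newly admitted sequences
    become the next iteration's queries.  With the default threshold,
    family members derived from a common ancestor at <=20% divergence each
    are always admitted while unrelated proteins (fractional distance
    around 0.75) never are.
    """

    max_dist_frac: float = 0.5

    def __call__(self, query: str, refdb: Mapping[str, str], iterations: int) -> set[str]:
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        matched: set[str] = set()
        queries = [query]
        for _ in range(iterations):
            new: list[str] = []
            for q in queries:
                for sid, seq in refdb.items():
                    if sid in matched:
                        continue
                    limit = int(self.max_dist_frac * max(len(q), len(seq)))
                    res = edlib.align(q, seq, mode="NW", task="distance", k=limit)
                    if res["editDistance"] != -1:
                        matched.add(sid)
                        new.append(seq)
            if not new:
                break
            queries = new
        return matched


def find_missing(assignments: AssignmentTable, hits: HitTable,
                 seqs: Mapping[str, str],
                 class_filter: Iterable[int] = DEFAULT_CLASS_FILTER) -> list[str]:
    """Unmatched classified sequences, one representative per 4-level prefix.

    Applies the class filter, keeps sequences with zero domain hits, and
    collapses each group sharing the first four TC levels to its longest
    member (ties to the lexicographically smallest id).
    """
    kept = filter_by_class(assignments, class_filter)
    orphan_ids = set(unmatched_sequences(kept.seq_ids, hits))
    orphan_table = AssignmentTable((sid, tc) for sid, tc in kept.rows if sid in orphan_ids)
    if not len(orphan_table):
        return []
    return dedup_representatives(orphan_table, seqs)


@dataclass
class CandidateFamilySeed:
    """One orphan representative with its expansion evidence."""

    seq_id: str
    tc_prefix4: str
    n_matches_after_k_iters: int
    retained: bool
    failed: bool = False


def expand_and_retain(seeds: Sequence[str], backend: SearchBackend,
                      refdb: Mapping[str, str], seqs: Mapping[str, str],
                      assignments: AssignmentTable,
                      iterations: int = 2,
                      retain_threshold: int = 100) -> list[CandidateFamilySeed]:
    """Expand each seed through the search backend and apply the retention rule.

    A seed is retained when its expansion reaches *retain_threshold*
    matches (inclusive); the count includes the query itself only when it
    is present in the reference store.  A backend failure marks the record
    failed and processing continues.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out: list[CandidateFamilySeed] = []
    for sid in seeds:
        tcs = assignments.tc_numbers(sid)
        prefix = tcs[0].prefix(4) if tcs else ""
        try:
            matches = backend(seqs[sid], refdb, iterations)
        except Exception:  # noqa: BLE001 - one bad seed must not kill the run
            logger.exception("search backend failed on seed %s", sid)
            out.append(CandidateFamilySeed(sid, prefix, 0, False, failed=True))
            continue
        n = len(matches)
        out.append(CandidateFamilySeed(sid, prefix, n, n >= retain_threshold))
    return out


def rescan_iteration(assignments: AssignmentTable, hits_prev: HitTable,
                     new_families: Sequence[tuple[str, Sequence[str]]],
                     seqs: Mapping[str, str],
                     class_filter: Iterable[int] = DEFAULT_CLASS_FILTER,
                     ) -> tuple[HitTable, list[str]]:
    """One re-scan round after adopting new families.

    Each member of a new family gains a full-length hit to it (sentinel
    E-value 1e-30); the augmented table yields a new, never larger,
    missing list.  New accessions must not collide with existing ones.
    """
    existing = set(hits_prev.families)
    new_accs = [acc for acc, _ in new_families]
    if len(set(new_accs)) != len(new_accs) or existing & set(new_accs):
        dup = sorted((set(new_accs) & existing) | {a for a in new_accs if new_accs.count(a) > 1})
        raise ValueError(f"duplicate family accession(s): {dup}")
    augmented = list(hits_prev.hits)
    for acc, members in new_families:
        for sid in members:
            length = len(seqs[sid]) if sid in seqs else 1
            augmented.append(DomainHit(sid, acc, None, 1, max(1, length),
                                       NEW_FAMILY_EVALUE, 0.0))
    new_table = HitTable(augmented)
    return new_table, find_missing(assignments, new_table, seqs, class_filter)


def match_unknown_function(hits: HitTable, registry: Sequence[FamilyEntry],
                           assignments: AssignmentTable) -> list[tuple[str, list[str]]]:
    """DUF/UPF families that match classified sequences.

    Returns every unknown-function family with at least one hit to an
    assigned sequence, together with the distinct level-3 TC family
    prefixes it touches (sorted), in registry order.
    """
    out = []
    for entry in registry:
        if not entry.is_unknown_function:
            continue
        touched: set[str] = set()
        for h in hits.for_family(entry.accession):
            for tc in assignments.tc_numbers(h.seq_id):
                touched.add(tc.prefix(3))
        if touched:
            out.append((entry.accession, sorted(touched)))
    return out
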