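"""famcross: cross-classification comparison toolkit for protein family systems.

Compares a hierarchical transporter-classification (TC-style) system with
a domain-family/clan database: finds proteins classified in one system but
absent from the other, builds family-level match matrices with pattern
detection, maps superfamilies to clans by majority rule, proposes
candidate entries, and applies the shuffle-null Monte-Carlo alignment
significance criterion used for homology decisions.
"""

from .classification import (DEFAULT_CLASS_FILTER, AssignmentTable, FamilyEntry,
                             TCNumber, TCParseError, dedup_representatives,
                             filter_by_class, parse_tc)
from .clans import (CandidateRecord, ClanCorrespondence, SuperfamilyDef,
                    candidate_pipeline, candidate_verdict, propose_clan_changes,
                    superfamily_to_clans)
from .coverage import (CandidateFamilySeed, EdlibSearchBackend, SearchBackend,
                       expand_and_retain, find_missing, match_unknown_function,
                       rescan_iteration)
from .hit_io import (DomainHit, HitTable, read_fasta, read_hits,
                     unmatched_sequences, write_fasta, write_hits)
from .homology import (AlignParams, HomologyVerdict, PairAlignment, align_pair,
                       align_score, map_tms_pairs, shuffle_z)
from .matrix import (MatchMatrix, MatrixPattern, build_matrix, find_patterns,
                     fraction_bin, read_svg, repfam_view, write_svg)
from .synth import FixtureBundle, FixtureSpec, generate
from .topology import TMSAnnotation, predict_tms, tms_count

__version__ = "0.1.0"


def grid_order(n_items: int) -> int:
    """Smallest k with k*k >= n_items — the order of the square grid that
    can display n_items elements (0 items need a 0-order grid)."""
    if n_items < 0:
        raise ValueError("n_items must be nonnegative")
    import math
    if n_items == 0:
        return 0
    k = math.isqrt(n_items - 1) + 1
    return k
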