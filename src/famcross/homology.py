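"""Shuffle-null alignment significance: the transporter-database homology criterion.

Two proteins are accepted as homologous when their global alignment score
stands more than 14 standard deviations above the mean score obtained by
re-aligning one sequence against at least 1000 random shuffles of the
other, AND the alignment pairs at least 60 residues, AND at least two
transmembrane segments align at equivalent positions in the two
topologies.  The z-score (in SDs) is

    z = (S_obs - mean(S_null)) / sd(S_null)

with the null built from independent uniform permutations of one
sequence's residues (composition and length preserved, order destroyed).

Alignment is global (Needleman-Wunsch) with BLOSUM62 scoring and affine
gaps; a gap of length L costs open + (L-1) * extend (defaults 8 and 2).
Ambiguity codes (B, Z, J, U, O, *) are mapped to X, which scores 0 against
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignParams",
    "PairAlignment",
    "HomologyVerdict",
    "align_pair",
    "align_score",
    "shuffle_z",
    "map_tms_pairs",
    "Z_CUTOFF",
    "MIN_ALIGNED_LENGTH",
    "MIN_TMS_PAIRS",
    "MIN_SHUFFLES",
]

#: Pass criteria: z strictly greater than 14 SD (a 13.7-SD comparison is
#: borderline and fails), at least 60 aligned residue pairs, at least two
#: aligned TMS pairs, from at least 1000 shuffles.
Z_CUTOFF = 14.0
MIN_ALIGNED_LENGTH = 60
MIN_TMS_PAIRS = 2
MIN_SHUFFLES = 1000

_AMBIGUOUS = str.maketrans({c: "X" for c in "BZJUO*"})


def _blosum62_x0() -> substitution_matrices.Array:
    """BLOSUM62 with the X row/column zeroed (unknown residues score 0)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    xi = m.alphabet.index("X")
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring parameters (substitution matrix + affine gaps)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 8.0
    gap_extend: float = 2.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        if self.matrix_name == "BLOSUM62":
            aligner.substitution_matrix = _blosum62_x0()
        else:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class PairAlignment:
    """A scored global alignment as a list of aligned residue-pair columns.

    ``columns`` holds (i, j) pairs of 1-based positions in sequences a and
    b for every residue-residue column; gap columns are not represented.
    """

    score: float
    columns: list[tuple[int, int]]

    @property
    def aligned_length(self) -> int:
        """Residue-residue columns (gaps excluded)."""
        return len(self.columns)


def _sanitize(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    return seq.upper().translate(_AMBIGUOUS)


def align_pair(a: str, b: str, params: AlignParams | None = None) -> PairAlignment:
    """Globally align two protein sequences; deterministic traceback."""
    params = params or AlignParams()
    a, b = _sanitize(a, "a"), _sanitize(b, "b")
    aligner = params.make_aligner()
    aln = aligner.align(a, b)[0]
    columns: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        columns.extend(zip(range(a0 + 1, a1 + 1), range(b0 + 1, b1 + 1)))
    return PairAlignment(score=float(aln.score), columns=columns)


def align_score(a: str, b: str, params: AlignParams | None = None,
                aligner: Align.PairwiseAligner | None = None) -> float:
    """Score-only global alignment (no traceback; used for the shuffle null)."""
    if aligner is None:
        aligner = (params or AlignParams()).make_aligner()
    return float(aligner.score(_sanitize(a, "a"), _sanitize(b, "b")))


@dataclass
class HomologyVerdict:
    """Outcome of the shuffle-null homology test for one sequence pair."""

    raw_score: float
    null_mean: float
    null_sd: float
    z: float
    aligned_length: int
    aligned_tms_pairs: int
    pass_z: bool
    pass_len: bool
    pass_tms: bool
    pass_all: bool
    n_shuffles: int
    seed: int
    indeterminate: bool = False
    null_scores: np.ndarray | None = field(default=None, repr=False)


def shuffle_z(a: str, b: str, n_shuffles: int = 1000, seed: int = 0,
              params: AlignParams | None = None,
              tms_a: Sequence[tuple[int, int]] = (),
              tms_b: Sequence[tuple[int, int]] = (),
              keep_null: bool = False,
              min_overlap_frac: float = 0.5) -> HomologyVerdict:
    """Score a pair against a shuffled-sequence null and apply the criterion.

    The null distribution is the set of global-alignment scores of *a*
    against *n_shuffles* independent uniform permutations of *b*'s
    residues.  For reportable verdicts use at least 1000 shuffles; smaller
    counts are permitted for exploration.  A degenerate null (sd = 0, e.g.
    homopolymers) yields an indeterminate verdict.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    params = params or AlignParams()
    a_s, b_s = _sanitize(a, "a"), _sanitize(b, "b")
    aligner = params.make_aligner()

    aln = align_pair(a_s, b_s, params)
    rng = np.random.default_rng(seed)
    b_arr = np.frombuffer(b_s.encode(), dtype="S1")
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(b_arr).tobytes().decode()
        null[k] = aligner.score(a_s, shuffled)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0

    indeterminate = sd == 0.0
    z = float("nan") if indeterminate else (aln.score - mean) / sd
    n_tms = map_tms_pairs(aln, list(tms_a), list(tms_b), min_overlap_frac=min_overlap_frac)

    pass_z = (not indeterminate) and z > Z_CUTOFF
    pass_len = aln.aligned_length >= MIN_ALIGNED_LENGTH
    pass_tms = n_tms >= MIN_TMS_PAIRS
    return HomologyVerdict(
        raw_score=aln.score, null_mean=mean, null_sd=sd, z=z,
        aligned_length=aln.aligned_length, aligned_tms_pairs=n_tms,
        pass_z=pass_z, pass_len=pass_len, pass_tms=pass_tms,
        pass_all=pass_z and pass_len and pass_tms,
        n_shuffles=n_shuffles, seed=seed, indeterminate=indeterminate,
        null_scores=null if keep_null else None,
    )


def map_tms_pairs(alignment: PairAlignment,
                  tms_a: Sequence[tuple[int, int]],
                  tms_b: Sequence[tuple[int, int]],
                  min_overlap_frac: float = 0.5) -> int:
    """Count transmembrane segments aligned at equivalent positions.

    A segment pair (one from each topology) counts when the alignment
    columns falling inside both segments cover at least
    *min_overlap_frac* of the shorter segment.  Each segment is used at
    most once; pairs are claimed greedily left-to-right.
    """
    if not tms_a or not tms_b:
        return 0
    tms_a = sorted(tms_a)
    tms_b = sorted(tms_b)
    # columns inside each (a-segment, b-segment) pair
    overlap = np.zeros((len(tms_a), len(tms_b)), dtype=int)
    for i, j in alignment.columns:
        ai = next((k for k, (s, e) in enumerate(tms_a) if s <= i <= e), None)
        bj = next((k for k, (s, e) in enumerate(tms_b) if s <= j <= e), None)
        if ai is not None and bj is not None:
            overlap[ai, bj] += 1
    used_b: set[int] = set()
    count = 0
    for ai, (sa, ea) in enumerate(tms_a):
        len_a = ea - sa + 1
        for bj, (sb, eb) in enumerate(tms_b):
            if bj in used_b:
                continue
            shorter = min(len_a, eb - sb + 1)
            if overlap[ai, bj] >= min_overlap_frac * shorter:
                used_b.add(bj)
                count += 1
                break
    return count
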