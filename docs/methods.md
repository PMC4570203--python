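# Methods

## The comparison model

`famcross` treats a database comparison as four linked procedures over
five inputs: protein sequences (FASTA), a sequence → TC-number assignment
table, a domain-hit table (sequence, family, clan, envelope coordinates,
E-value, bit score), a family registry (accession, name, clan,
unknown-function flag) and transmembrane-segment (TMS) annotations. All
coordinates are 1-based inclusive; all E-value thresholds are inclusive
(a hit at exactly the threshold is kept). Upstream significance filtering
(per-family gathering thresholds) is assumed to have been applied by
whatever search produced the hit table; the toolkit does not recompute
per-family cutoffs.

### Missing-family discovery

A sequence is an *orphan* when it has no hit in the table. The funnel is:
class filter (default keep {1,2,3,4,5,8}) → orphans → one representative
per 4-level TC prefix → expansion search → retention. The representative
is the longest sequence in the group, ties broken by lexicographically
smallest id: the choice only needs to be deterministic and reproducible.
The expansion search is a pluggable contract `(query, reference store,
iterations) → matched ids` so that an external iterative profile search
can be wired in. The shipped backend is a transitive pairwise search:
each iteration aligns the current queries against the reference store
(global edit distance, bit-vector algorithm) and admits sequences within
a fractional distance of 0.5 of the longer sequence; newly admitted
sequences become the next queries. At the generator's divergence levels
(≤ 0.2 per descendant, pairwise ≈ 0.35) true family members always fall
inside the threshold while unrelated proteins (fractional distance
≈ 0.75) never do. Retention is `n_matches ≥ 100` after 2 iterations, both
configurable; the count includes the query only if it is itself in the
reference store (it is not, in the generated universes).

Re-scanning: adopting a new family adds a full-length hit for each
member with a sentinel E-value of 1e-30, below every threshold used
anywhere in the toolkit, so adopted members always count as matched.
The missing list is non-increasing across rounds and reaches a fixed
point; multi-component systems whose subunits share a 4-level prefix
surface one subunit per round.

### Match matrix and patterns

cell(f, p) = (hits of domain family p over sequences of TC family f,
counting every hit) ÷ (sequences in f). Multiple hits per sequence are
deliberately counted, so tandem-repeat architectures give fractions
above 1; the shading bin is min(⌊10·fraction⌋, 9), putting everything
≥ 0.9 — including fractions > 1 — in the top bin. Rows with no matching
column are kept visible: an all-empty row is itself a finding (an
unrepresented TC family). Columns appear only when matched somewhere.

"Isolated" is read as: no other nonempty cell anywhere in the row or the
column — a unique 1:1 correspondence between the two systems. A stricter
adjacency-only reading (only the four immediate neighbours must be empty)
is available behind a flag; the whole-row/column reading is the default
because the pattern of interest is uniqueness of the correspondence, not
local sparsity.

The SVG writer stores row/column label order on the root element and
(row, col, fraction, bin) on every cell rect in a dedicated XML
namespace. The analysis pass reads those attributes rather than geometry,
which makes the hand-edit-then-analyse workflow robust: deleting a cell
element in a graphics editor removes exactly that cell. Fractions are
serialised with shortest-exact float representation, so write → read is
lossless. Geometric positions still follow row/column order, and the
pattern report emits pixel coordinates that locate cells in the file.

### Clan correspondence and candidate entries

Majority rule: matched families are those with ≥ 1 hit at E ≤ 1e-25
(applied per hit) to any sequence of any member TC family. The dominant
clan is the mode of clan labels over matched families; ties yield no
dominant clan and no proposals. Clanless matched families are excluded
from the majority denominator but are listed as outliers, so a clanless
family under a dominant clan is proposed to join it. Proposals are
emitted when the dominant fraction is ≥ 0.6 (inclusive).

The candidate pipeline deliberately uses a different quorum — strictly
more than half of a clan's families hitting the superfamily — because
the two procedures ask different questions (naming a counterpart vs.
screening for import candidates) and their thresholds are kept distinct.
Candidate E-values come from a Karlin–Altschul-style conversion of the
global alignment score, E = K·m·n·exp(−λS) with gapped BLOSUM62 defaults
λ = 0.267, K = 0.041, m the representative length and n the total residue
count of the classified-sequence set. The conversion is a calibration
device: any monotone score→E mapping against the same database preserves
the intent of the acceptance window [1e-7, 0.1] (inclusive at both ends
— the lower bound excludes near-identical matches, since the pipeline
looks for distant relatives representing novel subfamilies). Best-match
selection is deterministic: highest score, then smallest E, then
smallest sequence id.

### Homology significance

Global (Needleman–Wunsch) alignment under BLOSUM62 with affine gaps; a
gap of length L costs open + (L−1)·extend, defaults open 8, extend 2.
Ambiguity codes (B, Z, J, U, O, *) map to X, which scores 0 against
everything. The null distribution is built by aligning sequence *a*
against n ≥ 1000 independent uniform permutations of *b*'s residues
(single-integer seed, recorded in the verdict; permutations from numpy's
PCG64 generator). Shuffling one sequence rather than both preserves
*a*'s composition structure; a swap-invariance property test (|Δz| < 1.5
at n = 1000) guards against bias from the choice. The null SD is the
sample SD (ddof = 1); a degenerate null (SD = 0, e.g. homopolymers)
yields an indeterminate verdict rather than an infinite z.

Criteria: z strictly > 14 (a 13.7-SD comparison fails), aligned length
≥ 60 counted as residue–residue columns (the stricter reading — gap
columns are excluded), and ≥ 2 aligned TMS pairs. A TMS pair counts when
the alignment columns inside both segments cover ≥ 50 % of the shorter
segment; segments are claimed greedily left-to-right, each at most once.

### Topology

The built-in predictor slides a 19-residue window over Kyte–Doolittle
hydropathy; centers above 1.6 form runs, each run is emitted as the
residue span its windows cover (half a window beyond the first and last
center), extents closer than 5 residues are merged, and extents shorter
than 15 residues are discarded. Window 19 and threshold 1.6 are the
standard hydropathy-plot conventions for membrane helices; all four
numbers are configurable. Emitting window extents rather than bare
center runs is what makes a 21-residue helix (the canonical
membrane-spanning length) detectable at all: its above-threshold center
run is necessarily shorter than the helix itself. Precomputed ("given")
annotations always override prediction. The predictor does not attempt
inside/outside orientation or posterior probabilities.

## The synthetic generator

Each family is a set of descendants of a random ancestor: substitutions
at the divergence fraction (default 0.15 per descendant), no indels by
default (an indel mode with rate 0.01/site exists for stress-testing the
aligner; it is off by default because indels complicate planted-TMS
bookkeeping). Loops draw from the full 20-letter alphabet and membrane
segments from a hydrophobic-enriched mixture (85 % {L,I,V,F,A,M}, 15 %
uniform). Pure-hydrophobic segments and reduced loop alphabets were
rejected: such low-complexity sequences share enough chance structure
that even unrelated pairs score many SDs above their shuffle null, which
no realistic protein pair does. Planting is constraint-based so the
manifest is true by construction: segment draws are rejected until every
fully-interior window exceeds 2.1, loop draws until every pure-loop
window stays below 1.1 (the predictor threshold ± 0.5), and mutated
sequences are redrawn until they still satisfy both constraints. The
constraints are expressed directly on window means, independent of the
predictor's run/merge/extent logic, so prediction tests remain
informative about that logic.

Default universe: 3 superfamilies × 5 families × 20 sequences of
260–340 residues with 4 planted TMSs each; 12 % of families orphaned
(absent from the hit table); 20 % flagged DUF; 10 % with tandem double
hits; 10 % clan-label noise; one class-9 family (exercising the default
class filter); hit E-values synthesised as 10^(−30·(1−divergence)) so
E-thresholds bind meaningfully; a reference database giving alternating
orphan families 120 and 30 members (either side of the 100-hit retention
cutoff) plus 40 unrelated decoys. Candidate families come in a planted
cycle of three: a distant relative with matching topology (divergence
0.9 — the twilight-zone matches the pipeline targets), a close relative
(0.5, rejected by the E-window's lower bound as already effectively
present), and a distant relative with two extra segments (rejected by
the TMS filter).

What the generator does not emulate: realistic substitution processes,
domain architecture beyond one family per sequence, multi-component
systems (tests construct those directly), or the content of any real
database. Passing tests therefore demonstrate the correctness of the
procedures and thresholds on data with known truth, not recovery of any
real database's counts, which depend on actual sequence inventories.

## Numerical and design notes

- Alignment is scored with Biopython's pairwise aligner (C
  implementation); an independent naive Gotoh dynamic program in the
  test suite verifies exact score agreement, and a closed-form
  homopolymer case pins the scoring convention.
- The shuffle z-score costs one alignment score per shuffle; at
  ~0.35 ms per 300-residue pair, a 1000-shuffle verdict takes ≈ 0.4 s.
  Monte-Carlo test sizes (100 pairs per side) were chosen to give
  two-digit rate resolution at modest runtime.
- The borderline-comparison fixture is found by bisecting the divergence
  of a mutated pair (fixed seeds throughout) until the measured z lands
  just under the cutoff; it exists to demonstrate that the criterion is
  strictly greater-than.
- The engineered E-value formula, the sentinel 1e-30, and the shortest
  exact float serialisation in hit tables and SVG are all chosen so that
  thresholds and round-trips are exact, with no tolerance juggling.
- Degenerate inputs: empty sequences are rejected by the aligner; a
  backend failure on one expansion seed flags that record and continues;
  missing TMS annotations skip the sequence with a warning (matrix
  reports) or flag the record without a verdict (candidate pipeline).

## Known limitations

- The hydropathy predictor is a stand-in with segment-list output; it
  does not reproduce HMM-based topology prediction quality on real
  proteins.
- Karlin–Altschul parameters for *global* alignment are a calibration
  convenience, not a rigorous extreme-value fit.
- The clan-correspondence majority rule sees only hit evidence; real
  clan membership decisions also weigh structural evidence the toolkit
  cannot see.
- Multi-component systems are handled only through the iterate-and-rescan
  mechanism and an optional exclusion list; there is no subunit ontology.
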