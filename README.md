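# famcross

A toolkit for comparing two protein-family classification systems: a
hierarchical transporter classification (TC-style — five levels
`class.subclass.family.subfamily.system`, e.g. `2.A.7.27.1`, plus curated
superfamily groupings) and a domain-family database organised as families
grouped into clans. The two systems classify overlapping protein sets on
different principles — whole transport systems by function and phylogeny
on one side, homologous domains on the other — so reconciling them is a
many-to-many mapping problem. `famcross` is written for database curators
and comparative genomicists who need to find what one system has that the
other lacks, and to decide, with an explicit statistical criterion,
whether a proposed link is supported by homology.

## What it computes

**Missing-family funnel.** Classified sequences with no domain hit are
candidates for founding new families in the other system. The procedure:
filter to the classes of interest (default 1–5 and 8; class 9, systems of
unknown mechanism, is excluded), take the unmatched sequences, keep one
representative per 4-level TC prefix, and expand each representative
through an iterative search of a reference database. Representatives
whose expansion reaches ≥100 matches after two iterations are retained as
likely seeds of large families. After new families are adopted the scan
repeats; members skipped earlier (e.g. the second, nonhomologous subunit
of a multi-component system with the same 4-level prefix) surface in
later rounds, until a fixed point.

**Match matrix (subclass viewer).** For a chosen subclass, a TC-family ×
domain-family grid where cell *(f, p)* holds the average number of hits
of family *p* per sequence of TC family *f* (counting multiple hits per
sequence, so tandem repeats give values > 1). Cells are shaded on a
10-increment scale, bin = min(⌊10·f⌋, 9); averages above 1 fall in the
top (0.9–1.0) bin. The SVG output carries machine-readable cell
attributes, so it can be hand-edited (irrelevant cells deleted) and then
re-analysed for patterns — in particular *isolated cells*, whose row and
column contain no other match: candidate 1:1 family correspondences.

**Clan ↔ superfamily correspondence.** For each superfamily, the domain
families matching its sequences (per-hit E ≤ 1e-25) are tallied by clan;
when ≥ 60 % share one clan, that clan is the counterpart and the outlier
families become reclassification proposals. The reverse direction — the
candidate-entry pipeline — selects clans where more than half the member
families hit the superfamily, takes those clans' families with *no* hit
to any classified sequence, aligns each family's representative against
the classified sequences, and accepts candidates whose transmembrane
segment (TMS) count is within ±1 of the closest match and whose alignment
E-value lies in [1e-7, 0.1] — distant enough to be a novel subfamily,
close enough to be credibly related.

**Homology significance (shuffle null).** Two sequences are accepted as
homologous when

&nbsp;&nbsp;&nbsp;&nbsp;*z* = (S_obs − mean(S_null)) / sd(S_null) > 14,

where S_null are global-alignment scores of one sequence against ≥ 1000
random shuffles of the other, **and** the alignment pairs ≥ 60 residues,
**and** ≥ 2 transmembrane segments align at equivalent positions. The
cutoff is strict: a 13.7-SD comparison is borderline and fails.

All of this runs on synthetic universes from the built-in generator,
which plants family structure (descendants of common ancestors), membrane
topology, orphan families, DUF naming, clan noise and tandem hits, and
records every planted fact in a manifest that serves as ground truth.

## Worked example

Generate a universe, run the funnel, and test one pair for homology:

```bash
famcross synth --seed 1 --out bundle
famcross missing --seqs bundle/sequences.fasta --assignments bundle/assignments.tsv \
                 --hits bundle/hits.tsv --out missing.tsv
famcross expand  --seeds missing.tsv --seqs bundle/sequences.fasta \
                 --assignments bundle/assignments.tsv --refdb bundle/refdb.fasta \
                 --out expanded.tsv
```

`missing.tsv` lists one representative per orphaned 4-level TC group:

```
# seq_id
SF2_F02_S01
SF2_F03_S01
```

`expanded.tsv` shows the expansion counts and the retention decision
(≥ 100 matches after two iterations):

```
# seq_id	tc_prefix4	n_matches	retained	failed
SF2_F02_S01	1.A.2.1	120	1	0
SF2_F03_S01	1.A.3.1	30	0	0
```

The first seed's planted family has 120 reference-database members, so it
is retained as a candidate new family; the second, with 30, is not.
Testing two members of the same planted family for homology:

```bash
famcross gsat A.fasta B.fasta --shuffles 1000 --seed 42 --tms-a A.tms --tms-b B.tms
```

```
SF1_F01_S01 vs SF1_F01_S02: score=976 null=-57.41+/-19.91 z=51.90SD len=280
tms_pairs=4 pass_z=True pass_len=True pass_tms=True PASS=True (n=1000, seed=42)
```

The observed alignment score (976) sits 51.9 standard deviations above
the shuffled-sequence null (mean −57.4, SD 19.9), 280 residue pairs are
aligned and all 4 transmembrane segments align at equivalent positions,
so the pair passes all three criteria.

Other subcommands: `scv1` / `scv-analyze` (match matrix and pattern
report), `rescan`, `duf-match`, `repfam`, `clanview`, `candidates`,
`tms`. See `famcross --help`.

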