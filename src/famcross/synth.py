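"""Seeded synthetic universes with planted structure.

The generator emulates the inputs of a two-database comparison: protein
families derived from common ancestors with planted transmembrane
segments, a hierarchical TC-style assignment table, a domain-family
registry with clan labels, a hit table consistent with the planted family
structure, TMS annotations, and a reference database for expansion
searches.  Every planted fact is recorded in a manifest so each pipeline
stage has an exact ground-truth oracle.

What it emulates: family structure by descent (substitutions from a
common ancestor), stable membrane topology (hydrophobic segments mutate
within a hydrophobic alphabet, loops within a hydrophilic one), orphan
families absent from the hit table, unknown-function (DUF) naming, clan
label noise, tandem-repeat double hits, and expansion families above and
below the retention threshold.  What it does not emulate: indels (off by
default), realistic substitution processes, domain architecture beyond
one family per sequence, or the content of any real database.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classification import (AssignmentTable, FamilyEntry, parse_tc,
                             write_assignments, write_registry)
from .clans import SuperfamilyDef
from .hit_io import DomainHit, HitTable, write_fasta, write_hits
from .topology import TMSAnnotation, write_tms_table

__all__ = ["FixtureSpec", "FixtureBundle", "generate", "mutate", "borderline_pair"]

HYDROPHOBIC = "LIVFAM"         # strongly positive Kyte-Doolittle
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TMS_LEN = 21
LOOP_LEN = 30
#: Membrane segments are hydrophobic-enriched, not hydrophobic-pure: some
#: segment positions draw from the full alphabet, keeping the windowed
#: hydropathy well above threshold while avoiding the low-complexity
#: sequences that would inflate chance alignment similarity.
TMS_MIX = 0.85
#: Planting is constraint-based so the manifest's topology is true by
#: construction: windows fully inside a planted segment stay above
#: TMS_FLOOR, windows fully inside a loop stay below LOOP_CEIL (the
#: default predictor threshold 1.6 with a +-0.5 margin).  Draws violating
#: the constraints are rejected and redrawn.
TMS_FLOOR = 2.1
LOOP_CEIL = 1.1
_HYD_WINDOW = 19


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic universe (all fields planted facts)."""

    seed: int = 0
    n_superfamilies: int = 3
    families_per_superfamily: int = 5
    seqs_per_family: int = 20
    seq_len_range: tuple[int, int] = (260, 340)
    divergence: float = 0.15          # substitution fraction from the ancestor
    tms_per_family: int = 4
    orphan_fraction: float = 0.12     # fraction of families absent from the hit table
    duf_fraction: float = 0.2         # fraction of families flagged DUF
    multi_hit_fraction: float = 0.1   # fraction of families with tandem double hits
    clan_noise: float = 0.1           # fraction of families given a wrong clan label
    n_candidate_families: int = 3     # clan families with no hits, per superfamily
    candidate_divergence: float = 0.9  # distant relatives: the matches the pipeline targets
    candidate_close_divergence: float = 0.5  # "too close" planting (already effectively present)
    refdb_large: int = 120            # expansion-family size above the retention cutoff
    refdb_small: int = 30             # and below it
    n_decoys: int = 40                # unrelated reference sequences
    include_class9: bool = True       # add one class-9 family (excluded by default filter)
    indel_rate: float = 0.0           # per-site; geometric lengths when > 0

    def __post_init__(self) -> None:
        for name in ("divergence", "orphan_fraction", "duf_fraction",
                     "multi_hit_fraction", "clan_noise", "candidate_divergence",
                     "candidate_close_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_superfamilies", "families_per_superfamily", "seqs_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class FixtureBundle:
    """In-memory fixture universe plus the ground-truth manifest."""

    spec: FixtureSpec
    seqs: dict[str, str]                   # classified (TC) sequences
    refdb: dict[str, str]                  # expansion reference database
    assignments: AssignmentTable
    hits: HitTable
    registry: list[FamilyEntry]
    tms: dict[str, TMSAnnotation]
    superfamilies: list[SuperfamilyDef]
    family_reps: dict[str, str]            # candidate accession -> rep seq id
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain-text files (deterministic byte-for-byte)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.seqs, out / "sequences.fasta")
        write_fasta(self.refdb, out / "refdb.fasta")
        write_assignments(self.assignments, out / "assignments.tsv")
        write_hits(self.hits, out / "hits.tsv")
        write_registry(self.registry, out / "registry.tsv")
        write_tms_table(self.tms.values(), out / "tms.tsv")
        with open(out / "superfamilies.tsv", "w") as fh:
            fh.write("# superfamily_name\ttc_prefix\n")
            for sf in self.superfamilies:
                for m in sf.members:
                    fh.write(f"{sf.name}\t{m}\n")
        with open(out / "family_reps.tsv", "w") as fh:
            fh.write("# accession\trep_seq_id\n")
            for acc, rid in sorted(self.family_reps.items()):
                fh.write(f"{acc}\t{rid}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _window_means(seq: str, window: int = _HYD_WINDOW) -> np.ndarray:
    from Bio.SeqUtils.ProtParamData import kd
    hyd = np.array([kd.get(c, 0.0) for c in seq])
    if len(hyd) < window:
        return np.empty(0)
    return np.convolve(hyd, np.ones(window) / window, mode="valid")


def _tms_residue(rng: np.random.Generator) -> str:
    if rng.random() < TMS_MIX:
        return HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
    return AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]


def _tms_seq(rng: np.random.Generator, n: int) -> str:
    """Segment draw, rejected until every interior window clears TMS_FLOOR."""
    while True:
        s = "".join(_tms_residue(rng) for _ in range(n))
        w = _window_means(s)
        if w.size == 0 or w.min() >= TMS_FLOOR:
            return s


def _loop_seq(rng: np.random.Generator, n: int) -> str:
    """Loop draw, rejected until every interior window stays below LOOP_CEIL."""
    while True:
        s = _random_seq(rng, AMINO_ACIDS, n)
        w = _window_means(s)
        if w.size == 0 or w.max() <= LOOP_CEIL:
            return s


def _ancestor(rng: np.random.Generator, length: int, n_tms: int) -> tuple[str, list[tuple[int, int]]]:
    """Random protein with *n_tms* planted hydrophobic-enriched stretches."""
    needed = n_tms * TMS_LEN + (n_tms + 1) * LOOP_LEN
    length = max(length, needed)
    extra = length - needed
    pad = extra // (n_tms + 1)
    chunks: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_tms):
        loop = LOOP_LEN + pad + (extra % (n_tms + 1) if i == 0 else 0)
        chunks.append(_loop_seq(rng, loop))
        pos += loop
        segments.append((pos + 1, pos + TMS_LEN))
        chunks.append(_tms_seq(rng, TMS_LEN))
        pos += TMS_LEN
    chunks.append(_loop_seq(rng, LOOP_LEN + pad))
    return "".join(chunks), segments


def _topology_ok(seq: str, segments: list[tuple[int, int]]) -> bool:
    """Planting constraints on a full sequence: interior segment windows
    above TMS_FLOOR, pure-loop windows below LOOP_CEIL."""
    w = _window_means(seq)
    if w.size == 0:
        return True
    for c0 in range(w.size):
        lo, hi = c0 + 1, c0 + _HYD_WINDOW  # window residue span, 1-based
        inside = any(lo >= s and hi <= e for s, e in segments)
        touches = any(not (hi < s or lo > e) for s, e in segments)
        if inside and w[c0] < TMS_FLOOR:
            return False
        if not touches and w[c0] > LOOP_CEIL:
            return False
    return True


def mutate(rng: np.random.Generator, seq: str, segments: list[tuple[int, int]],
           divergence: float, indel_rate: float = 0.0,
           ) -> tuple[str, list[tuple[int, int]]]:
    """Substitute a *divergence* fraction of sites, preserving topology class.

    Positions inside planted segments draw replacements from the
    hydrophobic-enriched segment distribution, loop positions from the
    full alphabet.  The substituted sequence is rejected and redrawn
    until it satisfies the planting constraints (interior segment windows
    above TMS_FLOOR, pure-loop windows below LOOP_CEIL), so the planted
    topology remains true after mutation.  With *indel_rate* > 0, short
    geometric indels are applied and segment coordinates shifted.
    """
    in_tms = np.zeros(len(seq), dtype=bool)
    for s, e in segments:
        in_tms[s - 1:e] = True
    for _attempt in range(200):
        chars = list(seq)
        mask = rng.random(len(seq)) < divergence
        for i in np.flatnonzero(mask):
            chars[i] = _tms_residue(rng) if in_tms[i] else \
                AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        if _topology_ok("".join(chars), segments):
            break
    if indel_rate <= 0:
        return "".join(chars), list(segments)
    # indels only in loops; coordinates of downstream segments shift
    out: list[str] = []
    new_segments = [list(s) for s in segments]
    shift = 0
    for i, ch in enumerate(chars):
        if not in_tms[i] and rng.random() < indel_rate:
            if rng.random() < 0.5:  # deletion
                delta = -1
            else:                   # insertion
                out.append(ch)
                out.append(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))])
                delta = 1
            for seg in new_segments:
                if seg[0] > i + 1:
                    seg[0] += delta
                    seg[1] += delta
            if delta == -1:
                continue
        else:
            out.append(ch)
    return "".join(out), [(s, e) for s, e in new_segments]


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build one deterministic universe from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, str] = {}
    refdb: dict[str, str] = {}
    rows: list[tuple[str, object]] = []
    registry: list[FamilyEntry] = []
    hits: list[DomainHit] = []
    tms: dict[str, TMSAnnotation] = {}
    superfamilies: list[SuperfamilyDef] = []
    family_reps: dict[str, str] = {}

    n_fam_total = spec.n_superfamilies * spec.families_per_superfamily
    n_orphan = max(0, round(spec.orphan_fraction * n_fam_total))
    orphan_idx = set(rng.choice(n_fam_total, size=n_orphan, replace=False).tolist())
    n_duf = round(spec.duf_fraction * n_fam_total)
    duf_idx = set(rng.choice(n_fam_total, size=n_duf, replace=False).tolist())
    n_multi = round(spec.multi_hit_fraction * n_fam_total)
    multi_idx = set(rng.choice(n_fam_total, size=n_multi, replace=False).tolist())
    n_noise = round(spec.clan_noise * n_fam_total)
    noise_idx = set(rng.choice(n_fam_total, size=n_noise, replace=False).tolist())

    evalue = 10.0 ** (-30.0 * (1.0 - spec.divergence))
    classes = [2, 1, 3]  # cycled over superfamilies; all inside the default class filter

    fam_manifest: list[dict] = []
    orphan_seq_ids: list[str] = []
    expansion: dict[str, dict] = {}
    duf_links: dict[str, list[str]] = {}
    candidates: list[dict] = []
    ancestors: list[tuple[str, list[tuple[int, int]]]] = []

    fam_global = 0
    n_retained_sizes = 0
    for si in range(spec.n_superfamilies):
        cls = classes[si % len(classes)]
        letter = chr(ord("A") + (si // len(classes)) % 26)
        clan = f"CL{si + 1:04d}"
        sf_prefixes: list[str] = []
        for fi in range(spec.families_per_superfamily):
            idx = fam_global
            fam_global += 1
            fam_no = fi + 1
            prefix3 = f"{cls}.{letter}.{fam_no}"
            prefix4 = f"{prefix3}.1"
            acc = f"PF{idx + 1:05d}"
            is_duf = idx in duf_idx
            is_orphan = idx in orphan_idx
            is_multi = idx in multi_idx
            if idx in noise_idx:
                assigned_clan = f"CL{((si + 1) % spec.n_superfamilies) + 1:04d}"
            else:
                assigned_clan = clan
            name = f"DUF{1000 + idx}" if is_duf else f"Fam{acc[2:]}"
            registry.append(FamilyEntry(acc, name, assigned_clan, is_duf))
            sf_prefixes.append(prefix3)

            length = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
            anc, segments = _ancestor(rng, length, spec.tms_per_family)
            ancestors.append((anc, segments))
            member_ids: list[str] = []
            for k in range(spec.seqs_per_family):
                sid = f"SF{si + 1}_F{fi + 1:02d}_S{k + 1:02d}"
                seq, segs = mutate(rng, anc, segments, spec.divergence, spec.indel_rate)
                seqs[sid] = seq
                tms[sid] = TMSAnnotation(sid, segs, source="given")
                rows.append((sid, parse_tc(f"{prefix4}.{k + 1}")))
                member_ids.append(sid)
                if not is_orphan:
                    mid = len(seq) // 2
                    if is_multi:
                        hits.append(DomainHit(sid, acc, assigned_clan, 3, mid, evalue, 150.0))
                        hits.append(DomainHit(sid, acc, assigned_clan, mid + 1, len(seq) - 2,
                                              evalue, 150.0))
                    else:
                        hits.append(DomainHit(sid, acc, assigned_clan, 3, len(seq) - 2,
                                              evalue, 150.0))
            if is_orphan:
                orphan_seq_ids.extend(member_ids)
                size = spec.refdb_large if n_retained_sizes % 2 == 0 else spec.refdb_small
                n_retained_sizes += 1
                ref_ids = []
                for r in range(size):
                    rid = f"REF_{acc}_{r + 1:03d}"
                    rseq, _ = mutate(rng, anc, segments, spec.divergence, 0.0)
                    refdb[rid] = rseq
                    ref_ids.append(rid)
                rep = min(member_ids, key=lambda s: (-len(seqs[s]), s))
                expansion[rep] = {
                    "family": acc, "tc_prefix4": prefix4, "refdb_ids": ref_ids,
                    "n_refdb": size, "retained": size >= 100,
                }
            elif is_duf:
                duf_links[acc] = [prefix3]
            fam_manifest.append({
                "accession": acc, "superfamily": f"SF{si + 1}",
                "tc_prefix3": prefix3, "tc_prefix4": prefix4,
                "clan_true": clan, "clan_assigned": assigned_clan,
                "duf": is_duf, "orphan": is_orphan, "multi_hit": is_multi,
                "member_ids": member_ids,
                "tms_count": spec.tms_per_family,
                "hit_fraction": 0.0 if is_orphan else (2.0 if is_multi else 1.0),
            })
        superfamilies.append(SuperfamilyDef(f"SF{si + 1}", tuple(sf_prefixes)))

        # candidate families: in the clan, zero hits, representative planted.
        # Cycle of three plantings: distant relative with matching topology
        # (the pipeline's target), a too-close relative (fails the E-value
        # window's lower bound), and a distant relative with two extra
        # segments (fails the TMS filter).
        for ci in range(spec.n_candidate_families):
            acc = f"PF9{si + 1:02d}{ci + 1:02d}"
            registry.append(FamilyEntry(acc, f"Cand{acc[2:]}", clan, False))
            src = si * spec.families_per_superfamily + ci % spec.families_per_superfamily
            anc, segments = ancestors[src]
            rep_id = f"CANDREP_{acc}"
            kind = ci % 3
            div = spec.candidate_close_divergence if kind == 1 else spec.candidate_divergence
            extra_tms = 2 if kind == 2 else 0
            rseq, rsegs = mutate(rng, anc, segments, div, 0.0)
            for _ in range(extra_tms):
                tail = len(rseq)
                rseq = rseq + _tms_seq(rng, TMS_LEN) + _loop_seq(rng, LOOP_LEN)
                rsegs = rsegs + [(tail + 1, tail + TMS_LEN)]
            seqs[rep_id] = rseq
            tms[rep_id] = TMSAnnotation(rep_id, rsegs, source="given")
            family_reps[acc] = rep_id
            candidates.append({
                "accession": acc, "clan": clan, "rep_id": rep_id,
                "tms_count": spec.tms_per_family + extra_tms,
                "source_family": fam_manifest[src]["accession"],
                "delta_tms_planted": extra_tms,
                "divergence_planted": div,
            })

    class9_ids: list[str] = []
    if spec.include_class9:
        length = int(rng.integers(*spec.seq_len_range))
        anc, segments = _ancestor(rng, length, spec.tms_per_family)
        for k in range(spec.seqs_per_family):
            sid = f"C9_F01_S{k + 1:02d}"
            seq, segs = mutate(rng, anc, segments, spec.divergence, spec.indel_rate)
            seqs[sid] = seq
            tms[sid] = TMSAnnotation(sid, segs, source="given")
            rows.append((sid, parse_tc(f"9.B.1.1.{k + 1}")))
            class9_ids.append(sid)

    for d in range(spec.n_decoys):
        length = int(rng.integers(*spec.seq_len_range))
        refdb[f"DECOY_{d + 1:03d}"] = _random_seq(rng, AMINO_ACIDS, length)

    assignments = AssignmentTable(rows)
    hit_table = HitTable(hits)
    expected_missing = sorted(expansion)
    manifest = {
        "spec": {**asdict(spec), "seq_len_range": list(spec.seq_len_range)},
        "families": fam_manifest,
        "orphan_seq_ids": sorted(orphan_seq_ids),
        "class9_seq_ids": class9_ids,
        "expected_missing_representatives": expected_missing,
        "expansion": expansion,
        "duf_links": duf_links,
        "candidates": candidates,
        "n_sequences": len(seqs),
        "n_families": n_fam_total,
    }
    return FixtureBundle(spec, seqs, refdb, assignments, hit_table, registry,
                         tms, superfamilies, family_reps, manifest)


def borderline_pair(seed: int = 0, n_shuffles: int = 1000,
                    z_window: tuple[float, float] = (12.0, 14.0),
                    max_steps: int = 16) -> tuple[str, str, float]:
    """Engineer a sequence pair whose shuffle z-score falls just below the cutoff.

    Bisects the divergence of a mutated copy of a random membrane-like
    protein until the measured z (fixed seed, fixed shuffle count) lands
    inside *z_window*.  Returns (a, b, z).  Used to exercise the strict
    '>14 SD' rule on a borderline comparison.
    """
    from .homology import shuffle_z  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    anc, segments = _ancestor(rng, 300, 4)
    lo, hi = 0.3, 1.0
    best: tuple[str, str, float] | None = None
    for step in range(max_steps):
        d = 0.5 * (lo + hi)
        sub_rng = np.random.default_rng(seed * 100003 + step)
        b, _ = mutate(sub_rng, anc, segments, d)
        v = shuffle_z(anc, b, n_shuffles=n_shuffles, seed=seed)
        if z_window[0] <= v.z < z_window[1]:
            return anc, b, v.z
        if v.z >= z_window[1]:
            lo = d
        else:
            hi = d
        if best is None or abs(v.z - sum(z_window) / 2) < abs(best[2] - sum(z_window) / 2):
            best = (anc, b, v.z)
    return best  # closest found; caller asserts on the returned z
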