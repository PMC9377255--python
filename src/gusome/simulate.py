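"""Synthetic cohort generator.

Builds a fully labeled stand-in for the study's controlled-access data:
a protein catalog with planted GUS genes and decoys, read counts with a
planted gene-length bias, activity-based-probe peptide intensity tables,
and MPAG reaction time courses whose true rates depend linearly on the
planted FMN-class abundance.  Every generator is a pure function of its
configuration and seed; randomness is stream-split by stage name so stages
can be regenerated independently.

The default parameters mirror the study conditions: nine samples (five
MMF-treated transplant recipients, four healthy), an assay start
concentration of 400 uM MPAG, five endpoints including t=0, and three
biological replicates per time course.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser

from .align import AlignParams, align_pair
from .types import GUS_CLASSES, ProteinRecord, RepresentativeGus, SampleMeta

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TRYPSIN_RULE = r"[KR](?=[^P])"  # cleave after K/R, not before P

#: Class plan for the 17-member synthetic representative set.
_REP_PLAN = (
    ("L1", 3), ("mL1", 2), ("L2", 3), ("mL2", 2),
    ("mL1_2", 2), ("NL", 3), ("FMN", 2),
)
_LOOP_INSERTS = {
    "L1": (17, 0), "mL1": (8, 0), "L2": (0, 17), "mL2": (0, 8),
    "mL1_2": (8, 8), "NL": (0, 0), "FMN": (0, 0),
}
_CATALYTIC_FRACS = (0.12, 0.20, 0.35, 0.50, 0.62, 0.75, 0.85)
_CATALYTIC_MOTIF = ("N", "E", "Y", "E", "K", "Y", "R")
_SYNTH_TAXA = (
    "Bacteroides synth-A", "Faecalibacterium synth-B", "Roseburia synth-C",
    "Eubacterium synth-D", "Clostridium synth-E", "Parabacteroides synth-F",
    "Blautia synth-G", "Ruminococcus synth-H",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Seeded generator for one pipeline stage, split by stage name."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class RecordTruth:
    is_gus: bool
    gus_class: str | None = None
    decoy_kind: str | None = None  # low_identity | residue_ablated | random
    source_rep: str | None = None
    group: str | None = None  # planted redundancy-cluster group id


@dataclass
class TruthLabels:
    """Ground truth for a generated cohort (used only by tests/validation)."""

    records: dict[str, RecordTruth] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    bias_slope: float | None = None
    class_effects: dict[str, float] | None = None
    rate_model: dict[str, float] | None = None
    expressed: dict[str, set[str]] | None = None  # sample -> gene ids
    class_log2_intensity: pd.DataFrame | None = None  # planted, sample x class
    fmn_driver: dict[str, float] | None = None  # predictor fed to the rate model
    true_rates: dict[str, float] | None = None
    shared_peptides: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# representatives


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA20, n))


def _mutate_positions(
    seq: str, positions: Iterable[int], rng: np.random.Generator
) -> str:
    """Substitute each 0-based position with a different uniform letter."""
    out = list(seq)
    for i in positions:
        choices = AA20[AA20 != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def _mutate_fraction(
    seq: str, identity: float, preserve0: set[int], rng: np.random.Generator
) -> str:
    free = [i for i in range(len(seq)) if i not in preserve0]
    n_mut = int(round((1 - identity) * len(seq)))
    n_mut = min(n_mut, len(free))
    picks = rng.choice(len(free), size=n_mut, replace=False) if n_mut else []
    return _mutate_positions(seq, [free[i] for i in picks], rng)


def make_representatives(
    seed: int = 2022,
    core_length: int = 420,
    fmn_tail: int = 120,
    plan: Sequence[tuple[str, int]] = _REP_PLAN,
) -> list[RepresentativeGus]:
    """Deterministically build a synthetic representative GUS set.

    All representatives descend from one core scaffold carrying seven
    catalytic residues; classes differ by loop segments inserted at two
    anchor sites (so the loop windows encode class architecture) and FMN
    representatives carry an extra C-terminal FMN-binding segment.
    """
    rng = stage_rng(seed, "representatives")
    L = core_length
    ancestor = list(_random_seq(rng, L))
    cat_core = []
    for frac, letter in zip(_CATALYTIC_FRACS, _CATALYTIC_MOTIF):
        pos = int(round(frac * L))  # 1-based
        ancestor[pos - 1] = letter
        cat_core.append(pos)
    ancestor = "".join(ancestor)
    a1 = int(round(0.28 * L))
    a2 = int(round(0.68 * L))
    # The catalytic residues and their +/-3 flanks are conserved across the
    # whole family, as in real active sites; this is also what anchors
    # optimal local alignments at these positions.
    preserve0 = {
        q - 1
        for p in cat_core
        for q in range(p - 3, p + 4)
        if 1 <= q <= L
    }

    fmn_tail_scaffold = _random_seq(rng, fmn_tail)

    reps: list[RepresentativeGus] = []
    tax_cycle = 0
    for gus_class, n in plan:
        class_scaffold = _mutate_fraction(ancestor, 0.55, preserve0, rng)
        ins1, ins2 = _LOOP_INSERTS[gus_class]
        loop1_seg = _random_seq(rng, ins1)
        loop2_seg = _random_seq(rng, ins2)
        for k in range(n):
            core = _mutate_fraction(class_scaffold, 0.85, preserve0, rng)
            seq = core[:a1] + loop1_seg + core[a1:a2] + loop2_seg + core[a2:]
            cat = []
            for pos, letter in zip(cat_core, _CATALYTIC_MOTIF):
                p = pos
                if p > a1:
                    p += ins1
                if pos > a2:
                    p += ins2
                cat.append((p, letter))
            loop1 = (a1 - 1, a1 + ins1 + 2)
            loop2 = (a2 + ins1 - 1, a2 + ins1 + ins2 + 2)
            fmn_seg = None
            if gus_class == "FMN":
                tail = _mutate_fraction(fmn_tail_scaffold, 0.85, set(), rng)
                start = len(seq) + 1
                seq = seq + tail
                fmn_seg = (start, len(seq))
            reps.append(
                RepresentativeGus(
                    id=f"rep_{gus_class}_{k + 1}",
                    seq=seq,
                    gus_class=gus_class,
                    catalytic_positions=tuple(cat),
                    loop1_window=loop1,
                    loop2_window=loop2,
                    fmn_segment=fmn_seg,
                    taxonomy=_SYNTH_TAXA[tax_cycle % len(_SYNTH_TAXA)],
                )
            )
            tax_cycle += 1
    return reps


# ---------------------------------------------------------------------------
# catalog


def mutate_to_identity(
    scaffold: str,
    target_identity: float,
    preserve: Iterable[int] = (),
    seed: int | np.random.Generator = 0,
    params: AlignParams | None = None,
    tolerance: float = 0.02,
    max_adjust: int = 60,
    avoid_termini: int = 0,
) -> str:
    """Mutate ``scaffold`` (substitutions only) to a target pairwise identity.

    ``preserve`` are 1-based positions left untouched.  Identity is measured
    with the same local aligner the discovery stage uses; the returned
    sequence is within ``tolerance`` of the target, adjusted greedily by
    adding or reverting substitutions when the local alignment trims ends.
    ``avoid_termini`` additionally protects that many residues at each end
    (useful when the result must not lose terminal columns to local-
    alignment trimming, e.g. near-identical cluster variants).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or AlignParams()
    L = len(scaffold)
    preserve0 = set()
    for p in preserve:
        if not (1 <= p <= L):
            raise ValueError(f"preserve position {p} outside sequence of length {L}")
        preserve0.add(p - 1)
    if avoid_termini:
        preserve0.update(range(min(avoid_termini, L)))
        preserve0.update(range(max(L - avoid_termini, 0), L))
    if not (0 < target_identity <= 1):
        raise ValueError("target identity must be in (0, 1]")
    floor = len(preserve0) / L
    if target_identity < floor:
        raise ValueError(
            f"target identity {target_identity} below achievable floor "
            f"{floor:.3f} given {len(preserve0)} preserved positions on "
            f"length {L}"
        )
    if target_identity == 1.0:
        return scaffold

    free = [i for i in range(L) if i not in preserve0]
    n_mut = min(int(round((1 - target_identity) * L)), len(free))
    order = rng.permutation(len(free))
    mutated: list[int] = [free[i] for i in order[:n_mut]]
    untouched: list[int] = [free[i] for i in order[n_mut:]]
    seq = _mutate_positions(scaffold, mutated, rng)

    for _ in range(max_adjust):
        ident = align_pair(seq, scaffold, params).identity
        if abs(ident - target_identity) <= tolerance:
            return seq
        if ident > target_identity and untouched:
            pos = untouched.pop()
            mutated.append(pos)
            seq = _mutate_positions(seq, [pos], rng)
        elif ident < target_identity and mutated:
            pos = mutated.pop()
            untouched.append(pos)
            seq = seq[:pos] + scaffold[pos] + seq[pos + 1 :]
        else:
            break
    raise ValueError(
        f"could not reach identity {target_identity} within +/-{tolerance}"
    )


def _plant_shared_segment(
    seqs: dict[str, str],
    truth: TruthLabels,
    reps_by_id: Mapping[str, RepresentativeGus],
    rng: np.random.Generator,
) -> str | None:
    """Copy one tryptic peptide between true genes of different classes.

    Returns the shared peptide sequence, or None when no safe site exists.
    The recipient keeps a valid cleavage context so in-silico digestion of
    both proteins yields the identical peptide.
    """
    true_ids = [i for i, t in truth.records.items() if t.is_gus]
    by_class: dict[str, list[str]] = {}
    for i in true_ids:
        by_class.setdefault(truth.records[i].gus_class, []).append(i)
    classes = [c for c, ids in by_class.items() if ids]
    if len(classes) < 2:
        return None
    c1, c2 = rng.choice(classes, size=2, replace=False)
    donor = by_class[c1][0]
    recipient = by_class[c2][0]
    dseq = seqs[donor]
    for start, pep in pyt_parser.icleave(dseq, TRYPSIN_RULE, min_length=10, max_length=20):
        end = start + len(pep)  # 0-based half-open on donor
        rseq = seqs[recipient]
        if end + 1 >= len(rseq) or start < 1:
            continue
        rep = reps_by_id[truth.records[recipient].source_rep]
        cat = {
            q - 1
            for p, _ in rep.catalytic_positions
            for q in range(p - 3, p + 4)
        }
        if rep.fmn_segment is not None:
            cat.update(range(rep.fmn_segment[0] - 1, rep.fmn_segment[1]))
        if any(start - 1 <= c <= end for c in cat):
            continue
        before = rseq[start - 1]
        if before not in "KR":
            before = "K"
        after = rseq[end]
        if after == "P":
            continue
        new = rseq[: start - 1] + before + pep + rseq[end:]
        assert len(new) == len(rseq)
        seqs[recipient] = new
        return pep
    return None


def generate_catalog(
    n_true: Mapping[str, int] | int = 2,
    n_decoys: Mapping[str, int] | None = None,
    representatives: Sequence[RepresentativeGus] | None = None,
    seed: int = 0,
    identity_band: tuple[float, float] = (0.42, 0.95),
    redundancy_prob: float = 0.5,
    variant_identity: float = 0.96,
    n_shared_segments: int = 1,
    catalytic_context: int = 3,
    params: AlignParams | None = None,
) -> tuple[list[ProteinRecord], TruthLabels]:
    """Generate a labeled protein catalog of true GUS genes and decoys.

    True genes are drawn from representatives at identities inside
    ``identity_band`` with all seven catalytic residues preserved; with
    probability ``redundancy_prob`` a gene receives a near-identical
    variant (>= ``variant_identity``) to exercise redundancy clustering.
    Decoy kinds: ``residue_ablated`` (homologous but with >=1 catalytic
    residue substituted), ``low_identity`` (global identity to every
    representative < 0.20), ``random`` (composition-shuffled non-homologs).

    ``catalytic_context`` residues on each side of every catalytic
    position are preserved along with the position itself, emulating the
    conserved active-site microenvironment; an exact 7-residue block is
    what keeps optimal local alignments from sliding a gap across a
    catalytic position at the low end of the identity band.
    """
    if representatives is None:
        representatives = make_representatives()
    params = params or AlignParams()
    if n_decoys is None:
        n_decoys = {"residue_ablated": 4, "low_identity": 4, "random": 8}
    n_decoys = dict(n_decoys)
    lo, hi = identity_band
    if not (0 < lo <= hi <= 1):
        raise ValueError(f"impossible identity band {identity_band}")
    rng = stage_rng(seed, "catalog")
    reps_by_class: dict[str, list[RepresentativeGus]] = {}
    for r in representatives:
        reps_by_class.setdefault(r.gus_class, []).append(r)
    classes = [c for c in GUS_CLASSES if c in reps_by_class]
    if isinstance(n_true, int):
        n_true = {c: n_true for c in classes}

    truth = TruthLabels()
    seqs: dict[str, str] = {}
    qparams = AlignParams(
        matrix=params.matrix, gap_open=params.gap_open,
        gap_extend=params.gap_extend, identity_mode="query_length",
    )

    def _context(rep: RepresentativeGus) -> list[int]:
        keep: set[int] = set()
        for p, _ in rep.catalytic_positions:
            keep.update(
                q for q in range(p - catalytic_context, p + catalytic_context + 1)
                if 1 <= q <= rep.length
            )
        if rep.fmn_segment is not None:
            # The FMN-binding domain is conserved above the family average:
            # every other residue of the segment is kept intact.
            a, b = rep.fmn_segment
            keep.update(range(a, b + 1, 2))
        return sorted(keep)

    for c in classes:
        for k in range(int(n_true.get(c, 0))):
            rep = reps_by_class[c][k % len(reps_by_class[c])]
            # FMN genes keep their conserved domain, which raises the
            # attainable identity floor for that class.
            c_lo = max(lo, 0.45) if c == "FMN" else lo
            target = rng.uniform(c_lo, max(hi, c_lo))
            gid = f"gene_{c}_{k + 1:03d}"
            seqs[gid] = mutate_to_identity(
                rep.seq, target, _context(rep), seed=rng, params=params
            )
            group = f"grp_{c}_{k + 1:03d}"
            truth.records[gid] = RecordTruth(True, c, None, rep.id, group)
            truth.groups[group] = [gid]

    # Shared tryptic segments are planted before variants are drawn so a
    # modified base gene and its near-identical variant stay consistent.
    reps_by_id = {r.id: r for r in representatives}
    shared = []
    for _ in range(n_shared_segments):
        pep = _plant_shared_segment(seqs, truth, reps_by_id, rng)
        if pep:
            shared.append(pep)
    truth.shared_peptides = shared

    for group, members in list(truth.groups.items()):
        gid = members[0]
        rep = reps_by_id[truth.records[gid].source_rep]
        if rng.random() < redundancy_prob:
            vid = gid + "v"
            seqs[vid] = mutate_to_identity(
                seqs[gid], min(1.0, variant_identity + rng.uniform(0, 0.02)),
                _context(rep), seed=rng, params=params, avoid_termini=10,
            )
            truth.records[vid] = RecordTruth(
                True, truth.records[gid].gus_class, None, rep.id, group
            )
            truth.groups[group].append(vid)

    for k in range(n_decoys.get("residue_ablated", 0)):
        rep = representatives[rng.integers(len(representatives))]
        cat_pos = [p for p, _ in rep.catalytic_positions]
        seq = mutate_to_identity(
            rep.seq, rng.uniform(0.45, 0.85), _context(rep), seed=rng, params=params
        )
        n_ablate = int(rng.integers(1, 4))
        which = rng.choice(len(cat_pos), size=n_ablate, replace=False)
        out = list(seq)
        for w in which:
            pos = cat_pos[w]
            out[pos - 1] = "A" if out[pos - 1] != "A" else "G"
        did = f"decoy_ablated_{k + 1:03d}"
        seqs[did] = "".join(out)
        truth.records[did] = RecordTruth(False, None, "residue_ablated", rep.id, None)

    for k in range(n_decoys.get("low_identity", 0)):
        rep = representatives[rng.integers(len(representatives))]
        for _ in range(20):  # redraw until global identity to all reps < 0.20
            seq = _mutate_fraction(rep.seq, 0.12, set(), rng)
            if all(
                align_pair(seq, r.seq, qparams).identity < 0.20
                for r in representatives
            ):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("failed to construct a low-identity decoy")
        did = f"decoy_lowid_{k + 1:03d}"
        seqs[did] = seq
        truth.records[did] = RecordTruth(False, None, "low_identity", rep.id, None)

    for k in range(n_decoys.get("random", 0)):
        rep = representatives[rng.integers(len(representatives))]
        seq = "".join(rng.permutation(list(rep.seq)))
        did = f"decoy_random_{k + 1:03d}"
        seqs[did] = seq
        truth.records[did] = RecordTruth(False, None, "random", None, None)

    catalog = [ProteinRecord(id=i, seq=s) for i, s in seqs.items()]
    return catalog, truth


# ---------------------------------------------------------------------------
# cohort metadata and read counts


def make_cohort_metadata(n_mmf: int = 5, n_healthy: int = 4) -> list[SampleMeta]:
    """Default cohort layout: T1..Tn MMF recipients, H1..Hm healthy."""
    samples = [
        SampleMeta(f"T{i + 1}", "MMF_recipient") for i in range(n_mmf)
    ] + [SampleMeta(f"H{i + 1}", "healthy") for i in range(n_healthy)]
    return samples


def generate_counts(
    catalog: Sequence[ProteinRecord],
    samples: Sequence[SampleMeta],
    bias_slope: float = 8e-4,
    seed: int = 0,
    gene_sd: float = 0.5,
    sample_gene_sd: float = 0.3,
    depth_range: tuple[int, int] = (200_000, 800_000),
) -> pd.DataFrame:
    """Multinomial read counts with a planted log10-abundance/length bias.

    Gene weights are ``10 ** (u_g + bias_slope * length + e_gs)`` so the
    expected log10 relative count rises linearly in gene length with the
    planted slope.  Per-sample totals are drawn log-uniformly over
    ``depth_range`` (>= 2-fold spread) to exercise library-size scaling.
    """
    if not np.isfinite(bias_slope):
        raise ValueError("bias_slope must be finite")
    rng = stage_rng(seed, "counts")
    lengths = np.array([r.length for r in catalog], dtype=float)
    u = rng.normal(0.0, gene_sd, size=len(catalog))
    table = {"gene_id": [r.id for r in catalog], "length": lengths.astype(int)}
    lo, hi = depth_range
    for s in samples:
        depth = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        e = rng.normal(0.0, sample_gene_sd, size=len(catalog))
        w = np.power(10.0, u + bias_slope * lengths + e)
        p = w / w.sum()
        table[s.sample_id] = rng.multinomial(depth, p)
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# proteome


def tryptic_peptides(
    seq: str, min_len: int = 7, max_len: int = 30, missed: int = 0
) -> list[tuple[int, str]]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns (0-based start, peptide) in sequence order, keeping peptides
    of ``min_len``..``max_len`` residues.
    """
    return [
        (start, pep)
        for start, pep in pyt_parser.icleave(
            seq, TRYPSIN_RULE, missed_cleavages=missed,
            min_length=min_len, max_length=max_len,
        )
    ]


def generate_proteome(
    catalog: Sequence[ProteinRecord],
    truth: TruthLabels,
    samples: Sequence[SampleMeta],
    class_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    expressed_fraction: float = 0.7,
    base_log2: float = 20.0,
    protein_sd: float = 1.0,
    sample_sd: float = 1.0,
    peptide_sd: float = 0.5,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Peptide intensity table from an expressed subset of true GUS genes.

    ``class_effects`` maps a GUS class to a log2 intensity shift applied in
    the MMF-recipient group (healthy group unshifted); the default plants
    the study's qualitative pattern: FMN elevated (+2) and No-Loop depleted
    (-2) in MMF recipients.  Intensities are lognormal around protein-level
    means; peptides come from tryptic digestion (length 7-30).  Updates and
    returns ``truth`` with the expressed map and the planted per-sample
    class log2 intensities.
    """
    if class_effects is None:
        class_effects = {"FMN": 2.0, "NL": -2.0}
    rng = stage_rng(seed, "proteome")
    by_id = {r.id: r for r in catalog}

    base_genes = [gids[0] for gids in truth.groups.values()]
    base_genes = [g for g in base_genes if truth.records[g].is_gus]
    n_expr = max(1, int(round(expressed_fraction * len(base_genes)))) if base_genes else 0
    picked = sorted(
        rng.choice(len(base_genes), size=n_expr, replace=False)
    ) if n_expr else []
    # Always include one FMN gene when present so the rate model has its driver.
    expressed_genes = {base_genes[i] for i in picked}
    fmn_genes = [g for g in base_genes if truth.records[g].gus_class == "FMN"]
    if fmn_genes and not (expressed_genes & set(fmn_genes)):
        expressed_genes.add(fmn_genes[0])

    protein_offset = {g: rng.normal(0.0, protein_sd) for g in sorted(expressed_genes)}
    rows: list[tuple[str, str, float]] = []
    expressed: dict[str, set[str]] = {s.sample_id: set() for s in samples}
    class_totals = {
        s.sample_id: {c: 0.0 for c in GUS_CLASSES} for s in samples
    }
    for s in samples:
        for g in sorted(expressed_genes):
            cls = truth.records[g].gus_class
            shift = class_effects.get(cls, 0.0) if s.group == "MMF_recipient" else 0.0
            log2_protein = base_log2 + protein_offset[g] + shift + rng.normal(0.0, sample_sd)
            peps = tryptic_peptides(by_id[g].seq)
            if not peps:
                continue
            expressed[s.sample_id].add(g)
            class_totals[s.sample_id][cls] += 2.0 ** log2_protein
            per_pep = log2_protein - np.log2(len(peps))
            for _, pep in peps:
                rows.append(
                    (s.sample_id, pep, 2.0 ** (per_pep + rng.normal(0.0, peptide_sd)))
                )

    truth.expressed = expressed
    truth.class_effects = dict(class_effects)
    cls_df = pd.DataFrame(
        {
            s.sample_id: {
                c: (np.log2(v) if v > 0 else np.nan)
                for c, v in class_totals[s.sample_id].items()
            }
            for s in samples
        }
    ).T
    cls_df.index.name = "sample_id"
    truth.class_log2_intensity = cls_df
    table = pd.DataFrame(rows, columns=["sample_id", "peptide", "intensity"])
    return table, truth


# ---------------------------------------------------------------------------
# time courses


def generate_timecourses(
    fmn_abundance: Mapping[str, float],
    a: float = 12.0,
    b: float = 8.0,
    noise_sd: float = 3.0,
    times_s: Sequence[float] = (0.0, 900.0, 1800.0, 2700.0, 3600.0),
    n_replicates: int = 3,
    start_nM: float = 400_000.0,
    measurement_sd_nM: float = 2000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """MPAG-decline time courses with rates linear in FMN abundance.

    Per sample the true reactivation rate is ``r = a + b * fmn + eps`` with
    ``eps ~ N(0, noise_sd^2)``, clipped at 0 (the fitting stage flags
    rising traces).  ``fmn_abundance`` is per-sample log2 FMN intensity,
    used as-is.  Default design: five endpoints including t=0 (seconds),
    three replicates, 400 uM start.  Returns the table and the true rates.
    """
    if start_nM < 0:
        raise ValueError("start concentration must be non-negative")
    if len(set(times_s)) < 2:
        raise ValueError("need at least two distinct time points")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = stage_rng(seed, "timecourses")
    fmn = pd.Series(dict(fmn_abundance), dtype=float)
    rows = []
    true_rates: dict[str, float] = {}
    for sample_id, x in fmn.items():
        r = a + b * x + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        r = max(r, 0.0)
        true_rates[sample_id] = r
        for rep in range(1, n_replicates + 1):
            for t in times_s:
                c = start_nM - r * t
                if measurement_sd_nM > 0:
                    c += rng.normal(0.0, measurement_sd_nM)
                rows.append((sample_id, rep, float(t), max(c, 0.0)))
    df = pd.DataFrame(rows, columns=["sample_id", "replicate", "time_s", "mpag_nM"])
    return df, true_rates


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SyntheticCohort:
    representatives: list[RepresentativeGus]
    samples: list[SampleMeta]
    catalog: list[ProteinRecord]
    counts: pd.DataFrame
    peptides: pd.DataFrame
    timecourses: pd.DataFrame
    truth: TruthLabels


def generate_cohort(
    seed: int = 0,
    representatives: Sequence[RepresentativeGus] | None = None,
    n_true: Mapping[str, int] | int = 2,
    n_decoys: Mapping[str, int] | None = None,
    bias_slope: float = 8e-4,
    class_effects: Mapping[str, float] | None = None,
    rate_a: float = 12.0,
    rate_b: float = 8.0,
    rate_noise_sd: float = 3.0,
    n_mmf: int = 5,
    n_healthy: int = 4,
    **catalog_kwargs,
) -> SyntheticCohort:
    """Generate the full labeled cohort with one seed.

    Time-course rates are driven by the planted per-sample log2 FMN-class
    intensity, so the end-to-end association analysis has a known truth.
    """
    reps = list(representatives) if representatives is not None else make_representatives()
    samples = make_cohort_metadata(n_mmf, n_healthy)
    catalog, truth = generate_catalog(
        n_true=n_true, n_decoys=n_decoys, representatives=reps, seed=seed,
        **catalog_kwargs,
    )
    counts = generate_counts(catalog, samples, bias_slope=bias_slope, seed=seed)
    truth.bias_slope = bias_slope
    peptides, truth = generate_proteome(
        catalog, truth, samples, class_effects=class_effects, seed=seed
    )
    fmn = truth.class_log2_intensity["FMN"].dropna()
    fmn = fmn.reindex([s.sample_id for s in samples]).fillna(fmn.min() - 1.0)
    fmn = fmn - fmn.mean()  # centre so rate_a is the cohort-mean rate
    truth.fmn_driver = fmn.to_dict()
    tcs, true_rates = generate_timecourses(
        fmn.to_dict(), a=rate_a, b=rate_b, noise_sd=rate_noise_sd, seed=seed
    )
    truth.rate_model = {"a": rate_a, "b": rate_b, "noise_sd": rate_noise_sd}
    truth.true_rates = true_rates
    return SyntheticCohort(reps, samples, catalog, counts, peptides, tcs, truth)
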