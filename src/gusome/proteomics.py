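"""Downstream-of-search metaproteomics quantification.

Consumes an FDR-filtered peptide table (sample, peptide, intensity) from
the activity-based-probe experiment and maps each peptide onto the cohort
GUS catalog.  Quantification is strictly unique-peptide: a peptide counts
toward a protein only when it matches exactly one redundancy cluster (I/L
treated as indistinguishable, since the two residues are isobaric).
Protein intensity is the sum of unique-peptide peak areas, log2 applied
afterwards; proteins with no unique signal are absent rows, never zeros.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AA_ALPHABET, GusCluster, ProteinRecord

_IL_TABLE = str.maketrans("L", "I")


def _il_collapse(seq: str, il_equivalence: bool = True) -> str:
    return seq.translate(_IL_TABLE) if il_equivalence else seq


@dataclass
class PeptideMatch:
    sample_id: str
    peptide: str
    intensity: float
    matched_proteins: tuple[str, ...] = ()
    matched_clusters: tuple[str, ...] = ()
    unique: bool = False


def map_peptides(
    peptides: pd.DataFrame,
    catalog: Sequence[ProteinRecord],
    clusters: Sequence[GusCluster],
    il_equivalence: bool = True,
) -> list[PeptideMatch]:
    """Match peptides to catalog proteins by exact substring (I/L-blind).

    Uniqueness is defined at the cluster level: a peptide occurring in
    several members of one redundancy cluster is still unique.  Peptides
    matching no protein are kept, flagged unmatched.
    """
    cluster_of = {m: cl.cluster_id for cl in clusters for m in cl.member_ids}
    searchable = [
        (rec.id, cluster_of.get(rec.id), _il_collapse(rec.seq, il_equivalence))
        for rec in catalog
    ]
    out: list[PeptideMatch] = []
    cache: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for row in peptides.itertuples(index=False):
        pep = str(row.peptide).upper()
        bad = set(pep) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"peptide {pep!r} contains invalid letters {''.join(sorted(bad))}"
            )
        if pep not in cache:
            key = _il_collapse(pep, il_equivalence)
            prots = tuple(pid for pid, _, seq in searchable if key in seq)
            cls = tuple(
                sorted({c for pid, c, seq in searchable if key in seq and c})
            )
            cache[pep] = (prots, cls)
        prots, cls = cache[pep]
        out.append(
            PeptideMatch(
                sample_id=row.sample_id,
                peptide=pep,
                intensity=float(row.intensity),
                matched_proteins=prots,
                matched_clusters=cls,
                unique=len(cls) == 1,
            )
        )
    return out


def protein_intensity(
    matches: Sequence[PeptideMatch],
    clusters: Sequence[GusCluster],
) -> pd.DataFrame:
    """Summed unique-peptide intensity per (cluster, sample).

    Rows are emitted only where the sum is positive; log2 is applied to
    the sum (never averaged over peptide logs).  Duplicate observations
    of the same peptide sequence in a sample all contribute.
    """
    class_of = {cl.cluster_id: cl.gus_class for cl in clusters}
    sums: dict[tuple[str, str], float] = {}
    for m in matches:
        if not m.unique or not m.matched_clusters:
            continue
        key = (m.matched_clusters[0], m.sample_id)
        sums[key] = sums.get(key, 0.0) + m.intensity
    rows = [
        {
            "cluster_id": c,
            "sample_id": s,
            "intensity": v,
            "log2_intensity": np.log2(v),
            "gus_class": class_of.get(c, "NC"),
        }
        for (c, s), v in sorted(sums.items())
        if v > 0
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "sample_id", "intensity", "log2_intensity", "gus_class"]
    )


def sequence_coverage(
    protein: ProteinRecord,
    peptides: Sequence[str],
    il_equivalence: bool = True,
) -> float:
    """Fraction of residues covered by the union of peptide occurrences.

    Every occurrence of every peptide contributes its interval; a peptide
    that does not match the protein raises.
    """
    target = _il_collapse(protein.seq, il_equivalence)
    intervals: list[tuple[int, int]] = []
    for pep in peptides:
        key = _il_collapse(pep.upper(), il_equivalence)
        start = target.find(key)
        if start < 0:
            raise ValueError(f"peptide {pep!r} does not match protein {protein.id!r}")
        while start >= 0:
            intervals.append((start, start + len(key)))
            start = target.find(key, start + 1)
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_a, cur_b = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    covered += cur_b - cur_a
    return covered / protein.length


def class_protein_abundance(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-class summed intensity, log2 after summing.

    Input is the ``protein_intensity`` output.  Classes undetected in a
    sample are absent (NaN), mirroring detected-only reporting.
    """
    if rows.empty:
        return pd.DataFrame()
    raw = rows.pivot_table(
        index="sample_id", columns="gus_class", values="intensity", aggfunc="sum"
    ).rename_axis(columns=None)
    return np.log2(raw)


def total_protein_abundance(rows: pd.DataFrame) -> pd.Series:
    """Per-sample log2 of total summed GUS intensity."""
    if rows.empty:
        return pd.Series(dtype=float)
    return np.log2(rows.groupby("sample_id")["intensity"].sum())


def welch_t(x: Sequence[float], y: Sequence[float]) -> dict:
    """Welch's unequal-variance t-test, two-sided.

    Degenerate contracts: both groups constant with equal means -> p = 1;
    both constant with different means -> p = 0 with ``degenerate`` set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(x.size + y.size - 2), "p": 1.0,
                    "degenerate": True}
        return {"t": np.inf if x.mean() > y.mean() else -np.inf,
                "df": float(x.size + y.size - 2), "p": 0.0, "degenerate": True}
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p), "degenerate": False}


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> dict:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped; n >= 3 required afterwards.  W is the
    smaller of the signed-rank sums.  The p-value is exact (full sign
    enumeration, via the exact distribution) for n <= ``exact_max_n``
    with no ties, else a tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples differ in length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 3:
        raise ValueError(f"need >= 3 nonzero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    W = min(w_pos, w_neg)
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max_n and not has_ties:
        mode = "exact"
        _, p = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        mode = "approx"
        _, p = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=False
        )
    return {"W": W, "p": float(min(p, 1.0)), "n": int(n), "mode": mode}


def group_tests(
    class_log2: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Welch's t-test per GUS class between the two cohort groups.

    ``class_log2`` is samples x classes (NaN = undetected, excluded);
    classes with fewer than two detected samples in either group are
    skipped.
    """
    rows = []
    for cls in class_log2.columns:
        vals = class_log2[cls].dropna()
        g1 = vals[[groups.get(s) == "MMF_recipient" for s in vals.index]]
        g2 = vals[[groups.get(s) == "healthy" for s in vals.index]]
        if len(g1) < 2 or len(g2) < 2:
            continue
        res = welch_t(g1, g2)
        rows.append(
            {
                "gus_class": cls,
                "mean_mmf": g1.mean(),
                "mean_healthy": g2.mean(),
                "t": res["t"],
                "df": res["df"],
                "p": res["p"],
                "n_mmf": len(g1),
                "n_healthy": len(g2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gus_class", "mean_mmf", "mean_healthy", "t", "df", "p",
                 "n_mmf", "n_healthy"],
    )
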