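"""Independent reference implementations used only to check the package.

These deliberately re-derive results by different routes: a plain-Python
dynamic-programming aligner, a Biopython-based screening oracle, a
per-residue bitmap for coverage, and a full 2^n sign enumeration for the
signed-rank test.  None of them share code with the implementation.
"""
from __future__ import annotations

import itertools

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_bruteforce(query: str, target: str, gap_open: int = 11, gap_extend: int = 1):
    """Plain-loop affine Smith-Waterman; returns (score, identity, matches).

    Identity is identical/aligned columns of one optimal traceback using
    the same preference order as the implementation (diag > up > left,
    best cell at smallest (i, j)); intended for short sequences.
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = _B62[query[i - 1]][target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return 0, 0.0, 0
    i, j, state = bi, bj, "H"
    n_id = n_al = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + _B62[query[i - 1]][target[j - 1]]:
                n_al += 1
                n_id += query[i - 1] == target[j - 1]
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            close = F[i][j] == H[i - 1][j] - gap_open - gap_extend
            i -= 1
            if close:
                state = "H"
        else:
            close = E[i][j] == H[i][j - 1] - gap_open - gap_extend
            j -= 1
            if close:
                state = "H"
    return int(best), (n_id / n_al if n_al else 0.0), n_id


def biopython_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _B62
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def screen_oracle(candidate_seq: str, reps, threshold: float = 0.25) -> bool:
    """Accept/reject decision recomputed with Biopython alignments.

    Best representative by alignment score; identity over aligned columns
    must strictly exceed the threshold and all seven catalytic residues
    must align identically (gap or absence = failure).
    """
    al = biopython_aligner()
    scored = []
    for idx, rep in enumerate(reps):
        scored.append((al.score(candidate_seq, rep.seq), -idx, rep))
    _, _, best = max(scored)
    aln = al.align(candidate_seq, best.seq)[0]
    qa, ta = aln[0], aln[1]
    n_id = n_al = 0
    tpos_to_q: dict[int, int] = {}
    qi = aln.coordinates[0][0]
    ti = aln.coordinates[1][0]
    for a, b in zip(qa, ta):
        if a != "-" and b != "-":
            n_al += 1
            n_id += a == b
            tpos_to_q[ti + 1] = qi + 1
        if a != "-":
            qi += 1
        if b != "-":
            ti += 1
    identity = n_id / n_al if n_al else 0.0
    if identity <= threshold:
        return False
    for pos, letter in best.catalytic_positions:
        q = tpos_to_q.get(pos)
        if q is None or candidate_seq[q - 1] != letter:
            return False
    return True


def coverage_bitmap(protein_seq: str, peptides, il_equivalence: bool = True) -> float:
    """Per-residue marking oracle for sequence coverage."""
    table = str.maketrans("L", "I")
    target = protein_seq.translate(table) if il_equivalence else protein_seq
    hit = np.zeros(len(target), dtype=bool)
    for pep in peptides:
        key = pep.translate(table) if il_equivalence else pep
        start = target.find(key)
        while start >= 0:
            hit[start : start + len(key)] = True
            start = target.find(key, start + 1)
    return hit.mean()


def wilcoxon_enumeration(diffs) -> float:
    """Exact two-sided signed-rank p by full 2^n sign enumeration."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        s = np.asarray(signs)
        w = min(ranks[s > 0].sum(), ranks[s < 0].sum())
        count += w <= w_obs
        total += 1
    return count / total
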