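"""Structure-guided GUS discovery.

The screen mirrors the structural-metagenomics workflow: every catalog
protein is aligned pairwise to the representative GUS enzymes; candidates
with identity strictly above the threshold (default 25%) to at least one
representative are checked for the seven conserved active-site residues,
and only candidates carrying all seven are accepted.  Accepted sequences
are collapsed at 90% identity by greedy longest-first clustering, and each
cluster representative receives a structural class and a taxonomy label.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .align import AlignParams, PairwiseAlignment, align_pair
from .config import ClassThresholds
from .types import GUS_CLASSES, GusCall, GusCluster, ProteinRecord, RepresentativeGus


def check_conserved_residues(
    aln: PairwiseAlignment,
    positions: Sequence[tuple[int, str]],
    query_seq: str,
) -> tuple[bool, ...]:
    """Evaluate the seven-conserved-residue rule on one alignment.

    Boolean i is True iff the representative's i-th catalytic position
    aligns to a query residue (not a gap, not outside the local alignment)
    identical to the annotated letter.  Conservative substitutions count
    as mismatches: the rule is exact by design.
    """
    out = []
    for pos, letter in positions:
        if pos < 1 or pos > len(aln.target_to_query) - 1:
            raise ValueError(
                f"catalytic annotation {pos} outside target of length "
                f"{len(aln.target_to_query) - 1}"
            )
        q = int(aln.target_to_query[pos])
        out.append(q > 0 and query_seq[q - 1] == letter)
    return tuple(out)


def screen_candidate(
    candidate: ProteinRecord,
    reps: Sequence[RepresentativeGus],
    threshold: float = 0.25,
    params: AlignParams | None = None,
    residue_check_mode: str = "best_rep",
) -> GusCall:
    """Screen one candidate against the representative set.

    The best representative is the one with the highest alignment score
    (the reporting convention of protein-protein search tools; ties go to
    the earlier representative in input order), and the identity of that
    best-scoring alignment is thresholded strictly (``> threshold``).
    Ranking hits by raw identity is unsound under local alignment - short
    spurious alignments reach high identity fractions - so score ranks and
    identity gates.  In the default ``best_rep`` mode the residue check
    runs against the best representative only; ``any_rep`` accepts if any
    above-threshold representative passes the check.
    """
    if not reps:
        raise ValueError("representative set is empty")
    params = params or AlignParams()
    alignments = [align_pair(candidate.seq, r.seq, params, candidate.id, r.id) for r in reps]
    best_i = max(range(len(reps)), key=lambda i: (alignments[i].score, -i))
    best = alignments[best_i]
    best_rep = reps[best_i]

    if best.identity <= threshold:
        matches = check_conserved_residues(
            best, best_rep.catalytic_positions, candidate.seq
        )
        return GusCall(candidate.id, best_rep.id, best.identity, matches, False,
                       "below_identity")

    if residue_check_mode == "any_rep":
        best_matches = None
        order = sorted(range(len(alignments)), key=lambda i: (-alignments[i].score, i))
        for i in (k for k in order if alignments[k].identity > threshold):
            aln = alignments[i]
            matches = check_conserved_residues(
                aln, reps[i].catalytic_positions, candidate.seq
            )
            if best_matches is None or sum(matches) > sum(best_matches):
                best_matches = matches
            if all(matches):
                return GusCall(candidate.id, reps[i].id, best.identity, matches,
                               True, "none")
        return GusCall(candidate.id, best_rep.id, best.identity,
                       best_matches or (False,) * 7, False, "missing_residue")

    matches = check_conserved_residues(best, best_rep.catalytic_positions, candidate.seq)
    if all(matches):
        return GusCall(candidate.id, best_rep.id, best.identity, matches, True, "none")
    return GusCall(candidate.id, best_rep.id, best.identity, matches, False,
                   "missing_residue")


def screen_catalog(
    catalog: Sequence[ProteinRecord],
    reps: Sequence[RepresentativeGus],
    threshold: float = 0.25,
    params: AlignParams | None = None,
    residue_check_mode: str = "best_rep",
) -> list[GusCall]:
    return [
        screen_candidate(rec, reps, threshold, params, residue_check_mode)
        for rec in catalog
    ]


def cluster_greedy(
    accepted: Sequence[ProteinRecord],
    threshold: float = 0.90,
    params: AlignParams | None = None,
) -> list[GusCluster]:
    """Greedy incremental redundancy clustering (CD-HIT-style scheme).

    Sequences are sorted by length descending (ties by id ascending); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold`` identity, else founds a new cluster.  Output order is
    founding order, so the partition is invariant to input order.

    Membership identity follows the redundancy tool's convention:
    identical columns of the best local alignment divided by the shorter
    sequence's length.  (The aligned-columns ratio is useless here - a
    13-column perfect local hit would merge unrelated genes.)
    """
    if not (0 < threshold <= 1):
        raise ValueError("cluster threshold must be in (0, 1]")
    params = params or AlignParams()
    ordered = sorted(accepted, key=lambda r: (-r.length, r.id))
    clusters: list[GusCluster] = []
    rep_seqs: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for i, rep in enumerate(rep_seqs):
            aln = align_pair(rec.seq, rep.seq, params)
            ident = aln.n_identical / min(rec.length, rep.length)
            if ident >= threshold:
                clusters[i].member_ids = clusters[i].member_ids + (rec.id,)
                placed = True
                break
        if not placed:
            clusters.append(
                GusCluster(
                    cluster_id=f"cluster_{len(clusters) + 1:03d}",
                    representative_id=rec.id,
                    member_ids=(rec.id,),
                )
            )
            rep_seqs.append(rec)
    return clusters


def _fmn_segment_identity(
    candidate: ProteinRecord, rep: RepresentativeGus, params: AlignParams
) -> tuple[float, float]:
    """Identity and coverage of the candidate over an FMN C-terminal segment."""
    a, b = rep.fmn_segment
    segment = rep.seq[a - 1 : b]
    aln = align_pair(candidate.seq, segment, params)
    if aln.n_aligned == 0:
        return 0.0, 0.0
    coverage = aln.n_aligned / len(segment)
    return aln.identity, coverage


def _window_span(aln: PairwiseAlignment, window: tuple[int, int]) -> int | None:
    """Query residue span projected onto a target window via the column map.

    Returns the number of candidate residues spanning the window (including
    insertions), or None when no window residue is aligned ("no coverage").
    """
    lo, hi = window
    hi = min(hi, len(aln.target_to_query) - 1)
    mapped = [int(q) for q in aln.target_to_query[lo : hi + 1] if q > 0]
    if not mapped:
        return None
    return max(mapped) - min(mapped) + 1


def assign_class(
    cluster_rep: ProteinRecord,
    reps: Sequence[RepresentativeGus],
    thresholds: ClassThresholds | None = None,
    params: AlignParams | None = None,
) -> tuple[str, str]:
    """Structural-class assignment for a cluster representative.

    Two-step rule: (1) FMN test - if the candidate matches any FMN
    representative's C-terminal segment at or above the identity cutoff
    with sufficient segment coverage, the class is FMN; (2) otherwise the
    candidate is projected onto the nearest (highest-identity)
    representative's loop windows and classified by the projected span:
    long loop-1 -> L1, long loop-2 -> L2, both mini -> mL1_2, one mini ->
    mL1/mL2, neither -> NL.  Unalignable windows fall back to the nearest
    representative's class, flagged ``by_nearest``.  Returns
    (class, flag) where flag is "", "by_nearest" or "ambiguous".
    """
    thresholds = thresholds or ClassThresholds()
    params = params or AlignParams()
    if not reps:
        raise ValueError("representative set is empty")

    for rep in reps:
        if rep.fmn_segment is None:
            continue
        ident, cov = _fmn_segment_identity(cluster_rep, rep, params)
        if ident >= thresholds.fmn_identity_cutoff and cov >= thresholds.fmn_min_coverage:
            return "FMN", ""

    alignments = [
        align_pair(cluster_rep.seq, r.seq, params, cluster_rep.id, r.id) for r in reps
    ]
    best_score = max(a.score for a in alignments)
    if best_score == 0:
        raise ValueError(f"no representative alignable to {cluster_rep.id!r}")
    tied = [i for i, a in enumerate(alignments) if a.score == best_score]
    flag = ""
    if len(tied) > 1 and len({reps[i].gus_class for i in tied}) > 1:
        tied.sort(key=lambda i: (GUS_CLASSES.index(reps[i].gus_class), i))
        flag = "ambiguous"
    best_i = tied[0]
    best, rep = alignments[best_i], reps[best_i]

    l1 = _window_span(best, rep.loop1_window)
    l2 = _window_span(best, rep.loop2_window)
    if l1 is None or l2 is None:
        return rep.gus_class, ("by_nearest" if not flag else flag)

    T_long, T_mini = thresholds.loop_long, thresholds.loop_mini
    if l1 >= T_long:
        cls = "L1"
    elif l2 >= T_long:
        cls = "L2"
    elif l1 >= T_mini and l2 >= T_mini:
        cls = "mL1_2"
    elif l1 >= T_mini:
        cls = "mL1"
    elif l2 >= T_mini:
        cls = "mL2"
    else:
        cls = "NL"
    return cls, flag


def assign_taxonomy(
    cluster_rep: ProteinRecord,
    reference_db: Sequence[tuple[str, str]],
    floor: float = 0.40,
    params: AlignParams | None = None,
) -> tuple[str, float]:
    """Label a cluster representative by its nearest labeled reference.

    ``reference_db`` is (label, sequence) pairs; the nearest reference is
    the best-scoring alignment and its identity is reported.  Below the
    identity floor the label is "unassigned".
    """
    if not reference_db:
        raise ValueError("taxonomy reference database is empty")
    params = params or AlignParams()
    best_label, best_ident, best_score = "unassigned", 0.0, -1
    for label, seq in reference_db:
        aln = align_pair(cluster_rep.seq, seq, params)
        if aln.score > best_score:
            best_label, best_ident, best_score = label, aln.identity, aln.score
    if best_ident < floor:
        return "unassigned", best_ident
    return best_label, best_ident


def discover(
    catalog: Sequence[ProteinRecord],
    reps: Sequence[RepresentativeGus],
    identity_threshold: float = 0.25,
    cluster_threshold: float = 0.90,
    params: AlignParams | None = None,
    thresholds: ClassThresholds | None = None,
    taxonomy_floor: float = 0.40,
    residue_check_mode: str = "best_rep",
) -> tuple[list[GusCall], list[GusCluster]]:
    """Run the full screen: calls, clustering, class and taxonomy labels."""
    params = params or AlignParams()
    calls = screen_catalog(catalog, reps, identity_threshold, params, residue_check_mode)
    by_id = {r.id: r for r in catalog}
    accepted = [by_id[c.candidate_id] for c in calls if c.accepted]
    clusters = cluster_greedy(accepted, cluster_threshold, params)
    taxdb = [(r.taxonomy or r.id, r.seq) for r in reps]
    for cl in clusters:
        rep_rec = by_id[cl.representative_id]
        cl.gus_class, cl.class_flag = assign_class(rep_rec, reps, thresholds, params)
        cl.taxonomy, cl.taxonomy_identity = assign_taxonomy(
            rep_rec, taxdb, taxonomy_floor, params
        )
    return calls, clusters


def clusters_to_newick(
    clusters: Sequence[GusCluster],
    catalog: Sequence[ProteinRecord],
    params: AlignParams | None = None,
) -> str:
    """Average-linkage tree on 1 - identity distances between cluster reps."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    params = params or AlignParams()
    by_id = {r.id: r for r in catalog}
    seqs = [by_id[c.representative_id].seq for c in clusters]
    names = [c.cluster_id for c in clusters]
    n = len(seqs)
    if n == 1:
        return f"({names[0]});"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - align_pair(seqs[i], seqs[j], params).identity
            D[i, j] = D[j, i] = max(d, 0.0)
    Z = hierarchy.average(squareform(D, checks=False))
    node = hierarchy.to_tree(Z)

    def _nw(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        ld = max(node.dist - left.dist, 0.0)
        rd = max(node.dist - right.dist, 0.0)
        return f"({_nw(left)}:{ld:.6f},{_nw(right)}:{rd:.6f})"

    return _nw(node) + ";"
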