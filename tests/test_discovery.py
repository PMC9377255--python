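"""The structure-guided screen: residue rule, thresholds, clustering,
class and taxonomy assignment, and the screen's soundness properties."""
import numpy as np
import pytest

from gusome.align import AlignParams, align_pair
from gusome.config import ClassThresholds
from gusome.discovery import (
    assign_class,
    assign_taxonomy,
    check_conserved_residues,
    cluster_greedy,
    screen_candidate,
    screen_catalog,
)
from gusome.simulate import generate_catalog, mutate_to_identity
from gusome.types import ProteinRecord


def _rec(rid, seq):
    return ProteinRecord(id=rid, seq=seq)


def test_representative_screens_itself(reps):
    call = screen_candidate(_rec("self", reps[0].seq), reps)
    assert call.accepted
    assert call.best_identity == 1.0
    assert all(call.residue_matches)


def test_ablated_catalytic_residue_rejected(reps):
    rep = reps[0]
    pos, letter = rep.catalytic_positions[3]
    seq = rep.seq[: pos - 1] + ("A" if letter != "A" else "G") + rep.seq[pos:]
    call = screen_candidate(_rec("ablated", seq), reps)
    assert not call.accepted
    assert call.reject_reason == "missing_residue"
    assert sum(call.residue_matches) == 6


def test_low_identity_decoy_below_identity_in_query_length_mode(reps):
    """With the global-coverage identity statistic, a non-homolog falls
    under the screen threshold and is rejected for identity, not residues."""
    catalog, truth = generate_catalog(
        n_true=0, n_decoys={"low_identity": 2}, representatives=reps, seed=4
    )
    qmode = AlignParams(identity_mode="query_length")
    for rec in catalog:
        call = screen_candidate(rec, reps, params=qmode)
        assert not call.accepted
        assert call.reject_reason == "below_identity"


def test_decoys_never_accepted_default_mode(reps):
    catalog, truth = generate_catalog(
        n_true=0,
        n_decoys={"residue_ablated": 3, "low_identity": 3, "random": 3},
        representatives=reps, seed=9,
    )
    for call in screen_catalog(catalog, reps):
        assert not call.accepted


def test_threshold_is_strict(reps):
    rec = _rec("self", reps[0].seq)
    call = screen_candidate(rec, reps, threshold=1.0)
    assert not call.accepted
    assert call.reject_reason == "below_identity"


def test_raising_threshold_never_grows_accepted_set(reps):
    catalog, _ = generate_catalog(n_true=1, representatives=reps, seed=12)
    accepted = {}
    for thr in (0.25, 0.45, 0.65, 0.95):
        calls = screen_catalog(catalog, reps, threshold=thr)
        accepted[thr] = {c.candidate_id for c in calls if c.accepted}
    assert accepted[0.95] <= accepted[0.65] <= accepted[0.45] <= accepted[0.25]


def test_conserved_residue_self_alignment_all_true(reps):
    rep = reps[0]
    aln = align_pair(rep.seq, rep.seq)
    assert all(check_conserved_residues(aln, rep.catalytic_positions, rep.seq))


def test_conservative_substitution_is_a_mismatch(reps):
    """E -> D at a catalytic Glu fails the exact-match rule."""
    rep = reps[0]
    pos, letter = next((p, a) for p, a in rep.catalytic_positions if a == "E")
    seq = rep.seq[: pos - 1] + "D" + rep.seq[pos:]
    aln = align_pair(seq, rep.seq)
    matches = check_conserved_residues(aln, rep.catalytic_positions, seq)
    idx = [p for p, _ in rep.catalytic_positions].index(pos)
    assert not matches[idx]
    assert sum(matches) == 6


def test_gap_spanning_catalytic_position_is_false(reps):
    """Deleting a region around a catalytic position leaves its boolean false."""
    rep = reps[0]
    pos, _ = rep.catalytic_positions[2]
    seq = rep.seq[: pos - 6] + rep.seq[pos + 5 :]
    aln = align_pair(seq, rep.seq)
    matches = check_conserved_residues(aln, rep.catalytic_positions, seq)
    idx = 2
    assert not matches[idx]


def test_annotation_outside_target_errors(reps):
    rep = reps[0]
    aln = align_pair(rep.seq, rep.seq)
    with pytest.raises(ValueError):
        check_conserved_residues(aln, ((10**6, "E"),), rep.seq)


def test_identical_sequences_form_one_cluster(reps):
    a = _rec("a", reps[0].seq)
    b = _rec("b", reps[0].seq)
    clusters = cluster_greedy([a, b])
    assert len(clusters) == 1
    assert clusters[0].representative_id == "a"  # ties by id ascending
    assert set(clusters[0].member_ids) == {"a", "b"}


def test_pair_below_threshold_splits(reps):
    base = reps[0].seq
    other = mutate_to_identity(base, 0.85, seed=3)
    clusters = cluster_greedy([_rec("a", base), _rec("b", other)], threshold=0.90)
    assert len(clusters) == 2


def test_planted_groups_recovered_and_postconditions_hold(reps):
    catalog, truth = generate_catalog(
        n_true=2, n_decoys={}, representatives=reps, seed=21, redundancy_prob=1.0
    )
    clusters = cluster_greedy(catalog, threshold=0.90)
    assert len(clusters) == len(truth.groups)
    by_id = {r.id: r for r in catalog}
    for cl in clusters:
        rep = by_id[cl.representative_id]
        for m in cl.member_ids:
            aln = align_pair(by_id[m].seq, rep.seq)
            ident = aln.n_identical / min(by_id[m].length, rep.length)
            assert ident >= 0.90
    # partition property
    members = [m for cl in clusters for m in cl.member_ids]
    assert sorted(members) == sorted(by_id)


def test_cluster_partition_invariant_to_input_order(reps):
    catalog, _ = generate_catalog(
        n_true=1, n_decoys={}, representatives=reps, seed=22, redundancy_prob=1.0
    )
    rng = np.random.default_rng(0)
    shuffled = [catalog[i] for i in rng.permutation(len(catalog))]
    p1 = [set(c.member_ids) for c in cluster_greedy(catalog)]
    p2 = [set(c.member_ids) for c in cluster_greedy(shuffled)]
    assert p1 == p2


def test_class_of_representative_is_its_own(reps):
    for rep in (reps[0], reps[-1]):
        cls, flag = assign_class(_rec(rep.id, rep.seq), reps)
        assert cls == rep.gus_class


def test_planted_long_loop_insertion_reclassifies_nl_as_l1(reps):
    """An NL scaffold gaining a 17-residue loop-1 insertion becomes L1."""
    nl = next(r for r in reps if r.gus_class == "NL")
    lo, hi = nl.loop1_window
    mid = (lo + hi) // 2
    rng = np.random.default_rng(1)
    insert = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 17))
    seq = nl.seq[:mid] + insert + nl.seq[mid:]
    cls, _ = assign_class(_rec("ins", seq), reps)
    assert cls == "L1"


def test_equidistant_tie_breaks_by_class_order(reps):
    """A candidate equally near two representatives, with unalignable loop
    windows, takes the class earlier in the fixed order, flagged ambiguous."""
    from dataclasses import replace

    nl = next(r for r in reps if r.gus_class == "NL")
    # delete both loop windows so the loop rule cannot run
    (l1a, l1b), (l2a, l2b) = nl.loop1_window, nl.loop2_window
    seq = nl.seq[: l1a - 1] + nl.seq[l1b : l2a - 1] + nl.seq[l2b:]
    twin_a = replace(nl, id="twinA", gus_class="NL")
    twin_b = replace(nl, id="twinB", gus_class="mL1")
    cls, flag = assign_class(_rec("q", seq), [twin_a, twin_b], ClassThresholds())
    assert flag == "ambiguous"
    assert cls == "mL1"  # mL1 precedes NL in the fixed class order


def test_taxonomy_exact_match_and_floor(reps):
    db = [(r.taxonomy, r.seq) for r in reps]
    label, ident = assign_taxonomy(_rec("q", reps[0].seq), db)
    assert label == reps[0].taxonomy
    assert ident == 1.0
    label, ident = assign_taxonomy(_rec("q", reps[0].seq), db, floor=1.01)
    assert label == "unassigned"


def test_taxonomy_derived_sequence_keeps_scaffold_label(reps):
    derived = mutate_to_identity(reps[3].seq, 0.80, seed=6)
    db = [(r.taxonomy, r.seq) for r in reps]
    label, ident = assign_taxonomy(_rec("q", derived), db)
    assert label == reps[3].taxonomy
    assert ident == pytest.approx(0.80, abs=0.05)
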