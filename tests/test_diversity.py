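"""Diversity analytics: Shannon, Bray-Curtis, PCoA geometry, PERMANOVA
behaviour; cross-checked against scikit-bio where it implements the same
statistic."""
import numpy as np
import pandas as pd
import pytest

from gusome.diversity import (
    bray_curtis,
    distance_matrix,
    pcoa,
    permanova,
    shannon_index,
)


def test_shannon_uniform_four_taxa_is_two_bits():
    assert shannon_index([0.25] * 4) == pytest.approx(2.0, abs=1e-12)


def test_shannon_single_taxon_is_zero():
    assert shannon_index([5.0]) == 0.0


def test_shannon_hand_computed_mixture():
    assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.5, abs=1e-12)


def test_shannon_renormalizes_and_rejects_negative():
    assert shannon_index([2, 2, 2, 2]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        shannon_index([0.5, -0.1])


def test_shannon_base_e_matches_scipy():
    from scipy.stats import entropy

    p = [0.1, 0.2, 0.3, 0.4]
    assert shannon_index(p, base=np.e) == pytest.approx(entropy(p), abs=1e-12)


def test_bray_curtis_identity_and_disjoint():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
    assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0


def test_bray_curtis_hand_value():
    assert bray_curtis([2, 0], [1, 1]) == pytest.approx(0.5)


def test_bray_curtis_properties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.uniform(0, 5, 6)
        y = rng.uniform(0, 5, 6)
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


def test_bray_curtis_matches_scipy():
    from scipy.spatial.distance import braycurtis

    rng = np.random.default_rng(1)
    x, y = rng.uniform(0, 3, 8), rng.uniform(0, 3, 8)
    assert bray_curtis(x, y) == pytest.approx(braycurtis(x, y), abs=1e-12)


def test_pcoa_all_zero_distances():
    res = pcoa(np.zeros((4, 4)))
    assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)


def test_pcoa_two_samples_symmetric_coordinates():
    D = np.array([[0.0, 0.8], [0.8, 0.0]])
    res = pcoa(D)
    assert np.allclose(np.abs(res.coordinates[:, 0]), 0.4)


def test_pcoa_collinear_points_recover_line():
    pts = np.array([0.0, 1.0, 3.0])
    D = np.abs(pts[:, None] - pts[None, :])
    res = pcoa(D)
    axis1 = res.coordinates[:, 0]
    got = np.abs(axis1[:, None] - axis1[None, :])
    assert np.allclose(got, D, atol=1e-8)


def test_pcoa_euclidean_distances_reproduced():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(7, 3))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    res = pcoa(D)
    C = res.coordinates
    got = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
    assert np.allclose(got, D, atol=1e-8)


def test_pcoa_rejects_asymmetry():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_pcoa_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as sk_pcoa

    rng = np.random.default_rng(3)
    X = rng.normal(size=(6, 4))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    ours = pcoa(D)
    theirs = sk_pcoa(skbio.DistanceMatrix(D))
    k = ours.coordinates.shape[1]
    sk_coords = theirs.samples.to_numpy()[:, :k]
    for j in range(k):  # sign is conventional
        col = ours.coordinates[:, j]
        assert np.allclose(col, sk_coords[:, j], atol=1e-6) or np.allclose(
            col, -sk_coords[:, j], atol=1e-6
        )


def test_permanova_single_group_errors():
    with pytest.raises(ValueError):
        permanova(np.zeros((4, 4)), ["g"] * 4)


def test_permanova_separated_groups_minimal_p():
    """Tightly clustered groups far apart: every permutation mixing the
    groups lowers F, so p hits the add-one floor."""
    X = np.vstack([np.zeros((4, 2)), 100 + np.zeros((5, 2))])
    X += np.random.default_rng(0).normal(0, 0.01, X.shape)
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    labels = ["a"] * 4 + ["b"] * 5
    res = permanova(D, labels, n_perm=199, seed=1)
    assert res["p_value"] == pytest.approx(1 / 200)


def test_permanova_pseudo_f_matches_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(4)
    X = rng.normal(size=(9, 3))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    labels = ["a"] * 5 + ["b"] * 4
    ours = permanova(D, labels, n_perm=99, seed=0)
    theirs = sk_permanova(skbio.DistanceMatrix(D), grouping=labels, permutations=99)
    assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"], abs=1e-10)


def test_distance_matrix_frame_round():
    table = pd.DataFrame(
        [[1.0, 0.0, 2.0], [0.0, 1.0, 2.0]], index=["s1", "s2"], columns=list("abc")
    )
    D = distance_matrix(table)
    assert D.loc["s1", "s2"] == pytest.approx(bray_curtis([1, 0, 2], [0, 1, 2]))
    assert D.loc["s1", "s1"] == 0.0


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st

finite_vec = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=12
)


@settings(max_examples=60, derandomize=True)
@given(finite_vec, finite_vec)
def test_bray_curtis_symmetry_and_bounds_property(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if sum(x) + sum(y) == 0:
        return
    d = bray_curtis(x, y)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(bray_curtis(y, x))
    assert bray_curtis(x, x) == 0.0 or sum(x) == 0
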