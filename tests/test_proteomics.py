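"""Peptide mapping, unique-peptide quantification, coverage, and the two
group tests, each checked against an independent route."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gusome.proteomics import (
    class_protein_abundance,
    map_peptides,
    protein_intensity,
    sequence_coverage,
    welch_t,
    wilcoxon_signed_rank,
)
from gusome.types import GusCluster, ProteinRecord

from .oracles import coverage_bitmap, wilcoxon_enumeration

P1 = ProteinRecord(id="p1", seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
P2 = ProteinRecord(id="p2", seq="MKTAYIAKQRWWWWHHHHGGGGCCCCDDDDEE")
P3 = ProteinRecord(id="p3", seq="NNNNNNYIAKQRNNNNNNNNWWWWPPPP")

C1 = GusCluster("c1", "p1", ("p1",), gus_class="FMN")
C2 = GusCluster("c2", "p2", ("p2", "p3"), gus_class="NL")
CATALOG = [P1, P2, P3]
CLUSTERS = [C1, C2]


def _pep_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "intensity"])


def test_exact_substring_match_is_unique():
    table = _pep_table([("s1", "QISFVKSHFSR", 100.0)])
    (m,) = map_peptides(table, CATALOG, CLUSTERS)
    assert m.matched_proteins == ("p1",)
    assert m.unique


def test_same_cluster_shared_peptide_is_still_unique():
    table = _pep_table([("s1", "WWWW", 10.0)])
    (m,) = map_peptides(table, CATALOG, CLUSTERS)
    assert set(m.matched_proteins) == {"p2", "p3"}
    assert m.matched_clusters == ("c2",)
    assert m.unique


def test_cross_cluster_peptide_not_unique():
    table = _pep_table([("s1", "TAYIAK", 10.0)])  # in p1 and p2
    (m,) = map_peptides(table, CATALOG, CLUSTERS)
    assert not m.unique
    assert set(m.matched_clusters) == {"c1", "c2"}


def test_il_equivalence_in_matching():
    table = _pep_table([("s1", "QLEERIGI", 5.0)])  # L/I swapped vs p1
    (m,) = map_peptides(table, CATALOG, CLUSTERS)
    assert m.matched_proteins == ("p1",)
    (m2,) = map_peptides(table, CATALOG, CLUSTERS, il_equivalence=False)
    assert m2.matched_proteins == ()


def test_invalid_peptide_letters_error():
    with pytest.raises(ValueError):
        map_peptides(_pep_table([("s1", "QIS*FVK", 1.0)]), CATALOG, CLUSTERS)


def test_protein_intensity_sums_and_log2():
    table = _pep_table(
        [("s1", "QISFVKSHFSR", 100.0), ("s1", "QLEERLGLIEVQ", 50.0)]
    )
    rows = protein_intensity(map_peptides(table, CATALOG, CLUSTERS), CLUSTERS)
    assert len(rows) == 1
    r = rows.iloc[0]
    assert r["intensity"] == 150.0
    assert r["log2_intensity"] == pytest.approx(np.log2(150), abs=1e-6)
    assert r["log2_intensity"] == pytest.approx(7.2288, abs=1e-3)


def test_only_nonunique_peptides_gives_no_row():
    table = _pep_table([("s1", "TAYIAK", 10.0)])
    rows = protein_intensity(map_peptides(table, CATALOG, CLUSTERS), CLUSTERS)
    assert rows.empty


def test_duplicate_peptide_rows_both_sum():
    table = _pep_table(
        [("s1", "QISFVKSHFSR", 100.0), ("s1", "QISFVKSHFSR", 25.0)]
    )
    rows = protein_intensity(map_peptides(table, CATALOG, CLUSTERS), CLUSTERS)
    assert rows.iloc[0]["intensity"] == 125.0


def test_removing_nonunique_peptide_changes_nothing():
    base = [("s1", "QISFVKSHFSR", 100.0)]
    with_shared = base + [("s1", "TAYIAK", 999.0)]
    r1 = protein_intensity(map_peptides(_pep_table(base), CATALOG, CLUSTERS), CLUSTERS)
    r2 = protein_intensity(
        map_peptides(_pep_table(with_shared), CATALOG, CLUSTERS), CLUSTERS
    )
    assert r1.equals(r2)


def test_coverage_simple_and_overlap():
    prot = ProteinRecord(id="x", seq="A" * 40 + "MKTAYIAKQR" + "C" * 50)
    assert sequence_coverage(prot, ["MKTAYIAKQR"]) == pytest.approx(0.10)
    prot2 = ProteinRecord(id="y", seq="ACDEFGHIKLMNPQRSTVWY" * 5)
    a = "ACDEFGHIKL"
    b = "FGHIKLMNPQ"  # overlaps a by 5
    assert sequence_coverage(prot2, [a, b], il_equivalence=False) == pytest.approx(
        coverage_bitmap(prot2.seq, [a, b], il_equivalence=False)
    )


def test_coverage_no_peptides_is_zero():
    assert sequence_coverage(P1, []) == 0.0


def test_coverage_nonmatching_peptide_errors():
    with pytest.raises(ValueError):
        sequence_coverage(P1, ["WWWWWWW"])


def test_coverage_equals_bitmap_oracle_on_random_sets():
    rng = np.random.default_rng(5)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(25):
        seq = "".join(rng.choice(aa, 120))
        prot = ProteinRecord(id="r", seq=seq)
        peps = []
        for _ in range(rng.integers(1, 6)):
            start = rng.integers(0, 110)
            length = rng.integers(7, 12)
            peps.append(seq[start : start + length])
        assert sequence_coverage(prot, peps) == pytest.approx(
            coverage_bitmap(seq, peps)
        )


def test_class_abundance_sum_then_log():
    rows = pd.DataFrame(
        {
            "cluster_id": ["c1", "c2"],
            "sample_id": ["s1", "s1"],
            "intensity": [2.0**10, 2.0**10],
            "log2_intensity": [10.0, 10.0],
            "gus_class": ["FMN", "FMN"],
        }
    )
    out = class_protein_abundance(rows)
    assert out.loc["s1", "FMN"] == pytest.approx(11.0)
    # class log2 >= max member log2: the sum dominates any single member
    assert out.loc["s1", "FMN"] >= rows["log2_intensity"].max()


def test_welch_identical_groups():
    res = welch_t([1, 2, 3], [1, 2, 3])
    assert res["t"] == 0.0
    assert res["p"] == 1.0


def test_welch_matches_scipy_textbook_case():
    x, y = [1, 2, 3, 4], [3, 4, 5, 6]
    res = welch_t(x, y)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    assert res["t"] == pytest.approx(t, abs=1e-12)
    assert res["p"] == pytest.approx(p, abs=1e-12)
    assert res["df"] == pytest.approx(6.0, abs=1e-9)


def test_welch_agrees_with_scipy_on_random_data():
    rng = np.random.default_rng(6)
    for _ in range(50):
        x = rng.normal(0, 1, rng.integers(3, 12))
        y = rng.normal(0.5, 2, rng.integers(3, 12))
        res = welch_t(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res["t"] == pytest.approx(t, abs=1e-8)
        assert res["p"] == pytest.approx(p, abs=1e-8)


def test_welch_degenerate_groups():
    res = welch_t([2, 2, 2], [5, 5, 5])
    assert res["p"] == 0.0
    assert res["degenerate"]
    with pytest.raises(ValueError):
        welch_t([1.0], [1, 2, 3])


def test_wilcoxon_all_positive_small_n():
    res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
    assert res["p"] == pytest.approx(0.25)
    assert res["mode"] == "exact"


def test_wilcoxon_too_few_nonzero_differences():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1, 2, 5], [2, 1, 5])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1, 1], [1, 1])


def test_wilcoxon_exact_matches_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 11))
        # distinct magnitudes avoid rank ties so the exact null applies
        mags = rng.permutation(np.arange(1, n + 1)).astype(float)
        signs = rng.choice([-1.0, 1.0], n)
        d = mags * signs
        if np.all(d > 0) or np.all(d < 0):
            d[0] = -d[0]
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res["p"] == pytest.approx(wilcoxon_enumeration(d), abs=1e-12)


def test_wilcoxon_specific_enumerated_case():
    d = [5.0, -1.0, 4.0, 3.0]
    res = wilcoxon_signed_rank(d, [0.0] * 4)
    assert res["p"] == pytest.approx(wilcoxon_enumeration(d), abs=1e-12)
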