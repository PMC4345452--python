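"""Kinship recursion, family relatedness, and dyad classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinflows import DyadCategory, Pedigree, PedigreeError, UnknownIdError
from kinflows.simulate import SocietyConfig, simulate_pedigree
from kinflows.validation import gene_drop_relatedness, random_pedigree

from conftest import make_pedigree


@pytest.mark.parametrize(
    "i,j,expected",
    [
        (1, 3, 0.5),      # parent-child
        (3, 4, 0.5),      # full siblings
        (3, 6, 0.25),     # half siblings
        (1, 8, 0.25),     # grandparent-grandchild
        (8, 10, 0.125),   # first cousins
        (1, 7, 0.0),      # affinal only
        (3, 3, 1.0),      # self, non-inbred
        (2, 6, 0.0),      # stepmother
    ],
)
def test_textbook_relatedness(textbook_ped, i, j, expected):
    assert textbook_ped.relatedness(i, j) == pytest.approx(expected)
    assert textbook_ped.relatedness(j, i) == pytest.approx(expected)


def test_unknown_id_raises(textbook_ped):
    with pytest.raises(UnknownIdError):
        textbook_ped.relatedness(1, 999)


def test_family_relatedness_enumerated():
    # fam 1 = father, mother, child; fam 2 = father's full brother, his
    # unrelated wife, their child.  Nine pairwise coefficients averaging
    # (0.5 + 0 + 0.25 + 0 + 0 + 0 + 0.25 + 0 + 0.125) / 9 = 0.125.
    ped = make_pedigree([
        (1, "M", 1940, None, None, [2], 10, 1),
        (2, "F", 1941, None, None, [1], 10, 1),
        (3, "M", 1965, 2, 1, [4], 1, 1),
        (4, "F", 1966, None, None, [3], 1, 1),
        (5, "M", 1990, 4, 3, [], 1, 1),
        (6, "M", 1967, 2, 1, [7], 2, 1),
        (7, "F", 1968, None, None, [6], 2, 1),
        (8, "F", 1991, 7, 6, [], 2, 1),
    ])
    assert ped.family_relatedness(1, 2) == pytest.approx(0.125)


def test_single_parent_rejected():
    with pytest.raises(PedigreeError, match="one parent"):
        make_pedigree([
            (1, "F", 1950, None, None, [], 1, 1),
            (2, "M", 1980, 1, None, [], 2, 1),
        ])


def test_overlapping_groups_error(textbook_ped):
    with pytest.raises(PedigreeError, match="overlap"):
        textbook_ped.mean_cross_relatedness([1, 2], [2, 3])


def test_all_founder_families_unrelated():
    ped = make_pedigree([
        (1, "M", 1940, None, None, [2], 1, 1),
        (2, "F", 1941, None, None, [1], 1, 1),
        (3, "M", 1945, None, None, [4], 2, 1),
        (4, "F", 1946, None, None, [3], 2, 1),
    ])
    assert ped.family_relatedness(1, 2) == 0.0
    assert ped.classify_family_dyad(1, 2, ref_year=2000) is DyadCategory.NON_KIN


def test_spouse_symmetry_enforced():
    with pytest.raises(PedigreeError, match="symmetric"):
        make_pedigree([
            (1, "M", 1940, None, None, [2], 1, 1),
            (2, "F", 1941, None, None, [], 1, 1),
        ])


def test_cycle_detected():
    with pytest.raises(PedigreeError):
        make_pedigree([
            (1, "M", 1940, 3, 2, [], 1, 1),
            (2, "F", 1941, None, None, [], 1, 1),
            (3, "F", 1990, 2, 1, [], 1, 1),
        ])


class TestDyadClassification:
    def test_parent_offspring(self, textbook_ped):
        assert textbook_ped.classify_family_dyad(1, 2) is DyadCategory.PARENT_OFFSPRING

    def test_sibling(self, textbook_ped):
        # heads 3 and 4 are full siblings
        assert textbook_ped.classify_family_dyad(2, 3) is DyadCategory.SIBLING

    def test_precedence_parent_over_sibling(self):
        # fam A holds a father and his adult son; fam B holds another son.
        # The cross-family head links are both parent-offspring (father in A)
        # and sibling (brother in A); precedence keeps parent-offspring.
        ped = make_pedigree([
            (1, "M", 1940, None, None, [2], 1, 1),
            (2, "F", 1941, None, None, [1], 1, 1),
            (3, "M", 1965, 2, 1, [], 1, 1),
            (4, "M", 1967, 2, 1, [5], 2, 1),
            (5, "F", 1968, None, None, [4], 2, 1),
        ])
        assert ped.classify_family_dyad(1, 2, ref_year=2000) is DyadCategory.PARENT_OFFSPRING

    def test_other_kin_uncle_nephew(self):
        # uncle-headed vs nephew-headed family: r > 0, heads linked neither
        # as parent-offspring nor as siblings
        ped = make_pedigree([
            (1, "M", 1925, None, None, [2], 1, 1),
            (2, "F", 1926, None, None, [1], 1, 1),
            (3, "M", 1950, 2, 1, [5], 2, 1),
            (4, "M", 1952, 2, 1, [], 3, 1),   # uncle heads family 3
            (5, "F", 1951, None, None, [3], 2, 1),
            (6, "M", 1975, 5, 3, [7], 4, 1),  # nephew heads family 4
            (7, "F", 1976, None, None, [6], 4, 1),
            (8, "F", 2000, 7, 6, [], 4, 1),
        ])
        assert ped.classify_family_dyad(3, 4, ref_year=2005) is DyadCategory.OTHER_KIN
        assert ped.family_relatedness(3, 4) > 0

    def test_no_core_adult_errors(self):
        ped = make_pedigree([
            (1, "M", 1940, None, None, [2], 1, 1),
            (2, "F", 1941, None, None, [1], 1, 1),
            (3, "M", 2005, 2, 1, [], 2, 1),  # child alone in family 2
        ])
        with pytest.raises(PedigreeError, match="core adult"):
            ped.classify_family_dyad(1, 2)

    def test_partition_exhaustive(self, small_society):
        run, _ = small_society
        ped = run.ped
        fams = sorted(ped.families())
        for a in range(len(fams)):
            for b in range(a + 1, min(a + 6, len(fams))):
                if ped.family_community(fams[a]) != ped.family_community(fams[b]):
                    continue
                cat = ped.classify_family_dyad(fams[a], fams[b])
                rbar = ped.family_relatedness(fams[a], fams[b])
                if cat is DyadCategory.NON_KIN:
                    assert rbar == 0.0
                else:
                    assert isinstance(cat, DyadCategory)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_relatedness_symmetric_and_bounded(seed):
    cfg = SocietyConfig(n_communities=1, families_per_community=6, study_days=0, seed=seed)
    ped = simulate_pedigree(cfg)
    ids = ped.ids[:15]
    for a in range(len(ids)):
        assert ped.relatedness(ids[a], ids[a]) == pytest.approx(1.0)
        for b in range(a + 1, len(ids)):
            r = ped.relatedness(ids[a], ids[b])
            assert r == ped.relatedness(ids[b], ids[a])
            assert 0.0 <= r <= 1.0


def test_gene_drop_oracle_agrees():
    """Recursion vs allele-dropping on one random 25-person pedigree."""
    ped = random_pedigree(25, seed=42)
    gd = gene_drop_relatedness(ped, n_drops=50_000, seed=1)
    from scipy.stats import norm
    m = int((gd["se"] > 0).sum())
    zcrit = norm.ppf(1 - 0.00135 / max(m, 1))  # family-wise 3-sigma
    for row in gd.itertuples():
        r = ped.relatedness(row.i, row.j)
        if row.se == 0:
            assert r == pytest.approx(row.r_hat, abs=1e-12)
        else:
            assert abs(r - row.r_hat) <= zcrit * row.se


def test_io_round_trip(tmp_path, textbook_ped):
    path = tmp_path / "ped.tsv"
    textbook_ped.to_csv(path)
    back = Pedigree.from_csv(path)
    assert back.ids == textbook_ped.ids
    for i in (1, 3, 8):
        for j in (2, 4, 10):
            assert back.relatedness(i, j) == textbook_ped.relatedness(i, j)
    # sentinel token for missing parents survives the round trip
    content = path.read_text()
    assert "NA" in content
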