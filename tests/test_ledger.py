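"""Net-transfer matrices, focal sums, and profiles from sharing ledgers."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinflows import (
    NetTransferMatrix,
    SharingLedger,
    family_net_matrix,
    focal_category_sum,
    individual_net_matrix,
    net_production_profile,
    oriented_family_dyads,
)
from kinflows.ledger import LedgerError

from conftest import make_pedigree


def ledger_from(records, persons, days, study_days=None):
    """All listed persons observed on all listed days."""
    rec = pd.DataFrame(records, columns=["date", "rtype", "producer", "recipient", "kcal"])
    obs = pd.DataFrame(
        [(p, d) for p in persons for d in days], columns=["person", "date"]
    )
    return SharingLedger(rec, obs, study_days or (max(days) + 1))


def test_one_way_gift_rate():
    led = ledger_from([(0, "raw-gift", 1, 2, 600.0), (1, "raw-gift", 1, 2, 400.0)],
                      [1, 2], [0, 1])
    T = individual_net_matrix(led)
    assert T.get(1, 2) == pytest.approx(500.0)
    assert T.get(2, 1) == pytest.approx(-500.0)


def test_reciprocal_flows_cancel():
    led = ledger_from(
        [(0, "raw-gift", 1, 2, 700.0), (0, "raw-gift", 2, 1, 700.0)], [1, 2], [0]
    )
    assert individual_net_matrix(led).get(1, 2) == 0.0


def test_equal_portion_meal_attribution():
    # one 1200-kcal dish produced by 1, eaten equally by 1, 2, 3 on one day
    rows = [(0, "meal-portion", 1, p, 400.0) for p in (1, 2, 3)]
    T = individual_net_matrix(ledger_from(rows, [1, 2, 3], [0]))
    assert T.get(1, 2) == pytest.approx(400.0)
    assert T.get(1, 3) == pytest.approx(400.0)
    assert T.get(2, 3) == 0.0


def test_zero_observed_days_with_records_errors():
    rec = pd.DataFrame(
        [(0, "raw-gift", 1, 2, 100.0)],
        columns=["date", "rtype", "producer", "recipient", "kcal"],
    )
    obs = pd.DataFrame([(1, 0)], columns=["person", "date"])  # person 2 unobserved
    with pytest.raises(LedgerError, match="zero observed days"):
        individual_net_matrix(SharingLedger(rec, obs, 1))


def test_gift_to_self_rejected():
    with pytest.raises(LedgerError, match="producer == recipient"):
        ledger_from([(0, "raw-gift", 1, 1, 100.0)], [1], [0])


def test_negative_kcal_rejected():
    with pytest.raises(LedgerError, match="negative"):
        ledger_from([(0, "raw-gift", 1, 2, -5.0)], [1, 2], [0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 100_000))
def test_matrix_antisymmetry_and_conservation(seed):
    """Random ledgers: antisymmetric matrices, zero ordered-pair sum, and
    family aggregation that preserves member-level totals."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    persons = list(range(1, n + 1))
    days = list(range(int(rng.integers(1, 6))))
    rows = []
    for _ in range(int(rng.integers(1, 40))):
        i, j = rng.choice(persons, 2, replace=False)
        rows.append(
            (int(rng.choice(days)), "raw-gift", int(i), int(j), float(rng.uniform(1, 900)))
        )
    led = ledger_from(rows, persons, days)
    T = individual_net_matrix(led)
    np.testing.assert_allclose(T.values, -T.values.T, atol=1e-9)
    assert T.values.sum() == pytest.approx(0.0, abs=1e-9)
    assert np.diag(T.values).sum() == 0.0

    # two arbitrary families partitioning the persons
    half = n // 2
    ped = make_pedigree(
        [(p, "M" if p % 2 else "F", 1970, None, None, [],
          1 if k < half else 2, 1) for k, p in enumerate(persons)]
    )
    Tf = family_net_matrix(T, ped)
    a, b = Tf.ids.index(1), Tf.ids.index(2)
    ia = [T.ids.index(p) for p in persons[:half]]
    ib = [T.ids.index(p) for p in persons[half:]]
    assert Tf.values[a, b] == pytest.approx(T.values[np.ix_(ia, ib)].sum())
    np.testing.assert_allclose(Tf.values, -Tf.values.T, atol=1e-9)


def test_edgelist_round_trip():
    led = ledger_from(
        [(0, "raw-gift", 1, 2, 300.0), (0, "raw-gift", 3, 1, 120.0)], [1, 2, 3], [0]
    )
    T = individual_net_matrix(led)
    back = NetTransferMatrix.from_edgelist(T.to_edgelist(), "individual", T.ids)
    np.testing.assert_allclose(back.values, T.values)
    off = ~np.eye(len(T.ids), dtype=bool)  # edge lists carry no diagonal
    np.testing.assert_array_equal(back.days[off], T.days[off])


class TestFocalCategorySum:
    @pytest.fixture(scope="class")
    def grandfather_world(self):
        # grandfather 1 -> grandchildren 8 (via son 3) and 9 (via daughter 4)
        ped = make_pedigree([
            (1, "M", 1940, None, None, [2], 1, 1),
            (2, "F", 1942, None, None, [1], 1, 1),
            (3, "M", 1965, 2, 1, [5], 2, 1),
            (4, "F", 1967, 2, 1, [6], 3, 1),
            (5, "F", 1966, None, None, [3], 2, 1),
            (6, "M", 1964, None, None, [4], 3, 1),
            (8, "M", 1990, 5, 3, [], 2, 1),
            (9, "F", 1992, 4, 6, [], 3, 1),
        ])
        led = ledger_from(
            [(0, "raw-gift", 1, 8, 100.0), (0, "raw-gift", 1, 9, 237.0)],
            ped.ids, [0],
        )
        return ped, individual_net_matrix(led)

    def test_additive_over_alters(self, grandfather_world):
        ped, T = grandfather_world
        assert focal_category_sum(T, ped, 1, "grandchildren", "from-focal") == pytest.approx(337.0)

    def test_direction_reversal_negates(self, grandfather_world):
        ped, T = grandfather_world
        out = focal_category_sum(T, ped, 1, "grandchildren", "from-focal")
        back = focal_category_sum(T, ped, 1, "grandchildren", "to-focal")
        assert back == -out

    def test_empty_category_zero(self, grandfather_world):
        ped, T = grandfather_world
        assert focal_category_sum(T, ped, 8, "children", "from-focal") == 0.0

    def test_unknown_category_errors(self, grandfather_world):
        ped, T = grandfather_world
        with pytest.raises(LedgerError, match="unknown relationship"):
            focal_category_sum(T, ped, 1, "second-cousins")

    def test_partition_sums_to_total_outflow(self, grandfather_world):
        ped, T = grandfather_world
        # focal 1's alters are exactly his grandchildren (all flows involve them)
        total = sum(T.values[T.ids.index(1), :])
        parts = sum(
            focal_category_sum(T, ped, 1, cat, "from-focal")
            for cat in ("children", "grandchildren", "spouse", "children-in-law")
        )
        assert parts == pytest.approx(total)


class TestFamilyLevel:
    def test_two_singleton_families_equal_person_flow(self):
        ped = make_pedigree([
            (1, "M", 1950, None, None, [], 1, 1),
            (2, "F", 1955, None, None, [], 2, 1),
        ])
        led = ledger_from([(0, "raw-gift", 1, 2, 250.0)], [1, 2], [0])
        T = individual_net_matrix(led)
        Tf = family_net_matrix(T, ped)
        assert Tf.get(1, 2) == T.get(1, 2) == 250.0

    def test_orientation_older_family_first(self):
        ped = make_pedigree([
            (1, "M", 1950, None, None, [], 1, 1),   # head aged 60 at ref 2010
            (2, "F", 1980, None, None, [], 2, 1),   # head aged 30
        ])
        led = ledger_from([(0, "raw-gift", 2, 1, 100.0)], [1, 2], [0])
        Tf = family_net_matrix(individual_net_matrix(led), ped)
        dy = oriented_family_dyads(Tf, ped, ref_year=2010)
        assert dy.iloc[0]["fam_i"] == 1 and dy.iloc[0]["fam_j"] == 2
        assert dy.iloc[0]["net_transfer"] == pytest.approx(-100.0)

    def test_cross_community_dyads_dropped(self):
        ped = make_pedigree([
            (1, "M", 1950, None, None, [], 1, 1),
            (2, "F", 1955, None, None, [], 2, 2),
        ])
        led = ledger_from([(0, "raw-gift", 1, 2, 250.0)], [1, 2], [0])
        Tf = family_net_matrix(individual_net_matrix(led), ped)
        assert Tf.days.sum() == 0


class TestNetProductionProfile:
    def test_simple_rates(self):
        ped = make_pedigree([(1, "M", 1970, None, None, [], 1, 1)])
        led = ledger_from(
            [(0, "meal-portion", 1, 1, 3000.0), (0, "raw-gift", 1, 1, 0.0)][:1],
            [1], [0],
        )
        # production 3000, consumption 3000 -> net 0; now give 1000 away
        prof = net_production_profile(led, ped, "individual", ref_year=2010)
        assert prof.iloc[0]["mean"] == pytest.approx(0.0)

    def test_producer_surplus(self):
        ped = make_pedigree([
            (1, "M", 1970, None, None, [], 1, 1),
            (2, "F", 1972, None, None, [], 2, 1),
        ])
        led = ledger_from(
            [(0, "meal-portion", 1, 1, 2000.0), (0, "raw-gift", 1, 2, 1000.0)],
            [1, 2], [0],
        )
        prof = net_production_profile(led, ped, "individual", ref_year=2010)
        by_age = dict(zip(prof["age_lo"], prof["mean"]))
        assert by_age[40] == pytest.approx(1000.0)   # person 1: 3000 prod, 2000 eaten
        assert by_age[35] == pytest.approx(-1000.0)  # person 2: ate the gift

    def test_empty_bins_excluded(self):
        ped = make_pedigree([(1, "M", 1970, None, None, [], 1, 1)])
        led = ledger_from([(0, "meal-portion", 1, 1, 100.0)], [1], [0])
        prof = net_production_profile(led, ped, "individual", ref_year=2010)
        assert (prof["n"] > 0).all()
        assert len(prof) == 1
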