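import logging

import pandas as pd
import pytest

from kinflows import Pedigree, SharingLedger, SocietyConfig, emit_ledger, simulate_society

logging.getLogger("kinflows").setLevel(logging.ERROR)


def make_pedigree(rows):
    """rows: (id, sex, birth, mother, father, spouses, family, community[, alive])"""
    cols = ["id", "sex", "birth_year", "mother_id", "father_id", "spouse_ids",
            "family_id", "community_id", "alive"]
    rows = [list(r) + [True] * (9 - len(r)) for r in rows]
    return Pedigree(pd.DataFrame(rows, columns=cols))


@pytest.fixture(scope="session")
def textbook_ped():
    """Three generations with full sibs, half sibs, cousins and in-laws.

    Founders 1 (M) + 2 (F) -> children 3 (M), 4 (F); founder 5 (F) + 1 ->
    half-sib 6 (M).  3 x 7 -> child 8; 4 x 9 -> child 10 (8 and 10 are
    first cousins).
    """
    return make_pedigree([
        (1, "M", 1940, None, None, [2, 5], 1, 1),
        (2, "F", 1942, None, None, [1], 1, 1),
        (5, "F", 1945, None, None, [1], 5, 1),
        (3, "M", 1965, 2, 1, [7], 2, 1),
        (4, "F", 1967, 2, 1, [9], 3, 1),
        (6, "M", 1970, 5, 1, [], 5, 1),
        (7, "F", 1966, None, None, [3], 2, 1),
        (9, "M", 1966, None, None, [4], 3, 1),
        (8, "M", 1990, 7, 3, [], 2, 1),
        (10, "F", 1992, 4, 9, [], 3, 1),
    ])


@pytest.fixture(scope="session")
def small_cfg():
    return SocietyConfig(n_communities=2, families_per_community=12, study_days=60, seed=7)


@pytest.fixture(scope="session")
def small_society(small_cfg):
    run = simulate_society(small_cfg)
    ledger = emit_ledger(run)
    return run, ledger
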