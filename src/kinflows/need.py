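"""Family net-need indices: measured and instrumental (estimated).

Measured net need is a family's realized daily consumption minus gross
production — positive when the family eats more than it produces.  Because
realized flows contain measurement error and are partly determined by the
transfers being modelled, an instrumental variant is computed as well:
expected need predicted from the family's age-sex composition alone, using
production/consumption cell means fitted on the rest of the sample
(leave-one-family-out), so it is exogenous to the family's own realized
output by construction.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ledger import LedgerError, SharingLedger, person_rates
from .pedigree import Pedigree

log = logging.getLogger(__name__)


class NeedError(ValueError):
    """Invalid need-index computation."""


def standardize(values) -> np.ndarray:
    """(x - mean) / s.d. with the n-1 denominator; errors on constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise NeedError("standardize needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise NeedError("cannot standardize a constant (zero-variance) input")
    return (x - x.mean()) / sd


def measured_need(ledger: SharingLedger, ped: Pedigree, family) -> float:
    """Realized (consumption - gross production) in kcal per observed day."""
    members = set(ped.family_members(family))
    rates = person_rates(ledger)
    rates = rates[rates["person"].isin(members)]
    if not len(rates) or rates["days"].sum() == 0:
        raise NeedError(f"family {family!r} has no observed days")
    # members share the family's interview days, so summing member rates
    # equals family totals over family days observed
    return float((rates["consumption"] - rates["production"]).sum())


def _cell_of(age: np.ndarray, bin_width: int = 5, cap: int = 80) -> np.ndarray:
    return np.minimum(age // bin_width * bin_width, cap).astype(int)


def estimated_need(
    ledger: SharingLedger,
    ped: Pedigree,
    families: list | None = None,
    ref_year: int | None = None,
    bin_width: int = 5,
) -> pd.Series:
    """Instrumental net need per family from age-sex composition alone.

    Expected production and consumption are fitted as age-bin x sex cell
    means over every observed person *outside* the focal family, then the
    family's need is the sum of (expected consumption - expected production)
    over its members.  Two families with identical rosters therefore get
    identical values regardless of realized output.  Cells with no data
    borrow from the nearest populated cell of the same sex (logged).
    """
    if ref_year is None:
        ref_year = int(max(ped.birth_year(i) for i in ped.ids))
    if families is None:
        families = sorted(ped.families())

    rates = person_rates(ledger)
    rates = rates[rates["days"] > 0].copy()
    if not len(rates):
        raise NeedError("no observed persons to fit age-sex cell means")
    rates["age"] = [ped.age(p, ref_year) for p in rates["person"]]
    rates["sex"] = [ped.sex(p) for p in rates["person"]]
    rates["cell"] = _cell_of(rates["age"].to_numpy(), bin_width)
    rates["fam"] = [ped.family_of(p) for p in rates["person"]]

    sums = rates.groupby(["sex", "cell"])[["production", "consumption"]].sum()
    counts = rates.groupby(["sex", "cell"]).size()

    out = {}
    for fam in families:
        members = ped.family_members(fam)
        if not members:
            raise NeedError(f"family {fam!r} has no living members")
        fam_rows = rates[rates["fam"] == fam]
        fam_sums = fam_rows.groupby(["sex", "cell"])[["production", "consumption"]].sum()
        fam_counts = fam_rows.groupby(["sex", "cell"]).size()
        need = 0.0
        for p in members:
            sex = ped.sex(p)
            cell = int(_cell_of(np.array([ped.age(p, ref_year)]), bin_width)[0])
            best = None
            # nearest populated cell of the same sex after removing own family
            cells = sorted(counts.loc[sex].index) if sex in counts.index.levels[0] else []
            for c in sorted(cells, key=lambda c: abs(c - cell)):
                n = counts.get((sex, c), 0) - fam_counts.get((sex, c), 0)
                if n > 0:
                    ps = sums.loc[(sex, c)] - (
                        fam_sums.loc[(sex, c)]
                        if (sex, c) in fam_sums.index
                        else pd.Series({"production": 0.0, "consumption": 0.0})
                    )
                    best = (ps["consumption"] - ps["production"]) / n
                    if c != cell:
                        log.info(
                            "empty age-sex cell (%s, %s) for family %s: borrowed from cell %s",
                            sex, cell, fam, c,
                        )
                    break
            if best is None:
                # no same-sex data at all outside the family: overall mean
                n = len(rates) - len(fam_rows)
                if n <= 0:
                    raise NeedError("sample too small to leave out family " + str(fam))
                tot = rates[["production", "consumption"]].sum() - fam_rows[
                    ["production", "consumption"]
                ].sum()
                best = (tot["consumption"] - tot["production"]) / n
                log.info("no same-sex cells for family %s; used overall mean", fam)
            need += float(best)
        out[fam] = need
    return pd.Series(out, name="estimated_need")


def need_table(
    ledger: SharingLedger,
    ped: Pedigree,
    families: list | None = None,
    ref_year: int | None = None,
) -> pd.DataFrame:
    """Per-family measured and estimated net need (kcal/day), unstandardized.

    Standardization is applied downstream over the dyadic modelling sample
    (families enter once per dyad), matching how the interaction models
    scale their inputs.
    """
    if families is None:
        families = sorted(ped.families())
    est = estimated_need(ledger, ped, families, ref_year=ref_year)
    meas = {f: measured_need(ledger, ped, f) for f in families}
    return pd.DataFrame(
        {
            "family": families,
            "measured_need": [meas[f] for f in families],
            "estimated_need": [est[f] for f in families],
        }
    )
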