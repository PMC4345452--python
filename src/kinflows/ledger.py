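"""Sharing ledgers and dyadic net-transfer matrices.

A :class:`SharingLedger` holds interview-style records of who produced food
and who ate it (meal portions within a pooling household) or received it
raw (gifts between households), in kcal, together with the days on which
each person was actually observed.  This module reduces a ledger to:

* per-person gross production and consumption rates (kcal/day observed),
* antisymmetric person x person and family x family net-transfer matrices,
* sums of net transfers between a focal individual and a named relationship
  category (children, grandparents, ...),
* age profiles of net production (production minus consumption).

Rates are per *jointly observed* day for dyadic quantities, which keeps the
estimates unbiased under intermittent interview sampling.
"""
from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

log = logging.getLogger(__name__)

RECORD_TYPES = ("meal-portion", "raw-gift")

RELATION_CATEGORIES = (
    "children",
    "grandchildren",
    "spouse",
    "children-in-law",
    "parents",
    "grandparents",
    "parents-in-law",
)


class LedgerError(ValueError):
    """Structurally inconsistent ledger or invalid ledger query."""


@dataclass
class SharingLedger:
    """Dated production/consumption/gift records plus observation coverage.

    ``records`` columns: ``date`` (int day index within the study window),
    ``rtype`` (``meal-portion`` or ``raw-gift``), ``producer``, ``recipient``
    (person ids) and ``kcal`` (>= 0).  Meal portions may have producer ==
    recipient (own consumption of own production); raw gifts may not.

    ``observations`` columns: ``person``, ``date`` — one row per person-day
    on which that person's family was interviewed about (so flows involving
    them on that day are in the ledger).
    """

    records: pd.DataFrame
    observations: pd.DataFrame
    study_days: int

    def __post_init__(self) -> None:
        rec = self.records
        need = {"date", "rtype", "producer", "recipient", "kcal"}
        if not need.issubset(rec.columns):
            raise LedgerError(f"records missing columns {sorted(need - set(rec.columns))}")
        if len(rec):
            if (rec["kcal"] < 0).any():
                raise LedgerError("negative kcal in ledger records")
            bad = rec[(rec["rtype"] == "raw-gift") & (rec["producer"] == rec["recipient"])]
            if len(bad):
                raise LedgerError("raw-gift records with producer == recipient")
            if not rec["rtype"].isin(RECORD_TYPES).all():
                raise LedgerError(f"record types must be one of {RECORD_TYPES}")
            if (rec["date"] < 0).any() or (rec["date"] >= self.study_days).any():
                raise LedgerError("record dates outside the study window")
        obs = self.observations
        if not {"person", "date"}.issubset(obs.columns):
            raise LedgerError("observations need columns person, date")

    # ------------------------------------------------------------------ props
    def persons(self) -> list:
        if not hasattr(self, "_persons_cache"):
            ps = set(self.observations["person"])
            ps |= set(self.records["producer"]) | set(self.records["recipient"])
            self._persons_cache = sorted(ps)
        return list(self._persons_cache)

    def days_observed(self) -> pd.Series:
        """Number of distinct observed days per person."""
        if not hasattr(self, "_days_cache"):
            self._days_cache = self.observations.groupby("person")["date"].nunique()
        return self._days_cache

    def observation_matrix(self, ids: list) -> np.ndarray:
        """Boolean (person x day) coverage matrix in the order of ``ids``."""
        idx = {p: k for k, p in enumerate(ids)}
        m = np.zeros((len(ids), self.study_days), dtype=bool)
        obs = self.observations
        keep = obs["person"].isin(idx)
        m[obs["person"][keep].map(idx).to_numpy(), obs["date"][keep].to_numpy()] = True
        return m

    # --------------------------------------------------------------------- io
    def write(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(d / "records.tsv", sep="\t", index=False)
        self.observations.to_csv(d / "observations.tsv", sep="\t", index=False)
        (d / "ledger.json").write_text(json.dumps({"study_days": int(self.study_days)}))

    @classmethod
    def read(cls, directory) -> "SharingLedger":
        d = pathlib.Path(directory)
        rec = pd.read_csv(d / "records.tsv", sep="\t")
        obs = pd.read_csv(d / "observations.tsv", sep="\t")
        meta = json.loads((d / "ledger.json").read_text())
        return cls(rec, obs, meta["study_days"])


@dataclass
class NetTransferMatrix:
    """Antisymmetric net kcal/day flows between persons or families.

    ``values[a, b]`` is the net daily flow from ``ids[a]`` to ``ids[b]``;
    ``days[a, b]`` the number of jointly observed days behind the estimate.
    """

    level: str  # "individual" | "family"
    ids: list
    values: np.ndarray
    days: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("individual", "family"):
            raise LedgerError(f"level must be individual|family, got {self.level!r}")
        if not np.allclose(self.values, -self.values.T, atol=1e-8):
            raise LedgerError("net-transfer matrix is not antisymmetric")

    def get(self, i, j) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.values[a, b])

    def to_edgelist(self) -> pd.DataFrame:
        """Long-format edge list (each unordered dyad once, donor first)."""
        rows = []
        n = len(self.ids)
        for a in range(n):
            for b in range(a + 1, n):
                if self.days[a, b] > 0:
                    v = self.values[a, b]
                    donor, recip = (a, b) if v >= 0 else (b, a)
                    rows.append(
                        {
                            "donor": self.ids[donor],
                            "recipient": self.ids[recip],
                            "kcal_per_day": abs(float(v)),
                            "days": int(self.days[a, b]),
                        }
                    )
        return pd.DataFrame(rows, columns=["donor", "recipient", "kcal_per_day", "days"])

    @classmethod
    def from_edgelist(cls, df: pd.DataFrame, level: str, ids: list | None = None) -> "NetTransferMatrix":
        if ids is None:
            ids = sorted(set(df["donor"]) | set(df["recipient"]))
        idx = {p: k for k, p in enumerate(ids)}
        n = len(ids)
        vals = np.zeros((n, n))
        days = np.zeros((n, n), dtype=int)
        for row in df.itertuples(index=False):
            a, b = idx[row.donor], idx[row.recipient]
            vals[a, b] = row.kcal_per_day
            vals[b, a] = -row.kcal_per_day
            days[a, b] = days[b, a] = row.days
        return cls(level, list(ids), vals, days)


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------

def person_rates(ledger: SharingLedger) -> pd.DataFrame:
    """Per-person gross production and consumption in kcal per observed day.

    Production counts every kcal a person produced (eaten by anyone or given
    away); consumption counts every kcal they ate, regardless of source.
    """
    if hasattr(ledger, "_rates_cache"):
        return ledger._rates_cache.copy()
    ids = ledger.persons()
    days = ledger.days_observed().reindex(ids).fillna(0).astype(int)
    rec = ledger.records
    inconsistent = (set(rec["producer"]) | set(rec["recipient"])) - set(days[days > 0].index)
    if inconsistent:
        raise LedgerError(
            "persons with ledger records but zero observed days: "
            f"{sorted(map(str, inconsistent))[:5]}"
        )
    prod = rec.groupby("producer")["kcal"].sum().reindex(ids).fillna(0.0)
    cons = rec.groupby("recipient")["kcal"].sum().reindex(ids).fillna(0.0)
    out = pd.DataFrame(
        {
            "person": ids,
            "days": days.to_numpy(),
            "production": prod.to_numpy() / np.maximum(days.to_numpy(), 1),
            "consumption": cons.to_numpy() / np.maximum(days.to_numpy(), 1),
        }
    )
    out["net_production"] = out["production"] - out["consumption"]
    ledger._rates_cache = out
    return out.copy()


def individual_net_matrix(ledger: SharingLedger) -> NetTransferMatrix:
    """Person x person net kcal/day matrix from a sharing ledger.

    Flows are restricted to days on which *both* members of a dyad were
    observed, and divided by the count of those days, so intermittent
    sampling does not bias the daily rate.
    """
    if not len(ledger.records):
        raise LedgerError("cannot build a net-transfer matrix from an empty ledger")
    ids = ledger.persons()
    days = ledger.days_observed()
    rec_people = set(ledger.records["producer"]) | set(ledger.records["recipient"])
    no_days = rec_people - set(days[days > 0].index)
    if no_days:
        raise LedgerError(
            f"persons with records but zero observed days: {sorted(map(str, no_days))[:5]}"
        )
    idx = {p: k for k, p in enumerate(ids)}
    obs = ledger.observation_matrix(ids)
    dyad_days = obs.astype(np.int32) @ obs.astype(np.int32).T

    rec = ledger.records
    pi = rec["producer"].map(idx).to_numpy()
    ri = rec["recipient"].map(idx).to_numpy()
    di = rec["date"].to_numpy()
    joint = obs[pi, di] & obs[ri, di] & (pi != ri)
    flows = np.zeros((len(ids), len(ids)))
    np.add.at(flows, (pi[joint], ri[joint]), rec["kcal"].to_numpy()[joint])

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(dyad_days > 0, (flows - flows.T) / np.maximum(dyad_days, 1), 0.0)
    np.fill_diagonal(values, 0.0)
    return NetTransferMatrix("individual", ids, values, dyad_days)


def focal_category_sum(
    T: NetTransferMatrix,
    ped: Pedigree,
    focal,
    category: str,
    direction: str = "from-focal",
) -> float:
    """Sum of net transfers between ``focal`` and all living alters in the
    named relationship category, signed per ``direction``."""
    if category not in RELATION_CATEGORIES:
        raise LedgerError(
            f"unknown relationship category {category!r}; expected one of {RELATION_CATEGORIES}"
        )
    if direction not in ("from-focal", "to-focal"):
        raise LedgerError(f"direction must be from-focal|to-focal, got {direction!r}")
    alters = ped.relation_alters(focal, category)
    if focal not in T.ids:
        raise LedgerError(f"focal {focal!r} not in transfer matrix")
    a = T.ids.index(focal)
    total = 0.0
    for alt in alters:
        if alt in T.ids:
            total += T.values[a, T.ids.index(alt)]
    return total if direction == "from-focal" else -total


def family_net_matrix(T: NetTransferMatrix, ped: Pedigree) -> NetTransferMatrix:
    """Aggregate an individual matrix to nuclear families.

    Family-to-family values are sums of member-level net rates; only
    co-resident (same community) dyads carry data.  Within-family flows
    cancel by antisymmetry.  ``days`` is the maximum member-pair joint
    observation count.
    """
    if T.level != "individual":
        raise LedgerError("family_net_matrix expects an individual-level matrix")
    fams = ped.families()
    fam_ids = sorted(fams)
    fidx = {f: k for k, f in enumerate(fam_ids)}
    n = len(fam_ids)
    member_idx = {
        f: [T.ids.index(p) for p in members if p in T.ids] for f, members in fams.items()
    }
    values = np.zeros((n, n))
    days = np.zeros((n, n), dtype=int)
    for a, fa in enumerate(fam_ids):
        for b in range(a + 1, n):
            fb = fam_ids[b]
            if ped.family_community(fa) != ped.family_community(fb):
                continue
            ia, ib = member_idx[fa], member_idx[fb]
            if not ia or not ib:
                continue
            block = T.values[np.ix_(ia, ib)]
            dblock = T.days[np.ix_(ia, ib)]
            values[a, b] = block.sum()
            values[b, a] = -values[a, b]
            days[a, b] = days[b, a] = int(dblock.max()) if dblock.size else 0
    return NetTransferMatrix("family", fam_ids, values, days, meta={"from": "individual"})


def oriented_family_dyads(
    Tfam: NetTransferMatrix, ped: Pedigree, ref_year: int | None = None
) -> pd.DataFrame:
    """List each observed co-resident family dyad once, oriented from the
    family with the older eldest core adult (ties broken by smaller family
    id, logged)."""
    if ref_year is None:
        ref_year = int(max(ped.birth_year(i) for i in ped.ids))
    rows = []
    fam_ids = Tfam.ids
    for a in range(len(fam_ids)):
        for b in range(a + 1, len(fam_ids)):
            if Tfam.days[a, b] <= 0:
                continue
            fa, fb = fam_ids[a], fam_ids[b]
            age_a = max(ped.age(i, ref_year) for i in ped.core_adults(fa, ref_year=ref_year))
            age_b = max(ped.age(i, ref_year) for i in ped.core_adults(fb, ref_year=ref_year))
            if age_a == age_b:
                log.info("orientation tie between families %s and %s; using smaller id", fa, fb)
                older, younger = (fa, fb) if str(fa) <= str(fb) else (fb, fa)
            elif age_a > age_b:
                older, younger = fa, fb
            else:
                older, younger = fb, fa
            oa, ob = fam_ids.index(older), fam_ids.index(younger)
            rows.append(
                {
                    "fam_i": older,
                    "fam_j": younger,
                    "community": ped.family_community(older),
                    "net_transfer": float(Tfam.values[oa, ob]),
                    "days": int(Tfam.days[oa, ob]),
                    "age_i": max(age_a, age_b),
                    "age_j": min(age_a, age_b),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["fam_i", "fam_j", "community", "net_transfer", "days", "age_i", "age_j"],
    )


def net_production_profile(
    ledger: SharingLedger,
    ped: Pedigree,
    level: str = "individual",
    bins: np.ndarray | None = None,
    ref_year: int | None = None,
) -> pd.DataFrame:
    """Mean +- s.e. of net production (kcal/day) per age bin.

    Individual level bins persons by age; family level sums member rates and
    bins by the age of the oldest core adult.  Empty bins are excluded (and
    logged).
    """
    if ref_year is None:
        ref_year = int(max(ped.birth_year(i) for i in ped.ids))
    if bins is None:
        bins = np.arange(0, 90, 5) if level == "individual" else np.arange(15, 90, 10)
    rates = person_rates(ledger)
    rates = rates[rates["days"] > 0]
    if level == "individual":
        ages = np.array([ped.age(p, ref_year) for p in rates["person"]])
        net = rates["net_production"].to_numpy()
    elif level == "family":
        fam_of = {p: ped.family_of(p) for p in rates["person"]}
        df = rates.assign(fam=[fam_of[p] for p in rates["person"]])
        g = df.groupby("fam")["net_production"].sum()
        ages = np.array([max(ped.age(i, ref_year) for i in ped.core_adults(f)) for f in g.index])
        net = g.to_numpy()
    else:
        raise LedgerError(f"level must be individual|family, got {level!r}")

    out = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        mask = (ages >= lo) & (ages < hi)
        n = int(mask.sum())
        if n == 0:
            log.debug("empty age bin [%s, %s) excluded", lo, hi)
            continue
        vals = net[mask]
        out.append(
            {
                "age_lo": int(lo),
                "age_hi": int(hi),
                "n": n,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(out, columns=["age_lo", "age_hi", "n", "mean", "se"])
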