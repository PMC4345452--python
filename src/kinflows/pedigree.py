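"""Genealogy representation and coefficients of relatedness.

The pedigree is the substrate for every kin-directed quantity in this
package: pairwise relatedness ``r`` between individuals, mean relatedness
between nuclear families, and the categorical classification of family
dyads (parent-offspring, sibling, other kin, non-kin) used in the
between-family transfer models.

Relatedness is Wright's coefficient of relationship, computed as twice the
kinship coefficient via the standard recursion over parents, with founders
assumed mutually unrelated and non-inbred.  This is the quantity ``r`` that
enters Hamilton's rule ``b r > c``.
"""
from __future__ import annotations

import enum
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel token for a missing parent / no spouse in delimited files.
MISSING = "NA"

REQUIRED_COLUMNS = (
    "id",
    "sex",
    "birth_year",
    "mother_id",
    "father_id",
    "spouse_ids",
    "family_id",
    "community_id",
)


class PedigreeError(ValueError):
    """A structurally invalid pedigree or an invalid pedigree query."""


class UnknownIdError(PedigreeError):
    """A person, family or community id that is not in the pedigree."""


class DyadCategory(str, enum.Enum):
    """Relationship category of an (ordered) family dyad.

    Categories are exhaustive and mutually exclusive, with precedence
    parent-offspring > sibling > other-kin; non-kin means the mean
    cross-family relatedness is exactly zero.
    """

    PARENT_OFFSPRING = "parent-offspring"
    SIBLING = "sibling"
    OTHER_KIN = "other-kin"
    NON_KIN = "non-kin"


class Pedigree:
    """A genealogy with nuclear-family and community membership.

    Parameters
    ----------
    table:
        One row per person with columns ``id, sex, birth_year, mother_id,
        father_id, spouse_ids, family_id, community_id`` and optionally
        ``alive`` (bool, defaults to True).  ``mother_id``/``father_id`` are
        either both present or both missing (founder).  ``spouse_ids`` is an
        iterable (or ``;``-joined string) of person ids.

    Notes
    -----
    Dead individuals stay in the table (they are needed as genealogical
    links) but are excluded from family membership accessors by default.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy().reset_index(drop=True)
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing_cols:
            raise PedigreeError(f"pedigree table missing columns: {missing_cols}")
        if "alive" not in table.columns:
            table["alive"] = True
        table["alive"] = table["alive"].astype(bool)

        ids = table["id"].tolist()
        if len(set(ids)) != len(ids):
            dupes = table["id"][table["id"].duplicated()].tolist()
            raise PedigreeError(f"duplicate person ids: {dupes}")
        self._ids = ids
        self._idset = set(ids)

        bad_sex = set(table["sex"]) - {"F", "M"}
        if bad_sex:
            raise PedigreeError(f"sex must be 'F' or 'M', got {sorted(bad_sex)}")

        def _norm_parent(v):
            if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
                return None
            if isinstance(v, str) and v in ("", MISSING):
                return None
            if isinstance(v, float) and v.is_integer():
                return int(v)  # pandas coerces int columns with missing to float
            return v

        self._mother = {}
        self._father = {}
        for row in table.itertuples(index=False):
            m = _norm_parent(row.mother_id)
            f = _norm_parent(row.father_id)
            if (m is None) != (f is None):
                raise PedigreeError(
                    f"person {row.id}: one parent known, one missing; founders "
                    "must have both parents absent"
                )
            for p in (m, f):
                if p is not None and p not in self._idset:
                    raise UnknownIdError(f"person {row.id} has unknown parent {p}")
            self._mother[row.id] = m
            self._father[row.id] = f

        self._spouses = {}
        for row in table.itertuples(index=False):
            v = row.spouse_ids
            if isinstance(v, str):
                toks = [t for t in v.split(";") if t not in ("", MISSING)]
                sp = []
                for t in toks:
                    try:
                        sp.append(type(row.id)(t))
                    except (TypeError, ValueError):
                        sp.append(t)
            elif v is None:
                sp = []
            else:
                sp = list(v)
            self._spouses[row.id] = sp
        for i, sps in self._spouses.items():
            for s in sps:
                if s not in self._idset:
                    raise UnknownIdError(f"person {i} has unknown spouse {s}")
                if i not in self._spouses[s]:
                    raise PedigreeError(f"spouse link {i} -> {s} is not symmetric")

        # Topological depth (generation number); also proves acyclicity.
        depth: dict = {}
        children_of: dict = {i: [] for i in ids}
        indeg = {}
        for i in ids:
            parents = [p for p in (self._mother[i], self._father[i]) if p is not None]
            indeg[i] = len(parents)
            for p in parents:
                children_of[p].append(i)
        frontier = [i for i in ids if indeg[i] == 0]
        for i in frontier:
            depth[i] = 0
        order = []
        while frontier:
            i = frontier.pop()
            order.append(i)
            for c in children_of[i]:
                indeg[c] -= 1
                d = depth[i] + 1
                depth[c] = max(depth.get(c, 0), d)
                if indeg[c] == 0:
                    frontier.append(c)
        if len(order) != len(ids):
            raise PedigreeError("parent links contain a cycle")
        self._depth = depth
        self._order = order  # parents before children

        table["spouse_ids"] = [list(self._spouses[i]) for i in ids]
        self._table = table
        self._fam_of = dict(zip(ids, table["family_id"]))
        self._comm_of = dict(zip(ids, table["community_id"]))
        self._sex = dict(zip(ids, table["sex"]))
        self._birth = dict(zip(ids, table["birth_year"]))
        self._alive = dict(zip(ids, table["alive"]))
        self._phi_memo: dict = {}
        self._fam_cache: dict = {}
        self._core_cache: dict = {}
        self._children_of: dict = {i: [] for i in ids}
        for c in ids:
            for p in (self._mother[c], self._father[c]):
                if p is not None:
                    self._children_of[p].append(c)

    # ------------------------------------------------------------------ access
    @property
    def ids(self) -> list:
        return list(self._ids)

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, i) -> bool:
        return i in self._idset

    def _check(self, i) -> None:
        if i not in self._idset:
            raise UnknownIdError(f"unknown person id: {i!r}")

    def sex(self, i) -> str:
        self._check(i)
        return self._sex[i]

    def birth_year(self, i) -> int:
        self._check(i)
        return self._birth[i]

    def age(self, i, ref_year: int) -> int:
        self._check(i)
        return ref_year - self._birth[i]

    def is_alive(self, i) -> bool:
        self._check(i)
        return self._alive[i]

    def mother(self, i):
        self._check(i)
        return self._mother[i]

    def father(self, i):
        self._check(i)
        return self._father[i]

    def parents(self, i) -> tuple:
        self._check(i)
        return (self._mother[i], self._father[i])

    def spouses(self, i) -> list:
        self._check(i)
        return list(self._spouses[i])

    def children(self, i) -> list:
        self._check(i)
        return list(self._children_of[i])

    def family_of(self, i):
        self._check(i)
        return self._fam_of[i]

    def community_of(self, i):
        self._check(i)
        return self._comm_of[i]

    def founders(self) -> list:
        return [i for i in self._ids if self._mother[i] is None]

    def families(self, include_dead: bool = False) -> dict:
        """Mapping family id -> member ids (living members by default)."""
        if include_dead not in self._fam_cache:
            out: dict = {}
            for i in self._ids:
                if include_dead or self._alive[i]:
                    out.setdefault(self._fam_of[i], []).append(i)
            self._fam_cache[include_dead] = out
        return {f: list(v) for f, v in self._fam_cache[include_dead].items()}

    def communities(self) -> dict:
        out: dict = {}
        for i in self._ids:
            out.setdefault(self._comm_of[i], set()).add(self._fam_of[i])
        return {c: sorted(v) for c, v in out.items()}

    def family_members(self, fam, include_dead: bool = False) -> list:
        fams = self.families(include_dead=include_dead)
        all_fams = set(self._fam_of.values())
        if fam not in all_fams:
            raise UnknownIdError(f"unknown family id: {fam!r}")
        return fams.get(fam, [])

    def family_community(self, fam):
        for i in self._ids:
            if self._fam_of[i] == fam:
                return self._comm_of[i]
        raise UnknownIdError(f"unknown family id: {fam!r}")

    def core_adults(self, fam, adult_age: int = 16, ref_year: int | None = None) -> list:
        """Household heads: living adult members who are not offspring of a
        co-resident member (i.e. the founding couple of the nuclear unit)."""
        key = (fam, adult_age, ref_year)
        if key in self._core_cache:
            return list(self._core_cache[key])
        members = self.family_members(fam)
        mset = set(members)
        if ref_year is None:
            ref_year = max((self._birth[i] for i in self._ids), default=0)
        core = [
            i
            for i in members
            if (ref_year - self._birth[i]) >= adult_age
            and self._mother[i] not in mset
            and self._father[i] not in mset
        ]
        if not core:
            raise PedigreeError(f"family {fam!r} has no core adult")
        self._core_cache[key] = core
        return list(core)

    # ------------------------------------------------------------- relatedness
    def kinship(self, i, j) -> float:
        """Kinship coefficient phi(i, j): probability a random allele drawn
        from i is identical by descent to a random allele drawn from j."""
        self._check(i)
        self._check(j)
        return self._phi(i, j)

    def _phi(self, i, j) -> float:
        if self._depth[i] < self._depth[j] or (
            self._depth[i] == self._depth[j] and str(i) > str(j)
        ):
            i, j = j, i
        key = (i, j)
        hit = self._phi_memo.get(key)
        if hit is not None:
            return hit
        if i == j:
            m, f = self._mother[i], self._father[i]
            val = 0.5 * (1.0 + (self._phi(m, f) if m is not None else 0.0))
        else:
            # i is at least as deep as j, hence i is not an ancestor of j.
            m, f = self._mother[i], self._father[i]
            if m is None:
                val = 0.0
            else:
                val = 0.5 * (self._phi(m, j) + self._phi(f, j))
        self._phi_memo[key] = val
        return val

    def relatedness(self, i, j) -> float:
        """Coefficient of relatedness r(i, j) = 2 phi(i, j).

        On the diagonal this equals 1 + F_i (the inbreeding coefficient), i.e.
        exactly 1 for non-inbred individuals, which is the only case arising
        from the non-incestuous pedigrees this package simulates.
        """
        return 2.0 * self.kinship(i, j)

    def relatedness_matrix(self, ids: Sequence | None = None) -> pd.DataFrame:
        if ids is None:
            ids = self._ids
        n = len(ids)
        r = np.zeros((n, n))
        for a in range(n):
            r[a, a] = self.relatedness(ids[a], ids[a])
            for b in range(a + 1, n):
                r[a, b] = r[b, a] = self.relatedness(ids[a], ids[b])
        return pd.DataFrame(r, index=ids, columns=ids)

    def mean_cross_relatedness(self, ids_a: Iterable, ids_b: Iterable) -> float:
        ids_a, ids_b = list(ids_a), list(ids_b)
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise PedigreeError(
                f"groups overlap (a person cannot be in both): {sorted(map(str, overlap))}"
            )
        if not ids_a or not ids_b:
            raise PedigreeError("cannot average relatedness over an empty group")
        vals = [self.relatedness(a, b) for a in ids_a for b in ids_b]
        return float(np.mean(vals))

    def family_relatedness(self, fam_i, fam_j) -> float:
        """Mean relatedness over all cross-family pairs of living members."""
        return self.mean_cross_relatedness(
            self.family_members(fam_i), self.family_members(fam_j)
        )

    def classify_family_dyad(self, fam_i, fam_j, ref_year: int | None = None) -> DyadCategory:
        """Relationship category between two families, judged from the
        genealogical links between their core adults.

        Precedence: parent-offspring > sibling > other-kin; non-kin iff the
        mean cross-family relatedness is zero.
        """
        core_i = self.core_adults(fam_i, ref_year=ref_year)
        core_j = self.core_adults(fam_j, ref_year=ref_year)
        for a, b in itertools.product(core_i, core_j):
            if a in self.parents(b) or b in self.parents(a):
                return DyadCategory.PARENT_OFFSPRING
        for a, b in itertools.product(core_i, core_j):
            pa = {p for p in self.parents(a) if p is not None}
            pb = {p for p in self.parents(b) if p is not None}
            if pa & pb:
                return DyadCategory.SIBLING
        if self.family_relatedness(fam_i, fam_j) > 0.0:
            return DyadCategory.OTHER_KIN
        return DyadCategory.NON_KIN

    # ------------------------------------------------------------ relationships
    def relation_alters(self, focal, relation: str) -> list:
        """Living alters standing in the named relation to ``focal``.

        Relations: children, grandchildren, spouse, children-in-law,
        parents, grandparents, parents-in-law.
        """
        self._check(focal)
        kids = self.children(focal)
        if relation == "children":
            out = kids
        elif relation == "grandchildren":
            out = [g for c in kids for g in self.children(c)]
        elif relation == "spouse":
            out = self.spouses(focal)
        elif relation == "children-in-law":
            out = [s for c in kids for s in self.spouses(c)]
        elif relation == "parents":
            out = [p for p in self.parents(focal) if p is not None]
        elif relation == "grandparents":
            out = [
                g
                for p in self.parents(focal)
                if p is not None
                for g in self.parents(p)
                if g is not None
            ]
        elif relation == "parents-in-law":
            out = [
                p
                for s in self.spouses(focal)
                for p in self.parents(s)
                if p is not None
            ]
        else:
            raise PedigreeError(f"unknown relationship category: {relation!r}")
        seen: list = []
        for a in out:
            if a not in seen and self._alive[a]:
                seen.append(a)
        return seen

    # --------------------------------------------------------------------- io
    def to_frame(self) -> pd.DataFrame:
        """Serializable table; missing parents/spouses use the ``NA`` token."""
        df = self._table.copy()
        df["mother_id"] = [self._mother[i] if self._mother[i] is not None else MISSING for i in self._ids]
        df["father_id"] = [self._father[i] if self._father[i] is not None else MISSING for i in self._ids]
        df["spouse_ids"] = [
            ";".join(str(s) for s in self._spouses[i]) or MISSING for i in self._ids
        ]
        df["alive"] = df["alive"].astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("id", "birth_year", "family_id", "community_id"):
            df[col] = df[col].astype(int)
        for col in ("mother_id", "father_id"):
            df[col] = [None if v == MISSING else int(v) for v in df[col]]
        df["spouse_ids"] = [
            [] if v == MISSING else [int(t) for t in v.split(";")] for v in df["spouse_ids"]
        ]
        if "alive" in df.columns:
            df["alive"] = df["alive"].astype(int).astype(bool)
        return cls(df)
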