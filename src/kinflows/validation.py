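"""Monte-Carlo validation utilities for pedigree relatedness.

``gene_drop_relatedness`` estimates relatedness by explicit transmission of
founder alleles through the pedigree ("gene dropping").  It shares no code
with the recursive kinship computation in :mod:`kinflows.pedigree` and is
used as an independent oracle in the test battery.

``random_pedigree`` generates small random-mating pedigrees for stress
tests; it is deliberately unstructured (no family economics), unlike the
society simulator.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .pedigree import Pedigree


def gene_drop_relatedness(
    ped: Pedigree,
    pairs: list[tuple] | None = None,
    n_drops: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate r(i, j) by gene dropping.

    Each founder receives two unique alleles; every descendant inherits one
    random allele from each parent, independently per drop.  The kinship
    coefficient is estimated as the probability that a random allele of i is
    identical by descent to a random allele of j, and relatedness as twice
    that.

    Returns a DataFrame with columns ``i, j, r_hat, se`` where ``se`` is the
    Monte-Carlo standard error of ``r_hat``.
    """
    rng = np.random.default_rng(seed)
    ids = ped.ids
    if pairs is None:
        pairs = list(itertools.combinations(ids, 2))

    # Transmit alleles in topological order (parents first).
    order = sorted(ids, key=lambda i: ped._depth[i])
    alleles: dict = {}
    next_allele = 0
    for i in order:
        m, f = ped.parents(i)
        if m is None:
            a0 = np.full(n_drops, next_allele, dtype=np.int32)
            a1 = np.full(n_drops, next_allele + 1, dtype=np.int32)
            next_allele += 2
        else:
            ma = alleles[m]
            fa = alleles[f]
            pick_m = rng.integers(0, 2, n_drops)
            pick_f = rng.integers(0, 2, n_drops)
            a0 = np.where(pick_m == 0, ma[0], ma[1])
            a1 = np.where(pick_f == 0, fa[0], fa[1])
        alleles[i] = (a0, a1)

    rows = []
    for i, j in pairs:
        ai0, ai1 = alleles[i]
        aj0, aj1 = alleles[j]
        phi_per_drop = (
            (ai0 == aj0).astype(np.float64)
            + (ai0 == aj1)
            + (ai1 == aj0)
            + (ai1 == aj1)
        ) / 4.0
        r_hat = 2.0 * phi_per_drop.mean()
        se = 2.0 * phi_per_drop.std(ddof=1) / np.sqrt(n_drops)
        rows.append({"i": i, "j": j, "r_hat": float(r_hat), "se": float(se)})
    return pd.DataFrame(rows)


def random_pedigree(n_members: int, seed: int = 0, founder_fraction: float = 0.4) -> Pedigree:
    """A random-mating pedigree of ``n_members`` people (single community).

    Founders are created first; each subsequent person gets a random existing
    (female, male) parent pair, so sibships, half-sibships and multi-
    generation links arise naturally.  Parent links are acyclic by
    construction.
    """
    if n_members < 4:
        raise ValueError("need at least 4 members")
    rng = np.random.default_rng(seed)
    n_founders = max(4, int(round(n_members * founder_fraction)))
    n_founders = min(n_founders, n_members)
    if n_founders % 2:
        n_founders += 1
        n_founders = min(n_founders, n_members)

    sexes = ["F", "M"] * (n_founders // 2)
    birth = {i: 1940 + int(rng.integers(0, 10)) for i in range(1, n_founders + 1)}
    mother = {i: None for i in range(1, n_founders + 1)}
    father = dict(mother)
    sex = {i + 1: sexes[i] for i in range(n_founders)}

    nid = n_founders
    while nid < n_members:
        females = [i for i in sex if sex[i] == "F"]
        males = [i for i in sex if sex[i] == "M"]
        m = int(rng.choice(females))
        f = int(rng.choice(males))
        nid += 1
        sex[nid] = "F" if rng.random() < 0.5 else "M"
        mother[nid] = m
        father[nid] = f
        birth[nid] = max(birth[m], birth[f]) + int(rng.integers(18, 30))

    ids = sorted(sex)
    # Spouses: couples that produced a child together.
    couple_of: dict = {}
    spouses: dict = {i: [] for i in ids}
    for c in ids:
        if mother[c] is not None:
            pair = (mother[c], father[c])
            if pair not in couple_of:
                couple_of[pair] = len(couple_of) + 1
                if father[c] not in spouses[mother[c]]:
                    spouses[mother[c]].append(father[c])
                    spouses[father[c]].append(mother[c])

    # Nuclear families: a couple plus its children; everyone else singleton.
    fam: dict = {}
    next_fam = len(couple_of) + 1
    for pair, fid in couple_of.items():
        fam[pair[0]] = fid
        fam[pair[1]] = fid
    for c in ids:
        if mother[c] is not None and c not in fam:
            fam[c] = couple_of[(mother[c], father[c])]
    for i in ids:
        if i not in fam:
            fam[i] = next_fam
            next_fam += 1

    table = pd.DataFrame(
        {
            "id": ids,
            "sex": [sex[i] for i in ids],
            "birth_year": [birth[i] for i in ids],
            "mother_id": [mother[i] for i in ids],
            "father_id": [father[i] for i in ids],
            "spouse_ids": [spouses[i] for i in ids],
            "family_id": [fam[i] for i in ids],
            "community_id": 1,
        }
    )
    return Pedigree(table)
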