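"""End-to-end analysis pipeline: ledger + pedigree -> tables.

This is the layer the command-line interface wraps: it builds the family
dyad table (net transfers, relatedness, both need variants, relationship
category), fits the interaction and per-category models, computes net
production and age-transfer profiles, and bundles everything into plain
DataFrames ready to be written as delimited tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .ledger import (
    NetTransferMatrix,
    SharingLedger,
    family_net_matrix,
    individual_net_matrix,
    net_production_profile,
    oriented_family_dyads,
)
from .need import need_table, standardize
from .pedigree import Pedigree
from .simulate import SocietyConfig, emit_ledger, simulate_society

log = logging.getLogger(__name__)

#: The seven age-profile panels: (name, relationship category, direction)
PROFILE_PANELS = (
    ("to_children", "children", "from-focal"),
    ("from_parents", "parents", "to-focal"),
    ("to_grandchildren", "grandchildren", "from-focal"),
    ("from_grandparents", "grandparents", "to-focal"),
    ("to_spouse", "spouse", "from-focal"),
    ("to_children_in_law", "children-in-law", "from-focal"),
    ("from_parents_in_law", "parents-in-law", "to-focal"),
)


def check_ids(ped: Pedigree, ledger: SharingLedger) -> None:
    """Every person in the ledger must exist in the pedigree."""
    unknown = [p for p in ledger.persons() if p not in ped]
    if unknown:
        raise ValueError(
            f"ledger mentions persons absent from the pedigree: {sorted(map(str, unknown))[:10]}"
        )


def build_family_dyads(
    ped: Pedigree,
    ledger: SharingLedger,
    ref_year: int | None = None,
    T: NetTransferMatrix | None = None,
) -> pd.DataFrame:
    """Family-dyad modelling table: one row per observed co-resident dyad,
    oriented older -> younger, with net transfer (kcal/day), mean
    relatedness, relationship category, and both need variants."""
    check_ids(ped, ledger)
    if T is None:
        T = individual_net_matrix(ledger)
    Tf = family_net_matrix(T, ped)
    dy = oriented_family_dyads(Tf, ped, ref_year=ref_year)
    if not len(dy):
        return dy
    fams = sorted(set(dy["fam_i"]) | set(dy["fam_j"]))
    needs = need_table(ledger, ped, fams, ref_year=ref_year).set_index("family")
    dy["rbar"] = [
        ped.family_relatedness(i, j) for i, j in zip(dy["fam_i"], dy["fam_j"])
    ]
    dy["category"] = [
        ped.classify_family_dyad(i, j, ref_year=ref_year).value
        for i, j in zip(dy["fam_i"], dy["fam_j"])
    ]
    for side in ("i", "j"):
        dy[f"need_{side}_meas"] = needs.loc[dy[f"fam_{side}"], "measured_need"].to_numpy()
        dy[f"need_{side}_est"] = needs.loc[dy[f"fam_{side}"], "estimated_need"].to_numpy()
    return dy


@dataclass
class AnalysisResult:
    dyads: pd.DataFrame
    interaction_models: dict  # need variant -> ModelFit
    category_models: pd.DataFrame
    net_production_individual: pd.DataFrame
    net_production_family: pd.DataFrame
    profiles: dict = field(default_factory=dict)  # panel name -> DataFrame

    def family_need_table(self) -> pd.DataFrame:
        """Per-family raw and standardized need; z-scores are scaled over
        the dyadic modelling sample (families enter once per dyad)."""
        dy = self.dyads
        if not len(dy):
            return pd.DataFrame()
        out = pd.concat(
            [
                dy[["fam_i", "need_i_meas", "need_i_est"]].rename(
                    columns={"fam_i": "family", "need_i_meas": "measured_need",
                             "need_i_est": "estimated_need"}
                ),
                dy[["fam_j", "need_j_meas", "need_j_est"]].rename(
                    columns={"fam_j": "family", "need_j_meas": "measured_need",
                             "need_j_est": "estimated_need"}
                ),
            ]
        )
        for col in ("measured_need", "estimated_need"):
            out[f"{col}_z"] = standardize(out[col])
        return out.drop_duplicates("family").sort_values("family").reset_index(drop=True)

    def model_manifest(self) -> dict:
        """Formula, random-effect variances and convergence per fit."""
        return {
            variant: {
                "formula": fit.formula,
                "random_effects": fit.random_effects,
                "converged": fit.converged,
                "method": fit.method,
                "n": fit.n,
                "flags": fit.flags,
            }
            for variant, fit in self.interaction_models.items()
        }

    def tables(self) -> dict:
        out = {
            "family_dyads": self.dyads,
            "family_need": self.family_need_table(),
            "category_models": self.category_models,
            "net_production_individual": self.net_production_individual,
            "net_production_family": self.net_production_family,
        }
        for variant, fit in self.interaction_models.items():
            out[f"interaction_model_{variant}_need"] = fit.to_frame()
        for name, df in self.profiles.items():
            out[f"age_profile_{name}"] = df
        return out


def analyze(
    ped: Pedigree,
    ledger: SharingLedger,
    ref_year: int | None = None,
    profiles: bool = True,
    profile_bin_width: int = 10,
) -> AnalysisResult:
    """Run the full analysis chain on a pedigree + sharing ledger."""
    if not len(ledger.records):
        log.warning("empty ledger: producing empty analysis outputs")
        empty = pd.DataFrame()
        return AnalysisResult(empty, {}, empty, empty, empty, {})
    check_ids(ped, ledger)
    T = individual_net_matrix(ledger)
    dyads = build_family_dyads(ped, ledger, ref_year=ref_year, T=T)
    interaction = {}
    for variant in ("estimated", "measured"):
        try:
            interaction[variant] = models.fit_family_interaction_model(dyads, variant)
        except models.ModelError as exc:
            log.warning("interaction model (%s need) not fit: %s", variant, exc)
    by_category = models.fit_by_relationship(dyads)
    np_ind = net_production_profile(ledger, ped, "individual", ref_year=ref_year)
    np_fam = net_production_profile(ledger, ped, "family", ref_year=ref_year)
    prof = {}
    if profiles:
        for name, cat, direction in PROFILE_PANELS:
            prof[name] = models.fit_age_profiles(
                T, ped, cat, direction, bin_width=profile_bin_width, ref_year=ref_year
            )
    return AnalysisResult(dyads, interaction, by_category, np_ind, np_fam, prof)


# ---------------------------------------------------------------------------
# Replicate studies (sign recovery across seeds)
# ---------------------------------------------------------------------------

def _all_ages_mean(profile: pd.DataFrame, sex: str) -> float:
    row = profile[(profile["sex"] == sex) & (profile["age_lo"] == -1)]
    return float(row["mean"].iloc[0]) if len(row) else np.nan


def _peak_bin(profile: pd.DataFrame, sex: str) -> float:
    rows = profile[(profile["sex"] == sex) & (profile["age_lo"] >= 0)]
    if not len(rows):
        return np.nan
    return float(rows.loc[rows["mean"].idxmax(), "age_lo"])


def seed_summary(
    cfg: SocietyConfig, profiles: bool = True, categories: bool = True
) -> dict:
    """Simulate one society under ``cfg`` and distil the headline
    quantities used in sign-recovery studies."""
    run = simulate_society(cfg)
    ledger = emit_ledger(run)
    ped = run.ped
    out: dict = {"seed": cfg.seed}

    T = individual_net_matrix(ledger)
    dyads = build_family_dyads(ped, ledger, ref_year=cfg.study_year, T=T)
    for variant, suff in (("estimated", "est"), ("measured", "meas")):
        fit = models.fit_family_interaction_model(dyads, variant)
        for term, short in (
            ("rbar", "rbar"),
            ("need_i", "ni"),
            ("need_j", "nj"),
            ("need_i_x_rbar", "ni_r"),
            ("need_j_x_rbar", "nj_r"),
        ):
            c = fit.coef(term)
            out[f"b_{short}_{suff}"] = c.B
            out[f"p_{short}_{suff}"] = c.p
        out[f"converged_{suff}"] = fit.converged
    out["n_dyads"] = len(dyads)

    t2 = (
        models.fit_by_relationship(dyads).set_index("category")
        if categories
        else pd.DataFrame()
    )
    for cat, short in (
        ("parent-offspring", "parent"),
        ("sibling", "sibling"),
        ("other-kin", "otherkin"),
        ("non-kin", "nonkin"),
    ):
        if cat in t2.index and "mean" in t2.columns:
            out[f"mean_{short}"] = t2.loc[cat].get("mean", np.nan)
            out[f"se_{short}"] = t2.loc[cat].get("mean_se", np.nan)

    fam_needs = pd.concat(
        [
            dyads[["fam_i", "need_i_est", "need_i_meas"]].rename(
                columns={"fam_i": "family", "need_i_est": "est", "need_i_meas": "meas"}
            ),
            dyads[["fam_j", "need_j_est", "need_j_meas"]].rename(
                columns={"fam_j": "family", "need_j_est": "est", "need_j_meas": "meas"}
            ),
        ]
    ).drop_duplicates("family")
    out["corr_est_meas"] = float(np.corrcoef(fam_needs["est"], fam_needs["meas"])[0, 1])

    if profiles:
        to_children = models.fit_age_profiles(
            T, ped, "children", "from-focal", bin_width=10, ref_year=cfg.study_year
        )
        to_grandchildren = models.fit_age_profiles(
            T, ped, "grandchildren", "from-focal", bin_width=10, ref_year=cfg.study_year
        )
        from_parents = models.fit_age_profiles(
            T, ped, "parents", "to-focal", bin_width=5, ref_year=cfg.study_year
        )
        out["mother_mean"] = _all_ages_mean(to_children, "F")
        out["father_mean"] = _all_ages_mean(to_children, "M")
        out["grandmother_mean"] = _all_ages_mean(to_grandchildren, "F")
        out["grandfather_mean"] = _all_ages_mean(to_grandchildren, "M")
        out["daughter_peak_bin"] = _peak_bin(from_parents, "F")
        out["son_peak_bin"] = _peak_bin(from_parents, "M")
    return out


def replicate(
    cfg: SocietyConfig,
    n_seeds: int,
    base_seed: int = 0,
    profiles: bool = True,
    categories: bool = True,
) -> pd.DataFrame:
    """Re-run the simulate + analyze chain over ``n_seeds`` seeds."""
    rows = []
    import dataclasses as _dc

    for k in range(n_seeds):
        c = _dc.replace(cfg, seed=int(base_seed + k))
        rows.append(seed_summary(c, profiles=profiles, categories=categories))
    return pd.DataFrame(rows)


def sign_recovery(rep: pd.DataFrame, alpha: float = 0.05, suff: str = "est") -> dict:
    """Fraction of seeds recovering the predicted interaction sign pattern:
    positive relatedness effect, negative donor-need x r, positive
    recipient-need x r (each with p < alpha)."""
    ok = (
        (rep[f"b_rbar_{suff}"] > 0)
        & (rep[f"p_rbar_{suff}"] < alpha)
        & (rep[f"b_ni_r_{suff}"] < 0)
        & (rep[f"p_ni_r_{suff}"] < alpha)
        & (rep[f"b_nj_r_{suff}"] > 0)
        & (rep[f"p_nj_r_{suff}"] < alpha)
    )
    return {"rate": float(ok.mean()), "n": int(len(rep))}
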