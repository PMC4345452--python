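"""Mixed-effect models of dyadic net transfers.

Three model families, mirroring the analysis chain the package implements:

* ``fit_family_interaction_model`` — net transfers from older family i to
  younger family j regressed on mean relatedness r, the (standardized) net
  need of each family, and the need x r interactions, with random
  intercepts for donor family, recipient family and community.  The key
  inclusive-fitness predictions are a negative donor-need x r and a
  positive recipient-need x r coefficient.
* ``fit_by_relationship`` — per relationship category (parent-offspring,
  sibling, other kin, non-kin): the mean net transfer, and standardized
  coefficients of donor/recipient need.
* ``fit_age_profiles`` — age-bin x sex means of a focal person's summed net
  transfers to/from a relationship category, with community random
  intercepts.

Estimation uses maximum likelihood via ``statsmodels`` MixedLM with Wald
p-values; degenerate fits fall back to OLS with cluster-robust (by
community) standard errors and are flagged loudly.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ledger import RELATION_CATEGORIES, NetTransferMatrix, focal_category_sum
from .need import standardize
from .pedigree import DyadCategory, Pedigree

log = logging.getLogger(__name__)

CATEGORY_ORDER = [c.value for c in DyadCategory]

INTERACTION_TERMS = ("intercept", "rbar", "need_i", "need_j", "need_i_x_rbar", "need_j_x_rbar")


class ModelError(ValueError):
    """Invalid model specification or unusable design matrix."""


@dataclass
class CoefficientEstimate:
    term: str
    B: float
    beta: float
    se: float
    p: float
    n: int


@dataclass
class ModelFit:
    formula: str
    coefficients: list[CoefficientEstimate]
    random_effects: dict = field(default_factory=dict)
    converged: bool = True
    method: str = "mixedlm-ml"
    n: int = 0
    flags: list[str] = field(default_factory=list)

    def coef(self, term: str) -> CoefficientEstimate:
        for c in self.coefficients:
            if c.term == term:
                return c
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": c.term, "B": c.B, "beta": c.beta, "se": c.se, "p": c.p, "n": c.n}
                for c in self.coefficients
            ]
        )


def _check_rank(X: pd.DataFrame) -> None:
    """Raise naming the collinear columns if the design is rank deficient."""
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        bad = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
        if not bad:
            _, R = np.linalg.qr(mat)
            diag = np.abs(np.diag(R))
            bad = [X.columns[k] for k in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise ModelError(f"rank-deficient design; collinear or constant terms: {bad}")


def _mixed_or_ols(
    data: pd.DataFrame,
    fixed_terms: list[str],
    outcome: str = "y",
    vc: bool = True,
) -> tuple[pd.Series, pd.Series, pd.Series, str, bool, dict]:
    """Fit outcome ~ fixed_terms with community / donor / recipient random
    intercepts; fall back to cluster-robust OLS when the mixed fit is
    degenerate.  Returns (params, bse, pvalues, method, converged, re_var)."""
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{outcome} ~ {rhs}"
    n_comm = data["community"].nunique()
    n_par = len(fixed_terms) + 1

    ols = (
        smf.ols(formula, data).fit(
            cov_type="cluster", cov_kwds={"groups": data["community"]}
        )
        if n_comm >= 2
        else smf.ols(formula, data).fit()
    )

    if n_comm >= 2 and len(data) >= max(8, n_par + 5):
        vc_formula = (
            {"donor": "0 + C(fam_i)", "recipient": "0 + C(fam_j)"}
            if vc and data["fam_i"].nunique() > 1 and data["fam_j"].nunique() > 1
            else None
        )
        ols_bse = np.asarray(ols.bse)

        def _sane(bse):
            return (
                np.all(np.isfinite(bse))
                and np.all(bse > 0)
                and np.all(bse < 100.0 * np.maximum(ols_bse, 1e-12))
                and np.all(bse > 0.01 * np.maximum(ols_bse, 1e-12))
            )

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    formula,
                    data,
                    groups="community",
                    re_formula="1",
                    vc_formula=vc_formula,
                )
                res = md.fit(reml=False, method="lbfgs", maxiter=200, disp=False)
                k = len(res.fe_params)
                bse = np.asarray(res.bse_fe)[:k]
                if not res.converged and not _sane(bse):
                    # restart from the stalled point; boundary variance
                    # components often stall the first pass harmlessly
                    res = md.fit(
                        reml=False,
                        method="lbfgs",
                        maxiter=200,
                        disp=False,
                        start_params=res.params_object,
                    )
                    bse = np.asarray(res.bse_fe)[:k]
                pvals = np.asarray(res.pvalues)[:k]
            sane = _sane(bse)
            if sane:
                re_var = {"community": float(res.cov_re.iloc[0, 0])}
                if vc_formula:
                    re_var.update(
                        {nm: float(v) for nm, v in zip(md.exog_vc.names, res.vcomp)}
                    )
                re_var["residual"] = float(res.scale)
                return (
                    res.fe_params,
                    pd.Series(bse, index=res.fe_params.index),
                    pd.Series(pvals, index=res.fe_params.index),
                    "mixedlm-ml",
                    bool(res.converged),
                    re_var,
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("mixed model failed (%s); falling back to OLS", exc)
    log.warning("degenerate or under-sized mixed fit; cluster OLS fallback for %r", formula)
    return ols.params, ols.bse, ols.pvalues, "ols-cluster", False, {}


def fit_family_interaction_model(
    dyads: pd.DataFrame, need_variant: str = "estimated", scale: bool = True
) -> ModelFit:
    """Net transfers i -> j on relatedness, need, and need x r interactions.

    ``dyads`` needs columns ``net_transfer, rbar, community, fam_i, fam_j``
    and ``need_i_<v>, need_j_<v>`` for the chosen variant (``estimated`` or
    ``measured``).  With ``scale=True`` (default) outcome and needs are
    standardized over the dyad sample before fitting, as in the reference
    analysis; r stays on its natural [0, 1] scale.  ``scale=False`` fits the
    inputs as given (used for estimator calibration on pre-scaled data).
    """
    if need_variant not in ("estimated", "measured"):
        raise ModelError(f"need_variant must be estimated|measured, got {need_variant!r}")
    if dyads["community"].nunique() < 2:
        raise ModelError("family interaction model needs dyads from >= 2 communities")
    suff = "est" if need_variant == "estimated" else "meas"
    _z = standardize if scale else (lambda v: np.asarray(v, dtype=float))
    data = pd.DataFrame(
        {
            "y": _z(dyads["net_transfer"]),
            "rbar": dyads["rbar"].to_numpy(),
            "need_i": _z(dyads[f"need_i_{suff}"]),
            "need_j": _z(dyads[f"need_j_{suff}"]),
            "community": dyads["community"].to_numpy(),
            "fam_i": dyads["fam_i"].to_numpy(),
            "fam_j": dyads["fam_j"].to_numpy(),
        }
    )
    data["need_i_x_rbar"] = data["need_i"] * data["rbar"]
    data["need_j_x_rbar"] = data["need_j"] * data["rbar"]

    X = data[["rbar", "need_i", "need_j", "need_i_x_rbar", "need_j_x_rbar"]].copy()
    X.insert(0, "intercept", 1.0)
    _check_rank(X)

    fixed = ["rbar", "need_i", "need_j", "need_i_x_rbar", "need_j_x_rbar"]
    params, bse, pvals, method, converged, re_var = _mixed_or_ols(data, fixed)
    name_map = {"Intercept": "intercept", **{t: t for t in fixed}}
    coefs = [
        CoefficientEstimate(
            term=name_map.get(nm, nm),
            B=float(params[nm]),
            beta=float(params[nm]),
            se=float(bse[nm]),
            p=float(pvals[nm]),
            n=len(data),
        )
        for nm in params.index
    ]
    if converged:
        flags = []
    elif method.startswith("mixedlm"):
        flags = ["optimizer-not-converged"]
    else:
        flags = ["ols-fallback"]
    return ModelFit(
        formula=f"z(net_transfer) ~ rbar * z(need_i) + rbar * z(need_j) [{need_variant}]",
        coefficients=coefs,
        random_effects=re_var,
        converged=converged,
        method=method,
        n=len(data),
        flags=flags,
    )


def fit_by_relationship(dyads: pd.DataFrame, min_dyads: int = 3) -> pd.DataFrame:
    """Per relationship category: mean net transfer and standardized need
    coefficients (both need variants).

    Returns one row per category with columns ``n, mean, mean_se, mean_p``
    and ``beta_need_{i,j}_{est,meas}`` (+ se/p), NaN-flagged when a category
    has fewer than ``min_dyads`` dyads.
    """
    if "category" not in dyads.columns:
        raise ModelError("dyads need a 'category' column")
    unknown = set(dyads["category"]) - set(CATEGORY_ORDER)
    if unknown:
        raise ModelError(f"unknown relationship categories: {sorted(unknown)}")
    rows = []
    for cat in CATEGORY_ORDER:
        sub = dyads[dyads["category"] == cat]
        row: dict = {"category": cat, "n": len(sub)}
        if len(sub) < min_dyads:
            row["flag"] = "insufficient-dyads"
            rows.append(row)
            continue
        params, bse, pvals, method, conv, _ = _mixed_or_ols(
            sub.assign(y=sub["net_transfer"].to_numpy()), [], vc=True
        )
        row.update(
            mean=float(params["Intercept"]),
            mean_se=float(bse["Intercept"]),
            mean_p=float(pvals["Intercept"]),
        )
        flags = [] if conv else ["ols-fallback"]
        for suff in ("est", "meas"):
            cols = [f"need_i_{suff}", f"need_j_{suff}"]
            try:
                z = sub.assign(
                    y=standardize(sub["net_transfer"]),
                    need_i=standardize(sub[cols[0]]),
                    need_j=standardize(sub[cols[1]]),
                )
            except Exception:
                row[f"flag_{suff}"] = "constant-input"
                continue
            params, bse, pvals, method, conv, _ = _mixed_or_ols(z, ["need_i", "need_j"])
            for side in ("need_i", "need_j"):
                row[f"beta_{side}_{suff}"] = float(params[side])
                row[f"beta_{side}_{suff}_se"] = float(bse[side])
                row[f"beta_{side}_{suff}_p"] = float(pvals[side])
            if not conv:
                flags.append(f"ols-fallback-{suff}")
        if flags:
            row["flag"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_age_profiles(
    T: NetTransferMatrix,
    ped: Pedigree,
    category: str,
    direction: str = "from-focal",
    bin_width: int = 10,
    ref_year: int | None = None,
    min_age: int = 0,
) -> pd.DataFrame:
    """Mean net transfer (kcal/day) between focals and a relationship
    category, by age bin and sex, plus an all-ages row per sex.

    Focals are living persons with at least one living alter in the
    category.  Each focal contributes one row (its age falls in one bin);
    community random intercepts absorb village-level clustering.  Bins with
    a single focal are reported without a p-value and flagged.
    """
    if category not in RELATION_CATEGORIES:
        raise ModelError(f"unknown relationship category {category!r}")
    if ref_year is None:
        ref_year = int(max(ped.birth_year(i) for i in ped.ids))
    recs = []
    for focal in ped.ids:
        if not ped.is_alive(focal) or focal not in T.ids:
            continue
        alters = ped.relation_alters(focal, category)
        if not alters:
            continue
        age = ped.age(focal, ref_year)
        if age < min_age:
            continue
        recs.append(
            {
                "focal": focal,
                "sex": ped.sex(focal),
                "age": age,
                "bin": int(age // bin_width * bin_width),
                "community": ped.community_of(focal),
                "y": focal_category_sum(T, ped, focal, category, direction),
            }
        )
    df = pd.DataFrame(recs)
    out = []
    if not len(df):
        return pd.DataFrame(
            columns=["sex", "age_lo", "age_hi", "n", "mean", "se", "p", "flag"]
        )
    for sex in ("F", "M"):
        sdf = df[df["sex"] == sex]
        if not len(sdf):
            continue
        groups = [("all", sdf)] + [
            (b, sdf[sdf["bin"] == b]) for b in sorted(sdf["bin"].unique())
        ]
        for b, bdf in groups:
            rec = {
                "sex": sex,
                "age_lo": -1 if b == "all" else int(b),
                "age_hi": -1 if b == "all" else int(b) + bin_width,
                "n": len(bdf),
            }
            if len(bdf) == 1:
                rec.update(mean=float(bdf["y"].iloc[0]), se=np.nan, p=np.nan, flag="single-focal")
            else:
                params, bse, pvals, method, conv, _ = _mixed_or_ols(
                    bdf.assign(fam_i=0, fam_j=0), [], vc=False
                )
                rec.update(
                    mean=float(params["Intercept"]),
                    se=float(bse["Intercept"]),
                    p=float(pvals["Intercept"]),
                    flag="" if conv else "ols-fallback",
                )
            out.append(rec)
    return pd.DataFrame(out, columns=["sex", "age_lo", "age_hi", "n", "mean", "se", "p", "flag"])


# ---------------------------------------------------------------------------
# Calibration data generator (model's own assumptions)
# ---------------------------------------------------------------------------

def simulate_lmm_dyads(
    seed: int,
    n_communities: int = 8,
    families_per_community: int = 28,
    betas: dict | None = None,
    sd_community: float = 0.2,
    sd_donor: float = 0.3,
    sd_recipient: float = 0.3,
    sd_resid: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Dyadic data generated exactly under the interaction model's
    assumptions (linear fixed effects + Gaussian crossed intercepts), for
    estimator calibration.  Returns (dyads, true_betas)."""
    if betas is None:
        betas = {
            "intercept": 0.0,
            "rbar": 1.0,
            "need_i": 0.0,
            "need_j": 0.0,
            "need_i_x_rbar": -1.5,
            "need_j_x_rbar": 0.6,
        }
    rng = np.random.default_rng(seed)
    rows = []
    fam_counter = 0
    for comm in range(n_communities):
        fams = np.arange(fam_counter, fam_counter + families_per_community)
        fam_counter += families_per_community
        need = rng.normal(0, 1, families_per_community)
        u_comm = rng.normal(0, sd_community)
        u_don = rng.normal(0, sd_donor, families_per_community)
        u_rec = rng.normal(0, sd_recipient, families_per_community)
        for a in range(families_per_community):
            for b in range(a + 1, families_per_community):
                related = rng.random() < 0.4
                rbar = float(rng.choice([0.0625, 0.125, 0.25, 0.5])) if related else 0.0
                y = (
                    betas["intercept"]
                    + betas["rbar"] * rbar
                    + betas["need_i"] * need[a]
                    + betas["need_j"] * need[b]
                    + betas["need_i_x_rbar"] * need[a] * rbar
                    + betas["need_j_x_rbar"] * need[b] * rbar
                    + u_comm
                    + u_don[a]
                    + u_rec[b]
                    + rng.normal(0, sd_resid)
                )
                rows.append(
                    {
                        "fam_i": fams[a],
                        "fam_j": fams[b],
                        "community": comm,
                        "net_transfer": y,
                        "rbar": rbar,
                        "need_i_est": need[a],
                        "need_j_est": need[b],
                        "need_i_meas": need[a],
                        "need_j_meas": need[b],
                    }
                )
    return pd.DataFrame(rows), betas
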