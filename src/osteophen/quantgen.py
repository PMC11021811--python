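"""Variance decomposition, broad-sense heritability and covariate handling.

Implements the strain-panel quantitative-genetics workflow: a two-factor
(strain x sex) ANOVA decomposition, broad-sense heritability from the
sum-of-squares quotients

    sigma2_strain = SS_strain / n_avg        (n_avg = average group size)
    sigma2_sex    = SS_sex / df_sex
    sigma2_res    = SS_res / df_res
    H2 = sigma2_strain / (sigma2_strain + sigma2_sex + sigma2_res)

plus per-strain allometric body-mass adjustment with p > 0.20 slope zeroing,
a mass-covariate general linear model, Sidak-corrected post hoc contrasts and
fasting-blood-glucose classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ContrastError, DesignError, MappingError, ValidationError

__all__ = [
    "AnovaDecomposition",
    "H2Result",
    "AdjustmentModel",
    "anova_ss",
    "broad_sense_h2",
    "h2_table",
    "fit_mass_slopes",
    "apply_mass_adjustment",
    "covariate_significance",
    "strain_sex_posthoc",
    "sidak_adjust",
    "classify_glycemia",
    "HYPERGLYCEMIA_THRESHOLD_MG_DL",
]

HYPERGLYCEMIA_THRESHOLD_MG_DL = 250.0


@dataclass(frozen=True)
class AnovaDecomposition:
    trait: str
    ss_strain: float
    ss_sex: float
    ss_res: float
    df_strain: int
    df_sex: int
    df_res: int
    n_avg: float  # animals with the trait / number of strains (or cells)
    n_obs: int
    model: str  # "additive" | "interaction"
    ss_type: str  # "I" | "II" | "III"
    ss_interaction: float = 0.0
    df_interaction: int = 0
    degenerate: bool = False  # zero total variance


@dataclass(frozen=True)
class H2Result:
    trait: str
    sigma2_strain: float
    sigma2_sex: float
    sigma2_res: float
    H2: float
    n_obs: int
    degenerate: bool = False


def _prepare(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    need = {"strain", "sex", trait}
    missing = need - set(table.columns)
    if missing:
        raise DesignError(f"table lacks columns {sorted(missing)}")
    df = table[["strain", "sex", trait]].dropna(subset=[trait]).copy()
    df = df.rename(columns={trait: "value"})
    if df["strain"].nunique() < 2:
        raise DesignError(f"{trait}: need at least 2 strains")
    if df["sex"].nunique() < 2:
        raise DesignError(f"{trait}: need both sexes")
    cells = df.groupby(["strain", "sex"], observed=True).size()
    if not (cells >= 2).any():
        raise DesignError(f"{trait}: need >= 2 replicates in at least one strain-sex cell")
    return df


def anova_ss(
    table: pd.DataFrame,
    trait: str,
    model: str = "additive",
    ss_type: str = "III",
    group: str = "strain",
) -> AnovaDecomposition:
    """Two-factor least-squares ANOVA decomposition of one trait.

    ``model`` selects the additive (strain + sex) or the full interaction
    model; ``ss_type`` governs the partition on unbalanced data (Type III with
    sum-to-zero contrasts by default).  ``group`` chooses whether ``n_avg``
    counts strain-level groups (default, 8 groups) or strain-sex cells.
    Rows with a missing trait value are dropped.
    """
    if model not in ("additive", "interaction"):
        raise ValueError(f"unknown model {model!r}")
    if ss_type not in ("I", "II", "III"):
        raise ValueError(f"unknown ss_type {ss_type!r}")
    if group not in ("strain", "cell"):
        raise ValueError(f"unknown group {group!r}")
    df = _prepare(table, trait)
    n_obs = len(df)
    n_groups = (
        df["strain"].nunique()
        if group == "strain"
        else df.groupby(["strain", "sex"], observed=True).ngroups
    )
    n_avg = n_obs / n_groups
    s, x = df["strain"].nunique(), df["sex"].nunique()
    df_strain, df_sex = s - 1, x - 1

    total_ss = float(((df["value"] - df["value"].mean()) ** 2).sum())
    if total_ss <= 1e-12 * max(1.0, float(df["value"].abs().max()) ** 2):
        df_res = n_obs - 1 - df_strain - df_sex - (df_strain * df_sex if model == "interaction" else 0)
        return AnovaDecomposition(
            trait, 0.0, 0.0, 0.0, df_strain, df_sex, max(df_res, 1), n_avg, n_obs,
            model, ss_type, degenerate=True,
        )

    rhs = "C(strain, Sum) + C(sex, Sum)"
    if model == "interaction":
        rhs += " + C(strain, Sum):C(sex, Sum)"
    fit = smf.ols(f"value ~ {rhs}", data=df).fit()
    typ = {"I": 1, "II": 2, "III": 3}[ss_type]
    tab = sm.stats.anova_lm(fit, typ=typ)

    def _row(key_part: str) -> tuple[float, int]:
        for idx in tab.index:
            if key_part in idx and (":" in key_part) == (":" in idx):
                return float(tab.loc[idx, "sum_sq"]), int(tab.loc[idx, "df"])
        raise KeyError(key_part)

    ss_strain, _ = _row("C(strain, Sum)")
    ss_sex, _ = _row("C(sex, Sum)")
    ss_res = float(tab.loc["Residual", "sum_sq"])
    df_res = int(tab.loc["Residual", "df"])
    ss_int, df_int = (0.0, 0)
    if model == "interaction":
        ss_int, df_int = _row("C(strain, Sum):C(sex, Sum)")
    return AnovaDecomposition(
        trait, ss_strain, ss_sex, ss_res, df_strain, df_sex, df_res, n_avg, n_obs,
        model, ss_type, ss_interaction=ss_int, df_interaction=df_int,
    )


def broad_sense_h2(decomp: AnovaDecomposition) -> H2Result:
    """Broad-sense heritability from the SS-quotient variance components."""
    if decomp.degenerate:
        return H2Result(decomp.trait, 0.0, 0.0, 0.0, 0.0, decomp.n_obs, degenerate=True)
    s2_strain = decomp.ss_strain / decomp.n_avg
    s2_sex = decomp.ss_sex / decomp.df_sex
    s2_res = decomp.ss_res / decomp.df_res
    total = s2_strain + s2_sex + s2_res
    h2 = s2_strain / total if total > 0 else 0.0
    return H2Result(decomp.trait, s2_strain, s2_sex, s2_res, h2, decomp.n_obs,
                    degenerate=total <= 0)


def h2_table(
    table: pd.DataFrame,
    traits: list[str],
    model: str = "additive",
    ss_type: str = "III",
    group: str = "strain",
) -> pd.DataFrame:
    """Heritability of every trait, sorted descending (most heritable first)."""
    rows = []
    for t in traits:
        res = broad_sense_h2(anova_ss(table, t, model=model, ss_type=ss_type, group=group))
        rows.append({
            "trait": t, "H2": res.H2, "sigma2_strain": res.sigma2_strain,
            "sigma2_sex": res.sigma2_sex, "sigma2_res": res.sigma2_res,
            "n": res.n_obs, "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows).sort_values("H2", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# body-mass adjustment


@dataclass(frozen=True)
class StrainSlope:
    slope: float
    p_value: float
    zeroed: bool
    reason: str  # "" | "p>0.20" | "insufficient_n"
    n: int


@dataclass(frozen=True)
class AdjustmentModel:
    trait: str
    slopes: dict[str, StrainSlope] = field(default_factory=dict)
    grand_mean_mass: float = float("nan")  # unweighted mean of strain mean masses
    p_threshold: float = 0.20


def fit_mass_slopes(
    table: pd.DataFrame, trait: str, p_threshold: float = 0.20
) -> AdjustmentModel:
    """Per-strain OLS slope of trait on body mass, with p > threshold zeroing.

    Uses founder rows only.  Slopes whose two-sided regression p-value is
    strictly above the threshold are set to 0 (boundary p == threshold keeps
    the slope); strains with fewer than 3 usable animals are zeroed with a
    distinct flag.  The grand mean mass is the unweighted mean of the strain
    mean masses (mean of the 8 means).
    """
    df = table
    if "population" in df.columns:
        df = df[df["population"] == "founder"]
    df = df.dropna(subset=["body_mass", trait])
    if df.empty:
        raise DesignError(f"{trait}: no founder rows with both mass and trait")
    slopes: dict[str, StrainSlope] = {}
    strain_means = []
    for strain, grp in df.groupby("strain", observed=True):
        strain_means.append(grp["body_mass"].mean())
        n = len(grp)
        if n < 3 or grp["body_mass"].nunique() < 2:
            slopes[strain] = StrainSlope(0.0, float("nan"), True, "insufficient_n", n)
            continue
        res = stats.linregress(grp["body_mass"], grp[trait])
        zero = res.pvalue > p_threshold
        slopes[strain] = StrainSlope(
            0.0 if zero else float(res.slope), float(res.pvalue), zero,
            "p>%.2f" % p_threshold if zero else "", n,
        )
    return AdjustmentModel(trait, slopes, float(np.mean(strain_means)), p_threshold)


def apply_mass_adjustment(
    table: pd.DataFrame, trait: str, model: AdjustmentModel
) -> pd.Series:
    """Trait_adjusted = Trait - slope * (body mass - grand mean mass),
    using each animal's own strain slope (zeroed strains pass through)."""
    unknown = set(table["strain"].unique()) - set(model.slopes)
    if unknown:
        raise MappingError(f"{trait}: strains not in adjustment model: {sorted(unknown)}")
    slope = table["strain"].map({s: sl.slope for s, sl in model.slopes.items()})
    adjusted = table[trait] - slope * (table["body_mass"] - model.grand_mean_mass)
    return adjusted.rename(f"{trait}_adj")


def covariate_significance(
    table: pd.DataFrame, trait: str, alpha: float = 0.05
) -> tuple[float, bool, str]:
    """Two-sided p-value for body mass in a strain + sex + mass linear model.

    Returns (p, significant at ``alpha``, flag); a constant-mass design is
    flagged ``"degenerate"`` with p = nan.
    """
    need = {"strain", "sex", "body_mass", trait}
    missing = need - set(table.columns)
    if missing:
        raise DesignError(f"table lacks columns {sorted(missing)}")
    df = table[["strain", "sex", "body_mass", trait]].dropna().rename(columns={trait: "value"})
    if df["strain"].nunique() < 2 or df["sex"].nunique() < 2:
        raise DesignError(f"{trait}: need >= 2 strains and both sexes")
    if df["body_mass"].nunique() < 2:
        return float("nan"), False, "degenerate"
    fit = smf.ols("value ~ C(strain, Sum) + C(sex, Sum) + body_mass", data=df).fit()
    p = float(fit.pvalues["body_mass"])
    if not np.isfinite(p):
        return float("nan"), False, "degenerate"
    return p, p < alpha, ""


# ---------------------------------------------------------------------------
# post hoc contrasts


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def _pooled_residual(df: pd.DataFrame, by: list[str]) -> tuple[float, int]:
    """Within-cell pooled residual variance (cell-means model MSE) and df."""
    grp = df.groupby(by, observed=True)["value"]
    sse = float((grp.transform("mean") - df["value"]).pow(2).sum())
    df_res = len(df) - grp.ngroups
    if df_res <= 0:
        raise DesignError("no residual degrees of freedom for post hoc tests")
    return sse / df_res, df_res


def strain_sex_posthoc(
    table: pd.DataFrame,
    trait: str,
    reference: str = "B6",
    include_population_contrast: bool = True,
) -> pd.DataFrame:
    """Sidak-corrected post hoc comparisons.

    Two contrast families per sex: every founder strain vs the reference
    strain, and (when DO rows are present) the pooled founder population vs
    DO.  Each contrast is a t-type comparison using the pooled within-cell
    residual variance of its family's model; Sidak adjustment is applied
    within each family.
    """
    df = table.dropna(subset=[trait]).rename(columns={trait: "value"})
    founders = df[df.get("population", "founder") == "founder"]
    if reference not in set(founders["strain"]):
        raise ContrastError(f"reference strain {reference!r} absent from table")
    rows = []

    mse, df_res = _pooled_residual(founders, ["strain", "sex"])
    for sex, sub in founders.groupby("sex", observed=True):
        others = sorted(s for s in sub["strain"].unique() if s != reference)
        m = len(others)
        ref = sub[sub["strain"] == reference]["value"]
        for strain in others:
            g = sub[sub["strain"] == strain]["value"]
            diff = g.mean() - ref.mean()
            se = np.sqrt(mse * (1 / len(g) + 1 / len(ref)))
            t = diff / se if se > 0 else 0.0
            p = float(2 * stats.t.sf(abs(t), df_res))
            rows.append({
                "family": f"strain_vs_{reference}_{sex}", "contrast": f"{strain} vs {reference} ({sex})",
                "trait": trait, "mean_1": g.mean(), "mean_2": ref.mean(), "diff": diff,
                "p": p, "p_adj": sidak_adjust(p, m), "m": m,
            })

    if include_population_contrast and "population" in df.columns:
        pops = df[df["population"].isin(["founder", "DO"])]
        if pops["population"].nunique() == 2:
            mse_p, df_res_p = _pooled_residual(pops, ["population", "sex"])
            fam = [(sex, sub) for sex, sub in pops.groupby("sex", observed=True)]
            m = len(fam)
            for sex, sub in fam:
                a = sub[sub["population"] == "founder"]["value"]
                b = sub[sub["population"] == "DO"]["value"]
                diff = b.mean() - a.mean()
                se = np.sqrt(mse_p * (1 / len(a) + 1 / len(b)))
                t = diff / se if se > 0 else 0.0
                p = float(2 * stats.t.sf(abs(t), df_res_p))
                rows.append({
                    "family": "founder_vs_DO", "contrast": f"DO vs founder ({sex})",
                    "trait": trait, "mean_1": b.mean(), "mean_2": a.mean(), "diff": diff,
                    "p": p, "p_adj": sidak_adjust(p, m), "m": m,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# glycemia


def classify_glycemia(fbg):
    """Classify fasting blood glucose: hyperglycemic iff strictly > 250 mg/dL.

    Accepts a scalar or array; returns ``"hyperglycemic"``/``"normal"``
    (elementwise for arrays).  Negative values are rejected.
    """
    arr = np.asarray(fbg, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("fasting blood glucose cannot be negative")
    out = np.where(arr > HYPERGLYCEMIA_THRESHOLD_MG_DL, "hyperglycemic", "normal")
    return out.item() if np.isscalar(fbg) or np.ndim(fbg) == 0 else out
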