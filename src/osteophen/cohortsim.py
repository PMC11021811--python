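"""Synthetic founder-strain and Diversity Outbred (DO) cohort generator.

Emulates the study design of an 8-founder-strain inbred panel (two sexes,
replicated animals per strain x sex cell) plus an outbred DO cohort whose
phenotypes are convex admixtures of the founder strain effects.  Every trait
is generated from an additive model

    trait = grand_mean + strain_effect + sex_effect
            + mass_slope * (body_mass - mean_mass) + residual

with known ground truth, so that the downstream heritability, mechanics,
correlation/PCA and Raman stages can all be tested for parameter recovery
without any external data.

Calibration note.  The broad-sense heritability estimator implemented in
:mod:`osteophen.quantgen` uses the sum-of-squares quotients

    sigma2_strain = SS_strain / n_avg,  sigma2_sex = SS_sex / df_sex,
    sigma2_res = SS_res / df_res,

which for a balanced S-strain design inflate the between-strain component by
roughly a factor (S - 1) relative to the generative intraclass variance.
The generator therefore calibrates the raw effect scales analytically so that
the *expected estimator components* are proportional to the requested
``var_frac_*`` targets, then rescales each trait column so its total variance
equals ``total_sd**2`` (the H2 quotient is scale invariant, so both properties
hold simultaneously).  See docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DependencyError, ValidationError

__all__ = [
    "DEFAULT_STRAINS",
    "TraitSpec",
    "SimulationConfig",
    "FounderEffects",
    "MechanicalTruth",
    "default_trait_panel",
    "simulate_founder_cohort",
    "simulate_do_cohort",
    "simulate_bend_curve",
    "simulate_raman_spectrum",
    "RAMAN_BAND_CENTERS",
    "RAMAN_BAND_SIGMAS",
]

#: The 8 inbred founder strains of the Diversity Outbred population.
DEFAULT_STRAINS = ("CAST", "PWK", "WSB", "A/J", "B6", "129S1", "NOD", "NZO")

SEXES = ("F", "M")

_FRAC_TOL = 1e-9


@dataclass(frozen=True)
class TraitSpec:
    """Target generative structure for one trait.

    ``var_frac_strain/sex/res`` are the target fractions of the estimator-scale
    variance decomposition (they must sum to 1).  ``mass_slope`` couples the
    trait allometrically to body mass (trait units per gram).  Traits sharing a
    ``latent_factor`` label ("size", "material", "lacunar", ...) receive
    correlated strain and residual effects with the given loading.
    """

    name: str
    units: str = ""
    var_frac_strain: float = 0.8
    var_frac_sex: float = 0.05
    var_frac_res: float = 0.15
    grand_mean: float = 0.0
    total_sd: float = 1.0
    mass_slope: float = 0.0
    latent_factor: str | None = None
    latent_loading: float = 0.0

    def validate(self) -> None:
        fracs = (self.var_frac_strain, self.var_frac_sex, self.var_frac_res)
        for label, f in zip(("var_frac_strain", "var_frac_sex", "var_frac_res"), fracs):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{self.name}: {label} must lie in [0, 1], got {f}")
        if abs(sum(fracs) - 1.0) > _FRAC_TOL:
            raise ConfigurationError(
                f"{self.name}: variance fractions must sum to 1, got {sum(fracs)!r}"
            )
        if not self.total_sd > 0:
            raise ConfigurationError(f"{self.name}: total_sd must be positive")
        if not -1.0 <= self.latent_loading <= 1.0:
            raise ConfigurationError(f"{self.name}: latent_loading must lie in [-1, 1]")


def default_trait_panel() -> list[TraitSpec]:
    """Default trait panel: whole-body, radial morphology/mechanics/material,
    lacunar morphometry and Raman composition blocks.

    Variance-fraction targets follow the reported pattern for this study
    design: morphology and whole-bone mechanics are strain dominated
    (strain >> sex), material properties vary with strain but barely with sex,
    and post-yield displacement is mostly residual.  Grand means and SDs are
    realistic magnitudes for 22-week mouse radii; the within-strain SDs are
    stated placeholders, not measured values.
    """
    T = TraitSpec
    return [
        # whole body
        T("BMC", "mg", 0.993, 0.004, 0.003, 450.0, 110.0, 6.0, "size", 0.95),
        T("FBG", "mg/dL", 0.91, 0.02, 0.07, 140.0, 30.0, 0.0, None, 0.0),
        # radius morphology (uCT)
        T("Ct.Ar", "mm^2", 0.884, 0.015, 0.101, 0.40, 0.09, 0.004, "size", 0.92),
        T("Tt.Ar", "mm^2", 0.799, 0.021, 0.180, 1.00, 0.22, 0.010, "size", 0.90),
        T("Ma.Ar", "mm^2", 0.722, 0.030, 0.248, 0.60, 0.15, 0.004, "size", 0.75),
        T("Ct.Th", "mm", 0.985, 0.005, 0.010, 0.25, 0.05, 0.0, "material", 0.70),
        T("pMOI", "mm^4", 0.799, 0.021, 0.180, 0.12, 0.04, 0.002, "size", 0.88),
        T("TMD", "mgHA/cm^3", 0.967, 0.003, 0.030, 1220.0, 45.0, 0.0, "material", 0.85),
        # radius 3-point bending, whole bone
        T("K", "N/mm", 0.776, 0.024, 0.200, 80.0, 22.0, 0.8, "size", 0.85),
        T("Fu", "N", 0.836, 0.014, 0.150, 8.0, 2.2, 0.08, "size", 0.88),
        T("Fy", "N", 0.718, 0.022, 0.260, 6.0, 1.7, 0.06, "size", 0.82),
        T("PYD", "mm", 0.209, 0.041, 0.750, 0.30, 0.12, 0.0, None, 0.0),
        T("work", "mJ", 0.741, 0.019, 0.240, 2.5, 0.9, 0.02, "size", 0.70),
        # radius material properties (beam theory)
        T("Su", "MPa", 0.746, 0.004, 0.250, 140.0, 25.0, 0.0, "material", 0.80),
        T("Sy", "MPa", 0.717, 0.003, 0.280, 105.0, 20.0, 0.0, "material", 0.75),
        T("E", "MPa", 0.684, 0.006, 0.310, 10000.0, 2400.0, 0.0, "material", 0.80),
        # tibia lacunar morphometry (XRM)
        T("Lc.NDensity", "1/mm^3", 0.966, 0.004, 0.030, 65000.0, 9000.0, 0.0, "lacunar", 0.85),
        T("Lc.Sphericity", "", 0.887, 0.013, 0.100, 0.82, 0.04, 0.0, "lacunar", 0.80),
        T("Lc.AspectRatio", "", 0.755, 0.045, 0.200, 0.22, 0.05, 0.0, "lacunar", 0.75),
        T("Lc.Vol", "um^3", 0.383, 0.067, 0.550, 220.0, 45.0, 0.0, "lacunar", 0.55),
        T("Lc.SD.Phi", "deg", 0.835, 0.035, 0.130, 25.0, 6.0, 0.0, "lacunar", 0.60),
        # femur Raman composition
        T("Raman.v1.proline", "", 0.55, 0.05, 0.40, 5.0, 0.5, 0.0, "material", 0.55),
        T("Raman.v2.amideIII", "", 0.30, 0.05, 0.65, 0.55, 0.08, 0.0, "material", 0.40),
        T("Raman.carb.phos", "", 0.25, 0.05, 0.70, 0.30, 0.03, 0.0, "material", 0.35),
        T("Raman.crystallinity", "1/cm", 0.60, 0.05, 0.35, 0.055, 0.004, 0.0, "material", 0.50),
    ]


def default_mass_spec() -> TraitSpec:
    """Body mass (g): strain dominated with a clear male bias."""
    return TraitSpec("body_mass", "g", 0.84, 0.06, 0.10, 30.0, 8.0, 0.0, "size", 0.95)


@dataclass(frozen=True)
class SimulationConfig:
    strains: tuple[str, ...] = DEFAULT_STRAINS
    n_per_group: int = 9
    n_do_per_sex: int = 25
    traits: tuple[TraitSpec, ...] = field(default_factory=lambda: tuple(default_trait_panel()))
    mass: TraitSpec = field(default_factory=default_mass_spec)
    do_admixture_concentration: float = 0.5
    seed: int = 0
    #: optional fixed strain-effect table (strain x trait, trait units) used
    #: verbatim instead of random draws ("fixed-effects" replication mode)
    fixed_strain_effects: pd.DataFrame | None = None
    #: per (strain, sex) fasting-blood-glucose mean shift in mg/dL; defaults
    #: emulate hyperglycemic NOD females and NZO males
    hyperglycemia_shifts: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("NOD", "F"): 180.0, ("NZO", "M"): 180.0}
    )
    hyperglycemia_extra_sd: float = 60.0
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if len(self.strains) < 2:
            raise ConfigurationError("strains: need at least 2 strains")
        if len(set(self.strains)) != len(self.strains):
            raise ConfigurationError("strains: labels must be unique")
        if self.n_per_group < 2:
            raise ConfigurationError(
                "n_per_group: variance components need replicates (n_per_group >= 2)"
            )
        if self.n_do_per_sex < 0:
            raise ConfigurationError("n_do_per_sex: must be non-negative")
        if not self.do_admixture_concentration >= 0:
            raise ConfigurationError("do_admixture_concentration: must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate: must lie in [0, 1)")
        if not self.traits:
            raise ConfigurationError("traits: at least one TraitSpec required")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigurationError("traits: trait names must be unique")
        for spec in (*self.traits, self.mass):
            spec.validate()


@dataclass
class FounderEffects:
    """Ground truth shared between the founder and DO generators.

    ``strain_effects`` holds the realized per-strain additive effects in trait
    units (one row per strain, one column per trait, body mass included);
    ``sex_effects`` the +/- male/female shifts and ``residual_sd`` the
    within-group SD, both in trait units.
    """

    strains: tuple[str, ...]
    strain_effects: pd.DataFrame
    sex_effects: pd.Series
    residual_sd: pd.Series
    latent_residual_loading: pd.Series
    latent_factor: pd.Series
    mass_grand_mean: float


@dataclass(frozen=True)
class MechanicalTruth:
    """Ground-truth bending parameters for one simulated test."""

    K_true: float  # N/mm
    Fy_true: float  # N
    Fu_true: float  # N
    PYD_true: float  # mm
    geometry: "object | None" = None  # BeamGeometry, optional

    def validate(self) -> None:
        for label, v in (("K_true", self.K_true), ("Fy_true", self.Fy_true),
                         ("Fu_true", self.Fu_true), ("PYD_true", self.PYD_true)):
            if not v > 0:
                raise ValidationError(f"{label} must be positive, got {v}")
        if self.Fy_true > self.Fu_true:
            raise ValidationError(
                f"Fy_true ({self.Fy_true}) must not exceed Fu_true ({self.Fu_true})"
            )


# ---------------------------------------------------------------------------
# effect-scale calibration


_CALIB_DRAWS = 60_000
_calib_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _calibration_draws(n_strains: int, df_res: int):
    """Fixed quadrature draws of the three estimator components' sampling
    distributions (strain: chi2_{S-1}; sex: (z + shift)^2; residual:
    chi2_df/df), shared across traits so calibration is deterministic."""
    key = (n_strains, df_res)
    if key not in _calib_cache:
        rng = np.random.default_rng(0x05EED)
        c_strain = rng.chisquare(n_strains - 1, _CALIB_DRAWS)
        z_sex = rng.standard_normal(_CALIB_DRAWS)
        c_res = rng.chisquare(df_res, _CALIB_DRAWS) / df_res
        _calib_cache[key] = (c_strain, z_sex, c_res)
    return _calib_cache[key]


def calibrate_effect_scales(
    spec: TraitSpec, n_strains: int, n_per_group: int
) -> tuple[float, float, float]:
    """Raw (tau_strain, d_sex, sigma_res) scales for one trait, pre-rescaling.

    The SS-quotient heritability estimator implemented in
    :func:`osteophen.quantgen.broad_sense_h2` is a nonlinear ratio of skewed
    components, so its expectation is solved for directly.  For a balanced
    S x 2 x n design the components' sampling distributions are known exactly:

        SS_strain/n_avg ~ (tau^2 + sigma_e^2/n_avg) * chi2_{S-1}
        SS_sex/df_sex   ~ (sigma_e * z + sqrt(N) * d)^2,  z ~ N(0, 1)
        SS_res/df_res   ~ sigma_e^2 * chi2_{df_res}/df_res

    The sex and residual scales come from the linear targets
    E[SS_res/df_res] = f_res and E[SS_sex/df_sex] = max(f_sex, f_res) (the
    estimator's sex component can never fall below the residual variance, so
    the sex effect floors at zero when f_sex < f_res); the strain scale tau is
    then found by monotone bisection so that E[H2] equals ``var_frac_strain``
    under fixed quadrature draws.  Returned scales are on an arbitrary common
    scale; the caller rescales the finished column to total_sd.
    """
    S = n_strains
    N = S * 2 * n_per_group
    n_avg = N / S
    df_res = N - S - 1  # additive two-factor model
    f_a, f_x, f_e = spec.var_frac_strain, spec.var_frac_sex, spec.var_frac_res
    if f_a >= 1.0 - 1e-12:
        return 1.0, 0.0, 0.0
    sigma_e2 = f_e
    d2 = max(0.0, f_x - f_e) / N
    if f_a <= 1e-12:
        return 0.0, float(np.sqrt(d2)), float(np.sqrt(sigma_e2))

    c_strain, z_sex, c_res = _calibration_draws(S, df_res)
    sigma_e = np.sqrt(sigma_e2)
    comp_sex = (sigma_e * z_sex + np.sqrt(N * d2)) ** 2
    comp_res = sigma_e2 * c_res
    b = comp_sex + comp_res

    def mean_h2(tau2: float) -> float:
        a = (tau2 + sigma_e2 / n_avg) * c_strain
        return float(np.mean(a / (a + b)))

    # bisection on tau^2; mean_h2 is strictly increasing in tau^2
    lo, hi = 0.0, 1.0
    while mean_h2(hi) < f_a:
        hi *= 4.0
        if hi > 1e9:  # pragma: no cover - unreachable for f_a < 1
            break
    if mean_h2(lo) >= f_a:
        tau2 = 0.0
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_h2(mid) < f_a:
                lo = mid
            else:
                hi = mid
        tau2 = 0.5 * (lo + hi)
    return float(np.sqrt(tau2)), float(np.sqrt(d2)), float(np.sqrt(sigma_e2))


def _draw_effects(
    config: SimulationConfig,
    rng: np.random.Generator,
) -> FounderEffects:
    """Draw per-strain, per-sex and residual-scale ground truth for all traits."""
    specs = [config.mass, *config.traits]
    strains = config.strains
    S = len(strains)
    factors = sorted({t.latent_factor for t in specs if t.latent_factor})
    latent_strain = {f: rng.standard_normal(S) for f in factors}

    eff = {}
    sex_eff = {}
    res_sd = {}
    res_loading = {}
    factor_of = {}
    for spec in specs:
        tau, d, sig = calibrate_effect_scales(spec, S, config.n_per_group)
        rho = spec.latent_loading if spec.latent_factor else 0.0
        if spec.latent_factor:
            z = latent_strain[spec.latent_factor]
            raw = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(S)
        else:
            raw = rng.standard_normal(S)
        # scale of the whole raw column before rescaling to total_sd
        raw_var = tau**2 + d**2 + sig**2
        scale = spec.total_sd / np.sqrt(raw_var) if raw_var > 0 else 0.0
        eff[spec.name] = scale * tau * raw
        sex_eff[spec.name] = scale * d  # +d for M, -d for F
        res_sd[spec.name] = scale * sig
        res_loading[spec.name] = rho
        factor_of[spec.name] = spec.latent_factor or ""

    if config.fixed_strain_effects is not None:
        fixed = config.fixed_strain_effects
        missing = set(fixed.index) - set(strains)
        if missing:
            raise ConfigurationError(f"fixed_strain_effects: unknown strains {sorted(missing)}")
        for trait in fixed.columns:
            col = fixed[trait].reindex(strains).to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ConfigurationError(
                    f"fixed_strain_effects: trait {trait!r} missing some strains"
                )
            eff[trait] = col

    names = [s.name for s in specs]
    return FounderEffects(
        strains=tuple(strains),
        strain_effects=pd.DataFrame(eff, index=list(strains))[names],
        sex_effects=pd.Series(sex_eff)[names],
        residual_sd=pd.Series(res_sd)[names],
        latent_residual_loading=pd.Series(res_loading)[names],
        latent_factor=pd.Series(factor_of)[names],
        mass_grand_mean=config.mass.grand_mean,
    )


def _residual_matrix(
    specs: Sequence[TraitSpec],
    effects: FounderEffects,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-animal residuals, correlated within latent-factor blocks."""
    factors = sorted({t.latent_factor for t in specs if t.latent_factor})
    latent = {f: rng.standard_normal(n) for f in factors}
    out = {}
    for spec in specs:
        rho = effects.latent_residual_loading[spec.name]
        sig = effects.residual_sd[spec.name]
        if spec.latent_factor:
            z = latent[spec.latent_factor]
            raw = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        else:
            raw = rng.standard_normal(n)
        out[spec.name] = sig * raw
    return out


def _assemble(
    config: SimulationConfig,
    effects: FounderEffects,
    strain_effect_rows: pd.DataFrame,
    strain_labels: np.ndarray,
    sexes: np.ndarray,
    population: str,
    ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build the trait table given per-animal strain-effect rows."""
    n = len(ids)
    specs = [config.mass, *config.traits]
    resid = _residual_matrix(specs, effects, n, rng)
    sex_sign = np.where(sexes == "M", 1.0, -1.0)

    mass_spec = config.mass
    mass = (
        mass_spec.grand_mean
        + strain_effect_rows["body_mass"].to_numpy()
        + sex_sign * effects.sex_effects["body_mass"]
        + resid["body_mass"]
    )
    mass = np.maximum(mass, 1.0)  # grams; guard against absurd draws

    data: dict[str, object] = {
        "animal_id": ids,
        "population": population,
        "strain": strain_labels,
        "sex": sexes,
        "body_mass": mass,
    }
    for spec in config.traits:
        col = (
            spec.grand_mean
            + strain_effect_rows[spec.name].to_numpy()
            + sex_sign * effects.sex_effects[spec.name]
            + resid[spec.name]
            + spec.mass_slope * (mass - effects.mass_grand_mean)
        )
        if spec.name == "FBG":
            if population == "founder":
                for (st, sx), shift in config.hyperglycemia_shifts.items():
                    hit = (strain_labels == st) & (sexes == sx)
                    col = col + np.where(
                        hit,
                        shift + config.hyperglycemia_extra_sd * rng.standard_normal(n),
                        0.0,
                    )
            col = np.maximum(col, 10.0)
        data[spec.name] = col
    df = pd.DataFrame(data)
    df["fbg"] = df["FBG"] if "FBG" in df.columns else np.nan
    return df


def simulate_founder_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, FounderEffects]:
    """Simulate the inbred founder cohort.

    Returns the cohort table (one row per animal, ``strains x 2 sexes x
    n_per_group`` rows before optional dropout) together with the realized
    :class:`FounderEffects` ground truth needed by :func:`simulate_do_cohort`
    and by recovery tests.  Deterministic for a fixed config (including seed).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_eff, rng_tab, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))
    effects = _draw_effects(config, rng_eff)

    strain_labels, sexes, ids = [], [], []
    for st in config.strains:
        for sx in SEXES:
            for i in range(config.n_per_group):
                strain_labels.append(st)
                sexes.append(sx)
                ids.append(f"F-{st.replace('/', '')}-{sx}{i + 1:02d}")
    strain_labels = np.asarray(strain_labels)
    sexes = np.asarray(sexes)
    rows = effects.strain_effects.loc[strain_labels].reset_index(drop=True)
    table = _assemble(config, effects, rows, strain_labels, sexes, "founder", ids, rng_tab)

    if config.dropout_rate > 0:
        keep = rng_drop.random(len(table)) >= config.dropout_rate
        table = table.loc[keep].reset_index(drop=True)
    return table, effects


def admixture_weights(
    n: int, n_strains: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet(alpha) weight vector per DO animal (rows sum to 1).

    ``alpha -> 0`` degenerates to a one-hot draw (each animal copies a single
    founder), implemented explicitly below 1e-6 where the Dirichlet sampler
    becomes numerically unstable.
    """
    if alpha < 1e-6:
        w = np.zeros((n, n_strains))
        w[np.arange(n), rng.integers(0, n_strains, size=n)] = 1.0
        return w
    return rng.dirichlet(alpha * np.ones(n_strains), size=n)


def simulate_do_cohort(
    config: SimulationConfig, founder_effects: FounderEffects | None
) -> pd.DataFrame:
    """Simulate the DO cohort as phenotypic admixtures of the founder effects.

    Each animal draws one Dirichlet(alpha) weight vector over the 8 founders,
    shared across all traits (preserving trait correlations), and its strain
    effect for every trait is the corresponding convex combination of the
    founder strain effects; sex effects and residual scales are the founder
    ones.  Convexity bounds each DO strain effect inside the founder range,
    reproducing the observed elimination of extreme values.
    """
    config.validate()
    if founder_effects is None:
        raise DependencyError(
            "simulate_do_cohort requires founder_effects from simulate_founder_cohort"
        )
    ss = np.random.SeedSequence((config.seed, 0x0D0))
    rng_w, rng_tab = (np.random.default_rng(s) for s in ss.spawn(2))

    n = 2 * config.n_do_per_sex
    sexes = np.asarray(["F"] * config.n_do_per_sex + ["M"] * config.n_do_per_sex)
    ids = [f"DO-{sx}{i + 1:03d}" for sx in SEXES for i in range(config.n_do_per_sex)]
    w = admixture_weights(n, len(config.strains), config.do_admixture_concentration, rng_w)
    mixed = pd.DataFrame(
        w @ founder_effects.strain_effects.to_numpy(),
        columns=founder_effects.strain_effects.columns,
    )
    table = _assemble(
        config, founder_effects, mixed, np.asarray(["DO"] * n), sexes, "DO", ids, rng_tab
    )
    table.attrs["admixture_weights"] = w
    return table


# ---------------------------------------------------------------------------
# bending curves


def simulate_bend_curve(
    truth: MechanicalTruth,
    noise_sd: float = 0.0,
    n_points: int = 500,
    seed: int | np.random.Generator | None = 0,
    span_mm: float = 7.0,
) -> pd.DataFrame:
    """Synthesize a monotonic-to-failure 3-point-bending record.

    Piecewise-linear force model: elastic segment of slope ``K_true`` up to
    ``Fy_true``, linear hardening to ``Fu_true`` over the first 60% of
    ``PYD_true``, linear softening to 45% of ``Fu_true`` over the remainder,
    then an abrupt fracture drop to 2% of ``Fu_true``.  Additive Gaussian
    force noise; the displacement grid is exact and strictly increasing.

    Returns a two-column DataFrame (displacement_mm, force_N) with the model
    metadata in ``attrs``.
    """
    truth.validate()
    if n_points < 50:
        raise ValidationError(f"n_points must be >= 50, got {n_points}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    K, Fy, Fu, pyd = truth.K_true, truth.Fy_true, truth.Fu_true, truth.PYD_true
    dy = Fy / K
    du = dy + 0.6 * pyd
    dfail = dy + pyd
    dend = dfail + max(0.25 * pyd, 0.02)
    d = np.linspace(0.0, dend, n_points)
    # snap the nearest grid samples onto the model knots so the constructed
    # extrema (yield, ultimate, failure) are represented exactly
    for knot in (dy, du, dfail):
        d[np.argmin(np.abs(d - knot))] = knot
    d = np.unique(d)
    f = np.where(
        d <= dy,
        K * d,
        np.where(
            d <= du,
            Fy + (Fu - Fy) * (d - dy) / (du - dy),
            np.where(d <= dfail, Fu - 0.55 * Fu * (d - du) / (dfail - du), 0.02 * Fu),
        ),
    )
    if noise_sd > 0:
        f = f + noise_sd * rng.standard_normal(n_points)
    curve = pd.DataFrame({"displacement_mm": d, "force_N": f})
    curve.attrs.update(
        span_mm=span_mm,
        truth=truth,
        yield_displacement_true=dy,
        failure_displacement_true=dfail,
    )
    return curve


def truth_work(truth: MechanicalTruth, n: int = 20_000) -> float:
    """Work-to-fracture (mJ = N*mm) of the noiseless model curve, by fine
    trapezoidal integration up to the true failure displacement."""
    curve = simulate_bend_curve(truth, noise_sd=0.0, n_points=n)
    d = curve["displacement_mm"].to_numpy()
    f = curve["force_N"].to_numpy()
    dfail = curve.attrs["failure_displacement_true"]
    m = d <= dfail
    return float(np.trapezoid(np.clip(f[m], 0.0, None), d[m]))


# ---------------------------------------------------------------------------
# Raman spectra

#: Canonical bone Raman band centers (cm^-1).
RAMAN_BAND_CENTERS = {
    "v1_phosphate": 959.0,
    "v2_phosphate": 431.0,
    "amideIII": 1256.0,
    "proline": 855.0,
    "v1_carbonate": 1070.0,
}

#: Default Gaussian sigmas (cm^-1) for the non-v1 bands.
RAMAN_BAND_SIGMAS = {
    "v2_phosphate": 12.0,
    "amideIII": 20.0,
    "proline": 7.0,
    "v1_carbonate": 9.0,
}

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def simulate_raman_spectrum(
    band_areas: Mapping[str, float],
    fwhm_v1: float = 18.0,
    baseline_coeffs: Sequence[float] = (),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    wavenumber: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthesize a bone Raman spectrum with known band areas.

    Gaussian bands at the canonical centers with the given integrated areas;
    the v1 phosphate band width is set by ``fwhm_v1`` (cm^-1).
    ``baseline_coeffs`` are polynomial coefficients (lowest order first) in the
    normalized coordinate u = (w - w_min)/(w_max - w_min); additive Gaussian
    intensity noise.  Grid defaults to 300-1800 cm^-1 at 1 cm^-1.
    """
    for name, area in band_areas.items():
        if name not in RAMAN_BAND_CENTERS:
            raise ValidationError(f"unknown band {name!r}")
        if area < 0:
            raise ValidationError(f"band {name!r}: area must be non-negative, got {area}")
    if not fwhm_v1 > 0:
        raise ValidationError("fwhm_v1 must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    w = np.arange(300.0, 1800.0 + 1e-9, 1.0) if wavenumber is None else np.asarray(wavenumber, float)
    y = np.zeros_like(w)
    for name, area in band_areas.items():
        sigma = fwhm_v1 / _FWHM_PER_SIGMA if name == "v1_phosphate" else RAMAN_BAND_SIGMAS[name]
        mu = RAMAN_BAND_CENTERS[name]
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((w - mu) / sigma) ** 2)
    if len(baseline_coeffs):
        u = (w - w[0]) / (w[-1] - w[0])
        y += np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs, float))
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(w.size)
    spec = pd.DataFrame({"wavenumber_cm1": w, "intensity": y})
    spec.attrs.update(band_areas=dict(band_areas), fwhm_v1=fwhm_v1)
    return spec
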