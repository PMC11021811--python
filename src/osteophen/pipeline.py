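"""Cohort-table I/O, configuration and the end-to-end analysis driver.

The pipeline runs the stages of the multi-scale bone phenomics workflow in
dependency order on either a simulated cohort (synthetic study with known
ground truth) or an ingested cohort CSV:

    simulate/ingest -> mechanics -> heritability (+ mass adjustment)
    -> correlations/clustering -> founder PCA + DO projection -> Raman
    -> post hoc comparisons -> report

Every stage writes plain CSV into the output directory and records itself in
a :class:`RunReport`; a fixed seed makes the whole run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bendmech, cohortsim, multivar, quantgen, ramanmatrix
from .errors import ConfigurationError, IntegrityError, SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "PipelineConfig",
    "RunReport",
    "load_trait_registry",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("osteophen")

REQUIRED_COLUMNS = ("animal_id", "population", "strain", "sex", "body_mass")

#: Radial + whole-body panel used for the founder PCA and DO projection.
DEFAULT_PCA_TRAITS = [
    "BMC", "body_mass", "Ct.Ar", "Tt.Ar", "Ma.Ar", "Ct.Th", "pMOI", "TMD",
    "K", "Fu", "Fy", "PYD", "work", "Su", "Sy", "E",
]

#: Lacunar panel, clustered into 3 groups like the lacunar correlation matrix.
DEFAULT_LACUNAR_TRAITS = [
    "Lc.NDensity", "Lc.Sphericity", "Lc.AspectRatio", "Lc.Vol", "Lc.SD.Phi",
]


def load_trait_registry() -> pd.DataFrame:
    """Trait registry (name, units, length-scale tag) shipped with the package."""
    with resources.files("osteophen").joinpath("trait_registry.csv").open() as fh:
        return pd.read_csv(fh).fillna({"units": ""})


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Requires the columns animal_id, population, strain, sex, body_mass; all
    other columns are parsed as numeric traits (empty cells and "NA" are
    missing, never zero).  Columns not in the trait registry are preserved
    and listed in ``attrs['unregistered']`` with a warning.
    """
    df = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(col)
    dup = df["animal_id"][df["animal_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"duplicate animal_id: {sorted(dup.unique())}")
    for col in ("animal_id", "population", "strain", "sex"):
        df[col] = df[col].astype(str)
    trait_cols = [c for c in df.columns if c not in ("animal_id", "population", "strain", "sex")]
    for col in trait_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    registry = set(load_trait_registry()["name"]) | {"fbg"}
    unregistered = [c for c in trait_cols if c not in registry]
    if unregistered:
        log.warning("unregistered trait columns kept as-is: %s", unregistered)
    df.attrs["unregistered"] = unregistered
    return df


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV (missing values as empty cells)."""
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    simulation: cohortsim.SimulationConfig | None = field(
        default_factory=cohortsim.SimulationConfig
    )
    cohort_csv: str | None = None
    out_dir: str = "results/run"
    seed: int = 0
    # stage toggles
    mechanics: bool = True
    heritability: bool = True
    adjustment: bool = True
    correlations: bool = True
    pca: bool = True
    raman: bool = True
    posthoc: bool = True
    # stage parameters
    cluster_k: int = 3
    pca_traits: list[str] = field(default_factory=lambda: list(DEFAULT_PCA_TRAITS))
    lacunar_traits: list[str] = field(default_factory=lambda: list(DEFAULT_LACUNAR_TRAITS))
    curve_points: int = 400
    curve_noise_frac: float = 0.005  # force noise as a fraction of Fu
    spots_per_animal: int = 3
    raman_noise_frac: float = 0.01  # intensity noise as a fraction of the v1 peak
    write_curves: bool = False
    write_spectra: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulation is None) == (self.cohort_csv is None):
            raise ConfigurationError(
                "exactly one of {simulation, cohort_csv} must be active"
            )
        if self.cluster_k < 1:
            raise ConfigurationError("cluster_k: must be >= 1")
        if self.simulation is not None:
            self.simulation.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            sim["traits"] = [dataclasses.asdict(t) for t in self.simulation.traits]
            sim["mass"] = dataclasses.asdict(self.simulation.mass)
            sim["strains"] = list(self.simulation.strains)
            sim["hyperglycemia_shifts"] = {
                f"{k[0]}|{k[1]}": v for k, v in self.simulation.hyperglycemia_shifts.items()
            }
            sim.pop("fixed_strain_effects", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            sim["traits"] = tuple(cohortsim.TraitSpec(**t) for t in sim.get("traits", []))
            if "mass" in sim:
                sim["mass"] = cohortsim.TraitSpec(**sim["mass"])
            sim["strains"] = tuple(sim.get("strains", cohortsim.DEFAULT_STRAINS))
            if "hyperglycemia_shifts" in sim:
                sim["hyperglycemia_shifts"] = {
                    tuple(k.split("|")): v for k, v in sim["hyperglycemia_shifts"].items()
                }
            sim = cohortsim.SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    out_dir: str
    manifest: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stages_run: list[str] = field(default_factory=list)
    stages_failed: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__

    def record(self, name: str, path: Path) -> None:
        self.manifest[name] = str(path)

    def write(self) -> Path:
        path = Path(self.out_dir) / "report.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# stage helpers


def _numeric_traits(table: pd.DataFrame) -> list[str]:
    skip = {"animal_id", "population", "strain", "sex", "fbg"}
    return [
        c for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]


def _mechanics_truth(row: pd.Series) -> cohortsim.MechanicalTruth | None:
    """Per-animal ground-truth bending parameters from the cohort traits,
    clamped into the physically admissible region."""
    try:
        k = float(row["K"]); fy = float(row["Fy"]); fu = float(row["Fu"]); pyd = float(row["PYD"])
    except (KeyError, TypeError):
        return None
    if not np.all(np.isfinite([k, fy, fu, pyd])):
        return None
    k = max(k, 5.0)
    fu = max(fu, 0.5)
    fy = min(max(fy, 0.2), 0.95 * fu)
    pyd = max(pyd, 0.02)
    return cohortsim.MechanicalTruth(k, fy, fu, pyd)


def _geometry(row: pd.Series) -> bendmech.BeamGeometry | None:
    """Section properties estimated from morphology: the bending moment of
    inertia as half the polar moment, the fiber distance as the equivalent
    circular radius of the total area."""
    try:
        pmoi = float(row["pMOI"]); ttar = float(row["Tt.Ar"])
    except (KeyError, TypeError):
        return None
    if not (np.isfinite(pmoi) and pmoi > 0 and np.isfinite(ttar) and ttar > 0):
        return None
    return bendmech.BeamGeometry(I=pmoi / 2.0, c=float(np.sqrt(ttar / np.pi)))


def _raman_truth(row: pd.Series) -> tuple[dict[str, float], float] | None:
    """Per-animal band areas and v1 FWHM from the Raman ratio traits, with the
    v1 phosphate area fixed at 10 (spectra are only defined up to intensity
    normalization) and the amide III area fixed at 4."""
    try:
        r_v1_pro = float(row["Raman.v1.proline"])
        r_v2_am3 = float(row["Raman.v2.amideIII"])
        r_cp = float(row["Raman.carb.phos"])
        crys = float(row["Raman.crystallinity"])
    except (KeyError, TypeError):
        return None
    vals = [r_v1_pro, r_v2_am3, r_cp, crys]
    if not np.all(np.isfinite(vals)) or min(vals) <= 0:
        return None
    v1, am3 = 10.0, 4.0
    areas = {
        "v1_phosphate": v1,
        "proline": v1 / max(r_v1_pro, 0.5),
        "amideIII": am3,
        "v2_phosphate": r_v2_am3 * am3,
        "v1_carbonate": r_cp * v1,
    }
    fwhm = 1.0 / min(max(crys, 0.02), 0.2)
    return areas, fwhm


# ---------------------------------------------------------------------------
# the driver


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order; see the module docstring.

    A stage failure is recorded and aborts only its downstream dependents.
    Returns the :class:`RunReport`, also written as ``report.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = RunReport(out_dir=str(out), config_hash=config.config_hash())
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    report.record("config", config_path)

    # --- stage: simulate or ingest ----------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        founders, effects = cohortsim.simulate_founder_cohort(sim)
        do = cohortsim.simulate_do_cohort(sim, effects) if sim.n_do_per_sex else None
        table = pd.concat([founders, do], ignore_index=True) if do is not None else founders
        report.stages_run.append("simulate")
    else:
        table = read_cohort(config.cohort_csv)
        report.stages_run.append("ingest")
        report.warnings.extend(
            f"unregistered column: {c}" for c in table.attrs.get("unregistered", [])
        )
    cohort_path = out / "cohort.csv"
    write_cohort(table, cohort_path)
    report.record("cohort", cohort_path)
    report.counts["animals_in"] = len(table)
    report.counts["founders"] = int((table["population"] == "founder").sum())
    report.counts["DO"] = int((table["population"] == "DO").sum())

    if "fbg" in table.columns and table["fbg"].notna().any():
        glyc = table[["animal_id", "strain", "sex", "fbg"]].dropna(subset=["fbg"]).copy()
        glyc["status"] = [quantgen.classify_glycemia(v) for v in glyc["fbg"]]
        p = out / "glycemia.csv"
        glyc.to_csv(p, index=False)
        report.record("glycemia", p)
        report.counts["hyperglycemic"] = int((glyc["status"] == "hyperglycemic").sum())

    # --- stage: mechanics --------------------------------------------------
    if config.mechanics and config.simulation is not None:
        try:
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xBE7D)))
            curves: dict[str, pd.DataFrame] = {}
            geoms: dict[str, bendmech.BeamGeometry] = {}
            for _, row in table.iterrows():
                truth = _mechanics_truth(row)
                if truth is None:
                    continue
                curve = cohortsim.simulate_bend_curve(
                    truth,
                    noise_sd=config.curve_noise_frac * truth.Fu_true,
                    n_points=config.curve_points,
                    seed=rng,
                )
                curves[row["animal_id"]] = curve
                geom = _geometry(row)
                if geom is not None:
                    geoms[row["animal_id"]] = geom
            if not curves:
                report.warnings.append(
                    "mechanics: no animals carry bending truth traits (K, Fy, Fu, PYD)"
                )
            else:
                mech = bendmech.analyze_batch(curves, geoms)
                p = out / "mechanics.csv"
                mech.to_csv(p, index=False)
                report.record("mechanics", p)
                n_fail = int((mech["error"] != "").sum())
                if n_fail:
                    report.warnings.append(f"mechanics: {n_fail} curve(s) failed analysis")
                report.counts["curves_analyzed"] = len(mech) - n_fail
                if config.write_curves:
                    cdir = out / "curves"
                    cdir.mkdir(exist_ok=True)
                    for cid, curve in curves.items():
                        curve.to_csv(cdir / f"{cid}.csv", index=False)
                # measured values replace the simulated mechanical traits
                mech_ok = mech[mech["error"] == ""].set_index("curve_id")
                for col in ("K", "Fy", "Fu", "PYD", "work", "Su", "Sy", "E"):
                    if col in table.columns and col in mech_ok.columns:
                        table[col] = table["animal_id"].map(mech_ok[col])
            report.stages_run.append("mechanics")
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.stages_failed["mechanics"] = f"{type(exc).__name__}: {exc}"
            log.exception("mechanics stage failed")

    # --- stage: raman ------------------------------------------------------
    if config.raman and config.simulation is not None:
        try:
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x4A3A)))
            rows = []
            founders_mask = table["population"] == "founder"
            for _, row in table[founders_mask].iterrows():
                truth = _raman_truth(row)
                if truth is None:
                    continue
                areas, fwhm = truth
                v1_peak = areas["v1_phosphate"] / (
                    fwhm / cohortsim._FWHM_PER_SIGMA * np.sqrt(2 * np.pi)
                )
                spot_results = []
                for spot in range(config.spots_per_animal):
                    spec = cohortsim.simulate_raman_spectrum(
                        areas, fwhm_v1=fwhm,
                        baseline_coeffs=(2.0, 1.5, -0.8, 0.6),
                        noise_sd=config.raman_noise_frac * v1_peak,
                        seed=rng,
                    )
                    corrected = ramanmatrix.subtract_baseline(spec, order=11)
                    spot_results.append(ramanmatrix.compute_ratios(corrected))
                    if config.write_spectra and spot == 0:
                        sdir = out / "spectra"
                        sdir.mkdir(exist_ok=True)
                        spec.to_csv(sdir / f"{row['animal_id']}.csv", index=False)
                agg = ramanmatrix.aggregate_spots(spot_results)
                rows.append({
                    "animal_id": row["animal_id"],
                    "Raman.v1.proline": agg.mineral_matrix_v1_proline,
                    "Raman.v2.amideIII": agg.mineral_matrix_v2_amideIII,
                    "Raman.carb.phos": agg.carbonate_phosphate,
                    "Raman.crystallinity": agg.crystallinity,
                })
            raman = pd.DataFrame(rows)
            p = out / "raman.csv"
            raman.to_csv(p, index=False)
            report.record("raman", p)
            report.counts["raman_animals"] = len(raman)
            if not raman.empty:
                merged = raman.set_index("animal_id")
                for col in merged.columns:
                    if col in table.columns:
                        measured = table["animal_id"].map(merged[col])
                        table[col] = measured.where(measured.notna(), table[col])
            report.stages_run.append("raman")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["raman"] = f"{type(exc).__name__}: {exc}"
            log.exception("raman stage failed")

    analysis_path = out / "cohort_analyzed.csv"
    write_cohort(table, analysis_path)
    report.record("cohort_analyzed", analysis_path)

    founders = table[table["population"] == "founder"]
    do = table[table["population"] == "DO"]
    traits = _numeric_traits(table)

    # --- stage: heritability ----------------------------------------------
    if config.heritability:
        try:
            h2 = quantgen.h2_table(founders, traits)
            p = out / "h2.csv"
            h2.to_csv(p, index=False)
            report.record("h2", p)
            report.counts["h2_traits"] = len(h2)
            report.stages_run.append("heritability")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["heritability"] = f"{type(exc).__name__}: {exc}"
            log.exception("heritability stage failed")

    # --- stage: mass adjustment -------------------------------------------
    if config.adjustment:
        try:
            adjusted = founders.copy()
            slope_rows = []
            cov_rows = []
            for t in traits:
                if t == "body_mass":
                    continue
                model = quantgen.fit_mass_slopes(founders, t)
                adjusted[t] = quantgen.apply_mass_adjustment(founders, t, model)
                for strain, sl in model.slopes.items():
                    slope_rows.append({
                        "trait": t, "strain": strain, "slope": sl.slope,
                        "p": sl.p_value, "zeroed": sl.zeroed, "reason": sl.reason,
                        "grand_mean_mass": model.grand_mean_mass,
                    })
                pval, sig, flag = quantgen.covariate_significance(founders, t)
                cov_rows.append({"trait": t, "p_mass": pval, "significant": sig, "flag": flag})
            p = out / "cohort_adjusted.csv"
            write_cohort(adjusted, p)
            report.record("cohort_adjusted", p)
            p = out / "mass_slopes.csv"
            pd.DataFrame(slope_rows).to_csv(p, index=False)
            report.record("mass_slopes", p)
            p = out / "mass_covariate.csv"
            pd.DataFrame(cov_rows).to_csv(p, index=False)
            report.record("mass_covariate", p)
            report.stages_run.append("adjustment")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["adjustment"] = f"{type(exc).__name__}: {exc}"
            log.exception("adjustment stage failed")

    # --- stage: correlations / clustering ----------------------------------
    if config.correlations:
        try:
            panel = [t for t in config.pca_traits if t in table.columns]
            for label, sub in (("founder", founders), ("DO", do)):
                if sub.empty:
                    continue
                corr = multivar.pearson_matrix(sub, panel)
                corr.r.to_csv(out / f"corr_{label}_r.csv")
                corr.p.to_csv(out / f"corr_{label}_p.csv")
                report.record(f"corr_{label}_r", out / f"corr_{label}_r.csv")
                report.record(f"corr_{label}_p", out / f"corr_{label}_p.csv")
            lac = [t for t in config.lacunar_traits if t in founders.columns]
            if len(lac) >= config.cluster_k:
                lac_corr = multivar.pearson_matrix(founders, lac)
                clusters = multivar.cluster_traits(lac_corr, config.cluster_k)
                p = out / "lacunar_clusters.csv"
                clusters.rename_axis("trait").to_csv(p)
                report.record("lacunar_clusters", p)
            report.stages_run.append("correlations")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["correlations"] = f"{type(exc).__name__}: {exc}"
            log.exception("correlations stage failed")

    # --- stage: PCA + DO projection ----------------------------------------
    if config.pca:
        try:
            panel = [t for t in config.pca_traits if t in founders.columns]
            model = multivar.fit_pca(founders, panel)
            model.weightings.rename_axis("trait").to_csv(out / "pca_loadings.csv")
            pd.Series(model.explained, name="explained",
                      index=model.weightings.columns).rename_axis("PC").to_csv(
                out / "pca_explained.csv")
            scores = model.scores.copy()
            scores["population"] = "founder"
            strain_of = table.set_index("animal_id")["strain"]
            scores["strain"] = scores.index.map(strain_of)
            if not do.empty:
                proj = multivar.project_onto_pca(model, do)
                if proj.attrs["skipped"]:
                    report.warnings.append(
                        f"pca: {proj.attrs['skipped']} DO row(s) skipped (missing traits)"
                    )
                proj["population"] = "DO"
                proj["strain"] = "DO"
                scores = pd.concat([scores, proj])
            else:
                report.warnings.append("pca: no DO rows; projection skipped")
            scores.to_csv(out / "pca_scores.csv")
            ellipses = multivar.normal_ellipse(
                model.scores, scores.loc[model.scores.index, "strain"], level=1.0
            )
            pd.DataFrame([dataclasses.asdict(e) for e in ellipses]).to_csv(
                out / "pca_ellipses.csv", index=False)
            for name in ("pca_loadings", "pca_explained", "pca_scores", "pca_ellipses"):
                report.record(name, out / f"{name}.csv")
            report.stages_run.append("pca")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["pca"] = f"{type(exc).__name__}: {exc}"
            log.exception("pca stage failed")

    # --- stage: post hoc comparisons ---------------------------------------
    if config.posthoc:
        try:
            frames = []
            for t in [t for t in config.pca_traits if t in table.columns]:
                frames.append(quantgen.strain_sex_posthoc(table, t))
            comp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            p = out / "comparisons.csv"
            comp.to_csv(p, index=False)
            report.record("comparisons", p)
            report.stages_run.append("posthoc")
        except Exception as exc:  # noqa: BLE001
            report.stages_failed["posthoc"] = f"{type(exc).__name__}: {exc}"
            log.exception("posthoc stage failed")

    report.counts["animals_out"] = len(table)
    report_path = report.write()
    report.record("report", report_path)
    return report
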