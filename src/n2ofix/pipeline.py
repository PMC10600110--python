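"""End-to-end analyses over tidy vial tables.

Each ``run_*`` function consumes the long-format CSV schemas the simulator
emits (or equivalently formatted field data), validates them with explicit
errors, and returns tidy result tables plus summary dictionaries.  All
steps are deterministic given their inputs and any seed they take.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .gases import (
    GasSpec,
    VialGeometry,
    air_water_flux,
    equilibrium_concentration,
)
from .kinetics import MMKinetics, areal_budget, fit_michaelis_menten, in_situ_rate
from .saturation import (
    GcCalibration,
    IrmsReading,
    drift_correct,
    expected_vial_ratio,
    gc_n2o_concentration,
    n2_saturation,
    n2o_saturation,
)
from .simulate import air_channel_concentration
from .temperature import TemperatureFit, fit_median_temperature_response
from .tracer import (
    IncubationVial,
    LabellingScheme,
    assimilation_rate,
    cohort_summary,
    delta_15n2,
    discrimination_report,
    enrichment,
    excess_15n2_rate,
    fixation_partition,
    n2o_15n_concentration,
    total_reduction_rate,
    trimmed_mean,
)

__all__ = [
    "SchemaError",
    "run_saturation",
    "run_tracer",
    "run_kinetics",
    "run_budget",
    "run_temperature",
    "run_report",
]


class SchemaError(ValueError):
    """An input table does not match the documented schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError(f"{table} table contains no vials")


# ----------------------------------------------------------------------
# saturation

SATURATION_COLUMNS = [
    "month", "pond", "vial", "gas", "role", "run_index",
    "v_headspace_mL", "v_water_mL", "temperature_field_C",
    "temperature_lab_C", "gc_response", "m28", "m40", "injection_volume_mL",
]


def run_saturation(
    measurements: pd.DataFrame,
    gc_calibration: pd.DataFrame,
    transfer_velocity_m_d: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Raw vial signals -> dissolved concentration and saturation.

    N2O rows go through the GC calibration inverse and headspace
    back-partition; N2 rows go through per-month drift correction against
    air standards and the N2:Ar double ratio against the run's
    lab-equilibrated reference vials.  If a gas transfer velocity is given,
    monthly air--water N2O fluxes are added to the QC summary.
    """
    _require_columns(measurements, SATURATION_COLUMNS, "measurements")
    _require_columns(gc_calibration, ["amount_nmol", "response"], "gc_calibration")
    cal_df = gc_calibration.sort_values("amount_nmol")
    cal = GcCalibration(cal_df["amount_nmol"].to_numpy(),
                        cal_df["response"].to_numpy())
    n2 = GasSpec.from_constants("N2")
    ar = GasSpec.from_constants("Ar")
    n2o = GasSpec.from_constants("N2O")

    results: list[dict] = []

    # --- N2O via GC -----------------------------------------------------
    n2o_rows = measurements[measurements["gas"] == "N2O"]
    for row in n2o_rows.itertuples():
        geom = VialGeometry(row.v_headspace_mL, row.v_water_mL,
                            row.temperature_field_C, row.temperature_lab_C)
        conc_nM, flags = gc_n2o_concentration(
            row.gc_response, cal, geom,
            injection_volume_mL=row.injection_volume_mL, n2o=n2o)
        res = n2o_saturation(conc_nM, row.temperature_field_C, n2o=n2o, flags=flags)
        results.append({
            "month": row.month, "pond": row.pond, "vial": row.vial,
            "gas": "N2O", "conc_nM": conc_nM,
            "saturation_percent": res.saturation_percent,
            "temperature_field_C": row.temperature_field_C,
            "flags": ";".join(flags),
        })

    # --- N2 via IRMS ----------------------------------------------------
    n2_rows = measurements[measurements["gas"] == "N2"]
    if len(n2_rows) == 0 and len(n2o_rows) == 0:
        raise SchemaError("measurements table contains no vials")
    for month, run in n2_rows.groupby("month"):
        t_lab = float(run["temperature_lab_C"].iloc[0])
        nominals = {
            "m28": air_channel_concentration(n2, t_lab),
            "m40": air_channel_concentration(ar, t_lab),
        }
        readings = [
            IrmsReading(
                signals={"m28": r.m28, "m40": r.m40},
                run_index=int(r.run_index),
                role=("air_standard" if r.role == "air_standard"
                      else "reference_water" if r.role == "reference_water"
                      else "sample"),
            )
            for r in run.itertuples()
        ]
        corrected = drift_correct(readings, nominals)
        by_run = {r.run_index: r for r in corrected}
        run_sorted = run.sort_values("run_index")

        refs = run_sorted[run_sorted["role"] == "reference_water"]
        if len(refs) == 0:
            raise SchemaError(f"month {month}: no reference_water vials for Eq. 5")
        ref_ratios = []
        ref_expected = []
        for r in refs.itertuples():
            geom = VialGeometry(r.v_headspace_mL, r.v_water_mL,
                                t_lab, t_lab)
            ref_ratios.append(by_run[int(r.run_index)].ratio("m28", "m40"))
            ref_expected.append(expected_vial_ratio(geom, n2, ar))
        ref_reading = IrmsReading(
            signals={"m28": float(np.mean(ref_ratios)), "m40": 1.0},
            run_index=-1, role="reference_water")
        exp_ref = float(np.mean(ref_expected))

        for r in run_sorted[run_sorted["role"] == "sample"].itertuples():
            geom = VialGeometry(r.v_headspace_mL, r.v_water_mL,
                                r.temperature_field_C, r.temperature_lab_C)
            res = n2_saturation(
                by_run[int(r.run_index)], ref_reading,
                expected_vial_ratio(geom, n2, ar), exp_ref)
            results.append({
                "month": r.month, "pond": r.pond, "vial": r.vial,
                "gas": "N2", "conc_nM": math.nan,
                "saturation_percent": res.saturation_percent,
                "temperature_field_C": r.temperature_field_C,
                "flags": "",
            })

    sat = pd.DataFrame(results)
    qc: dict = {}
    for gas in ("N2O", "N2"):
        sub = sat[sat["gas"] == gas]["saturation_percent"]
        if len(sub):
            qc[f"mean_saturation_{gas}"] = float(sub.mean())
            qc[f"se_saturation_{gas}"] = float(sub.std(ddof=1) / math.sqrt(len(sub)))
            qc[f"n_{gas}"] = int(len(sub))
    sub = sat[sat["gas"] == "N2O"]
    if transfer_velocity_m_d is not None and len(sub):
        n2o_spec = GasSpec.from_constants("N2O")
        fluxes = []
        for month, grp in sub.groupby("month"):
            t_field = float(grp["temperature_field_C"].iloc[0])
            eq_uM = equilibrium_concentration(n2o_spec, t_field)
            flux = air_water_flux(
                float(grp["conc_nM"].mean()) / 1000.0, eq_uM,
                transfer_velocity_m_d)
            fluxes.append({"month": month, "flux_umol_m2_d": flux})
        qc["n2o_flux_monthly"] = fluxes
        qc["n2o_flux_mean"] = float(np.mean([f["flux_umol_m2_d"] for f in fluxes]))
    return sat, qc


# ----------------------------------------------------------------------
# tracer rates

TRACER_COLUMNS = [
    "vial", "treatment", "biomass_type", "timepoint", "temperature_C",
    "dry_weight_g", "water_volume_L", "incubation_time_d",
    "conc45_uM", "conc46_uM", "d29_excess_uM", "d30_excess_uM",
    "pon_nmol", "atom_percent_15n",
]


def run_tracer(
    vials: pd.DataFrame,
    scheme: LabellingScheme | None = None,
    *,
    below_lod: str = "zero",
    lod_uM: float = 0.14,
) -> tuple[pd.DataFrame, dict, dict]:
    """Incubation vial table -> per-vial rates, cohort summaries and the
    direct-vs-indirect discrimination report.

    Cohorts pair Tf vials with their T0 cohort of the same treatment,
    biomass type and temperature; enrichment is referenced to the parallel
    control cohort.  Returns ``(rates, cohorts, report)``.
    """
    scheme = scheme or LabellingScheme()
    _require_columns(vials, TRACER_COLUMNS, "vials")
    bad_treat = set(vials["treatment"]) - {"control", "tracer_N2", "tracer_N2O"}
    if bad_treat:
        raise SchemaError(f"unknown treatments: {sorted(bad_treat)}")
    vials = vials.copy()
    vials["conc15"] = vials["conc45_uM"] + 2.0 * vials["conc46_uM"]

    def cohort_mean(treatment, timepoint, biomass, temp, column):
        sel = vials[(vials["treatment"] == treatment)
                    & (vials["timepoint"] == timepoint)
                    & (vials["biomass_type"] == biomass)
                    & (vials["temperature_C"] == temp)]
        if len(sel) == 0:
            raise SchemaError(
                f"no {treatment}/{timepoint} cohort for biomass={biomass}, "
                f"T={temp} degC (pairing error)")
        return float(sel[column].mean())

    records: list[dict] = []
    for row in vials[(vials["timepoint"] == "Tf")
                     & (vials["treatment"] != "control")].itertuples():
        biomass, temp = row.biomass_type, row.temperature_C
        vial = IncubationVial(
            treatment=("tracer_N2" if row.treatment == "tracer_N2" else "tracer_N2O"),
            biomass_type=biomass,
            dry_weight_g=row.dry_weight_g,
            incubation_time_d=row.incubation_time_d,
            temperature_C=temp,
            water_volume_L=row.water_volume_L,
            timepoint="Tf",
        )
        enrich = enrichment(
            cohort_mean(row.treatment, "T0", biomass, temp, "atom_percent_15n"),
            row.atom_percent_15n,
            cohort_mean("control", "T0", biomass, temp, "atom_percent_15n"),
            cohort_mean("control", "Tf", biomass, temp, "atom_percent_15n"),
        )
        assim = assimilation_rate(row.pon_nmol, enrich, vial)
        rec = {
            "vial": row.vial, "treatment": row.treatment,
            "biomass_type": biomass, "temperature_C": temp,
            "season": getattr(row, "season", ""),
            "assimilation_nmolN_per_g_d": assim,
            "assimilation_gross_nmolN_per_g_d": assim / (
                scheme.f_n2() if row.treatment == "tracer_N2" else scheme.f_n2o()),
            "enrichment_fraction": enrich,
            "reduction_nmolN_per_g_d": math.nan,
            "n2_production_nmolN_per_g_d": math.nan,
            "fixation_nmolN_per_g_d": math.nan,
            "din_production_nmolN_per_g_d": math.nan,
            "nox_production_nmolN_per_g_d": math.nan,
            "nox_fraction": math.nan,
            "delta15n2_below_lod": "",
            "flags": "negative_enrichment" if enrich < 0 else "",
        }
        if row.treatment == "tracer_N2O":
            t0 = cohort_mean("tracer_N2O", "T0", biomass, temp, "conc15")
            tf = n2o_15n_concentration(row.conc45_uM, row.conc46_uM)
            reduction = total_reduction_rate(t0, tf, vial)
            delta = delta_15n2(row.d29_excess_uM, row.d30_excess_uM,
                               lod_uM=lod_uM, below_lod=below_lod)
            n2_prod = excess_15n2_rate(delta, vial)
            nox = math.nan
            if "nox_delta_uM" in vials.columns and np.isfinite(row.nox_delta_uM):
                nox = (row.nox_delta_uM * vial.water_volume_L * 1000.0
                       / (vial.incubation_time_d * vial.dry_weight_g))
            part = fixation_partition(
                reduction, n2_prod, assim,
                None if math.isnan(nox) else nox)
            rec.update({
                "reduction_nmolN_per_g_d": reduction,
                "n2_production_nmolN_per_g_d": n2_prod,
                "fixation_nmolN_per_g_d": part.total_fixation,
                "din_production_nmolN_per_g_d": part.din_production,
                "nox_production_nmolN_per_g_d": nox,
                "nox_fraction": (part.nox_fraction
                                 if part.nox_fraction is not None else math.nan),
                "delta15n2_below_lod": str(delta.below_lod),
                "flags": ";".join([f for f in [rec["flags"]] + part.flags if f]),
            })
        records.append(rec)

    rates = pd.DataFrame(records)

    cohorts: dict = {}
    for treatment, grp in rates.groupby("treatment"):
        cohorts[treatment] = {
            "assimilation": cohort_summary(grp["assimilation_nmolN_per_g_d"]),
        }
        if treatment == "tracer_N2O":
            cohorts[treatment]["reduction"] = cohort_summary(
                grp["reduction_nmolN_per_g_d"])
            nox_ok = grp["nox_fraction"].dropna()
            if len(nox_ok):
                cohorts[treatment]["nox_fraction_median"] = float(nox_ok.median())

    rate_n2 = trimmed_mean(
        rates.loc[rates["treatment"] == "tracer_N2", "assimilation_nmolN_per_g_d"])
    rate_n2o = trimmed_mean(
        rates.loc[rates["treatment"] == "tracer_N2O", "assimilation_nmolN_per_g_d"])
    report = discrimination_report(scheme, rate_n2, rate_n2o)
    return rates, cohorts, report


# ----------------------------------------------------------------------
# kinetics / budget / temperature

def run_kinetics(kinetics: pd.DataFrame) -> MMKinetics:
    """Fit the Michaelis--Menten curve from a (conc_nM, rate) table."""
    _require_columns(kinetics, ["conc_nM", "rate_nmolN_per_g_d"], "kinetics")
    return fit_michaelis_menten(kinetics["conc_nM"].to_numpy(),
                                kinetics["rate_nmolN_per_g_d"].to_numpy())


def run_budget(
    fit: MMKinetics,
    ambient_conc_nM: float,
    biomass_density_g_m2: float,
    airwater_flux_umol_m2_d: float,
):
    """In-situ rate at ambient N2O, scaled to the pond area, versus flux."""
    rate = in_situ_rate(fit, ambient_conc_nM)
    return areal_budget(rate, biomass_density_g_m2, airwater_flux_umol_m2_d)


def run_temperature(
    rates: pd.DataFrame, *, seed: int = 0, n_boot: int = 1000
) -> dict[str, TemperatureFit]:
    """Median temperature-response fits for each tracer pathway."""
    _require_columns(rates, ["treatment", "temperature_C",
                             "assimilation_nmolN_per_g_d"], "rates")
    fits: dict[str, TemperatureFit] = {}
    for treatment, pathway in (("tracer_N2", "N2"), ("tracer_N2O", "N2O")):
        grp = rates[rates["treatment"] == treatment]
        if len(grp) == 0:
            continue
        fits[pathway] = fit_median_temperature_response(
            grp["assimilation_nmolN_per_g_d"].to_numpy(),
            grp["temperature_C"].to_numpy(),
            pathway=pathway, seed=seed, n_boot=n_boot)
    return fits


# ----------------------------------------------------------------------
# combined report

@dataclass
class ReportConfig:
    """Knobs of the combined report (flux model and upscaling inputs)."""

    transfer_velocity_m_d: float = 0.7
    biomass_density_g_m2: float = 340.0
    ambient_n2o_nM: float = 10.0
    labelling: LabellingScheme = field(default_factory=LabellingScheme)
    seed: int = 0
    n_boot: int = 1000


def run_report(
    measurements: pd.DataFrame,
    gc_calibration: pd.DataFrame,
    incubations: Mapping[str, pd.DataFrame],
    kinetics: pd.DataFrame,
    config: ReportConfig | None = None,
) -> dict:
    """Full-campaign summary: saturation means, seasonal extremes, rate
    cohorts per season, kinetics fit, areal budget and temperature fits."""
    config = config or ReportConfig()
    sat, qc = run_saturation(measurements, gc_calibration,
                             transfer_velocity_m_d=config.transfer_velocity_m_d)
    monthly = (sat[sat["gas"] == "N2O"]
               .groupby("month")["saturation_percent"].mean())
    report: dict = {
        "saturation": qc,
        "n2o_seasonal_min_month": int(monthly.idxmin()),
        "n2o_seasonal_max_month": int(monthly.idxmax()),
    }
    seasons: dict = {}
    all_rates = []
    for season, table in incubations.items():
        rates, cohorts, disc = run_tracer(table, config.labelling)
        seasons[season] = {"cohorts": cohorts, "discrimination": disc}
        all_rates.append(rates)
    report["incubations"] = seasons
    fit = run_kinetics(kinetics)
    report["kinetics"] = {"vmax": fit.vmax, "km_nM": fit.km}
    budget = run_budget(fit, config.ambient_n2o_nM,
                        config.biomass_density_g_m2,
                        qc.get("n2o_flux_mean", math.nan))
    report["budget"] = {
        "in_situ_reduction_areal": budget.in_situ_reduction_areal,
        "airwater_flux": budget.airwater_flux,
        "fraction_explained": budget.fraction_explained,
    }
    if all_rates:
        combined = pd.concat(all_rates, ignore_index=True)
        fits = run_temperature(combined, seed=config.seed, n_boot=config.n_boot)
        report["temperature"] = {
            p: {"slope": f.slope, "slope_ci": f.slope_ci, "q10": f.q10,
                "q10_ci": f.q10_ci}
            for p, f in fits.items()
        }
    return report
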