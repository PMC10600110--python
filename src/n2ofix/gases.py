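"""Dissolved-gas physics for freshwater: solubility, equilibrium
concentrations, vial headspace partitioning and air--water flux.

All solubilities are for salinity 0 (freshwater ponds). The equilibrium
behaviour of each gas is expressed internally as a dimensionless
Ostwald-style coefficient ``K`` (aqueous concentration / gas-phase
concentration at equilibrium), so the vial mole balance

    C_hs * V_hs + C_hs * K_lab * V_aq  =  C_field * K_field * V_aq

reads directly in terms of measurable concentrations.  Published solubility
functions (see ``constants.yaml`` for provenance) are evaluated once per call
and converted to ``K``; no coefficients are hard-coded outside the constants
file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Tuple

import yaml

__all__ = [
    "GasSpec",
    "VialGeometry",
    "GasRangeError",
    "load_constants",
    "water_density",
    "water_vapour_pressure",
    "equilibrium_concentration",
    "ostwald_coefficient",
    "headspace_partition",
    "expected_headspace_ratio",
    "air_water_flux",
]

TEMP_MIN_C = 0.0
TEMP_MAX_C = 35.0


class GasRangeError(ValueError):
    """Temperature outside the validity range of a solubility function."""


@lru_cache(maxsize=1)
def load_constants() -> dict:
    """Load the bundled physical-constants file (parsed once per process)."""
    text = resources.files("n2ofix").joinpath("constants.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class GasSpec:
    """Identity, atmospheric abundance and solubility model of one gas.

    ``atmospheric_mole_fraction`` is the dry-air mole fraction (e.g. 0.7808
    for N2, ~332e-9 for ambient N2O).  ``solubility_form`` selects the
    published temperature function and ``solubility_params`` carries its
    coefficient vector.
    """

    name: str
    atmospheric_mole_fraction: float
    solubility_form: str
    solubility_params: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.atmospheric_mole_fraction <= 1.0:
            raise ValueError(
                f"atmospheric mole fraction must be in [0, 1], got "
                f"{self.atmospheric_mole_fraction}"
            )

    @classmethod
    def from_constants(cls, name: str, mole_fraction: float | None = None) -> "GasSpec":
        """Build the spec for ``name`` (N2, Ar, O2, N2O) from the bundled file."""
        consts = load_constants()
        try:
            sol = consts["solubility"][name]
        except KeyError as exc:
            raise KeyError(f"no solubility model for gas {name!r}") from exc
        if mole_fraction is None:
            mole_fraction = float(consts["atmosphere"][name.lower()])
        return cls(
            name=name,
            atmospheric_mole_fraction=mole_fraction,
            solubility_form=sol["form"],
            solubility_params=tuple(float(c) for c in sol["coefficients"]),
        )


@dataclass
class VialGeometry:
    """Geometry and thermal history of one analytical vial.

    Volumes in mL (headspace + water should add to the nominal vial volume);
    ``temperature_field_C`` is the in-situ water temperature at sampling and
    ``temperature_lab_C`` the temperature of headspace equilibration.
    """

    v_headspace_mL: float
    v_water_mL: float
    temperature_field_C: float
    temperature_lab_C: float = 22.0
    pressure_atm: float = 1.0
    nominal_volume_mL: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.v_headspace_mL < 0 or self.v_water_mL < 0:
            raise ValueError("vial volumes must be non-negative")
        for t in (self.temperature_field_C, self.temperature_lab_C):
            if not 0.0 <= t <= 40.0:
                raise ValueError(f"vial temperature {t} degC outside [0, 40]")
        if self.nominal_volume_mL is not None:
            total = self.v_headspace_mL + self.v_water_mL
            if not math.isclose(total, self.nominal_volume_mL, rel_tol=0.02):
                raise ValueError(
                    f"headspace + water = {total:.3f} mL does not match the "
                    f"nominal vial volume {self.nominal_volume_mL} mL"
                )


def _check_temperature(gas: GasSpec, temperature_C: float) -> None:
    if not TEMP_MIN_C <= temperature_C <= TEMP_MAX_C:
        raise GasRangeError(
            f"temperature {temperature_C} degC outside the valid range "
            f"[{TEMP_MIN_C}, {TEMP_MAX_C}] degC of the {gas.name} solubility model"
        )


def water_density(temperature_C: float) -> float:
    """Density of air-free water, kg/L (Kell 1975 polynomial)."""
    t = temperature_C
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.87985e-3 * t) / 1000.0


def water_vapour_pressure(temperature_C: float) -> float:
    """Saturation water vapour pressure in atm."""
    a1, a2, a3 = load_constants()["vapour_pressure"]
    T = temperature_C + 273.15
    return math.exp(a1 + a2 * (100.0 / T) + a3 * math.log(T / 100.0))


def _air_equilibrium_uM(gas: GasSpec, temperature_C: float) -> float:
    """Dissolved concentration (uM) at equilibrium with water-saturated air
    at 1 atm total pressure, at the gas's *atmospheric* mole fraction for the
    polynomial forms, or per unit mole fraction times F for Weiss-Price."""
    T = temperature_C + 273.15
    p = gas.solubility_params
    if gas.solubility_form == "hamme_emerson":
        ts = math.log((298.15 - temperature_C) / (273.15 + temperature_C))
        ln_c = sum(c * ts**i for i, c in enumerate(p))
        # umol/kg -> umol/L
        return math.exp(ln_c) * water_density(temperature_C)
    if gas.solubility_form == "weiss_price":
        ln_f = (
            p[0] + p[1] * (100.0 / T) + p[2] * math.log(T / 100.0) + p[3] * (T / 100.0) ** 2
        )
        # F in mol/L/atm; C = F * x' * P with x' the dry mole fraction
        return math.exp(ln_f) * gas.atmospheric_mole_fraction * 1e6
    raise ValueError(f"unknown solubility form {gas.solubility_form!r}")


def equilibrium_concentration(
    gas: GasSpec, temperature_C: float, pressure_atm: float = 1.0
) -> float:
    """Dissolved concentration (uM) at equilibrium with the atmosphere.

    Linear in the gas's atmospheric mole fraction and in total pressure;
    the moist-air vapour correction at 1 atm is inside the published
    solubility functions.
    """
    _check_temperature(gas, temperature_C)
    if pressure_atm <= 0:
        raise ValueError("pressure must be positive")
    c_std = _air_equilibrium_uM(gas, temperature_C)
    if gas.solubility_form == "hamme_emerson":
        # polynomial is defined at the standard atmospheric composition;
        # rescale to the spec's configured mole fraction
        x_std = float(load_constants()["atmosphere"][gas.name.lower()])
        c_std *= gas.atmospheric_mole_fraction / x_std
    return c_std * pressure_atm


def ostwald_coefficient(gas: GasSpec, temperature_C: float) -> float:
    """Dimensionless aqueous/gas-phase concentration ratio at equilibrium.

    Strictly decreasing with temperature over 0--35 degC for all four gases.
    """
    _check_temperature(gas, temperature_C)
    consts = load_constants()
    R = float(consts["gas_constant_L_atm"])
    T = temperature_C + 273.15
    p_dry = 1.0 - water_vapour_pressure(temperature_C)
    if gas.solubility_form == "weiss_price":
        c_aq = _air_equilibrium_uM(gas, temperature_C) / gas.atmospheric_mole_fraction
        c_gas = p_dry / (R * T) * 1e6
        return c_aq / c_gas
    c_aq = _air_equilibrium_uM(gas, temperature_C)
    x_std = float(consts["atmosphere"][gas.name.lower()])
    c_gas = x_std * p_dry / (R * T) * 1e6
    return c_aq / c_gas


def headspace_partition(
    total_nmol: float, geom: VialGeometry, k_lab: float
) -> Tuple[float, float]:
    """Partition a vial's gas inventory between headspace and water.

    Returns ``(conc_headspace, conc_aqueous)`` in uM (nmol/mL).  Mole
    conservation ``c_hs*V_hs + c_aq*V_aq == total`` holds exactly, with
    ``c_aq = K_lab * c_hs``.
    """
    if total_nmol < 0:
        raise ValueError("total moles must be non-negative")
    if k_lab < 0:
        raise ValueError("Ostwald coefficient must be non-negative")
    denom = geom.v_headspace_mL + k_lab * geom.v_water_mL
    if denom <= 0:
        raise ValueError("degenerate vial geometry: both phases have zero capacity")
    if geom.v_headspace_mL == 0:
        return 0.0, total_nmol / geom.v_water_mL
    c_hs = total_nmol / denom
    return c_hs, k_lab * c_hs


def expected_headspace_ratio(
    gases: Tuple[GasSpec, GasSpec], geom: VialGeometry
) -> float:
    """Expected headspace molar ratio of two gases after lab equilibration of
    field-equilibrated water.

    Each gas's field inventory is ``C_eq(T_field) * V_aq`` and is
    re-partitioned at lab temperature; the ratio of the resulting headspace
    concentrations is returned (N2/Ar for the saturation double ratio).
    """
    g_num, g_den = gases
    concs = []
    for g in (g_num, g_den):
        c_field = equilibrium_concentration(g, geom.temperature_field_C, geom.pressure_atm)
        k_lab = ostwald_coefficient(g, geom.temperature_lab_C)
        total = c_field * geom.v_water_mL
        if geom.v_headspace_mL == 0:
            raise ValueError("headspace ratio undefined for a vial with no headspace")
        c_hs, _ = headspace_partition(total, geom, k_lab)
        concs.append(c_hs)
    if concs[1] <= 0:
        raise ZeroDivisionError(f"zero expected headspace {g_den.name}")
    return concs[0] / concs[1]


def air_water_flux(
    conc_measured_uM: float, conc_equilibrium_uM: float, transfer_velocity_m_d: float
) -> float:
    """Two-layer air--water flux F = k (C - C_eq), in umol m^-2 d^-1.

    Negative flux means transfer into the water (undersaturation).  1 uM is
    1 mmol m^-3, hence the factor 1000.
    """
    if transfer_velocity_m_d <= 0:
        raise ValueError("gas transfer velocity k must be positive")
    if conc_measured_uM < 0 or conc_equilibrium_uM < 0:
        raise ValueError("concentrations must be non-negative")
    return transfer_velocity_m_d * (conc_measured_uM - conc_equilibrium_uM) * 1000.0
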