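"""From raw detector signals to dissolved-gas saturation.

Two instrument paths:

* GC-uECD peak responses for N2O, inverted through a calibration curve and
  the vial headspace partition back to the original water concentration,
  then compared to atmospheric equilibrium at field temperature.
* IRMS channel signals (m/z 28/40) for the N2:Ar double-ratio method:
  saturation is the sample's measured-to-expected N2/Ar ratio divided by
  that of a laboratory-equilibrated reference, times 100.  Argon serves as
  the biologically inert internal standard, cancelling detector gain.

Air standards interspersed through an IRMS run anchor a piecewise-linear
drift correction in run order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .gases import (
    GasSpec,
    VialGeometry,
    equilibrium_concentration,
    expected_headspace_ratio,
    ostwald_coefficient,
)

__all__ = [
    "IrmsReading",
    "GcCalibration",
    "SaturationResult",
    "drift_correct",
    "gc_n2o_concentration",
    "n2_saturation",
    "n2o_saturation",
]

Role = Literal["sample", "air_standard", "reference_water"]


@dataclass
class IrmsReading:
    """One analytical run position: channel signals keyed 'm28', 'm29',
    'm30', 'm40', 'm44', 'm45', 'm46' (arbitrary detector units)."""

    signals: dict[str, float]
    run_index: int
    role: Role = "sample"

    def __post_init__(self) -> None:
        if self.role not in ("sample", "air_standard", "reference_water"):
            raise ValueError(f"unknown role {self.role!r}")
        for ch, v in self.signals.items():
            if v < 0:
                raise ValueError(f"negative signal on channel {ch}")

    def ratio(self, num: str, den: str) -> float:
        d = self.signals[den]
        if d <= 0:
            raise ZeroDivisionError(
                f"undefined ratio {num}/{den}: {den} signal is {d}"
            )
        return self.signals[num] / d


def drift_correct(
    sequence: Sequence[IrmsReading],
    nominals: Mapping[str, float],
) -> list[IrmsReading]:
    """Correct instrument drift against interspersed air standards.

    For each channel in ``nominals``, the observed standard signals are
    piecewise-linearly interpolated over run index; every reading is scaled
    by nominal/interpolated so that standards map onto their nominal value.
    With identical standards the correction is a constant factor; samples
    outside the bracketing standards fall back to nearest-standard scaling
    (with a warning).  Channels not listed are passed through unchanged.
    """
    order = sorted(range(len(sequence)), key=lambda i: sequence[i].run_index)
    runs = np.array([sequence[i].run_index for i in order], dtype=float)
    std_pos = [i for i in order if sequence[i].role == "air_standard"]
    if len(std_pos) < 2:
        raise ValueError("drift correction needs at least 2 air standards")
    std_runs = np.array([sequence[i].run_index for i in std_pos], dtype=float)
    if runs.min() < std_runs.min() or runs.max() > std_runs.max():
        warnings.warn(
            "samples outside the bracketing air standards: nearest-standard "
            "scaling applied at the run ends",
            stacklevel=2,
        )
    corrected: list[IrmsReading] = []
    factors: dict[str, np.ndarray] = {}
    for ch, nominal in nominals.items():
        obs = np.array([sequence[i].signals[ch] for i in std_pos], dtype=float)
        if np.any(obs <= 0):
            raise ValueError(f"non-positive air-standard signal on channel {ch}")
        interp = np.interp(runs, std_runs, obs)  # constant beyond the ends
        factors[ch] = nominal / interp
    for k, i in enumerate(order):
        r = sequence[i]
        sig = dict(r.signals)
        for ch in nominals:
            if ch in sig:
                sig[ch] = sig[ch] * float(factors[ch][k])
        corrected.append(IrmsReading(signals=sig, run_index=r.run_index, role=r.role))
    return corrected


@dataclass
class GcCalibration:
    """GC-uECD response curve from natural-abundance N2O standards.

    ``amounts_nmol`` must be positive and sorted ascending.  The default
    model is linear through the origin (response = a * amount); a quadratic
    term can be enabled for detector nonlinearity over wide ranges.  The
    fitted curve must be strictly increasing over the calibrated range.
    """

    amounts_nmol: np.ndarray
    responses: np.ndarray
    quadratic: bool = False
    coefficients: np.ndarray = field(init=False)
    residual_rms: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.amounts_nmol, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if a.size < 2:
            raise ValueError("need at least 2 calibration standards")
        if np.any(a <= 0):
            raise ValueError("standard amounts must be strictly positive")
        if np.any(np.diff(a) <= 0):
            raise ValueError("standard amounts must be sorted ascending")
        if a.shape != r.shape:
            raise ValueError("amounts and responses must have equal length")
        X = np.column_stack([a, a**2]) if self.quadratic else a[:, None]
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        self.amounts_nmol = a
        self.responses = r
        self.coefficients = coef
        self.residual_rms = float(np.sqrt(np.mean((X @ coef - r) ** 2)))
        grid = np.linspace(a.min(), a.max(), 256)
        if np.any(np.diff(self.forward(grid)) <= 0):
            raise ValueError("fitted calibration curve is not strictly increasing")

    def forward(self, amount_nmol):
        x = np.asarray(amount_nmol, dtype=float)
        if self.quadratic:
            return self.coefficients[0] * x + self.coefficients[1] * x**2
        return self.coefficients[0] * x

    def invert(self, response: float) -> tuple[float, bool]:
        """Amount (nmol) for a response, plus an extrapolation flag.

        Negative (below-blank) responses are clipped to zero and flagged.
        """
        if response < 0:
            return 0.0, True
        if self.quadratic:
            a2, a1 = self.coefficients[1], self.coefficients[0]
            if abs(a2) < 1e-30:
                amount = response / a1
            else:
                disc = a1**2 + 4.0 * a2 * response
                amount = (-a1 + math.sqrt(max(disc, 0.0))) / (2.0 * a2)
        else:
            amount = response / float(self.coefficients[0])
        lo, hi = self.forward(self.amounts_nmol[0]), self.forward(self.amounts_nmol[-1])
        extrapolated = not (lo <= response <= hi)
        return float(max(amount, 0.0)), bool(extrapolated)


@dataclass
class SaturationResult:
    """Dissolved concentration and % of atmospheric equilibrium for one vial."""

    gas: str
    concentration: float        # uM for N2, nM for N2O
    concentration_unit: str
    saturation_percent: float
    reference_basis: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.saturation_percent < 0:
            raise ValueError("saturation cannot be negative")


def gc_n2o_concentration(
    peak_response: float,
    cal: GcCalibration,
    geom: VialGeometry,
    *,
    injection_volume_mL: float = 0.1,
    n2o: GasSpec | None = None,
) -> tuple[float, list[str]]:
    """Dissolved N2O in the original water sample (nM) from a GC peak.

    Inverts the calibration curve to nmol in the injected headspace
    aliquot, converts to headspace concentration, and back-partitions the
    vial inventory (headspace + dissolved at lab temperature) to the
    concentration of the water before the headspace was created.
    """
    if injection_volume_mL <= 0:
        raise ValueError("injection volume must be positive")
    if geom.v_water_mL <= 0:
        raise ValueError("vial has no water to back-partition into")
    n2o = n2o or GasSpec.from_constants("N2O")
    amount, extrapolated = cal.invert(peak_response)
    flags = []
    if peak_response < 0:
        flags.append("below_blank_clipped")
    if extrapolated:
        flags.append("calibration_extrapolation")
    c_hs = amount / injection_volume_mL  # uM in the gas phase
    k_lab = ostwald_coefficient(n2o, geom.temperature_lab_C)
    total_nmol = c_hs * (geom.v_headspace_mL + k_lab * geom.v_water_mL)
    conc_nM = total_nmol / geom.v_water_mL * 1000.0
    return conc_nM, flags


def n2_saturation(
    sample: IrmsReading,
    reference: IrmsReading,
    expected_ratio_sample: float,
    expected_ratio_reference: float,
    *,
    reference_basis: str = "lab-equilibrated pond water",
) -> SaturationResult:
    """N2 saturation (%) by the N2:Ar double-ratio method.

    saturation = [(N2/Ar)_meas / (N2/Ar)_exp]_sample
               / [(N2/Ar)_meas / (N2/Ar)_exp]_reference * 100.

    Invariant to any common multiplicative gain applied to all channels of
    both readings.
    """
    if expected_ratio_sample <= 0 or expected_ratio_reference <= 0:
        raise ValueError("expected ratios must be positive")
    meas_s = sample.ratio("m28", "m40")
    meas_r = reference.ratio("m28", "m40")
    if meas_r <= 0:
        raise ZeroDivisionError("reference N2/Ar ratio is zero")
    sat = (meas_s / expected_ratio_sample) / (meas_r / expected_ratio_reference) * 100.0
    return SaturationResult(
        gas="N2",
        concentration=math.nan,
        concentration_unit="uM",
        saturation_percent=sat,
        reference_basis=reference_basis,
    )


def n2o_saturation(
    conc_nM: float,
    temperature_field_C: float,
    *,
    n2o: GasSpec | None = None,
    pressure_atm: float = 1.0,
    flags: list[str] | None = None,
) -> SaturationResult:
    """N2O saturation (%) relative to atmospheric equilibrium at field
    temperature."""
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    n2o = n2o or GasSpec.from_constants("N2O")
    eq_nM = equilibrium_concentration(n2o, temperature_field_C, pressure_atm) * 1000.0
    return SaturationResult(
        gas="N2O",
        concentration=conc_nM,
        concentration_unit="nM",
        saturation_percent=conc_nM / eq_nM * 100.0,
        reference_basis="atmospheric equilibrium at field temperature",
        flags=flags or [],
    )


def expected_vial_ratio(geom: VialGeometry, n2: GasSpec | None = None,
                        ar: GasSpec | None = None) -> float:
    """Expected headspace N2/Ar ratio for one vial's geometry/temperatures."""
    n2 = n2 or GasSpec.from_constants("N2")
    ar = ar or GasSpec.from_constants("Ar")
    return expected_headspace_ratio((n2, ar), geom)
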