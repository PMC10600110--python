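"""Michaelis--Menten kinetics of N2O reduction and areal flux budgets.

The concentration dependence of total N2O reduction, measured from
atmospheric-equilibrium levels (~9.2 nM) up to 20 uM, is summarised by a
Michaelis--Menten fit; evaluating the fit at in-situ concentrations and
scaling by benthic biomass areal density yields an areal reduction rate
comparable with the diffusive air--water N2O flux.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MMKinetics",
    "FluxBudget",
    "MMFitError",
    "fit_michaelis_menten",
    "in_situ_rate",
    "areal_budget",
    "gpp_equivalent",
]

REDFIELD_C_TO_N = 106.0 / 16.0


class MMFitError(RuntimeError):
    """Nonlinear Michaelis--Menten fit failed to converge."""


@dataclass
class MMKinetics:
    """Fitted Michaelis--Menten parameters.

    ``vmax`` in nmol N g^-1 d^-1, ``km`` in nM; ``conc_range`` records the
    concentration support of the fit (evaluations below it are flagged as
    extrapolation by :func:`in_situ_rate`).
    """

    vmax: float
    km: float
    covariance: np.ndarray | None = None
    conc_range: tuple[float, float] = (9.2, 20000.0)

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")

    def predict(self, conc_nM):
        s = np.asarray(conc_nM, dtype=float)
        return self.vmax * s / (self.km + s)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def _hanes_woolf_init(conc: np.ndarray, rate: np.ndarray) -> tuple[float, float]:
    """Starting values from the Hanes--Woolf linearisation S/v = S/Vmax + Km/Vmax."""
    pos = (rate > 0) & (conc > 0)
    if pos.sum() < 2:
        return float(rate.max()), float(np.median(conc))
    s, v = conc[pos], rate[pos]
    slope, intercept = np.polyfit(s, s / v, 1)
    if slope <= 0 or intercept <= 0:
        return float(rate.max()), float(np.median(conc))
    return 1.0 / slope, intercept / slope


def fit_michaelis_menten(conc_nM, rates) -> MMKinetics:
    """Least-squares fit of rate = Vmax * S / (Km + S).

    Requires at least four distinct concentrations spanning at least one
    order of magnitude.  Initialised by the Hanes--Woolf linearisation; on
    non-convergence, restarts from a log-spaced Km grid before raising.
    """
    s = np.asarray(conc_nM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if s.shape != v.shape:
        raise ValueError("concentration and rate arrays must have equal length")
    distinct = np.unique(s)
    if distinct.size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if distinct.min() <= 0 or distinct.max() / distinct.min() < 10.0:
        raise ValueError("concentrations must span at least one order of magnitude")
    inits = [_hanes_woolf_init(s, v)]
    inits += [(float(max(v.max(), 1e-9)), km0) for km0 in np.geomspace(s.min(), s.max(), 5)]
    last_err: Exception | None = None
    for vmax0, km0 in inits:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _mm, s, v, p0=(vmax0, km0),
                    bounds=((1e-12, 1e-12), (np.inf, np.inf)), maxfev=20000,
                )
            return MMKinetics(
                vmax=float(popt[0]), km=float(popt[1]), covariance=pcov,
                conc_range=(float(distinct.min()), float(distinct.max())),
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
    raise MMFitError(
        f"Michaelis-Menten fit did not converge (n={s.size}, "
        f"conc range {distinct.min():.3g}-{distinct.max():.3g} nM, "
        f"rate range {v.min():.3g}-{v.max():.3g}); tried Hanes-Woolf and "
        f"grid restarts"
    ) from last_err


def in_situ_rate(fit: MMKinetics, ambient_conc_nM: float) -> float:
    """Evaluate the fitted curve at an ambient concentration (nmol N g^-1 d^-1).

    Warns when extrapolating below the lowest measured concentration.
    """
    if ambient_conc_nM < 0:
        raise ValueError("ambient concentration must be non-negative")
    if ambient_conc_nM < fit.conc_range[0]:
        warnings.warn(
            f"evaluating below the fitted range "
            f"({ambient_conc_nM:.3g} < {fit.conc_range[0]:.3g} nM)",
            stacklevel=2,
        )
    return float(fit.predict(ambient_conc_nM))


@dataclass
class FluxBudget:
    """Areal-scale N2O budget (umol m^-2 d^-1, into-water negative)."""

    in_situ_reduction_areal: float
    airwater_flux: float
    fraction_explained: float | None
    biomass_areal_density_g_m2: float


def areal_budget(
    rate_per_g: float,
    biomass_density_g_m2: float,
    airwater_flux_umol_m2_d: float,
) -> FluxBudget:
    """Scale a per-gram reduction rate to the pond area and compare to flux.

    ``rate_per_g`` is a consumption rate in nmol N2O g^-1 d^-1 (positive =
    N2O consumed); the areal reduction is reported negative (a sink, i.e.
    a flux into the biomass).  ``fraction_explained`` compares magnitudes:
    100 * |areal reduction| / |air-water flux|.
    """
    for v in (rate_per_g, biomass_density_g_m2, airwater_flux_umol_m2_d):
        if not math.isfinite(v):
            raise ValueError("budget inputs must be finite")
    areal = -abs(rate_per_g) * biomass_density_g_m2 / 1000.0  # nmol -> umol
    if airwater_flux_umol_m2_d == 0:
        fraction = None
    else:
        fraction = 100.0 * abs(areal) / abs(airwater_flux_umol_m2_d)
    return FluxBudget(
        in_situ_reduction_areal=areal,
        airwater_flux=airwater_flux_umol_m2_d,
        fraction_explained=fraction,
        biomass_areal_density_g_m2=biomass_density_g_m2,
    )


def gpp_equivalent(n2_flux_umol_m2_d: float, c_to_n: float = REDFIELD_C_TO_N) -> float:
    """Gross primary production supportable by an N2 flux, umol C m^-2 d^-1.

    Each N2 carries two N atoms; C:N defaults to Redfield 106:16.
    """
    if c_to_n <= 0:
        raise ValueError("C:N ratio must be positive")
    return abs(n2_flux_umol_m2_d) * 2.0 * c_to_n
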