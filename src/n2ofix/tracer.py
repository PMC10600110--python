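"""15N bookkeeping for dual-tracer (15N2 / 15N2O) incubations.

The central quantities:

* labelling fraction ``F`` of a substrate pool after tracer addition,
* isotopologue-based concentrations (15N2O = 45 + 2*46; D15N2 = D29 + 2*D30),
* total 15N2O reduction, 15N assimilation into PON (enrichment * PON),
* the fixation partition
      total fixation = total reduction - 15N2 production
                     = assimilation + 15DIN production,
* and the direct-vs-indirect discrimination statistic: the upper threshold
  for indirect assimilation (via reduction of N2O to N2 first) is
  ``(F_N2' / F_N2) * rate(15N2 direct)``; measured 15N2O assimilation far
  above that threshold indicates direct N2O fixation.

Rates are reported as 15N-based (as measured, uncorrected for F); gross
(F-corrected) variants are provided alongside where meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "NATURAL_ABUNDANCE_15N",
    "LabellingScheme",
    "EaResult",
    "IncubationVial",
    "RatePartition",
    "Delta15N2",
    "DirectnessVerdict",
    "labelling_fraction",
    "indirect_upper_threshold",
    "classify_direct",
    "n2o_15n_concentration",
    "delta_15n2",
    "total_reduction_rate",
    "enrichment",
    "assimilation_rate",
    "fixation_partition",
    "trimmed_mean",
    "cohort_summary",
    "discrimination_report",
]

#: natural 15N atom fraction of atmospheric N2
NATURAL_ABUNDANCE_15N = 0.00366

DELTA_15N2_LOD_UM = 0.14


@dataclass(frozen=True)
class LabellingScheme:
    """Tracer additions and ambient pools defining the labelling fractions.

    Defaults are the pond-incubation scheme: 9 uM of >98 atom% tracer gas
    added against 487 uM ambient N2 and 0.01 uM ambient N2O; the
    indirect-fixation scenario allows at most ``max_15n2_produced_uM`` of
    15N2 to be generated into the ambient N2 pool.
    """

    added_tracer_uM: float = 9.0
    tracer_purity: float = 0.98
    ambient_n2_uM: float = 487.0
    ambient_n2o_uM: float = 0.01
    max_15n2_produced_uM: float = 0.63
    natural_abundance: float = NATURAL_ABUNDANCE_15N

    def __post_init__(self) -> None:
        for name in ("added_tracer_uM", "ambient_n2_uM", "ambient_n2o_uM",
                     "max_15n2_produced_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError("tracer purity must be in (0, 1]")

    def f_n2(self, **kw) -> float:
        """Initial 15N labelling of the N2 pool in the 15N2 treatment."""
        return labelling_fraction(
            self.added_tracer_uM, self.tracer_purity, self.ambient_n2_uM, **kw
        )

    def f_n2o(self, **kw) -> float:
        """Initial 15N labelling of the N2O pool in the 15N2O treatment."""
        return labelling_fraction(
            self.added_tracer_uM, self.tracer_purity, self.ambient_n2o_uM, **kw
        )

    def f_n2_prime(self, **kw) -> float:
        """Maximum 15N labelling of the N2 pool under the indirect scenario."""
        return labelling_fraction(
            self.max_15n2_produced_uM, self.tracer_purity, self.ambient_n2_uM, **kw
        )


@dataclass
class EaResult:
    """One elemental-analysis measurement: PON and 15N atom percent."""

    pon_nmol: float
    atom_percent_15n: float
    timepoint: Literal["T0", "Tf"] = "Tf"
    treatment: str = "control"

    def __post_init__(self) -> None:
        if self.pon_nmol <= 0:
            raise ValueError("PON must be positive")
        if not 0.3 <= self.atom_percent_15n <= 100.0:
            raise ValueError(
                "15N atom percent must lie between the natural-abundance floor "
                f"(0.3%) and 100%, got {self.atom_percent_15n}"
            )


@dataclass
class IncubationVial:
    """Metadata for one incubation vial (geometry of the rate calculation)."""

    treatment: Literal["control", "tracer_N2", "tracer_N2O"]
    biomass_type: Literal["floating", "benthic"]
    dry_weight_g: float
    incubation_time_d: float
    temperature_C: float
    water_volume_L: float
    timepoint: Literal["T0", "Tf"] = "Tf"

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise ValueError("dry weight must be positive")
        if self.incubation_time_d <= 0:
            raise ValueError("incubation time must be positive")
        if self.water_volume_L <= 0:
            raise ValueError("water volume must be positive")


@dataclass
class Delta15N2:
    """Excess 15N2 production with limit-of-detection censoring."""

    value_uM: float
    below_lod: bool
    budget_value_uM: float  # value used in the fixation partition


@dataclass
class RatePartition:
    """Per-incubation 15N budget, all rates in nmol N g^-1 d^-1."""

    total_reduction: float
    n2_production: float
    assimilation: float
    total_fixation: float
    din_production: float
    nox_fraction: float | None = None
    closure_residual: float = 0.0
    flags: list[str] = field(default_factory=list)


@dataclass
class DirectnessVerdict:
    verdict: Literal["direct-dominant", "indistinguishable"]
    fold_ratio: float
    threshold: float


def labelling_fraction(
    added_uM: float,
    purity: float,
    ambient_uM: float,
    *,
    include_natural_abundance: bool = False,
    natural_abundance: float = NATURAL_ABUNDANCE_15N,
    table_literal: bool = False,
) -> float:
    """15N atom fraction of a gas pool after tracer addition.

    Default is the tracer-derived (excess) labelling
    ``F = purity * added / (added + ambient)``.  ``table_literal=True``
    drops the purity factor (the pool-ratio form); setting
    ``include_natural_abundance`` adds the ambient pool's natural 15N so the
    result is a total atom fraction rather than an excess.

    Monotone increasing in ``added`` and decreasing in ``ambient``.
    """
    if added_uM < 0 or ambient_uM < 0:
        raise ValueError("pool sizes must be non-negative")
    if not 0.0 < purity <= 1.0:
        raise ValueError("tracer purity must be in (0, 1]")
    total = added_uM + ambient_uM
    if total <= 0:
        raise ZeroDivisionError("labelling fraction undefined for an empty pool")
    if added_uM == 0 and not include_natural_abundance:
        return natural_abundance if not table_literal else natural_abundance
    f = (1.0 if table_literal else purity) * added_uM / total
    if include_natural_abundance:
        f += natural_abundance * ambient_uM / total
    return f


def indirect_upper_threshold(
    f_indirect: float, f_direct: float, rate_direct: float
) -> float:
    """Upper bound on indirect 15N assimilation, nmol N g^-1 d^-1.

    If the labelled gas were first reduced to N2, assimilation of its 15N
    could proceed at most in proportion ``F'/F`` to the directly measured
    rate with the 15N2 tracer.
    """
    if f_direct <= 0:
        raise ZeroDivisionError("threshold undefined for zero direct labelling")
    if rate_direct < 0:
        raise ValueError("direct rate must be non-negative")
    return (f_indirect / f_direct) * rate_direct


def classify_direct(
    measured_n2o_assimilation: float,
    threshold: float,
    *,
    factor: float = 1.0,
) -> DirectnessVerdict:
    """Compare measured 15N2O assimilation against the indirect upper bound.

    Verdict is ``direct-dominant`` iff the measured rate strictly exceeds
    ``factor * threshold``.  The fold ratio (measured / threshold) is
    invariant to common rescaling of rate and threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    fold = math.inf if threshold == 0 else measured_n2o_assimilation / threshold
    verdict = (
        "direct-dominant"
        if measured_n2o_assimilation > factor * threshold
        else "indistinguishable"
    )
    return DirectnessVerdict(verdict=verdict, fold_ratio=fold, threshold=threshold)


def n2o_15n_concentration(m45_uM: float, m46_uM: float) -> float:
    """15N in N2O (uM-N) from isotopologue concentrations: 45 + 2*46."""
    if m45_uM < 0 or m46_uM < 0:
        raise ValueError("isotopologue concentrations must be non-negative")
    return m45_uM + 2.0 * m46_uM


def delta_15n2(
    d29_uM: float,
    d30_uM: float,
    lod_uM: float = DELTA_15N2_LOD_UM,
    below_lod: Literal["zero", "half", "keep"] = "zero",
) -> Delta15N2:
    """Excess 15N2 production (uM-N): D29 + 2*D30, censored at the LOD.

    Values with magnitude below ``lod_uM`` are flagged; the budget value
    used in the fixation partition is 0 by default (conservative for
    fixation), LOD/2 with ``below_lod='half'``, or kept as measured.
    """
    value = d29_uM + 2.0 * d30_uM
    censored = abs(value) < lod_uM
    if not censored:
        budget = value
    elif below_lod == "zero":
        budget = 0.0
    elif below_lod == "half":
        budget = math.copysign(lod_uM / 2.0, value)
    elif below_lod == "keep":
        budget = value
    else:
        raise ValueError(f"unknown below-LOD policy {below_lod!r}")
    return Delta15N2(value_uM=value, below_lod=censored, budget_value_uM=budget)


def _conc_to_rate(delta_uM: float, vial: IncubationVial) -> float:
    """uM-N change over the incubation -> nmol N g^-1 d^-1."""
    return (
        delta_uM
        * vial.water_volume_L
        * 1000.0
        / (vial.incubation_time_d * vial.dry_weight_g)
    )


def total_reduction_rate(
    t0_conc_uM: float, tf_conc_uM: float, vial: IncubationVial
) -> float:
    """Total 15N2O reduction rate from the T0 - Tf concentration drop.

    Negative rates (apparent production) are allowed and should be flagged
    downstream, not truncated.
    """
    return _conc_to_rate(t0_conc_uM - tf_conc_uM, vial)


def excess_15n2_rate(delta: Delta15N2, vial: IncubationVial) -> float:
    """15N2 production rate (nmol N g^-1 d^-1) from the censored excess."""
    return _conc_to_rate(delta.budget_value_uM, vial)


def enrichment(
    treatment_t0_atom_percent: float,
    treatment_tf_atom_percent: float,
    control_t0_atom_percent: float,
    control_tf_atom_percent: float,
) -> float:
    """Excess 15N atom fraction of biomass relative to parallel controls.

    The treatment's T0->Tf excess atom% minus the control's, returned as an
    atom *fraction* (atom% / 100).  May be negative (flag downstream).
    """
    excess_treatment = treatment_tf_atom_percent - treatment_t0_atom_percent
    excess_control = control_tf_atom_percent - control_t0_atom_percent
    return (excess_treatment - excess_control) / 100.0


def assimilation_rate(
    pon_nmol: float, enrich_fraction: float, vial: IncubationVial
) -> float:
    """15N assimilation into PON, nmol 15N g^-1 d^-1: PON * enrichment / (dt * dw)."""
    if pon_nmol <= 0:
        raise ValueError("PON must be positive")
    return pon_nmol * enrich_fraction / (vial.incubation_time_d * vial.dry_weight_g)


def fixation_partition(
    total_reduction: float,
    n2_production: float,
    assimilation: float,
    nox_production: float | None = None,
) -> RatePartition:
    """Partition total 15N2O reduction into its fates.

    fixation = reduction - N2 production; DIN production closes the budget
    (fixation - assimilation), with the closure residual reported rather
    than silently absorbed when an independent NOx measurement exists.
    """
    flags: list[str] = []
    if n2_production > total_reduction:
        flags.append("n2_production_exceeds_reduction")
    fixation = total_reduction - n2_production
    din = fixation - assimilation
    residual = 0.0
    if nox_production is not None:
        residual = din - nox_production
    nox_fraction = None
    if nox_production is not None and total_reduction > 0:
        nox_fraction = nox_production / total_reduction
        if not 0.0 <= nox_fraction <= 1.0:
            flags.append("nox_fraction_out_of_range")
    if total_reduction < 0:
        flags.append("negative_reduction")
    if assimilation < 0:
        flags.append("negative_assimilation")
    return RatePartition(
        total_reduction=total_reduction,
        n2_production=n2_production,
        assimilation=assimilation,
        total_fixation=fixation,
        din_production=din,
        nox_fraction=nox_fraction,
        closure_residual=residual,
        flags=flags,
    )


def trimmed_mean(
    values: Iterable[float], lower_pct: float = 2.5, upper_pct: float = 97.5
) -> float:
    """Mean of the values inside the [lower, upper] percentile window.

    The 2.5--97.5% trim mirrors reporting '95% of the dataset' for skewed
    rate distributions.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return math.nan
    lo, hi = np.percentile(x, [lower_pct, upper_pct])
    inside = x[(x >= lo) & (x <= hi)]
    return float(inside.mean()) if inside.size else math.nan


def cohort_summary(values: Sequence[float]) -> dict:
    """Mean, s.e., median and percentile-trimmed summary of a rate cohort."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        return {"n": 0}
    lo, hi = np.percentile(x, [2.5, 97.5])
    trimmed = x[(x >= lo) & (x <= hi)]
    return {
        "n": int(n),
        "mean": float(x.mean()),
        "se": float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        "median": float(np.median(x)),
        "trimmed_mean": float(trimmed.mean()),
        "trimmed_se": (
            float(trimmed.std(ddof=1) / math.sqrt(trimmed.size))
            if trimmed.size > 1
            else math.nan
        ),
        "trimmed_n": int(trimmed.size),
    }


def discrimination_report(
    scheme: LabellingScheme,
    rate_direct_n2: float,
    rate_measured_n2o: float,
) -> dict:
    """The direct-vs-indirect discrimination table for one labelling scheme.

    Returns the three labelling fractions, the indirect upper threshold,
    the measured-to-threshold fold ratio, the theoretical suppression factor
    (direct-tracer rate / threshold) and the verdict.
    """
    f_n2 = scheme.f_n2()
    f_n2o = scheme.f_n2o()
    f_prime = scheme.f_n2_prime()
    threshold = indirect_upper_threshold(f_prime, f_n2, rate_direct_n2)
    verdict = classify_direct(rate_measured_n2o, threshold)
    return {
        "F_N2": f_n2,
        "F_N2O": f_n2o,
        "F_N2_prime": f_prime,
        "rate_direct_n2": rate_direct_n2,
        "rate_measured_n2o": rate_measured_n2o,
        "indirect_upper_threshold": threshold,
        "fold_ratio_measured": verdict.fold_ratio,
        "suppression_factor": (
            math.inf if threshold == 0 else rate_direct_n2 / threshold
        ),
        "verdict": verdict.verdict,
    }
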