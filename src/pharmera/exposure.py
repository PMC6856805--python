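"""Use-based predicted environmental concentrations (PECs).

The exposure tier turns national API sales into per-capita daily use, then
into a sewage-treatment-plant (STP) influent PEC and a receiving-surface-
water PEC:

    use [ug/person/d]   = (mass_active + stoichiometric active from prodrug)
                          / population / 365
    PEC_STP [ug/L]      = use / W                (W = wastewater per capita)
    PEC_SW  [ug/L]      = PEC_STP * (f_t*(1-R) + (1-f_t)) / D

where ``f_t`` is the fraction of wastewater that is treated, ``R`` the STP
removal applied to that treated fraction, and ``D`` the dilution factor of
the effluent in the receiving water. The initial (regulatory-default)
scenario uses W = 200 L/person/d, no removal and D = 10; refined scenarios
substitute country-specific water use, modelled removal for 80 % of the
mass (the untreated 20 % passes unchanged) and country dilution factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidParameterError, NoDataError
from .substance import prodrug_to_active

__all__ = [
    "CountryUseRecord",
    "ExposureScenario",
    "PecResult",
    "per_capita_daily_use",
    "pec_stp",
    "pec_surface",
    "derive_pec",
    "weighted_summary",
]

UG_PER_KG = 1e9
DAYS_PER_YEAR = 365.0  # fixed-year basis; leap years ignored


@dataclass(frozen=True)
class CountryUseRecord:
    """One country-year of API sales (kg of active and of prodrug)."""

    country: str
    year: int
    mpa_sold: float  # kg/yr of the active moiety sold as such
    mpm_sold: float  # kg/yr sold as prodrug
    population: int

    def __post_init__(self):
        if self.mpa_sold < 0 or self.mpm_sold < 0:
            raise InvalidParameterError("sold masses must be >= 0")
        if not self.population > 0:
            raise InvalidParameterError("population must be > 0")


@dataclass(frozen=True)
class ExposureScenario:
    """Scenario constants that turn use into PECs.

    Defaults are the regulatory initial scenario: 200 L wastewater per
    person per day, all mass treated with zero removal, dilution factor 10.
    """

    wastewater_per_capita: float = 200.0  # L/person/d
    treated_fraction: float = 1.0         # dimensionless in [0, 1]
    stp_removal: float = 0.0              # dimensionless in [0, 1]
    dilution_factor: float = 10.0         # dimensionless >= 1

    def __post_init__(self):
        if not self.wastewater_per_capita > 0:
            raise InvalidParameterError("wastewater_per_capita must be > 0")
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise InvalidParameterError("treated_fraction must be in [0, 1]")
        if not 0.0 <= self.stp_removal <= 1.0:
            raise InvalidParameterError("stp_removal must be in [0, 1]")
        if not self.dilution_factor >= 1.0:
            raise InvalidParameterError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class PecResult:
    stp_influent_pec: float   # ug/L
    surface_water_pec: float  # ug/L
    scenario: ExposureScenario


def per_capita_daily_use(record: CountryUseRecord, mw_active: float, mw_prodrug: float) -> float:
    """Daily per-capita use of the active moiety, in ug/person/d.

    Sums the mass sold as active and the stoichiometric active-moiety
    fraction of the mass sold as prodrug, converts kg/yr to ug/d and
    divides by the population.
    """
    active_kg = record.mpa_sold + prodrug_to_active(record.mpm_sold, mw_active, mw_prodrug)
    return active_kg * UG_PER_KG / record.population / DAYS_PER_YEAR


def pec_stp(use: float, wastewater_per_capita: float) -> float:
    """STP influent PEC (ug/L) from per-capita use (ug/person/d)."""
    if not wastewater_per_capita > 0:
        raise InvalidParameterError("wastewater_per_capita must be > 0")
    if use < 0:
        raise InvalidParameterError("use must be >= 0")
    return use / wastewater_per_capita


def pec_surface(stp_pec: float, scenario: ExposureScenario) -> float:
    """Surface-water PEC (ug/L) from an STP influent PEC and a scenario.

    Removal applies only to the treated fraction of the mass; the untreated
    remainder is discharged unchanged. The combined load is then diluted:

        PEC_SW = PEC_STP * (f_t*(1-R) + (1-f_t)) / D
    """
    if stp_pec < 0:
        raise InvalidParameterError("stp_pec must be >= 0")
    s = scenario
    passing = s.treated_fraction * (1.0 - s.stp_removal) + (1.0 - s.treated_fraction)
    return stp_pec * passing / s.dilution_factor


def derive_pec(use: float, scenario: ExposureScenario) -> PecResult:
    """Convenience: per-capita use -> (PEC_STP, PEC_SW) under one scenario."""
    stp = pec_stp(use, scenario.wastewater_per_capita)
    return PecResult(stp_influent_pec=stp,
                     surface_water_pec=pec_surface(stp, scenario),
                     scenario=scenario)


def weighted_summary(pecs: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Population-weighted summary of per-country PECs.

    Parameters
    ----------
    pecs : sequence of (value, weight)
        Typically (country surface-water PEC, country population).

    Returns
    -------
    dict with ``weighted_mean``, ``weighted_median`` (lower weighted
    median: the smallest value whose cumulative weight reaches 50 % of the
    total), ``min`` and ``max``.
    """
    pairs = [(float(v), float(w)) for v, w in pecs]
    if not pairs:
        raise NoDataError("weighted_summary needs at least one (value, weight) pair")
    if any(w <= 0 for _, w in pairs):
        raise InvalidParameterError("weights must be > 0")
    total = sum(w for _, w in pairs)
    mean = sum(v * w for v, w in pairs) / total
    cum = 0.0
    median = pairs[-1][0]
    for v, w in sorted(pairs):
        cum += w
        if cum >= 0.5 * total:
            median = v
            break
    values = [v for v, _ in pairs]
    return {"weighted_mean": mean, "weighted_median": median,
            "min": min(values), "max": max(values)}
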