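"""Risk characterization: quotients, exceedance, ADE/MTDI, secondary poisoning.

The aquatic tier divides each exposure concentration (PEC or MEC) by a
PNEC; a risk quotient (RQ) above 1 flags potential risk, and a quotient of
exactly 1 is still "no significant risk" (the flag is strict).

The secondary-poisoning tier protects fish-eating consumers. A mammalian
point of departure (NOAEL/NOEL, mg/kg bw/d) is scaled to a reference human
and divided by an ordered chain of adjustment factors, each carrying its
rationale, to give an acceptable daily exposure (ADE, mg/person/d). The
ADE is body-weight-scaled to a wildlife maximum tolerable daily intake
(MTDI). Daily intake combines water drunk directly with residues in fish,
where fish tissue concentration = water concentration x BCF.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .effects import PnecResult
from .errors import InvalidParameterError, NoDataError
from .mec_stats import RankedDistribution, fraction_above

__all__ = [
    "Verdict",
    "RiskQuotient",
    "PodKind",
    "AdeDerivation",
    "AdeResult",
    "IntakeScenario",
    "Consumer",
    "ROUNDING_POLICIES",
    "risk_quotient",
    "exceedance_summary",
    "derive_ade",
    "select_ade",
    "mtdi_scale",
    "fish_tissue_concentration",
    "daily_intake",
    "secondary_poisoning_rq",
]


class Verdict(str, enum.Enum):
    no_significant_risk = "no_significant_risk"
    potential_risk = "potential_risk"


@dataclass(frozen=True)
class RiskQuotient:
    exposure: float   # ug/L (or ug/d for intake-based quotients)
    threshold: float  # same unit as exposure
    quotient: float
    verdict: Verdict

    def to_row(self) -> dict:
        return {"exposure": self.exposure, "threshold": self.threshold,
                "quotient": self.quotient, "verdict": self.verdict.value}


def _rq(exposure: float, threshold: float) -> RiskQuotient:
    if not threshold > 0:
        raise InvalidParameterError("threshold must be > 0")
    if exposure < 0:
        raise InvalidParameterError("exposure must be >= 0")
    q = exposure / threshold
    verdict = Verdict.potential_risk if q > 1.0 else Verdict.no_significant_risk
    return RiskQuotient(exposure=exposure, threshold=threshold, quotient=q, verdict=verdict)


def risk_quotient(exposure: float, pnec: PnecResult | float) -> RiskQuotient:
    """Exposure / PNEC with a strict >1 potential-risk verdict."""
    threshold = pnec.value if isinstance(pnec, PnecResult) else float(pnec)
    return _rq(exposure, threshold)


def exceedance_summary(distribution: "RankedDistribution | Sequence[float]",
                       pnec: PnecResult | float) -> dict:
    """Fraction of a concentration distribution above / at-or-below a PNEC.

    Accepts either a censored :class:`RankedDistribution` (nondetect
    handling is delegated to :func:`pharmera.mec_stats.fraction_above`,
    which raises on indeterminate censoring) or a plain sequence of
    concentrations such as simulated per-segment PECs.
    """
    threshold = pnec.value if isinstance(pnec, PnecResult) else float(pnec)
    if isinstance(distribution, RankedDistribution):
        res = fraction_above(distribution.ordered_values, threshold)
        n, count = res.n_total, res.count
    else:
        values = list(distribution)
        if not values:
            raise NoDataError("empty distribution")
        n = len(values)
        count = sum(1 for v in values if v > threshold)
    frac = count / n
    return {"n": n, "n_at_risk": count,
            "fraction_at_risk": frac, "fraction_safe": 1.0 - frac}


# ---------------------------------------------------------------------------
# ADE / MTDI chain
# ---------------------------------------------------------------------------

class PodKind(str, enum.Enum):
    NOAEL = "NOAEL"
    NOEL = "NOEL"
    LOAEL = "LOAEL"


def _round_two_decimals(x: float) -> float:
    return round(x, 2)


def _round_down_one_sig_fig(x: float) -> float:
    if x <= 0:
        return 0.0
    exp = math.floor(math.log10(x))
    step = 10.0 ** exp
    return math.floor(x / step) * step


def _round_nearest_0p005(x: float) -> float:
    return round(x / 0.005) * 0.005


#: Named rounding strategies applied to derived ADEs. Different published
#: derivations round differently, so the policy is an explicit label and
#: the unrounded value is always retained.
ROUNDING_POLICIES: dict[str, Callable[[float], float]] = {
    "two_decimals": _round_two_decimals,
    "down_one_sig_fig": _round_down_one_sig_fig,
    "nearest_0p005": _round_nearest_0p005,
    "none": lambda x: x,
}


@dataclass(frozen=True)
class AdeDerivation:
    """A point of departure plus an ordered adjustment-factor chain."""

    label: str
    point_of_departure: float  # mg/kg bw/d
    pod_kind: PodKind
    body_weight: float         # kg (reference consumer)
    factors: tuple[tuple[float, str], ...]  # (value >= 1, rationale)
    rounding: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "pod_kind", PodKind(self.pod_kind))
        if not self.point_of_departure > 0:
            raise InvalidParameterError("point of departure must be > 0")
        if not self.body_weight > 0:
            raise InvalidParameterError("body weight must be > 0")
        factors = tuple((float(v), str(r)) for v, r in self.factors)
        if not factors:
            raise InvalidParameterError("factor chain must be non-empty")
        for v, r in factors:
            if not v >= 1:
                raise InvalidParameterError(f"adjustment factor {v} must be >= 1")
            if not r:
                raise InvalidParameterError("every factor needs a rationale")
        if self.rounding not in ROUNDING_POLICIES:
            raise InvalidParameterError(f"unknown rounding policy {self.rounding!r}")
        object.__setattr__(self, "factors", factors)


@dataclass(frozen=True)
class AdeResult:
    derivation: AdeDerivation
    unrounded: float  # mg/person/d
    value: float      # mg/person/d after the rounding policy

    def to_dict(self) -> dict:
        d = self.derivation
        return {"label": d.label, "pod_mg_per_kg_bw_d": d.point_of_departure,
                "pod_kind": d.pod_kind.value, "body_weight_kg": d.body_weight,
                "factors": [{"value": v, "rationale": r} for v, r in d.factors],
                "rounding": d.rounding,
                "ade_unrounded_mg_per_d": self.unrounded,
                "ade_mg_per_d": self.value}


def derive_ade(derivation: AdeDerivation) -> AdeResult:
    """ADE = PoD x body weight / product(adjustment factors), then rounded.

    The unrounded value is invariant under reordering of the factor chain
    and is retained alongside the policy-rounded value.
    """
    product = math.prod(v for v, _ in derivation.factors)
    unrounded = derivation.point_of_departure * derivation.body_weight / product
    value = ROUNDING_POLICIES[derivation.rounding](unrounded)
    return AdeResult(derivation=derivation, unrounded=unrounded, value=value)


def select_ade(results: Iterable[AdeResult]) -> AdeResult:
    """The protective (minimum) ADE across candidate derivations."""
    results = list(results)
    if not results:
        raise NoDataError("no ADE derivations to select from")
    return min(results, key=lambda r: r.value)


def mtdi_scale(ade: float, reference_bw: float, target_bw: float) -> float:
    """Body-weight scaling of a daily limit: ade * target_bw / reference_bw.

    Units are preserved (mg/d in, mg/d out). E.g. 75 ug/d for a 60-kg
    human becomes an MTDI of 12.5 ug/d for a 10-kg otter.
    """
    if not (reference_bw > 0 and target_bw > 0):
        raise InvalidParameterError("body weights must be > 0")
    if ade < 0:
        raise InvalidParameterError("ade must be >= 0")
    return ade * target_bw / reference_bw


# ---------------------------------------------------------------------------
# Intake
# ---------------------------------------------------------------------------

class Consumer(str, enum.Enum):
    top_predator = "top_predator"
    human = "human"


def fish_tissue_concentration(water_pec: float, bcf: float) -> float:
    """Steady-state fish residue (ug/kg) = water concentration (ug/L) x BCF."""
    if water_pec < 0 or bcf < 0:
        raise InvalidParameterError("water concentration and BCF must be >= 0")
    return water_pec * bcf


@dataclass(frozen=True)
class IntakeScenario:
    """Daily water-plus-fish intake for one consumer."""

    consumer: Consumer
    body_weight: float                 # kg
    fish_intake: float                 # kg fish/d
    water_intake: float                # L/d
    water_concentration: float         # ug/L
    fish_tissue_concentration: float   # ug/kg

    def __post_init__(self):
        object.__setattr__(self, "consumer", Consumer(self.consumer))
        for name in ("body_weight", "fish_intake", "water_intake",
                     "water_concentration", "fish_tissue_concentration"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def daily_intake(scenario: IntakeScenario) -> float:
    """Total daily uptake (ug/d) = fish route + drinking-water route."""
    return (scenario.fish_intake * scenario.fish_tissue_concentration
            + scenario.water_intake * scenario.water_concentration)


def secondary_poisoning_rq(intake: float, limit: float) -> RiskQuotient:
    """Intake (ug/d) over the consumer's daily limit (ADE or MTDI, ug/d)."""
    return _rq(intake, limit)
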