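"""Effect thresholds: PNEC derivations and the PBT hazard screen.

Predicted no-effect concentrations (PNECs) are derived as the lowest
relevant chronic endpoint divided by an assessment factor (AF, default 10).
Two additional PNEC variants address selection for antibiotic resistance
(PNEC_ABR), derived from bacterial minimal inhibitory concentrations
(MICs) by two published conventions:

* lowest MIC / 100;
* a percentile-style method restricted to species with at least 10 MIC
  observations: one (lowest) MIC per eligible species, scaled by the size
  of the species set relative to a 41-species reference panel and a
  general factor of 10, then rounded down to the standard two-fold
  antimicrobial dilution series (..., 16, 32, 64, 128 ug/L).

The final PNEC_ABR is the lower of the two candidates.

The PBT screen is deliberately evidence-based for persistence (simulation
tests either demonstrate degradability or they do not), threshold-based
for bioaccumulation (BCF >= 2000 or log D >= 4.5) and for toxicity
(any chronic NOEC < 10 ug/L, or CMR properties).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InvalidParameterError, NoDataError
from .substance import SubstanceProfile

__all__ = [
    "TaxonGroup",
    "EndpointKind",
    "EcotoxEndpoint",
    "MicRecord",
    "PnecResult",
    "PbtFlag",
    "PbtVerdict",
    "AQUATIC_TAXA",
    "pnec_aquatic",
    "pnec_stp",
    "pnec_abr_lowest_mic",
    "pnec_abr_percentile",
    "pnec_abr",
    "round_down_mic_series",
    "pbt_screen",
]

UG_PER_MG = 1000.0


class TaxonGroup(str, enum.Enum):
    fish = "fish"
    daphnid = "daphnid"
    green_alga = "green_alga"
    cyanobacterium = "cyanobacterium"
    sludge_microorganisms = "sludge_microorganisms"
    other = "other"


class EndpointKind(str, enum.Enum):
    NOEC = "NOEC"
    EC10 = "EC10"
    EC50 = "EC50"
    LOEC = "LOEC"


#: Taxa eligible for the aquatic (surface-water) PNEC.
AQUATIC_TAXA = frozenset({TaxonGroup.fish, TaxonGroup.daphnid,
                          TaxonGroup.green_alga, TaxonGroup.cyanobacterium})


@dataclass(frozen=True)
class EcotoxEndpoint:
    taxon_group: TaxonGroup
    endpoint_kind: EndpointKind
    value: float  # ug/L
    duration: str = ""
    basis: str = ""
    species: str = ""

    def __post_init__(self):
        object.__setattr__(self, "taxon_group", TaxonGroup(self.taxon_group))
        object.__setattr__(self, "endpoint_kind", EndpointKind(self.endpoint_kind))
        if not self.value > 0:
            raise InvalidParameterError("endpoint value must be > 0")


@dataclass(frozen=True)
class MicRecord:
    species: str
    strain: str
    mic: float  # mg/L

    def __post_init__(self):
        if not self.mic > 0:
            raise InvalidParameterError("MIC must be > 0")


@dataclass(frozen=True)
class PnecResult:
    """A PNEC with full derivation provenance."""

    value: float  # ug/L
    method: str
    assessment_factor: float = 1.0
    basis: object = None          # the endpoint/MIC the value rests on
    raw_value: float | None = None  # pre-rounding value, where applicable

    def to_dict(self) -> dict:
        basis = self.basis
        if isinstance(basis, (EcotoxEndpoint, MicRecord)):
            basis = {k: (v.value if isinstance(v, enum.Enum) else v)
                     for k, v in vars(basis).items()}
        return {"value_ug_per_L": self.value, "method": self.method,
                "assessment_factor": self.assessment_factor,
                "raw_value_ug_per_L": self.raw_value, "basis": basis}


def pnec_aquatic(endpoints: Iterable[EcotoxEndpoint],
                 kind: EndpointKind | str,
                 assessment_factor: float = 10.0) -> PnecResult:
    """Aquatic PNEC: lowest chronic endpoint of ``kind`` across the four
    aquatic taxa, divided by the assessment factor."""
    kind = EndpointKind(kind)
    if kind not in (EndpointKind.NOEC, EndpointKind.EC10):
        raise InvalidParameterError("aquatic PNEC uses NOEC or EC10 endpoints")
    if not assessment_factor >= 1:
        raise InvalidParameterError("assessment factor must be >= 1")
    pool = [e for e in endpoints
            if e.endpoint_kind == kind and e.taxon_group in AQUATIC_TAXA]
    if not pool:
        raise NoDataError(f"no aquatic {kind.value} endpoints available")
    lowest = min(pool, key=lambda e: e.value)
    return PnecResult(value=lowest.value / assessment_factor,
                      method=f"aquatic_{kind.value.lower()}",
                      assessment_factor=assessment_factor, basis=lowest)


def pnec_stp(ec10_sludge: float, assessment_factor: float = 10.0) -> PnecResult:
    """STP microorganism PNEC: sludge respiration-inhibition EC10 / AF."""
    if not ec10_sludge > 0:
        raise InvalidParameterError("sludge EC10 must be > 0")
    if not assessment_factor >= 1:
        raise InvalidParameterError("assessment factor must be >= 1")
    return PnecResult(value=ec10_sludge / assessment_factor, method="stp_ec10",
                      assessment_factor=assessment_factor,
                      basis={"ec10_ug_per_L": ec10_sludge,
                             "taxon": "sludge_microorganisms"})


def pnec_abr_lowest_mic(mics: Sequence[MicRecord], factor: float = 100.0) -> PnecResult:
    """Resistance-selection PNEC: lowest MIC (converted to ug/L) / factor."""
    if not mics:
        raise NoDataError("no MIC records")
    if not factor >= 1:
        raise InvalidParameterError("factor must be >= 1")
    lowest = min(mics, key=lambda m: m.mic)
    return PnecResult(value=lowest.mic * UG_PER_MG / factor,
                      method="abr_lowest_mic", assessment_factor=factor,
                      basis=lowest)


def round_down_mic_series(value_ug_l: float) -> float:
    """Round down to the standard two-fold MIC dilution series.

    The series is 2**n ug/L for integer n (..., 0.125, 0.25, 0.5, 1, 2, 4,
    ..., 16, 32, 64, 128, ...), matching the concentrations actually used
    in antimicrobial susceptibility testing; e.g. 76.2 -> 64.
    """
    if not value_ug_l > 0:
        raise InvalidParameterError("value must be > 0")
    return 2.0 ** math.floor(math.log2(value_ug_l))


def pnec_abr_percentile(mics: Sequence[MicRecord],
                        min_obs_per_species: int = 10,
                        reference_species_count: int = 41,
                        general_factor: float = 10.0) -> PnecResult:
    """Resistance-selection PNEC by the size-adjusted percentile method.

    Only species with at least ``min_obs_per_species`` MIC observations are
    eligible; one value (the lowest MIC) is taken per eligible species.

        raw = lowest_MIC[ug/L] * n_eligible / reference_species_count
              / general_factor

    and the reported PNEC is ``raw`` rounded down to the two-fold MIC
    dilution series. Both values are retained.
    """
    if not mics:
        raise NoDataError("no MIC records")
    counts: dict[str, int] = {}
    for m in mics:
        counts[m.species] = counts.get(m.species, 0) + 1
    eligible = {sp for sp, n in counts.items() if n >= min_obs_per_species}
    if not eligible:
        raise NoDataError(
            f"no species has >= {min_obs_per_species} MIC observations "
            f"(filter: min_obs_per_species)")
    per_species_lowest = {
        sp: min(m.mic for m in mics if m.species == sp) for sp in eligible}
    sp_lowest, mic_lowest = min(per_species_lowest.items(), key=lambda kv: kv[1])
    raw = (mic_lowest * UG_PER_MG) * len(eligible) / reference_species_count / general_factor
    return PnecResult(value=round_down_mic_series(raw), method="abr_percentile",
                      assessment_factor=general_factor, raw_value=raw,
                      basis={"species": sp_lowest, "lowest_mic_mg_per_L": mic_lowest,
                             "n_eligible_species": len(eligible),
                             "reference_species_count": reference_species_count})


def pnec_abr(mics: Sequence[MicRecord], **kwargs) -> PnecResult:
    """Final resistance PNEC: the lower of the two candidate derivations.

    Falls back to the lowest-MIC method alone when the percentile method
    has no eligible species.
    """
    low = pnec_abr_lowest_mic(mics)
    try:
        perc = pnec_abr_percentile(mics, **kwargs)
    except NoDataError:
        return low
    return min((low, perc), key=lambda p: p.value)


@dataclass(frozen=True)
class PbtFlag:
    """One leg of the PBT screen: True/False, or None for undetermined."""

    verdict: bool | None
    rationale: str

    def __post_init__(self):
        if not self.rationale:
            raise InvalidParameterError("rationale must be non-empty")


@dataclass(frozen=True)
class PbtVerdict:
    persistent: PbtFlag
    bioaccumulative: PbtFlag
    toxic: PbtFlag

    def to_dict(self) -> dict:
        return {name: {"verdict": flag.verdict, "rationale": flag.rationale}
                for name, flag in (("persistent", self.persistent),
                                   ("bioaccumulative", self.bioaccumulative),
                                   ("toxic", self.toxic))}


def pbt_screen(profile: SubstanceProfile | None,
               degradation_evidence: bool | None,
               endpoints: Sequence[EcotoxEndpoint] = (),
               cmr: bool | None = None,
               bcf_threshold: float = 2000.0,
               logd_threshold: float = 4.5,
               noec_threshold: float = 10.0) -> PbtVerdict:
    """Screening-level persistent / bioaccumulative / toxic verdict.

    Persistence is an evidence flag: ``degradation_evidence=True`` means
    simulation tests demonstrated degradation (hence not persistent);
    ``None`` leaves the leg undetermined. Bioaccumulation triggers on
    max BCF >= 2000 or max log D >= 4.5. Toxicity triggers on any chronic
    NOEC below 10 ug/L or on CMR (carcinogenic/mutagenic/reprotoxic)
    properties; with neither chronic data nor a CMR flag it is
    undetermined. Each rationale names the datum that decided the leg.
    """
    # P leg
    if degradation_evidence is None:
        p = PbtFlag(None, "no degradation simulation evidence supplied")
    elif degradation_evidence:
        p = PbtFlag(False, "degradation demonstrated in simulation tests")
    else:
        p = PbtFlag(True, "no significant degradation in simulation tests")

    # B leg
    bcfs = profile.bcf_by_ph if profile is not None else {}
    logds = profile.log_dow_by_ph if profile is not None else {}
    if not bcfs and not logds:
        b = PbtFlag(None, "no BCF or log D data supplied")
    else:
        reasons = []
        trigger = False
        if bcfs:
            mx = max(bcfs.values())
            if mx >= bcf_threshold:
                trigger, reasons = True, [f"max BCF {mx:g} >= {bcf_threshold:g}"]
            else:
                reasons.append(f"max BCF {mx:g} < {bcf_threshold:g}")
        if logds:
            mx = max(logds.values())
            if mx >= logd_threshold:
                trigger = True
                reasons = [f"max log D {mx:g} >= {logd_threshold:g}"]
            else:
                reasons.append(f"max log D {mx:g} < {logd_threshold:g}")
        b = PbtFlag(trigger, "; ".join(reasons))

    # T leg
    noecs = [e for e in endpoints if e.endpoint_kind == EndpointKind.NOEC]
    low = min(noecs, key=lambda e: e.value) if noecs else None
    if low is not None and low.value < noec_threshold:
        t = PbtFlag(True, f"chronic NOEC {low.value:g} ug/L "
                          f"({low.taxon_group.value}) < {noec_threshold:g} ug/L")
    elif cmr:
        t = PbtFlag(True, "CMR properties in mammals")
    elif low is not None and cmr is not None:
        t = PbtFlag(False, f"lowest chronic NOEC {low.value:g} ug/L >= "
                           f"{noec_threshold:g} ug/L and no CMR flag")
    else:
        t = PbtFlag(None, "insufficient chronic/CMR data for the toxicity leg")

    return PbtVerdict(persistent=p, bioaccumulative=b, toxic=t)
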