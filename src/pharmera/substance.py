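"""Substance identity, physicochemical constants and bioconcentration inputs.

A :class:`SubstanceProfile` bundles the constants an assessment needs for one
active pharmaceutical ingredient (API): molecular weights of the active
moiety and, where the API is marketed as a prodrug, of the prodrug;
pH-dependent distribution coefficients (log D_OW), solubilities and modelled
bioconcentration factors (BCFs); and screening-level hydrolysis/photolysis
data, which are carried as inert data (no kinetics are derived from them
here).

Two derivations live in this module because they are pure functions of the
profile: stoichiometric prodrug-to-active conversion and selection of a
single BCF as the geometric mean of the tabulated values inside an
environmentally relevant pH window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from .errors import InvalidParameterError, NoDataError

__all__ = [
    "SubstanceProfile",
    "BcfSelection",
    "mpa_equivalent",
    "prodrug_to_active",
    "select_bcf",
]


def _check_ph_map(name: str, mapping: Mapping[float, float], *, positive: bool = True) -> dict[float, float]:
    out: dict[float, float] = {}
    for ph, value in mapping.items():
        ph = float(ph)
        if not 0.0 <= ph <= 14.0:
            raise InvalidParameterError(f"{name}: pH key {ph} outside [0, 14]")
        if positive and not value > 0:
            raise InvalidParameterError(f"{name}: value {value} at pH {ph} must be > 0")
        if ph in out:
            raise InvalidParameterError(f"{name}: duplicate pH key {ph}")
        out[ph] = float(value)
    return out


@dataclass(frozen=True)
class SubstanceProfile:
    """Physicochemical and fate constants for one API.

    Parameters
    ----------
    name : str
        Substance name (active moiety).
    molecular_weight : float
        g/mol of the active moiety; must be > 0.
    prodrug_molecular_weight : float, optional
        g/mol of the prodrug, if the API is administered as one.
    pka_values : tuple of float
        Acid dissociation constants.
    log_dow_by_ph : dict
        pH -> n-octanol/water distribution coefficient (may be negative).
    water_solubility_by_ph : dict
        pH -> mg/L.
    vapor_pressure : float, optional
        hPa; must be > 0 when given.
    bcf_by_ph : dict
        pH -> modelled wet-weight fish bioconcentration factor.
    hydrolysis_loss_screen : dict
        pH -> % substance loss in a screening hydrolysis test (data only).
    photolysis_rate_by_condition : dict
        condition label -> 1/min (data only).
    """

    name: str
    molecular_weight: float
    prodrug_molecular_weight: float | None = None
    prodrug_name: str | None = None
    pka_values: tuple[float, ...] = ()
    log_dow_by_ph: dict[float, float] = field(default_factory=dict)
    water_solubility_by_ph: dict[float, float] = field(default_factory=dict)
    vapor_pressure: float | None = None
    bcf_by_ph: dict[float, float] = field(default_factory=dict)
    hydrolysis_loss_screen: dict[float, float] = field(default_factory=dict)
    photolysis_rate_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.molecular_weight > 0:
            raise InvalidParameterError("molecular_weight must be > 0")
        if self.prodrug_molecular_weight is not None and not self.prodrug_molecular_weight > 0:
            raise InvalidParameterError("prodrug_molecular_weight must be > 0")
        if self.vapor_pressure is not None and not self.vapor_pressure > 0:
            raise InvalidParameterError("vapor_pressure must be > 0")
        object.__setattr__(self, "pka_values", tuple(float(p) for p in self.pka_values))
        object.__setattr__(self, "log_dow_by_ph", _check_ph_map("log_dow_by_ph", self.log_dow_by_ph, positive=False))
        object.__setattr__(self, "water_solubility_by_ph", _check_ph_map("water_solubility_by_ph", self.water_solubility_by_ph))
        object.__setattr__(self, "bcf_by_ph", _check_ph_map("bcf_by_ph", self.bcf_by_ph))
        object.__setattr__(self, "hydrolysis_loss_screen", _check_ph_map("hydrolysis_loss_screen", self.hydrolysis_loss_screen, positive=False))
        for label, rate in self.photolysis_rate_by_condition.items():
            if rate < 0:
                raise InvalidParameterError(f"photolysis rate for {label!r} must be >= 0")

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pka_values"] = list(self.pka_values)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstanceProfile":
        d = dict(d)
        for key in ("log_dow_by_ph", "water_solubility_by_ph", "bcf_by_ph", "hydrolysis_loss_screen"):
            if key in d and d[key] is not None:
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubstanceProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class BcfSelection:
    """Outcome of selecting a single BCF over a pH window.

    ``values_used`` records the (pH, BCF) pairs inside the closed interval
    in ascending pH order; ``selected_bcf`` is their geometric mean and is
    bounded by the minimum and maximum of the values used.
    """

    ph_low: float
    ph_high: float
    values_used: tuple[tuple[float, float], ...]
    selected_bcf: float


def prodrug_to_active(mass_prodrug: float, mw_active: float, mw_prodrug: float) -> float:
    """Stoichiometric mass of active moiety released by a prodrug mass.

    Assumes complete cleavage of one mole of active per mole of prodrug,
    so the conversion is simply ``mass_prodrug * mw_active / mw_prodrug``.
    Linear in mass; any mass unit is preserved.

    Raises
    ------
    InvalidParameterError
        If either molecular weight is not strictly positive or the mass is
        negative.
    """
    if not (mw_active > 0 and mw_prodrug > 0):
        raise InvalidParameterError("molecular weights must be > 0")
    if mass_prodrug < 0:
        raise InvalidParameterError("mass_prodrug must be >= 0")
    return mass_prodrug * mw_active / mw_prodrug


#: Alias used throughout the MPA worked example: mycophenolate mofetil
#: (MPM, 433.5 g/mol) is fully cleft to mycophenolic acid (MPA, 320.34 g/mol).
mpa_equivalent = prodrug_to_active


def select_bcf(bcf_by_ph: Mapping[float, float], ph_low: float, ph_high: float) -> BcfSelection:
    """Geometric mean of the tabulated BCFs with pH in ``[ph_low, ph_high]``.

    Both interval endpoints are inclusive. The MPA worked example takes the
    SciFinder-modelled BCFs at pH 5-9, {161, 23.2, 2.49, 1.0, 1.0}, giving
    a selected BCF of 6.22.

    Raises
    ------
    NoDataError
        If no tabulated pH falls inside the interval.
    """
    table = _check_ph_map("bcf_by_ph", bcf_by_ph)
    used = sorted((ph, v) for ph, v in table.items() if ph_low <= ph <= ph_high)
    if not used:
        raise NoDataError(f"no BCF tabulated for pH in [{ph_low}, {ph_high}]")
    gm = math.exp(sum(math.log(v) for _, v in used) / len(used))
    return BcfSelection(ph_low=float(ph_low), ph_high=float(ph_high),
                        values_used=tuple(used), selected_bcf=gm)
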