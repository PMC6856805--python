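"""Seeded generators for every input class, plus the bundled MPA fixture.

The generators emulate the statistical structure of the real inputs a
tiered assessment consumes — country-by-year API sales tables, censored
monitoring datasets with a stated limit of quantitation, mineralization
curves, and tree-shaped river networks — with explicit, documented
parameters. Every generator takes a ``seed`` and creates its own
``numpy.random.Generator``; there is no global random state, and equal
seeds give bit-identical output.

Defaults follow the MPA study conditions where those are stated (24
countries, 14 years, 110 monitoring samples with LOQ 0.001 ug/L and a
55 % detection fraction, a mineralization plateau of 82.2 %); remaining
scale parameters are documented field-plausible choices.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .catchment import RiverNetwork, Segment, StpNode
from .effects import EcotoxEndpoint, MicRecord
from .errors import InvalidParameterError
from .exposure import CountryUseRecord
from .fate import MineralizationCurve
from .mec_stats import CensoredSample, Matrix
from .risk import AdeDerivation
from .substance import SubstanceProfile

__all__ = [
    "gen_use_table",
    "gen_mec_dataset",
    "gen_mineralization_curve",
    "gen_network",
    "MpaFixture",
    "mpa_fixture",
]


def gen_use_table(seed: int,
                  n_countries: int = 24,
                  n_years: int = 14,
                  first_year: int = 2004,
                  median_use_ug_d: float = 300.0,
                  log_sd: float = 0.5,
                  population_range: tuple[float, float] = (1e6, 8e7),
                  prodrug_mass_share: float = 0.9,
                  mw_active: float = 320.34,
                  mw_prodrug: float = 433.5) -> list[CountryUseRecord]:
    """Synthetic country-by-year sales table.

    Per-capita daily use of the active moiety is lognormal with the given
    median (ug/person/d) and log-standard deviation; country populations
    are log-uniform in ``population_range``. The corresponding annual
    masses are split between active and prodrug sales by
    ``prodrug_mass_share`` of the active-equivalent mass.
    """
    if n_countries < 1 or n_years < 1:
        raise InvalidParameterError("need at least one country and one year")
    if not median_use_ug_d > 0 or log_sd < 0:
        raise InvalidParameterError("median use must be > 0 and log_sd >= 0")
    if not 0.0 <= prodrug_mass_share <= 1.0:
        raise InvalidParameterError("prodrug_mass_share must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = population_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_countries)).astype(int)
    records = []
    for c in range(n_countries):
        country = f"C{c:02d}"
        for y in range(n_years):
            use = median_use_ug_d * np.exp(rng.normal(0.0, log_sd)) if log_sd > 0 else median_use_ug_d
            active_eq_kg = use * pops[c] * 365.0 / 1e9
            mpa_kg = active_eq_kg * (1.0 - prodrug_mass_share)
            # prodrug mass carrying the remaining active-equivalent mass
            mpm_kg = active_eq_kg * prodrug_mass_share * mw_prodrug / mw_active
            records.append(CountryUseRecord(country=country, year=first_year + y,
                                            mpa_sold=float(mpa_kg), mpm_sold=float(mpm_kg),
                                            population=int(pops[c])))
    return records


def gen_mec_dataset(seed: int,
                    n: int = 110,
                    loq: float = 0.001,
                    detection_fraction: float = 0.55,
                    log_sd: float = 1.8,
                    matrix: Matrix = Matrix.surface_water) -> list[CensoredSample]:
    """Synthetic censored monitoring dataset.

    Concentrations are lognormal; the distribution median is placed so
    that the probability of a draw exceeding the LOQ equals
    ``detection_fraction`` (the realized detect count is then binomial).
    Draws below the LOQ are emitted as nondetects. The default width
    (log-sd 1.8) spans roughly three orders of magnitude, matching pooled
    surface-water monitoring data.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not loq > 0:
        raise InvalidParameterError("LOQ must be > 0")
    if not 0.0 <= detection_fraction <= 1.0:
        raise InvalidParameterError("detection_fraction must be in [0, 1]")
    if not log_sd > 0:
        raise InvalidParameterError("log_sd must be > 0")
    rng = np.random.default_rng(seed)
    # P(X > loq) = detection_fraction for lognormal(mu, log_sd)
    mu = np.log(loq) - log_sd * norm.ppf(1.0 - detection_fraction)
    draws = np.exp(rng.normal(mu, log_sd, size=n))
    samples = []
    for i, x in enumerate(draws):
        if x >= loq:
            samples.append(CensoredSample(value=float(x), loq=loq, detected=True,
                                          matrix=matrix, site=f"site-{i:03d}",
                                          source="synthetic"))
        else:
            samples.append(CensoredSample(value=None, loq=loq, detected=False,
                                          matrix=matrix, site=f"site-{i:03d}",
                                          source="synthetic"))
    return samples


def gen_mineralization_curve(k_per_hour: float,
                             plateau: float,
                             noise_sd: float = 0.0,
                             seed: int = 0,
                             times_h: tuple[float, ...] = (24, 48, 96, 168, 336, 672)
                             ) -> MineralizationCurve:
    """First-order rise-to-plateau curve, optionally with relative noise.

    ``noise_sd`` is the relative Gaussian noise level (0.05 = 5 %).
    Default sampling times are 1, 2, 4, 7, 14 and 28 days.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if not k_per_hour > 0 or not 0 < plateau <= 110:
        raise InvalidParameterError("need k > 0 and plateau in (0, 110]")
    t = np.asarray(times_h, dtype=float)
    y = plateau * (1.0 - np.exp(-k_per_hour * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_sd, size=y.size))
    y = np.clip(y, 0.0, 110.0)
    return MineralizationCurve(times=tuple(t), cumulative_mineralized=tuple(y))


def gen_network(seed: int,
                n_segments: int = 50,
                branching: float = 0.5,
                stp_fraction: float = 0.3,
                flow_median: float = 10.0,
                flow_log_sd: float = 1.0,
                flow_seasonal_ratio: float = 4.0,
                population_range: tuple[float, float] = (5e3, 2e6),
                per_capita_use: float = 300.0,
                removal: float = 0.12,
                travel_time_range_h: tuple[float, float] = (2.0, 48.0)) -> RiverNetwork:
    """Random tree-shaped river network with STP discharge nodes.

    Segment 0 is the outlet. Each further segment attaches downstream of
    segment ``i-1`` with probability ``1-branching`` (chain growth) or of
    a uniformly chosen earlier segment (branch growth). Mean flows are
    lognormal; low/high flows divide/multiply the mean by
    ``flow_seasonal_ratio``. A fraction of segments receives one STP with
    a log-uniform population.
    """
    if n_segments < 1:
        raise InvalidParameterError("n_segments must be >= 1")
    if not 0.0 <= branching <= 1.0 or not 0.0 <= stp_fraction <= 1.0:
        raise InvalidParameterError("branching and stp_fraction must be in [0, 1]")
    if not flow_seasonal_ratio >= 1.0:
        raise InvalidParameterError("flow_seasonal_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    parents: list[str | None] = [None]
    for i in range(1, n_segments):
        if branching > 0 and rng.random() < branching:
            j = int(rng.integers(0, i))
        else:
            j = i - 1
        parents.append(f"S{j:03d}")
    segments = []
    for i in range(n_segments):
        mean = flow_median * float(np.exp(rng.normal(0.0, flow_log_sd)))
        segments.append(Segment(
            id=f"S{i:03d}", downstream_id=parents[i],
            flow_mean=mean, flow_min=mean / flow_seasonal_ratio,
            flow_max=mean * flow_seasonal_ratio,
            travel_time=float(rng.uniform(*travel_time_range_h))))
    stps = []
    lo, hi = population_range
    for seg in segments:
        if rng.random() < stp_fraction:
            pop = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            stps.append(StpNode(segment_id=seg.id, population=pop,
                                per_capita_use=per_capita_use, removal=removal))
    return RiverNetwork(segments=tuple(segments), stp_nodes=tuple(stps))


# ---------------------------------------------------------------------------
# Bundled MPA constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MpaFixture:
    """Typed bundle of the literature-derived MPA assessment constants."""

    profile: SubstanceProfile
    aquatic_endpoints: tuple[EcotoxEndpoint, ...]
    sludge_ec10: float            # ug/L
    mic_records: tuple[MicRecord, ...]
    ade_derivations: tuple[AdeDerivation, ...]
    ade_mpa_rounding: str
    fate: dict
    exposure: dict
    intake_defaults: dict
    reference_concentrations: dict
    cmr: bool
    degradation_evidence: bool
    raw: dict

    def to_json(self) -> str:
        return json.dumps(self.raw, indent=2, sort_keys=True)


def _load_raw() -> dict:
    ref = importlib.resources.files("pharmera").joinpath("data/mpa.json")
    return json.loads(ref.read_text())


def mpa_fixture() -> MpaFixture:
    """Load the bundled mycophenolic-acid constants.

    Strain-level MIC detail beyond the reported range endpoints is a
    synthetic stand-in (see the ``notes`` field of the bundled JSON); all
    derivation-relevant values are literature constants.
    """
    raw = _load_raw()
    profile = SubstanceProfile.from_dict(raw["substance"])
    endpoints = tuple(EcotoxEndpoint(**e) for e in raw["aquatic_endpoints"])
    mics = tuple(MicRecord(**m) for m in raw["mic_records"])
    ades = tuple(AdeDerivation(label=d["label"],
                               point_of_departure=d["point_of_departure"],
                               pod_kind=d["pod_kind"],
                               body_weight=d["body_weight"],
                               factors=tuple((v, r) for v, r in d["factors"]),
                               rounding=d["rounding"])
                 for d in raw["ade_derivations"])
    return MpaFixture(profile=profile, aquatic_endpoints=endpoints,
                      sludge_ec10=raw["sludge_ec10_ug_L"], mic_records=mics,
                      ade_derivations=ades,
                      ade_mpa_rounding=raw["ade_mpa_rounding"],
                      fate=raw["fate"], exposure=raw["exposure"],
                      intake_defaults=raw["intake_defaults"],
                      reference_concentrations=raw["reference_concentrations"],
                      cmr=raw["cmr"],
                      degradation_evidence=raw["degradation_evidence"],
                      raw=raw)
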