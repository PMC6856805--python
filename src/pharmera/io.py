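"""Config parsing, schema-validated table IO and report assembly.

Tables are comma-separated UTF-8 with "." decimals; concentrations are
ug/L in all outputs (MIC inputs are mg/L and converted on read). Every
reader attaches row numbers to validation errors. A full run is
deterministic: the same config produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
import yaml

from . import effects, exposure, mec_stats, risk
from .errors import ConfigError, EraError, NoDataError
from .pipeline import assess_mpa
from .substance import SubstanceProfile
from .synthetic import mpa_fixture

__all__ = [
    "RunConfig",
    "read_table",
    "read_use_table",
    "read_endpoints",
    "read_mics",
    "read_mecs",
    "write_ranked_csv",
    "run_era",
]


# ---------------------------------------------------------------------------
# Schema-validated CSV reading
# ---------------------------------------------------------------------------

def _to_bool(x: str) -> bool:
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {x!r}")


def read_table(path: str | Path, schema: dict[str, tuple[Callable, bool]]) -> list[dict]:
    """Read a CSV into schema-validated row dicts.

    ``schema`` maps column name to ``(converter, required)``. Missing
    required columns raise :class:`ConfigError`; conversion failures raise
    it with the 1-based data row number. A header-only file yields an
    empty list.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, sep=",", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ConfigError(f"{path}: file is empty (no header)")
    missing = [c for c, (_, req) in schema.items() if req and c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    rows = []
    for i, rec in enumerate(df.to_dict(orient="records"), start=1):
        out = {}
        for col, (conv, req) in schema.items():
            raw = rec.get(col, "")
            if raw == "" or raw is None:
                out[col] = None
                continue
            try:
                out[col] = conv(raw)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"{path}: row {i}, column {col!r}: {exc}")
        out["__row__"] = i
        rows.append(out)
    return rows


USE_SCHEMA = {"country": (str, True), "year": (int, True),
              "mpa_kg": (float, True), "mpm_kg": (float, True),
              "population": (lambda x: int(float(x)), True)}

ENDPOINT_SCHEMA = {"taxon_group": (str, True), "kind": (str, True),
                   "value_ugL": (float, True), "species": (str, False),
                   "duration": (str, False), "basis": (str, False)}

MIC_SCHEMA = {"species": (str, True), "strain": (str, True),
              "mic_mgL": (float, True)}

MEC_SCHEMA = {"value_ugL": (float, False), "loq_ugL": (float, True),
              "detected": (_to_bool, True), "matrix": (str, False),
              "site": (str, False), "source": (str, False)}


def read_use_table(path: str | Path) -> list[exposure.CountryUseRecord]:
    return [exposure.CountryUseRecord(country=r["country"], year=r["year"],
                                      mpa_sold=r["mpa_kg"], mpm_sold=r["mpm_kg"],
                                      population=r["population"])
            for r in read_table(path, USE_SCHEMA)]


def read_endpoints(path: str | Path) -> list[effects.EcotoxEndpoint]:
    return [effects.EcotoxEndpoint(taxon_group=r["taxon_group"],
                                   endpoint_kind=r["kind"], value=r["value_ugL"],
                                   species=r.get("species") or "",
                                   duration=r.get("duration") or "",
                                   basis=r.get("basis") or "")
            for r in read_table(path, ENDPOINT_SCHEMA)]


def read_mics(path: str | Path) -> list[effects.MicRecord]:
    return [effects.MicRecord(species=r["species"], strain=r["strain"],
                              mic=r["mic_mgL"])
            for r in read_table(path, MIC_SCHEMA)]


def read_mecs(path: str | Path) -> list[mec_stats.CensoredSample]:
    return [mec_stats.CensoredSample(value=r["value_ugL"], loq=r["loq_ugL"],
                                     detected=r["detected"],
                                     matrix=r.get("matrix") or "surface_water",
                                     site=r.get("site") or "",
                                     source=r.get("source") or "")
            for r in read_table(path, MEC_SCHEMA)]


def write_use_table(path: str | Path, records: Sequence[exposure.CountryUseRecord]) -> None:
    pd.DataFrame([{"country": r.country, "year": r.year, "mpa_kg": r.mpa_sold,
                   "mpm_kg": r.mpm_sold, "population": r.population}
                  for r in records]).to_csv(path, index=False)


def write_mec_table(path: str | Path, samples: Sequence[mec_stats.CensoredSample]) -> None:
    pd.DataFrame([{"value_ugL": "" if s.value is None else s.value,
                   "loq_ugL": s.loq, "detected": s.detected,
                   "matrix": s.matrix.value, "site": s.site, "source": s.source}
                  for s in samples]).to_csv(path, index=False)


def write_ranked_csv(path: str | Path, dist: mec_stats.RankedDistribution) -> None:
    rows = []
    n = dist.n_total
    for rank, s in enumerate(dist.ordered_values, start=1):
        rows.append({"rank": rank, "percentile": 100.0 * rank / n,
                     "value_or_censored": s.value if s.detected else mec_stats.BELOW_LOQ})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"substance", "use_table", "endpoints", "mics", "mecs",
               "scenario", "assessment_factor", "output_dir", "seed"}
_SCENARIO_KEYS = {"wastewater_per_capita", "treated_fraction", "stp_removals",
                  "dilution_factor"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (YAML or JSON on disk)."""

    substance: str = "mpa"     # "mpa" (builtin) or path to a profile JSON
    use_table: str | None = None
    endpoints: str | None = None
    mics: str | None = None
    mecs: str | None = None
    scenario: dict = field(default_factory=dict)
    assessment_factor: float = 10.0
    output_dir: str = "era_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        scen = data.get("scenario", {}) or {}
        bad = set(scen) - _SCENARIO_KEYS
        if bad:
            raise ConfigError(f"unknown scenario key(s): {sorted(bad)}")
        cfg = cls(**data)
        base = path.parent
        for name in ("use_table", "endpoints", "mics", "mecs"):
            p = getattr(cfg, name)
            if p is not None:
                p = str((base / p) if not Path(p).is_absolute() else Path(p))
                object.__setattr__(cfg, name, p)
                if not Path(p).exists():
                    raise ConfigError(f"{name}: file not found: {p}")
        if cfg.substance != "mpa":
            sp = (base / cfg.substance) if not Path(cfg.substance).is_absolute() else Path(cfg.substance)
            if not sp.exists():
                raise ConfigError(f"substance: file not found: {sp}")
            object.__setattr__(cfg, "substance", str(sp))
        return cfg

    def scenario_for(self, stp_removal: float) -> exposure.ExposureScenario:
        s = self.scenario
        return exposure.ExposureScenario(
            wastewater_per_capita=s.get("wastewater_per_capita", 200.0),
            treated_fraction=s.get("treated_fraction", 0.8),
            stp_removal=stp_removal,
            dilution_factor=s.get("dilution_factor", 10.0))

    @property
    def stp_removals(self) -> list[float]:
        return list(self.scenario.get("stp_removals", [0.12, 0.436, 0.731]))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sig3(x: float) -> float:
    return float(f"{x:.3g}")


def run_era(config: RunConfig) -> dict:
    """Run the configured assessment and write the report bundle.

    Writes ``pec.csv``, ``pnec.json``, ``risk.csv``, ``ade_audit.json``
    and ``summary.md`` into ``config.output_dir`` and returns the paths.
    Missing optional inputs skip their tier; an empty required table
    raises :class:`NoDataError` naming the file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = mpa_fixture()
    if config.substance == "mpa":
        profile = fx.profile
    else:
        profile = SubstanceProfile.from_json(config.substance)
    mw_p = profile.prodrug_molecular_weight or profile.molecular_weight

    summary: list[str] = [f"# ERA report: {profile.name}", ""]
    paths: dict[str, str] = {}

    # exposure tier -------------------------------------------------------
    pec_rows = []
    country_sw_pecs: dict[float, list[tuple[str, float, int]]] = {}
    if config.use_table:
        records = read_use_table(config.use_table)
        if not records:
            raise NoDataError(f"use table is empty: {config.use_table}")
        by_country: dict[str, list[exposure.CountryUseRecord]] = {}
        for r in records:
            by_country.setdefault(r.country, []).append(r)
        for country in sorted(by_country):
            recs = by_country[country]
            uses = [exposure.per_capita_daily_use(r, profile.molecular_weight, mw_p)
                    for r in recs]
            use = max(uses)  # highest year-specific per-capita use
            pop = recs[-1].population
            row = {"country": country, "per_capita_use_ug_d": use}
            scen0 = config.scenario_for(config.stp_removals[0])
            row["stp_pec_ugL"] = exposure.pec_stp(use, scen0.wastewater_per_capita)
            for rr in config.stp_removals:
                sw = exposure.pec_surface(row["stp_pec_ugL"], config.scenario_for(rr))
                row[f"sw_pec_ugL_removal_{rr:g}"] = sw
                country_sw_pecs.setdefault(rr, []).append((country, sw, pop))
            pec_rows.append(row)
        pd.DataFrame(pec_rows).to_csv(out / "pec.csv", index=False)
        paths["pec"] = str(out / "pec.csv")
        summary.append(f"Exposure: {len(pec_rows)} countries; removal scenarios "
                       f"{config.stp_removals}.")
        for rr in config.stp_removals:
            stats = exposure.weighted_summary(
                [(pec, pop) for _, pec, pop in country_sw_pecs[rr]])
            summary.append(
                f"- removal {rr:g}: population-weighted mean "
                f"{stats['weighted_mean']:.3g} ug/L, weighted median "
                f"{stats['weighted_median']:.3g} ug/L, range "
                f"{stats['min']:.3g}-{stats['max']:.3g} ug/L")
        summary.append("")

    # effects tier --------------------------------------------------------
    pnecs: dict[str, effects.PnecResult] = {}
    if config.endpoints:
        eps = read_endpoints(config.endpoints)
        if not eps:
            raise NoDataError(f"endpoint table is empty: {config.endpoints}")
        for kind in ("NOEC", "EC10"):
            try:
                pnecs[f"aquatic_{kind.lower()}"] = effects.pnec_aquatic(
                    eps, kind, config.assessment_factor)
            except NoDataError:
                pass
    if config.mics:
        mics = read_mics(config.mics)
        if not mics:
            raise NoDataError(f"MIC table is empty: {config.mics}")
        pnecs["abr"] = effects.pnec_abr(mics)
    if pnecs:
        (out / "pnec.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in pnecs.items()}, indent=2, sort_keys=True))
        paths["pnec"] = str(out / "pnec.json")
        for k, v in sorted(pnecs.items()):
            summary.append(f"PNEC[{k}] = {v.value:.4g} ug/L ({v.method})")
        summary.append("")

    # risk tier -----------------------------------------------------------
    risk_rows = []
    for pnec_name, pnec in sorted(pnecs.items()):
        for rr, entries in sorted(country_sw_pecs.items()):
            for country, sw, _pop in entries:
                q = risk.risk_quotient(sw, pnec)
                risk_rows.append({"exposure_source": f"{country}@removal={rr:g}",
                                  "pnec_method": pnec_name,
                                  "quotient_3sf": _sig3(q.quotient),
                                  "quotient": q.quotient,
                                  "verdict": q.verdict.value})
    if risk_rows:
        pd.DataFrame(risk_rows).to_csv(out / "risk.csv", index=False)
        paths["risk"] = str(out / "risk.csv")
        n_risk = sum(1 for r in risk_rows if r["verdict"] == "potential_risk")
        summary.append(f"Risk: {len(risk_rows)} quotients, "
                       f"{n_risk} flagged potential_risk.")
        summary.append("")

    # measured concentrations ---------------------------------------------
    if config.mecs:
        mecs = read_mecs(config.mecs)
        if not mecs:
            raise NoDataError(f"MEC table is empty: {config.mecs}")
        dist = mec_stats.percent_rank(mecs)
        write_ranked_csv(out / "mec_rank.csv", dist)
        paths["mec_rank"] = str(out / "mec_rank.csv")
        mean = mec_stats.censored_mean(mecs)
        summary.append(f"MECs: n={dist.n_total}, nondetects={dist.n_nondetect}, "
                       f"half-LOQ mean {mean:.4g} ug/L.")
        for p in (50.0, 90.0, 95.0):
            summary.append(f"- {p:g}th percentile: {dist.percentile_of.get(p, dist.percentile(p))}")
        for pnec_name, pnec in sorted(pnecs.items()):
            try:
                ex = risk.exceedance_summary(dist, pnec)
                summary.append(f"- above PNEC[{pnec_name}]: {ex['n_at_risk']}/{ex['n']} "
                               f"({100 * ex['fraction_at_risk']:.2g} %)")
            except EraError as exc:
                summary.append(f"- PNEC[{pnec_name}] exceedance indeterminate: {exc}")
        summary.append("")

    # secondary poisoning audit trail (bundled constants) -------------------
    if config.substance == "mpa":
        report = assess_mpa(fx)
        (out / "ade_audit.json").write_text(json.dumps(
            report["secondary_poisoning"], indent=2, sort_keys=True))
        paths["ade_audit"] = str(out / "ade_audit.json")
        sp = report["secondary_poisoning"]
        summary.append(
            f"Secondary poisoning: ADE {sp['ade_active_mg_d']:.3g} mg/d, "
            f"MTDI {sp['mtdi_top_predator_ug_d']:.3g} ug/d, top-predator RQ "
            f"{sp['top_predator_rq']['quotient']:.3g}, human RQ "
            f"{sp['human_rq']['quotient']:.3g}.")
        summary.append("")

    (out / "summary.md").write_text("\n".join(summary))
    paths["summary"] = str(out / "summary.md")
    return paths
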