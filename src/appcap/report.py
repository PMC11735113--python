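"""End-to-end scenario runs: cascade -> apportionment -> capacity -> diversion.

``run_scenario`` executes the whole pipeline for every PCN in a register
file against an area appointment file, producing a per-PCN table, an
aggregate row, the scaled multi-PCN headline figures, and provenance
(input digests, package version, seed). Runs are deterministic: identical
config and inputs give byte-identical serialized reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .apportion import (
    AppointmentVolume,
    annualize_volume,
    apportion as apportion_volume,
    population_share,
    read_appointments,
)
from .capacity import AnnualCapacity, annual_capacity
from .cascade import PCNRegister, cascade_for_register, read_register
from .config import ScenarioConfig
from .diversion import run_diversion, scale_pcns
from .errors import ConfigError, ModelError
from .rounding import report_int

logger = logging.getLogger(__name__)

try:
    _VERSION = version("appcap")
except PackageNotFoundError:  # pragma: no cover - editable-install edge
    _VERSION = "unknown"

#: Columns whose aggregate is a plain sum; the rest are left blank in the
#: aggregate row (shares and WTEs are recomputed, not summed).
_SUM_COLUMNS = [
    "total_population",
    "adult_population",
    "mh_population",
    "in_scope_population",
    "population_share",
    "gp_appointments_year",
    "mh_appointments_year",
    "brief_appointments",
    "triage_appointments",
    "group_participants",
    "group_person_sessions",
    "community_engagement_hours",
    "diverted_per_app",
    "patients_served_per_app",
    "freed_low",
    "freed_high",
    "wte_low",
    "wte_high",
    "freed_band_low",
    "freed_band_high",
    "self_referral_demand",
    "absorbed_triage",
    "unmet_triage",
]


@dataclass
class ScenarioReport:
    """Everything one scenario run produced."""

    config: ScenarioConfig
    per_pcn: pd.DataFrame
    aggregate: dict[str, float]
    scaled: dict[str, float]
    provenance: dict[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.model_dump(mode="json", exclude_none=True),
            "per_pcn": self.per_pcn.to_dict(orient="records"),
            "aggregate": self.aggregate,
            "scaled": self.scaled,
            "provenance": self.provenance,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pcn_row(
    register: PCNRegister,
    config: ScenarioConfig,
    annual_gp: dict[str, float],
    area_population: float,
    capacity: AnnualCapacity,
    area_id: str,
) -> dict[str, float]:
    cascade = cascade_for_register(register, config.cascade)
    share = population_share(register.total_population, area_population)
    volume = AppointmentVolume(
        area_id=area_id,
        period_start=date(2000, 1, 1),
        period_end=date(2000, 12, 31),
        appointments_by_staff_type=annual_gp,
    )
    # annual_gp is already annualized; apportion uses the counts as given
    sliced = apportion_volume(volume, share, config.apportionment, pcn_id=register.pcn_id)
    result = run_diversion(
        sliced.pcn_mh_appointments, capacity, config.diversion, config.reduction_band
    )
    return {
        "pcn_id": register.pcn_id,
        "n_practices": len(register.practices),
        "total_population": cascade.total_population,
        "adult_population": cascade.adult_population,
        "mh_population": cascade.mh_population,
        "in_scope_population": cascade.in_scope_population,
        "population_share": share,
        "gp_appointments_year": sliced.pcn_gp_appointments,
        "mh_appointments_year": sliced.pcn_mh_appointments,
        "brief_appointments": capacity.brief_appointments,
        "triage_appointments": capacity.triage_appointments,
        "group_participants": capacity.group_participants,
        "group_person_sessions": capacity.group_person_sessions,
        "community_engagement_hours": capacity.community_engagement_hours,
        "diverted_per_app": result.diverted_appointments_per_app,
        "patients_served_per_app": result.patients_served_per_app,
        "freed_low": result.freed_gp_appointments_low,
        "freed_high": result.freed_gp_appointments_high,
        "wte_low": result.wte_required_low,
        "wte_high": result.wte_required_high,
        "freed_band_low": result.freed_band_low,
        "freed_band_high": result.freed_band_high,
        "self_referral_demand": result.self_referral_demand,
        "absorbed_triage": result.absorbed_triage,
        "unmet_triage": result.unmet_triage,
    }


def run_scenario(
    config: ScenarioConfig,
    register_path: str | Path,
    appointments_path: str | Path,
    seed: Optional[int] = None,
) -> ScenarioReport:
    """Run the full pipeline over every PCN in the register file.

    ``seed`` is recorded in provenance only; the pipeline itself is
    deterministic. Stage failures are re-raised with the stage named.
    """
    register_path = Path(register_path)
    appointments_path = Path(appointments_path)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ModelError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    registers = _stage("register", read_register, register_path)
    volumes = _stage("appointments", read_appointments, appointments_path)

    # pool (annualized) area volumes in case the file spans several periods
    annual_gp: dict[str, float] = {"gp": 0.0, "other_staff": 0.0}
    for volume in volumes:
        for staff, count in annualize_volume(volume).items():
            annual_gp[staff] = annual_gp.get(staff, 0.0) + count
    area_id = volumes[0].area_id if volumes else "AREA"

    area_population = config.area_population
    if area_population is None:
        area_population = sum(r.total_population for r in registers)

    template = config.week_templates[config.active_template]
    capacity = _stage(
        "capacity", annual_capacity, template, config.annualization, config.group_cycle
    )

    rows = [
        _stage("pcn", _pcn_row, register, config, annual_gp, area_population, capacity, area_id)
        for register in registers
    ]
    per_pcn = pd.DataFrame(rows, columns=["pcn_id", "n_practices"] + _SUM_COLUMNS)

    if rows:
        aggregate = {col: float(per_pcn[col].sum()) for col in _SUM_COLUMNS}
        aggregate["n_practices"] = int(per_pcn["n_practices"].sum())
    else:
        aggregate = {col: 0.0 for col in _SUM_COLUMNS}
        aggregate["n_practices"] = 0
    aggregate["n_pcns_in_register"] = len(rows)

    scaled = {
        "n_pcns": config.n_pcns,
        "diverted_appointments_all_pcns": scale_pcns(
            capacity.brief_appointments, config.n_pcns, "none"
        ),
        "diverted_appointments_all_pcns_display": scale_pcns(
            capacity.brief_appointments, config.n_pcns, "two_sig_figs"
        ),
        "group_participants_all_pcns": scale_pcns(
            capacity.group_participants, config.n_pcns, "none"
        ),
        "group_person_sessions_all_pcns": scale_pcns(
            capacity.group_person_sessions, config.n_pcns, "none"
        ),
    }

    provenance = {
        "register_sha256": _sha256_file(register_path),
        "appointments_sha256": _sha256_file(appointments_path),
        "config_sha256": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
        "package_version": _VERSION,
        "seed": seed,
        "active_template": config.active_template,
    }
    logger.info(
        "scenario run: %d PCNs, template %s, area population %s",
        len(rows), config.active_template, report_int(area_population) if area_population else 0,
    )
    return ScenarioReport(
        config=config,
        per_pcn=per_pcn,
        aggregate=aggregate,
        scaled=scaled,
        provenance=provenance,
    )


def write_report(
    report: ScenarioReport,
    out_dir: str | Path,
    formats: Iterable[str] = ("csv", "json"),
) -> list[Path]:
    """Write the report as tidy CSV (per-PCN rows + aggregate row) and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - {"csv", "json"}
    if unknown:
        raise ConfigError(f"unknown report formats {sorted(unknown)}")
    paths: list[Path] = []
    if "csv" in formats:
        frame = report.per_pcn.copy()
        agg_row = {"pcn_id": "ALL", **report.aggregate}
        agg_row.pop("n_pcns_in_register", None)
        frame = pd.concat([frame, pd.DataFrame([agg_row])], ignore_index=True)
        csv_path = out_dir / "report.csv"
        frame.to_csv(csv_path, index=False)
        paths.append(csv_path)
    if "json" in formats:
        json_path = out_dir / "report.json"
        json_path.write_text(
            json.dumps(report.to_json_dict(), indent=2, sort_keys=True, default=str)
            + "\n"
        )
        paths.append(json_path)
    return paths


def _resolve_dotted(config: ScenarioConfig, dotted: str):
    node = config
    parts = dotted.split(".")
    for part in parts[:-1]:
        if not hasattr(node, part):
            raise ConfigError(f"unknown config path {dotted!r}")
        node = getattr(node, part)
    if not hasattr(node, parts[-1]):
        raise ConfigError(f"unknown config path {dotted!r}")
    return node, parts[-1]


def sensitivity_sweep(
    config: ScenarioConfig,
    parameter_path: str,
    values: Iterable[object],
    register_path: str | Path,
    appointments_path: str | Path,
) -> pd.DataFrame:
    """Re-run the scenario for each value of one dotted config parameter.

    Returns a long-format table keyed by (parameter, value, metric); metrics
    are the aggregate row plus the scaled headline figures.
    """
    rows = []
    for value in values:
        varied = config.model_copy(deep=True)
        node, attr = _resolve_dotted(varied, parameter_path)
        setattr(node, attr, value)
        report = run_scenario(varied, register_path, appointments_path)
        for metric, result in {**report.aggregate, **report.scaled}.items():
            rows.append(
                {
                    "parameter": parameter_path,
                    "value": value,
                    "metric": metric,
                    "result": result,
                }
            )
    return pd.DataFrame(rows, columns=["parameter", "value", "metric", "result"])
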