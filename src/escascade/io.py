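"""Readers and writers for catchments, parameters, scenarios and reports.

File dialects
-------------
* **Catchment CSV** — long format, UTF-8, header ``catchment,field,value``,
  one row per field.  Fields are namespaced: ``land_cover.cropland``,
  ``river.main_river_length``, ``river.corridor_share_built_up``,
  ``beneficiaries.households`` …  Booleans are written as 0/1.
* **Parameter YAML** — flat mapping of parameter name to number; omitted
  parameters keep their defaults, unknown names are an error.
* **Scenario YAML** — keys ``scenario_id``, ``land_cover_change``
  (with either ``target_fractions`` or ``deltas_ha``),
  ``river_metric_changes`` and ``parameter_overrides``; an empty file is
  the identity scenario.
* **Account / comparison CSV** — the long tables produced by
  :meth:`ServiceAccount.to_frame` / :meth:`ComparisonReport.to_frame`.

An optional importer reads a user-supplied supplementary workbook
(XLSX) of per-scenario land-cover tables; it is layout-tolerant and
never required by the core pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .accounting import (
    ComparisonLine,
    ComparisonReport,
    ServiceAccount,
)
from .domain import (
    BeneficiaryProfile,
    CatchmentState,
    CorridorShares,
    LandCoverState,
    POOLED_CLASSES,
    RiverMetrics,
    ServiceParameterSet,
    ValidationError,
)
from .scenarios import ScenarioDefinition
from .services import ServiceValue

__all__ = [
    "InputError",
    "RunConfig",
    "read_catchment",
    "write_catchment",
    "read_parameters",
    "write_parameters",
    "read_pooling_table",
    "read_scenario",
    "write_scenario",
    "write_account",
    "write_comparison",
    "read_comparison",
    "import_s1_workbook",
    "packaged_path",
]

logger = logging.getLogger("escascade")


class InputError(ValidationError):
    """A file could not be parsed into a valid domain object."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one CLI run."""

    catchment_path: Path
    scenario_paths: tuple[Path, ...] = ()
    parameter_path: Path | None = None
    output_dir: Path = Path(".")
    rounding: int = 2
    normalizer: str = "mean"
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ValidationError("rounding must be >= 0")


def packaged_path(name: str):
    """Path to a packaged data file (context manager)."""
    return resources.as_file(
        resources.files("escascade").joinpath("data", name)
    )


# ---------------------------------------------------------------------------
# catchment CSV
# ---------------------------------------------------------------------------

_RIVER_FLOATS = (
    "main_river_length", "shaded_fraction", "riparian_fraction",
    "floodplain_area", "hydropower_generation", "drinking_water_extraction",
    "flood_p_sedimentation",
)
_CORRIDOR = ("built_up", "agricultural", "woodland")


def write_catchment(state: CatchmentState, path: str | Path) -> None:
    rows: list[tuple[str, str, float]] = []
    rows.append((state.name, "land_cover.catchment_area",
                 state.land_cover.catchment_area))
    for cls in POOLED_CLASSES:
        rows.append((state.name, f"land_cover.{cls}",
                     getattr(state.land_cover, cls)))
    for name in _RIVER_FLOATS:
        rows.append((state.name, f"river.{name}", getattr(state.river, name)))
    for name in _CORRIDOR:
        rows.append((state.name, f"river.corridor_share_{name}",
                     getattr(state.river.corridor_shares, name)))
    rows.append((state.name, "river.discharges_directly_to_sea",
                 float(state.river.discharges_directly_to_sea)))
    for f in fields(BeneficiaryProfile):
        rows.append((state.name, f"beneficiaries.{f.name}",
                     getattr(state.beneficiaries, f.name)))
    frame = pd.DataFrame(rows, columns=["catchment", "field", "value"])
    frame.to_csv(path, index=False, float_format="%.10g")


def read_catchment(path: str | Path) -> CatchmentState:
    """Parse a long-format catchment CSV into a validated state."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"catchment file not found: {path}") from None
    required = {"catchment", "field", "value"}
    if not required.issubset(frame.columns):
        raise InputError(
            f"{path}: expected columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    names = frame["catchment"].unique()
    if len(names) != 1:
        raise InputError(
            f"{path}: expected exactly one catchment, found {list(names)}"
        )
    values: dict[str, float] = {}
    for i, row in frame.iterrows():
        try:
            values[str(row["field"])] = float(row["value"])
        except (TypeError, ValueError):
            raise InputError(
                f"{path} row {i + 2}: non-numeric value {row['value']!r} "
                f"for field {row['field']!r}"
            ) from None

    def take(prefix: str, name: str, default: float | None = None) -> float:
        key = f"{prefix}.{name}"
        if key in values:
            return values.pop(key)
        if default is not None:
            return default
        raise InputError(f"{path}: missing required field {key!r}")

    try:
        land_cover = LandCoverState(
            catchment_area=take("land_cover", "catchment_area"),
            **{cls: take("land_cover", cls, 0.0) for cls in POOLED_CLASSES},
        )
        river = RiverMetrics(
            **{name: take("river", name, 0.0) for name in _RIVER_FLOATS},
            corridor_shares=CorridorShares(
                **{n: take("river", f"corridor_share_{n}",
                           1.0 if n == "woodland" else 0.0)
                   for n in _CORRIDOR}
            ),
            discharges_directly_to_sea=bool(
                take("river", "discharges_directly_to_sea", 0.0)
            ),
        )
        beneficiaries = BeneficiaryProfile(
            **{f.name: take("beneficiaries", f.name, float(f.default))
               for f in fields(BeneficiaryProfile)}
        )
        state = CatchmentState(
            name=str(names[0]), land_cover=land_cover, river=river,
            beneficiaries=beneficiaries,
        )
    except ValidationError as exc:
        raise InputError(f"{path}: {exc}") from exc
    if values:
        raise InputError(
            f"{path}: unknown field(s): {', '.join(sorted(values))}"
        )
    return state


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def read_parameters(path: str | Path) -> ServiceParameterSet:
    """Read a flat YAML mapping of parameter overrides over the defaults."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"{path}: expected a mapping of parameter: value")
    try:
        params = ServiceParameterSet().replace(
            **{k: float(v) for k, v in raw.items()}
        )
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: {exc}") from exc
    if raw:
        logger.info(
            "parameters from %s override defaults for: %s",
            path, ", ".join(sorted(raw)),
        )
    return params


def write_parameters(params: ServiceParameterSet, path: str | Path) -> None:
    data = {f.name: getattr(params, f.name)
            for f in fields(ServiceParameterSet)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_pooling_table(path: str | Path) -> dict[int, str]:
    """Read a CORINE pooling table CSV (corine_code, pooled_class)."""
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"corine_code", "pooled_class"}.issubset(frame.columns):
        raise InputError(
            f"{path}: expected columns corine_code, pooled_class"
        )
    table: dict[int, str] = {}
    for i, row in frame.iterrows():
        cls = str(row["pooled_class"])
        if cls not in POOLED_CLASSES:
            raise InputError(
                f"{path} row {i + 2}: unknown pooled class {cls!r}"
            )
        table[int(row["corine_code"])] = cls
    return table


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def read_scenario(path: str | Path) -> ScenarioDefinition:
    """Read a scenario YAML file; an empty file is the identity scenario."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"scenario file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"{path}: expected a mapping at top level")
    known = {"scenario_id", "land_cover_change", "river_metric_changes",
             "parameter_overrides"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise InputError(
            f"{path}: unknown top-level key(s): {', '.join(unknown)}"
        )
    change = raw.get("land_cover_change") or {}
    if not isinstance(change, dict) or (
        set(change) - {"target_fractions", "deltas_ha"}
    ):
        raise InputError(
            f"{path}: land_cover_change must hold target_fractions "
            "and/or deltas_ha"
        )
    try:
        return ScenarioDefinition(
            scenario_id=str(raw.get("scenario_id", path.stem)),
            target_fractions={
                str(k): float(v)
                for k, v in (change.get("target_fractions") or {}).items()
            },
            deltas_ha={
                str(k): float(v)
                for k, v in (change.get("deltas_ha") or {}).items()
            },
            river_metric_changes={
                str(k): (bool(v) if k == "discharges_directly_to_sea"
                         else float(v))
                for k, v in (raw.get("river_metric_changes") or {}).items()
            },
            parameter_overrides={
                str(k): float(v)
                for k, v in (raw.get("parameter_overrides") or {}).items()
            },
        )
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_scenario(scenario: ScenarioDefinition, path: str | Path) -> None:
    data: dict = {"scenario_id": scenario.scenario_id}
    change: dict = {}
    if scenario.target_fractions:
        change["target_fractions"] = dict(scenario.target_fractions)
    if scenario.deltas_ha:
        change["deltas_ha"] = dict(scenario.deltas_ha)
    if change:
        data["land_cover_change"] = change
    if scenario.river_metric_changes:
        data["river_metric_changes"] = dict(scenario.river_metric_changes)
    if scenario.parameter_overrides:
        data["parameter_overrides"] = dict(scenario.parameter_overrides)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _maybe_round(frame: pd.DataFrame, rounding: int | None) -> pd.DataFrame:
    return frame if rounding is None else frame.round(rounding)


def write_account(
    account: ServiceAccount, path: str | Path, rounding: int | None = None
) -> None:
    """Write the long per-service table; full precision unless rounded."""
    _maybe_round(account.to_frame(), rounding).to_csv(path, index=False)


def write_summary(
    account: ServiceAccount, path: str | Path, rounding: int | None = None
) -> None:
    _maybe_round(account.summary_frame(), rounding).to_csv(path, index=False)


def write_comparison(
    report: ComparisonReport, path: str | Path, rounding: int | None = None
) -> None:
    _maybe_round(report.to_frame(), rounding).to_csv(path, index=False)


def read_comparison(path: str | Path) -> ComparisonReport:
    """Re-read a comparison CSV into an in-memory report."""
    frame = pd.read_csv(path)
    lines = tuple(
        ComparisonLine(
            line=row.line, kind=row.kind,
            value_a=row.value_a, value_b=row.value_b,
            abs_difference=row.abs_difference,
            rel_difference=row.rel_difference,
            significance_ratio=row.significance_ratio,
            significant=bool(row.significant),
        )
        for row in frame.itertuples()
    )
    first = frame.iloc[0]
    return ComparisonReport(
        catchment=str(first["catchment"]),
        scenario_a=str(first["scenario_a"]),
        scenario_b=str(first["scenario_b"]),
        normalizer="mean",
        lines=lines,
    )


def read_account(path: str | Path) -> ServiceAccount:
    """Re-read an account CSV (as written at full precision)."""
    frame = pd.read_csv(path)
    services = tuple(
        ServiceValue(
            service_id=row.service_id, bundle=row.bundle,
            value=row.value_eur_per_ha_yr,
            flow=None if pd.isna(row.biophysical_flow)
            else float(row.biophysical_flow),
            flow_unit=None if pd.isna(row.flow_unit) else str(row.flow_unit),
        )
        for row in frame.itertuples()
    )
    bundle_sums = {
        b: sum(s.value for s in services if s.bundle == b)
        for b in ("provisioning", "regulating", "cultural")
    }
    first = frame.iloc[0]
    return ServiceAccount(
        catchment=str(first["catchment"]), scenario=str(first["scenario"]),
        services=services, bundle_sums=bundle_sums,
        tev=sum(bundle_sums.values()),
    )


# ---------------------------------------------------------------------------
# supplementary workbook importer
# ---------------------------------------------------------------------------

def import_s1_workbook(
    path: str | Path,
) -> tuple[dict[str, LandCoverState], dict[str, list[ScenarioDefinition]]]:
    """Import per-scenario land-cover tables from a supplementary workbook.

    The importer scans every sheet for a header row containing scenario
    labels (``NBP0`` … ``NBP5``) and reads the land-cover rows beneath it
    (first column: pooled class name, one column per scenario, values in
    ha).  Returns baseline land covers and per-catchment scenario lists
    (as target-fraction definitions).  Layout mismatches fail loudly with
    the sheet names found.
    """
    from openpyxl import load_workbook

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary workbook not provided: {path}"
        )
    wb = load_workbook(path, read_only=True, data_only=True)
    covers: dict[str, LandCoverState] = {}
    suites: dict[str, list[ScenarioDefinition]] = {}
    for ws in wb.worksheets:
        rows = [[c for c in row] for row in ws.iter_rows(values_only=True)]
        header_idx, scen_cols = None, {}
        for i, row in enumerate(rows):
            cols = {
                j: str(cell).strip().upper()
                for j, cell in enumerate(row)
                if isinstance(cell, str) and cell.strip().upper().startswith("NBP")
            }
            if cols:
                header_idx, scen_cols = i, cols
                break
        if header_idx is None:
            continue
        areas: dict[str, dict[str, float]] = {s: {} for s in scen_cols.values()}
        for row in rows[header_idx + 1:]:
            if not row or not isinstance(row[0], str):
                continue
            cls = row[0].strip().lower().replace(" ", "_")
            if cls not in POOLED_CLASSES:
                continue
            for j, scen in scen_cols.items():
                if j < len(row) and isinstance(row[j], (int, float)):
                    areas[scen][cls] = float(row[j])
        usable = {s: a for s, a in areas.items() if a}
        if not usable:
            continue
        baseline_label = min(usable)  # NBP0 first
        base_areas = usable[baseline_label]
        total = sum(base_areas.values())
        covers[ws.title] = LandCoverState(
            catchment_area=total,
            **{c: base_areas.get(c, 0.0) for c in POOLED_CLASSES},
        )
        suite = []
        for scen, a in sorted(usable.items()):
            scen_total = sum(a.values())
            suite.append(
                ScenarioDefinition(
                    scenario_id=scen,
                    target_fractions={
                        c: a.get(c, 0.0) / scen_total for c in POOLED_CLASSES
                    },
                )
            )
        suites[ws.title] = suite
    if not covers:
        raise InputError(
            "no sheet with scenario land-cover tables found; sheets present: "
            + ", ".join(ws.title for ws in wb.worksheets)
        )
    return covers, suites
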