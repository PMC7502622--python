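"""Service accounts, bundle aggregation and scenario comparison.

An account runs all 15 service valuations for one catchment × scenario,
sums them into the provisioning / regulating / cultural bundles and into
an approximate total economic value (TEV, € per catchment-hectare per
year).  Two accounts for the same catchment are compared line by line
with a significance screen: the relative difference of each line is
divided by the relative standard error of TEV estimates from comparable
studies (default 0.24); a ratio above 1 flags a likely significant
difference.

The comparison's normalizer is configurable (mean of the two values,
the baseline value, or their max) because "relative difference" admits
several reasonable definitions; the mean-normalized form is the default
as it is symmetric and bounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .domain import CatchmentState, ServiceParameterSet, ValidationError
from .services import BUNDLES, SERVICE_REGISTRY, ServiceValue

__all__ = [
    "ServiceAccount",
    "ComparisonLine",
    "ComparisonReport",
    "compute_account",
    "compare_scenarios",
]

Normalizer = Literal["mean", "baseline", "max"]


@dataclass(frozen=True)
class ServiceAccount:
    """The 15 per-service value flows for one catchment × scenario."""

    catchment: str
    scenario: str
    services: tuple[ServiceValue, ...]
    bundle_sums: dict[str, float]
    tev: float

    def __post_init__(self) -> None:
        ids = [s.service_id for s in self.services]
        if len(ids) != len(SERVICE_REGISTRY) or len(set(ids)) != len(ids):
            raise ValidationError(
                f"account must hold exactly {len(SERVICE_REGISTRY)} unique "
                f"services, got {len(ids)}"
            )

    def service(self, service_id: str) -> ServiceValue:
        for s in self.services:
            if s.service_id == service_id:
                return s
        raise KeyError(service_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per service."""
        return pd.DataFrame(
            {
                "catchment": self.catchment,
                "scenario": self.scenario,
                "service_id": s.service_id,
                "bundle": s.bundle,
                "biophysical_flow": s.flow,
                "flow_unit": s.flow_unit,
                "value_eur_per_ha_yr": s.value,
            }
            for s in self.services
        )

    def summary_frame(self) -> pd.DataFrame:
        """Bundle sums plus TEV, one row each."""
        rows = [
            {
                "catchment": self.catchment,
                "scenario": self.scenario,
                "line": bundle,
                "value_eur_per_ha_yr": self.bundle_sums[bundle],
            }
            for bundle in BUNDLES
        ]
        rows.append(
            {
                "catchment": self.catchment,
                "scenario": self.scenario,
                "line": "tev",
                "value_eur_per_ha_yr": self.tev,
            }
        )
        return pd.DataFrame(rows)


def compute_account(
    state: CatchmentState,
    params: ServiceParameterSet,
    scenario: str = "NBP0",
) -> ServiceAccount:
    """Evaluate all 15 services and aggregate bundles and TEV."""
    values: list[ServiceValue] = []
    for service_id, fn in SERVICE_REGISTRY.items():
        try:
            values.append(fn(state, params))
        except ValidationError as exc:
            raise ValidationError(f"service {service_id}: {exc}") from exc
    bundle_sums = {
        bundle: sum(v.value for v in values if v.bundle == bundle)
        for bundle in BUNDLES
    }
    tev = sum(bundle_sums.values())
    return ServiceAccount(
        catchment=state.name,
        scenario=scenario,
        services=tuple(values),
        bundle_sums=bundle_sums,
        tev=tev,
    )


@dataclass(frozen=True)
class ComparisonLine:
    """One compared line (a service, a bundle, or TEV)."""

    line: str
    kind: str  # "service" | "bundle" | "tev"
    value_a: float
    value_b: float
    abs_difference: float
    rel_difference: float
    significance_ratio: float
    significant: bool


@dataclass(frozen=True)
class ComparisonReport:
    """Line-by-line comparison of two accounts for one catchment."""

    catchment: str
    scenario_a: str
    scenario_b: str
    normalizer: str
    lines: tuple[ComparisonLine, ...]

    def line(self, name: str) -> ComparisonLine:
        for ln in self.lines:
            if ln.line == name:
                return ln
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "catchment": self.catchment,
                "scenario_a": self.scenario_a,
                "scenario_b": self.scenario_b,
                "line": ln.line,
                "kind": ln.kind,
                "value_a": ln.value_a,
                "value_b": ln.value_b,
                "abs_difference": ln.abs_difference,
                "rel_difference": ln.rel_difference,
                "significance_ratio": ln.significance_ratio,
                "significant": ln.significant,
            }
            for ln in self.lines
        )


def _relative_difference(a: float, b: float, normalizer: Normalizer) -> float:
    if a == 0.0 and b == 0.0:
        return 0.0  # a degenerate line is reported as no difference
    if normalizer == "mean":
        norm = (a + b) / 2.0
    elif normalizer == "baseline":
        norm = a
    elif normalizer == "max":
        norm = max(a, b)
    else:
        raise ValidationError(f"unknown normalizer {normalizer!r}")
    if norm == 0.0:
        return 0.0
    return abs(b - a) / norm


def _compare_line(
    name: str,
    kind: str,
    a: float,
    b: float,
    rse: float,
    normalizer: Normalizer,
) -> ComparisonLine:
    rel = _relative_difference(a, b, normalizer)
    ratio = rel / rse if rse > 0 else 0.0
    return ComparisonLine(
        line=name,
        kind=kind,
        value_a=a,
        value_b=b,
        abs_difference=abs(b - a),
        rel_difference=rel,
        significance_ratio=ratio,
        significant=ratio > 1.0,
    )


def compare_scenarios(
    account_a: ServiceAccount,
    account_b: ServiceAccount,
    params: ServiceParameterSet | None = None,
    normalizer: Normalizer = "mean",
) -> ComparisonReport:
    """Screen two accounts of the same catchment for likely significance.

    For every service, bundle and TEV the relative difference is divided
    by ``params.tev_relative_standard_error``; ratios above 1 are flagged
    significant.  With the default mean normalizer the report is
    symmetric in (a, b).
    """
    params = params or ServiceParameterSet()
    if account_a.catchment != account_b.catchment:
        raise ValidationError(
            "cannot compare accounts of different catchments: "
            f"{account_a.catchment!r} vs {account_b.catchment!r}"
        )
    rse = params.tev_relative_standard_error
    lines: list[ComparisonLine] = []
    for sv_a in account_a.services:
        sv_b = account_b.service(sv_a.service_id)
        lines.append(
            _compare_line(
                sv_a.service_id, "service", sv_a.value, sv_b.value, rse,
                normalizer,
            )
        )
    for bundle in BUNDLES:
        lines.append(
            _compare_line(
                bundle, "bundle",
                account_a.bundle_sums[bundle], account_b.bundle_sums[bundle],
                rse, normalizer,
            )
        )
    lines.append(
        _compare_line("tev", "tev", account_a.tev, account_b.tev, rse,
                      normalizer)
    )
    return ComparisonReport(
        catchment=account_a.catchment,
        scenario_a=account_a.scenario,
        scenario_b=account_b.scenario,
        normalizer=normalizer,
        lines=tuple(lines),
    )
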