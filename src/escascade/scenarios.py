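"""Land-use scenario engine.

A scenario (a Nordic Bioeconomy Pathway, NBP0–NBP5) is pure data: a
land-cover redistribution — either target fractions per pooled class or
additive hectare deltas — optional overrides of river metrics, and sparse
overrides of the service parameters (e.g. a higher carbon price under the
sustainability pathway).  Scenarios only move area between classes and
override parameters; land-use *intensity* is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

from .domain import (
    AREA_RTOL,
    CatchmentState,
    LandCoverState,
    POOLED_CLASSES,
    RiverMetrics,
    ServiceParameterSet,
    ValidationError,
)

__all__ = ["ScenarioDefinition", "apply_scenario", "resolve_parameters"]

_RIVER_FIELDS = tuple(f.name for f in fields(RiverMetrics))


@dataclass(frozen=True)
class ScenarioDefinition:
    """One named land-use scenario.

    Exactly one of ``target_fractions`` (summing to 1) or ``deltas_ha``
    (summing to 0) may be non-empty; an empty definition is the identity
    scenario.
    """

    scenario_id: str = "NBP0"
    target_fractions: Mapping[str, float] = field(default_factory=dict)
    deltas_ha: Mapping[str, float] = field(default_factory=dict)
    river_metric_changes: Mapping[str, float | bool] = field(
        default_factory=dict
    )
    parameter_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_fractions and self.deltas_ha:
            raise ValidationError(
                f"scenario {self.scenario_id}: give either target_fractions "
                "or deltas_ha, not both"
            )
        for mapping, kind in (
            (self.target_fractions, "target fraction"),
            (self.deltas_ha, "delta"),
        ):
            unknown = sorted(set(mapping) - set(POOLED_CLASSES))
            if unknown:
                raise ValidationError(
                    f"scenario {self.scenario_id}: unknown land-cover "
                    f"class(es) in {kind}s: {', '.join(unknown)}"
                )
        if self.target_fractions:
            total = sum(self.target_fractions.values())
            if not math.isclose(total, 1.0, rel_tol=AREA_RTOL):
                raise ValidationError(
                    f"scenario {self.scenario_id}: target fractions sum to "
                    f"{total}, expected 1"
                )
            bad = {c: v for c, v in self.target_fractions.items() if v < 0}
            if bad:
                raise ValidationError(
                    f"scenario {self.scenario_id}: negative target "
                    f"fraction(s): {bad}"
                )
        unknown_river = sorted(
            set(self.river_metric_changes) - set(_RIVER_FIELDS)
        )
        if unknown_river:
            raise ValidationError(
                f"scenario {self.scenario_id}: unknown river metric(s): "
                f"{', '.join(unknown_river)}"
            )

    @property
    def is_identity(self) -> bool:
        return not (
            self.target_fractions
            or self.deltas_ha
            or self.river_metric_changes
            or self.parameter_overrides
        )


def _apply_land_cover(
    baseline: LandCoverState, scenario: ScenarioDefinition
) -> LandCoverState:
    area = baseline.catchment_area
    if scenario.target_fractions:
        new_areas = {
            cls: scenario.target_fractions.get(cls, 0.0) * area
            for cls in POOLED_CLASSES
        }
        # renormalize the sub-ppm rounding slack so total area is exact
        total = sum(new_areas.values())
        new_areas = {cls: a * area / total for cls, a in new_areas.items()}
        return LandCoverState(catchment_area=area, **new_areas)
    if scenario.deltas_ha:
        delta_sum = sum(scenario.deltas_ha.values())
        if not math.isclose(delta_sum, 0.0, abs_tol=AREA_RTOL * area):
            raise ValidationError(
                f"scenario {scenario.scenario_id}: hectare deltas sum to "
                f"{delta_sum}, expected 0 (within {AREA_RTOL} of area)"
            )
        new_areas = {}
        for cls in POOLED_CLASSES:
            new = getattr(baseline, cls) + scenario.deltas_ha.get(cls, 0.0)
            if new < 0:
                shortfall = -new
                raise ValidationError(
                    f"scenario {scenario.scenario_id}: delta drives "
                    f"{cls} negative by {shortfall:g} ha"
                )
            new_areas[cls] = new
        return LandCoverState(catchment_area=area, **new_areas)
    return baseline


def apply_scenario(
    baseline: CatchmentState, scenario: ScenarioDefinition
) -> CatchmentState:
    """Project a baseline catchment to the scenario's 2050 state.

    Total area is conserved; classes and river metrics the scenario does
    not mention are unchanged.  Raises :class:`ValidationError` if a delta
    drives a class negative or the redistribution is inconsistent.
    """
    land_cover = _apply_land_cover(baseline.land_cover, scenario)
    river = baseline.river
    if scenario.river_metric_changes:
        river = replace(river, **dict(scenario.river_metric_changes))
    return CatchmentState(
        name=baseline.name,
        land_cover=land_cover,
        river=river,
        beneficiaries=baseline.beneficiaries,
    )


def resolve_parameters(
    base: ServiceParameterSet, scenario: ScenarioDefinition
) -> ServiceParameterSet:
    """Apply a scenario's sparse parameter overrides to a base set."""
    if not scenario.parameter_overrides:
        return base
    return base.replace(**dict(scenario.parameter_overrides))
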