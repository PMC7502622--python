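"""Seeded synthetic catchments and scenario suites.

Two archetypes emulate the contrast between the study landscapes the
framework was designed around: ``cropland_small``, a small first-order
catchment dominated by intensive cropland that drains directly to the
sea (so no downstream flood damage, no hydropower, no drinking-water
extraction), and ``forest_large``, a large, mainly forest-covered
catchment with hydropower generation (9 GWh yr⁻¹), surface drinking
water (2700 m³ day⁻¹) and an upstream floodplain.  A ``custom``
archetype draws land cover from user-supplied Dirichlet weights.

All randomness flows from a single integer seed; a fixed seed gives a
bit-identical catchment.  The generated states are valid by
construction (they pass every domain invariant) and every generated
scenario is applicable to its state without driving a class negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .domain import (
    BeneficiaryProfile,
    CatchmentState,
    CorridorShares,
    LandCoverState,
    POOLED_CLASSES,
    RiverMetrics,
    ValidationError,
)
from .scenarios import ScenarioDefinition

__all__ = ["ArchetypeSpec", "generate_catchment", "generate_scenario_suite"]

ARCHETYPES = ("cropland_small", "forest_large", "custom")

_DEFAULT_AREAS = {"cropland_small": 470.0, "forest_large": 150_000.0,
                  "custom": 10_000.0}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one synthetic catchment."""

    archetype: str = "cropland_small"
    catchment_area: float | None = None  # ha; archetype default if None
    class_weights: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(
                f"unknown archetype {self.archetype!r}; "
                f"expected one of {ARCHETYPES}"
            )
        if self.catchment_area is not None and self.catchment_area <= 0:
            raise ValidationError("catchment_area must be > 0")
        if self.class_weights:
            unknown = sorted(set(self.class_weights) - set(POOLED_CLASSES))
            if unknown:
                raise ValidationError(
                    f"unknown class(es) in weights: {', '.join(unknown)}"
                )
            if any(w < 0 for w in self.class_weights.values()):
                raise ValidationError("class weights must be >= 0")
            if not any(w > 0 for w in self.class_weights.values()):
                raise ValidationError("class weights must not all be zero")
        elif self.archetype == "custom":
            raise ValidationError("custom archetype requires class_weights")

    @property
    def area(self) -> float:
        if self.catchment_area is not None:
            return self.catchment_area
        return _DEFAULT_AREAS[self.archetype]


def _split_residual(
    rng: np.random.Generator,
    residual: float,
    classes: tuple[str, ...],
    weights: tuple[float, ...],
) -> dict[str, float]:
    shares = rng.dirichlet(weights)
    return {cls: residual * s for cls, s in zip(classes, shares)}


def _cropland_small_cover(
    rng: np.random.Generator, area: float
) -> LandCoverState:
    crop_frac = rng.uniform(0.65, 0.80)
    rest = _split_residual(
        rng,
        1.0 - crop_frac,
        ("grassland", "coniferous_forest", "deciduous_forest",
         "riparian_woodland", "wetland", "built_up", "open_water", "other"),
        (4.0, 0.5, 2.0, 0.5, 1.0, 2.0, 0.3, 2.0),
    )
    fracs = {"cropland": crop_frac, **rest}
    return LandCoverState(
        catchment_area=area,
        **{cls: frac * area for cls, frac in fracs.items()},
    )


def _forest_large_cover(
    rng: np.random.Generator, area: float
) -> LandCoverState:
    forest_frac = rng.uniform(0.55, 0.75)
    conif_share = rng.uniform(0.6, 0.8)
    rest = _split_residual(
        rng,
        1.0 - forest_frac,
        ("cropland", "grassland", "riparian_woodland", "wetland",
         "built_up", "open_water", "other"),
        (3.0, 1.5, 0.3, 1.5, 0.7, 2.0, 0.6),
    )
    fracs = {
        "coniferous_forest": forest_frac * conif_share,
        "deciduous_forest": forest_frac * (1.0 - conif_share),
        **rest,
    }
    return LandCoverState(
        catchment_area=area,
        **{cls: frac * area for cls, frac in fracs.items()},
    )


def _custom_cover(
    rng: np.random.Generator, area: float, weights: Mapping[str, float]
) -> LandCoverState:
    classes = tuple(c for c in POOLED_CLASSES if weights.get(c, 0.0) > 0)
    shares = rng.dirichlet(tuple(weights[c] for c in classes))
    areas = {c: 0.0 for c in POOLED_CLASSES}
    for cls, s in zip(classes, shares):
        areas[cls] = s * area
    return LandCoverState(catchment_area=area, **areas)


def generate_catchment(spec: ArchetypeSpec) -> CatchmentState:
    """Draw one valid synthetic catchment from an archetype recipe."""
    rng = np.random.default_rng(spec.seed)
    area = spec.area
    if spec.archetype == "cropland_small":
        land_cover = _cropland_small_cover(rng, area)
        river = RiverMetrics(
            main_river_length=rng.uniform(3.0, 8.0),
            shaded_fraction=round(rng.uniform(0.0, 0.3), 3),
            riparian_fraction=rng.uniform(0.05, 0.30),
            floodplain_area=0.0,
            corridor_shares=CorridorShares(
                built_up=0.02, agricultural=0.90, woodland=0.08
            ),
            discharges_directly_to_sea=True,
            hydropower_generation=0.0,
            drinking_water_extraction=0.0,
            flood_p_sedimentation=0.0,
        )
        households = float(rng.integers(300, 800))
        beneficiaries = BeneficiaryProfile(
            households=households,
            angler_household_fraction=0.1,
            resident_visits_value_base=households * rng.uniform(1.0, 3.0),
            tourist_visitors=float(rng.integers(500, 3000)),
            wtp_resident=10.0,
            wtp_tourist=20.0,
            wtp_biodiversity_household=5.0,
            conservation_household_fraction=rng.uniform(0.3, 0.7),
        )
        name = f"cropland_small_{spec.seed}"
    elif spec.archetype == "forest_large":
        land_cover = _forest_large_cover(rng, area)
        river = RiverMetrics(
            main_river_length=rng.uniform(80.0, 150.0),
            shaded_fraction=round(rng.uniform(0.4, 0.8), 3),
            riparian_fraction=rng.uniform(0.3, 0.7),
            floodplain_area=rng.uniform(100.0, 400.0),
            corridor_shares=CorridorShares(
                built_up=0.05, agricultural=0.45, woodland=0.50
            ),
            discharges_directly_to_sea=False,
            hydropower_generation=9.0e6,
            drinking_water_extraction=2700.0,
            flood_p_sedimentation=500.0,
        )
        households = float(rng.integers(10_000, 18_000))
        beneficiaries = BeneficiaryProfile(
            households=households,
            angler_household_fraction=0.1,
            resident_visits_value_base=households * rng.uniform(1.0, 2.0),
            tourist_visitors=float(rng.integers(10_000, 50_000)),
            wtp_resident=10.0,
            wtp_tourist=20.0,
            wtp_biodiversity_household=5.0,
            conservation_household_fraction=rng.uniform(0.3, 0.7),
        )
        name = f"forest_large_{spec.seed}"
    else:  # custom
        land_cover = _custom_cover(rng, area, spec.class_weights)
        river = RiverMetrics(
            main_river_length=rng.uniform(5.0, 50.0),
            shaded_fraction=round(rng.uniform(0.0, 1.0), 3),
            riparian_fraction=rng.uniform(0.0, 1.0),
            floodplain_area=rng.uniform(0.0, 0.01) * area,
            corridor_shares=CorridorShares(
                built_up=0.1, agricultural=0.5, woodland=0.4
            ),
            discharges_directly_to_sea=bool(rng.integers(0, 2)),
            hydropower_generation=float(rng.uniform(0.0, 1.0e7)),
            drinking_water_extraction=float(rng.uniform(0.0, 3000.0)),
            flood_p_sedimentation=float(rng.uniform(0.0, 1000.0)),
        )
        households = float(rng.integers(100, 20_000))
        beneficiaries = BeneficiaryProfile(
            households=households,
            angler_household_fraction=rng.uniform(0.0, 0.3),
            resident_visits_value_base=households * rng.uniform(0.0, 3.0),
            tourist_visitors=float(rng.integers(0, 50_000)),
            wtp_resident=rng.uniform(0.0, 30.0),
            wtp_tourist=rng.uniform(0.0, 50.0),
            wtp_biodiversity_household=rng.uniform(0.0, 20.0),
            conservation_household_fraction=rng.uniform(0.0, 1.0),
        )
        name = f"custom_{spec.seed}"
    return CatchmentState(
        name=name, land_cover=land_cover, river=river,
        beneficiaries=beneficiaries,
    )


def _move(
    sources: Mapping[str, float], sinks: Mapping[str, float]
) -> dict[str, float]:
    """Deltas taking the source amounts and distributing them to sinks."""
    total = sum(sources.values())
    deltas = {
        cls: -float(amount) for cls, amount in sources.items() if amount > 0
    }
    for cls, share in sinks.items():
        deltas[cls] = float(deltas.get(cls, 0.0) + total * share)
    return deltas


def generate_scenario_suite(
    state: CatchmentState, seed: int = 0
) -> list[ScenarioDefinition]:
    """Stylized NBP0–NBP5 scenario suite for one catchment.

    NBP0 is the identity baseline.  NBP1 (sustainability / circular)
    diversifies: at least 10% of the cropland and production-forest area
    moves toward grassland, riparian woodland and wetland, riparian
    cover and shading rise, and the carbon price is overridden to
    20 € t C⁻¹.  NBP2 is near-baseline; NBP3 and NBP5 intensify toward
    cropland and coniferous production forest; NBP4 urbanizes at the
    field margin.  Move fractions carry a small seeded jitter so suites
    differ between draws while remaining valid by construction.
    """
    rng = np.random.default_rng(seed)
    lc = state.land_cover
    jitter = lambda base: float(base * rng.uniform(0.9, 1.1))  # noqa: E731

    nbp0 = ScenarioDefinition(scenario_id="NBP0")

    nbp1 = ScenarioDefinition(
        scenario_id="NBP1",
        deltas_ha=_move(
            {
                "cropland": jitter(0.20) * lc.cropland,
                "coniferous_forest": jitter(0.12) * lc.coniferous_forest,
            },
            {"grassland": 0.4, "riparian_woodland": 0.3, "wetland": 0.3},
        ),
        river_metric_changes={
            "riparian_fraction": float(min(1.0, state.river.riparian_fraction + 0.2)),
            "shaded_fraction": float(min(1.0, state.river.shaded_fraction + 0.1)),
        },
        parameter_overrides={"carbon_price": 20.0},
    )

    nbp2 = ScenarioDefinition(
        scenario_id="NBP2",
        deltas_ha=_move(
            {"cropland": jitter(0.02) * lc.cropland},
            {"grassland": 1.0},
        ),
    )

    nbp3 = ScenarioDefinition(
        scenario_id="NBP3",
        deltas_ha=_move(
            {
                "grassland": jitter(0.30) * lc.grassland,
                "wetland": jitter(0.50) * lc.wetland,
                "deciduous_forest": jitter(0.20) * lc.deciduous_forest,
            },
            {"cropland": 0.6, "coniferous_forest": 0.4},
        ),
    )

    nbp4 = ScenarioDefinition(
        scenario_id="NBP4",
        deltas_ha=_move(
            {
                "cropland": jitter(0.05) * lc.cropland,
                "grassland": jitter(0.05) * lc.grassland,
            },
            {"built_up": 1.0},
        ),
    )

    nbp5 = ScenarioDefinition(
        scenario_id="NBP5",
        deltas_ha=_move(
            {
                "grassland": jitter(0.40) * lc.grassland,
                "wetland": jitter(0.60) * lc.wetland,
                "deciduous_forest": jitter(0.30) * lc.deciduous_forest,
                "riparian_woodland": jitter(0.20) * lc.riparian_woodland,
            },
            {"cropland": 0.55, "coniferous_forest": 0.45},
        ),
        river_metric_changes={
            "riparian_fraction": float(max(0.0, state.river.riparian_fraction - 0.1)),
        },
    )

    return [nbp0, nbp1, nbp2, nbp3, nbp4, nbp5]
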