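"""Typed representation of a catchment's ecosystem structure.

A catchment enters the valuation cascade as three pieces of structure:

* pooled CORINE land cover (tabulated areas in hectares, no geometry),
* river and corridor metrics (length, shading, riparian cover, floodplain),
* a beneficiary profile (households, anglers, visitors and their
  willingness to pay).

Alongside these sits :class:`ServiceParameterSet`, the full ledger of unit
values, rates and knowledge-rule thresholds used by the 15 service
valuations.  Every numeric constant any service operation needs lives
there, so a scenario can override it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Tuple

__all__ = [
    "ValidationError",
    "POOLED_CLASSES",
    "DEFAULT_CORINE_POOLING",
    "LandCoverState",
    "CorridorShares",
    "RiverMetrics",
    "BeneficiaryProfile",
    "ServiceParameterSet",
    "CatchmentState",
    "pool_corine",
    "fractions",
]

#: Relative tolerance for area bookkeeping checks.
AREA_RTOL = 1e-6


class ValidationError(ValueError):
    """An input violates a domain invariant."""


#: The pooled working land-use classes, in canonical order.
POOLED_CLASSES: Tuple[str, ...] = (
    "cropland",
    "grassland",
    "coniferous_forest",
    "deciduous_forest",
    "riparian_woodland",
    "wetland",
    "built_up",
    "open_water",
    "other",
)

# Default pooling of CORINE level-3 codes into the working classes.
# Mixed forest (313) is pooled with deciduous so its carbon uses the more
# conservative deciduous sequestration rate.  Riparian woodland is not a
# CORINE class: it is supplied directly as an area plus a river-length
# fraction, because the valuation treats it by river length, not polygons.
DEFAULT_CORINE_POOLING: Mapping[int, str] = {
    # arable land
    211: "cropland", 212: "cropland", 213: "cropland",
    # pastures and natural grassland
    231: "grassland", 321: "grassland",
    # forest
    312: "coniferous_forest",
    311: "deciduous_forest", 313: "deciduous_forest",
    # wetlands
    411: "wetland", 412: "wetland",
    # artificial surfaces
    111: "built_up", 112: "built_up", 121: "built_up",
    # water bodies
    511: "open_water", 512: "open_water",
    # remaining common level-3 codes -> other
    122: "other", 123: "other", 124: "other", 131: "other", 132: "other",
    133: "other", 141: "other", 142: "other", 221: "other", 222: "other",
    241: "other", 242: "other", 243: "other", 244: "other", 322: "other",
    323: "other", 324: "other", 331: "other", 332: "other", 333: "other",
    334: "other", 335: "other", 421: "other", 422: "other", 423: "other",
    521: "other", 522: "other", 523: "other",
}


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class LandCoverState:
    """Pooled land-cover areas for one catchment, in hectares.

    Class areas must sum to ``catchment_area`` within a relative
    tolerance of 1e-6.
    """

    catchment_area: float
    cropland: float = 0.0
    grassland: float = 0.0
    coniferous_forest: float = 0.0
    deciduous_forest: float = 0.0
    riparian_woodland: float = 0.0
    wetland: float = 0.0
    built_up: float = 0.0
    open_water: float = 0.0
    other: float = 0.0

    def __post_init__(self) -> None:
        if self.catchment_area <= 0:
            raise ValidationError(
                f"catchment_area must be > 0, got {self.catchment_area}"
            )
        for cls in POOLED_CLASSES:
            _check_nonneg(f"area of {cls}", getattr(self, cls))
        total = sum(getattr(self, cls) for cls in POOLED_CLASSES)
        if not math.isclose(total, self.catchment_area, rel_tol=AREA_RTOL):
            raise ValidationError(
                f"class areas sum to {total} ha but catchment_area is "
                f"{self.catchment_area} ha (relative tolerance {AREA_RTOL})"
            )

    def areas(self) -> dict[str, float]:
        """Areas by pooled class, in canonical order."""
        return {cls: getattr(self, cls) for cls in POOLED_CLASSES}

    @property
    def forest_area(self) -> float:
        """Forest in the timber/scenic sense: coniferous + deciduous, ha."""
        return self.coniferous_forest + self.deciduous_forest

    @property
    def woodland_area(self) -> float:
        """Woodland in the knowledge-rule sense: forest + riparian, ha."""
        return self.forest_area + self.riparian_woodland


def fractions(state: LandCoverState) -> dict[str, float]:
    """Land-cover fractions by pooled class (each in [0,1], summing to 1)."""
    if state.catchment_area <= 0:
        raise ValidationError("cannot take fractions of a zero-area catchment")
    return {cls: a / state.catchment_area for cls, a in state.areas().items()}


def pool_corine(
    raw_cover: Iterable[Tuple[int, float]],
    pooling_table: Mapping[int, str] | None = None,
) -> LandCoverState:
    """Pool raw CORINE (code, area-ha) records into a :class:`LandCoverState`.

    Duplicate codes accumulate; the catchment area is the total raw area.
    Raises :class:`ValidationError` for an unknown code, a negative area,
    or empty input.
    """
    table = DEFAULT_CORINE_POOLING if pooling_table is None else pooling_table
    records = list(raw_cover)
    if not records:
        raise ValidationError("empty CORINE cover: no (code, area) records")
    pooled = {cls: 0.0 for cls in POOLED_CLASSES}
    for code, area in records:
        if area < 0:
            raise ValidationError(f"negative area {area} for CORINE code {code}")
        if code not in table:
            raise ValidationError(f"unknown CORINE code {code}")
        target = table[code]
        if target not in pooled:
            raise ValidationError(
                f"pooling table maps code {code} to unknown class {target!r}"
            )
        pooled[target] += area
    total = sum(pooled.values())
    if total <= 0:
        raise ValidationError("total CORINE area is zero")
    return LandCoverState(catchment_area=total, **pooled)


@dataclass(frozen=True)
class CorridorShares:
    """Land-use shares over the river corridor (must sum to 1)."""

    built_up: float = 0.0
    agricultural: float = 0.0
    woodland: float = 0.0

    def __post_init__(self) -> None:
        for name in ("built_up", "agricultural", "woodland"):
            _check_fraction(f"corridor share {name}", getattr(self, name))
        total = self.built_up + self.agricultural + self.woodland
        if not math.isclose(total, 1.0, rel_tol=AREA_RTOL, abs_tol=AREA_RTOL):
            raise ValidationError(
                f"corridor shares must sum to 1, got {total}"
            )


@dataclass(frozen=True)
class RiverMetrics:
    """River and corridor metrics for one catchment.

    ``flood_p_sedimentation`` is the phosphorus settled on the floodplain
    during flood passage, normalized to kg P per year.
    """

    main_river_length: float = 0.0  # km
    shaded_fraction: float = 0.0
    riparian_fraction: float = 0.0
    floodplain_area: float = 0.0  # ha
    corridor_shares: CorridorShares = field(
        default_factory=lambda: CorridorShares(0.0, 0.0, 1.0)
    )
    discharges_directly_to_sea: bool = False
    hydropower_generation: float = 0.0  # kWh / yr
    drinking_water_extraction: float = 0.0  # m^3 / day
    flood_p_sedimentation: float = 0.0  # kg P / yr

    def __post_init__(self) -> None:
        _check_nonneg("main_river_length", self.main_river_length)
        _check_fraction("shaded_fraction", self.shaded_fraction)
        _check_fraction("riparian_fraction", self.riparian_fraction)
        _check_nonneg("floodplain_area", self.floodplain_area)
        _check_nonneg("hydropower_generation", self.hydropower_generation)
        _check_nonneg(
            "drinking_water_extraction", self.drinking_water_extraction
        )
        _check_nonneg("flood_p_sedimentation", self.flood_p_sedimentation)


@dataclass(frozen=True)
class BeneficiaryProfile:
    """Who benefits, and what they are willing to pay.

    WTP rates are € per year per beneficiary; the angling default is the
    conservative reported rate of 275 € per angler per year.
    """

    households: float = 0.0
    angler_household_fraction: float = 0.0
    resident_visits_value_base: float = 0.0  # resident users / yr
    tourist_visitors: float = 0.0  # visitors / yr
    wtp_angler: float = 275.0
    wtp_resident: float = 0.0
    wtp_tourist: float = 0.0
    wtp_biodiversity_household: float = 0.0
    conservation_household_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("households", "resident_visits_value_base",
                     "tourist_visitors"):
            _check_nonneg(name, getattr(self, name))
        for name in ("angler_household_fraction",
                     "conservation_household_fraction"):
            _check_fraction(name, getattr(self, name))
        for name in ("wtp_angler", "wtp_resident", "wtp_tourist",
                     "wtp_biodiversity_household"):
            _check_nonneg(name, getattr(self, name))


# parameter-name groups used for invariant checking
_FRACTION_PARAMS = frozenset({
    "game_share", "flood_depth_factor", "pest_woodland_threshold",
    "pest_reduced_productivity", "shade_threshold", "residual_trout_survival",
    "scenic_low_forest_threshold", "scenic_high_forest_threshold",
    "scenic_low_appreciation", "scenic_high_appreciation",
})
_OPEN_UNIT_INTERVAL_PARAMS = frozenset({
    "pest_woodland_threshold", "shade_threshold",
    "scenic_low_forest_threshold", "scenic_high_forest_threshold",
})


@dataclass(frozen=True)
class ServiceParameterSet:
    """Every unit value, rate and threshold used by the service valuations.

    Defaults are the published benchmark values (approximately 2010 euros);
    any field can be overridden per scenario, e.g. the carbon price rises
    from 5 to 20 € per t C under the sustainability pathway.
    """

    # provisioning unit values
    crop_revenue: float = 400.0          # € / ha cropland / yr
    dairy_revenue: float = 500.0         # € / ha grassland / yr
    timber_annuity: float = 200.0        # € / ha forest / yr
    wild_products_rate: float = 24.0     # € / ha woodland / yr
    game_share: float = 0.8              # share of wild products due to game
    electricity_price: float = 0.05      # € / kWh (half median consumer price)
    water_price: float = 0.5             # € / m^3 (half consumer price)
    # regulating rates and prices
    c_seq_coniferous: float = 6.0        # t C / ha / yr
    c_seq_deciduous: float = 5.0         # t C / ha / yr
    c_seq_riparian: float = 4.0          # t C / ha / yr
    carbon_price: float = 5.0            # € / t C
    p_price: float = 1.1322              # € / kg P (fertilizer market)
    erodible_p_grassland: float = 1.0    # kg P / ha / yr
    erodible_p_cropland: float = 2.0     # kg P / ha / yr
    flood_damage_built: float = 252.0    # € / m^2
    flood_damage_agri: float = 7.0       # € / m^2
    flood_damage_wood: float = 1.0       # € / m^2
    flood_depth_factor: float = 0.2      # flood-wave height adjustment
    flood_annualization: float = 0.01    # 1/100-yr flood -> annual rate
    instream_p_retention: float = 10.0   # kg P / km river / yr
    # knowledge-rule thresholds and factors
    pest_woodland_threshold: float = 0.25
    pest_reduced_productivity: float = 0.8
    shade_threshold: float = 0.5
    residual_trout_survival: float = 0.1
    scenic_low_forest_threshold: float = 0.2
    scenic_high_forest_threshold: float = 0.7
    scenic_low_appreciation: float = 0.6
    scenic_high_appreciation: float = 0.8
    # significance screen
    tev_relative_standard_error: float = 0.24

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            _check_nonneg(f.name, value)
            if f.name in _FRACTION_PARAMS:
                _check_fraction(f.name, value)
            if f.name in _OPEN_UNIT_INTERVAL_PARAMS and not 0 < value < 1:
                raise ValidationError(
                    f"{f.name} must be strictly inside (0, 1), got {value}"
                )

    @classmethod
    def parameter_names(cls) -> Tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def replace(self, **overrides: float) -> "ServiceParameterSet":
        """Return a copy with ``overrides`` applied; unknown names error."""
        known = set(self.parameter_names())
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ValidationError(
                f"unknown parameter name(s): {', '.join(unknown)}"
            )
        return replace(self, **overrides)


@dataclass(frozen=True)
class CatchmentState:
    """A catchment's full ecosystem structure at one point in time."""

    name: str
    land_cover: LandCoverState
    river: RiverMetrics
    beneficiaries: BeneficiaryProfile

    def __post_init__(self) -> None:
        if self.land_cover.riparian_woodland > self.land_cover.catchment_area:
            raise ValidationError(
                "riparian_woodland area exceeds catchment_area"
            )
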