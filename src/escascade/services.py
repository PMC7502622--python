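"""The 15 ecosystem-service valuations.

Each operation maps a :class:`~escascade.domain.CatchmentState` plus a
:class:`~escascade.domain.ServiceParameterSet` to a monetary value flow in
€ per catchment-hectare per year, normalizing by the whole catchment area
so that services of very different spatial footprint are comparable and
additive.  Where the service has a natural biophysical flow (kg P, t C,
kWh, m³) that flow is reported alongside the euro value.

Three services are threshold "knowledge rules" rather than linear
lookups — pest control via woodland cover, trout survival via riparian
shading, and scenic appreciation via forest cover.  They are exposed as
standalone functions so they can be inspected and tested on their own.

Double-counting guards: pest control and riparian shading act as
modulations of another service (crops, angling).  The provisioning and
cultural lines carry the modulated totals; the regulating lines report
only the increment attributable to the woodland or shade — the avoided
crop loss, and the angling value above the residual-survival floor — so
that the total economic value stays additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from .domain import (
    CatchmentState,
    ServiceParameterSet,
    ValidationError,
    fractions,
)

__all__ = [
    "ServiceValue",
    "BUNDLES",
    "SERVICE_REGISTRY",
    "SERVICE_IDS",
    "pest_modulation_factor",
    "trout_survival",
    "scenic_appreciation",
    "crops_value",
    "dairy_value",
    "timber_value",
    "wild_products_value",
    "hydropower_value",
    "drinking_water_value",
    "carbon_value",
    "erosion_control_value",
    "flood_prevention_value",
    "pest_regulation_value",
    "nutrient_retention_value",
    "temperature_regulation_value",
    "angling_value",
    "recreation_value",
    "biodiversity_nonuse_value",
]

BUNDLES = ("provisioning", "regulating", "cultural")

M2_PER_HA = 10_000.0
DAYS_PER_YEAR = 365.0  # convention; leap years ignored


@dataclass(frozen=True)
class ServiceValue:
    """One service's annual flow for one catchment.

    ``value`` is € per catchment-hectare per year.  ``flow``/``flow_unit``
    carry the biophysical flow where one is defined (pure willingness-to-pay
    services have none).
    """

    service_id: str
    bundle: str
    value: float
    flow: Optional[float] = None
    flow_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bundle not in BUNDLES:
            raise ValidationError(f"unknown bundle {self.bundle!r}")
        if self.value < 0:
            raise ValidationError(
                f"service {self.service_id}: negative value {self.value}"
            )


# ---------------------------------------------------------------------------
# knowledge rules
# ---------------------------------------------------------------------------

def pest_modulation_factor(
    woodland_fraction: float,
    params: ServiceParameterSet | None = None,
) -> float:
    """Crop-productivity factor from woodland-borne pest control.

    Below the woodland-cover threshold (default 25%, strict) crop
    productivity drops to the reduced factor (default 80%); at or above
    the threshold it is 1.0.
    """
    params = params or ServiceParameterSet()
    if not 0.0 <= woodland_fraction <= 1.0:
        raise ValidationError(
            f"woodland_fraction must be in [0, 1], got {woodland_fraction}"
        )
    if woodland_fraction < params.pest_woodland_threshold:
        return params.pest_reduced_productivity
    return 1.0


def trout_survival(
    shaded_fraction: float,
    params: ServiceParameterSet | None = None,
) -> float:
    """Trout survival fraction as a function of riparian shading.

    Full survival once at least half the main river length is shaded
    (default threshold 0.5).  Below the threshold survival declines
    stepwise — the shaded fraction is floored to 0.1 steps, then survival
    interpolates linearly from the residual (default 10%) at zero shade up
    to 1.0 at the threshold.  Never drops below the residual.
    """
    params = params or ServiceParameterSet()
    if not 0.0 <= shaded_fraction <= 1.0:
        raise ValidationError(
            f"shaded_fraction must be in [0, 1], got {shaded_fraction}"
        )
    if shaded_fraction >= params.shade_threshold:
        return 1.0
    residual = params.residual_trout_survival
    # floor to 0.1 steps; the epsilon guards against 0.3 -> 0.2999...
    stepped = math.floor(shaded_fraction * 10 + 1e-9) / 10.0
    survival = residual + (1.0 - residual) * (stepped / params.shade_threshold)
    return min(1.0, max(residual, survival))


def scenic_appreciation(
    forest_fraction: float,
    params: ServiceParameterSet | None = None,
) -> float:
    """Tourist appreciation factor of the landscape's forest cover.

    Drops to 60% when forest cover falls below 20% (strict), to 80% when
    it rises above 70% (strict); full appreciation in between.
    """
    params = params or ServiceParameterSet()
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValidationError(
            f"forest_fraction must be in [0, 1], got {forest_fraction}"
        )
    if forest_fraction < params.scenic_low_forest_threshold:
        return params.scenic_low_appreciation
    if forest_fraction > params.scenic_high_forest_threshold:
        return params.scenic_high_appreciation
    return 1.0


# ---------------------------------------------------------------------------
# provisioning services
# ---------------------------------------------------------------------------

def _woodland_fraction(state: CatchmentState) -> float:
    return state.land_cover.woodland_area / state.land_cover.catchment_area


def _forest_fraction(state: CatchmentState) -> float:
    return state.land_cover.forest_area / state.land_cover.catchment_area


def crops_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Crops (CICES 1.1.1.1): net farmgate revenue of arable land.

    Carries the pest-modulated total; the unmodulated/modulated difference
    is credited to pest regulation.
    """
    lc = state.land_cover
    factor = pest_modulation_factor(_woodland_fraction(state), params)
    value = params.crop_revenue * lc.cropland * factor / lc.catchment_area
    return ServiceValue("crops", "provisioning", value)


def dairy_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Dairy, meat, hides, fleece (1.1.3.1/1.1.3.2): grassland revenue."""
    lc = state.land_cover
    value = params.dairy_revenue * lc.grassland / lc.catchment_area
    return ServiceValue("dairy", "provisioning", value)


def timber_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Timber (1.1.5.2): annualized net present value of forest."""
    lc = state.land_cover
    value = params.timber_annuity * lc.forest_area / lc.catchment_area
    return ServiceValue("timber", "provisioning", value)


def wild_products_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Berries, mushrooms and game (1.1.5.1/1.1.6.1).

    The biophysical flow reported is the game component (default 80% of
    the woodland rate).
    """
    lc = state.land_cover
    value = params.wild_products_rate * lc.woodland_area / lc.catchment_area
    return ServiceValue(
        "wild_products", "provisioning", value,
        flow=params.game_share * value, flow_unit="EUR/ha/yr (game share)",
    )


def hydropower_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Hydropower (4.2.1.3): reported generation at half median price."""
    gen = state.river.hydropower_generation
    value = gen * params.electricity_price / state.land_cover.catchment_area
    return ServiceValue(
        "hydropower", "provisioning", value, flow=gen, flow_unit="kWh/yr"
    )


def drinking_water_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Drinking water (4.2.1.1): surface-water extraction at half price."""
    annual_m3 = state.river.drinking_water_extraction * DAYS_PER_YEAR
    value = annual_m3 * params.water_price / state.land_cover.catchment_area
    return ServiceValue(
        "drinking_water", "provisioning", value,
        flow=annual_m3, flow_unit="m3/yr",
    )


# ---------------------------------------------------------------------------
# regulating services
# ---------------------------------------------------------------------------

def carbon_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Greenhouse-gas reduction (2.2.6.1): woodland carbon sequestration."""
    lc = state.land_cover
    flow = (
        params.c_seq_coniferous * lc.coniferous_forest
        + params.c_seq_deciduous * lc.deciduous_forest
        + params.c_seq_riparian * lc.riparian_woodland
    )  # t C / yr
    value = flow * params.carbon_price / lc.catchment_area
    return ServiceValue(
        "carbon_sequestration", "regulating", value,
        flow=flow, flow_unit="t C/yr",
    )


def erosion_control_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Erosion control (2.2.1.1/2.2.1.2): riparian retention of erodible P.

    The potential P load from grassland and cropland is retained in
    proportion to the riparian-woodland fraction of river length; at
    fraction 1 the whole potential load is retained.
    """
    lc = state.land_cover
    potential = (
        params.erodible_p_grassland * lc.grassland
        + params.erodible_p_cropland * lc.cropland
    )  # kg P / yr
    retained = state.river.riparian_fraction * potential
    value = retained * params.p_price / lc.catchment_area
    return ServiceValue(
        "erosion_control", "regulating", value,
        flow=retained, flow_unit="kg P/yr",
    )


def flood_prevention_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Flood prevention (2.2.1.3): damage avoided by upstream flooding.

    One flooded upstream reach is assumed to spare a median downstream
    reach of equal area; damages follow the corridor land-use mix,
    adjusted for flood-wave height and annualized as a 1/100-yr event.
    Zero for catchments discharging directly to the sea (no downstream
    reach to protect).
    """
    river = state.river
    if river.discharges_directly_to_sea or river.floodplain_area == 0:
        return ServiceValue("flood_prevention", "regulating", 0.0)
    shares = river.corridor_shares
    damage_per_m2 = (
        shares.built_up * params.flood_damage_built
        + shares.agricultural * params.flood_damage_agri
        + shares.woodland * params.flood_damage_wood
    )
    avoided = (
        river.floodplain_area * M2_PER_HA * damage_per_m2
        * params.flood_depth_factor * params.flood_annualization
    )  # € / yr
    value = avoided / state.land_cover.catchment_area
    return ServiceValue("flood_prevention", "regulating", value)


def pest_regulation_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Pest regulation (2.2.3.1/2.2.3.2): avoided crop loss from woodland.

    Credits only the increment over the degraded floor — the 20% crop
    loss avoided when woodland cover meets the threshold — so the euro is
    not counted both here and under crops.
    """
    lc = state.land_cover
    factor = pest_modulation_factor(_woodland_fraction(state), params)
    increment = factor - params.pest_reduced_productivity
    value = params.crop_revenue * lc.cropland * increment / lc.catchment_area
    return ServiceValue("pest_regulation", "regulating", value)


def nutrient_retention_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Nutrient retention (2.2.5.1): in-stream + floodplain P retention."""
    river = state.river
    retained = (
        params.instream_p_retention * river.main_river_length
        + river.flood_p_sedimentation
    )  # kg P / yr
    value = retained * params.p_price / state.land_cover.catchment_area
    return ServiceValue(
        "nutrient_retention", "regulating", value,
        flow=retained, flow_unit="kg P/yr",
    )


def temperature_regulation_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Water temperature regulation (2.2.6.2): shading keeps trout alive.

    Credits the angling value above the residual-survival floor — the
    part attributable to riparian shade; angling itself carries the
    survival-modulated total.
    """
    ben = state.beneficiaries
    survival = trout_survival(state.river.shaded_fraction, params)
    anglers = ben.households * ben.angler_household_fraction
    increment = survival - params.residual_trout_survival
    value = (
        anglers * ben.wtp_angler * increment
        / state.land_cover.catchment_area
    )
    return ServiceValue("temperature_regulation", "regulating", value)


# ---------------------------------------------------------------------------
# cultural services
# ---------------------------------------------------------------------------

def angling_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Recreative angling (1.1.6.1): angler WTP modulated by trout survival."""
    ben = state.beneficiaries
    survival = trout_survival(state.river.shaded_fraction, params)
    anglers = ben.households * ben.angler_household_fraction
    value = (
        anglers * ben.wtp_angler * survival / state.land_cover.catchment_area
    )
    return ServiceValue(
        "angling", "cultural", value, flow=anglers, flow_unit="anglers"
    )


def recreation_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Active recreation (CICES 3.1 pooled): residents plus tourists.

    Tourist willingness to pay is modulated by the scenic-appreciation
    rule on forest cover.
    """
    ben = state.beneficiaries
    appreciation = scenic_appreciation(_forest_fraction(state), params)
    value = (
        ben.resident_visits_value_base * ben.wtp_resident
        + ben.tourist_visitors * ben.wtp_tourist * appreciation
    ) / state.land_cover.catchment_area
    return ServiceValue("recreation", "cultural", value)


def biodiversity_nonuse_value(
    state: CatchmentState, params: ServiceParameterSet
) -> ServiceValue:
    """Biodiversity non-use (CICES 3.2 pooled): conservation WTP."""
    ben = state.beneficiaries
    value = (
        ben.households * ben.conservation_household_fraction
        * ben.wtp_biodiversity_household / state.land_cover.catchment_area
    )
    return ServiceValue("biodiversity_nonuse", "cultural", value)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

ServiceFn = Callable[[CatchmentState, ServiceParameterSet], ServiceValue]

#: All 15 services in reporting order, grouped by bundle.
SERVICE_REGISTRY: dict[str, ServiceFn] = {
    "crops": crops_value,
    "dairy": dairy_value,
    "timber": timber_value,
    "wild_products": wild_products_value,
    "hydropower": hydropower_value,
    "drinking_water": drinking_water_value,
    "carbon_sequestration": carbon_value,
    "erosion_control": erosion_control_value,
    "flood_prevention": flood_prevention_value,
    "pest_regulation": pest_regulation_value,
    "nutrient_retention": nutrient_retention_value,
    "temperature_regulation": temperature_regulation_value,
    "angling": angling_value,
    "recreation": recreation_value,
    "biodiversity_nonuse": biodiversity_nonuse_value,
}

SERVICE_IDS = tuple(SERVICE_REGISTRY)
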