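"""The 15 service valuations: frozen worked examples, knowledge rules,
and property checks (non-negativity, per-ha scale invariance, oracle
equivalence against independent one-line arithmetic)."""

from __future__ import annotations

import math

import pytest

from escascade.domain import (
    BeneficiaryProfile,
    CatchmentState,
    CorridorShares,
    LandCoverState,
    RiverMetrics,
    ServiceParameterSet,
    ValidationError,
)
from escascade.services import (
    SERVICE_REGISTRY,
    angling_value,
    biodiversity_nonuse_value,
    carbon_value,
    crops_value,
    dairy_value,
    drinking_water_value,
    erosion_control_value,
    flood_prevention_value,
    hydropower_value,
    nutrient_retention_value,
    pest_modulation_factor,
    pest_regulation_value,
    recreation_value,
    scenic_appreciation,
    temperature_regulation_value,
    timber_value,
    trout_survival,
    wild_products_value,
)
from escascade.synthetic import ArchetypeSpec, generate_catchment

from conftest import make_state


# ---------------------------------------------------------------------------
# knowledge rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "woodland, expected",
    [(0.10, 0.8), (0.30, 1.0), (0.25, 1.0), (0.0, 0.8), (1.0, 1.0)],
)
def test_pest_rule(woodland, expected, params):
    assert pest_modulation_factor(woodland, params) == expected


@pytest.mark.parametrize(
    "shaded, expected",
    [
        (0.5, 1.0),     # threshold met: full survival
        (0.0, 0.1),     # no shade: residual floor
        (0.25, 0.46),   # floored to 0.2 step, then linear
        (0.1, 0.28),
        (0.49, 0.82),
        (1.0, 1.0),
    ],
)
def test_trout_survival_rule(shaded, expected, params):
    assert trout_survival(shaded, params) == pytest.approx(expected)


@pytest.mark.parametrize(
    "forest, expected",
    [(0.10, 0.6), (0.75, 0.8), (0.45, 1.0), (0.2, 1.0), (0.7, 1.0)],
)
def test_scenic_rule(forest, expected, params):
    assert scenic_appreciation(forest, params) == expected


@pytest.mark.parametrize(
    "rule", [pest_modulation_factor, trout_survival, scenic_appreciation]
)
def test_rules_reject_out_of_range_fractions(rule, params):
    with pytest.raises(ValidationError):
        rule(1.5, params)
    with pytest.raises(ValidationError):
        rule(-0.1, params)


def test_trout_survival_codomain(params):
    for i in range(101):
        s = trout_survival(i / 100, params)
        assert params.residual_trout_survival <= s <= 1.0


# ---------------------------------------------------------------------------
# worked examples, frozen from hand arithmetic
# ---------------------------------------------------------------------------

def test_crops_modulated_by_missing_woodland(params):
    state = make_state(100, cropland=100)  # woodland fraction 0
    assert crops_value(state, params).value == pytest.approx(320.0)


def test_crops_zero_without_cropland(params):
    assert crops_value(make_state(100), params).value == 0.0


def test_crops_full_productivity_above_threshold(params):
    state = make_state(100, cropland=50, coniferous_forest=30)
    assert crops_value(state, params).value == pytest.approx(200.0)


def test_dairy_examples(params):
    assert dairy_value(make_state(50, grassland=25), params).value == 250.0
    assert dairy_value(make_state(50), params).value == 0.0
    assert dairy_value(make_state(50, grassland=50), params).value == 500.0


def test_timber_examples(params):
    state = make_state(200, coniferous_forest=60, deciduous_forest=50)
    assert timber_value(state, params).value == pytest.approx(110.0)
    assert timber_value(make_state(200), params).value == 0.0
    all_forest = make_state(200, coniferous_forest=200)
    assert timber_value(all_forest, params).value == 200.0


def test_wild_products_with_game_share(params):
    state = make_state(100, deciduous_forest=50)
    sv = wild_products_value(state, params)
    assert sv.value == pytest.approx(12.0)
    assert sv.flow == pytest.approx(9.6)  # game component
    assert wild_products_value(make_state(100), params).value == 0.0


def test_hydropower_examples(params):
    river = RiverMetrics(hydropower_generation=9e6)
    state = make_state(100_000, river=river)
    assert hydropower_value(state, params).value == pytest.approx(4.5)
    no_gen = make_state(100_000)
    assert hydropower_value(no_gen, params).value == 0.0
    double = make_state(
        100_000, river=RiverMetrics(hydropower_generation=18e6)
    )
    assert hydropower_value(double, params).value == pytest.approx(9.0)


def test_drinking_water_365_day_convention(params):
    river = RiverMetrics(drinking_water_extraction=2700)
    state = make_state(100_000, river=river)
    assert drinking_water_value(state, params).value == pytest.approx(
        2700 * 365 * 0.5 / 1e5
    )
    assert drinking_water_value(make_state(100_000), params).value == 0.0


def test_carbon_rates_and_price(params):
    state = make_state(
        100, coniferous_forest=50, deciduous_forest=30, riparian_woodland=20
    )
    sv = carbon_value(state, params)
    assert sv.flow == pytest.approx(530.0)  # t C / yr
    assert sv.value == pytest.approx(26.5)
    high = carbon_value(state, params.replace(carbon_price=20))
    assert high.value == pytest.approx(106.0)
    assert carbon_value(make_state(100), params).value == 0.0


def test_erosion_full_riparian_retains_all(params):
    river = RiverMetrics(riparian_fraction=1.0)
    state = make_state(100, cropland=60, grassland=40, river=river)
    sv = erosion_control_value(state, params)
    assert sv.flow == pytest.approx(2 * 60 + 1 * 40)  # whole potential load


def test_erosion_half_riparian(params):
    river = RiverMetrics(riparian_fraction=0.5)
    state = make_state(100, cropland=60, grassland=40, river=river)
    assert erosion_control_value(state, params).value == pytest.approx(
        0.90576
    )


def test_erosion_zero_without_riparian(params):
    state = make_state(100, cropland=60, grassland=40)
    assert erosion_control_value(state, params).value == 0.0


def test_flood_zero_when_discharging_to_sea(params, sea_river):
    state = make_state(100, cropland=100, river=sea_river)
    assert flood_prevention_value(state, params).value == 0.0


def test_flood_corridor_damage_mix(params):
    river = RiverMetrics(
        floodplain_area=10,
        corridor_shares=CorridorShares(0.01, 0.70, 0.29),
    )
    state = make_state(10_000, river=river)
    assert flood_prevention_value(state, params).value == pytest.approx(
        0.1542
    )


def test_flood_zero_without_floodplain(params):
    state = make_state(10_000)
    assert flood_prevention_value(state, params).value == 0.0


def test_pest_regulation_credits_avoided_loss(params):
    state = make_state(100, cropland=50, coniferous_forest=30)
    assert pest_regulation_value(state, params).value == pytest.approx(40.0)


def test_pest_regulation_zero_at_floor(params):
    state = make_state(100, cropland=50, coniferous_forest=10)
    assert pest_regulation_value(state, params).value == 0.0
    no_crop = make_state(100, coniferous_forest=30)
    assert pest_regulation_value(no_crop, params).value == 0.0


def test_nutrient_retention_examples(params):
    river = RiverMetrics(main_river_length=20)
    state = make_state(1000, river=river)
    assert nutrient_retention_value(state, params).value == pytest.approx(
        0.22644
    )
    assert nutrient_retention_value(make_state(1000), params).value == 0.0
    with_sed = make_state(
        1000,
        river=RiverMetrics(main_river_length=20, flood_p_sedimentation=100),
    )
    delta = (
        nutrient_retention_value(with_sed, params).value
        - nutrient_retention_value(state, params).value
    )
    assert delta == pytest.approx(100 * 1.1322 / 1000)


_ANGLERS = BeneficiaryProfile(
    households=10_000, angler_household_fraction=0.1
)


def test_temperature_regulation_increment_over_residual(params):
    shaded = RiverMetrics(shaded_fraction=0.5)
    state = make_state(50_000, river=shaded, beneficiaries=_ANGLERS)
    expected = 1000 * 275 * 0.9 / 50_000
    assert temperature_regulation_value(state, params).value == pytest.approx(
        expected
    )


def test_temperature_regulation_zero_without_shade_or_anglers(params):
    no_shade = make_state(50_000, beneficiaries=_ANGLERS)
    assert temperature_regulation_value(no_shade, params).value == 0.0
    no_anglers = make_state(
        50_000, river=RiverMetrics(shaded_fraction=0.5)
    )
    assert temperature_regulation_value(no_anglers, params).value == 0.0


def test_angling_examples(params):
    shaded = RiverMetrics(shaded_fraction=0.5)
    state = make_state(50_000, river=shaded, beneficiaries=_ANGLERS)
    assert angling_value(state, params).value == pytest.approx(5.5)
    unshaded = make_state(50_000, beneficiaries=_ANGLERS)
    assert angling_value(unshaded, params).value == pytest.approx(0.55)
    empty = make_state(50_000)
    assert angling_value(empty, params).value == 0.0


_VISITORS = BeneficiaryProfile(
    resident_visits_value_base=5000, tourist_visitors=2000,
    wtp_resident=10, wtp_tourist=20,
)


def test_recreation_with_scenic_modulation(params):
    state = make_state(
        10_000, coniferous_forest=4500, beneficiaries=_VISITORS
    )
    assert recreation_value(state, params).value == pytest.approx(9.0)
    low_forest = make_state(
        10_000, coniferous_forest=1000, beneficiaries=_VISITORS
    )
    assert recreation_value(low_forest, params).value == pytest.approx(7.4)
    no_visitors = make_state(10_000)
    assert recreation_value(no_visitors, params).value == 0.0


def test_biodiversity_nonuse(params):
    profile = BeneficiaryProfile(
        households=10_000, conservation_household_fraction=1.0,
        wtp_biodiversity_household=5,
    )
    state = make_state(50_000, beneficiaries=profile)
    assert biodiversity_nonuse_value(state, params).value == pytest.approx(1.0)
    none = make_state(50_000, beneficiaries=BeneficiaryProfile(
        households=10_000, wtp_biodiversity_household=5))
    assert biodiversity_nonuse_value(none, params).value == 0.0
    double = make_state(50_000, beneficiaries=BeneficiaryProfile(
        households=20_000, conservation_household_fraction=1.0,
        wtp_biodiversity_household=5))
    assert biodiversity_nonuse_value(double, params).value == pytest.approx(
        2.0
    )


# ---------------------------------------------------------------------------
# independent oracle: one-line arithmetic per service, straight from fields
# ---------------------------------------------------------------------------

def _oracle(state: CatchmentState, p: ServiceParameterSet) -> dict[str, float]:
    lc, rv, bn = state.land_cover, state.river, state.beneficiaries
    A = lc.catchment_area
    wood = (lc.coniferous_forest + lc.deciduous_forest
            + lc.riparian_woodland) / A
    forest = (lc.coniferous_forest + lc.deciduous_forest) / A
    pest = p.pest_reduced_productivity if wood < p.pest_woodland_threshold else 1.0
    if rv.shaded_fraction >= p.shade_threshold:
        surv = 1.0
    else:
        stepped = math.floor(rv.shaded_fraction * 10 + 1e-9) / 10
        surv = min(1.0, max(
            p.residual_trout_survival,
            p.residual_trout_survival
            + (1 - p.residual_trout_survival) * stepped / p.shade_threshold,
        ))
    if forest < p.scenic_low_forest_threshold:
        scenic = p.scenic_low_appreciation
    elif forest > p.scenic_high_forest_threshold:
        scenic = p.scenic_high_appreciation
    else:
        scenic = 1.0
    anglers = bn.households * bn.angler_household_fraction
    cs = rv.corridor_shares
    flood = 0.0 if (rv.discharges_directly_to_sea or rv.floodplain_area == 0) else (
        rv.floodplain_area * 1e4
        * (cs.built_up * p.flood_damage_built
           + cs.agricultural * p.flood_damage_agri
           + cs.woodland * p.flood_damage_wood)
        * p.flood_depth_factor * p.flood_annualization / A
    )
    return {
        "crops": p.crop_revenue * lc.cropland * pest / A,
        "dairy": p.dairy_revenue * lc.grassland / A,
        "timber": p.timber_annuity * (lc.coniferous_forest + lc.deciduous_forest) / A,
        "wild_products": p.wild_products_rate * wood * A / A,
        "hydropower": rv.hydropower_generation * p.electricity_price / A,
        "drinking_water": rv.drinking_water_extraction * 365 * p.water_price / A,
        "carbon_sequestration": (p.c_seq_coniferous * lc.coniferous_forest
                                 + p.c_seq_deciduous * lc.deciduous_forest
                                 + p.c_seq_riparian * lc.riparian_woodland)
        * p.carbon_price / A,
        "erosion_control": rv.riparian_fraction
        * (p.erodible_p_grassland * lc.grassland
           + p.erodible_p_cropland * lc.cropland) * p.p_price / A,
        "flood_prevention": flood,
        "pest_regulation": p.crop_revenue * lc.cropland
        * (pest - p.pest_reduced_productivity) / A,
        "nutrient_retention": (p.instream_p_retention * rv.main_river_length
                               + rv.flood_p_sedimentation) * p.p_price / A,
        "temperature_regulation": anglers * bn.wtp_angler
        * (surv - p.residual_trout_survival) / A,
        "angling": anglers * bn.wtp_angler * surv / A,
        "recreation": (bn.resident_visits_value_base * bn.wtp_resident
                       + bn.tourist_visitors * bn.wtp_tourist * scenic) / A,
        "biodiversity_nonuse": bn.households
        * bn.conservation_household_fraction
        * bn.wtp_biodiversity_household / A,
    }


def _random_states(n: int, seed0: int = 1000):
    weights = {
        "cropland": 2, "grassland": 1, "coniferous_forest": 2,
        "deciduous_forest": 1, "riparian_woodland": 0.3, "wetland": 0.5,
        "built_up": 0.5, "open_water": 0.5, "other": 0.5,
    }
    for i in range(n):
        yield generate_catchment(
            ArchetypeSpec(archetype="custom", class_weights=weights,
                          seed=seed0 + i)
        )


def test_oracle_equivalence_on_random_states(params):
    """Every service equals an independent one-line recomputation."""
    for state in _random_states(100):
        expected = _oracle(state, params)
        for service_id, fn in SERVICE_REGISTRY.items():
            got = fn(state, params).value
            assert got == pytest.approx(expected[service_id], rel=1e-12), (
                service_id, state.name
            )


def test_values_nonnegative_on_random_states(params):
    for state in _random_states(50, seed0=2000):
        for fn in SERVICE_REGISTRY.values():
            assert fn(state, params).value >= 0.0


def _scaled(state: CatchmentState, k: float) -> CatchmentState:
    lc = state.land_cover
    rv = state.river
    bn = state.beneficiaries
    return CatchmentState(
        name=state.name,
        land_cover=LandCoverState(
            catchment_area=lc.catchment_area * k,
            **{c: getattr(lc, c) * k for c in (
                "cropland", "grassland", "coniferous_forest",
                "deciduous_forest", "riparian_woodland", "wetland",
                "built_up", "open_water", "other")},
        ),
        river=RiverMetrics(
            main_river_length=rv.main_river_length * k,
            shaded_fraction=rv.shaded_fraction,
            riparian_fraction=rv.riparian_fraction,
            floodplain_area=rv.floodplain_area * k,
            corridor_shares=rv.corridor_shares,
            discharges_directly_to_sea=rv.discharges_directly_to_sea,
            hydropower_generation=rv.hydropower_generation * k,
            drinking_water_extraction=rv.drinking_water_extraction * k,
            flood_p_sedimentation=rv.flood_p_sedimentation * k,
        ),
        beneficiaries=BeneficiaryProfile(
            households=bn.households * k,
            angler_household_fraction=bn.angler_household_fraction,
            resident_visits_value_base=bn.resident_visits_value_base * k,
            tourist_visitors=bn.tourist_visitors * k,
            wtp_angler=bn.wtp_angler,
            wtp_resident=bn.wtp_resident,
            wtp_tourist=bn.wtp_tourist,
            wtp_biodiversity_household=bn.wtp_biodiversity_household,
            conservation_household_fraction=bn.conservation_household_fraction,
        ),
    )


@pytest.mark.parametrize("k", [0.1, 3.0, 1000.0])
def test_per_ha_values_scale_invariant(k, params):
    """Jointly scaling areas, counts and rates leaves €/ha values fixed."""
    for state in _random_states(10, seed0=3000):
        scaled = _scaled(state, k)
        for service_id, fn in SERVICE_REGISTRY.items():
            assert fn(scaled, params).value == pytest.approx(
                fn(state, params).value, rel=1e-9
            ), service_id


_PRICE_OF = {
    "crops": "crop_revenue",
    "dairy": "dairy_revenue",
    "timber": "timber_annuity",
    "wild_products": "wild_products_rate",
    "hydropower": "electricity_price",
    "drinking_water": "water_price",
    "carbon_sequestration": "carbon_price",
    "erosion_control": "p_price",
    "flood_prevention": "flood_damage_built",
    "pest_regulation": "crop_revenue",
    "nutrient_retention": "p_price",
}


def test_values_monotone_in_own_price(params):
    """Each valuation is weakly non-decreasing in its unit price."""
    for state in _random_states(10, seed0=4000):
        for service_id, param_name in _PRICE_OF.items():
            fn = SERVICE_REGISTRY[service_id]
            base = fn(state, params).value
            bumped = fn(
                state,
                params.replace(
                    **{param_name: getattr(params, param_name) * 2}
                ),
            ).value
            assert bumped >= base - 1e-12, service_id
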