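from __future__ import annotations

import pytest

from escascade.domain import (
    BeneficiaryProfile,
    CatchmentState,
    CorridorShares,
    LandCoverState,
    RiverMetrics,
    ServiceParameterSet,
)


def make_state(
    area: float,
    *,
    name: str = "toy",
    river: RiverMetrics | None = None,
    beneficiaries: BeneficiaryProfile | None = None,
    **areas: float,
) -> CatchmentState:
    """Toy catchment: unnamed area goes to 'other'."""
    used = sum(areas.values())
    assert used <= area + 1e-9
    areas.setdefault("other", 0.0)
    areas["other"] += area - used
    return CatchmentState(
        name=name,
        land_cover=LandCoverState(catchment_area=area, **areas),
        river=river or RiverMetrics(),
        beneficiaries=beneficiaries or BeneficiaryProfile(),
    )


@pytest.fixture
def params() -> ServiceParameterSet:
    return ServiceParameterSet()


@pytest.fixture
def sea_river() -> RiverMetrics:
    return RiverMetrics(
        discharges_directly_to_sea=True,
        corridor_shares=CorridorShares(0.0, 1.0, 0.0),
    )
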