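"""Shared fixtures and small hand-built model objects."""

from __future__ import annotations

import pytest

from spmcost.model import (
    AGE_BANDS,
    CARE_LEVELS,
    AgeSexDistribution,
    CareLevelRecipe,
    DistrictProfile,
    EpidemiologyProfile,
    Facility,
    ResourceItem,
    ServiceDefinition,
    StaffTimeItem,
    WageTable,
)


def uniform_age_sex() -> AgeSexDistribution:
    """Flat pyramid, equal sexes: 1/32 of the population in each cell."""
    share = 1.0 / (2 * len(AGE_BANDS))
    return AgeSexDistribution(
        female={b: share for b in AGE_BANDS},
        male={b: share for b in AGE_BANDS},
    )


def make_facility(fid: str, kind: str, x: float = 0.0, y: float = 0.0, **kw) -> Facility:
    defaults = dict(
        annual_operating_cost=0.0, annualised_capital=0.0, indirect_staff_cost=0.0,
        non_spm_bed_days=0.0, non_spm_outpatient_visits=0.0, catchment_population=0,
    )
    defaults.update(kw)
    return Facility(id=fid, kind=kind, x=x, y=y, **defaults)


def make_district(
    population: int = 100_000,
    facilities: list[Facility] | None = None,
    rates: dict[str, float] | None = None,
    age_sex: AgeSexDistribution | None = None,
    area_km2: float = 1000.0,
    dho_admin_cost: float = 0.0,
    district_id: str = "D-test",
) -> DistrictProfile:
    if facilities is None:
        facilities = [
            make_facility("H1", "district_hospital", 0.0, 0.0),
            make_facility("P1", "health_centre_nobeds", 3.0, 4.0,
                          catchment_population=population),
        ]
    return DistrictProfile(
        id=district_id,
        population=population,
        age_sex=age_sex or uniform_age_sex(),
        epi=EpidemiologyProfile(rates=rates or {"diarrhoea": 0.1, "malaria": 0.05}),
        facilities=facilities,
        area_km2=area_km2,
        dho_admin_cost=dho_admin_cost,
    )


def empty_recipes() -> dict[str, CareLevelRecipe]:
    return {level: CareLevelRecipe(level=level) for level in CARE_LEVELS}


def make_service(
    sid: str = "svc",
    target_selector: str = "all",
    incidence_key: str | None = None,
    facility_need: float = 1.0,
    referral_fraction: float = 0.0,
    admission_fraction: float = 0.0,
    self_referral_fraction: float = 0.0,
    coverage_target: float = 0.9,
    utilisation_fraction: float | None = None,
    attribution: str = "population",
    programme_overhead_per_capita: float = 0.0,
    recipes: dict[str, CareLevelRecipe] | None = None,
    inpatient_days: float = 0.0,
) -> ServiceDefinition:
    if recipes is None:
        recipes = empty_recipes()
        if inpatient_days > 0:
            recipes["hospital_inpatient"] = CareLevelRecipe(
                level="hospital_inpatient", inpatient_days=inpatient_days,
            )
    return ServiceDefinition(
        id=sid, name=sid, target_selector=target_selector, incidence_key=incidence_key,
        facility_need=facility_need, referral_fraction=referral_fraction,
        admission_fraction=admission_fraction,
        self_referral_fraction=self_referral_fraction,
        coverage_target=coverage_target, utilisation_fraction=utilisation_fraction,
        attribution=attribution,
        programme_overhead_per_capita=programme_overhead_per_capita,
        recipes=recipes,
    )


def primary_recipe(items: list[ResourceItem] | None = None,
                   staff: list[StaffTimeItem] | None = None) -> CareLevelRecipe:
    return CareLevelRecipe(level="primary", items=items or [], staff=staff or [])


@pytest.fixture
def wages() -> WageTable:
    return WageTable(daily_salary={"doctor": 40.0, "specialist": 60.0,
                                   "midwife": 18.0, "nurse": 15.0})
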