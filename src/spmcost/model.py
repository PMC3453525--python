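"""Domain model for district-level costing of a minimum health-service package.

The package costs a politically mandated set of essential services (maternal
and neonatal care, family planning, child health, priority communicable
diseases) for an administrative district.  Each service ``j`` is described by
a *service definition*: the population target group it applies to (``t``),
the fraction of that group presenting with the condition (``d``), the
fraction of cases that need care at a medical facility (``n``), a referral
fraction (``pi``), an admission fraction (``m``), a coverage target, and
resource recipes (drugs/supplies and staff minutes) at three care levels —
primary, hospital outpatient and hospital inpatient.

Each district ``i`` is described by a *district profile*: population, an
age/sex distribution in 5-year bands, per-driver epidemiology rates, and a
facility roster (health centres with or without beds, district hospitals)
with coordinates, annual fixed-cost pools and non-package workload.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: 5-year age bands used for population pyramids.
AGE_BANDS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75+",
)

#: female reproductive-age bands (15-49), used for maternal attributions.
REPRODUCTIVE_BANDS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)

Cadre = Literal["doctor", "specialist", "midwife", "nurse"]
CareLevel = Literal["primary", "hospital_outpatient", "hospital_inpatient"]
CARE_LEVELS: tuple[str, ...] = ("primary", "hospital_outpatient", "hospital_inpatient")

FacilityKind = Literal["health_centre_beds", "health_centre_nobeds", "district_hospital"]

Attribution = Literal["maternal", "child", "female", "male", "population"]

#: recognised epidemiology drivers.  Rates are annual fractions of the
#: driver's natural denominator expressed per head of total population
#: (birth_rate, infants_u1, ...) or point prevalence within the target group
#: (malnutrition among children, malaria, ...).
KNOWN_DRIVERS: set[str] = {
    "birth_rate",
    "infants_u1",
    "children_1_5",
    "eligible_couples",
    "malnutrition",
    "tuberculosis",
    "malaria",
    "dengue",
    "pneumonia",
    "diarrhoea",
}


def register_driver(name: str) -> None:
    """Register an additional epidemiology driver key.

    The driver set is extensible so new conditions can be added to the
    package without touching the model code; unknown keys are still rejected
    at load time to catch typos.
    """
    KNOWN_DRIVERS.add(name)


class AgeSexDistribution(BaseModel):
    """Population shares by 5-year age band and sex.

    ``female[band] + male[band]`` over all bands sums to 1.
    """

    model_config = ConfigDict(frozen=True)

    female: dict[str, float]
    male: dict[str, float]

    @field_validator("female", "male")
    @classmethod
    def _check_bands(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(AGE_BANDS):
            missing = set(AGE_BANDS) - set(v)
            extra = set(v) - set(AGE_BANDS)
            raise ValueError(f"age bands mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
        for band, share in v.items():
            if share < 0:
                raise ValueError(f"negative share for band {band}")
        return {band: v[band] for band in AGE_BANDS}

    @model_validator(mode="after")
    def _check_total(self) -> "AgeSexDistribution":
        total = sum(self.female.values()) + sum(self.male.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age/sex shares sum to {total!r}, expected 1")
        return self

    def band_share(self, band: str) -> float:
        """Share of total population in a band, both sexes."""
        return self.female[band] + self.male[band]

    @property
    def under5(self) -> float:
        return self.band_share("0-4")

    @property
    def over5(self) -> float:
        return 1.0 - self.under5

    @property
    def female_15_49(self) -> float:
        return sum(self.female[b] for b in REPRODUCTIVE_BANDS)


class EpidemiologyProfile(BaseModel):
    """Per-driver rates for one district (fractions in [0, 1])."""

    model_config = ConfigDict(frozen=True)

    rates: dict[str, float]

    @field_validator("rates")
    @classmethod
    def _check_rates(cls, v: dict[str, float]) -> dict[str, float]:
        for key, rate in v.items():
            if key not in KNOWN_DRIVERS:
                raise ValueError(f"unknown epidemiology driver {key!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"driver {key!r} rate {rate!r} outside [0, 1]")
        return dict(v)

    def rate(self, driver: str) -> float:
        try:
            return self.rates[driver]
        except KeyError:
            raise KeyError(f"epidemiology driver {driver!r} not present in profile") from None


class Facility(BaseModel):
    """One facility in the district roster.

    The three annual money fields form the facility's fixed-overhead pool
    (operating + annualised capital + indirect staffing).  Non-package
    workload (``non_spm_*``) records activity attributable to conditions
    outside the package, so overheads are shared rather than loaded wholly
    onto package episodes (economies of scope).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    kind: FacilityKind
    x: float
    y: float
    annual_operating_cost: float = Field(ge=0)
    annualised_capital: float = Field(ge=0)
    indirect_staff_cost: float = Field(ge=0)
    non_spm_bed_days: float = Field(default=0.0, ge=0)
    non_spm_outpatient_visits: float = Field(default=0.0, ge=0)
    catchment_population: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_kind_fields(self) -> "Facility":
        if self.kind == "health_centre_nobeds" and self.non_spm_bed_days > 0:
            raise ValueError(f"facility {self.id!r} has no beds but records bed-day workload")
        return self

    @property
    def overhead_pool(self) -> float:
        return self.annual_operating_cost + self.annualised_capital + self.indirect_staff_cost

    @property
    def is_hospital(self) -> bool:
        return self.kind == "district_hospital"


class DistrictProfile(BaseModel):
    """District ``i``: population, demography, epidemiology and facilities."""

    model_config = ConfigDict(frozen=True)

    id: str
    population: int = Field(gt=0)
    age_sex: AgeSexDistribution
    epi: EpidemiologyProfile
    facilities: list[Facility]
    area_km2: float = Field(gt=0)
    dho_admin_cost: float = Field(default=0.0, ge=0)
    coord_system: Literal["planar_km", "latlon"] = "planar_km"

    @model_validator(mode="after")
    def _check_roster(self) -> "DistrictProfile":
        if not any(f.is_hospital for f in self.facilities):
            raise ValueError("district roster invalid: >=1 district_hospital required")
        ids = [f.id for f in self.facilities]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate facility ids in roster")
        catchment = sum(f.catchment_population for f in self.facilities if not f.is_hospital)
        if abs(catchment - self.population) > 1e-3 * self.population:
            raise ValueError(
                f"health-centre catchments sum to {catchment}, "
                f"population is {self.population} (must agree within 0.1%)"
            )
        return self

    @property
    def density(self) -> float:
        """Persons per km^2 (derived)."""
        return self.population / self.area_km2

    @property
    def hospitals(self) -> list[Facility]:
        return [f for f in self.facilities if f.is_hospital]

    @property
    def health_centres(self) -> list[Facility]:
        return [f for f in self.facilities if not f.is_hospital]


class ResourceItem(BaseModel):
    """A drug or medical supply line in a treatment recipe."""

    model_config = ConfigDict(frozen=True)

    name: str
    unit_price: float = Field(ge=0)
    quantity: float = Field(ge=0)
    use_probability: float = Field(ge=0, le=1)


class StaffTimeItem(BaseModel):
    """Minutes of one cadre's time per episode, tagged by activity."""

    model_config = ConfigDict(frozen=True)

    cadre: Cadre
    minutes: float = Field(ge=0)
    activity: str = "consultation"


class CareLevelRecipe(BaseModel):
    """Resource recipe at one care level.

    ``inpatient_days`` is the normative length of stay and may be positive
    only at hospital-inpatient level.
    """

    model_config = ConfigDict(frozen=True)

    level: CareLevel
    items: list[ResourceItem] = Field(default_factory=list)
    staff: list[StaffTimeItem] = Field(default_factory=list)
    inpatient_days: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check_days(self) -> "CareLevelRecipe":
        if self.inpatient_days > 0 and self.level != "hospital_inpatient":
            raise ValueError(f"inpatient_days > 0 at non-admission level {self.level!r}")
        return self


class ServiceDefinition(BaseModel):
    """One package condition ``j`` and its care path.

    ``self_referral_fraction`` (sigma) is the share of facility-seeking cases
    that bypass primary care and present directly at hospital — common for
    emergencies and in urban populations even under a gatekeeper norm.
    ``utilisation_fraction`` is the observed uptake used in utilisation mode
    in place of the normative coverage target.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    target_selector: str
    incidence_key: Optional[str] = None
    facility_need: float = Field(ge=0, le=1)
    referral_fraction: float = Field(ge=0, le=1)
    admission_fraction: float = Field(ge=0, le=1)
    self_referral_fraction: float = Field(default=0.0, ge=0, le=1)
    coverage_target: float = Field(ge=0, le=1)
    utilisation_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    attribution: Attribution = "population"
    programme_overhead_per_capita: float = Field(default=0.0, ge=0)
    recipes: dict[str, CareLevelRecipe]

    @field_validator("incidence_key")
    @classmethod
    def _check_driver(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in KNOWN_DRIVERS:
            raise ValueError(f"incidence_key {v!r} is not a known driver")
        return v

    @field_validator("recipes")
    @classmethod
    def _check_recipes(cls, v: dict[str, CareLevelRecipe]) -> dict[str, CareLevelRecipe]:
        if set(v) != set(CARE_LEVELS):
            raise ValueError(f"recipes must cover exactly {CARE_LEVELS}, got {sorted(v)}")
        for level, recipe in v.items():
            if recipe.level != level:
                raise ValueError(f"recipe keyed {level!r} declares level {recipe.level!r}")
        return {level: v[level] for level in CARE_LEVELS}


class WageTable(BaseModel):
    """Daily salaries and effective contact hours per cadre.

    Effective hours reflect realistic staff availability during a working
    day (roughly 4 h for doctors/specialists and 6 h for nurses/midwives,
    the remainder typically absorbed by private practice), so a minute of
    contact time carries a full-salary cost share.
    """

    model_config = ConfigDict(frozen=True)

    daily_salary: dict[str, float]
    effective_hours: dict[str, float] = Field(
        default_factory=lambda: {"doctor": 4.0, "specialist": 4.0, "midwife": 6.0, "nurse": 6.0}
    )

    @field_validator("daily_salary")
    @classmethod
    def _check_salary(cls, v: dict[str, float]) -> dict[str, float]:
        for cadre, salary in v.items():
            if salary < 0:
                raise ValueError(f"negative daily salary for {cadre!r}")
        return dict(v)

    @field_validator("effective_hours")
    @classmethod
    def _check_hours(cls, v: dict[str, float]) -> dict[str, float]:
        for cadre, hours in v.items():
            if not 0 < hours <= 24:
                raise ValueError(f"effective hours for {cadre!r} must lie in (0, 24]")
        return dict(v)

    def cost_per_minute(self, cadre: str) -> float:
        try:
            return self.daily_salary[cadre] / (self.effective_hours[cadre] * 60.0)
        except KeyError:
            raise KeyError(f"cadre {cadre!r} missing from wage table") from None


def default_wage_table() -> WageTable:
    """Civil-service scale daily salaries in USD with default availability."""
    return WageTable(daily_salary={"specialist": 40.0, "doctor": 30.0, "midwife": 18.0, "nurse": 15.0})


def target_proportion(service: ServiceDefinition, district: DistrictProfile) -> float:
    """Resolve ``t``: the fraction of the district population in the
    service's target group.

    Selectors are either structural ("all", "age>5", "age<5",
    "female_15_49") resolved against the age/sex pyramid, or the name of an
    epidemiology driver ("births" maps to the birth_rate driver, collapsing
    t*d into a single per-capita rate for delivery services).
    """
    sel = service.target_selector
    if sel == "all":
        return 1.0
    if sel == "births":
        return district.epi.rate("birth_rate")
    if sel == "age>5":
        return district.age_sex.over5
    if sel == "age<5":
        return district.age_sex.under5
    if sel == "female_15_49":
        return district.age_sex.female_15_49
    if sel in KNOWN_DRIVERS:
        return district.epi.rate(sel)
    raise ValueError(f"unresolvable target selector {sel!r} for service {service.id!r}")
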