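"""Reproducible synthetic districts and service catalogues.

The generator emulates the inputs the costing model consumes in the field:
a district population pyramid (bottom-heavy high-fertility, balanced, or
aging with student/retiree bulges), epidemiology rates spanning the
observed inter-provincial ranges, and a facility roster whose size and
spread follow population density (sparse districts need more facilities
per head).  Demographic drivers (births, infants, young children, eligible
couples) are derived from the pyramid so that pyramid shape propagates into
need, which is the dominant real-world mechanism behind inter-district cost
differences.

A single integer seed drives one named random stream per sub-generator, so
adding a generator never perturbs existing outputs and identical seeds give
byte-identical serialisations.
"""

from __future__ import annotations

import zlib
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import (
    AgeSexDistribution,
    AGE_BANDS,
    CareLevelRecipe,
    DistrictProfile,
    EpidemiologyProfile,
    Facility,
    ResourceItem,
    ServiceDefinition,
    StaffTimeItem,
)
from .overheads import annualise_capital

#: default per-driver [low, high] ranges spanning observed inter-provincial
#: variation (fractions of the driver's denominator population).
DEFAULT_EPI_RANGES: dict[str, tuple[float, float]] = {
    "birth_rate": (0.017, 0.037),
    "infants_u1": (0.011, 0.023),
    "children_1_5": (0.052, 0.108),
    "eligible_couples": (0.157, 0.198),
    "malnutrition": (0.090, 0.221),
    "tuberculosis": (0.001, 0.011),
    "malaria": (0.003, 0.261),
    "dengue": (0.002, 0.025),
    "pneumonia": (0.020, 0.080),
    "diarrhoea": (0.100, 0.300),
}

PyramidShape = Literal["bottom_heavy", "balanced", "aging"]


class GeneratorConfig(BaseModel):
    """Settings for one synthetic district."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    population: int = Field(default=300_000, gt=0)
    pyramid_shape: PyramidShape = "balanced"
    density_target: float = Field(default=109.0, gt=0)
    epi_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_EPI_RANGES)
    )
    n_health_centres: Optional[int] = Field(default=None, ge=1)
    n_hospitals: int = Field(default=1, ge=1)
    beds_fraction: float = Field(default=0.3, ge=0, le=1)

    @field_validator("epi_ranges")
    @classmethod
    def _check_ranges(cls, v):
        for driver, (lo, hi) in v.items():
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"epi range for {driver!r} must satisfy 0 <= lo <= hi <= 1")
        return v


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named random stream: stable under addition of other streams."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode("utf-8"))])


# aging base shape: student-age (15-29) bulge plus a large 60+ population;
# bottom_heavy/balanced are geometric decays.
_AGING_BASE = np.array([
    0.055, 0.055, 0.058, 0.075, 0.080, 0.078, 0.062, 0.060,
    0.060, 0.058, 0.055, 0.050, 0.048, 0.045, 0.040, 0.050,
])
_DECAY = {"bottom_heavy": 0.92, "balanced": 0.97}


def _pyramid(config: GeneratorConfig) -> AgeSexDistribution:
    rng = _rng(config.seed, "pyramid")
    if config.pyramid_shape in _DECAY:
        base = _DECAY[config.pyramid_shape] ** np.arange(len(AGE_BANDS))
    else:
        base = _AGING_BASE.copy()
    # bounded jitter keeps bottom_heavy strictly decreasing with age
    base = base * rng.uniform(0.97, 1.03, size=base.size)
    base /= base.sum()
    female_frac = 0.488 + 0.003 * np.arange(len(AGE_BANDS)) + rng.uniform(-0.005, 0.005, base.size)
    female = base * female_frac
    male = base - female
    # exact renormalisation so the distribution invariant holds to 1e-9
    total = female.sum() + male.sum()
    female, male = female / total, male / total
    return AgeSexDistribution(
        female={band: float(female[i]) for i, band in enumerate(AGE_BANDS)},
        male={band: float(male[i]) for i, band in enumerate(AGE_BANDS)},
    )


def _clip_range(value: float, bounds: tuple[float, float]) -> float:
    return float(min(max(value, bounds[0]), bounds[1]))


def _epidemiology(config: GeneratorConfig, pyramid: AgeSexDistribution) -> EpidemiologyProfile:
    ranges = config.epi_ranges
    demo_rng = _rng(config.seed, "epi_demographic")
    disease_rng = _rng(config.seed, "epi_disease")
    under5 = pyramid.under5
    share5_9 = pyramid.band_share("5-9")
    jitter = demo_rng.uniform(0.95, 1.05, size=4)
    # under-1s are roughly a fifth of the 0-4 band; births exceed surviving
    # infants (mortality, census undercount); couples ~65% of women 15-49
    infants = under5 * 0.21 * jitter[0]
    rates = {
        "infants_u1": infants,
        "birth_rate": infants * 1.55 * jitter[1],
        "children_1_5": (under5 * 0.8 + share5_9 * 0.2) * jitter[2],
        "eligible_couples": pyramid.female_15_49 * 0.65 * jitter[3],
    }
    rates = {k: _clip_range(v, ranges[k]) for k, v in rates.items()}
    for driver in ("malnutrition", "tuberculosis", "malaria", "dengue", "pneumonia", "diarrhoea"):
        lo, hi = ranges[driver]
        rates[driver] = float(disease_rng.uniform(lo, hi))
    return EpidemiologyProfile(rates=rates)


def _facility_count(config: GeneratorConfig) -> int:
    if config.n_health_centres is not None:
        return config.n_health_centres
    # one centre per ~30,000 persons, scaled up in sparse districts where
    # geography forces a denser facility network per head
    sparsity = float(np.clip((109.0 / config.density_target) ** 0.3, 1.0, 3.0))
    return max(1, round(config.population / 30_000 * sparsity))


def _place_points(rng: np.random.Generator, n: int, side: float) -> np.ndarray:
    """Matern-style thinned point process: spread-out facility sites."""
    if n == 0:
        return np.empty((0, 2))
    candidates = rng.uniform(0.0, side, size=(max(4 * n, 16), 2))
    min_sep = 0.4 * side / np.sqrt(n)
    kept: list[np.ndarray] = []
    rejected: list[np.ndarray] = []
    for point in candidates:
        if all(np.linalg.norm(point - k) >= min_sep for k in kept):
            kept.append(point)
        else:
            rejected.append(point)
        if len(kept) == n:
            break
    while len(kept) < n and rejected:
        kept.append(rejected.pop(0))
    return np.array(kept[:n])


def _integer_partition(rng: np.random.Generator, total: int, n: int) -> list[int]:
    """Partition ``total`` into ``n`` positive-ish integers (largest remainder)."""
    weights = rng.gamma(5.0, 1.0, size=n)
    weights /= weights.sum()
    raw = weights * total
    floors = np.floor(raw).astype(int)
    shortfall = total - int(floors.sum())
    order = np.argsort(-(raw - floors), kind="stable")
    for i in range(shortfall):
        floors[order[i % n]] += 1
    return [int(x) for x in floors]


def generate_district(config: GeneratorConfig) -> DistrictProfile:
    """Generate one valid district profile; identical config => identical output."""
    pyramid = _pyramid(config)
    epi = _epidemiology(config, pyramid)
    area = config.population / config.density_target
    side = float(np.sqrt(area))
    n_centres = _facility_count(config)

    geo_rng = _rng(config.seed, "geography")
    fin_rng = _rng(config.seed, "finance")
    catch_rng = _rng(config.seed, "catchment")

    facilities: list[Facility] = []
    centre = side / 2.0
    scale = config.population / 300_000
    for h in range(config.n_hospitals):
        x, y = centre + geo_rng.uniform(-0.05, 0.05, 2) * side
        operating = fin_rng.uniform(1.5e6, 3.0e6) * scale / config.n_hospitals
        capital = (
            annualise_capital(fin_rng.uniform(4.0e6, 8.0e6) * scale / config.n_hospitals, 20, 0.03)
            + annualise_capital(fin_rng.uniform(1.0e6, 2.0e6) * scale / config.n_hospitals, 5, 0.03)
        )
        indirect = fin_rng.uniform(3.0e5, 6.0e5) * scale / config.n_hospitals
        facilities.append(Facility(
            id=f"H{h + 1:02d}",
            kind="district_hospital",
            x=float(x), y=float(y),
            annual_operating_cost=operating,
            annualised_capital=capital,
            indirect_staff_cost=indirect,
            non_spm_bed_days=config.population * fin_rng.uniform(0.12, 0.18) / config.n_hospitals,
            non_spm_outpatient_visits=config.population * fin_rng.uniform(0.20, 0.30) / config.n_hospitals,
            catchment_population=0,
        ))

    points = _place_points(geo_rng, n_centres, side)
    catchments = _integer_partition(catch_rng, config.population, n_centres)
    n_beds = round(config.beds_fraction * n_centres)
    for c in range(n_centres):
        kind = "health_centre_beds" if c < n_beds else "health_centre_nobeds"
        pop_c = catchments[c]
        facilities.append(Facility(
            id=f"P{c + 1:03d}",
            kind=kind,
            x=float(points[c, 0]), y=float(points[c, 1]),
            annual_operating_cost=fin_rng.uniform(6.0e4, 1.1e5),
            annualised_capital=(
                annualise_capital(fin_rng.uniform(1.2e5, 2.2e5), 20, 0.03)
                + annualise_capital(fin_rng.uniform(2.5e4, 5.0e4), 5, 0.03)
            ),
            indirect_staff_cost=fin_rng.uniform(1.5e4, 3.0e4),
            non_spm_bed_days=(pop_c * fin_rng.uniform(0.003, 0.008)
                              if kind == "health_centre_beds" else 0.0),
            non_spm_outpatient_visits=pop_c * fin_rng.uniform(0.4, 0.8),
            catchment_population=pop_c,
        ))

    return DistrictProfile(
        id=f"synthetic-{config.seed}-{config.pyramid_shape}",
        population=config.population,
        age_sex=pyramid,
        epi=epi,
        facilities=facilities,
        area_km2=area,
        dho_admin_cost=config.population * fin_rng.uniform(2.5, 4.0),
    )


# One row per package condition: id, name, target selector, epidemiology
# driver, facility-need fraction (carrying the complication incidence among
# births for obstetric services, where every complication needs facility
# care), referral fraction pi, admission fraction m, self-referral sigma,
# coverage target, benefit attribution, inpatient days, per-level variable
# cost targets (primary, hospital OPD, hospital inpatient, USD), per-level
# staff minutes (doctor, specialist, midwife, nurse), and population-based
# programme overhead per capita.
_SPM_TEMPLATE: list[tuple] = [
    # id, name, sel, driver, n, pi, m, sigma, cov, attr, days,
    #   (vp, vh, vha), staff_p, staff_h, staff_ha, ppc
    ("anc", "Basic Antenatal Care", "births", None, 1.0, 0.02, 0.3, 0.0, 0.95, "maternal", 1,
     (6, 10, 30), (0, 0, 120, 15), (15, 10, 0, 10), (30, 0, 0, 120), 0.0),
    ("abortion", "Post-abortion Care", "births", None, 0.04, 1.0, 0.75, 0.5, 0.85, "maternal", 1,
     (2, 5, 15), (0, 0, 30, 0), (15, 20, 0, 15), (30, 45, 30, 120), 0.0),
    ("aph", "Antepartum Haemorrhage", "births", None, 0.015, 1.0, 0.9, 0.2, 0.85, "maternal", 4,
     (2, 10, 75), (0, 0, 30, 0), (20, 20, 0, 15), (40, 60, 60, 300), 0.0),
    ("pet", "Hypertension of Pregnancy (PET)", "births", None, 0.03, 1.0, 0.85, 0.2, 0.85, "maternal", 4,
     (2, 8, 55), (0, 0, 30, 0), (20, 20, 0, 15), (40, 45, 60, 300), 0.0),
    ("anaemia", "Severe Anaemia in Pregnancy", "births", None, 0.05, 0.8, 0.7, 0.1, 0.85, "maternal", 3,
     (5, 10, 55), (0, 0, 40, 0), (15, 10, 0, 10), (30, 30, 60, 200), 0.0),
    ("premature", "Premature Labour", "births", None, 0.05, 1.0, 0.9, 0.2, 0.85, "maternal", 3,
     (2, 15, 135), (0, 0, 30, 0), (20, 20, 0, 15), (40, 45, 90, 240), 0.0),
    ("malpresentation", "Abnormal Foetal Presentation", "births", None, 0.04, 1.0, 0.9, 0.2, 0.85, "maternal", 3,
     (2, 8, 35), (0, 0, 30, 0), (20, 20, 0, 15), (40, 60, 90, 240), 0.0),
    ("prolonged", "Prolonged Labour", "births", None, 0.06, 1.0, 0.85, 0.2, 0.85, "maternal", 2,
     (2, 8, 30), (0, 0, 30, 0), (20, 20, 0, 15), (40, 60, 90, 180), 0.0),
    ("caesarean", "Caesarean Section", "births", None, 0.06, 1.0, 1.0, 0.3, 0.85, "maternal", 4,
     (1, 2, 33), (0, 0, 30, 0), (15, 15, 0, 10), (60, 120, 120, 240), 0.0),
    ("rupture", "Uterine Rupture & Hysterectomy", "births", None, 0.004, 1.0, 1.0, 0.3, 0.85, "maternal", 6,
     (1, 2, 60), (0, 0, 30, 0), (15, 15, 0, 10), (90, 180, 120, 360), 0.0),
    ("sepsis", "Intrapartum & Postpartum Infection", "births", None, 0.03, 1.0, 0.8, 0.2, 0.85, "maternal", 4,
     (3, 10, 100), (0, 0, 30, 0), (20, 15, 0, 15), (40, 30, 90, 300), 0.0),
    ("pph", "Postpartum Haemorrhage", "births", None, 0.05, 1.0, 0.9, 0.2, 0.85, "maternal", 3,
     (2, 5, 30), (0, 0, 30, 0), (20, 20, 0, 15), (60, 120, 120, 240), 0.0),
    ("delivery", "Normal Delivery", "births", None, 0.75, 0.05, 0.6, 0.1, 0.90, "maternal", 1,
     (12, 12, 18), (0, 0, 300, 30), (10, 0, 120, 20), (20, 0, 180, 120), 0.0),
    ("pnc", "Routine Postpartum Care", "births", None, 1.0, 0.02, 0.3, 0.0, 0.90, "maternal", 1,
     (1, 2, 4), (0, 0, 90, 0), (10, 0, 30, 10), (15, 0, 30, 60), 0.0),
    ("neonatal", "Neonatal Complications", "births", None, 0.12, 1.0, 0.9, 0.2, 0.85, "child", 5,
     (5, 30, 215), (0, 0, 30, 15), (20, 20, 0, 15), (45, 60, 30, 420), 0.0),
    ("infant_checks", "Routine Infant Health Checks", "infants_u1", None, 1.0, 0.01, 0.3, 0.0, 0.90, "child", 1,
     (0.4, 1, 3), (0, 0, 100, 40), (15, 0, 0, 10), (20, 0, 0, 60), 0.0),
    ("child_checks", "Routine Child Health Checks", "children_1_5", None, 1.0, 0.005, 0.3, 0.0, 0.90, "child", 1,
     (0.4, 1, 3), (5, 0, 0, 100), (15, 0, 0, 10), (20, 0, 0, 60), 0.0),
    ("immunisation", "Child Immunisation", "infants_u1", None, 1.0, 0.0, 0.0, 0.0, 0.95, "child", 0,
     (17, 0, 0), (0, 0, 0, 45), (0, 0, 0, 0), (0, 0, 0, 0), 0.0),
    ("feeding", "Supplementary Feeding", "children_1_5", "malnutrition", 0.5, 0.0, 0.0, 0.0, 0.80, "child", 0,
     (28, 0, 0), (0, 0, 20, 30), (0, 0, 0, 0), (0, 0, 0, 0), 0.0),
    ("severe_malnutrition", "Severe Malnutrition", "children_1_5", "malnutrition", 0.15, 0.8, 0.9, 0.1, 0.80, "child", 7,
     (10, 20, 45), (10, 0, 0, 30), (20, 10, 0, 15), (30, 30, 0, 420), 0.0),
    ("school_health", "School Health", "age>5", None, 0.25, 0.0, 0.0, 0.0, 0.90, "population", 0,
     (0.2, 0, 0), (2, 0, 0, 10), (0, 0, 0, 0), (0, 0, 0, 0), 0.0),
    ("fp_nonpermanent", "Family Planning (Non-permanent)", "eligible_couples", None, 0.8, 0.005, 0.2, 0.0, 0.75, "female", 1,
     (9, 9, 12), (0, 0, 15, 0), (10, 0, 10, 5), (15, 15, 15, 60), 0.0),
    ("fp_permanent", "Family Planning (Permanent)", "eligible_couples", None, 0.025, 1.0, 0.8, 1.0, 0.75, "female", 1,
     (2, 20, 85), (0, 0, 15, 0), (15, 30, 0, 10), (30, 90, 30, 120), 0.0),
    ("pneumonia_u5", "Pneumonia <5 years", "age<5", "pneumonia", 0.9, 0.15, 0.85, 0.05, 0.86, "child", 3,
     (22, 25, 40), (10, 0, 0, 10), (15, 10, 0, 10), (30, 20, 0, 180), 0.0),
    ("diarrhoea_u5", "Diarrhoea <5 years", "age<5", "diarrhoea", 0.6, 0.05, 0.8, 0.05, 0.80, "child", 2,
     (11, 12, 20), (8, 0, 0, 10), (12, 0, 0, 10), (25, 0, 0, 120), 0.0),
    ("diarrhoea_o5", "Diarrhoea >5 years", "age>5", "diarrhoea", 0.35, 0.02, 0.6, 0.05, 0.80, "population", 2,
     (14, 15, 22), (8, 0, 0, 10), (12, 0, 0, 10), (25, 0, 0, 120), 0.0),
    ("malaria_u5", "Malaria <5 years", "age<5", "malaria", 0.9, 0.10, 0.8, 0.05, 0.75, "child", 2,
     (5, 6, 10), (10, 0, 0, 12), (12, 0, 0, 10), (25, 0, 0, 120), 0.0),
    ("malaria_o5", "Malaria >5 years", "age>5", "malaria", 0.9, 0.05, 0.75, 0.05, 0.75, "population", 2,
     (9, 10, 14), (10, 0, 0, 12), (12, 0, 0, 10), (25, 0, 0, 120), 0.05),
    ("tb_u5", "Tuberculosis <5 years", "age<5", "tuberculosis", 1.0, 0.3, 0.5, 0.05, 0.85, "child", 5,
     (42, 45, 55), (12, 0, 0, 20), (15, 10, 0, 10), (30, 30, 0, 240), 0.0),
    ("tb_o5", "Tuberculosis >5 years", "age>5", "tuberculosis", 1.0, 0.2, 0.5, 0.05, 0.85, "population", 5,
     (40, 42, 50), (12, 0, 0, 20), (15, 10, 0, 10), (30, 30, 0, 240), 0.10),
    ("dengue_u5", "Dengue <5 years", "age<5", "dengue", 1.0, 0.8, 0.9, 0.3, 0.80, "child", 4,
     (8, 30, 90), (10, 0, 0, 12), (15, 10, 0, 10), (30, 30, 0, 240), 0.0),
    ("dengue_o5", "Dengue >5 years", "age>5", "dengue", 1.0, 0.8, 0.9, 0.3, 0.80, "population", 4,
     (8, 30, 94), (10, 0, 0, 12), (15, 10, 0, 10), (30, 30, 0, 240), 0.40),
]

_CADRES = ("doctor", "specialist", "midwife", "nurse")


def _staff_items(minutes: tuple, level: str) -> list[StaffTimeItem]:
    items = []
    for cadre, mins in zip(_CADRES, minutes):
        if mins <= 0:
            continue
        if level == "hospital_inpatient":
            activity = "ward_day" if cadre in ("nurse", "midwife") else "admission"
        else:
            activity = "consultation"
        items.append(StaffTimeItem(cadre=cadre, minutes=float(mins), activity=activity))
    return items


def _split_items(rng: np.random.Generator, v_target: float, label: str) -> list[ResourceItem]:
    """Split a variable-cost target into 1-3 drug/supply lines whose
    expected cost (price * quantity * probability) sums exactly to target."""
    if v_target <= 0:
        return []
    k = int(rng.integers(1, 4))
    weights = rng.dirichlet(np.ones(k) * 2.0)
    items = []
    for j in range(k):
        prob = float(rng.uniform(0.5, 1.0))
        qty = float(rng.integers(1, 3))
        items.append(ResourceItem(
            name=f"{label}_item{j + 1}",
            unit_price=float(weights[j]) * v_target / (prob * qty),
            quantity=qty,
            use_probability=prob,
        ))
    return items


def _build_service(seed: int, row: tuple, jitter: bool) -> ServiceDefinition:
    (sid, name, sel, driver, n, pi, m, sigma, cov, attr, days,
     v_targets, staff_p, staff_h, staff_ha, ppc) = row
    rng = _rng(seed, f"catalogue:{sid}")
    v_factor = rng.uniform(0.85, 1.15, size=3) if jitter else np.ones(3)
    s_factor = float(rng.uniform(0.9, 1.1)) if jitter else 1.0
    staff_by_level = {"primary": staff_p, "hospital_outpatient": staff_h, "hospital_inpatient": staff_ha}
    recipes = {}
    for li, level in enumerate(("primary", "hospital_outpatient", "hospital_inpatient")):
        minutes = tuple(x * s_factor for x in staff_by_level[level])
        recipes[level] = CareLevelRecipe(
            level=level,
            items=_split_items(rng, float(v_targets[li]) * float(v_factor[li]), f"{sid}_{level}"),
            staff=_staff_items(minutes, level),
            inpatient_days=float(days) if level == "hospital_inpatient" else 0.0,
        )
    utilisation = cov * float(rng.uniform(0.55, 0.90))
    return ServiceDefinition(
        id=sid, name=name, target_selector=sel, incidence_key=driver,
        facility_need=n, referral_fraction=pi, admission_fraction=m,
        self_referral_fraction=sigma, coverage_target=cov,
        utilisation_fraction=utilisation, attribution=attr,
        programme_overhead_per_capita=ppc, recipes=recipes,
    )


_MINIMAL_TEMPLATE: list[tuple] = [
    ("basic_primary", "Basic Primary Care", "all", "diarrhoea", 0.5, 0.0, 0.0, 0.0, 0.80,
     "population", 0, (5, 0, 0), (10, 0, 0, 15), (0, 0, 0, 0), (0, 0, 0, 0), 0.0),
    ("referral_care", "Delivery with Referral", "births", None, 1.0, 0.3, 0.6, 0.0, 0.90,
     "maternal", 3, (12, 10, 30), (0, 0, 120, 0), (15, 0, 30, 10), (30, 30, 60, 180), 0.0),
    ("vector_control", "Dengue Care & Vector Control", "all", "dengue", 1.0, 0.5, 0.8, 0.0, 0.80,
     "population", 4, (10, 25, 80), (10, 0, 0, 10), (15, 10, 0, 10), (30, 30, 0, 240), 0.30),
]


def generate_catalogue(seed: int, template: str = "spm_like") -> list[ServiceDefinition]:
    """Generate a deterministic service catalogue.

    ``spm_like`` yields the full package (32 conditions across maternal,
    child, reproductive and communicable-disease groups) with per-service
    seeded jitter on costs and staff minutes; ``minimal`` yields three fixed
    services (primary-only, referral path, population-overhead) for quick
    pipelines and tests.
    """
    if template == "spm_like":
        return [_build_service(seed, row, jitter=True) for row in _SPM_TEMPLATE]
    if template == "minimal":
        return [_build_service(seed, row, jitter=False) for row in _MINIMAL_TEMPLATE]
    raise ValueError(f"unknown catalogue template {template!r}")
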