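"""Fixed-overhead pools and their apportionment to episode costs.

Three pools are costed:

1. facility overheads — each facility's operating cost, annualised capital
   and indirect staffing (administration, clinical support, ancillary);
2. programme overheads attributable to particular services (e.g. vector
   spraying, surveillance), varying on a population basis;
3. administrative overheads of running the District Health Office (DHO).

Facility pools are spread over *all* projected workload — package episodes
plus an estimate of activity attributable to other conditions — so package
episodes bear only their share of fixed costs (economies of scope).
Hospital pools are split between inpatient and outpatient streams by a cost
weight, then divided by total bed-days and visits; health-centre pools are
divided by total primary visit-equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CareLevelRecipe, DistrictProfile, ServiceDefinition


@dataclass(frozen=True)
class OverheadPools:
    """Annual fixed-cost pools for one district."""

    facility_pool: dict[str, float]
    programme_pool: dict[str, float]
    dho_admin_pool: float = 0.0

    def __post_init__(self) -> None:
        if self.dho_admin_pool < 0:
            raise ValueError("negative DHO admin pool")
        for mapping in (self.facility_pool, self.programme_pool):
            for key, value in mapping.items():
                if value < 0:
                    raise ValueError(f"negative overhead pool for {key!r}")


@dataclass(frozen=True)
class OverheadRates:
    """Per-unit apportionment rates derived from the pools."""

    per_bed_day: float = 0.0
    per_outpatient_visit: float = 0.0
    per_primary_visit: float = 0.0
    per_capita_programme: dict[str, float] = field(default_factory=dict)
    per_capita_admin: float = 0.0


@dataclass(frozen=True)
class SpmWorkload:
    """Annual package workload by stream (episode counts and bed-days)."""

    primary_visits: float = 0.0
    outpatient_visits: float = 0.0
    bed_days: float = 0.0


def annualise_capital(cost: float, life_years: int, discount_rate: float) -> float:
    """Equivalent annual cost of a capital outlay over its useful life.

    Uses the annuity-factor method ``cost * r / (1 - (1 + r)^-n)``; a zero
    discount rate degenerates to straight-line ``cost / n``.
    """
    if life_years < 1:
        raise ValueError("life_years must be >= 1")
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    if discount_rate == 0:
        return cost / life_years
    return cost * discount_rate / (1.0 - (1.0 + discount_rate) ** -life_years)


def build_pools(district: DistrictProfile, catalogue: list[ServiceDefinition]) -> OverheadPools:
    """Assemble the three overhead pools from district and catalogue inputs."""
    facility_pool = {f.id: f.overhead_pool for f in district.facilities}
    programme_pool = {
        s.id: s.programme_overhead_per_capita * district.population for s in catalogue
    }
    return OverheadPools(
        facility_pool=facility_pool,
        programme_pool=programme_pool,
        dho_admin_pool=district.dho_admin_cost,
    )


def compute_overhead_rates(
    district: DistrictProfile,
    pools: OverheadPools,
    spm_workload: SpmWorkload,
    hospital_inpatient_weight: float = 0.7,
    centre_bed_day_equivalent: float = 2.0,
) -> OverheadRates:
    """Apportion pools to per-unit rates over total (package + other) workload.

    ``hospital_inpatient_weight`` splits each hospital's pool between the
    bed-day and outpatient-visit streams.  Bedded health centres' non-package
    bed-days enter the primary stream as visit-equivalents (default 2 visits
    per bed-day) so that every pool is fully recovered by its stream.
    """
    if not 0 <= hospital_inpatient_weight <= 1:
        raise ValueError("hospital_inpatient_weight must lie in [0, 1]")

    hospital_pool = sum(pools.facility_pool.get(f.id, 0.0) for f in district.hospitals)
    centre_pool = sum(pools.facility_pool.get(f.id, 0.0) for f in district.health_centres)

    total_bed_days = spm_workload.bed_days + sum(f.non_spm_bed_days for f in district.hospitals)
    total_opd = spm_workload.outpatient_visits + sum(
        f.non_spm_outpatient_visits for f in district.hospitals
    )
    total_primary = spm_workload.primary_visits + sum(
        f.non_spm_outpatient_visits + centre_bed_day_equivalent * f.non_spm_bed_days
        for f in district.health_centres
    )

    def _rate(pool: float, units: float, stream: str) -> float:
        if pool == 0:
            return 0.0
        if units <= 0:
            raise ValueError(f"positive {stream} pool but zero total {stream} workload")
        return pool / units

    inpatient_pool = hospital_inpatient_weight * hospital_pool
    outpatient_pool = (1.0 - hospital_inpatient_weight) * hospital_pool
    population = district.population
    return OverheadRates(
        per_bed_day=_rate(inpatient_pool, total_bed_days, "inpatient"),
        per_outpatient_visit=_rate(outpatient_pool, total_opd, "outpatient"),
        per_primary_visit=_rate(centre_pool, total_primary, "primary"),
        per_capita_programme={k: v / population for k, v in pools.programme_pool.items()},
        per_capita_admin=pools.dho_admin_pool / population,
    )


def overhead_for_recipe(
    recipe: CareLevelRecipe,
    rates: OverheadRates,
    admission_includes_visit: bool = False,
) -> float:
    """Fixed overhead borne by one episode at the recipe's care level."""
    if recipe.level == "primary":
        return rates.per_primary_visit
    if recipe.level == "hospital_outpatient":
        return rates.per_outpatient_visit
    overhead = recipe.inpatient_days * rates.per_bed_day
    if admission_includes_visit:
        overhead += rates.per_outpatient_visit
    return overhead
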