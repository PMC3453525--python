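"""District aggregation: service loads, total and per-capita budgets.

The annual district budget for the package is

    TotalCost_i = N_i * sum_j t_ij * d_ij * n_j * cov_j * c_ij
                  + population-based programme and DHO overheads

where ``N`` is population, ``t`` the target-group proportion, ``d`` the
presentation rate within the target group, ``n`` the fraction of cases
needing facility care, ``cov`` the coverage target (or observed utilisation
in utilisation mode) and ``c`` the blended per-episode unit cost.  The
report exposes both the total and the per-capita budget, plus service,
age-band and sex decompositions of the allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .episodes import (
    CostComponents,
    EpisodeCost,
    blend_episode_cost,
    cost_direct_staff,
    cost_variable,
    overhead_share,
)
from .geography import build_distance_map, referral_transport_cost
from .model import (
    AGE_BANDS,
    CARE_LEVELS,
    REPRODUCTIVE_BANDS,
    DistrictProfile,
    ServiceDefinition,
    WageTable,
    default_wage_table,
    target_proportion,
)
from .overheads import (
    OverheadRates,
    SpmWorkload,
    build_pools,
    compute_overhead_rates,
    overhead_for_recipe,
)


@dataclass(frozen=True)
class ServiceLoad:
    """Annual case-flow chain for one service in one district.

    Counts are expected values (fractional persons/episodes are kept, since
    they multiply unit costs).  ``referred_count`` is all episodes reaching
    hospital, whether transported from primary care or self-referred.
    """

    target_count: float
    case_count: float
    treated_count: float
    referred_count: float
    admitted_count: float

    def __post_init__(self) -> None:
        chain = (self.target_count, self.case_count, self.treated_count,
                 self.referred_count, self.admitted_count)
        if any(x < 0 for x in chain):
            raise ValueError("negative count in service load")
        for hi, lo in zip(chain, chain[1:]):
            if lo > hi * (1 + 1e-12) + 1e-9:
                raise ValueError("service load ordering violated (target >= case >= treated >= referred >= admitted)")


def service_load(service: ServiceDefinition, district: DistrictProfile,
                 mode: str = "need") -> ServiceLoad:
    """Expected annual case flow: N*t -> *d -> *n*coverage -> *pi -> *m."""
    t = target_proportion(service, district)
    if service.incidence_key is None:
        d = 1.0
    else:
        try:
            d = district.epi.rate(service.incidence_key)
        except KeyError:
            raise KeyError(
                f"service {service.id!r} needs epidemiology driver "
                f"{service.incidence_key!r}, absent from district {district.id!r}"
            ) from None
    if mode == "utilisation":
        cov = (service.utilisation_fraction
               if service.utilisation_fraction is not None else service.coverage_target)
    elif mode == "need":
        cov = service.coverage_target
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pi = service.referral_fraction
    m = service.admission_fraction
    sigma = service.self_referral_fraction
    target = district.population * t
    case = target * d
    treated = case * service.facility_need * cov
    referred = treated * ((1.0 - sigma) * pi + sigma)
    admitted = referred * m
    return ServiceLoad(target, case, treated, referred, admitted)


def spm_workload(catalogue: list[ServiceDefinition],
                 loads: dict[str, ServiceLoad]) -> SpmWorkload:
    """Aggregate package workload by stream over the whole catalogue."""
    primary = outpatient = bed_days = 0.0
    for s in catalogue:
        load = loads[s.id]
        primary += load.treated_count * (1.0 - s.self_referral_fraction)
        outpatient += load.referred_count - load.admitted_count
        bed_days += load.admitted_count * s.recipes["hospital_inpatient"].inpatient_days
    return SpmWorkload(primary_visits=primary, outpatient_visits=outpatient, bed_days=bed_days)


@dataclass(frozen=True)
class DistrictCostReport:
    """Costed annual budget for one district."""

    district_id: str
    population: int
    mode: str
    per_service: pd.DataFrame
    total_cost: float
    per_capita: float
    admin_overhead: float
    programme_overhead: float
    overhead_grand_total: float
    referral_cost_per_patient: float
    age_sex_shares: pd.DataFrame
    rates: OverheadRates


_PER_SERVICE_COLUMNS = [
    "service", "name", "target_count", "case_count", "treated_count",
    "referred_count", "admitted_count", "variable", "direct_staff",
    "overhead", "referral_transport", "episode_total", "overhead_pct",
    "service_cost", "programme_overhead", "total_cost", "per_capita",
]


def _attribution_weights(service: ServiceDefinition, district: DistrictProfile) -> pd.DataFrame:
    """Normalised (band x sex) benefit weights for one service."""
    dist = district.age_sex
    grid = pd.DataFrame(0.0, index=list(AGE_BANDS), columns=["female", "male"])
    rule = service.attribution
    if rule == "maternal":
        for band in REPRODUCTIVE_BANDS:
            grid.loc[band, "female"] = dist.female[band]
    elif rule == "child":
        grid.loc["0-4", "female"] = dist.female["0-4"]
        grid.loc["0-4", "male"] = dist.male["0-4"]
    elif rule == "female":
        for band in AGE_BANDS:
            grid.loc[band, "female"] = dist.female[band]
    elif rule == "male":
        for band in AGE_BANDS:
            grid.loc[band, "male"] = dist.male[band]
    elif rule == "population":
        for band in AGE_BANDS:
            grid.loc[band, "female"] = dist.female[band]
            grid.loc[band, "male"] = dist.male[band]
    else:  # pragma: no cover - pydantic Literal prevents this
        raise ValueError(f"service {service.id!r} has unattributable rule {rule!r}")
    total = float(grid.to_numpy().sum())
    if total <= 0:
        raise ValueError(f"attribution rule {rule!r} matches nobody in district {district.id!r}")
    return grid / total


def age_sex_allocation(
    service_costs: dict[str, float],
    catalogue: list[ServiceDefinition],
    district: DistrictProfile,
    admin_overhead: float = 0.0,
) -> pd.DataFrame:
    """Decompose the budget into benefit shares by age band and sex.

    Each service's cost is spread over the population cells its attribution
    rule names (maternal care to women 15-49, child services to under-fives
    by sex ratio, the rest population-proportionally); DHO administration is
    spread population-proportionally.  Shares sum to 1.
    """
    weighted = pd.DataFrame(0.0, index=list(AGE_BANDS), columns=["female", "male"])
    for service in catalogue:
        cost = service_costs.get(service.id, 0.0)
        if cost <= 0:
            continue
        weighted += cost * _attribution_weights(service, district)
    if admin_overhead > 0:
        pop_grid = pd.DataFrame(
            {"female": [district.age_sex.female[b] for b in AGE_BANDS],
             "male": [district.age_sex.male[b] for b in AGE_BANDS]},
            index=list(AGE_BANDS),
        )
        weighted += admin_overhead * pop_grid
    total = float(weighted.to_numpy().sum())
    if total > 0:
        weighted /= total
    return weighted


def cost_district(
    district: DistrictProfile,
    catalogue: list[ServiceDefinition],
    wages: Optional[WageTable] = None,
    config: Optional[RunConfig] = None,
) -> DistrictCostReport:
    """Full bottom-up costing of one district for one catalogue."""
    wages = wages or default_wage_table()
    config = config or RunConfig()

    loads = {s.id: service_load(s, district, mode=config.mode) for s in catalogue}
    workload = spm_workload(catalogue, loads)
    pools = build_pools(district, catalogue)
    rates = compute_overhead_rates(
        district, pools, workload,
        hospital_inpatient_weight=config.hospital_split,
        centre_bed_day_equivalent=config.centre_bed_day_equivalent,
    )
    dmap = build_distance_map(district)
    referral = referral_transport_cost(
        dmap, district, cost_per_km=config.cost_per_km, round_trip=config.round_trip,
    )

    rows = []
    service_costs: dict[str, float] = {}
    for s in catalogue:
        load = loads[s.id]
        level_costs = {
            level: CostComponents(
                variable=cost_variable(s.recipes[level]),
                direct_staff=cost_direct_staff(s.recipes[level], wages),
                overhead=overhead_for_recipe(
                    s.recipes[level], rates,
                    admission_includes_visit=config.admission_includes_visit,
                ),
            )
            for level in CARE_LEVELS
        }
        episode = blend_episode_cost(
            s, level_costs, referral_cost=referral.r_i,
            referral_cost_mode=config.referral_cost_mode,
        )
        service_cost = load.treated_count * episode.total
        programme = s.programme_overhead_per_capita * district.population
        total_j = service_cost + programme
        service_costs[s.id] = total_j
        rows.append({
            "service": s.id,
            "name": s.name,
            "target_count": load.target_count,
            "case_count": load.case_count,
            "treated_count": load.treated_count,
            "referred_count": load.referred_count,
            "admitted_count": load.admitted_count,
            "variable": episode.blended.variable,
            "direct_staff": episode.blended.direct_staff,
            "overhead": episode.blended.overhead,
            "referral_transport": episode.referral_transport,
            "episode_total": episode.total,
            "overhead_pct": 100.0 * overhead_share(episode) if episode.total > 0 else 0.0,
            "service_cost": service_cost,
            "programme_overhead": programme,
            "total_cost": total_j,
            "per_capita": total_j / district.population,
        })
    per_service = pd.DataFrame(rows, columns=_PER_SERVICE_COLUMNS)

    admin = pools.dho_admin_pool
    programme_total = float(per_service["programme_overhead"].sum()) if rows else 0.0
    total_cost = (float(per_service["total_cost"].sum()) if rows else 0.0) + admin
    overhead_grand = (
        (float((per_service["overhead"] * per_service["treated_count"]).sum()) if rows else 0.0)
        + programme_total + admin
    )
    shares = age_sex_allocation(service_costs, catalogue, district, admin_overhead=admin)
    return DistrictCostReport(
        district_id=district.id,
        population=district.population,
        mode=config.mode,
        per_service=per_service,
        total_cost=total_cost,
        per_capita=total_cost / district.population,
        admin_overhead=admin,
        programme_overhead=programme_total,
        overhead_grand_total=overhead_grand,
        referral_cost_per_patient=referral.r_i,
        age_sex_shares=shares,
        rates=rates,
    )
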