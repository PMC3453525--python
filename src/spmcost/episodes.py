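"""Per-episode unit costs.

An episode cost at each care level splits into three components:

    c = v + s + f

where ``v`` is variable cost (drugs, laboratory tests, supplies), ``s`` is
direct staffing (contact minutes priced at salary per effective minute) and
``f`` is the apportioned fixed overhead of the facility.  The blended unit
cost of a full care path combines the levels through the referral fraction
``pi`` and the admission fraction ``m``:

    c = c_primary + pi * [(1 - m) * c_hosp_outpatient + m * c_hosp_inpatient]

plus referral transport.  A self-referral fraction ``sigma`` of
facility-seeking cases bypasses primary care and starts at hospital level
with no primary cost and no system transport cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .model import CareLevelRecipe, ServiceDefinition, WageTable

ReferralCostMode = Literal["per_referred", "per_episode"]


@dataclass(frozen=True)
class CostComponents:
    """The (v, s, f) money triplet of an episode cost."""

    variable: float = 0.0
    direct_staff: float = 0.0
    overhead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("variable", "direct_staff", "overhead"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} cost component")

    @property
    def total(self) -> float:
        return self.variable + self.direct_staff + self.overhead

    def __add__(self, other: "CostComponents") -> "CostComponents":
        return CostComponents(
            variable=self.variable + other.variable,
            direct_staff=self.direct_staff + other.direct_staff,
            overhead=self.overhead + other.overhead,
        )

    def scale(self, factor: float) -> "CostComponents":
        return CostComponents(
            variable=self.variable * factor,
            direct_staff=self.direct_staff * factor,
            overhead=self.overhead * factor,
        )


@dataclass(frozen=True)
class EpisodeCost:
    """Blended unit cost of one episode of a service in one district."""

    per_level: dict[str, CostComponents]
    blended: CostComponents
    referral_transport: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", self.blended.total + self.referral_transport)


def cost_variable(recipe: CareLevelRecipe) -> float:
    """Expected drug/supply cost of a recipe.

    Each line contributes ``unit_price * quantity * use_probability`` — the
    probability captures that not every patient with the condition needs
    every listed item.
    """
    return sum(i.unit_price * i.quantity * i.use_probability for i in recipe.items)


def cost_direct_staff(recipe: CareLevelRecipe, wages: WageTable) -> float:
    """Direct staffing cost: contact minutes priced per cadre.

    A cadre's minute costs ``daily_salary / (effective_hours * 60)``, so
    limited availability (private practice absorbing part of the day) raises
    the cost of each contact minute.
    """
    return sum(s.minutes * wages.cost_per_minute(s.cadre) for s in recipe.staff)


def blend_episode_cost(
    service: ServiceDefinition,
    level_costs: Mapping[str, CostComponents],
    referral_cost: float = 0.0,
    referral_cost_mode: ReferralCostMode = "per_referred",
) -> EpisodeCost:
    """Combine per-level cost triplets into one blended episode cost.

    ``referral_cost`` is the district's mean transport cost per referred
    patient.  In the default ``per_referred`` mode it is weighted by the
    fraction of episodes that actually travel (pi, excluding
    self-referrals); ``per_episode`` charges it to every episode instead.
    """
    pi = service.referral_fraction
    m = service.admission_fraction
    sigma = service.self_referral_fraction

    def _blend(attr: str) -> float:
        p = getattr(level_costs["primary"], attr)
        h = getattr(level_costs["hospital_outpatient"], attr)
        ha = getattr(level_costs["hospital_inpatient"], attr)
        hospital = (1.0 - m) * h + m * ha
        standard = p + pi * hospital
        return (1.0 - sigma) * standard + sigma * hospital

    blended = CostComponents(
        variable=_blend("variable"),
        direct_staff=_blend("direct_staff"),
        overhead=_blend("overhead"),
    )
    if referral_cost_mode == "per_referred":
        transport = (1.0 - sigma) * pi * referral_cost
    elif referral_cost_mode == "per_episode":
        transport = referral_cost
    else:
        raise ValueError(f"unknown referral_cost_mode {referral_cost_mode!r}")
    return EpisodeCost(
        per_level={level: level_costs[level] for level in level_costs},
        blended=blended,
        referral_transport=transport,
    )


def overhead_share(cost: EpisodeCost) -> float:
    """Fixed-overhead fraction of the blended episode total (in [0, 1])."""
    if cost.total <= 0:
        raise ValueError("overhead share undefined for zero-total episode cost")
    return cost.blended.overhead / cost.total


def overhead_percent(cost: EpisodeCost) -> int:
    """Overhead share as the whole percentage used in episode-cost tables."""
    return round(100.0 * overhead_share(cost))
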