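"""One-driver-at-a-time sensitivity sweeps and elasticities.

The elasticity of the per-capita package cost with respect to a need driver
is the percentage change in cost per one percentage-point change in the
driver level, holding all other inputs constant:

    elasticity = 100 * [(c_hi - c_lo) / (L_hi - L_lo)] / c_lo

with levels ``L`` expressed in percentage points for rate drivers.  A
positive elasticity means per-capita cost rises with the driver; demographic
drivers (births, infants, young children) dominate communicable-disease
prevalences because they expose a large population to a wide range of
sometimes expensive conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import RunConfig
from .district import cost_district
from .model import KNOWN_DRIVERS, DistrictProfile, ServiceDefinition, WageTable


@dataclass(frozen=True)
class ElasticityResult:
    """One sensitivity-table row: costs at min/avg/max driver levels."""

    driver: str
    level_min: float
    level_avg: float
    level_max: float
    cost_min_level: float
    cost_avg: float
    cost_max_level: float
    elasticity: float


def elasticity(cost_lo: float, cost_hi: float, level_lo: float, level_hi: float) -> float:
    """Percent cost change per unit driver change, normalised at the low level."""
    if level_hi == level_lo:
        raise ValueError("driver levels must differ")
    if cost_lo <= 0:
        raise ValueError("cost at the low level must be positive")
    return 100.0 * ((cost_hi - cost_lo) / (level_hi - level_lo)) / cost_lo


def _district_at_level(district: DistrictProfile, driver: str, level: float) -> DistrictProfile:
    rates = dict(district.epi.rates)
    rates[driver] = level
    return district.model_copy(update={"epi": district.epi.model_copy(update={"rates": rates})})


def sweep_driver(
    district: DistrictProfile,
    catalogue: list[ServiceDefinition],
    driver: str,
    levels: Sequence[float],
    wages: Optional[WageTable] = None,
    config: Optional[RunConfig] = None,
) -> list[float]:
    """Per-capita cost at each driver level, all else held constant.

    Levels are fractions in [0, 1].  The baseline district object is never
    mutated; each point re-costs a copy with only the driver changed.
    """
    if driver not in KNOWN_DRIVERS:
        raise ValueError(f"unknown driver {driver!r}")
    if driver not in district.epi.rates:
        raise ValueError(f"driver {driver!r} not present in district {district.id!r}")
    costs = []
    for level in levels:
        modified = _district_at_level(district, driver, float(level))
        costs.append(cost_district(modified, catalogue, wages=wages, config=config).per_capita)
    return costs


def driver_elasticity(
    district: DistrictProfile,
    catalogue: list[ServiceDefinition],
    driver: str,
    levels: Sequence[float],
    wages: Optional[WageTable] = None,
    config: Optional[RunConfig] = None,
) -> ElasticityResult:
    """Sweep (min, avg, max) driver levels and compute the elasticity.

    ``levels`` are fractions; the elasticity denominator uses percentage
    points, matching how sensitivity tables print driver levels.
    """
    lo, avg, hi = sorted(float(x) for x in levels)
    c_lo, c_avg, c_hi = sweep_driver(district, catalogue, driver, [lo, avg, hi],
                                     wages=wages, config=config)
    return ElasticityResult(
        driver=driver,
        level_min=lo, level_avg=avg, level_max=hi,
        cost_min_level=c_lo, cost_avg=c_avg, cost_max_level=c_hi,
        elasticity=elasticity(c_lo, c_hi, 100.0 * lo, 100.0 * hi),
    )
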