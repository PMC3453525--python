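"""Run configuration shared across the costing pipeline."""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """Tunable pipeline settings with conventional costing defaults.

    ``mode`` selects the budget concept: ``need`` costs the politically set
    coverage targets, ``utilisation`` costs observed uptake instead.
    ``cost_per_km`` is the emergency-transport tariff in USD per vehicle-km.
    ``hospital_split`` is the share of a hospital's fixed pool attributed to
    the inpatient (bed-day) stream.
    """

    model_config = ConfigDict(frozen=True)

    mode: Literal["need", "utilisation"] = "need"
    currency: str = "USD"
    referral_cost_mode: Literal["per_referred", "per_episode"] = "per_referred"
    round_trip: bool = True
    cost_per_km: float = Field(default=0.5, ge=0)
    discount_rate: float = Field(default=0.03, ge=0, le=1)
    building_life_years: int = Field(default=20, ge=1)
    equipment_life_years: int = Field(default=5, ge=1)
    hospital_split: float = Field(default=0.7, ge=0, le=1)
    centre_bed_day_equivalent: float = Field(default=2.0, ge=0)
    admission_includes_visit: bool = False
    log_level: str = "INFO"
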