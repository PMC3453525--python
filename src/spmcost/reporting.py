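"""Tabular report writers.

CSV reports carry display rounding (whole USD per episode, two-decimal
per-capita figures, conventional for published episode-cost tables); the
JSON run summary carries full-precision values plus input digests and the
configuration, so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .district import DistrictCostReport

EPISODE_REPORT_COLUMNS = [
    "service", "direct_supplies", "direct_staff", "overhead", "total",
    "overhead_pct", "per_capita",
]


def write_episode_report(report: DistrictCostReport, path: str | os.PathLike) -> Path:
    """Write the per-service episode-cost table.

    Columns: service, direct_supplies, direct_staff, overhead, total,
    overhead_pct (whole percent of the episode total that is fixed
    overhead), per_capita (service cost per district resident, 2 d.p.).
    """
    src = report.per_service
    out = pd.DataFrame({
        "service": src["name"],
        "direct_supplies": src["variable"].round(0).astype(int),
        "direct_staff": src["direct_staff"].round(0).astype(int),
        "overhead": src["overhead"].round(0).astype(int),
        "total": src["episode_total"].round(0).astype(int),
        "overhead_pct": src["overhead_pct"].round(0).astype(int),
        "per_capita": src["per_capita"].round(2),
    }, columns=EPISODE_REPORT_COLUMNS)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def write_district_report(report: DistrictCostReport, path: str | os.PathLike) -> Path:
    """Write the full per-service district costing table (full precision)."""
    path = Path(path)
    report.per_service.to_csv(path, index=False, float_format="%.10g")
    return path


def _digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_summary(
    report: DistrictCostReport,
    config: RunConfig,
    path: str | os.PathLike,
    input_paths: dict[str, str | os.PathLike] | None = None,
) -> Path:
    """Write the JSON run summary (full precision, reproducibility metadata)."""
    summary = {
        "district": report.district_id,
        "population": report.population,
        "mode": report.mode,
        "total_cost": report.total_cost,
        "per_capita": report.per_capita,
        "admin_overhead": report.admin_overhead,
        "programme_overhead": report.programme_overhead,
        "overhead_grand_total": report.overhead_grand_total,
        "referral_cost_per_patient": report.referral_cost_per_patient,
        "age_sex_shares": {
            sex: {band: report.age_sex_shares.loc[band, sex] for band in report.age_sex_shares.index}
            for sex in report.age_sex_shares.columns
        },
        "config": config.model_dump(),
        "input_digests": {name: _digest(p) for name, p in (input_paths or {}).items()},
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
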