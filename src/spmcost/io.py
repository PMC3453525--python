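"""Readers and writers for service catalogues and district profiles.

Both entities are stored as a YAML manifest referencing one CSV per record
kind (diffable and spreadsheet-editable, mirroring the condition-specific
costing sheets the inputs originate from).  All CSVs are UTF-8,
comma-separated, header row required, decimal point.  Money columns may be
in a local currency; the manifest's ``fx_to_usd`` rate is applied once at
load so the in-memory model is always USD.
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
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


class CatalogueError(ValueError):
    """Raised when a service-catalogue file fails schema validation."""


class DistrictError(ValueError):
    """Raised when a district-profile file fails schema validation."""


_SERVICE_COLUMNS = [
    "id", "name", "target_selector", "incidence_key", "facility_need",
    "referral_fraction", "admission_fraction", "self_referral_fraction",
    "coverage_target", "utilisation_fraction", "attribution",
    "programme_overhead_per_capita", "inpatient_days",
]
_ITEM_COLUMNS = ["service_id", "level", "name", "unit_price", "quantity", "use_probability"]
_STAFF_COLUMNS = ["service_id", "level", "cadre", "minutes", "activity"]
_FACILITY_MONEY = ["annual_operating_cost", "annualised_capital", "indirect_staff_cost"]


def _first_error(exc: ValidationError) -> str:
    err = exc.errors()[0]
    loc = ".".join(str(p) for p in err["loc"]) or "<model>"
    return f"{loc}: {err['msg']}"


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _read_manifest(path: str | os.PathLike) -> tuple[dict, Path]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError(f"manifest {path} is not a mapping")
    return manifest, path.parent


def _read_csv(path) -> pd.DataFrame:
    # round_trip float parsing so save -> load is an exact identity
    return pd.read_csv(path, float_precision="round_trip")


def load_service_catalogue(path: str | os.PathLike) -> list[ServiceDefinition]:
    """Load a service catalogue from its YAML manifest.

    Raises :class:`CatalogueError` naming the offending file, row and field
    on any schema or invariant violation.
    """
    manifest, base = _read_manifest(path)
    fx = float(manifest.get("fx_to_usd", 1.0))
    services_df = _read_csv(base / manifest["services"])
    items_df = _read_csv(base / manifest["items"]) if manifest.get("items") else pd.DataFrame(columns=_ITEM_COLUMNS)
    staff_df = _read_csv(base / manifest["staff"]) if manifest.get("staff") else pd.DataFrame(columns=_STAFF_COLUMNS)

    items_by_key: dict[tuple[str, str], list[ResourceItem]] = {}
    for i, row in items_df.iterrows():
        try:
            item = ResourceItem(
                name=str(row["name"]),
                unit_price=float(row["unit_price"]) * fx,
                quantity=float(row["quantity"]),
                use_probability=float(row["use_probability"]),
            )
        except (ValidationError, ValueError) as exc:
            msg = _first_error(exc) if isinstance(exc, ValidationError) else str(exc)
            raise CatalogueError(f"items.csv row {i}: {msg}") from None
        items_by_key.setdefault((str(row["service_id"]), str(row["level"])), []).append(item)

    staff_by_key: dict[tuple[str, str], list[StaffTimeItem]] = {}
    for i, row in staff_df.iterrows():
        try:
            entry = StaffTimeItem(
                cadre=str(row["cadre"]),
                minutes=float(row["minutes"]),
                activity=str(row["activity"]),
            )
        except ValidationError as exc:
            raise CatalogueError(f"staff.csv row {i}: {_first_error(exc)}") from None
        staff_by_key.setdefault((str(row["service_id"]), str(row["level"])), []).append(entry)

    catalogue: list[ServiceDefinition] = []
    seen: set[str] = set()
    for i, row in services_df.iterrows():
        sid = str(row["id"])
        if sid in seen:
            raise CatalogueError(f"services.csv row {i}: duplicate service id {sid!r}")
        seen.add(sid)
        recipes = {}
        for level in CARE_LEVELS:
            days = float(row["inpatient_days"]) if level == "hospital_inpatient" else 0.0
            recipes[level] = CareLevelRecipe(
                level=level,
                items=items_by_key.get((sid, level), []),
                staff=staff_by_key.get((sid, level), []),
                inpatient_days=days,
            )
        try:
            service = ServiceDefinition(
                id=sid,
                name=str(row["name"]),
                target_selector=str(row["target_selector"]),
                incidence_key=_opt_str(row.get("incidence_key")),
                facility_need=float(row["facility_need"]),
                referral_fraction=float(row["referral_fraction"]),
                admission_fraction=float(row["admission_fraction"]),
                self_referral_fraction=float(row.get("self_referral_fraction", 0.0)),
                coverage_target=float(row["coverage_target"]),
                utilisation_fraction=_opt_float(row.get("utilisation_fraction")),
                attribution=str(row.get("attribution", "population")),
                programme_overhead_per_capita=float(row.get("programme_overhead_per_capita", 0.0)) * fx,
                recipes=recipes,
            )
        except ValidationError as exc:
            raise CatalogueError(f"services.csv row {i} (id={sid}): {_first_error(exc)}") from None
        catalogue.append(service)
    if not catalogue:
        raise CatalogueError("catalogue is empty")
    return catalogue


def save_service_catalogue(catalogue: list[ServiceDefinition], directory: str | os.PathLike,
                           manifest_name: str = "catalogue.yaml") -> Path:
    """Write a catalogue as manifest + CSVs; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    svc_rows, item_rows, staff_rows = [], [], []
    for s in catalogue:
        svc_rows.append({
            "id": s.id, "name": s.name, "target_selector": s.target_selector,
            "incidence_key": s.incidence_key if s.incidence_key is not None else "",
            "facility_need": s.facility_need, "referral_fraction": s.referral_fraction,
            "admission_fraction": s.admission_fraction,
            "self_referral_fraction": s.self_referral_fraction,
            "coverage_target": s.coverage_target,
            "utilisation_fraction": "" if s.utilisation_fraction is None else s.utilisation_fraction,
            "attribution": s.attribution,
            "programme_overhead_per_capita": s.programme_overhead_per_capita,
            "inpatient_days": s.recipes["hospital_inpatient"].inpatient_days,
        })
        for level in CARE_LEVELS:
            recipe = s.recipes[level]
            for item in recipe.items:
                item_rows.append({
                    "service_id": s.id, "level": level, "name": item.name,
                    "unit_price": item.unit_price, "quantity": item.quantity,
                    "use_probability": item.use_probability,
                })
            for st in recipe.staff:
                staff_rows.append({
                    "service_id": s.id, "level": level, "cadre": st.cadre,
                    "minutes": st.minutes, "activity": st.activity,
                })
    pd.DataFrame(svc_rows, columns=_SERVICE_COLUMNS).to_csv(directory / "services.csv", index=False)
    pd.DataFrame(item_rows, columns=_ITEM_COLUMNS).to_csv(directory / "items.csv", index=False)
    pd.DataFrame(staff_rows, columns=_STAFF_COLUMNS).to_csv(directory / "staff.csv", index=False)
    manifest = {
        "kind": "service_catalogue",
        "currency": "USD",
        "fx_to_usd": 1.0,
        "services": "services.csv",
        "items": "items.csv",
        "staff": "staff.csv",
    }
    manifest_path = directory / manifest_name
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def load_district(path: str | os.PathLike) -> DistrictProfile:
    """Load a district profile from its YAML manifest.

    Facility coordinates may be planar km (``x_km,y_km``) or geographic
    (``lat,lon``); the coordinate system is recorded on the profile and
    drives the distance computation downstream.
    """
    manifest, base = _read_manifest(path)
    fx = float(manifest.get("fx_to_usd", 1.0))

    age_df = _read_csv(base / manifest["age_sex"])
    female = {str(r["band"]): float(r["female"]) for _, r in age_df.iterrows()}
    male = {str(r["band"]): float(r["male"]) for _, r in age_df.iterrows()}
    epi_df = _read_csv(base / manifest["epidemiology"])
    rates = {str(r["driver"]): float(r["rate"]) for _, r in epi_df.iterrows()}

    fac_df = _read_csv(base / manifest["facilities"])
    if {"lat", "lon"} <= set(fac_df.columns):
        coord_system, xcol, ycol = "latlon", "lon", "lat"
    elif {"x_km", "y_km"} <= set(fac_df.columns):
        coord_system, xcol, ycol = "planar_km", "x_km", "y_km"
    else:
        raise DistrictError("facilities.csv needs either x_km,y_km or lat,lon columns")

    facilities = []
    for i, row in fac_df.iterrows():
        try:
            facilities.append(Facility(
                id=str(row["id"]),
                kind=str(row["kind"]),
                x=float(row[xcol]),
                y=float(row[ycol]),
                annual_operating_cost=float(row["annual_operating_cost"]) * fx,
                annualised_capital=float(row["annualised_capital"]) * fx,
                indirect_staff_cost=float(row["indirect_staff_cost"]) * fx,
                non_spm_bed_days=float(row.get("non_spm_bed_days", 0.0)),
                non_spm_outpatient_visits=float(row.get("non_spm_outpatient_visits", 0.0)),
                catchment_population=int(row.get("catchment_population", 0)),
            ))
        except ValidationError as exc:
            raise DistrictError(f"facilities.csv row {i}: {_first_error(exc)}") from None

    try:
        return DistrictProfile(
            id=str(manifest["id"]),
            population=int(manifest["population"]),
            age_sex=AgeSexDistribution(female=female, male=male),
            epi=EpidemiologyProfile(rates=rates),
            facilities=facilities,
            area_km2=float(manifest["area_km2"]),
            dho_admin_cost=float(manifest.get("dho_admin_cost", 0.0)) * fx,
            coord_system=coord_system,
        )
    except ValidationError as exc:
        raise DistrictError(f"district manifest {path}: {_first_error(exc)}") from None


def save_district(district: DistrictProfile, directory: str | os.PathLike,
                  manifest_name: str = "district.yaml") -> Path:
    """Write a district profile as manifest + CSVs; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    age_rows = [
        {"band": band, "female": district.age_sex.female[band], "male": district.age_sex.male[band]}
        for band in AGE_BANDS
    ]
    pd.DataFrame(age_rows, columns=["band", "female", "male"]).to_csv(directory / "age_sex.csv", index=False)
    epi_rows = [{"driver": k, "rate": v} for k, v in sorted(district.epi.rates.items())]
    pd.DataFrame(epi_rows, columns=["driver", "rate"]).to_csv(directory / "epi.csv", index=False)

    xcol, ycol = ("lon", "lat") if district.coord_system == "latlon" else ("x_km", "y_km")
    fac_rows = []
    for f in district.facilities:
        fac_rows.append({
            "id": f.id, "kind": f.kind, xcol: f.x, ycol: f.y,
            "annual_operating_cost": f.annual_operating_cost,
            "annualised_capital": f.annualised_capital,
            "indirect_staff_cost": f.indirect_staff_cost,
            "non_spm_bed_days": f.non_spm_bed_days,
            "non_spm_outpatient_visits": f.non_spm_outpatient_visits,
            "catchment_population": f.catchment_population,
        })
    fac_cols = ["id", "kind", xcol, ycol, *_FACILITY_MONEY,
                "non_spm_bed_days", "non_spm_outpatient_visits", "catchment_population"]
    pd.DataFrame(fac_rows, columns=fac_cols).to_csv(directory / "facilities.csv", index=False)

    manifest = {
        "kind": "district_profile",
        "id": district.id,
        "population": district.population,
        "area_km2": district.area_km2,
        "dho_admin_cost": district.dho_admin_cost,
        "currency": "USD",
        "fx_to_usd": 1.0,
        "age_sex": "age_sex.csv",
        "epidemiology": "epi.csv",
        "facilities": "facilities.csv",
    }
    manifest_path = directory / manifest_name
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
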