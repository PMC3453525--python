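"""Straight-line referral geography.

The system bears the cost of transporting referred patients from health
centres to hospital.  A simple map computes the straight-line distance
between every health centre and every district hospital; each centre refers
to its nearest hospital and the district referral cost ``r`` is the
catchment-population-weighted mean transport cost across centres.

Straight lines understate true travel (roads bend, terrain and water
crossings slow and cost more), so ``r`` is a floor on the real transport
cost; local knowledge should augment it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import DistrictProfile

_EARTH_RADIUS_KM = 6371.0088


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class DistanceMap:
    """Centre-to-hospital distances (km) and nearest-hospital assignment."""

    distances: pd.DataFrame  # index: centre ids, columns: hospital ids (sorted)
    nearest_hospital: dict[str, str]

    def nearest_distance(self, centre_id: str) -> float:
        return float(self.distances.loc[centre_id, self.nearest_hospital[centre_id]])


@dataclass(frozen=True)
class ReferralCost:
    """District referral transport cost per referred patient."""

    r_i: float
    per_centre: dict[str, float]


def build_distance_map(district: DistrictProfile) -> DistanceMap:
    """Distances from every health centre to every hospital.

    Coordinates are planar km by default; profiles tagged lat/lon use
    great-circle (haversine) distances.  Nearest-hospital ties break on
    lexicographic facility id, so reruns are deterministic.
    """
    hospitals = sorted(district.hospitals, key=lambda f: f.id)
    centres = district.health_centres
    if not hospitals:
        raise ValueError("district has no hospital")
    centre_ids = [c.id for c in centres]
    hospital_ids = [h.id for h in hospitals]
    if centres:
        if district.coord_system == "latlon":
            clat = np.array([[c.y] for c in centres])
            clon = np.array([[c.x] for c in centres])
            hlat = np.array([[h.y for h in hospitals]])
            hlon = np.array([[h.x for h in hospitals]])
            dist = _haversine_km(clat, clon, hlat, hlon)
        else:
            cxy = np.array([[c.x, c.y] for c in centres])
            hxy = np.array([[h.x, h.y] for h in hospitals])
            dist = cdist(cxy, hxy)
    else:
        dist = np.empty((0, len(hospitals)))
    frame = pd.DataFrame(dist, index=centre_ids, columns=hospital_ids)
    # idxmin returns the first (lexicographically smallest, columns sorted)
    # minimiser, giving the deterministic tie-break.
    nearest = {cid: str(frame.loc[cid].idxmin()) for cid in centre_ids}
    return DistanceMap(distances=frame, nearest_hospital=nearest)


def referral_transport_cost(
    dmap: DistanceMap,
    district: DistrictProfile,
    cost_per_km: float,
    round_trip: bool = True,
    tariff_multiplier: Optional[Mapping[str, float]] = None,
) -> ReferralCost:
    """Impute the district transport cost per referred patient.

    ``tariff_multiplier`` is a per-centre hook for edges that are costlier
    per km (e.g. water crossings); default multiplier is 1.  ``round_trip``
    doubles the distance (the vehicle returns).
    """
    if cost_per_km < 0:
        raise ValueError("cost_per_km must be >= 0")
    trip_factor = 2.0 if round_trip else 1.0
    per_centre: dict[str, float] = {}
    for centre in district.health_centres:
        mult = 1.0 if tariff_multiplier is None else float(tariff_multiplier.get(centre.id, 1.0))
        per_centre[centre.id] = dmap.nearest_distance(centre.id) * cost_per_km * trip_factor * mult
    weights = {c.id: c.catchment_population for c in district.health_centres}
    total_weight = sum(weights.values())
    if not per_centre or total_weight == 0:
        r_i = 0.0
    else:
        r_i = sum(per_centre[cid] * w for cid, w in weights.items()) / total_weight
    return ReferralCost(r_i=r_i, per_centre=per_centre)
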