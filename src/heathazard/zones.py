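"""Zonal statistics and ranking of hazard surfaces over polygons.

Zones come from GeoJSON (FeatureCollection of Polygon/MultiPolygon).  A
pixel belongs to a zone iff its center falls inside the polygon — simple,
reproducible and resolution-appropriate for fine grids.  Per zone we report
the mean AH over covered valid pixels, the OLS slope and p-value of the
zone-mean annual hazard over the years, and descending ranks by AH and by
slope (ties broken by zone id).  Zones with no valid pixel are flagged and
excluded from the rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .hazard import linear_trend

__all__ = ["Zone", "read_zones", "zonal_statistics"]


@dataclass(frozen=True)
class Zone:
    zone_id: str
    name: str
    geometry: object  # shapely geometry


def read_zones(path, id_property: str = "id", name_property: str = "name"):
    """Zones from a GeoJSON FeatureCollection.

    Falls back to the feature index for missing ids and to the id for
    missing names.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    zones = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        zid = str(props.get(id_property, feat.get("id", i)))
        zones.append(Zone(zone_id=zid, name=str(props.get(name_property, zid)),
                          geometry=shapely_shape(feat["geometry"])))
    if not zones:
        raise ValueError("zone file contains no features")
    return zones


def _pixel_membership(zone: Zone, lon: np.ndarray, lat: np.ndarray):
    gx, gy = np.meshgrid(lon, lat)
    return shapely.contains_xy(zone.geometry, gx.ravel(), gy.ravel()).reshape(gx.shape)


def zonal_statistics(ah, hazard_by_year, years, lon, lat, zones,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Zone table: mean AH, hazard trend, and descending ranks.

    Parameters
    ----------
    ah : (ny, nx) array — average hazard surface (NaN = invalid pixel).
    hazard_by_year : (n_years, ny, nx) array.
    years : length n_years.
    lon, lat : pixel-center coordinate vectors.
    zones : sequence of :class:`Zone`.
    """
    ah = np.asarray(ah, dtype=float)
    hz = np.asarray(hazard_by_year, dtype=float)
    if not zones:
        raise ValueError("empty zone set")
    rows = []
    for z in zones:
        inside = _pixel_membership(z, np.asarray(lon), np.asarray(lat))
        valid = inside & np.isfinite(ah)
        n = int(valid.sum())
        if n == 0:
            rows.append({"zone_id": z.zone_id, "name": z.name, "n_pixels": 0,
                         "mean_ah": np.nan, "slope": np.nan, "p": np.nan,
                         "significant": False, "valid": False})
            continue
        series = hz[:, valid].mean(axis=1)
        tr = linear_trend(series, years, alpha=alpha)
        rows.append({"zone_id": z.zone_id, "name": z.name, "n_pixels": n,
                     "mean_ah": float(ah[valid].mean()),
                     "slope": tr["slope"], "p": tr["p"],
                     "significant": bool(tr["significant"]), "valid": True})
    df = pd.DataFrame(rows)
    for col, rank_col in (("mean_ah", "rank_ah"), ("slope", "rank_slope")):
        ok = df["valid"]
        sub = df.loc[ok].sort_values([col, "zone_id"],
                                     ascending=[False, True], kind="stable")
        df[rank_col] = pd.Series(np.arange(1, ok.sum() + 1), index=sub.index)
        df[rank_col] = df[rank_col].astype("Int64")
    return df
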