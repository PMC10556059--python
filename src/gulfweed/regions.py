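"""Regional grouping of sample locations in the western Atlantic.

Samples are grouped into the northern Sargasso Sea (NSS), Sargasso Sea (SS),
Caribbean (CAR) and western tropical Atlantic (WTA); anything outside those
polygons falls back to "other".  The default polygons are simple lon/lat
boxes approximating the published groupings (the exact boundaries were never
published as coordinates), and any scheme can be supplied as a YAML file of
polygons, so the grouping is reproducible and user-overridable.

Assignment is deterministic point-in-polygon with an explicit precedence
order: polygons are tested in list order and the first containing (boundary
inclusive) polygon wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

__all__ = ["RegionScheme", "default_region_scheme", "assign_region", "assign_regions"]

REGION_CODES = ("NSS", "SS", "CAR", "WTA", "other")


@dataclass
class RegionScheme:
    """Ordered list of (region_code, polygon); order is precedence."""

    regions: list[tuple[str, Polygon]]
    fallback: str = "other"

    def __post_init__(self):
        for code, poly in self.regions:
            if not poly.is_valid:
                raise ValueError(f"polygon for region {code!r} is not simple/valid")

    @classmethod
    def from_yaml(cls, path) -> "RegionScheme":
        doc = yaml.safe_load(Path(path).read_text())
        regions = [
            (entry["code"], Polygon([(lon, lat) for lon, lat in entry["polygon"]]))
            for entry in doc["regions"]
        ]
        return cls(regions=regions, fallback=doc.get("fallback", "other"))

    def to_yaml(self, path) -> None:
        doc = {
            "fallback": self.fallback,
            "regions": [
                {"code": code, "polygon": [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]]}
                for code, poly in self.regions
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _box(lon_w: float, lon_e: float, lat_s: float, lat_n: float) -> Polygon:
    return Polygon(
        [(lon_w, lat_s), (lon_e, lat_s), (lon_e, lat_n), (lon_w, lat_n)]
    )


def default_region_scheme() -> RegionScheme:
    """Box approximation of the western-Atlantic sample groupings.

    NSS north of 30N between ~75W and 45W; SS 22-30N; CAR the Caribbean
    interior west of 64W between 12N and 22N; WTA south of 12N.  Precedence
    NSS > SS > CAR > WTA (boxes are disjoint, so order only resolves shared
    edges).
    """
    return RegionScheme(
        regions=[
            ("NSS", _box(-75.0, -45.0, 30.0, 40.0)),
            ("SS", _box(-75.0, -45.0, 22.0, 30.0)),
            ("CAR", _box(-90.0, -64.0, 12.0, 22.0)),
            ("WTA", _box(-75.0, -45.0, 0.0, 12.0)),
        ]
    )


def assign_region(longitude: float, latitude: float, scheme: RegionScheme | None = None) -> str:
    """Deterministic, total region assignment for one point.

    Boundary points resolve by precedence (first polygon covering the point,
    boundary inclusive); anything uncovered gets the fallback code.
    """
    if scheme is None:
        scheme = default_region_scheme()
    if not (np.isfinite(longitude) and np.isfinite(latitude)):
        return scheme.fallback
    pt = Point(float(longitude), float(latitude))
    for code, poly in scheme.regions:
        if poly.covers(pt):
            return code
    return scheme.fallback


def assign_regions(frame, scheme: RegionScheme | None = None,
                   lon_col: str = "longitude", lat_col: str = "latitude"):
    """Vector helper: add/overwrite a ``region`` column on a tissue table."""
    if scheme is None:
        scheme = default_region_scheme()
    frame = frame.copy()
    frame["region"] = [
        assign_region(lon, lat, scheme) for lon, lat in zip(frame[lon_col], frame[lat_col])
    ]
    return frame
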