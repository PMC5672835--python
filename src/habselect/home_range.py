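"""Minimum convex polygon home ranges and per-animal availability.

Under a use/availability design in which each animal defines its own
availability (design III), the available resource units are those whose
centres fall inside the animal's 100% MCP — the convex hull of all its
locations for a period.  The categorical habitat of an RU is its dominant
cover class (largest proportion, ties to the smallest class code).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .resource_units import RasterGrid, RUStack, dominant_class


@dataclass
class HomeRangePolygon:
    """100% (or percent-trimmed) minimum convex polygon for one animal/period."""

    animal_id: str
    period: str
    vertices: np.ndarray  # closed CCW ring, shape (k+1, 2)
    area: float           # m^2, shoelace

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def __geo_interface__(self):
        return {
            "type": "Feature",
            "properties": {
                "animal_id": self.animal_id,
                "period": self.period,
                "area_m2": self.area,
            },
            "geometry": {
                "type": "Polygon",
                "coordinates": [self.vertices.tolist()],
            },
        }


@dataclass
class AvailabilitySet:
    """RUs available to one animal/period with category proportions."""

    animal_id: str
    period: str
    ru_ids: np.ndarray
    proportions: pd.Series  # index = cover class, sums to 1


def _shoelace(ring: np.ndarray) -> float:
    x, y = ring[:-1, 0], ring[:-1, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def mcp(
    points: np.ndarray,
    animal_id: str = "",
    period: str = "",
    percent: float = 100.0,
) -> HomeRangePolygon:
    """Minimum convex polygon of a point set.

    ``percent < 100`` first removes the ``(100 - percent)%`` of points
    farthest from the centroid.  Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    if percent < 100:
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        k = max(3, int(np.ceil(len(pts) * percent / 100.0)))
        pts = pts[np.argsort(d)[:k]]
    if len(pts) < 3:
        raise ValueError(f"animal {animal_id!r}: need >= 3 points for an MCP")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(
            f"animal {animal_id!r}: points are collinear, MCP undefined"
        ) from exc
    ring = pts[hull.vertices]  # CCW for 2-D qhull
    ring = np.vstack([ring, ring[:1]])
    return HomeRangePolygon(animal_id, period, ring, _shoelace(ring))


def write_geojson(polys: list[HomeRangePolygon], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [p.__geo_interface__() for p in polys],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


def availability(
    stack: RUStack,
    polygon: HomeRangePolygon,
    include_ru_ids: np.ndarray | None = None,
) -> AvailabilitySet:
    """Available RUs: those whose centre lies inside (or on) the MCP.

    Category proportions are over the dominant class of each available RU.
    ``include_ru_ids`` force-includes extra RUs (typically the RUs containing
    the animal's locations: a point near the hull boundary can fall in a cell
    whose centre lies just outside, and used RUs must stay a subset of the
    available set).
    """
    poly = polygon.polygon()
    table = stack.table
    xy = table[["x", "y"]].to_numpy()
    # bounding-box prefilter, then exact covers test (boundary counts as in)
    minx, miny, maxx, maxy = poly.bounds
    cand = np.nonzero(
        (xy[:, 0] >= minx) & (xy[:, 0] <= maxx)
        & (xy[:, 1] >= miny) & (xy[:, 1] <= maxy)
    )[0]
    inside = np.array(
        [i for i in cand if poly.covers(Point(xy[i]))], dtype=int
    )
    if inside.size == 0:
        raise ValueError(
            f"animal {polygon.animal_id!r}: no RU centre inside the MCP"
        )
    if include_ru_ids is not None and len(include_ru_ids):
        extra = np.nonzero(
            table["ru_id"].isin(np.unique(include_ru_ids)).to_numpy()
        )[0]
        inside = np.union1d(inside, extra)
    sub = table.iloc[inside]
    dom = dominant_class(sub, stack.cover_classes)
    counts = pd.Series(dom).value_counts().sort_index()
    props = counts / counts.sum()
    props.index.name = "category"
    return AvailabilitySet(
        polygon.animal_id,
        polygon.period,
        sub["ru_id"].to_numpy(),
        props,
    )


def used_units(
    points: np.ndarray, stack: RUStack
) -> tuple[np.ndarray, pd.Series]:
    """Map locations to RUs; return per-point RU ids and used counts per class.

    Points follow the half-open cell rule (boundary ties to the east/south
    cell).  A point outside the grid, or in a dropped (nodata) RU, raises.
    """
    any_grid = next(iter(stack.grids.values()))
    table = stack.table.set_index("ru_id")
    ids = []
    for k, (x, y) in enumerate(np.asarray(points, dtype=float)):
        try:
            r, c = any_grid.point_to_cell(x, y)
        except ValueError as exc:
            raise ValueError(f"location record {k} at ({x}, {y}): {exc}") from exc
        ru = r * any_grid.n_cols + c
        if ru not in table.index:
            raise ValueError(
                f"location record {k} at ({x}, {y}) falls in a nodata RU"
            )
        ids.append(ru)
    ru_ids = np.asarray(ids)
    sub = table.loc[ru_ids].reset_index()
    dom = dominant_class(sub, stack.cover_classes)
    counts = pd.Series(dom).value_counts().sort_index()
    counts.index.name = "category"
    return ru_ids, counts
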