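"""Two-level administrative hierarchies (departments and provinces).

An :class:`AdminHierarchy` is a flat list of admin2 units (provinces), each
carrying the identifier of its admin1 parent (department).  Synthetic studies
build one by rectangular partition of the square region; real boundaries load
from GeoJSON through the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import box, mapping, shape
from shapely.strtree import STRtree

from .grid import RasterGrid

__all__ = ["AdminUnit", "AdminHierarchy"]


@dataclass(frozen=True)
class AdminUnit:
    admin1_id: str
    admin2_id: str
    geometry: shapely.Geometry


def _near_square_factors(n: int) -> tuple[int, int]:
    r = int(np.floor(np.sqrt(n)))
    while n % r:
        r -= 1
    return r, n // r


class AdminHierarchy:
    """Nested admin1 → admin2 polygons with stable identifiers."""

    def __init__(self, units: list[AdminUnit]):
        if not units:
            raise ValueError("an admin hierarchy needs at least one unit")
        self.units = list(units)
        ids = [u.admin2_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("admin2 identifiers must be unique")
        self._tree = STRtree([u.geometry for u in self.units])

    # -- construction -----------------------------------------------------
    @classmethod
    def rectangular(
        cls,
        region_size_km: float,
        n_admin1: int,
        n_admin2_per_admin1: int,
    ) -> "AdminHierarchy":
        """Partition the square [0, L]² into a regular two-level hierarchy.

        admin1 units tile the square in a near-square r×c arrangement and each
        is subdivided the same way into admin2 rectangles.
        """
        if n_admin1 < 1 or n_admin2_per_admin1 < 1:
            raise ValueError("admin counts must be >= 1")
        L = float(region_size_km)
        r1, c1 = _near_square_factors(n_admin1)
        r2, c2 = _near_square_factors(n_admin2_per_admin1)
        units: list[AdminUnit] = []
        k1 = 0
        for i1 in range(r1):
            for j1 in range(c1):
                k1 += 1
                a1 = f"D{k1:02d}"
                x_lo, x_hi = L * j1 / c1, L * (j1 + 1) / c1
                y_lo, y_hi = L * i1 / r1, L * (i1 + 1) / r1
                k2 = 0
                for i2 in range(r2):
                    for j2 in range(c2):
                        k2 += 1
                        a2 = f"{a1}P{k2:02d}"
                        g = box(
                            x_lo + (x_hi - x_lo) * j2 / c2,
                            y_lo + (y_hi - y_lo) * i2 / r2,
                            x_lo + (x_hi - x_lo) * (j2 + 1) / c2,
                            y_lo + (y_hi - y_lo) * (i2 + 1) / r2,
                        )
                        units.append(AdminUnit(a1, a2, g))
        return cls(units)

    # -- lookup -----------------------------------------------------------
    @property
    def admin1_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u.admin1_id, None)
        return list(seen)

    @property
    def admin2_ids(self) -> list[str]:
        return [u.admin2_id for u in self.units]

    @property
    def parent_of(self) -> dict[str, str]:
        return {u.admin2_id: u.admin1_id for u in self.units}

    def assign_points(self, points: np.ndarray, level: int = 2) -> np.ndarray:
        """Admin ids of the units containing each (x, y) point.

        Points on a shared boundary go to the first matching unit; points
        outside every polygon are assigned to the nearest one.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        geoms = shapely.points(points[:, 0], points[:, 1])
        idx = np.full(len(geoms), -1, dtype=int)
        q = self._tree.query(geoms, predicate="intersects")
        # first match wins for boundary points
        for pt_i, unit_i in zip(q[0][::-1], q[1][::-1]):
            idx[pt_i] = min(unit_i, idx[pt_i]) if idx[pt_i] >= 0 else unit_i
        missing = np.flatnonzero(idx < 0)
        if missing.size:
            idx[missing] = self._tree.nearest(geoms[missing])
        if level == 1:
            return np.array([self.units[i].admin1_id for i in idx])
        return np.array([self.units[i].admin2_id for i in idx])

    def cell_labels(self, grid: RasterGrid, level: int = 2) -> np.ndarray:
        """Admin id of each grid cell (by cell-center containment), row-major."""
        return self.assign_points(grid.cell_centers(), level=level)

    # -- I/O --------------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"admin1_id": u.admin1_id, "admin2_id": u.admin2_id},
                "geometry": mapping(u.geometry),
            }
            for u in self.units
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AdminHierarchy":
        data = json.loads(Path(path).read_text())
        units = [
            AdminUnit(
                f["properties"]["admin1_id"],
                f["properties"]["admin2_id"],
                shape(f["geometry"]),
            )
            for f in data["features"]
        ]
        return cls(units)
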