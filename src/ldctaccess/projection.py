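"""Equal-area conic projection with planar coordinates in miles.

Buffer radii and area fractions are computed in a planar system where one
unit equals one statute mile.  An Albers equal-area conic on the authalic
sphere is used: it preserves areas exactly (so tract area fractions are
unbiased) and keeps distance distortion small between its standard
parallels, which is what a fixed-radius "Euclidean distance" buffer
analysis needs.  Forward and inverse transforms are closed-form, so
round-tripping vertices is accurate to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

# Authalic Earth radius (sphere with the ellipsoid's surface area), in miles.
EARTH_RADIUS_MILES = 6371.0072 / 1.609344


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic, planar units in miles.

    Parameters
    ----------
    lon0, lat0
        Projection origin (degrees); ``forward(lon0, lat0) == (0, 0)``.
    std_parallels
        The two standard parallels (degrees) along which scale is true.
        Defaults span a regional study area a few hundred miles tall;
        widen them (e.g. to the classic 29.5/45.5) for a continent-scale
        region.
    validity_halfwidth_deg
        Half-width of the longitude/latitude window outside which
        :meth:`check_validity` warns.
    """

    lon0: float = -96.0
    lat0: float = 37.5
    std_parallels: tuple[float, float] = (35.5, 39.5)
    radius_miles: float = EARTH_RADIUS_MILES
    validity_halfwidth_deg: float = 15.0

    @property
    def _n(self) -> float:
        p1, p2 = np.radians(self.std_parallels)
        return (np.sin(p1) + np.sin(p2)) / 2.0

    @property
    def _C(self) -> float:
        p1, _ = np.radians(self.std_parallels)
        return float(np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1))

    def _rho(self, lat_rad: np.ndarray) -> np.ndarray:
        n = self._n
        return self.radius_miles / n * np.sqrt(self._C - 2.0 * n * np.sin(lat_rad))

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Project WGS84 degrees to planar miles (vectorized)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n = self._n
        rho = self._rho(np.radians(lat))
        rho0 = self._rho(np.radians(np.asarray(self.lat0)))
        theta = n * np.radians(lon - self.lon0)
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Planar miles back to WGS84 degrees (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        R = self.radius_miles
        rho0 = self._rho(np.radians(np.asarray(self.lat0)))
        sgn = np.sign(n) if n != 0 else 1.0
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(sgn * x, sgn * (rho0 - y))
        lon = self.lon0 + np.degrees(theta / n)
        s = (self._C - (rho * n / R) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
        return lon, lat

    # -- geometry helpers -------------------------------------------------

    def project_geometry(self, geom: shapely.Geometry) -> shapely.Geometry:
        def _f(coords: np.ndarray) -> np.ndarray:
            x, y = self.forward(coords[:, 0], coords[:, 1])
            return np.column_stack([x, y])

        return shapely.transform(geom, _f)

    def unproject_geometry(self, geom: shapely.Geometry) -> shapely.Geometry:
        def _f(coords: np.ndarray) -> np.ndarray:
            lon, lat = self.inverse(coords[:, 0], coords[:, 1])
            return np.column_stack([lon, lat])

        return shapely.transform(geom, _f)

    def check_validity(self, lon, lat, unit_id: str | None = None) -> bool:
        """Warn (never raise) when coordinates fall outside the window
        where the projection's distortion guarantees were assessed."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        h = self.validity_halfwidth_deg
        ok = bool(
            np.all(np.abs(lon - self.lon0) <= h) and np.all(np.abs(lat - self.lat0) <= h)
        )
        if not ok:
            tag = f" (unit {unit_id})" if unit_id else ""
            warnings.warn(
                f"geometry{tag} lies outside the projection validity window "
                f"(±{h}° around {self.lon0}, {self.lat0})",
                stacklevel=2,
            )
        return ok


def project_layer(layer, projection: AlbersEqualArea, id_column: str | None = None):
    """Project a layer's ``geometry`` column from WGS84 to planar miles.

    ``layer`` is a pandas DataFrame with a shapely ``geometry`` column; a
    copy with projected geometries is returned.  Geometries outside the
    projection's validity window trigger a warning carrying the unit id.
    """
    out = layer.copy()
    geoms = []
    for idx, geom in zip(layer.index, layer["geometry"]):
        uid = str(layer.at[idx, id_column]) if id_column else str(idx)
        xmin, ymin, xmax, ymax = geom.bounds
        projection.check_validity([xmin, xmax], [ymin, ymax], unit_id=uid)
        geoms.append(projection.project_geometry(geom))
    out["geometry"] = geoms
    return out


def unproject_layer(layer, projection: AlbersEqualArea):
    """Inverse of :func:`project_layer`: planar miles back to WGS84."""
    out = layer.copy()
    out["geometry"] = [projection.unproject_geometry(g) for g in layer["geometry"]]
    return out
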