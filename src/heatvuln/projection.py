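"""Map projections for reprojecting geographic vector input.

The working reference system for the whole pipeline is a projected,
metre-unit system.  The default is RGF93 / Lambert-93 (EPSG:2154), the
official projection for metropolitan France, implemented here in closed
form (Lambert conformal conic, two standard parallels, GRS80 ellipsoid).

Rasters are never reprojected; only vector vertices pass through these
formulas when a source file arrives in geographic coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4258", "OGC:CRS84"}


def is_geographic(crs_id: str) -> bool:
    return crs_id.upper() in GEOGRAPHIC_CRS


@dataclass(frozen=True)
class LambertConformalConic:
    """Lambert conformal conic, 2SP form (Snyder 1987, eq. 15-1..15-11)."""

    lat_1: float  # first standard parallel, degrees
    lat_2: float  # second standard parallel, degrees
    lat_0: float  # latitude of false origin, degrees
    lon_0: float  # longitude of false origin, degrees
    x_0: float    # false easting, metres
    y_0: float    # false northing, metres
    a: float = 6378137.0          # GRS80 semi-major axis
    inv_f: float = 298.257222101  # GRS80 inverse flattening

    @property
    def e(self) -> float:
        f = 1.0 / self.inv_f
        return math.sqrt(2 * f - f * f)

    def _m(self, phi: float) -> float:
        return math.cos(phi) / math.sqrt(1 - (self.e * math.sin(phi)) ** 2)

    def _t(self, phi: float) -> float:
        e = self.e
        return math.tan(math.pi / 4 - phi / 2) / (
            (1 - e * math.sin(phi)) / (1 + e * math.sin(phi))
        ) ** (e / 2)

    def _constants(self):
        p1 = math.radians(self.lat_1)
        p2 = math.radians(self.lat_2)
        p0 = math.radians(self.lat_0)
        m1, m2 = self._m(p1), self._m(p2)
        t0, t1, t2 = self._t(p0), self._t(p1), self._t(p2)
        n = (math.log(m1) - math.log(m2)) / (math.log(t1) - math.log(t2))
        big_f = m1 / (n * t1**n)
        rho0 = self.a * big_f * t0**n
        return n, big_f, rho0

    def forward(self, lon: float, lat: float) -> tuple[float, float]:
        """(longitude, latitude) degrees -> (x, y) metres."""
        n, big_f, rho0 = self._constants()
        t = self._t(math.radians(lat))
        rho = self.a * big_f * t**n
        theta = n * math.radians(lon - self.lon_0)
        x = self.x_0 + rho * math.sin(theta)
        y = self.y_0 + rho0 - rho * math.cos(theta)
        return x, y

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        """(x, y) metres -> (longitude, latitude) degrees."""
        n, big_f, rho0 = self._constants()
        dx = x - self.x_0
        dy = rho0 - (y - self.y_0)
        rho = math.copysign(math.hypot(dx, dy), n)
        theta = math.atan2(dx, dy)
        t = (rho / (self.a * big_f)) ** (1.0 / n)
        lon = math.degrees(theta / n) + self.lon_0
        # iterate the latitude (Snyder 7-9)
        e = self.e
        phi = math.pi / 2 - 2 * math.atan(t)
        for _ in range(12):
            s = e * math.sin(phi)
            phi = math.pi / 2 - 2 * math.atan(t * ((1 - s) / (1 + s)) ** (e / 2))
        return lon, math.degrees(phi)


#: Projections usable as the working reference system for geographic input.
PROJECTIONS: dict[str, LambertConformalConic] = {
    "EPSG:2154": LambertConformalConic(
        lat_1=44.0, lat_2=49.0, lat_0=46.5, lon_0=3.0,
        x_0=700_000.0, y_0=6_600_000.0,
    ),
}
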