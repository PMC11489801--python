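"""Planar projections and radial buffers.

Neighborhood context measures are defined on a disk of given radius around a
location.  All areal arithmetic (intersection areas, weights) happens on a
planar frame in meters; this module provides the projections and the circle
construction.

Two projection families are supported, both centered on an arbitrary
reference point and exact inverses of their forwards:

``aeqd``
    Azimuthal equidistant on a sphere whose radius is the WGS84 Gaussian
    radius of curvature at the reference latitude.  Distances from the
    reference point are preserved, which makes it the natural frame for a
    radial buffer: the default is a fresh frame centered on each buffer, so
    the buffer boundary sits at true ground distance and area distortion
    over a few kilometers is far below the 1 % contract.

``tmerc``
    Spherical transverse Mercator on the same Gaussian sphere, offered as an
    explicit alternative frame (e.g. to emulate a state-plane-style zone
    projection centered elsewhere) and used by the projection-insensitivity
    tests.

Using the Gaussian radius ``sqrt(M * N)`` at the reference latitude keeps the
local metric of the ellipsoid to within a few parts per million over the
≤ 5 km neighborhoods this package targets; the residual error is quadratic in
(distance / earth radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, ValidationError

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
_E2 = WGS84_F * (2.0 - WGS84_F)

DEFAULT_SEGMENTS = 64


def gaussian_radius(lat_deg: float) -> float:
    """WGS84 Gaussian radius of curvature sqrt(M*N) at a latitude."""
    s2 = math.sin(math.radians(lat_deg)) ** 2
    w2 = 1.0 - _E2 * s2
    # M = a(1-e^2)/w^3, N = a/w  ->  sqrt(MN) = a sqrt(1-e^2)/w^2
    return WGS84_A * math.sqrt(1.0 - _E2) / w2


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 point; latitude/longitude in decimal degrees.

    Bounds are enforced at construction: lat in [-90, 90], lon in
    [-180, 180].
    """

    lat: float
    lon: float

    def __post_init__(self):
        lat, lon = float(self.lat), float(self.lon)
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValidationError(f"non-finite coordinates ({self.lat}, {self.lon})")
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
        if not -180.0 <= lon <= 180.0:
            raise ValidationError(f"longitude {lon} outside [-180, 180]")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)


class Projection:
    """A planar projection in meters with an exact analytic inverse."""

    id: str

    def forward(self, lon, lat):
        raise NotImplementedError

    def inverse(self, x, y):
        raise NotImplementedError


@dataclass(frozen=True)
class AzimuthalEquidistant(Projection):
    """Spherical azimuthal equidistant frame centered on ``center``."""

    center: GeoPoint
    radius: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "radius", gaussian_radius(self.center.lat))

    @property
    def id(self) -> str:
        return f"aeqd:{self.center.lat:.6f},{self.center.lon:.6f}"

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lat0 = math.radians(self.center.lat)
        dlon = lon - math.radians(self.center.lon)
        sin_lat, cos_lat = np.sin(lat), np.cos(lat)
        cos_c = math.sin(lat0) * sin_lat + math.cos(lat0) * cos_lat * np.cos(dlon)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius * k * cos_lat * np.sin(dlon)
        y = self.radius * k * (math.cos(lat0) * sin_lat - math.sin(lat0) * cos_lat * np.cos(dlon))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        lat0 = math.radians(self.center.lat)
        rho = np.hypot(x, y)
        c = rho
        sin_c, cos_c = np.sin(c), np.cos(c)
        safe_rho = np.where(rho > 1e-15, rho, 1.0)
        lat = np.arcsin(np.clip(cos_c * math.sin(lat0) + y * sin_c * math.cos(lat0) / safe_rho, -1, 1))
        lon = math.radians(self.center.lon) + np.arctan2(
            x * sin_c, safe_rho * cos_c * math.cos(lat0) - y * sin_c * math.sin(lat0)
        )
        lat = np.where(rho > 1e-15, lat, lat0)
        lon = np.where(rho > 1e-15, lon, math.radians(self.center.lon))
        return np.degrees(lon), np.degrees(lat)


@dataclass(frozen=True)
class TransverseMercator(Projection):
    """Spherical transverse Mercator centered on ``center`` (central
    meridian through it, false northing so the center maps to the origin)."""

    center: GeoPoint
    radius: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "radius", gaussian_radius(self.center.lat))

    @property
    def id(self) -> str:
        return f"tmerc:{self.center.lat:.6f},{self.center.lon:.6f}"

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        dlon = lon - math.radians(self.center.lon)
        b = np.clip(np.cos(lat) * np.sin(dlon), -1 + 1e-15, 1 - 1e-15)
        x = self.radius * np.arctanh(b)
        y = self.radius * (np.arctan2(np.tan(lat), np.cos(dlon)) - math.radians(self.center.lat))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float)
        d = y / self.radius + math.radians(self.center.lat)
        lat = np.arcsin(np.clip(np.sin(d) / np.cosh(x), -1, 1))
        lon = math.radians(self.center.lon) + np.arctan2(np.sinh(x), np.cos(d))
        return np.degrees(lon), np.degrees(lat)


def get_projection(spec: str | Projection, center: GeoPoint | None = None) -> Projection:
    """Resolve a projection config value.

    ``spec`` is either a :class:`Projection` instance, ``"aeqd"`` (local
    frame centered on ``center``, which must then be given),
    ``"aeqd:<lat>,<lon>"`` or ``"tmerc:<lat>,<lon>"``.
    """
    if isinstance(spec, Projection):
        return spec
    if not isinstance(spec, str):
        raise ConfigurationError(f"projection spec must be a string or Projection, got {type(spec)!r}")
    name, _, arg = spec.partition(":")
    name = name.strip().lower()
    if name == "aeqd" and not arg:
        if center is None:
            raise ConfigurationError("projection 'aeqd' needs a center point in this context")
        return AzimuthalEquidistant(center)
    if name in ("aeqd", "tmerc"):
        try:
            lat_s, lon_s = arg.split(",")
            pt = GeoPoint(float(lat_s), float(lon_s))
        except (ValueError, ValidationError) as exc:
            raise ConfigurationError(f"bad projection center in {spec!r}: {exc}") from exc
        cls = AzimuthalEquidistant if name == "aeqd" else TransverseMercator
        return cls(pt)
    raise ConfigurationError(
        f"unknown projection {spec!r}; expected 'aeqd', 'aeqd:<lat>,<lon>' or 'tmerc:<lat>,<lon>'"
    )


def project_geometry(geometry: BaseGeometry, projection: Projection) -> BaseGeometry:
    """Project a WGS84 (lon/lat) shapely geometry to the planar frame (meters)."""
    if geometry.is_empty:
        return geometry
    return shapely.transform(geometry, lambda pts: np.column_stack(projection.forward(pts[:, 0], pts[:, 1])))


def unproject_geometry(geometry: BaseGeometry, projection: Projection) -> BaseGeometry:
    """Inverse of :func:`project_geometry`: planar meters back to WGS84 lon/lat."""
    if geometry.is_empty:
        return geometry
    return shapely.transform(geometry, lambda pts: np.column_stack(projection.inverse(pts[:, 0], pts[:, 1])))


@dataclass(frozen=True)
class RadialBuffer:
    """A radius-``radius_m`` disk around ``center``, approximated by a regular
    ``n_segments``-gon inscribed in the true circle on the planar frame."""

    center: GeoPoint
    radius_m: float
    polygon: Polygon
    projection: Projection
    n_segments: int

    @property
    def projection_id(self) -> str:
        return self.projection.id

    @property
    def center_xy(self) -> tuple[float, float]:
        x, y = self.projection.forward(self.center.lon, self.center.lat)
        return float(x), float(y)

    @property
    def area(self) -> float:
        return self.polygon.area


def build_buffer(
    center: GeoPoint,
    radius_m: float,
    projection: str | Projection = "aeqd",
    n_segments: int = DEFAULT_SEGMENTS,
) -> RadialBuffer:
    """Construct the radial buffer polygon around ``center``.

    The circle is drawn in the planar frame around the projected center; by
    default that frame is a fresh azimuthal-equidistant projection centered
    on the point itself, so every vertex sits at exactly ``radius_m`` ground
    distance.  The inscribed n-gon area is ``pi r^2 * (n/2pi) sin(2pi/n)``
    (99.84 % of the disk at the default 64 segments).
    """
    if not isinstance(center, GeoPoint):
        center = GeoPoint(*center)
    if not (radius_m > 0):
        raise ValidationError(f"radius must be positive, got {radius_m}")
    if int(n_segments) < 16:
        raise ValidationError(f"n_segments must be >= 16, got {n_segments}")
    n_segments = int(n_segments)
    proj = get_projection(projection, center=center)
    cx, cy = (float(v) for v in proj.forward(center.lon, center.lat))
    theta = np.linspace(0.0, 2.0 * math.pi, n_segments, endpoint=False)
    ring = np.column_stack((cx + radius_m * np.cos(theta), cy + radius_m * np.sin(theta)))
    return RadialBuffer(center=center, radius_m=float(radius_m), polygon=Polygon(ring), projection=proj, n_segments=n_segments)
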