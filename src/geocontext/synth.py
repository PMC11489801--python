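"""Seeded synthetic-data generators.

Every other module is testable offline because this module can fabricate
all four external inputs from parameters and a seed: square tract grids
with count/proportion measures, synthetic cities built from annular-sector
tracts with an exact radial density profile, point-event clouds, and street
gazetteers paired with a truth table for geocoder-recovery tests.

The city generator is the reference object for density-gradient analyses: a
*compact* city has population density ``d(r) = d0 * exp(-r / lambda)``
falling with distance ``r`` from city hall, a *sprawl* city has constant
density ``d0``.  Tracts are annular sectors so each tract's population can
be assigned as the exact analytic integral of the density over its land
area; assembling buffer densities over the city then probes the whole
geometry + interpolation stack against closed-form truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .areal import ArealDataset, ArealUnit, MeasureDefinition
from .errors import ValidationError
from .geocoding import GazetteerRecord
from .geometry import AzimuthalEquidistant, GeoPoint, unproject_geometry

DEFAULT_ORIGIN = GeoPoint(47.60, -122.33)


def _ordinal(n: int) -> str:
    if 10 <= n % 100 <= 20:
        return f"{n}th"
    return f"{n}{ {1: 'st', 2: 'nd', 3: 'rd'}.get(n % 10, 'th') }"


def _wgs84_polygon(xy: np.ndarray, frame: AzimuthalEquidistant) -> Polygon:
    lon, lat = frame.inverse(xy[:, 0], xy[:, 1])
    return Polygon(np.column_stack((lon, lat)))


def generate_tract_grid(
    n: int,
    cell_km: float = 1.0,
    origin: GeoPoint = DEFAULT_ORIGIN,
    measures: dict | None = None,
    seed: int = 0,
) -> ArealDataset:
    """An n x n grid of square tracts centered on ``origin``.

    ``measures`` maps measure name to a spec dict: ``{"kind": ..., "value":
    c}`` for a constant, or ``{"kind": ..., "low": a, "high": b}`` for
    uniform random draws (reproducible under ``seed``).  A ``land_area``
    count measure equal to each cell's polygon area is always included.
    Count draws are nonnegative; proportion draws are clipped to [0, 1].
    """
    if n <= 0 or cell_km <= 0:
        raise ValidationError(f"grid dimensions must be positive, got n={n}, cell_km={cell_km}")
    rng = np.random.default_rng(seed)
    if measures is None:
        measures = {
            "population": {"kind": "count", "low": 500, "high": 3000},
            "pct_poverty": {"kind": "proportion", "low": 0.05, "high": 0.40},
        }
    frame = AzimuthalEquidistant(origin)
    cell = cell_km * 1000.0
    half = n * cell / 2.0
    defs = [MeasureDefinition(name=k, kind=v["kind"], units=v.get("units", "")) for k, v in measures.items()]
    defs.append(MeasureDefinition(name="land_area", kind="count", units="m^2"))
    units = []
    for i in range(n):
        for j in range(n):
            x0, y0 = -half + i * cell, -half + j * cell
            xy = np.array([(x0, y0), (x0 + cell, y0), (x0 + cell, y0 + cell), (x0, y0 + cell), (x0, y0)])
            poly = _wgs84_polygon(xy, frame)
            values = {}
            for name, spec in measures.items():
                if "value" in spec:
                    v = float(spec["value"])
                else:
                    v = float(rng.uniform(spec["low"], spec["high"]))
                if spec["kind"] == "count":
                    v = max(v, 0.0)
                else:
                    v = min(max(v, 0.0), 1.0)
                values[name] = v
            values["land_area"] = cell * cell
            units.append(ArealUnit(unit_id=f"g{i}_{j}", geometry=poly, values=values))
    return ArealDataset(units=units, measures=defs, name=f"grid{n}x{n}")


@dataclass(frozen=True)
class SyntheticCitySpec:
    """Parameters of an annular-sector synthetic city.

    ``d0`` is the central population density in persons per m² of land
    (0.006 ≈ a dense US urban core); ``lambda_m`` the e-folding distance of
    the compact profile.  ``water_sectors`` lists sector indices whose
    tracts are partly water: their ``land_area`` is reduced by
    ``water_fraction`` and their population scaled accordingly, so density
    per land area is unchanged but naive per-buffer-area division is not.
    """

    center: GeoPoint = DEFAULT_ORIGIN
    n_rings: int = 8
    n_sectors: int = 12
    ring_width_m: float = 750.0
    profile: str = "compact"  # or "sprawl"
    d0: float = 0.006
    lambda_m: float = 2000.0
    water_sectors: tuple[int, ...] = ()
    water_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.profile not in ("compact", "sprawl"):
            raise ValidationError(f"profile must be compact|sprawl, got {self.profile!r}")
        if self.profile == "compact" and not self.lambda_m > 0:
            raise ValidationError(f"lambda_m must be positive for a compact city, got {self.lambda_m}")
        if self.n_rings <= 0 or self.n_sectors <= 0 or self.ring_width_m <= 0 or self.d0 <= 0:
            raise ValidationError("n_rings, n_sectors, ring_width_m and d0 must be positive")


def _radial_mass(spec: SyntheticCitySpec, r0: float, r1: float) -> float:
    """Integral of d(r) * r dr over [r0, r1] (per unit angle)."""
    if spec.profile == "sprawl":
        return spec.d0 * (r1 * r1 - r0 * r0) / 2.0
    lam = spec.lambda_m
    antideriv = lambda r: -lam * (r + lam) * math.exp(-r / lam)  # ∫ r e^{-r/λ} dr
    return spec.d0 * (antideriv(r1) - antideriv(r0))


def generate_city(spec: SyntheticCitySpec) -> ArealDataset:
    """Annular-sector city with exact per-tract populations.

    Each tract's population equals the analytic integral of the density
    profile over the tract's land area (within arc-discretization error,
    well under 1 %), so buffer-assembled densities have closed-form truth.
    Measures: ``population`` (count) and ``land_area`` (count, m²).
    """
    frame = AzimuthalEquidistant(spec.center)
    arc_pts = max(8, 96 // spec.n_sectors)  # vertices per arc; keeps area error << 1%
    dtheta = 2.0 * math.pi / spec.n_sectors
    units = []
    for ring in range(spec.n_rings):
        r0, r1 = ring * spec.ring_width_m, (ring + 1) * spec.ring_width_m
        for s in range(spec.n_sectors):
            t0, t1 = s * dtheta, (s + 1) * dtheta
            ts = np.linspace(t0, t1, arc_pts + 1)
            outer = np.column_stack((r1 * np.cos(ts), r1 * np.sin(ts)))
            if r0 == 0:
                xy = np.vstack((outer, [[0.0, 0.0]], outer[:1]))
            else:
                inner = np.column_stack((r0 * np.cos(ts[::-1]), r0 * np.sin(ts[::-1])))
                xy = np.vstack((outer, inner, outer[:1]))
            poly = _wgs84_polygon(xy, frame)
            sector_area = dtheta * (r1 * r1 - r0 * r0) / 2.0
            land_frac = 1.0 - (spec.water_fraction if s in spec.water_sectors else 0.0)
            population = dtheta * _radial_mass(spec, r0, r1) * land_frac
            units.append(
                ArealUnit(
                    unit_id=f"r{ring}_s{s}",
                    geometry=poly,
                    values={"population": population, "land_area": sector_area * land_frac},
                )
            )
    defs = [
        MeasureDefinition(name="population", kind="count", units="persons"),
        MeasureDefinition(name="land_area", kind="count", units="m^2"),
    ]
    return ArealDataset(units=units, measures=defs, name=f"city_{spec.profile}")


def analytic_buffer_density(spec: SyntheticCitySpec, radius_m: float) -> float:
    """Closed-form buffer-averaged density at ``radius_m`` from the center.

    Population within the disk divided by land area within the disk; with a
    radially symmetric water mask this equals ∫₀ᴿ d(r) r dr / (R²/2).
    """
    return _radial_mass(spec, 0.0, radius_m) / (radius_m * radius_m / 2.0)


def generate_points(
    n: int,
    law: str = "uniform",
    seed: int = 0,
    center: GeoPoint = DEFAULT_ORIGIN,
    radius_m: float = 5000.0,
    dataset: ArealDataset | None = None,
    rate_measure: str = "population",
    source: str = "events",
) -> "PointDataset":
    """Point events: ``uniform`` in a disk, or ``poisson`` per tract with
    rate proportional to a count measure (expected total ``n``)."""
    from .points import PointDataset

    if n < 0:
        raise ValidationError(f"n must be nonnegative, got {n}")
    rng = np.random.default_rng(seed)
    pts: list[tuple[str, GeoPoint, dict]] = []
    if law == "uniform":
        frame = AzimuthalEquidistant(center)
        r = radius_m * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * math.pi, n)
        lon, lat = frame.inverse(r * np.cos(th), r * np.sin(th))
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        for i in range(n):
            pts.append((f"p{i}", GeoPoint(float(lat[i]), float(lon[i])), {"weight": float(rng.uniform(0.5, 1.5))}))
    elif law == "poisson":
        if dataset is None:
            raise ValidationError("law='poisson' needs an areal dataset")
        values = dataset.values_for(rate_measure)
        total = sum(v for v in values.values() if v == v)
        k = 0
        for unit in dataset.units:
            v = values.get(unit.unit_id, 0.0)
            lam = n * (v / total) if total > 0 else 0.0
            count = int(rng.poisson(lam))
            minx, miny, maxx, maxy = unit.geometry.bounds
            placed = 0
            while placed < count:
                x = rng.uniform(minx, maxx, 4 * (count - placed) + 8)
                y = rng.uniform(miny, maxy, 4 * (count - placed) + 8)
                inside = shapely.contains_xy(unit.geometry, x, y)
                for xi, yi in zip(x[inside], y[inside]):
                    if placed >= count:
                        break
                    pts.append((f"p{k}", GeoPoint(float(yi), float(xi)), {"weight": 1.0}))
                    placed += 1
                    k += 1
    else:
        raise ValidationError(f"unknown point law {law!r}")
    return PointDataset(points=pts, source=source)


@dataclass(frozen=True)
class StreetGridSpec:
    """A rectangular street grid of numbered avenues (N-S) and streets (E-W)."""

    center: GeoPoint = DEFAULT_ORIGIN
    n_avenues: int = 8
    n_streets: int = 8
    spacing_m: float = 200.0
    city: str = "synthville"
    state: str = "wa"
    zip: str = "98000"


def generate_gazetteer(spec: StreetGridSpec = StreetGridSpec(), seed: int = 0):
    """Gazetteer records plus a truth table for geocoder recovery.

    One address per (avenue, street) corner; numbered street names exercise
    the abbreviation-expansion path (truth addresses use "Ave"/"St").
    Returns ``(records, truth)`` where ``truth`` pairs each raw address
    string with its true coordinates.
    """
    rng = np.random.default_rng(seed)
    frame = AzimuthalEquidistant(spec.center)
    records, truth_rows = [], []
    half_x = (spec.n_avenues - 1) * spec.spacing_m / 2.0
    half_y = (spec.n_streets - 1) * spec.spacing_m / 2.0
    k = 0
    for i in range(spec.n_avenues):
        for j in range(spec.n_streets):
            x = i * spec.spacing_m - half_x
            y = j * spec.spacing_m - half_y + float(rng.uniform(-20, 20))
            lon, lat = (float(v) for v in frame.inverse(x, y))
            house = str(100 * (j + 1) + 2 * i)
            name = _ordinal(i + 1)
            records.append(
                GazetteerRecord(
                    house_number=house,
                    street=name,
                    street_type="avenue",
                    city=spec.city,
                    state=spec.state,
                    zip=spec.zip,
                    point=GeoPoint(lat, lon),
                )
            )
            truth_rows.append(
                {
                    "location_id": f"L{k:04d}",
                    "address": f"{house} {name} Ave, {spec.city.title()}, {spec.state.upper()} {spec.zip}",
                    "lat": lat,
                    "lon": lon,
                }
            )
            k += 1
    truth = pd.DataFrame(truth_rows, columns=["location_id", "address", "lat", "lon"])
    return records, truth
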