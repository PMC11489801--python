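"""Area-weighted areal interpolation of tract-style measures onto radial buffers.

The estimator assumes each source unit's measure is uniformly distributed
over the unit.  A buffer is partitioned against the units; each piece falls
into exactly one unit.  Count measures (population, counts of anything)
are then combined by summing ``weight_i * value_i`` where ``weight_i`` is the
fraction of unit *i* covered by the buffer; proportion measures (shares,
rates in [0, 1] or [0, 100]) are combined by averaging values weighted by
the intersection areas.

Missing values: units whose value is missing are dropped from the sum /
average, and the output row carries ``coverage_fraction`` and ``n_missing``
so the user can filter biased rows; ``strict=True`` instead returns a
missing result whenever any intersecting unit is missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, ValidationError
from .geometry import (
    DEFAULT_SEGMENTS,
    GeoPoint,
    Projection,
    RadialBuffer,
    build_buffer,
    project_geometry,
)

RESULT_COLUMNS = ["location_id", "radius_m", "measure", "value", "coverage_fraction", "n_units", "n_missing"]

VALID_KINDS = ("count", "proportion")


@dataclass(frozen=True)
class MeasureDefinition:
    """Declaration of one context measure and its combination semantics."""

    name: str
    kind: str  # 'count' (sum area-fraction-weighted) or 'proportion' (area-weighted mean)
    units: str = ""
    year: int | None = None
    source: str = ""

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"measure {self.name!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}")

    @property
    def key(self) -> str:
        """Measure key; the year is part of the identity when present."""
        return f"{self.name}@{self.year}" if self.year is not None else self.name


@dataclass
class ArealUnit:
    unit_id: str
    geometry: BaseGeometry  # WGS84 lon/lat polygon or multipolygon
    values: dict = field(default_factory=dict)


@dataclass
class ArealDataset:
    """A collection of polygon units with per-unit measure values."""

    units: list[ArealUnit]
    measures: list[MeasureDefinition]
    name: str = ""

    def __post_init__(self):
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate unit_id(s): {dupes}")
        declared = {m.key for m in self.measures} | {m.name for m in self.measures}
        for u in self.units:
            unknown = set(u.values) - declared
            if unknown:
                raise ValidationError(f"unit {u.unit_id!r} carries undeclared measures {sorted(unknown)}")

    @property
    def measure_names(self) -> list[str]:
        return [m.key for m in self.measures]

    def measure(self, name: str) -> MeasureDefinition:
        for m in self.measures:
            if m.key == name or m.name == name:
                return m
        raise ConfigurationError(f"unknown measure {name!r}; available: {self.measure_names}")

    def values_for(self, name: str) -> dict:
        key = self.measure(name).key
        out = {}
        for u in self.units:
            v = u.values.get(key, u.values.get(self.measure(name).name))
            out[u.unit_id] = v
        return out


@dataclass(frozen=True)
class PartitionPiece:
    unit_id: str
    intersection_area: float
    unit_total_area: float

    @property
    def weight(self) -> float:
        if self.unit_total_area <= 0:
            return 0.0
        return min(self.intersection_area / self.unit_total_area, 1.0)


@dataclass(frozen=True)
class BufferPartition:
    """The buffer cut against the areal units; each piece lies in exactly one unit."""

    pieces: tuple[PartitionPiece, ...]
    buffer_area: float

    @property
    def covered_area(self) -> float:
        return sum(p.intersection_area for p in self.pieces)

    @property
    def coverage_fraction(self) -> float:
        if self.buffer_area <= 0:
            return 0.0
        return min(self.covered_area / self.buffer_area, 1.0)


def _clean(geom: BaseGeometry) -> BaseGeometry | None:
    """Repair an invalid polygon by zero-width buffering; None if hopeless."""
    if geom is None or geom.is_empty:
        return None
    if not geom.is_valid:
        geom = geom.buffer(0)
        if geom.is_empty or not geom.is_valid:
            return None
    return geom


def partition_buffer(buffer: RadialBuffer, dataset: ArealDataset) -> BufferPartition:
    """Overlay the buffer on the dataset's units.

    Returns one piece per unit with positive intersection area.  Invalid
    unit polygons are repaired by zero-width buffering; irreparable ones are
    skipped with a warning.  An empty dataset yields an empty partition with
    coverage 0 (not an error).
    """
    pieces = []
    buf_poly = buffer.polygon
    shapely.prepare(buf_poly)
    minx, miny, maxx, maxy = buf_poly.bounds
    for unit in dataset.units:
        geom = project_geometry(unit.geometry, buffer.projection)
        geom = _clean(geom)
        if geom is None:
            warnings.warn(f"unit {unit.unit_id!r}: invalid geometry could not be repaired; skipped")
            continue
        gx0, gy0, gx1, gy1 = geom.bounds
        if gx0 > maxx or gx1 < minx or gy0 > maxy or gy1 < miny:
            continue
        inter = buf_poly.intersection(geom)
        if inter.is_empty or inter.area <= 0:
            continue
        pieces.append(PartitionPiece(unit.unit_id, float(inter.area), float(geom.area)))
    return BufferPartition(pieces=tuple(pieces), buffer_area=float(buf_poly.area))


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def interpolate_count(partition: BufferPartition, values: Mapping[str, float], strict: bool = False) -> float:
    """Sum of area-fraction-weighted unit values over the partition.

    Each piece contributes ``(intersection_area / unit_area) * value`` —
    the share of the unit's count attributed to the buffer under the
    uniform-distribution assumption.  Missing-valued units are dropped
    (``strict=True``: any missing unit makes the result missing).  Returns
    NaN when no piece has a value.
    """
    total, n_used = 0.0, 0
    for p in partition.pieces:
        v = values.get(p.unit_id)
        if _is_missing(v):
            if strict:
                return float("nan")
            continue
        v = float(v)
        if v < 0:
            warnings.warn(f"unit {p.unit_id!r}: negative value {v} for a count measure")
        total += p.weight * v
        n_used += 1
    return total if n_used else float("nan")


def interpolate_proportion(partition: BufferPartition, values: Mapping[str, float], strict: bool = False) -> float:
    """Intersection-area-weighted mean of unit values over the partition.

    Values are expected in [0, 1] or [0, 100]; out-of-range values warn but
    are used.  Returns NaN when the total intersecting area with values is
    zero.
    """
    num, den, n_used = 0.0, 0.0, 0
    for p in partition.pieces:
        v = values.get(p.unit_id)
        if _is_missing(v):
            if strict:
                return float("nan")
            continue
        v = float(v)
        if not (0.0 <= v <= 100.0):
            warnings.warn(f"unit {p.unit_id!r}: proportion value {v} outside [0, 100]")
        num += p.intersection_area * v
        den += p.intersection_area
        n_used += 1
    if den <= 0 or n_used == 0:
        return float("nan")
    return num / den


_INTERPOLATORS = {"count": interpolate_count, "proportion": interpolate_proportion}


def assemble_context_measures(
    locations: Iterable[tuple[str, GeoPoint]],
    radius_m: float | Sequence[float],
    datasets: Sequence[ArealDataset] | ArealDataset,
    measures: Sequence[str] | None = None,
    projection: str | Projection = "aeqd",
    n_segments: int = DEFAULT_SEGMENTS,
    strict: bool = False,
) -> pd.DataFrame:
    """Assemble one output row per (location, radius, measure).

    Dispatches to count or proportion interpolation according to each
    measure's declared kind; deterministic given inputs.  ``measures`` of
    None selects every registered measure across the datasets; an unknown
    name raises a configuration error listing the available ones.
    """
    if isinstance(datasets, ArealDataset):
        datasets = [datasets]
    radii = [float(radius_m)] if np.isscalar(radius_m) else [float(r) for r in radius_m]
    for r in radii:
        if r <= 0:
            raise ValidationError(f"radius must be positive, got {r}")

    available: dict[str, tuple[ArealDataset, MeasureDefinition]] = {}
    for ds in datasets:
        for m in ds.measures:
            available.setdefault(m.key, (ds, m))
    selected = list(available) if measures is None else list(measures)
    unknown = [m for m in selected if m not in available]
    if unknown:
        raise ConfigurationError(f"unknown measure(s) {unknown}; available: {sorted(available)}")

    rows = []
    for location_id, point in locations:
        if not isinstance(point, GeoPoint):
            point = GeoPoint(*point)
        for r in radii:
            buf = build_buffer(point, r, projection=projection, n_segments=n_segments)
            partitions: dict[int, BufferPartition] = {}
            for mkey in selected:
                ds, mdef = available[mkey]
                part = partitions.get(id(ds))
                if part is None:
                    part = partitions[id(ds)] = partition_buffer(buf, ds)
                values = ds.values_for(mkey)
                inter = {p.unit_id: values.get(p.unit_id) for p in part.pieces}
                n_missing = sum(1 for v in inter.values() if _is_missing(v))
                value = _INTERPOLATORS[mdef.kind](part, values, strict=strict)
                rows.append(
                    {
                        "location_id": location_id,
                        "radius_m": r,
                        "measure": mkey,
                        "value": value,
                        "coverage_fraction": part.coverage_fraction,
                        "n_units": len(part.pieces),
                        "n_missing": n_missing,
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def population_density(
    location: GeoPoint,
    radius_m: float,
    dataset: ArealDataset,
    population_measure: str = "population",
    land_area_measure: str = "land_area",
    projection: str | Projection = "aeqd",
    n_segments: int = DEFAULT_SEGMENTS,
) -> float:
    """Population per square meter of land within the buffer.

    Both measures must be count-kind; land area (m² per unit) excludes
    water, so dividing the interpolated population by the interpolated land
    area gives density over land rather than over the raw disk.  Returns NaN
    with a warning if the interpolated land area is not positive.
    """
    for mname in (population_measure, land_area_measure):
        if dataset.measure(mname).kind != "count":
            raise ValidationError(f"{mname!r} must be a count measure for density computation")
    buf = build_buffer(location, radius_m, projection=projection, n_segments=n_segments)
    part = partition_buffer(buf, dataset)
    pop = interpolate_count(part, dataset.values_for(population_measure))
    land = interpolate_count(part, dataset.values_for(land_area_measure))
    if not (land > 0):
        warnings.warn(f"interpolated land area {land!r} is not positive; density undefined")
        return float("nan")
    return pop / land
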