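"""External formats: GeoJSON areal datasets, CSV location/point/gazetteer
tables, YAML/JSON measure registries, and CSV result export.

All areal interchange is GeoJSON FeatureCollection (RFC 7946, lon-lat
order) with a required ``unit_id`` property per feature.  CSV loaders
validate coordinates row by row and report every bad row in one pass, and
every loader checks the physical line count against the parsed row count so
silently truncated files are rejected.  Missing numeric cells ("" or "NA")
become missing values — never zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .areal import ArealDataset, ArealUnit, MeasureDefinition, RESULT_COLUMNS
from .errors import SchemaError, ValidationError
from .geocoding import GazetteerRecord
from .geometry import GeoPoint
from .points import PointDataset

GAZETTEER_COLUMNS = ["house_number", "street", "street_type", "city", "state", "zip", "lat", "lon"]


@dataclass(frozen=True)
class RegistryEntry:
    """One measure bound to the areal dataset file that carries it."""

    measure: MeasureDefinition
    path: str = ""
    unit_id_property: str = "unit_id"
    geography: str = ""  # e.g. "census tract", "grid cell"


@dataclass
class MeasureRegistry:
    entries: list[RegistryEntry] = field(default_factory=list)

    @property
    def measures(self) -> list[MeasureDefinition]:
        return [e.measure for e in self.entries]

    def measures_for(self, path: str | Path) -> list[MeasureDefinition]:
        name = Path(path).name
        return [e.measure for e in self.entries if not e.path or Path(e.path).name == name]


def load_registry(path: str | Path, base_dir: str | Path | None = None) -> MeasureRegistry:
    """Load and validate a YAML/JSON measure registry.

    Validation is total: every problem (bad kind, duplicate name@year,
    missing bound file) is collected and reported in a single error.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if isinstance(raw, dict) and "measures" in raw:
        raw = raw["measures"]
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: registry must be a list of measure entries")
    base = Path(base_dir) if base_dir is not None else path.parent
    errors, entries, seen = [], [], set()
    for i, item in enumerate(raw):
        if not isinstance(item, dict):
            errors.append(f"entry {i}: not a mapping")
            continue
        name = item.get("name")
        kind = item.get("kind")
        if not name:
            errors.append(f"entry {i}: missing name")
        if kind not in ("count", "proportion"):
            errors.append(f"entry {i} ({name}): kind must be count|proportion, got {kind!r}")
        year = item.get("year")
        key = (name, year)
        if key in seen:
            errors.append(f"entry {i} ({name}): duplicate (name, year) {key}")
        seen.add(key)
        fpath = item.get("path", "")
        if fpath and not (base / fpath).exists():
            errors.append(f"entry {i} ({name}): bound file {fpath!r} not found under {base}")
        if name and kind in ("count", "proportion"):
            entries.append(
                RegistryEntry(
                    measure=MeasureDefinition(
                        name=name, kind=kind, units=item.get("units", ""), year=year, source=item.get("source", "")
                    ),
                    path=str(base / fpath) if fpath else "",
                    unit_id_property=item.get("unit_id_property", "unit_id"),
                    geography=item.get("geography", ""),
                )
            )
    if errors:
        raise SchemaError(f"{path}: invalid registry", details=errors)
    return MeasureRegistry(entries=entries)


def load_areal_dataset(path: str | Path, registry: MeasureRegistry | list[MeasureDefinition]) -> ArealDataset:
    """Load a GeoJSON FeatureCollection as a validated areal dataset.

    Properties not registered as measures are preserved on the units but
    excluded from assembly.  Missing ``unit_id`` or duplicates are schema
    errors naming the feature index.
    """
    path = Path(path)
    gj = json.loads(path.read_text(encoding="utf-8"))
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    measures = registry.measures_for(path) if isinstance(registry, MeasureRegistry) else list(registry)
    keys = {m.key for m in measures} | {m.name for m in measures}
    errors, units, seen = [], [], set()
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        uid = props.get("unit_id")
        if uid is None:
            errors.append(f"feature {i}: missing unit_id property")
            continue
        uid = str(uid)
        if uid in seen:
            errors.append(f"feature {i}: duplicate unit_id {uid!r}")
            continue
        seen.add(uid)
        values = {}
        for k, v in props.items():
            if k in keys:
                if v is None or (isinstance(v, str) and v.strip() in ("", "NA")):
                    values[k] = float("nan")
                else:
                    values[k] = float(v)
        units.append(ArealUnit(unit_id=uid, geometry=shape(feat["geometry"]), values=values))
    if errors:
        raise SchemaError(f"{path}: invalid areal dataset", details=errors)
    return ArealDataset(units=units, measures=measures, name=path.stem)


def write_areal_dataset(dataset: ArealDataset, path: str | Path) -> None:
    """Write an areal dataset as a GeoJSON FeatureCollection (lon-lat)."""
    features = []
    for u in dataset.units:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(u.geometry),
                "properties": {"unit_id": u.unit_id, **u.values},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True), encoding="utf-8"
    )


def _read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    df = pd.read_csv(path, dtype={"location_id": str, "point_id": str, "zip": str}, keep_default_na=True,
                     na_values=["", "NA"])
    n_lines = sum(1 for line in text.splitlines() if line.strip())
    if n_lines and n_lines - 1 != len(df):
        raise SchemaError(f"{path}: parsed {len(df)} rows but file has {n_lines - 1} data lines (truncated or malformed?)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def _validate_coords(df: pd.DataFrame, path, allow_missing: bool = False) -> None:
    errors = []
    for idx, row in df.iterrows():
        lat, lon = row.get("lat"), row.get("lon")
        if pd.isna(lat) or pd.isna(lon):
            if not allow_missing:
                errors.append(f"row {idx}: missing coordinates")
            continue
        try:
            GeoPoint(float(lat), float(lon))
        except ValidationError as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise SchemaError(f"{path}: invalid coordinates", details=errors)


def load_points(path: str | Path) -> PointDataset:
    """Load a point-event CSV (point_id, lat, lon, attribute columns)."""
    df = _read_csv_checked(path, ["point_id", "lat", "lon"])
    _validate_coords(df, path)
    attrs_cols = [c for c in df.columns if c not in ("point_id", "lat", "lon")]
    points = [
        (str(r["point_id"]), GeoPoint(float(r["lat"]), float(r["lon"])), {c: r[c] for c in attrs_cols})
        for _, r in df.iterrows()
    ]
    return PointDataset(points=points, source=Path(path).stem)


def load_locations(path: str | Path) -> pd.DataFrame:
    """Load a location CSV with location_id plus address and/or lat+lon."""
    df = _read_csv_checked(path, ["location_id"])
    has_addr = "address" in df.columns
    has_coords = "lat" in df.columns and "lon" in df.columns
    if not has_addr and not has_coords:
        raise SchemaError(f"{path}: need an 'address' column or 'lat'+'lon' columns")
    if has_coords:
        _validate_coords(df, path, allow_missing=has_addr)
    if df["location_id"].duplicated().any():
        dupes = sorted(df.loc[df["location_id"].duplicated(), "location_id"].unique())
        raise SchemaError(f"{path}: duplicate location_id(s) {dupes}")
    return df


def locations_to_points(df: pd.DataFrame) -> list[tuple[str, GeoPoint]]:
    """Rows with valid coordinates as (location_id, GeoPoint) pairs."""
    out = []
    for _, r in df.iterrows():
        if pd.notna(r.get("lat")) and pd.notna(r.get("lon")):
            out.append((str(r["location_id"]), GeoPoint(float(r["lat"]), float(r["lon"]))))
    return out


def load_gazetteer(path: str | Path) -> list[GazetteerRecord]:
    """Load a gazetteer CSV into normalized records."""
    df = _read_csv_checked(path, GAZETTEER_COLUMNS)
    _validate_coords(df, path)
    return [
        GazetteerRecord(
            house_number=str(r["house_number"]),
            street=str(r["street"]),
            street_type=str(r["street_type"]),
            city=str(r["city"]),
            state=str(r["state"]),
            zip=str(r["zip"]),
            point=GeoPoint(float(r["lat"]), float(r["lon"])),
        )
        for _, r in df.iterrows()
    ]


def write_gazetteer(records: list[GazetteerRecord], path: str | Path) -> None:
    rows = [
        {
            "house_number": r.house_number,
            "street": r.street,
            "street_type": r.street_type,
            "city": r.city,
            "state": r.state,
            "zip": r.zip,
            "lat": r.point.lat,
            "lon": r.point.lon,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GAZETTEER_COLUMNS).to_csv(path, index=False)


def write_results(rows: pd.DataFrame, path: str | Path) -> None:
    """Write assembler/point output CSV with the canonical column order."""
    cols = [c for c in RESULT_COLUMNS if c in rows.columns] + [c for c in rows.columns if c not in RESULT_COLUMNS]
    rows[cols].to_csv(path, index=False)
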