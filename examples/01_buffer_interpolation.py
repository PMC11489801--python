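"""Radial-buffer areal interpolation on a synthetic tract grid.

Builds a 1 km buffer around Seattle City Hall, overlays it on a 3x3 grid of
1 km tracts with known values, and prints the area-weighted estimates.
"""

import math

import geocontext as gc

city_hall = gc.GeoPoint(47.60, -122.33)
buffer_ = gc.build_buffer(city_hall, radius_m=1000.0)
print(f"buffer area: {buffer_.area / 1e6:.4f} km^2 (ideal disk {math.pi:.4f} km^2)")

tracts = gc.generate_tract_grid(
    3,
    cell_km=1.0,
    origin=city_hall,
    measures={
        "population": {"kind": "count", "low": 500, "high": 3000},
        "pct_poverty": {"kind": "proportion", "low": 0.05, "high": 0.40},
    },
    seed=42,
)

partition = gc.partition_buffer(buffer_, tracts)
print(f"buffer intersects {len(partition.pieces)} tracts, coverage {partition.coverage_fraction:.3f}")
for piece in partition.pieces:
    print(f"  tract {piece.unit_id}: {100 * piece.weight:.1f}% of the tract falls in the buffer")

pop = gc.interpolate_count(partition, tracts.values_for("population"))
pov = gc.interpolate_proportion(partition, tracts.values_for("pct_poverty"))
print(f"estimated population in buffer: {pop:.0f} people (sum of tract shares)")
print(f"estimated poverty share: {100 * pov:.1f}% (intersection-area-weighted mean)")
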