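"""Areal interpolation: partitioning, count/proportion semantics, density."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

import geocontext as gc
from geocontext.areal import BufferPartition, PartitionPiece
from geocontext.errors import ConfigurationError, ValidationError

from conftest import mc_partition_check


def make_partition(weights, unit_areas=None):
    """Synthetic partition with prescribed area-fraction weights."""
    unit_areas = unit_areas or [100.0] * len(weights)
    pieces = tuple(
        PartitionPiece(unit_id=f"t{i+1}", intersection_area=w * a, unit_total_area=a)
        for i, (w, a) in enumerate(zip(weights, unit_areas))
    )
    return BufferPartition(pieces=pieces, buffer_area=sum(p.intersection_area for p in pieces))


class TestInterpolateCount:
    def test_worked_population_example(self):
        """Four tracts covered at 6/12/12/6 percent with populations
        2000/1800/3000/1800 contribute 120+216+360+108 = 804 people."""
        part = make_partition([0.06, 0.12, 0.12, 0.06])
        values = {"t1": 2000, "t2": 1800, "t3": 3000, "t4": 1800}
        assert gc.interpolate_count(part, values) == pytest.approx(804.0, abs=1e-9)

    def test_single_piece_identity(self):
        part = make_partition([1.0])
        assert gc.interpolate_count(part, {"t1": 500.0}) == pytest.approx(500.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            weights = rng.uniform(0.01, 0.9, size=5)
            areas = rng.uniform(50, 500, size=5)
            part = make_partition(weights, list(areas))
            values = {f"t{i+1}": float(v) for i, v in enumerate(rng.uniform(0, 5000, size=5))}
            expected = sum(w * values[f"t{i+1}"] for i, w in enumerate(weights))
            assert gc.interpolate_count(part, values) == pytest.approx(expected, rel=1e-12)

    def test_missing_policy(self):
        part = make_partition([0.5, 0.5])
        assert gc.interpolate_count(part, {"t1": 100.0, "t2": float("nan")}) == pytest.approx(50.0)
        assert math.isnan(gc.interpolate_count(part, {"t1": 100.0, "t2": None}, strict=True))
        assert math.isnan(gc.interpolate_count(part, {}))

    def test_negative_count_warns(self):
        part = make_partition([1.0])
        with pytest.warns(UserWarning, match="negative"):
            gc.interpolate_count(part, {"t1": -5.0})


class TestInterpolateProportion:
    def test_equal_areas_average(self):
        part = make_partition([0.3, 0.3])
        assert gc.interpolate_proportion(part, {"t1": 0.2, "t2": 0.6}) == pytest.approx(0.4)

    def test_constant_value_recovered(self):
        part = make_partition([0.1, 0.5, 0.9], unit_areas=[100, 300, 700])
        assert gc.interpolate_proportion(part, {"t1": 0.37, "t2": 0.37, "t3": 0.37}) == pytest.approx(0.37)

    def test_weighted_mean_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            areas = rng.uniform(10, 400, size=4)
            inter = areas * rng.uniform(0.05, 1.0, size=4)
            pieces = tuple(
                PartitionPiece(f"t{i+1}", float(a), float(t)) for i, (a, t) in enumerate(zip(inter, areas))
            )
            part = BufferPartition(pieces=pieces, buffer_area=float(inter.sum()))
            values = {f"t{i+1}": float(v) for i, v in enumerate(rng.uniform(0, 1, size=4))}
            expected = float(np.average([values[f"t{i+1}"] for i in range(4)], weights=inter))
            assert gc.interpolate_proportion(part, values) == pytest.approx(expected, rel=1e-12)

    def test_bounds_property(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            part = make_partition(list(rng.uniform(0.05, 1.0, size=k)))
            values = {f"t{i+1}": float(v) for i, v in enumerate(rng.uniform(0, 1, size=k))}
            out = gc.interpolate_proportion(part, values)
            assert min(values.values()) - 1e-12 <= out <= max(values.values()) + 1e-12

    def test_zero_area_missing(self):
        part = BufferPartition(pieces=(), buffer_area=100.0)
        assert math.isnan(gc.interpolate_proportion(part, {"t1": 0.5}))


class TestPartitionBuffer:
    def test_buffer_inside_single_tract(self, seattle):
        big = gc.generate_tract_grid(1, cell_km=10.0, origin=seattle,
                                     measures={"population": {"kind": "count", "value": 2000}}, seed=0)
        buf = gc.build_buffer(seattle, 1000.0)
        part = gc.partition_buffer(buf, big)
        assert len(part.pieces) == 1
        piece = part.pieces[0]
        assert piece.weight == pytest.approx(buf.area / piece.unit_total_area, rel=1e-9)
        assert part.coverage_fraction == pytest.approx(1.0, abs=1e-9)

    def test_buffer_equal_to_union_of_two_tracts(self, seattle):
        """Split the buffer polygon into two halves used as the 'tracts':
        both weights are 1 and coverage is exactly 1."""
        buf = gc.build_buffer(seattle, 1000.0)
        left = buf.polygon.intersection(box(-2000, -2000, 0, 2000))
        right = buf.polygon.intersection(box(0, -2000, 2000, 2000))
        units = [
            gc.ArealUnit("L", gc.unproject_geometry(left, buf.projection), {"v": 10.0}),
            gc.ArealUnit("R", gc.unproject_geometry(right, buf.projection), {"v": 20.0}),
        ]
        ds = gc.ArealDataset(units=units, measures=[gc.MeasureDefinition("v", "count")])
        part = gc.partition_buffer(buf, ds)
        assert len(part.pieces) == 2
        for p in part.pieces:
            assert p.weight == pytest.approx(1.0, abs=1e-6)
        assert part.coverage_fraction == pytest.approx(1.0, abs=1e-6)
        # pycnophylactic conservation: the union's count is the exact sum
        assert gc.interpolate_count(part, ds.values_for("v")) == pytest.approx(30.0, rel=1e-6)

    def test_monte_carlo_oracle_small(self, seattle):
        rng = np.random.default_rng(5)
        for i in range(5):
            origin = gc.GeoPoint(seattle.lat + float(rng.uniform(-0.01, 0.01)),
                                 seattle.lon + float(rng.uniform(-0.01, 0.01)))
            ds = gc.generate_tract_grid(3, cell_km=float(rng.uniform(0.8, 1.6)), origin=origin, seed=i)
            buf = gc.build_buffer(seattle, float(rng.uniform(800, 2000)))
            mc_partition_check(buf, ds, n_samples=200_000, rng=rng)

    def test_empty_dataset(self, seattle):
        ds = gc.ArealDataset(units=[], measures=[gc.MeasureDefinition("v", "count")])
        buf = gc.build_buffer(seattle, 1000.0)
        part = gc.partition_buffer(buf, ds)
        assert part.pieces == () and part.coverage_fraction == 0.0

    def test_invalid_unit_repaired_or_skipped(self, seattle):
        bowtie = Polygon([(-122.34, 47.59), (-122.32, 47.61), (-122.34, 47.61), (-122.32, 47.59)])
        units = [gc.ArealUnit("bt", bowtie, {"v": 1.0})]
        ds = gc.ArealDataset(units=units, measures=[gc.MeasureDefinition("v", "count")])
        buf = gc.build_buffer(seattle, 1000.0)
        part = gc.partition_buffer(buf, ds)  # zero-width-buffer repair handles the bowtie
        assert all(0.0 <= p.weight <= 1.0 for p in part.pieces)

    def test_coverage_never_exceeds_buffer(self, seattle, unit_grid):
        for r in (500.0, 1500.0, 4000.0):
            buf = gc.build_buffer(seattle, r)
            part = gc.partition_buffer(buf, unit_grid)
            assert part.covered_area <= part.buffer_area * (1 + 1e-9)
            assert all(0.0 <= p.weight <= 1.0 for p in part.pieces)


class TestAssemble:
    def test_weight_tenth_of_tract(self, seattle):
        """Buffer one tenth of a uniform tract: count 2000 scales to 200."""
        cell_area_km2 = math.pi * 1e6 * 10 / 1e6
        side_km = math.sqrt(cell_area_km2)
        ds = gc.generate_tract_grid(1, cell_km=side_km, origin=seattle,
                                    measures={"population": {"kind": "count", "value": 2000}}, seed=0)
        out = gc.assemble_context_measures([("loc1", seattle)], 1000.0, ds, measures=["population"])
        assert len(out) == 1
        # polygon area is 99.84% of pi r^2, so compare against the exact ratio
        expected = 2000 * gc.build_buffer(seattle, 1000.0).area / (cell_area_km2 * 1e6)
        assert out["value"].iloc[0] == pytest.approx(expected, rel=1e-4)

    def test_empty_locations(self, unit_grid):
        from geocontext.areal import RESULT_COLUMNS

        out = gc.assemble_context_measures([], 1000.0, unit_grid)
        assert len(out) == 0
        assert list(out.columns) == RESULT_COLUMNS

    def test_unknown_measure_lists_available(self, unit_grid, seattle):
        with pytest.raises(ConfigurationError, match="available"):
            gc.assemble_context_measures([("a", seattle)], 1000.0, unit_grid, measures=["nope"])

    def test_compositional_oracle(self, seattle, unit_grid):
        """Assembled rows equal direct partition_buffer + interpolate_* calls."""
        locs = [("a", seattle), ("b", gc.GeoPoint(47.61, -122.32)), ("c", gc.GeoPoint(47.585, -122.345))]
        radii = [700.0, 1200.0, 2000.0, 3100.0, 4500.0]
        out = gc.assemble_context_measures(locs, radii, unit_grid)
        for _, row in out.iterrows():
            pt = dict(locs)[row["location_id"]]
            buf = gc.build_buffer(pt, row["radius_m"])
            part = gc.partition_buffer(buf, unit_grid)
            mdef = unit_grid.measure(row["measure"])
            fn = gc.interpolate_count if mdef.kind == "count" else gc.interpolate_proportion
            expected = fn(part, unit_grid.values_for(row["measure"]))
            if math.isnan(expected):
                assert math.isnan(row["value"])
            else:
                assert row["value"] == pytest.approx(expected, rel=1e-12)

    def test_count_monotone_in_radius(self, seattle, unit_grid):
        out = gc.assemble_context_measures(
            [("a", seattle)], [500.0, 1000.0, 2000.0, 3000.0], unit_grid, measures=["population"]
        )
        vals = out.sort_values("radius_m")["value"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-9)

    def test_uniform_field_recovery(self, seattle):
        """Counts equal to density x unit area recover density x covered area."""
        density = 0.0025
        ds = gc.generate_tract_grid(4, cell_km=1.0, origin=seattle,
                                    measures={"population": {"kind": "count", "value": density * 1e6}}, seed=0)
        buf = gc.build_buffer(seattle, 1500.0)
        part = gc.partition_buffer(buf, ds)
        est = gc.interpolate_count(part, ds.values_for("population"))
        assert est == pytest.approx(density * part.covered_area, rel=0.005)


class TestPopulationDensity:
    def test_uniform_land_city(self, seattle):
        d = 0.004
        ds = gc.generate_tract_grid(6, cell_km=1.5, origin=seattle,
                                    measures={"population": {"kind": "count", "value": d * 1.5e3 ** 2}}, seed=0)
        for r in (800.0, 2000.0):
            assert gc.population_density(seattle, r, ds) == pytest.approx(d, rel=0.01)

    def test_half_water_doubles_density(self, seattle):
        """Halving the land-area attribute (half-water tract) doubles density
        relative to dividing the same population by the full buffer area."""
        pop = 5000.0
        full = gc.generate_tract_grid(1, cell_km=8.0, origin=seattle,
                                      measures={"population": {"kind": "count", "value": pop}}, seed=0)
        half = gc.generate_tract_grid(1, cell_km=8.0, origin=seattle,
                                      measures={"population": {"kind": "count", "value": pop}}, seed=0)
        for u in half.units:
            u.values["land_area"] = u.values["land_area"] / 2.0
        r = 1000.0
        d_full = gc.population_density(seattle, r, full)
        d_half = gc.population_density(seattle, r, half)
        assert d_half == pytest.approx(2.0 * d_full, rel=1e-9)
        buf = gc.build_buffer(seattle, r)
        part = gc.partition_buffer(buf, half)
        naive = gc.interpolate_count(part, half.values_for("population")) / part.covered_area
        assert d_half == pytest.approx(2.0 * naive, rel=1e-6)

    def test_zero_population(self, seattle):
        ds = gc.generate_tract_grid(2, cell_km=3.0, origin=seattle,
                                    measures={"population": {"kind": "count", "value": 0}}, seed=0)
        assert gc.population_density(seattle, 1000.0, ds) == pytest.approx(0.0, abs=1e-12)

    def test_zero_land_is_missing(self, seattle):
        ds = gc.generate_tract_grid(1, cell_km=5.0, origin=seattle,
                                    measures={"population": {"kind": "count", "value": 100}}, seed=0)
        for u in ds.units:
            u.values["land_area"] = 0.0
        with pytest.warns(UserWarning, match="land area"):
            assert math.isnan(gc.population_density(seattle, 1000.0, ds))

    def test_requires_count_kind(self, seattle):
        ds = gc.generate_tract_grid(2, cell_km=3.0, origin=seattle, seed=0)  # has pct_poverty (proportion)
        with pytest.raises(ValidationError):
            gc.population_density(seattle, 1000.0, ds, population_measure="population",
                                  land_area_measure="pct_poverty")
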