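import numpy as np
import pytest
import shapely

import geocontext as gc

SEATTLE = gc.GeoPoint(47.60, -122.33)


@pytest.fixture
def seattle():
    return SEATTLE


@pytest.fixture
def unit_grid():
    """3x3 grid of 1 km cells with uniform population 1000."""
    return gc.generate_tract_grid(
        3, cell_km=1.0, measures={"population": {"kind": "count", "value": 1000}}, seed=7
    )


@pytest.fixture
def small_gazetteer():
    rec = gc.GazetteerRecord("600", "4th", "Ave", "Seattle", "WA", "98104", gc.GeoPoint(47.60, -122.33))
    rec2 = gc.GazetteerRecord("1410", "ne campus", "Pkwy", "Seattle", "WA", "98195", gc.GeoPoint(47.656, -122.315))
    return [rec, rec2]


def mc_partition_check(buffer, dataset, n_samples, rng, max_abs_z=3.0):
    """Monte-Carlo rejection-sampling oracle for partition intersection areas.

    Samples ``n_samples`` uniform points inside the buffer polygon and
    compares each piece's intersection area against the binomial estimate
    within ``max_abs_z`` standard errors.  Returns the max |z| seen.
    """
    poly = buffer.polygon
    shapely.prepare(poly)
    minx, miny, maxx, maxy = poly.bounds
    xs, ys, got = [], [], 0
    while got < n_samples:
        k = int(1.4 * (n_samples - got)) + 100
        x = rng.uniform(minx, maxx, k)
        y = rng.uniform(miny, maxy, k)
        m = shapely.contains_xy(poly, x, y)
        xs.append(x[m])
        ys.append(y[m])
        got += int(m.sum())
    x = np.concatenate(xs)[:n_samples]
    y = np.concatenate(ys)[:n_samples]

    part = gc.partition_buffer(buffer, dataset)
    units = {u.unit_id: u for u in dataset.units}
    worst = 0.0
    for piece in part.pieces:
        g = gc.project_geometry(units[piece.unit_id].geometry, buffer.projection)
        shapely.prepare(g)
        hits = int(shapely.contains_xy(g, x, y).sum())
        p0 = piece.intersection_area / poly.area  # implementation value as the null
        mu = n_samples * p0
        if mu < 9.0 or n_samples * (1.0 - p0) < 9.0:
            # sliver piece: normal approximation invalid, use Poisson-style slack
            assert abs(hits - mu) <= 3.0 * np.sqrt(mu) + 3.0, (
                f"unit {piece.unit_id}: {hits} MC hits vs expected {mu:.2f}"
            )
            continue
        z = abs(hits - mu) / np.sqrt(mu * (1.0 - p0))
        worst = max(worst, z)
        assert z < max_abs_z, (
            f"unit {piece.unit_id}: area {piece.intersection_area:.1f} vs MC "
            f"{hits / n_samples * poly.area:.1f} (z={z:.2f})"
        )
    return worst
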