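"""NDRE1, inward buffering and zonal statistics vs. brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp
from shapely.geometry import Point, Polygon

from spectransfer import (
    GridTransform,
    MeasurementDate,
    PlotGeometry,
    RasterLayer,
    STAT_NAMES,
    buffer_inward,
    extract_plot_stats,
    ndre1,
    read_raster_pair,
    stats_from_pixels,
    write_raster_pair,
)
from spectransfer.spectral import (
    QUANTILE_LEVELS,
    pixel_values_in_polygon,
    read_plots_geojson,
    records_to_long,
    records_to_wide,
    stats_from_pixel_matrix,
    write_plots_geojson,
)

T = GridTransform(0.0, 10.0, 0.1, -0.1)
DATE = MeasurementDate.from_iso("2020-05-29", 65)


def layer(arr, band=780, transform=T):
    return RasterLayer(np.asarray(arr, dtype=float), transform, band)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Sort-and-interpolate quantile, written from the definition."""
    v = np.sort(np.asarray(values, dtype=float))
    h = q * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def point_in_polygon_oracle(poly_xy, x, y):
    """Ray casting, independent of shapely."""
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def zonal_oracle(index, poly_xy):
    """Loop every pixel of the raster; collect centers inside the polygon."""
    vals = []
    nrow, ncol = index.shape
    for r in range(nrow):
        for c in range(ncol):
            x, y = index.transform.pixel_center(r, c)
            v = index.values[r, c]
            if v != index.nodata and np.isfinite(v):
                if point_in_polygon_oracle(poly_xy, float(x), float(y)):
                    vals.append(v)
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# NDRE1
# ---------------------------------------------------------------------------

class TestNdre1:
    @pytest.mark.parametrize(
        "nir,re,expected",
        [(0.5, 0.5, 0.0), (0.6, 0.2, 0.5), (0.8, 0.4, 1 / 3)],
    )
    def test_pixel_values(self, nir, re, expected):
        out = ndre1(layer([[nir]]), layer([[re]], 700))
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_pixel_becomes_nodata(self):
        out = ndre1(layer([[0.0]]), layer([[0.0]], 700))
        assert out.values[0, 0] == out.nodata

    def test_nodata_propagates(self):
        nir = layer([[-9999.0, 0.6]])
        re = layer([[0.2, -9999.0]], 700)
        out = ndre1(nir, re)
        assert (out.values == out.nodata).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape or transform"):
            ndre1(layer(np.zeros((2, 2))), layer(np.zeros((2, 3)), 700))
        with pytest.raises(ValueError, match="shape or transform"):
            ndre1(layer([[0.5]]), layer([[0.5]], 700, GridTransform(1, 1, 0.1, -0.1)))

    @settings(max_examples=50, derandomize=True)
    @given(
        nir1=st_hyp.floats(0.01, 1.0),
        nir2=st_hyp.floats(0.01, 1.0),
        re=st_hyp.floats(0.01, 1.0),
    )
    def test_monotone_in_nir(self, nir1, nir2, re):
        lo, hi = sorted([nir1, nir2])
        v_lo = ndre1(layer([[lo]]), layer([[re]], 700)).values[0, 0]
        v_hi = ndre1(layer([[hi]]), layer([[re]], 700)).values[0, 0]
        assert v_hi >= v_lo
        assert -1.0 <= v_lo <= 1.0


# ---------------------------------------------------------------------------
# buffering
# ---------------------------------------------------------------------------

def rect(w, h):
    return PlotGeometry("p", Polygon([(0, 0), (w, 0), (w, h), (0, h)]), 1, "G")


class TestBufferInward:
    def test_rectangle_shrinks_by_twice_the_buffer(self):
        out = buffer_inward(rect(1.5, 8.0), 0.2)
        minx, miny, maxx, maxy = out.polygon.bounds
        assert (maxx - minx, maxy - miny) == pytest.approx((1.1, 7.6))
        assert out.polygon.area == pytest.approx(1.1 * 7.6)

    def test_tiny_plot_collapses_to_empty(self):
        out = buffer_inward(rect(0.3, 0.3), 0.2)
        assert out.is_empty

    def test_zero_buffer_is_identity(self):
        plot = rect(1.5, 8.0)
        assert buffer_inward(plot, 0.0).polygon.equals(plot.polygon)

    def test_convex_polygon_area_decreases(self):
        hexagon = Polygon(
            [(np.cos(a) * 2, np.sin(a) * 2) for a in np.linspace(0, 2 * np.pi, 7)[:-1]]
        )
        plot = PlotGeometry("h", hexagon, 1, "G")
        out = buffer_inward(plot, 0.3)
        assert 0 < out.polygon.area < hexagon.area


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestStats:
    def test_constant_field(self):
        s = stats_from_pixels(np.full(50, 0.37))
        assert (s[:21] == 0.37).all()
        assert s["mean"] == pytest.approx(0.37)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_four_pixel_example_against_oracle(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        s = stats_from_pixels(vals)
        assert s["q000"] == pytest.approx(0.1)
        assert s["q100"] == pytest.approx(0.4)
        assert s["q050"] == pytest.approx(0.25)
        for name, q in zip(STAT_NAMES[:21], QUANTILE_LEVELS):
            assert s[name] == pytest.approx(quantile_oracle(vals, q), abs=1e-12)
        assert s["sd"] == pytest.approx(vals.std(ddof=1))

    def test_exactly_23_statistics(self):
        assert len(STAT_NAMES) == 23
        assert len(stats_from_pixels([0.1, 0.2, 0.3])) == 23

    @settings(max_examples=30, derandomize=True)
    @given(st_hyp.lists(st_hyp.floats(-1, 1), min_size=2, max_size=60),
           st_hyp.randoms(use_true_random=False))
    def test_permutation_invariance_and_sorted_quantiles(self, vals, rng):
        s1 = stats_from_pixels(np.asarray(vals))
        shuffled = list(vals)
        rng.shuffle(shuffled)
        s2 = stats_from_pixels(np.asarray(shuffled))
        assert np.allclose(s1.to_numpy(), s2.to_numpy())
        q = s1[:21].to_numpy()
        assert (np.diff(q) >= 0).all()
        assert q[0] <= s1["mean"] <= q[20]

    def test_matrix_path_matches_per_plot_path(self):
        rng = np.random.default_rng(0)
        block = rng.uniform(-1, 1, size=(5, 40))
        wide = stats_from_pixel_matrix(block)
        for i in range(5):
            assert np.allclose(wide.iloc[i].to_numpy(),
                               stats_from_pixels(block[i]).to_numpy())


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def make_index(self, seed=0, shape=(50, 50)):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-0.2, 0.9, size=shape)
        vals[rng.random(shape) < 0.05] = -9999.0  # sprinkle nodata
        return RasterLayer(vals, GridTransform(0.0, shape[0] * 0.1, 0.1, -0.1), None)

    def test_constant_plot(self):
        idx = RasterLayer(np.full((30, 30), 0.42), T, None)
        plot = PlotGeometry("p", Polygon([(0.2, 7), (2.5, 7), (2.5, 9.8), (0.2, 9.8)]),
                            1, "G")
        (rec,) = extract_plot_stats(idx, [plot], DATE, buffer_m=0.2)
        assert (rec.quantiles == 0.42).all()
        assert rec.mean == pytest.approx(0.42)
        assert rec.sd == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        idx = self.make_index(seed)
        rng = np.random.default_rng(100 + seed)
        # buffered polygon applied manually: buffer 0 in the call
        cx, cy = rng.uniform(1.5, 3.5, 2)
        poly_xy = [
            (cx + np.cos(a) * r, cy + np.sin(a) * r)
            for a, r in zip(np.linspace(0, 2 * np.pi, 8)[:-1], rng.uniform(0.8, 1.4, 7))
        ]
        plot = PlotGeometry("p", Polygon(poly_xy), 1, "G")
        (rec,) = extract_plot_stats(idx, [plot], DATE, buffer_m=0.0, min_pixels=5)
        oracle_vals = zonal_oracle(idx, poly_xy)
        assert rec.n_pixels == oracle_vals.size
        for name, q in zip(STAT_NAMES[:21], QUANTILE_LEVELS):
            assert rec.as_series()[name] == pytest.approx(
                quantile_oracle(oracle_vals, q), abs=1e-12
            )
        assert rec.mean == pytest.approx(oracle_vals.mean(), abs=1e-12)
        assert rec.sd == pytest.approx(oracle_vals.std(ddof=1), abs=1e-12)

    def test_small_plots_omitted(self):
        idx = self.make_index()
        big = PlotGeometry("big", Polygon([(1, 1), (4, 1), (4, 4), (1, 4)]), 1, "G")
        tiny = PlotGeometry("tiny", Polygon([(0, 0), (0.5, 0), (0.5, 0.5), (0, 0.5)]),
                            2, "G")
        recs = extract_plot_stats(idx, [big, tiny], DATE, buffer_m=0.2)
        assert [r.plot_id for r in recs] == ["big"]


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

class TestIO:
    def test_raster_pair_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        nir = layer(rng.uniform(0, 1, (12, 9)).astype(np.float32))
        re = layer(rng.uniform(0, 1, (12, 9)).astype(np.float32), 700)
        path = tmp_path / "pair.tif"
        write_raster_pair(path, nir, re)
        nir2, re2 = read_raster_pair(path)
        np.testing.assert_allclose(nir2.values, nir.values, atol=1e-7)
        assert nir2.transform == nir.transform
        assert (nir2.band_center_nm, re2.band_center_nm) == (780, 700)

    def test_geojson_roundtrip(self, tmp_path):
        plots = [rect(1.5, 8.0), PlotGeometry("q", Polygon([(2, 0), (3, 0), (3, 5), (2, 5)]),
                                              2, "REF_A", True)]
        path = tmp_path / "plots.geojson"
        write_plots_geojson(path, plots)
        back = read_plots_geojson(path)
        assert [p.plot_id for p in back] == ["p", "q"]
        assert back[1].is_reference
        assert back[0].polygon.equals(plots[0].polygon)

    def test_record_tables(self):
        idx = RasterLayer(np.full((30, 30), 0.3), T, None)
        plot = PlotGeometry("p1", Polygon([(0.2, 7), (2.5, 7), (2.5, 9.8), (0.2, 9.8)]),
                            1, "G")
        recs = extract_plot_stats(idx, [plot], DATE, trial_id="HZ_20")
        wide = records_to_wide(recs)
        assert wide.shape == (1, 23) and list(wide.columns) == STAT_NAMES
        long = records_to_long(recs)
        assert len(long) == 23
        assert set(long["stat_name"]) == set(STAT_NAMES)
        assert (long["trial_id"] == "HZ_20").all()
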