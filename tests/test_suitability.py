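import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplodyn as hd
from haplodyn.rasters import Raster
from haplodyn.suitability_dynamics import (
    half_sample_mode,
    jitter_localities,
    range_change,
)


def flat_raster(value, nrows=50, ncols=50, xll=-98.0, yll=16.0, cellsize=0.1):
    return Raster(np.full((nrows, ncols), value), xll, yll, cellsize)


class TestRasterIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        r = Raster(rng.random((12, 9)), -97.5, 17.25, 0.05)
        path = tmp_path / "grid.asc"
        hd.write_ascii_grid(r, path, fmt="%.8g")
        back = hd.read_ascii_grid(path)
        assert back.same_geometry(r)
        np.testing.assert_allclose(back.data, r.data, rtol=1e-7)

    def test_cell_boundary_floor_convention(self):
        r = Raster(np.arange(4.0).reshape(2, 2), 0.0, 0.0, 1.0)
        # data rows are north-first: value at (row 1, col 0) covers
        # lat [0,1), lon [0,1); a point exactly on the boundary lat=1.0
        # belongs to the upper cell
        assert r.sample_nearest(0.5, 0.5) == 2.0
        assert r.sample_nearest(1.0, 0.0) == 0.0
        assert r.sample_nearest(0.0, 1.0) == 3.0

    def test_nodata_returns_nan(self):
        data = np.array([[0.5, -9999.0]])
        r = Raster(data, 0.0, 0.0, 1.0)
        assert np.isnan(r.sample_nearest(0.5, 1.5))


class TestJitter:
    def test_replicate_count_and_bounds(self):
        coords = {"A": (17.0, -97.0)}
        reps = jitter_localities(coords, n_reps=100, half_width=0.08, seed=1)
        assert reps["A"].shape == (100, 2)
        offsets = reps["A"] - np.array([17.0, -97.0])
        assert np.abs(offsets).max() <= 0.04 + 1e-12

    def test_zero_width_degenerates_to_locality(self):
        reps = jitter_localities({"A": (17.0, -97.0)}, n_reps=5,
                                 half_width=0.0, seed=2)
        np.testing.assert_allclose(reps["A"], [[17.0, -97.0]] * 5)

    def test_deterministic_under_seed(self):
        coords = {"A": (17.0, -97.0), "B": (18.0, -96.0)}
        r1 = jitter_localities(coords, seed=3)
        r2 = jitter_localities(coords, seed=3)
        assert all(np.array_equal(r1[k], r2[k]) for k in coords)

    def test_resampling_keeps_replicates_inside_extent(self):
        raster = flat_raster(0.5, nrows=10, ncols=10, xll=-97.05, yll=16.95,
                             cellsize=0.01)
        # locality near the raster corner: naive jitter would often exit
        reps = jitter_localities({"A": (16.96, -97.04)}, n_reps=50,
                                 half_width=0.08, seed=4,
                                 extent_raster=raster)
        assert all(raster.contains(lat, lon) for lat, lon in reps["A"])

    def test_locality_outside_extent_rejected(self):
        raster = flat_raster(0.5)
        with pytest.raises(ValueError, match="outside raster extent"):
            jitter_localities({"A": (50.0, 0.0)}, seed=0,
                              extent_raster=raster)


class TestExtraction:
    def test_constant_raster_constant_values(self):
        rasters = {e: flat_raster(0.5) for e in ("LIG", "LGM", "MH", "PRE")}
        reps = jitter_localities({"A": (17.0, -97.0)}, n_reps=20, seed=5)
        series = hd.extract_suitability(rasters, reps)
        assert np.allclose(series.values["value"], 0.5)
        assert np.allclose(series.hsm.loc["A"], 0.5)

    def test_epoch_order_independence(self):
        coords = {"A": (17.0, -97.0)}
        trends = {"A": (0.2, 0.4, 0.6, 0.8)}
        from haplodyn.synthetic_data import make_suitability_rasters

        rasters = make_suitability_rasters(coords, trends, seed=6)
        reps = jitter_localities(coords, n_reps=30, seed=7)
        fwd = hd.extract_suitability(rasters, reps)
        rev = hd.extract_suitability(dict(reversed(rasters.items())), reps)
        for e in rasters:
            assert fwd.hsm.loc["A", e] == rev.hsm.loc["A", e]

    def test_geometry_mismatch_rejected(self):
        rasters = {"LIG": flat_raster(0.5), "PRE": flat_raster(0.5, nrows=10)}
        with pytest.raises(ValueError, match="geometry"):
            hd.extract_suitability(rasters,
                                   {"A": np.array([[17.0, -97.0]])})


class TestHalfSampleMode:
    def test_hand_run_recursion(self):
        assert half_sample_mode([1, 2, 2, 2, 3]) == 2.0

    def test_single_value(self):
        assert half_sample_mode([0.7]) == 0.7

    def test_two_values_mean(self):
        assert half_sample_mode([0.2, 0.6]) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            half_sample_mode([])

    def test_mode_of_symmetric_unimodal_sample(self):
        """On a large symmetric unimodal sample the HSM tracks the true
        mode."""
        rng = np.random.default_rng(8)
        sample = rng.normal(0.5, 0.1, size=10000)
        assert half_sample_mode(sample) == pytest.approx(0.5, abs=0.02)

    def test_resists_contamination_better_than_mean(self):
        """A secondary mass of outliers barely moves the HSM."""
        rng = np.random.default_rng(18)
        sample = np.concatenate([rng.normal(0.3, 0.02, 800),
                                 rng.uniform(0.8, 1.0, 200)])
        assert half_sample_mode(sample) == pytest.approx(0.3, abs=0.02)
        assert abs(sample.mean() - 0.3) > 0.05

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40),
           st.floats(0.1, 3.0), st.floats(-5.0, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_equivariance(self, values, a, b):
        hsm = half_sample_mode(values)
        scaled = half_sample_mode([a * v + b for v in values])
        assert scaled == pytest.approx(a * hsm + b, abs=1e-5)

    def test_within_sample_range(self):
        rng = np.random.default_rng(9)
        sample = rng.random(37)
        hsm = half_sample_mode(sample)
        assert sample.min() <= hsm <= sample.max()


class TestRangeChange:
    def test_identical_rasters_hundred_percent(self):
        rasters = {"PRE": flat_raster(0.8), "LGM": flat_raster(0.8)}
        rc = range_change(rasters, 0.5, "LGM")
        assert rc.ratio_percent == pytest.approx(100.0)

    def test_doubled_suitable_region(self):
        base = np.zeros((4, 10))
        base[0, :5] = 0.9  # a suitable band in the top (same-latitude) row
        doubled = base.copy()
        doubled[0, 5:] = 0.9
        rasters = {
            "PRE": Raster(base, 0.0, 0.0, 0.5),
            "LGM": Raster(doubled, 0.0, 0.0, 0.5),
        }
        rc = range_change(rasters, 0.5, "LGM")
        assert rc.ratio_percent == pytest.approx(200.0)

    def test_latitude_weighting_shrinks_polar_cells(self):
        top = np.zeros((2, 2))
        top[0, :] = 1.0  # suitable row at ~60N
        bottom = np.zeros((2, 2))
        bottom[1, :] = 1.0  # suitable row at ~0N
        rasters = {
            "PRE": Raster(bottom, 0.0, 0.0, 60.0),
            "LGM": Raster(top, 0.0, 0.0, 60.0),
        }
        rc = range_change(rasters, 0.5, "LGM")
        assert rc.ratio_percent < 100.0

    def test_threshold_validated(self):
        rasters = {"PRE": flat_raster(0.8), "LGM": flat_raster(0.8)}
        with pytest.raises(ValueError):
            range_change(rasters, 1.0, "LGM")

    def test_zero_reference_area_rejected(self):
        rasters = {"PRE": flat_raster(0.1), "LGM": flat_raster(0.8)}
        with pytest.raises(ValueError, match="zero suitable"):
            range_change(rasters, 0.5, "LGM")
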