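"""MESS extrapolation scores, half-ignorance maps, Bhattacharyya distance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hiersdm.grids import GridSpec, RasterLayer, RasterStack
from hiersdm.synthetic import VirtualSpeciesConfig, sample_occurrences
from hiersdm.uncertainty import (
    bhattacharyya_distance,
    ignorance_map,
    mess_layer,
    mess_proportion,
    mess_similarity,
)


class TestMessSimilarity:
    def test_median_target_scores_100(self):
        ref = np.arange(100, dtype=float)  # strictly-below fraction of 50.0 at 50
        assert mess_similarity(ref, np.array([50.0]))[0] == pytest.approx(100.0)

    def test_below_minimum_is_negative(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert mess_similarity(ref, np.array([0.0]))[0] < 0

    def test_at_minimum_is_zero(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert mess_similarity(ref, np.array([1.0]))[0] == pytest.approx(0.0)

    def test_above_maximum_is_negative(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert mess_similarity(ref, np.array([4.0]))[0] < 0

    def test_reference_points_never_negative(self, rng):
        ref = rng.normal(size=200)
        assert mess_similarity(ref, ref).min() >= 0

    def test_affine_equivariance(self, rng):
        ref = rng.normal(size=150)
        t = rng.normal(size=80)
        np.testing.assert_allclose(
            mess_similarity(ref, t),
            mess_similarity(3.5 * ref - 2.0, 3.5 * t - 2.0),
            atol=1e-9,
        )

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mess_similarity(np.array([1.0, 1.0]), np.array([1.0]))


class TestMessLayer:
    def test_matches_per_point_loop_oracle(self, rng):
        """Vectorized MESS equals an independent per-point, per-variable loop."""
        grid = GridSpec(0, 0, 0.25, 20, 50)  # 1000 cells
        names = ["climate_01", "climate_02", "climate_03"]
        stack = RasterStack(
            grid, [RasterLayer(grid, n, rng.normal(size=grid.shape)) for n in names]
        )
        ref = pd.DataFrame(rng.normal(size=(60, 3)), columns=names)
        result = mess_layer(ref, stack)

        def loop_similarity(refv, t):
            refv = np.sort(refv)
            p = 100.0 * (refv < t).sum() / len(refv)
            mn, mx = refv[0], refv[-1]
            if p == 0:
                return (t - mn) / (mx - mn) * 100
            if p <= 50:
                return 2 * p
            if p < 100:
                return 2 * (100 - p)
            return (mx - t) / (mx - mn) * 100

        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                expected = min(
                    loop_similarity(ref[n].to_numpy(), stack[n].values[r, c])
                    for n in names
                )
                assert result.values[r, c] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_variable_skipped_with_warning(self, rng, caplog):
        grid = GridSpec(0, 0, 0.25, 4, 4)
        stack = RasterStack(
            grid,
            [
                RasterLayer(grid, "a", rng.normal(size=grid.shape)),
                RasterLayer(grid, "b", rng.normal(size=grid.shape)),
            ],
        )
        ref = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        with caplog.at_level("WARNING"):
            result = mess_layer(ref, stack)
        assert "degenerate" in caplog.text
        assert np.isfinite(result.valid_values).all()


class TestMessProportion:
    def test_counts_negative_species_fraction(self):
        grid = GridSpec(0, 0, 0.25, 1, 1)
        layers = {
            f"s{i}": RasterLayer(grid, f"s{i}", np.array([[v]]))
            for i, v in enumerate([-5.0, -1.0, -0.5] + [10.0] * 12)
        }
        prop = mess_proportion(layers)
        assert prop.values[0, 0] == pytest.approx(3 / 15)

    def test_all_similar_gives_zero_and_loop_oracle(self, rng):
        grid = GridSpec(0, 0, 0.25, 5, 5)
        vals = [rng.normal(size=grid.shape) for _ in range(4)]
        layers = {f"s{i}": RasterLayer(grid, f"s{i}", v) for i, v in enumerate(vals)}
        prop = mess_proportion(layers)
        expected = np.mean([v < 0 for v in vals], axis=0)
        np.testing.assert_allclose(prop.values, expected, atol=1e-12)
        all_pos = {f"s{i}": RasterLayer(grid, f"s{i}", np.abs(v)) for i, v in enumerate(vals)}
        assert mess_proportion(all_pos).values.max() == 0.0


class TestIgnorance:
    def test_empty_cell_full_ignorance_and_half_point(self):
        grid = GridSpec(0, 0, 0.25, 2, 2)
        rec = pd.DataFrame(
            {"species": ["a"], "lon": [0.1], "lat": [0.1], "family": ["F"]}
        )
        ign = ignorance_map(rec, grid, half_saturation=1.0)
        assert ign.values[0, 0] == pytest.approx(0.5)  # n = h = 1
        assert ign.values[1, 1] == pytest.approx(1.0)  # empty cell

    def test_monotone_in_record_count(self):
        grid = GridSpec(0, 0, 0.25, 1, 1)
        prev = 2.0
        for n in [1, 2, 5, 20]:
            rec = pd.DataFrame(
                {"species": ["a"] * n, "lon": [0.1] * n, "lat": [0.1] * n,
                 "family": ["F"] * n}
            )
            val = ignorance_map(rec, grid).values[0, 0]
            assert val < prev
            prev = val

    def test_per_group_maps(self):
        grid = GridSpec(0, 0, 0.25, 1, 2)
        rec = pd.DataFrame(
            {
                "species": ["a", "b"],
                "lon": [0.1, 0.3],
                "lat": [0.1, 0.1],
                "family": ["F1", "F2"],
            }
        )
        maps = ignorance_map(rec, grid, per_group=True)
        assert set(maps) == {"F1", "F2"}
        assert maps["F1"].values[0, 0] == pytest.approx(0.5)
        assert maps["F1"].values[0, 1] == pytest.approx(1.0)

    def test_biased_sampling_shows_in_ignorance(self):
        """Ignorance correlates negatively with the effort (bias) layer."""
        grid = GridSpec(0, 0, 0.25, 30, 30)
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter
        from scipy.special import expit

        bias_field = gaussian_filter(rng.standard_normal(grid.shape), 3.0)
        bias = RasterLayer(grid, "bias", expit(2 * (bias_field / bias_field.std())))
        truth = RasterLayer(grid, "t", np.ones(grid.shape) * 0.5)
        cfg = VirtualSpeciesConfig(
            "v", {"climate_01": 1.0}, n_records=1500, p_error_records=0.0, seed=3
        )
        rec = sample_occurrences(truth, cfg, bias)
        ign = ignorance_map(rec, grid)
        rho = stats.spearmanr(ign.values.ravel(), bias.values.ravel()).statistic
        assert rho < -0.3


class TestBhattacharyya:
    def test_identical_maps_zero_and_symmetry(self, rng):
        grid = GridSpec(0, 0, 0.25, 6, 6)
        a = RasterLayer(grid, "a", rng.uniform(size=grid.shape))
        b = RasterLayer(grid, "b", rng.uniform(size=grid.shape))
        assert bhattacharyya_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert bhattacharyya_distance(a, b) == pytest.approx(
            bhattacharyya_distance(b, a), abs=1e-12
        )

    def test_hand_computed_value(self):
        """p=(0.5,0.5), q=(0.9,0.1): -ln(sqrt(0.45)+sqrt(0.05)) ~ 0.1122."""
        grid = GridSpec(0, 0, 0.25, 1, 2)
        a = RasterLayer(grid, "a", np.array([[0.5, 0.5]]))
        b = RasterLayer(grid, "b", np.array([[0.9, 0.1]]))
        expected = -np.log(np.sqrt(0.45) + np.sqrt(0.05))  # = 0.111572
        assert bhattacharyya_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_support_infinite(self):
        grid = GridSpec(0, 0, 0.25, 1, 2)
        a = RasterLayer(grid, "a", np.array([[1.0, 0.0]]))
        b = RasterLayer(grid, "b", np.array([[0.0, 1.0]]))
        assert bhattacharyya_distance(a, b) == float("inf")

    def test_zero_map_rejected(self):
        grid = GridSpec(0, 0, 0.25, 1, 2)
        a = RasterLayer(grid, "a", np.array([[1.0, 0.0]]))
        z = RasterLayer(grid, "z", np.zeros((1, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            bhattacharyya_distance(a, z)
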