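import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fracnet as fn
from fracnet.similarity import PairImage, default_scales

from oracles import brute_binary_count, brute_dbc_count


def _image_from_grid(grid, g):
    grid = np.asarray(grid, dtype=np.int64)
    return PairImage(grid=grid, counts=(grid > 1).astype(np.int64), m=grid.shape[0], g=g)


class TestPearson:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.standard_normal(32)
        assert fn.pearson_correlation(x, x) == pytest.approx(1.0)
        assert fn.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # means 2.5 and 3; cross products sum to 7, variances 5 and 10
        assert fn.pearson_correlation([1, 2, 3, 4], [1, 2, 4, 5]) == pytest.approx(
            7 / np.sqrt(50), abs=1e-12
        )

    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance_and_range(self, seed, a, b):
        x = np.random.default_rng(seed).standard_normal(24)
        y = np.random.default_rng(seed + 1).standard_normal(24)
        r = fn.pearson_correlation(x, y)
        assert -1.0 <= r <= 1.0
        assert fn.pearson_correlation(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert fn.pearson_correlation(y, x) == pytest.approx(r, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            fn.pearson_correlation([1, 2, 3, 4], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="x has zero variance"):
            fn.pearson_correlation([2, 2, 2, 2], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="y has zero variance"):
            fn.pearson_correlation([1, 2, 3, 4], [5, 5, 5, 5])


class TestJointHistogram:
    def test_direct_binning(self):
        h = fn.joint_histogram([0, 0, 1, 1], [0, 0, 1, 1], 2, 2)
        assert h.counts.tolist() == [[2, 0], [0, 2]]
        assert h.total == 4

    def test_conservation_and_marginals(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        h = fn.joint_histogram(x, y, 5, 7)
        assert h.total == 100
        assert h.joint_p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(h.marginal_x.sum(), 1.0)
        assert h.counts.shape == (5, 7)

    def test_constant_series_single_cell_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            h = fn.joint_histogram([1, 1, 1, 1], [2, 2, 2, 2], 2, 2)
        assert (h.counts > 0).sum() == 1
        assert h.total == 4


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[2, 0], [0, 2]], 1.0),  # perfectly dependent 2x2
            ([[1, 1], [1, 1]], 0.0),  # exactly independent
        ],
    )
    def test_hand_computed_tables(self, counts, expected):
        assert fn.mutual_information_from_counts(counts) == pytest.approx(expected)

    def test_self_information_is_entropy(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        assert fn.mutual_information(x, x, n_bins=4) == pytest.approx(2.0)

    @given(seed=st.integers(0, 10_000), bins=st.integers(2, 12))
    def test_nonnegative_symmetric_bounded(self, seed, bins):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(64), r.standard_normal(64)
        mi = fn.mutual_information(x, y, n_bins=bins)
        assert 0.0 <= mi <= np.log2(bins) + 1e-12
        assert fn.mutual_information(y, x, n_bins=bins) == pytest.approx(mi, abs=1e-12)


class TestPairImage:
    def test_diagonal_geometry(self):
        img = fn.build_pair_image([0, 1, 2, 3], [0, 1, 2, 3], m=4, g=4)
        assert np.array_equal(img.counts, np.eye(4, dtype=int))
        assert img.grid.diagonal().min() == img.g  # occupied cells at top gray
        off = img.grid[~np.eye(4, dtype=bool)]
        assert np.all(off == 1)  # empty cells at gray 1

    def test_equal_series_mass_on_diagonal(self, rng):
        x = rng.standard_normal(64)
        img = fn.build_pair_image(x, x.copy(), m=16, g=8)
        assert img.counts.sum() == 64
        assert np.tril(img.counts, -2).sum() + np.triu(img.counts, 2).sum() == 0

    def test_count_conservation(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        img = fn.build_pair_image(x, y, m=10, g=5)
        assert img.counts.sum() == 50

    def test_constant_series_rejected(self, rng):
        x = rng.standard_normal(16)
        with pytest.raises(ValueError, match="constant"):
            fn.build_pair_image(np.ones(16), x)
        with pytest.raises(ValueError, match="constant"):
            fn.build_pair_image(x, np.ones(16))

    def test_parameter_validation(self, rng):
        x, y = rng.standard_normal(16), rng.standard_normal(16)
        with pytest.raises(ValueError, match="M"):
            fn.build_pair_image(x, y, m=3)
        with pytest.raises(ValueError, match="G"):
            fn.build_pair_image(x, y, m=8, g=1)
        with pytest.raises(ValueError, match="G"):
            fn.build_pair_image(x, y, m=8, g=9)


class TestBoxCounting:
    def test_flat_surface_one_box_per_block(self):
        img = _image_from_grid(np.full((8, 8), 5), g=8)
        for s in (2, 4):
            assert fn.dbc_box_count(img, s) == int(np.ceil(8 / s)) ** 2

    def test_hand_counted_block(self):
        # one 2x2 block spans gray {1,2,3,4}; with s'=2 it needs 2 boxes
        grid = np.ones((4, 4), dtype=int)
        grid[:2, :2] = [[1, 2], [3, 4]]
        img = _image_from_grid(grid, g=4)
        assert fn.dbc_box_count(img, 2) == 2 + 1 + 1 + 1

    def test_full_range_block_contributes_m_over_s(self):
        # a block spanning all gray levels costs exactly M/s boxes
        grid = np.ones((8, 8), dtype=int)
        grid[:2, :2] = [[1, 8], [1, 8]]
        img = _image_from_grid(grid, g=8)
        # 15 flat blocks at 1 box each + the spanning block at 8/2 = 4
        assert fn.dbc_box_count(img, 2) == 15 + 4

    def test_scale_validation(self):
        img = _image_from_grid(np.full((8, 8), 3), g=8)
        for s in (1, 5, 8):
            with pytest.raises(ValueError, match="scale"):
                fn.dbc_box_count(img, s)

    @pytest.mark.parametrize("m", [16, 23])
    def test_matches_bruteforce_oracle(self, rng, m):
        for _ in range(10):
            x, y = rng.standard_normal(m), rng.standard_normal(m)
            img = fn.build_pair_image(x, y, m=m, g=min(16, m))
            for s in range(2, m // 2 + 1):
                assert fn.dbc_box_count(img, s) == brute_dbc_count(img.grid, img.g, s)
                assert fn.binary_box_count(img, s) == brute_binary_count(img.counts, s)

    def test_pyramid_table_equals_per_scale_counts(self, rng):
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        img = fn.build_pair_image(x, y, m=64, g=32)
        for variant, fn_single in (
            ("dbc", fn.dbc_box_count),
            ("binary", fn.binary_box_count),
        ):
            table = fn.box_count_table(img, variant=variant)
            assert table.n_boxes.tolist() == [
                fn_single(img, int(s)) for s in table.scales
            ]

    def test_counts_nonincreasing_in_scale(self, rng):
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        img = fn.build_pair_image(x, y, m=64, g=16)
        for variant in ("dbc", "binary"):
            n = fn.box_count_table(img, variant=variant).n_boxes
            assert np.all(np.diff(n) <= 0)

    def test_default_scales_are_powers_of_two(self):
        assert default_scales(16).tolist() == [2, 4, 8]
        assert default_scales(230).tolist() == [2, 4, 8, 16, 32, 64]


class TestFractalFit:
    @pytest.mark.parametrize(
        "r, n, expected",
        [
            ([0.5, 0.25], [4, 16], 2.0),
            ([0.5, 0.25], [2, 4], 1.0),
            ([0.5, 0.25, 0.125], [4, 16, 64], 2.0),
        ],
    )
    def test_exact_power_laws(self, r, n, expected):
        table = fn.BoxCountTable(
            scales=np.rint(np.asarray(r) * 16).astype(int),
            r=np.asarray(r),
            n_boxes=np.asarray(n),
        )
        fit = fn.fit_fractal_dimension(table)
        assert fit.dimension == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_single_scale_rejected(self):
        table = fn.BoxCountTable(
            scales=np.array([2]), r=np.array([0.125]), n_boxes=np.array([9])
        )
        with pytest.raises(ValueError, match="scales"):
            fn.fit_fractal_dimension(table)


class TestBCFD:
    def test_flat_image_dimension_two(self):
        img = _image_from_grid(np.full((16, 16), 7), g=16)
        fit = fn.fit_fractal_dimension(fn.box_count_table(img, variant="dbc"))
        assert fit.dimension == pytest.approx(2.0, abs=1e-12)

    def test_symmetric_under_argument_swap(self, rng):
        for _ in range(5):
            x, y = rng.standard_normal(64), rng.standard_normal(64)
            assert fn.bcfd(x, y) == fn.bcfd(y, x)
            assert fn.bcfd(x, y, variant="binary") == fn.bcfd(y, x, variant="binary")

    @given(seed=st.integers(0, 5_000))
    def test_finite_on_nondegenerate_pairs(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(16), r.standard_normal(16)
        for variant in ("dbc", "binary"):
            assert np.isfinite(fn.bcfd(x, y, g=8, variant=variant))

    def test_deterministic(self, rng):
        x, y = rng.standard_normal(128), rng.standard_normal(128)
        assert fn.bcfd(x, y) == fn.bcfd(x, y)


class TestMeasureRegistry:
    def test_lookup_and_dispatch(self, rng):
        x, y = rng.standard_normal(64), rng.standard_normal(64)
        assert fn.get_measure("lc")(x, y) == fn.pearson_correlation(x, y)
        assert fn.get_measure("mi", n_bins=6)(x, y) == fn.mutual_information(
            x, y, n_bins=6
        )
        assert fn.get_measure("bcfd", variant="binary")(x, y) == fn.bcfd(
            x, y, variant="binary"
        )

    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="unknown measure"):
            fn.get_measure("coherence")
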