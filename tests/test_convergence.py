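"""Tests for convergence maps, the noise filters and the s* pipeline."""

import numpy as np
import pytest

from beatflow.convergence import (
    ScalarMap,
    contractility_pipeline,
    contrast_weight,
    finite_difference_convergence,
    high_pass_filter,
    local_contrast,
    median_filter,
    radial_profile,
    threshold_contractility,
    tile_aggregate,
)
from beatflow.errors import InputError
from beatflow.piv import FlowGrid


def _radial_flow(alpha, n=9, spacing=8.0, center=None):
    """u = -alpha * r: pure inward linear field, div(u) = -2*alpha."""
    x = np.arange(n) * spacing
    X, Y = np.meshgrid(x, x)
    if center is None:
        center = (x.mean(), x.mean())
    vec = np.stack([-alpha * (X - center[0]), -alpha * (Y - center[1])], axis=-1)
    return FlowGrid(vec, spacing, (0.0, 0.0))


class TestFiniteDifferenceConvergence:
    def test_uniform_field_zero(self):
        vec = np.broadcast_to([3.0, -1.0], (5, 5, 2)).copy()
        C = finite_difference_convergence(FlowGrid(vec, 8.0, (0.0, 0.0)))
        assert np.allclose(C.values, 0.0)

    def test_linear_inward_field_exact(self):
        C = finite_difference_convergence(_radial_flow(alpha=0.1))
        assert np.allclose(C.values, 0.2)  # 2*alpha, exact for linear fields

    def test_border_flagged(self):
        C = finite_difference_convergence(_radial_flow(0.1, n=5))
        assert C.border[0].all() and C.border[-1].all()
        assert C.border[:, 0].all() and C.border[:, -1].all()
        assert not C.border[1:-1, 1:-1].any()

    def test_too_few_nodes(self):
        vec = np.zeros((2, 5, 2))
        with pytest.raises(InputError):
            finite_difference_convergence(FlowGrid(vec, 8.0, (0.0, 0.0)))

    def test_free_sheet_outer_field_second_order(self):
        # u = a/r has zero divergence; central differences converge to 0
        # at second order in the spacing
        a = 5.0

        def sample(spacing):
            x = np.arange(12) * spacing + 40.0  # away from the origin
            X, Y = np.meshgrid(x, x)
            r = np.hypot(X, Y)
            vec = np.stack([a * X / r**2, a * Y / r**2], axis=-1)
            flow = FlowGrid(vec, spacing, (40.0, 40.0))
            C = finite_difference_convergence(flow)
            return np.abs(C.values[1:-1, 1:-1]).max()

        e1, e2 = sample(4.0), sample(2.0)
        assert e2 < e1 / 3.0


class TestMedianFilter:
    def test_constant_unchanged(self):
        m = ScalarMap(np.full((6, 6), 2.5), 8.0, (0.0, 0.0))
        assert np.allclose(median_filter(m).values, 2.5)

    def test_spike_removed(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 10.0
        m = median_filter(ScalarMap(vals, 8.0, (0.0, 0.0)))
        assert m.values[3, 3] == 0.0

    def test_step_edge_preserved(self):
        vals = np.zeros((8, 8))
        vals[:, 4:] = 1.0
        out = median_filter(ScalarMap(vals, 8.0, (0.0, 0.0)))
        assert np.array_equal(out.values, vals)

    def test_idempotent_on_piecewise_constant(self):
        vals = np.zeros((8, 8))
        vals[:, 4:] = 1.0
        once = median_filter(ScalarMap(vals, 8.0, (0.0, 0.0)))
        twice = median_filter(once)
        assert np.array_equal(once.values, twice.values)

    def test_invalid_radius(self):
        with pytest.raises(InputError):
            median_filter(ScalarMap(np.zeros((4, 4)), 8.0, (0.0, 0.0)), radius=0)


class TestHighPassFilter:
    def test_constant_series_fixed_point(self):
        series = np.full((50, 3, 3), 4.2)
        out = high_pass_filter(series, q=0.7)
        assert np.allclose(out, 4.2)

    def test_linear_drift_removed(self):
        beta, q = 0.3, 0.5
        t = np.arange(400.0)
        series = (beta * t)[:, None, None] * np.ones((1, 2, 2))
        out = high_pass_filter(series, q)
        M = series.mean(axis=0)
        # closed-form fixed point of the recursion: M + beta*q/(1-q)
        assert np.allclose(out[-1], M + beta * q / (1.0 - q), rtol=1e-10)

    def test_impulse_decays_geometrically(self):
        q = 0.8
        series = np.zeros((40, 1, 1))
        series[10] = 1.0
        out = high_pass_filter(series, q)[:, 0, 0]
        M = 1.0 / 40
        for t in range(13, 30):
            assert out[t] - M == pytest.approx(q * (out[t - 1] - M), rel=1e-12)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_q(self, q):
        with pytest.raises(InputError):
            high_pass_filter(np.zeros((5, 2, 2)), q)

    def test_stationary_mean_preserved(self):
        # periodic stationary series, mean over whole periods after the
        # transient has died: preserved to machine precision
        q = 0.9
        p = 25
        t = np.arange(40 * p)
        series = np.sin(2 * np.pi * t / p)[:, None] * np.ones((1, 4)) + 1.7
        out = high_pass_filter(series, q)
        M = series.mean(axis=0)
        assert np.allclose(out[-10 * p :].mean(axis=0), M, atol=1e-12)


class TestLocalContrast:
    def test_constant_image_zero(self):
        w = local_contrast(np.full((64, 64), 0.5))
        assert np.allclose(w.values, 0.0)

    def test_checkerboard_saturates_at_one(self):
        board = np.indices((64, 64)).sum(axis=0) % 2
        w = local_contrast(board.astype(float))
        assert w.values.max() == pytest.approx(1.0)
        assert w.values.min() >= 0.0

    def test_half_blank_frame(self):
        rng = np.random.default_rng(0)
        frame = np.full((64, 64), 0.5)
        frame[:, :32] = rng.random((64, 32))
        w = local_contrast(frame, window=8)
        assert np.all(w.values[:, 40:] < 1e-5)
        assert w.values[:, :24].min() > 0.5

    def test_window_validation(self):
        with pytest.raises(InputError):
            local_contrast(np.zeros((32, 32)), window=1)


class TestContrastWeight:
    def _map(self, vals):
        return ScalarMap(np.asarray(vals, dtype=float), 8.0, (0.0, 0.0))

    def test_identity_weight(self):
        m = self._map(np.arange(9.0).reshape(3, 3))
        out = contrast_weight(m, self._map(np.ones((3, 3))))
        assert np.array_equal(out.values, m.values)

    def test_zero_weight(self):
        m = self._map(np.arange(9.0).reshape(3, 3))
        out = contrast_weight(m, self._map(np.zeros((3, 3))))
        assert np.all(out.values == 0.0)

    def test_product(self):
        out = contrast_weight(self._map([[2.0]]), self._map([[0.05]]))
        assert out.values[0, 0] == pytest.approx(0.1)

    def test_lattice_mismatch(self):
        with pytest.raises(InputError):
            contrast_weight(self._map(np.zeros((3, 3))), self._map(np.zeros((4, 4))))


class TestThresholdContractility:
    def test_definition(self):
        m = ScalarMap(np.array([[-1.0, 0.0, 2.0]]), 8.0, (0.0, 0.0))
        assert np.array_equal(
            threshold_contractility(m).values, [[0.0, 0.0, 2.0]]
        )

    def test_all_negative(self):
        m = ScalarMap(-np.ones((3, 3)), 8.0, (0.0, 0.0))
        assert np.all(threshold_contractility(m).values == 0.0)

    def test_idempotent_and_nonnegative(self, rng):
        m = ScalarMap(rng.normal(size=(6, 6)), 8.0, (0.0, 0.0))
        once = threshold_contractility(m)
        twice = threshold_contractility(once)
        assert np.all(once.values >= 0.0)
        assert np.array_equal(once.values, twice.values)


class TestPipeline:
    def test_static_stack_zero(self, static_stack):
        maps = contractility_pipeline(static_stack)
        for m in maps:
            assert np.all(m.values[np.isfinite(m.values)] == 0.0)
        assert all(m.kind == "contractility" for m in maps)

    def test_single_center_localized(self, beating_movie, beating_sstar):
        _, _, spec = beating_movie
        total = np.nansum([m.values for m in beating_sstar], axis=0)
        j, i = np.unravel_index(np.nanargmax(total), total.shape)
        X, Y = beating_sstar[0].node_positions()
        cx, cy = spec.centers[0].position
        dist_nodes = np.hypot(X[j, i] - cx, Y[j, i] - cy) / beating_sstar[0].spacing
        assert dist_nodes <= 2.0

    def test_translation_equivariance(self, beating_movie):
        # two crops of the same scene offset by one grid spacing: the
        # s* maps agree on interior nodes shifted by one lattice step
        from beatflow.piv import PIVConfig

        stack, _, _ = beating_movie
        frames = stack.frames[:8]
        cfg = PIVConfig(coarse_tile=32, coarse_search=8, fine_tile=16, fine_search=4)
        shift = 2 * cfg.fine_spacing  # a whole number of grid spacings
        a = contractility_pipeline(frames[:, :144, :144], cfg, reference_index=0)
        b = contractility_pipeline(frames[:, shift:, shift:], cfg, reference_index=0)
        ta = np.nansum([m.values for m in a], axis=0)
        tb = np.nansum([m.values for m in b], axis=0)
        inner_a = ta[4:-2, 4:-2]
        inner_b = tb[2:-4, 2:-4]
        assert inner_a.shape == inner_b.shape
        assert np.allclose(inner_a, inner_b, atol=0.1 * max(ta.max(), 1e-9))


class TestTileAggregate:
    def test_constant_maps(self):
        ones = np.ones((4, 4))
        pairs = tile_aggregate(ones, ones, tile=2)
        assert pairs.shape == (4, 2)
        assert np.all(pairs == 4.0)

    def test_proportional_maps_correlate_perfectly(self, rng):
        img = rng.random((64, 64))
        pairs = tile_aggregate(3.5 * img, img, tile=8)
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_independent_maps_uncorrelated(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((80, 80))
        b = rng.random((80, 80))
        pairs = tile_aggregate(a, b, tile=8)  # 100 tiles
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 0.3

    def test_scalar_map_nodes_assigned_by_position(self):
        vals = np.ones((4, 4))
        smap = ScalarMap(vals, 2.0, (0.0, 0.0))  # nodes at 0,2,4,6
        img = np.ones((8, 8))
        pairs = tile_aggregate(smap, img, tile=4)
        assert np.all(pairs[:, 0] == 4.0)  # 2x2 nodes per tile
        assert np.all(pairs[:, 1] == 16.0)

    def test_tile_too_large(self):
        with pytest.raises(InputError):
            tile_aggregate(np.ones((4, 4)), np.ones((4, 4)), tile=8)


class TestRadialProfile:
    def _map_from_function(self, f, n=41, spacing=1.0):
        x = np.arange(n) * spacing
        X, Y = np.meshgrid(x, x)
        r = np.hypot(X - x.mean(), Y - x.mean())
        return ScalarMap(f(r), spacing, (0.0, 0.0)), (x.mean(), x.mean())

    def test_exponential_profile(self):
        smap, center = self._map_from_function(lambda r: np.exp(-r / 5.0))
        radii, means = radial_profile(smap, center, bin_width=2.0)
        ref = np.exp(-radii / 5.0)
        sel = radii < 15
        assert np.allclose(means[sel], ref[sel], rtol=0.12)

    def test_constant_flat(self):
        smap, center = self._map_from_function(lambda r: np.full_like(r, 3.0))
        _, means = radial_profile(smap, center, bin_width=2.0)
        assert np.allclose(means[~np.isnan(means)], 3.0)

    def test_empty_annulus_nan(self):
        smap = ScalarMap(np.ones((3, 3)), 1.0, (0.0, 0.0))
        radii, means = radial_profile(smap, (0.0, 0.0), bin_width=0.5)
        assert np.isnan(means).any()

    def test_free_sheet_profile_is_step(self):
        from beatflow.mechanics import SheetParams, solve_uniform_core

        sol = solve_uniform_core(SheetParams(c1=1, c2=1, k=0, sigma_star=1, r0=10.0))
        smap, center = self._map_from_function(
            lambda r: sol.convergence(np.maximum(r, 1e-9)), n=61
        )
        radii, means = radial_profile(smap, center, bin_width=2.0)
        plateau = 2.0 / 3.0  # 2*sigma*/(c1+2c2)
        assert np.allclose(means[radii < 8], plateau, rtol=1e-9)
        assert np.allclose(means[(radii > 12) & (radii < 28)], 0.0, atol=1e-12)


class TestAgainstMechanicsOracle:
    def test_adhered_sheet_convergence_second_order(self):
        """Central differences of the analytic displacement approach the
        analytic convergence at second order in the lattice spacing."""
        from beatflow.mechanics import SheetParams, solve_uniform_core

        sol = solve_uniform_core(SheetParams(c1=1, c2=1, k=2, sigma_star=1, r0=1))

        def fd_error(spacing):
            x = np.arange(1.5, 4.0, spacing)  # outside the core: smooth
            X, Y = np.meshgrid(x, x)
            r = np.hypot(X, Y)
            ur = sol.u(r)
            vec = np.stack([ur * X / r, ur * Y / r], axis=-1)
            flow = FlowGrid(vec, spacing, (x[0], x[0]))
            C = finite_difference_convergence(flow)
            ref = sol.convergence(r)
            return np.abs(C.values - ref)[1:-1, 1:-1].max()

        e1, e2 = fd_error(0.04), fd_error(0.02)
        assert 3.0 < e1 / e2 < 5.0
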