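"""Correlation sums, D2, K2, LLE and the data-length bounds."""

import numpy as np
import pytest

from oculodyn.core import TimeSeries
from oculodyn.embedding import delay_embed
from oculodyn.exceptions import (
    DegenerateInputError,
    InsufficientPairsError,
    InvalidParameterError,
)
from oculodyn.invariants import (
    CorrelationSumResult,
    RadiusGrid,
    correlation_sum,
    correlation_sums,
    estimate_d2,
    k2_entropy,
    lle_rosenstein,
    radius_grid,
    required_n,
    sample_size_bound,
    scaling_exponents,
    takens_minimum_dim,
)


def enumerate_correlation_sum(x, tau, m, w, radii, n_vectors=None):
    """Independent oracle: direct enumeration of admissible pairs.

    Counts pairs (i, j), j >= i + 1 + w, whose Euclidean delay-vector
    distance is <= r, normalised by (M - w)(M - w - 1)/2.
    """
    x = np.asarray(x, dtype=float)
    big_m = len(x) - (m - 1) * tau if n_vectors is None else n_vectors
    counts = np.zeros(len(radii))
    for i in range(big_m):
        for j in range(i + 1 + w, big_m):
            d = np.sqrt(
                sum((x[i + k * tau] - x[j + k * tau]) ** 2 for k in range(m))
            )
            counts += d <= radii
    return counts / ((big_m - w) * (big_m - w - 1) / 2.0)


class TestRadiusGrid:
    def test_unit_stdev_bounds(self, rng):
        x = rng.normal(size=400)
        x = x / np.std(x, ddof=1)
        grid = radius_grid(x)
        assert grid.rmin == pytest.approx(0.1)
        assert grid.rmax == pytest.approx(10.0)
        assert grid.n_radii == 100

    def test_small_stdev_scales(self, rng):
        x = rng.normal(size=400)
        x = 0.02 * x / np.std(x, ddof=1)
        grid = radius_grid(x)
        assert grid.rmin == pytest.approx(0.002)
        assert grid.rmax == pytest.approx(0.2)

    def test_two_radius_grid_is_the_bounds(self, rng):
        x = rng.normal(size=50)
        grid = radius_grid(x, n_radii=2)
        assert np.allclose(grid.radii, [grid.rmin, grid.rmax])

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            radius_grid(np.full(100, 2.0))


class TestCorrelationSum:
    def test_four_point_worked_example(self):
        """{0,1,2,3}, m=1, r=1.5: pairs (0,1),(1,2),(2,3) of 6 lie within r
        -> C = 0.5; with w = 1 the admissible pairs (0,2),(0,3),(1,3) are
        all farther than 1.5 -> C = 0."""
        emb = delay_embed(np.array([0.0, 1, 2, 3]), tau=1, m=1)
        grid = RadiusGrid(np.array([1.5, 10.0]), 1.5, 10.0)
        res = correlation_sum(emb, grid, theiler_w=0)
        assert res.C[0, 0] == pytest.approx(0.5)
        assert res.C[0, 1] == pytest.approx(1.0)  # r >= diameter
        res_w1 = correlation_sum(emb, grid, theiler_w=1)
        assert res_w1.C[0, 0] == 0.0

    def test_fast_kernel_matches_enumeration_oracle(self, rng):
        """The jitted multi-m counting path must agree exactly with direct
        pair enumeration for random (N, m, tau, w, r) draws."""
        for _ in range(40):
            n = int(rng.integers(30, 120))
            tau = int(rng.integers(1, 4))
            m_max = int(rng.integers(2, 6))
            if (m_max - 1) * tau + 5 >= n:
                continue
            w = int(rng.integers(0, 6))
            x = rng.normal(size=n)
            scale = np.std(x)
            radii = np.sort(rng.uniform(0.05 * scale, 4 * scale, size=6))
            grid = RadiusGrid(radii, radii[0], radii[-1])
            m_values = list(range(1, m_max + 1))
            res = correlation_sums(x, tau, m_values, radii=grid, theiler_w=w)
            shared_m = n - (m_max - 1) * tau
            for k, m in enumerate(m_values):
                expected = enumerate_correlation_sum(
                    x, tau, m, w, radii, n_vectors=shared_m
                )
                assert np.array_equal(res.C[k], expected), (n, tau, m, w)

    def test_monotone_in_radius_and_dimension(self, henon5000):
        res = correlation_sums(henon5000, 1, [2, 3, 4], theiler_w=10)
        assert np.all(np.diff(res.C, axis=1) >= 0)  # non-decreasing in r
        assert np.all(res.C[1] <= res.C[0] + 1e-15)  # higher m never closer
        assert np.all(res.C[2] <= res.C[1] + 1e-15)
        assert np.all((res.C >= 0) & (res.C <= 1))

    def test_larger_theiler_window_never_increases_c_for_smooth_signals(
        self, sine_series
    ):
        """Growing the Theiler window can only remove admissible close
        pairs, so the in-range pair count never increases with w.  (The
        normalised sum C itself is confounded by its shrinking denominator
        and is not monotone in general.)"""
        grid = radius_grid(sine_series, 30)
        emb = delay_embed(sine_series, 25, 2)
        big_m = emb.n_vectors

        def counts(w):
            res = correlation_sum(emb, grid, theiler_w=w)
            return res.C * ((big_m - w) * (big_m - w - 1) / 2.0)

        previous = counts(0)
        for w in (2, 5, 10, 60):
            current = counts(w)
            assert np.all(current <= previous + 1e-6)
            previous = current

    def test_insufficient_pairs_error_names_geometry(self):
        emb = delay_embed(np.arange(20.0), tau=1, m=1)
        with pytest.raises(InsufficientPairsError, match="M=20"):
            correlation_sum(emb, RadiusGrid(np.array([1.0, 2.0]), 1, 2), theiler_w=19)


class TestScalingExponents:
    def _result(self, radii, C):
        grid = RadiusGrid(radii, radii[0], radii[-1])
        return CorrelationSumResult(
            radii=grid,
            m_values=np.arange(C.shape[0]) + 1,
            C=C,
            theiler_w=0,
            n_vectors=np.full(C.shape[0], 100),
        )

    def test_exact_power_law_has_constant_slope(self):
        r = np.geomspace(0.01, 1.0, 40)
        res = self._result(r, (r**2)[None, :])
        slopes = scaling_exponents(res)
        assert np.allclose(slopes[0], 2.0)

    def test_saturated_sum_has_zero_slope(self):
        r = np.geomspace(0.1, 1.0, 20)
        res = self._result(r, np.full((1, 20), 0.5))
        assert np.allclose(scaling_exponents(res)[0], 0.0)

    def test_zero_counts_flagged_as_nan(self):
        r = np.geomspace(0.1, 1.0, 10)
        C = np.concatenate([np.zeros(4), np.linspace(0.1, 1, 6)])[None, :]
        slopes = scaling_exponents(self._result(r, C))
        assert np.isnan(slopes[0, :3]).all()


class TestEstimateD2:
    def test_exact_synthetic_slope_recovered(self):
        r = np.geomspace(0.01, 1.0, 50)
        grid = RadiusGrid(r, r[0], r[-1])
        C = np.vstack([0.9 * r**0.9 for _ in range(4)])
        res = CorrelationSumResult(grid, np.arange(3, 7), C, 0, np.full(4, 100))
        est = estimate_d2(res, region=(0.02, 0.5))
        assert est.value == pytest.approx(0.9, abs=1e-9)
        assert est.fit_quality == pytest.approx(1.0)
        assert est.plateau_found

    def test_uniform_noise_fills_one_dimension(self):
        """For uniform i.i.d. samples at m=1 the analytic correlation sum is
        C(r) = r(2 - r); the fitted slope must match the analytic-oracle
        slope on the same radii."""
        x = np.random.default_rng(11).uniform(size=5000)
        grid = radius_grid(x)
        res = correlation_sums(x, 1, [1], radii=grid, theiler_w=0)
        est = estimate_d2(res, region=(0.03, 0.1))
        mask = (grid.radii >= 0.03) & (grid.radii <= 0.1)
        r_in = grid.radii[mask]
        analytic = np.polyfit(np.log10(r_in), np.log10(r_in * (2 - r_in)), 1)[0]
        assert est.value == pytest.approx(analytic, abs=0.05)
        assert 0.9 <= est.value <= 1.05

    def test_no_plateau_flag_for_noise(self, white_noise_5000):
        res = correlation_sums(white_noise_5000, 1, range(2, 8), theiler_w=10)
        est = estimate_d2(res)
        assert not est.plateau_found

    def test_unfittable_region_returns_flagged_nan(self):
        r = np.geomspace(0.1, 1.0, 10)
        grid = RadiusGrid(r, r[0], r[-1])
        res = CorrelationSumResult(grid, np.array([3]), np.zeros((1, 10)), 0, np.array([50]))
        est = estimate_d2(res, region=(0.1, 1.0))
        assert np.isnan(est.value) and "no_valid_fit" in est.flags


class TestSampleSizeBounds:
    @pytest.mark.parametrize(
        "n,expected",
        [(1000, 6.0), (1500, 6.3522), (2999, 6.9539)],
    )
    def test_bound_matches_printed_table(self, n, expected):
        # the tabulated values are truncated at 4 decimals
        assert sample_size_bound(n) == pytest.approx(expected, abs=1e-4)

    def test_required_n_inverts_the_bound(self):
        assert required_n(6.0) == 1000
        assert required_n(0.0) == 1
        assert sample_size_bound(required_n(4.2)) >= 4.2

    def test_takens_bound(self):
        assert takens_minimum_dim(1) == 3
        assert takens_minimum_dim(2.06) == 7


class TestK2Entropy:
    def test_geometric_closed_form(self):
        r = np.geomspace(0.1, 1.0, 10)
        grid = RadiusGrid(r, r[0], r[-1])
        q = 0.41
        C = np.vstack([np.full(10, q**m) for m in range(2, 7)])
        res = CorrelationSumResult(grid, np.arange(2, 7), C, 0, np.full(5, 100))
        est = k2_entropy(res, region=(0.1, 1.0))
        assert est.value == pytest.approx(np.log(1 / q), abs=1e-12)
        assert est.plateau_found

    def test_vanishing_higher_dimension_raises(self):
        r = np.geomspace(0.1, 1.0, 10)
        grid = RadiusGrid(r, r[0], r[-1])
        C = np.vstack([np.full(10, 0.5), np.zeros(10)])
        res = CorrelationSumResult(grid, np.array([2, 3]), C, 0, np.full(2, 100))
        with pytest.raises(InsufficientPairsError):
            k2_entropy(res, region=(0.1, 1.0))


class TestLLE:
    def test_sine_has_no_divergence(self, sine_series):
        emb = delay_embed(sine_series, 25, 2)
        est = lle_rosenstein(emb, dt=1.0, theiler_w=50)
        assert abs(est.value) <= 0.01

    def test_duplicated_trajectories_are_excluded_not_divided(self):
        x = np.tile(np.sin(np.linspace(0, 8 * np.pi, 200)), 3)
        emb = delay_embed(TimeSeries(x + 1e-12), 5, 2)
        est = lle_rosenstein(emb, dt=1.0, theiler_w=3, max_steps=10)
        assert np.isfinite(est.value)

    def test_insufficient_pairs(self):
        emb = delay_embed(np.arange(40.0), tau=1, m=2)
        with pytest.raises(InsufficientPairsError):
            lle_rosenstein(emb, theiler_w=30, max_steps=5)


class TestValidation:
    def test_bad_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            RadiusGrid(np.array([2.0, 1.0]), 1, 2)
        with pytest.raises(InvalidParameterError):
            RadiusGrid.from_bounds(-1.0, 2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_size_bound(1)
        with pytest.raises(InvalidParameterError):
            required_n(-0.5)
        with pytest.raises(InvalidParameterError):
            correlation_sums(np.arange(100.0), 0, [2])
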