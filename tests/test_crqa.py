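"""CRQA engine against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tapdyn as td
from tapdyn.crqa import EmbeddingConfig


# ---------------------------------------------------------------- oracles

def brute_embed(x, tau, d):
    n_pts = len(x) - (d - 1) * tau
    return np.array([[x[i + j * tau] for j in range(d)] for i in range(n_pts)])


def brute_matrix(xe, ye, r):
    n, m = len(xe), len(ye)
    out = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            out[i, j] = np.sqrt(np.sum((xe[i] - ye[j]) ** 2)) <= r
    return out


def brute_lmax(matrix, lmin=2):
    n, m = matrix.shape
    best = 0
    for i0 in range(n):
        for j0 in range(m):
            if i0 > 0 and j0 > 0:
                continue  # only start diagonals at an edge
            i, j, run = i0, j0, 0
            while i < n and j < m:
                run = run + 1 if matrix[i, j] else 0
                best = max(best, run)
                i, j = i + 1, j + 1
    return best if best >= lmin else 0


def brute_drp(matrix, max_lag):
    lags = range(-max_lag, max_lag + 1)
    rates = []
    for k in lags:
        cells = [matrix[i, i + k] for i in range(matrix.shape[0])
                 if 0 <= i + k < matrix.shape[1]]
        rates.append(100.0 * np.mean(cells))
    return np.array(rates)


def brute_triangles(matrix):
    n, m = matrix.shape
    upper = sum(matrix[i, j] for i in range(n) for j in range(m) if j > i)
    lower = sum(matrix[i, j] for i in range(n) for j in range(m) if j < i)
    return upper, lower


# ------------------------------------------------------------------ tests

class TestRescaleUnit:
    def test_simple_example(self):
        assert np.allclose(td.rescale_unit([0.0, 5.0, 10.0]), [0, 0.5, 1])

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        once = td.rescale_unit(x)
        assert np.allclose(td.rescale_unit(once), once)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            td.rescale_unit(np.full(10, 3.0))


class TestDelayEmbed:
    def test_paper_parameter_arithmetic(self):
        xe = td.delay_embed(np.arange(599.0), tau=2, d=5)
        assert xe.shape == (591, 5)

    def test_dimension_one_is_identity(self, rng):
        x = rng.normal(size=20)
        assert np.allclose(td.delay_embed(x, tau=3, d=1).ravel(), x)

    def test_enumeration_small(self):
        x = np.arange(10.0)
        xe = td.delay_embed(x, tau=2, d=3)
        assert np.array_equal(xe, brute_embed(x, 2, 3))
        assert xe.shape == (6, 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            td.delay_embed(np.arange(8.0), tau=2, d=5)


class TestCrossRecurrence:
    def test_self_recurrence_on_diagonal(self, rng):
        xe = td.delay_embed(rng.normal(size=30), 1, 3)
        m = td.cross_recurrence(xe, xe, r=1e-12)
        assert np.diag(m).all()

    def test_huge_radius_all_true(self, rng):
        xe = td.delay_embed(rng.normal(size=30), 1, 3)
        m = td.cross_recurrence(xe, xe, r=1e6)
        assert m.all()
        assert td.percent_recurrence(m) == 100.0

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            td.cross_recurrence(rng.normal(size=(5, 3)),
                                rng.normal(size=(5, 2)), r=1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            xe, ye = td.delay_embed(x, 2, 3), td.delay_embed(y, 2, 3)
            m = td.cross_recurrence(xe, ye, r=0.8)
            assert np.array_equal(m, brute_matrix(xe, ye, 0.8))
            assert td.percent_recurrence(m) == pytest.approx(
                100.0 * brute_matrix(xe, ye, 0.8).mean(), abs=1e-12)


class TestLongestDiagonal:
    def test_identical_periodic_inputs_unbroken_diagonal(self):
        t = np.arange(100)
        x = np.sin(2 * np.pi * t / 10)
        xe = td.delay_embed(x, 2, 3)
        m = td.cross_recurrence(xe, xe, r=1e-9)
        assert td.longest_diagonal(m) == len(xe)

    def test_all_false_is_zero(self):
        assert td.longest_diagonal(np.zeros((10, 10), dtype=bool)) == 0

    def test_runs_below_lmin_do_not_count(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2, 4] = True  # isolated point
        assert td.longest_diagonal(m, lmin=2) == 0
        m[3, 5] = True  # now a 2-line
        assert td.longest_diagonal(m, lmin=2) == 2

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2 ** 16))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((rng.integers(2, 15), rng.integers(2, 15))) < 0.4
        assert td.longest_diagonal(m) == brute_lmax(m)


class TestDelaySelection:
    @pytest.mark.parametrize("freq,fs,expected", [
        (7.19, 59.94, 2),   # professional mean tapping frequency
        (6.67, 59.94, 2),   # amateur mean tapping frequency
        (10.0, 40.0, 1),    # quarter cycle equals one frame
    ])
    def test_quarter_cycle(self, freq, fs, expected):
        assert td.select_delay_quarter_cycle(freq, fs) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            td.select_delay_quarter_cycle(40.0, 59.94)


class TestAverageMutualInformation:
    def test_lag_zero_is_maximal(self, rng):
        x = np.sin(np.arange(2000) * 0.3) + 0.1 * rng.standard_normal(2000)
        ami, _ = td.average_mutual_information(x, max_lag=10)
        assert ami[0] == ami.max()

    def test_independent_noise_has_near_zero_ami(self, rng):
        x = rng.standard_normal(10000)
        ami, _ = td.average_mutual_information(x, max_lag=5, n_bins=10)
        assert ami[1:].max() < 0.05

    def test_sine_first_minimum_near_quarter_cycle(self):
        t = np.arange(599) / 59.94
        _, suggested = td.average_mutual_information(np.sin(2 * np.pi * 7 * t),
                                                     max_lag=10)
        assert abs(suggested - 2) <= 1

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            td.average_mutual_information(np.ones(100), max_lag=5)


class TestRadiusScalingScan:
    def test_percent_rec_monotone_and_ceiling_flagged(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        cfg = EmbeddingConfig(tau=2, d=5, r=0.2)
        grid = np.geomspace(0.02, 5.0, 15)
        scan = td.radius_scaling_scan(x, y, cfg, grid)
        assert (np.diff(scan.percent_rec) >= 0).all()
        assert scan.ceiling_violating[-1]  # radius spans the data diameter
        assert scan.percent_rec[-1] == 100.0

    def test_hkb_pair_has_linear_region(self):
        params = td.HKBParams(a=1, b=1, Q=0.3, seed=4)
        traj = td.simulate_relative_phase(params, phi0=np.pi)
        rec = td.synthesize_recording(traj, params, td.KinematicProfile(),
                                      seed=5)
        clean = td.preprocess_recording(rec)
        cfg = EmbeddingConfig()
        grid = np.geomspace(0.03, 0.6, 14)
        scan = td.radius_scaling_scan(clean.x_left, clean.x_right, cfg, grid)
        assert scan.linear_region is not None
        lo, hi = scan.linear_region
        assert lo < hi

    def test_tiny_grid_rejected(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        with pytest.raises(ValueError):
            td.radius_scaling_scan(x, y, EmbeddingConfig(), np.array([1e-9]))


class TestTriangleAsymmetry:
    def test_symmetric_matrix_ratio_one(self, rng):
        xe = td.delay_embed(rng.normal(size=40), 1, 2)
        m = td.cross_recurrence(xe, xe, r=1.0)
        assert td.triangle_asymmetry(m) == pytest.approx(1.0)

    def test_transpose_inverts_ratio(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        xe, ye = td.delay_embed(x, 1, 2), td.delay_embed(y, 1, 2)
        m_xy = td.cross_recurrence(xe, ye, r=0.7)
        m_yx = td.cross_recurrence(ye, xe, r=0.7)
        assert np.array_equal(m_yx, m_xy.T)
        r_xy = td.triangle_asymmetry(m_xy)
        r_yx = td.triangle_asymmetry(m_yx)
        assert r_yx == pytest.approx(1.0 / r_xy)

    def test_empty_lower_triangle_undefined(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0, 3] = True
        with pytest.warns(RuntimeWarning):
            assert np.isnan(td.triangle_asymmetry(m))

    def test_injected_lead_lag_brackets_one(self):
        # shifting one series forward moves recurrence mass off-diagonal
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 25) + 0.05 * np.sin(2 * np.pi * t / 7)
        shift = 3
        y = np.roll(x, shift)
        cfg = EmbeddingConfig(tau=2, d=3, r=0.1)
        m_fwd = td.run_crqa(x, y, cfg).triangle_ratio
        m_bwd = td.run_crqa(y, x, cfg).triangle_ratio
        assert (m_fwd - 1.0) * (m_bwd - 1.0) < 0  # ratios bracket 1


class TestDiagonalRecurrenceProfile:
    def test_identical_inputs_peak_at_zero(self, rng):
        x = np.sin(np.arange(200) * 0.4)
        xe = td.delay_embed(x, 1, 2)
        m = td.cross_recurrence(xe, xe, r=0.05)
        _, _, peak = td.diagonal_recurrence_profile(m, max_lag=10)
        assert peak == 0

    def test_shifted_copy_peaks_at_shift(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 25)
        for shift in (-4, 4):
            y = np.roll(x, shift)
            cfg = EmbeddingConfig(tau=2, d=3, r=0.05)
            res = td.run_crqa(x, y, cfg, max_lag=8)
            assert res.drp_argmax_lag == shift

    def test_symmetric_matrix_profile_is_even(self, rng):
        xe = td.delay_embed(rng.normal(size=50), 1, 2)
        m = td.cross_recurrence(xe, xe, r=0.8)
        lags, rate, _ = td.diagonal_recurrence_profile(m, max_lag=6)
        assert np.allclose(rate, rate[::-1])

    def test_matches_brute_force(self, rng):
        m = rng.random((12, 12)) < 0.3
        _, rate, _ = td.diagonal_recurrence_profile(m, max_lag=5)
        assert np.allclose(rate, brute_drp(m, 5))
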