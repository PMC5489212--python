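import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rsdenoise as rd


class TestSidak:
    def test_published_values(self):
        # 61 shifted variants: 8.4e-4 at alpha 0.05, 1.6e-4 at alpha 0.01
        # (both to the printed two significant figures)
        import math

        def sig2(x):
            return round(x, -int(math.floor(math.log10(x))) + 1)

        assert sig2(rd.sidak(0.05, 61)) == 8.4e-4
        assert sig2(rd.sidak(0.01, 61)) == 1.6e-4

    def test_single_test_is_alpha(self):
        assert rd.sidak(0.37, 1) == pytest.approx(0.37, abs=1e-15)

    @given(alpha=st.floats(1e-6, 0.5), m=st.integers(1, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_by_bonferroni_and_alpha(self, alpha, m):
        s = rd.sidak(alpha, m)
        assert alpha / m - 1e-12 <= s <= alpha + 1e-12
        assert s > alpha / m * (1 - alpha) - 1e-12

    def test_invalid(self):
        with pytest.raises(ValueError):
            rd.sidak(0.0, 10)
        with pytest.raises(ValueError):
            rd.sidak(0.05, 0)


class TestResampleLinear:
    def test_same_dt_returns_demeaned_input(self, rng):
        y = rng.standard_normal(100)
        out = rd.resample_linear(y, 0.5, 0.5)
        assert np.allclose(out, y - y.mean(), atol=1e-12)

    def test_affine_input_exact(self):
        y = 3.0 + 0.7 * np.arange(50)
        out = rd.resample_linear(y, 1.0, 0.13)
        t = np.arange(out.size) * 0.13
        ref = 3.0 + 0.7 * t
        assert np.allclose(out, ref - ref.mean(), atol=1e-10)

    def test_piecewise_linear_oracle(self, rng):
        y = rng.standard_normal(30)
        out = rd.resample_linear(y, 1.0, 0.1)
        t_out = np.arange(out.size) * 0.1
        ref = np.empty_like(t_out)
        for i, t in enumerate(t_out):  # explicit piecewise-linear evaluation
            j = min(int(t), y.size - 2)
            frac = t - j
            ref[i] = y[j] * (1 - frac) + y[j + 1] * frac
        assert np.allclose(out, ref - ref.mean(), atol=1e-12)


class TestShiftedVariants:
    def test_grid_count_81(self, rng):
        # -4 to +12 s in 0.2 s steps: 81 variants
        grid = rd.ShiftGrid(-4.0, 12.0, 0.2)
        assert grid.m_variants == 81
        fine = rng.standard_normal(800)
        variants = rd.shifted_variants(fine, 0.2, grid, 160, 2.0)
        assert len(variants) == 81
        assert variants[0].shift_s == pytest.approx(-4.0)
        assert variants[-1].shift_s == pytest.approx(12.0)

    def test_zero_grid_is_resampled_input(self, rng):
        y = rng.standard_normal(160)
        variants = rd.shifted_variants(y, 2.0, rd.ShiftGrid(0, 0, 0.2), 160, 2.0)
        assert len(variants) == 1
        assert np.allclose(variants[0].values, y - y.mean(), atol=1e-12)

    def test_integer_tr_shift_equals_index_roll(self, rng):
        y = rng.standard_normal(100)
        yd = y - y.mean()
        variants = rd.shifted_variants(y, 1.0, rd.ShiftGrid(3, 3, 1), 100, 1.0)
        expected = np.r_[np.zeros(3), yd[:-3]]  # delay by 3 samples, zero-fill
        assert np.allclose(variants[0].values, expected, atol=1e-12)

    def test_value_conservation_under_shift(self, rng):
        y = rng.standard_normal(400)
        yd = y - y.mean()
        grid = rd.ShiftGrid(-4, 12, 0.4)
        variants = rd.shifted_variants(y, 0.2, grid, 150, 0.4)
        for v in variants[::10]:
            t_out = np.arange(150) * 0.4
            covered = (t_out - v.shift_s >= 0) & (t_out - v.shift_s <= 399 * 0.2)
            ref = np.interp(t_out[covered] - v.shift_s, np.arange(400) * 0.2, yd)
            assert np.allclose(v.values[covered], ref, atol=1e-10)


class TestOptimiseShift:
    def test_identical_variant_wins(self, rng):
        y = rng.standard_normal(200)
        variants = rd.shifted_variants(y, 1.0, rd.ShiftGrid(-3, 3, 1), 200, 1.0)
        res = rd.optimise_shift(y, variants)
        assert res.best_shift_s == 0.0
        assert res.best_r == pytest.approx(1.0, abs=1e-10)
        assert res.significant

    def test_single_variant_reduces_to_plain_correlation(self, rng):
        y = rng.standard_normal(160)
        v = rd.shifted_variants(rng.standard_normal(160), 1.0,
                                rd.ShiftGrid(0, 0, 1), 160, 1.0)
        res = rd.optimise_shift(y, v, alpha=0.05)
        assert res.alpha_sidak == pytest.approx(0.05)
        assert res.r_threshold_sidak == pytest.approx(rd.critical_r(160, 0.05))

    def test_grid_expansion_never_decreases_best_r(self, rng):
        y = rng.standard_normal(300)
        src = rng.standard_normal(300)
        prev = 0.0
        for half_width in (1, 3, 5, 8):
            grid = rd.ShiftGrid(-half_width, half_width, 1.0)
            variants = rd.shifted_variants(src, 1.0, grid, 300, 1.0)
            res = rd.optimise_shift(y, variants)
            assert abs(res.best_r) >= prev - 1e-12
            prev = abs(res.best_r)

    def test_fpr_inflation_and_sidak_control(self, rng):
        # independent pairs, 21-shift grid: max-|r| selection inflates the
        # single-test FPR >= 10x nominal; the Šidák threshold restores it
        # (scaled to 2,000 pairs here; the full 10,000-pair run lives in the
        # vectorised acceptance suite)
        n, npairs, alpha = 160, 2_000, 0.05
        grid = rd.ShiftGrid(-10, 10, 1.0)
        thr_single = rd.critical_r(n, alpha)
        thr_sidak = rd.critical_r(n, rd.sidak(alpha, grid.m_variants))
        hits_single = hits_sidak = 0
        for _ in range(npairs):
            y = rng.standard_normal(n)
            src = rng.standard_normal(n)
            variants = rd.shifted_variants(src, 1.0, grid, n, 1.0)
            res = rd.optimise_shift(y, variants, alpha)
            hits_single += abs(res.best_r) > thr_single
            hits_sidak += abs(res.best_r) > thr_sidak
        assert hits_single / npairs >= 10 * alpha
        se = np.sqrt(alpha * (1 - alpha) / npairs)
        assert hits_sidak / npairs <= alpha + 2.58 * se

    def test_zero_variance_y(self, rng):
        v = rd.shifted_variants(rng.standard_normal(100), 1.0,
                                rd.ShiftGrid(0, 0, 1), 100, 1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            rd.optimise_shift(np.ones(100), v)


class TestSplitHalfValidate:
    def test_recovers_injected_lag_in_both_halves(self, rng):
        # high-SNR series built with a +6 s lag: both halves find 6 +/- step
        tr, n = 2.0, 160
        trace = rd.synth_physio(n * tr, 0.2, "rest", rng_seed=11)
        fine = rd.resample_linear(trace, 0.2, 0.2)
        lagged = np.interp(np.arange(n) * tr - 6.0, np.arange(fine.size) * 0.2,
                           fine, left=0, right=0)
        y = lagged + 0.02 * lagged.std() * rng.standard_normal(n)
        grid = rd.ShiftGrid(-4, 12, 0.2)
        first, second = rd.split_half_validate(y, fine, 0.2, grid, out_dt=tr)
        assert abs(first.best_shift_s - 6.0) <= 0.2 + 1e-9
        assert abs(second.best_shift_s - 6.0) <= 0.2 + 1e-9

    def test_deterministic_exact_shift_agrees(self, rng):
        tr, n = 2.0, 200
        fine = rd.resample_linear(rng.standard_normal(n * 10), 0.2, 0.2)
        y = np.interp(np.arange(n) * tr - 4.0, np.arange(fine.size) * 0.2,
                      fine, left=0, right=0)
        first, second = rd.split_half_validate(y, fine, 0.2,
                                               rd.ShiftGrid(-4, 12, 0.2), out_dt=tr)
        assert first.best_shift_s == second.best_shift_s == pytest.approx(4.0)

    def test_pure_noise_halves_unrelated(self, rng):
        # across 100 synthetic null subjects the two half-shifts are unrelated
        tr, n = 2.0, 160
        grid = rd.ShiftGrid(-4, 12, 0.4)
        pairs = []
        for _ in range(100):
            y = rng.standard_normal(n)
            fine = rd.resample_linear(rng.standard_normal(n * 10), 0.2, 0.2)
            first, second = rd.split_half_validate(y, fine, 0.2, grid, out_dt=tr)
            pairs.append((first.best_shift_s, second.best_shift_s))
        r, p = rd.group_shift_reliability(pairs)
        assert abs(r) < rd.critical_r(100, 0.01)  # no reliable coupling


class TestGroupShiftReliability:
    def test_identical_pairs_give_r1(self):
        shifts = [1.0, 4.0, 6.0, 2.0, 8.0]
        r, p = rd.group_shift_reliability([(s, s) for s in shifts])
        assert r == pytest.approx(1.0)

    def test_null_cohorts_nominal_rate(self, rng):
        # 1,000 cohorts of 12 subjects with independent shifts: mean r ~ 0,
        # ~5% significant at alpha = 0.05
        rs, ps = [], []
        for _ in range(1000):
            pairs = rng.uniform(-4, 12, size=(12, 2))
            r, p = rd.group_shift_reliability(pairs)
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.03
        rate = np.mean(np.array(ps) < 0.05)
        assert abs(rate - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / 1000)

    def test_lag_coupled_cohort(self, rng):
        true = rng.uniform(0, 10, 12)
        pairs = np.column_stack([true + 0.3 * rng.standard_normal(12),
                                 true + 0.3 * rng.standard_normal(12)])
        r, _ = rd.group_shift_reliability(pairs)
        assert r > 0.8

    def test_constant_shifts_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            rd.group_shift_reliability([(2.0, 1.0), (2.0, 3.0), (2.0, 5.0)])
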