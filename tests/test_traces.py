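"""Evoked I/V analysis, charge integration and charge-to-flux ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cotransport import (
    CurrentTrace,
    IVCurve,
    charge_to_flux,
    estimate_erev,
    evoked_iv,
    integrate_charge,
    moles_from_tracer,
    normalize_iv,
    rectification_degree,
)
from cotransport.thermo import DEFAULT_CONSTANTS
from cotransport.traces import NonReversingError

GRID = np.arange(-150.0, 31.0, 20.0)


def iv_from(currents, potentials=GRID, sem=None):
    currents = np.asarray(currents, dtype=float)
    if sem is None:
        sem = np.zeros_like(currents)
    return IVCurve(potential=np.asarray(potentials, dtype=float),
                   current=currents, sem=np.asarray(sem, dtype=float))


def ols_slope(x, y):
    """Textbook OLS slope, independent of numpy.polyfit."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    return float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))


def square_trace(amplitude_na=-100.0, duration=60.0, pad=5.0, dt=1e-3,
                 baseline_na=0.0):
    n = int(round((2 * pad + duration) / dt))
    t = np.arange(n + 1) / (1.0 / dt if dt == 1e-3 else 1.0 / dt)
    t = np.arange(n + 1) * dt
    current = np.full(t.shape, baseline_na)
    inside = (t >= pad) & (t <= pad + duration)
    current[inside] = baseline_na + amplitude_na
    return CurrentTrace(time=t, current=current, holding_potential=-60.0,
                        application_window=(pad, pad + duration))


class TestEvokedIV:
    def test_zero_background_is_identity(self):
        with_gly = iv_from(-2.0 * GRID)
        zero = iv_from(np.zeros_like(GRID))
        np.testing.assert_array_equal(
            evoked_iv(with_gly, zero).current, with_gly.current
        )

    def test_identical_curves_cancel(self):
        iv = iv_from(-2.0 * GRID, sem=np.ones_like(GRID))
        np.testing.assert_array_equal(evoked_iv(iv, iv).current, 0.0 * GRID)

    def test_pointwise_difference_and_quadrature_sem(self):
        a = iv_from(np.full(GRID.shape, -50.0), sem=np.full(GRID.shape, 3.0))
        b = iv_from(np.full(GRID.shape, -10.0), sem=np.full(GRID.shape, 4.0))
        out = evoked_iv(a, b)
        assert out.current[0] == pytest.approx(-40.0)
        assert out.sem[0] == pytest.approx(5.0)

    def test_grid_mismatch_rejected(self):
        a = iv_from(-GRID)
        b = iv_from(-GRID[:-1] - 5.0, potentials=GRID[:-1] + 5.0)
        with pytest.raises(ValueError):
            evoked_iv(a, b)


class TestNormalizeIV:
    def test_reference_value_is_minus_one_for_inward(self):
        iv = iv_from(2.0 * (GRID - 10.0))  # inward at -150
        out = normalize_iv(iv)
        assert out.current[0] == pytest.approx(-1.0)

    def test_linear_curve_stays_linear(self):
        iv = iv_from(0.5 * GRID)
        out = normalize_iv(iv)
        np.testing.assert_allclose(out.current, GRID / 150.0)

    def test_idempotence(self):
        iv = iv_from(2.0 * (GRID - 10.0), sem=np.abs(GRID) / 10)
        once = normalize_iv(iv)
        twice = normalize_iv(once)
        np.testing.assert_allclose(twice.current, once.current)
        np.testing.assert_allclose(twice.sem, once.sem)

    def test_missing_reference_potential_rejected(self):
        iv = iv_from(-GRID)
        with pytest.raises(ValueError):
            normalize_iv(iv, reference_potential=-155.0)

    def test_zero_reference_current_rejected(self):
        iv = iv_from(GRID - GRID[0])
        with pytest.raises(ValueError):
            normalize_iv(iv)


class TestEstimateErev:
    def test_symmetric_bracket_interpolates_to_zero(self):
        iv = iv_from([-15, -10, -5, 5, 15, 25],
                     potentials=[-50, -30, -10, 10, 30, 50])
        assert estimate_erev(iv) == pytest.approx(0.0)

    def test_exact_grid_zero_is_returned(self):
        iv = iv_from(0.5 * (GRID + 30.0))
        assert estimate_erev(iv) == pytest.approx(-30.0)

    def test_matches_numpy_interp_on_bracketing_pair(self):
        """Independent oracle: invert the line through the sign-change pair."""
        currents = 0.3 * (GRID + 42.0) ** 1.0 + 0.001 * (GRID + 42.0) ** 2
        iv = iv_from(currents)
        k = np.flatnonzero(currents[:-1] * currents[1:] < 0)[0]
        expected = np.interp(0.0, currents[k:k + 2], GRID[k:k + 2])
        assert estimate_erev(iv) == pytest.approx(expected, abs=1e-12)

    def test_non_reversing_curve_raises(self):
        with pytest.raises(NonReversingError):
            estimate_erev(iv_from(0.5 * GRID - 100.0))

    def test_multiple_crossings_ambiguous(self):
        iv = iv_from([-1, 1, -1, 1], potentials=[-60, -40, -20, 0])
        with pytest.raises(ValueError, match="ambiguous"):
            estimate_erev(iv)


class TestRectificationDegree:
    def test_affine_iv_gives_unity(self):
        assert rectification_degree(iv_from(0.7 * GRID + 3.0)) == pytest.approx(1.0)

    def test_cubic_iv_matches_two_regression_oracle(self):
        currents = 0.4 * GRID + 2e-5 * GRID**3
        iv = iv_from(currents)
        expected = ols_slope(GRID[:3], currents[:3]) / ols_slope(GRID[-3:], currents[-3:])
        assert rectification_degree(iv) == pytest.approx(expected, rel=1e-12)

    def test_piecewise_linear_fourfold_ratio(self):
        """Negative limb 4x steeper than positive limb -> degree 4."""
        currents = np.where(GRID < -60.0, 4.0 * (GRID + 60.0), 1.0 * (GRID + 60.0))
        assert rectification_degree(iv_from(currents)) == pytest.approx(4.0)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_current_scaling(self, scale):
        currents = 0.4 * GRID + 2e-5 * GRID**3
        d0 = rectification_degree(iv_from(currents))
        d1 = rectification_degree(iv_from(scale * currents))
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_flat_positive_limb_gives_infinity(self):
        currents = np.where(GRID <= -10.0, 2.0 * (GRID + 10.0), 0.0)
        assert rectification_degree(iv_from(currents)) == np.inf

    def test_too_few_points_rejected(self):
        iv = iv_from([-3, -2, -1, 0], potentials=[-60, -40, -20, 0])
        with pytest.raises(ValueError):
            rectification_degree(iv, k=3)


class TestIntegrateCharge:
    def test_rectangular_pulse(self):
        """-100 nA above baseline for 60 s -> |Q| = 6 uC, inward negative."""
        q = integrate_charge(square_trace(amplitude_na=-100.0))
        assert q == pytest.approx(-6.0e-6, rel=1e-12)

    def test_zero_evoked_current(self):
        q = integrate_charge(square_trace(amplitude_na=0.0))
        assert q == 0.0

    def test_baseline_offset_is_removed(self):
        q = integrate_charge(square_trace(amplitude_na=-100.0, baseline_na=-40.0))
        assert q == pytest.approx(-6.0e-6, rel=1e-10)

    def test_ramp_matches_triangle_area(self):
        t = np.arange(0, 70_001) * 1e-3
        current = np.zeros_like(t)
        inside = (t >= 5.0) & (t <= 65.0)
        current[inside] = -(t[inside] - 5.0)  # ramps to -60 nA over 60 s
        trace = CurrentTrace(time=t, current=current, holding_potential=-60.0,
                             application_window=(5.0, 65.0))
        expected = -0.5 * 60.0 * 60.0 * 1e-9  # triangle area in C
        assert integrate_charge(trace) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_adjacent_windows(self):
        trace = square_trace(amplitude_na=-80.0)
        q_full = integrate_charge(trace, (5.0, 65.0))
        q_split = integrate_charge(trace, (5.0, 30.0)) + integrate_charge(
            trace, (30.0, 65.0)
        )
        assert q_split == pytest.approx(q_full, rel=1e-12)

    def test_linear_in_current(self):
        q1 = integrate_charge(square_trace(amplitude_na=-50.0))
        q2 = integrate_charge(square_trace(amplitude_na=-100.0))
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            integrate_charge(square_trace(), (5.0, 1000.0))


class TestMolesFromTracer:
    def test_background_equal_to_sample_gives_zero(self):
        assert moles_from_tracer(500.0, 500.0, 0.4) == 0.0

    def test_known_dpm_arithmetic(self):
        # 8.88e5 dpm / (2.22e12 dpm/Ci x 0.4 Ci/mmol) = 1e-6 mmol = 1e-9 mol
        assert moles_from_tracer(8.88e5, 0.0, 0.4) == pytest.approx(1.0e-9, rel=1e-12)

    def test_doubling_specific_activity_halves_moles(self):
        m1 = moles_from_tracer(1e6, 0.0, 0.4)
        m2 = moles_from_tracer(1e6, 0.0, 0.8)
        assert m2 == pytest.approx(m1 / 2, rel=1e-12)

    def test_background_exceeding_sample_rejected(self):
        with pytest.raises(ValueError):
            moles_from_tracer(100.0, 200.0, 0.4)

    def test_nonpositive_specific_activity_rejected(self):
        with pytest.raises(ValueError):
            moles_from_tracer(100.0, 0.0, 0.0)


class TestChargeToFlux:
    @pytest.mark.parametrize("z", [1.0, 2.0])
    def test_integer_charge_by_construction(self, z):
        m = 3.7e-12  # mol substrate
        res = charge_to_flux(-z * DEFAULT_CONSTANTS.faraday * m, m)
        assert res.ratio == pytest.approx(z, rel=1e-12)

    def test_sign_is_preserved_in_raw_charge(self):
        res = charge_to_flux(-1e-6, 1e-11)
        assert res.charge_c < 0 and res.ratio > 0

    def test_zero_substrate_rejected(self):
        with pytest.raises(ValueError):
            charge_to_flux(-1e-6, 0.0)
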