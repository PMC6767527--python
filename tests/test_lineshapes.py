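"""Lorentzian / super-Lorentzian lineshapes and the forward z-spectrum model."""

import numpy as np
import pytest
from scipy.integrate import quad

from cestkit.constants import FieldConstants
from cestkit.lineshapes import (
    DEFAULT_SPLINE,
    LorentzianPool,
    SplineConfig,
    SuperLorentzianPool,
    ZModelParams,
    forward_zspectrum,
    lorentzian,
    super_lorentzian_analytic,
    super_lorentzian_patched,
    super_lorentzian_raw,
)
from cestkit.lineshapes import _build_nodes


def adaptive_sl_oracle(delta_ppm: float, t2b_us: float) -> float:
    """Independent adaptive-quadrature evaluation of the orientation integral."""
    constants = FieldConstants()
    dw = 2.0 * np.pi * delta_ppm * constants.larmor_mhz
    t2b = t2b_us * 1e-6

    def f(theta):
        u = 3.0 * np.cos(theta) ** 2 - 1.0
        return np.sin(theta) * np.sqrt(2 / np.pi) * (t2b / abs(u)) * np.exp(
            -2.0 * (dw * t2b / u) ** 2
        )

    thm = np.arccos(1.0 / np.sqrt(3.0))
    v1, _ = quad(f, 0.0, thm, epsabs=0, epsrel=1e-12, limit=500)
    v2, _ = quad(f, thm, np.pi / 2, epsabs=0, epsrel=1e-12, limit=500)
    return v1 + v2


class TestLorentzian:
    def test_center_value_closed_form(self):
        pool = LorentzianPool(0.0, 2.0, 0.1)
        assert lorentzian(0.0, pool) == pytest.approx(2 * 0.1 / (np.pi * 2.0), rel=1e-12)

    def test_half_maximum_at_half_width(self):
        pool = LorentzianPool(1.0, 3.0, 0.5)
        center = lorentzian(1.0, pool)
        assert lorentzian(1.0 + 1.5, pool) == pytest.approx(center / 2, rel=1e-12)
        assert lorentzian(1.0 - 1.5, pool) == pytest.approx(center / 2, rel=1e-12)

    @pytest.mark.parametrize("x", [0.5, 1.7, 3.1])
    def test_even_about_center(self, x):
        pool = LorentzianPool(-3.5, 2.0, 0.2)
        assert lorentzian(-3.5 + x, pool) == pytest.approx(lorentzian(-3.5 - x, pool), rel=1e-12)

    def test_invalid_pool_rejected(self):
        with pytest.raises(ValueError):
            LorentzianPool(0.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            LorentzianPool(0.0, 1.0, -0.1)


class TestSuperLorentzian:
    @pytest.mark.parametrize("t2b", [1.0, 2.0, 5.0, 10.0, 30.0, 50.0])
    @pytest.mark.parametrize("delta", [21.0, 40.0, 100.0, 300.0])
    def test_fixed_quadrature_matches_adaptive_oracle(self, t2b, delta):
        got = super_lorentzian_raw(delta, t2b)
        ref = adaptive_sl_oracle(delta, t2b)
        assert got == pytest.approx(ref, rel=1e-6)

    def test_quadrature_order_doubling_converged(self):
        nodes, weights = _build_nodes(512)
        base = super_lorentzian_raw(30.0, 10.0)
        fine = super_lorentzian_raw(30.0, 10.0, nodes=nodes, weights=weights)
        assert fine == pytest.approx(base, rel=1e-6)

    @pytest.mark.parametrize("delta", [25.0, 40.0, 100.0])
    def test_analytic_even_about_center(self, delta):
        pool = SuperLorentzianPool(-1.27, 10.0, 0.3)
        plus = super_lorentzian_analytic(-1.27 + delta, pool)
        minus = super_lorentzian_analytic(-1.27 - delta, pool)
        assert plus == pytest.approx(minus, rel=1e-10)

    def test_amplitude_linearity(self):
        a = SuperLorentzianPool(0.0, 10.0, 0.2)
        b = SuperLorentzianPool(0.0, 10.0, 0.4)
        assert super_lorentzian_analytic(30.0, b) == pytest.approx(
            2 * super_lorentzian_analytic(30.0, a), rel=1e-12
        )

    def test_pole_region_rejected_by_analytic(self):
        pool = SuperLorentzianPool(-1.27, 10.0, 0.3)
        with pytest.raises(ValueError, match="pole"):
            super_lorentzian_analytic(0.0, pool)

    def test_nonpositive_t2b_rejected(self):
        with pytest.raises(ValueError):
            SuperLorentzianPool(0.0, 0.0, 0.1)


class TestPolePatch:
    def test_continuity_at_window_edges(self):
        pool = SuperLorentzianPool(-1.27, 10.0, 0.5)
        for edge in (-1.27 - 20.0, -1.27 + 20.0):
            patched = super_lorentzian_patched(edge, pool)
            analytic = super_lorentzian_analytic(edge, pool)
            assert abs(patched - analytic) < 1e-9 * analytic

    @pytest.mark.parametrize("t2b", [5.0, 10.0, 30.0])
    def test_patched_center_finite_and_above_edges(self, t2b):
        pool = SuperLorentzianPool(0.0, t2b, 1.0)
        center = super_lorentzian_patched(0.0, pool)
        edge = super_lorentzian_analytic(20.0, pool)
        assert np.isfinite(center)
        assert center >= edge

    def test_patched_center_equals_amplitude(self):
        # peak-normalized convention: the MT height is the amplitude itself
        pool = SuperLorentzianPool(-1.27, 12.0, 0.37)
        assert super_lorentzian_patched(-1.27, pool) == pytest.approx(0.37, rel=1e-12)

    @pytest.mark.parametrize("delta", [0.0, 5.0, 15.0])
    def test_patch_even_about_center(self, delta):
        pool = SuperLorentzianPool(-1.27, 10.0, 0.5)
        plus = super_lorentzian_patched(-1.27 + delta, pool)
        minus = super_lorentzian_patched(-1.27 - delta, pool)
        assert plus == pytest.approx(minus, rel=1e-12)

    def test_anchors_inside_window_rejected(self):
        with pytest.raises(ValueError):
            SplineConfig(half_window_ppm=20.0, anchor_offsets_ppm=(15.0, 25.0, 30.0))

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            SplineConfig(anchor_offsets_ppm=(20.0, 25.0))


class TestSuperLorentzianTable:
    def test_matches_direct_evaluation(self, sl_table, rng):
        worst = 0.0
        for t2b in (1.0, 3.3, 10.0, 27.0, 49.0):
            pool = SuperLorentzianPool(-1.27, t2b, 1.0)
            offs = np.concatenate([rng.uniform(-300, 300, 100), rng.uniform(-25, 25, 100)])
            ref = super_lorentzian_patched(offs, pool)
            got = sl_table(offs, pool)
            worst = max(worst, float(np.max(np.abs(got - ref))))
        assert worst < 2e-4

    def test_range_overflow_rejected(self, sl_table):
        pool = SuperLorentzianPool(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            sl_table(500.0, pool)


def _empty_model(**kw):
    return ZModelParams(
        water=LorentzianPool(0.0, 1.0, kw.get("water", 0.0)),
        amide=LorentzianPool(3.5, 2.0, kw.get("amide", 0.0)),
        noe=LorentzianPool(-3.5, 2.0, kw.get("noe", 0.0)),
        mt=SuperLorentzianPool(-1.27, 10.0, kw.get("mt", 0.0)),
        h_ppm=kw.get("h", 0.0),
        v=kw.get("v", 0.0),
    )


class TestForwardModel:
    def test_empty_model_is_unity(self, schedule):
        mz = forward_zspectrum(_empty_model(), schedule.as_array())
        assert np.allclose(mz, 1.0)

    def test_water_only_closed_form(self):
        params = _empty_model(water=0.8)
        mz = forward_zspectrum(params, 0.0)
        assert mz == pytest.approx(1 - 2 * 0.8 / np.pi, abs=1e-4)

    def test_shifted_amide_minimum_location(self, schedule):
        params = _empty_model(amide=0.3, h=0.2)
        offs = schedule.as_array()
        inner = offs[np.abs(offs) <= 5]
        mz = forward_zspectrum(params, inner)
        wmin = inner[np.argmin(mz)]
        dense = np.linspace(-5, 5, 2001)
        expected = dense[np.argmin(forward_zspectrum(params, dense))]
        assert wmin == pytest.approx(3.7, abs=0.13)
        assert abs(wmin - expected) <= 0.25  # nearest grid point

    def test_vertical_offset_scales_signal(self, schedule, tz_params):
        from dataclasses import replace

        offs = schedule.as_array()
        base = forward_zspectrum(tz_params, offs)
        with_v = forward_zspectrum(replace(tz_params, v=0.05), offs)
        assert np.allclose(with_v, 0.95 * base, rtol=0, atol=1e-12)

    def test_bounded_above(self, schedule, tz_params):
        mz = forward_zspectrum(tz_params, schedule.as_array())
        assert np.all(mz <= 1 + abs(tz_params.v) + 1e-12)
        assert np.all(mz >= 0)

    def test_smooth_in_parameters(self, tz_params):
        # finite-difference continuity: small parameter nudges give small output changes
        from dataclasses import replace

        offs = np.linspace(-6, 6, 49)
        base = forward_zspectrum(tz_params, offs)
        eps = 1e-6
        nudged = [
            replace(tz_params, h_ppm=tz_params.h_ppm + eps),
            replace(tz_params, v=tz_params.v + eps),
            replace(tz_params, mt=SuperLorentzianPool(-1.27, tz_params.mt.t2b_us + eps, tz_params.mt.amplitude)),
            replace(tz_params, water=LorentzianPool(0.0, tz_params.water.gamma_ppm + eps, tz_params.water.amplitude)),
        ]
        for p in nudged:
            assert np.max(np.abs(forward_zspectrum(p, offs) - base)) < 1e-4
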