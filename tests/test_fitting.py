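"""Four-pool fitting: closure, renormalization, bounds, MT-offset estimation."""

from dataclasses import replace

import numpy as np
import pytest

from cestkit import (
    FitConfig,
    LorentzianPool,
    PhantomConfig,
    SuperLorentzianPool,
    ZModelParams,
    ZSpectrum,
    ZSpectrumVolume,
    estimate_mt_offset,
    fit_maps,
    fit_zspectrum,
    forward_zspectrum,
    make_phantom,
    region_masks,
    roi_average_spectrum,
    simulate_scan,
)
from cestkit.fitting import ParamSpec, _model_signal
from cestkit.phantom import default_region_params


def _make_truth(amide_h=0.113, noe_h=0.109, mt_h=0.222, h=0.0, v=0.0, t2b=9.0):
    return ZModelParams(
        water=LorentzianPool(0.0, 1.4, 0.75),
        amide=LorentzianPool(3.5, 2.2, amide_h * np.pi * 2.2 / 2),
        noe=LorentzianPool(-3.5, 2.5, noe_h * np.pi * 2.5 / 2),
        mt=SuperLorentzianPool(-1.27, t2b, mt_h),
        h_ppm=h,
        v=v,
    )


def _heights(p: ZModelParams) -> dict:
    return {
        "amide": p.amide.peak_height,
        "noe": p.noe.peak_height,
        "mt": p.mt.amplitude,
        "water": p.water.peak_height,
    }


class TestFitClosure:
    @pytest.mark.parametrize(
        "truth",
        [
            _make_truth(),
            _make_truth(amide_h=0.09, noe_h=0.13, mt_h=0.30, h=0.12, t2b=15.0),
            _make_truth(v=0.05),
            _make_truth(amide_h=0.102, noe_h=0.096, mt_h=0.26, h=-0.08, v=-0.03),
        ],
    )
    def test_noiseless_parameter_recovery(self, schedule, truth):
        offs = schedule.as_array()
        spec = ZSpectrum(offs, forward_zspectrum(truth, offs))
        res = fit_zspectrum(spec)
        assert res.converged
        want = _heights(truth)
        for k in ("amide", "noe", "mt", "water"):
            assert res.peak_heights[k] == pytest.approx(want[k], abs=1e-3), k
        assert res.params.v == pytest.approx(truth.v, abs=1e-3)
        assert res.params.h_ppm == pytest.approx(truth.h_ppm, abs=1e-3)

    def test_renormalization_recovers_v_free_truth(self, schedule):
        """Data synthesized with v=0.05 fit back to the v=0 heights."""
        truth_v = _make_truth(v=0.05)
        truth_0 = replace(truth_v, v=0.0)
        offs = schedule.as_array()
        res = fit_zspectrum(ZSpectrum(offs, forward_zspectrum(truth_v, offs)))
        want = _heights(truth_0)
        assert res.params.v == pytest.approx(0.05, abs=2e-3)
        for k in ("amide", "noe", "mt"):
            assert res.peak_heights[k] == pytest.approx(want[k], abs=1e-3), k

    def test_renormalized_output_refits_with_zero_v(self, schedule):
        truth = _make_truth(v=0.04)
        offs = schedule.as_array()
        res = fit_zspectrum(ZSpectrum(offs, forward_zspectrum(truth, offs)))
        renormed = forward_zspectrum(res.params, offs, apply_vertical=False)
        # amplitudes in res.params are already renormalized -> v should refit to ~0
        res2 = fit_zspectrum(ZSpectrum(offs, renormed))
        assert abs(res2.params.v) < 0.002

    def test_rss_not_worse_than_start(self, schedule, rng):
        truth = _make_truth()
        offs = schedule.as_array()
        sig = forward_zspectrum(truth, offs) + rng.normal(0, 0.005, offs.size)
        config = FitConfig()
        res = fit_zspectrum(ZSpectrum(offs, sig), config)
        x0, _, _ = config.vectors()
        from cestkit.lineshapes import super_lorentzian_patched

        def sl(delta, t2b):
            return super_lorentzian_patched(delta, SuperLorentzianPool(0.0, t2b, 1.0))

        rss0 = float(np.sum((sig - _model_signal(x0, offs, sl)) ** 2))
        assert res.rss <= rss0 + 1e-12

    def test_point_order_invariance(self, schedule, rng):
        truth = _make_truth(h=0.1, v=0.02)
        offs = schedule.as_array()
        sig = forward_zspectrum(truth, offs) + rng.normal(0, 0.003, offs.size)
        perm = rng.permutation(offs.size)
        a = fit_zspectrum(ZSpectrum(offs, sig))
        b = fit_zspectrum(ZSpectrum(offs[perm], sig[perm]))
        for k in a.peak_heights:
            assert abs(a.peak_heights[k] - b.peak_heights[k]) < 1e-8

    def test_bounds_respected_on_noisy_fits(self, schedule, sl_table, rng):
        truth = _make_truth()
        offs = schedule.as_array()
        clean = forward_zspectrum(truth, offs)
        config = FitConfig()
        _, lb, ub = config.vectors()
        for _ in range(25):
            sig = clean + rng.normal(0, 0.01, offs.size)
            res = fit_zspectrum(ZSpectrum(offs, sig), config, sl_table=sl_table)
            p = res.params
            raw = [
                p.water.omega0_ppm, p.water.gamma_ppm, p.water.amplitude * (1 - p.v),
                p.amide.omega0_ppm, p.amide.gamma_ppm, p.amide.amplitude * (1 - p.v),
                p.noe.omega0_ppm, p.noe.gamma_ppm, p.noe.amplitude * (1 - p.v),
                p.mt.omega0_ppm, p.mt.t2b_us, p.mt.amplitude * (1 - p.v),
                p.h_ppm, p.v,
            ]
            assert np.all(np.asarray(raw) >= lb - 1e-9)
            assert np.all(np.asarray(raw) <= ub + 1e-9)

    def test_degenerate_inputs_rejected(self, schedule):
        offs = schedule.as_array()
        with pytest.raises(ValueError, match="flat"):
            fit_zspectrum(ZSpectrum(offs, np.ones(offs.size)))
        with pytest.raises(ValueError, match="15"):
            fit_zspectrum(ZSpectrum(offs[:10], np.linspace(0, 1, 10)))

    def test_param_spec_ordering_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec(start=2.0, lower=0.0, upper=1.0)


class TestRoiAverage:
    def test_single_voxel_roi_identity(self, schedule, small_truth):
        zvol, _ = simulate_scan(small_truth, schedule, 1)
        iy, ix = np.argwhere(small_truth.mask)[0]
        roi = np.zeros(small_truth.mask.shape, dtype=bool)
        roi[iy, ix] = True
        spec = roi_average_spectrum(zvol, roi)
        assert np.array_equal(spec.signal, zvol.signal[iy, ix])
        assert spec.n_averaged == 1

    def test_mean_within_envelope(self, schedule):
        truth = make_phantom(PhantomConfig(shape=(16, 16), noise_sigma=0.01), seed=3)
        zvol, _ = simulate_scan(truth, schedule, 5)
        roi = truth.label_map == 2
        spec = roi_average_spectrum(zvol, roi)
        members = zvol.signal[roi & zvol.mask]
        assert np.all(spec.signal >= members.min(axis=0) - 1e-12)
        assert np.all(spec.signal <= members.max(axis=0) + 1e-12)

    def test_averaging_suppresses_noise_like_sqrt_n(self, schedule, tz_params):
        sigma, n = 0.01, 64
        offs = schedule.as_array()
        clean = forward_zspectrum(tz_params, offs)
        rng = np.random.default_rng(8)
        resid_sd = []
        for _ in range(200):
            noisy = clean + rng.normal(0, sigma, (n, offs.size))
            resid_sd.append(np.std(noisy.mean(axis=0) - clean))
        assert np.mean(resid_sd) == pytest.approx(sigma / np.sqrt(n), rel=0.1)

    def test_empty_roi_rejected(self, schedule, small_truth):
        zvol, _ = simulate_scan(small_truth, schedule, 1)
        with pytest.raises(ValueError, match="empty"):
            roi_average_spectrum(zvol, np.zeros(small_truth.mask.shape, dtype=bool))


class TestFitMaps:
    def test_two_region_recovery_and_h_bounds(self, schedule, sl_table):
        truth = make_phantom(
            PhantomConfig(shape=(20, 20), noise_sigma=0.005, b0_amplitude_ppm=0.0), seed=6
        )
        zvol, _ = simulate_scan(truth, schedule, 17)
        maps = fit_maps(zvol, sl_table=sl_table)
        masks = region_masks(truth)
        for name in ("tz", "pz"):
            want = truth.region_params[name].mt.amplitude
            got = np.nanmedian(maps["mt"][masks[name]])
            assert got == pytest.approx(want, rel=0.05), name
        # ordering: muscle MT > tz MT > pz MT
        med = {n: np.nanmedian(maps["mt"][m]) for n, m in masks.items()}
        assert med["muscle"] > med["tz"] > med["pz"]
        h_vals = maps["h"][truth.mask]
        assert np.all(np.abs(h_vals[np.isfinite(h_vals)]) <= 0.3 + 1e-9)

    def test_all_background_mask_gives_empty_maps(self, schedule, small_truth):
        zvol, _ = simulate_scan(small_truth, schedule, 1)
        zvol.mask[:] = False
        maps = fit_maps(zvol)
        assert np.all(np.isnan(maps["amide"]))
        assert not maps["converged"].any()


class TestEstimateMtOffset:
    def test_recovers_shifted_mt_centre(self, schedule, sl_table):
        truth = make_phantom(
            PhantomConfig(shape=(14, 14), noise_sigma=0.0, b0_amplitude_ppm=0.0), seed=9
        )
        zvol, _ = simulate_scan(truth, schedule, 2)
        est = estimate_mt_offset(zvol, sl_table=sl_table)
        assert est.median_ppm == pytest.approx(-1.27, abs=0.02)
        assert est.n_voxels == int(truth.mask.sum())

    def test_symmetric_mt_estimates_zero(self, schedule, sl_table):
        params = default_region_params()["tz"]
        sym = replace(params, mt=replace(params.mt, omega0_ppm=0.0))
        offs = schedule.as_array()
        sig = forward_zspectrum(sym, offs)
        vol = ZSpectrumVolume(np.tile(sig, (2, 2, 1)), schedule)
        est = estimate_mt_offset(vol, sl_table=sl_table)
        assert abs(est.median_ppm) < 0.02

    def test_requires_outer_points(self, schedule, small_truth):
        zvol, _ = simulate_scan(small_truth, schedule, 1)
        keep = np.abs(zvol.offsets_ppm) <= 15.0
        from cestkit.constants import OffsetSchedule

        trimmed = ZSpectrumVolume(
            zvol.signal[..., keep],
            OffsetSchedule(tuple(zvol.offsets_ppm[keep])),
            mask=zvol.mask,
        )
        with pytest.raises(ValueError, match=">= 6"):
            estimate_mt_offset(trimmed)

    def test_default_fit_config_pins_protocol_constant(self):
        config = FitConfig()
        spec = config.params["mt_omega0"]
        assert spec.start == -1.27
        assert (spec.lower, spec.upper) == (-1.27001, -1.26999)
        moved = config.with_mt_offset(-1.0)
        assert moved.params["mt_omega0"].start == -1.0
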