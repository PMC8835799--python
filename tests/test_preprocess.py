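"""Chirp, reference subtraction, baselines, and band integration."""

import dataclasses

import numpy as np
import pytest

import fsrskit as fk
from fsrskit.preprocess import ChirpError


def chirp_surface(chirp_coeffs, axis=None, noise=None):
    """Broad step-response band across the axis with an injected chirp."""
    if axis is None:
        axis = np.arange(700.0, 1600.0 + 1e-9, 10.0)
    scheme = fk.KineticScheme(components=((5.0, "decay"),))
    band = fk.SpectralBand(
        center=float(np.mean(axis)), fwhm=5 * np.ptp(axis),
        amplitude_per_component=(1.0,),
    )
    pre = fk.SyntheticPreset(
        name="chirp_test", scheme=scheme, bands=(band,),
        instrument=fk.InstrumentModel(t0=0.0, chirp_coeffs=chirp_coeffs),
        axis=axis, axis_kind="raman_shift_cm",
        delays=np.arange(-1.0, 4.0, 0.02),
    )
    return fk.generate_surface(pre, noise)


class TestEstimateChirp:
    def test_recovers_injected_polynomial(self):
        surface = chirp_surface((0.1, 0.001, 0.0))
        model = fk.estimate_chirp(surface, (-0.5, 3.5))
        assert model.coeffs[0] == pytest.approx(0.1, rel=0.05)
        assert model.coeffs[1] == pytest.approx(0.001, rel=0.05)
        assert abs(model.coeffs[2]) < 1e-7

    def test_chirp_free_surface_recovers_constant(self):
        surface = chirp_surface(())
        model = fk.estimate_chirp(surface, (-0.5, 3.5))
        assert abs(model.coeffs[1]) < 1e-4
        assert abs(model.coeffs[2]) < 1e-4

    def test_flat_surface_no_artifact(self):
        surface = fk.DelaySpectraSurface(
            np.arange(5.0), np.arange(20.0) * 0.1 - 1.0,
            np.zeros((5, 20)), "wavelength_nm",
        )
        with pytest.raises(ChirpError, match="no artifact detected"):
            fk.estimate_chirp(surface, (-1.0, 0.9))


class TestApplyChirpCorrection:
    def test_zero_chirp_is_identity(self, small_surface):
        model = fk.ChirpModel(coeffs=(0.0, 0.0), reference_position=660.0)
        out = fk.apply_chirp_correction(small_surface, model)
        assert np.array_equal(out.values, small_surface.values)

    def test_single_channel_integer_shift(self):
        delays = np.arange(0.0, 10.0, 1.0)
        values = np.arange(10.0)[None, :]
        surface = fk.DelaySpectraSurface([500.0], delays, values, "wavelength_nm")
        # shift of exactly one grid step: t0(500) − t0(ref) = 1
        model = fk.ChirpModel(coeffs=(0.0, 1.0 / 500.0), reference_position=0.0)
        out = fk.apply_chirp_correction(surface, model)
        expected = np.concatenate([values[0, 1:], [values[0, -1]]])
        assert np.allclose(out.values[0], expected, atol=1e-12)

    def test_compose_and_reestimate_removes_chirp(self):
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(20):
            # chirp centered on the axis so every channel's time zero stays
            # inside the recorded artifact window
            c0 = rng.uniform(-0.2, 0.2)
            c1 = rng.uniform(-8e-4, 8e-4)
            surface = chirp_surface((c0 - c1 * 1150.0, c1))
            model = fk.estimate_chirp(surface, (-0.8, 3.5))
            corrected = fk.apply_chirp_correction(surface, model)
            re_model = fk.estimate_chirp(corrected, (-0.8, 3.5))
            ax = surface.axis
            slope = lambda m: (m.t0(ax[-1]) - m.t0(ax[0])) / np.ptp(ax)
            before, after = slope(model), slope(re_model)
            # only chirps whose total spread exceeds the 20 fs delay step by
            # a clear margin are measurable enough for a reduction ratio
            if abs(before) * np.ptp(ax) > 0.05:
                ratios.append(abs(after / before))
        assert ratios and max(ratios) < 0.10

    def test_excessive_shift_rejected(self, small_surface):
        model = fk.ChirpModel(coeffs=(0.0, 0.1), reference_position=640.0)
        with pytest.raises(ValueError, match="half the delay span"):
            fk.apply_chirp_correction(small_surface, model)


class TestSubtractReference:
    def test_reference_column_becomes_zero(self, fsrs_surface):
        diff = fk.subtract_reference(fsrs_surface, -5.0)
        idx = int(np.argmin(np.abs(diff.delays + 5.0)))
        assert np.all(diff.values[:, idx] == 0.0)

    def test_delay_independent_surface_vanishes(self):
        surface = fk.DelaySpectraSurface(
            [1.0, 2.0], [-5.0, 0.0, 5.0], np.outer([3.0, 4.0], [1.0, 1.0, 1.0]),
            "wavelength_nm",
        )
        diff = fk.subtract_reference(surface, -5.0)
        assert np.all(diff.values == 0.0)

    def test_ground_band_depletion_sign(self, fsrs_surface, fsrs_preset):
        # after fluorescence-background removal, the ν_C=C,C=O region shows a
        # negative (depletion) difference signal at later delays
        diff = fk.subtract_reference(fsrs_surface, -5.0)
        j = int(np.argmin(np.abs(diff.delays - 10.0)))
        windows = tuple(
            (b.center, 1.5 * b.fwhm)
            for b in fsrs_preset.bands
            if b.fwhm < 100.0
        )
        spec = fk.BaselineSpec(order=4, exclusion_windows=windows)
        _, corrected = fk.fit_baseline(diff.axis, diff.values[:, j], spec)
        i = int(np.argmin(np.abs(diff.axis - 1631.0)))
        assert corrected[i] < 0.0

    def test_exact_linearity(self, small_surface):
        doubled = small_surface.replace_values(2.0 * small_surface.values)
        d1 = fk.subtract_reference(small_surface, -1.0)
        d2 = fk.subtract_reference(doubled, -1.0)
        assert np.array_equal(d2.values, 2.0 * d1.values)

    def test_out_of_range_reference_rejected(self, small_surface):
        with pytest.raises(ValueError, match="outside the delay range"):
            fk.subtract_reference(small_surface, -100.0)


class TestFitBaseline:
    def test_polynomial_input_exact_removal(self):
        x = np.linspace(600.0, 1700.0, 300)
        y = 1.0 - 2e-3 * x + 3e-6 * x**2 - 5e-10 * x**3
        spec = fk.BaselineSpec(order=3)
        baseline, corrected = fk.fit_baseline(x, y, spec)
        assert np.max(np.abs(corrected)) < 1e-10 * np.max(np.abs(y))

    def test_masked_band_on_ramp_recovered(self):
        x = np.linspace(600.0, 800.0, 400)
        band = 0.8 * np.exp(-4 * np.log(2) * ((x - 700.0) / 15.0) ** 2)
        y = band + 0.5 + 2e-3 * x
        spec = fk.BaselineSpec(order=1, exclusion_windows=((700.0, 30.0),))
        _, corrected = fk.fit_baseline(x, y, spec)
        i = int(np.argmin(np.abs(x - 700.0)))
        assert corrected[i] == pytest.approx(0.8, rel=0.01)

    def test_all_masked_rejected(self):
        x = np.linspace(0.0, 10.0, 50)
        spec = fk.BaselineSpec(order=2, exclusion_windows=((5.0, 100.0),))
        with pytest.raises(ValueError, match="all points masked"):
            fk.fit_baseline(x, np.ones_like(x), spec)

    def test_corrected_is_exactly_input_minus_baseline(self):
        rng = np.random.default_rng(3)
        x = np.linspace(600.0, 800.0, 101)
        y = rng.normal(size=x.size)
        for mode in ("full_range_poly", "local_linear"):
            baseline, corrected = fk.fit_baseline(x, y, fk.BaselineSpec(mode=mode))
            # bitwise tautology guard: no other transformation is applied
            assert np.array_equal(corrected, y - baseline)
            assert np.allclose(corrected + baseline, y, rtol=0, atol=1e-14)

    def test_local_linear_through_endpoint_means(self):
        x = np.arange(0.0, 12.0)
        y = 2.0 + 0.5 * x
        baseline, corrected = fk.fit_baseline(
            x, y, fk.BaselineSpec(mode="local_linear")
        )
        assert np.allclose(baseline, y, atol=1e-12)
        assert np.allclose(corrected, 0.0, atol=1e-12)


class TestBandIntegral:
    def test_single_row_bandwidth(self, small_surface):
        trace = fk.band_integral(small_surface, 656.0, 2.0)
        assert np.array_equal(trace.values, small_surface.values[4])

    def test_lone_band_mono_exponential_recovery(self, irf):
        scheme = fk.KineticScheme(components=((5.0, "decay"),))
        band = fk.SpectralBand(center=1000.0, fwhm=15.0, amplitude_per_component=(1.0,))
        pre = fk.SyntheticPreset(
            name="lone", scheme=scheme, bands=(band,),
            instrument=fk.InstrumentModel(),
            axis=np.arange(900.0, 1100.0, 2.0), axis_kind="raman_shift_cm",
            delays=np.concatenate(
                [np.arange(-0.5, 2.0, 0.02), np.geomspace(2.0, 60.0, 50)]
            ),
        )
        surface = fk.generate_surface(pre)
        trace = fk.band_integral(surface, 1000.0, 25.0)
        res = fk.fit_trace(trace, 1, pre.instrument.irf, seed=0)
        assert res.taus[0] == pytest.approx(5.0, abs=0.1)

    def test_locality_between_separated_bands(self, irf):
        scheme = fk.KineticScheme(components=((5.0, "decay"),))
        make = lambda amp_b: fk.SyntheticPreset(
            name="two", scheme=scheme,
            bands=(
                fk.SpectralBand(center=700.0, fwhm=14.0, amplitude_per_component=(1.0,)),
                fk.SpectralBand(center=1500.0, fwhm=14.0, amplitude_per_component=(amp_b,)),
            ),
            instrument=fk.InstrumentModel(),
            axis=np.arange(600.0, 1700.0, 2.0), axis_kind="raman_shift_cm",
            delays=np.arange(-0.5, 10.0, 0.1),
        )
        t1 = fk.band_integral(fk.generate_surface(make(1.0)), 700.0, 25.0)
        t2 = fk.band_integral(fk.generate_surface(make(5.0)), 700.0, 25.0)
        assert np.max(np.abs(t1.values - t2.values)) < 1e-12
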