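import numpy as np
import pytest

from holoseg.errors import ParameterError
from holoseg.imaging import RasterImage
from holoseg.osh import (OSHParams, Spectrum, circular_highpass,
                         forward_spectrum, fzp_hologram, fzp_kernels,
                         inverse_reconstruct, phase_current_amplitude,
                         phase_current_map, pure_phase_filter, reference_gain,
                         subtract_background)


def gray(arr):
    return RasterImage(np.asarray(arr, dtype=float), "GRAY")


class TestForwardSpectrum:
    def test_constant_image_concentrates_at_dc(self):
        h = w = 16
        spec = forward_spectrum(gray(np.full((h, w), 0.5)))
        dc = spec.values[h // 2, w // 2]
        assert dc == pytest.approx(0.5 * h * w)
        off = spec.values.copy()
        off[h // 2, w // 2] = 0
        assert np.abs(off).max() < 1e-10

    def test_delta_has_flat_magnitude(self):
        arr = np.zeros((16, 16))
        arr[3, 5] = 1.0
        spec = forward_spectrum(gray(arr))
        np.testing.assert_allclose(np.abs(spec.values), 1.0, atol=1e-12)

    def test_parseval(self, rng):
        arr = rng.random((32, 32))
        spec = forward_spectrum(gray(arr))
        lhs = np.sum(np.abs(spec.values) ** 2)
        rhs = arr.size * np.sum(arr ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestPurePhaseFilter:
    def test_unit_modulus_normalisation(self):
        vals = np.full((8, 8), 1.0, dtype=complex)
        vals[0, 0] = 3 + 4j
        out = pure_phase_filter(Spectrum(vals, (8, 8)))
        assert out.values[0, 0] == pytest.approx(0.6 + 0.8j)

    def test_zero_bin_guarded(self):
        vals = np.ones((8, 8), dtype=complex)
        vals[2, 2] = 0.0
        out = pure_phase_filter(Spectrum(vals, (8, 8)))
        assert out.values[2, 2] == 0.0

    def test_output_modulus_zero_or_one(self, rng):
        vals = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        vals[0, :4] = 0.0
        out = pure_phase_filter(Spectrum(vals, (16, 16)))
        mags = np.abs(out.values)
        nonzero = mags[mags > 0]
        assert np.max(np.abs(nonzero - 1.0)) < 1e-12


class TestCircularHighpass:
    def test_zeroed_bin_count_matches_brute_force(self):
        # independent enumeration of the stop-band disk on a 64x64 grid
        h = w = 64
        vals = np.ones((h, w), dtype=complex)
        out = circular_highpass(Spectrum(vals, (h, w)), 0.15)
        zeroed = int(np.sum(out.values == 0))
        brute = 0
        for i in range(h):
            for j in range(w):
                fy = (i - h // 2) / (h / 2)
                fx = (j - w // 2) / (w / 2)
                if np.hypot(fy, fx) < 0.15:
                    brute += 1
        assert zeroed == brute

    def test_dc_always_zeroed_others_kept_for_tiny_radius(self):
        h = w = 32
        vals = np.ones((h, w), dtype=complex)
        out = circular_highpass(Spectrum(vals, (h, w)), 1e-9)
        assert out.values[h // 2, w // 2] == 0.0
        assert int(np.sum(out.values == 0)) == 1

    def test_idempotent(self, rng):
        vals = rng.normal(size=(24, 24)) + 1j * rng.normal(size=(24, 24))
        once = circular_highpass(Spectrum(vals, (24, 24)), 0.2)
        twice = circular_highpass(once, 0.2)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_energy_never_increases(self, rng):
        vals = rng.normal(size=(24, 24)) + 1j * rng.normal(size=(24, 24))
        out = circular_highpass(Spectrum(vals, (24, 24)), 0.15)
        assert np.sum(np.abs(out.values) ** 2) <= np.sum(np.abs(vals) ** 2)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 2.0])
    def test_radius_validation(self, bad):
        with pytest.raises(ParameterError):
            circular_highpass(Spectrum(np.ones((8, 8), dtype=complex), (8, 8)), bad)


class TestInverseReconstruct:
    def test_roundtrip(self, rng):
        arr = rng.random((32, 32))
        field = inverse_reconstruct(forward_spectrum(gray(arr)))
        assert np.abs(field - arr).max() < 1e-8

    def test_linearity(self, rng):
        s1 = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        s2 = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        lhs = inverse_reconstruct(Spectrum(2.0 * s1 + 3.0 * s2, (16, 16)))
        rhs = (2.0 * inverse_reconstruct(Spectrum(s1, (16, 16)))
               + 3.0 * inverse_reconstruct(Spectrum(s2, (16, 16))))
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_zero_spectrum(self):
        field = inverse_reconstruct(Spectrum(np.zeros((8, 8), dtype=complex), (8, 8)))
        assert np.abs(field).max() == 0.0


class TestAmplitudeScales:
    def test_zero_field_zero_amplitude(self):
        out = phase_current_amplitude(np.zeros((8, 8), dtype=complex))
        assert out.amplitude.max() == 0.0

    def test_minmax_scale_invariance(self, rng):
        field = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        a1 = phase_current_amplitude(field).amplitude
        a2 = phase_current_amplitude(2.0 * field).amplitude
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_amplitude_bounds(self, rng):
        field = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        amp = phase_current_amplitude(field).amplitude
        assert amp.min() >= 0.0 and amp.max() <= 255.0

    def test_reference_scale_needs_gain(self, rng):
        field = rng.normal(size=(8, 8)).astype(complex)
        with pytest.raises(ParameterError):
            phase_current_amplitude(field, scale="reference")

    def test_reference_calibration_target_maps_to_255(self):
        from holoseg.osh import _calibration_target
        gain = reference_gain((64, 64))
        img = gray(_calibration_target((64, 64)))
        out = phase_current_map(
            img, OSHParams(scale="reference", amplitude_sigma=0.0), gain=gain)
        assert out.amplitude.max() == pytest.approx(255.0, abs=1e-6)


class TestBackgroundSubtraction:
    def test_self_subtraction_zero(self, rng):
        field = rng.normal(size=(8, 8)).astype(complex)
        m = phase_current_amplitude(field)
        out = subtract_background(m, m)
        assert out.amplitude.max() == 0.0

    def test_zero_reference_identity(self, rng):
        field = rng.normal(size=(8, 8)).astype(complex)
        m = phase_current_amplitude(field)
        ref = phase_current_amplitude(np.zeros((8, 8), dtype=complex))
        np.testing.assert_array_equal(subtract_background(m, ref).amplitude,
                                      m.amplitude)

    def test_clipping_at_zero(self):
        m = phase_current_amplitude(np.full((8, 8), 100.0, dtype=complex),
                                    scale="reference", gain=1.0)
        ref = phase_current_amplitude(np.full((8, 8), 130.0, dtype=complex),
                                      scale="reference", gain=1.0)
        assert subtract_background(m, ref).amplitude.max() == 0.0

    def test_shape_mismatch(self, rng):
        a = phase_current_amplitude(rng.normal(size=(8, 8)).astype(complex))
        b = phase_current_amplitude(rng.normal(size=(16, 16)).astype(complex))
        with pytest.raises(ParameterError):
            subtract_background(a, b)


class TestFullChain:
    def test_deterministic(self, rng):
        arr = rng.random((64, 64))
        params = OSHParams(scale="minmax255")
        m1 = phase_current_map(gray(arr), params)
        m2 = phase_current_map(gray(arr), params)
        np.testing.assert_array_equal(m1.amplitude, m2.amplitude)
        np.testing.assert_array_equal(m1.field, m2.field)

    def test_bright_disk_peak_lands_inside_disk(self, rng):
        # edge enhancement concentrates energy at the object
        params = OSHParams(scale="minmax255")
        hits = 0
        for _ in range(20):
            arr = np.full((96, 96), 0.1)
            cy, cx = rng.integers(25, 71, size=2)
            yy, xx = np.ogrid[:96, :96]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 12 ** 2
            arr[disk] = 0.9
            m = phase_current_map(gray(arr), params)
            peak = np.unravel_index(np.argmax(m.amplitude), m.amplitude.shape)
            hits += bool(disk[peak])
        assert hits == 20

    def test_line_scan_mode_shape_and_determinism(self, rng):
        arr = rng.random((32, 32))
        params = OSHParams(scale="minmax255", line_scan=True)
        m1 = phase_current_map(gray(arr), params)
        m2 = phase_current_map(gray(arr), params)
        assert m1.amplitude.shape == (32, 32)
        np.testing.assert_array_equal(m1.amplitude, m2.amplitude)

    def test_radius_frac_band_enforced(self):
        with pytest.raises(ParameterError):
            OSHParams(filter_radius_frac=0.3)
        OSHParams(filter_radius_frac=0.3, allow_out_of_band=True)


class TestFZP:
    def test_delta_input_reproduces_kernel(self):
        arr = np.zeros((33, 33))
        arr[16, 16] = 1.0
        params = OSHParams(mode="fzp", k0=0.1, z=1.0, allow_out_of_band=True)
        holo = fzp_hologram(gray(arr), params)
        ksin, kcos = fzp_kernels((33, 33), 0.1, 1.0)
        np.testing.assert_allclose(holo.h_sin, ksin, atol=1e-10)
        np.testing.assert_allclose(holo.h_cos, kcos, atol=1e-10)

    def test_complex_composition_exact(self, rng):
        params = OSHParams(mode="fzp", k0=0.1, z=1.0)
        holo = fzp_hologram(gray(rng.random((16, 16))), params)
        np.testing.assert_array_equal(holo.h_complex,
                                      holo.h_cos + 1j * holo.h_sin)

    def test_linearity(self, rng):
        params = OSHParams(mode="fzp", k0=0.1, z=1.0)
        a = rng.random((16, 16)) * 0.5
        b = rng.random((16, 16)) * 0.5
        hab = fzp_hologram(gray(np.clip(a + b, 0, 1)), params)
        ha = fzp_hologram(gray(a), params)
        hb = fzp_hologram(gray(b), params)
        np.testing.assert_allclose(hab.h_sin, ha.h_sin + hb.h_sin, atol=1e-8)

    def test_fzp_mode_parameter_validation(self):
        with pytest.raises(ParameterError):
            OSHParams(mode="fzp", k0=-1.0)
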