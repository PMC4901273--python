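"""Forward-model geometry, pupil, sub-spectrum windows, dense oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fpmrecon as fp


# ---------------------------------------------------------------------------
# Illumination geometry
# ---------------------------------------------------------------------------


class TestLEDWavevectors:
    def test_on_axis_led_gives_zero_frequency(self):
        geom = fp.LEDGeometry(rows=1, cols=1, pitch_mm=4.0, height_mm=80.0)
        optics = fp.paper_scale_optics()
        wv = fp.led_wavevectors(geom, optics)
        assert wv.shape == (1, 2)
        np.testing.assert_allclose(wv, 0.0, atol=1e-15)

    def test_standard_15x15_grid(self):
        """15x15 grid, 4 mm pitch, 84.8 mm height: 225 wavevectors whose
        largest direction sine is 28*sqrt(2)/sqrt((28*sqrt(2))^2 + 84.8^2)."""
        geom = fp.paper_scale_geometry()
        optics = fp.paper_scale_optics()
        wv = fp.led_wavevectors(geom, optics)
        assert len(wv) == 225
        corner = 28.0 * np.sqrt(2.0)
        expected = corner / np.hypot(corner, 84.8)  # 0.42310...
        got = np.max(np.hypot(wv[:, 0], wv[:, 1])) * optics.wavelength_um
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        np.testing.assert_allclose(got, 0.4231, atol=5e-5)

    def test_sign_convention_led_at_plus_x(self):
        geom = fp.LEDGeometry(rows=1, cols=2, pitch_mm=8.0, height_mm=80.0,
                              center_offset_mm=(4.0, 0.0))
        optics = fp.paper_scale_optics()
        wv = fp.led_wavevectors(geom, optics)
        # second LED sits at +x offset: its fx must be negative
        assert wv[1, 0] < 0
        assert wv[1, 1] == pytest.approx(0.0, abs=1e-15)

    def test_rejects_nonpositive_height(self):
        with pytest.raises(ValueError):
            fp.LEDGeometry(rows=3, cols=3, pitch_mm=4.0, height_mm=0.0)


class TestSyntheticNA:
    def test_single_on_axis_led_adds_nothing(self):
        geom = fp.LEDGeometry(rows=1, cols=1, pitch_mm=1.0, height_mm=50.0)
        optics = fp.paper_scale_optics()
        assert fp.synthetic_na(geom, optics) == pytest.approx(0.08)

    def test_simulated_setup_is_about_half(self):
        na = fp.synthetic_na(fp.paper_scale_geometry(), fp.paper_scale_optics())
        assert na == pytest.approx(0.503, abs=2e-3)
        assert round(na, 1) == 0.5

    def test_combined_na_from_parts(self):
        assert fp.combined_na(0.325, 0.1) == pytest.approx(0.425)


# ---------------------------------------------------------------------------
# Pupil
# ---------------------------------------------------------------------------


class TestPupilMask:
    def test_huge_radius_covers_grid(self):
        optics = fp.OpticalConfig(0.9, 0.5, 4.0, 16, 16)
        with pytest.warns(UserWarning, match="no low-pass"):
            pupil = fp.pupil_mask(optics)
        assert pupil.radius_px >= 16 * np.sqrt(2) / 2
        assert pupil.mask.all()

    def test_tiny_radius_keeps_origin_only(self):
        # radius just below 1 px: inclusive boundary leaves only the DC pixel
        optics = fp.OpticalConfig(0.007, 0.5, 4.0, 16, 16)
        with pytest.warns(UserWarning, match="degenerate"):
            pupil = fp.pupil_mask(optics)
        assert pupil.radius_px < 1
        assert pupil.mask.sum() == 1
        assert pupil.mask[8, 8]

    def test_pixel_count_matches_lattice_enumeration(self):
        # 16x16 grid, radius 5.3 px: brute-force count of lattice points
        optics = fp.OpticalConfig(0.04140625, 0.5, 4.0, 32, 16)
        pupil = fp.pupil_mask(optics)
        assert pupil.radius_px == pytest.approx(5.3)
        count = sum(
            1
            for iy in range(16)
            for ix in range(16)
            if (iy - 8) ** 2 + (ix - 8) ** 2 <= 5.3**2
        )
        assert pupil.mask.sum() == count

    def test_rotation_symmetry_about_origin(self):
        optics = fp.OpticalConfig(0.05, 0.5, 4.0, 32, 16)  # radius 6.4 px
        mask = fp.pupil_mask(optics).mask
        inner = mask[1:, 1:]
        np.testing.assert_array_equal(inner, inner[::-1, ::-1])

    @settings(max_examples=20, derandomize=True)
    @given(
        na_small=st.floats(0.05, 0.4),
        extra=st.floats(0.01, 0.3),
    )
    def test_monotone_in_na(self, na_small, extra):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # huge/tiny pupils expected
            small = fp.pupil_mask(fp.OpticalConfig(na_small, 0.5, 4.0, 32, 16)).mask
            large = fp.pupil_mask(fp.OpticalConfig(na_small + extra, 0.5, 4.0, 32, 16)).mask
        assert (large | small == large).all()  # superset


# ---------------------------------------------------------------------------
# Sub-spectrum extract / embed
# ---------------------------------------------------------------------------


class TestExtractEmbed:
    def test_zero_shift_allones_pupil_is_central_block(self, toy_optics):
        pupil = fp.Pupil(radius_px=99.0, mask=np.ones((4, 4), dtype=bool))
        spectrum = np.arange(64, dtype=complex).reshape(8, 8)
        sub = fp.extract_subspectrum(spectrum, np.array([0.0, 0.0]), pupil, toy_optics)
        np.testing.assert_array_equal(sub, spectrum[2:6, 2:6])

    def test_shifted_window_by_hand_indexing(self, toy_optics):
        """+1 frequency-pixel shift in x: window slides one column right."""
        pupil = fp.Pupil(radius_px=99.0, mask=np.ones((4, 4), dtype=bool))
        spectrum = (np.arange(1, 65, dtype=float) + 0j).reshape(8, 8)
        wv = np.array([toy_optics.delta_f, 0.0])
        sub = fp.extract_subspectrum(spectrum, wv, pupil, toy_optics)
        np.testing.assert_array_equal(sub, spectrum[2:6, 3:7])

    def test_delta_outside_window_gives_zeros(self, toy_optics, toy_pupil):
        spectrum = np.zeros((8, 8), dtype=complex)
        spectrum[4, 4] = 1.0  # DC
        wv = np.array([-2.0, 2.0]) * toy_optics.delta_f
        sub = fp.extract_subspectrum(spectrum, wv, toy_pupil, toy_optics)
        # shifted window center is 2px away; pupil radius 1.5 excludes DC
        assert np.all(sub == 0)

    def test_out_of_bounds_window_is_an_error(self, toy_optics, toy_pupil):
        spectrum = np.ones((8, 8), dtype=complex)
        wv = np.array([3.0, 0.0]) * toy_optics.delta_f
        with pytest.raises(fp.WindowOutOfBoundsError):
            fp.extract_subspectrum(spectrum, wv, toy_pupil, toy_optics)
        with pytest.raises(fp.WindowOutOfBoundsError):
            fp.embed_subspectrum(np.ones((4, 4)), wv, toy_pupil, toy_optics)

    def test_embed_of_extract_restricts_to_window(self, toy_optics):
        pupil = fp.Pupil(radius_px=99.0, mask=np.ones((4, 4), dtype=bool))
        rng = np.random.default_rng(3)
        spectrum = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        wv = np.array([0.0, 0.0])
        out = fp.embed_subspectrum(
            fp.extract_subspectrum(spectrum, wv, pupil, toy_optics), wv, pupil, toy_optics
        )
        expected = np.zeros_like(spectrum)
        expected[2:6, 2:6] = spectrum[2:6, 2:6]
        np.testing.assert_array_equal(out, expected)

    def test_zero_in_zero_out(self, toy_optics, toy_pupil):
        out = fp.embed_subspectrum(
            np.zeros((4, 4)), np.array([1.0, -1.0]) * toy_optics.delta_f, toy_pupil, toy_optics
        )
        assert np.all(out == 0)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), shift_x=st.integers(-2, 2), shift_y=st.integers(-2, 2))
    def test_extract_embed_adjoint_identity(self, toy_optics, toy_pupil, seed, shift_x, shift_y):
        """<extract(S), w> == <S, embed(w)> for random fields and shifts."""
        rng = np.random.default_rng(seed)
        s = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        w = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        wv = np.array([shift_x, shift_y]) * toy_optics.delta_f
        lhs = np.vdot(w, fp.extract_subspectrum(s, wv, toy_pupil, toy_optics))
        rhs = np.vdot(fp.embed_subspectrum(w, wv, toy_pupil, toy_optics), s)
        assert abs(lhs - rhs) <= 1e-12 * (np.linalg.norm(s) * np.linalg.norm(w))


# ---------------------------------------------------------------------------
# Forward model and dense oracle
# ---------------------------------------------------------------------------


class TestForwardModel:
    def test_unit_object_gives_unit_brightfield(self):
        optics = fp.default_optics()
        pupil = fp.pupil_mask(optics)
        spectrum = fp.fft2c(np.ones((optics.n_hr, optics.n_hr), dtype=complex))
        stack = fp.forward_capture(spectrum, np.array([[0.0, 0.0]]), pupil, optics)
        np.testing.assert_allclose(stack.images[0], 1.0, atol=1e-12)

    def test_matches_dense_operator(self, toy_spectrum, toy_wavevectors, toy_pupil, toy_optics):
        a = fp.dense_operator(toy_wavevectors, toy_pupil, toy_optics)
        assert a.shape == (len(toy_wavevectors) * 16, 64)
        dense = np.abs(a @ toy_spectrum.ravel()) ** 2
        fft = fp.forward_capture(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics)
        np.testing.assert_allclose(fft.images.ravel(), dense, atol=1e-10)

    def test_dense_operator_refuses_large_grids(self):
        optics = fp.OpticalConfig(0.3, 0.8, 1.0, 32, 8)
        with pytest.raises(ValueError, match="toy"):
            fp.dense_operator(np.array([[0.0, 0.0]]), fp.pupil_mask(optics), optics)

    def test_dense_single_capture_is_scaled_synthesis_matrix(self):
        """2x2 grids, all-ones pupil, zero shift: A is the centered inverse
        DFT (checked against numpy's FFT applied to basis spectra)."""
        optics = fp.OpticalConfig(0.5, 0.8, 1.0, 2, 2)
        pupil = fp.Pupil(radius_px=9.0, mask=np.ones((2, 2), dtype=bool))
        a = fp.dense_operator(np.array([[0.0, 0.0]]), pupil, optics)
        for k in range(4):
            e = np.zeros(4, dtype=complex)
            e[k] = 1.0
            np.testing.assert_allclose(
                a @ e, fp.ifft2c(e.reshape(2, 2)).ravel(), atol=1e-12
            )

    def test_global_phase_invariance_of_captures(
        self, toy_spectrum, toy_wavevectors, toy_pupil, toy_optics
    ):
        base = fp.forward_capture(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics)
        rot = fp.forward_capture(
            toy_spectrum * np.exp(1j * 0.77), toy_wavevectors, toy_pupil, toy_optics
        )
        np.testing.assert_allclose(base.images, rot.images, atol=1e-12)

    def test_parseval_energy_per_capture(
        self, toy_spectrum, toy_wavevectors, toy_pupil, toy_optics
    ):
        stack = fp.forward_capture(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics)
        s2 = toy_optics.amplitude_scale**2
        for i, wv in enumerate(toy_wavevectors):
            sub = fp.extract_subspectrum(toy_spectrum, wv, toy_pupil, toy_optics)
            assert stack.images[i].sum() == pytest.approx(s2 * np.linalg.norm(sub) ** 2)

    @settings(max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_operator_adjoint_identity(
        self, toy_wavevectors, toy_pupil, toy_optics, seed
    ):
        """|<Az, w> - <z, A^H w>| <= 1e-10 ||z|| ||w|| on random toys."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        w = rng.standard_normal((5, 4, 4)) + 1j * rng.standard_normal((5, 4, 4))
        plan = fp.OperatorPlan(toy_wavevectors, toy_pupil, toy_optics)
        lhs = np.vdot(w, plan.fields(z))
        rhs = np.vdot(plan.adjoint(w), z)
        assert abs(lhs - rhs) <= 1e-10 * np.linalg.norm(z) * np.linalg.norm(w)

    def test_energy_equality_with_dense_rows(
        self, toy_spectrum, toy_wavevectors, toy_pupil, toy_optics
    ):
        a = fp.dense_operator(toy_wavevectors, toy_pupil, toy_optics)
        fields = fp.forward_fields(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics)
        assert np.linalg.norm(a @ toy_spectrum.ravel()) ** 2 == pytest.approx(
            np.linalg.norm(fields) ** 2, abs=1e-10
        )

    def test_operator_norm_is_scaled_max_coverage(
        self, toy_wavevectors, toy_pupil, toy_optics
    ):
        plan = fp.OperatorPlan(toy_wavevectors, toy_pupil, toy_optics)
        a = fp.dense_operator(toy_wavevectors, toy_pupil, toy_optics)
        gram_eigs = np.linalg.eigvalsh(a.conj().T @ a)
        assert plan.operator_norm_sq() == pytest.approx(gram_eigs.max(), abs=1e-12)


class TestOpticalConfig:
    def test_requires_integral_ratio(self):
        with pytest.raises(ValueError, match="multiple"):
            fp.OpticalConfig(0.1, 0.6, 2.0, 60, 16)

    def test_frequency_pitch_consistent_between_grids(self):
        optics = fp.default_optics()
        hr_pitch = 1.0 / (optics.n_hr * optics.pixel_size_hr_um)
        assert optics.delta_f == pytest.approx(hr_pitch)
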