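import numpy as np
import pytest

from abpspectra import (
    build_decay_operator,
    diagonalize,
    highq_characteristic,
    highq_fourier_coefficients,
    lowq_characteristic,
    lowq_mode_projection,
    slowest_mode,
    toeplitz_limit,
)


class TestLowQCharacteristic:
    def test_ground_mode_substitution(self):
        assert lowq_characteristic(0, 0.1) == pytest.approx(0.00125)

    @pytest.mark.parametrize("r, q", [(0, 0.05), (1, 0.1), (2, 0.1), (3, 0.2)])
    def test_series_matches_diagonalization(self, r, q):
        w = np.sort(diagonalize(build_decay_operator(q, 40)).eigenvalues.real)
        assert lowq_characteristic(r, q) == pytest.approx(w[r], abs=q**4)

    def test_residual_is_fourth_order(self, slowest):
        """|lambda0(q) - q^2/8| shrinks ~16x per halving of q."""
        res = []
        for q in (0.04, 0.02, 0.01):
            lam, _ = slowest(q, 50)
            res.append(abs(lam.real - lowq_characteristic(0, q)))
        assert res[0] / res[1] == pytest.approx(16.0, rel=0.1)
        assert res[1] / res[2] == pytest.approx(16.0, rel=0.1)


class TestLowQModeProjection:
    def test_polar_overlap_is_linear_with_sqrt2_over_4(self, slowest):
        q = 0.01
        pred = lowq_mode_projection(0, q)
        _, mags = slowest(q, 50)
        assert pred["c1"] == pytest.approx(np.sqrt(2) / 4 * q)
        assert mags[1] == pytest.approx(pred["c1"], rel=1e-3)

    def test_nematic_overlap_is_second_order(self, slowest):
        q = 0.01
        pred = lowq_mode_projection(0, q)
        _, mags = slowest(q, 50)
        assert pred["c2"] == pytest.approx(np.sqrt(2) / 64 * q * q)
        assert mags[2] == pytest.approx(pred["c2"], rel=1e-2)

    def test_first_order_vector_is_normalized(self):
        v = lowq_mode_projection(2, 0.05)["vector"]
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_warns_outside_series_range(self):
        with pytest.warns(UserWarning):
            lowq_mode_projection(0, 0.5)


class TestToeplitzLimit:
    def test_two_mode_advection_eigenvalues(self):
        out = toeplitz_limit(1, 3.0)
        assert np.allclose(sorted(out["eigenvalues"].imag), [-1.5, 1.5])
        assert np.allclose(out["re_correction"], 0.5)

    def test_zeroth_order_exact_on_advection_matrix(self):
        Q, q = 7, 5.0
        A = build_decay_operator(q, Q, fold="printed").matrix
        np.fill_diagonal(A, 0.0)
        out = toeplitz_limit(Q, q)
        got = np.sort(np.linalg.eigvals(A).imag)
        assert np.allclose(got, np.sort(out["eigenvalues"].imag), atol=1e-10)

    def test_first_order_matches_full_diagonalization(self):
        Q, q = 6, 1e4
        pred = np.sort(toeplitz_limit(Q, q)["re_correction"])
        full = np.sort(diagonalize(build_decay_operator(q, Q, fold="printed")).eigenvalues.real)
        assert np.all(np.abs(full - pred) / pred <= 0.01)


class TestHighQCharacteristic:
    def test_ground_mode_against_diagonalization(self, slowest):
        lam, _ = slowest(100.0, 200)
        a = highq_characteristic(0, 100.0)
        assert a.real / 4 == pytest.approx(lam.real, rel=0.02)
        assert abs(a.imag) / 4 == pytest.approx(abs(lam.imag), rel=0.02)

    def test_sqrt_q_scaling(self):
        qs = np.logspace(3, 5, 5)
        re = np.array([highq_characteristic(0, q).real for q in qs])
        slope = np.polyfit(np.log(qs), np.log(re), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.01)

    def test_mode_ratio_approaches_odd_integers(self):
        q = 1e4
        r = highq_characteristic(1, q).real / highq_characteristic(0, q).real
        assert r == pytest.approx(3.0, rel=0.01)

    @pytest.mark.parametrize("r", [0, 1, 2, 3])
    def test_excited_pairs_match_even_sector_mathieu_modes(self, r):
        """The operator's r-th conjugate pair is the 2r-th Mathieu mode
        (the even pi-periodic sector keeps every other index, s = 4r+1);
        Re and Im both match within 2% at q = 100 s^2, Q=400."""
        m = 2 * r
        q = 100.0 * (2 * m + 1) ** 2
        w = diagonalize(build_decay_operator(q, 400)).eigenvalues
        lam = w[2 * r]
        a = highq_characteristic(m, q)
        assert a.real / 4 == pytest.approx(lam.real, rel=0.02)
        assert abs(a.imag) / 4 == pytest.approx(abs(lam.imag), rel=0.02)


class TestHighQFourierCoefficients:
    def test_sixteen_fold_activity_ratio(self):
        ratio = highq_fourier_coefficients(2, 16e3) / highq_fourier_coefficients(2, 1e3)
        assert ratio == pytest.approx(16 ** (-1 / 8))

    def test_leading_harmonics_decay_as_minus_one_eighth(self, high_sweep):
        lq = np.log(high_sweep["q"])
        for l in (0, 1):
            slope = np.polyfit(lq, np.log(high_sweep[f"c{l}"]), 1)[0]
            assert slope == pytest.approx(-0.125, abs=0.03)

    @pytest.mark.parametrize("l", [2, 3])
    def test_higher_harmonics_approach_the_law_at_larger_activity(self, l):
        """The -1/8 law is asymptotic: each harmonic joins it once q is
        large enough, so the slope deviation shrinks as the window moves up."""
        from abpspectra.scaling import spectral_sweep, fit_loglog_slope

        devs = []
        for window in ((1e3, 1e4), (1e4, 1e5)):
            s = spectral_sweep(400, window, 10)
            devs.append(abs(fit_loglog_slope(s["q"], s[f"c{l}"]).slope + 0.125))
        assert devs[1] < devs[0]
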