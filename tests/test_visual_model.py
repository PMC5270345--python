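import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plumavis.spectra import GRID_5NM, ReflectanceSpectrum, downsample_5nm
from plumavis.visual_model import (
    achromatic_distance,
    build_visual_system,
    chromatic_distance,
    compute_receptor_noise,
    govardovskii_a1,
    noise_quadratic_form,
    quantum_catch,
    xyz_embed,
)


class TestReceptorNoise:
    def test_average_cone_proportions_give_printed_ratios(self):
        omega = compute_receptor_noise(0.05, (0.38, 0.69, 1.14, 1.0))
        assert np.allclose(omega, [0.0811, 0.0602, 0.0468, 0.05], atol=5e-5)
        assert omega[3] == 0.05

    def test_equal_proportions(self):
        assert np.allclose(compute_receptor_noise(0.1, (1, 1, 1, 1)), 0.1)

    def test_quarter_proportion_doubles_noise(self):
        assert np.allclose(compute_receptor_noise(0.05, (0.25, 1.0)), [0.1, 0.05])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_receptor_noise(0.0, (1, 1))
        with pytest.raises(ValueError):
            compute_receptor_noise(0.05, (1, -1))


class TestVisualSystem:
    def test_sensitivity_peaks_normalized_at_lambda_max(self, vs):
        for i, lm in enumerate(vs.lambda_max):
            s = vs.sensitivities[i]
            assert s.max() == pytest.approx(1.0)
            peak_wl = GRID_5NM[np.argmax(s)]
            assert abs(peak_wl - lm) <= 5.0
            assert np.all(s >= 0)

    def test_template_matches_direct_formula(self):
        # independent evaluation of the pigment template at lmax +/- 50 nm
        lmax = 535.0
        for wl in (lmax - 50.0, lmax + 50.0):
            x = lmax / wl
            a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
            alpha = 1.0 / (
                np.exp(69.7 * (a - x))
                + np.exp(28.0 * (0.922 - x))
                + np.exp(-14.9 * (1.104 - x))
                + 0.674
            )
            lam_b = 189.0 + 0.315 * lmax
            b = -40.5 + 0.195 * lmax
            beta = 0.26 * np.exp(-(((wl - lam_b) / b) ** 2))
            assert govardovskii_a1(np.array([wl]), lmax)[0] == pytest.approx(
                alpha + beta, rel=1e-12
            )

    def test_lambda_max_bounds(self):
        with pytest.raises(ValueError, match="lambda_max"):
            build_visual_system(lambda_max=(250, 480, 535, 565))


class TestQuantumCatch:
    def test_flat_white_gives_unit_catches(self, vs, flat_spectrum):
        c = quantum_catch(flat_spectrum(100.0), vs)
        assert np.allclose(c.q, 1.0)
        assert np.allclose(c.f, 0.0)
        assert c.q_d == pytest.approx(1.0)

    def test_linearity_flat_half(self, vs, flat_spectrum):
        c = quantum_catch(flat_spectrum(50.0), vs)
        assert np.allclose(c.q, 0.5)
        assert c.q_d == pytest.approx(0.5)

    def test_zero_reflectance_is_error(self, vs, flat_spectrum):
        with pytest.raises(ValueError, match="zero catch"):
            quantum_catch(flat_spectrum(0.0), vs)

    def test_gaussian_vs_fine_grid_oracle(self, vs):
        # 1-nm trapezoid integration of the same templates as oracle
        wl1 = np.arange(300.0, 701.0)
        refl1 = 60.0 * np.exp(-((wl1 - 400.0) ** 2) / (2 * 50.0**2))
        from plumavis.illuminants import _D65_SPD
        from plumavis.visual_model import DEFAULT_LAMBDA_MAX

        illum1 = np.interp(wl1, GRID_5NM, _D65_SPD) * wl1
        q_oracle = []
        for lm in DEFAULT_LAMBDA_MAX:
            sens5 = govardovskii_a1(GRID_5NM, lm)
            sens1 = govardovskii_a1(wl1, lm) / sens5.max()
            num = np.trapezoid(sens1 * illum1 * refl1 / 100.0, wl1)
            den = np.trapezoid(sens1 * illum1, wl1)
            q_oracle.append(num / den)
        s5 = downsample_5nm(ReflectanceSpectrum(wl1, refl1))
        c = quantum_catch(s5, vs)
        assert np.allclose(c.q, q_oracle, rtol=0.01)


class TestChromaticDistance:
    def _catch_pair(self, vs, rng, seed=0):
        r = np.random.default_rng(seed)
        a = quantum_catch(
            ReflectanceSpectrum(GRID_5NM.copy(), r.uniform(5, 90, 81)), vs
        )
        b = quantum_catch(
            ReflectanceSpectrum(GRID_5NM.copy(), r.uniform(5, 90, 81)), vs
        )
        return a, b

    def test_identity(self, vs, random_spectrum):
        a = quantum_catch(random_spectrum(1), vs)
        assert chromatic_distance(a, a) == 0.0

    def test_quadratic_form_oracle_single_cone_offset(self, vs):
        # direct evaluation of the published quadratic form
        w = vs.omega
        df = np.array([0.0, 0.0, 0.0, 0.3])
        num = (
            (w[0] * w[1]) ** 2 * (df[3] - df[2]) ** 2
            + (w[0] * w[2]) ** 2 * (df[3] - df[1]) ** 2
            + (w[0] * w[3]) ** 2 * (df[2] - df[1]) ** 2
            + (w[1] * w[2]) ** 2 * (df[3] - df[0]) ** 2
            + (w[1] * w[3]) ** 2 * (df[2] - df[0]) ** 2
            + (w[2] * w[3]) ** 2 * (df[1] - df[0]) ** 2
        )
        den = (
            (w[0] * w[1] * w[2]) ** 2
            + (w[0] * w[1] * w[3]) ** 2
            + (w[0] * w[2] * w[3]) ** 2
            + (w[1] * w[2] * w[3]) ** 2
        )
        expected = np.sqrt(num / den)
        M = noise_quadratic_form(w)
        assert np.sqrt(df @ M @ df) == pytest.approx(expected, rel=1e-12)

    def test_dichromat_closed_form_limit(self, vs):
        # equal df within cone pairs collapses to |dfx - dfy|/sqrt(wx^2 + wy^2)
        # using equal omegas so the pooled pair behaves as one mechanism
        w = np.full(4, 0.05)
        M = noise_quadratic_form(w)
        dfx, dfy = 0.7, 0.2
        df = np.array([dfx, dfx, dfy, dfy])
        # two pooled mechanisms with noise w/sqrt(2) each
        wx = wy = 0.05 / np.sqrt(2.0)
        expected = abs(dfx - dfy) / np.sqrt(wx**2 + wy**2)
        assert np.sqrt(df @ M @ df) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_nonnegativity(self, vs, random_spectrum):
        a = quantum_catch(random_spectrum(2), vs)
        b = quantum_catch(random_spectrum(3), vs)
        assert chromatic_distance(a, b) == pytest.approx(chromatic_distance(b, a))
        assert chromatic_distance(a, b) >= 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(delta=st.floats(0.01, 2.0), cone=st.integers(0, 3))
    def test_monotone_in_single_cone_offset(self, vs, delta, cone):
        M = noise_quadratic_form(vs.omega)
        d1 = np.zeros(4)
        d1[cone] = delta
        d2 = np.zeros(4)
        d2[cone] = delta + 0.1
        assert np.sqrt(d2 @ M @ d2) > np.sqrt(d1 @ M @ d1)

    def test_common_offset_invariance(self, vs):
        M = noise_quadratic_form(vs.omega)
        df = np.array([0.1, -0.2, 0.3, 0.05])
        assert df @ M @ df == pytest.approx((df + 5.0) @ M @ (df + 5.0))


class TestAchromatic:
    def test_equal_catches_zero(self, vs, random_spectrum):
        a = quantum_catch(random_spectrum(4), vs)
        assert achromatic_distance(a, a) == 0.0

    def test_ratio_e_gives_twenty_jnd(self, vs, flat_spectrum):
        a = quantum_catch(flat_spectrum(np.e * 30.0), vs)
        b = quantum_catch(flat_spectrum(30.0), vs)
        assert achromatic_distance(a, b, omega_d=0.05) == pytest.approx(20.0)

    def test_formula_oracle_random_pairs(self, vs, random_spectrum):
        for seed in range(5):
            a = quantum_catch(random_spectrum(10 + seed), vs)
            b = quantum_catch(random_spectrum(20 + seed), vs)
            expected = abs(np.log(a.q_d / b.q_d)) / vs.omega_d
            assert achromatic_distance(a, b) == pytest.approx(expected, rel=1e-12)


class TestEmbedding:
    def test_identical_catches_identical_coordinates(self, vs, random_spectrum):
        a = quantum_catch(random_spectrum(5), vs)
        assert np.allclose(xyz_embed(a), xyz_embed(a))

    def test_euclidean_metric_equals_receptor_noise_distance(self, vs):
        r = np.random.default_rng(42)
        for _ in range(100):
            a = quantum_catch(
                ReflectanceSpectrum(GRID_5NM.copy(), r.uniform(2, 95, 81)), vs
            )
            b = quantum_catch(
                ReflectanceSpectrum(GRID_5NM.copy(), r.uniform(2, 95, 81)), vs
            )
            ds = chromatic_distance(a, b)
            dxyz = np.linalg.norm(xyz_embed(a) - xyz_embed(b))
            assert abs(ds - dxyz) < 1e-8

    def test_common_log_catch_offset_leaves_xyz_distance_unchanged(self, vs, flat_spectrum):
        # scaling reflectance scales all catches equally: same position shift
        a = quantum_catch(flat_spectrum(20.0), vs)
        b = quantum_catch(flat_spectrum(60.0), vs)
        assert np.linalg.norm(xyz_embed(a) - xyz_embed(b)) == pytest.approx(0.0, abs=1e-10)


class TestIlluminantInvariance:
    def test_scaled_illuminant_leaves_catches_and_jnds_unchanged(self, random_spectrum):
        from plumavis.illuminants import d65_quanta

        vs1 = build_visual_system(illuminant=d65_quanta())
        vs2 = build_visual_system(illuminant=3.7 * d65_quanta())
        s1, s2 = random_spectrum(7), random_spectrum(8)
        a1, b1 = quantum_catch(s1, vs1), quantum_catch(s2, vs1)
        a2, b2 = quantum_catch(s1, vs2), quantum_catch(s2, vs2)
        assert np.allclose(a1.q, a2.q)
        assert chromatic_distance(a1, b1) == pytest.approx(
            chromatic_distance(a2, b2), rel=1e-12
        )
        assert achromatic_distance(a1, b1) == pytest.approx(
            achromatic_distance(a2, b2), rel=1e-12
        )
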