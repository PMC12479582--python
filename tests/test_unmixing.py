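"""LASSO solver against closed forms and a brute-force KKT oracle, plus the
image-analysis operators."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srpsim import (
    HyperspectralStack,
    SpectraMatrix,
    default_beta,
    lasso_solve,
    median_despeckle,
    pearson_fidelity,
    profile_resolution,
    ratio_map,
    unmix_stack,
)
from srpsim.unmixing import lasso_objective


def orthonormal_refs(n=16, k=3):
    """Orthonormal rows via QR of a fixed random matrix."""
    rng = np.random.default_rng(42)
    q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    wn = np.linspace(2800, 3000, n)
    return SpectraMatrix(q.T, [f"c{i}" for i in range(k)], wn)


def brute_force_lasso(d, S, beta):
    """Exhaustive sign-pattern QP oracle for the unit-norm-row LASSO.

    For each support/sign pattern solve the stationarity system
    S_A S_A^T c_A = S_A d - beta * sign_A and keep the feasible candidate
    with the lowest objective (checking every pattern makes feasibility
    checks unnecessary for the minimum, but they prune ties).
    """
    k = S.shape[0]
    best, best_obj = np.zeros(k), 0.5 * float(d @ d)
    for signs in itertools.product((-1, 0, 1), repeat=k):
        active = [i for i, s in enumerate(signs) if s]
        if not active:
            continue
        sa = np.array([signs[i] for i in active], float)
        Sa = S[active]
        try:
            ca = np.linalg.solve(Sa @ Sa.T, Sa @ d - beta * sa)
        except np.linalg.LinAlgError:
            continue
        if np.any(np.sign(ca) * sa < 0):
            continue
        c = np.zeros(k)
        c[np.array(active)] = ca
        obj = lasso_objective(d, S, c, beta, normalized=False)
        if obj < best_obj - 1e-15:
            best, best_obj = c, obj
    return best, best_obj


class TestLassoSolve:
    def test_beta_zero_orthonormal_is_least_squares(self):
        s = orthonormal_refs()
        rng = np.random.default_rng(0)
        d = rng.normal(size=16)
        c = lasso_solve(d, s, 0.0)
        np.testing.assert_allclose(c, s.spectra @ d, atol=1e-8)

    def test_orthonormal_soft_threshold_closed_form(self):
        s = orthonormal_refs()
        d = 1.0 * s.spectra[0] + 0.2 * s.spectra[1]
        c = lasso_solve(d, s, 0.3)
        np.testing.assert_allclose(c, [0.7, 0.0, 0.0], atol=1e-8)

    def test_zero_spectrum_zero_solution(self):
        s = orthonormal_refs()
        assert not lasso_solve(np.zeros(16), s, 0.5).any()

    def test_matches_brute_force_qp_oracle(self):
        """Random correlated 3-component problems: objective within 1e-6 of
        the exhaustive sign-pattern QP solution."""
        rng = np.random.default_rng(123)
        for trial in range(20):
            S = rng.normal(size=(3, 12))
            S /= np.linalg.norm(S, axis=1, keepdims=True)
            d = rng.normal(size=12)
            beta = float(rng.uniform(0.05, 0.8))
            c = lasso_solve(d, S, beta)
            obj = lasso_objective(d, S, c, beta)
            _, obj_oracle = brute_force_lasso(d, S, beta)
            assert obj == pytest.approx(obj_oracle, abs=1e-6)

    def test_matches_sklearn_reference(self):
        """Independent library cross-check on a correlated design."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(5)
        S = rng.normal(size=(4, 20))
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        d = rng.normal(size=20)
        beta = 0.25
        c = lasso_solve(d, S, beta)
        ref = Lasso(alpha=beta / 20, fit_intercept=False, tol=1e-12,
                    max_iter=100_000).fit(S.T, d)
        np.testing.assert_allclose(c, ref.coef_, atol=1e-6)

    @given(beta=st.floats(0.0, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_support_shrinks_with_beta_on_orthonormal_design(self, beta):
        s = orthonormal_refs()
        d = 1.5 * s.spectra[0] + 0.8 * s.spectra[1] - 0.3 * s.spectra[2]
        c = lasso_solve(d, s, beta)
        # orthonormal closed form: per-coefficient soft threshold
        expected = [math.copysign(max(abs(z) - beta, 0.0), z)
                    for z in (1.5, 0.8, -0.3)]
        np.testing.assert_allclose(c, expected, atol=1e-7)

    def test_nonnegative_mode(self):
        s = orthonormal_refs()
        d = 1.0 * s.spectra[0] - 0.5 * s.spectra[1]
        c = lasso_solve(d, s, 0.1, nonnegative=True)
        assert np.all(c >= 0)
        np.testing.assert_allclose(c, [0.9, 0.0, 0.0], atol=1e-8)

    def test_dimension_mismatch_and_negative_beta(self):
        s = orthonormal_refs()
        with pytest.raises(ValueError):
            lasso_solve(np.zeros(7), s, 0.1)
        with pytest.raises(ValueError):
            lasso_solve(np.zeros(16), s, -0.1)


class TestUnmixStack:
    def test_zero_stack_zero_maps(self, references, wavenumbers):
        stack = HyperspectralStack(
            np.zeros((4, 5, wavenumbers.size)), wavenumbers)
        cm = unmix_stack(stack, references, 0.1)
        assert not cm.maps.any()

    def test_single_pixel_equals_lasso_solve(self, references, wavenumbers):
        rng = np.random.default_rng(3)
        d = np.abs(rng.normal(size=wavenumbers.size))
        stack = HyperspectralStack(d[None, None, :], wavenumbers)
        cm = unmix_stack(stack, references, 0.2)
        np.testing.assert_array_equal(
            cm.maps[:, 0, 0], lasso_solve(d, references, 0.2))

    def test_noiseless_phantom_recovery(self, references, phantom):
        truth, stack = phantom
        cm = unmix_stack(stack, references, 1e-6)
        for k in range(truth.maps.shape[0]):
            r = np.corrcoef(cm.maps[k].ravel(), truth.maps[k].ravel())[0, 1]
            assert r >= 0.99

    def test_permutation_equivariance(self, references, phantom):
        _, stack = phantom
        perm = [2, 0, 3, 1]
        s_perm = SpectraMatrix(references.spectra[perm],
                               [references.names[i] for i in perm],
                               references.wavenumbers)
        cm = unmix_stack(stack, references, 0.05)
        cm_perm = unmix_stack(stack, s_perm, 0.05)
        # agreement is limited by the coordinate-descent tolerance, not
        # exact permutation of a shared solve
        np.testing.assert_allclose(cm_perm.maps, cm.maps[perm], atol=1e-6)

    def test_disjoint_axis_rejected(self, references, wavenumbers):
        stack = HyperspectralStack(
            np.ones((2, 2, wavenumbers.size)), wavenumbers)
        s_off = SpectraMatrix(references.spectra, references.names,
                              references.wavenumbers + 400.0)
        with pytest.raises(ValueError, match="80%"):
            unmix_stack(stack, s_off, 0.1)

    def test_support_recovery_on_noisy_phantom(self, references, phantom):
        """At pixel SNR ~20 the default beta heuristic recovers the active
        set with F1 >= 0.9."""
        from srpsim import PhantomTruth, make_phantom_stack

        truth, clean = phantom
        signal_rms = float(np.sqrt(np.mean(clean.data**2)))
        noisy = make_phantom_stack(
            PhantomTruth(truth.maps, list(truth.names),
                         noise_sigma=signal_rms / 20, seed=99),
            references)
        cm = unmix_stack(noisy, references,
                         default_beta(noisy.data, references))
        # estimated support: exact LASSO nonzeros; true support: pixels
        # above 5% of each component's peak (the smooth maps never reach 0)
        est = np.abs(cm.maps) > 0
        tru = truth.maps > 0.05 * truth.maps.max(axis=(1, 2), keepdims=True)
        true_pos = (est & tru).sum()
        prec = true_pos / max(est.sum(), 1)
        rec = true_pos / tru.sum()
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 >= 0.9


class TestPearsonFidelity:
    def test_reference_cases(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pearson_fidelity(a, a) == pytest.approx(1.0)
        assert pearson_fidelity(a, -a) == pytest.approx(-1.0)
        assert pearson_fidelity(a, np.array([1.0, 3.0, 2.0])) == \
            pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_fidelity(np.ones(5), np.arange(5.0))


class TestRatioMap:
    def test_identical_images_unity(self):
        img = np.full((4, 4), 3.0)
        out = ratio_map(img, img, floor=0.1)
        assert np.allclose(out.filled(0), 1.0)
        assert not out.mask.any()

    def test_pixel_arithmetic_and_floor_mask(self):
        a = np.array([[2.0, 1.0]])
        b = np.array([[4.0, 1e-6]])
        out = ratio_map(a, b, floor=0.01)
        assert out[0, 0] == pytest.approx(0.5)
        assert out.mask[0, 1]
        assert np.isfinite(out.filled(0)).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ratio_map(np.ones((2, 2)), np.ones((3, 3)), 0.1)


class TestMedianDespeckle:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 2.5)
        np.testing.assert_array_equal(median_despeckle(img, 3), img)

    def test_impulse_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert not median_despeckle(img, 3).any()

    def test_fringe_amplitude_suppressed(self):
        """A sinusoidal fringe with period <= window loses >= 80% of its
        FFT peak amplitude."""
        n, period = 64, 3
        x = np.arange(n)
        img = 1.0 + 0.2 * np.sin(2 * np.pi * x / period)[None, :] \
            * np.ones((n, 1))
        out = median_despeckle(img, 3)
        k = round(n / period)
        amp_in = abs(np.fft.fft(img[0])[k]) / n
        amp_out = abs(np.fft.fft(out[0])[k]) / n
        assert amp_out <= 0.2 * amp_in

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_despeckle(np.ones((4, 4)), 4)


class TestProfileResolution:
    def test_exact_gaussian_closed_form(self):
        x = np.linspace(-6, 6, 401)
        prof = np.exp(-0.5 * x**2)
        res = profile_resolution(prof, spacing=x[1] - x[0], bead_diameter=0.0)
        assert res.fwhm == pytest.approx(2.3548, rel=1e-3)
        assert res.resolution == res.fwhm
        assert not res.bead_limited

    def test_quadrature_bead_deconvolution(self):
        """FWHM 260 nm with a 100 nm bead deconvolves to 240 nm."""
        sigma = 260e-9 / (2 * math.sqrt(2 * math.log(2)))
        x = np.linspace(-1e-6, 1e-6, 801)
        prof = 0.1 + np.exp(-0.5 * (x / sigma) ** 2)
        res = profile_resolution(prof, spacing=x[1] - x[0],
                                 bead_diameter=100e-9)
        assert res.fwhm == pytest.approx(260e-9, rel=1e-3)
        assert res.resolution == pytest.approx(240.0e-9, rel=2e-3)

    def test_bead_limited_flagged(self):
        sigma = 50e-9 / 2.3548
        x = np.linspace(-0.5e-6, 0.5e-6, 801)
        prof = np.exp(-0.5 * (x / sigma) ** 2)
        res = profile_resolution(prof, spacing=x[1] - x[0],
                                 bead_diameter=100e-9)
        assert res.bead_limited
        assert res.resolution == res.fwhm

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_resolution(np.ones(32), 1e-8)
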