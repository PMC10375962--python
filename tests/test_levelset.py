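"""Level set primitives and evolution dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from unls.grid import ImageGrid, LabelMask, ProbabilityMap
from unls.levelset import (InitSpec, LevelSetField, LevelSetParams, curvature,
                           dirac_eps, energy, evolve_step, heaviside_eps,
                           init_phi, segment)

EPS = 1.5


def uniform_prior(shape):
    """A completely uninformative prior field (P_K = P_B = 0.5)."""
    return ProbabilityMap(np.full(shape, 0.5))


class TestHeavisideDirac:
    def test_branch_values(self):
        assert heaviside_eps(0.0, EPS) == pytest.approx(0.5, abs=1e-15)
        assert heaviside_eps(2.0, EPS) == 1.0
        assert heaviside_eps(-2.0, EPS) == 0.0
        assert dirac_eps(2.0, EPS) == 0.0
        assert dirac_eps(0.0, EPS) == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_continuity_at_band_edges(self):
        inner = 0.5 + EPS / (2 * EPS) + np.sin(np.pi) / (2 * np.pi)
        assert heaviside_eps(EPS, EPS) == pytest.approx(inner, abs=1e-12)
        assert heaviside_eps(EPS, EPS) == pytest.approx(1.0, abs=1e-12)
        assert heaviside_eps(-EPS, EPS) == pytest.approx(0.0, abs=1e-12)
        assert dirac_eps(EPS, EPS) == pytest.approx(0.0, abs=1e-12)

    def test_heaviside_nondecreasing(self):
        phi = np.linspace(-2 * EPS, 2 * EPS, 4001)
        # non-decreasing up to float rounding of the sin term
        assert np.all(np.diff(heaviside_eps(phi, EPS)) >= -1e-12)

    def test_dirac_even_and_maximal_at_zero(self):
        phi = np.linspace(-2 * EPS, 2 * EPS, 4001)
        d = dirac_eps(phi, EPS)
        assert np.allclose(d, d[::-1], atol=1e-15)
        assert d.max() == dirac_eps(0.0, EPS)

    def test_dirac_integrates_to_one(self):
        val, _ = quad(lambda p: dirac_eps(p, EPS), -EPS, EPS, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_dirac_is_derivative_of_heaviside(self):
        phi = np.linspace(-2 * EPS, 2 * EPS, 60001)
        h = 1e-5
        numeric = (heaviside_eps(phi + h, EPS) - heaviside_eps(phi - h, EPS)) / (2 * h)
        assert np.max(np.abs(numeric - dirac_eps(phi, EPS))) < 1e-4

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            heaviside_eps(0.0, 0.0)
        with pytest.raises(ValueError):
            dirac_eps(0.0, -1.0)

    @settings(derandomize=True, max_examples=200)
    @given(phi=st.floats(-10, 10), eps=st.floats(0.1, 5))
    def test_regularised_pair_properties(self, phi, eps):
        """For any band width: V in [0,1], delta >= 0, odd symmetry of V
        about 1/2, and evenness of delta."""
        v = heaviside_eps(phi, eps)
        d = dirac_eps(phi, eps)
        assert 0.0 <= v <= 1.0
        assert d >= 0.0
        assert v + heaviside_eps(-phi, eps) == pytest.approx(1.0, abs=1e-12)
        assert d == pytest.approx(dirac_eps(-phi, eps), abs=1e-12)


class TestCurvature:
    @pytest.mark.parametrize("r", [10, 20, 40])
    def test_circle_signed_distance_curvature(self, r):
        n = 101
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        c = (n - 1) / 2
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        phi = r - rho  # positive inside
        kappa = curvature(phi)
        on_contour = (np.abs(rho - r) < 0.5) & (rho > 3)
        assert np.allclose(kappa[on_contour], -1.0 / r, rtol=0.05)

    def test_planar_field_has_zero_curvature(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(np.float64)
        phi = 0.3 * xx - 0.7 * yy + 2.0
        assert np.max(np.abs(curvature(phi)[2:-2, 2:-2])) < 1e-10

    def test_constant_field_safeguarded(self):
        kappa = curvature(np.full((32, 32), 5.0))
        assert np.all(np.isfinite(kappa))
        assert np.max(np.abs(kappa)) == 0.0


class TestEnergy:
    @pytest.fixture()
    def setup(self, rng):
        shape = (32, 32)
        u = ProbabilityMap(rng.uniform(size=shape))
        prior = ProbabilityMap(rng.uniform(0.1, 0.9, size=shape))
        return shape, u, prior, LevelSetParams()

    def test_all_kidney_field(self, setup):
        shape, u, prior, params = setup
        et, el, ed = energy(LevelSetField(np.full(shape, 10.0)), u, prior, params)
        assert el == 0.0
        assert ed == pytest.approx(np.sum(u.p_background * prior.p_background))
        assert et == pytest.approx(params.lambda2 * ed)

    def test_all_background_field(self, setup):
        shape, u, prior, params = setup
        _, el, ed = energy(LevelSetField(np.full(shape, -10.0)), u, prior, params)
        assert el == 0.0
        assert ed == pytest.approx(np.sum(u.p_kidney * prior.p_kidney))

    def test_energy_minimal_at_agreement(self):
        """With U and the prior both concentrated on the truth, the truth
        configuration scores a lower data energy than shifted contours."""
        yy, xx = np.mgrid[0:64, 0:64]
        truth = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 15 ** 2)
        u = ProbabilityMap(truth.astype(float))
        prior = ProbabilityMap(np.clip(truth.astype(float), 0.05, 0.95))
        params = LevelSetParams()

        def data_energy(mask):
            phi = init_phi(InitSpec("from_mask",
                                    mask=LabelMask(mask.astype(np.uint8))),
                           (64, 64))
            return energy(phi, u, prior, params)[2]

        e_truth = data_energy(truth)
        for shift in (3, 6):
            assert e_truth < data_energy(np.roll(truth, shift, axis=1))

    def test_all_energies_nonnegative(self, setup, rng):
        shape, u, prior, params = setup
        phi = LevelSetField(rng.normal(0, 2, size=shape))
        et, el, ed = energy(phi, u, prior, params)
        assert et >= 0 and el >= 0 and ed >= 0


class TestEvolveStep:
    def test_out_of_band_pixels_bit_identical(self, rng):
        phi = rng.normal(0, 3, size=(32, 32))
        u = ProbabilityMap(rng.uniform(size=(32, 32)))
        prior = ProbabilityMap(rng.uniform(0.1, 0.9, size=(32, 32)))
        field = LevelSetField(phi.copy())
        out = evolve_step(field, u, prior, LevelSetParams())
        frozen = np.abs(phi) > 1.5
        assert frozen.any()
        assert np.array_equal(out.phi[frozen], phi[frozen])

    def test_no_band_means_no_change(self):
        phi = np.full((16, 16), 10.0)
        u = ProbabilityMap(np.random.default_rng(0).uniform(size=(16, 16)))
        out = evolve_step(LevelSetField(phi), u, uniform_prior((16, 16)),
                          LevelSetParams())
        assert np.array_equal(out.phi, phi)

    def test_balanced_force_leaves_phi_unchanged(self):
        """With U_K P_K = U_B P_B everywhere and negligible curvature weight
        the update vanishes."""
        phi = np.zeros((16, 16))
        u = ProbabilityMap(np.full((16, 16), 0.5))
        params = LevelSetParams(lambda1=1e-12)
        out = evolve_step(LevelSetField(phi), u, uniform_prior((16, 16)), params)
        assert np.allclose(out.phi, phi, atol=1e-12)

    def test_kidney_evidence_raises_phi(self):
        """Where kidney evidence dominates, phi strictly increases."""
        phi = np.zeros((16, 16))
        p_k = np.full((16, 16), 0.5)
        p_k[8, 8] = 0.9
        u = ProbabilityMap(p_k)
        params = LevelSetParams(lambda1=1e-12)
        out = evolve_step(LevelSetField(phi), u, uniform_prior((16, 16)), params)
        assert out.phi[8, 8] > 0

    def test_degenerate_prior_reduces_to_probability_drive(self, rng):
        """P = 0.5 everywhere: the data force is lambda2 * 0.5 * (U_K - U_B),
        checked against a direct recomputation at random pixels."""
        shape = (32, 32)
        phi = rng.normal(0, 1, size=shape)
        u = ProbabilityMap(rng.uniform(size=shape))
        params = LevelSetParams(lambda1=1e-12)
        out = evolve_step(LevelSetField(phi.copy()), u, uniform_prior(shape),
                          params)
        rows = rng.integers(0, 32, 100)
        cols = rng.integers(0, 32, 100)
        for r, c in zip(rows, cols):
            expected = phi[r, c] + params.tau * dirac_eps(phi[r, c], params.eps) \
                * (params.lambda2 * 0.5 * (u.p_kidney[r, c] - u.p_background[r, c]))
            assert out.phi[r, c] == pytest.approx(expected, abs=1e-9)


class TestInitPhi:
    def test_circle_signed_distance(self):
        field = init_phi(InitSpec("circle", center=(32, 32), radius=10), (64, 64))
        assert field.phi[32, 32] == pytest.approx(10.0)
        yy, xx = np.mgrid[0:64, 0:64]
        on = np.abs(np.sqrt((yy - 32.0) ** 2 + (xx - 32.0) ** 2) - 10) < 0.5
        assert np.max(np.abs(field.phi[on])) <= 1.0

    def test_from_mask_sign_agreement(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((yy - 30) ** 2 + (xx - 34) ** 2 <= 12 ** 2).astype(np.uint8)
        field = init_phi(InitSpec("from_mask", mask=LabelMask(mask)), (64, 64))
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(mask) + \
            ndimage.distance_transform_edt(1 - mask)
        away = dist > 1
        assert np.array_equal(field.phi[away] > 0, mask[away] > 0)

    def test_two_disjoint_seeds_both_positive(self):
        mask = np.zeros((64, 64), np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 16) ** 2 + (xx - 16) ** 2 <= 36] = 1
        mask[(yy - 48) ** 2 + (xx - 48) ** 2 <= 36] = 1
        field = init_phi(InitSpec("from_mask", mask=LabelMask(mask)), (64, 64))
        assert field.phi[16, 16] > 0 and field.phi[48, 48] > 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            init_phi(InitSpec("circle", center=(100, 100), radius=5), (64, 64))
        with pytest.raises(ValueError):
            init_phi(InitSpec("rectangle", corners=((0, 0), (80, 10))), (64, 64))


class TestSegment:
    def test_recovers_disk_from_probability_map(self):
        yy, xx = np.mgrid[0:64, 0:64]
        truth = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 14 ** 2)
        u = ProbabilityMap(truth.astype(float))
        prior = ProbabilityMap(np.where(truth, 0.9, 0.1))
        image = ImageGrid(truth.astype(float))
        mask, diag = segment(image, u, prior,
                             InitSpec("circle", center=(10, 50), radius=6))
        from unls import dice
        assert dice(mask, LabelMask(truth.astype(np.uint8))) > 0.98
        assert diag.converged

    def test_energy_descends_without_reinit(self):
        yy, xx = np.mgrid[0:64, 0:64]
        truth = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 14 ** 2)
        u = ProbabilityMap(truth.astype(float))
        prior = ProbabilityMap(np.where(truth, 0.9, 0.1))
        image = ImageGrid(truth.astype(float))
        params = LevelSetParams(reinit_every=0)
        _, diag = segment(image, u, prior,
                          InitSpec("circle", center=(10, 50), radius=6), params)
        e = np.array(diag.e_total)
        assert diag.converged
        assert np.all(np.diff(e) <= 1e-3 * e[0])
        assert e[-1] <= e[0]

    def test_deterministic(self):
        yy, xx = np.mgrid[0:64, 0:64]
        truth = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 14 ** 2)
        u = ProbabilityMap(np.clip(truth.astype(float), 0.02, 0.98))
        prior = ProbabilityMap(np.where(truth, 0.8, 0.2))
        image = ImageGrid(truth.astype(float))
        spec = InitSpec("rectangle", corners=((5, 5), (25, 25)))
        m1, _ = segment(image, u, prior, spec)
        m2, _ = segment(image, u, prior, spec)
        assert np.array_equal(m1.labels, m2.labels)
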