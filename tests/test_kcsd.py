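"""Kernel CSD: bases, forward-mapped basis potentials, ridge estimator."""

import numpy as np
import pytest
from scipy.special import erf

from laminarpop.forward import PotentialRecording, uniform_array
from laminarpop.kcsd import (
    BasisConfig,
    KernelCSD,
    basis_potentials,
    build_basis,
    choose_lambda,
    traditional_csd,
)

SIGMA = 0.3


@pytest.fixture(scope="module")
def small_array():
    return uniform_array(8, pitch=100.0, top=100.0)


@pytest.fixture(scope="module")
def small_config():
    return BasisConfig(n_bases=24, width=60.0, disc_radius=150.0, span=(0.0, 1000.0), n_grid=50)


@pytest.fixture(scope="module")
def small_estimator(small_array, small_config):
    rec = PotentialRecording(
        array=small_array, values=np.zeros((8, 1)), sigma=SIGMA, dt=0.1
    )
    est = KernelCSD(
        n_bases=small_config.n_bases,
        width=small_config.width,
        disc_radius=small_config.disc_radius,
        span=small_config.span,
        n_grid=small_config.n_grid,
        lam=1e-8,
    )
    return est.fit(rec)


def _rec(array, values):
    return PotentialRecording(array=array, values=np.atleast_2d(values), sigma=SIGMA, dt=0.1)


class TestBasis:
    def test_gaussian_centers_equally_spaced(self, small_config):
        basis = build_basis(small_config)
        d = np.diff(basis.centers)
        np.testing.assert_allclose(d, d[0], rtol=1e-12)

    def test_gaussian_mass_matches_error_function(self, small_config):
        basis = build_basis(small_config)
        i = small_config.n_bases // 2
        lo, hi = small_config.span
        z = np.linspace(lo, hi, 20001)
        numeric = np.trapezoid(basis.profiles(z)[:, i], z)
        w = small_config.width
        c = basis.centers[i]
        analytic = w * np.sqrt(np.pi / 2) * (
            erf((hi - c) / (np.sqrt(2) * w)) - erf((lo - c) / (np.sqrt(2) * w))
        )
        assert numeric == pytest.approx(analytic, rel=1e-6)

    def test_step_supports_tile_span(self):
        cfg = BasisConfig(n_bases=10, basis="step", width=50.0, span=(0.0, 1000.0))
        basis = build_basis(cfg)
        z = np.linspace(0, 1000, 5000, endpoint=False)
        profiles = basis.profiles(z)
        np.testing.assert_array_equal(profiles.sum(axis=1), np.ones(len(z)))

    def test_too_few_bases_rejected(self, small_array):
        cfg = BasisConfig(n_bases=4, span=(0.0, 1000.0))
        with pytest.raises(ValueError, match="n_bases"):
            cfg.validate_for(small_array)


class TestBasisPotentials:
    def test_positive_and_peaks_near_center(self, small_config, small_array):
        basis = build_basis(small_config)
        phi = basis_potentials(basis, small_array.depths, SIGMA)
        assert np.all(phi > 0)
        i = small_config.n_bases // 2
        nearest = np.abs(small_array.depths - basis.centers[i]).argmin()
        assert phi[:, i].argmax() == nearest

    def test_monte_carlo_cross_check(self):
        """Quadrature agrees with 3D Monte Carlo over the disc-smeared source."""
        cfg = BasisConfig(n_bases=8, width=60.0, disc_radius=150.0, span=(0.0, 800.0))
        basis = build_basis(cfg)
        i = 4
        x = 430.0  # evaluation depth off the basis center
        phi = basis_potentials(basis, np.array([x]), SIGMA)[0, i]
        rng = np.random.default_rng(0)
        n = 10**6
        lo, hi = basis.support(i)
        z = rng.uniform(lo, hi, n)
        r = np.sqrt(rng.uniform(0, cfg.disc_radius**2, n))
        weights = basis.profiles(z)[:, i]
        # volume density b(z) over discs: V = int b(z)/(4 pi sigma d) dV
        dist = np.hypot(r, z - x)
        vol = (hi - lo) * np.pi * cfg.disc_radius**2
        mc = vol * np.mean(weights / (4 * np.pi * SIGMA * dist))
        assert phi == pytest.approx(mc, rel=5e-3)

    def test_conductivity_scaling(self, small_config, small_array):
        basis = build_basis(small_config)
        a = basis_potentials(basis, small_array.depths, SIGMA)
        b = basis_potentials(basis, small_array.depths, 2.0 * SIGMA)
        np.testing.assert_allclose(a, 2.0 * b, rtol=1e-9)


class TestReconstruct:
    def test_zero_potentials_zero_csd(self, small_estimator, small_array):
        csd = small_estimator.transform(_rec(small_array, np.zeros((8, 3))))
        assert np.all(csd.values == 0)

    def test_recovers_single_basis_element(self, fitted_kcsd, dataset):
        """Potentials from one basis element reconstruct that element.

        Uses the default 26-contact geometry; the element must lie within
        the electrode span (sources far outside it are unobservable).
        """
        est = fitted_kcsd
        centers = est.basis_.centers
        inside = np.flatnonzero(
            (centers > dataset.array.depths[0]) & (centers < dataset.array.depths[-1])
        )
        i = int(inside[len(inside) // 2])
        v = est.phi_contacts_[:, i][:, None]
        rec = PotentialRecording(
            array=dataset.array, values=v, sigma=dataset.sigma, dt=0.1
        )
        alpha = est._solve(rec.values, 1e-8)
        recon = (est.Kcross_ @ alpha)[:, 0]
        rho = np.corrcoef(recon, est.btilde_grid_[:, i])[0, 1]
        assert rho >= 0.99

    def test_csd_norm_monotone_in_lambda(self, small_estimator, small_array, rng):
        v = rng.normal(size=(8, 5))
        rec = _rec(small_array, v)
        norms = []
        for lam in np.logspace(-8, 2, 15):
            alpha = small_estimator._solve(rec.values, lam)
            norms.append(np.linalg.norm(small_estimator.Kcross_ @ alpha))
        assert np.all(np.diff(norms) < 0)

    def test_linearity_in_potentials(self, small_estimator, small_array, rng):
        a = rng.normal(size=(8, 4))
        b = rng.normal(size=(8, 4))
        ca = small_estimator.transform(_rec(small_array, a)).values
        cb = small_estimator.transform(_rec(small_array, b)).values
        cab = small_estimator.transform(_rec(small_array, 2 * a - b)).values
        np.testing.assert_allclose(cab, 2 * ca - cb, rtol=1e-9, atol=1e-12)

    def test_kernel_symmetric_psd(self, small_estimator):
        K = small_estimator.K_
        np.testing.assert_allclose(K, K.T, rtol=1e-12)
        ev = np.linalg.eigvalsh(K)
        assert ev.min() >= -1e-10 * ev.max()

    def test_basis_density_stability(self, small_array, rng):
        """Doubling M (fixed width, span) barely changes reconstructions."""
        v = rng.normal(size=(8, 1))
        csds = []
        for m in (24, 48):
            est = KernelCSD(
                n_bases=m, width=60.0, span=(0.0, 1000.0), n_grid=50, lam=1e-6
            ).fit(_rec(small_array, v))
            # smooth input: potentials of a mid-depth dipole source
            csds.append(est)
        src_v = csds[0].phi_contacts_[:, 10] - csds[0].phi_contacts_[:, 13]
        rec = _rec(small_array, src_v[:, None])
        c1 = csds[0].transform(rec).values
        c2 = csds[1].transform(rec).values
        rel = np.linalg.norm(c1 - c2) / np.linalg.norm(c1)
        assert rel < 0.01

    def test_potentials_reproduced_at_small_lambda(self, small_estimator, small_array):
        # data synthesized within the basis representation is interpolated
        v = (small_estimator.phi_contacts_[:, 7] + 0.5 * small_estimator.phi_contacts_[:, 12])
        rec = _rec(small_array, v[:, None])
        fitted = small_estimator.fitted_potentials(rec, lam=1e-10)
        rel = np.linalg.norm(fitted[:, 0] - v) / np.linalg.norm(v)
        assert rel < 1e-6

    def test_geometry_mismatch_rejected(self, small_estimator):
        other = uniform_array(8, pitch=90.0, top=100.0)
        with pytest.raises(ValueError, match="geometry"):
            small_estimator.transform(_rec(other, np.zeros((8, 1))))


class TestChooseLambda:
    def test_single_candidate_returned(self, small_estimator, small_array):
        rec = _rec(small_array, np.zeros((8, 1)))
        assert choose_lambda(rec, estimator=small_estimator, lambdas=[0.123]) == 0.123

    def test_noise_free_consistent_data_selects_smallest(self, small_estimator, small_array):
        # data exactly representable by the kernel at the contacts: any
        # ridge shrinkage only hurts, so CV picks the smallest candidate
        c = np.exp(-0.5 * ((np.arange(8) - 4) / 1.5) ** 2)[:, None]
        v = small_estimator.K_ @ c
        rec = _rec(small_array, v)
        lam = choose_lambda(
            rec, estimator=small_estimator, lambdas=np.logspace(-10, -2, 5)
        )
        assert lam == pytest.approx(1e-10)

    def test_noise_raises_selected_lambda(self, small_estimator, small_array, rng):
        v = small_estimator.phi_contacts_[:, 9][:, None]
        lam_clean = choose_lambda(
            _rec(small_array, v), estimator=small_estimator,
            lambdas=np.logspace(-10, 1, 12),
        )
        noisy = v + rng.normal(0, 0.5 * np.abs(v).max(), v.shape)
        lam_noisy = choose_lambda(
            _rec(small_array, noisy), estimator=small_estimator,
            lambdas=np.logspace(-10, 1, 12),
        )
        assert lam_noisy >= lam_clean

    def test_matches_exhaustive_error_table(self, small_estimator, small_array, rng):
        """Selection equals the argmin of an independently computed table."""
        v = rng.normal(size=(8, 6))
        rec = _rec(small_array, v)
        lambdas = np.logspace(-6, 0, 7)
        K = small_estimator.K_
        kap = small_estimator.kappa_
        errs = []
        for lam in lambdas:  # independent LOO implementation
            e = 0.0
            for j in range(8):
                keep = [i for i in range(8) if i != j]
                Koo = K[np.ix_(keep, keep)] + lam * kap * np.eye(7)
                pred = K[j, keep] @ np.linalg.solve(Koo, v[keep])
                e += np.sum((v[j] - pred) ** 2)
            errs.append(e)
        expected = lambdas[int(np.argmin(errs))]
        got = choose_lambda(rec, estimator=small_estimator, lambdas=lambdas)
        assert got == pytest.approx(expected)


class TestTraditionalCSD:
    def test_linear_profile_gives_zero(self, small_array):
        v = np.repeat(small_array.depths[:, None], 3, axis=1) * 0.01
        csd = traditional_csd(_rec(small_array, v))
        np.testing.assert_allclose(csd.values, 0.0, atol=1e-12)

    def test_quadratic_profile_gives_constant(self, small_array):
        v = (small_array.depths**2)[:, None]
        csd = traditional_csd(_rec(small_array, v))
        np.testing.assert_allclose(csd.values, -2.0 * SIGMA, rtol=1e-9)

    def test_interior_contacts_only(self, small_array):
        csd = traditional_csd(_rec(small_array, np.zeros((8, 2))))
        np.testing.assert_array_equal(csd.grid, small_array.depths[1:-1])

    def test_agrees_with_kcsd_on_smooth_source(self, small_estimator, small_array):
        """Both estimators see the same smooth dipolar source."""
        v = small_estimator.phi_contacts_[:, 9] - small_estimator.phi_contacts_[:, 14]
        rec = _rec(small_array, v[:, None])
        trad = traditional_csd(rec)
        kcsd = small_estimator.transform(rec)
        interp = np.interp(trad.grid, kcsd.grid, kcsd.values[:, 0])
        rho = np.corrcoef(trad.values[:, 0], interp)[0, 1]
        assert rho >= 0.95

    def test_unequal_spacing_rejected(self):
        from laminarpop.forward import ElectrodeArray

        arr = ElectrodeArray(depths=np.array([0.0, 50.0, 150.0]))
        with pytest.raises(ValueError, match="spaced"):
            traditional_csd(_rec(arr, np.zeros((3, 1))))
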