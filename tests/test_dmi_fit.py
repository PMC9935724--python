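"""Spherical means, closed-form kernels, linear oracle, Bayesian estimator."""

import numpy as np
import pytest

from myodmi.dmi_fit import (
    PriorConfig,
    fit_fractions_bayes,
    fit_fractions_linear,
    forward_shell_means,
    kernel_spherical_means,
    shell_spherical_mean,
    train_posterior_regressor,
)
from myodmi.errors import ConfigurationError, DegenerateModelError, ValidationError
from myodmi.io_formats import DWIStack
from myodmi.model import (
    TissueParams,
    add_rician,
    mixture_signal,
    sample_simplex,
    sample_sphere,
)
from myodmi.synthetic import default_scheme


def _sphere_quadrature_kernel(b, D, n=200_000, seed=0):
    """Independent oracle: Monte-Carlo average of exp(-b D cos^2 theta)."""
    rng = np.random.default_rng(seed)
    cos = rng.uniform(-1, 1, n)  # cos(theta) uniform <=> uniform on sphere
    return np.exp(-b * D * cos**2).mean()


class TestShellMeans:
    def test_constant_signal(self, scheme):
        sig = np.full(len(scheme), 3.0)
        m = shell_spherical_mean(sig, scheme)
        assert m.m0 == pytest.approx(3.0)
        assert np.allclose(m.m, 1.0)

    def test_isotropic_voxel_direction_independent(self, scheme, tissue):
        sig = mixture_signal(
            scheme.effective_bvals, scheme.bvecs,
            np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, 1.0]]), tissue,
        )[0]
        m = shell_spherical_mean(sig, scheme)
        assert m.m[1] == pytest.approx(np.exp(-1000 * tissue.d_iso), abs=1e-12)

    def test_stick_mean_converges_to_kernel(self, tissue):
        """12-direction quadrature is close; 1000 directions converge."""
        k_1000 = kernel_spherical_means(tissue, 1000.0)[0]
        errs = {}
        for n_dirs in (12, 1000):
            sch = default_scheme(n_dirs=n_dirs)
            sig = mixture_signal(
                sch.effective_bvals, sch.bvecs,
                np.array([[1.0, 0.0, 0.0]]), np.array([[0.36, 0.48, 0.8]]), tissue,
            )[0]
            m = shell_spherical_mean(sig, sch)
            errs[n_dirs] = abs(m.m[1] - k_1000)
        assert errs[1000] < errs[12]
        assert errs[1000] < 1e-3

    def test_zero_m0_marks_invalid(self, scheme):
        sig = np.zeros(len(scheme))
        m = shell_spherical_mean(sig, scheme)
        assert not m.valid
        assert np.all(np.isnan(m.m))


class TestKernels:
    def test_unity_at_b0(self, tissue):
        assert kernel_spherical_means(tissue, 0.0) == (1.0, 1.0, 1.0)

    def test_iso_closed_form(self, tissue):
        assert kernel_spherical_means(tissue, 1000.0)[2] == pytest.approx(
            np.exp(-3.0), abs=1e-12
        )

    @pytest.mark.parametrize("b", [600.0, 1000.0])
    def test_kernels_match_sphere_quadrature(self, tissue, b):
        k_intra, k_extra, k_iso = kernel_spherical_means(tissue, b)
        assert k_intra == pytest.approx(
            _sphere_quadrature_kernel(b, tissue.d_a, n=4_000_000), abs=5e-4
        )
        expected_extra = np.exp(-b * tissue.d_r) * _sphere_quadrature_kernel(
            b, tissue.d_a - tissue.d_r, n=4_000_000
        )
        assert k_extra == pytest.approx(expected_extra, abs=5e-4)

    def test_intra_reference_value(self, tissue):
        # frozen quadrature result for b = 1000, D_a = 1.7e-3
        assert kernel_spherical_means(tissue, 1000.0)[0] == pytest.approx(
            0.6354, abs=5e-4
        )

    def test_invalid_diffusivities(self):
        with pytest.raises(ValidationError):
            TissueParams(d_a=0.5e-3, d_r=0.7e-3)


class TestLinearOracle:
    def test_exact_recovery_from_kernel_means(self, tissue, rng):
        fr = sample_simplex(200, rng)
        means = forward_shell_means(fr, tissue, [600.0, 1000.0])
        est = fit_fractions_linear(means, tissue)
        assert np.max(np.abs(est - fr)) < 1e-9

    def test_pure_free_water(self, tissue):
        means = forward_shell_means(np.array([0.0, 0.0, 1.0]), tissue, [600.0, 1000.0])
        est = fit_fractions_linear(means, tissue)[0]
        assert np.allclose(est, [0.0, 0.0, 1.0], atol=1e-10)

    def test_needs_two_shells(self, tissue):
        means = forward_shell_means(np.array([0.3, 0.3, 0.4]), tissue, [1000.0])
        with pytest.raises(ValidationError, match="2 distinct"):
            fit_fractions_linear(means, tissue)

    def test_degenerate_shells_raise(self, tissue):
        means = forward_shell_means(
            np.array([0.3, 0.3, 0.4]), tissue, [999.0, 1000.0]
        )
        with pytest.raises(DegenerateModelError):
            fit_fractions_linear(means, tissue, cond_threshold=1e3)

    def test_result_on_simplex_under_noise(self, tissue, rng):
        means = forward_shell_means(sample_simplex(50, rng), tissue, [600.0, 1000.0])
        means.m += rng.normal(0, 0.05, means.m.shape)
        est = fit_fractions_linear(means, tissue)
        assert np.all(est >= -1e-9)
        assert np.allclose(est.sum(axis=-1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def small_prior():
    return PriorConfig(n_samples=20_000)


class TestBayesEstimator:
    def test_sample_floor_enforced(self):
        with pytest.raises(ConfigurationError, match="floor"):
            PriorConfig(n_samples=5000)

    def test_noiseless_matches_linear_oracle(self, scheme, tissue, rng):
        reg = train_posterior_regressor(
            scheme, tissue, PriorConfig(n_samples=20_000, snr=None), seed=1
        )
        fr = sample_simplex(300, rng)
        means = forward_shell_means(fr, tissue, scheme.shells)
        bayes = reg.predict(means.m)
        linear = fit_fractions_linear(means, tissue)
        assert np.mean(np.abs(bayes - linear)) < 0.02

    def test_shrinkage_toward_prior_mean_at_low_snr(self, scheme, tissue, rng):
        """Posterior means contract toward (1/3, 1/3, 1/3) as noise grows."""
        fr = sample_simplex(300, rng)
        ori = sample_sphere(300, rng)
        clean = mixture_signal(scheme.effective_bvals, scheme.bvecs, fr, ori, tissue)
        dists = {}
        for snr in (40.0, 2.0):
            reg = train_posterior_regressor(
                scheme, tissue, PriorConfig(n_samples=20_000, snr=snr), seed=2
            )
            noisy = add_rician(clean, 1.0 / snr, np.random.default_rng(3))
            est = reg.predict(shell_spherical_mean(noisy, scheme).m)
            dists[snr] = np.mean(np.abs(est - 1.0 / 3.0))
        assert dists[2.0] < dists[40.0]

    def test_monotone_shell_means_in_v_iso(self, tissue):
        """Raising v_iso at fixed v_intra:v_extra ratio lowers both means."""
        ratios = np.linspace(0.0, 0.9, 10)
        prev = None
        for v_iso in ratios:
            rest = 1.0 - v_iso
            fr = np.array([0.6 * rest, 0.4 * rest, v_iso])
            m = forward_shell_means(fr, tissue, [600.0, 1000.0]).m[0]
            if prev is not None:
                assert np.all(m < prev)
            prev = m

    def test_map_fit_respects_simplex_and_mask(self, scheme, tissue, small_prior, rng):
        data = np.zeros((6, 6, 3, len(scheme)))
        fr = sample_simplex(36, rng).reshape(6, 6, 1, 3)
        ori = sample_sphere(36, rng).reshape(6, 6, 1, 3)
        inner = mixture_signal(
            scheme.effective_bvals, scheme.bvecs,
            fr.reshape(-1, 3), ori.reshape(-1, 3), tissue,
        ).reshape(6, 6, 1, -1)
        data[:, :, 1:2, :] = inner  # slabs 0 and 2 stay background
        stack = DWIStack(data=data, voxel_size=np.array([2.0, 2.0, 4.0]), scheme=scheme)
        cmap = fit_fractions_bayes(stack, tissue, small_prior, seed=4)
        assert cmap.valid_mask[:, :, 1].all()
        assert not cmap.valid_mask[:, :, 0].any()
        stacked = cmap.stacked()[cmap.valid_mask]
        assert np.all(stacked >= 0) and np.all(stacked <= 1)
        assert np.allclose(stacked.sum(axis=-1), 1.0, atol=1e-6)

    def test_rotational_invariance_of_estimates(self, tissue, small_prior, rng):
        """Rotating fibers and gradients together moves noiseless estimates
        by < 1e-3."""
        from scipy.spatial.transform import Rotation

        scheme = default_scheme()
        reg = train_posterior_regressor(
            scheme, tissue, PriorConfig(n_samples=20_000, snr=None), seed=5
        )
        fr = sample_simplex(100, rng)
        ori = sample_sphere(100, rng)
        R = Rotation.from_euler("zyx", [17, 43, -64], degrees=True).as_matrix()
        est = {}
        for tag, (bv, o) in {
            "orig": (scheme.bvecs, ori),
            "rot": (scheme.bvecs @ R.T, ori @ R.T),
        }.items():
            sig = mixture_signal(scheme.effective_bvals, bv, fr, o, tissue)
            est[tag] = reg.predict(shell_spherical_mean(sig, scheme).m)
        assert np.max(np.abs(est["orig"] - est["rot"])) < 1e-3
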