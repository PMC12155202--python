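"""Richardson–Lucy engine: fixed points, conservation laws, likelihood
monotonicity, brick planning and depth-variant reassembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import fftconvolve

from widefield3d import (
    BrickPlan,
    DeconvSettings,
    deconvolve,
    deconvolve_depth_variant,
    plan_bricks,
    rl_step,
)
from widefield3d.deconv import poisson_loglik
from widefield3d._fft import FFTConvolver


def _unit_kernel(rng, shape):
    k = rng.random(shape)
    return k / k.sum()


class TestSettings:
    def test_zero_iterations_forbidden(self):
        with pytest.raises(ValueError, match="max_iterations"):
            DeconvSettings(max_iterations=0)

    def test_snr_scales_iteration_budget(self):
        lo = DeconvSettings(snr=10.0, base_iterations=40, max_iterations=1000)
        hi = DeconvSettings(snr=40.0, base_iterations=40, max_iterations=1000)
        assert lo.effective_iterations == 20
        assert hi.effective_iterations == 80

    def test_acuity_multiplies_budget(self):
        s = DeconvSettings(snr=20.0, base_iterations=40, acuity=0.5, max_iterations=1000)
        assert s.effective_iterations == 60

    def test_budget_capped_by_max_iterations(self):
        s = DeconvSettings(snr=40.0, base_iterations=40, max_iterations=25)
        assert s.effective_iterations == 25


class TestConvolver:
    def test_matches_scipy_same_mode(self, rng):
        x = rng.random((12, 13, 14))
        k = _unit_kernel(rng, (5, 3, 5))
        conv = FFTConvolver(k, x.shape, "zero_pad")
        ref = fftconvolve(x, k, mode="same")
        assert np.allclose(conv.conv(x), ref, atol=1e-10)

    def test_adjoint_identity_zero_pad(self, rng):
        # <Kx, y> == <x, K^T y> for an exact transpose pair
        x = rng.random((10, 11))
        y = rng.random((10, 11))
        k = _unit_kernel(rng, (5, 5))
        conv = FFTConvolver(k, x.shape, "zero_pad")
        assert np.vdot(conv.conv(x), y) == pytest.approx(
            np.vdot(x, conv.conv_adjoint(y)), rel=1e-10)

    def test_adjoint_identity_circular(self, rng):
        x = rng.random((16,))
        y = rng.random((16,))
        k = _unit_kernel(rng, (7,))
        conv = FFTConvolver(k, x.shape, "circular")
        assert np.vdot(conv.conv(x), y) == pytest.approx(
            np.vdot(x, conv.conv_adjoint(y)), rel=1e-10)

    def test_kernel_larger_than_volume_rejected_for_circular(self, rng):
        with pytest.raises(ValueError, match="circular"):
            FFTConvolver(_unit_kernel(rng, (9,)), (4,), "circular")


class TestRLStep:
    def test_delta_kernel_fixed_point(self, rng):
        obs = rng.random((8, 8, 8)) * 10
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        out = rl_step(obs, obs, delta, boundary="circular")
        assert np.allclose(out, obs, atol=1e-9)

    def test_flux_conservation_circular(self, rng):
        obs = rng.random((16, 16, 16)) * 100
        k = _unit_kernel(rng, (5, 5, 5))
        e = rng.random(obs.shape) + 0.1
        for _ in range(5):
            e = rl_step(e, obs, k, boundary="circular")
            assert e.sum() == pytest.approx(obs.sum(), rel=1e-9)

    def test_nonnegativity_preserved(self, rng):
        obs = rng.random((12, 12)) * 5
        k = _unit_kernel(rng, (5, 5))
        e = rng.random(obs.shape)
        for _ in range(10):
            e = rl_step(e, obs, k, boundary="reflect")
            assert e.min() >= 0

    def test_nonfinite_input_rejected(self, rng):
        obs = rng.random((8, 8))
        obs[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rl_step(obs, obs, _unit_kernel(rng, (3, 3)))

    @pytest.mark.parametrize("shape,kshape", [((32,), (5,)), ((12, 12, 12), (5, 5, 5))])
    def test_monotone_poisson_likelihood(self, rng, shape, kshape):
        # likelihood evaluated directly each step; exact adjoint boundary
        k = _unit_kernel(rng, kshape)
        truth = rng.random(shape) * 50
        obs = rng.poisson(fftconvolve(truth, k, mode="same").clip(0)).astype(float)
        conv = FFTConvolver(k, shape, "circular")
        e = np.full(shape, obs.mean() + 0.1)
        lik_prev = -np.inf
        for i in range(100):
            e = rl_step(e, obs, k, boundary="circular", _convolver=conv)
            lik = poisson_loglik(obs, conv.conv(e))
            assert lik >= lik_prev - 1e-7 * abs(lik_prev)
            lik_prev = lik


class TestDeconvolve:
    def test_all_zero_volume_warns_and_returns_zeros(self, rng):
        k = _unit_kernel(rng, (3, 3, 3))
        with pytest.warns(RuntimeWarning, match="zero"):
            out = deconvolve(np.zeros((8, 8, 8)), k, DeconvSettings(max_iterations=5))
        assert not out.any()

    def test_negative_input_rejected(self, rng):
        k = _unit_kernel(rng, (3, 3, 3))
        with pytest.raises(ValueError, match="non-negative"):
            deconvolve(rng.random((8, 8, 8)) - 2.0, k, DeconvSettings(max_iterations=5))

    def test_noiseless_bead_sharpened_and_centered(self, rng):
        # blurred bead: deconvolution must raise the peak and keep the
        # centroid within half a voxel (forward model known exactly)
        truth = np.zeros((24, 24, 24))
        truth[12, 12, 12] = 80.0
        truth[12, 12, 13] = 40.0
        k = np.zeros((9, 9, 9))
        zz, yy, xx = np.mgrid[-4:5, -4:5, -4:5]
        k[(zz**2 / 9 + yy**2 / 4 + xx**2 / 4) <= 1] = 1.0
        k /= k.sum()
        obs = fftconvolve(truth, k, mode="same").clip(0)
        out = deconvolve(obs, k, DeconvSettings(algorithm="mle_classic",
                                                max_iterations=50, base_iterations=50,
                                                precision="float64"))
        assert out.max() > 2 * obs.max()
        idx = np.indices(out.shape)
        com = [(idx[d] * out).sum() / out.sum() for d in range(3)]
        com_true = [12, 12, 12 + 40 / 120]
        assert all(abs(a - b) < 0.5 for a, b in zip(com, com_true))

    def test_qmle_reaches_classic_quality_in_fewer_iterations(self, rng):
        truth = np.zeros((32, 32))
        truth[10, 12] = 100.0
        truth[20, 18] = 60.0
        k = _unit_kernel(rng, (7, 7))
        obs = fftconvolve(truth, k, mode="same").clip(0)
        classic = deconvolve(obs, k, DeconvSettings(
            algorithm="mle_classic", max_iterations=60, base_iterations=60))
        quick = deconvolve(obs, k, DeconvSettings(
            algorithm="qmle_accelerated", max_iterations=30, base_iterations=30))
        conv = FFTConvolver(k, obs.shape, "reflect")
        lik_classic = poisson_loglik(obs, conv.conv(np.asarray(classic, float)))
        lik_quick = poisson_loglik(obs, conv.conv(np.asarray(quick, float)))
        assert lik_quick >= lik_classic - 0.01 * abs(lik_classic)


class TestPlanBricks:
    def test_seven_bricks_of_625(self):
        plan = plan_bricks(625, 7, psf_axial_support=61)
        sizes = [b - a for a, b in plan.cores]
        assert sum(sizes) == 625
        assert max(sizes) - min(sizes) <= 1
        assert plan.pad == 31
        assert plan.cores[0][0] == 0 and plan.cores[-1][1] == 625

    def test_single_brick_degenerates_to_whole_stack(self):
        plan = plan_bricks(625, 1, psf_axial_support=61)
        assert plan.cores == ((0, 625),)

    def test_more_bricks_than_planes_errors(self):
        with pytest.raises(ValueError, match="bricks"):
            plan_bricks(4, 8, psf_axial_support=3)

    @settings(max_examples=50, deadline=None)
    @given(n_z=st.integers(1, 400), n_bricks=st.integers(1, 12),
           support=st.integers(1, 81))
    def test_cores_partition_and_pad_rule(self, n_z, n_bricks, support):
        if n_bricks > n_z:
            with pytest.raises(ValueError):
                plan_bricks(n_z, n_bricks, support)
            return
        plan = plan_bricks(n_z, n_bricks, support)
        # disjoint contiguous cover with <=1 size spread
        assert plan.cores[0][0] == 0
        assert plan.cores[-1][1] == n_z
        for (a0, a1), (b0, b1) in zip(plan.cores, plan.cores[1:]):
            assert a1 == b0
        sizes = [b - a for a, b in plan.cores]
        assert max(sizes) - min(sizes) <= 1
        assert plan.pad == -(-support // 2)
        for i in range(plan.n_bricks):
            p0, p1 = plan.padded(i)
            assert 0 <= p0 <= plan.cores[i][0]
            assert plan.cores[i][1] <= p1 <= n_z

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            BrickPlan(n_z=10, cores=((0, 4), (5, 10)), pad=1)


class TestDepthVariant:
    def test_matched_index_equals_whole_stack(self, matched_optics, rng):
        # depth invariance collapses bricking to single-kernel deconvolution
        from scipy.ndimage import gaussian_filter

        obs = gaussian_filter(rng.random((40, 32, 32)) * 50, (2, 1, 1)) + 1.0
        settings = DeconvSettings(max_iterations=10, base_iterations=10,
                                  precision="float64")
        support = (21, 11, 11)
        bricked = deconvolve_depth_variant(
            obs, matched_optics, settings, plan_bricks(40, 4, support[0]),
            psf_support=support)
        whole = deconvolve_depth_variant(
            obs, matched_optics, settings, plan_bricks(40, 1, support[0]),
            psf_support=support)
        scale = np.abs(whole).max()
        assert np.abs(bricked - whole).max() <= 0.01 * scale

    def test_seam_continuity_on_smooth_phantom(self, matched_optics, rng):
        from scipy.ndimage import gaussian_filter

        obs = gaussian_filter(rng.random((36, 24, 24)) * 20, (3, 2, 2)) + 5.0
        settings = DeconvSettings(max_iterations=8, base_iterations=8)
        plan = plan_bricks(36, 3, 15)
        out = deconvolve_depth_variant(obs, matched_optics, settings, plan,
                                       psf_support=(15, 9, 9))
        dz = np.abs(np.diff(out, axis=0)).max(axis=(1, 2))
        boundary_planes = [c[1] - 1 for c in plan.cores[:-1]]
        interior = [i for i in range(len(dz)) if i not in boundary_planes
                    and i - 1 not in boundary_planes and i + 1 not in boundary_planes]
        assert max(dz[i] for i in boundary_planes) <= 1.5 * max(dz[i] for i in interior)

    def test_plan_must_match_stack(self, matched_optics, rng):
        obs = rng.random((20, 16, 16))
        with pytest.raises(ValueError, match="plan"):
            deconvolve_depth_variant(obs, matched_optics,
                                     DeconvSettings(max_iterations=2),
                                     plan_bricks(30, 3, 5))
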