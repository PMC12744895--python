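import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmcdce import kinetics as kin
from kmcdce.io_core import DataError, DynamicSeries, RegionLabels
from kmcdce.kinetics import (PseCurve, auc30, compute_pse, emm2_eval,
                             emm3_eval, fit_emm2_curve, fit_emm3_curve)


def _curve(A, alpha, beta=0.0, n_post=18, spacing_min=5 / 60.0, noise=None,
           rng=None):
    """Noiseless (or noisy) model curve with 5 precontrast frames."""
    times = (np.arange(5 + n_post) - 4) * spacing_min
    pse = emm3_eval(A, alpha, beta, times)
    if noise:
        pse = pse + rng.normal(0, noise, pse.shape)
    return PseCurve(times=times, pse=pse, baseline=100.0)


class TestComputePse:
    def test_pse_arithmetic(self):
        vox = np.zeros((1, 1, 1, 6))
        vox[0, 0, 0] = [100, 102, 98, 101, 99, 150]
        s = DynamicSeries(voxels=vox, frame_times=np.arange(6) / 12.0,
                          n_precontrast=5)
        curve = compute_pse(s, (0, 0, 0))
        assert curve.pse[-1] == pytest.approx(50.0)   # baseline mean is 100
        assert curve.baseline == pytest.approx(100.0)

    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (2.0, 100.0)])
    def test_reference_points(self, factor, expected):
        vox = np.full((1, 1, 1, 6), 80.0)
        vox[0, 0, 0, -1] = 80.0 * factor
        s = DynamicSeries(voxels=vox, frame_times=np.arange(6) / 12.0,
                          n_precontrast=5)
        assert compute_pse(s, (0, 0, 0)).pse[-1] == pytest.approx(expected)

    def test_region_mean_uses_raw_signal_average(self):
        vox = np.zeros((2, 1, 1, 6))
        vox[0, 0, 0] = [100] * 5 + [150]
        vox[1, 0, 0] = [300] * 5 + [330]
        s = DynamicSeries(voxels=vox, frame_times=np.arange(6) / 12.0,
                          n_precontrast=5)
        curve = compute_pse(s, np.ones((2, 1, 1), dtype=bool))
        # mean signal 200 -> 240 = +20%, not the mean of (50%, 10%) = 30%
        assert curve.pse[-1] == pytest.approx(20.0)


class TestModelEvaluation:
    def test_emm2_reference_value(self):
        assert emm2_eval(100, 4, 0.5) == pytest.approx(50.0)

    def test_emm3_reference_value(self):
        assert emm3_eval(100, 4, 0.1, 0.5) == pytest.approx(
            50 * np.exp(-0.05), rel=1e-9)

    def test_zero_time_and_beta_reduction(self):
        t = np.linspace(0, 3, 50)
        assert emm2_eval(80, 3, 0.0) == 0.0
        np.testing.assert_allclose(emm3_eval(80, 3, 0.0, t),
                                   emm2_eval(80, 3, t))

    def test_saturation_limit(self):
        assert emm2_eval(80, 3, 1e4) == pytest.approx(80, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(A=st.floats(0, 500), alpha=st.floats(0, 50),
           t1=st.floats(0, 5), dt=st.floats(1e-6, 5))
    def test_emm2_monotone_nondecreasing(self, A, alpha, t1, dt):
        assert emm2_eval(A, alpha, t1 + dt) >= emm2_eval(A, alpha, t1) - 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(A=st.floats(0, 500), alpha=st.floats(0.01, 50),
           beta=st.floats(0, 2), t=st.floats(0, 5))
    def test_washout_only_lowers_the_curve(self, A, alpha, beta, t):
        assert emm3_eval(A, alpha, beta, t) <= emm2_eval(A, alpha, t) + 1e-12


class TestAuc30:
    def test_zero_amplitude(self):
        assert auc30(0, 4, 0.3) == 0.0

    def test_closed_form_beta_zero(self):
        # A*(t30 - arctan(sqrt(alpha)*t30)/sqrt(alpha))
        assert auc30(100, 4, 0.0) == pytest.approx(
            100 * (0.5 - np.arctan(1.0) / 2.0), abs=1e-8)

    def test_quadrature_matches_simpson_oracle(self, rng):
        from scipy.integrate import simpson
        t = np.linspace(0, 0.5, 10001)
        for _ in range(20):
            A = rng.uniform(10, 300)
            alpha = rng.uniform(0.1, 30)
            beta = rng.uniform(-0.5, 2)
            oracle = simpson(emm3_eval(A, alpha, beta, t), x=t)
            assert auc30(A, alpha, beta) == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(A=st.floats(1, 300), alpha=st.floats(0.05, 30))
    def test_closed_form_identity_at_beta_zero(self, A, alpha):
        ra = np.sqrt(alpha)
        closed = A * (0.5 - np.arctan(ra * 0.5) / ra)
        assert auc30(A, alpha, 0.0) == pytest.approx(closed, abs=1e-8)


class TestEmm2Fit:
    def test_noiseless_recovery(self):
        fit = fit_emm2_curve(_curve(80, 3))
        assert fit.A == pytest.approx(80, rel=1e-3)
        assert fit.alpha == pytest.approx(3, rel=1e-3)
        assert fit.converged

    def test_flat_signal_flagged_low_enhancement(self):
        fit = fit_emm2_curve(_curve(0, 1))
        assert fit.A == pytest.approx(0, abs=1e-9)
        assert fit.low_enhancement

    def test_noisy_median_recovery(self, rng):
        # Gaussian PSE noise SD 2 (percent points) on A=80, alpha=3
        As = [fit_emm2_curve(_curve(80, 3, noise=2.0, rng=rng)).A
              for _ in range(500)]
        assert abs(np.median(As) - 80) / 80 < 0.05

    def test_deterministic(self):
        c = _curve(45, 1.2, 0.02)
        f1, f2 = fit_emm2_curve(c), fit_emm2_curve(c)
        assert (f1.A, f1.alpha) == (f2.A, f2.alpha)

    def test_too_few_frames_rejected(self):
        with pytest.raises(DataError):
            fit_emm2_curve(_curve(50, 2, n_post=3))


class TestEmm3Fit:
    @pytest.mark.parametrize("truth", [(60, 5, 0.2), (60, 5, -0.05)])
    def test_noiseless_recovery_including_negative_washout(self, truth):
        A, alpha, beta = truth
        fit = fit_emm3_curve(_curve(A, alpha, beta))
        assert fit.A == pytest.approx(A, rel=1e-3)
        assert fit.alpha == pytest.approx(alpha, rel=1e-3)
        assert fit.beta == pytest.approx(beta, rel=1e-3, abs=1e-4)
        assert fit.auc30 == pytest.approx(auc30(A, alpha, beta), rel=1e-3)

    def test_zero_curve_flagged(self):
        fit = fit_emm3_curve(_curve(0, 1))
        assert fit.A == pytest.approx(0, abs=1e-2)
        assert fit.low_enhancement


class TestVoxelwiseFit:
    def test_noiseless_phantom_truth_recovery(self, uptake_only_phantom):
        series, labels, truth = uptake_only_phantom
        maps = kin.fit_emm2_voxelwise(series, labels, region=2)
        m = labels.mask(2)
        rel_a = np.abs(maps["A"][m] - truth.voxel_maps["A"][m]) \
            / truth.voxel_maps["A"][m]
        rel_al = np.abs(maps["alpha"][m] - truth.voxel_maps["alpha"][m]) \
            / truth.voxel_maps["alpha"][m]
        assert np.nanmax(rel_a) < 1e-3
        assert np.nanmax(rel_al) < 1e-3

    def test_empty_region_rejected(self, uptake_only_phantom):
        series, labels, _ = uptake_only_phantom
        empty = RegionLabels(labels=np.zeros(labels.labels.shape,
                                             dtype=np.int16))
        with pytest.raises(DataError):
            kin.fit_emm2_voxelwise(series, empty, region=3)
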