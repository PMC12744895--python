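import numpy as np
import pytest

import kmcdce as K
from kmcdce.io_core import DataError
from kmcdce.phantom import CohortSpec, PhantomSpec, generate_cohort, \
    generate_phantom


class TestPhantomGeometry:
    def test_regions_present_and_disjoint(self, small_phantom):
        series, labels, truth = small_phantom
        lab = labels.labels
        for code in (1, 2):
            assert (lab == code).sum() > 100
        assert (lab == 3).sum() > 40
        assert labels.check_tumor_side()
        # parenchymal voxel counts are bilaterally equal (mirror cavity)
        assert (lab == 1).sum() == (lab == 2).sum()

    def test_truth_table_lists_all_region_bands(self, small_phantom):
        _, _, truth = small_phantom
        assert len(truth.table) == 15          # 3 regions x 5 bands
        assert set(truth.table.region) == {
            "ipsilateral_parenchyma", "contralateral_parenchyma", "tumor"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(DataError):
            PhantomSpec(asymmetry_r=0.0).validate()
        with pytest.raises(DataError):
            PhantomSpec(spacing_s=20.0).validate()
        with pytest.raises(DataError):
            PhantomSpec(noise_sd_frac=-0.1).validate()


class TestPhantomSignal:
    def test_mirror_identity_at_unit_asymmetry(self, small_phantom):
        series, labels, _ = small_phantom   # r=1, zero noise, dispersion>0
        vox = series.voxels
        mirrored = vox[::-1, :, :, :]
        par = np.isin(labels.labels, (1, 2))
        np.testing.assert_allclose(vox[par], mirrored[par], rtol=1e-12)

    def test_voxel_pse_matches_model_arithmetic(self):
        # A=50, alpha=2, beta=0 at t=0.5 min: PSE = 50*(2*0.25)/(1+2*0.25)
        spec = PhantomSpec(shape=(16, 32, 8), dispersion_sigma=0.0,
                           parenchyma_bands={"A": (50.0,) * 5,
                                             "alpha": (2.0,) * 5,
                                             "beta": (0.0,) * 5})
        series, labels, _ = generate_phantom(spec)
        i, j, k = np.argwhere(labels.labels == 2)[0]
        t_rel = series.frame_times - series.frame_times[4]
        frame = int(np.argmin(np.abs(t_rel - 0.5)))
        assert t_rel[frame] == pytest.approx(0.5)
        pse = 100 * (series.voxels[i, j, k, frame] / spec.s0 - 1)
        assert pse == pytest.approx(50 * 0.5 / 1.5, rel=1e-9)

    def test_asymmetry_scales_truth_rate(self):
        spec = PhantomSpec(shape=(16, 32, 8), asymmetry_r=1.4, seed=1)
        _, labels, truth = generate_phantom(spec)
        a_alpha = truth.voxel_maps["a_alpha"]
        ips = np.sort(a_alpha[labels.labels == 1])
        con = np.sort(a_alpha[labels.labels == 2])
        np.testing.assert_allclose(ips, 1.4 * con, rtol=1e-10)

    def test_seed_determinism(self):
        spec = PhantomSpec(shape=(16, 32, 8), seed=9, noise="rician",
                           noise_sd_frac=0.02)
        s1, _, _ = generate_phantom(spec)
        s2, _, _ = generate_phantom(PhantomSpec(shape=(16, 32, 8), seed=9,
                                                noise="rician",
                                                noise_sd_frac=0.02))
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_rician_noise_never_negative(self):
        spec = PhantomSpec(shape=(16, 32, 8), seed=2, noise="rician",
                           noise_sd_frac=0.3, background_s0=1.0)
        s, _, _ = generate_phantom(spec)
        assert np.all(s.voxels >= 0)

    def test_concentration_mode_tofts_truth_recovery(self):
        """Concentration-mode voxels must carry exactly the ETM kinetics the
        truth table says, when inverted and refit."""
        spec = PhantomSpec(shape=(16, 32, 8), mode="concentration",
                           dispersion_sigma=0.0, include_vessels=False)
        series, labels, truth = generate_phantom(spec)
        curve = K.compute_pse(series, tuple(np.argwhere(labels.labels == 3)[0]))
        conc = K.pse_to_concentration(curve, t10_s=spec.t10_s,
                                      relaxivity=spec.relaxivity,
                                      tr_s=spec.tr_s, flip_deg=spec.flip_deg)
        fit = K.fit_etm(conc, spec.aif)
        row = truth.voxel_maps
        i, j, k = np.argwhere(labels.labels == 3)[0]
        assert fit.ktrans == pytest.approx(row["ktrans"][i, j, k], rel=0.02)
        assert fit.vp == pytest.approx(row["vp"][i, j, k], rel=0.05, abs=1e-4)


class TestCohortSimulator:
    def test_group_means_near_targets(self):
        # n = (30, 26) with the published Ktrans I/C group parameters
        cohort = generate_cohort(CohortSpec(seed=0))
        non = cohort[cohort.outcome == 0]["kBPE_Ktrans_IC"]
        pcr = cohort[cohort.outcome == 1]["kBPE_Ktrans_IC"]
        assert abs(non.mean() - 1.45) < 3 * 0.56 / np.sqrt(30)
        assert abs(pcr.mean() - 1.03) < 3 * 0.12 / np.sqrt(26)

    def test_zero_sd_collapses_group(self):
        spec = CohortSpec(features={"kT_A": (1.5, 0.0, 2.5, 0.0)},
                          bounds={}, seed=0)
        cohort = generate_cohort(spec)
        assert cohort[cohort.outcome == 0]["kT_A"].nunique() == 1
        assert cohort[cohort.outcome == 1]["kT_A"].iloc[0] == 2.5

    def test_seed_controls_identity(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=5))
        c = generate_cohort(CohortSpec(seed=6))
        assert a.equals(b)
        assert not a.equals(c)

    def test_physical_bounds_enforced(self):
        cohort = generate_cohort(CohortSpec(seed=3))
        assert (cohort["kT_ve"] <= 1.0).all()
        assert (cohort["kBPE_Ktrans_IC"] > 0).all()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(DataError):
            generate_cohort(CohortSpec(n_pcr=0))
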