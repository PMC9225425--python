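"""Phantom generator: geometry, signal models, cohort structure, histology."""

import numpy as np
import pandas as pd
import pytest

from qmri import phantom
from qmri.phantom import (AcquisitionSpec, DesignSpec, PlacementError, TissueSpec,
                          default_tissues, make_label_volume,
                          simulate_cohort, simulate_dce, simulate_histology_image,
                          simulate_multi_echo, uptake_curve)


class TestLabelVolume:
    def test_all_tissues_placed_with_background(self, tissues):
        acq = AcquisitionSpec(matrix=(92, 92, 25))
        rois = make_label_volume(acq, tissues)
        assert len(np.unique(rois.labels)) == 11  # 10 tissues + background
        assert all(c >= 1 for c in rois.counts().values())

    def test_too_small_matrix_names_unplaceable_tissue(self, tissues):
        acq = AcquisitionSpec(matrix=(4, 4, 1))
        with pytest.raises(PlacementError, match="meninges"):
            make_label_volume(acq, tissues)

    def test_meninges_thinner_than_cortex(self, labels):
        counts = labels.counts()
        assert counts["meninges"] < counts["cortex"]

    def test_duplicate_labels_rejected(self, small_acq):
        t = default_tissues()
        with pytest.raises(ValueError, match="unique"):
            make_label_volume(small_acq, t + [t[0]])


class TestMultiEcho:
    def test_noiseless_matches_closed_form_everywhere(self, small_acq, tissues, labels):
        stack = simulate_multi_echo(labels, tissues, small_acq, 0.0, seed=0)
        for t in tissues:
            m = labels.mask(t.label)
            expected = t.s0 * np.exp(-np.asarray(small_acq.echo_times_ms) / t.t2_ms)
            np.testing.assert_allclose(
                stack.data[m], np.broadcast_to(expected, stack.data[m].shape),
                rtol=1e-12)

    def test_single_voxel_value(self):
        # s0=100, t2=50 at TE=10 -> 100*exp(-0.2)
        mu = 100 * np.exp(-10.0 / 50.0)
        assert mu == pytest.approx(81.873, abs=1e-3)
        acq = AcquisitionSpec(matrix=(16, 16, 4))
        tis = [TissueSpec("meninges", s0=100, t2_ms=50),
               TissueSpec("cortex", s0=100, t2_ms=50),
               TissueSpec("muscle", s0=100, t2_ms=50)]
        rois = make_label_volume(acq, tis)
        stack = simulate_multi_echo(rois, tis, acq, 0.0, seed=0)
        assert stack.data[rois.mask("meninges")][0, 0] == pytest.approx(mu, rel=1e-12)

    def test_background_is_rayleigh(self, rng):
        # pure-noise magnitude voxels have mean sigma*sqrt(pi/2)
        sigma = 5.0
        vals = np.hypot(rng.normal(0, sigma, 100_000), rng.normal(0, sigma, 100_000))
        assert vals.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)
        acq = AcquisitionSpec(matrix=(24, 24, 8))
        tis = default_tissues()
        rois = make_label_volume(acq, tis)
        stack = simulate_multi_echo(rois, tis, acq, sigma, seed=3)
        bg = stack.data[rois.labels == 0]
        assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_rician_bias_at_high_snr(self, rng):
        # for s0 >> sigma the magnitude mean approaches sqrt(mu^2 + sigma^2)
        mu, sigma = 100.0, 5.0
        vals = np.hypot(mu + rng.normal(0, sigma, 50_000), rng.normal(0, sigma, 50_000))
        assert vals.mean() == pytest.approx(np.hypot(mu, sigma), rel=0.01)

    def test_seed_reproducibility(self, small_acq, tissues, labels):
        a = simulate_multi_echo(labels, tissues, small_acq, 2.0, seed=11)
        b = simulate_multi_echo(labels, tissues, small_acq, 2.0, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_negative_sigma_rejected(self, small_acq, tissues, labels):
        with pytest.raises(ValueError):
            simulate_multi_echo(labels, tissues, small_acq, -1.0, seed=0)


class TestDce:
    def test_null_enhancement_gives_constant_series(self, small_acq):
        tis = [TissueSpec("meninges", 90, 60, 0.0), TissueSpec("cortex", 100, 45, 0.0),
               TissueSpec("muscle", 80, 30, 0.0)]
        rois = make_label_volume(small_acq, tis)
        ser = simulate_dce(rois, tis, small_acq, noise_sigma=0.0, seed=0)
        assert np.all(ser.data == ser.data[..., :1])

    def test_infinite_rate_is_step_to_amp(self, small_acq):
        tis = [TissueSpec("meninges", 90, 60, 0.5, uptake_rate=1e9),
               TissueSpec("cortex", 100, 45, 0.0),
               TissueSpec("muscle", 80, 30, 0.0, uptake_rate=1.0)]
        rois = make_label_volume(small_acq, tis)
        ser = simulate_dce(rois, tis, small_acq, noise_sigma=0.0, seed=0)
        vox = ser.data[rois.mask("meninges")][0]
        post = ser.frame_times_min >= small_acq.injection_start_min
        np.testing.assert_allclose(vox[post], 1.5 * 90.0, rtol=1e-9)
        np.testing.assert_allclose(vox[~post], 90.0)

    def test_uptake_matches_closed_form_at_midpoints(self, small_acq, core_tissues):
        rois = make_label_volume(small_acq, core_tissues)
        ser = simulate_dce(rois, core_tissues, small_acq, noise_sigma=0.0, seed=0)
        men = [t for t in core_tissues if t.label == "meninges"][0]
        vox = ser.data[rois.mask("meninges")][0]
        t = ser.frame_times_min
        expected = men.s0 * (1 + np.where(
            t < 2.0, 0.0,
            men.enhancement_amp * (1 - np.exp(-men.uptake_rate * (t - 2.0)))))
        np.testing.assert_allclose(vox, expected, rtol=1e-12)

    def test_muscle_required(self, small_acq):
        tis = [TissueSpec("meninges", 90, 60, 0.5), TissueSpec("cortex", 100, 45, 0.1)]
        rois = make_label_volume(small_acq, tis)
        with pytest.raises(ValueError, match="muscle"):
            simulate_dce(rois, tis, small_acq)


class TestCohort:
    def test_session_count(self, tiny_acq, core_tissues):
        design = DesignSpec(n_per_cell=2, seed=0)
        cohort = simulate_cohort(design, tiny_acq, core_tissues)
        assert len(cohort) == 8 * 3
        assert len(list(cohort.iter_sessions(multi_echo=False))) == 24

    def test_null_design_balances_groups(self, tiny_acq, core_tissues):
        design = DesignSpec(n_per_cell=50, injury_effects={}, sex_effects={}, seed=5)
        cohort = simulate_cohort(design, tiny_acq, core_tissues)
        t = cohort.truth
        men = t[(t.roi == "meninges") & (t.day == "Day1")]
        a = men[men.injury == "CHIMERA"].amp_true.mean()
        b = men[men.injury == "Sham"].amp_true.mean()
        assert a == pytest.approx(b, rel=0.2)

    def test_injury_effect_scales_truth(self, tiny_acq, core_tissues):
        design = DesignSpec(n_per_cell=100, injury_effects={("meninges", "Day1"): 2.0},
                            seed=6)
        cohort = simulate_cohort(design, tiny_acq, core_tissues)
        t = cohort.truth
        men = t[(t.roi == "meninges") & (t.day == "Day1")]
        ratio = (men[men.injury == "CHIMERA"].amp_true.mean()
                 / men[men.injury == "Sham"].amp_true.mean())
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_truth_and_images_deterministic(self, tiny_acq, core_tissues):
        design = DesignSpec(n_per_cell=2, seed=9)
        c1 = simulate_cohort(design, tiny_acq, core_tissues)
        c2 = simulate_cohort(design, tiny_acq, core_tissues)
        pd.testing.assert_frame_equal(c1.truth, c2.truth)
        s1 = next(c1.iter_sessions())
        s2 = next(c2.iter_sessions())
        assert np.array_equal(s1.dce.data, s2.dce.data)
        assert np.array_equal(s1.multi_echo.data, s2.multi_echo.data)

    def test_injection_multiplier_hits_muscle_but_not_auc_norm(self, tiny_acq, core_tissues):
        design = DesignSpec(n_per_cell=2, injection_sd=0.5, between_animal_sd=0.0,
                            injury_effects={}, seed=3)
        truth = simulate_cohort(design, tiny_acq, core_tissues).truth
        men = truth[truth.roi == "meninges"]
        # raw AUC varies with injection efficiency, normalized AUC does not
        assert men.auc_true.std() / men.auc_true.mean() > 0.1
        assert men.auc_norm_true.std() < 1e-12


class TestHistology:
    @pytest.mark.parametrize("frac,expected", [(0.25, 25), (0.0, 0), (1.0, 100)])
    def test_exact_counts(self, frac, expected):
        img = simulate_histology_image(frac, (10, 10), seed=0)
        assert img.sum() == expected

    def test_reproducible_and_clumped(self):
        a = simulate_histology_image(0.3, (64, 64), seed=7)
        b = simulate_histology_image(0.3, (64, 64), seed=7)
        assert np.array_equal(a, b)
        # clumping: stained pixels share more stained neighbours than chance
        from scipy import ndimage
        nb = ndimage.uniform_filter(a.astype(float), 3)
        assert nb[a].mean() > 0.5

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            simulate_histology_image(1.5, (10, 10), seed=0)


class TestValidation:
    def test_tissue_spec_invariants(self):
        with pytest.raises(ValueError):
            TissueSpec("meninges", s0=-1, t2_ms=50)
        with pytest.raises(ValueError):
            TissueSpec("meninges", s0=1, t2_ms=0)
        with pytest.raises(ValueError):
            TissueSpec("meninges", s0=1, t2_ms=50, enhancement_amp=-0.1)

    def test_design_spec_invariants(self):
        with pytest.raises(ValueError):
            DesignSpec(n_per_cell=1)
        with pytest.raises(ValueError):
            DesignSpec(days=("Baseline", "Day1"))

    def test_uptake_curve_zero_before_injection(self):
        t = np.linspace(0, 11, 23)
        e = uptake_curve(t, 0.5, 1.0, 2.0)
        assert np.all(e[t < 2.0] == 0)
        assert np.all(np.diff(e) >= 0)
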