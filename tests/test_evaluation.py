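import numpy as np
import pytest

from conftest import gaussian_blob
from pamnet.evaluation import (
    PairedComparison,
    confusion_report,
    count_sources,
    image_snr,
    localization_error,
    main_lobe_radii,
    nrmse,
    pslr,
    psnr,
    sign_test,
)


class TestPSNR:
    def test_closed_form_20db(self, rng):
        truth = rng.random((10, 10, 10))
        truth.flat[0] = 1.0  # I_max = 1
        # construct a prediction with MSE exactly 0.01
        delta = np.full(truth.shape, 0.1)
        assert psnr(truth, truth + delta) == pytest.approx(20.0, abs=1e-9)

    def test_identical_gives_sentinel(self, rng):
        x = rng.random((5, 5, 5))
        assert psnr(x, x) == np.inf

    def test_joint_scale_invariance(self, rng):
        truth, pred = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        assert psnr(3 * truth, 3 * pred) == pytest.approx(psnr(truth, pred), abs=1e-9)


class TestNRMSE:
    def test_identical_zero(self, rng):
        x = rng.random((5, 5, 5))
        assert nrmse(x, x) == 0.0

    def test_constant_offset_closed_form(self, rng):
        truth = rng.random((6, 6, 6))
        c = 0.37
        expected = c / (truth.max() - truth.min())
        assert nrmse(truth, truth + c) == pytest.approx(expected, abs=1e-9)

    def test_joint_affine_invariance(self, rng):
        truth, pred = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        assert nrmse(2 * truth + 1, 2 * pred + 1) == pytest.approx(
            nrmse(truth, pred), abs=1e-9)

    def test_flat_truth_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones((3, 3, 3)), np.zeros((3, 3, 3)))


class TestCountSources:
    def test_single_blob(self):
        vol = gaussian_blob((41, 41, 41), (20, 20, 20), (2, 2, 2))
        assert count_sources(vol).count == 1

    def test_two_separated_blobs(self):
        """Centers 4 mm apart at 0.25 mm pitch, sigma 0.5 mm: resolved."""
        s = (2, 2, 2)  # 0.5 mm in voxels
        vol = (gaussian_blob((41, 41, 41), (12, 20, 20), s)
               + gaussian_blob((41, 41, 41), (28, 20, 20), s))  # 16 voxels = 4 mm
        assert count_sources(vol).count == 2

    def test_close_blobs_merge(self):
        """Separation below the -3 dB width gives one component."""
        s = (4, 4, 4)
        vol = (gaussian_blob((41, 41, 41), (18, 20, 20), s)
               + gaussian_blob((41, 41, 41), (24, 20, 20), s))
        assert count_sources(vol).count == 1

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            count_sources(np.zeros((5, 5, 5)))

    def test_component_peaks_reported(self):
        vol = gaussian_blob((21, 21, 21), (10, 10, 10), (1.5, 1.5, 1.5))
        det = count_sources(vol)
        assert tuple(det.peak_locations[0]) == (10, 10, 10)
        assert det.peak_intensities[0] == pytest.approx(vol.max())


class TestPSLR:
    def test_constructed_secondary_lobe(self):
        vol = gaussian_blob((31, 31, 31), (10, 15, 15), (1.5, 1.5, 1.5))
        vol += 0.5 * gaussian_blob((31, 31, 31), (24, 15, 15), (1.5, 1.5, 1.5))
        det = count_sources(vol)
        assert pslr(vol, det) == pytest.approx(0.5, abs=0.01)

    def test_unimodal_below_threshold(self):
        vol = gaussian_blob((31, 31, 31), (15, 15, 15), (2, 2, 2))
        det = count_sources(vol)
        assert pslr(vol, det) < 0.501

    def test_bounded_by_one(self, rng):
        vol = rng.random((11, 11, 11))
        det = count_sources(vol)
        assert pslr(vol, det) <= 1.0

    def test_single_voxel_volume(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        det = count_sources(vol)
        assert pslr(vol, det) == 0.0


class TestImageSNR:
    def test_known_background_std(self, rng):
        vol = 0.01 * rng.standard_normal((41, 41, 41)) + 0.05
        vol[20, 20, 20] = 1.0
        det = count_sources(vol)
        snr = image_snr(vol, wavelength=2.45, detection=det, voxel_pitch=0.25)
        assert snr == pytest.approx(1.0 / 0.01, rel=0.1)

    def test_constant_shift_invariant_std(self, rng):
        vol = 0.01 * rng.standard_normal((41, 41, 41)) + 0.05
        vol[20, 20, 20] = 1.0
        det = count_sources(vol)
        a = image_snr(vol, 2.45, det, 0.25)
        shifted = vol + 0.2
        det2 = count_sources(shifted)
        b = image_snr(shifted, 2.45, det2, 0.25)
        assert b == pytest.approx(a * shifted.max() / vol.max(), rel=1e-6)

    def test_empty_background_rejected(self, rng):
        vol = rng.random((5, 5, 5))
        det = count_sources(vol)
        with pytest.raises(ValueError):
            image_snr(vol, wavelength=100.0, detection=det, voxel_pitch=0.25)


class TestLocalization:
    def test_identical_zero(self, rng):
        x = rng.random((9, 9, 9))
        assert localization_error(x, x, 0.25) == 0.0

    def test_single_axis_shift(self):
        a = gaussian_blob((21, 21, 21), (10, 10, 10), (1.5, 1.5, 1.5))
        b = gaussian_blob((21, 21, 21), (11, 10, 10), (1.5, 1.5, 1.5))
        assert localization_error(a, b, 0.25) == pytest.approx(0.25)

    def test_diagonal_shift(self):
        a = gaussian_blob((21, 21, 21), (10, 10, 10), (1.5, 1.5, 1.5))
        b = gaussian_blob((21, 21, 21), (11, 11, 11), (1.5, 1.5, 1.5))
        assert localization_error(a, b, 0.25) == pytest.approx(0.25 * np.sqrt(3))


class TestMainLobeRadii:
    def test_gaussian_halfwidths(self):
        """-3 dB half-width of a Gaussian: sigma * sqrt(0.3 ln 10)."""
        pitch = 0.25
        sig_mm = np.array([0.5, 0.5, 1.5])
        vol = gaussian_blob((41, 41, 41), (20, 20, 20), sig_mm / pitch)
        det = count_sources(vol)
        radii = main_lobe_radii(vol, det, pitch)
        expected = sig_mm * np.sqrt(0.6 * np.log(10.0))
        assert np.allclose(radii, expected, atol=pitch)
        assert expected == pytest.approx([0.589, 0.589, 1.766], abs=0.01)

    def test_isotropic_short_axes_equal(self):
        vol = gaussian_blob((41, 41, 41), (20, 20, 20), (3, 3, 3))
        det = count_sources(vol)
        r = main_lobe_radii(vol, det, 0.25)
        assert r[0] == pytest.approx(r[1], abs=1e-9)

    def test_radii_scale_with_sigma(self):
        det_of = lambda v: count_sources(v)
        v1 = gaussian_blob((61, 61, 61), (30, 30, 30), (2, 2, 2))
        v2 = gaussian_blob((61, 61, 61), (30, 30, 30), (4, 4, 4))
        r1 = main_lobe_radii(v1, det_of(v1), 0.25)
        r2 = main_lobe_radii(v2, det_of(v2), 0.25)
        assert r2[0] == pytest.approx(2 * r1[0], rel=0.05)

    def test_single_voxel_lobe_warns_zero(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        det = count_sources(vol)
        with pytest.warns(UserWarning):
            assert main_lobe_radii(vol, det, 0.25) == (0.0, 0.0, 0.0)


class TestSignTest:
    def test_ten_concordant(self):
        assert sign_test([1.0] * 10) == pytest.approx(2 * 0.5**10)

    def test_balanced(self):
        assert sign_test([1, -1, 1, -1, 1, -1, 1, -1, 1, -1]) == pytest.approx(1.0)

    def test_magnitude_invariant(self, rng):
        signs = rng.choice([-1.0, 1.0], size=20)
        assert sign_test(signs) == pytest.approx(sign_test(signs * rng.random(20)))

    def test_zeros_excluded(self):
        assert sign_test([0.0, 0.0, 1.0, 1.0, 1.0]) == pytest.approx(2 * 0.5**3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sign_test([0.0, 0.0])

    def test_paired_comparison_summary(self):
        pc = PairedComparison.from_pairs([1, 2, 3, 4], [2, 3, 4, 5])
        assert pc.median_difference == 1.0
        assert pc.p_value == pytest.approx(2 * 0.5**4)


class TestConfusionReport:
    def test_perfect_predictions(self):
        counts = [1, 2, 3, 4, 5, 1, 2, 3]
        rep = confusion_report(counts, counts)
        for k in range(1, 6):
            assert rep[k]["TPR"] == 1.0
            assert rep[k]["FPR"] == 0.0

    def test_hand_worked_six_frames(self):
        """One miscount (a true 2 predicted as 1) tallied by hand."""
        true_c = [1, 2, 3, 1, 2, 3]
        pred_c = [1, 1, 3, 1, 2, 3]
        rep = confusion_report(true_c, pred_c)
        assert rep[1]["TPR"] == 1.0            # both true 1s found
        assert rep[1]["FPR"] == pytest.approx(1 / 4)   # one false "1" among 4 non-1 frames
        assert rep[2]["TPR"] == pytest.approx(1 / 2)
        assert rep[2]["FNR"] == pytest.approx(1 / 2)
        assert rep[3]["TPR"] == 1.0

    def test_rates_complementary(self, rng):
        true_c = rng.integers(1, 6, 40)
        pred_c = rng.integers(1, 6, 40)
        rep = confusion_report(true_c, pred_c)
        for k in range(1, 6):
            if not np.isnan(rep[k]["TPR"]):
                assert rep[k]["TPR"] + rep[k]["FNR"] == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_report([1, 2], [1])
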