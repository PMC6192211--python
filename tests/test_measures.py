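import numpy as np
import pytest
from scipy import ndimage

from smlm_fidelity import otsu_threshold, q_binarized, q_freq, q_l2, q_pearson
from smlm_fidelity.errors import DegenerateInputError, ParameterError

from conftest import random_image


class TestPearson:
    def test_self_correlation_is_one(self):
        a = random_image(0)
        assert q_pearson(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        a = random_image(1)
        assert q_pearson(a, 3.0 * a + 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_anticorrelation(self):
        ref = np.array([[0.0, 1.0], [2.0, 3.0]])
        rec = np.array([[3.0, 2.0], [1.0, 0.0]])
        assert q_pearson(ref, rec) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            q_pearson(np.ones((8, 8)), random_image(2, (8, 8)))

    def test_symmetry_and_bounds(self):
        for seed in range(5):
            a, b = random_image(seed), random_image(seed + 100)
            q = q_pearson(a, b)
            assert q == q_pearson(b, a)
            assert -1.0 <= q <= 1.0


class TestOtsu:
    def test_separates_bimodal_halves(self):
        img = np.zeros((32, 32))
        img[16:] = 1.0
        assert 0.0 < otsu_threshold(img) < 1.0

    def test_scale_equivariance(self):
        img = random_image(3)
        assert otsu_threshold(img * 10.0) == pytest.approx(
            10.0 * otsu_threshold(img), rel=1e-6
        )

    def test_two_gaussian_clusters_misclassification(self):
        rng = np.random.default_rng(4)
        lo = rng.normal(0.2, 0.03, size=2000)
        hi = rng.normal(0.8, 0.03, size=2000)
        img = np.concatenate([lo, hi]).reshape(50, 80)
        thr = otsu_threshold(img)
        labels = img > thr
        truth = np.concatenate(
            [np.zeros(2000, bool), np.ones(2000, bool)]
        ).reshape(50, 80)
        assert (labels != truth).mean() < 0.01

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((8, 8), 2.0))


class TestBinarizedOverlap:
    def test_identical_binarizations_score_one(self):
        img = random_image(5)
        assert q_binarized(img, img.copy()) == pytest.approx(1.0)

    def test_all_background_reconstruction_scores_zero(self):
        ref = np.zeros((20, 20), dtype=bool)
        ref[:5, :20] = True  # 100 foreground pixels
        rec = np.zeros((20, 20), dtype=bool)
        assert q_binarized(ref, rec) == pytest.approx(0.0)

    def test_false_positives_halve_the_score(self):
        ref = np.zeros((20, 20), dtype=bool)
        ref[:5] = True  # 100 foreground pixels
        rec = ref.copy()
        rec[5:7, :5] = True  # hits all 100, adds 10 false positives... scaled
        rec[7:11, :10] = True  # total 50 extra pixels
        assert q_binarized(ref, rec) == pytest.approx(1.0 - 50 / 100)

    def test_can_go_negative_unclamped(self):
        ref = np.zeros((20, 20), dtype=bool)
        ref[0, :10] = True
        rec = ~ref  # misses all 10, adds 390 false positives
        assert q_binarized(ref, rec) == pytest.approx(1.0 - 400 / 10)

    def test_empty_reference_foreground_rejected(self):
        with pytest.raises(DegenerateInputError):
            q_binarized(np.zeros((8, 8), dtype=bool), np.ones((8, 8), dtype=bool))


class TestL2:
    def test_perfect_agreement_is_zero(self):
        a = random_image(6)
        assert q_l2(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_contrast_invariance(self):
        a = random_image(7)
        assert q_l2(a, 5.0 * a + 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair_scores_two(self):
        a = random_image(8)
        b = random_image(9)
        ca = a - a.mean()
        cb = b - b.mean()
        cb -= (ca * cb).sum() / (ca * ca).sum() * ca  # orthogonalize
        assert q_l2(ca, cb) == pytest.approx(2.0, abs=1e-10)
        # brute-force expansion: 2 - 2 * (unit dot product)
        ua = ca / np.sqrt((ca * ca).sum())
        ub_ = (cb - cb.mean())
        ub = ub_ / np.sqrt((ub_ * ub_).sum())
        assert q_l2(ca, cb) == pytest.approx(2 - 2 * (ua * ub).sum(), abs=1e-10)

    def test_identity_with_pearson(self):
        """q_l2 == 2 (1 - q_pearson): the primary cross-check of the two
        scalar measures, both functions of the same centered unit vectors."""
        for seed in range(100):
            a, b = random_image(seed, (32, 32)), random_image(seed + 500, (32, 32))
            assert abs(q_l2(a, b) - 2.0 * (1.0 - q_pearson(a, b))) < 1e-10

    def test_bounds_and_symmetry(self):
        for seed in range(5):
            a, b = random_image(seed), random_image(seed + 50)
            assert 0.0 <= q_l2(a, b) <= 4.0
            assert q_l2(a, b) == pytest.approx(q_l2(b, a), abs=1e-12)


class TestFreqSimilarity:
    def test_identical_images_score_one_on_every_ring(self):
        a = random_image(10, (128, 128))
        fs = q_freq(a, a.copy(), k=16)
        assert np.all(fs.values == 1.0)
        assert len(fs.frequencies) == 16
        assert np.all(np.diff(fs.frequencies) > 0)

    def test_blur_plus_noise_decays_with_frequency(self, filament_small):
        """Low rings stay near 1, high rings fall toward 0 after Gaussian
        blur with added noise."""
        ref = filament_small.values
        rng = np.random.default_rng(11)
        rec = ndimage.gaussian_filter(ref, sigma=4.0) + rng.normal(0, 0.05, ref.shape)
        fs = q_freq(ref, rec, k=32)
        assert fs.values[0] > 0.9
        assert np.nanmean(fs.values[-8:]) < 0.2
        assert np.nanmean(fs.values[:8]) > np.nanmean(fs.values[-8:])

    def test_independent_noise_rings_near_zero(self):
        """Ring means of independent white-noise pairs obey the CLT bound
        4 / sqrt(ring count)."""
        h = w = 128
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        fr = np.sqrt(fx**2 + fy**2)
        k = 16
        ring = np.ceil(fr / (0.5 / k)).astype(int) - 1
        counts = np.bincount(ring[(ring >= 0) & (ring < k)].ravel(), minlength=k)
        for seed in range(5):
            a = random_image(seed, (h, w))
            b = random_image(seed + 1000, (h, w))
            fs = q_freq(a, b, k=k)
            assert np.all(np.abs(fs.values) < 4.0 / np.sqrt(counts))

    def test_amplitude_rescaling_leaves_phases_untouched(self):
        a, b = random_image(12), random_image(13)
        fs = q_freq(a, b, k=8)
        fs_scaled = q_freq(a, 7.5 * b, k=8)
        assert np.allclose(fs.values, fs_scaled.values, atol=1e-12)

    def test_translation_hits_high_frequencies_first(self, filament_small):
        ref = filament_small.values
        rec = np.roll(ref, 1, axis=1)
        fs = q_freq(ref, rec, k=32)
        assert fs.values[0] > 0.9
        assert np.nanmean(fs.values[:8]) > np.nanmean(fs.values[-8:])

    def test_symmetry(self):
        a, b = random_image(14), random_image(15)
        assert np.allclose(q_freq(a, b, k=8).values, q_freq(b, a, k=8).values)

    def test_physical_frequency_axis(self):
        a = random_image(16, (128, 128))
        fs = q_freq(a, a, k=16, pixel_size=6.4)
        # last ring edge is the Nyquist frequency of the 6.4 nm grid
        assert fs.frequencies[-1] + fs.delta_f / 2 == pytest.approx(1 / (2 * 6.4))
        assert fs.freq_unit == "cycles/nm"

    def test_tukey_window_keeps_perfect_agreement(self):
        a = random_image(17, (128, 128))
        fs = q_freq(a, a.copy(), k=8, window="tukey")
        assert np.all(fs.values[~np.isnan(fs.values)] == 1.0)

    def test_parameter_errors(self):
        a = random_image(18, (32, 32))
        with pytest.raises(ParameterError):
            q_freq(a, a, k=17)  # only 16 resolvable rings on a 32 px grid
        with pytest.raises(ParameterError):
            q_freq(a, a, k=1)
        with pytest.raises(ParameterError):
            q_freq(a, random_image(19, (16, 16)))
        with pytest.raises(ParameterError):
            q_freq(a, a, k=8, window="hann")

    def test_serialization(self, tmp_path):
        a, b = random_image(20), random_image(21)
        fs = q_freq(a, b, k=8, pixel_size=6.4)
        fs.to_csv(tmp_path / "spec.csv")
        header = (tmp_path / "spec.csv").read_text().splitlines()[0]
        assert header == "f_cycles_per_nm,q"
        payload = fs.to_json(tmp_path / "spec.json")
        import json

        assert json.loads(payload)["k"] == 8


def test_shape_mismatch_rejected_everywhere():
    a, b = random_image(22, (16, 16)), random_image(23, (16, 18))
    for fn in (q_pearson, q_l2, q_binarized):
        with pytest.raises(ParameterError):
            fn(a, b)
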