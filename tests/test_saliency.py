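import numpy as np
import pytest

from tls2d.saliency import (
    SaliencyParams,
    abstract_elements,
    assign_saliency,
    compute_saliency,
    distribution,
    tumor_probability,
    uniqueness,
)


def blob_image(h=64, w=64, cy=30, cx=34, r=7, bright=0.8, bg=0.15):
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    img = np.full((h, w), bg)
    img += (bright - bg) * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
    return img


class TestAbstractElements:
    def test_element_count_band_and_coverage(self):
        el = abstract_elements(blob_image(), n_elements=100)
        assert 50 <= el.n_elements <= 200
        assert el.labels.min() == 0
        assert el.labels.max() == el.n_elements - 1
        assert set(np.unique(el.labels)) == set(range(el.n_elements))

    def test_half_and_half_separates_cleanly(self):
        # a two-valued image: every element is pure black or pure white
        img = np.zeros((40, 40))
        img[:, 20:] = 1.0
        el = abstract_elements(img, n_elements=8, compactness=1.0)
        assert np.all(
            (np.abs(el.intensity) < 0.05) | (np.abs(el.intensity - 1) < 0.05)
        )
        assert el.intensity.min() < 0.05 < 0.95 < el.intensity.max()

    def test_constant_image_single_element(self):
        el = abstract_elements(np.full((32, 32), 0.5), n_elements=50)
        assert np.ptp(el.intensity) == 0.0

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            abstract_elements(np.zeros((16, 16)), n_elements=1)


class TestContrastMeasures:
    def test_equal_intensities_zero_uniqueness(self):
        el = abstract_elements(np.full((32, 32), 0.3), n_elements=10)
        assert np.abs(uniqueness(el)).max() == 0.0

    def test_bright_element_has_max_uniqueness(self):
        el = abstract_elements(blob_image(), n_elements=60)
        U = uniqueness(el)
        assert el.intensity[np.argmax(U)] == el.intensity.max()

    def test_uniqueness_matches_double_loop(self):
        el = abstract_elements(blob_image(), n_elements=40)
        sigma_p = 20.0
        U = uniqueness(el, sigma_p=sigma_p)
        N = el.n_elements
        ref = np.zeros(N)
        for i in range(N):
            ws = np.array(
                [
                    np.exp(
                        -np.sum((el.position[i] - el.position[j]) ** 2)
                        / (2 * sigma_p**2)
                    )
                    for j in range(N)
                ]
            )
            ws /= ws.sum()
            ref[i] = np.sum(
                ws * (el.intensity[i] - el.intensity) ** 2
            )
        assert np.abs(U - ref).max() < 1e-10

    def test_distribution_matches_double_loop(self):
        el = abstract_elements(blob_image(), n_elements=40)
        sigma_c = 0.1
        D = distribution(el, sigma_c=sigma_c)
        N = el.n_elements
        ref = np.zeros(N)
        for i in range(N):
            wc = np.exp(
                -((el.intensity[i] - el.intensity) ** 2) / (2 * sigma_c**2)
            )
            wc /= wc.sum()
            mu = wc @ el.position
            ref[i] = np.sum(wc * np.sum((el.position - mu) ** 2, axis=1))
        assert np.abs(D - ref).max() < 1e-10

    def test_compact_unique_blob_low_distribution(self):
        el = abstract_elements(blob_image(), n_elements=60)
        D = distribution(el)
        bright = np.argmax(el.intensity)
        assert D[bright] <= np.median(D)

    def test_scattered_intensity_spreads_distribution(self):
        # same bright intensity at two opposite corners vs one compact blob
        img = np.full((48, 48), 0.2)
        img[4:12, 4:12] = 0.9
        img[36:44, 36:44] = 0.9
        el2 = abstract_elements(img, n_elements=80, compactness=0.5)
        D2 = distribution(el2)
        img1 = np.full((48, 48), 0.2)
        img1[4:12, 4:12] = 0.9
        el1 = abstract_elements(img1, n_elements=80, compactness=0.5)
        D1 = distribution(el1)
        bright2 = D2[el2.intensity > 0.6].min()
        bright1 = D1[el1.intensity > 0.6].min()
        assert bright2 > bright1


class TestSaliencyMap:
    def test_constant_image_all_zero(self):
        sal = compute_saliency(np.full((32, 32), 0.7))
        assert np.abs(sal).max() == 0.0

    def test_bright_blob_attains_max(self):
        img = blob_image()
        sal = compute_saliency(img)
        assert sal.max() == pytest.approx(1.0)
        # the map's peak lies inside the blob
        iy, ix = np.unravel_index(sal.argmax(), sal.shape)
        assert (iy - 30) ** 2 + (ix - 34) ** 2 <= 10**2

    def test_range_contract(self, standard_phantom):
        img = standard_phantom.observed_images[0]
        sal = compute_saliency(img)
        assert sal.min() >= 0.0 and sal.max() <= 1.0

    def test_requires_contrast_measures(self):
        el = abstract_elements(blob_image(), n_elements=20)
        with pytest.raises(ValueError):
            assign_saliency(el)

    def test_tumor_region_dominates_saliency(self, standard_phantom):
        i = standard_phantom.tumor_indices()[0]
        sal = compute_saliency(standard_phantom.observed_images[i])
        m = standard_phantom.tumor_masks[i]
        assert sal[m].mean() >= 5 * sal[~m].mean()


class TestTumorProbability:
    def test_empty_mask_zero_map(self):
        P = tumor_probability(np.zeros((8, 8), bool), np.random.default_rng(0).random((8, 8)))
        assert not P.any()

    def test_full_saliency_returns_mask(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        P = tumor_probability(mask, np.ones((8, 8)))
        assert np.array_equal(P, mask.astype(float))

    def test_pointwise_product(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        sal = np.full((4, 4), 0.7)
        P = tumor_probability(mask, sal)
        assert P[1, 1] == pytest.approx(0.7)
        assert P.sum() == pytest.approx(0.7)

    def test_bounded_by_both_factors(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 10)) > 0.5
        sal = rng.random((10, 10))
        P = tumor_probability(mask, sal)
        assert np.all(P <= mask.astype(float) + 1e-12)
        assert np.all(P <= sal + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tumor_probability(np.zeros((4, 4), bool), np.zeros((5, 4)))

    def test_saliency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tumor_probability(np.zeros((4, 4), bool), np.full((4, 4), 1.2))
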