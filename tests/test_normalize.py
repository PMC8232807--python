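"""The six intensity-normalization methods and their contracts."""

import numpy as np
import pytest

from mriharm.core import ImageVolume
from mriharm.normalize import (
    estimate_wm_mean_fcm,
    estimate_wm_mean_gmm,
    find_wm_peak_kde,
    normalize_volume,
    nyul_apply,
    nyul_learn_standard_histogram,
    whitestripe_normalize,
    wm_ratio_normalize,
    zscore_normalize,
)

from conftest import synthetic_brain_1d, volume_from_1d


@pytest.fixture
def brain_volume(rng):
    vals = synthetic_brain_1d(rng)
    return volume_from_1d(vals)


class TestZScore:
    def test_hand_computed_example(self):
        vol = ImageVolume(np.array([2.0, 4.0, 6.0]).reshape(3, 1, 1), (1, 1, 1))
        mask = np.ones(vol.shape, bool)
        out, params = zscore_normalize(vol, mask)
        assert params.mu == pytest.approx(4.0)
        assert params.sigma == pytest.approx(np.sqrt(8.0 / 3.0))
        np.testing.assert_allclose(
            out.values.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_masked_mean_zero_std_one(self, brain_volume):
        vol, mask = brain_volume
        out, _ = zscore_normalize(vol, mask)
        assert out.values[mask].mean() == pytest.approx(0.0, abs=1e-8)
        assert out.values[mask].std() == pytest.approx(1.0, abs=1e-8)

    def test_idempotent_on_standardized_input(self, brain_volume):
        vol, mask = brain_volume
        once, _ = zscore_normalize(vol, mask)
        twice, _ = zscore_normalize(once, mask)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_constant_region_rejected(self):
        vol = ImageVolume(np.full((4, 4, 4), 3.0), (1, 1, 1))
        with pytest.raises(ValueError):
            zscore_normalize(vol, np.ones(vol.shape, bool))


class TestWhiteStripe:
    def test_stripe_mean_zero(self, brain_volume):
        vol, mask = brain_volume
        out, params = whitestripe_normalize(vol, mask)
        # the stripe in output units: recompute around the output's WM peak
        vals = out.values[mask]
        assert params.mu == pytest.approx(200.0, abs=5.0)
        # voxels near the WM mode should now sit near 0
        stripe = vals[np.abs(vals) < 0.5]
        assert abs(stripe.mean()) < 0.2

    def test_affine_equivariance(self, brain_volume):
        vol, mask = brain_volume
        out1, _ = whitestripe_normalize(vol, mask)
        shifted = ImageVolume(2.5 * vol.values + 40.0, vol.spacing)
        out2, _ = whitestripe_normalize(shifted, mask)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-6)

    def test_wide_stripe_approaches_zscore(self, rng):
        vals = rng.normal(150.0, 20.0, 20000)  # unimodal input
        vol, mask = volume_from_1d(vals)
        ws, _ = whitestripe_normalize(vol, mask, stripe_halfwidth=0.5)
        zs, _ = zscore_normalize(vol, mask)
        rms = np.sqrt(np.mean((ws.values[mask] - zs.values[mask]) ** 2))
        scale = np.sqrt(np.mean(zs.values[mask] ** 2))
        assert rms / scale < 0.05


class TestWMEstimators:
    def test_fcm_on_separated_mixture(self, rng):
        vals = np.concatenate(
            [rng.normal(m, 5.0, 4000) for m in (50.0, 120.0, 200.0)]
        )
        vol, mask = volume_from_1d(vals)
        assert estimate_wm_mean_fcm(vol, mask) == pytest.approx(200.0, abs=3.0)

    def test_fcm_three_distinct_constants(self):
        vals = np.repeat([10.0, 20.0, 30.0], 200)
        vol, mask = volume_from_1d(vals)
        assert estimate_wm_mean_fcm(vol, mask) == pytest.approx(30.0, abs=1e-6)

    def test_fcm_permutation_invariant(self, rng):
        vals = np.concatenate([rng.normal(m, 5.0, 1000) for m in (50, 120, 200)])
        vol1, mask = volume_from_1d(vals)
        shuffled = vals.copy()
        rng.shuffle(shuffled)
        vol2, _ = volume_from_1d(shuffled)
        assert estimate_wm_mean_fcm(vol1, mask) == pytest.approx(
            estimate_wm_mean_fcm(vol2, mask), abs=1e-9
        )

    def test_gmm_on_separated_mixture(self, rng):
        vals = np.concatenate([rng.normal(m, 5.0, 4000) for m in (50, 120, 200)])
        vol, mask = volume_from_1d(vals)
        gmm = estimate_wm_mean_gmm(vol, mask)
        assert gmm == pytest.approx(200.0, abs=3.0)
        fcm = estimate_wm_mean_fcm(vol, mask)
        assert abs(gmm - fcm) / fcm < 0.05  # cross-method agreement

    def test_kde_bimodal_returns_brightest_mode(self, rng):
        vals = np.concatenate([rng.normal(120, 10, 6000), rng.normal(200, 10, 6000)])
        vol, mask = volume_from_1d(vals)
        peak = find_wm_peak_kde(vol, mask)
        assert peak == pytest.approx(200.0, abs=5.0)

    def test_kde_unimodal(self, rng):
        vals = rng.normal(150.0, 10.0, 10000)
        vol, mask = volume_from_1d(vals)
        assert find_wm_peak_kde(vol, mask) == pytest.approx(150.0, abs=3.0)

    def test_kde_affine_equivariant(self, rng):
        vals = np.concatenate([rng.normal(120, 10, 5000), rng.normal(200, 10, 5000)])
        vol, mask = volume_from_1d(vals)
        p1 = find_wm_peak_kde(vol, mask)
        vol2, _ = volume_from_1d(3.0 * vals + 7.0)
        p2 = find_wm_peak_kde(vol2, mask)
        assert p2 == pytest.approx(3.0 * p1 + 7.0, abs=5.0)


class TestWMRatio:
    def test_direct_substitution(self):
        vol = ImageVolume(np.array([50.0, 100.0, 150.0]).reshape(3, 1, 1), (1, 1, 1))
        out = wm_ratio_normalize(vol, mu=100.0, c=1.0)
        np.testing.assert_allclose(out.values.ravel(), [0.5, 1.0, 1.5])

    def test_c_equal_mu_is_identity(self, brain_volume):
        vol, mask = brain_volume
        out = wm_ratio_normalize(vol, mu=100.0, c=100.0)
        np.testing.assert_allclose(out.values, vol.values)

    def test_nonpositive_mu_rejected(self, brain_volume):
        vol, _ = brain_volume
        with pytest.raises(ValueError):
            wm_ratio_normalize(vol, mu=0.0)

    def test_round_trip_pins_wm_mean_to_c(self, brain_volume):
        """Re-estimating the WM mean on fcm-normalized output yields c."""
        vol, mask = brain_volume
        out, params = normalize_volume(vol, mask, "fcm", c=1.0)
        mu2 = estimate_wm_mean_fcm(out, mask)
        assert mu2 == pytest.approx(1.0, rel=0.01)


class TestNyul:
    def test_single_image_training_is_fixed_point(self, brain_volume):
        vol, mask = brain_volume
        scale = nyul_learn_standard_histogram([vol, vol], [mask, mask])
        out, _ = nyul_apply(vol, mask, scale)
        lm_in = np.percentile(vol.values[mask], scale.percentiles)
        lm_out = np.percentile(out.values[mask], scale.percentiles)
        np.testing.assert_allclose(lm_out, scale.landmarks, atol=1e-9)
        assert lm_out[0] == pytest.approx(1.0, abs=1e-9)

    def test_affine_related_images_learn_identical_landmarks(self, brain_volume):
        vol, mask = brain_volume
        vol2 = ImageVolume(1.7 * vol.values + 25.0, vol.spacing)
        s1 = nyul_learn_standard_histogram([vol, vol], [mask, mask])
        s2 = nyul_learn_standard_histogram([vol2, vol2], [mask, mask])
        np.testing.assert_allclose(s1.landmarks, s2.landmarks, atol=1e-9)

    def test_learned_landmarks_strictly_increasing(self, brain_volume):
        vol, mask = brain_volume
        vol2 = ImageVolume(vol.values**1.1, vol.spacing)
        scale = nyul_learn_standard_histogram([vol, vol2], [mask, mask])
        assert np.all(np.diff(scale.landmarks) > 0)

    def test_mapping_is_monotone(self, brain_volume, rng):
        vol, mask = brain_volume
        scale = nyul_learn_standard_histogram([vol, vol], [mask, mask])
        out, _ = nyul_apply(vol, mask, scale)
        x = vol.values[mask]
        y = out.values[mask]
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-12)

    def test_affine_pair_histograms_match(self, brain_volume):
        """Two affinely related images map to nearly identical histograms."""
        vol, mask = brain_volume
        vol2 = ImageVolume(1.8 * vol.values + 30.0, vol.spacing)
        scale = nyul_learn_standard_histogram([vol, vol2], [mask, mask])
        o1, _ = nyul_apply(vol, mask, scale)
        o2, _ = nyul_apply(vol2, mask, scale)
        lo = min(o1.values[mask].min(), o2.values[mask].min())
        hi = max(o1.values[mask].max(), o2.values[mask].max())
        h1, _ = np.histogram(o1.values[mask], bins=512, range=(lo, hi), density=False)
        h2, _ = np.histogram(o2.values[mask], bins=512, range=(lo, hi), density=False)
        l1 = np.abs(h1 / h1.sum() - h2 / h2.sum()).sum()
        assert l1 < 0.05


@pytest.mark.parametrize("method", ["zscore", "whitestripe", "fcm", "gmm", "kde", "nyul"])
def test_every_method_neutralizes_global_affine_change(method, rng):
    """Paired volumes differing by a positive affine map end up comparable.

    This is the mechanism that closes the intensity gap between paired
    field-strength acquisitions: after any method the masked-mean ratio
    of the pair is within [0.9, 1.1].
    """
    vals = synthetic_brain_1d(rng)
    vol1, mask = volume_from_1d(vals)
    vol2, _ = volume_from_1d(1.8 * vals + 10.0)
    scale = None
    if method == "nyul":
        scale = nyul_learn_standard_histogram([vol1, vol2], [mask, mask])
    o1, _ = normalize_volume(vol1, mask, method, scale=scale)
    o2, _ = normalize_volume(vol2, mask, method, scale=scale)
    m1, m2 = o1.values[mask].mean(), o2.values[mask].mean()
    if method in ("zscore", "whitestripe"):
        # means are ~0 by construction; compare spread instead
        ratio = o2.values[mask].std() / o1.values[mask].std()
    else:
        ratio = m2 / m1
    assert 0.9 < ratio < 1.1


def test_geometry_untouched(rng):
    vals = synthetic_brain_1d(rng)
    vol, mask = volume_from_1d(vals, spacing=(0.9, 0.9, 3.0))
    out, _ = normalize_volume(vol, mask, "zscore")
    assert out.spacing == vol.spacing
    assert out.shape == vol.shape
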