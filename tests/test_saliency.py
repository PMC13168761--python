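"""Guided backprop gating, group t-maps, and random-field inference."""

import numpy as np
import pytest
from scipy import ndimage, stats

from svcikit import nn
from svcikit.densenet import DenseNetConfig, build_model
from svcikit.saliency import (
    estimate_fwhm,
    grf_correct,
    grf_threshold,
    group_ttest,
    guided_backprop,
    salient_regions,
)


class _ToyRelu(nn.Module):
    """y = relu(w . x) followed by a linear head with two outputs."""

    def __init__(self, w):
        rng = np.random.default_rng(0)
        self.w = np.asarray(w, dtype=np.float32)
        self.relu = nn.ReLU()

    def modules(self):
        yield self
        yield self.relu

    def parameters(self):
        return []

    def forward(self, x, train=False):
        self._x = x
        pre = (x.reshape(x.shape[0], -1) * self.w.ravel()).sum(axis=1, keepdims=True)
        h = self.relu.forward(pre)
        return np.hstack([-h, h])  # class 1 logit = relu(w.x)

    def backward(self, gout):
        g = gout[:, 1:2] - gout[:, 0:1]
        g = self.relu.backward(g)
        return (g * self.w.ravel()).reshape(self._x.shape)

    # the guided_backprop entry point expects the classifier surface
    config = type("C", (), {"in_channels": 1})


class TestGuidedBackprop:
    def test_closed_form_positive_path(self):
        """With w > 0 and a positive pre-activation the gates are inactive and
        the saliency equals |w|."""
        w = np.full((1, 16, 16, 16), 0.5, np.float32)
        model = _ToyRelu(w)
        x = np.ones((1, 1, 16, 16, 16), np.float32)
        maps = guided_backprop(model, x, target_class=1, normalize=False)
        np.testing.assert_allclose(maps[0], 0.5, rtol=1e-6)

    def test_negative_preactivation_blocks_gradient(self):
        w = np.full((1, 16, 16, 16), 0.5, np.float32)
        model = _ToyRelu(w)
        x = -np.ones((1, 1, 16, 16, 16), np.float32)
        maps = guided_backprop(model, x, target_class=1, normalize=False)
        np.testing.assert_array_equal(maps[0], 0.0)

    def test_relu_relevance_nonnegative_under_guided_mode(self):
        """At every gated rectifier the propagated relevance is nonnegative
        for random inputs."""
        rng = np.random.default_rng(0)
        relu = nn.ReLU()
        relu.guided = True
        for _ in range(100):
            x = rng.normal(size=(4, 5)).astype(np.float32)
            g = rng.normal(size=(4, 5)).astype(np.float32)
            relu.forward(x)
            assert (relu.backward(g) >= 0).all()
        relu.guided = False

    def test_deterministic_per_subject(self):
        model = build_model(
            DenseNetConfig(in_channels=1, init_filters=8, growth=4), seed=0
        )
        x = np.random.default_rng(1).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
        a = guided_backprop(model, x)
        b = guided_backprop(model, x)
        np.testing.assert_array_equal(a, b)

    def test_guided_mode_restored_after_call(self):
        model = build_model(
            DenseNetConfig(in_channels=1, init_filters=8, growth=4), seed=0
        )
        x = np.zeros((1, 1, 16, 16, 16), np.float32)
        guided_backprop(model, x)
        assert not any(
            m.guided for m in model.modules() if isinstance(m, nn.ReLU)
        )


class TestGroupTtest:
    def test_matches_textbook_t_on_random_voxels(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(0.3, 1.0, size=(12, 5, 5, 5))
        t_map, valid = group_ttest(maps)
        for _ in range(10):
            idx = tuple(rng.integers(0, 5, 3))
            expected = stats.ttest_1samp(maps[(slice(None),) + idx], 0.0).statistic
            assert t_map[idx] == pytest.approx(expected, rel=1e-10)
        assert valid.all()

    def test_zero_variance_voxel_masked(self):
        maps = np.random.default_rng(1).normal(size=(5, 4, 4, 4))
        maps[:, 0, 0, 0] = 2.5
        t_map, valid = group_ttest(maps)
        assert not valid[0, 0, 0]
        assert t_map[0, 0, 0] == 0.0

    def test_type_one_rate_on_null(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(20, 12, 12, 12))
        t_map, _ = group_ttest(maps)
        crit = stats.t.isf(0.025, 19)
        rate = (np.abs(t_map) > crit).mean()
        assert abs(rate - 0.05) < 0.015

    def test_too_few_maps(self):
        with pytest.raises(ValueError):
            group_ttest(np.zeros((2, 4, 4, 4)))


class TestGRF:
    def test_single_resel_limit_approaches_uncorrected(self):
        tiny = np.zeros((8, 8, 8), bool)
        tiny[3:5, 3:5, 3:5] = True
        thr = grf_threshold(tiny, fwhm=np.full(3, 16.0), alpha=0.05)
        assert abs(thr - stats.norm.isf(0.05)) < 0.5

    def test_fwer_controlled_on_smooth_nulls(self):
        """Family-wise false-positive rate over 200 smooth null fields."""
        rng = np.random.default_rng(0)
        shape, fwhm = (24, 24, 24), 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        mask = np.ones(shape, bool)
        hits = 0
        for _ in range(200):
            f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
            f /= f.std()
            sig, _ = grf_correct(f, mask, np.full(3, fwhm), alpha=0.05)
            hits += bool(sig.any())
        assert hits / 200 <= 0.08

    def test_agrees_with_max_statistic_permutation(self):
        """GRF threshold within 10% (z units) of the empirical 95th percentile
        of the field maximum on matched smooth nulls."""
        rng = np.random.default_rng(1)
        shape, fwhm = (24, 24, 24), 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        maxima = []
        for _ in range(200):
            f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
            maxima.append((f / f.std()).max())
        emp = np.percentile(maxima, 95)
        thr = grf_threshold(np.ones(shape, bool), np.full(3, fwhm), alpha=0.05)
        assert abs(thr - emp) / emp < 0.10

    def test_smoothness_estimate_recovers_fwhm(self):
        rng = np.random.default_rng(2)
        fwhm = 4.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        maps = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)), sigma, mode="wrap")
                for _ in range(8)
            ]
        )
        est = estimate_fwhm(maps, np.ones((24, 24, 24), bool))
        assert np.all(np.abs(est - fwhm) / fwhm < 0.25)

    def test_invalid_inputs(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            grf_threshold(mask, np.array([np.inf, 3, 3]), 0.05)
        with pytest.raises(ValueError):
            grf_threshold(mask, np.full(3, 3.0), alpha=1.5)

    def test_t_to_z_conversion_matches_tails(self):
        t = np.array([[[2.0]]])
        mask = np.ones((1, 1, 1), bool)
        sig, thr = grf_correct(t, mask, np.full(3, 2.0), alpha=0.5, df=10)
        z_expected = stats.norm.isf(stats.t.sf(2.0, 10))
        assert (z_expected >= thr) == bool(sig[0, 0, 0])


class TestSalientRegions:
    def test_confined_mask_single_region(self):
        atlas = np.zeros((6, 6, 6), int)
        atlas[:3] = 1
        atlas[3:] = 2
        sig = atlas == 2
        table = salient_regions(np.ones((6, 6, 6)), sig, atlas)
        assert table["region"].tolist() == [2]
        assert table["weight"].iloc[0] == 1.0

    def test_weights_sorted_descending(self):
        rng = np.random.default_rng(3)
        atlas = rng.integers(0, 5, size=(8, 8, 8))
        sig = rng.random((8, 8, 8)) > 0.3
        table = salient_regions(rng.random((8, 8, 8)), sig, atlas)
        w = table["weight"].to_numpy()
        assert np.all(np.diff(w) <= 0)

    def test_empty_mask_warns(self):
        atlas = np.ones((4, 4, 4), int)
        with pytest.warns(UserWarning, match="empty"):
            table = salient_regions(
                np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool), atlas
            )
        assert len(table) == 0


class TestEndToEndLocalization:
    def test_group_saliency_localizes_to_lesions(self, e2e):
        """The corrected group saliency mask overlaps planted lesion regions
        better than 95% of randomly rolled masks."""
        smaps = e2e["saliency"]
        mask = e2e["mask"]
        atlas = e2e["atlas"]
        t_map, valid = group_ttest(smaps)
        fwhm = np.clip(estimate_fwhm(smaps - smaps.mean(axis=0), mask), 1.0, 10.0)
        sig, _ = grf_correct(t_map, mask & valid, fwhm, alpha=0.05, df=len(smaps) - 1)
        assert sig.sum() > 0
        lesion = np.isin(atlas, e2e["config"].lesion_regions)

        def dice(a, b):
            return 2.0 * (a & b).sum() / (a.sum() + b.sum())

        observed = dice(sig, lesion)
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            shift = tuple(rng.integers(0, s) for s in sig.shape)
            null.append(dice(np.roll(sig, shift, axis=(0, 1, 2)), lesion))
        assert observed > np.percentile(null, 95)

    def test_top_salient_region_is_lesioned(self, e2e):
        smaps = e2e["saliency"]
        mask = e2e["mask"]
        t_map, valid = group_ttest(smaps)
        fwhm = np.clip(estimate_fwhm(smaps - smaps.mean(axis=0), mask), 1.0, 10.0)
        sig, _ = grf_correct(t_map, mask & valid, fwhm, alpha=0.05, df=len(smaps) - 1)
        table = salient_regions(smaps.mean(axis=0), sig, e2e["atlas"])
        assert int(table["region"].iloc[0]) in e2e["config"].lesion_regions
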