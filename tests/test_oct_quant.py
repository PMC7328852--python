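"""Unit and property tests for B-scan segmentation and layer metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemoassay import oct_quant as oq
from chemoassay import synthetic_data as sd


def otsu_exhaustive(histogram, n_classes):
    """Independent brute-force search over all ordered threshold tuples."""
    levels = np.asarray(sorted(histogram), dtype=float)
    counts = np.asarray([histogram[k] for k in sorted(histogram)], dtype=float)
    occ = counts > 0
    levels, counts = levels[occ], counts[occ]
    best_crit, best = -np.inf, None
    for combo in itertools.combinations(range(levels.size - 1), n_classes - 1):
        edges = (-1, *combo, levels.size - 1)
        crit = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            w = counts[lo + 1:hi + 1].sum()
            if w > 0:
                s = (counts[lo + 1:hi + 1] * levels[lo + 1:hi + 1]).sum()
                crit += s * s / w
        if crit > best_crit:
            best_crit, best = crit, combo
    return tuple(float(levels[k]) for k in best)


class TestMultilevelOtsu:
    def test_three_spike_histogram_fully_separated(self):
        # perfect 3-class separation: between-class variance equals total
        assert oq.multilevel_otsu({1: 100, 4: 100, 7: 100}, 3) == (1.0, 4.0)

    def test_two_spike_histogram_tie_breaks_low(self):
        assert oq.multilevel_otsu({0: 50, 9: 50}, 2) == (0.0,)

    def test_single_level_errors_with_deficit(self):
        with pytest.raises(oq.DegenerateHistogramError, match="deficit"):
            oq.multilevel_otsu({5: 17}, 2)

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_matches_exhaustive_search_random_histograms(self, rng, n_classes):
        for _ in range(50):
            n_levels = rng.integers(n_classes, 64)
            levels = rng.choice(64, size=n_levels, replace=False)
            hist = {int(l): int(c) for l, c in
                    zip(levels, rng.integers(1, 100, n_levels))}
            assert oq.multilevel_otsu(hist, n_classes) == \
                otsu_exhaustive(hist, n_classes)

    @settings(max_examples=60, deadline=None)
    @given(st.dictionaries(st.integers(0, 63), st.integers(0, 50),
                           min_size=3, max_size=64))
    def test_property_agrees_with_exhaustive(self, hist):
        occupied = sum(1 for c in hist.values() if c > 0)
        if occupied < 3:
            with pytest.raises(oq.DegenerateHistogramError):
                oq.multilevel_otsu(hist, 3)
        else:
            assert oq.multilevel_otsu(hist, 3) == otsu_exhaustive(hist, 3)

    def test_cross_check_against_skimage(self, rng):
        # independent library implementation on a well-separated image
        from skimage.filters import threshold_multiotsu
        img = np.concatenate([
            rng.normal(30, 3, 4000), rng.normal(120, 5, 3000),
            rng.normal(220, 5, 3000),
        ]).clip(0, 255).astype(np.uint8)
        t_ours = oq.multilevel_otsu(np.unique(img, return_counts=True), 3)
        t_skim = threshold_multiotsu(img, classes=3)
        # same class partition on this image within one grey level
        assert abs(t_ours[0] - t_skim[0]) <= 1
        assert abs(t_ours[1] - t_skim[1]) <= 1


class TestSegmentation:
    def test_noiseless_phantom_segments_exactly(self, noiseless_oct_params):
        pre, _, truth = sd.generate_oct_pair(noiseless_oct_params, 30.0, 10.0)
        mask = oq.segment_layers(pre)
        assert np.array_equal(mask.labels, truth.pre_mask)

    def test_speckled_phantom_high_mask_agreement(self, quiet_oct_params):
        pre, _, truth = sd.generate_oct_pair(quiet_oct_params, 30.0, 10.0)
        mask = oq.segment_layers(pre)
        assert (mask.labels == truth.pre_mask).mean() >= 0.99

    def test_blank_scan_warns_and_returns_background(self):
        scan = oq.BScan(pixels=np.full((40, 20), 7, dtype=np.uint16),
                        pixel_pitch_um=2.0, substrate_row=35)
        with pytest.warns(UserWarning, match="all-background"):
            mask = oq.segment_layers(scan)
        assert not mask.labels.any()

    def test_mask_respects_threshold_contract(self, quiet_oct_params):
        pre, _, _ = sd.generate_oct_pair(quiet_oct_params, 50.0, 20.0)
        mask = oq.segment_layers(pre)
        t1, t2 = mask.thresholds
        px = pre.pixels[: pre.substrate_row]
        lab = mask.labels[: pre.substrate_row]
        assert np.all(px[lab == oq.COHERENT] > t2)
        assert np.all((px[lab == oq.DISRUPTED] > t1)
                      & (px[lab == oq.DISRUPTED] <= t2))
        assert np.all(px[lab == oq.BACKGROUND] <= t1)

    def test_pixel_count_conservation(self, quiet_oct_params):
        pre, _, _ = sd.generate_oct_pair(quiet_oct_params, 50.0, 20.0)
        mask = oq.segment_layers(pre)
        counts = np.stack([(mask.labels == k).sum(axis=0) for k in range(3)])
        assert np.all(counts.sum(axis=0) == pre.pixels.shape[0])


class TestHeightsAndMetrics:
    def test_column_height_is_pixel_count_times_pitch(self):
        labels = np.zeros((200, 3), dtype=np.uint8)
        labels[50:150, 0] = oq.COHERENT          # 100 coherent px
        labels[100:150, 1] = oq.DISRUPTED        # 50 disrupted px
        scan = oq.BScan(pixels=np.ones((200, 3)), pixel_pitch_um=2.0,
                        substrate_row=180)
        prof = oq.column_heights(oq.LayerMask(labels, (0.5, 0.8)), scan)
        assert prof.coherent_um[0] == 200.0
        assert prof.disrupted_um[1] == 100.0
        assert prof.coherent_um[2] == prof.disrupted_um[2] == 0.0

    def test_shape_mismatch_rejected(self):
        scan = oq.BScan(pixels=np.ones((10, 4)), pixel_pitch_um=1.0,
                        substrate_row=9)
        mask = oq.LayerMask(np.zeros((10, 5), dtype=np.uint8), (0.0, 0.5))
        with pytest.raises(ValueError, match="shape"):
            oq.column_heights(mask, scan)

    def test_dissolution_arithmetic(self):
        pre = oq.HeightProfile(np.full(5, 200.0), np.full(5, 50.0))
        post = oq.HeightProfile(np.full(5, 100.0), np.full(5, 175.0))
        assert oq.dissolution_pct(pre, post) == pytest.approx(50.0)
        assert oq.disruption_pct(pre, post) == pytest.approx(50.0)
        assert oq.dissolution_pct(pre, pre) == 0.0
        assert oq.disruption_pct(pre, pre) == 0.0

    def test_zero_pre_height_rejected(self):
        empty = oq.HeightProfile(np.zeros(4), np.zeros(4))
        full = oq.HeightProfile(np.full(4, 10.0), np.zeros(4))
        with pytest.raises(ZeroDivisionError):
            oq.dissolution_pct(empty, full)
        with pytest.raises(ZeroDivisionError):
            oq.disruption_pct(empty, full)

    def test_noiseless_half_dissolution_recovered(self, noiseless_oct_params):
        pre, post, _ = sd.generate_oct_pair(noiseless_oct_params, 50.0, 0.0)
        pre_h = oq.column_heights(oq.segment_layers(pre), pre)
        post_h = oq.column_heights(oq.segment_layers(post), post)
        assert pre_h.mean_coherent_um == pytest.approx(200.0)
        assert post_h.mean_coherent_um == pytest.approx(100.0)
        assert oq.dissolution_pct(pre_h, post_h) == pytest.approx(50.0)

    def test_measured_dissolution_monotone_in_truth(self, noiseless_oct_params):
        measured = []
        for true_diss in range(0, 101, 10):
            pre, post, _ = sd.generate_oct_pair(
                noiseless_oct_params, float(true_diss), 0.0)
            measured.append(oq.analyze_pair(pre, post).dissolution_pct)
        assert np.all(np.diff(measured) >= 0)

    def test_noiseless_recovery_within_pixel_quantization(self):
        params = sd.OCTPhantomParams(speckle_sd=0.0, roughness_um=0.0, seed=3)
        tol = 100.0 * params.pixel_pitch_um / (
            params.nominal_thickness_um * (1 - params.disrupted_fraction))
        for true_diss in range(0, 101, 10):
            pre, post, _ = sd.generate_oct_pair(params, float(true_diss), 0.0)
            m = oq.analyze_pair(pre, post)
            assert abs(m.dissolution_pct - true_diss) <= tol
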