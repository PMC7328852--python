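"""Tests of the phantom generators: ground-truth fidelity and determinism."""

import numpy as np
import pandas as pd
import pytest

from chemoassay import oct_quant as oq
from chemoassay import synthetic_data as sd


class TestOCTPhantom:
    def test_identity_case_renders_identical_pair(self):
        params = sd.OCTPhantomParams(speckle_sd=0.0, seed=5)
        pre, post, _ = sd.generate_oct_pair(params, 0.0, 0.0)
        assert np.array_equal(pre.pixels, post.pixels)

    def test_full_dissolution_annihilates_coherent_stratum(self):
        params = sd.OCTPhantomParams(speckle_sd=0.0, roughness_um=0.0, seed=5)
        _, post, truth = sd.generate_oct_pair(params, 100.0, 0.0)
        assert (truth.post_mask == oq.COHERENT).sum() == 0
        # rendered image holds no coherent-intensity pixels above substrate
        coh_i = params.mean_intensities[2]
        assert not (post.pixels[: post.substrate_row] == coh_i).any()

    def test_half_dissolution_pixel_count_oracle(self, noiseless_oct_params):
        params = noiseless_oct_params
        pre, post, truth = sd.generate_oct_pair(params, 50.0, 0.0)
        px = params.pixel_pitch_um
        pre_um = (truth.pre_mask == oq.COHERENT).sum(axis=0) * px
        post_um = (truth.post_mask == oq.COHERENT).sum(axis=0) * px
        assert pre_um.mean() == pytest.approx(200.0)
        assert post_um.mean() == pytest.approx(100.0)

    def test_out_of_range_dissolution_rejected(self, noiseless_oct_params):
        with pytest.raises(ValueError, match="dissolution_pct"):
            sd.generate_oct_pair(noiseless_oct_params, 120.0, 0.0)
        with pytest.raises(ValueError, match="dissolution_pct"):
            sd.generate_oct_pair(noiseless_oct_params, -5.0, 0.0)
        # swelling admitted only behind the flag
        pre, post, _ = sd.generate_oct_pair(noiseless_oct_params, -5.0, 0.0,
                                            allow_negative=True)
        assert post.pixels.shape == pre.pixels.shape

    def test_oversized_strata_rejected(self):
        params = sd.OCTPhantomParams(height_px=80, substrate_row=70, seed=1)
        with pytest.raises(ValueError, match="exceed"):
            sd.generate_oct_pair(params, 0.0, 500.0)

    def test_strictly_increasing_intensities_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            sd.OCTPhantomParams(mean_intensities=(80, 10, 200))


class TestRelaxationPhantom:
    def test_initial_stress_is_strain_times_total_modulus(self):
        params = sd.RelaxationPhantomParams(E_true=(1, 1, 1, 1),
                                            tau_true=(0.1, 1, 10, 1000))
        rec, _, _ = sd.generate_relaxation_curve(params)
        assert rec.stress_pa[0] == pytest.approx(0.8, abs=1e-12)

    def test_bin_violating_tau_rejected(self):
        with pytest.raises(ValueError, match="component bins"):
            sd.RelaxationPhantomParams(E_true=(1, 1, 1, 1),
                                       tau_true=(0.1, 0.2, 10, 1000))

    def test_nonpositive_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            sd.RelaxationPhantomParams(E_true=(1, 1, 1, 1),
                                       tau_true=(0.1, 1, 10, 1000),
                                       sample_rate_hz=0.0)


class TestCLSMPhantom:
    def test_pure_live_leaves_other_channels_background(self, rng):
        params = sd.CLSMPhantomParams(fractions_pct=(100, 0, 0))
        stack, truth = sd.generate_clsm_stack(params, rng=rng)
        assert truth.counts[1] == truth.counts[2] == 0
        assert not truth.masks[1].any() and not truth.masks[2].any()
        assert stack.dead.max() < 50  # background only

    def test_counts_within_one_voxel_of_targets(self, rng):
        params = sd.CLSMPhantomParams(shape_vox=(16, 64, 64),
                                      fractions_pct=(33.4, 33.3, 33.3),
                                      biomass_fill=0.5)
        _, truth = sd.generate_clsm_stack(params, rng=rng)
        n_bio = sum(truth.counts)
        assert n_bio == round(0.5 * 16 * 64 * 64)
        targets = np.array([33.4, 33.3, 33.3]) / 100 * n_bio
        assert np.abs(np.array(truth.counts) - targets).max() <= 1.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="summing to 100"):
            sd.CLSMPhantomParams(fractions_pct=(50, 30, 30))


class TestGroupTruthSampling:
    def test_sample_calibration_hits_exact_moments(self, rng):
        design = sd.oct_reference_group(300, n=30)
        truths = sd.sample_group_truths(design, rng)
        d = truths["true_dissolution_pct"]
        assert d.mean() == pytest.approx(81.3, abs=1e-6)
        assert d.std(ddof=1) == pytest.approx(24.0, abs=1e-6)
        r = truths["true_disruption_pct"]
        assert r.mean() == pytest.approx(72.6, abs=1e-6)
        assert r.std(ddof=1) == pytest.approx(25.3, abs=1e-6)

    def test_llct_group_importances_and_derived_R(self, rng):
        design = sd.llct_reference_group(40)
        truths = sd.sample_group_truths(design, rng)
        f = truths["true_imp_free_water"]
        b = truths["true_imp_bacteria"]
        assert f.mean() == pytest.approx(44.2, abs=1e-6)
        assert b.mean() == pytest.approx(35.2, abs=1e-6)
        # importances sum to 100 per sample
        imps = truths[["true_imp_free_water", "true_imp_bound_water",
                       "true_imp_eps", "true_imp_bacteria"]].to_numpy()
        assert np.allclose(imps.sum(axis=1), 100.0)
        assert np.all(imps >= 0)
        # derived R: mean matches the group target, values consistent with
        # the shared time constants
        assert truths["true_R_pct"].mean() == pytest.approx(64.3, abs=1e-6)
        tau = truths[["tau1_s", "tau2_s", "tau3_s", "tau4_s"]].iloc[0].to_numpy()
        expected = 100.0 * (1.0 - (imps / 100.0) @ np.exp(-100.0 / tau))
        assert np.allclose(truths["true_R_pct"], expected)

    def test_group_taus_respect_bins(self, rng):
        for vol in (20, 40):
            truths = sd.sample_group_truths(sd.llct_reference_group(vol), rng)
            t = truths[["tau1_s", "tau2_s", "tau3_s", "tau4_s"]].iloc[0]
            assert t.iloc[0] < 0.5 < t.iloc[1] < 3 < t.iloc[2] < 100 < t.iloc[3]

    def test_population_mode_respects_truncation(self, rng):
        design = sd.GroupDesign(time_s=60, volume_ul=20, n=200,
                                true_dissolution_pct=20.0,
                                between_sample_sd=30.0)
        truths = sd.sample_group_truths(design, rng)
        d = truths["true_dissolution_pct"]
        assert d.min() >= 0.0 and d.max() <= 100.0

    def test_infeasible_sample_spread_rejected(self, rng):
        # SD above the Bhatia-Davis bound for [0, 100] cannot be realized
        design = sd.GroupDesign(time_s=60, volume_ul=20, n=30,
                                true_dissolution_pct=16.5,
                                between_sample_sd=41.8, calibrate="sample")
        with pytest.raises(ValueError, match="unattainable"):
            sd.sample_group_truths(design, rng)
        # ...unless swelling (negative dissolution) is admitted
        design2 = sd.GroupDesign(time_s=60, volume_ul=20, n=30,
                                 true_dissolution_pct=16.5,
                                 between_sample_sd=41.8, calibrate="sample",
                                 allow_negative_dissolution=True)
        truths = sd.sample_group_truths(design2, rng)
        assert truths["true_dissolution_pct"].mean() == pytest.approx(
            16.5, abs=1e-6)

    def test_design_invariants_enforced(self):
        with pytest.raises(ValueError, match="n must be"):
            sd.GroupDesign(time_s=60, volume_ul=20, n=0)
        with pytest.raises(ValueError, match="summing to 100"):
            sd.GroupDesign(time_s=60, volume_ul=20,
                           true_importance_pct=(40, 30, 20, 20))
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            sd.GroupDesign(time_s=60, volume_ul=20, true_dissolution_pct=101)


class TestGenerateStudy(object):
    def test_single_sample_layout(self, tmp_path):
        g = sd.GroupDesign(time_s=60, volume_ul=20, n=1)
        manifest = sd.generate_study([g], tmp_path / "s", seed=4)
        assert len(manifest) == 1
        sdir = tmp_path / "s" / manifest["sample_id"].iloc[0]
        names = {p.name for p in sdir.iterdir()}
        assert {"oct_pre.tif", "oct_post.tif", "relaxation.csv",
                "evaporation_ref.csv", "clsm.tif"} <= names

    def test_determinism_byte_identical(self, tmp_path):
        g = sd.GroupDesign(time_s=120, volume_ul=40, n=2)
        sd.generate_study([g], tmp_path / "a", seed=9)
        sd.generate_study([g], tmp_path / "b", seed=9)
        a = (tmp_path / "a" / "manifest.csv").read_bytes()
        b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert a == b
        ta = (tmp_path / "a" / "t120_v40_s000" / "oct_pre.tif").read_bytes()
        tb = (tmp_path / "b" / "t120_v40_s000" / "oct_pre.tif").read_bytes()
        assert ta == tb

    def test_refuses_overwrite_without_force(self, tmp_path):
        g = sd.GroupDesign(time_s=60, volume_ul=20, n=1)
        sd.generate_study([g], tmp_path / "s", seed=4)
        with pytest.raises(FileExistsError):
            sd.generate_study([g], tmp_path / "s", seed=4)
        sd.generate_study([g], tmp_path / "s", seed=4, force=True)

    def test_full_factorial_row_count(self, tmp_path):
        groups = [sd.GroupDesign(time_s=t, volume_ul=v, n=2)
                  for t in (60, 120, 300) for v in (20, 40)]
        manifest = sd.generate_study(groups, tmp_path / "s", seed=2)
        assert len(manifest) == 12
        cells = manifest.groupby(["time_s", "volume_ul"]).size()
        assert (cells == 2).all() and len(cells) == 6

    def test_empty_group_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="at least one group"):
            sd.generate_study([], tmp_path / "s", seed=0)
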