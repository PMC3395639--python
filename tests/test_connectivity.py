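"""Fisher-z, weight-matrix and ROI connectivity contracts."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinet.connectivity import (
    Z_CLAMP,
    build_weight_matrix,
    fisher_z,
    interhemispheric_fc,
    intrahemispheric_volume,
    seed_map,
)
from epinet.synthetic import BoldSimConfig, generate_bold
from conftest import CODES, make_bold_from_series


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.0, 0.0),
            # 0.5 * ln((1 + r) / (1 - r)) evaluated directly
            (0.5, 0.5 * np.log(1.5 / 0.5)),
            (-0.5, -0.5 * np.log(1.5 / 0.5)),
        ],
    )
    def test_matches_half_log_ratio(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)

    def test_odd_function(self):
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(fisher_z(r) + fisher_z(-r), 0.0, atol=1e-12)

    def test_clamps_perfect_correlation(self, caplog):
        with caplog.at_level(logging.WARNING):
            z = fisher_z(1.0)
        assert z == pytest.approx(Z_CLAMP)
        assert fisher_z(-1.0) == pytest.approx(-Z_CLAMP)
        assert np.isfinite(z)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.001)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_monotone_odd_and_bounded(self, r):
        z = fisher_z(r)
        assert np.isfinite(z)
        assert abs(z) <= Z_CLAMP
        assert z == pytest.approx(-fisher_z(-r), abs=1e-12)
        if abs(r) < 1 - 1e-6:
            assert np.sign(z) == np.sign(r) or r == 0


class TestBuildWeightMatrix:
    def _dataset(self, series):
        labels = [CODES["gm_left"]] * series.shape[0]
        return make_bold_from_series(series, labels)

    def test_three_voxel_toy_matches_hand_computation(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((3, 60))
        wm = build_weight_matrix(self._dataset(series))
        # oracle: per-pair Pearson + arctanh evaluated independently
        for i in range(3):
            for j in range(3):
                if i == j:
                    expected = 0.0
                else:
                    x, y = series[i], series[j]
                    r = ((x - x.mean()) @ (y - y.mean())) / (
                        np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                    )
                    expected = max(0.0, np.arctanh(r))
                assert wm.w[i, j] == pytest.approx(expected, abs=1e-12)

    def test_negative_correlations_zeroed(self):
        t = np.linspace(0, 1, 80)
        base = np.sin(2 * np.pi * 3 * t)
        rng = np.random.default_rng(0)
        x = base + 0.3 * rng.standard_normal(80)
        y = -base + 0.3 * rng.standard_normal(80)
        assert np.corrcoef(x, y)[0, 1] < -0.5
        wm = build_weight_matrix(self._dataset(np.stack([x, y, base])))
        assert wm.w[0, 1] == 0.0

    def test_identical_voxels_clamped_not_infinite(self):
        s = np.random.default_rng(1).standard_normal(50)
        wm = build_weight_matrix(self._dataset(np.stack([s, s])))
        assert wm.w[0, 1] == pytest.approx(Z_CLAMP)

    def test_zero_variance_voxel_zeroed_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((3, 40))
        series[1] = 4.2
        with caplog.at_level(logging.WARNING):
            wm = build_weight_matrix(self._dataset(series))
        assert "zero-variance" in caplog.text
        assert np.all(wm.w[1] == 0) and np.all(wm.w[:, 1] == 0)
        assert wm.n_nodes == 3  # kept, not dropped

    def test_invariant_under_linear_rescaling(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((4, 70))
        w1 = build_weight_matrix(self._dataset(series)).w
        scaled = series.copy()
        scaled[2] = 5.0 * scaled[2] - 7.0
        w2 = build_weight_matrix(self._dataset(scaled)).w
        assert np.allclose(w1, w2, atol=1e-10)

    def test_symmetry_and_zero_diagonal(self, small_bold):
        wm = build_weight_matrix(small_bold)
        assert np.array_equal(wm.w, wm.w.T)
        assert np.all(np.diag(wm.w) == 0)
        assert np.all(wm.w >= 0)


class TestSeedMap:
    def test_threshold_semantics_strict(self):
        # voxel correlations engineered around the threshold
        rng = np.random.default_rng(8)
        cmap_vals = {0.1: False, 0.2: True}
        for z_target, survives in cmap_vals.items():
            r_target = np.tanh(z_target)
            seed = rng.standard_normal(5000)
            noise = rng.standard_normal(5000)
            # make the sample correlation exact via Gram-Schmidt
            seed_c = (seed - seed.mean()) / np.linalg.norm(seed - seed.mean())
            noise_c = noise - noise.mean()
            noise_c -= (noise_c @ seed_c) * seed_c
            noise_c /= np.linalg.norm(noise_c)
            v = r_target * seed_c + np.sqrt(1 - r_target**2) * noise_c
            series = np.stack([seed_c, v])
            ds = make_bold_from_series(series, [CODES["sm_left"], CODES["gm_left"]])
            cmap = seed_map(ds, "sm_left", threshold=0.15)
            assert bool(cmap.suprathreshold()[1, 0, 0]) is survives

    def test_seed_voxels_at_clamp_when_coherent(self):
        cfg_intra_one = BoldSimConfig(n_voxels_per_hemisphere=4, n_frames=200,
                                      roi_fraction=1.0, inter_corr=0.0,
                                      intra_corr=1.0, noise_sd=0.0, seed=2)
        ds = generate_bold(cfg_intra_one)
        cmap = seed_map(ds, "sm_left")
        seed_mask = ds.mask_for("sm_left")
        assert np.allclose(cmap.z[seed_mask], Z_CLAMP)

    def test_independent_voxel_near_zero_at_large_n(self):
        rng = np.random.default_rng(10)
        series = rng.standard_normal((2, 10000))
        ds = make_bold_from_series(series, [CODES["sm_left"], CODES["gm_left"]])
        cmap = seed_map(ds, "sm_left")
        assert abs(cmap.z[1, 0, 0]) < 0.05

    def test_empty_seed_errors(self, small_bold):
        labels = small_bold.labels.copy()
        labels[labels == CODES["sm_left"]] = CODES["gm_left"]
        ds = small_bold.copy_with(small_bold.data)
        ds.labels = labels
        with pytest.raises(ValueError):
            seed_map(ds, "sm_left")


class TestInterhemisphericFC:
    def test_planted_correlation_recovered_exactly_noiseless(self):
        # intra = 1 makes the ROI mean equal the latent, so z' = arctanh(0.6)
        cfg = BoldSimConfig(n_voxels_per_hemisphere=10, n_frames=600,
                            roi_fraction=1.0, inter_corr=0.6, intra_corr=1.0,
                            noise_sd=0.0, seed=4)
        ds = generate_bold(cfg)
        assert interhemispheric_fc(ds) == pytest.approx(np.arctanh(0.6), abs=1e-10)

    def test_identical_means_clamped(self):
        s = np.random.default_rng(0).standard_normal(100)
        ds = make_bold_from_series(np.stack([s, s]), [CODES["sm_left"], CODES["sm_right"]])
        assert interhemispheric_fc(ds) == pytest.approx(Z_CLAMP)

    def test_independent_hemispheres_near_zero(self):
        rng = np.random.default_rng(6)
        series = rng.standard_normal((2, 20000))
        ds = make_bold_from_series(series, [CODES["sm_left"], CODES["sm_right"]])
        assert abs(interhemispheric_fc(ds)) < 0.05

    def test_symmetric_in_argument_order(self, small_bold):
        a = interhemispheric_fc(small_bold, "sm_left", "sm_right")
        b = interhemispheric_fc(small_bold, "sm_right", "sm_left")
        assert a == pytest.approx(b, abs=1e-12)

    def test_anticorrelation_keeps_sign(self):
        cfg = BoldSimConfig(n_voxels_per_hemisphere=10, n_frames=600,
                            roi_fraction=1.0, inter_corr=-0.4, intra_corr=1.0,
                            noise_sd=0.0, seed=4)
        assert interhemispheric_fc(generate_bold(cfg)) == pytest.approx(
            np.arctanh(-0.4), abs=1e-10)

    def test_estimator_consistency_small_ensemble(self):
        # scaled version of the 200-seed consistency check (full version in
        # the acceptance suite): modest bias at 1200 frames
        zs = []
        for seed in range(8):
            cfg = BoldSimConfig(n_voxels_per_hemisphere=300, n_frames=1200,
                                roi_fraction=1.0, inter_corr=0.6, intra_corr=0.6,
                                noise_sd=1.0, n_wm_voxels=4, n_csf_voxels=4,
                                seed=seed)
            zs.append(interhemispheric_fc(generate_bold(cfg)))
        assert abs(np.mean(zs) - np.arctanh(0.6)) < 0.06

    def test_empty_roi_errors(self, small_bold):
        with pytest.raises(KeyError):
            interhemispheric_fc(small_bold, "nonexistent", "sm_right")


class TestIntrahemisphericVolume:
    def test_fully_coherent_hemisphere_counts_everything(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(100)
        series = np.tile(base, (100, 1))
        labels = [CODES["sm_left"]] * 10 + [CODES["gm_left"]] * 90
        ds = make_bold_from_series(series, labels, voxel_size=(0.5, 0.5, 1.5))
        vol = intrahemispheric_volume(ds, "sm_left", "left", 0.15)
        assert vol == pytest.approx(100 * 0.375)

    def test_threshold_above_clamp_gives_zero(self):
        rng = np.random.default_rng(1)
        series = np.tile(rng.standard_normal(50), (4, 1))
        labels = [CODES["sm_left"]] * 2 + [CODES["gm_left"]] * 2
        ds = make_bold_from_series(series, labels)
        assert intrahemispheric_volume(ds, "sm_left", "left", Z_CLAMP + 1) == 0.0

    def test_independent_voxels_count_only_seed(self):
        rng = np.random.default_rng(2)
        seed_series = np.tile(rng.standard_normal(5000), (3, 1))
        others = rng.standard_normal((30, 5000))
        series = np.vstack([seed_series, others])
        labels = [CODES["sm_left"]] * 3 + [CODES["gm_left"]] * 30
        ds = make_bold_from_series(series, labels, voxel_size=(1, 1, 1))
        vol = intrahemispheric_volume(ds, "sm_left", "left", 0.15)
        assert vol == pytest.approx(3.0)
        vol_ex = intrahemispheric_volume(ds, "sm_left", "left", 0.15, include_seed=False)
        assert vol_ex == pytest.approx(0.0)

    def test_scales_with_planted_intra_correlation(self):
        vols = []
        for intra in (0.2, 0.5, 0.8):
            v = []
            for seed in range(5):
                cfg = BoldSimConfig(n_voxels_per_hemisphere=40, n_frames=600,
                                    roi_fraction=0.3, inter_corr=0.3,
                                    intra_corr=intra, noise_sd=1.0, seed=seed)
                v.append(intrahemispheric_volume(generate_bold(cfg), "sm_left", "left"))
            vols.append(np.mean(v))
        assert vols[0] < vols[1] < vols[2]
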