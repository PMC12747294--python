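"""Wave-locked BOLD features, k-means subtyping, cross-subject matching."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnotype.cluster import (
    ClusterSolution,
    cluster_waves,
    extract_features,
    match_clusters_across_subjects,
    remove_spindle_contribution,
    WaveFeatureMatrix,
)
from somnotype.glm import Regressor, build_regressor, convolve_hrf
from somnotype.io import Hypnogram, PipelineConfig, RoiBoldSeries
from somnotype.simulate import BoldParams, bold_template


def _wave_df(onsets):
    return pd.DataFrame(
        dict(
            kind="slow_wave",
            onset_s=np.asarray(onsets, float),
            peak_s=np.asarray(onsets, float) + 0.3,
            duration_s=0.6,
            amplitude=80.0,
            stage="N2",
        )
    )


class TestRemoveSpindleContribution:
    def _setup(self, n_vol=200):
        cfg = PipelineConfig()
        cfg.regressor_rate = 25.0
        hyp = Hypnogram(stages=["N2"] * 20)  # 600 s
        rng = np.random.default_rng(0)
        onsets = np.sort(rng.uniform(5, 570, 30))
        ev = pd.DataFrame(
            dict(kind="spindle", onset_s=onsets, peak_s=np.nan, duration_s=1.0,
                 amplitude=np.nan, stage="N2")
        )
        reg = build_regressor(ev, "spindle", hyp, cfg, duration_s=600.0)
        conv = convolve_hrf(reg, tr=3.0, n_volumes=n_vol, cfg=cfg)
        return cfg, reg, conv

    def test_pure_regressor_signal_removed(self):
        cfg, reg, conv = self._setup()
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A"], data=(2.5 * conv)[None, :])
        out = remove_spindle_contribution(bold, reg, cfg)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_no_spindles_returns_input_unchanged(self):
        cfg, reg, conv = self._setup()
        empty = Regressor("spindle", reg.rate, np.zeros_like(reg.samples),
                          reg.zeroed_mask, reg.events.iloc[:0])
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A"], data=np.random.default_rng(1).normal(size=(1, 200)))
        out = remove_spindle_contribution(bold, empty, cfg)
        np.testing.assert_array_equal(out.data, bold.data)

    def test_component_orthogonal_to_design_survives(self):
        cfg, reg, conv = self._setup()
        n_vol = len(conv)
        sine = np.sin(2 * np.pi * np.arange(n_vol) / 25.0)
        # orthogonalise against [1, conv] in closed form (OLS projection)
        X = np.column_stack([np.ones(n_vol), conv])
        sine_perp = sine - X @ np.linalg.lstsq(X, sine, rcond=None)[0]
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A"], data=(conv + sine_perp)[None, :])
        out = remove_spindle_contribution(bold, reg, cfg)
        np.testing.assert_allclose(out.data[0], sine_perp, atol=1e-9)

    def test_censored_volumes_pass_through(self):
        cfg, reg, conv = self._setup()
        data = 2.0 * conv
        censor = np.ones(len(conv), bool)
        censor[50:55] = False
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A"], data=data[None, :], censor_mask=censor)
        out = remove_spindle_contribution(bold, reg, cfg)
        np.testing.assert_array_equal(out.data[0, 50:55], data[50:55])


class TestExtractFeatures:
    def _bold(self, data, tr=3.0, rois=None):
        rois = rois or [f"R{i}" for i in range(data.shape[0])]
        return RoiBoldSeries(tr=tr, roi_labels=rois, data=data)

    def test_linear_trend_gives_zero_features(self, cfg):
        tv = np.arange(200) * 3.0
        data = np.vstack([0.5 * tv + 3.0, -0.2 * tv])
        fm = extract_features(self._bold(data), _wave_df([300.0]), cfg)
        np.testing.assert_allclose(fm.features, 0.0, atol=1e-9)

    def test_feature_count_seven_rois_five_timepoints(self, cfg):
        data = np.random.default_rng(0).normal(size=(7, 200))
        fm = extract_features(self._bold(data), _wave_df([300.0]), cfg)
        assert fm.n_features == 35

    def test_feature_count_follows_tr(self, cfg):
        data = np.random.default_rng(0).normal(size=(3, 400))
        bold = self._bold(data, tr=2.0)
        fm = extract_features(bold, _wave_df([300.0]), cfg)
        assert fm.n_features == 3 * (int(12 / 2.0) + 1)

    def test_noise_free_template_matches_detrended_oracle(self, cfg):
        bp = BoldParams()
        tr, n_vol = 3.0, 200
        tv = np.arange(n_vol) * tr
        onset = 300.0  # on-grid onset
        resp = bold_template(tv - onset, "A", bp)
        fm = extract_features(self._bold(resp[None, :]), _wave_df([onset]), cfg)
        # independent oracle: polyfit-detrend the window, pick nearest volumes
        in_win = (tv >= onset - 21) & (tv <= onset + 21)
        tw, seg = tv[in_win], resp[in_win]
        coef = np.polyfit(tw, seg, 1)
        detr = seg - np.polyval(coef, tw)
        expected = [detr[np.abs(tw - (onset + k)).argmin()] for k in (0, 3, 6, 9, 12)]
        np.testing.assert_allclose(fm.features[0], expected, atol=1e-10)

    def test_wave_near_run_edge_dropped(self, cfg):
        data = np.zeros((2, 200))
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A", "B"], data=data, run_offsets=[0.0, 300.0])
        fm = extract_features(bold, _wave_df([290.0, 450.0]), cfg)
        assert fm.dropped["window_out_of_run"] == 1
        assert fm.n_waves == 1

    def test_censored_window_dropped(self, cfg):
        data = np.zeros((2, 200))
        censor = np.ones(200, bool)
        censor[100] = False  # volume at 300 s
        bold = RoiBoldSeries(tr=3.0, roi_labels=["A", "B"], data=data, censor_mask=censor)
        fm = extract_features(bold, _wave_df([295.0, 450.0]), cfg)
        assert fm.dropped["censored_volume"] == 1
        assert fm.n_waves == 1


def _two_family_features(n_per=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(5) * 3.0
    bp = BoldParams()
    fam_a = np.tile(bold_template(t, "A", bp), 7)
    fam_b = np.tile(bold_template(t, "B", bp), 7)
    feats = np.vstack(
        [fam_a + noise * rng.normal(size=35) for _ in range(n_per)]
        + [fam_b + noise * rng.normal(size=35) for _ in range(n_per)]
    )
    truth = np.array(["A"] * n_per + ["B"] * n_per)
    return WaveFeatureMatrix(
        wave_ids=np.arange(2 * n_per), features=feats, roi_order=list("SMFPVAV"),
        timepoints_s=t, dropped={},
    ), truth


class TestClusterWaves:
    def test_separable_families_give_k2_exact_labels(self, cfg):
        fm, truth = _two_family_features(noise=0.001)
        sol = cluster_waves(fm, seed=0, cfg=cfg)
        assert sol.k == 2
        a_labels = set(sol.labels[truth == "A"])
        b_labels = set(sol.labels[truth == "B"])
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_duplicating_vectors_preserves_solution(self, cfg):
        fm, _ = _two_family_features(noise=0.01)
        dup = WaveFeatureMatrix(
            wave_ids=np.arange(2 * fm.n_waves),
            features=np.vstack([fm.features, fm.features]),
            roi_order=fm.roi_order, timepoints_s=fm.timepoints_s, dropped={},
        )
        s1 = cluster_waves(fm, seed=1, cfg=cfg)
        s2 = cluster_waves(dup, seed=1, cfg=cfg)
        assert s2.k == s1.k == 2
        # duplicated points get the same partition (up to label permutation)
        first, second = s2.labels[: fm.n_waves], s2.labels[fm.n_waves :]
        np.testing.assert_array_equal(first, second)

    def test_centroid_is_member_mean(self, cfg):
        fm, _ = _two_family_features(noise=0.01)
        sol = cluster_waves(fm, seed=2, cfg=cfg)
        for m in range(1, sol.k + 1):
            np.testing.assert_allclose(
                sol.centroids[m - 1], fm.features[sol.labels == m].mean(axis=0)
            )

    def test_zero_variance_vector_dropped(self, cfg):
        fm, _ = _two_family_features(noise=0.01)
        fm.features[5] = 1.0  # constant vector: correlation undefined
        sol = cluster_waves(fm, seed=3, cfg=cfg)
        assert 5 not in sol.wave_ids

    def test_too_few_waves_rejected(self, cfg):
        fm, _ = _two_family_features(n_per=4)
        with pytest.raises(ValueError, match=">= 10 waves"):
            cluster_waves(fm, seed=0, cfg=cfg)


class TestMatching:
    def _solution(self, centroids, subject):
        k = len(centroids)
        return ClusterSolution(
            k=k, labels=np.arange(1, k + 1), centroids=np.asarray(centroids, float),
            criterion_by_k={k: 1.0}, wave_ids=np.arange(k), subject=subject,
        )

    def test_identical_centroids_identity_mapping(self):
        t = np.arange(5) * 3.0
        bp = BoldParams()
        c = [np.tile(bold_template(t, "A", bp), 7), np.tile(bold_template(t, "B", bp), 7)]
        sols = [self._solution(c, s) for s in range(3)]
        maps = match_clusters_across_subjects(sols, timepoints_s=t)
        assert all(m == maps[0] for m in maps)
        assert maps[0][1] == "C1"  # early-positive template is C1
        assert maps[0][2] == "C2"

    def test_swapped_subject_is_unswapped(self):
        t = np.arange(5) * 3.0
        bp = BoldParams()
        a = np.tile(bold_template(t, "A", bp), 7)
        b = np.tile(bold_template(t, "B", bp), 7)
        sols = [self._solution([a, b], 0), self._solution([b, a], 1)]
        maps = match_clusters_across_subjects(sols, timepoints_s=t)
        assert maps[0] == {1: "C1", 2: "C2"}
        assert maps[1] == {1: "C2", 2: "C1"}

    def test_mixed_k_rejected(self):
        t = np.arange(5) * 3.0
        bp = BoldParams()
        a = np.tile(bold_template(t, "A", bp), 7)
        b = np.tile(bold_template(t, "B", bp), 7)
        s2 = self._solution([a, b], 0)
        s3 = self._solution([a, b, a + b], 1)
        with pytest.raises(ValueError, match="mixed k"):
            match_clusters_across_subjects([s2, s3], timepoints_s=t)
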