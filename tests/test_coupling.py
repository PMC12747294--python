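"""Event associations, shuffle nulls, paired comparisons, topographic test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnotype.io import Hypnogram
from somnotype.stats import (
    adjacency_from_positions,
    associate,
    compare_feature_family,
    compare_features,
    fdr_adjust,
    shuffle_null_z,
    topo_cluster_test,
)


def _waves(peaks, clusters=None, stages=None):
    peaks = np.asarray(peaks, float)
    return pd.DataFrame(
        dict(
            kind="slow_wave",
            onset_s=peaks - 0.3,
            peak_s=peaks,
            duration_s=0.6,
            amplitude=60.0,
            stage=stages if stages is not None else ["N2"] * len(peaks),
            cluster=clusters if clusters is not None else ["C1"] * len(peaks),
        )
    )


def _others(onsets, stages=None, dur=1.0):
    onsets = np.asarray(onsets, float)
    return pd.DataFrame(
        dict(
            onset_s=onsets,
            duration_s=np.full(len(onsets), dur),
            stage=stages if stages is not None else ["N2"] * len(onsets),
        )
    )


class TestAssociate:
    def test_pwa_window_inclusion(self):
        waves = _waves([100.0])
        assert associate(waves, _others([103.0]), (-1.0, 5.0))[0]
        assert not associate(waves, _others([106.0]), (-1.0, 5.0))[0]
        assert associate(waves, _others([99.0]), (-1.0, 5.0))[0]
        assert not associate(waves, _others([98.5]), (-1.0, 5.0))[0]

    def test_spindle_window_exclusion(self):
        waves = _waves([100.0])
        assert not associate(waves, _others([101.3]), (-1.2, 1.2))[0]
        assert associate(waves, _others([101.1]), (-1.2, 1.2))[0]

    def test_empty_others(self):
        assert not associate(_waves([100.0]), _others([]), (-1.0, 5.0)).any()


class TestShuffleNullZ:
    def test_empty_others_gives_flagged_z(self):
        hyp = Hypnogram(stages=["N2"] * 20)
        res = shuffle_null_z(_waves([100.0, 200.0]), _others([]), hyp, (-1.2, 1.2), n_shuffles=50)
        assert (res.table["observed"] == 0).all()
        assert res.table["z"].isna().all()

    def test_counts_preserved_and_stage_respected(self):
        hyp = Hypnogram(stages=["N2", "N3"] * 10)
        others = _others([40.0, 100.0], stages=["N3", "N3"])
        waves = _waves([50.0, 110.0])
        res = shuffle_null_z(waves, others, hyp, (-1.2, 1.2), n_shuffles=100, seed=0)
        assert set(res.table["stage_group"]) <= {"all_nrem", "light", "deep"}

    def test_planted_coupling_ranks_clusters(self):
        # drops follow half of C1 waves; C2 waves are uncoupled
        rng = np.random.default_rng(0)
        hyp = Hypnogram(stages=["N1", "N2", "N2", "N2", "N3"] * 24)  # 1 h
        n = 60
        c1 = np.sort(rng.uniform(50, 3400, n))
        c2 = np.sort(rng.uniform(50, 3400, n))
        waves = _waves(
            np.concatenate([c1, c2]),
            clusters=["C1"] * n + ["C2"] * n,
            stages=[hyp.stage_at(t) for t in np.concatenate([c1, c2])],
        )
        waves = waves[waves["stage"].isin(["N1", "N2", "N3"])]
        coupled = c1[rng.random(n) < 0.5] + 2.0
        indep = rng.uniform(50, 3400, 10)
        onsets = np.concatenate([coupled, indep])
        others = _others(onsets, stages=[hyp.stage_at(t) for t in onsets])
        others = others[others["stage"].isin(["N1", "N2", "N3"])]
        res = shuffle_null_z(waves, others, hyp, (-1.0, 5.0), n_shuffles=300, seed=1)
        t = res.table
        z1 = t[(t.cluster == "C1") & (t.stage_group == "all_nrem")]["z"].iloc[0]
        z2 = t[(t.cluster == "C2") & (t.stage_group == "all_nrem")]["z"].iloc[0]
        assert z1 > 3.0
        assert z1 > z2

    def test_null_calibration_mean_near_zero(self):
        from somnotype.evaluation import assoc_null_calibration

        r = assoc_null_calibration(7, n_repeats=20, n_shuffles=300)
        assert abs(r["mean"]) < 0.3


class TestCompareFeatures:
    def _df(self, a, b):
        rows = []
        for s, (x, y) in enumerate(zip(a, b)):
            rows.append(dict(subject=s, cluster="C1", value=x))
            rows.append(dict(subject=s, cluster="C2", value=y))
        return pd.DataFrame(rows)

    def test_identical_values_no_effect(self):
        vals = np.arange(8.0)
        res = compare_features(self._df(vals, vals))
        assert res["p"] == 1.0

    def test_consistent_shift_significant_after_fdr(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        results = {}
        for name in ("amplitude", "duration", "sync"):
            results[name] = compare_features(self._df(base + 1.0 + 0.01 * rng.normal(size=12), base))
        table = compare_feature_family(results)
        assert (table["q"] < 0.05).all()

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        skew = base + np.concatenate([np.full(18, 0.01), [8.0, 12.0]])  # heavy outliers
        res = compare_features(self._df(skew, base))
        assert res["test"] == "wilcoxon"

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 3 subjects"):
            compare_features(self._df([1.0, 2.0], [0.5, 1.5]))


class TestFdr:
    def test_benjamini_hochberg_hand_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.5, 0.9])
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, [0.006, 0.03, 0.04, 0.3, 0.6, 0.9])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(20))
        q = fdr_adjust(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= p - 1e-12).all()


def _grid_adjacency(nx=8, ny=4):
    pos = np.array([[x, y] for x in range(nx) for y in range(ny)], float)
    return adjacency_from_positions(pos, radius=1.01)


class TestTopoClusterTest:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((10, 32))
        res = topo_cluster_test(a, a.copy(), _grid_adjacency(), n_perm=200, seed=0)
        assert res.clusters == []
        assert res.significant == []

    def test_planted_contiguous_patch_detected(self):
        adjacency = _grid_adjacency()
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            a = rng.standard_normal((12, 32))
            b = rng.standard_normal((12, 32))
            a[:, :10] += 1.0  # 1-sd effect on a contiguous 10-channel patch
            res = topo_cluster_test(a, b, adjacency, n_perm=500, seed=seed)
            if any(len(set(c) & set(range(10))) >= 3 for c in res.significant):
                detected += 1
        assert detected >= 4

    def test_channel_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((12, 32))
        b = rng.standard_normal((12, 32))
        a[:, 4:9] += 0.8
        adjacency = _grid_adjacency()
        perm = rng.permutation(32)
        inv = np.argsort(perm)
        adj_perm = [set(int(inv[v]) for v in adjacency[perm[i]]) for i in range(32)]
        r1 = topo_cluster_test(a, b, adjacency, n_perm=300, seed=9)
        r2 = topo_cluster_test(a[:, perm], b[:, perm], adj_perm, n_perm=300, seed=9)
        np.testing.assert_allclose(np.sort(r1.cluster_mass), np.sort(r2.cluster_mass))
        np.testing.assert_allclose(r1.null_max_mass, r2.null_max_mass)

    def test_empty_adjacency_warns_single_channels(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((10, 6))
        b = a + 0.0
        b[:, 2] -= 2.0
        res = topo_cluster_test(a, b, None, n_perm=200, seed=1)
        assert all(len(c) == 1 for c in res.clusters)
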