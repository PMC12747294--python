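"""Slow-wave detector: envelope rule, half-wave segmentation, features."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from somnotype.io import EegRecording, EventTable, Hypnogram, PipelineConfig
from somnotype.slowwaves import (
    EnvelopeSeries,
    SlowWave,
    detect_halfwaves,
    flag_isolation,
    kcomplex_overlap,
    negative_envelope,
    wave_features,
)

import pandas as pd


def _rec(data: np.ndarray, rate: float = 100.0) -> EegRecording:
    return EegRecording(
        sample_rate=rate,
        channel_labels=[f"E{i}" for i in range(data.shape[0])],
        data=data,
    )


class TestNegativeEnvelope:
    def test_stated_selection_rule_on_one_frame(self):
        # frame [-10, -8, -5, -3, 1]: drop the most negative, average the
        # 2nd-4th -> -16/3; pairing with the mirrored frame keeps the mean 0
        frame = np.array([-10.0, -8.0, -5.0, -3.0, 1.0])
        mirrored = -frame
        data = np.column_stack([frame, mirrored])
        env = negative_envelope(_rec(data), prefiltered=True)
        assert env.values[0] == pytest.approx(-16.0 / 3.0)

    def test_identical_constant_channels_center_to_zero(self):
        data = np.full((5, 200), -7.0)
        env = negative_envelope(_rec(data), prefiltered=True)
        np.testing.assert_allclose(env.values, 0.0, atol=1e-12)

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.normal(scale=30.0, size=(60, 500))
        env = negative_envelope(_rec(data), prefiltered=True)
        srt = np.sort(data, axis=0)
        oracle = srt[1:4].mean(axis=0)
        oracle -= oracle.mean()
        np.testing.assert_allclose(env.values, oracle, atol=1e-12)

    def test_requires_four_usable_channels(self):
        data = np.zeros((3, 100))
        with pytest.raises(ValueError, match="4 usable channels"):
            negative_envelope(_rec(data), prefiltered=True)

    def test_bad_channels_excluded(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(6, 100))
        rec = _rec(data)
        rec.bad_channels = {"E5"}
        env = negative_envelope(rec, prefiltered=True)
        srt = np.sort(data[:5], axis=0)
        oracle = srt[1:4].mean(axis=0)
        oracle -= oracle.mean()
        np.testing.assert_allclose(env.values, oracle, atol=1e-12)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(8, 300))
        env1 = negative_envelope(_rec(data), prefiltered=True)
        env2 = negative_envelope(_rec(data + 13.0), prefiltered=True)
        np.testing.assert_allclose(env1.values, env2.values, atol=1e-10)


class TestDetectHalfwaves:
    def _env(self, values, rate=500.0):
        return EnvelopeSeries(rate=rate, values=np.asarray(values, float))

    def test_single_sine_lobe(self, n2_hypnogram):
        t = np.arange(0, 1.0, 1 / 500)
        env = self._env(-np.sin(2 * np.pi * 1.0 * t))
        waves = detect_halfwaves(env, n2_hypnogram)
        assert len(waves) == 1
        w = waves[0]
        assert w.halfwave_duration_s == pytest.approx(0.5, abs=0.005)
        assert w.peak_s == pytest.approx(0.25, abs=0.005)
        assert w.amplitude_uV == pytest.approx(1.0, abs=1e-4)

    def test_short_lobes_rejected(self, n2_hypnogram):
        t = np.arange(0, 2.0, 1 / 500)
        env = self._env(-np.sin(2 * np.pi * 3.0 * t))  # lobes of 1/6 s
        assert detect_halfwaves(env, n2_hypnogram) == []

    def test_only_mid_duration_lobe_kept(self, n2_hypnogram):
        rate = 500.0
        pieces = []
        for dur in (0.2, 0.6, 1.2):
            n = int(dur * rate)
            pieces.append(-np.sin(np.pi * np.arange(n) / n))
            pieces.append(np.ones(int(0.5 * rate)))  # positive separator
        env = self._env(np.concatenate(pieces), rate)
        waves = detect_halfwaves(env, Hypnogram(stages=["N2"] * 10))
        assert len(waves) == 1
        assert waves[0].halfwave_duration_s == pytest.approx(0.6, abs=0.005)

    def test_non_nrem_onsets_discarded(self):
        t = np.arange(0, 60.0, 1 / 100)
        env = self._env(-np.sin(2 * np.pi * 1.0 * t), rate=100.0)
        hyp = Hypnogram(stages=["W", "N2"])
        waves = detect_halfwaves(env, hyp)
        assert all(w.onset_s >= 30.0 for w in waves)
        assert len(waves) == 30

    @settings(max_examples=25, deadline=None)
    @given(seed=hst.integers(0, 10_000))
    def test_duration_bounds_hold_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        env = self._env(rng.normal(size=600), rate=100.0)
        for w in detect_halfwaves(env, Hypnogram(stages=["N2"] * 20)):
            assert 0.25 <= w.halfwave_duration_s <= 1.0


class TestWaveFeatures:
    def _wave(self, amplitude=10.0):
        # slopes: amplitude / 0.1 = 100 uV/s down, amplitude / (1/15) = 150 up
        return SlowWave(
            onset_s=1.0, end_s=1.0 + 0.1 + 1.0 / 15.0, peak_s=1.1,
            amplitude_uV=amplitude, stage="N2",
        )

    def test_sync_score_direct_evaluation(self, cfg):
        data = np.zeros((60, 300))
        data[:30] = -10.0  # 30 of 60 channels involved
        rec = _rec(data)
        w = wave_features(self._wave(), rec, cfg, filtered=data)
        assert w.descending_slope == pytest.approx(100.0)
        assert w.ascending_slope == pytest.approx(150.0)
        assert w.n_involved == 30
        assert w.sync_score == pytest.approx(62.5)

    def test_involvement_threshold_is_strict(self, cfg):
        data = np.zeros((6, 300))
        data[0] = -10.0  # involved
        data[1] = -5.0  # exactly at threshold: NOT involved
        data[2] = -4.99
        rec = _rec(data)
        w = wave_features(self._wave(), rec, cfg, filtered=data)
        assert w.n_involved == 1
        assert w.involvement[1] == pytest.approx(-5.0)

    def test_constant_channel_involvement_value(self, cfg):
        data = np.full((5, 300), -10.0)
        w = wave_features(self._wave(), _rec(data), cfg, filtered=data)
        np.testing.assert_allclose(w.involvement, -10.0)
        assert w.n_involved == 5


class TestIsolation:
    def _w(self, onset, peak):
        return SlowWave(onset_s=onset, end_s=peak + 0.2, peak_s=peak, amplitude_uV=1.0, stage="N2")

    def test_single_wave_isolated(self):
        waves = flag_isolation([self._w(100.0, 100.3)])
        assert waves[0].isolated is True

    def test_close_pair_not_isolated(self):
        waves = flag_isolation([self._w(100.0, 100.3), self._w(103.0, 103.3)])
        assert waves[0].isolated is False
        assert waves[1].isolated is False

    def test_plus_five_bound_brute_force(self):
        # B peaks 5.1 s after A's onset: outside A's [-12, +5] window
        a = self._w(100.0, 100.3)
        b = self._w(104.9, 105.1)
        waves = flag_isolation([a, b])
        assert waves[0].isolated is True
        # A's peak (100.3) lies inside B's window [92.9, 109.9]
        assert waves[1].isolated is False


class TestKComplexOverlap:
    def _waves(self, intervals, clusters):
        return [
            SlowWave(onset_s=a, end_s=b, peak_s=(a + b) / 2, amplitude_uV=1.0,
                     stage="N2", cluster=c)
            for (a, b), c in zip(intervals, clusters)
        ]

    def _kcs(self, intervals):
        return EventTable(
            pd.DataFrame(
                dict(
                    kind=["k_complex"] * len(intervals),
                    onset_s=[a for a, _ in intervals],
                    duration_s=[b - a for a, b in intervals],
                    stage=["N2"] * len(intervals),
                )
            )
        )

    def test_half_open_interval_intersection(self):
        waves = self._waves([(10.0, 10.8)], ["C1"])
        assert kcomplex_overlap(waves, self._kcs([(10.5, 11.5)]))["C1"] == 100.0
        assert kcomplex_overlap(waves, self._kcs([(10.8, 11.5)]))["C1"] == 0.0

    def test_percentage_per_cluster(self):
        waves = self._waves(
            [(10, 10.8), (20, 20.8), (30, 30.8), (40, 40.8)], ["C1"] * 4
        )
        kcs = self._kcs([(10.5, 11), (20.5, 21), (30.5, 31)])
        assert kcomplex_overlap(waves, kcs)["C1"] == 75.0

    def test_empty_kc_table_gives_zero(self):
        waves = self._waves([(10, 10.8)], ["C1"])
        assert kcomplex_overlap(waves, EventTable())["C1"] == 0.0
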