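"""Spindle detector: sigma power, MAD thresholds, duration and ratio filters."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as ss

from somnotype.io import Hypnogram, PipelineConfig
from somnotype.spindles import (
    PowerSeries,
    detect_spindles,
    epoch_thresholds,
    power_ratio_filter,
    sigma_power,
    Spindle,
)

RATE = 100.0


class TestSigmaPower:
    def test_pure_in_band_sine_has_half_power(self):
        t = np.arange(0, 30, 1 / RATE)
        power = sigma_power(np.sin(2 * np.pi * 13 * t), RATE)
        mid = power.values[500:2500]
        assert np.median(mid) == pytest.approx(0.5, abs=0.05)

    def test_out_of_band_sine_suppressed(self):
        t = np.arange(0, 30, 1 / RATE)
        power = sigma_power(np.sin(2 * np.pi * 5 * t), RATE)
        assert power.values[500:2500].max() < 0.01

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        power = sigma_power(rng.normal(size=3000), RATE)
        assert (power.values >= 0).all()

    def test_chirp_matches_filter_square_smooth_oracle(self):
        t = np.arange(0, 30, 1 / RATE)
        x = ss.chirp(t, f0=8.0, f1=18.0, t1=30.0)
        power = sigma_power(x, RATE)
        # independent re-derivation of the stated construction
        sos = ss.butter(6, [10 / (RATE / 2), 16 / (RATE / 2)], "band", output="sos")
        filt = ss.sosfiltfilt(sos, x)
        oracle = ss.convolve(filt**2, np.ones(10) / 10, mode="same")
        np.testing.assert_allclose(power.values, oracle, atol=1e-6)


class TestThresholds:
    def test_median_plus_mad_multiples(self, n2_hypnogram, cfg):
        # one epoch whose power has median 1.0 and MAD 0.2
        vals = np.tile([0.8, 1.0, 1.2], 1000)[:3000]
        power = PowerSeries(rate=RATE, values=vals)
        thr = epoch_thresholds(power, Hypnogram(stages=["N2"]), cfg)
        assert thr[0, 0] == pytest.approx(1.8)
        assert thr[0, 1] == pytest.approx(1.4)

    def test_thresholds_depend_only_on_own_epoch(self, cfg):
        rng = np.random.default_rng(1)
        hyp = Hypnogram(stages=["N2", "N2"])
        a = rng.random(6000)
        b = a.copy()
        b[3000:] = rng.random(3000) * 10  # perturb only epoch 2
        ta = epoch_thresholds(PowerSeries(RATE, a), hyp, cfg)
        tb = epoch_thresholds(PowerSeries(RATE, b), hyp, cfg)
        np.testing.assert_allclose(ta[0], tb[0])
        assert not np.allclose(ta[1], tb[1])


def _burst_power(background: float, burst: float, t0: float, dur: float) -> np.ndarray:
    """30-s power trace: alternating background (median bg, small MAD) with a
    plateau burst."""
    vals = np.tile([background * 0.95, background, background * 1.05], 1000)[:3000]
    i0, i1 = int(t0 * RATE), int((t0 + dur) * RATE)
    vals[i0:i1] = burst
    return vals


class TestDetectSpindles:
    def test_burst_detected_with_low_threshold_boundaries(self, cfg):
        hyp = Hypnogram(stages=["N2"])
        vals = _burst_power(1.0, 2.0, t0=10.0, dur=1.0)
        power = PowerSeries(rate=RATE, values=vals)
        thr = epoch_thresholds(power, hyp, cfg)
        assert thr[0, 0] < 2.0  # burst crosses the high threshold
        events = detect_spindles(power, hyp, cfg)
        assert len(events) == 1
        # brute-force oracle: first/last sample of the low-threshold interval
        low = thr[0, 1]
        above = np.flatnonzero(vals >= low)
        assert events[0].onset_s == pytest.approx(above[0] / RATE, abs=0.02)
        assert events[0].end_s == pytest.approx((above[-1] + 1) / RATE, abs=0.02)

    def test_short_burst_rejected(self, cfg):
        hyp = Hypnogram(stages=["N2"])
        power = PowerSeries(RATE, _burst_power(1.0, 2.0, t0=10.0, dur=0.2))
        assert detect_spindles(power, hyp, cfg) == []

    def test_overlong_burst_rejected(self, cfg):
        hyp = Hypnogram(stages=["N2"])
        power = PowerSeries(RATE, _burst_power(1.0, 2.0, t0=10.0, dur=4.0))
        assert detect_spindles(power, hyp, cfg) == []

    def test_wake_epoch_events_dropped(self, cfg):
        hyp = Hypnogram(stages=["W"])
        power = PowerSeries(RATE, _burst_power(1.0, 2.0, t0=10.0, dur=1.0))
        assert detect_spindles(power, hyp, cfg) == []

    def test_transitional_n1_kept_isolated_n1_dropped(self, cfg):
        vals = np.concatenate(
            [_burst_power(1.0, 2.0, t0=10.0, dur=1.0), np.full(3000, 1.0)]
        )
        kept = detect_spindles(
            PowerSeries(RATE, vals), Hypnogram(stages=["N1", "N2"]), cfg
        )
        assert len(kept) == 1 and kept[0].stage == "N1"
        dropped = detect_spindles(
            PowerSeries(RATE, vals), Hypnogram(stages=["N1", "W"]), cfg
        )
        assert dropped == []


class TestPowerRatio:
    def test_pure_sigma_burst_retained(self, cfg):
        t = np.arange(0, 30, 1 / RATE)
        x = 0.1 * np.random.default_rng(0).normal(size=len(t))
        x[1000:1150] += 10 * np.sin(2 * np.pi * 13 * t[1000:1150])
        sp = Spindle(onset_s=10.0, end_s=11.5, peak_power=1.0, stage="N2")
        kept = power_ratio_filter([sp], x, RATE, cfg)
        assert len(kept) == 1
        assert kept[0].power_ratio > 3

    def test_broadband_flat_burst_rejected(self, cfg):
        # white noise is flat across 8-18 Hz: per-Hz ratio ~ 1 < 3
        rng = np.random.default_rng(5)
        x = rng.normal(size=int(30 * RATE))
        sp = Spindle(onset_s=10.0, end_s=13.0, peak_power=1.0, stage="N2")
        kept = power_ratio_filter([sp], x, RATE, cfg)
        assert kept == []

    def test_threshold_is_strict(self, cfg):
        # set the threshold to the event's own measured ratio: strict > drops it
        t = np.arange(0, 30, 1 / RATE)
        rng = np.random.default_rng(9)
        x = rng.normal(size=len(t))
        x[1000:1100] += 2 * np.sin(2 * np.pi * 13 * t[1000:1100])
        sp = Spindle(onset_s=10.0, end_s=11.0, peak_power=1.0, stage="N2")
        kept = power_ratio_filter([sp], x, RATE, cfg)
        assert len(kept) == 1 and np.isfinite(kept[0].power_ratio)
        cfg.spindle_ratio_threshold = kept[0].power_ratio
        sp2 = Spindle(onset_s=10.0, end_s=11.0, peak_power=1.0, stage="N2")
        assert power_ratio_filter([sp2], x, RATE, cfg) == []


class TestRecovery:
    def test_planted_spindles_recovered_on_synthetic_eeg(self, cfg):
        from somnotype.simulate import SimulationSpec, simulate_subject
        from somnotype.spindles import detect_all_spindles

        eeg, hyp, _, _, truth = simulate_subject(SimulationSpec(seed=21, duration_s=3000.0))
        events = detect_all_spindles(eeg.channel("Cz"), eeg.sample_rate, hyp, cfg)
        ints = np.array([(s.onset_s, s.end_s) for s in events])
        hits = [
            np.any((ints[:, 0] < b) & (ints[:, 1] > a))
            for a, b in zip(
                truth.spindles["onset_s"],
                truth.spindles["onset_s"] + truth.spindles["duration_s"],
            )
        ]
        assert np.mean(hits) >= 0.9
        false = sum(
            1
            for s in events
            if not np.any(
                (truth.spindles["onset_s"].to_numpy() < s.end_s)
                & ((truth.spindles["onset_s"] + truth.spindles["duration_s"]).to_numpy() > s.onset_s)
            )
        )
        assert false / 50.0 <= 0.5  # false events per minute

    def test_retained_events_satisfy_all_predicates(self, cfg):
        from somnotype.simulate import SimulationSpec, simulate_subject
        from somnotype.spindles import detect_all_spindles

        eeg, hyp, _, _, _ = simulate_subject(SimulationSpec(seed=22, duration_s=600.0))
        events = detect_all_spindles(eeg.channel("Cz"), eeg.sample_rate, hyp, cfg)
        for s in events:
            assert 0.3 <= s.duration_s <= 3.0
            assert s.power_ratio > 3
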