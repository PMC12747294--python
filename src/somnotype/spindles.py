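"""Sleep-spindle detection on a single channel (Cz by default).

Sigma-band (10-16 Hz) power is computed by band-pass filtering, squaring and
smoothing with a 100-ms sliding window.  Candidate spindles cross a
high threshold (epoch median + 4 MAD of power) and are delimited by the
surrounding crossings of a low threshold (median + 2 MAD); both thresholds
are recomputed within each 30-s epoch.  Events must last 0.3-3 s, start in
N2/N3 or a transitional N1 epoch, and show a sigma-to-flank power ratio > 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import EventTable, Hypnogram, PipelineConfig, get_logger

log = get_logger(__name__)

__all__ = [
    "Spindle",
    "PowerSeries",
    "sigma_power",
    "epoch_thresholds",
    "detect_spindles",
    "power_ratio_filter",
    "detect_all_spindles",
    "spindles_to_event_table",
]


@dataclass
class Spindle:
    onset_s: float
    end_s: float
    peak_power: float
    stage: str
    power_ratio: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class PowerSeries:
    rate: float
    values: np.ndarray


def _band_filter(
    x: np.ndarray, rate: float, band: tuple[float, float], kind: str = "iir"
) -> np.ndarray:
    """Zero-phase band-pass; default a 6th-order Butterworth, optionally a
    linear-phase FIR kernel (the wavelet-like alternative)."""
    nyq = rate / 2.0
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.98)
    if kind == "fir":
        ntaps = int(4 * rate / band[0]) | 1
        taps = signal.firwin(ntaps, [lo, hi], pass_zero=False)
        return signal.filtfilt(taps, [1.0], x)
    sos = signal.butter(6, [lo, hi], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def sigma_power(
    eeg_channel: np.ndarray,
    rate: float,
    band: tuple[float, float] = (10.0, 16.0),
    smooth: float = 0.100,
    filter_kind: str = "iir",
) -> PowerSeries:
    """Band-filtered signal squared, then boxcar-smoothed (centred window)."""
    filt = _band_filter(np.asarray(eeg_channel, float), rate, band, filter_kind)
    power = filt**2
    n = max(1, int(round(smooth * rate)))
    kernel = np.ones(n) / n
    smoothed = signal.convolve(power, kernel, mode="same")
    return PowerSeries(rate=rate, values=smoothed)


def epoch_thresholds(
    power: PowerSeries, hyp: Hypnogram, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Per-epoch (high, low) thresholds: median + 4*MAD and median + 2*MAD of
    the epoch's power samples (raw median absolute deviation)."""
    cfg = cfg or PipelineConfig()
    n_per_epoch = int(round(hyp.epoch_length * power.rate))
    out = np.full((hyp.n_epochs, 2), np.nan)
    for e in range(hyp.n_epochs):
        seg = power.values[e * n_per_epoch : (e + 1) * n_per_epoch]
        if len(seg) == 0:
            continue
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        out[e] = (med + cfg.spindle_high_mad * mad, med + cfg.spindle_low_mad * mad)
    return out


def _transitional_n1(hyp: Hypnogram) -> np.ndarray:
    """N1 epochs whose immediately preceding or following epoch is N2/N3."""
    stages = hyp.stage_array()
    n1 = stages == "N1"
    deep = np.isin(stages, ("N2", "N3"))
    prev_deep = np.concatenate([[False], deep[:-1]])
    next_deep = np.concatenate([deep[1:], [False]])
    return n1 & (prev_deep | next_deep)


def detect_spindles(
    power: PowerSeries,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
) -> list[Spindle]:
    """MAD-threshold detection with low-threshold boundaries.

    Events straddling an epoch boundary take the thresholds of the epoch
    containing the high-threshold crossing; overlapping low-threshold
    intervals are merged.
    """
    cfg = cfg or PipelineConfig()
    thr = epoch_thresholds(power, hyp, cfg)
    v = power.values
    rate = power.rate
    n_per_epoch = int(round(hyp.epoch_length * rate))
    trans_n1 = _transitional_n1(hyp)
    lo_dur, hi_dur = cfg.spindle_duration

    epoch_idx = np.minimum(np.arange(len(v)) // n_per_epoch, hyp.n_epochs - 1)
    above_hi = v > thr[epoch_idx, 0]
    d = np.diff(above_hi.astype(np.int8))
    hi_starts = np.flatnonzero(d == 1) + 1
    if above_hi[0]:
        hi_starts = np.concatenate([[0], hi_starts])

    intervals: list[tuple[int, int, int]] = []  # (i0, i1, crossing epoch)
    for s in hi_starts:
        e = int(epoch_idx[s])
        low = thr[e, 1]
        below = v < low
        i0 = s
        while i0 > 0 and not below[i0 - 1]:
            i0 -= 1
        i1 = s
        while i1 < len(v) and not below[i1]:
            i1 += 1
        if intervals and i0 <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(i1, intervals[-1][1]), intervals[-1][2])
        else:
            intervals.append((i0, i1, e))

    spindles: list[Spindle] = []
    for i0, i1, e in intervals:
        onset = i0 / rate
        end = i1 / rate
        dur = end - onset
        if dur < lo_dur or dur > hi_dur:
            continue
        stage = hyp.stages[min(int(onset // hyp.epoch_length), hyp.n_epochs - 1)]
        onset_epoch = min(int(onset // hyp.epoch_length), hyp.n_epochs - 1)
        if not (stage in ("N2", "N3") or (stage == "N1" and trans_n1[onset_epoch])):
            continue
        spindles.append(
            Spindle(
                onset_s=onset,
                end_s=end,
                peak_power=float(v[i0:i1].max()),
                stage=stage,
            )
        )
    return spindles


def power_ratio_filter(
    spindles: list[Spindle],
    eeg_channel: np.ndarray,
    rate: float,
    cfg: PipelineConfig | None = None,
) -> list[Spindle]:
    """Keep events whose mean sigma-band spectral density over the event
    interval exceeds 3x the mean density pooled over the 8-10 and 16-18 Hz
    flanks (strict >).  Band means are computed from a zero-padded
    periodogram of the raw event segment."""
    cfg = cfg or PipelineConfig()
    x = np.asarray(eeg_channel, float)
    band = cfg.spindle_band
    flanks = cfg.spindle_flank_bands
    nfft = max(int(4 * rate), 256)

    kept: list[Spindle] = []
    for sp in spindles:
        i0, i1 = int(round(sp.onset_s * rate)), int(round(sp.end_s * rate))
        seg = x[i0:i1]
        if len(seg) < 4:
            continue
        freqs, psd = signal.periodogram(seg, fs=rate, nfft=nfft, detrend="constant")
        in_band = (freqs >= band[0]) & (freqs < band[1])
        in_flank = np.zeros_like(freqs, dtype=bool)
        for lo, hi in flanks:
            in_flank |= (freqs >= lo) & (freqs < hi)
        flank_power = psd[in_flank].mean()
        band_power = psd[in_band].mean()
        if flank_power <= 0:
            log.warning("zero flank power for spindle at %.2f s; retained", sp.onset_s)
            sp.power_ratio = np.inf
            kept.append(sp)
            continue
        sp.power_ratio = float(band_power / flank_power)
        if sp.power_ratio > cfg.spindle_ratio_threshold:
            kept.append(sp)
    return kept


def detect_all_spindles(
    eeg_channel: np.ndarray,
    rate: float,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
) -> list[Spindle]:
    """Full spindle pipeline on one channel: power, thresholds, ratio filter."""
    cfg = cfg or PipelineConfig()
    power = sigma_power(
        eeg_channel, rate, cfg.spindle_band, cfg.spindle_power_smooth, cfg.spindle_filter_kind
    )
    cands = detect_spindles(power, hyp, cfg)
    kept = power_ratio_filter(cands, eeg_channel, rate, cfg)
    log.info("spindles: %d candidates, %d after power-ratio filter", len(cands), len(kept))
    return kept


def spindles_to_event_table(spindles: list[Spindle]) -> EventTable:
    rows = [
        dict(
            kind="spindle",
            onset_s=s.onset_s,
            peak_s=np.nan,
            duration_s=s.duration_s,
            amplitude=np.nan,
            stage=s.stage,
            cluster=None,
            extras=dict(peak_power=s.peak_power, power_ratio=s.power_ratio),
        )
        for s in spindles
    ]
    return EventTable(pd.DataFrame(rows) if rows else None)
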