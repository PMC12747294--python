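"""Pulse-wave-amplitude extraction and vasoconstriction-drop detection.

Per cardiac cycle the pulse-wave amplitude (PWA) is the max-min of the blood
volume pulse.  Drops — transient reductions exceeding 10 % of a locally
stable baseline — index peripheral vasoconstriction and sympathetic
activation.  Candidates are local peaks of the PWA local variance with a
negative PWA first derivative; the baseline is the mean of the five most
recent beats belonging to a "stable" baseline mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import EventTable, Hypnogram, PipelineConfig, get_logger

log = get_logger(__name__)

__all__ = ["PwaSeries", "PwaDrop", "extract_pwa", "detect_drops", "drops_to_event_table"]


@dataclass
class PwaSeries:
    """Per-beat pulse-wave amplitudes with validity and baseline masks."""

    beat_times: np.ndarray  # s, one per cardiac cycle (time of the pulse maximum)
    pwa: np.ndarray  # smoothed per-beat amplitude, signal units
    valid: np.ndarray  # usable beats
    baseline_mask: np.ndarray | None = None
    raw_pwa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, float)
        self.pwa = np.asarray(self.pwa, float)
        self.valid = np.asarray(self.valid, bool)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class PwaDrop:
    onset_beat: int
    onset_s: float
    depth: float  # fraction of baseline, > 0.10
    duration_s: float
    baseline_value: float
    extras: dict = field(default_factory=dict)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average with edge correction (mean of available points)."""
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def extract_pwa(
    ppg: np.ndarray, rate: float, cfg: PipelineConfig | None = None
) -> PwaSeries:
    """Segment beats and extract per-beat pulse-wave amplitude.

    The PPG is band-pass filtered (configurable front end), Savitzky-Golay
    smoothed and linearly detrended; beats are alternating local
    maximum/minimum pairs.  Cycles lacking a clear max-min pair, or implying
    a heart rate above 250 bpm, are marked invalid.  The PWA sequence is
    smoothed with a 5-beat centred moving average.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(ppg, float)
    if rate < 50:
        raise ValueError("PPG must be sampled at >= 50 Hz")

    nyq = rate / 2.0
    lo, hi = cfg.pwa_frontend_band
    if lo > 0 or hi < nyq:
        sos = signal.butter(2, [max(lo, 1e-3) / nyq, min(hi, 0.98 * nyq) / nyq], "band", output="sos")
        x = signal.sosfiltfilt(sos, x)
    win = int(round(cfg.pwa_savgol_window_s * rate)) | 1
    if win > cfg.pwa_savgol_order + 1:
        x = signal.savgol_filter(x, win, cfg.pwa_savgol_order)
    x = signal.detrend(x, type="linear")

    prominence = 0.25 * np.std(x)
    maxima, _ = signal.find_peaks(x, prominence=prominence)
    minima, _ = signal.find_peaks(-x, prominence=prominence)
    if len(maxima) == 0:
        log.warning("no detectable beats in PPG")
        return PwaSeries(np.array([]), np.array([]), np.array([], bool))

    beat_times, raw_pwa, valid = [], [], []
    min_interval = 60.0 / cfg.pwa_max_hr
    for b, imax in enumerate(maxima):
        nxt = maxima[b + 1] if b + 1 < len(maxima) else len(x)
        mins_in_cycle = minima[(minima > imax) & (minima < nxt)]
        t = imax / rate
        if len(mins_in_cycle) == 0:
            amp = np.nan
            ok = False  # lacks a clear consecutive max-min pair
        else:
            amp = x[imax] - x[mins_in_cycle[0]]
            ok = True
        if beat_times and t - beat_times[-1] < min_interval:
            ok = False  # implausible heart rate (> 250 bpm)
        if beat_times and t <= beat_times[-1]:
            continue
        beat_times.append(t)
        raw_pwa.append(amp)
        valid.append(ok)

    beat_times = np.array(beat_times)
    raw_pwa = np.array(raw_pwa)
    valid = np.array(valid, bool)
    filled = raw_pwa.copy()
    if (~valid).any() and valid.any():
        filled[~valid] = np.interp(
            beat_times[~valid], beat_times[valid], raw_pwa[valid]
        )
    smoothed = _moving_average(filled, cfg.pwa_smooth_beats)
    return PwaSeries(
        beat_times=beat_times, pwa=smoothed, valid=valid, raw_pwa=raw_pwa
    )


def _trailing_mean(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="full")[: len(x)]
    den = np.convolve(np.ones_like(x), kernel, mode="full")[: len(x)]
    return num / den


def _baseline_mask(pwa: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Stable tracts: relative deviation from the trailing running mean below
    the stability tolerance for at least ``pwa_stable_beats`` consecutive
    beats.  (A trailing mean lags on ramps, so drop transients are excluded.)"""
    local_mean = _trailing_mean(pwa, cfg.pwa_smooth_beats)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_dev = np.abs(pwa - local_mean) / np.abs(local_mean)
    stable = rel_dev < cfg.pwa_stability_tol
    mask = np.zeros_like(stable)
    run = 0
    for i, s in enumerate(stable):
        run = run + 1 if s else 0
        if run >= cfg.pwa_stable_beats:
            mask[i - run + 1 : i + 1] = True
    return mask


def detect_drops(
    pwa: PwaSeries, cfg: PipelineConfig | None = None
) -> list[PwaDrop]:
    """Detect PWA drops via the local-variance / first-derivative criteria.

    Candidates are local maxima of the windowed PWA variance showing a
    negative PWA first difference at the same beat; a candidate is retained
    iff ``(baseline - pwa) / baseline > 0.10`` with the baseline the mean of
    the five most recent baseline-mask beats.  Drop duration counts the
    consecutive beats below ``(1 - 0.10) x baseline`` from the drop start.
    """
    cfg = cfg or PipelineConfig()
    if pwa.valid.sum() < 10:
        log.warning("fewer than 10 valid beats; no drops detectable")
        return []
    v = pwa.pwa
    n = len(v)
    mask = _baseline_mask(v, cfg)
    pwa.baseline_mask = mask

    w = cfg.pwa_variance_beats
    m1 = _moving_average(v, w)
    m2 = _moving_average(v**2, w)
    local_var = np.maximum(m2 - m1**2, 0.0)  # rolling variance within the window
    diff = np.diff(v, prepend=v[0])

    half = w // 2
    candidates = []
    for i in range(1, n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        # local maximum of the variance, ties allowed (relative tolerance so
        # the rule is invariant to rescaling the PPG)
        if local_var[i] <= 0 or local_var[i] < local_var[lo:hi].max() * (1 - 1e-9):
            continue
        if diff[i] < 0:
            candidates.append(i)

    drops: list[PwaDrop] = []
    last_end = -1
    baseline_idx = np.flatnonzero(mask)
    for i in candidates:
        if i <= last_end:
            continue
        prev = baseline_idx[baseline_idx < i]
        if len(prev) < 1:
            log.warning("no baseline beats before candidate at beat %d; skipped", i)
            continue
        baseline = v[prev[-cfg.pwa_baseline_beats :]].mean()
        if baseline <= 0:
            continue
        # the drop amplitude is read at the trough the candidate leads into
        # (the variance peak sits on the falling edge)
        i_tr = i
        while i_tr + 1 < n and v[i_tr + 1] < v[i_tr]:
            i_tr += 1
        depth = (baseline - v[i_tr]) / baseline
        if depth <= cfg.pwa_drop_threshold:
            continue
        i = i_tr
        thr = (1.0 - cfg.pwa_drop_threshold) * baseline
        j0 = i
        while j0 > 0 and v[j0 - 1] <= thr:
            j0 -= 1
        j1 = i
        while j1 + 1 < n and v[j1 + 1] <= thr:
            j1 += 1
        last_end = j1
        t0 = pwa.beat_times[j0]
        t1 = pwa.beat_times[min(j1 + 1, n - 1)]
        drops.append(
            PwaDrop(
                onset_beat=int(j0),
                onset_s=float(t0),
                depth=float(depth),
                duration_s=float(max(t1 - t0, np.diff(pwa.beat_times).mean())),
                baseline_value=float(baseline),
            )
        )
    log.info("PWA drops detected: %d", len(drops))
    return drops


def drops_to_event_table(
    drops: list[PwaDrop], hyp: Hypnogram | None = None
) -> EventTable:
    rows = []
    for d in drops:
        stage = None
        if hyp is not None and 0 <= d.onset_s < hyp.duration_s:
            stage = hyp.stage_at(d.onset_s)
        rows.append(
            dict(
                kind="pwa_drop",
                onset_s=d.onset_s,
                peak_s=np.nan,
                duration_s=d.duration_s,
                amplitude=d.depth,
                stage=stage,
                cluster=None,
                extras=dict(baseline=d.baseline_value, onset_beat=d.onset_beat),
            )
        )
    return EventTable(pd.DataFrame(rows) if rows else None)
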