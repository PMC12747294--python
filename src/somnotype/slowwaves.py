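"""Slow-wave detection on the multi-channel negative envelope.

The detector works on an artificial channel built, per time point, from the
four most negative channel values: the single most negative sample is
discarded (guarding against residual large-amplitude artifacts in isolated
electrodes) and the remaining three are averaged.  After zero-mean centring,
negative half-waves are segmented at consecutive zero-crossings; only waves
with a half-wave duration of 0.25-1.0 s (full-wave 0.5-2.0 Hz) whose onset
falls in an NREM epoch are kept.  No amplitude threshold is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import (
    EegRecording,
    EventTable,
    Hypnogram,
    NREM_STAGES,
    PipelineConfig,
    get_logger,
)

log = get_logger(__name__)

__all__ = [
    "EnvelopeSeries",
    "SlowWave",
    "negative_envelope",
    "detect_halfwaves",
    "wave_features",
    "flag_isolation",
    "kcomplex_overlap",
    "detect_slow_waves",
    "waves_to_event_table",
]


@dataclass
class EnvelopeSeries:
    """Zero-mean negative signal envelope at the EEG sample rate (uV)."""

    rate: float
    values: np.ndarray

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


@dataclass
class SlowWave:
    onset_s: float
    end_s: float
    peak_s: float
    amplitude_uV: float
    stage: str
    descending_slope: float = np.nan  # uV/s
    ascending_slope: float = np.nan  # uV/s
    involvement: np.ndarray | None = None  # per-channel mean voltage at the peak
    n_involved: int = -1
    sync_score: float = np.nan
    isolated: bool | None = None
    cluster: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def halfwave_duration_s(self) -> float:
        return self.end_s - self.onset_s


def _bandpass(data: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = rate / 2.0
    hi = min(band[1], 0.98 * nyq)
    sos = signal.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def negative_envelope(
    eeg: EegRecording,
    band: tuple[float, float] | None = None,
    hyp: Hypnogram | None = None,
    cfg: PipelineConfig | None = None,
    prefiltered: bool = False,
) -> EnvelopeSeries:
    """Negative envelope: mean of the 2nd-4th most negative channels per sample.

    The input is band-pass filtered (default 0.3-45 Hz) after excluding bad
    channels; the envelope is then zero-mean centred.  When a hypnogram is
    supplied, the centring baseline is the mean over artifact-free epochs.
    """
    cfg = cfg or PipelineConfig()
    band = band or cfg.sw_band
    _, data = eeg.good_channel_data()
    k_sel, k_drop = cfg.envelope_k_select, cfg.envelope_k_drop
    if data.shape[0] < k_sel:
        raise ValueError(
            f"negative envelope needs >= {k_sel} usable channels, got {data.shape[0]}"
        )
    filtered = data if prefiltered else _bandpass(data, eeg.sample_rate, band)
    part = np.partition(filtered, kth=k_sel - 1, axis=0)[:k_sel]
    env = np.sort(part, axis=0)[k_drop:k_sel].mean(axis=0)

    if hyp is not None and hyp.artifact_flags.any():
        epoch_idx = np.minimum(
            (np.arange(len(env)) / eeg.sample_rate // hyp.epoch_length).astype(int),
            hyp.n_epochs - 1,
        )
        usable = ~hyp.artifact_flags[epoch_idx]
        baseline = env[usable].mean() if usable.any() else env.mean()
    else:
        baseline = env.mean()
    return EnvelopeSeries(rate=eeg.sample_rate, values=env - baseline)


def detect_halfwaves(
    env: EnvelopeSeries,
    hyp: Hypnogram,
    dur: tuple[float, float] | None = None,
    cfg: PipelineConfig | None = None,
) -> list[SlowWave]:
    """Segment negative half-waves at consecutive zero-crossings.

    A wave is a maximal run of strictly negative envelope samples; a sample
    exactly equal to zero counts as non-negative, making intervals half-open
    and deterministic.  Waves outside the duration bounds or whose onset
    epoch is not N1/N2/N3 are discarded; no amplitude threshold is applied.
    """
    cfg = cfg or PipelineConfig()
    lo, hi = dur or cfg.sw_halfwave_duration
    v = env.values
    neg = v < 0
    # run boundaries of the negative mask
    d = np.diff(neg.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if neg[0]:
        starts = np.concatenate([[0], starts])
    if neg[-1]:
        ends = np.concatenate([ends, [len(v)]])

    waves: list[SlowWave] = []
    for i0, i1 in zip(starts, ends):
        onset = i0 / env.rate
        end = i1 / env.rate
        duration = end - onset
        if duration < lo or duration > hi:
            continue
        if onset >= hyp.duration_s or hyp.stage_at(onset) not in NREM_STAGES:
            continue
        ipk = i0 + int(np.argmin(v[i0:i1]))
        waves.append(
            SlowWave(
                onset_s=onset,
                end_s=end,
                peak_s=ipk / env.rate,
                amplitude_uV=float(abs(v[ipk])),
                stage=hyp.stage_at(onset),
            )
        )
    return waves


def wave_features(
    wave: SlowWave,
    eeg: EegRecording,
    cfg: PipelineConfig | None = None,
    filtered: np.ndarray | None = None,
) -> SlowWave:
    """Fill per-wave slopes, channel involvement and synchronisation score.

    Involvement of a channel is its mean voltage in a 40-ms window centred on
    the negative peak; a channel is "involved" strictly below -5 uV.  The
    synchronisation score is the mean of descending and ascending slopes
    (envelope amplitude over phase duration) times the involved fraction.
    ``filtered`` lets callers pass the band-passed multichannel signal once.
    """
    cfg = cfg or PipelineConfig()
    if filtered is None:
        _, data = eeg.good_channel_data()
        filtered = _bandpass(data, eeg.sample_rate, cfg.sw_band)

    half = cfg.involvement_window / 2.0
    i0 = int(np.floor((wave.peak_s - half) * eeg.sample_rate))
    i1 = int(np.ceil((wave.peak_s + half) * eeg.sample_rate)) + 1
    if i0 < 0 or i1 > filtered.shape[1]:
        log.warning("involvement window truncated at recording edge (peak %.2f s)", wave.peak_s)
        i0, i1 = max(i0, 0), min(i1, filtered.shape[1])
    if cfg.involvement_mode == "peak_sample":
        ipk = int(round(wave.peak_s * eeg.sample_rate))
        inv = filtered[:, min(ipk, filtered.shape[1] - 1)]
    else:
        inv = filtered[:, i0:i1].mean(axis=1)

    wave.involvement = inv
    wave.n_involved = int(np.sum(inv < cfg.involvement_threshold))
    desc_dur = wave.peak_s - wave.onset_s
    asc_dur = wave.end_s - wave.peak_s
    wave.descending_slope = wave.amplitude_uV / desc_dur if desc_dur > 0 else np.nan
    wave.ascending_slope = wave.amplitude_uV / asc_dur if asc_dur > 0 else np.nan
    wave.sync_score = (
        0.5
        * (wave.descending_slope + wave.ascending_slope)
        * (wave.n_involved / filtered.shape[0])
    )
    return wave


def flag_isolation(
    waves: list[SlowWave],
    window: tuple[float, float] | None = None,
    cfg: PipelineConfig | None = None,
) -> list[SlowWave]:
    """A wave is isolated iff no other wave peaks within -12..+5 s of its onset."""
    cfg = cfg or PipelineConfig()
    w0, w1 = window or cfg.isolation_window
    peaks = np.array([w.peak_s for w in waves])
    order = np.argsort(peaks)
    sorted_peaks = peaks[order]
    for i, w in enumerate(waves):
        lo = w.onset_s + w0
        hi = w.onset_s + w1
        a = np.searchsorted(sorted_peaks, lo, side="left")
        b = np.searchsorted(sorted_peaks, hi, side="right")
        hits = b - a
        if a <= np.searchsorted(sorted_peaks, w.peak_s) < b:
            hits -= 1  # the wave's own peak
        w.isolated = bool(hits == 0)
    return waves


def kcomplex_overlap(waves: list[SlowWave] | EventTable, kcs: EventTable) -> dict[str, float]:
    """Percentage of waves per cluster whose ``[onset, end)`` interval
    intersects any K-complex ``[onset, onset + duration)`` interval."""
    if isinstance(waves, EventTable):
        wdf = waves.of_kind("slow_wave")
        onsets = wdf["onset_s"].to_numpy(float)
        ends = onsets + wdf["duration_s"].to_numpy(float)
        clusters = [c if c else "unassigned" for c in wdf["cluster"].fillna("unassigned")]
    else:
        onsets = np.array([w.onset_s for w in waves])
        ends = np.array([w.end_s for w in waves])
        clusters = [w.cluster or "unassigned" for w in waves]

    kdf = kcs.of_kind("k_complex")
    k_on = kdf["onset_s"].to_numpy(float)
    k_off = k_on + kdf["duration_s"].to_numpy(float)

    out: dict[str, float] = {}
    for cl in sorted(set(clusters)):
        idx = [i for i, c in enumerate(clusters) if c == cl]
        if not idx:
            continue
        if len(k_on) == 0:
            out[cl] = 0.0
            continue
        n_hit = sum(
            1 for i in idx if np.any((onsets[i] < k_off) & (ends[i] > k_on))
        )
        out[cl] = 100.0 * n_hit / len(idx)
    return out


def detect_slow_waves(
    eeg: EegRecording,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
) -> list[SlowWave]:
    """Full slow-wave pipeline: envelope, half-wave detection, features,
    isolation flags."""
    cfg = cfg or PipelineConfig()
    env = negative_envelope(eeg, cfg.sw_band, hyp, cfg)
    waves = detect_halfwaves(env, hyp, cfg.sw_halfwave_duration, cfg)
    _, data = eeg.good_channel_data()
    filtered = _bandpass(data, eeg.sample_rate, cfg.sw_band)
    for w in waves:
        wave_features(w, eeg, cfg, filtered=filtered)
    flag_isolation(waves, cfg.isolation_window, cfg)
    log.info("slow waves detected: %d", len(waves))
    return waves


def waves_to_event_table(waves: list[SlowWave]) -> EventTable:
    rows = []
    for w in waves:
        rows.append(
            dict(
                kind="slow_wave",
                onset_s=w.onset_s,
                peak_s=w.peak_s,
                duration_s=w.halfwave_duration_s,
                amplitude=w.amplitude_uV,
                stage=w.stage,
                cluster=w.cluster,
                extras=dict(
                    descending_slope=w.descending_slope,
                    ascending_slope=w.ascending_slope,
                    n_involved=w.n_involved,
                    sync_score=w.sync_score,
                    isolated=bool(w.isolated) if w.isolated is not None else None,
                    **w.extras,
                ),
            )
        )
    return EventTable(pd.DataFrame(rows, columns=None) if rows else None)
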