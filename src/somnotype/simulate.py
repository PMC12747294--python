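"""Seeded synthetic EEG / hypnogram / PPG / ROI-BOLD generator with ground truth.

The generator plants two slow-wave morphologies (type A: large, widespread;
type B: small, narrow), sleep spindles whose occurrence rate is modulated by
a ~0.02 Hz infraslow rhythm, wave-type-specific thalamic BOLD impulse
responses on top of AR(1) noise, and a pulsatile photoplethysmogram with
amplitude drops coupled to type-A waves in light NREM sleep.  Type-A wave
onsets are drawn from a von Mises distribution centred in the descending
infraslow phase, type-B onsets in the rising phase.

Everything is driven by one :class:`numpy.random.SeedSequence`; per-signal
sub-streams keep the cross-signal structure stable when one component's
parameters change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_ROI_LABELS,
    EegRecording,
    Hypnogram,
    RoiBoldSeries,
    get_logger,
)

log = get_logger(__name__)

__all__ = [
    "WaveTypeParams",
    "SpindleParams",
    "BoldParams",
    "PpgParams",
    "SimulationSpec",
    "GroundTruth",
    "PpgSignal",
    "wave_template",
    "bold_template",
    "draw_onset_phases",
    "build_hypnogram",
    "simulate_subject",
]

DEFAULT_CHANNELS = ["Fz", "Cz", "Pz", "C3", "C4", "F3", "F4", "Oz"]

#: centres of the descending (330-140 deg) and rising (140-330 deg) arcs
DESCENDING_CENTER_DEG = 55.0
RISING_CENTER_DEG = 235.0


@dataclass
class WaveTypeParams:
    rate_per_min: float = 3.0
    amplitude_uv: float = -80.0  # template negative-peak amplitude
    neg_duration_s: float = 0.6  # negative half-wave duration
    channel_spread: float = 0.8  # fraction of channels carrying the wave
    phase_mu_deg: float = DESCENDING_CENTER_DEG
    phase_kappa: float = 1.2  # von Mises concentration of onset phases

    @property
    def pos_duration_s(self) -> float:
        # positive lobe sized so the biphasic template integrates to zero
        return 1.5 * self.neg_duration_s

    @property
    def duration_s(self) -> float:
        return self.neg_duration_s + self.pos_duration_s


@dataclass
class SpindleParams:
    rate_per_min: float = 7.0
    freq_hz: float = 13.0
    duration_s: float = 1.0
    amplitude_uv: float = 25.0
    modulation_depth: float = 0.6  # infraslow rate modulation (0..1)
    cooccur_prob_a: float = 0.3  # extra spindle at each type-A wave


@dataclass
class BoldParams:
    amp_a: float = 0.3  # % signal change, early-positive template
    amp_b: float = 0.3  # % signal change, early-negative template
    spindle_amp: float = 0.05
    ar1_coef: float = 0.4
    noise_sd: float = 0.15
    censor_frac: float = 0.0


@dataclass
class PpgParams:
    sample_rate: float = 100.0
    heart_rate_bpm: float = 60.0
    pulse_amplitude: float = 1.0
    beat_jitter: float = 0.02  # fractional sd of beat intervals
    drop_prob: float = 0.5  # per type-A wave in N1/N2
    drop_depth: float = 0.25  # fraction of baseline amplitude
    drop_duration_beats: int = 8
    drop_delay_s: tuple[float, float] = (1.0, 3.0)  # after the wave peak
    independent_drop_rate_per_min: float = 0.5


@dataclass
class SimulationSpec:
    seed: int = 0
    duration_s: float = 2400.0
    n_channels: int = 8
    eeg_rate: float = 100.0
    tr: float = 3.0
    run_length_s: float = 600.0
    #: repeating (stage, n_epochs) cycle used to fill the hypnogram
    hypnogram_plan: tuple[tuple[str, int], ...] = (
        ("W", 1),
        ("N1", 2),
        ("N2", 16),
        ("N3", 10),
        ("N2", 8),
        ("REM", 2),
        ("N1", 1),
    )
    type_a_wave: WaveTypeParams = field(default_factory=WaveTypeParams)
    type_b_wave: WaveTypeParams = field(
        default_factory=lambda: WaveTypeParams(
            rate_per_min=3.0,
            amplitude_uv=-30.0,
            neg_duration_s=0.4,
            channel_spread=0.5,
            phase_mu_deg=RISING_CENTER_DEG,
            phase_kappa=1.2,
        )
    )
    spindle_params: SpindleParams = field(default_factory=SpindleParams)
    infraslow_freq: float = 0.02
    sigma_tone_uv: float = 0.5  # baseline sigma-band tone amplitude (Cz/Pz)
    sigma_mod_depth: float = 0.6  # infraslow amplitude modulation of the tone
    background_sd_uv: float = 12.0
    bold_params: BoldParams = field(default_factory=BoldParams)
    ppg_params: PpgParams = field(default_factory=PpgParams)
    min_wave_sep_s: float = 2.5

    def validate(self) -> None:
        for wt in (self.type_a_wave, self.type_b_wave):
            if wt.rate_per_min < 0:
                raise ValueError("wave rates must be >= 0")
        if self.spindle_params.rate_per_min < 0:
            raise ValueError("spindle rate must be >= 0")
        if self.duration_s <= 0 or self.eeg_rate <= 0 or self.tr <= 0:
            raise ValueError("duration, eeg_rate and tr must be positive")


@dataclass
class GroundTruth:
    """Planted events with their true type labels, phases and couplings."""

    waves: pd.DataFrame  # onset_s, peak_s, duration_s, amplitude, type, phase_deg, stage
    spindles: pd.DataFrame  # onset_s, duration_s, phase_deg, stage
    drops: pd.DataFrame  # onset_s, depth, duration_s, wave_onset_s (nan if independent)
    infraslow_freq: float

    @staticmethod
    def empty(infraslow_freq: float = 0.02) -> "GroundTruth":
        return GroundTruth(
            waves=pd.DataFrame(
                columns=["onset_s", "peak_s", "duration_s", "amplitude", "type", "phase_deg", "stage"]
            ),
            spindles=pd.DataFrame(columns=["onset_s", "duration_s", "phase_deg", "stage"]),
            drops=pd.DataFrame(columns=["onset_s", "depth", "duration_s", "wave_onset_s"]),
            infraslow_freq=infraslow_freq,
        )


@dataclass
class PpgSignal:
    rate: float
    values: np.ndarray


# ---------------------------------------------------------------------------
# Closed-form templates
# ---------------------------------------------------------------------------

def wave_template(t_rel: np.ndarray | float, params: WaveTypeParams) -> np.ndarray:
    """Biphasic slow-wave template (uV per unit spread weight).

    Zero at ``t_rel = 0`` and at ``t_rel = duration``; a single negative lobe
    (half-sine, peak = ``amplitude_uv``) followed by a positive lobe scaled so
    the template integrates to zero.  Returns 0 outside the support.
    """
    t = np.asarray(t_rel, dtype=float)
    d_neg = params.neg_duration_s
    d_pos = params.pos_duration_s
    out = np.zeros_like(t)
    neg = (t >= 0) & (t <= d_neg)
    out[neg] = params.amplitude_uv * np.sin(np.pi * t[neg] / d_neg)
    pos = (t > d_neg) & (t <= d_neg + d_pos)
    pos_amp = -params.amplitude_uv * d_neg / d_pos
    out[pos] = pos_amp * np.sin(np.pi * (t[pos] - d_neg) / d_pos)
    return out


def _bump(t: np.ndarray, t_peak: float, shape: float) -> np.ndarray:
    """Gamma-like unit-peak bump: 0 at t<=0, maximum 1 at ``t_peak``."""
    out = np.zeros_like(t)
    m = t > 0
    r = t[m] / t_peak
    out[m] = r**shape * np.exp(shape * (1.0 - r))
    return out


def bold_template(t_rel: np.ndarray | float, kind: str, params: BoldParams) -> np.ndarray:
    """Wave-locked BOLD impulse response (% signal change) over 0-21 s.

    Template A: early positive peak near 3 s with an undershoot near 10 s.
    Template B: early trough near 3-4 s with a late positive peak near 12 s.
    """
    t = np.asarray(t_rel, dtype=float)
    if kind == "A":
        resp = params.amp_a * (_bump(t, 3.0, 3.0) - 0.7 * _bump(t, 10.5, 12.0))
    elif kind == "B":
        resp = params.amp_b * (-0.8 * _bump(t, 3.5, 4.0) + _bump(t, 12.0, 12.0))
    elif kind == "spindle":
        resp = params.spindle_amp * _bump(t, 4.0, 3.0)
    else:
        raise ValueError(f"unknown BOLD template kind {kind!r}")
    return np.where(t <= 21.0, resp, 0.0)


def draw_onset_phases(
    n: int, mu_deg: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` infraslow onset phases (degrees in [0, 360)) from a von Mises."""
    if kappa <= 0:
        return rng.uniform(0.0, 360.0, n)
    ph = rng.vonmises(np.deg2rad(mu_deg), kappa, n)
    return np.rad2deg(ph) % 360.0


# ---------------------------------------------------------------------------
# Hypnogram and event placement
# ---------------------------------------------------------------------------

def build_hypnogram(spec: SimulationSpec) -> Hypnogram:
    """Fill the session duration by repeating the spec's stage plan."""
    n_epochs = int(np.ceil(spec.duration_s / 30.0))
    stages: list[str] = []
    while len(stages) < n_epochs:
        for stage, n in spec.hypnogram_plan:
            stages.extend([stage] * n)
    return Hypnogram(stages=stages[:n_epochs])


def _phase_deg_at(t: np.ndarray | float, freq: float) -> np.ndarray:
    """True infraslow phase at time ``t``; 0 deg at each sigma-envelope peak."""
    return (360.0 * freq * np.asarray(t, dtype=float)) % 360.0


def _in_stages(hyp: Hypnogram, t: float, stages: frozenset | set) -> bool:
    return 0 <= t < hyp.duration_s and hyp.stage_at(t) in stages


def _place_waves(
    spec: SimulationSpec, hyp: Hypnogram, rng: np.random.Generator
) -> pd.DataFrame:
    """Plant both wave types at von Mises infraslow phases inside NREM sleep."""
    nrem = {"N1", "N2", "N3"}
    freq = spec.infraslow_freq
    n_cycles = max(1, int(np.floor(spec.duration_s * freq)))
    placed: list[dict] = []
    onsets: list[float] = []

    for kind, params in (("A", spec.type_a_wave), ("B", spec.type_b_wave)):
        nrem_min = hyp.stage_minutes(nrem)
        n_target = int(round(params.rate_per_min * nrem_min))
        n_ok = 0
        for _ in range(n_target):
            for _attempt in range(60):
                theta = draw_onset_phases(1, params.phase_mu_deg, params.phase_kappa, rng)[0]
                k = rng.integers(0, n_cycles)
                t = (theta / 360.0 + k) / freq
                end = t + params.duration_s
                if t < 1.0 or end > spec.duration_s - 1.0:
                    continue
                if not (_in_stages(hyp, t, nrem) and _in_stages(hyp, end, nrem)):
                    continue
                if any(abs(t - o) < spec.min_wave_sep_s for o in onsets):
                    continue
                onsets.append(t)
                placed.append(
                    dict(
                        onset_s=t,
                        peak_s=t + params.neg_duration_s / 2.0,
                        duration_s=params.neg_duration_s,
                        amplitude=abs(params.amplitude_uv),
                        type=kind,
                        phase_deg=theta,
                        stage=hyp.stage_at(t),
                    )
                )
                n_ok += 1
                break
        if n_ok < n_target:
            warnings.warn(
                f"placed only {n_ok}/{n_target} type-{kind} waves "
                "(rate too high for non-overlapping placement)",
                stacklevel=2,
            )
    df = pd.DataFrame(placed, columns=["onset_s", "peak_s", "duration_s", "amplitude", "type", "phase_deg", "stage"])
    return df.sort_values("onset_s").reset_index(drop=True)


def _place_spindles(
    spec: SimulationSpec,
    hyp: Hypnogram,
    waves: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Spindles in N2/N3, rate modulated as (1 + m cos(phase)), plus
    co-occurring spindles at a random subset of type-A waves."""
    sp = spec.spindle_params
    freq = spec.infraslow_freq
    segs = hyp.segments(["N2", "N3"])
    total_min = sum(e - s for s, e in segs) / 60.0
    n_target = int(round(sp.rate_per_min * total_min))
    seg_arr = np.array(segs) if segs else np.zeros((0, 2))
    seg_len = seg_arr[:, 1] - seg_arr[:, 0] if len(seg_arr) else np.array([])

    out: list[dict] = []
    onsets: list[float] = []

    def try_add(t: float) -> bool:
        if t < 1.0 or t + sp.duration_s > spec.duration_s - 1.0:
            return False
        if not _in_stages(hyp, t, {"N2", "N3"}):
            return False
        if any(abs(t - o) < sp.duration_s + 0.5 for o in onsets):
            return False
        onsets.append(t)
        out.append(
            dict(
                onset_s=t,
                duration_s=sp.duration_s,
                phase_deg=_phase_deg_at(t, freq),
                stage=hyp.stage_at(t),
            )
        )
        return True

    n_ok = 0
    max_attempts = 80 * max(n_target, 1)
    attempts = 0
    while n_ok < n_target and attempts < max_attempts and len(seg_arr):
        attempts += 1
        seg = rng.choice(len(seg_arr), p=seg_len / seg_len.sum())
        t = rng.uniform(seg_arr[seg, 0], seg_arr[seg, 1] - sp.duration_s)
        accept_p = (1.0 + sp.modulation_depth * np.cos(np.deg2rad(_phase_deg_at(t, freq)))) / (
            1.0 + sp.modulation_depth
        )
        if rng.random() > accept_p:
            continue
        if try_add(t):
            n_ok += 1

    if sp.cooccur_prob_a > 0 and len(waves):
        for _, w in waves[waves["type"] == "A"].iterrows():
            if rng.random() < sp.cooccur_prob_a:
                try_add(w["peak_s"] + rng.uniform(-0.5, 0.5))

    df = pd.DataFrame(out, columns=["onset_s", "duration_s", "phase_deg", "stage"])
    return df.sort_values("onset_s").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum (low-cut 0.5 Hz)."""
    white = rng.standard_normal(n)
    spec_f = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    scale = 1.0 / np.maximum(freqs, 0.5)
    scale[0] = 0.0
    x = np.fft.irfft(spec_f * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_eeg(
    spec: SimulationSpec,
    hyp: Hypnogram,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> EegRecording:
    n = int(round(spec.duration_s * spec.eeg_rate))
    t = np.arange(n) / spec.eeg_rate
    labels = (DEFAULT_CHANNELS + [f"EEG{i}" for i in range(len(DEFAULT_CHANNELS), spec.n_channels)])[
        : spec.n_channels
    ]
    data = np.zeros((spec.n_channels, n))

    for ch in range(spec.n_channels):
        if spec.background_sd_uv > 0:
            data[ch] = spec.background_sd_uv * _one_over_f_noise(n, spec.eeg_rate, rng)

    # sigma-band tone with infraslow amplitude modulation on Cz and Pz
    if spec.sigma_tone_uv > 0:
        envelope = 1.0 + spec.sigma_mod_depth * np.cos(2 * np.pi * spec.infraslow_freq * t)
        for name, gain in (("Cz", 1.0), ("Pz", 1.0)):
            if name in labels:
                phi = rng.uniform(0, 2 * np.pi)
                data[labels.index(name)] += (
                    spec.sigma_tone_uv * gain * envelope * np.sin(2 * np.pi * 13.5 * t + phi)
                )

    # planted spindle bursts (Hann-windowed sigma oscillation) on Cz/Pz
    sp = spec.spindle_params
    for _, ev in truth.spindles.iterrows():
        i0 = int(round(ev["onset_s"] * spec.eeg_rate))
        ns = int(round(ev["duration_s"] * spec.eeg_rate))
        if ns < 2 or i0 + ns > n:
            continue
        tt = np.arange(ns) / spec.eeg_rate
        burst = sp.amplitude_uv * np.hanning(ns) * np.sin(2 * np.pi * sp.freq_hz * tt)
        for name, gain in (("Cz", 1.0), ("Pz", 0.7)):
            if name in labels:
                data[labels.index(name), i0 : i0 + ns] += gain * burst

    # planted slow waves: template on a random channel subset, unit weight
    for _, ev in truth.waves.iterrows():
        params = spec.type_a_wave if ev["type"] == "A" else spec.type_b_wave
        n_inv = max(1, int(round(params.channel_spread * spec.n_channels)))
        chans = rng.choice(spec.n_channels, size=n_inv, replace=False)
        i0 = int(round(ev["onset_s"] * spec.eeg_rate))
        nw = int(round(params.duration_s * spec.eeg_rate)) + 1
        i1 = min(i0 + nw, n)
        tpl = wave_template(t[i0:i1] - ev["onset_s"], params)
        data[chans[:, None], np.arange(i0, i1)[None, :]] += tpl[None, :]

    return EegRecording(sample_rate=spec.eeg_rate, channel_labels=labels, data=data)


def synthesize_bold(
    spec: SimulationSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    roi_labels: list[str] | None = None,
) -> RoiBoldSeries:
    roi_labels = roi_labels or list(DEFAULT_ROI_LABELS)
    n_roi = len(roi_labels)
    bp = spec.bold_params
    n_vol = int(np.floor(spec.duration_s / spec.tr))
    tv = np.arange(n_vol) * spec.tr
    n_runs = max(1, int(np.ceil(spec.duration_s / spec.run_length_s)))
    run_offsets = [i * spec.run_length_s for i in range(n_runs)]
    run_ends = np.array(run_offsets[1:] + [spec.duration_s])

    gains = np.linspace(0.85, 1.15, n_roi)
    signal = np.zeros((n_roi, n_vol))

    def add_events(onsets: np.ndarray, kind: str) -> None:
        for onset in onsets:
            run = int(np.searchsorted(run_offsets, onset, side="right")) - 1
            in_run = (tv >= onset) & (tv < run_ends[run])
            resp = bold_template(tv[in_run] - onset, kind, bp)
            signal[:, in_run] += gains[:, None] * resp[None, :]

    if len(truth.waves):
        for kind in ("A", "B"):
            add_events(truth.waves.loc[truth.waves["type"] == kind, "onset_s"].to_numpy(), kind)
    if len(truth.spindles) and bp.spindle_amp != 0:
        add_events(truth.spindles["onset_s"].to_numpy(), "spindle")

    if bp.noise_sd > 0:
        e = rng.standard_normal((n_roi, n_vol)) * bp.noise_sd * np.sqrt(1 - bp.ar1_coef**2)
        noise = np.empty_like(e)
        noise[:, 0] = e[:, 0] / np.sqrt(1 - bp.ar1_coef**2)
        for v in range(1, n_vol):
            noise[:, v] = bp.ar1_coef * noise[:, v - 1] + e[:, v]
        signal += noise

    censor = np.ones(n_vol, dtype=bool)
    if bp.censor_frac > 0:
        censor[rng.random(n_vol) < bp.censor_frac] = False

    return RoiBoldSeries(
        tr=spec.tr,
        roi_labels=roi_labels,
        data=signal,
        run_offsets=run_offsets,
        censor_mask=censor,
    )


def _pulse_shape(u: np.ndarray) -> np.ndarray:
    """Asymmetric single-beat waveform on the unit cycle (fast systolic rise,
    slow decay); unit peak amplitude."""
    return _bump(u, 0.25, 2.0)


def synthesize_ppg(
    spec: SimulationSpec,
    hyp: Hypnogram,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[PpgSignal, pd.DataFrame]:
    """Pulse train with planted amplitude drops; returns the PPG and the
    planted-drop table."""
    pp = spec.ppg_params
    n = int(round(spec.duration_s * pp.sample_rate))
    t = np.arange(n) / pp.sample_rate

    mean_ibi = 60.0 / pp.heart_rate_bpm
    n_beats = int(np.ceil(spec.duration_s / mean_ibi)) + 2
    ibis = mean_ibi * (1.0 + pp.beat_jitter * rng.standard_normal(n_beats))
    ibis = np.clip(ibis, 0.3, 2.0)
    beat_starts = np.concatenate([[0.0], np.cumsum(ibis)])
    beat_starts = beat_starts[beat_starts < spec.duration_s]

    # planted drops: coupled to type-A waves in light NREM, plus independent ones
    drop_rows: list[dict] = []
    drop_starts: list[float] = []
    # drops are kept >= 20 s apart so each planted event is a discrete,
    # recoverable vasoconstriction episode
    min_sep = 20.0
    if len(truth.waves):
        light_a = truth.waves[(truth.waves["type"] == "A") & (truth.waves["stage"].isin(["N1", "N2"]))]
        for _, w in light_a.iterrows():
            if rng.random() < pp.drop_prob:
                t0 = w["peak_s"] + rng.uniform(*pp.drop_delay_s)
                if t0 + pp.drop_duration_beats * mean_ibi < spec.duration_s and all(
                    abs(t0 - d) > min_sep for d in drop_starts
                ):
                    drop_starts.append(t0)
                    drop_rows.append(dict(onset_s=t0, wave_onset_s=w["onset_s"]))
    n_indep = int(round(pp.independent_drop_rate_per_min * spec.duration_s / 60.0))
    for _ in range(n_indep):
        for _attempt in range(40):
            t0 = rng.uniform(5.0, spec.duration_s - 15.0)
            if _in_stages(hyp, t0, {"N1", "N2", "N3"}) and all(
                abs(t0 - d) > 20.0 for d in drop_starts
            ):
                drop_starts.append(t0)
                drop_rows.append(dict(onset_s=t0, wave_onset_s=np.nan))
                break

    # per-beat amplitude envelope with multiplicative drops
    amp = np.full(len(beat_starts), pp.pulse_amplitude)
    for row in drop_rows:
        b0 = int(np.searchsorted(beat_starts, row["onset_s"]))
        b1 = min(b0 + pp.drop_duration_beats, len(amp))
        amp[b0:b1] *= 1.0 - pp.drop_depth
        row["onset_s"] = float(beat_starts[b0]) if b0 < len(beat_starts) else row["onset_s"]
        row["depth"] = pp.drop_depth
        row["duration_s"] = float((b1 - b0) * mean_ibi)

    ppg = np.zeros(n)
    for b, t0 in enumerate(beat_starts):
        ibi = (beat_starts[b + 1] - t0) if b + 1 < len(beat_starts) else mean_ibi
        i0 = int(round(t0 * pp.sample_rate))
        i1 = min(int(round((t0 + ibi) * pp.sample_rate)), n)
        u = (t[i0:i1] - t0) / ibi
        ppg[i0:i1] = amp[b] * _pulse_shape(u)

    drops = pd.DataFrame(drop_rows, columns=["onset_s", "depth", "duration_s", "wave_onset_s"])
    drops = drops.sort_values("onset_s").reset_index(drop=True)
    return PpgSignal(rate=pp.sample_rate, values=ppg), drops


# ---------------------------------------------------------------------------
# Top-level
# ---------------------------------------------------------------------------

def simulate_subject(
    spec: SimulationSpec,
) -> tuple[EegRecording, Hypnogram, PpgSignal, RoiBoldSeries, GroundTruth]:
    """Generate one synthetic subject; identical seeds give identical outputs."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_spindle, rng_eeg, rng_bold, rng_ppg = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    hyp = build_hypnogram(spec)
    waves = _place_waves(spec, hyp, rng_place)
    spindles = _place_spindles(spec, hyp, waves, rng_spindle)
    truth = GroundTruth(
        waves=waves,
        spindles=spindles,
        drops=pd.DataFrame(columns=["onset_s", "depth", "duration_s", "wave_onset_s"]),
        infraslow_freq=spec.infraslow_freq,
    )

    eeg = synthesize_eeg(spec, hyp, truth, rng_eeg)
    bold = synthesize_bold(spec, truth, rng_bold)
    ppg, drops = synthesize_ppg(spec, hyp, truth, rng_ppg)
    truth = replace(truth, drops=drops)
    log.info(
        "simulated subject: %d waves (%d A / %d B), %d spindles, %d PWA drops",
        len(waves),
        int((waves["type"] == "A").sum()) if len(waves) else 0,
        int((waves["type"] == "B").sum()) if len(waves) else 0,
        len(spindles),
        len(drops),
    )
    return eeg, hyp, ppg, bold, truth
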