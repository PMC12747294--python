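"""Infraslow (~0.02 Hz) sigma-power oscillation: peak frequency, phase,
and cluster x phase occurrence statistics.

Sigma power (12-15 Hz, Pz) fluctuates at an infraslow timescale during NREM
sleep; its rising phase (140-330 deg) marks stable sleep and its descending
phase (330-140 deg) marks fragile sleep with elevated autonomic activity.
The subject-specific infraslow frequency is the spectral peak of the
dB-normalised sigma power within 0.015-0.025 Hz during N2 (default 0.02 Hz
when no clear peak exists); the power series is then band-passed around that
frequency and the analytic-signal phase (0 deg at the envelope peak) is read
out at each slow-wave onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .io import EventTable, Hypnogram, PipelineConfig, get_logger

log = get_logger(__name__)

__all__ = [
    "InfraslowModel",
    "PhaseCoupling",
    "fit_infraslow",
    "phase_at_onsets",
    "phase_anova",
    "circular_mean_deg",
    "rayleigh_test",
]


@dataclass
class InfraslowModel:
    subject: str | int | None
    sigma_band: tuple[float, float]
    peak_freq_hz: float
    defaulted: bool
    rate: float  # sample rate of the phase/analytic series (Hz)
    analytic: np.ndarray  # complex analytic signal of the band-passed dB power
    spectrum_freqs: np.ndarray = field(default_factory=lambda: np.array([]))
    spectrum_db: np.ndarray = field(default_factory=lambda: np.array([]))

    def phase_deg(self, t: np.ndarray | float) -> np.ndarray:
        """Infraslow phase (degrees in [0, 360)) at times ``t``, interpolating
        the analytic signal to avoid wrap-around artefacts."""
        t = np.atleast_1d(np.asarray(t, float))
        grid = np.arange(len(self.analytic)) / self.rate
        re = np.interp(t, grid, self.analytic.real)
        im = np.interp(t, grid, self.analytic.imag)
        return np.rad2deg(np.arctan2(im, re)) % 360.0

    @property
    def duration_s(self) -> float:
        return len(self.analytic) / self.rate


@dataclass
class PhaseCoupling:
    subject: str | int | None
    cluster: str
    phases_deg: np.ndarray
    p_descending: float
    p_rising: float
    circ_mean_deg: float
    n: int


def circular_mean_deg(phases_deg: np.ndarray) -> float:
    rad = np.deg2rad(np.asarray(phases_deg, float))
    deg = float(np.rad2deg(np.angle(np.mean(np.exp(1j * rad)))) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def rayleigh_test(phases_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (z, p)."""
    rad = np.deg2rad(np.asarray(phases_deg, float))
    n = len(rad)
    r = np.abs(np.mean(np.exp(1j * rad)))
    z = n * r**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (r * n) ** 2)) - (1 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def _block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def sigma_power_db(
    eeg_channel: np.ndarray,
    rate: float,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Sigma (12-15 Hz) Hilbert power in dB re mean artifact-free NREM power,
    decimated to the infraslow analysis rate.  Returns (db_series, out_rate)."""
    cfg = cfg or PipelineConfig()
    nyq = rate / 2.0
    lo, hi = cfg.sigma_band_infraslow
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(eeg_channel, float))
    power = np.abs(signal.hilbert(filt)) ** 2

    t = np.arange(len(power)) / rate
    epoch = np.minimum((t // hyp.epoch_length).astype(int), hyp.n_epochs - 1)
    stages = hyp.stage_array()[epoch]
    nrem = np.isin(stages, ("N1", "N2", "N3")) & ~hyp.artifact_flags[epoch]
    ref = power[nrem].mean() if nrem.any() else power.mean()
    db = 10.0 * np.log10(np.maximum(power, 1e-12 * ref) / ref)

    factor = max(1, int(round(rate / cfg.infraslow_rate)))
    out = _block_mean(db, factor)
    return out, rate / factor


def _cwt_spectrum(
    x: np.ndarray, rate: float, freqs: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Mean wavelet power (dB) per frequency over the kept samples, using an
    analytic Morlet-type kernel."""
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * rate / freqs
    coeffs, _ = pywt.cwt(x - x.mean(), scales, wavelet, sampling_period=1.0 / rate)
    power = np.abs(coeffs[:, keep]) ** 2
    return 10.0 * np.log10(np.maximum(power.mean(axis=1), 1e-30))


def fit_infraslow(
    eeg_channel: np.ndarray,
    rate: float,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
    subject: str | int | None = None,
    min_n2_minutes: float = 10.0,
) -> InfraslowModel:
    """Individualised infraslow frequency and phase series.

    The peak frequency is the most prominent local maximum (prominence
    >= 1 dB) of the mean N2 wavelet spectrum of the dB sigma power within
    the 0.015-0.025 Hz search band; 0.02 Hz is assigned when no clear peak
    exists.  The dB power is then band-passed at peak +/- 0.005 Hz
    (2nd-order Butterworth) over the whole recording and the analytic-signal
    angle is referenced so that 0 deg falls at the envelope peak.
    """
    cfg = cfg or PipelineConfig()
    n2_min = hyp.stage_minutes(["N2"])
    if n2_min < min_n2_minutes:
        raise ValueError(
            f"insufficient N2 sleep: {n2_min:.1f} min < the {min_n2_minutes:.0f}-min minimum"
        )

    db, out_rate = sigma_power_db(eeg_channel, rate, hyp, cfg)
    t = np.arange(len(db)) / out_rate
    epoch = np.minimum((t // hyp.epoch_length).astype(int), hyp.n_epochs - 1)
    in_n2 = (hyp.stage_array()[epoch] == "N2") & ~hyp.artifact_flags[epoch]

    freqs = np.arange(0.005, 0.0505, 0.0005)
    spec = _cwt_spectrum(db, out_rate, freqs, in_n2)

    lo, hi = cfg.infraslow_search
    peaks, props = signal.find_peaks(spec, prominence=cfg.infraslow_prominence_db)
    in_band = [p for p in peaks if lo <= freqs[p] <= hi]
    if in_band:
        best = max(in_band, key=lambda p: spec[p])
        peak_freq, defaulted = float(freqs[best]), False
    else:
        peak_freq, defaulted = cfg.infraslow_default, True
        log.info("no clear infraslow peak; defaulting to %.3f Hz", peak_freq)

    half = cfg.infraslow_halfwidth
    nyq = out_rate / 2.0
    sos = signal.butter(
        2, [max(peak_freq - half, 1e-4) / nyq, (peak_freq + half) / nyq], "band", output="sos"
    )
    narrow = signal.sosfiltfilt(sos, db - db.mean())
    analytic = signal.hilbert(narrow)
    return InfraslowModel(
        subject=subject,
        sigma_band=cfg.sigma_band_infraslow,
        peak_freq_hz=peak_freq,
        defaulted=defaulted,
        rate=out_rate,
        analytic=analytic,
        spectrum_freqs=freqs,
        spectrum_db=spec,
    )


def phase_in_descending(phases_deg: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Half-open phase bins: descending [330, 360) + [0, 140), rising [140, 330)."""
    cfg = cfg or PipelineConfig()
    d0, d1 = cfg.phase_descending
    ph = np.asarray(phases_deg, float) % 360.0
    if d0 > d1:  # arc wrapping through 0
        return (ph >= d0) | (ph < d1)
    return (ph >= d0) & (ph < d1)


def phase_at_onsets(
    model: InfraslowModel,
    waves: EventTable | pd.DataFrame,
    cfg: PipelineConfig | None = None,
    subject: str | int | None = None,
) -> list[PhaseCoupling]:
    """Infraslow phase at each wave onset, binned per cluster.

    Waves outside the phase-series support are excluded (and counted in the
    log).  Per cluster, P(descending) + P(rising) = 1 exactly.
    """
    cfg = cfg or PipelineConfig()
    df = waves.of_kind("slow_wave") if isinstance(waves, EventTable) else waves
    onsets = df["onset_s"].to_numpy(float)
    inside = (onsets >= 0) & (onsets < model.duration_s)
    if (~inside).sum():
        log.info("excluded %d waves outside the phase-series support", int((~inside).sum()))
    df = df[inside]
    onsets = onsets[inside]
    phases = model.phase_deg(onsets)

    clusters = df["cluster"].fillna("unassigned") if "cluster" in df else pd.Series(["unassigned"] * len(df))
    out: list[PhaseCoupling] = []
    for cl in sorted(clusters.unique()):
        ph = phases[clusters.to_numpy() == cl]
        if len(ph) == 0:
            continue
        desc = phase_in_descending(ph, cfg)
        out.append(
            PhaseCoupling(
                subject=subject if subject is not None else model.subject,
                cluster=str(cl),
                phases_deg=ph,
                p_descending=float(desc.mean()),
                p_rising=float(1.0 - desc.mean()),
                circ_mean_deg=circular_mean_deg(ph),
                n=len(ph),
            )
        )
    return out


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    t = diff.mean() / (sd / np.sqrt(n))
    from scipy.stats import t as t_dist

    return float(t), float(2 * t_dist.sf(abs(t), n - 1))


def phase_anova(couplings: list[PhaseCoupling]) -> dict:
    """2 (cluster) x 2 (phase) within-subject ANOVA on occurrence
    probabilities, with post-hoc paired t-tests per cluster and circular
    summaries.

    The interaction F(1, n-1) is computed from the per-subject interaction
    contrast (equivalent to the squared paired-t on the cluster difference of
    phase preferences).  Subjects missing either cluster are excluded.
    """
    df = pd.DataFrame(
        [
            dict(
                subject=c.subject,
                cluster=c.cluster,
                p_desc=c.p_descending,
                p_rise=c.p_rising,
                circ=c.circ_mean_deg,
            )
            for c in couplings
        ]
    )
    clusters = sorted(df["cluster"].unique())
    if len(clusters) != 2:
        raise ValueError(f"need exactly 2 clusters, got {clusters}")
    c1, c2 = clusters
    wide = df.pivot(index="subject", columns="cluster", values=["p_desc", "p_rise", "circ"])
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        log.warning("excluding %d subjects missing a cluster cell", int(incomplete.sum()))
        wide = wide[~incomplete]
    n = len(wide)
    if n < 2:
        raise ValueError("need >= 2 subjects with both clusters")

    y11 = wide[("p_desc", c1)].to_numpy()
    y12 = wide[("p_rise", c1)].to_numpy()
    y21 = wide[("p_desc", c2)].to_numpy()
    y22 = wide[("p_rise", c2)].to_numpy()

    def f_from_contrast(c: np.ndarray) -> tuple[float, float]:
        t, p = _paired_t(c)
        return (float(t**2) if np.isfinite(t) else np.inf, p)

    f_inter, p_inter = f_from_contrast(y11 - y12 - y21 + y22)
    f_phase, p_phase = f_from_contrast(y11 + y21 - y12 - y22)
    f_clust, p_clust = f_from_contrast(y11 + y12 - y21 - y22)

    post = {}
    for cl, a, b in ((c1, y11, y12), (c2, y21, y22)):
        t, p = _paired_t(a - b)
        post[cl] = dict(t=t, p=p)

    circ_summary = {}
    for cl in clusters:
        means = wide[("circ", cl)].to_numpy()
        z, p = rayleigh_test(means)
        circ_summary[cl] = dict(
            circ_mean_deg=circular_mean_deg(means), rayleigh_z=z, rayleigh_p=p
        )

    return dict(
        n_subjects=n,
        interaction=dict(F=f_inter, df=(1, n - 1), p=p_inter),
        phase_main=dict(F=f_phase, df=(1, n - 1), p=p_phase),
        cluster_main=dict(F=f_clust, df=(1, n - 1), p=p_clust),
        posthoc=post,
        circular=circ_summary,
    )
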