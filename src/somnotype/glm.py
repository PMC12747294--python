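"""Event regressors, gamma HRF convolution and timing-shuffle GLM z-scores.

Slow waves are modelled as square waves spanning the descending phase
(onset to negative peak) with height equal to the absolute negative-peak
amplitude; spindles as unit-height square waves over their detected extent.
Regressors are convolved with a gamma-variate hemodynamic response function
h(t) = (t/(p*q))**p * exp(p - t/q) (defaults p = 8.6, q = 0.547, peaking
near 4.7 s), sampled on the TR grid per run, and fitted by ordinary least
squares.  Betas are converted to z-scores against a null distribution of
betas obtained by re-drawing event onsets uniformly within usable
same-stage segments (event counts preserved, zeroed segments avoided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import EventTable, Hypnogram, PipelineConfig, RoiBoldSeries, get_logger

log = get_logger(__name__)

__all__ = [
    "Regressor",
    "GlmResult",
    "gamma_hrf",
    "build_regressor",
    "convolve_hrf",
    "fit_glm",
    "group_z_test",
]


@dataclass
class Regressor:
    """Square-wave event regressor on a fine sample grid.

    ``events`` keeps (onset_s, duration_s, height, stage) so the timing-
    shuffle null can redraw onsets; ``zeroed_mask`` marks wake/REM/artifact
    samples where the regressor is forced to zero.
    """

    name: str
    rate: float
    samples: np.ndarray
    zeroed_mask: np.ndarray
    events: pd.DataFrame
    convolved: np.ndarray | None = None  # TR-grid values, filled by convolve_hrf

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class GlmResult:
    roi_labels: list[str]
    regressor_names: list[str]
    beta: np.ndarray  # rois x regressors
    z: np.ndarray  # rois x regressors (NaN where the null sd was 0)
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_shuffles: int


def gamma_hrf(t: np.ndarray, p: float = 8.6, q: float = 0.547) -> np.ndarray:
    """Gamma-variate HRF, unit peak at t = p*q."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    m = t > 0
    out[m] = (t[m] / (p * q)) ** p * np.exp(p - t[m] / q)
    return out


def _zeroed_mask(hyp: Hypnogram, rate: float, n: int) -> np.ndarray:
    """True where regressors must be zero: wake, REM or artifact epochs."""
    epoch = np.minimum(
        (np.arange(n) / rate // hyp.epoch_length).astype(int), hyp.n_epochs - 1
    )
    stages = hyp.stage_array()[epoch]
    zero = ~np.isin(stages, ("N1", "N2", "N3"))
    zero |= hyp.artifact_flags[epoch]
    return zero


def _boxcar(
    events: pd.DataFrame, rate: float, n: int, zeroed: np.ndarray
) -> np.ndarray:
    """Sum-of-boxcars on the sample grid via a cumulative step construction
    (overlapping boxcars sum by design)."""
    onset = events["onset_s"].to_numpy(float)
    dur = events["duration_s"].to_numpy(float)
    height = events["height"].to_numpy(float)
    i0 = np.minimum(np.round(onset * rate).astype(int), n)
    i1 = np.minimum(np.round((onset + dur) * rate).astype(int), n)
    keep = i1 > i0
    delta = np.zeros(n + 1)
    np.add.at(delta, i0[keep], height[keep])
    np.add.at(delta, i1[keep], -height[keep])
    reg = np.cumsum(delta[:-1])
    cover = np.zeros(n + 1)
    np.add.at(cover, i0[keep], 1)
    np.add.at(cover, i1[keep], -1)
    n_overlap = int(np.sum(np.diff((np.cumsum(cover[:-1]) > 1).astype(np.int8)) == 1))
    if n_overlap:
        log.debug("summed overlapping boxcars in %d regions", n_overlap)
    reg[zeroed] = 0.0
    return reg


def build_regressor(
    events: EventTable | pd.DataFrame,
    kind: str,
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
    duration_s: float | None = None,
    name: str | None = None,
) -> Regressor:
    """Square-wave regressor for one event kind (optionally one cluster).

    Slow waves: support ``[onset, peak)`` (the descending phase), height
    ``|amplitude|``.  Spindles: support ``[onset, end)``, height 1.  Samples
    in wake/REM/artifact segments are set to zero.
    """
    cfg = cfg or PipelineConfig()
    df = events.of_kind(kind) if isinstance(events, EventTable) else events
    rate = cfg.regressor_rate
    duration_s = duration_s if duration_s is not None else hyp.duration_s
    n = int(round(duration_s * rate))
    zeroed = _zeroed_mask(hyp, rate, n)

    if kind == "slow_wave":
        ev = pd.DataFrame(
            dict(
                onset_s=df["onset_s"].to_numpy(float),
                duration_s=df["peak_s"].to_numpy(float) - df["onset_s"].to_numpy(float),
                height=np.abs(df["amplitude"].to_numpy(float)),
                stage=df["stage"].to_numpy(object),
            )
        )
    else:
        ev = pd.DataFrame(
            dict(
                onset_s=df["onset_s"].to_numpy(float),
                duration_s=df["duration_s"].to_numpy(float),
                height=np.ones(len(df)),
                stage=df["stage"].to_numpy(object),
            )
        )
    ev = ev[ev["duration_s"] > 0].reset_index(drop=True)
    samples = _boxcar(ev, rate, n, zeroed)
    return Regressor(
        name=name or kind,
        rate=rate,
        samples=samples,
        zeroed_mask=zeroed,
        events=ev,
    )


def _convolve_batch(
    samples: np.ndarray,
    rate: float,
    tr: float,
    run_offsets: list[float] | None,
    n_volumes: int | None,
    cfg: PipelineConfig,
) -> np.ndarray:
    """Convolve rows of a sample-grid regressor matrix with the gamma HRF,
    per run, and sample the TR grid.  Returns (n_rows, n_volumes)."""
    from scipy.signal import fftconvolve

    x = np.atleast_2d(samples)
    dt = 1.0 / rate
    hrf_t = np.arange(0.0, 32.0, dt)
    kernel = gamma_hrf(hrf_t, cfg.hrf_p, cfg.hrf_q) * dt

    run_offsets = run_offsets or [0.0]
    bounds = [int(round(o * rate)) for o in run_offsets] + [x.shape[1]]
    conv = np.zeros_like(x)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            conv[:, a:b] = fftconvolve(x[:, a:b], kernel[None, :], axes=1)[:, : b - a]

    n_vol = n_volumes if n_volumes is not None else int(np.floor(x.shape[1] * dt / tr))
    idx = np.minimum(np.round(np.arange(n_vol) * tr * rate).astype(int), x.shape[1] - 1)
    return conv[:, idx]


def convolve_hrf(
    reg: Regressor,
    tr: float,
    run_offsets: list[float] | None = None,
    n_volumes: int | None = None,
    cfg: PipelineConfig | None = None,
    samples: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve the sample-grid regressor with the gamma HRF and sample the
    TR grid; runs are convolved independently and concatenated."""
    cfg = cfg or PipelineConfig()
    x = reg.samples if samples is None else samples
    out = _convolve_batch(x, reg.rate, tr, run_offsets, n_volumes, cfg)[0]
    if samples is None:
        reg.convolved = out
    return out


def _shuffle_onsets(
    events: pd.DataFrame,
    hyp: Hypnogram,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw event onsets uniformly within artifact-free epochs of each
    event's own stage, keeping each event inside one usable segment."""
    onsets = np.empty(len(events))
    stage_arr = events["stage"].to_numpy(object)
    dur_arr = events["duration_s"].to_numpy(float)
    for stage in pd.unique(stage_arr):
        m = stage_arr == stage
        segs = np.array(hyp.segments([stage], artifact_free=True))
        if len(segs) == 0:
            raise ValueError(f"no usable segments for stage {stage}")
        starts, ends = segs[:, 0], segs[:, 1]
        room = np.maximum(ends[None, :] - starts[None, :] - dur_arr[m, None], 0.0)
        cum = np.cumsum(room, axis=1)
        total = cum[:, -1]
        if np.any(total <= 0):
            raise ValueError(f"no room to place events in stage {stage}")
        u = rng.uniform(0.0, total)
        seg = np.sum(cum < u[:, None], axis=1)
        prev = np.where(seg > 0, np.take_along_axis(cum, np.maximum(seg - 1, 0)[:, None], 1)[:, 0], 0.0)
        onsets[m] = starts[seg] + (u - prev)
    return onsets


def fit_glm(
    bold: RoiBoldSeries,
    regressors: list[Regressor],
    hyp: Hypnogram,
    cfg: PipelineConfig | None = None,
    n_shuffles: int | None = None,
    seed: int = 0,
) -> GlmResult:
    """Per-ROI OLS with an intercept; z-scores versus the timing-shuffle null.

    For each regressor of interest the null refits the full model with that
    regressor's event onsets redrawn (counts preserved, same-stage segments,
    never inside zeroed segments — asserted in the loop).
    """
    cfg = cfg or PipelineConfig()
    n_shuffles = n_shuffles if n_shuffles is not None else cfg.n_shuffles_glm
    rng = np.random.default_rng(seed)

    for reg in regressors:
        if reg.convolved is None:
            convolve_hrf(reg, bold.tr, bold.run_offsets, bold.n_volumes, cfg)

    usable = bold.censor_mask
    Y = bold.data[:, usable].T  # volumes x rois
    X = np.column_stack(
        [np.ones(bold.n_volumes)] + [reg.convolved for reg in regressors]
    )[usable]
    beta_all, *_ = np.linalg.lstsq(X, Y, rcond=None)
    beta = beta_all[1:].T  # rois x regressors

    rate = regressors[0].rate if regressors else cfg.regressor_rate
    null_mean = np.zeros_like(beta)
    null_sd = np.zeros_like(beta)
    chunk = 64
    for j, reg in enumerate(regressors):
        nulls = np.empty((n_shuffles, bold.n_rois))
        ev = reg.events
        for s0 in range(0, n_shuffles, chunk):
            s1 = min(s0 + chunk, n_shuffles)
            mats = np.empty((s1 - s0, len(reg.samples)))
            for si in range(s0, s1):
                shuffled = ev.copy()
                shuffled["onset_s"] = _shuffle_onsets(ev, hyp, rng)
                assert len(shuffled) == len(ev)
                idx0 = np.round(shuffled["onset_s"].to_numpy() * rate).astype(int)
                assert not reg.zeroed_mask[np.minimum(idx0, len(reg.zeroed_mask) - 1)].any(), (
                    "shuffled event placed in a zeroed segment"
                )
                mats[si - s0] = _boxcar(shuffled, rate, len(reg.samples), reg.zeroed_mask)
            convs = _convolve_batch(mats, rate, bold.tr, bold.run_offsets, bold.n_volumes, cfg)
            for si in range(s0, s1):
                Xs = X.copy()
                Xs[:, j + 1] = convs[si - s0][usable]
                b, *_ = np.linalg.lstsq(Xs, Y, rcond=None)
                nulls[si] = b[j + 1]
        null_mean[:, j] = nulls.mean(axis=0)
        null_sd[:, j] = nulls.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (beta - null_mean) / null_sd
    z[null_sd == 0] = np.nan
    if np.isnan(z).any():
        log.warning("undefined z for %d cells (null sd = 0)", int(np.isnan(z).sum()))
    return GlmResult(
        roi_labels=list(bold.roi_labels),
        regressor_names=[r.name for r in regressors],
        beta=beta,
        z=z,
        null_mean=null_mean,
        null_sd=null_sd,
        n_shuffles=n_shuffles,
    )


def group_z_test(
    z_by_subject: np.ndarray, q_threshold: float = 0.001
) -> pd.DataFrame:
    """Random-intercept one-sample test of subject z-scores against zero.

    ``z_by_subject`` is subjects x ROIs; rows with undefined z are dropped
    per ROI.  Benjamini-Hochberg FDR across ROIs; ``significant`` marks
    q < ``q_threshold``.
    """
    z = np.asarray(z_by_subject, float)
    n_roi = z.shape[1]
    t_vals = np.full(n_roi, np.nan)
    p_vals = np.full(n_roi, np.nan)
    for r in range(n_roi):
        col = z[:, r]
        col = col[np.isfinite(col)]
        if len(col) >= 2 and col.std(ddof=1) > 0:
            t_vals[r], p_vals[r] = sps.ttest_1samp(col, 0.0)
    ok = np.isfinite(p_vals)
    q_vals = np.full(n_roi, np.nan)
    if ok.any():
        q_vals[ok] = multipletests(p_vals[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        dict(t=t_vals, p=p_vals, q=q_vals, significant=q_vals < q_threshold)
    )
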