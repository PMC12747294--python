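"""Wave-locked thalamic BOLD feature extraction and k-means subtyping.

For every slow wave a +/-21 s window of each ROI's BOLD series is linearly
detrended, then sampled at the volumes nearest to onset + {0, 3, ..., 12} s;
concatenating the seven ROIs gives a 35-dimensional feature vector per wave
(n_rois x (floor(12/TR) + 1) in general).  Waves are clustered per subject
with k-means under correlation distance (implemented as Euclidean k-means
on per-vector standardised features), with the number of clusters selected
by the silhouette criterion; clusters are then matched across subjects by
mean pairwise centroid correlation, and the shared label C1 is assigned to
the group with the larger early (0-6 s) response.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .io import EventTable, PipelineConfig, RoiBoldSeries, get_logger
from .glm import Regressor, convolve_hrf

log = get_logger(__name__)

__all__ = [
    "WaveFeatureMatrix",
    "ClusterSolution",
    "remove_spindle_contribution",
    "extract_features",
    "cluster_waves",
    "match_clusters_across_subjects",
]


@dataclass
class WaveFeatureMatrix:
    """Per-wave wave-locked BOLD features (waves x n_rois * n_timepoints)."""

    wave_ids: np.ndarray  # indices into the source wave table
    features: np.ndarray
    roi_order: list[str]
    timepoints_s: np.ndarray
    dropped: dict[str, int]

    @property
    def n_waves(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1..k per retained wave
    centroids: np.ndarray  # k x n_features, mean of members' raw feature vectors
    criterion_by_k: dict[int, float]
    wave_ids: np.ndarray
    subject: str | int | None = None


def remove_spindle_contribution(
    bold: RoiBoldSeries,
    spindle_reg: Regressor | None,
    cfg: PipelineConfig | None = None,
) -> RoiBoldSeries:
    """Residualise each ROI on the HRF-convolved spindle regressor.

    Censored volumes are excluded from the least-squares fit and passed
    through unchanged; an all-zero regressor returns the input unchanged.
    """
    cfg = cfg or PipelineConfig()
    if spindle_reg is None or not np.any(spindle_reg.samples):
        log.info("spindle regressor empty; BOLD returned unchanged")
        return bold
    conv = (
        spindle_reg.convolved
        if spindle_reg.convolved is not None and len(spindle_reg.convolved) == bold.n_volumes
        else convolve_hrf(spindle_reg, bold.tr, bold.run_offsets, bold.n_volumes, cfg)
    )
    usable = bold.censor_mask
    X = np.column_stack([np.ones(bold.n_volumes), conv])
    beta, *_ = np.linalg.lstsq(X[usable], bold.data[:, usable].T, rcond=None)
    fitted = X @ beta  # volumes x rois
    residual = bold.data.copy()
    residual[:, usable] = (bold.data[:, usable].T - fitted[usable]).T
    return RoiBoldSeries(
        tr=bold.tr,
        roi_labels=list(bold.roi_labels),
        data=residual,
        run_offsets=list(bold.run_offsets),
        censor_mask=bold.censor_mask.copy(),
    )


def extract_features(
    bold: RoiBoldSeries,
    waves: EventTable | pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> WaveFeatureMatrix:
    """Wave-locked, detrended BOLD features sampled on the post-onset grid.

    A wave is dropped (with a per-reason count) when its +/-21 s window
    leaves its run or contains a censored volume.
    """
    cfg = cfg or PipelineConfig()
    df = waves.of_kind("slow_wave") if isinstance(waves, EventTable) else waves
    onsets = df["onset_s"].to_numpy(float)
    w0, w1 = cfg.cluster_window
    f0, f1 = cfg.cluster_feature_window
    offsets = np.arange(f0, f1 + bold.tr / 2, bold.tr)
    tv = bold.volume_times()
    bounds = bold.run_bounds()

    rows, ids = [], []
    dropped = {"window_out_of_run": 0, "censored_volume": 0}
    for wid, onset in enumerate(onsets):
        run = [i for i, (a, b) in enumerate(bounds) if a <= onset < b]
        if not run:
            dropped["window_out_of_run"] += 1
            continue
        a, b = bounds[run[0]]
        if onset + w0 < a or onset + w1 > b:
            dropped["window_out_of_run"] += 1
            continue
        in_win = (tv >= onset + w0) & (tv <= onset + w1)
        if not bold.censor_mask[in_win].all():
            dropped["censored_volume"] += 1
            continue
        t_win = tv[in_win]
        seg = bold.data[:, in_win]
        # least-squares linear detrend within the window, per ROI
        A = np.column_stack([np.ones(len(t_win)), t_win - t_win.mean()])
        coef, *_ = np.linalg.lstsq(A, seg.T, rcond=None)
        detr = seg - (A @ coef).T
        if cfg.feature_sampling == "linear":
            feats = np.vstack(
                [np.interp(onset + offsets, t_win, detr[r]) for r in range(bold.n_rois)]
            )
        else:  # nearest volume to each grid time
            idx = np.abs(t_win[None, :] - (onset + offsets)[:, None]).argmin(axis=1)
            feats = detr[:, idx]
        rows.append(feats.ravel())  # ROI-major concatenation, fixed label order
        ids.append(wid)

    features = np.array(rows) if rows else np.empty((0, bold.n_rois * len(offsets)))
    if any(dropped.values()):
        log.info("extract_features dropped waves: %s", dropped)
    return WaveFeatureMatrix(
        wave_ids=np.array(ids, dtype=int),
        features=features,
        roi_order=list(bold.roi_labels),
        timepoints_s=offsets,
        dropped=dropped,
    )


def _standardise_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-vector z-scoring; returns (standardised rows, valid-row mask)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[valid] = (x[valid] - mu[valid]) / sd[valid]
    return z, valid


def cluster_waves(
    fm: WaveFeatureMatrix,
    k_range: tuple[int, int] | None = None,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    subject: str | int | None = None,
) -> ClusterSolution:
    """k-means under correlation (or cosine) distance with criterion-based k.

    Correlation distance d(x, y) = 1 - r(x, y) is realised as Euclidean
    k-means on per-vector standardised features; zero-variance vectors are
    dropped.  k maximises the mean silhouette (or Calinski-Harabasz score)
    over the searched range, with seeded restarts.
    """
    cfg = cfg or PipelineConfig()
    k_lo, k_hi = k_range or cfg.k_range
    if fm.n_waves < 10:
        raise ValueError(f"need >= 10 waves to cluster, got {fm.n_waves}")

    if cfg.kmeans_distance == "cosine":
        norms = np.linalg.norm(fm.features, axis=1)
        valid = norms > 0
        z = np.zeros_like(fm.features)
        z[valid] = fm.features[valid] / norms[valid, None]
        metric = "cosine"
    else:
        z, valid = _standardise_rows(fm.features)
        metric = "correlation"
    if not valid.all():
        log.warning("dropped %d zero-variance feature vectors", int((~valid).sum()))
    zv = z[valid]
    raw = fm.features[valid]
    ids = fm.wave_ids[valid]

    crit: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for k in range(k_lo, min(k_hi, len(zv) - 1) + 1):
        km = KMeans(
            n_clusters=k,
            n_init=cfg.kmeans_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(zv)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            crit[k] = -np.inf
            continue
        if cfg.k_selection == "calinski_harabasz":
            crit[k] = float(calinski_harabasz_score(zv, labels))
        else:
            crit[k] = float(silhouette_score(zv, labels, metric=metric))
        fits[k] = labels
    best_k = max(crit, key=crit.get)
    labels = fits[best_k] + 1  # 1..k
    centroids = np.vstack([raw[labels == m].mean(axis=0) for m in range(1, best_k + 1)])
    return ClusterSolution(
        k=best_k,
        labels=labels,
        centroids=centroids,
        criterion_by_k=crit,
        wave_ids=ids,
        subject=subject,
    )


def _early_mean(centroid: np.ndarray, timepoints: np.ndarray, cutoff: float = 6.0) -> float:
    n_t = len(timepoints)
    per_roi = centroid.reshape(-1, n_t)
    return float(per_roi[:, timepoints <= cutoff].mean())


def match_clusters_across_subjects(
    solutions: list[ClusterSolution],
    timepoints_s: np.ndarray | None = None,
) -> list[dict[int, str]]:
    """Align cluster labels across subjects by centroid correlation.

    For each subject the permutation of its clusters maximising the mean
    Pearson correlation with a running reference (the mean of already
    matched centroids) is chosen exhaustively.  Shared label C1 goes to the
    matched group whose mean centroid has the larger mean value over the
    0-6 s features (the early-positive thalamic response); the rest are
    C2, C3, ... ordered by decreasing early response.
    """
    ks = {s.k for s in solutions}
    if len(ks) != 1:
        raise ValueError(f"solutions have mixed k = {sorted(ks)}; re-fit with a common k")
    k = ks.pop()

    reference = solutions[0].centroids.astype(float).copy()
    perms: list[tuple[int, ...]] = [tuple(range(k))]
    counts = np.ones(1)
    for sol in solutions[1:]:
        best, best_score = None, -np.inf
        for perm in permutations(range(k)):
            score = np.mean(
                [pearsonr(reference[m], sol.centroids[perm[m]])[0] for m in range(k)]
            )
            if score > best_score:
                best, best_score = perm, score
        perms.append(best)
        reference = (reference * len(counts) + sol.centroids[list(best)]) / (len(counts) + 1)
        counts = np.append(counts, 1)

    if timepoints_s is None:
        n_feat = reference.shape[1]
        n_t = 5 if n_feat % 5 == 0 else n_feat
        timepoints_s = np.arange(n_t) * 3.0
    early = [_early_mean(reference[m], np.asarray(timepoints_s)) for m in range(k)]
    order = np.argsort(early)[::-1]  # C1 = largest early response
    shared = {int(order[i]): f"C{i + 1}" for i in range(k)}

    mappings: list[dict[int, str]] = []
    for sol, perm in zip(solutions, perms):
        mapping = {int(perm[m]) + 1: shared[m] for m in range(k)}
        mappings.append(mapping)
    return mappings
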