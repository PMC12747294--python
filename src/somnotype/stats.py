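"""Event co-occurrence statistics, cluster-feature comparisons and the
topographic cluster-mass permutation test.

Associations: a slow wave is associated with a PWA drop when the drop starts
between 1 s before and 5 s after the wave's negative peak, and with a
spindle when the spindle occurs within +/-1.2 s of the peak.  Observed
association probabilities are z-scored against a null built by re-drawing
the other events' onsets uniformly within artifact-free epochs of their own
sleep stage (event counts preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import Hypnogram, get_logger

log = get_logger(__name__)

__all__ = [
    "AssociationResult",
    "TopoComparison",
    "associate",
    "shuffle_null_z",
    "compare_features",
    "fdr_adjust",
    "topo_cluster_test",
    "adjacency_from_positions",
]

STAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "all_nrem": ("N1", "N2", "N3"),
    "light": ("N1", "N2"),
    "deep": ("N3",),
}


@dataclass
class AssociationResult:
    """Per subject x cluster x stage-group association z-scores."""

    subject: str | int | None
    table: pd.DataFrame  # cluster, stage_group, n_waves, observed, null_mean, null_sd, z


@dataclass
class TopoComparison:
    t_values: np.ndarray  # per channel paired t
    clusters: list[list[int]]  # candidate channel clusters (connected sets)
    cluster_mass: np.ndarray
    cluster_p: np.ndarray
    null_max_mass: np.ndarray
    significant: list[list[int]]


def _wave_anchor(df: pd.DataFrame) -> np.ndarray:
    peak = df["peak_s"].to_numpy(float)
    onset = df["onset_s"].to_numpy(float)
    return np.where(np.isfinite(peak), peak, onset)


def _other_anchor(df: pd.DataFrame, anchor: str) -> np.ndarray:
    onset = df["onset_s"].to_numpy(float)
    if anchor == "midpoint":
        return onset + df["duration_s"].to_numpy(float) / 2.0
    return onset


def associate(
    waves: pd.DataFrame,
    others: pd.DataFrame,
    window: tuple[float, float],
    anchor: str = "onset",
) -> np.ndarray:
    """Per-wave boolean: any other-event anchor in [peak + w0, peak + w1]."""
    if len(others) == 0:
        return np.zeros(len(waves), dtype=bool)
    peaks = _wave_anchor(waves)
    times = np.sort(_other_anchor(others, anchor))
    lo = np.searchsorted(times, peaks + window[0], side="left")
    hi = np.searchsorted(times, peaks + window[1], side="right")
    return hi > lo


def _shuffled_onsets_by_stage(
    stages: np.ndarray,
    segments_by_stage: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw one onset per event uniformly within the artifact-free epochs
    of its own stage."""
    out = np.empty(len(stages))
    for stage in pd.unique(stages):
        segs = segments_by_stage[stage]
        lens = segs[:, 1] - segs[:, 0]
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        m = stages == stage
        u = rng.uniform(0.0, cum[-1], m.sum())
        idx = np.searchsorted(cum, u, side="right") - 1
        out[m] = segs[idx, 0] + (u - cum[idx])
    return out


def shuffle_null_z(
    waves: pd.DataFrame,
    others: pd.DataFrame,
    hyp: Hypnogram,
    window: tuple[float, float],
    n_shuffles: int = 1000,
    seed: int = 0,
    anchor: str = "onset",
    subject: str | int | None = None,
) -> AssociationResult:
    """Observed association probabilities and timing-shuffle z-scores.

    Cells are cluster x stage-group (all NREM / light N1-N2 / deep N3,
    grouped by the wave's stage).  Each shuffle redraws the other events'
    onsets within artifact-free epochs of their own stage, preserving
    counts; z = (observed - null mean) / null sd, flagged NaN when the null
    sd is zero.
    """
    rng = np.random.default_rng(seed)
    waves = waves.reset_index(drop=True)
    clusters = (
        waves["cluster"].fillna("unassigned").to_numpy()
        if "cluster" in waves
        else np.array(["unassigned"] * len(waves))
    )
    wave_stages = waves["stage"].to_numpy(object)

    cells = []
    for cl in sorted(pd.unique(clusters)):
        for gname, gstages in STAGE_GROUPS.items():
            m = (clusters == cl) & np.isin(wave_stages, gstages)
            if m.sum():
                cells.append((cl, gname, m))

    obs_assoc = associate(waves, others, window, anchor)
    observed = {key[:2]: obs_assoc[key[2]].mean() for key in cells}

    other_stages = others["stage"].to_numpy(object) if len(others) else np.array([])
    segments_by_stage = {
        s: np.array(hyp.segments([s], artifact_free=True)) for s in pd.unique(other_stages)
    }
    for s, segs in segments_by_stage.items():
        if len(segs) == 0:
            raise ValueError(f"no artifact-free epochs of stage {s} to shuffle into")

    peaks = _wave_anchor(waves)
    nulls = {key[:2]: np.empty(n_shuffles) for key in cells}
    if len(others):
        offsets = _other_anchor(others, anchor) - others["onset_s"].to_numpy(float)
        for i in range(n_shuffles):
            onsets = _shuffled_onsets_by_stage(other_stages, segments_by_stage, rng)
            assert len(onsets) == len(others)
            times = np.sort(onsets + offsets)
            lo = np.searchsorted(times, peaks + window[0], side="left")
            hi = np.searchsorted(times, peaks + window[1], side="right")
            assoc = hi > lo
            for cl, gname, m in cells:
                nulls[(cl, gname)][i] = assoc[m].mean()
    else:
        for key in nulls:
            nulls[key][:] = 0.0

    rows = []
    for cl, gname, m in cells:
        null = nulls[(cl, gname)]
        sd = null.std(ddof=1)
        z = (observed[(cl, gname)] - null.mean()) / sd if sd > 0 else np.nan
        if sd == 0:
            log.warning("undefined association z for (%s, %s): null sd = 0", cl, gname)
        rows.append(
            dict(
                cluster=cl,
                stage_group=gname,
                n_waves=int(m.sum()),
                observed=observed[(cl, gname)],
                null_mean=null.mean(),
                null_sd=sd,
                z=z,
            )
        )
    return AssociationResult(subject=subject, table=pd.DataFrame(rows))


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def compare_features(
    per_subject: pd.DataFrame,
    feature: str = "value",
    cluster_col: str = "cluster",
) -> dict:
    """Normality-gated paired comparison of a per-subject feature between the
    two clusters.

    ``per_subject`` needs columns subject, cluster and the feature (one row
    per subject x cluster, e.g. per-subject mean amplitude).  Shapiro-Wilk on
    the paired differences selects a paired t-test (normal) or a Wilcoxon
    signed-rank test.
    """
    wide = per_subject.pivot(index="subject", columns=cluster_col, values=feature)
    clusters = sorted(wide.columns)
    if len(clusters) != 2:
        raise ValueError(f"need exactly two clusters, got {clusters}")
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError(f"need >= 3 subjects, got {len(wide)}")
    diff = (wide[clusters[0]] - wide[clusters[1]]).to_numpy()

    if np.allclose(diff, 0):
        return dict(test="paired_t", statistic=0.0, p=1.0, n=len(diff), normal=True)
    if np.ptp(diff) == 0:  # constant nonzero difference: trivially directional
        return dict(test="paired_t", statistic=np.inf, p=0.0, n=len(diff), normal=True)
    sw_p = sps.shapiro(diff).pvalue
    if sw_p > 0.05:
        stat, p = sps.ttest_rel(wide[clusters[0]], wide[clusters[1]])
        return dict(test="paired_t", statistic=float(stat), p=float(p), n=len(diff), normal=True)
    stat, p = sps.wilcoxon(diff)
    return dict(test="wilcoxon", statistic=float(stat), p=float(p), n=len(diff), normal=False)


def compare_feature_family(results: dict[str, dict]) -> pd.DataFrame:
    """FDR adjustment across a family of feature comparisons."""
    names = list(results)
    p = np.array([results[n]["p"] for n in names])
    q = fdr_adjust(p)
    return pd.DataFrame(
        dict(
            feature=names,
            test=[results[n]["test"] for n in names],
            statistic=[results[n]["statistic"] for n in names],
            p=p,
            q=q,
        )
    )


def adjacency_from_positions(positions: np.ndarray, radius: float) -> list[set[int]]:
    """Channel neighbourhoods: channels within ``radius`` of each other."""
    pos = np.asarray(positions, float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    return [set(np.flatnonzero((d[i] <= radius) & (np.arange(len(pos)) != i))) for i in range(len(pos))]


def _connected_components(nodes: np.ndarray, adjacency: list[set[int]]) -> list[list[int]]:
    node_set = set(int(n) for n in nodes)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in sorted(node_set):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adjacency[u]:
                if v in node_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def topo_cluster_test(
    involvement_a: np.ndarray,
    involvement_b: np.ndarray,
    adjacency: list[set[int]] | None,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TopoComparison:
    """Paired cluster-mass permutation test over scalp channels.

    Per-channel paired t-values; channels with p < ``alpha`` form candidate
    clusters under the adjacency; cluster mass is the sum of |t|.  The null
    distribution of the maximal cluster mass comes from random within-subject
    sign flips of the condition difference; a cluster is significant iff its
    mass exceeds the null's 95th percentile.
    """
    a = np.asarray(involvement_a, float)
    b = np.asarray(involvement_b, float)
    n_sub, n_chan = a.shape
    if adjacency is None or not any(adjacency):
        log.warning("empty adjacency; every channel forms its own cluster")
        adjacency = [set() for _ in range(n_chan)]

    d = a - b
    rng = np.random.default_rng(seed)
    t_crit = sps.t.ppf(1 - alpha / 2, n_sub - 1)

    ss = (d**2).sum(axis=0)

    def t_stats(mean_d: np.ndarray) -> np.ndarray:
        # for sign-flipped data, sum of squares is flip-invariant
        var = (ss / n_sub - mean_d**2) * n_sub / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / np.sqrt(var / n_sub)
        return np.where(var > 0, t, 0.0)

    t_obs = t_stats(d.mean(axis=0))
    supra = np.flatnonzero(np.abs(t_obs) > t_crit)
    clusters = _connected_components(supra, adjacency) if len(supra) else []
    mass = np.array([np.abs(t_obs[c]).sum() for c in clusters])

    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    mean_perm = flips @ d / n_sub  # n_perm x n_chan
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_p = t_stats(mean_perm[i])
        sp = np.flatnonzero(np.abs(t_p) > t_crit)
        if len(sp) == 0:
            continue
        comps = _connected_components(sp, adjacency)
        null_max[i] = max(np.abs(t_p[c]).sum() for c in comps)

    thresh = np.percentile(null_max, 95)
    cluster_p = np.array([(null_max >= m).mean() for m in mass])
    significant = [c for c, m in zip(clusters, mass) if m > thresh]
    return TopoComparison(
        t_values=t_obs,
        clusters=clusters,
        cluster_mass=mass,
        cluster_p=cluster_p,
        null_max_mass=null_max,
        significant=significant,
    )
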