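"""Domain types, readers/writers, configuration and epoch/stage bookkeeping.

All event times are seconds from recording start, samples are 0-based, and
intervals are half-open ``[start, end)``.  Sleep stages use the AASM codes
``W, N1, N2, N3, REM``; "NREM" means ``{N1, N2, N3}``.  EEG voltages are
expressed in microvolts throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STAGES",
    "NREM_STAGES",
    "Hypnogram",
    "EegRecording",
    "RoiBoldSeries",
    "EventTable",
    "PipelineConfig",
    "read_eeg",
    "read_hypnogram",
    "stage_at",
    "write_edf",
    "get_logger",
]

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = frozenset({"N1", "N2", "N3"})

EPOCH_LENGTH_S = 30.0


def get_logger(name: str = "somnotype") -> logging.Logger:
    """Package logger writing per-stage counters to stderr.

    Handlers live on the package root logger only; module loggers propagate.
    """
    root = logging.getLogger("somnotype")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s: %(levelname)s: %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    if not name.startswith("somnotype"):
        name = f"somnotype.{name}"
    return logging.getLogger(name)


log = get_logger()


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

@dataclass
class Hypnogram:
    """30-s-epoch sleep-stage sequence with per-epoch artifact flags."""

    stages: list[str]
    artifact_flags: np.ndarray | None = None
    epoch_length: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage codes: {bad}; allowed: {STAGES}")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(self.stages), dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if len(self.artifact_flags) != len(self.stages):
                raise ValueError("artifact_flags length must equal number of epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length

    def epoch_of(self, t: float) -> int:
        if t < 0 or t >= self.duration_s:
            raise ValueError(
                f"time {t} s outside hypnogram range [0, {self.duration_s}) s"
            )
        return int(t // self.epoch_length)

    def stage_at(self, t: float) -> str:
        """Stage of the half-open epoch ``[30k, 30k+30)`` containing ``t``."""
        return self.stages[self.epoch_of(t)]

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def segments(
        self,
        stages: Sequence[str] | None = None,
        artifact_free: bool = True,
    ) -> list[tuple[float, float]]:
        """Merged half-open ``(start, end)`` intervals of the selected epochs."""
        wanted = set(stages) if stages is not None else set(STAGES)
        out: list[tuple[float, float]] = []
        for i, s in enumerate(self.stages):
            if s not in wanted:
                continue
            if artifact_free and self.artifact_flags[i]:
                continue
            start = i * self.epoch_length
            end = start + self.epoch_length
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
        return out

    def stage_minutes(self, stages: Sequence[str], artifact_free: bool = True) -> float:
        return sum(e - s for s, e in self.segments(stages, artifact_free)) / 60.0

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, a in zip(self.stages, self.artifact_flags):
                fh.write(f"{s},{int(a)}\n" if a else f"{s}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram: one stage code per line or CSV field.

    An optional second CSV field per line holds the 0/1 artifact flag.
    Unknown stage tokens raise a :class:`ValueError` naming the line.
    """
    stages: list[str] = []
    flags: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            for tok in line.split(","):
                tok = tok.strip()
                if not tok:
                    continue
                if tok in ("0", "1") and stages and len(flags) == len(stages) - 1:
                    flags.append(tok == "1")
                    continue
                if tok not in STAGES:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown stage token {tok!r}"
                    )
                if len(flags) < len(stages):
                    flags.append(False)
                stages.append(tok)
    if len(flags) < len(stages):
        flags.extend([False] * (len(stages) - len(flags)))
    if not stages:
        raise ValueError(f"{path}: empty hypnogram")
    return Hypnogram(stages=stages, artifact_flags=np.asarray(flags))


def stage_at(hyp: Hypnogram, t: float) -> str:
    """Stage code at time ``t`` (seconds); epochs are half-open ``[30k, 30k+30)``."""
    return hyp.stage_at(t)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class EegRecording:
    """Multi-channel scalp EEG; ``data`` is channels x samples in microvolts."""

    sample_rate: float
    channel_labels: list[str]
    data: np.ndarray
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for "
                f"{len(self.channel_labels)} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in recording") from exc

    def good_channel_data(self) -> tuple[list[str], np.ndarray]:
        keep = [i for i, c in enumerate(self.channel_labels) if c not in self.bad_channels]
        return [self.channel_labels[i] for i in keep], self.data[keep]


def read_eeg(path: str | Path, format: str | None = None) -> EegRecording:
    """Read an EDF or BrainVision recording into microvolts.

    ``format`` may be ``"edf"`` or ``"brainvision"``; when ``None`` it is
    inferred from the file extension (``.edf`` / ``.vhdr``).
    """
    import mne

    path = Path(path)
    if format is None:
        format = {"edf": "edf", "vhdr": "brainvision"}.get(path.suffix.lstrip(".").lower())
        if format is None:
            raise ValueError(f"cannot infer EEG format from extension of {path}")
    try:
        if format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown EEG format {format!r}")
    except (OSError, ValueError, KeyError, struct.error) as exc:
        raise ValueError(f"unreadable {format} file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne holds SI volts internally
    return EegRecording(
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        data=data_uv,
    )


def write_edf(
    path: str | Path,
    rec: EegRecording,
    patient_id: str = "X",
    recording_id: str = "somnotype",
) -> None:
    """Write a 16-bit EDF file (1-s data records).

    A deliberately small writer covering continuous multi-channel data in
    microvolts; the last record is zero-padded when the duration is not an
    integer number of seconds.
    """
    rate = rec.sample_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    ns = int(round(rate))
    n_rec = int(np.ceil(rec.n_samples / ns))
    n_ch = rec.n_channels

    data = np.zeros((n_ch, n_rec * ns))
    data[:, : rec.n_samples] = rec.data
    pmin = np.minimum(data.min(axis=1), -1.0)
    pmax = np.maximum(data.max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f(patient_id, 80),
            f(recording_id, 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(f(c, 16) for c in rec.channel_labels),
            b"".join(f("EEG", 80) for _ in range(n_ch)),
            b"".join(f("uV", 8) for _ in range(n_ch)),
            b"".join(f(f"{v:.6g}", 8) for v in pmin),
            b"".join(f(f"{v:.6g}", 8) for v in pmax),
            b"".join(f(str(dmin), 8) for _ in range(n_ch)),
            b"".join(f(str(dmax), 8) for _ in range(n_ch)),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f(str(ns), 8) for _ in range(n_ch)),
            b"".join(f("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * ns : (r + 1) * ns].tobytes())


# ---------------------------------------------------------------------------
# ROI BOLD
# ---------------------------------------------------------------------------

#: the seven thalamic functional-connectivity networks of the default configuration
DEFAULT_ROI_LABELS = ["SM", "FP", "VA", "V", "DA", "DM", "L"]


@dataclass
class RoiBoldSeries:
    """TR-sampled per-ROI percent-signal-change series over concatenated runs.

    Volume ``v`` is acquired at time ``v * tr`` on the concatenated session
    clock; ``run_offsets`` holds the start time of each run on that clock and
    ``censor_mask`` is True for usable volumes.
    """

    tr: float
    roi_labels: list[str]
    data: np.ndarray  # rois x volumes
    run_offsets: list[float] = field(default_factory=lambda: [0.0])
    censor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.roi_labels):
            raise ValueError("data row count must equal number of ROI labels")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_volumes, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if len(self.censor_mask) != self.n_volumes:
                raise ValueError("censor_mask length must equal volume count")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def run_bounds(self) -> list[tuple[float, float]]:
        starts = list(self.run_offsets)
        ends = starts[1:] + [self.duration_s]
        return list(zip(starts, ends))

    def run_of(self, t: float) -> int:
        idx = int(np.searchsorted(self.run_offsets, t, side="right")) - 1
        if idx < 0 or t >= self.duration_s:
            raise ValueError(f"time {t} s outside the concatenated session")
        return idx

    def to_tsv(self, path: str | Path) -> None:
        run_idx = np.searchsorted(self.run_offsets, self.volume_times(), side="right") - 1
        df = pd.DataFrame({"time_s": self.volume_times(), "run": run_idx})
        for i, roi in enumerate(self.roi_labels):
            df[roi] = self.data[i]
        df["censor"] = self.censor_mask.astype(int)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiBoldSeries":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        times = df["time_s"].to_numpy(float)
        if len(times) < 2:
            raise ValueError(f"{path}: need at least two volumes")
        tr = float(times[1] - times[0])
        rois = [c for c in df.columns if c not in ("time_s", "run", "censor")]
        run_offsets = [0.0]
        if "run" in df.columns:
            runs = df["run"].to_numpy(int)
            starts = np.flatnonzero(np.diff(runs) != 0) + 1
            run_offsets = [0.0] + [float(times[i]) for i in starts]
        censor = (
            df["censor"].to_numpy(int).astype(bool)
            if "censor" in df.columns
            else None
        )
        return cls(
            tr=tr,
            roi_labels=rois,
            data=df[rois].to_numpy(float).T,
            run_offsets=run_offsets,
            censor_mask=censor,
        )


# ---------------------------------------------------------------------------
# Event table
# ---------------------------------------------------------------------------

EVENT_KINDS = ("slow_wave", "spindle", "pwa_drop", "k_complex")
EVENT_COLUMNS = ["kind", "onset_s", "peak_s", "duration_s", "amplitude", "stage", "cluster", "extras"]
CLUSTER_LABELS = ("C1", "C2", "unassigned")


class EventTable:
    """Unified table of detected events (slow waves, spindles, PWA drops, ...).

    Thin wrapper around a :class:`pandas.DataFrame` with a fixed schema;
    ``extras`` holds a per-event dict (slopes, involvement, sync score,
    isolation flag, ...) serialised as JSON in the TSV representation.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        df = df.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("peak_s", "amplitude") else None
        if "extras" in df.columns:
            df["extras"] = df["extras"].apply(lambda x: x if isinstance(x, dict) else {})
        self.df = df[EVENT_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        d = self.df
        if len(d) == 0:
            return
        bad_kind = set(d["kind"]) - set(EVENT_KINDS)
        if bad_kind:
            raise ValueError(f"unknown event kinds: {sorted(bad_kind)}")
        if (d["onset_s"].to_numpy(float) < 0).any():
            raise ValueError("onset_s must be >= 0")
        if (d["duration_s"].to_numpy(float) <= 0).any():
            raise ValueError("duration_s must be > 0")
        sw = d[d["kind"] == "slow_wave"]
        if len(sw):
            onset = sw["onset_s"].to_numpy(float)
            peak = sw["peak_s"].to_numpy(float)
            dur = sw["duration_s"].to_numpy(float)
            if np.any(peak < onset - 1e-9) or np.any(peak > onset + dur + 1e-9):
                raise ValueError("slow-wave peak_s must lie within [onset_s, onset_s + duration_s]")
        clusters = set(str(c) for c in d["cluster"].dropna()) - {"None"}
        bad_cl = clusters - set(CLUSTER_LABELS)
        if bad_cl:
            raise ValueError(f"unknown cluster labels: {sorted(bad_cl)}")

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["extras"] = out["extras"].apply(lambda x: json.dumps(x, sort_keys=True))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"kind": str, "stage": str, "cluster": str},
            float_precision="round_trip",
        )
        if "extras" in df.columns:
            df["extras"] = df["extras"].apply(
                lambda x: json.loads(x) if isinstance(x, str) and x else {}
            )
        if "cluster" in df.columns:
            df["cluster"] = df["cluster"].where(df["cluster"].notna(), None)
        return cls(df)

    @classmethod
    def concat(cls, tables: Sequence["EventTable"]) -> "EventTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every numeric constant of the pipeline, overridable from a YAML file."""

    # slow-wave detection
    sw_band: tuple[float, float] = (0.3, 45.0)
    sw_halfwave_duration: tuple[float, float] = (0.25, 1.0)
    envelope_k_select: int = 4
    envelope_k_drop: int = 1
    involvement_window: float = 0.040  # s, centred on the negative peak
    involvement_threshold: float = -5.0  # uV, strict <
    isolation_window: tuple[float, float] = (-12.0, 5.0)  # s around wave onset
    involvement_mode: str = "window_mean"  # or "peak_sample"
    # spindle detection
    spindle_channel: str = "Cz"
    spindle_band: tuple[float, float] = (10.0, 16.0)
    spindle_power_smooth: float = 0.100  # s
    spindle_high_mad: float = 4.0
    spindle_low_mad: float = 2.0
    spindle_duration: tuple[float, float] = (0.3, 3.0)
    spindle_ratio_threshold: float = 3.0
    spindle_flank_bands: tuple[tuple[float, float], tuple[float, float]] = (
        (8.0, 10.0),
        (16.0, 18.0),
    )
    spindle_filter_kind: str = "iir"  # or "fir"
    # PWA-drop detection
    pwa_drop_threshold: float = 0.10
    pwa_baseline_beats: int = 5
    pwa_stable_beats: int = 2
    pwa_smooth_beats: int = 5
    pwa_max_hr: float = 250.0  # bpm
    pwa_stability_tol: float = 0.05
    pwa_variance_beats: int = 5
    pwa_frontend_band: tuple[float, float] = (0.5, 16.0)
    pwa_savgol_window_s: float = 0.1
    pwa_savgol_order: int = 3
    # wave-locked BOLD clustering
    cluster_window: tuple[float, float] = (-21.0, 21.0)
    cluster_feature_window: tuple[float, float] = (0.0, 12.0)
    kmeans_distance: str = "correlation"  # or "cosine"
    k_selection: str = "silhouette"  # or "calinski_harabasz"
    k_range: tuple[int, int] = (2, 6)
    kmeans_restarts: int = 20
    feature_sampling: str = "nearest"  # or "linear"
    # GLM
    hrf_p: float = 8.6
    hrf_q: float = 0.547
    regressor_rate: float = 100.0  # Hz grid for boxcar construction
    n_shuffles_glm: int = 1000
    fdr_q_map: float = 0.001
    # infraslow sigma phase
    sigma_band_infraslow: tuple[float, float] = (12.0, 15.0)
    infraslow_search: tuple[float, float] = (0.015, 0.025)
    infraslow_default: float = 0.02
    infraslow_halfwidth: float = 0.005
    infraslow_prominence_db: float = 1.0
    infraslow_rate: float = 1.0  # Hz, decimated sigma-power rate
    phase_descending: tuple[float, float] = (330.0, 140.0)
    phase_rising: tuple[float, float] = (140.0, 330.0)
    # associations
    assoc_pwa_window: tuple[float, float] = (-1.0, 5.0)  # s around wave peak
    assoc_spindle_window: tuple[float, float] = (-1.2, 1.2)
    assoc_spindle_anchor: str = "onset"  # or "midpoint"
    n_shuffles_assoc: int = 1000
    n_perm_topo: int = 10000
    topo_alpha: float = 0.05

    _TUPLE_FIELDS = {
        "sw_band",
        "sw_halfwave_duration",
        "isolation_window",
        "spindle_band",
        "spindle_duration",
        "cluster_window",
        "cluster_feature_window",
        "k_range",
        "sigma_band_infraslow",
        "infraslow_search",
        "phase_descending",
        "phase_rising",
        "assoc_pwa_window",
        "assoc_spindle_window",
        "pwa_frontend_band",
    }

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "PipelineConfig":
        """Load the configuration; keys absent from the file keep their defaults."""
        cfg = cls()
        if path is None:
            return cfg
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in overrides.items():
            if key not in valid:
                raise ValueError(f"{path}: unknown configuration key {key!r}")
            if key == "spindle_flank_bands":
                value = tuple(tuple(float(x) for x in band) for band in value)
            elif key in cls._TUPLE_FIELDS:
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def to_file(self, path: str | Path) -> None:
        data = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = [list(x) if isinstance(x, tuple) else x for x in v]
            data[f.name] = v
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
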