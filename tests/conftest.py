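"""Shared fixtures and small file-format helpers for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from somnotype.io import Hypnogram, PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def n2_hypnogram() -> Hypnogram:
    """Ten minutes of N2."""
    return Hypnogram(stages=["N2"] * 20)


def make_hypnogram(pattern: str, repeat: int = 1) -> Hypnogram:
    """Build a hypnogram from a comma-separated stage pattern."""
    stages = [s.strip() for s in pattern.split(",")] * repeat
    return Hypnogram(stages=stages)


def write_brainvision(
    directory: Path,
    data_uv: np.ndarray,
    rate: float,
    labels: list[str],
    unit: str = "µV",
    stem: str = "test",
) -> Path:
    """Write a minimal BrainVision triplet (vhdr/vmrk/eeg, IEEE float32).

    ``data_uv`` is channels x samples in the declared unit.
    """
    n_ch = len(labels)
    vhdr = directory / f"{stem}.vhdr"
    vmrk = directory / f"{stem}.vmrk"
    eeg = directory / f"{stem}.eeg"
    sampling_interval_us = 1e6 / rate
    chans = "\n".join(
        f"Ch{i + 1}={lab},,1,{unit}" for i, lab in enumerate(labels)
    )
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={stem}.eeg\n"
        f"MarkerFile={stem}.vmrk\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={n_ch}\n"
        f"SamplingInterval={sampling_interval_us:g}\n"
        "[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n"
        "[Channel Infos]\n"
        f"{chans}\n",
        encoding="utf-8",
    )
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={stem}.eeg\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,0\n",
        encoding="utf-8",
    )
    eeg.write_bytes(
        np.asarray(data_uv, dtype="<f4").T.ravel().tobytes()
    )
    return vhdr
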