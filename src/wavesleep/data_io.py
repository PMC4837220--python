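"""EDF and hypnogram I/O, stage-label mapping and in-bed segmentation.

Raw hypnograms use the legacy scoring alphabet ``{W, R, 1, 2, 3, 4, M, ?}``
(wake, REM, non-REM depths 1–4, movement, unscored).  :func:`map_stages`
converts them to the canonical five-stage scheme, merging stages 3 and 4
into N3 and dropping movement/unscored epochs while preserving the
original epoch indices.

The plain-text hypnogram format is one stage label per line preceded by a
``lights_out=<epoch>`` header.  EDF reading goes through :mod:`mne`;
writing uses a minimal 16-bit EDF writer so synthetic recordings can be
round-tripped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import EPOCH_S, STAGES

__all__ = [
    "Recording",
    "LabelledEpochSet",
    "InBedSegment",
    "RAW_STAGE_MAP",
    "read_edf_channel",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "hypnogram_from_annotations",
    "map_stages",
    "in_bed_segment",
]

#: Raw-label → canonical-label map; ``None`` marks labels to drop.
RAW_STAGE_MAP: dict[str, str | None] = {
    "W": "W",
    "R": "R",
    "1": "N1",
    "2": "N2",
    "3": "N3",
    "4": "N3",
    "M": None,
    "?": None,
    # canonical labels map to themselves so the mapping is idempotent
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
}


@dataclass
class Recording:
    """A night of single-channel EEG with its raw per-epoch stage labels."""

    subject_id: str
    recording_id: str
    samples: np.ndarray
    fs: float
    raw_stages: list[str]
    lights_out_epoch: int = 0
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        n_epochs = int(len(self.samples) // (self.fs * self.epoch_s))
        if len(self.raw_stages) != n_epochs:
            raise ValueError(
                f"raw_stages has {len(self.raw_stages)} labels but the signal "
                f"holds {n_epochs} complete {self.epoch_s}-s epochs"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.raw_stages)

    def epoch_samples(self, e: int) -> np.ndarray:
        """Samples of epoch ``e`` (0-based, half-open sample range)."""
        n = int(self.fs * self.epoch_s)
        return self.samples[e * n : (e + 1) * n]


@dataclass
class LabelledEpochSet:
    """Epoch indices retained after label mapping, with canonical stages."""

    epoch_indices: list[int]
    stages: list[str]

    def __post_init__(self) -> None:
        if len(self.epoch_indices) != len(self.stages):
            raise ValueError("indices and stages must have equal length")
        if any(b <= a for a, b in zip(self.epoch_indices, self.epoch_indices[1:])):
            raise ValueError("epoch_indices must be strictly increasing")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"non-canonical stages present: {sorted(bad)}")


@dataclass(frozen=True)
class InBedSegment:
    """Time-in-bed boundaries: lights-out start, sleep onset, end of sleep."""

    start: int
    onset: int
    end: int

    @property
    def time_in_bed(self) -> int:
        """Number of epochs from lights out through the last sleep epoch."""
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# EDF


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel: str = "Fpz-Cz",
    physical_unit: str = "uV",
) -> None:
    """Write a single-channel EDF file (16-bit, 1-s data records).

    The physical range is the symmetric integer range just covering the
    signal, so the quantization step is ``2*pmax/65535``.  ``fs`` must be
    an integer number of samples per second; trailing samples that do not
    fill a whole 1-s record are dropped.
    """
    samples = np.asarray(samples, dtype=float)
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = len(samples) // spr
    if n_records == 0:
        raise ValueError("signal shorter than one 1-s data record")
    data = samples[: n_records * spr]

    pmax = float(np.max(np.abs(data))) if np.any(data) else 1.0
    pmax = float(max(math.ceil(pmax), 1))
    dig_min, dig_max = -32768, 32767
    # inverse of the reader's affine map so quantization error <= step/2
    scale = (2 * pmax) / (dig_max - dig_min)
    digital = np.clip(
        np.round((data + pmax) / scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def f(value, width: int) -> bytes:
        s = str(value)
        if len(s) > width:
            raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),  # version
            f("X X X X", 80),  # local patient identification
            f("Startdate X X X X", 80),  # local recording identification
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(256 + 256, 8),  # header bytes: fixed + one signal header
            f("", 44),
            f(n_records, 8),
            f(1, 8),  # record duration (s)
            f(1, 4),  # number of signals
            # per-signal header fields
            f(channel, 16),
            f("", 80),  # transducer
            f(physical_unit, 8),
            f(-pmax, 8),
            f(pmax, 8),
            f(dig_min, 8),
            f(dig_max, 8),
            f("", 80),  # prefiltering
            f(spr, 8),
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf_channel(path, channel_name: str) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF file.

    Returns ``(samples, fs)`` with samples in microvolts.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the channel is absent; the message lists available channels.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel_name not in raw.ch_names:
        raise ValueError(
            f"channel {channel_name!r} not found in {path.name}; "
            f"available channels: {raw.ch_names}"
        )
    raw = mne.io.read_raw_edf(
        path, include=[channel_name], preload=True, verbose="error"
    )
    data = raw.get_data(picks=[channel_name], units="uV")[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Hypnograms


def write_hypnogram(path, stages: list[str], lights_out: int = 0) -> None:
    """Write a plain-text hypnogram: header line then one label per line."""
    with open(path, "w") as fh:
        fh.write(f"lights_out={lights_out}\n")
        for s in stages:
            fh.write(f"{s}\n")


def read_hypnogram(path) -> tuple[list[str], int]:
    """Read a plain-text hypnogram; returns ``(labels, lights_out_epoch)``.

    A missing ``lights_out=`` header defaults to epoch 0.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    lights_out = 0
    if lines and lines[0].startswith("lights_out="):
        lights_out = int(lines[0].split("=", 1)[1])
        lines = lines[1:]
    return lines, lights_out


def hypnogram_from_annotations(
    records: list[tuple[float, float, str]], epoch_s: float = EPOCH_S
) -> list[str]:
    """Expand EDF+-style ``(onset_s, duration_s, label)`` records to epochs.

    Records must tile the recording contiguously from 0 with durations
    that are multiples of ``epoch_s``; a final partial epoch is dropped.
    """
    labels: list[str] = []
    expected_onset = 0.0
    for onset, duration, label in records:
        if abs(onset - expected_onset) > 1e-6:
            raise ValueError(
                f"annotation at {onset} s does not continue from {expected_onset} s"
            )
        n_full = int(duration // epoch_s)
        labels.extend([label] * n_full)
        expected_onset = onset + n_full * epoch_s
        if duration - n_full * epoch_s > 1e-6:
            break  # trailing partial epoch: drop and stop
    return labels


# ---------------------------------------------------------------------------
# Stage mapping and segmentation


def map_stages(raw_stages: list[str]) -> LabelledEpochSet:
    """Map raw labels to the canonical scheme, dropping M/? epochs.

    Stages 3 and 4 merge into N3.  Dropped epochs keep their positions
    out of the index list, so indices refer to the original hypnogram.
    """
    indices: list[int] = []
    stages: list[str] = []
    for i, raw in enumerate(raw_stages):
        if raw not in RAW_STAGE_MAP:
            raise ValueError(f"unknown stage label {raw!r} at epoch {i}")
        mapped = RAW_STAGE_MAP[raw]
        if mapped is None:
            continue
        indices.append(i)
        stages.append(mapped)
    return LabelledEpochSet(epoch_indices=indices, stages=stages)


def in_bed_segment(stages: list[str], lights_out_epoch: int = 0) -> InBedSegment:
    """Locate time in bed: lights-out through the last sleep epoch.

    Sleep onset is the first non-W epoch at or after lights out; end of
    sleep is the last non-W epoch.  Raises ``ValueError`` when no sleep
    occurs after lights out.
    """
    if not stages:
        raise ValueError("empty hypnogram")
    if not 0 <= lights_out_epoch < len(stages):
        raise ValueError("lights_out_epoch outside the hypnogram")
    non_w = [
        i for i in range(lights_out_epoch, len(stages)) if stages[i] != "W"
    ]
    if not non_w:
        raise ValueError("no sleep: no non-W epoch after lights out")
    return InBedSegment(start=lights_out_epoch, onset=non_w[0], end=non_w[-1])
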