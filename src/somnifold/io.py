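"""Reading and writing polysomnography recordings and hypnograms.

EDF signal files are read through :mod:`mne`; a minimal 16-bit EDF writer is
provided for producing recordings (e.g. simulated nights).  Hypnograms use a
plain two-column CSV sidecar ``onset_s,stage`` at 30-s resolution; staging
may follow AASM (W/N1/N2/N3/REM) or R&K (S0-S4 + REM), the latter being
mapped onto AASM on read.

Conventions: epoch indices are 0-based; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AASM_STAGES = ("W", "N1", "N2", "N3", "REM")
#: R&K -> AASM stage mapping (S3 and S4 both collapse onto N3).
RK_TO_AASM = {"S0": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3",
              "REM": "REM", "R": "REM"}
EPOCH_LEN_S = 30.0

__all__ = [
    "EEGRecording", "Hypnogram", "read_recording", "write_edf",
    "read_hypnogram", "write_hypnogram", "map_stages", "load_config",
    "AASM_STAGES", "RK_TO_AASM", "EPOCH_LEN_S",
]


@dataclass
class EEGRecording:
    """Multichannel EEG (µV) at a common sampling rate, optional ECG."""

    channels: list[str]
    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    ecg: np.ndarray | None = None  # (n_samples,)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels do not match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_samples < EPOCH_LEN_S * self.fs:
            raise ValueError("recording shorter than one 30-s epoch")
        if self.ecg is not None and len(self.ecg) != self.n_samples:
            raise ValueError("ECG length does not match EEG length")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Hypnogram:
    """30-s-epoch sleep stage labels (AASM vocabulary)."""

    stages: list[str]
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self):
        bad = sorted(set(self.stages) - set(AASM_STAGES))
        if bad:
            raise ValueError(f"unknown stage token(s): {bad}")

    def stage_at(self, t_s: float) -> str:
        idx = int(t_s // self.epoch_len)
        if not 0 <= idx < len(self.stages):
            raise IndexError(f"time {t_s} s outside the hypnogram")
        return self.stages[idx]

    def sleep_scores(self) -> np.ndarray:
        """Numeric sleep depth per epoch: W=0, N1=1, N2=2, N3=3, REM=2."""
        score = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 2}
        return np.array([score[s] for s in self.stages], dtype=float)


def map_stages(stages, scheme: str = "AASM") -> list[str]:
    """Map a stage-label sequence to the AASM vocabulary."""
    if scheme == "AASM":
        bad = sorted(set(stages) - set(AASM_STAGES))
        if bad:
            raise ValueError(f"unknown AASM stage token(s): {bad}")
        return list(stages)
    if scheme == "RK":
        out = []
        for s in stages:
            if s not in RK_TO_AASM:
                raise ValueError(f"unknown R&K stage token: {s!r}")
            out.append(RK_TO_AASM[s])
        return out
    raise ValueError(f"unknown staging scheme: {scheme!r}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_recording(path, channel_spec=None, ecg_channel: str | None = None
                   ) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording`.

    ``channel_spec`` selects EEG channels by label (all non-ECG channels if
    omitted); labels are preserved verbatim.  ``ecg_channel`` names an
    optional ECG channel loaded into ``.ecg``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channel_spec is None:
        channel_spec = [ch for ch in available if ch != ecg_channel]
    for label in list(channel_spec) + ([ecg_channel] if ecg_channel else []):
        if label not in available:
            raise KeyError(
                f"channel {label!r} not found in {path}; available: {available}")
    data_v = raw.get_data(picks=list(channel_spec))
    ecg = None
    if ecg_channel is not None:
        ecg = raw.get_data(picks=[ecg_channel])[0] * 1e6
    return EEGRecording(channels=list(channel_spec), data=data_v * 1e6,
                        fs=float(raw.info["sfreq"]), ecg=ecg)


def write_edf(path, recording: EEGRecording, ecg_label: str = "ECG") -> None:
    """Write an :class:`EEGRecording` as a 16-bit EDF file.

    Uses 1-s data records (so ``fs`` must be an integer) and per-channel
    physical scaling; amplitudes round-trip to 16-bit quantisation of the
    channel range.  The ECG channel, if present, is appended last.
    """
    fs = int(round(recording.fs))
    if abs(fs - recording.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    sigs = [recording.data[i] for i in range(len(recording.channels))]
    labels = list(recording.channels)
    if recording.ecg is not None:
        sigs.append(recording.ecg)
        labels.append(ecg_label)
    n_records = min(len(s) for s in sigs) // fs
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    ns = len(sigs)

    def pad(text, width):
        b = str(text).encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 * (1 + ns), 8), pad("", 44), pad(n_records, 8),
        pad(1, 8), pad(ns, 4),
    ])
    phys_min, phys_max, scaled = [], [], []
    for s in sigs:
        s = np.asarray(s, dtype=float)[: n_records * fs]
        lo, hi = float(np.min(s)), float(np.max(s))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((s - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    def field_block(values, width):
        return b"".join(pad(v, width) for v in values)

    header += field_block(labels, 16)
    header += field_block([""] * ns, 80)
    header += field_block(["uV"] * ns, 8)
    header += field_block([f"{v:.3f}"[:8] for v in phys_min], 8)
    header += field_block([f"{v:.3f}"[:8] for v in phys_max], 8)
    header += field_block([-32768] * ns, 8)
    header += field_block([32767] * ns, 8)
    header += field_block([""] * ns, 80)
    header += field_block([fs] * ns, 8)
    header += field_block([""] * ns, 32)

    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            for sig in scaled:
                f.write(sig[rec * fs:(rec + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Hypnogram sidecar CSV
# ---------------------------------------------------------------------------

def read_hypnogram(path, scheme: str = "AASM") -> Hypnogram:
    """Read a two-column ``onset_s,stage`` CSV into a :class:`Hypnogram`."""
    df = pd.read_csv(path)
    required = {"onset_s", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram CSV needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    df = df.sort_values("onset_s")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if len(onsets) > 1 and not np.allclose(np.diff(onsets), EPOCH_LEN_S):
        raise ValueError("hypnogram epochs must be contiguous 30-s records")
    return Hypnogram(stages=map_stages(df["stage"].astype(str).tolist(), scheme))


def write_hypnogram(path, hypnogram: Hypnogram) -> None:
    onsets = np.arange(len(hypnogram.stages)) * hypnogram.epoch_len
    pd.DataFrame({"onset_s": onsets, "stage": hypnogram.stages}).to_csv(
        path, index=False)


def load_config(path) -> dict:
    """Load a YAML/TOML analysis configuration (bands, epoching, fit
    hyperparameters) shared by the CLI subcommands."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        with open(path) as f:
            return yaml.safe_load(f) or {}
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as f:
            return tomllib.load(f)
    raise ValueError(f"unsupported config format: {path.suffix}")
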