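"""EEG preprocessing: cardiac-artifact removal, bedtime trimming, epoching
and artifact-epoch rejection.

Cardiac interference is removed by template subtraction: R-peaks are found
in the ECG channel with the Pan-Tompkins detector (5-15 Hz band-pass,
differentiate, square, 150-ms moving-window integration, adaptive
threshold), the average R-peak-aligned 2-s EEG segment (the characteristic
cardiac signature, window centred on the R-peak) is computed per channel,
and that signature is subtracted at every beat.

Feature epochs are 6 s long with a 3-s (50%) hop.  Artifact flags are
unioned across channels: an epoch flagged in any channel is flagged in all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording, Hypnogram, EPOCH_LEN_S

__all__ = [
    "EpochGrid", "ArtifactMask", "detect_r_peaks", "remove_cardiac",
    "trim_noisy_start", "epoch_signal", "reject_artifact_epochs",
]


@dataclass
class EpochGrid:
    """6-s feature epochs with a 3-s hop over a recording."""

    fs: float
    n_samples: int
    epoch_len: float = 6.0
    hop: float = 3.0
    t0: float = 0.0  # recording-time of the first epoch start (s)

    def __post_init__(self):
        if abs(self.hop - self.epoch_len / 2) > 1e-9:
            raise ValueError("hop must be half the epoch length")
        self.n_epochs = int(
            (self.n_samples - self.epoch_len * self.fs) // (self.hop * self.fs)
        ) + 1 if self.n_samples >= self.epoch_len * self.fs else 0

    @property
    def start_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_epochs) * self.hop

    @property
    def center_times(self) -> np.ndarray:
        return self.start_times + self.epoch_len / 2


@dataclass
class ArtifactMask:
    """Per-epoch boolean flags (True = artifact), shared across channels."""

    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)


# ---------------------------------------------------------------------------
# Pan-Tompkins R-peak detection + template subtraction
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak sample indices via the Pan-Tompkins method.

    5-15 Hz band-pass, derivative, squaring, 150-ms moving-window
    integration, then peak picking on the integrated signal with an
    adaptive threshold and a 200-ms refractory period; each detection is
    snapped to the local band-passed maximum.
    """
    ecg = np.asarray(ecg, dtype=float)
    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(0.150 * fs), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(0.2 * fs)
    peaks, _ = signal.find_peaks(integ, distance=refractory)
    if len(peaks) == 0:
        return np.array([], dtype=int)
    # adaptive threshold: running estimate of signal vs noise peak levels
    spki, npki = np.max(integ[peaks[: max(len(peaks) // 10, 1)]]) * 0.5, 0.0
    keep = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if integ[p] >= thr:
            keep.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
    # snap to the nearest band-passed local maximum (R wave)
    half = int(0.1 * fs)
    snapped = []
    for p in keep:
        lo, hi = max(p - half, 0), min(p + half, len(bp))
        snapped.append(lo + int(np.argmax(bp[lo:hi])))
    return np.unique(snapped)


def remove_cardiac(rec: EEGRecording, window_s: float = 2.0) -> EEGRecording:
    """Subtract the R-peak-locked cardiac signature from every EEG channel.

    The signature is the average of all ``window_s`` EEG segments centred
    on detected R-peaks.  With fewer than 3 detected beats the recording is
    passed through unchanged with a warning.  Output length is unchanged.
    """
    if rec.ecg is None:
        raise ValueError("recording has no ECG channel")
    if rec.duration < 10:
        raise ValueError("recording too short for cardiac removal (< 10 s)")
    peaks = detect_r_peaks(rec.ecg, rec.fs)
    if len(peaks) < 3:
        warnings.warn("fewer than 3 R-peaks detected; skipping cardiac removal")
        return rec
    half = int(window_s * rec.fs / 2)
    valid = peaks[(peaks >= half) & (peaks < rec.n_samples - half)]
    # subtraction territory of each beat: clipped at midpoints to neighbours
    # so overlapping 2-s windows are not subtracted twice
    mids = (valid[:-1] + valid[1:]) // 2
    starts = np.r_[valid[0] - half, mids]
    stops = np.r_[mids, valid[-1] + half]
    cleaned = rec.data.copy()
    for ch in range(cleaned.shape[0]):
        segs = np.stack([cleaned[ch, p - half:p + half] for p in valid])
        template = segs.mean(axis=0)
        for p, lo, hi in zip(valid, starts, stops):
            lo = max(lo, p - half)
            hi = min(hi, p + half)
            cleaned[ch, lo:hi] -= template[lo - (p - half):hi - (p - half)]
    return EEGRecording(channels=list(rec.channels), data=cleaned,
                        fs=rec.fs, ecg=rec.ecg)


# ---------------------------------------------------------------------------
# Bedtime trimming and artifact rejection
# ---------------------------------------------------------------------------

def _rms_flags(rms: np.ndarray, factor: float, n_passes: int) -> np.ndarray:
    """Flag entries with RMS > factor * median, recomputing the median over
    unflagged entries on each repeat."""
    flags = np.zeros(len(rms), dtype=bool)
    for _ in range(n_passes):
        med = np.median(rms[~flags]) if (~flags).any() else np.nan
        flags |= rms > factor * med
    return flags


def trim_noisy_start(rec: EEGRecording, hypnogram: Hypnogram | None = None,
                     ) -> int:
    """Index of the first artifact-free 30-s epoch — the new bedtime.

    Per channel, 30-s-epoch RMS values above twice the median are flagged;
    the procedure is repeated twice with the median recomputed over
    unflagged epochs; flags are unioned across channels.
    """
    n_ep = int(rec.n_samples // (EPOCH_LEN_S * rec.fs))
    if n_ep < 2:
        raise ValueError("recording spans fewer than two 30-s epochs")
    ns = int(EPOCH_LEN_S * rec.fs)
    flags = np.zeros(n_ep, dtype=bool)
    for ch in range(rec.data.shape[0]):
        segs = rec.data[ch, : n_ep * ns].reshape(n_ep, ns)
        rms = np.sqrt(np.mean(segs**2, axis=1))
        flags |= _rms_flags(rms, factor=2.0, n_passes=2)
    clean = np.flatnonzero(~flags)
    if len(clean) == 0:
        raise ValueError("every 30-s epoch is flagged artefactual")
    return int(clean[0])


def epoch_signal(rec: EEGRecording, grid: EpochGrid | None = None
                 ) -> tuple[np.ndarray, EpochGrid]:
    """Segment every channel into overlapping 6-s epochs.

    Returns ``(epochs, grid)`` with ``epochs`` shaped
    ``(n_channels, n_epochs, epoch_len * fs)``.
    """
    if grid is None:
        grid = EpochGrid(fs=rec.fs, n_samples=rec.n_samples)
    if grid.n_epochs < 1:
        raise ValueError("recording shorter than one 6-s epoch")
    nlen = int(grid.epoch_len * rec.fs)
    nhop = int(grid.hop * rec.fs)
    off = int((grid.t0 - 0.0) * rec.fs)
    idx = off + np.arange(grid.n_epochs)[:, None] * nhop + np.arange(nlen)
    return rec.data[:, idx], grid


def reject_artifact_epochs(epochs: np.ndarray, factor: float = 2.5
                           ) -> ArtifactMask:
    """Flag 6-s epochs with RMS above ``factor`` times the channel median.

    ``epochs``: (n_channels, n_epochs, n_samples).  Flags are unioned
    across channels; downstream feature values at flagged epochs are NaN.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    if epochs.shape[1] < 1:
        raise ValueError("need at least one epoch")
    rms = np.sqrt(np.mean(epochs**2, axis=2))  # (n_ch, n_ep)
    med = np.median(rms, axis=1, keepdims=True)
    return ArtifactMask(np.any(rms > factor * med, axis=0))
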