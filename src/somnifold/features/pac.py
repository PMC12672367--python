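"""Phase-amplitude coupling (PAC) within a single EEG channel.

The epoch is whitened (first difference), filtered into the lower (phase)
and higher (amplitude) bands with a zero-phase even-order FIR filter, and
the analytic signal supplies the lower-band phase and higher-band
amplitude envelope.  The modulation signal ``z(t) = A(t) exp(i phi(t))``
is summed over complete phase cycles (one cycle spans -pi..pi) and
normalised by the per-cycle mean amplitudes, yielding a coupling value in
[0, 1] (1 = amplitude fully locked to phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .spectral import whiten

__all__ = ["PACComputation", "pac", "pac_all_pairs", "ORDERED_PAIRS"]

#: the six ordered (phase band, amplitude band) pairs, low phase -> high amp
ORDERED_PAIRS = (("delta", "theta"), ("delta", "alpha"), ("delta", "beta"),
                 ("theta", "alpha"), ("theta", "beta"), ("alpha", "beta"))


@dataclass
class PACComputation:
    value: float
    phase: np.ndarray
    amplitude: np.ndarray
    n_cycles: int


def _fir_bandpass(x: np.ndarray, fs: float, band, cycles: int = 3
                  ) -> np.ndarray:
    """Zero-phase even-order FIR band-pass; order = ``cycles`` cycles of the
    band's low edge, forced even."""
    lo, hi = band
    order = int(round(cycles * fs / lo))
    order += order % 2  # even order -> odd tap count, linear phase type I
    taps = signal.firwin(order + 1, [lo, hi], pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x, padlen=min(3 * order, len(x) - 1))


def pac(epoch: np.ndarray, phase_band, amp_band, fs: float,
        pre_whiten: bool = True) -> PACComputation:
    """Coupling of the higher band's amplitude to the lower band's phase.

    ``phase_band`` must lie entirely below ``amp_band``.  Returns NaN when
    the epoch is shorter than one phase-band cycle.
    """
    if phase_band[1] > amp_band[0]:
        raise ValueError("phase band must lie below the amplitude band")
    x = np.asarray(epoch, dtype=float)
    if len(x) < fs / phase_band[0]:
        return PACComputation(np.nan, np.array([]), np.array([]), 0)
    if pre_whiten:
        x = whiten(x)
    low = _fir_bandpass(x, fs, phase_band)
    high = _fir_bandpass(x, fs, amp_band)
    phi = np.angle(signal.hilbert(low))
    amp = np.abs(signal.hilbert(high))

    # cycle boundaries: wraps from +pi to -pi
    wraps = np.flatnonzero(np.diff(phi) < -np.pi)
    if len(wraps) < 2:
        return PACComputation(np.nan, phi, amp, 0)
    z_sum = 0.0 + 0.0j
    norm = 0.0
    n_cycles = 0
    for a, b in zip(wraps[:-1] + 1, wraps[1:] + 1):
        seg_amp = amp[a:b]
        z_sum += np.sum(seg_amp * np.exp(1j * phi[a:b]))
        norm += np.mean(seg_amp) * (b - a)
        n_cycles += 1
    value = float(np.abs(z_sum) / norm) if norm > 0 else np.nan
    return PACComputation(value, phi, amp, n_cycles)


def pac_all_pairs(epoch: np.ndarray, fs: float, bands: dict) -> dict:
    """PAC for the six ordered band pairs (lower phase -> higher amplitude)."""
    out = {}
    for pb, ab in ORDERED_PAIRS:
        out[f"pac_{pb}_{ab}"] = pac(epoch, bands[pb], bands[ab], fs).value
    return out
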