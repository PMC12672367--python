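"""Spectral EEG features: multitaper band powers, ratios, peaks, temporal
coherence and the aperiodic (1/f) slope.

Band powers follow the whitened-spectrum recipe: the epoch is band-pass
filtered to 0.1-32 Hz, first-differenced to flatten the 1/f background, a
multitaper PSD (4 DPSS tapers) is computed and normalised to unit total
power, and band powers are means of the normalised PSD over the band's
bins, log-transformed.  The PSD is evaluated on a 1-Hz bin grid
(bin width fs / nfft with nfft = fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

__all__ = [
    "SpectralConfig", "bandpass_broadband", "whiten", "compute_psd",
    "spectral_features", "spectral_slope", "temporal_coherence",
]


@dataclass
class SpectralConfig:
    bands: dict = field(default_factory=lambda: {
        "delta": (1.0, 4.0), "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0), "beta": (12.0, 30.0)})
    sigma: tuple = (12.0, 16.0)
    broadband: tuple = (0.1, 32.0)
    n_tapers: int = 4
    #: band-power ratios (numerator, denominator); log-transformed
    ratios: tuple = (("delta", "alpha"), ("theta", "beta"),
                     ("theta", "alpha"), ("delta", "theta"),
                     ("alpha", "beta"))

    def __post_init__(self):
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name} has nonincreasing edges")
            if not (self.broadband[0] <= lo and hi <= self.broadband[1]):
                raise ValueError(f"band {name} outside the broadband range")


def bandpass_broadband(x: np.ndarray, fs: float,
                       band=(0.1, 32.0)) -> np.ndarray:
    """Zero-phase 0.1-32 Hz band-pass (4th-order Butterworth)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def whiten(x: np.ndarray) -> np.ndarray:
    """First-difference filter y[n] = x[n] - x[n-1] (removes ~1/f trend)."""
    return np.diff(x, axis=-1, prepend=x[..., :1])


def _multitaper_psd(x: np.ndarray, fs: float, n_tapers: int):
    """Average-periodogram multitaper PSD on a 1-Hz bin grid.

    ``x``: (..., n) epochs.  DPSS tapers with NW = (K+1)/2; per-taper
    periodograms at native resolution are averaged and then aggregated into
    1-Hz bins centred on integer frequencies (0 .. fs/2).
    """
    n = x.shape[-1]
    nw = (n_tapers + 1) / 2.0
    tapers = dpss(n, nw, Kmax=n_tapers)  # (K, n)
    tapered = x[..., None, :] * tapers  # (..., K, n)
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (spec.real**2 + spec.imag**2).mean(axis=-2) / (fs * 0.5 * n) * 1.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # aggregate into 1-Hz bins [k-0.5, k+0.5)
    f_bins = np.arange(0, int(fs // 2) + 1)
    idx = np.clip(np.round(freqs).astype(int), 0, f_bins[-1])
    out = np.zeros(x.shape[:-1] + (len(f_bins),))
    counts = np.bincount(idx, minlength=len(f_bins))
    np.add.at(out, (..., idx), psd)
    out /= np.maximum(counts, 1)
    return f_bins.astype(float), out


def compute_psd(epoch: np.ndarray, fs: float,
                cfg: SpectralConfig | None = None):
    """Whitened, normalised multitaper PSD of one (or many) 6-s epochs.

    Returns ``(freqs, norm_psd, total_power)`` where ``norm_psd`` sums to 1
    over bins and ``total_power`` is the pre-normalisation total of the
    whitened spectrum.  Raises on an all-zero epoch (degenerate spectrum).
    """
    cfg = cfg or SpectralConfig()
    epoch = np.asarray(epoch, dtype=float)
    if not np.any(np.ptp(epoch, axis=-1)):
        raise ValueError("all-zero epoch: degenerate spectrum")
    y = whiten(bandpass_broadband(epoch, fs, cfg.broadband))
    freqs, psd = _multitaper_psd(y, fs, cfg.n_tapers)
    total = psd.sum(axis=-1)
    norm = psd / total[..., None]
    return freqs, norm, total


def spectral_features(freqs: np.ndarray, norm_psd: np.ndarray,
                      total_power: np.ndarray,
                      cfg: SpectralConfig | None = None) -> dict:
    """Band powers (log), ratios (log), peak band frequencies, log total
    power, spectrum centroid and sigma power from a normalised PSD.

    Vectorised over leading epoch axes of ``norm_psd``.
    """
    cfg = cfg or SpectralConfig()
    out = {}
    logbp = {}
    for name, (lo, hi) in cfg.bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} contains no frequency bins")
        bp = norm_psd[..., sel].mean(axis=-1)
        logbp[name] = np.log(bp)
        out[f"{name}_power"] = logbp[name]
        band_f = freqs[sel]
        out[f"{name}_peak_freq"] = band_f[np.argmax(norm_psd[..., sel], axis=-1)]
    for num, den in cfg.ratios:
        out[f"{num}_{den}_ratio"] = logbp[num] - logbp[den]
    sel = (freqs >= cfg.sigma[0]) & (freqs <= cfg.sigma[1])
    out["sigma_power"] = np.log(norm_psd[..., sel].mean(axis=-1))
    bb = (freqs >= cfg.broadband[0]) & (freqs <= cfg.broadband[1])
    w = norm_psd[..., bb]
    out["spectrum_centroid"] = (w * freqs[bb]).sum(axis=-1) / w.sum(axis=-1)
    out["total_power"] = np.log(total_power)
    return out


def spectral_slope(epoch: np.ndarray, fs: float,
                   f_range=(0.1, 32.0)) -> float | np.ndarray:
    """Aperiodic exponent of the raw (un-whitened) power spectrum.

    Fits ``log10 P = b - a log10 f`` over ``f_range`` with one robust
    reweighting pass (bins more than one residual s.d. above the first fit
    — oscillatory peaks — are dropped before refitting).  Returns the
    exponent ``a`` (positive = decaying spectrum); NaN if the fit is
    degenerate.  Vectorised over leading axes.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    nw = 2.5
    tapers = dpss(n, nw, Kmax=4)
    spec = np.fft.rfft(epoch[..., None, :] * tapers, axis=-1)
    psd = (spec.real**2 + spec.imag**2).mean(axis=-2)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= max(f_range[0], freqs[1])) & (freqs <= f_range[1])
    lf = np.log10(freqs[sel])
    lp = np.log10(np.maximum(psd[..., sel], 1e-300))

    def _fit(lp_, mask):
        x = lf[mask]
        y = lp_[mask]
        if len(x) < 3 or np.ptp(x) == 0:
            return np.nan, np.nan
        A = np.vstack([np.ones_like(x), x]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef[0], coef[1]

    flat = lp.reshape(-1, lp.shape[-1])
    slopes = np.empty(flat.shape[0])
    for i, row in enumerate(flat):
        b, a = _fit(row, np.ones_like(lf, dtype=bool))
        if np.isnan(a):
            slopes[i] = np.nan
            continue
        res = row - (b + a * lf)
        keep = res <= res.std()  # drop strong positive (peak) residuals
        b2, a2 = _fit(row, keep)
        slopes[i] = -(a2 if np.isfinite(a2) else a)
    out = slopes.reshape(lp.shape[:-1])
    return float(out) if out.ndim == 0 else out


def temporal_coherence(epoch: np.ndarray, fs: float,
                       cfg: SpectralConfig | None = None,
                       n_segments: int = 6, nperseg: int = 64) -> dict:
    """Within-epoch temporal coherence per band.

    The (whitened) epoch is split into ``n_segments`` 1-s segments; the
    magnitude-squared coherence spectrum is computed for every segment pair
    and averaged; the feature is the sum of the averaged coherence over
    each band's bins.  Vectorised over a leading epoch axis.
    """
    cfg = cfg or SpectralConfig()
    epoch = np.asarray(epoch, dtype=float)
    squeeze = epoch.ndim == 1
    if squeeze:
        epoch = epoch[None]
    y = whiten(epoch)
    n = y.shape[-1]
    seg_len = n // n_segments
    segs = y[..., : n_segments * seg_len].reshape(
        y.shape[0], n_segments, seg_len)
    pairs = [(i, j) for i in range(n_segments) for j in range(i + 1, n_segments)]
    acc = None
    for i, j in pairs:
        f, c = signal.coherence(segs[:, i], segs[:, j], fs=fs,
                                nperseg=min(nperseg, seg_len), axis=-1)
        acc = c if acc is None else acc + c
    mean_coh = acc / len(pairs)
    out = {}
    for name, (lo, hi) in cfg.bands.items():
        sel = (f >= lo) & (f <= hi)
        val = mean_coh[..., sel].sum(axis=-1)
        out[f"{name}_coherence"] = float(val[0]) if squeeze else val
    return out
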