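"""Feature registry and the per-epoch feature-matrix extractor.

The full feature base has 50 features: 15 spectral (4 log band powers,
4 peak band frequencies, 5 log band-power ratios, log total power,
spectrum centroid), 6 phase-amplitude couplings (ordered low-phase to
high-amplitude band pairs), 4 per-band temporal coherences, the 22
CATCH-22 canonical features, plus sigma (spindle-band) power, the LZ76
entropy rate and the aperiodic spectral slope.  The 47-feature variant
omits the last three.

Features are computed per channel per 6-s epoch and averaged across the
configured channels; artifact-masked epochs are NaN for every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from sklearn.base import BaseEstimator, TransformerMixin

from ..io import EEGRecording
from ..preprocess import EpochGrid, ArtifactMask, epoch_signal
from .catch22 import CATCH22_NAMES, catch22_features
from .complexity import entropy_rate
from .pac import ORDERED_PAIRS, _fir_bandpass
from .spectral import (SpectralConfig, compute_psd, spectral_features,
                       spectral_slope, temporal_coherence, whiten)

__all__ = ["FeatureTimeseries", "FeatureExtractor", "compute_feature_matrix",
           "feature_names", "FIELD_ALIASES", "REGIONS"]

#: descriptive aliases used in the sleep literature for two CATCH-22 features
FIELD_ALIASES = {
    "dwelling_time": "SB_BinaryStats_mean_longstretch1",
    "prediction_error": "FC_LocalSimple_mean3_stderr",
}

#: channel-name prefixes defining scalp regions
REGIONS = {"frontal": ("F",), "central": ("C",), "occipital": ("O",)}

_EXTRA_50 = ["sigma_power", "entropy_rate", "spectral_slope"]


def feature_names(feature_set: int = 50,
                  cfg: SpectralConfig | None = None) -> list[str]:
    """Ordered names of the 47- or 50-feature base."""
    cfg = cfg or SpectralConfig()
    names = [f"{b}_power" for b in cfg.bands]
    names += [f"{b}_peak_freq" for b in cfg.bands]
    names += [f"{num}_{den}_ratio" for num, den in cfg.ratios]
    names += ["total_power", "spectrum_centroid"]
    names += [f"pac_{a}_{b}" for a, b in ORDERED_PAIRS]
    names += [f"{b}_coherence" for b in cfg.bands]
    names += CATCH22_NAMES
    if feature_set == 50:
        names += _EXTRA_50
    elif feature_set != 47:
        raise ValueError("feature_set must be 47 or 50")
    return names


@dataclass
class FeatureTimeseries:
    """M features x T epochs; NaN marks artifact-masked epochs."""

    values: np.ndarray
    feature_names: list[str]
    epoch_times: np.ndarray  # seconds from recording start (epoch centers)
    channel_set: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape != (len(self.feature_names),
                                 len(self.epoch_times)):
            raise ValueError("values must be (n_features, n_epochs)")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    def row(self, name: str) -> np.ndarray:
        name = FIELD_ALIASES.get(name, name)
        return self.values[self.feature_names.index(name)]

    def select(self, names) -> "FeatureTimeseries":
        names = [FIELD_ALIASES.get(n, n) for n in names]
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTimeseries(self.values[idx], names, self.epoch_times,
                                 self.channel_set)


def _pac_batch(epochs: np.ndarray, fs: float, cfg: SpectralConfig
               ) -> dict[str, np.ndarray]:
    """PAC for all 6 ordered pairs, vectorised over epochs.

    Band filtering and Hilbert transforms run on the whole epoch batch;
    the per-cycle summation follows the same normalisation as
    :func:`somnifold.features.pac.pac`.
    """
    y = whiten(epochs)
    analytic = {}
    for band, edges in cfg.bands.items():
        filt = _fir_bandpass(y, fs, edges)
        analytic[band] = _sig.hilbert(filt, axis=-1)
    out = {f"pac_{a}_{b}": np.full(epochs.shape[0], np.nan)
           for a, b in ORDERED_PAIRS}
    for pb, ab in ORDERED_PAIRS:
        phi = np.angle(analytic[pb])
        amp = np.abs(analytic[ab])
        for e in range(epochs.shape[0]):
            wraps = np.flatnonzero(np.diff(phi[e]) < -np.pi) + 1
            if len(wraps) < 2:
                continue
            a_seg = amp[e, wraps[0]:wraps[-1]]
            p_seg = phi[e, wraps[0]:wraps[-1]]
            z = np.abs(np.sum(a_seg * np.exp(1j * p_seg)))
            norm = np.sum(a_seg)  # = sum over cycles of mean_amp * length
            if norm > 0:
                out[f"pac_{pb}_{ab}"][e] = z / norm
    return out


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform an :class:`EEGRecording` into a :class:`FeatureTimeseries`.

    Parameters
    ----------
    feature_set : 47 or 50, selecting the feature base variant.
    cfg : spectral configuration (bands, tapers, ratio list).
    region : None (all channels), a region name from :data:`REGIONS`, or an
        explicit list of channel labels; features are averaged over the
        selected channels.
    """

    def __init__(self, feature_set: int = 50,
                 cfg: SpectralConfig | None = None,
                 region: str | list | None = None):
        self.feature_set = feature_set
        self.cfg = cfg
        self.region = region

    def fit(self, X=None, y=None):
        return self

    def _pick_channels(self, rec: EEGRecording) -> list[int]:
        if self.region is None:
            return list(range(len(rec.channels)))
        if isinstance(self.region, str):
            prefixes = REGIONS.get(self.region)
            if prefixes is None:
                raise ValueError(f"unknown region {self.region!r}")
            idx = [i for i, ch in enumerate(rec.channels)
                   if ch.upper().startswith(prefixes)]
        else:
            missing = [ch for ch in self.region if ch not in rec.channels]
            if missing:
                raise KeyError(f"channels not in recording: {missing}")
            idx = [rec.channels.index(ch) for ch in self.region]
        if not idx:
            raise ValueError("channel selection is empty")
        return idx

    def transform(self, rec: EEGRecording, mask: ArtifactMask | None = None,
                  grid: EpochGrid | None = None) -> FeatureTimeseries:
        cfg = self.cfg or SpectralConfig()
        names = feature_names(self.feature_set, cfg)
        epochs, grid = epoch_signal(rec, grid)
        ch_idx = self._pick_channels(rec)
        n_ep = grid.n_epochs
        per_channel = np.empty((len(ch_idx), len(names), n_ep))
        for row, ch in enumerate(ch_idx):
            per_channel[row] = self._channel_features(
                epochs[ch], rec.fs, cfg, names)
        values = per_channel.mean(axis=0)
        if mask is not None:
            values[:, mask.flags] = np.nan
        return FeatureTimeseries(values, names, grid.center_times,
                                 [rec.channels[i] for i in ch_idx])

    def _channel_features(self, ep: np.ndarray, fs: float,
                          cfg: SpectralConfig, names: list[str]) -> np.ndarray:
        n_ep = ep.shape[0]
        feats: dict[str, np.ndarray] = {}
        freqs, norm_psd, total = compute_psd(ep, fs, cfg)
        feats.update(spectral_features(freqs, norm_psd, total, cfg))
        feats.update(_pac_batch(ep, fs, cfg))
        feats.update(temporal_coherence(ep, fs, cfg))
        c22 = np.empty((n_ep, len(CATCH22_NAMES)))
        for e in range(n_ep):
            c22[e] = list(catch22_features(ep[e]).values())
        for j, nm in enumerate(CATCH22_NAMES):
            feats[nm] = c22[:, j]
        if self.feature_set == 50:
            feats["spectral_slope"] = np.atleast_1d(
                spectral_slope(ep, fs, cfg.broadband))
            feats["entropy_rate"] = np.array(
                [entropy_rate(ep[e]).rate for e in range(n_ep)])
            # sigma_power already provided by spectral_features
        out = np.empty((len(names), n_ep))
        for i, nm in enumerate(names):
            out[i] = feats[nm]
        return out


def compute_feature_matrix(rec: EEGRecording, hypnogram=None,
                           cfg: SpectralConfig | None = None,
                           feature_set: int = 50, region=None,
                           mask: ArtifactMask | None = None,
                           grid: EpochGrid | None = None) -> FeatureTimeseries:
    """Functional wrapper over :class:`FeatureExtractor`."""
    ext = FeatureExtractor(feature_set=feature_set, cfg=cfg, region=region)
    return ext.transform(rec, mask=mask, grid=grid)
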