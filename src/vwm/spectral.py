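"""IAF-anchored band power and the engagement index.

Band boundaries are anchored to each subject's individual alpha frequency
(IAF), estimated from the eyes-closed rest segment as the peak of the
channel-averaged Welch spectrum over posterior sites:

    theta       [IAF-6,  IAF-2]
    low alpha   [IAF-2,  IAF  ]
    upper alpha [IAF,    IAF+2]
    alpha       [IAF-2,  IAF+2]
    beta        [IAF+2,  IAF+16]
    gamma       [IAF+16, IAF+30]  (clipped to the 45 Hz analysis limit)

Power spectral densities are Welch estimates per epoch and channel (1 s
Hanning windows, 50% overlap), integrated over each band; task powers are
normalized to the passive-baseline block per channel and band (ratio by
default, dB selectable) and then averaged over electrode clusters.

The engagement index EI = Beta / (Alpha + Theta) is a dimensionless
band-power ratio used as a brainwave index of attentive engagement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Epochs, Recording
from .montage import ClusterDef, IAF_CHANNELS

ANALYSIS_FMIN = 1.0
ANALYSIS_FMAX = 45.0

BAND_OFFSETS = {
    "theta": (-6.0, -2.0),
    "low_alpha": (-2.0, 0.0),
    "upper_alpha": (0.0, 2.0),
    "alpha": (-2.0, 2.0),
    "beta": (2.0, 16.0),
    "gamma": (16.0, 30.0),
}

#: The four non-overlapping bands that tile [IAF-6, IAF+30].
PRIMARY_BANDS = ("theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandScheme:
    """IAF value plus the six IAF-relative band intervals in Hz."""

    iaf_hz: float
    bands: dict

    def __getitem__(self, band: str) -> tuple[float, float]:
        return self.bands[band]


def band_scheme(iaf_hz: float, fmax: float = ANALYSIS_FMAX) -> BandScheme:
    """Build the IAF-relative band table; gamma's top is clipped to ``fmax``."""
    if not 7.0 <= iaf_hz <= 13.0:
        raise ValueError(f"IAF {iaf_hz} Hz outside the plausible range [7, 13]")
    bands = {}
    for name, (lo, hi) in BAND_OFFSETS.items():
        a, b = iaf_hz + lo, iaf_hz + hi
        if b > fmax:
            b = fmax
        bands[name] = (a, b)
    return BandScheme(iaf_hz=float(iaf_hz), bands=bands)


def _parabolic_peak(freqs: np.ndarray, power: np.ndarray, i: int) -> float:
    """Refine a spectral peak position by fitting a parabola to 3 bins."""
    if i <= 0 or i >= len(power) - 1:
        return float(freqs[i])
    y0, y1, y2 = power[i - 1], power[i], power[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def estimate_iaf(closed_eyes, fs: float | None = None,
                 channels=IAF_CHANNELS,
                 search_range: tuple[float, float] = (7.0, 13.0),
                 window_s: float = 2.0, min_peak_ratio: float = 1.5) -> float:
    """Estimate the individual alpha frequency from an eyes-closed segment.

    ``closed_eyes`` may be a :class:`Recording` (its leading eyes-closed
    segment and the default posterior channels are used) or a plain
    (channels, samples) array with ``fs`` given.  The IAF is the
    parabolically interpolated peak of the channel-averaged Welch spectrum
    within ``search_range``.  If no convincing interior peak exists (peak
    power below ``min_peak_ratio`` times the in-range median, or the maximum
    sits at the range edge), the canonical 10 Hz is returned with a warning.
    """
    if isinstance(closed_eyes, Recording):
        seg = closed_eyes.closed_eyes_segment()
        data = seg[[closed_eyes.ch_index(c) for c in channels]]
        fs = closed_eyes.fs
    else:
        data = np.atleast_2d(np.asarray(closed_eyes, dtype=float))
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
    if data.shape[1] < 30 * fs:
        raise ValueError("closed-eyes segment must be at least 30 s long")
    nperseg = int(round(window_s * fs))
    freqs, psd = sps.welch(data, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant", axis=-1)
    spectrum = psd.mean(axis=0)
    lo, hi = search_range
    sel = (freqs >= lo) & (freqs <= hi)
    idx = np.flatnonzero(sel)
    sub = spectrum[idx]
    i_max = int(np.argmax(sub))
    interior = 0 < i_max < len(sub) - 1
    prominent = sub[i_max] > min_peak_ratio * np.median(sub)
    if not (interior and prominent):
        warnings.warn("no alpha peak found in the search range; "
                      "falling back to IAF = 10 Hz")
        return 10.0
    return _parabolic_peak(freqs, spectrum, idx[i_max])


def compute_psd(data: np.ndarray, fs: float, window_s: float = 1.0,
                overlap_s: float = 0.5):
    """Welch PSD along the last axis (Hanning window, mean detrending)."""
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    if data.shape[-1] < nperseg:
        raise ValueError(f"epoch length {data.shape[-1]} shorter than the "
                         f"{nperseg}-sample Welch window")
    return sps.welch(data, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=noverlap, detrend="constant", axis=-1)


def band_power_from_psd(freqs: np.ndarray, psd: np.ndarray,
                        band: tuple[float, float]) -> np.ndarray:
    """Integrate a PSD over ``[lo, hi)`` (rectangle rule over Welch bins)."""
    lo, hi = band
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo) & (freqs < hi)
    return psd[..., sel].sum(axis=-1) * df


def compute_band_power(epochs, scheme: BandScheme, fs: float | None = None,
                       window_s: float = 1.0, overlap_s: float = 0.5,
                       bands=None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Band power per epoch x channel x band, in µV².

    ``epochs`` may be an :class:`Epochs` object or a raw
    (n_epochs, n_channels, n_samples) array with ``fs`` given.  Band edges
    above the Nyquist frequency are clipped with a warning.
    """
    if isinstance(epochs, Epochs):
        data, fs = epochs.data, epochs.fs
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
    bands = tuple(bands) if bands is not None else tuple(scheme.bands)
    freqs, psd = compute_psd(data, fs, window_s, overlap_s)
    nyq = fs / 2.0
    out = np.empty(data.shape[:-1] + (len(bands),))
    for k, name in enumerate(bands):
        lo, hi = scheme[name]
        if hi > nyq:
            warnings.warn(f"band {name} upper edge {hi} Hz above Nyquist; clipped")
            hi = nyq
        out[..., k] = band_power_from_psd(freqs, psd, (lo, hi))
    return out, bands


def baseline_normalize(task_power: np.ndarray, baseline_power: np.ndarray,
                       mode: str = "ratio") -> np.ndarray:
    """Normalize task band power to the passive-baseline power.

    ``ratio`` returns the dimensionless task/baseline quotient; ``db``
    returns 10·log10 of it.  Baseline values must be strictly positive.
    """
    task_power = np.asarray(task_power, dtype=float)
    baseline_power = np.asarray(baseline_power, dtype=float)
    bad = ~(baseline_power > 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"baseline power must be positive everywhere; first offending "
            f"entry at index {tuple(int(i) for i in idx)}")
    ratio = task_power / baseline_power
    if mode == "ratio":
        return ratio
    if mode == "db":
        return 10.0 * np.log10(ratio)
    raise ValueError(f"unknown normalization mode {mode!r}; use 'ratio' or 'db'")


def cluster_average(power: np.ndarray, ch_names, cluster: ClusterDef,
                    apply_aliases: bool = True, channel_axis: int = -2
                    ) -> np.ndarray:
    """Arithmetic mean of band power over the cluster's channels.

    Cluster channels are resolved through the montage alias map (e.g. the
    legacy "T4" maps onto the recorded T8) unless ``apply_aliases`` is off.
    """
    names = list(ch_names)
    idx = []
    for c in cluster.resolved(apply_aliases):
        if c not in names:
            raise KeyError(f"cluster {cluster.name!r} references channel {c!r} "
                           f"absent from the data")
        idx.append(names.index(c))
    return np.take(power, idx, axis=channel_axis).mean(axis=channel_axis)


def engagement_index(beta_power, alpha_power, theta_power):
    """EI = Beta / (Alpha + Theta); dimensionless, scale-invariant."""
    beta_power = np.asarray(beta_power, dtype=float)
    denom = np.asarray(alpha_power, dtype=float) + np.asarray(theta_power, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("engagement index undefined: alpha + theta power "
                         "must be positive")
    return beta_power / denom
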