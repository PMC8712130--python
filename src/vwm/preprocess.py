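"""EEG cleaning and segmentation.

Stages, in pipeline order: 50 Hz notch, 5th-order Butterworth 1-45 Hz
band-pass (both applied forward-backward for zero phase shift, so epoch
timing is preserved), regression-based blink removal driven by the forehead
channel, stimulus-locked epoching (-500 ms to +3000 ms around onset, i.e.
2500 ms after the 500 ms stimulus offset), and three-criterion artifact
flagging:

* threshold — any sample beyond ±80 µV;
* trend — least-squares slope over the epoch above 40 µV/s, or a
  flat/disconnected channel (|slope| < 0.3 µV/s with peak-to-peak range
  under 1 µV);
* jump — any successive-sample absolute difference above 30 µV.

An epoch is artifactual when any criterion fires on any analysis channel,
and flagged epochs are excluded from every downstream computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Epochs, Recording
from .montage import BLINK_CHANNEL
from .synth import blink_template

logger = logging.getLogger(__name__)

EPOCH_PRE_MS = 500.0
EPOCH_POST_MS = 3000.0  # 2500 ms after the 500 ms stimulus offset


@dataclass(frozen=True)
class ArtifactCriteria:
    """Thresholds of the three epoch-rejection criteria.

    ``slope_min_uV_s`` together with ``flat_range_uV`` forms the
    flat-channel guard: a channel is flagged only when its drift is
    negligible *and* its whole-epoch range is below ``flat_range_uV``
    (otherwise ordinary zero-drift epochs would be rejected).
    """

    amp_uV: float = 80.0
    slope_max_uV_s: float = 40.0
    slope_min_uV_s: float = 0.3
    jump_uV: float = 30.0
    flat_range_uV: float = 1.0

    def __post_init__(self):
        for name in ("amp_uV", "slope_max_uV_s", "slope_min_uV_s", "jump_uV",
                     "flat_range_uV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_recording(recording: Recording, notch_hz: float = 50.0,
                     band: tuple[float, float] = (1.0, 45.0),
                     order: int = 5, notch_q: float = 30.0) -> Recording:
    """Apply the notch then the Butterworth band-pass, zero-phase.

    Both filters run forward-backward (``filtfilt``) so that no latency is
    introduced; the effective magnitude response is squared.
    """
    nyq = recording.fs / 2.0
    lo, hi = band
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band edges {band} must satisfy 0 < low < high < "
                         f"Nyquist ({nyq} Hz)")
    out = recording.copy()
    if notch_hz:
        if not 0.0 < notch_hz < nyq:
            raise ValueError(f"notch frequency {notch_hz} outside (0, {nyq})")
        b, a = signal.iirnotch(notch_hz, notch_q, fs=recording.fs)
        out.data = signal.filtfilt(b, a, out.data, axis=-1)
    sos = signal.butter(order, band, btype="bandpass", fs=recording.fs,
                        output="sos")
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


def detect_blink_windows(blink_sig: np.ndarray, fs: float,
                         threshold_sd: float = 3.0,
                         min_amp_uV: float = 60.0,
                         pad_s: float = 0.25) -> np.ndarray:
    """Matched-filter blink detection on the forehead channel.

    Correlates the signal with the canonical half-cosine blink pulse, picks
    response peaks exceeding ``threshold_sd`` robust standard deviations
    whose local amplitude also clears ``min_amp_uV`` (so background noise
    alone never triggers), and marks a window of one template length plus
    ``pad_s`` around each peak.  Returns a boolean mask over samples.
    """
    tpl = blink_template(fs)
    tplc = (tpl - tpl.mean()) / np.linalg.norm(tpl - tpl.mean())
    score = signal.fftconvolve(blink_sig, tplc[::-1], mode="same")
    score = np.abs(score - np.median(score))
    mad = np.median(np.abs(score - np.median(score))) * 1.4826
    peaks, _ = signal.find_peaks(score, height=threshold_sd * max(mad, 1e-12),
                                 distance=int(0.2 * fs))
    half = tpl.size // 2 + int(round(pad_s * fs))
    out = np.zeros(blink_sig.size, dtype=bool)
    for i in peaks:
        lo, hi = max(0, i - half), min(blink_sig.size, i + half + 1)
        seg = blink_sig[lo:hi]
        # amplitude gate relative to the window's own baseline, so slow
        # background drift never opens a window on its own
        if np.abs(seg - np.median(seg)).max() < min_amp_uV:
            continue
        out[lo:hi] = True
    return out


def remove_blinks(recording: Recording, blink_channel: str = BLINK_CHANNEL,
                  threshold_sd: float = 3.0) -> Recording:
    """Regress the blink channel out of every other channel in blink windows.

    Blink windows are found on the blink channel with a matched filter; a
    single least-squares coefficient per channel (fitted over all windows)
    scales the blink-channel signal, which is then subtracted inside the
    windows only, so non-blink segments are untouched.  The blink channel
    itself is retained unchanged for QC and excluded from analysis clusters
    downstream.
    """
    if blink_channel not in recording.ch_names:
        raise KeyError(f"blink channel {blink_channel!r} missing from recording")
    out = recording.copy()
    bi = out.ch_index(blink_channel)
    ref = out.data[bi]
    mask = detect_blink_windows(ref, out.fs, threshold_sd)
    if not mask.any():
        return out
    # blink-channel background variance, for the errors-in-variables
    # correction: the regressor carries its own noise, which attenuates a
    # plain least-squares coefficient by noise/signal
    outside = ref[~mask]
    noise_var = float(outside.var()) if outside.size > 100 else 0.0
    # regress per contiguous window so that a channel with no blink content
    # in one window (e.g. a disconnected electrode) is left untouched there
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    for lo, hi in zip(starts, stops):
        r = ref[lo:hi] - ref[lo:hi].mean()
        rr = float(r @ r)
        denom = max(rr - noise_var * r.size, 0.25 * rr)
        if denom <= 0:
            continue
        for c in range(out.data.shape[0]):
            if c == bi:
                continue
            y = out.data[c, lo:hi]
            beta = float(r @ (y - y.mean())) / denom
            out.data[c, lo:hi] = y - beta * r
    return out


def epoch_recording(recording: Recording, events: pd.DataFrame,
                    pre_ms: float = EPOCH_PRE_MS,
                    post_ms: float = EPOCH_POST_MS) -> Epochs:
    """Cut one epoch per stimulus event; onsets are absolute in the recording.

    Epochs run from ``pre_ms`` before onset to ``post_ms`` after onset
    (896 samples at 256 Hz for the default 3.5 s window).  Sample values are
    copied exactly.  Events whose window does not fit inside the recording
    are dropped with a logged warning.
    """
    fs = recording.fs
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    n_len = n_pre + n_post
    rows, slabs = [], []
    n_dropped = 0
    for _, ev in events.iterrows():
        start = int(round(ev["onset_ms"] / 1000.0 * fs)) - n_pre
        if start < 0 or start + n_len > recording.n_samples:
            n_dropped += 1
            continue
        slabs.append(recording.data[:, start:start + n_len])
        rows.append(ev)
    if n_dropped:
        logger.warning("dropped %d event(s) too close to the recording edge",
                       n_dropped)
    data = np.stack(slabs) if slabs else np.empty((0, recording.data.shape[0], n_len))
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return Epochs(data=data, fs=fs, ch_names=tuple(recording.ch_names),
                  metadata=meta, t0_ms=-pre_ms)


def _criterion_flags(data: np.ndarray, fs: float, criteria: ArtifactCriteria
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-epoch criterion evaluation over (epochs, channels, samples)."""
    # threshold
    thr = np.any(np.abs(data) > criteria.amp_uV, axis=(1, 2))
    # trend: OLS slope per epoch x channel, in µV/s
    n = data.shape[2]
    t = np.arange(n) / fs
    tc = t - t.mean()
    slope = data @ tc / float(tc @ tc)           # (epochs, channels)
    ptp = data.max(axis=2) - data.min(axis=2)
    flat = (np.abs(slope) < criteria.slope_min_uV_s) & \
           (ptp < criteria.flat_range_uV)
    trend = np.any((np.abs(slope) > criteria.slope_max_uV_s) | flat, axis=1)
    # jump
    jump = np.any(np.abs(np.diff(data, axis=2)) > criteria.jump_uV, axis=(1, 2))
    return thr, trend, jump


def detect_artifacts(epochs: Epochs, criteria: ArtifactCriteria | None = None,
                     exclude_channels: tuple[str, ...] = (BLINK_CHANNEL,)
                     ) -> Epochs:
    """Flag artifactual epochs in place and return the epochs.

    Criteria are evaluated on every analysis channel (all channels except
    ``exclude_channels``); an epoch is flagged if any channel violates any
    criterion.
    """
    if len(epochs) == 0:
        raise ValueError("cannot run artifact detection on an empty epoch set")
    criteria = criteria or ArtifactCriteria()
    keep = [i for i, c in enumerate(epochs.ch_names) if c not in exclude_channels]
    thr, trend, jump = _criterion_flags(epochs.data[:, keep, :], epochs.fs,
                                        criteria)
    flags = []
    for i in range(len(epochs)):
        f = set()
        if thr[i]:
            f.add("threshold")
        if trend[i]:
            f.add("trend")
        if jump[i]:
            f.add("jump")
        flags.append(f)
    epochs.artifact_flags = flags
    return epochs


def qc_counts(epochs: Epochs) -> pd.DataFrame:
    """Per-flag epoch counts, for the cleaning audit trail."""
    rows = {"n_epochs": len(epochs),
            "n_artifact": int(epochs.is_artifact.sum())}
    for flag in ("threshold", "trend", "jump"):
        rows[f"n_{flag}"] = sum(flag in f for f in epochs.artifact_flags)
    return pd.DataFrame([rows])
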