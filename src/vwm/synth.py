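"""Synthetic child-cohort generator: EEG recordings and behavior with known truth.

The generator emulates the statistical structure the analysis assumes for a
cohort of school-age children performing the dual-modality n-back task:

* a 60 s eyes-closed rest segment with a strong posterior alpha rhythm at a
  subject-specific individual alpha frequency (IAF);
* load-modulated frontal/midline/left-hemisphere theta power (multiplicative
  gain per n-back step), a modality-by-load parietal gamma modulation, and a
  per-condition engagement level that scales beta power;
* 1/f^beta background plus white sensor noise, blink transients largest at
  the forehead channel, and optional supra-threshold artifact injections
  (spikes, ramps, flat channels), all logged as ground truth;
* per-trial accuracy and lognormal reaction times that worsen with memory
  load, differ by modality, and couple negatively to engagement.

Oscillations are amplitude-modulated sinusoids whose phase is re-randomized
for each stimulus interval — the simplest process with controllable band
power.  All signals are in microvolts.  The generator's defaults define the
simulated study conditions; they are documented in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import Recording, Epochs
from .montage import CHANNELS, BLINK_CHANNEL
from . import protocol
from .protocol import SessionPlan, TrialResponse, MODALITIES, LEVELS

FS = 256.0
CLOSED_EYES_S = 60.0
EPOCH_PRE_MS = 500.0
EPOCH_POST_MS = 3000.0  # stimulus duration + 2500 ms after offset

#: Per-channel topography weights for each rhythm (unlisted channels get the
#: second value).  Theta is strongest over frontal, midline and left-
#: hemisphere sites; alpha posterior; gamma parietal.
_THETA_STRONG = {"F3", "F4", "F7", "F8", "Fz", "Cz", "Pz", "C3", "T7", "P3", "O1"}
_ALPHA_STRONG = {"O1", "O2", "P3", "P4", "P7", "P8", "Pz"}
_GAMMA_STRONG = {"P3", "P4", "P7", "P8", "Pz"}

#: Blink spatial profile: anterior-to-posterior gain relative to Fpz.
_BLINK_GAIN = {
    "Fpz": 1.0, "Fz": 0.50, "F3": 0.45, "F4": 0.45, "F7": 0.40, "F8": 0.40,
    "Cz": 0.20, "C3": 0.18, "C4": 0.18, "T7": 0.12, "T8": 0.12,
    "Cp5": 0.10, "Cp6": 0.10,
    "Pz": 0.08, "P3": 0.07, "P4": 0.07, "P7": 0.06, "P8": 0.06,
    "O1": 0.04, "O2": 0.04,
}

_CELLS = [(m, l) for m in MODALITIES for l in LEVELS]


def _topo(strong: set, w_strong: float = 1.0, w_weak: float = 0.35) -> np.ndarray:
    return np.array([w_strong if c in strong else w_weak for c in CHANNELS])


@dataclass
class SubjectProfile:
    """Generative parameters for one simulated child.

    Powers are in µV² (sinusoid of amplitude A has power A²/2); the
    per-condition dictionaries are keyed by (modality, level).
    """

    subject_id: str = "s01"
    iaf_hz: float = 10.0
    theta_base_power: float = 18.0          # µV², level-0 / baseline theta
    theta_load_gain: float = 1.25           # multiplicative power gain per load step
    gamma_base_power: float = 4.5           # µV² parietal gamma at gain 1
    gamma_modality_gain: dict = field(default_factory=lambda: {
        # parietal gamma scaling per modality x level; audio decreases with
        # load while video stays flat (a load-by-modality interaction)
        ("audio", 0): 1.22, ("audio", 1): 1.03, ("audio", 2): 0.75,
        ("video", 0): 1.00, ("video", 1): 1.00, ("video", 2): 1.00,
    })
    alpha_closed_power: float = 200.0       # µV², eyes-closed posterior alpha
    alpha_task_power: float = 32.0          # µV², residual alpha during task
    beta_base_power: float = 8.0            # µV²
    beta_engagement_slope: float = 0.20     # fractional beta-power change per
                                            # engagement z-unit
    engagement_by_condition: dict = field(default_factory=lambda: {
        (m, l): 0.4 * l for m, l in _CELLS})  # engagement rises with load
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 150.0
    noise_1f_exponent: float = 1.0
    noise_1f_rms_uv: float = 9.0            # background RMS over 1-45 Hz
    noise_white_rms_uv: float = 2.0
    rt_base_ms: float = 470.0               # video 0-back mean
    rt_load_slope_ms: float = 130.0
    rt_modality_shift_ms: float = 130.0     # audio minus video
    rt_sigma_log: float = 0.28
    ei_rt_coupling_ms: float = 150.0        # RT decrease per engagement z-unit
    acc_by_condition: dict = field(default_factory=lambda: {
        # population accuracies per modality x level
        ("audio", 0): 0.970, ("audio", 1): 0.876, ("audio", 2): 0.870,
        ("video", 0): 0.909, ("video", 1): 0.833, ("video", 2): 0.740,
    })

    def __post_init__(self) -> None:
        if not 8.0 <= self.iaf_hz <= 12.0:
            raise ValueError(f"iaf_hz must lie in [8, 12]; got {self.iaf_hz}")
        for name in ("theta_base_power", "gamma_base_power", "alpha_closed_power",
                     "alpha_task_power", "beta_base_power"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for cell, p in self.acc_by_condition.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"accuracy for {cell} must lie in (0, 1]")

    # -- derived band-centre frequencies -----------------------------------
    @property
    def theta_hz(self) -> float:
        return self.iaf_hz - 4.0

    @property
    def beta_hz(self) -> float:
        return self.iaf_hz + 9.0

    @property
    def gamma_hz(self) -> float:
        return min(self.iaf_hz + 23.0, 42.0)

    def condition_powers(self, modality: str, level: int) -> dict:
        """Analytic oscillation power (µV², topography weight 1) per band."""
        e = self.engagement_by_condition[(modality, level)]
        return {
            "theta": self.theta_base_power * self.theta_load_gain ** level,
            "alpha": self.alpha_task_power,
            "beta": self.beta_base_power * max(0.05, 1.0 + self.beta_engagement_slope * e),
            "gamma": self.gamma_base_power * self.gamma_modality_gain[(modality, level)],
        }


@dataclass
class GroundTruthLog:
    """What was injected, for downstream recovery checks."""

    artifact_epochs: list = field(default_factory=list)   # (epoch_index, type)
    blink_times_s: list = field(default_factory=list)
    condition_powers: dict = field(default_factory=dict)  # (mod, level) -> band -> µV²
    engagement: dict = field(default_factory=dict)        # (mod, level) -> z
    iaf_hz: float = 10.0


# ---------------------------------------------------------------------------
# signal primitives

def pink_noise(rng: np.random.Generator, n: int, beta: float = 1.0,
               fs: float = FS, band: tuple = (1.0, 45.0),
               size: tuple = ()) -> np.ndarray:
    """1/f^beta noise normalized to unit RMS within ``band``.

    ``size`` prepends leading axes (e.g. ``(n_epochs, n_channels)``); each
    trace is independent and individually normalized.
    """
    shape = tuple(int(s) for s in np.atleast_1d(size)) if size != () else ()
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = (rng.normal(size=shape + (freqs.size,))
            + 1j * rng.normal(size=shape + (freqs.size,)))
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    # normalise using in-band power only
    px = np.fft.rfft(x, axis=-1)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    rms_inband = np.sqrt(np.sum(np.abs(px[..., inband]) ** 2, axis=-1)
                         / (n * n / 2.0))
    return x / np.maximum(rms_inband, 1e-30)[..., None]


def oscillation(rng: np.random.Generator, n: int, freq: float, amp: float,
                fs: float = FS, amp_jitter: float = 0.1) -> np.ndarray:
    """One burst of an amplitude-jittered sinusoid with random phase."""
    phase = rng.uniform(0.0, 2.0 * np.pi)
    a = amp * max(0.0, 1.0 + amp_jitter * rng.normal())
    t = np.arange(n) / fs
    return a * np.sin(2.0 * np.pi * freq * t + phase)


def _power_to_amp(power: float) -> float:
    return float(np.sqrt(2.0 * max(power, 0.0)))


def blink_template(fs: float = FS, duration_ms: float = 400.0) -> np.ndarray:
    """Half-cosine blink pulse of unit peak amplitude."""
    n = int(round(duration_ms / 1000.0 * fs))
    return np.sin(np.pi * np.arange(n) / n) ** 2


# ---------------------------------------------------------------------------
# recording simulation

def _add_band_oscillations(data: np.ndarray, sl: slice, rng, profile: SubjectProfile,
                           powers: dict, seg_starts: np.ndarray) -> None:
    """Add the four rhythms over data[:, sl], re-randomizing phase per segment.

    ``seg_starts`` are sample offsets (within the slice) at which phase is
    re-drawn — one per stimulus interval.
    """
    n = sl.stop - sl.start
    topo = {
        "theta": _topo(_THETA_STRONG), "alpha": _topo(_ALPHA_STRONG),
        "beta": _topo(set(), 1.0, 1.0), "gamma": _topo(_GAMMA_STRONG),
    }
    freqs = {"theta": profile.theta_hz, "alpha": profile.iaf_hz,
             "beta": profile.beta_hz, "gamma": profile.gamma_hz}
    bounds = list(seg_starts) + [n]
    for band, power in powers.items():
        amp = _power_to_amp(power)
        sig = np.empty(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            sig[a:b] = oscillation(rng, b - a, freqs[band], amp)
        data[:, sl] += topo[band][:, None] * sig[None, :]


def _inject_blinks(data: np.ndarray, rng, profile: SubjectProfile,
                   fs: float) -> list:
    n = data.shape[1]
    tpl = blink_template(fs)
    n_blinks = rng.poisson(profile.blink_rate_per_min * (n / fs) / 60.0)
    gains = np.array([_BLINK_GAIN[c] for c in CHANNELS])
    times = []
    for _ in range(n_blinks):
        start = rng.integers(0, n - tpl.size)
        amp = profile.blink_amp_uv * (1.0 + 0.2 * rng.normal())
        data[:, start:start + tpl.size] += amp * gains[:, None] * tpl[None, :]
        times.append(start / fs)
    return sorted(times)


_ARTIFACT_TYPES = ("spike", "jump", "flat")


def _inject_recording_artifacts(data: np.ndarray, rng, events: pd.DataFrame,
                                n_artifact_epochs: int, fs: float,
                                analysis_idx: np.ndarray) -> list:
    """Corrupt a subset of stimulus epochs with supra-threshold artifacts."""
    if n_artifact_epochs <= 0:
        return []
    n_events = len(events)
    # keep injected epochs non-adjacent so neighbours stay clean
    order = rng.permutation(n_events)
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) > 1 for j in chosen):
            chosen.append(int(i))
        if len(chosen) == n_artifact_epochs:
            break
    log = []
    for k, ev_idx in enumerate(sorted(chosen)):
        kind = _ARTIFACT_TYPES[k % len(_ARTIFACT_TYPES)]
        onset = int(round(events["onset_ms"].iloc[ev_idx] / 1000.0 * fs))
        ch = int(rng.choice(analysis_idx))
        if kind == "spike":
            width = int(0.06 * fs)
            pos = onset + int(rng.uniform(0.2, 1.8) * fs)
            data[ch, pos:pos + width] += 130.0 * np.sin(
                np.pi * np.arange(width) / width)
        elif kind == "jump":
            pos = onset + int(rng.uniform(0.2, 1.8) * fs)
            width = int(0.05 * fs)
            data[ch, pos:pos + width] += 90.0  # step up and back down
        else:  # flat: replace the channel around the epoch with its mean
            a = max(0, onset - int(1.8 * fs))
            b = min(data.shape[1], onset + int((EPOCH_POST_MS / 1000.0 + 1.3) * fs))
            data[ch, a:b] = 0.0
        log.append((int(ev_idx), kind))
    return log


def make_events(plan: SessionPlan, offset_ms: float = CLOSED_EYES_S * 1000.0
                ) -> pd.DataFrame:
    """Event table with onsets absolute within the simulated recording."""
    df = protocol.session_table(plan)
    df["onset_ms"] = df["onset_ms"] + offset_ms
    return df


def simulate_recording(profile: SubjectProfile, plan: SessionPlan, seed,
                       n_artifact_epochs: int = 0,
                       closed_eyes_s: float = CLOSED_EYES_S,
                       fs: float = FS) -> tuple[Recording, GroundTruthLog]:
    """Simulate the continuous EEG for one subject-modality session.

    The recording concatenates a closed-eyes rest segment (posterior alpha at
    the subject's IAF), the passive baseline block, and the six task blocks,
    over a 1/f + white noise background.  Task-block rhythms follow the
    profile's per-condition powers; blinks and (optionally) supra-threshold
    epoch artifacts are injected and logged.
    """
    rng = np.random.default_rng(seed)
    n_total = int(round((closed_eyes_s + plan.duration_ms / 1000.0) * fs))
    data = np.zeros((len(CHANNELS), n_total))

    # background noise
    for c in range(len(CHANNELS)):
        data[c] = profile.noise_1f_rms_uv * pink_noise(
            rng, n_total, profile.noise_1f_exponent, fs)
        data[c] += profile.noise_white_rms_uv * rng.normal(size=n_total)

    # closed-eyes alpha (strong posterior), phase re-drawn every 2 s
    n_ce = int(round(closed_eyes_s * fs))
    seg = np.arange(0, n_ce, int(2 * fs))
    _add_band_oscillations(
        data, slice(0, n_ce), rng, profile,
        {"alpha": profile.alpha_closed_power,
         "theta": 0.3 * profile.theta_base_power,
         "beta": 0.3 * profile.beta_base_power,
         "gamma": 0.2 * profile.gamma_base_power},
        seg)

    gt = GroundTruthLog(iaf_hz=profile.iaf_hz,
                        engagement=dict(profile.engagement_by_condition))

    # blocks
    for blk in plan.blocks:
        start = int(round((closed_eyes_s + blk.start_ms / 1000.0) * fs))
        stop = min(int(round((closed_eyes_s + (blk.start_ms + blk.duration_ms)
                              / 1000.0) * fs)), n_total)
        if blk.kind == "baseline":
            powers = {"theta": profile.theta_base_power,
                      "alpha": profile.alpha_task_power,
                      "beta": profile.beta_base_power,
                      "gamma": profile.gamma_base_power}
        else:
            powers = profile.condition_powers(blk.modality, blk.level)
            gt.condition_powers.setdefault((blk.modality, blk.level), powers)
        seg_starts = np.array([int(round(it.onset_ms / 1000.0 * fs))
                               for it in blk.items])
        _add_band_oscillations(data, slice(start, stop), rng, profile,
                               powers, seg_starts)

    gt.blink_times_s = _inject_blinks(data, rng, profile, fs)

    events = make_events(plan, closed_eyes_s * 1000.0)
    analysis_idx = np.array([i for i, c in enumerate(CHANNELS)
                             if c != BLINK_CHANNEL])
    gt.artifact_epochs = _inject_recording_artifacts(
        data, rng, events, n_artifact_epochs, fs, analysis_idx)

    rec = Recording(data=data, fs=fs, ch_names=CHANNELS,
                    closed_eyes_s=closed_eyes_s,
                    subject_id=plan.subject_id, modality=plan.modality)
    return rec, gt


# ---------------------------------------------------------------------------
# epoch-level simulation (scaled-down studies and detector checks)

def simulate_condition_epochs(profile: SubjectProfile, modality: str, level,
                              n_epochs: int, seed,
                              channels=CHANNELS, fs: float = FS,
                              epoch_s: float = 3.5) -> np.ndarray:
    """Directly simulate stimulus epochs for one condition cell.

    ``level`` may be an integer load level or ``"baseline"``.  This is the
    same generative model as :func:`simulate_recording` restricted to
    isolated epoch windows — used by the scaled-down statistical studies
    where simulating full continuous sessions would add nothing.
    """
    rng = np.random.default_rng(seed)
    n = int(round(epoch_s * fs))
    ch_idx = [list(CHANNELS).index(c) for c in channels]
    if level == "baseline":
        powers = {"theta": profile.theta_base_power,
                  "alpha": profile.alpha_task_power,
                  "beta": profile.beta_base_power,
                  "gamma": profile.gamma_base_power}
    else:
        powers = profile.condition_powers(modality, level)
    topo = {
        "theta": _topo(_THETA_STRONG)[ch_idx], "alpha": _topo(_ALPHA_STRONG)[ch_idx],
        "beta": _topo(set(), 1.0, 1.0)[ch_idx], "gamma": _topo(_GAMMA_STRONG)[ch_idx],
    }
    freqs = {"theta": profile.theta_hz, "alpha": profile.iaf_hz,
             "beta": profile.beta_hz, "gamma": profile.gamma_hz}
    out = profile.noise_1f_rms_uv * pink_noise(
        rng, n, profile.noise_1f_exponent, fs, size=(n_epochs, len(channels)))
    out += profile.noise_white_rms_uv * rng.normal(size=out.shape)
    for e in range(n_epochs):
        for band, power in powers.items():
            sig = oscillation(rng, n, freqs[band], _power_to_amp(power))
            out[e] += topo[band][:, None] * sig[None, :]
    return out


def make_artifact_epochs(n_epochs: int, artifact_fraction: float, seed,
                         profile: Optional[SubjectProfile] = None,
                         channels=CHANNELS, fs: float = FS,
                         epoch_s: float = 3.5) -> tuple[Epochs, np.ndarray]:
    """Build a labelled epoch set: clean background epochs plus injections.

    Clean epochs are band-limited to the analysis band (1-45 Hz), matching
    what the artifact detector sees in the pipeline, where rejection runs
    after filtering; then an ``artifact_fraction`` of epochs receive one
    supra-threshold artifact each (cycled through amplitude spikes,
    sample-to-sample jumps, slow high-amplitude ramps and flat channels).
    Returns the epochs and the boolean ground-truth labels.
    """
    from scipy import signal as sps
    profile = profile or SubjectProfile()
    rng = np.random.default_rng(seed)
    data = simulate_condition_epochs(profile, "audio", 1, n_epochs,
                                     rng.integers(2 ** 31),
                                     channels=channels, fs=fs, epoch_s=epoch_s)
    sos = sps.butter(5, (1.0, 45.0), btype="bandpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=-1)
    n = data.shape[2]
    n_art = int(round(artifact_fraction * n_epochs))
    labels = np.zeros(n_epochs, dtype=bool)
    which = rng.choice(n_epochs, size=n_art, replace=False)
    kinds = ("spike", "jump", "ramp", "flat")
    t = np.arange(n) / fs
    for k, e in enumerate(sorted(which)):
        labels[e] = True
        kind = kinds[k % 4]
        ch = int(rng.integers(len(channels)))
        if kind == "spike":
            width = int(0.06 * fs)
            pos = int(rng.integers(0, n - width))
            data[e, ch, pos:pos + width] += 130.0 * np.sin(
                np.pi * np.arange(width) / width)
        elif kind == "jump":
            pos = int(rng.integers(1, n - 1))
            data[e, ch, pos:] += 60.0
        elif kind == "ramp":
            # |slope| ~ 45 µV/s over the epoch, peak below the 80 µV threshold
            slope = rng.choice([-45.0, 45.0])
            data[e, ch] += slope * (t - t.mean())
        else:  # flat channel (disconnected electrode)
            data[e, ch] = 0.0
    meta = pd.DataFrame({"epoch": np.arange(n_epochs)})
    epochs = Epochs(data=data, fs=fs, ch_names=tuple(channels), metadata=meta)
    return epochs, labels


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(profile: SubjectProfile, plan: SessionPlan, seed
                      ) -> list[TrialResponse]:
    """Simulate forced-choice responses for every task trial of a session.

    Correctness is Bernoulli with the profile's per-condition accuracy;
    reaction times (from stimulus offset) are lognormal around a mean that
    grows with load, shifts by modality, and decreases with the condition's
    engagement level (the engagement-RT coupling).
    """
    rng = np.random.default_rng(seed)
    out: list[TrialResponse] = []
    for blk in plan.task_blocks:
        cell = (blk.modality, blk.level)
        p_correct = profile.acc_by_condition[cell]
        e = profile.engagement_by_condition[cell]
        mean_rt = (profile.rt_base_ms
                   + profile.rt_load_slope_ms * blk.level
                   + (profile.rt_modality_shift_ms if blk.modality == "audio" else 0.0)
                   - profile.ei_rt_coupling_ms * e)
        mean_rt = max(mean_rt, 150.0)
        mu = np.log(mean_rt) - profile.rt_sigma_log ** 2 / 2.0
        for item in blk.items:
            correct = bool(rng.random() < p_correct)
            truth = "target" if item.is_target else "nontarget"
            resp = truth if correct else ("nontarget" if truth == "target" else "target")
            rt = float(np.exp(mu + profile.rt_sigma_log * rng.normal()))
            out.append(TrialResponse(block_id=blk.block_id, item_index=item.index,
                                     response=resp, correct=correct, rt_ms=rt))
    return out


# ---------------------------------------------------------------------------
# cohort

@dataclass
class CohortConfig:
    """Population-level means and between-subject spreads."""

    n_subjects: int = 11
    iaf_mean_hz: float = 10.0
    iaf_sd_hz: float = 0.8
    theta_load_gain_mean: float = 1.25
    theta_load_gain_sd: float = 0.25
    theta_base_power_cv: float = 0.2
    rt_base_sd_ms: float = 60.0
    acc_jitter_sd: float = 0.08
    engagement_sd: float = 0.6       # per-cell engagement spread (z units)
    gamma_gain_jitter_sd: float = 0.15
    blink_rate_per_min: float = 8.0
    n_artifact_epochs: int = 4       # per session


def draw_profile(config: CohortConfig, subject_id: str,
                 rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's generative parameters around the population means."""
    base = SubjectProfile(subject_id=subject_id)
    iaf = float(np.clip(rng.normal(config.iaf_mean_hz, config.iaf_sd_hz), 8.1, 11.9))
    gain = float(np.clip(rng.normal(config.theta_load_gain_mean,
                                    config.theta_load_gain_sd), 0.7, 2.5))
    acc = {cell: float(np.clip(p + config.acc_jitter_sd * rng.normal(), 0.4, 1.0))
           for cell, p in base.acc_by_condition.items()}
    eng = {cell: base.engagement_by_condition[cell]
           + config.engagement_sd * rng.normal() for cell in _CELLS}
    gamma = {cell: float(np.clip(
        base.gamma_modality_gain[cell]
        * (1.0 + config.gamma_gain_jitter_sd * rng.normal()), 0.2, None))
        for cell in _CELLS}
    return SubjectProfile(
        subject_id=subject_id,
        iaf_hz=iaf,
        theta_base_power=base.theta_base_power
        * float(np.exp(config.theta_base_power_cv * rng.normal())),
        theta_load_gain=gain,
        blink_rate_per_min=config.blink_rate_per_min,
        rt_base_ms=base.rt_base_ms + config.rt_base_sd_ms * rng.normal(),
        acc_by_condition=acc,
        engagement_by_condition=eng,
        gamma_modality_gain=gamma,
    )


def make_cohort(n_subjects: int = 11, effect_config: Optional[CohortConfig] = None,
                seed: int = 0, out_dir=None, write_recordings: bool = True):
    """Simulate a full cohort; optionally write it to disk.

    Writes, per subject and modality, a FIF recording, a TSV event/response
    table, and one cohort-wide YAML manifest with every profile and ground
    truth.  Returns the in-memory structures:
    ``(profiles, sessions)`` where ``sessions`` maps
    (subject_id, modality) -> dict(plan, recording, ground_truth, responses).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    config = effect_config or CohortConfig(n_subjects=n_subjects)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    profiles, sessions = [], {}
    manifest = {"seed": int(seed), "n_subjects": int(n_subjects), "subjects": {}}
    for i, sseq in enumerate(subject_seeds):
        sid = f"s{i + 1:02d}"
        rng = np.random.default_rng(sseq)
        prof = draw_profile(config, sid, rng)
        profiles.append(prof)
        subj_entry = {"iaf_hz": round(prof.iaf_hz, 4),
                      "theta_load_gain": round(prof.theta_load_gain, 4),
                      "sessions": {}}
        for modality in MODALITIES:
            plan_seed = int(rng.integers(2 ** 31))
            rec_seed = int(rng.integers(2 ** 31))
            beh_seed = int(rng.integers(2 ** 31))
            plan = protocol.generate_session(sid, modality, plan_seed)
            rec, gt = simulate_recording(prof, plan, rec_seed,
                                         n_artifact_epochs=config.n_artifact_epochs)
            responses = simulate_behavior(prof, plan, beh_seed)
            sessions[(sid, modality)] = {"plan": plan, "recording": rec,
                                         "ground_truth": gt,
                                         "responses": responses,
                                         "profile": prof}
            subj_entry["sessions"][modality] = {
                "plan_seed": plan_seed,
                "n_injected_artifacts": len(gt.artifact_epochs),
                "artifact_epochs": [[int(i), t] for i, t in gt.artifact_epochs],
            }
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                stem = f"{sid}_{modality}"
                if write_recordings:
                    rec.save(out / f"{stem}_raw.fif")
                protocol.write_session_tsv(out / f"{stem}_events.tsv",
                                           plan, responses)
        manifest["subjects"][sid] = subj_entry
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return profiles, sessions
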