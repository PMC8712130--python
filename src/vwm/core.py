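"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .montage import CHANNELS


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is (n_channels, n_samples).  A recording may open with an
    eyes-closed rest segment of ``closed_eyes_s`` seconds; the session's
    stimulus timeline starts immediately after it, so absolute stimulus
    onsets are session onsets plus ``closed_eyes_s * 1000`` ms.
    """

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...] = CHANNELS
    closed_eyes_s: float = 0.0
    subject_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"data must be (n_channels={len(self.ch_names)}, n_samples); "
                f"got shape {self.data.shape}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def ch_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name) if isinstance(self.ch_names, list) \
                else list(self.ch_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording "
                           f"(channels: {list(self.ch_names)})") from None

    def get_channels(self, names) -> np.ndarray:
        idx = [self.ch_index(n) for n in names]
        return self.data[idx]

    def closed_eyes_segment(self) -> np.ndarray:
        n = int(round(self.closed_eyes_s * self.fs))
        return self.data[:, :n]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())

    # -- interop with MNE (used for on-disk round trips) -------------------
    def to_mne(self):
        import mne
        info = mne.create_info(list(self.ch_names), self.fs, ch_types="eeg")
        # MNE raws are in volts
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        return raw

    def save(self, path) -> None:
        """Write to a FIF file (µV data stored as volts, MNE convention)."""
        raw = self.to_mne()
        raw.info["description"] = (
            f"subject={self.subject_id};modality={self.modality};"
            f"closed_eyes_s={self.closed_eyes_s}")
        raw.save(path, overwrite=True, verbose="error")

    @classmethod
    def load(cls, path) -> "Recording":
        import mne
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        meta = dict(kv.split("=") for kv in (raw.info["description"] or "").split(";")
                    if "=" in kv)
        return cls(data=raw.get_data() * 1e6, fs=raw.info["sfreq"],
                   ch_names=tuple(raw.ch_names),
                   closed_eyes_s=float(meta.get("closed_eyes_s", 0.0)),
                   subject_id=meta.get("subject", ""),
                   modality=meta.get("modality", ""))


@dataclass
class Epochs:
    """Stimulus-locked EEG windows with artifact annotations.

    ``data`` is (n_epochs, n_channels, n_samples) in µV.  Each epoch spans
    from 500 ms before stimulus onset to 2500 ms after stimulus offset
    (t0_ms = -500; 3.5 s, i.e. 896 samples at 256 Hz).  ``metadata`` carries
    one row per epoch (block, kind, level, modality, item_index, is_target).
    ``artifact_flags`` holds, per epoch, the subset of criteria violated
    ({"threshold", "trend", "jump"}); an epoch is artifactual if the set is
    non-empty.
    """

    data: np.ndarray
    fs: float
    ch_names: tuple[str, ...]
    metadata: "object"             # pandas.DataFrame, one row per epoch
    t0_ms: float = -500.0
    artifact_flags: Optional[list] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = [set() for _ in range(len(self.data))]

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def is_artifact(self) -> np.ndarray:
        return np.array([len(f) > 0 for f in self.artifact_flags])

    def ch_index(self, name: str) -> int:
        try:
            return list(self.ch_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def drop_artifacts(self) -> "Epochs":
        keep = ~self.is_artifact
        return Epochs(data=self.data[keep], fs=self.fs, ch_names=self.ch_names,
                      metadata=self.metadata.loc[keep].reset_index(drop=True),
                      t0_ms=self.t0_ms,
                      artifact_flags=[set() for _ in range(int(keep.sum()))])
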