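"""Filtering, blink removal, epoching and the three artifact criteria."""

import numpy as np
import pandas as pd
import pytest

from vwm import preprocess, synth
from vwm.core import Epochs, Recording
from vwm.preprocess import (ArtifactCriteria, detect_artifacts,
                            epoch_recording, filter_recording, remove_blinks)
from vwm.synth import blink_template

FS = 256.0


def sine_recording(freq, amp=10.0, dur_s=20.0, n_ch=2):
    t = np.arange(int(dur_s * FS)) / FS
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, fs=FS, ch_names=tuple(f"ch{i}" for i in range(n_ch)))


def rms(x, trim=256):
    """RMS away from the filter's edge transients."""
    return np.sqrt(np.mean(x[..., trim:-trim] ** 2))


class TestFilter:
    def test_notch_suppresses_mains(self):
        rec = sine_recording(50.0)
        out = filter_recording(rec)
        assert rms(out.data) <= 0.05 * rms(rec.data)

    def test_passband_preserved(self):
        rec = sine_recording(10.0)
        out = filter_recording(rec)
        assert rms(out.data) >= 0.90 * rms(rec.data)

    def test_dc_removed(self):
        rec = Recording(data=np.full((1, int(20 * FS)), 25.0), fs=FS,
                        ch_names=("ch0",))
        out = filter_recording(rec)
        assert np.abs(out.data[:, 256:-256]).max() < 0.1

    def test_idempotent_in_passband(self):
        rec = sine_recording(10.0)
        once = filter_recording(rec)
        twice = filter_recording(once)
        assert rms(twice.data - once.data) <= 0.02 * rms(once.data)

    def test_invalid_band_rejected(self):
        rec = sine_recording(10.0)
        with pytest.raises(ValueError, match="band"):
            filter_recording(rec, band=(1.0, 200.0))


@pytest.fixture(scope="module")
def blinky(audio_plan):
    prof = synth.SubjectProfile(blink_rate_per_min=10.0)
    rec, gt = synth.simulate_recording(prof, audio_plan, seed=21)
    return rec, gt


class TestRemoveBlinks:
    def _blink_corr(self, rec, gt):
        """Per-channel |correlation| with the blink template, pooled over all
        known blink windows (pooling averages out the 1/f background)."""
        tpl = blink_template(rec.fs)
        cors = []
        for ch in ("Fz", "Cz", "Pz", "O1"):
            segs, tpls = [], []
            for t0 in gt.blink_times_s:
                i = int(t0 * rec.fs)
                seg = rec.data[rec.ch_index(ch), i:i + tpl.size]
                if seg.size < tpl.size:
                    continue
                segs.append(seg)
                tpls.append(tpl)
            y = np.concatenate(segs)
            x = np.concatenate(tpls)
            cors.append(abs(np.corrcoef(x, y)[0, 1]))
        return np.array(cors)

    def test_blink_component_regressed_out(self, blinky):
        rec, gt = blinky
        before = self._blink_corr(rec, gt)
        cleaned = remove_blinks(rec)
        after = self._blink_corr(cleaned, gt)
        # contamination was real (strongest frontally, graded posteriorly)
        assert before[0] > 0.5 and before.mean() > 0.25
        assert after.mean() < 0.1
        # blink channel itself is retained for QC
        np.testing.assert_array_equal(cleaned.data[rec.ch_index("Fpz")],
                                      rec.data[rec.ch_index("Fpz")])

    def test_no_blinks_is_near_noop(self, simulated_session):
        rec, _ = simulated_session
        out = remove_blinks(rec)
        change = np.sqrt(np.mean((out.data - rec.data) ** 2))
        assert change < 0.01 * np.sqrt(np.mean(rec.data ** 2))

    def test_scale_invariance(self, audio_plan):
        """Doubling blink amplitude does not degrade removal quality."""
        prof = synth.SubjectProfile(blink_rate_per_min=10.0,
                                    blink_amp_uv=300.0)
        rec, gt = synth.simulate_recording(prof, audio_plan, seed=21)
        after = self._blink_corr(remove_blinks(rec), gt)
        assert after.mean() < 0.1

    def test_missing_channel(self):
        rec = sine_recording(10.0)
        with pytest.raises(KeyError, match="Fpz"):
            remove_blinks(rec)


class TestEpoching:
    def test_block_epochs(self, simulated_session, audio_plan):
        rec, _ = simulated_session
        events = synth.make_events(audio_plan)
        epochs = epoch_recording(rec, events)
        assert len(epochs) == 7 * 21
        assert epochs.data.shape[2] == 896        # 3.5 s at 256 Hz
        assert epochs.t0_ms == -500.0

    def test_sample_values_preserved(self, simulated_session):
        rec, _ = simulated_session
        ev = pd.DataFrame([{"onset_ms": 2000.0}])
        epochs = epoch_recording(rec, ev)
        start = int(1.5 * rec.fs)
        np.testing.assert_array_equal(epochs.data[0],
                                      rec.data[:, start:start + 896])

    def test_edge_event_dropped(self, simulated_session, caplog):
        rec, _ = simulated_session
        ev = pd.DataFrame([{"onset_ms": 100.0}, {"onset_ms": 5000.0}])
        with caplog.at_level("WARNING", logger="vwm.preprocess"):
            epochs = epoch_recording(rec, ev)
        assert len(epochs) == 1
        assert "dropped 1" in caplog.text


def make_epoch(signal, ch_names=("ch0",)):
    data = np.tile(signal, (len(ch_names), 1))[None]
    meta = pd.DataFrame({"epoch": [0]})
    return Epochs(data=data, fs=FS, ch_names=tuple(ch_names), metadata=meta)


class TestArtifactCriteria:
    n = 896
    t = np.arange(896) / FS

    def flags_of(self, signal):
        ep = detect_artifacts(make_epoch(signal), exclude_channels=())
        return ep.artifact_flags[0]

    def test_threshold_spike(self):
        sig = np.zeros(self.n)
        sig[100] = 100.0
        # an isolated 100 µV sample violates threshold (and the jump rule)
        assert "threshold" in self.flags_of(sig)

    def test_trend_ramp_only(self):
        # -75..+75 µV over 3.5 s: slope ~42.9 µV/s, peak 75 < 80,
        # per-sample step ~0.17 µV < 30
        sig = np.linspace(-75.0, 75.0, self.n)
        assert self.flags_of(sig) == {"trend"}

    def test_all_zero_epoch_is_flat(self):
        assert self.flags_of(np.zeros(self.n)) == {"trend"}

    def test_smooth_oscillation_clean(self):
        # 10 Hz at 40 µV: max successive-sample step ~9.8 µV < 30
        sig = 40.0 * np.sin(2 * np.pi * 10.0 * self.t)
        assert self.flags_of(sig) == set()

    def test_jump_step(self):
        sig = 10.0 * np.sin(2 * np.pi * 5.0 * self.t)
        sig[500:] += 40.0
        assert "jump" in self.flags_of(sig)

    def test_empty_epochs_rejected(self):
        ep = Epochs(data=np.empty((0, 1, 896)), fs=FS, ch_names=("ch0",),
                    metadata=pd.DataFrame())
        with pytest.raises(ValueError):
            detect_artifacts(ep)

    def test_blink_channel_excluded_by_default(self):
        sig = np.zeros((1, 2, self.n))
        sig[0, 0, 100] = 200.0          # huge spike, but on Fpz
        sig[0, 1] = 30 * np.sin(2 * np.pi * 8 * self.t)
        ep = Epochs(data=sig, fs=FS, ch_names=("Fpz", "Fz"),
                    metadata=pd.DataFrame({"epoch": [0]}))
        detect_artifacts(ep)
        assert ep.artifact_flags[0] == set()

    def test_monotone_in_criteria(self):
        """Loosening every threshold never flags more epochs."""
        epochs, _ = synth.make_artifact_epochs(60, 0.3, seed=5,
                                               channels=("Fz", "Pz"))
        strict = ArtifactCriteria()
        loose = ArtifactCriteria(amp_uV=120.0, slope_max_uV_s=60.0,
                                 slope_min_uV_s=0.1, jump_uV=45.0,
                                 flat_range_uV=0.5)
        n_strict = detect_artifacts(epochs, strict,
                                    exclude_channels=()).is_artifact.sum()
        n_loose = detect_artifacts(epochs, loose,
                                   exclude_channels=()).is_artifact.sum()
        assert n_loose <= n_strict

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            ArtifactCriteria(amp_uV=-1.0)


def test_detector_recall_and_false_positives():
    """Injected supra-threshold epochs are recovered; clean epochs pass."""
    from vwm.montage import EI_CHANNELS
    epochs, labels = synth.make_artifact_epochs(120, 0.25, seed=11,
                                                channels=EI_CHANNELS)
    detect_artifacts(epochs)
    found = epochs.is_artifact
    recall = (found & labels).sum() / labels.sum()
    fpr = (found & ~labels).sum() / (~labels).sum()
    assert recall >= 0.95
    assert fpr <= 0.05
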