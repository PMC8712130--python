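import numpy as np
import pytest

from vwm import protocol, synth


@pytest.fixture(scope="session")
def audio_plan():
    return protocol.generate_session("s01", "audio", seed=7)


@pytest.fixture(scope="session")
def quiet_profile():
    """A subject with no blinks, for tests that need artifact-free signal."""
    return synth.SubjectProfile(subject_id="s01", iaf_hz=10.0,
                                blink_rate_per_min=0.0)


@pytest.fixture(scope="session")
def simulated_session(quiet_profile, audio_plan):
    """One clean simulated session shared across preprocessing tests."""
    rec, gt = synth.simulate_recording(quiet_profile, audio_plan, seed=42)
    return rec, gt


def all_correct_responses(plan, rt_ms=500.0):
    """Ground-truth responses for every task trial of a plan."""
    out = []
    for blk in plan.task_blocks:
        for item in blk.items:
            out.append(protocol.TrialResponse(
                block_id=blk.block_id, item_index=item.index,
                response="target" if item.is_target else "nontarget",
                correct=True, rt_ms=rt_ms))
    return out
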