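"""Generate a dual-modality n-back session and score simulated responses.

Builds the audio session plan for one subject (baseline block + six task
blocks, two per load level, randomized order), then scores a perfect
responder to show the behavioral measures (ACC, mean correct RT, IES).
"""

from vwm import protocol

plan = protocol.generate_session("s01", "audio", seed=7)

print("blocks (in presentation order):")
for blk in plan.blocks:
    targets = sum(it.is_target for it in blk.items)
    level = "-" if blk.level is None else blk.level
    print(f"  {blk.block_id:<9} kind={blk.kind:<8} level={level} "
          f"items={len(blk.items)} targets={targets} "
          f"start={blk.start_ms / 1000:7.1f} s")

# a perfect responder: presses the correct key on every trial at 500 ms
responses = [
    protocol.TrialResponse(b.block_id, it.index,
                           "target" if it.is_target else "nontarget",
                           correct=True, rt_ms=500.0)
    for b in plan.task_blocks for it in b.items
]
for level in (0, 1, 2):
    sc = protocol.score_condition(responses, plan, level)
    print(f"level {level}: ACC={sc.acc:.2f}  RT={sc.mean_rt_correct_ms:.0f} ms"
          f"  IES={sc.ies_ms:.0f} ms")
# ACC 1.0 means every target/nontarget judgement was right; with no errors
# the inverse efficiency score equals the mean RT.
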