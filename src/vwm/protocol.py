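"""Dual-modality verbal n-back task: session generation and behavioral scoring.

The task presents sequences of spoken (audio) or displayed (video) consonants.
A stimulus is a *target* when it matches the one presented ``n`` positions
earlier; in the 0-back condition the fixed probe letter ``X`` is the target.
Each modality session opens with a passive 21-item baseline block (the seven
consonants, three times each, in random order) followed by six 21-stimulus
task blocks, two per load level, in randomized order.  Responses are
two-alternative forced choice on every stimulus; reaction times are measured
from stimulus offset.

Scoring produces per-condition accuracy (ACC), mean correct reaction time
(RT), proportion of errors (PE = 1 - ACC) and the inverse efficiency score
IES = RT / (1 - PE), a speed-accuracy composite interpretable as the RT
corrected for errors committed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Consonant stimulus alphabet (vowels excluded to discourage chunking).
ALPHABET: tuple[str, ...] = ("c", "g", "k", "p", "q", "t", "v")

#: Probe letter serving as the target in the 0-back condition only.
PROBE_LETTER = "X"

STIM_DURATION_MS = 500.0

#: Offset-to-next-onset interstimulus intervals per modality (task blocks).
ISI_MS = {"audio": 2500.0, "video": 3000.0}

#: The baseline block uses a 3000 ms ISI in both modalities.
BASELINE_ISI_MS = 3000.0

N_ITEMS_PER_BLOCK = 21
#: 30% of 21 is not an integer; the target count is fixed at 6 (28.6%) so
#: that every task block is exactly comparable.
N_TARGETS_PER_BLOCK = 6
LEVELS = (0, 1, 2)
MODALITIES = ("audio", "video")


@dataclass(frozen=True)
class StimulusItem:
    index: int
    letter: str
    onset_ms: float
    duration_ms: float
    is_target: bool


@dataclass(frozen=True)
class Block:
    block_id: str
    kind: str                      # "baseline" | "task"
    level: Optional[int]           # None for baseline blocks
    modality: str
    items: tuple[StimulusItem, ...]
    start_ms: float = 0.0          # block onset within the session timeline

    @property
    def duration_ms(self) -> float:
        last = self.items[-1]
        isi = BASELINE_ISI_MS if self.kind == "baseline" else ISI_MS[self.modality]
        return last.onset_ms + last.duration_ms + isi


@dataclass(frozen=True)
class SessionPlan:
    subject_id: str
    modality: str
    baseline_block: Block
    task_blocks: tuple[Block, ...]
    block_order_seed: int

    @property
    def blocks(self) -> tuple[Block, ...]:
        return (self.baseline_block,) + self.task_blocks

    @property
    def duration_ms(self) -> float:
        last = self.blocks[-1]
        return last.start_ms + last.duration_ms


@dataclass(frozen=True)
class TrialResponse:
    block_id: str
    item_index: int
    response: str                  # "target" | "nontarget" | "none"
    correct: bool
    rt_ms: Optional[float] = None  # from stimulus offset; absent iff no response


@dataclass(frozen=True)
class ConditionScore:
    subject_id: str
    modality: str
    level: int
    acc: float
    mean_rt_correct_ms: Optional[float]
    pe: float
    ies_ms: Optional[float]


def label_targets(letters: Sequence[str], level: int) -> list[bool]:
    """Flag targets in a letter sequence under the given n-back level.

    0-back: the probe letter ``X`` is the target.  1-back: a letter matching
    the immediately preceding one.  2-back: a letter matching the one two
    positions earlier.  The first ``level`` positions can never be targets.
    """
    if level not in LEVELS:
        raise ValueError(f"invalid n-back level {level!r}; valid levels are {LEVELS}")
    letters = list(letters)
    if level == 0:
        return [let == PROBE_LETTER for let in letters]
    return [i >= level and letters[i] == letters[i - level] for i in range(len(letters))]


def _soa_ms(modality: str, kind: str) -> float:
    isi = BASELINE_ISI_MS if kind == "baseline" else ISI_MS[modality]
    return STIM_DURATION_MS + isi


def _task_letters(level: int, rng: np.random.Generator,
                  n_items: int, n_targets: int) -> tuple[list[str], list[bool]]:
    """Draw a task-block letter sequence with an exact target count."""
    if level == 0:
        # Targets are probe letters at seed-chosen positions; non-targets
        # come from the consonant alphabet (which never contains "X").
        positions = rng.choice(n_items, size=n_targets, replace=False)
        flags = np.zeros(n_items, dtype=bool)
        flags[positions] = True
        letters = [PROBE_LETTER if flags[i] else str(rng.choice(ALPHABET))
                   for i in range(n_items)]
        return letters, flags.tolist()
    # Levels 1/2: pick admissible target positions (i >= level), copy the
    # letter from i-level there, and fill the rest avoiding accidental
    # repeats at lag `level`.  The probe letter is excluded entirely.
    positions = rng.choice(np.arange(level, n_items), size=n_targets, replace=False)
    flags = np.zeros(n_items, dtype=bool)
    flags[positions] = True
    letters: list[Optional[str]] = [None] * n_items
    for i in range(n_items):
        if flags[i]:
            letters[i] = letters[i - level]
        else:
            choices = [c for c in ALPHABET
                       if i < level or c != letters[i - level]]
            letters[i] = str(rng.choice(choices))
    return letters, flags.tolist()  # type: ignore[return-value]


def generate_block(level: Optional[int], modality: str, kind: str,
                   seed: int | np.random.Generator,
                   block_id: str = "block", start_ms: float = 0.0,
                   n_targets: int = N_TARGETS_PER_BLOCK) -> Block:
    """Generate one 21-stimulus block (task or passive baseline).

    Task blocks contain exactly ``n_targets`` targets placed at seed-chosen
    admissible positions; baseline blocks repeat each of the seven consonants
    three times in random order with no targets.  Stimulus onsets follow the
    modality's offset-to-onset ISI (audio 2500 ms, video 3000 ms; baseline
    3000 ms in both modalities).
    """
    if modality not in MODALITIES:
        raise ValueError(f"invalid modality {modality!r}; valid: {MODALITIES}")
    if kind not in ("baseline", "task"):
        raise ValueError(f"invalid block kind {kind!r}; valid: baseline, task")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if kind == "baseline":
        letters = list(ALPHABET) * 3
        rng.shuffle(letters)
        flags = [False] * len(letters)
        level = None
    else:
        if level not in LEVELS:
            raise ValueError(f"invalid n-back level {level!r}; valid levels are {LEVELS}")
        letters, flags = _task_letters(level, rng, N_ITEMS_PER_BLOCK, n_targets)
        assert flags == label_targets(letters, level)

    soa = _soa_ms(modality, kind)
    items = tuple(
        StimulusItem(index=i, letter=let, onset_ms=i * soa,
                     duration_ms=STIM_DURATION_MS, is_target=flag)
        for i, (let, flag) in enumerate(zip(letters, flags))
    )
    return Block(block_id=block_id, kind=kind, level=level, modality=modality,
                 items=items, start_ms=start_ms)


def generate_session(subject_id: str, modality: str, seed: int,
                     inter_block_gap_ms: float = 5000.0) -> SessionPlan:
    """Generate a full single-modality session plan.

    The session comprises the passive baseline block followed by six task
    blocks — two per load level — in a seed-determined random order, with a
    short rest gap between blocks.  Identical (subject, modality, seed)
    always yields the identical plan.
    """
    if modality not in MODALITIES:
        raise ValueError(f"invalid modality {modality!r}; valid: {MODALITIES}")
    rng = np.random.default_rng(seed)
    levels = np.repeat(LEVELS, 2)
    rng.shuffle(levels)

    t = 0.0
    baseline = generate_block(None, modality, "baseline", rng,
                              block_id="baseline", start_ms=t)
    t += baseline.duration_ms + inter_block_gap_ms
    task_blocks = []
    for k, lvl in enumerate(levels, start=1):
        blk = generate_block(int(lvl), modality, "task", rng,
                             block_id=f"task{k}", start_ms=t)
        task_blocks.append(blk)
        t += blk.duration_ms + inter_block_gap_ms
    return SessionPlan(subject_id=subject_id, modality=modality,
                       baseline_block=baseline, task_blocks=tuple(task_blocks),
                       block_order_seed=seed)


def inverse_efficiency(mean_rt_correct_ms: float, pe: float) -> float:
    """Inverse efficiency score IES = RT / (1 - PE), in ms."""
    if not 0.0 <= pe < 1.0:
        raise ValueError(f"proportion of errors must lie in [0, 1); got {pe}")
    if mean_rt_correct_ms <= 0:
        raise ValueError("mean correct RT must be positive")
    return mean_rt_correct_ms / (1.0 - pe)


def score_condition(responses: Iterable[TrialResponse], plan: SessionPlan,
                    level: int) -> ConditionScore:
    """Score one load level of a session (both blocks of that level).

    Every planned trial is expected to carry a response; trials with no
    matching response are scored incorrect.  Mean RT averages only over
    correct responses.  With zero correct responses the IES is undefined and
    reported as missing.
    """
    if level not in LEVELS:
        raise ValueError(f"invalid n-back level {level!r}; valid levels are {LEVELS}")
    by_key = {(r.block_id, r.item_index): r for r in responses}
    n_total = 0
    n_correct = 0
    rts: list[float] = []
    for blk in plan.task_blocks:
        if blk.level != level:
            continue
        for item in blk.items:
            n_total += 1
            resp = by_key.get((blk.block_id, item.index))
            if resp is None or resp.response == "none" or not resp.correct:
                continue
            n_correct += 1
            if resp.rt_ms is not None:
                rts.append(resp.rt_ms)
    if n_total == 0:
        raise ValueError(f"plan contains no task blocks at level {level}")
    acc = n_correct / n_total
    pe = 1.0 - acc
    if n_correct == 0 or not rts:
        warnings.warn(f"no correct responses at level {level}; IES undefined")
        return ConditionScore(plan.subject_id, plan.modality, level,
                              acc=acc, mean_rt_correct_ms=None, pe=pe, ies_ms=None)
    mean_rt = float(np.mean(rts))
    return ConditionScore(plan.subject_id, plan.modality, level, acc=acc,
                          mean_rt_correct_ms=mean_rt, pe=pe,
                          ies_ms=inverse_efficiency(mean_rt, pe))


# ---------------------------------------------------------------------------
# Tabular (TSV) serialization

EVENT_COLUMNS = ["block_id", "kind", "level", "modality", "item_index", "letter",
                 "onset_ms", "duration_ms", "is_target", "response", "correct",
                 "rt_ms"]


def session_table(plan: SessionPlan,
                  responses: Optional[Iterable[TrialResponse]] = None) -> pd.DataFrame:
    """Flatten a session plan (and optional responses) to one row per stimulus.

    ``onset_ms`` is absolute within the session timeline (block start plus
    within-block onset).
    """
    by_key = {}
    if responses is not None:
        by_key = {(r.block_id, r.item_index): r for r in responses}
    rows = []
    for blk in plan.blocks:
        for item in blk.items:
            resp = by_key.get((blk.block_id, item.index))
            rows.append({
                "block_id": blk.block_id,
                "kind": blk.kind,
                "level": -1 if blk.level is None else blk.level,
                "modality": blk.modality,
                "item_index": item.index,
                "letter": item.letter,
                "onset_ms": blk.start_ms + item.onset_ms,
                "duration_ms": item.duration_ms,
                "is_target": item.is_target,
                "response": resp.response if resp else "",
                "correct": resp.correct if resp else "",
                "rt_ms": resp.rt_ms if resp and resp.rt_ms is not None else "",
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_session_tsv(path, plan: SessionPlan,
                      responses: Optional[Iterable[TrialResponse]] = None) -> None:
    session_table(plan, responses).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_target"] = df["is_target"].astype(bool)
    return df
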