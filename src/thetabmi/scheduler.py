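"""Experimental-design state machine for coherence-contingent trial scheduling.

Sessions are organized in 10-trial blocks.  On the delayed-alternation (DA)
task each block holds 1 high-coherence, 1 low-coherence, 1 yoked-high,
1 yoked-low and 6 random-delay trials; on conditional discrimination (CD)
each block holds 4 high, 4 yoked-high and 2 random trials.  Experimental
(detector-triggered) trials must precede their yoked partners within the
block, because a yoked trial replays the exact delay its partner logged.
If a detector trial times out, the trial starts at the timeout and the
block's pending yoked partner is converted to a random-delay trial (with a
provenance flag), since there is no logged delay to replay.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

TrialType = Literal["high", "low", "yoked_high", "yoked_low", "random"]

YOKE_OF = {"high": "yoked_high", "low": "yoked_low"}
PARTNER_OF = {v: k for k, v in YOKE_OF.items()}

#: Simulated-outcome hook defaults: probability of a correct choice per trial
#: type.  Chosen to mirror the qualitative effect the interface is built to
#: detect (choices presented during strong theta coherence succeed more often
#: than delay-matched controls); they are a knob, not an estimate.
DEFAULT_P_CORRECT: dict[str, float] = {
    "high": 0.90,
    "low": 0.70,
    "yoked_high": 0.75,
    "yoked_low": 0.75,
    "random": 0.75,
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Task protocol: block composition, delay range, timeout, CD minimum wait."""

    name: Literal["delayed_alternation", "conditional_discrimination"]
    block_size: int = 10
    composition: dict[str, int] = field(default_factory=dict)
    random_delay_range: tuple[float, float] = (5.0, 30.0)
    timeout: float = 30.0
    cd_min_wait: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if sum(self.composition.values()) != self.block_size:
            raise ValueError("composition counts must sum to block_size")
        lo, hi = self.random_delay_range
        if not lo < hi:
            raise ValueError("delay range low must be below high")

    @classmethod
    def delayed_alternation(cls) -> "ProtocolSpec":
        return cls(
            name="delayed_alternation",
            composition={"high": 1, "low": 1, "yoked_high": 1, "yoked_low": 1, "random": 6},
            random_delay_range=(5.0, 30.0),
            timeout=30.0,
        )

    @classmethod
    def conditional_discrimination(cls) -> "ProtocolSpec":
        return cls(
            name="conditional_discrimination",
            composition={"high": 4, "yoked_high": 4, "random": 2},
            random_delay_range=(5.0, 30.0),
            timeout=20.0,
            cd_min_wait=(3.5, 5.0),
        )

    @classmethod
    def by_name(cls, name: str) -> "ProtocolSpec":
        if name in ("delayed_alternation", "da"):
            return cls.delayed_alternation()
        if name in ("conditional_discrimination", "cd"):
            return cls.conditional_discrimination()
        raise ValueError(f"unknown protocol {name!r}")


@dataclass
class TrialRecord:
    """One behavioral trial as the scheduler ran it."""

    index: int
    block: int
    type: str
    delay: float
    trigger_cause: Literal["threshold", "timeout", "clock"]
    outcome: Literal["correct", "error", "excluded"] = "error"
    paired_with: int | None = None
    was_yoked: bool = False
    turn: Literal["L", "R"] | None = None

    @property
    def excluded(self) -> bool:
        return self.outcome == "excluded"


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "block": [r.block for r in records],
            "type": [r.type for r in records],
            "delay": [r.delay for r in records],
            "trigger_cause": [r.trigger_cause for r in records],
            "outcome": [r.outcome for r in records],
            "paired_with": [r.paired_with for r in records],
            "was_yoked": [r.was_yoked for r in records],
            "turn": [r.turn for r in records],
        }
    )


def _admissible(order: Sequence[str]) -> bool:
    """Every prefix holds at least as many experimental trials of a type as
    yoked partners of that type (k-th yoked follows k-th experimental)."""
    counts = {t: 0 for t in ("high", "low", "yoked_high", "yoked_low")}
    for t in order:
        if t in counts:
            counts[t] += 1
        if counts["yoked_high"] > counts["high"] or counts["yoked_low"] > counts["low"]:
            return False
    return True


def plan_block(protocol: ProtocolSpec, rng: np.random.Generator) -> list[str]:
    """Pseudo-random trial-type order for one block.

    Uniform over admissible orderings by rejection sampling: shuffle the
    block composition until every yoked trial follows its matched
    experimental trial.
    """
    pool: list[str] = []
    for t, n in protocol.composition.items():
        pool.extend([t] * n)
    if len(pool) != protocol.block_size:
        raise ValueError("composition does not match block size")
    order = list(pool)
    while True:
        rng.shuffle(order)
        if _admissible(order):
            return list(order)


@dataclass
class SessionState:
    """Mutable bookkeeping across trials: logged delays and pending plan."""

    trial_index: int = 0
    block_index: int = 0
    logged: dict[str, deque] = field(
        default_factory=lambda: {"high": deque(), "low": deque()}
    )
    plan: list[dict] = field(default_factory=list)  # pending entries of current block


Detector = Callable[[str, float], tuple[float, str]]


def _draw_min_wait(protocol: ProtocolSpec, rng: np.random.Generator) -> float:
    if protocol.cd_min_wait is None:
        return 0.0
    lo, hi = protocol.cd_min_wait
    return float(rng.uniform(lo, hi))


def run_trial(
    entry: dict,
    protocol: ProtocolSpec,
    detector: Detector,
    state: SessionState,
    rng: np.random.Generator,
) -> TrialRecord:
    """Execute one planned entry and update session state.

    ``entry`` is a dict with keys ``type`` and ``was_yoked``; detector trials
    call ``detector(mode, timeout) -> (delay, cause)``.  On a detector
    timeout the earliest pending yoked partner in ``state.plan`` is mutated
    in place to a random-delay trial.
    """
    ttype = entry["type"]
    idx = state.trial_index
    min_wait = _draw_min_wait(protocol, rng)
    if ttype in ("high", "low"):
        delay, cause = detector(ttype, protocol.timeout)
        delay = max(float(delay), min_wait)
        if cause == "timeout":
            for pending in state.plan:
                if pending["type"] == YOKE_OF[ttype]:
                    pending["type"] = "random"
                    pending["was_yoked"] = True
                    break
        else:
            state.logged[ttype].append((delay, idx))
        record = TrialRecord(idx, state.block_index, ttype, delay, cause)
    elif ttype in ("yoked_high", "yoked_low"):
        queue = state.logged[PARTNER_OF[ttype]]
        if not queue:
            raise RuntimeError(f"yoked trial {ttype} has no logged partner delay")
        delay, partner = queue.popleft()
        record = TrialRecord(idx, state.block_index, ttype, delay, "clock", paired_with=partner)
    elif ttype == "random":
        lo, hi = protocol.random_delay_range
        delay = max(float(rng.uniform(lo, hi)), min_wait)
        record = TrialRecord(
            idx, state.block_index, ttype, delay, "clock", was_yoked=entry.get("was_yoked", False)
        )
    else:
        raise ValueError(f"unknown trial type {ttype!r}")
    state.trial_index += 1
    return record


def _default_outcome(
    record: TrialRecord,
    prev_turn: str | None,
    rng: np.random.Generator,
    p_correct: dict[str, float],
    protocol: ProtocolSpec,
) -> tuple[str, str]:
    """Simulated-outcome hook standing in for the rat.

    Returns (outcome, turn).  On DA the correct turn is the alternation of
    the previous turn; on CD a per-trial cue dictates the correct turn.
    """
    correct = rng.random() < p_correct.get(record.type, 0.75)
    if protocol.name == "delayed_alternation":
        correct_turn = "R" if prev_turn in (None, "L") else "L"
    else:
        correct_turn = "L" if rng.random() < 0.5 else "R"
    turn = correct_turn if correct else ("L" if correct_turn == "R" else "R")
    return ("correct" if correct else "error"), turn


def run_session(
    protocol: ProtocolSpec,
    n_blocks: int,
    detector: Detector,
    rng: np.random.Generator,
    p_correct: dict[str, float] | None = None,
    outcome_hook: Callable[..., tuple[str, str]] | None = None,
) -> list[TrialRecord]:
    """Run ``n_blocks`` planned blocks through the detector and outcome hook."""
    p_correct = dict(DEFAULT_P_CORRECT if p_correct is None else p_correct)
    state = SessionState()
    records: list[TrialRecord] = []
    prev_turn: str | None = None
    for b in range(n_blocks):
        state.block_index = b
        state.plan = [{"type": t, "was_yoked": False} for t in plan_block(protocol, rng)]
        while state.plan:
            entry = state.plan.pop(0)
            rec = run_trial(entry, protocol, detector, state, rng)
            hook = outcome_hook or _default_outcome
            rec.outcome, rec.turn = hook(rec, prev_turn, rng, p_correct, protocol)
            prev_turn = rec.turn
            records.append(rec)
    return records


@dataclass
class InclusionReport:
    """Session-level inclusion screen."""

    performance: float
    alternation: float
    n_experimental: int
    include: bool


def screen_session(records: Sequence[TrialRecord], protocol: ProtocolSpec) -> InclusionReport:
    """Apply the session inclusion screen.

    CD sessions require performance strictly above 70%, alternation strictly
    below 70%, and at least three experimental trials; DA sessions require
    performance of at least 70%.
    """
    if not records:
        raise ValueError("empty record list")
    kept = [r for r in records if not r.excluded]
    if not kept:
        raise ValueError("all trials excluded")
    performance = float(np.mean([r.outcome == "correct" for r in kept]))
    turns = [r.turn for r in kept if r.turn is not None]
    if len(turns) >= 2:
        alternation = float(
            np.mean([a != b for a, b in zip(turns[:-1], turns[1:])])
        )
    else:
        alternation = 0.0
    exp_types = ("high", "low") if protocol.name == "delayed_alternation" else ("high",)
    n_exp = sum(r.type in exp_types and r.trigger_cause == "threshold" for r in kept)
    if protocol.name == "conditional_discrimination":
        include = performance > 0.70 and alternation < 0.70 and n_exp >= 3
    else:
        include = performance >= 0.70
    return InclusionReport(performance, alternation, n_exp, include)


def summarize_choice_accuracy(
    records: Sequence[TrialRecord], types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-type choice accuracy over non-excluded trials, with paired
    high-vs-yoked-high and low-vs-yoked-low differences attached as attrs."""
    kept = [r for r in records if not r.excluded]
    if types is None:
        types = sorted({r.type for r in kept})
    rows = []
    acc: dict[str, float] = {}
    for t in types:
        sel = [r for r in kept if r.type == t]
        if not sel:
            raise ValueError(f"requested type {t!r} absent from records")
        a = float(np.mean([r.outcome == "correct" for r in sel]))
        acc[t] = a
        rows.append({"type": t, "n_trials": len(sel), "accuracy": a})
    table = pd.DataFrame(rows).set_index("type")
    diffs = {}
    for exp, yoked in YOKE_OF.items():
        if exp in acc and yoked in acc:
            diffs[f"{exp}_minus_{yoked}"] = acc[exp] - acc[yoked]
    table.attrs["paired_differences"] = diffs
    return table
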