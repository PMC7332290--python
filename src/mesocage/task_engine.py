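"""Staged go/no-go lick-task engine.

Implements the training protocol of the automated head-fixation cage as a
pure, seedable state machine: stage 1 dispenses rewards for showing up,
stage 2 trains lick withholding, stage 3 cues licking, and stage 4 runs the
full go/no-go discrimination with a self-timed delay between cue and
permitted response.  Hardware is abstracted behind an agent interface; the
engine emits the same :class:`~mesocage.eventlog.EventRecord` stream the
physical cage would print to its text files.

Outcome codes (go trials): +2 correct, -2 no/late response, -4 early lick
during the delay.  No-go trials: +1 correct rejection, -1 response-window
lick, -3 early lick.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .eventlog import EventRecord

__all__ = [
    "TaskConfig",
    "LickPolicy",
    "classify_trial",
    "draw_withhold",
    "run_session",
    "advance_stage",
    "weight_supplement_flag",
]


@dataclass(frozen=True)
class TaskConfig:
    """All tunable task parameters for one training stage.

    Defaults reflect a fully-trained stage-4 cage: 2 s lick withhold with a
    0.5 s mean random addition, 0.9 s self-timed delay, 1.25 s response
    window, reward delivered at delay + response_window after the cue,
    ~30 s fixations at 75% probability.
    """

    stage: int = 4
    withhold_base: float = 2.0  # s, 0.5-2 over training
    withhold_jitter_mean: float = 0.5  # s, mean of the random addition
    delay: float = 0.9  # s, 0.3-1.1 over training
    response_window: float = 1.25  # s
    headfix_probability: float = 0.75  # never 1.0 (safety)
    fix_duration: float = 30.0  # s, 19-45 typical
    skedaddle_time: float = 2.0  # s to un-break the beam and avoid re-fix
    nogo_fraction: float = 0.3  # i.i.d. Bernoulli per trial in stage 4
    entrance_reward_valve_ms: float = 200.0  # 100-500 ms valve opening
    alert_threshold: float = 700.0  # s in tube before a stranded-mouse alert
    inter_trial_gap: float = 0.5  # s between outcome and next withhold
    cue_go: str = "continuous_500ms"  # 500 ms continuous vibration
    cue_nogo: str = "pulsed_3x200ms_100ms"  # pulsed vibration triplet
    # daily increments used by advance_stage
    delay_increment: float = 0.075  # s/day (50-100 ms)
    withhold_increment: float = 0.1  # s/day toward 2 s
    delay_cap: float = 1.1
    withhold_cap: float = 2.0

    def __post_init__(self) -> None:
        if not 1 <= self.stage <= 4:
            raise ValueError("stage must be 1-4")
        if not 0.0 <= self.headfix_probability < 1.0:
            raise ValueError("headfix_probability must be in [0, 1)")
        if self.response_window <= 0:
            raise ValueError("response_window must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if not 0.0 <= self.nogo_fraction <= 1.0:
            raise ValueError("nogo_fraction must be in [0, 1]")


class LickPolicy(Protocol):
    """Agent callback: lick times for one trial, conditioned on task phase.

    Must be pure given the RNG so whole simulations are deterministic under
    a seed.
    """

    def __call__(
        self,
        cue_kind: str,
        delay: float,
        response_window: float,
        rng: np.random.Generator,
    ) -> Sequence[float]: ...


def classify_trial(
    cue_kind: str,
    delay: float,
    response_window: float,
    licks: Sequence[float],
) -> int:
    """Score one trial from its relative lick times.

    Window conventions: a first lick strictly before ``delay`` (including
    t = 0 exactly) is an early lick; the boundary at ``delay`` and at
    ``delay + response_window`` falls into the response window.
    """
    if cue_kind not in ("go", "nogo"):
        raise ValueError(f"cue_kind must be 'go' or 'nogo', got {cue_kind!r}")
    if delay < 0 or response_window <= 0:
        raise ValueError("invalid trial timing")
    licks = sorted(licks)
    if licks and licks[0] < 0:
        raise ValueError("negative lick time relative to cue")
    first = licks[0] if licks else None
    if cue_kind == "go":
        if first is None:
            return -2
        if first < delay:
            return -4
        if first <= delay + response_window:
            return 2
        return -2
    # no-go
    if first is None:
        return 1
    if first < delay:
        return -3
    if first <= delay + response_window:
        return -1
    return 1


def draw_withhold(config: TaskConfig, rng: np.random.Generator) -> float:
    """Draw a lick-withhold duration: base + exponential jitter.

    The random addition is exponential with the configured mean — the
    memoryless choice, so mice cannot exploit internal timing of the cue.
    """
    if config.withhold_jitter_mean < 0:
        raise ValueError("withhold_jitter_mean must be >= 0")
    if config.withhold_jitter_mean == 0:
        return config.withhold_base
    return config.withhold_base + rng.exponential(config.withhold_jitter_mean)


def _cue_payload(withhold: float, delay: float, window: float) -> str:
    return f"{withhold:.6f}|{delay:.6f}|{window:.6f}"


def run_session(
    tag: str,
    entry_time: float,
    lick_policy: LickPolicy,
    config: TaskConfig,
    rng: np.random.Generator,
    force_fixed: bool | None = None,
) -> list[EventRecord]:
    """Run one chamber visit and return the event stream it prints.

    Sequence: entry -> entrance reward -> Bernoulli(headfix_probability)
    fixation -> imaging LED on 3 s after fixation -> repeated
    withhold/cue/delay/response trials until ``fix_duration`` elapses (the
    last trial is allowed to finish) -> LED off 3 s before release ->
    release -> exit.  Rewards for +2 outcomes are delivered at
    delay + response_window after the cue.  A feedback tone is emitted for
    early licks (-4/-3) and, in stage 2, for inter-lick intervals < 1 s.
    """
    events: list[EventRecord] = []
    t = float(entry_time)
    events.append(EventRecord(t, tag, "entry"))
    t += 0.5
    events.append(
        EventRecord(t, tag, "reward_entrance", f"{config.entrance_reward_valve_ms:.0f}")
    )

    fixed = bool(rng.random() < config.headfix_probability) if force_fixed is None else force_fixed
    t += 1.5  # approach to the beam at the tube end
    fix_time = t
    if fixed:
        events.append(EventRecord(fix_time, tag, "fix_tight"))
    led_on = fix_time + 3.0
    events.append(EventRecord(led_on, tag, "BrainLEDON"))

    t = led_on
    last_lick: float | None = None
    if config.stage == 1:
        # stage 1: regular rewards for merely being at the imaging position
        while t - fix_time < config.fix_duration:
            t += 5.0
            events.append(EventRecord(t, tag, "reward_task"))
    else:
        while True:
            withhold = draw_withhold(config, rng)
            cue_time = t + withhold
            if cue_time - fix_time >= config.fix_duration:
                break
            if config.stage == 4 and rng.random() < config.nogo_fraction:
                cue_kind = "nogo"
            else:
                cue_kind = "go"
            delay = config.delay if config.stage >= 3 else 0.0
            window = config.response_window
            events.append(
                EventRecord(
                    cue_time,
                    tag,
                    "cue_go" if cue_kind == "go" else "cue_nogo",
                    _cue_payload(withhold, delay, window),
                )
            )
            licks = sorted(float(x) for x in lick_policy(cue_kind, delay, window, rng))
            for lk in licks:
                events.append(EventRecord(cue_time + lk, tag, "lick"))
                if (
                    config.stage == 2
                    and last_lick is not None
                    and cue_time + lk - last_lick < 1.0
                ):
                    events.append(EventRecord(cue_time + lk, tag, "tone_feedback"))
                last_lick = cue_time + lk
            outcome = classify_trial(cue_kind, delay, window, licks)
            outcome_time = cue_time + delay + window
            if outcome in (-4, -3):
                first_early = next(lk for lk in licks if lk < delay)
                events.append(EventRecord(cue_time + first_early, tag, "tone_feedback"))
            events.append(EventRecord(outcome_time, tag, "outcome", str(outcome)))
            if outcome == 2:
                events.append(EventRecord(outcome_time, tag, "reward_task"))
            t = outcome_time + config.inter_trial_gap

    led_off = max(t, led_on + 1.0 / 30.0) + 3.0
    events.append(EventRecord(led_off, tag, "BrainLEDOFF"))
    release_time = led_off + 3.0
    if fixed:
        events.append(EventRecord(release_time, tag, "fix_release"))
    if release_time - entry_time > config.alert_threshold:
        events.append(EventRecord(release_time, tag, "alert", f"{release_time - entry_time:.1f}"))
    events.append(EventRecord(release_time + 1.0, tag, "exit"))
    events.sort(key=lambda r: r.timestamp)
    return events


def advance_stage(history: dict[int, int], config: TaskConfig) -> TaskConfig:
    """Daily protocol advancement from a mouse's outcome tallies.

    The delay period grows by the configured daily increment (50-100 ms)
    up to its 1.1 s cap; the withhold base grows toward 2 s.  The stage
    advances from 3 to 4 once the mouse is reliably rewarded (>= 60% of
    scored go trials correct, >= 20 trials); per-mouse configs are
    supported by simply carrying per-mouse history.
    """
    if not history:
        raise ValueError("history must be nonempty")
    new_delay = min(config.delay + config.delay_increment, config.delay_cap)
    new_withhold = min(config.withhold_base + config.withhold_increment, config.withhold_cap)
    stage = config.stage
    if stage == 3:
        n_go = history.get(2, 0) + history.get(-2, 0) + history.get(-4, 0)
        if n_go >= 20 and history.get(2, 0) / n_go >= 0.6:
            stage = 4
    elif stage < 3:
        total = sum(history.values())
        if total >= 20:
            stage += 1
    return replace(config, stage=stage, delay=new_delay, withhold_base=new_withhold)


def weight_supplement_flag(current: float, baseline: float) -> bool:
    """Flag a mouse for water supplementation by the 15% weight-loss rule.

    Mice must stay *above* 85% of their post-restriction baseline, so a
    weight at exactly 0.85 x baseline is already flagged.
    """
    if current <= 0 or baseline <= 0:
        raise ValueError("weights must be positive")
    return current <= 0.85 * baseline
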