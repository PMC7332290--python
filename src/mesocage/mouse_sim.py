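"""Synthetic colonies and synthetic two-channel movies with ground truth.

The generators emulate the statistical structure of a group-housed
head-fixation cage — clustered, diurnally biased chamber entries,
per-mouse participation heterogeneity, stage-dependent licking policies
with settable hit/false-alarm rates — and of the mesoscale movies —
task-locked region-specific calcium transients, a shared multiplicative
hemodynamic artifact in both channels, and additive sensor noise.  Every
output is deterministic under a seed and ships a ground-truth sidecar so
each downstream stage can be tested without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eventlog import EventRecord, EventStore, Trial
from .imaging import ATLAS, ImagingStack, RoiSpec
from .task_engine import TaskConfig, run_session

__all__ = [
    "AgentParams",
    "StochasticLicker",
    "ColonyTruth",
    "simulate_colony",
    "RegionDrive",
    "SyntheticMovieConfig",
    "MovieTruth",
    "simulate_movie",
    "hour_of_day",
]

SECONDS_PER_DAY = 86400.0


def hour_of_day(timestamp: float) -> float:
    """Clock hour for a facility timestamp (day 0 starts at midnight)."""
    return (timestamp / 3600.0) % 24.0


@dataclass(frozen=True)
class AgentParams:
    """Behavioral phenotype of one simulated mouse.

    ``entry_rate`` is the mean chamber-entry rate in events/hour averaged
    over 24 h; entries arrive in bursts (a mouse that has just been
    released tends to re-enter within seconds) riding on a two-level
    day/night intensity.  ``participation`` is the probability that an
    entry proceeds to the imaging position (beam break); ``hit_rate`` and
    ``false_alarm_rate`` parameterize the stage-4 licking policy, and
    ``early_rate`` the fraction of trials with impulsive during-delay
    licks.
    """

    entry_rate: float = 1.5  # entries/hour, 24 h average
    night_bias: float = 0.69  # fraction of entries in the dark phase
    cluster_burst_mean: float = 3.0  # mean entries per burst (geometric)
    within_burst_gap_mean: float = 8.0  # s from release to re-entry
    participation: float = 0.8
    hit_rate: float = 0.75
    false_alarm_rate: float = 0.3
    early_rate: float = 0.1
    lick_rate: float = 6.0  # Hz within a licking bout
    bout_duration: float = 1.0  # s of licking once started

    def __post_init__(self) -> None:
        for name in ("night_bias", "participation", "hit_rate", "false_alarm_rate", "early_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.entry_rate < 0 or self.lick_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class StochasticLicker:
    """Lick policy implementing hit/false-alarm/early-lick probabilities.

    On go trials the agent responds inside the response window with
    probability ``hit_rate``; on no-go trials it fails to withhold with
    probability ``false_alarm_rate``.  Independently, with probability
    ``early_rate`` the first lick lands during the delay instead (scored
    -4/-3 and excluded from d' analysis).  A response is a bout of licks at
    ``lick_rate``.
    """

    params: AgentParams
    day_hit_rate: float | None = None  # optional diurnal performance split

    def __call__(
        self,
        cue_kind: str,
        delay: float,
        response_window: float,
        rng: np.random.Generator,
        hour: float | None = None,
    ) -> list[float]:
        p = self.params
        if delay > 0 and rng.random() < p.early_rate:
            first = rng.uniform(0.05, max(delay - 0.05, 0.06))
            return self._bout(first, rng)
        hit = p.hit_rate
        if self.day_hit_rate is not None and hour is not None and 7.0 <= hour < 19.0:
            hit = self.day_hit_rate
        respond = rng.random() < (hit if cue_kind == "go" else p.false_alarm_rate)
        if not respond:
            return []
        first = delay + rng.uniform(0.05, 0.8 * response_window)
        return self._bout(first, rng)

    def _bout(self, first: float, rng: np.random.Generator) -> list[float]:
        p = self.params
        n = max(1, int(round(p.bout_duration * p.lick_rate)))
        gaps = rng.exponential(1.0 / p.lick_rate, size=n - 1) if n > 1 else np.empty(0)
        return [first, *np.cumsum(gaps) + first][: n]


@dataclass
class ColonyTruth:
    """Ground-truth sidecar for a simulated colony."""

    sessions: pd.DataFrame  # tag, start, end, fixed, n_trials, night
    outcomes: pd.DataFrame  # tag, code, count
    per_mouse: pd.DataFrame  # tag, n_entries, n_sessions, night_fraction

    def session_count(self, tag: str | None = None) -> int:
        df = self.sessions
        return len(df if tag is None else df[df.tag == tag])


def _phase_bounds(day: int, night_first: bool = False) -> list[tuple[float, float, bool]]:
    """(start, end, is_night) segments of one day; lights on 07:00-19:00."""
    base = day * SECONDS_PER_DAY
    return [
        (base, base + 7 * 3600, True),
        (base + 7 * 3600, base + 19 * 3600, False),
        (base + 19 * 3600, base + 24 * 3600, True),
    ]


def simulate_colony(
    params: Mapping[str, AgentParams],
    days: int,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    start_day: int = 0,
) -> tuple[EventStore, ColonyTruth]:
    """Simulate a colony for ``days`` days; returns events + ground truth.

    Entry bursts follow an inhomogeneous Poisson process with a two-level
    night/day intensity (lights on at 07:00, 12 h cycle) whose overall
    mean matches ``entry_rate`` and whose night share matches
    ``night_bias``.  Each burst is a geometric number of back-to-back
    chamber visits; each visit runs :func:`~mesocage.task_engine.run_session`
    with the mouse's stochastic lick policy when the participation draw
    succeeds, otherwise it is an entry + entrance reward + exit only.
    """
    if not params:
        raise ValueError("need at least one mouse")
    config = config or TaskConfig()
    records: list[EventRecord] = []
    session_rows: list[dict] = []
    outcome_rows: dict[tuple[str, int], int] = {}
    mouse_rows: list[dict] = []

    for tag in sorted(params):
        p = params[tag]
        sub = np.random.default_rng(rng.integers(0, 2**31))
        policy = StochasticLicker(p)
        burst_rate = p.entry_rate / p.cluster_burst_mean  # bursts/hour average
        lam_night = 2.0 * burst_rate * p.night_bias
        lam_day = 2.0 * burst_rate * (1.0 - p.night_bias)
        burst_starts: list[float] = []
        for day in range(start_day, start_day + days):
            for t0, t1, is_night in _phase_bounds(day):
                lam = lam_night if is_night else lam_day
                hours = (t1 - t0) / 3600.0
                n = sub.poisson(lam * hours)
                burst_starts.extend(sub.uniform(t0, t1, size=n))
        burst_starts.sort()

        n_entries = 0
        n_sessions = 0
        night_sessions = 0
        t_free = 0.0  # earliest time this mouse is available again
        for bs in burst_starts:
            t = max(bs, t_free)
            n_visits = int(sub.geometric(1.0 / p.cluster_burst_mean)) if p.cluster_burst_mean > 1 else 1
            for _ in range(max(1, n_visits)):
                n_entries += 1
                if sub.random() < p.participation:
                    ev = run_session(tag, t, policy, config, sub)
                    records.extend(ev)
                    n_sessions += 1
                    fixed = any(r.event in ("fix_loose", "fix_tight") for r in ev)
                    n_trials = sum(r.event == "outcome" for r in ev)
                    led_on = next((r.timestamp for r in ev if r.event == "BrainLEDON"), t)
                    is_night = not (7.0 <= hour_of_day(led_on) < 19.0)
                    night_sessions += is_night
                    session_rows.append(
                        {
                            "tag": tag,
                            "start": ev[0].timestamp,
                            "end": ev[-1].timestamp,
                            "fixed": fixed,
                            "n_trials": n_trials,
                            "night": is_night,
                        }
                    )
                    for r in ev:
                        if r.event == "outcome":
                            key = (tag, r.outcome_code())
                            outcome_rows[key] = outcome_rows.get(key, 0) + 1
                    t = ev[-1].timestamp
                else:
                    records.append(EventRecord(t, tag, "entry"))
                    records.append(
                        EventRecord(t + 0.5, tag, "reward_entrance", f"{config.entrance_reward_valve_ms:.0f}")
                    )
                    records.append(EventRecord(t + 3.0, tag, "exit"))
                    t += 3.0
                t += sub.exponential(p.within_burst_gap_mean)
            t_free = t
        mouse_rows.append(
            {
                "tag": tag,
                "n_entries": n_entries,
                "n_sessions": n_sessions,
                "night_fraction": night_sessions / n_sessions if n_sessions else np.nan,
            }
        )

    store = EventStore(records)
    truth = ColonyTruth(
        sessions=pd.DataFrame(session_rows, columns=["tag", "start", "end", "fixed", "n_trials", "night"]),
        outcomes=pd.DataFrame(
            [{"tag": k[0], "code": k[1], "count": v} for k, v in sorted(outcome_rows.items())],
            columns=["tag", "code", "count"],
        ),
        per_mouse=pd.DataFrame(mouse_rows),
    )
    return store, truth


@dataclass(frozen=True)
class RegionDrive:
    """Epoch-locked activation of one cortical region in synthetic movies.

    ``epoch='cue'`` drives the region for the cue duration starting at the
    cue; ``'response'`` starts at the end of the delay (motor/licking
    regions); ``'pre'`` models pre-trial movement-related activity.
    ``amplitude`` is the peak dF/F contributed at the region center.
    """

    roi: RoiSpec
    amplitude: float = 0.05
    epoch: str = "cue"  # cue | response | pre
    duration: float = 0.5  # s of boxcar drive
    sigma_mm: float = 0.45  # spatial footprint SD


@dataclass
class SyntheticMovieConfig:
    """Study conditions for synthetic two-channel movies.

    Defaults follow the imaging preparation: 64 x 64 frames over an
    8.2 x 8.2 mm window at 30 Hz, hemodynamic artifact under 20% of the
    green signal amplitude, GCaMP6s-like 1 s decay.
    """

    shape: tuple[int, int] = (64, 64)
    mm_per_pixel: float = 8.2 / 64.0
    bregma: tuple[int, int] = (24, 32)
    frame_rate: float = 30.0
    pre_s: float = 2.5  # movie extent before each cue
    post_s: float = 3.5  # and after (>= 3 s post-stimulus for inclusion)
    regions: list[RegionDrive] = field(default_factory=list)
    artifact_gain: float = 0.10  # fractional amplitude vs green signal
    artifact_freqs: tuple[float, float] = (0.25, 1.1)  # Hz, vasomotor + heartbeat-ish
    noise_sd: float = 0.002  # additive sensor noise as a fraction of baseline
    calcium_tau: float = 1.0  # s, single-exponential indicator decay
    baseline_green: float = 120.0  # grey levels (below the 190/256 headroom)
    baseline_blue: float = 80.0
    movement_trial_fraction: float = 0.4  # trials with high pre-cue movement

    def default_regions(self) -> list[RegionDrive]:
        sensory = {"BC": 0.05, "HL": 0.04, "FL": 0.04}
        motor = {"ALM": 0.06, "M2": 0.045, "M1": 0.04}
        quiet = {"RS": 0.015, "V1": 0.01}
        out = []
        for name, amp in sensory.items():
            out.append(RegionDrive(ATLAS[name], amp, "cue"))
        for name, amp in motor.items():
            out.append(RegionDrive(ATLAS[name], amp, "response"))
        for name, amp in quiet.items():
            out.append(RegionDrive(ATLAS[name], amp, "cue"))
        return out


@dataclass
class MovieTruth:
    """Ground truth accompanying a synthetic movie."""

    neural: np.ndarray  # (T, H, W) noiseless neural dF/F
    artifact: np.ndarray  # (T,) shared multiplicative component
    region_traces: pd.DataFrame  # time x region peak-normalized drive
    trial_slices: list[slice]
    cue_frames: list[int]
    precue_movement: np.ndarray  # per trial, 1.0 = high-movement trial
    behavior: dict[str, np.ndarray]  # per-ROI movement traces (T,)


def _calcium_kernel(tau: float, frame_rate: float) -> np.ndarray:
    t = np.arange(0, 5 * tau, 1.0 / frame_rate)
    return np.exp(-t / tau)


def simulate_movie(
    trials: Sequence[Trial],
    config: SyntheticMovieConfig,
    rng: np.random.Generator,
) -> tuple[ImagingStack, MovieTruth]:
    """Render a two-channel synthetic movie around each trial's cue.

    green = baseline x (1 + neural dF/F + artifact) + noise,
    blue  = baseline x (1 + artifact) + noise: the hemodynamic component is
    multiplicative and identical in both channels, which is exactly the
    assumption the reflectance correction relies on.  Region drives are
    epoch-locked boxcars convolved with a slow calcium kernel and
    peak-normalized so the configured amplitude is the true dF/F peak.
    """
    if not trials:
        raise ValueError("need at least one trial")
    regions = config.regions or config.default_regions()
    H, W = config.shape
    fr = config.frame_rate
    n_pre = int(round(config.pre_s * fr))
    n_post = int(round(config.post_s * fr))
    per_trial = n_pre + n_post
    T = per_trial * len(trials)
    kernel = _calcium_kernel(config.calcium_tau, fr)

    # spatial footprints (bilateral gaussians), peak 1 at region centers
    yy, xx = np.mgrid[0:H, 0:W]
    footprints = []
    for drive in regions:
        roi = drive.roi
        row = config.bregma[0] - roi.ap_mm / config.mm_per_pixel
        sig = drive.sigma_mm / config.mm_per_pixel
        fp = np.zeros((H, W))
        for s in (-1, +1):
            col = config.bregma[1] + s * roi.ml_mm / config.mm_per_pixel
            fp += np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2 * sig**2))
        footprints.append(np.minimum(fp, 1.0))

    neural = np.zeros((T, H, W))
    traces = np.zeros((T, len(regions)))
    trial_slices: list[slice] = []
    cue_frames: list[int] = []
    high_move = rng.random(len(trials)) < config.movement_trial_fraction
    move_drive = np.zeros(T)

    for i, trial in enumerate(trials):
        s = slice(i * per_trial, (i + 1) * per_trial)
        trial_slices.append(s)
        cue_idx = i * per_trial + n_pre
        cue_frames.append(cue_idx)
        for j, drive in enumerate(regions):
            if drive.epoch == "cue":
                onset = 0.0
            elif drive.epoch == "response":
                onset = trial.delay
            elif drive.epoch == "pre":
                onset = -1.5
            else:
                raise ValueError(f"unknown epoch {drive.epoch!r}")
            k0 = cue_idx + int(round(onset * fr))
            box = np.zeros(per_trial + len(kernel))
            rel0 = k0 - i * per_trial
            rel1 = rel0 + int(round(drive.duration * fr))
            box[max(rel0, 0) : max(rel1, 0)] = 1.0
            tr = np.convolve(box, kernel)[: per_trial]
            if tr.max() > 0:
                tr = tr / tr.max() * drive.amplitude
            traces[s, j] += tr
        if high_move[i]:
            # body movement throughout the pre-cue window
            move_drive[s.start : cue_idx] = 1.0

    for j in range(len(regions)):
        neural += traces[:, j][:, None, None] * footprints[j][None]

    # shared multiplicative hemodynamic artifact, peak ~ gain x max signal
    tgrid = np.arange(T) / fr
    phases = rng.uniform(0, 2 * np.pi, size=2)
    osc = 0.7 * np.sin(2 * np.pi * config.artifact_freqs[0] * tgrid + phases[0]) + 0.3 * np.sin(
        2 * np.pi * config.artifact_freqs[1] * tgrid + phases[1]
    )
    max_amp = max((d.amplitude for d in regions), default=0.05)
    artifact = config.artifact_gain * max_amp * osc

    green = config.baseline_green * (1.0 + neural + artifact[:, None, None])
    blue = config.baseline_blue * np.broadcast_to((1.0 + artifact)[:, None, None], (T, H, W)).copy()
    if config.noise_sd > 0:
        green = green + config.baseline_green * config.noise_sd * rng.standard_normal(green.shape)
        blue = blue + config.baseline_blue * config.noise_sd * rng.standard_normal(blue.shape)

    times = tgrid
    stack = ImagingStack(
        green,
        blue,
        times,
        frame_rate=fr,
        mm_per_pixel=config.mm_per_pixel,
        bregma=config.bregma,
    )
    # behavioral ROI traces: hindlimb follows the movement drive; tongue
    # follows the licking (response) epochs; whiskers a mix
    resp = traces[:, [j for j, d in enumerate(regions) if d.epoch == "response"]]
    tongue = resp.sum(axis=1)
    tongue = tongue / tongue.max() if tongue.max() > 0 else tongue
    behavior = {
        "tongue": tongue,
        "whiskers": 0.5 * tongue + 0.5 * move_drive,
        "hindlimb": move_drive.copy(),
    }
    truth = MovieTruth(
        neural=neural,
        artifact=artifact,
        region_traces=pd.DataFrame(traces, columns=[d.roi.name for d in regions]),
        trial_slices=trial_slices,
        cue_frames=cue_frames,
        precue_movement=high_move.astype(float),
        behavior=behavior,
    )
    return stack, truth
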