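"""Stop-signal task (SST) schedules and race-model simulation.

The SST interleaves a two-choice go task with occasional stop signals.
Performance is modelled as a race between two independent processes: the go
process (response execution, here ex-Gaussian distributed finish times) and
the stop process, which starts at the stop-signal delay (SSD) and finishes
``ssd + ssrt`` later.  Whichever finishes first wins: if the stop process
finishes before the go process the response is withheld.  The SSD is adjusted
by a one-up/one-down staircase (+step after a successful stop, -step after a
failed stop) so that the probability of inhibition converges to ~0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskSchedule",
    "RaceParams",
    "TrialRecord",
    "build_schedule",
    "default_schedule",
    "staircase_update",
    "simulate_participant",
    "trials_to_frame",
    "write_trials",
    "read_trials",
]

GO_SYMBOLS = ("X", "O")

#: Column order of the trial-level delimited-text interface.
TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "is_stop",
    "ssd_ms",
    "responded",
    "correct",
    "rt_ms",
]


class ConfigurationError(ValueError):
    """Raised for invalid task or race-parameter configuration."""


@dataclass(frozen=True)
class ScheduledTrial:
    block: int
    trial: int
    go_stimulus: str
    is_stop: bool


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered trial list; block 0 (if present) is the practice block."""

    trials: tuple[ScheduledTrial, ...]
    practice_included: bool = False

    @property
    def experimental_trials(self) -> tuple[ScheduledTrial, ...]:
        return tuple(t for t in self.trials if t.block > 0)

    @property
    def n_experimental(self) -> int:
        return len(self.experimental_trials)


@dataclass(frozen=True)
class RaceParams:
    """Generating parameters for one simulated participant.

    Go finish times are ex-Gaussian: ``go_mu + go_sigma*N(0,1) + Exp(go_tau)``
    (mean ``go_mu + go_tau``, SD ``sqrt(go_sigma^2 + go_tau^2)``).  The stop
    process latency is normal truncated at zero.  Defaults put the go mean
    near 599 ms and the go SD near 159 ms, typical of school-age community
    samples on this task.
    """

    go_mu: float = 469.0
    go_sigma: float = 92.0
    go_tau: float = 130.0
    go_error_rate: float = 0.02
    go_omission_rate: float = 0.01
    ssrt_mean: float = 280.0
    ssrt_sd: float = 60.0
    initial_ssd: float = 250.0
    ssd_step: float = 50.0
    ssd_floor: float = 0.0
    response_window: float = 3000.0

    def validate(self) -> None:
        for name in ("go_mu", "go_sigma", "go_tau", "ssrt_mean", "ssrt_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("go_error_rate", "go_omission_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.ssd_step < 0:
            raise ConfigurationError("ssd_step must be non-negative")
        if self.response_window <= self.initial_ssd:
            raise ConfigurationError("response_window must exceed initial_ssd")


@dataclass(frozen=True)
class TrialRecord:
    """One realized trial; ``ssd`` only on stop trials, ``rt``/``correct``
    only when a response was emitted."""

    participant_id: str
    block: int
    trial: int
    is_stop: bool
    ssd: float | None
    responded: bool
    correct: bool | None
    rt: float | None


def staircase_update(
    current_ssd: float, inhibited: bool, step: float = 50.0, floor: float = 0.0
) -> float:
    """One-up/one-down tracking: lengthen the delay after a successful stop,
    shorten it (never below ``floor``) after a failed stop."""
    if step < 0:
        raise ConfigurationError("staircase step must be non-negative")
    if current_ssd < floor:
        raise ConfigurationError("current_ssd below the configured floor")
    if inhibited:
        return current_ssd + step
    return max(current_ssd - step, floor)


def _block_trials(
    block: int,
    n_trials: int,
    n_stop: int,
    start_trial: int,
    rng: np.random.Generator,
) -> list[ScheduledTrial]:
    stop_positions = set(rng.choice(n_trials, size=n_stop, replace=False).tolist())
    # Go stimuli balanced to within one per block.
    symbols = np.array([GO_SYMBOLS[i % 2] for i in range(n_trials)])
    rng.shuffle(symbols)
    return [
        ScheduledTrial(
            block=block,
            trial=start_trial + i,
            go_stimulus=str(symbols[i]),
            is_stop=i in stop_positions,
        )
        for i in range(n_trials)
    ]


def build_schedule(
    blocks: int = 4,
    trials_per_block: int = 24,
    stop_rate: float = 0.25,
    seed: int = 0,
    include_practice: bool = False,
    practice_trials: int = 24,
    practice_stops: int = 6,
) -> TaskSchedule:
    """Build a task schedule with exactly ``stop_rate`` stop trials per block,
    placed uniformly at random; deterministic for a given seed.

    The standard protocol is four experimental blocks of 24 trials (72 go,
    24 stop) after a 24-trial practice block (18 go, 6 stop).
    """
    if blocks < 1:
        raise ConfigurationError("need at least one block")
    n_stop = stop_rate * trials_per_block
    if abs(n_stop - round(n_stop)) > 1e-9:
        raise ConfigurationError(
            f"stop_rate {stop_rate} x {trials_per_block} trials is not an integer"
        )
    n_stop = int(round(n_stop))
    rng = np.random.default_rng(seed)
    trials: list[ScheduledTrial] = []
    trial_counter = 0
    if include_practice:
        trials.extend(_block_trials(0, practice_trials, practice_stops, 0, rng))
        trial_counter = practice_trials
    for b in range(1, blocks + 1):
        trials.extend(_block_trials(b, trials_per_block, n_stop, trial_counter, rng))
        trial_counter += trials_per_block
    return TaskSchedule(trials=tuple(trials), practice_included=include_practice)


def default_schedule(seed: int = 0, include_practice: bool = True) -> TaskSchedule:
    """The standard protocol: practice (24 trials, 6 stops) + 4 x 24."""
    return build_schedule(4, 24, 0.25, seed=seed, include_practice=include_practice)


def simulate_participant(
    schedule: TaskSchedule,
    params: RaceParams,
    seed: int,
    participant_id: str = "P0",
) -> list[TrialRecord]:
    """Simulate one participant under the independent race model.

    Per trial a go finish time is drawn; on stop trials a stop finish time is
    drawn at ``ssd + ssrt``.  A response is emitted iff the go process finishes
    first (stop trials) and within the response window, subject to the omission
    rate.  The SSD evolves through the staircase across stop trials in
    presentation order (practice included, so the experimental portion starts
    from a partially adapted delay, as in the live task).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = len(schedule.trials)
    go_finish = (
        params.go_mu
        + params.go_sigma * rng.standard_normal(n)
        + rng.exponential(params.go_tau, size=n)
    )
    np.clip(go_finish, 1.0, None, out=go_finish)
    omitted = rng.random(n) < params.go_omission_rate
    errors = rng.random(n) < params.go_error_rate
    # Stop latencies: normal truncated at zero by resampling.
    ssrt_draws = params.ssrt_mean + params.ssrt_sd * rng.standard_normal(n)
    bad = ssrt_draws <= 0
    while bad.any():
        ssrt_draws[bad] = params.ssrt_mean + params.ssrt_sd * rng.standard_normal(
            int(bad.sum())
        )
        bad = ssrt_draws <= 0

    ssd = params.initial_ssd
    records: list[TrialRecord] = []
    for i, t in enumerate(schedule.trials):
        if t.is_stop:
            stop_finish = ssd + ssrt_draws[i]
            responded = (
                not omitted[i]
                and go_finish[i] < stop_finish
                and go_finish[i] <= params.response_window
            )
            rec = TrialRecord(
                participant_id=participant_id,
                block=t.block,
                trial=t.trial,
                is_stop=True,
                ssd=ssd,
                responded=responded,
                correct=(not errors[i]) if responded else None,
                rt=float(go_finish[i]) if responded else None,
            )
            ssd = staircase_update(
                ssd, inhibited=not responded, step=params.ssd_step, floor=params.ssd_floor
            )
        else:
            responded = not omitted[i] and go_finish[i] <= params.response_window
            rec = TrialRecord(
                participant_id=participant_id,
                block=t.block,
                trial=t.trial,
                is_stop=False,
                ssd=None,
                responded=responded,
                correct=(not errors[i]) if responded else None,
                rt=float(go_finish[i]) if responded else None,
            )
        records.append(rec)
    return records


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as a data frame in the delimited-text column layout."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "block": [r.block for r in records],
            "trial": [r.trial for r in records],
            "is_stop": [int(r.is_stop) for r in records],
            "ssd_ms": [r.ssd for r in records],
            "responded": [int(r.responded) for r in records],
            "correct": [None if r.correct is None else int(r.correct) for r in records],
            "rt_ms": [r.rt for r in records],
        }
    )


def write_trials(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    return frame
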