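"""Stop-signal task behaviour: staircase tracking and session simulation.

The task mixes go trials (respond to a shape) with stop trials (a beep after a
variable stop-signal delay, SSD, instructs the subject to withhold the
response).  The SSD follows a one-up/one-down staircase -- successful stops
(SS) make the next stop harder (SSD + step), failed stops (FS) make it easier
(SSD - step) -- which drives the empirical stop rate towards 50%.

Stop-trial outcomes are generated by the standard independent horse-race
model: the go process finishes at a log-normally distributed reaction time,
the stop process finishes SSRT milliseconds after the stop signal, and the
faster finisher wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Shape -> responding hand mapping: a square requires a left-hand response
#: (LHR), a circle a right-hand response (RHR).
SHAPE_TO_HAND = {"square": "LHR", "circle": "RHR"}


@dataclass(frozen=True)
class TaskConfig:
    """Stop-signal session design.

    Defaults reproduce the study conditions: 100 trials, 25% stop trials,
    SSD staircase starting at 250 ms with 50 ms steps, 100 ms beep.
    """

    n_trials: int = 100
    stop_fraction: float = 0.25
    ssd_init_ms: float = 250.0
    ssd_step_ms: float = 50.0
    ssd_bounds_ms: tuple[float, float] = (50.0, 1000.0)
    beep_duration_ms: float = 100.0
    shape_to_hand: dict = field(default_factory=lambda: dict(SHAPE_TO_HAND))

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must lie strictly between 0 and 1")
        if self.n_trials < 4:
            raise ValueError("n_trials must be at least 4")
        lo, hi = self.ssd_bounds_ms
        if not lo <= self.ssd_init_ms <= hi:
            raise ValueError("ssd_init_ms must lie within ssd_bounds_ms")

    @property
    def n_stop(self) -> int:
        return round(self.n_trials * self.stop_fraction)


@dataclass(frozen=True)
class RaceModel:
    """Horse-race response model.

    Go reaction times are log-normal in milliseconds (``go_mu``/``go_sigma``
    are the log-scale parameters; the default median exp(go_mu) ~ 450 ms).
    The stop process latency (SSRT) is a constant plus Gaussian jitter,
    truncated at 1 ms so every sampled duration is positive.
    """

    go_mu: float = float(np.log(450.0))
    go_sigma: float = 0.2
    ssrt_ms: float = 200.0
    ssrt_sd_ms: float = 20.0

    def __post_init__(self) -> None:
        vals = [self.go_mu, self.go_sigma, self.ssrt_ms, self.ssrt_sd_ms]
        if not all(np.isfinite(vals)):
            raise ValueError("race model parameters must be finite")
        if self.go_sigma <= 0 or self.ssrt_ms <= 0 or self.ssrt_sd_ms < 0:
            raise ValueError("race model scales must be positive")

    def sample_go_rt(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.go_mu, self.go_sigma))

    def sample_ssrt(self, rng: np.random.Generator) -> float:
        return float(max(1.0, self.ssrt_ms + rng.normal(0.0, self.ssrt_sd_ms)))


@dataclass(frozen=True)
class StaircaseState:
    current_ssd: float
    step: float = 50.0
    bounds: tuple[float, float] = (50.0, 1000.0)


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """One-up/one-down SSD tracking: SS -> +step, FS -> -step, clamped to bounds."""
    if outcome == "SS":
        ssd = state.current_ssd + state.step
    elif outcome == "FS":
        ssd = state.current_ssd - state.step
    else:
        raise ValueError(f"staircase outcome must be SS or FS, got {outcome!r}")
    lo, hi = state.bounds
    return replace(state, current_ssd=float(min(max(ssd, lo), hi)))


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial.

    ``ssd_ms`` is present iff the trial is a stop trial, and the outcome is
    SS/FS iff the trial is a stop trial.  ``rt_ms`` is absent for successful
    stops (no response was emitted).
    """

    index: int
    trial_type: str          # "go" | "stop"
    shape: str               # "square" | "circle"
    hand: str                # "LHR" | "RHR"
    ssd_ms: float | None
    rt_ms: float | None
    outcome: str             # "go_correct" | "go_error" | "SS" | "FS"

    def __post_init__(self) -> None:
        if (self.trial_type == "stop") != (self.ssd_ms is not None):
            raise ValueError("ssd_ms present iff trial_type == 'stop'")
        if (self.trial_type == "stop") != (self.outcome in ("SS", "FS")):
            raise ValueError("SS/FS outcomes occur iff trial_type == 'stop'")


def simulate_session(
    config: TaskConfig = TaskConfig(),
    race: RaceModel = RaceModel(),
    seed: int = 0,
) -> list[TrialRecord]:
    """Simulate one stop-signal session.

    The stop-trial count is exact (``round(n_trials * stop_fraction)``), stop
    positions are randomised, and stop signals follow each shape equally often
    (the odd stop trial, if any, is assigned to a random shape).  Bit
    reproducible given ``(config, race, seed)``.
    """
    rng = np.random.default_rng(seed)
    n, n_stop = config.n_trials, config.n_stop

    # Balanced shape sequence; stop trials split evenly across shapes.
    shapes = np.array(["square", "circle"])[
        rng.permutation(np.arange(n) % 2)
    ]
    sq_idx = np.flatnonzero(shapes == "square")
    ci_idx = np.flatnonzero(shapes == "circle")
    n_sq_stop = n_stop // 2
    n_ci_stop = n_stop - n_sq_stop
    if n_stop % 2 and rng.random() < 0.5:
        n_sq_stop, n_ci_stop = n_ci_stop, n_sq_stop
    stop_set = set(rng.choice(sq_idx, size=n_sq_stop, replace=False).tolist())
    stop_set |= set(rng.choice(ci_idx, size=n_ci_stop, replace=False).tolist())

    stair = StaircaseState(config.ssd_init_ms, config.ssd_step_ms, config.ssd_bounds_ms)
    trials: list[TrialRecord] = []
    for i in range(n):
        shape = str(shapes[i])
        hand = config.shape_to_hand[shape]
        go_rt = race.sample_go_rt(rng)
        if i in stop_set:
            ssd = stair.current_ssd
            ssrt = race.sample_ssrt(rng)
            # Race rule: stop wins (SS) iff the go process outlasts ssd + ssrt.
            if go_rt > ssd + ssrt:
                outcome, rt = "SS", None
            else:
                outcome, rt = "FS", go_rt
            stair = staircase_update(stair, outcome)
            trials.append(TrialRecord(i, "stop", shape, hand, ssd, rt, outcome))
        else:
            trials.append(TrialRecord(i, "go", shape, hand, None, go_rt, "go_correct"))
    return trials


def session_frame(session: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate a session, one trial per row (documented column order)."""
    return pd.DataFrame(
        [
            {
                "index": t.index,
                "trial_type": t.trial_type,
                "shape": t.shape,
                "hand": t.hand,
                "ssd_ms": t.ssd_ms,
                "rt_ms": t.rt_ms,
                "outcome": t.outcome,
            }
            for t in session
        ]
    )


def write_session(session: Sequence[TrialRecord], path: str) -> None:
    session_frame(session).to_csv(path, index=False)


def read_session(path: str) -> list[TrialRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            TrialRecord(
                int(r["index"]),
                str(r["trial_type"]),
                str(r["shape"]),
                str(r["hand"]),
                None if pd.isna(r["ssd_ms"]) else float(r["ssd_ms"]),
                None if pd.isna(r["rt_ms"]) else float(r["rt_ms"]),
                str(r["outcome"]),
            )
        )
    return out


def stop_rate(session: Sequence[TrialRecord]) -> float:
    """Empirical P(successful stop) among stop trials."""
    outcomes = [t.outcome for t in session if t.trial_type == "stop"]
    if not outcomes:
        warnings.warn("session contains no stop trials")
        return float("nan")
    return outcomes.count("SS") / len(outcomes)
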