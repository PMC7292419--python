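"""Generative model of the volatile transition-probability task.

Binary tone sequences (tones ``A`` and ``B``) are produced from first-order
transition probabilities ``theta = (p(A|A), p(B|B))`` that stay fixed within a
segment and are abruptly resampled at change points.  Change points occur
independently on every trial with probability ``p_change``; at a change point
both probabilities are redrawn uniformly from ``[resample_low, resample_high]``
subject to the constraint that the odds of at least one of the two
probabilities change by a factor ``min_fold_change`` or more.

The module also generates the schedule of occasional probe questions that
interleave the tone stream (inter-question gaps with a median of 13 trials and
SD of 4.4 trials in the default configuration).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TONE_A",
    "TONE_B",
    "TaskConfig",
    "ToneSequence",
    "QuestionSchedule",
    "generate_sequence",
    "generate_question_schedule",
    "spawn_seeds",
]

TONE_A: int = 0
TONE_B: int = 1

_MAX_RESAMPLE_TRIES = 10_000


@dataclass(frozen=True)
class TaskConfig:
    """All generative and inference constants of the task.

    Parameters
    ----------
    p_change:
        Per-trial probability of a change point (default 1/75).
    n_trials, n_sessions, n_subjects:
        Trials per session, sessions per subject, and number of subjects.
    resample_low, resample_high:
        Interval from which transition probabilities are redrawn.
    min_fold_change:
        Minimal odds-ratio change required for at least one of the two
        transition probabilities at a change point.
    grid_n:
        Number of grid points per dimension used by the ideal observer.
    question_gap_median, question_gap_sd:
        Centre and spread of the inter-question gap distribution (trials).
    seed:
        Master seed for cohort-level simulations.
    """

    p_change: float = 1.0 / 75.0
    n_trials: int = 380
    n_sessions: int = 4
    n_subjects: int = 24
    resample_low: float = 0.1
    resample_high: float = 0.9
    min_fold_change: float = 4.0
    grid_n: int = 20
    question_gap_median: float = 13.0
    question_gap_sd: float = 4.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_change <= 1.0:
            raise ValueError(f"p_change must lie in [0, 1], got {self.p_change}")
        if not 0.0 < self.resample_low < self.resample_high < 1.0:
            raise ValueError("require 0 < resample_low < resample_high < 1")
        if self.min_fold_change < 1.0:
            raise ValueError("min_fold_change must be >= 1")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.n_trials < 0 or self.n_sessions < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TaskConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ToneSequence:
    """One generated session: tones, true parameters and change points.

    ``theta_true`` has shape ``(n_trials, 2)`` holding ``(p(A|A), p(B|B))``
    active on each trial; it is piecewise constant between change points.
    ``trials_since_cp`` counts observations since the last change point,
    1-based within each segment (a change-point trial itself counts 1).
    """

    tones: np.ndarray
    theta_true: np.ndarray
    changepoints: np.ndarray
    trials_since_cp: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trials_since_cp is None:
            object.__setattr__(
                self, "trials_since_cp", _trials_since_cp(len(self.tones), self.changepoints)
            )

    def __len__(self) -> int:
        return len(self.tones)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.tones)
        is_cp = np.zeros(n, dtype=bool)
        is_cp[self.changepoints] = True
        return pd.DataFrame(
            {
                "trial": np.arange(n),
                "tone": self.tones,
                "p_AA_true": self.theta_true[:, 0],
                "p_BB_true": self.theta_true[:, 1],
                "is_changepoint": is_cp,
                "trials_since_cp": self.trials_since_cp,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ToneSequence":
        df = pd.read_csv(path)
        return cls(
            tones=df["tone"].to_numpy(dtype=int),
            theta_true=df[["p_AA_true", "p_BB_true"]].to_numpy(),
            changepoints=np.flatnonzero(df["is_changepoint"].to_numpy()),
        )


@dataclass(frozen=True)
class QuestionSchedule:
    """Sorted trial indices at which a probe question replaces the stimulus."""

    question_trials: np.ndarray

    def __len__(self) -> int:
        return len(self.question_trials)

    def mask(self, n_trials: int) -> np.ndarray:
        m = np.zeros(n_trials, dtype=bool)
        m[self.question_trials] = True
        return m


def _trials_since_cp(n: int, changepoints: np.ndarray) -> np.ndarray:
    out = np.empty(n, dtype=int)
    count = 0
    cps = set(int(c) for c in np.asarray(changepoints).ravel())
    for t in range(n):
        count = 1 if (t == 0 or t in cps) else count + 1
        out[t] = count
    return out


def _log_odds(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _draw_theta(
    rng: np.random.Generator,
    config: TaskConfig,
    old: np.ndarray | None,
) -> np.ndarray:
    """Draw a transition-probability pair, rejecting until the fold-change
    constraint |log odds-ratio| >= log(min_fold_change) holds for at least
    one of the two probabilities."""
    log_fold = np.log(config.min_fold_change)
    for _ in range(_MAX_RESAMPLE_TRIES):
        new = rng.uniform(config.resample_low, config.resample_high, size=2)
        if old is None:
            return new
        if np.max(np.abs(_log_odds(new) - _log_odds(old))) >= log_fold:
            return new
    raise RuntimeError(
        "rejection sampling failed: fold-change constraint infeasible "
        f"within {_MAX_RESAMPLE_TRIES} tries"
    )


def generate_sequence(config: TaskConfig, seed: int | np.random.SeedSequence) -> ToneSequence:
    """Generate one session of tones from the task's generative process.

    The first tone is drawn with probability 0.5; every subsequent tone is
    drawn from the transition probability active on that trial, conditioned on
    the previous tone.  Change points are drawn i.i.d. per trial with
    probability ``config.p_change``; the same seed yields an identical
    sequence.
    """
    rng = np.random.default_rng(seed)
    n = config.n_trials
    tones = np.empty(n, dtype=int)
    theta = np.empty((n, 2))
    cps: list[int] = []

    cur = _draw_theta(rng, config, None)
    for t in range(n):
        if t > 0 and rng.random() < config.p_change:
            cur = _draw_theta(rng, config, cur)
            cps.append(t)
        theta[t] = cur
        if t == 0:
            p_a = 0.5
        elif tones[t - 1] == TONE_A:
            p_a = cur[0]
        else:
            p_a = 1.0 - cur[1]
        tones[t] = TONE_A if rng.random() < p_a else TONE_B

    return ToneSequence(tones=tones, theta_true=theta, changepoints=np.asarray(cps, dtype=int))


def generate_question_schedule(
    config: TaskConfig, seed: int | np.random.SeedSequence
) -> QuestionSchedule:
    """Draw the probe-question schedule for one session.

    Inter-question gaps are ``round(Normal(median, sd))`` redrawn until
    >= 2 trials, accumulated until the session ends.
    """
    rng = np.random.default_rng(seed)
    positions: list[int] = []
    pos = 0
    while True:
        gap = 0
        while gap < 2:
            gap = int(round(rng.normal(config.question_gap_median, config.question_gap_sd)))
        pos += gap
        if pos >= config.n_trials:
            break
        positions.append(pos)
    return QuestionSchedule(question_trials=np.asarray(positions, dtype=int))


def spawn_seeds(master: int | np.random.SeedSequence, n: int) -> list[np.random.SeedSequence]:
    """Deterministically spawn ``n`` independent child seeds from a master seed."""
    ss = master if isinstance(master, np.random.SeedSequence) else np.random.SeedSequence(master)
    return ss.spawn(n)
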