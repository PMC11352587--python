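"""Synthetic 2AFC observers for the flicker-adaptation experiment.

Each simulated observer answers two-alternative forced-choice trials with a
cumulative-Gaussian psychometric function

    P(correct | c) = guess + (1 - guess - lapse) * Phi((c - mu) / sigma)

with guess rate fixed at 0.5.  A cohort reproduces the study design: 30
observers, three tasks (sketch-based image discrimination, motion direction,
orientation), two conditions each (baseline, flicker adaptation), 100 trials
per contrast level on the task's contrast ladder.  Flicker adaptation acts
as a multiplicative shift of the threshold; the spread sigma scales with mu
(Weber-like), so the psychometric shape is invariant on log-contrast.

Task set points are the group thresholds the study design targets:
image 0.14 -> 0.29 (with a 0.1 lapse producing the ~90% performance
ceiling of that task), motion 0.045 -> 0.063, orientation 0.037 with a unit
flicker factor (no effect).  Between-observer variability is log-normal
with geometric SD 1.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "ObserverParams",
    "TaskSpec",
    "CohortSpec",
    "psychometric_p",
    "mu_from_threshold",
    "threshold_from_mu",
    "simulate_trials",
    "simulate_cohort",
    "default_cohort_spec",
    "IMAGE_LADDER",
    "MOTION_LADDER",
    "ORIENTATION_LADDER",
]

IMAGE_LADDER = (0.02, 0.05, 0.07, 0.1, 0.15, 0.2, 0.3, 0.5, 0.7, 1.0)
MOTION_LADDER = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06,
    0.07, 0.08, 0.09, 0.1, 0.15, 0.2,
)
ORIENTATION_LADDER = (
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1,
)


@dataclass(frozen=True)
class ObserverParams:
    """Cumulative-Gaussian 2AFC observer: location, spread, lapse rate."""

    mu: float
    sigma: float
    lapse: float = 0.0
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if 1 - self.lapse < self.guess:
            raise ValueError("asymptote 1 - lapse must be >= guess")


def psychometric_p(c, params: ObserverParams):
    """Probability of a correct 2AFC response at contrast ``c``."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("contrast must be >= 0")
    p = params.guess + (1 - params.guess - params.lapse) * ndtr(
        (c - params.mu) / params.sigma
    )
    return float(p) if p.ndim == 0 else p


def _criterion_z(criterion: float, guess: float, lapse: float) -> float:
    span = 1 - guess - lapse
    if span <= 0 or not guess < criterion < 1 - lapse:
        raise ValueError("criterion must lie strictly between guess and asymptote")
    return float(ndtri((criterion - guess) / span))


def threshold_from_mu(params: ObserverParams, criterion: float = 0.75) -> float:
    """Contrast at which the observer reaches ``criterion`` proportion correct."""
    return params.mu + params.sigma * _criterion_z(
        criterion, params.guess, params.lapse
    )


def mu_from_threshold(
    T: float,
    sigma_ratio: float,
    lapse: float = 0.0,
    criterion: float = 0.75,
    guess: float = 0.5,
) -> float:
    """Location mu that puts the criterion threshold at ``T`` when
    sigma = sigma_ratio * mu."""
    z = _criterion_z(criterion, guess, lapse)
    denom = 1.0 + sigma_ratio * z
    if denom <= 0:
        raise ValueError("incompatible sigma_ratio / criterion combination")
    return T / denom


@dataclass(frozen=True)
class TaskSpec:
    """Generator settings for one task (both conditions)."""

    name: str
    ladder: tuple[float, ...]
    threshold_median: float  # median baseline 75%-correct threshold
    effect_factor: float = 1.0  # multiplicative flicker effect on threshold
    lapse: float = 0.0
    sigma_ratio: float = 0.4  # sigma / mu (Weber-like spread)
    trials_per_level: int = 100
    fit_lapse_mode: str = "fixed"  # how downstream fitting treats the lapse

    def __post_init__(self) -> None:
        ladder = tuple(float(c) for c in self.ladder)
        if not all(0 < c <= 1 for c in ladder):
            raise ValueError("ladder contrasts must lie in (0, 1]")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ladder must be strictly increasing")
        if self.effect_factor <= 0:
            raise ValueError("effect factor must be > 0")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        object.__setattr__(self, "ladder", ladder)

    @property
    def max_contrast(self) -> float:
        return self.ladder[-1]


@dataclass(frozen=True)
class CohortSpec:
    """The simulated study: observers x tasks x conditions x contrast levels."""

    tasks: tuple[TaskSpec, ...]
    n_subjects: int = 30
    geometric_sd: float = 1.4  # between-observer log-normal threshold spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.geometric_sd < 1:
            raise ValueError("geometric SD must be >= 1")

    @property
    def trials_per_subject(self) -> int:
        return sum(2 * len(t.ladder) * t.trials_per_level for t in self.tasks)


def default_cohort_spec(seed: int = 0, effect: bool = True) -> CohortSpec:
    """The study-calibrated cohort; ``effect=False`` nulls all flicker effects."""
    tasks = (
        TaskSpec(
            name="image",
            ladder=IMAGE_LADDER,
            threshold_median=0.14,
            effect_factor=0.29 / 0.14 if effect else 1.0,
            lapse=0.1,
            fit_lapse_mode="free",
        ),
        TaskSpec(
            name="motion",
            ladder=MOTION_LADDER,
            threshold_median=0.045,
            effect_factor=0.063 / 0.045 if effect else 1.0,
        ),
        TaskSpec(
            name="orientation",
            ladder=ORIENTATION_LADDER,
            threshold_median=0.037,
            effect_factor=1.0,
        ),
    )
    return CohortSpec(tasks=tasks, seed=seed)


def _observer_for(task: TaskSpec, threshold: float) -> ObserverParams:
    mu = mu_from_threshold(threshold, task.sigma_ratio, task.lapse)
    return ObserverParams(mu=mu, sigma=task.sigma_ratio * mu, lapse=task.lapse)


def simulate_trials(
    params: ObserverParams,
    ladder,
    n_per_level: int,
    seed,
    subject: str = "s01",
    task: str = "task",
    condition: str = "baseline",
) -> pd.DataFrame:
    """Bernoulli 2AFC trials at every ladder level, reproducible from seed."""
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    ladder = np.asarray(ladder, dtype=float)
    rng = np.random.default_rng(seed)
    p = psychometric_p(ladder, params)
    contrasts = np.repeat(ladder, n_per_level)
    correct = rng.random(contrasts.size) < np.repeat(p, n_per_level)
    return pd.DataFrame(
        {
            "subject": subject,
            "task": task,
            "condition": condition,
            "contrast": contrasts,
            "correct": correct.astype(np.int8),
            "trial": np.arange(contrasts.size),
        }
    )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the full cohort as one tidy trial table.

    Per subject and task, the baseline threshold is drawn log-normally around
    the task median; the flicker condition multiplies it by the task's effect
    factor.  Each subject gets an independent random substream spawned from
    the master seed, so the table is bit-reproducible and insensitive to the
    order in which subjects are generated.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    log_gsd = np.log(spec.geometric_sd)
    frames: list[pd.DataFrame] = []
    for s_idx, s_seed in enumerate(subject_seeds):
        rng = np.random.default_rng(s_seed)
        sid = f"s{s_idx + 1:02d}"
        for task in spec.tasks:
            t_base = task.threshold_median * np.exp(log_gsd * rng.standard_normal())
            for condition, factor in (
                ("baseline", 1.0),
                ("flicker", task.effect_factor),
            ):
                params = _observer_for(task, t_base * factor)
                frames.append(
                    simulate_trials(
                        params,
                        task.ladder,
                        task.trials_per_level,
                        seed=rng.integers(0, 2**31),
                        subject=sid,
                        task=task.name,
                        condition=condition,
                    )
                )
    return pd.concat(frames, ignore_index=True)
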