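"""Synthetic noisy-response simulator for closed-loop testing.

Emulates a rating experiment in which each trial shows a stimulus with two
continuous attributes and records one bounded scalar rating.  The ground
truth is a quadratic surface with an interior maximum, optionally coupled
through a cross term; per-trial noise models rater heterogeneity; the
rating is clipped to the slider range.  Shock events force one dimension's
center mid-run to probe recovery of the feedback loop, and an optional
drift moves the optimum over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import LockInController
from .trajectory import TrajectoryLog

__all__ = [
    "ResponseSurface",
    "NoiseModel",
    "ShockEvent",
    "ShockSchedule",
    "Scenario",
    "ConfigError",
    "evaluate_surface",
    "conditional_optimum",
    "sample_response",
    "run_scenario",
]


class ConfigError(ValueError):
    """A scenario or controller configuration is inconsistent."""


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic two-attribute ground truth.

    ``y = a1*(x1-x1m)^2 + a2*(x2-x2m)^2 + cross*(x1-x1m)*(x2-x2m) + y0``

    Curvatures ``a1``, ``a2`` are negative for a maximization scenario
    (response units per attribute-unit^2).  ``cross`` couples the two
    attributes; it is parameterized around the optimum, so ``cross = 0``
    recovers the separable sum-of-parabolas exactly.  With a cross term the
    surface has a unique interior maximum iff ``4*a1*a2 - cross^2 > 0``.
    """

    a1: float = -0.01
    a2: float = -0.02
    x1m: float = 55.0
    x2m: float = 60.0
    y0: float = 70.0
    cross: float = 0.0

    def __post_init__(self) -> None:
        if self.cross != 0.0 and not (4.0 * self.a1 * self.a2 - self.cross**2 > 0):
            raise ConfigError(
                "cross term too strong for a unique interior extremum: "
                f"4*a1*a2 - cross^2 = {4 * self.a1 * self.a2 - self.cross**2:.4g} <= 0"
            )


def evaluate_surface(surface: ResponseSurface, x1: float, x2: float) -> float:
    """Noise-free expected response at ``(x1, x2)``."""
    d1 = x1 - surface.x1m
    d2 = x2 - surface.x2m
    return surface.a1 * d1 * d1 + surface.a2 * d2 * d2 + surface.cross * d1 * d2 + surface.y0


def conditional_optimum(surface: ResponseSurface, x1: float) -> float:
    """Response-maximizing ``x2`` given a fixed ``x1``.

    From ``d y / d x2 = 0``: ``x2* = x2m - cross*(x1 - x1m) / (2*a2)``.
    With no cross term this is simply ``x2m``.
    """
    return surface.x2m - surface.cross * (x1 - surface.x1m) / (2.0 * surface.a2)


@dataclass(frozen=True)
class NoiseModel:
    """Per-trial zero-mean rating noise plus slider clipping.

    ``kind`` is one of ``gaussian``, ``uniform`` (rescaled to the stated
    standard deviation) or ``none``.  ``clip`` is the closed response
    interval of the slider (``None`` disables clipping, e.g. for
    unbiasedness checks — the clip induces bias near the boundaries).
    Draws depend only on ``(seed, trial)``, so any trial's noise is
    reproducible in isolation.
    """

    kind: str = "gaussian"
    sd: float = 25.0
    clip: Optional[tuple] = (1.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform", "none"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ConfigError(f"sd must be non-negative, got {self.sd}")
        if self.clip is not None and not self.clip[0] < self.clip[1]:
            raise ConfigError(f"empty clip interval {self.clip}")

    def draw(self, trial: int, size: int | None = None):
        """Noise draw(s) for one trial, reproducible from ``(seed, trial)``."""
        if self.kind == "none" or self.sd == 0.0:
            return 0.0 if size is None else np.zeros(size)
        rng = np.random.default_rng([int(self.seed), int(trial)])
        if self.kind == "gaussian":
            return rng.normal(0.0, self.sd, size=size)
        half = math.sqrt(3.0) * self.sd  # uniform on [-h, h] has sd = h/sqrt(3)
        return rng.uniform(-half, half, size=size)

    def apply_clip(self, y):
        if self.clip is None:
            return y
        return np.clip(y, self.clip[0], self.clip[1])


@dataclass(frozen=True)
class ShockEvent:
    """Force dimension ``dim`` (1-based) to ``value`` at ``trial``."""

    trial: int
    dim: int
    value: float


@dataclass(frozen=True)
class ShockSchedule:
    events: tuple = ()

    def __post_init__(self) -> None:
        trials = [e.trial for e in self.events]
        if any(b <= a for a, b in zip(trials, trials[1:])):
            raise ConfigError("shock trials must be strictly increasing")

    def at(self, trial: int) -> list[ShockEvent]:
        return [e for e in self.events if e.trial == trial]


@dataclass(frozen=True)
class Scenario:
    """One simulated experiment: surface + noise + shocks + run length.

    ``drift`` optionally displaces the optimum: a callable mapping the trial
    index to ``(dx1, dx2)`` added to ``(x1m, x2m)`` at that trial.  Off by
    default.  ``round_response`` rounds ratings to integers to mimic a
    discrete slider (off by default; granularity of real sliders varies).
    """

    surface: ResponseSurface = field(default_factory=ResponseSurface)
    noise: NoiseModel = field(default_factory=NoiseModel)
    shocks: ShockSchedule = field(default_factory=ShockSchedule)
    n_trials: int = 3600
    drift: Optional[Callable[[int], tuple]] = None
    round_response: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be positive, got {self.n_trials}")

    def surface_at(self, trial: int) -> ResponseSurface:
        if self.drift is None:
            return self.surface
        dx1, dx2 = self.drift(trial)
        s = self.surface
        return ResponseSurface(
            a1=s.a1, a2=s.a2, x1m=s.x1m + dx1, x2m=s.x2m + dx2, y0=s.y0, cross=s.cross
        )


def sample_response(scenario: Scenario, x1: float, x2: float, trial: int) -> float:
    """One observed rating: surface value (with drift) + noise, clipped."""
    mu = evaluate_surface(scenario.surface_at(trial), x1, x2)
    y = float(scenario.noise.apply_clip(mu + scenario.noise.draw(trial)))
    return float(round(y)) if scenario.round_response else y


def run_scenario(
    scenario: Scenario,
    configs: Sequence,
    *,
    raw_sign: bool = False,
    baseline: str = "current",
    quantize: bool = False,
) -> TrajectoryLog:
    """Closed loop: propose, sample, record, update, for ``n_trials`` trials.

    Shock events overwrite the named dimension's center just before that
    trial's stimulus is proposed, leaving all other state untouched.  The
    returned log holds one row per trial with stimuli, rating, the centers
    in force at that trial, and post-warm-up lock-in sums.
    """
    if len(configs) != 2:
        raise ConfigError("a scenario couples a two-attribute surface; need 2 configs")
    for e in scenario.shocks.events:
        if not 1 <= e.trial <= scenario.n_trials:
            raise ConfigError(f"shock at trial {e.trial} outside run of {scenario.n_trials}")
        if not 1 <= e.dim <= len(configs):
            raise ConfigError(f"shock names dimension {e.dim}, run has {len(configs)}")
    ctl = LockInController(configs, raw_sign=raw_sign, baseline=baseline, quantize=quantize)
    log = TrajectoryLog(k=2)
    for i in range(1, scenario.n_trials + 1):
        for e in scenario.shocks.at(i):
            ctl.force_center(e.dim - 1, e.value)
        xs = ctl.propose(i)
        centers_used = [st.center_history[-1] for st in ctl.states]
        y = sample_response(scenario, xs[0], xs[1], i)
        ctl.observe(i, y)
        ylocks = [None if lk is None else lk.y_lock for lk in ctl.last_locks]
        log.append(i, xs, y, centers_used, ylocks)
    return log
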