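"""Diagnostics over trajectory logs.

Smoothing of the raw rating stream, quantitative convergence and
shock-recovery reports on the center trajectories, and an audit of the
frequency cross-talk between simultaneously dithered dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import TrajectoryLog

__all__ = [
    "ConvergenceReport",
    "RecoveryReport",
    "moving_average",
    "convergence_stats",
    "recovery_stats",
    "crosstalk",
]


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-dimension trailing statistics of the center trajectory.

    A dimension counts as converged when the trailing standard deviation is
    below the tolerance and every trailing center stays within the tolerance
    band around the trailing mean.  ``entered_trial`` is the first trial from
    which the center entered that band and never left it (None if it never
    settles).
    """

    trailing_window: int
    tolerance: float
    trailing_mean: tuple
    trailing_sd: tuple
    converged: tuple
    entered_trial: tuple

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveryReport:
    """How the feedback loop absorbed one forced center displacement."""

    dim: int
    shock_trial: int
    displacement: float
    baseline: float
    tolerance: float
    recovered: bool
    recovery_trial: Optional[int]
    recovery_duration: Optional[int]

    def to_dict(self) -> dict:
        return asdict(self)


def moving_average(series, window: int) -> np.ndarray:
    """Trailing mean over ``window`` entries; only full windows are emitted.

    The result has length ``len(series) - window + 1``: entry ``j`` is the
    mean of ``series[j : j + window]``.
    """
    x = np.asarray(series, dtype=float)
    window = int(window)
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    return pd.Series(x).rolling(window).mean().to_numpy()[window - 1 :]


def _entered_and_stayed(values: np.ndarray, center: float, tol: float, trials: np.ndarray):
    """First trial index from which |value - center| <= tol holds to the end."""
    inside = np.abs(values - center) <= tol
    if not inside[-1]:
        return None
    # last index where the series is outside the band
    outside = np.where(~inside)[0]
    first = 0 if outside.size == 0 else outside[-1] + 1
    return int(trials[first])


def convergence_stats(
    log: TrajectoryLog, trailing_window: int, tolerance: float = 5.0
) -> ConvergenceReport:
    """Trailing mean/sd of each dimension's center, with a converged flag."""
    n = len(log)
    trailing_window = int(trailing_window)
    if trailing_window < 1 or trailing_window > n:
        raise ValueError(f"trailing window {trailing_window} not in [1, {n}]")
    trials = log.frame["trial"].to_numpy()
    means, sds, flags, entered = [], [], [], []
    for d in range(1, log.k + 1):
        c = log.centers(d)
        tail = c[-trailing_window:]
        m = float(np.mean(tail))
        sd = float(np.std(tail, ddof=0))
        in_band = bool(np.all(np.abs(tail - m) <= tolerance))
        means.append(m)
        sds.append(sd)
        flags.append(bool(sd < tolerance and in_band))
        entered.append(_entered_and_stayed(c, m, tolerance, trials))
    return ConvergenceReport(
        trailing_window=trailing_window,
        tolerance=float(tolerance),
        trailing_mean=tuple(means),
        trailing_sd=tuple(sds),
        converged=tuple(flags),
        entered_trial=tuple(entered),
    )


def recovery_stats(
    log: TrajectoryLog,
    shock_trial: int,
    dim: int = 1,
    tolerance: float = 5.0,
    baseline_window: int = 150,
    sustain: int | None = None,
) -> RecoveryReport:
    """Recovery of one center after a forced displacement.

    The pre-shock baseline is the trailing mean of the center over
    ``baseline_window`` trials before the shock.  The loop counts as
    recovered at the first post-shock trial from which the center sits
    within ``tolerance`` of that baseline for ``sustain`` consecutive trials
    (default: ``baseline_window``) or through the end of the log if it ends
    sooner — a shock at the final trial is therefore unrecovered.
    """
    df = log.frame
    trials = df["trial"].to_numpy()
    c = log.centers(dim)
    pos = np.where(trials == shock_trial)[0]
    if pos.size == 0:
        raise ValueError(f"shock trial {shock_trial} not in log")
    p = int(pos[0])
    if p < 1:
        raise ValueError("no pre-shock trials to form a baseline")
    lo = max(0, p - baseline_window)
    baseline = float(np.mean(c[lo:p]))
    displacement = float(c[p] - baseline)
    sustain = baseline_window if sustain is None else int(sustain)

    post = c[p:]
    post_trials = trials[p:]
    if post.size <= 1 and abs(displacement) > tolerance:
        return RecoveryReport(dim, int(shock_trial), displacement, baseline,
                              float(tolerance), False, None, None)
    inside = np.abs(post - baseline) <= tolerance
    rec_idx = None
    run = 0
    for j in range(inside.size - 1, -1, -1):
        run = run + 1 if inside[j] else 0
        if inside[j] and (run >= sustain or j + run == inside.size):
            rec_idx = j
    if rec_idx is None:
        return RecoveryReport(dim, int(shock_trial), displacement, baseline,
                              float(tolerance), False, None, None)
    rec_trial = int(post_trials[rec_idx])
    return RecoveryReport(
        dim=dim,
        shock_trial=int(shock_trial),
        displacement=displacement,
        baseline=baseline,
        tolerance=float(tolerance),
        recovered=True,
        recovery_trial=rec_trial,
        recovery_duration=rec_trial - int(shock_trial),
    )


def crosstalk(omegas: Sequence[float], n_window: int) -> np.ndarray:
    """Normalized demodulation leakage between dither frequencies.

    Entry (a, b) is ``(2/n) * |sum_{i=1..n} cos(omega_a i) cos(omega_b i)|``:
    how strongly a unit-amplitude oscillation at ``omega_b`` contaminates
    the demodulated signal at ``omega_a`` over a window of ``n`` trials.
    The diagonal is ~1 (exactly 1 on whole-period windows); off-diagonal
    entries should be small for well-separated frequencies.
    """
    om = np.asarray(omegas, dtype=float)
    if np.any(om <= 0):
        raise ValueError("all frequencies must be positive")
    n = int(n_window)
    i = np.arange(1, n + 1)
    C = np.cos(np.outer(om, i))  # (K, n)
    return (2.0 / n) * np.abs(C @ C.T)
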