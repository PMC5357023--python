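"""Lock-in feedback controller.

A lock-in feedback (LiF) loop optimizes a noisy scalar response over one or
more continuous treatment variables.  Each treatment dimension is dithered
sinusoidally around a slowly-moving center::

    x_i = center + delta * cos(omega * i)

where ``i`` is the trial (participant) index — the time base is the sequence
of trials, not a clock.  The observed responses are demodulated over a
sliding window of ``n_window`` trials by multiplying with ``cos(omega * i)``
and summing; for a locally quadratic response the resulting *lock-in sum* is
proportional to the local gradient, so adding ``gamma`` times the sum to the
(window-averaged) center performs gradient ascent toward the optimum.

Phase bookkeeping always uses the absolute trial index, so the dither phase
is continuous across window slides and across shocks.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DimensionConfig",
    "DimensionState",
    "LockinResult",
    "SpectralDiagnostics",
    "LockInController",
    "SequencingError",
    "WarmupError",
    "DataError",
    "propose_stimulus",
    "record_response",
    "lockin_sum",
    "update_center",
    "spectral_diagnostics",
    "suggest_window",
]


class SequencingError(RuntimeError):
    """A trial index was skipped, duplicated or out of order."""


class WarmupError(RuntimeError):
    """An update was requested before a full demodulation window accumulated."""


class DataError(ValueError):
    """An observed response is unusable (non-finite or missing)."""


@dataclass(frozen=True)
class DimensionConfig:
    """Static LiF parameters for one treatment dimension.

    Parameters
    ----------
    omega : float
        Angular dither frequency, radians per trial.  Must be positive.
        A frequency whose period is not an integer number of trials avoids
        aliasing with the window length; ``suggest_window`` finds window
        lengths spanning whole periods when exact orthogonality is wanted.
    delta : float
        Dither amplitude in attribute units.  ``delta = 0`` disables the
        probe entirely (the controller degenerates to a static design).
    gamma : float
        Learn rate converting a lock-in sum into a center displacement,
        attribute units per (response x trial) unit.
    n_window : int
        Demodulation window length in trials (>= 2).  Also the warm-up
        length: the center stays at ``x_init`` for the first ``n_window``
        trials.
    x_init : float
        Initial center.
    lo, hi : float
        Closed attribute bounds.  Proposals are clipped to ``[lo, hi]``;
        centers are clipped to ``[lo + delta, hi - delta]`` so the full
        dither always fits inside the bounds.
    direction : str
        ``"maximize"`` (default) or ``"minimize"``.
    """

    omega: float
    delta: float
    gamma: float
    n_window: int
    x_init: float
    lo: float = 1.0
    hi: float = 100.0
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if self.n_window < 2:
            raise ValueError(f"n_window must be >= 2, got {self.n_window}")
        if self.lo >= self.hi:
            raise ValueError(f"empty bounds [{self.lo}, {self.hi}]")
        if not (self.lo + self.delta <= self.x_init <= self.hi - self.delta):
            raise ValueError(
                f"x_init={self.x_init} leaves no room for the dither "
                f"within [{self.lo}, {self.hi}] at delta={self.delta}"
            )
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be maximize|minimize, got {self.direction!r}")

    @property
    def sign(self) -> float:
        """Ascent/descent sign applied to ``gamma * y_lock``."""
        return 1.0 if self.direction == "maximize" else -1.0

    def center_bounds(self) -> tuple[float, float]:
        return self.lo + self.delta, self.hi - self.delta


@dataclass
class DimensionState:
    """Evolving state of one dithered dimension.

    ``center`` is the operating point x-tilde the feedback updates;
    ``buffer`` keeps the most recent up-to-``n_window`` (trial, response)
    pairs; ``center_history`` records the center *used* at every past trial,
    which the update rule averages over the window.
    """

    center: float
    trial: int = 0  # last trial processed; proposals are for trial + 1
    buffer: deque = field(default_factory=deque)
    center_history: list = field(default_factory=list)
    _pending: tuple | None = None  # (trial, proposed value) awaiting a response

    @classmethod
    def fresh(cls, config: "DimensionConfig") -> "DimensionState":
        """Initial state with a ring buffer sized to the config's window."""
        return cls(center=config.x_init, buffer=deque(maxlen=config.n_window))

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "trial": self.trial,
            "buffer": [[int(t), float(y)] for t, y in self.buffer],
            "center_history": [float(c) for c in self.center_history],
        }

    @classmethod
    def from_dict(cls, d: dict, n_window: int | None = None) -> "DimensionState":
        st = cls(center=d["center"], trial=d["trial"])
        st.buffer = deque(((int(t), float(y)) for t, y in d["buffer"]), maxlen=n_window)
        st.center_history = list(d["center_history"])
        return st


@dataclass(frozen=True)
class LockinResult:
    """Windowed cosine-weighted sum of responses."""

    y_lock: float
    window_start: int
    window_end: int


@dataclass(frozen=True)
class SpectralDiagnostics:
    """Fitted first- and second-harmonic content of a response window.

    The sign of ``amp_omega`` encodes the phase of the response relative to
    the dither: positive means in phase (center below the optimum of a
    concave response), negative means anti-phase (center above it), and
    ``amp_omega ~ 0`` with ``amp_2omega != 0`` signals the center sitting at
    the optimum, where the quadratic term folds the dither onto the doubled
    frequency.
    """

    amp_omega: float
    amp_2omega: float
    mean_level: float


# ---------------------------------------------------------------------------
# Per-dimension operations


def propose_stimulus(state: DimensionState, config: DimensionConfig, trial: int) -> float:
    """Dithered stimulus for ``trial``: center + delta*cos(omega*trial), clipped.

    ``trial`` must be ``state.trial + 1``; a gap or repeat signals a skipped
    or duplicated participant and raises :class:`SequencingError`.
    """
    if trial != state.trial + 1:
        raise SequencingError(
            f"expected trial {state.trial + 1}, got {trial} (skipped or duplicated?)"
        )
    x = state.center + config.delta * math.cos(config.omega * trial)
    x = min(max(x, config.lo), config.hi)
    state._pending = (trial, x)
    state.center_history.append(state.center)
    return x


def record_response(state: DimensionState, trial: int, y: float) -> DimensionState:
    """Append ``(trial, y)`` to the ring buffer, evicting the oldest entry."""
    if state._pending is None or state._pending[0] != trial:
        expected = None if state._pending is None else state._pending[0]
        raise SequencingError(f"response for trial {trial}, but proposal was for {expected}")
    if not math.isfinite(y):
        raise DataError(f"non-finite response {y!r} at trial {trial}")
    state.buffer.append((trial, float(y)))
    state.trial = trial
    state._pending = None
    return state


def lockin_sum(buffer, omega: float, n_window: int | None = None) -> LockinResult:
    """Demodulate a full window: ``y_lock = sum_i y_i * cos(omega * i)``.

    Each entry's *absolute* trial index enters the cosine, not its position
    in the buffer.  ``buffer`` must hold exactly ``n_window`` consecutive
    entries (``n_window`` defaults to the buffer length).
    """
    entries = list(buffer)
    n = len(entries) if n_window is None else int(n_window)
    if len(entries) < n or n == 0:
        raise WarmupError(f"need {n} responses for a lock-in sum, have {len(entries)}")
    entries = entries[-n:]
    idx = np.array([t for t, _ in entries], dtype=np.int64)
    if not np.all(np.diff(idx) == 1):
        raise SequencingError("buffer trial indices are not consecutive")
    y = np.array([v for _, v in entries], dtype=float)
    y_lock = float(np.dot(y, np.cos(omega * idx)))
    return LockinResult(y_lock=y_lock, window_start=int(idx[0]), window_end=int(idx[-1]))


def update_center(
    state: DimensionState,
    config: DimensionConfig,
    lock: LockinResult,
    *,
    raw_sign: bool = False,
    baseline: str = "current",
) -> float:
    """Feedback update: baseline center plus ``gamma`` times the lock-in sum.

    ``baseline="current"`` (default) starts from the instantaneous center —
    the classic ascent rule ``x0 := x0 + gamma * y_lock`` — whose closed-loop
    contraction per trial is ``gamma*|a|*delta*n`` for local curvature ``a``.
    ``baseline="window_mean"`` starts from the mean of the centers used over
    the demodulation window instead; with per-trial sliding updates that
    variant filters center noise much harder but slows convergence by a
    factor ~``n/2``, so it is offered for sensitivity analysis rather than
    as the default.

    The displacement is ``+gamma*y_lock`` when maximizing and
    ``-gamma*y_lock`` when minimizing; ``raw_sign=True`` flips that (a
    compatibility convention — for a concave response it walks away from
    the optimum).  The result is clipped so ``center +/- delta`` stays
    within bounds.
    """
    n = config.n_window
    if len(state.center_history) < n:
        raise WarmupError("update before warm-up completed")
    if baseline == "window_mean":
        base = float(np.mean(state.center_history[-n:]))
    elif baseline == "current":
        base = state.center
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    s = -config.sign if raw_sign else config.sign
    new = base + s * config.gamma * lock.y_lock
    lo_c, hi_c = config.center_bounds()
    return min(max(new, lo_c), hi_c)


def spectral_diagnostics(buffer, omega: float, n_window: int | None = None) -> SpectralDiagnostics:
    """First/second-harmonic amplitudes and mean of a full response window.

    ``amp_omega = (2/n) sum y_i cos(omega i)`` and likewise at ``2*omega``.
    An all-zero window yields all-zero diagnostics.
    """
    entries = list(buffer)
    n = len(entries) if n_window is None else int(n_window)
    if len(entries) < n or n == 0:
        raise WarmupError(f"need {n} responses for diagnostics, have {len(entries)}")
    entries = entries[-n:]
    idx = np.array([t for t, _ in entries], dtype=np.int64)
    y = np.array([v for _, v in entries], dtype=float)
    return SpectralDiagnostics(
        amp_omega=float(2.0 / n * np.dot(y, np.cos(omega * idx))),
        amp_2omega=float(2.0 / n * np.dot(y, np.cos(2.0 * omega * idx))),
        mean_level=float(np.mean(y)),
    )


def suggest_window(omega: float, max_n: int = 10_000) -> int:
    """Smallest window length spanning a whole number of dither periods.

    Returns the smallest ``n <= max_n`` with ``omega * n`` an integer
    multiple of ``2*pi`` (to ~1e-9 relative tolerance); if no exact match
    exists, the ``n`` minimizing the fractional part of ``omega*n/(2*pi)``.
    Whole-period windows make the demodulation exactly orthogonal to
    constants and to other harmonics, which removes leakage terms.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    best_n, best_err = 1, math.inf
    for n in range(2, max_n + 1):
        cycles = omega * n / (2.0 * math.pi)
        err = abs(cycles - round(cycles))
        if round(cycles) >= 1 and err < 1e-9 * max(1.0, cycles):
            return n
        if round(cycles) >= 1 and err < best_err:
            best_n, best_err = n, err
    return best_n


# ---------------------------------------------------------------------------
# Multi-dimensional controller


class LockInController:
    """K parallel lock-in loops sharing one scalar response per trial.

    Each dimension runs its own frequency, window and learn rate; all share
    the trial index.  During each dimension's warm-up (its first ``n_window``
    trials) the center is held at ``x_init``; afterwards the center is
    updated on every trial from the sliding window.

    Parameters
    ----------
    configs : sequence of DimensionConfig
    raw_sign : bool
        Apply the literal-minus update convention (see ``update_center``).
    baseline : str
        ``"current"`` (default) or ``"window_mean"`` — see ``update_center``.
    quantize : bool
        Round proposals to integers (a discrete stimulus grid) before
        clipping.  Off by default.
    first_trial : int
        Index of the first trial the controller will see (default 1).  The
        dither phase follows absolute trial indices, so a recorded stream
        numbered from an arbitrary offset replays with its original phase.
    """

    def __init__(
        self,
        configs,
        *,
        raw_sign: bool = False,
        baseline: str = "current",
        quantize: bool = False,
        first_trial: int = 1,
    ):
        self.configs: list[DimensionConfig] = list(configs)
        if not self.configs:
            raise ValueError("at least one dimension required")
        self.states = [DimensionState.fresh(c) for c in self.configs]
        for st in self.states:
            st.trial = int(first_trial) - 1
        self.raw_sign = bool(raw_sign)
        self.baseline = baseline
        self.quantize = bool(quantize)
        self.last_locks: list[LockinResult | None] = [None] * len(self.configs)

    @property
    def k(self) -> int:
        return len(self.configs)

    @property
    def trial(self) -> int:
        return self.states[0].trial

    @property
    def centers(self) -> list[float]:
        return [st.center for st in self.states]

    def propose(self, trial: int) -> list[float]:
        """Stimulus values for ``trial`` across all dimensions."""
        xs = [propose_stimulus(st, cfg, trial) for st, cfg in zip(self.states, self.configs)]
        if self.quantize:
            for d, (x, cfg) in enumerate(zip(xs, self.configs)):
                xs[d] = min(max(float(round(x)), cfg.lo), cfg.hi)
                self.states[d]._pending = (trial, xs[d])
        return xs

    def observe(self, trial: int, y: float) -> None:
        """Record the shared response and update every warmed-up dimension."""
        for st in self.states:
            record_response(st, trial, y)
        for d, (st, cfg) in enumerate(zip(self.states, self.configs)):
            if len(st.buffer) >= cfg.n_window:
                lock = lockin_sum(st.buffer, cfg.omega, cfg.n_window)
                self.last_locks[d] = lock
                st.center = update_center(
                    st, cfg, lock, raw_sign=self.raw_sign, baseline=self.baseline
                )
            else:
                self.last_locks[d] = None

    def step(self, trial: int, y: float) -> list[float]:
        """Record ``y`` for ``trial``, update centers, propose the next trial."""
        self.observe(trial, y)
        return self.propose(trial + 1)

    def force_center(self, dim: int, value: float) -> None:
        """Externally shock one dimension's center (clipped to its band)."""
        cfg = self.configs[dim]
        lo_c, hi_c = cfg.center_bounds()
        self.states[dim].center = min(max(float(value), lo_c), hi_c)

    # -- persistence ---------------------------------------------------

    def to_json(self) -> str:
        """JSON snapshot of all dimension states, for resumable runs."""
        return json.dumps(
            {
                "raw_sign": self.raw_sign,
                "baseline": self.baseline,
                "quantize": self.quantize,
                "states": [st.to_dict() for st in self.states],
            }
        )

    @classmethod
    def from_json(cls, payload: str, configs) -> "LockInController":
        d = json.loads(payload)
        ctl = cls(
            configs,
            raw_sign=d["raw_sign"],
            baseline=d["baseline"],
            quantize=d["quantize"],
        )
        if len(d["states"]) != ctl.k:
            raise ValueError("snapshot dimensionality does not match configs")
        ctl.states = [
            DimensionState.from_dict(s, n_window=cfg.n_window)
            for s, cfg in zip(d["states"], ctl.configs)
        ]
        return ctl
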