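"""Trial-level run records and the trajectory log container.

A :class:`TrajectoryLog` wraps a pandas DataFrame with one row per trial:
the stimuli shown, the observed response, the per-dimension centers in
force at that trial, and (after warm-up) the per-dimension lock-in sums.
It round-trips through CSV with 9 significant digits so downstream reports
are unchanged by serialization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialRecord", "TrajectoryLog"]


@dataclass(frozen=True)
class TrialRecord:
    """One observation: trial index, shown stimuli, response, centers."""

    trial: int
    shown: tuple
    y: float
    centers: tuple


class TrajectoryLog:
    """Ordered per-trial record of a closed-loop run.

    Columns: ``trial``, ``x{d}_shown``, ``y``, ``center{d}``, ``ylock{d}``
    for each dimension ``d`` starting at 1.  ``ylock`` columns are NaN
    during warm-up, when no full demodulation window exists yet.
    """

    def __init__(self, k: int, meta: dict | None = None):
        self.k = int(k)
        self.meta = dict(meta or {})
        self._rows: list[dict] = []
        self._frame: pd.DataFrame | None = None

    @property
    def columns(self) -> list[str]:
        cols = ["trial"]
        cols += [f"x{d}_shown" for d in range(1, self.k + 1)]
        cols += ["y"]
        cols += [f"center{d}" for d in range(1, self.k + 1)]
        cols += [f"ylock{d}" for d in range(1, self.k + 1)]
        return cols

    def append(self, trial: int, shown, y: float, centers, ylocks) -> None:
        row = {"trial": int(trial), "y": float(y)}
        for d in range(self.k):
            row[f"x{d + 1}_shown"] = float(shown[d])
            row[f"center{d + 1}"] = float(centers[d])
            row[f"ylock{d + 1}"] = np.nan if ylocks[d] is None else float(ylocks[d])
        self._rows.append(row)
        self._frame = None

    def __len__(self) -> int:
        return len(self._rows) if self._frame is None else len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(self._rows, columns=self.columns)
        return self._frame

    def records(self) -> list[TrialRecord]:
        df = self.frame
        shown_cols = [f"x{d}_shown" for d in range(1, self.k + 1)]
        center_cols = [f"center{d}" for d in range(1, self.k + 1)]
        return [
            TrialRecord(
                trial=int(r["trial"]),
                shown=tuple(r[c] for c in shown_cols),
                y=float(r["y"]),
                centers=tuple(r[c] for c in center_cols),
            )
            for _, r in df.iterrows()
        ]

    def centers(self, dim: int) -> np.ndarray:
        """Center series for dimension ``dim`` (1-based)."""
        return self.frame[f"center{dim}"].to_numpy()

    def responses(self) -> np.ndarray:
        return self.frame["y"].to_numpy()

    # -- serialization --------------------------------------------------

    def to_csv(self, path) -> None:
        # 9 significant digits: enough that convergence/recovery reports
        # are identical after a round trip.
        self.frame.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "TrajectoryLog":
        df = pd.read_csv(path)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrajectoryLog":
        k = sum(1 for c in df.columns if c.startswith("center"))
        if k == 0:
            raise ValueError("frame has no center columns; not a trajectory log")
        log = cls(k, meta=meta)
        log._frame = df.reset_index(drop=True)
        log._rows = df.to_dict("records")
        return log

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectoryLog):
            return NotImplemented
        return self.k == other.k and self.frame.equals(other.frame)
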