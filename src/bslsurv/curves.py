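"""Step-function survival curves and baseline hazards.

A :class:`SurvivalCurve` is a right-continuous step function S(t) on a time
grid starting at 0 with S(0) = 1.  It is the universal prediction object of
the package: Kaplan-Meier estimates, Cox-model predictions and counterfactual
potential outcomes are all represented this way.  Evaluation between knots
takes the value of the left knot (right-continuity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step survival function on a grid starting at 0.

    Parameters
    ----------
    times : array of float
        Strictly increasing knots, ``times[0] == 0``, in months.
    surv : array of float
        Survival probabilities at the knots; ``surv[0] == 1``,
        non-increasing, all values in [0, 1].
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times and surv must be 1-d arrays of equal length")
        if t.size == 0 or t[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if abs(s[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if s.min() < -1e-12 or s.max() > 1.0 + 1e-12:
            raise ValueError("survival probabilities must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", np.clip(s, 0.0, 1.0))

    def __call__(self, t) -> np.ndarray:
        """Evaluate S(t) with the left-knot (right-continuous) convention."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        out = self.surv[idx]
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow cumulative baseline hazard, defined at observed event times."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        h = np.asarray(self.cumulative_hazard, dtype=float)
        if t.ndim != 1 or h.shape != t.shape:
            raise ValueError("event_times and cumulative_hazard must match")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(h < -1e-12) or (h.size and np.any(np.diff(h) < -1e-12)):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "cumulative_hazard", h)

    def __call__(self, t) -> np.ndarray:
        """H(t): step evaluation, 0 before the first event time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumulative_hazard[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)


def curves_to_frame(curves, ids=None, arm=None):
    """Serialize curves to long format (patient_id, time, surv[, arm])."""
    import pandas as pd

    rows = []
    for i, c in enumerate(curves):
        pid = ids[i] if ids is not None else i
        d = {"patient_id": pid, "time": c.times, "surv": c.surv}
        if arm is not None:
            d["arm"] = arm
        rows.append(pd.DataFrame(d))
    return pd.concat(rows, ignore_index=True)
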