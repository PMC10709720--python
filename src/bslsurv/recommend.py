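"""Counterfactual curve pairs -> individual treatment effects and
recommendations.

The per-patient outcome Y under an arm is the first time the predicted
survival curve reaches 50%, truncated at the horizon tau; the individual
treatment effect (ITE) is Y(gross-total) - Y(subtotal) in months, and the
recommendation is gross-total resection exactly when the ITE is positive
(ties resolve to the less extensive surgery and are flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SurvivalCurve
from .survival import median_survival

__all__ = ["PotentialOutcomes", "ITERecord", "compute_ite", "recommend_batch",
           "consistency_labels"]

STR, GTR = 0, 1


@dataclass
class PotentialOutcomes:
    """Counterfactual survival matrices on a shared grid.

    ``surv_str`` and ``surv_gtr`` are (n_patients, len(grid)) step-function
    values; row i holds patient i's predicted curves under each arm.
    """

    grid: np.ndarray
    surv_str: np.ndarray
    surv_gtr: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.surv_str = np.atleast_2d(np.asarray(self.surv_str, dtype=float))
        self.surv_gtr = np.atleast_2d(np.asarray(self.surv_gtr, dtype=float))
        if self.surv_str.shape != self.surv_gtr.shape or \
                self.surv_str.shape[1] != self.grid.size:
            raise ValueError("both curve matrices must share the grid")

    @property
    def n(self) -> int:
        return self.surv_str.shape[0]

    def curve(self, i: int, arm: int) -> SurvivalCurve:
        s = (self.surv_gtr if arm == GTR else self.surv_str)[i]
        return SurvivalCurve(self.grid, np.minimum.accumulate(np.clip(s, 0, 1)))

    def to_frame(self, ids=None) -> pd.DataFrame:
        """Long-format export (patient_id, arm, time, surv)."""
        frames = []
        for arm, S in ((STR, self.surv_str), (GTR, self.surv_gtr)):
            for i in range(self.n):
                pid = ids[i] if ids is not None else i
                frames.append(pd.DataFrame({
                    "patient_id": pid, "arm": arm,
                    "time": self.grid, "surv": S[i]}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class ITERecord:
    y0: float           # months to 50% mortality under subtotal resection
    y1: float           # months under gross-total resection
    ite: float          # y1 - y0
    recommendation: int  # 1 = gross-total resection
    truncated0: bool
    truncated1: bool


def _median_from_matrix(grid, S, tau):
    """Vectorized first-crossing-of-0.5 with truncation at tau."""
    within = grid[None, :] <= tau
    hit = (S <= 0.5) & within
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1), 0)
    y = np.where(any_hit, np.minimum(grid[first], tau), tau)
    return y, ~any_hit


def compute_ite(po: PotentialOutcomes, tau: float = 60.0,
                tie_break: str = "curve"):
    """ITE records for every patient in a PotentialOutcomes container.

    The recommendation is gross-total resection when the ITE is positive and
    subtotal when it is negative.  A cohort with a low event rate leaves many
    patients with both truncated medians equal to the horizon (ite = 0); the
    default ``tie_break="curve"`` then recommends gross-total exactly when
    its predicted curve is strictly higher at the horizon, while
    ``tie_break="str"`` sends every tie to the less extensive surgery.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tie_break not in ("curve", "str"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    y0, tr0 = _median_from_matrix(po.grid, po.surv_str, tau)
    y1, tr1 = _median_from_matrix(po.grid, po.surv_gtr, tau)
    ite = y1 - y0
    rec = (ite > 0).astype(int)
    if tie_break == "curve":
        at_tau = np.searchsorted(po.grid, tau, side="right") - 1
        s0 = po.surv_str[:, at_tau]
        s1 = po.surv_gtr[:, at_tau]
        tie = ite == 0
        rec[tie] = (s1[tie] > s0[tie]).astype(int)
    return [ITERecord(float(y0[i]), float(y1[i]), float(ite[i]), int(rec[i]),
                      bool(tr0[i]), bool(tr1[i])) for i in range(po.n)]


def compute_ite_single(curve_str: SurvivalCurve, curve_gtr: SurvivalCurve,
                       tau: float = 60.0) -> ITERecord:
    """ITE from an explicit pair of survival curves (shared grid)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    y0 = median_survival(curve_str, tau)
    y1 = median_survival(curve_gtr, tau)
    ite = y1 - y0
    return ITERecord(y0, y1, ite, int(ite > 0), y0 == tau and
                     min(curve_str.surv[curve_str.times <= tau]) > 0.5,
                     y1 == tau and min(curve_gtr.surv[curve_gtr.times <= tau]) > 0.5)


def recommend_batch(model, X, tau: float = 60.0, grid=None,
                    tie_break: str = "curve") -> pd.DataFrame:
    """One recommendation row per patient; deterministic given the model."""
    from .model import predict_potential_outcomes

    po = predict_potential_outcomes(model, X, grid=grid)
    records = compute_ite(po, tau, tie_break=tie_break)
    return pd.DataFrame({
        "y0": [r.y0 for r in records],
        "y1": [r.y1 for r in records],
        "ite": [r.ite for r in records],
        "recommendation": [r.recommendation for r in records],
        "truncated0": [r.truncated0 for r in records],
        "truncated1": [r.truncated1 for r in records],
    })


def consistency_labels(recommendations, actual) -> np.ndarray:
    """"Consis" where the received treatment matches the recommendation."""
    rec = np.asarray(recommendations)
    act = np.asarray(actual)
    if rec.shape != act.shape:
        raise ValueError("recommendations and actual treatments differ in length")
    return np.where(rec == act, "Consis", "In-consis")
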