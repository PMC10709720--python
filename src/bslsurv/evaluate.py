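"""Model scoring and recommendation-effect estimation.

Discrimination is Harrell's concordance index; calibration is the
censoring-weighted integrated Brier score.  The recommendation effect
contrasts patients whose actual surgery matched the model's recommendation
("Consis") against those whose did not ("In-consis"), via the difference in
restricted mean survival time (with a percentile bootstrap CI) and an
unadjusted Cox hazard ratio, alongside Kaplan-Meier curves and a log-rank p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import kaplan_meier, log_rank, rmst

__all__ = ["concordance_index", "integrated_brier_score", "drmst",
           "recommendation_hr", "EvalReport", "evaluate_model"]


def concordance_index(eta, time, event) -> float:
    """Harrell's C: concordant / comparable pairs; eta ties count 1/2.

    A pair is comparable when the earlier time is an observed event; higher
    eta must predict shorter survival.
    """
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    lt = time[:, None] < time[None, :]
    comparable = lt & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    gt_eta = eta[:, None] > eta[None, :]
    eq_eta = eta[:, None] == eta[None, :]
    concordant = (comparable & gt_eta).sum() + 0.5 * (comparable & eq_eta).sum()
    return float(concordant / n_comp)


def integrated_brier_score(curves, time, event, t_max: float | None = None,
                           grid=None) -> float:
    """IPCW-weighted Brier score integrated over [0, t_max] / t_max.

    ``curves`` is either a list of SurvivalCurve or an (n, len(grid)) matrix
    with ``grid`` supplied.  The censoring distribution G is the
    Kaplan-Meier estimator of the flipped event indicator; times where G
    reaches 0 before t_max are truncated from the integration grid with a
    warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n = len(time)
    if t_max is None:
        t_max = float(np.quantile(time, 0.95))
    if t_max > time.max():
        raise ValueError("t_max exceeds maximum follow-up")

    # t = 0 is degenerate (S(0) = 1 for every model), so the integral runs
    # over the positive evaluation times with BS left-extended to 0
    eval_times = np.unique(np.concatenate([time[time <= t_max], [t_max]]))
    eval_times = eval_times[eval_times > 0]
    if grid is None:
        S = np.vstack([c(eval_times) for c in curves])
    else:
        grid = np.asarray(grid, dtype=float)
        curves = np.atleast_2d(np.asarray(curves, dtype=float))
        idx = np.clip(np.searchsorted(grid, eval_times, side="right") - 1, 0, None)
        S = curves[:, idx]

    G = kaplan_meier(time, 1 - event)
    G_at = np.asarray(G(eval_times))
    # G evaluated just before each subject's own time (left limit)
    G_T = np.asarray(G(np.maximum(time - 1e-9, 0.0)))

    alive = G_at > 0
    if not alive.all():
        warnings.warn("censoring survival reached 0 before t_max; grid truncated")
        eval_times, S, G_at = eval_times[alive], S[:, alive], G_at[alive]

    died = ((time[:, None] <= eval_times[None, :]) & (event[:, None] == 1))
    at_risk = time[:, None] > eval_times[None, :]
    w_died = np.where(G_T[:, None] > 0, died / np.maximum(G_T[:, None], 1e-300), 0.0)
    bs_t = (S ** 2 * w_died + (1.0 - S) ** 2 * at_risk / G_at[None, :]).mean(axis=0)

    area = bs_t[0] * eval_times[0] + np.trapezoid(bs_t, eval_times)
    return float(area / eval_times[-1])


def drmst(time, event, labels, tau: float = 60.0, n_boot: int = 1000,
          seed: int = 0, level: float = 0.95):
    """Difference in restricted mean survival time, Consis minus In-consis.

    Point estimate from the two groups' Kaplan-Meier curves; percentile
    bootstrap CI resampling patients within the whole sample.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = np.asarray(labels)
    is_c = labels == "Consis"
    if is_c.sum() < 2 or (~is_c).sum() < 2:
        raise ValueError("each consistency group needs at least 2 patients")

    def point(t, e, c):
        return rmst(kaplan_meier(t[c], e[c]), tau) - rmst(kaplan_meier(t[~c], e[~c]), tau)

    est = point(time, event, is_c)
    rng = np.random.default_rng(seed)
    n = len(time)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        c = is_c[idx]
        if c.sum() < 2 or (~c).sum() < 2 or event[idx][c].sum() == 0 \
                or event[idx][~c].sum() == 0:
            continue
        boots.append(point(time[idx], event[idx], c))
    a = (1.0 - level) / 2.0
    lo, hi = (np.quantile(boots, [a, 1 - a]) if boots else (np.nan, np.nan))
    return float(est), (float(lo), float(hi))


def recommendation_hr(time, event, labels, level: float = 0.95):
    """Unadjusted Cox HR of the Consis indicator (Consis = 1), Wald CI.

    HR < 1 means following the model's recommendation is protective.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    labels = np.asarray(labels)
    is_c = (labels == "Consis").astype(float)
    if is_c.min() == is_c.max():
        raise ValueError("both consistency groups must be non-empty")
    df = pd.DataFrame({"consis": is_c, "time": np.asarray(time, dtype=float),
                       "event": np.asarray(event).astype(int)})
    if df.groupby("consis")["event"].sum().min() == 0:
        raise ValueError("a consistency group has no events")
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError("Cox fit failed (possible complete separation)") from exc
    z = float(abs(np.round(_norm_ppf((1 - level) / 2), 10)))
    coef = float(cph.params_["consis"])
    se = float(cph.standard_errors_["consis"])
    return float(np.exp(coef)), (float(np.exp(coef - z * se)),
                                 float(np.exp(coef + z * se)))


def _norm_ppf(q):
    from scipy.stats import norm
    return norm.ppf(q)


@dataclass
class EvalReport:
    c_index: dict
    ibs: dict
    drmst: float
    drmst_ci: tuple
    hr: float
    hr_ci: tuple
    log_rank_p: float
    n_consis: int
    n_inconsis: int
    km: dict = field(default_factory=dict, repr=False)

    def to_dict(self):
        return {
            "c_index": self.c_index, "ibs": self.ibs,
            "drmst": self.drmst, "drmst_ci": list(self.drmst_ci),
            "hr": self.hr, "hr_ci": list(self.hr_ci),
            "log_rank_p": self.log_rank_p,
            "n_consis": self.n_consis, "n_inconsis": self.n_inconsis,
        }


def evaluate_model(model, dm, tau: float = 60.0, seed: int = 0,
                   n_boot: int = 1000) -> EvalReport:
    """Full test-set report: discrimination, calibration, recommendation effect.

    C-index and IBS are computed per arm from the factual-arm predictions
    (each arm's subjects scored by that arm's head) and overall by pooling
    the factual predictions.
    """
    from .model import predict_potential_outcomes
    from .recommend import compute_ite, consistency_labels

    e0, e1 = model.predict_eta(dm.X)
    eta_fact = np.where(dm.treatment == 1, e1, e0)

    po = predict_potential_outcomes(model, dm.X)
    S_fact = np.where((dm.treatment == 1)[:, None], po.surv_gtr, po.surv_str)

    c_index, ibs = {}, {}
    t_max = float(np.quantile(dm.time, 0.95))
    for name, rows in (("overall", np.arange(dm.n)),
                       ("str", np.flatnonzero(dm.treatment == 0)),
                       ("gtr", np.flatnonzero(dm.treatment == 1))):
        c_index[name] = concordance_index(eta_fact[rows], dm.time[rows],
                                          dm.event[rows])
        ibs[name] = integrated_brier_score(
            S_fact[rows], dm.time[rows], dm.event[rows],
            t_max=min(t_max, float(dm.time[rows].max())), grid=po.grid)

    records = compute_ite(po, tau)
    rec = np.array([r.recommendation for r in records])
    labels = consistency_labels(rec, dm.treatment)
    est, ci = drmst(dm.time, dm.event, labels, tau=tau, seed=seed, n_boot=n_boot)
    hr, hr_ci = recommendation_hr(dm.time, dm.event, labels)
    _, p = log_rank(dm.time, dm.event, (labels == "Consis").astype(int))

    km = {g: kaplan_meier(dm.time[labels == g], dm.event[labels == g])
          for g in ("Consis", "In-consis")}
    return EvalReport(c_index, ibs, est, ci, hr, hr_ci, p,
                      int((labels == "Consis").sum()),
                      int((labels == "In-consis").sum()), km)
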