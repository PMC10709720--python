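"""Model interpretation: time-dependent Shapley attribution of survival
curves and a linear-Shapley view of a logistic recommendation surrogate.

The time-dependent attribution assigns each covariate j a curve phi_j(t)
such that, at every time point, the attributions sum to the difference
between the patient's predicted survival curve and the background-average
curve (local accuracy).  Out-of-coalition features are marginalized
interventionally: they are replaced by the values of background rows drawn
from the data.  Exact enumeration over all coalitions is available for
small feature counts and anchors the Monte-Carlo permutation estimator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Attribution", "survshap_t", "survshap_t_exact", "aggregate_ranks",
           "fit_recommendation_surrogate"]


@dataclass
class Attribution:
    """Per-feature attribution curves for one patient.

    phi has shape (n_features, len(grid)); ``aggregate`` is the time
    integral of |phi_j(t)| (trapezoid on the grid), used for importance
    ranking.
    """

    grid: np.ndarray
    phi: np.ndarray
    feature_names: list
    baseline: np.ndarray        # background-average survival curve
    prediction: np.ndarray      # the explained patient's survival curve

    @property
    def aggregate(self) -> np.ndarray:
        return np.trapezoid(np.abs(self.phi), self.grid, axis=1)

    def local_accuracy_residual(self) -> float:
        return float(np.max(np.abs(self.phi.sum(0)
                                   - (self.prediction - self.baseline))))

    def to_frame(self, patient_id=0) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.feature_names):
            rows.append(pd.DataFrame({"patient_id": patient_id, "feature": name,
                                      "t": self.grid, "phi": self.phi[j]}))
        return pd.concat(rows, ignore_index=True)


def _groupwise(model, arm: int | None):
    """Survival-matrix prediction function S(t) for a model, optional arm.

    arm=None averages the two counterfactual heads (the combined output);
    arm=0/1 explains a single conditional output head.
    """
    from .model import predict_potential_outcomes

    def fn(X, grid):
        po = predict_potential_outcomes(model, X, grid=grid)
        if arm == 0:
            return po.surv_str
        if arm == 1:
            return po.surv_gtr
        return 0.5 * (po.surv_str + po.surv_gtr)

    return fn


def _value_function(predict, x, background, grid):
    """v(S) = mean over background rows of the curve with x on coalition S."""
    nb = background.shape[0]

    def v(coalition_mask):
        Xa = background.copy()
        Xa[:, coalition_mask] = x[coalition_mask]
        return predict(Xa, grid).mean(axis=0)

    return v


def survshap_t(model, x, background, grid=None, n_samples: int = 200,
               seed: int = 0, arm: int | None = None) -> Attribution:
    """Monte-Carlo permutation estimate of time-dependent Shapley curves.

    For each sampled permutation of the features, each feature's marginal
    contribution to the background-marginalized survival curve is accrued as
    it joins the coalition; the average over permutations is the Shapley
    attribution.  Local accuracy holds exactly per permutation, hence in the
    estimate.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    if grid is None:
        from .model import predict_potential_outcomes
        grid = predict_potential_outcomes(model, x[None, :]).grid
    grid = np.asarray(grid, dtype=float)

    predict = _groupwise(model, arm) if hasattr(model, "predict_eta") else model
    v = _value_function(predict, x, background, grid)
    rng = np.random.default_rng(seed)

    phi = np.zeros((p, grid.size))
    for _ in range(n_samples):
        perm = rng.permutation(p)
        mask = np.zeros(p, dtype=bool)
        prev = v(mask)
        for j in perm:
            mask[j] = True
            cur = v(mask)
            phi[j] += cur - prev
            prev = cur
    phi /= n_samples

    base = v(np.zeros(p, dtype=bool))
    pred = v(np.ones(p, dtype=bool))
    names = [c[0] for c in getattr(model, "columns", [])] or \
        [f"x{j}" for j in range(p)]
    return Attribution(grid, phi, names, base, pred)


def survshap_t_exact(model, x, background, grid=None,
                     arm: int | None = None) -> Attribution:
    """Exact Shapley curves by enumeration over all 2^p coalitions."""
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    if p > 12:
        raise ValueError("exact enumeration is limited to p <= 12")
    if grid is None:
        from .model import predict_potential_outcomes
        grid = predict_potential_outcomes(model, x[None, :]).grid
    grid = np.asarray(grid, dtype=float)
    predict = _groupwise(model, arm) if hasattr(model, "predict_eta") else model
    v = _value_function(predict, x, background, grid)

    values = {}
    for r in range(p + 1):
        for S in itertools.combinations(range(p), r):
            mask = np.zeros(p, dtype=bool)
            mask[list(S)] = True
            values[S] = v(mask)

    phi = np.zeros((p, grid.size))
    fact = math.factorial
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for r in range(p):
            w = fact(r) * fact(p - r - 1) / fact(p)
            for S in itertools.combinations(others, r):
                Sj = tuple(sorted(S + (j,)))
                phi[j] += w * (values[Sj] - values[S])

    names = [c[0] for c in getattr(model, "columns", [])] or \
        [f"x{j}" for j in range(p)]
    return Attribution(grid, phi, names, values[()],
                       values[tuple(range(p))])


def aggregate_ranks(attributions) -> pd.DataFrame:
    """Global importance table from per-patient attributions.

    For every feature: the count of patients at each importance rank
    (rank 1 = largest integrated |phi| for that patient) and the total
    aggregated |phi|; rows ordered by the total, descending.
    """
    attributions = list(attributions)
    if not attributions:
        raise ValueError("need at least one attribution")
    names = attributions[0].feature_names
    p = len(names)
    counts = np.zeros((p, p), dtype=int)
    total = np.zeros(p)
    for att in attributions:
        agg = att.aggregate
        order = np.argsort(-agg, kind="stable")
        for rank, j in enumerate(order):
            counts[j, rank] += 1
        total += agg
    df = pd.DataFrame(counts, index=names,
                      columns=[f"rank_{r + 1}" for r in range(p)])
    df["aggregate_abs_phi"] = total
    return df.sort_values("aggregate_abs_phi", ascending=False)


def fit_recommendation_surrogate(X, recommendations, feature_names=None):
    """Logistic surrogate of the recommendation rule + linear Shapley values.

    Fits recommendation ~ X by logistic regression and returns, per patient
    and feature, the exact linear Shapley value on the logit scale,
    phi_j = beta_j (x_j - mean(x_j)), together with a signed summary table.
    Returns ``(model, phi_matrix, summary_frame)``.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=float)
    rec = np.asarray(recommendations).astype(int)
    if rec.min() == rec.max():
        raise ValueError("recommendations contain a single class")
    lr = LogisticRegression(penalty=None, max_iter=2000)
    lr.fit(X, rec)
    beta = lr.coef_.ravel()
    phi = (X - X.mean(axis=0)) * beta[None, :]
    names = list(feature_names) if feature_names is not None else \
        [f"x{j}" for j in range(X.shape[1])]
    summary = pd.DataFrame({
        "feature": names,
        "coef": beta,
        "mean_abs_phi": np.abs(phi).mean(axis=0),
        "mean_phi_when_high": [
            phi[X[:, j] > np.median(X[:, j]), j].mean()
            if (X[:, j] > np.median(X[:, j])).any() else 0.0
            for j in range(X.shape[1])],
    }).sort_values("mean_abs_phi", ascending=False).reset_index(drop=True)
    return lr, phi, summary
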