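"""The balanced survival lasso-network (BSL) and T-learner base models.

The BSL couples a shared encoder with two arm-specific Cox heads trained
end-to-end: each head is a lasso-network (a linear skip path plus a small
nonlinear subnetwork) whose hierarchy constraint allows a latent feature to
enter the nonlinear part only while its linear skip weight is nonzero.  An
integral-probability-metric penalty on the latent representations of the two
treatment arms discourages the encoder from encoding treatment assignment,
which is what makes counterfactual head swapping defensible under
confounding.

Training is proximal gradient descent: an SGD-with-momentum step on the sum
of the two arm-specific Cox negative log partial likelihoods plus the
balance penalty, followed by the hierarchical proximal operator on every
(skip weight, first-layer row) pair.  Sparsity is swept dense-to-sparse
along a warm-started lambda path and selected by cross-validated partial
likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .cohort import DesignMatrix
from .curves import BaselineHazard
from .nets import MLP, SGD
from .survival import breslow_baseline, cox_npll, cox_npll_grad

__all__ = [
    "BSLConfig",
    "FittedModel",
    "hier_prox",
    "hier_prox_all",
    "ipm_penalty",
    "bsl_loss",
    "fit_bsl",
    "fit_tlearner",
    "fit_slearner_cox",
    "predict_potential_outcomes",
]


# --------------------------------------------------------------------------
# hierarchical proximal operator
# --------------------------------------------------------------------------

def hier_prox_all(theta: np.ndarray, W: np.ndarray, lam: float, M: float,
                  step: float):
    """Hierarchical proximal operator applied to every feature at once.

    For each feature j this solves

        min_{t, w}  1/2 (theta_j - t)^2 + 1/2 ||W_j - w||^2 + lam*step*|t|
        subject to  ||w||_inf <= M |t|

    via the sorted group-soft-threshold form: candidates
    ``s_m = soft(|theta_j| + M * sum of m largest |W_j|, lam*step) / (1 + m M^2)``
    with the unique m for which ``M s_m`` separates the m-th and (m+1)-th
    largest entries of |W_j|.  Guarantees t = 0 => w = 0.

    Parameters
    ----------
    theta : (d,) skip weights;  W : (d, K) first-layer rows.
    """
    if M <= 0 or lam < 0 or step <= 0:
        raise ValueError("require M > 0, lam >= 0, step > 0")
    theta = np.asarray(theta, dtype=float)
    W = np.asarray(W, dtype=float)
    d, K = W.shape
    absW = np.abs(W)
    ws = -np.sort(-absW, axis=1)                       # descending per row
    c = np.concatenate([np.zeros((d, 1)), np.cumsum(ws, axis=1)], axis=1)
    m = np.arange(K + 1)
    cand = np.maximum(np.abs(theta)[:, None] + M * c - lam * step, 0.0)
    s = cand / (1.0 + m * M * M)
    hi = np.concatenate([np.full((d, 1), np.inf), ws], axis=1)
    lo = np.concatenate([ws, np.zeros((d, 1))], axis=1)
    Ms = M * s
    ok = (Ms <= hi + 1e-12) & (Ms >= lo - 1e-12)
    ok[:, -1] |= ~ok.any(axis=1)                       # numerical safety net
    idx = np.argmax(ok, axis=1)
    s_star = s[np.arange(d), idx]
    theta_new = np.sign(theta) * s_star
    W_new = np.sign(W) * np.minimum(absW, (M * s_star)[:, None])
    W_new[s_star == 0.0] = 0.0
    return theta_new, W_new


def hier_prox(theta: float, W_row, lam: float, M: float, step: float):
    """Single-feature hierarchical proximal operator (see hier_prox_all)."""
    t, W = hier_prox_all(np.array([theta], dtype=float),
                         np.asarray(W_row, dtype=float)[None, :], lam, M, step)
    return float(t[0]), W[0]


# --------------------------------------------------------------------------
# integral probability metrics on latent representations
# --------------------------------------------------------------------------

def _sq_dists(A, B):
    return np.maximum(
        (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * A @ B.T, 0.0)


def _mmd_rbf(Z1, Z0, bandwidth=None, with_grad=False):
    """Biased (V-statistic) squared MMD with an RBF kernel.

    The biased form is exactly zero for identical sample sets and never
    negative; the bandwidth defaults to the median pooled pairwise distance
    and is treated as a constant in the gradient.
    """
    n, m_ = len(Z1), len(Z0)
    D11, D00, D10 = _sq_dists(Z1, Z1), _sq_dists(Z0, Z0), _sq_dists(Z1, Z0)
    if bandwidth is None:
        pooled = np.concatenate([D11.ravel(), D00.ravel(), D10.ravel()])
        med = np.median(pooled[pooled > 0]) if (pooled > 0).any() else 1.0
        bandwidth = np.sqrt(med / 2.0)
    g = 1.0 / (2.0 * bandwidth ** 2)
    K11, K00, K10 = np.exp(-g * D11), np.exp(-g * D00), np.exp(-g * D10)
    val = float(K11.mean() + K00.mean() - 2.0 * K10.mean())
    val = max(val, 0.0)
    if not with_grad:
        return val
    # d k(x,y)/dx = -2 g (x - y) k(x,y)
    G1 = (-2.0 * g) * (
        2.0 / (n * n) * (Z1 * K11.sum(1)[:, None] - K11 @ Z1)
        - 2.0 / (n * m_) * (Z1 * K10.sum(1)[:, None] - K10 @ Z0))
    G0 = (-2.0 * g) * (
        2.0 / (m_ * m_) * (Z0 * K00.sum(1)[:, None] - K00 @ Z0)
        - 2.0 / (n * m_) * (Z0 * K10.sum(0)[:, None] - K10.T @ Z1))
    return val, G1, G0


def _sinkhorn(Z1, Z0, reg_factor=0.05, n_iter=200, with_grad=False):
    """Entropy-regularized optimal transport cost between the two arms.

    Uniform marginals, squared-Euclidean cost, log-domain iterations; the
    gradient uses the converged plan (envelope approximation).  The entropic
    regularization biases the value upward, so identical sample sets give a
    small positive number rather than zero.
    """
    C = _sq_dists(Z1, Z0)
    eps = reg_factor * max(C.mean(), 1e-12)
    n, m_ = C.shape
    log_a, log_b = -np.log(n), -np.log(m_)
    f = np.zeros(n)
    g = np.zeros(m_)
    for _ in range(n_iter):
        f = -eps * _logsumexp((g[None, :] - C) / eps + log_b, axis=1)
        g = -eps * _logsumexp((f[:, None] - C) / eps + log_a, axis=0)
    logP = (f[:, None] + g[None, :] - C) / eps + log_a + log_b
    P = np.exp(logP)
    val = float((P * C).sum())
    if not with_grad:
        return val
    G1 = 2.0 * (Z1 * P.sum(1)[:, None] - P @ Z0)
    G0 = 2.0 * (Z0 * P.sum(0)[:, None] - P.T @ Z1)
    return val, G1, G0


def _logsumexp(X, axis):
    m = X.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(X - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def ipm_penalty(Z_treated, Z_control, method: str = "mmd-rbf"):
    """Distributional discrepancy between the arms' latent representations.

    Non-negative, symmetric in its arguments and differentiable in the
    inputs.  An empty arm yields 0 with a warning (the balance term is
    skipped for such a batch).
    """
    Z1 = np.atleast_2d(np.asarray(Z_treated, dtype=float))
    Z0 = np.atleast_2d(np.asarray(Z_control, dtype=float))
    if len(Z1) == 0 or len(Z0) == 0:
        warnings.warn("one arm empty; IPM penalty set to 0 for this batch")
        return 0.0
    if method == "mmd-rbf":
        return _mmd_rbf(Z1, Z0)
    if method == "sinkhorn":
        return _sinkhorn(Z1, Z0)
    raise ValueError(f"unknown IPM method {method!r}")


# --------------------------------------------------------------------------
# configuration and fitted-model containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BSLConfig:
    """Hyperparameters for the BSL and the neural T-learner base.

    alpha weighs the latent balance penalty; lam_path is the dense-to-sparse
    l1 path for the skip weights (selected by cross-validated partial
    likelihood); M bounds the nonlinear first-layer weights relative to the
    skip weight (hierarchy multiplier).
    """

    encoder_hidden: tuple = ()   # affine encoder; add widths for a deep one
    latent: int = 8
    head_hidden: tuple = (8,)
    dropout: float = 0.1
    alpha: float = 0.1
    lam_path: tuple = (0.0, 0.01)
    M: float = 10.0
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 0.0
    clip_grad: float = 5.0
    epochs: int = 60
    batch_size: int = 256
    seed: int = 0
    ties: str = "breslow"
    ipm: str = "mmd-rbf"
    encoder_init: str = "he"   # "identity" with encoder_hidden=() and latent=p
    encoder_trainable: bool = True  # freeze to select on raw input features
    cv_folds: int = 3
    selection_rule: str = "1se"  # "1se" (sparsest within one SE) or "min"

    def __post_init__(self):
        if self.alpha < 0 or self.M <= 0 or any(l < 0 for l in self.lam_path):
            raise ValueError("alpha, lambda >= 0 and M > 0 required")


class _Head:
    """Lasso-network Cox head: linear skip plus a small subnetwork."""

    def __init__(self, d, hidden, rng, dropout):
        self.theta = np.zeros(d)
        self.gtheta = np.zeros(d)
        self.net = MLP(d, list(hidden), 1, rng, dropout=dropout)
        # LassoNet skip starts at the least-squares-friendly zero; small
        # random init instead so the proximal path has something to shrink
        self.theta[...] = rng.normal(0.0, 0.1, d)

    def eta(self, Z, rng=None, train=False):
        return Z @ self.theta + self.net.forward(Z, rng=rng, train=train)[:, 0]

    def backward(self, Z, d_eta):
        self.gtheta[...] = Z.T @ d_eta
        dZ = self.net.backward(d_eta[:, None])
        return dZ + np.outer(d_eta, self.theta)

    def first_layer(self):
        return self.net.layers[0]

    def params(self):
        return [(self.theta, self.gtheta)] + self.net.params()


class _BSLNetwork:
    """Shared encoder + two lasso-network Cox heads."""

    def __init__(self, p, cfg: BSLConfig, rng):
        self.cfg = cfg
        self.encoder = MLP(p, list(cfg.encoder_hidden), cfg.latent, rng,
                           dropout=cfg.dropout, init=cfg.encoder_init)
        self.heads = [_Head(cfg.latent, cfg.head_hidden, rng, cfg.dropout)
                      for _ in range(2)]

    def encode(self, X, rng=None, train=False):
        return self.encoder.forward(X, rng=rng, train=train)

    def eta_all(self, X):
        Z = self.encode(X)
        return self.heads[0].eta(Z), self.heads[1].eta(Z)

    def params(self):
        out = self.encoder.params() if self.cfg.encoder_trainable else []
        for h in self.heads:
            out += h.params()
        return out

    def prox(self, lam, step):
        for h in self.heads:
            fl = h.first_layer()
            h.theta[...], fl.W[...] = hier_prox_all(
                h.theta, fl.W, lam, self.cfg.M, step)

    def state_arrays(self):
        arrs = {}
        for i, (p, _) in enumerate(self.params()):
            arrs[f"param_{i}"] = p
        return arrs


@dataclass
class FittedModel:
    """Trained model + per-arm Breslow baselines + training manifest."""

    kind: str                       # "bsl", "tlearner-linear", "tlearner-mlp", "slearner-cox"
    predict_eta_fn: object          # X -> (eta_str, eta_gtr)
    baselines: dict                 # {0: BaselineHazard, 1: BaselineHazard}
    columns: list
    scaler: dict
    manifest: dict = field(default_factory=dict)

    def predict_eta(self, X):
        e0, e1 = self.predict_eta_fn(np.asarray(X, dtype=float))
        return np.asarray(e0, dtype=float), np.asarray(e1, dtype=float)

    def save(self, path):
        """Single-file .npz archive (arrays + JSON manifest)."""
        payload = {"manifest": json.dumps(self.manifest, default=str)}
        net = self.manifest.get("_network")
        if net is not None:
            payload.update(net.state_arrays())
        for a in (0, 1):
            payload[f"base{a}_t"] = self.baselines[a].event_times
            payload[f"base{a}_h"] = self.baselines[a].cumulative_hazard
        np.savez(path, **payload)


def bsl_loss(batch: DesignMatrix, net: _BSLNetwork, alpha: float | None = None,
             ipm: str | None = None, ties: str = "breslow"):
    """Full BSL objective on a batch (no l1 term: sparsity is proximal).

    loss = NPLL(arm-0 subjects | head 0) + NPLL(arm-1 subjects | head 1)
         + alpha * IPM(latents of arm 1, latents of arm 0)
    """
    alpha = net.cfg.alpha if alpha is None else alpha
    ipm = net.cfg.ipm if ipm is None else ipm
    Z = net.encode(batch.X)
    total = 0.0
    for a in (0, 1):
        rows = np.flatnonzero(batch.treatment == a)
        if rows.size == 0:
            continue
        if batch.event[rows].sum() == 0:
            warnings.warn(f"arm {a} has no events in batch; NPLL term skipped")
            continue
        eta = net.heads[a].eta(Z[rows])
        total += cox_npll(eta, batch.time[rows], batch.event[rows], ties=ties)
    if alpha > 0:
        i1 = batch.treatment == 1
        if i1.any() and (~i1).any():
            total += alpha * ipm_penalty(Z[i1], Z[~i1], method=ipm)
        else:
            warnings.warn("batch lacks one arm; balance term skipped")
    return float(total)


def _stratified_batches(treatment, batch_size, rng):
    """Batches preserving the arm proportions (so the IPM sees both arms)."""
    n = len(treatment)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    parts = [[] for _ in range(n_batches)]
    for a in (0, 1):
        idx = np.flatnonzero(treatment == a)
        rng.shuffle(idx)
        for b, chunk in enumerate(np.array_split(idx, n_batches)):
            parts[b].extend(chunk.tolist())
    return [np.array(sorted(p)) for p in parts if len(p)]


def _train_network(net: _BSLNetwork, dm: DesignMatrix, lam: float, epochs: int,
                   rng: np.random.Generator, alpha: float, trajectory: list):
    cfg = net.cfg
    opt = SGD(net.params(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay, clip_grad=cfg.clip_grad)
    for _ in range(epochs):
        epoch_loss, n_terms = 0.0, 0
        for rows in _stratified_batches(dm.treatment, cfg.batch_size, rng):
            X = dm.X[rows]
            T = dm.treatment[rows]
            Z = net.encode(X, rng=rng, train=True)
            dZ = np.zeros_like(Z)
            loss = 0.0
            for a in (0, 1):
                sub = np.flatnonzero(T == a)
                if sub.size == 0 or dm.event[rows[sub]].sum() == 0:
                    continue
                t_a, e_a = dm.time[rows[sub]], dm.event[rows[sub]]
                eta = net.heads[a].eta(Z[sub], rng=rng, train=True)
                loss += cox_npll(eta, t_a, e_a, ties=cfg.ties)
                d_eta = cox_npll_grad(eta, t_a, e_a)
                dZ[sub] += net.heads[a].backward(Z[sub], d_eta)
            if alpha > 0:
                i1 = np.flatnonzero(T == 1)
                i0 = np.flatnonzero(T == 0)
                if i1.size and i0.size:
                    val, G1, G0 = _mmd_rbf(Z[i1], Z[i0], with_grad=True) \
                        if cfg.ipm == "mmd-rbf" else _sinkhorn(Z[i1], Z[i0], with_grad=True)
                    loss += alpha * val
                    dZ[i1] += alpha * G1
                    dZ[i0] += alpha * G0
            if cfg.encoder_trainable:
                net.encoder.backward(dZ)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}); trajectory={trajectory}")
            opt.step()
            net.prox(lam, cfg.lr)
            epoch_loss += loss
            n_terms += 1
        trajectory.append(epoch_loss / max(n_terms, 1))
    return net


def _val_npll(net: _BSLNetwork, dm: DesignMatrix, ties: str) -> float:
    """Mean of the two arm-specific validation partial likelihoods."""
    e0, e1 = net.eta_all(dm.X)
    vals = []
    for a, eta in ((0, e0), (1, e1)):
        rows = np.flatnonzero(dm.treatment == a)
        if rows.size and dm.event[rows].sum() > 0:
            vals.append(cox_npll(eta[rows], dm.time[rows], dm.event[rows], ties=ties))
    return float(np.mean(vals)) if vals else np.inf


def _arm_baselines(predict_eta_fn, dm: DesignMatrix) -> dict:
    """Per-arm Breslow baselines from the factual-arm linear predictors."""
    e0, e1 = predict_eta_fn(dm.X)
    out = {}
    for a, eta in ((0, e0), (1, e1)):
        rows = np.flatnonzero(dm.treatment == a)
        out[a] = breslow_baseline(eta[rows], dm.time[rows], dm.event[rows])
    return out


def fit_bsl(train: DesignMatrix, hyper: BSLConfig | None = None,
            folds=None) -> FittedModel:
    """Train the balanced survival lasso-network.

    Proximal-gradient training along the warm-started lambda path; the path
    point with the lowest mean validation partial likelihood across the
    cross-validation folds is refit on the full training set.  Per-arm
    Breslow baselines are computed from the final factual linear predictors.
    Fully deterministic given the config seed.
    """
    cfg = hyper or BSLConfig()
    _require_both_arms(train)
    from .cohort import cv_folds as make_folds
    if folds is None:
        folds = make_folds(train, cfg.cv_folds, cfg.seed)

    lam_path = tuple(cfg.lam_path)
    val_scores = {lam: [] for lam in lam_path}
    for f, (fit_idx, val_idx) in enumerate(folds):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17, f]))
        net = _BSLNetwork(train.p, cfg, rng)
        traj: list = []
        for lam in lam_path:  # warm-started dense-to-sparse path
            _train_network(net, train.subset(fit_idx), lam, cfg.epochs, rng,
                           cfg.alpha, traj)
            val_scores[lam].append(_val_npll(net, train.subset(val_idx), cfg.ties))

    mean_scores = {lam: float(np.mean(v)) for lam, v in val_scores.items()}
    best_lam = min(mean_scores, key=mean_scores.get)
    if cfg.selection_rule == "1se" and len(lam_path) > 1:
        k = len(val_scores[best_lam])
        se = float(np.std(val_scores[best_lam], ddof=1) / np.sqrt(k)) if k > 1 else 0.0
        within = [lam for lam in lam_path
                  if mean_scores[lam] <= mean_scores[best_lam] + se]
        best_lam = max(within)  # sparsest model within one standard error

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17, 999]))
    net = _BSLNetwork(train.p, cfg, rng)
    traj = []
    for lam in lam_path:
        _train_network(net, train, lam, cfg.epochs, rng, cfg.alpha, traj)
        if lam == best_lam:
            break

    predict = lambda X: net.eta_all(X)  # noqa: E731
    manifest = {
        "model": "bsl",
        "seed": cfg.seed,
        "hyperparameters": {k: v for k, v in asdict(cfg).items()},
        "selected_lambda": best_lam,
        "cv_mean_npll": mean_scores,
        "fold_sizes": [[len(a), len(b)] for a, b in folds],
        "loss_trajectory": traj,
        "skip_support": [int((np.abs(h.theta) > 1e-10).sum()) for h in net.heads],
        "_network": net,
    }
    return FittedModel("bsl", predict, _arm_baselines(predict, train),
                       train.columns, train.scaler, manifest)


def _require_both_arms(dm: DesignMatrix):
    for a in (0, 1):
        rows = dm.treatment == a
        if not rows.any():
            raise ValueError(f"treatment arm {a} is empty")
        if dm.event[rows].sum() == 0:
            raise ValueError(f"treatment arm {a} has no events")


def fit_tlearner(train: DesignMatrix, base: str = "linear-cox",
                 hyper: BSLConfig | None = None, seed: int = 0) -> FittedModel:
    """Two independent arm-specific survival models under one contract.

    ``linear-cox`` fits a Cox proportional-hazards model per arm (lifelines);
    ``mlp-cox`` trains an arm-specific feed-forward Cox network (five dense
    layers by default).  Baselines are per-arm Breslow estimates either way.
    """
    _require_both_arms(train)
    if base == "linear-cox":
        import pandas as pd
        from lifelines import CoxPHFitter

        betas = {}
        for a in (0, 1):
            rows = np.flatnonzero(train.treatment == a)
            df = pd.DataFrame(train.X[rows], columns=train.column_names())
            df["time"] = train.time[rows]
            df["event"] = train.event[rows]
            cph = CoxPHFitter(penalizer=0.0)
            cph.fit(df, duration_col="time", event_col="event")
            betas[a] = cph.params_.reindex(train.column_names()).to_numpy()

        def predict(X, betas=betas):
            return X @ betas[0], X @ betas[1]

        manifest = {"model": "tlearner-linear", "seed": seed,
                    "coefficients": {a: betas[a].tolist() for a in betas}}
        return FittedModel("tlearner-linear", predict,
                           _arm_baselines(predict, train), train.columns,
                           train.scaler, manifest)

    if base == "mlp-cox":
        cfg = hyper or BSLConfig(encoder_hidden=(), latent=train.p,
                                 encoder_init="identity", alpha=0.0,
                                 lam_path=(0.0,), dropout=0.1,
                                 head_hidden=(32, 32, 16), seed=seed)
        nets = {}
        traj: list = []
        for a in (0, 1):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 29, a]))
            sub = train.subset(np.flatnonzero(train.treatment == a))
            net = MLP(train.p, list(cfg.head_hidden), 1, rng, dropout=cfg.dropout)
            skip = np.zeros(train.p)
            gskip = np.zeros(train.p)
            opt = SGD(net.params() + [(skip, gskip)], lr=cfg.lr,
                      momentum=cfg.momentum, weight_decay=cfg.weight_decay,
                      clip_grad=cfg.clip_grad)
            for _ in range(cfg.epochs):
                order = rng.permutation(sub.n)
                for rows in np.array_split(order, max(1, sub.n // cfg.batch_size)):
                    if sub.event[rows].sum() == 0:
                        continue
                    X = sub.X[rows]
                    eta = net.forward(X, rng=rng, train=True)[:, 0] + X @ skip
                    loss = cox_npll(eta, sub.time[rows], sub.event[rows])
                    if not np.isfinite(loss):
                        raise FloatingPointError("mlp-cox training diverged")
                    d_eta = cox_npll_grad(eta, sub.time[rows], sub.event[rows])
                    net.backward(d_eta[:, None])
                    gskip[...] = X.T @ d_eta
                    opt.step()
                    traj.append(loss)
            nets[a] = (net, skip.copy())

        def predict(X, nets=nets):
            return tuple(nets[a][0].forward(X)[:, 0] + X @ nets[a][1]
                         for a in (0, 1))

        manifest = {"model": "tlearner-mlp", "seed": cfg.seed,
                    "hyperparameters": asdict(cfg),
                    "loss_trajectory_len": len(traj)}
        return FittedModel("tlearner-mlp", predict,
                           _arm_baselines(predict, train), train.columns,
                           train.scaler, manifest)

    raise ValueError(f"unknown base learner {base!r}")


def fit_slearner_cox(train: DesignMatrix) -> FittedModel:
    """Single Cox model with treatment as a covariate (naive comparator).

    Counterfactual prediction toggles the treatment column; both arms share
    the model's Breslow baseline.
    """
    import pandas as pd
    from lifelines import CoxPHFitter

    cols = train.column_names() + ["treatment"]
    df = pd.DataFrame(np.column_stack([train.X, train.treatment]), columns=cols)
    df["time"] = train.time
    df["event"] = train.event
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="time", event_col="event")
    beta = cph.params_.reindex(cols).to_numpy()
    beta_x, beta_t = beta[:-1], beta[-1]

    def predict(X):
        eta = X @ beta_x
        return eta, eta + beta_t

    eta_fact = train.X @ beta_x + train.treatment * beta_t
    base = breslow_baseline(eta_fact, train.time, train.event)
    manifest = {"model": "slearner-cox", "treatment_coef": float(beta_t)}
    return FittedModel("slearner-cox", predict, {0: base, 1: base},
                       train.columns, train.scaler, manifest)


def predict_potential_outcomes(model: FittedModel, X, grid=None):
    """Counterfactual survival-curve pairs for every row of X.

    Each row gets the head-0 linear predictor with the subtotal-resection
    baseline and the head-1 predictor with the gross-total baseline,
    regardless of the factual treatment.  Returns a
    :class:`~bslsurv.recommend.PotentialOutcomes`.
    """
    from .recommend import PotentialOutcomes

    X = np.asarray(X, dtype=float)
    if grid is None:
        knots = np.concatenate([model.baselines[0].event_times,
                                model.baselines[1].event_times])
        grid = np.unique(np.concatenate([[0.0], knots]))
    grid = np.asarray(grid, dtype=float)
    e0, e1 = model.predict_eta(X)
    curves = {}
    for a, eta in ((0, e0), (1, e1)):
        H = np.asarray(model.baselines[a](grid))
        S = np.exp(-np.outer(np.exp(eta), H))
        curves[a] = S
    return PotentialOutcomes(grid=grid, surv_str=curves[0], surv_gtr=curves[1])
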