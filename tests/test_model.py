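"""The balanced survival lasso-network: proximal operator, balance penalty,
loss decomposition, training invariants, and the T-learner bases."""

import numpy as np
import pytest
from dataclasses import replace

import bslsurv as bs
from bslsurv.cohort import DesignMatrix
from bslsurv.model import (BSLConfig, _BSLNetwork, _train_network, bsl_loss,
                           fit_bsl, fit_tlearner, hier_prox, hier_prox_all,
                           ipm_penalty, predict_potential_outcomes)
from bslsurv.survival import cox_npll


def prox_objective(theta, W, t, Wn, lam, step):
    return 0.5 * (theta - t) ** 2 + 0.5 * np.sum((W - Wn) ** 2) + lam * step * abs(t)


class TestHierProx:
    def test_feasible_inputs_unchanged_at_zero_lambda(self):
        t, W = hier_prox(1.0, np.array([0.5, -0.3]), 0.0, 1.0, 0.1)
        assert t == 1.0 and np.allclose(W, [0.5, -0.3])

    def test_tiny_inputs_fully_shrunk(self):
        t, W = hier_prox(1e-4, np.array([1e-5, -1e-5]), 10.0, 1.0, 0.1)
        assert t == 0.0 and np.all(W == 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_numeric_minimization(self, seed):
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(seed)
        theta = float(rng.normal() * 2)
        W = rng.normal(size=3) * 2
        lam, M, step = 0.3, 1.0, rng.choice([0.1, 0.5])

        t1, W1 = hier_prox(theta, W, lam, M, step)

        def best_at(t):
            Wc = np.clip(W, -M * abs(t), M * abs(t))
            return prox_objective(theta, W, t, Wc, lam, step)

        hi = abs(theta) + M * np.abs(W).sum() + 1.0
        res = minimize_scalar(lambda u: best_at(np.sign(theta) * u),
                              bounds=(0.0, hi), method="bounded",
                              options={"xatol": 1e-10})
        f_oracle = res.fun
        f_mine = prox_objective(theta, W, t1, W1, lam, step)
        assert f_mine <= f_oracle + 1e-4
        assert np.max(np.abs(W1)) <= M * abs(t1) + 1e-9

    def test_hierarchy_guarantee(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=20) * 0.01
        W = rng.normal(size=(20, 6)) * 0.01
        t, Wn = hier_prox_all(theta, W, lam=1.0, M=1.0, step=0.5)
        assert np.all(t == 0.0)
        assert np.all(Wn == 0.0)
        # theta zeroed implies the whole first-layer row is zeroed, always
        t2, W2 = hier_prox_all(rng.normal(size=20) * 0.3,
                               rng.normal(size=(20, 6)), lam=2.0, M=10.0,
                               step=0.5)
        assert np.all(W2[t2 == 0.0] == 0.0)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        theta = rng.normal(size=10)
        W = rng.normal(size=(10, 5))
        tv, Wv = hier_prox_all(theta, W, 0.2, 2.0, 0.3)
        for j in range(10):
            ts, Ws = hier_prox(theta[j], W[j], 0.2, 2.0, 0.3)
            assert tv[j] == pytest.approx(ts)
            assert np.allclose(Wv[j], Ws)


class TestIpmPenalty:
    def test_identical_sets_zero_mmd(self):
        Z = np.random.default_rng(0).normal(size=(60, 4))
        assert ipm_penalty(Z, Z) == pytest.approx(0.0, abs=1e-6)

    def test_separated_exceeds_identical(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0, 1, (500, 3))
        B = rng.normal(3, 1, (500, 3))
        for method in ("mmd-rbf", "sinkhorn"):
            assert ipm_penalty(A, B, method) > ipm_penalty(A, A, method)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(40, 3)), rng.normal(1.0, 1.0, (30, 3))
        v = ipm_penalty(A, B)
        assert v == pytest.approx(ipm_penalty(B, A))
        assert v == pytest.approx(ipm_penalty(A[rng.permutation(40)],
                                              B[rng.permutation(30)]))

    def test_empty_arm_warns_zero(self):
        with pytest.warns(UserWarning):
            assert ipm_penalty(np.empty((0, 3)), np.ones((5, 3))) == 0.0

    def test_mmd_gradient_matches_finite_differences(self):
        from bslsurv.model import _mmd_rbf

        rng = np.random.default_rng(5)
        A, B = rng.normal(size=(8, 2)), rng.normal(0.5, 1.0, (6, 2))
        _, G1, G0 = _mmd_rbf(A, B, bandwidth=1.0, with_grad=True)
        eps = 1e-6
        for (Z, G) in ((A, G1), (B, G0)):
            for i in (0, Z.shape[0] - 1):
                for j in range(Z.shape[1]):
                    up, dn = Z.copy(), Z.copy()
                    up[i, j] += eps
                    dn[i, j] -= eps
                    if Z is A:
                        fd = (_mmd_rbf(up, B, 1.0) - _mmd_rbf(dn, B, 1.0)) / (2 * eps)
                    else:
                        fd = (_mmd_rbf(A, up, 1.0) - _mmd_rbf(A, dn, 1.0)) / (2 * eps)
                    assert G[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def sparse_problem_instance(seed, n=2500, p=20):
    """Proportional-hazards data with 3 informative + (p-3) noise covariates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = 0.8 * X[:, 0] - 0.8 * X[:, 1] + 0.6 * X[:, 2]
    T = (rng.random(n) < 0.5).astype(int)
    u = rng.random(n)
    t = 40.0 * (-np.log(u) / np.exp(eta)) ** (1 / 1.3)
    cens = rng.uniform(20, 80, n)
    obs = np.minimum(t, cens)
    e = (t <= cens).astype(int)
    dm = DesignMatrix(X, [(f"x{j}", f"x{j}", None) for j in range(p)],
                      T, obs, e, {}, np.arange(n))
    # plain proximal regime: no momentum or dropout, full-ish batches, M=1,
    # so the hierarchical prox can drive skip weights exactly to zero; the
    # frozen identity encoder makes latent sparsity mean input sparsity
    cfg = BSLConfig(seed=0, latent=p, encoder_hidden=(),
                    encoder_init="identity", encoder_trainable=False,
                    head_hidden=(4,), epochs=25,
                    alpha=0.0, momentum=0.0, M=1.0, batch_size=n // 2,
                    dropout=0.0)
    return dm, cfg


def replace_cfg(cfg, **kw):
    from dataclasses import replace as _r
    return _r(cfg, **kw)


@pytest.fixture()
def sparse_problem():
    return sparse_problem_instance(100)


def tiny_design(rng, n=80, p=4, confounded=False):
    X = rng.normal(size=(n, p))
    logit = X[:, 0] if confounded else np.zeros(n)
    T = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    t = rng.exponential(20.0, n) + 0.5
    e = (rng.random(n) < 0.7).astype(int)
    cols = [(f"x{j}", f"x{j}", None) for j in range(p)]
    return DesignMatrix(X, cols, T, t, e, {}, np.arange(n))


class TestBslLoss:
    def test_alpha_zero_decomposes_into_arm_nplls(self):
        rng = np.random.default_rng(6)
        dm = tiny_design(rng)
        cfg = BSLConfig(alpha=0.0, latent=dm.p, encoder_hidden=(),
                        encoder_init="identity", seed=0)
        net = _BSLNetwork(dm.p, cfg, np.random.default_rng(0))
        total = bsl_loss(dm, net, alpha=0.0)
        e0, e1 = net.eta_all(dm.X)
        expected = sum(
            cox_npll(eta[dm.treatment == a], dm.time[dm.treatment == a],
                     dm.event[dm.treatment == a])
            for a, eta in ((0, e0), (1, e1)))
        assert total == pytest.approx(expected)

    def test_duplication_shifts_loss_by_known_constant(self):
        # duplicating every subject doubles each risk set, which adds exactly
        # log(2) to every event's partial-likelihood term (one constant per
        # arm); gradients in eta are unchanged, and the balance penalty is
        # exactly invariant
        rng = np.random.default_rng(7)
        dm = tiny_design(rng)
        dup = DesignMatrix(np.vstack([dm.X, dm.X]), dm.columns,
                           np.r_[dm.treatment, dm.treatment],
                           np.r_[dm.time, dm.time], np.r_[dm.event, dm.event],
                           {}, np.arange(2 * dm.n))
        cfg = BSLConfig(seed=0, latent=4, encoder_hidden=())
        net = _BSLNetwork(dm.p, cfg, np.random.default_rng(1))
        assert bsl_loss(dup, net) == pytest.approx(
            bsl_loss(dm, net) + 2 * np.log(2), rel=1e-9)
        assert ipm_penalty(np.vstack([dm.X, dm.X]), dm.X) == \
            pytest.approx(0.0, abs=1e-9)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(8)
        dm = tiny_design(rng, confounded=True)
        cfg = BSLConfig(seed=0, latent=4, encoder_hidden=())
        net = _BSLNetwork(dm.p, cfg, np.random.default_rng(2))
        losses = [bsl_loss(dm, net, alpha=a) for a in (0.0, 0.1, 1.0)]
        assert losses[0] <= losses[1] <= losses[2]


class TestTraining:
    def test_hierarchy_invariant_every_epoch(self):
        rng = np.random.default_rng(9)
        dm = tiny_design(rng, n=150)
        cfg = BSLConfig(seed=0, latent=4, encoder_hidden=(), head_hidden=(6,),
                        epochs=1, batch_size=64, lam_path=(0.05,))
        net = _BSLNetwork(dm.p, cfg, np.random.default_rng(3))
        train_rng = np.random.default_rng(4)
        for epoch in range(5):
            _train_network(net, dm, lam=0.05, epochs=1, rng=train_rng,
                           alpha=cfg.alpha, trajectory=[])
            for head in net.heads:
                bound = cfg.M * np.abs(head.theta)[:, None] + 1e-9
                assert np.all(np.abs(head.first_layer().W) <= bound)

    def test_lambda_path_support_is_non_increasing(self, sparse_problem):
        # dense-to-sparse: in the plain proximal regime (no momentum) the
        # warm-started skip-weight support shrinks monotonically along an
        # increasing lambda path
        dm, cfg = sparse_problem
        net = _BSLNetwork(dm.p, cfg, np.random.default_rng(5))
        train_rng = np.random.default_rng(6)
        supports = []
        for lam in (0.0, 0.3, 0.6, 1.2, 2.5):
            _train_network(net, dm, lam=lam, epochs=cfg.epochs, rng=train_rng,
                           alpha=0.0, trajectory=[])
            supports.append(sum(int((np.abs(h.theta) > 1e-10).sum())
                                for h in net.heads))
        assert all(a >= b for a, b in zip(supports, supports[1:]))
        assert supports[-1] < supports[0]

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(11)
        dm = tiny_design(rng, n=160)
        cfg = BSLConfig(seed=3, latent=4, encoder_hidden=(), head_hidden=(4,),
                        epochs=5, cv_folds=2, lam_path=(0.0,))
        m1 = fit_bsl(dm, cfg)
        m2 = fit_bsl(dm, cfg)
        X = rng.normal(size=(10, dm.p))
        for a, b in zip(m1.predict_eta(X), m2.predict_eta(X)):
            assert np.array_equal(a, b)
        assert m1.manifest["loss_trajectory"] == m2.manifest["loss_trajectory"]

    def test_null_cohort_chance_level_discrimination(self):
        cfg = replace(bs.default_config(n=1500, seed=12), beta_str={},
                      gtr_interactions={}, gtr_main=0.0)
        cohort, _ = bs.generate_cohort(cfg)
        dm = bs.encode_design(cohort)
        train, test, _, _ = bs.split_train_test(dm, 0.3, seed=0)
        model = fit_bsl(train, BSLConfig(seed=0, epochs=20, cv_folds=2))
        e0, e1 = model.predict_eta(test.X)
        for a, eta in ((0, e0), (1, e1)):
            rows = test.treatment == a
            c = bs.concordance_index(eta[rows], test.time[rows], test.event[rows])
            assert 0.40 <= c <= 0.60

    def test_sparsity_recovers_known_support(self, sparse_problem):
        # 3 informative + 17 noise covariates; identity encoder so the skip
        # weights act on the original features; cross-validated path with the
        # one-standard-error rule must zero most noise and keep the signal
        hits = 0
        for seed in range(3):
            dm, cfg = sparse_problem_instance(100 + seed)
            model = fit_bsl(dm, replace_cfg(cfg, seed=seed, cv_folds=3,
                                            epochs=40,
                                            lam_path=(0.0, 0.3, 0.6, 0.9)))
            net = model.manifest["_network"]
            ok = True
            for head in net.heads:
                active = np.abs(head.theta) > 1e-8
                ok &= (~active[3:]).mean() >= 0.8 and active[:3].mean() >= 2 / 3
            hits += ok
        assert hits >= 2  # majority of seeds

    def test_empty_arm_raises(self):
        rng = np.random.default_rng(13)
        dm = tiny_design(rng)
        dm.treatment[:] = 1
        with pytest.raises(ValueError, match="arm 0"):
            fit_bsl(dm, BSLConfig(seed=0, epochs=2))


class TestTLearner:
    def test_linear_cox_recovers_factor_coefficients(self):
        cfg = replace(
            bs.default_config(n=4000, seed=14),
            beta_str={"astro": 0.55, "oligo": -0.45, "confined": -0.45},
            gtr_interactions={}, gtr_main=0.0)
        cohort, _ = bs.generate_cohort(cfg)
        dm = bs.encode_design(cohort)
        model = fit_tlearner(dm, base="linear-cox")
        names = dm.column_names()
        # design-column truths relative to the reference levels
        truth = {"histology=oligodendroglioma": -1.0,
                 "histology=oligoastrocytoma": -0.55,
                 "extension=extended": 0.45}
        for arm in (0, 1):
            beta = np.asarray(model.manifest["coefficients"][arm])
            for col, val in truth.items():
                assert beta[names.index(col)] == pytest.approx(val, abs=0.30)

    def test_mlp_without_hidden_layers_matches_linear(self):
        from scipy.stats import spearmanr

        cohort, _ = bs.generate_cohort(bs.default_config(n=2000, seed=15))
        dm = bs.encode_design(cohort)
        lin = fit_tlearner(dm, base="linear-cox")
        mlp = fit_tlearner(dm, base="mlp-cox",
                           hyper=BSLConfig(seed=0, head_hidden=(), epochs=120,
                                           lr=0.05, dropout=0.0))
        for a in (0, 1):
            r = spearmanr(lin.predict_eta(dm.X)[a], mlp.predict_eta(dm.X)[a])[0]
            assert r > 0.99

    def test_eventless_arm_raises_with_arm_name(self):
        rng = np.random.default_rng(16)
        dm = tiny_design(rng)
        dm.event[dm.treatment == 1] = 0
        with pytest.raises(ValueError, match="arm 1"):
            fit_tlearner(dm, base="linear-cox")


class TestPredictPotentialOutcomes:
    def test_null_effect_curves_nearly_identical(self):
        # on null-effect data the two counterfactual curves differ only by
        # per-arm estimation noise (~500 events per arm here), which bounds
        # the mean sup-norm gap well below any real-effect separation
        cfg = replace(bs.default_config(n=4000, seed=17), gtr_main=0.0,
                      gtr_interactions={})
        cohort, _ = bs.generate_cohort(cfg)
        dm = bs.encode_design(cohort)
        model = fit_tlearner(dm, base="linear-cox")
        po = predict_potential_outcomes(model, dm.X[:400])
        gap = np.abs(po.surv_str - po.surv_gtr).max(axis=1)
        assert gap.mean() < 0.12
        # and the implied treatment effects are centred on zero
        ites = np.array([r.ite for r in bs.compute_ite(po, tau=60.0)])
        assert abs(ites.mean()) < 2.0

    def test_curve_invariants_hold(self, fitted_bsl):
        model, train, test, _, _ = fitted_bsl
        po = predict_potential_outcomes(model, test.X[:50])
        for i in range(po.n):
            for arm in (0, 1):
                c = po.curve(i, arm)  # SurvivalCurve validates its invariants
                assert c.surv[0] == 1.0
                assert np.all(np.diff(c.surv) <= 1e-12)

    def test_factual_discrimination_on_heterogeneous_cohort(self, fitted_bsl):
        model, train, test, _, _ = fitted_bsl
        e0, e1 = model.predict_eta(test.X)
        eta = np.where(test.treatment == 1, e1, e0)
        assert bs.concordance_index(eta, test.time, test.event) > 0.7
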