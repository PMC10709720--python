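# bslsurv — counterfactual surgery recommendation for low-grade glioma survival data

Should an individual WHO grade 2 glioma patient receive subtotal (STR) or
gross-total resection (GTR)? Registry data cannot answer this directly: each
patient received one surgery, assignment is confounded by prognosis (younger
patients with smaller, confined tumors more often get GTR), and responses are
heterogeneous. `bslsurv` estimates the **individual treatment effect (ITE)**
from right-censored, cause-specific survival data and turns it into a
per-patient surgery recommendation, for biostatisticians and clinical
researchers working with SEER-style extracts.

## The model

The core estimator is the **balanced survival lasso-network (BSL)**: a shared
encoder Φ maps covariates x to a latent representation z = Φ(x); two
arm-specific Cox heads produce log relative hazards

    η_a(x) = θ_aᵀ z + g_a(z),     a ∈ {STR, GTR},

where θ_a is a linear skip path and g_a a small feed-forward subnetwork.
Training minimizes the sum of the two arms' Cox negative log partial
likelihoods plus α·MMD(z₁, z₀), an integral-probability-metric penalty that
discourages the latent representation from encoding treatment assignment.
After every gradient step a hierarchical proximal operator enforces, per
latent feature j, the lasso-network constraint ‖W_{a,j}‖∞ ≤ M·|θ_{a,j}| with
ℓ1 shrinkage on θ — a feature enters the nonlinear part only while its linear
skip weight is nonzero. Sparsity is swept dense-to-sparse along a λ path and
selected by cross-validated partial likelihood (one-standard-error rule).

Per-arm Breslow baselines turn the heads into counterfactual survival curves
S_a(t|x) = exp(−H_a(t)·e^{η_a(x)}). The per-patient outcome is
Y_a = first t with S_a(t|x) ≤ 0.5, truncated at a horizon τ (60 months by
default), and

    ITE = Y_GTR − Y_STR   (months),  recommend GTR iff ITE > 0,

with exact-tie recommendations decided by comparing the two curves at τ.
Patients are labelled **Consis**/**In-consis** according to whether their
actual surgery matched the recommendation; the recommendation effect is the
difference in restricted mean survival time (**DRMST**) and the Cox hazard
ratio between these groups. Average-effect machinery (IPTW-weighted
Kaplan-Meier/log-rank/Cox, doubly-robust residual-on-residual odds ratios)
and time-dependent Shapley attribution of the predicted curves round out the
toolkit. A synthetic cohort generator with closed-form Weibull ground truth
makes every stage testable without registry access.

## Worked example

```python
import bslsurv as bs
from bslsurv.model import BSLConfig, fit_bsl
from bslsurv.evaluate import evaluate_model

cohort, truth = bs.generate_cohort(bs.default_config(n=5000, seed=0))
dm = bs.encode_design(cohort)
train, test, _, test_idx = bs.split_train_test(dm, test_fraction=0.2, seed=0)

model = fit_bsl(train, BSLConfig(seed=0))
rec = bs.recommend_batch(model, test.X, tau=60.0)
report = evaluate_model(model, test, tau=60.0, seed=0, n_boot=500)
```

This prints (exact output of the run above):

```
patients: 5000  events: 25.6%  GTR share: 56.1%
     y0    y1  ite  recommendation  truncated0  truncated1
0  60.0  51.9 -8.1               0        True       False
1  60.0  60.0  0.0               0        True        True
2  60.0  60.0  0.0               0        True        True
C-index overall: 0.80  IBS: 0.10
DRMST: 2.66 months (95% CI 0.65 to 4.65)
HR (Consis vs In-consis): 0.78 (95% CI 0.61 to 1.00)
agreement with ground-truth optimal arm: 71.0%
```

Patient 0's predicted median survival under GTR (51.9 months) is 8.1 months
shorter than under STR (beyond the 60-month horizon), so the model recommends
the conservative surgery. A C-index of 0.80 means the factual-arm risk
ordering is right for 80% of comparable patient pairs; the positive DRMST and
HR < 1 say that patients whose actual surgery matched the recommendation
lived longer within the 5-year window; and 71% of test patients are assigned
their true optimal arm, known here because the cohort is simulated.

## Command line

```bash
bslsurv --config config.yaml all        # simulate -> fit -> recommend -> evaluate -> ate -> explain
bslsurv --cohort-csv my_cohort.csv --output-dir out recommend
```

Each command writes CSV/JSON artifacts (recommendations with per-patient
counterfactual times, evaluation report, average-treatment-effect report,
Shapley attribution tables) to the output directory, stamped with the config
hash and seeds.

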