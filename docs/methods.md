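# Methods

`crashpath` models a binary severity outcome (e.g., whether a single-vehicle
run-off-road crash was fatal) from a few dozen categorical predictors in
three chained stages: penalized-regression variable selection, generalized
path analysis over the selected variables, and bootstrap external
validation. This note records the models, the defaults and why, the
numerical choices, and what the synthetic world does and does not establish.

## 1. Penalized selection

All predictors enter numerically: binary/ordinal variables as integer scores
0..K-1 in declared level order, nominal variables as indicator dummies with
the first listed level as reference. Ordinal scoring matches the downstream
reporting of a single per-variable odds ratio; a variable counts as
*selected* when any of its design columns carries a nonzero slope.

The estimator minimizes

    (1/n) sum_i nll_i(b0, beta)  +  lambda * [ alpha * sum_j w_j beta_j^2
                                             + (1-alpha) * sum_j w_j |beta_j| ]

with `nll` the binomial negative log-likelihood (a literal squared-error
mode, `RSS/(2n)`, is kept for equation-level testing). **alpha = 1 is pure
ridge and alpha = 0 pure lasso** — the reverse of the glmnet convention; a
`alpha_convention="glmnet"` flag on the estimator flips the reading.
Predictors are standardized (mean 0, SD 1) internally and the intercept is
never penalized; coefficients are reported on both scales.

Optimization is cyclic coordinate descent on the IRLS quadratic
approximation, warm-started down a log-spaced grid of 100 lambdas from the
data-driven lambda_max (the smallest all-zero lambda; pure ridge, which
never zeroes slopes, caps the grid at 1000x the same gradient bound) to
lambda_max * 1e-4. Convergence is a 1e-10 coefficient-change tolerance;
solutions satisfy the KKT conditions to ~1e-10 and match statsmodels'
ML fit at lambda = 0 and sklearn's saga solver at lambda > 0 to ~1e-8.
Slopes below 1e-12 after convergence are snapped to exact zero.

Three tuning rules:

* **tenfold CV** (stratified on the outcome, fold assignment from the run
  seed): mean held-out deviance per observation, chosen lambda = grid
  minimizer, ties toward the larger lambda;
* **min-BIC**: training deviance + (nonzero slopes + 1) * ln n;
* **adaptive lasso**: weights `1/|ridge slope|^gamma` (gamma = 1) from a
  CV-tuned ridge initializer — usable when p > n; zero initial slopes get
  infinite weight and can never enter. The adaptive stage picks lambda by
  the CV **one-standard-error rule** rather than the CV minimum: the
  minimum-CV lambda systematically overselects (in our benchmarks it
  recovered the exact support in ~20% of replicates, the 1-SE rule in
  ~100%), which would defeat the selection-consistency purpose of the
  adaptive weights.

Held-out fit is summarized by the binomial deviance and the deviance ratio
`1 - dev / dev_null`, where the null deviance applies the training-sample
prevalence to the test rows, so an intercept-only model scores exactly 0 and
larger is better. The pipeline's winner is the penalty x tuning combination
with the largest test deviance ratio; ties break toward the sparser model,
then lexicographically (so the verdict cannot depend on evaluation order).

## 2. Generalized path analysis

The selected variables, with substantively assigned roles (exogenous /
mediator / final outcome — role assignment is domain knowledge, supplied by
the model config, not inferred from data), form a recursive DAG on the
standard-normal latent responses assumed to underlie each categorical
variable:

    y*_j = sum_{k in pa(j)} b_jk y*_k + e_j,   e_j ~ N(0, psi_j),

with psi_j fixed so every latent has unit variance; the b's are therefore
standardized coefficients and the model-implied moment vector is a
correlation matrix. Exogenous latents may correlate freely where declared.

**Estimation** is two-step: probit thresholds from the marginal cumulative
proportions, then each pairwise polychoric correlation by maximizing the
bivariate-normal ordinal likelihood with thresholds held fixed (Olsson's
two-step). Rectangle probabilities use the single-integral arcsine identity
with 48-node Gauss-Legendre quadrature (agrees with scipy's numerical CDF to
~1e-13 across |rho| <= 0.999; estimates are clamped to +-0.999 at the
boundary with a warning). Each correlation carries an asymptotic variance
from the observed information — the diagonal weight of the DWLS
discrepancy —

    F(theta) = (s - sigma(theta))' D^-1 (s - sigma(theta)),

minimized by BFGS with explicit central-difference gradients from
equationwise normal-equations start values. Parameter values implying a
structural variance above 1 - 1e-3 are repelled by a smooth quadratic
barrier; a residual variance that small is substantively degenerate anyway.

**Inference.** The raw statistic `n * F_hat` is not chi-square distributed
under DWLS, so the test statistic is the mean-and-variance adjusted
(scale-and-shift) form `T = a * n * F_hat + b`, with a and b chosen so T has
mean df and variance 2 df under the model. The trace moments come from
`U * Gamma`, where U is the DWLS residual-weight operator and Gamma the full
asymptotic covariance of the polychoric vector estimated from empirical
influence functions (cross-products of per-observation scores divided by the
pairwise information). The reported df stays the nominal integer
moments-minus-parameters count. Threshold-estimation uncertainty is ignored
(two-step); on correctly specified synthetic data the 5%-level rejection
rate calibrates to ~0.03–0.06 and p-values are near-uniform, which is the
check that matters. Parameter standard errors use the usual sandwich
`(J'VJ)^-1 J'V Gamma V J (J'VJ)^-1 / n`.

Fit indices follow the conventional forms — chi2/df, CFI and TLI against an
independence baseline (all correlations zero, thresholds free, fitted by the
same machinery), RMSEA with a 90% noncentral-chi-square interval — with the
usual acceptability thresholds chi2/df < 5, CFI > 0.90, TLI > 0.90,
RMSEA < 0.08. CFI and TLI are clipped to [0, 1].

**Modification** indices are exact refits: for each declared fixed-to-zero
candidate path, delta-chi-square = T(restricted) - T(freed) with delta-df 1,
ranked descending; candidates that would create a cycle are skipped with a
note. The models in scope are tiny, so the exact refit replaces the score
test approximation at negligible cost. The pipeline's modification loop
accepts a candidate only if delta-chi-square > 3.84 (1-df, 5%) *and* the fit
improves, frees at most 3 paths, and never revisits a freed path.

**Effects.** Direct effect = the standardized edge coefficient; indirect
effect = the sum over all directed paths of length >= 2 of the products of
coefficients, computed through the closed form `(I - B)^-1 - I` (the matrix
geometric series of the nilpotent coefficient matrix — identical to
exhaustive path enumeration on a DAG but polynomial in the node count,
which matters when a non-sparse winner carries many variables forward;
tests verify it against a brute-force enumeration oracle); total = direct +
indirect identically. Only
structurally free effects are reported: a pair gets a direct entry only if
the edge exists and an indirect entry only if a mediating path exists.
Because probit-scale DWLS coefficients have no odds-ratio interpretation,
an equationwise maximum-likelihood solution is reported side by side:
ordinary logistic regression for binary endogenous variables and a
cumulative-logit (proportional-odds) model for multi-level mediators, with
OR = exp(beta) and Wald 95% intervals. Complete separation raises an error
naming the offending predictor.

## 3. Bootstrap validation

Case resampling with B = 1000 by default (B is not prescribed by the method;
1000 is conventional) refits the whole polychoric + DWLS stage per resample
and takes percentile intervals per effect — the simplest defensible choice;
no BCa. Failed refits are skipped and counted, with more than 20% failures
an error. The external-validity statistic compares interval widths:

    P_change = 100 * (width_original - width_bootstrap) / width_bootstrap,

where the original widths are the delta-method Wald intervals of the DWLS
fit. The model passes when every |P_change| is strictly below 15%.

## 4. The synthetic world

`default_crash_spec` states one world and the tests live in it: five causal
variables — binary passenger presence (56.74% yes), 4-level vehicle age,
3-level driver misconduct, 4-level collision type, binary fatality at 13.61%
prevalence — whose marginal frequencies follow a published registry
frequency template, plus 24 independent noise predictors with
registry-style margins (28 predictors total). Latents are jointly normal
with the model-implied correlation matrix (path coefficients 0.25–0.35,
exogenous correlation 0.15, magnitudes chosen as moderate effects consistent
with the stated fatality prevalence); observed levels come from thresholding
at the probit quantiles of the stated margins. Two consequences are used
throughout the tests: marginal frequencies are matched in expectation
exactly, and the polychoric/DWLS estimand *equals* the generating
coefficients, so parameter-recovery tolerances measure estimation error
only. `simulate_selection_benchmark` instead generates the outcome from a
logistic model on the integer scores (4 true slopes, intercept solved so the
realized prevalence hits 13.61%) — the right stated world for the selection
stage, where the estimand is the logistic slope itself.

What the generator does **not** emulate: dependence between noise predictors
and the causal block, missing data, misclassification, or any real-world
deviation from the latent-normal copula. A green recovery test therefore
establishes correctness of the estimator under its own assumptions, not
robustness to their violation.

## 5. Scaling of the heavier checks

To keep the default test run inside a small compute budget, the
bootstrap-coverage study uses 100 outer replicates with B = 500 on a
three-variable mediation chain at n = 750 (study-scale), and the CV-based
simulation examples run at 10 replicates with a 50-point lambda grid where
the underlying claim was stated at 50 replicates; the min-BIC support
recovery and chi-square calibration checks run at full size (50 and 200
replicates). Determinism: every random draw is routed through explicit
integer seeds; fits themselves are deterministic given their inputs.

## Known limitations

* WLSMV-style estimation follows the standard published formulations; exact
  numeric agreement with commercial SEM implementations is not promised.
* The gamma (asymptotic covariance) estimate ignores threshold uncertainty.
* Order/rank identification conditions are reported in their textbook form;
  for the recursive models in scope identification follows from
  triangularity, and the report says so rather than failing equations that
  the textbook counting cannot certify.
* Percentile bootstrap intervals for product-of-coefficients mediation
  effects are known to undercover slightly at registry-scale n (their
  sampling distribution is skewed and no bias correction is applied); the
  calibration suite tracks the realized coverage.
* No latent factors, no missing-data handling beyond complete-case, no
  continuous predictors beyond pass-through scores.
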