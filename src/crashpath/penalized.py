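"""Penalized logistic / least-squares regression with ridge, lasso and
elastic-net penalties.

The mixing parameter ``alpha`` follows the convention in which **alpha = 1 is
pure ridge and alpha = 0 is pure lasso**:

    penalty(beta) = lambda * [ alpha * sum_j w_j beta_j^2
                               + (1 - alpha) * sum_j w_j |beta_j| ]

This is the reverse of the glmnet convention; pass
``alpha_convention="glmnet"`` to flip it.  The loss is the mean binomial
negative log-likelihood (default) or the half-mean residual sum of squares
``RSS/(2n)``.  The intercept is never penalized.  Predictors are standardized
internally (mean 0, SD 1); coefficients are reported on both scales.

Solved by cyclic coordinate descent on the quadratic (IRLS) approximation,
warm-started along a descending lambda grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .specs import DesignMatrix

logger = logging.getLogger(__name__)

MAX_IRLS = 100
MAX_SWEEPS = 1000
TOL = 1e-10
P_CLIP = 1e-12
W_FLOOR = 1e-5


def lq_norm(x, q: float = 2.0) -> float:
    """``(sum |x_i|^q)^(1/q)`` for q >= 1 (q=2 is the Euclidean norm)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.any(x):
        return 0.0
    return float(np.sum(np.abs(x) ** q) ** (1.0 / q))


@dataclass(frozen=True)
class PenaltySpec:
    """lambda, mixing alpha (alpha=1 ridge / alpha=0 lasso) and weights."""

    lam: float
    alpha: float = 0.0
    weights: np.ndarray | None = None  # per-slope; np.inf pins a slope at 0
    loss: str = "logistic"  # or "squared"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.loss not in ("logistic", "squared"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def weight_vector(self, p: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(p)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (p,):
            raise ValueError("penalty weights have wrong length")
        if np.any(w[np.isfinite(w)] < 0):
            raise ValueError("penalty weights must be non-negative")
        return w


def _as_matrix(design) -> np.ndarray:
    return design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)


def _loss_value(eta: np.ndarray, y: np.ndarray, loss: str) -> float:
    n = len(y)
    if loss == "squared":
        return float(np.sum((y - eta) ** 2) / (2 * n))
    # mean binomial negative log-likelihood, numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def penalized_objective(beta, design, y, penalty: PenaltySpec, intercept: float = 0.0) -> float:
    """Loss + lambda * elastic-net penalty; the intercept is unpenalized."""
    X = _as_matrix(design)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    w = penalty.weight_vector(len(beta))
    inf_mask = ~np.isfinite(w)
    if np.any(inf_mask & (beta != 0)):
        return np.inf
    wf, bf = w[~inf_mask], beta[~inf_mask]
    pen = penalty.lam * (
        penalty.alpha * np.sum(wf * bf**2) + (1 - penalty.alpha) * np.sum(wf * np.abs(bf))
    )
    return _loss_value(intercept + X @ beta, y, penalty.loss) + float(pen)


@dataclass
class PenalizedFit:
    """Solution of one penalized fit, on both coefficient scales."""

    intercept: float
    coef: np.ndarray          # original (unstandardized) scale
    intercept_std: float
    coef_std: np.ndarray      # standardized-predictor scale
    penalty: PenaltySpec
    objective: float
    converged: bool
    n_iter: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    train_outcome_mean: float
    column_map: list | None = None

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.coef_std != 0.0)

    def linear_predictor(self, design) -> np.ndarray:
        return self.intercept + _as_matrix(design) @ self.coef

    def predict_proba(self, design) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(design))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _cd_sweeps(Xs, z, obs_w, beta, b0, lam, alpha, pw, tol=TOL, max_sweeps=MAX_SWEEPS):
    """Cyclic coordinate descent on (1/2n) sum obs_w (z - b0 - Xs beta)^2 + penalty."""
    n, p = Xs.shape
    sw = obs_w.sum()
    denom0 = (obs_w[:, None] * Xs**2).sum(axis=0) / n
    r = z - b0 - Xs @ beta
    pw_fin = np.where(np.isfinite(pw), pw, 0.0)  # inf-weight slopes never move
    l1 = lam * (1 - alpha) * pw_fin
    l2 = 2 * lam * alpha * pw_fin
    active = np.flatnonzero(np.isfinite(pw))
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in active:
            if denom0[j] == 0.0:
                continue
            num = (obs_w * Xs[:, j]) @ r / n + denom0[j] * beta[j]
            bj = np.sign(num) * max(abs(num) - l1[j], 0.0) / (denom0[j] + l2[j])
            d = beta[j] - bj
            if d != 0.0:
                r += Xs[:, j] * d
                beta[j] = bj
                delta = max(delta, abs(d))
        d0 = (obs_w @ r) / sw
        if d0 != 0.0:
            b0 += d0
            r -= d0
            delta = max(delta, abs(d0))
        if delta < tol:
            break
    return beta, b0, sweep + 1


def fit_penalized(
    design,
    y,
    penalty: PenaltySpec,
    coef_init: np.ndarray | None = None,
    intercept_init: float | None = None,
    tol: float = TOL,
) -> PenalizedFit:
    """Coordinate-descent solution of the penalized objective.

    For the logistic loss an outer IRLS loop re-quadratizes the likelihood;
    the squared-error loss needs a single quadratic solve.  Deterministic for
    fixed input; non-convergence sets a flag instead of raising.
    """
    X = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if penalty.loss == "logistic" and len(np.unique(y)) < 2:
        raise ValueError("outcome is constant in the training data")
    Xs, mean, scale = _standardize(X)
    pw = penalty.weight_vector(p)
    beta = np.zeros(p) if coef_init is None else np.asarray(coef_init, float).copy()
    beta[~np.isfinite(pw)] = 0.0

    converged = True
    if penalty.loss == "squared":
        b0 = float(np.mean(y)) if intercept_init is None else intercept_init
        beta, b0, n_iter = _cd_sweeps(Xs, y, np.ones(n), beta, b0, penalty.lam, penalty.alpha, pw, tol)
        converged = n_iter < MAX_SWEEPS
    else:
        ybar = float(np.clip(y.mean(), P_CLIP, 1 - P_CLIP))
        b0 = float(np.log(ybar / (1 - ybar))) if intercept_init is None else intercept_init
        n_iter = 0
        for it in range(MAX_IRLS):
            eta = b0 + Xs @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(prob * (1 - prob), W_FLOOR, None)
            z = eta + (y - prob) / w
            old = beta.copy()
            old0 = b0
            beta, b0, sweeps = _cd_sweeps(Xs, z, w, beta, b0, penalty.lam, penalty.alpha, pw, tol)
            n_iter += sweeps
            if max(np.max(np.abs(beta - old), initial=0.0), abs(b0 - old0)) < 10 * tol:
                break
        else:
            converged = False
            logger.warning("IRLS did not converge in %d iterations", MAX_IRLS)

    beta[np.abs(beta) < 1e-12] = 0.0  # snap numerically-zero slopes exactly
    coef = beta / scale
    intercept = b0 - float(np.sum(beta * mean / scale))
    obj = penalized_objective(beta, Xs, y, penalty, intercept=b0)
    return PenalizedFit(
        intercept=intercept,
        coef=coef,
        intercept_std=b0,
        coef_std=beta,
        penalty=penalty,
        objective=obj,
        converged=converged,
        n_iter=n_iter,
        x_mean=mean,
        x_scale=scale,
        train_outcome_mean=float(y.mean()),
        column_map=getattr(design, "column_map", None),
    )


def kkt_residual(fit: PenalizedFit, design, y) -> float:
    """Max violation of the subgradient optimality conditions (standardized scale)."""
    X = _as_matrix(design)
    Xs = (X - fit.x_mean) / fit.x_scale
    y = np.asarray(y, float)
    n = len(y)
    pen = fit.penalty
    eta = fit.intercept_std + Xs @ fit.coef_std
    if pen.loss == "squared":
        g = Xs.T @ (eta - y) / n
        g0 = float(np.mean(eta - y))
    else:
        prob = 1.0 / (1.0 + np.exp(-eta))
        g = Xs.T @ (prob - y) / n
        g0 = float(np.mean(prob - y))
    pw = pen.weight_vector(len(fit.coef_std))
    finite = np.isfinite(pw)
    resid = abs(g0)
    for j in np.flatnonzero(finite):
        gj = g[j] + 2 * pen.lam * pen.alpha * pw[j] * fit.coef_std[j]
        t = pen.lam * (1 - pen.alpha) * pw[j]
        if fit.coef_std[j] != 0.0:
            resid = max(resid, abs(gj + t * np.sign(fit.coef_std[j])))
        else:
            resid = max(resid, max(abs(gj) - t, 0.0))
    return resid


# ---------------------------------------------------------------------------
# lambda grid and path


RIDGE_CAP = 1e3


def compute_lambda_grid(
    design, y, alpha: float, n_lambda: int = 100, ratio: float = 1e-4,
    weights: np.ndarray | None = None, loss: str = "logistic",
) -> np.ndarray:
    """Descending log-spaced grid from the smallest all-zero lambda.

    With an l1 component (alpha < 1) the top of the grid is the data-driven
    lambda_max at which every penalized slope is exactly zero; pure ridge
    (alpha = 1) never zeroes slopes, so a fixed multiple of the same gradient
    bound caps the grid instead.
    """
    X = _as_matrix(design)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; lambda grid undefined")
    Xs, _, _ = _standardize(X)
    n = len(y)
    pw = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    resid = y - y.mean()  # slope gradient at the intercept-only fit (both losses)
    g = np.abs(Xs.T @ resid) / n
    finite = np.isfinite(pw) & (pw > 0)
    if alpha < 1.0:
        lam_max = float(np.max(g[finite] / ((1 - alpha) * pw[finite])))
    else:
        lam_max = float(np.max(g[finite])) * RIDGE_CAP
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_path(design, y, lambdas, alpha, weights=None, loss="logistic", tol=1e-8):
    """Warm-started fits along a descending lambda grid."""
    fits = []
    coef, icpt = None, None
    for lam in lambdas:
        pen = PenaltySpec(lam=lam, alpha=alpha, weights=weights, loss=loss)
        f = fit_penalized(design, y, pen, coef_init=coef, intercept_init=icpt, tol=tol)
        coef, icpt = f.coef_std, f.intercept_std
        fits.append(f)
    return fits


def binomial_deviance(y, prob) -> float:
    y = np.asarray(y, float)
    prob = np.clip(np.asarray(prob, float), P_CLIP, 1 - P_CLIP)
    return float(-2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


# ---------------------------------------------------------------------------
# tuning


@dataclass
class TuningResult:
    lambdas: np.ndarray
    criterion: np.ndarray
    lambda_opt: float
    method: str
    criterion_se: np.ndarray | None = None

    @property
    def index_opt(self) -> int:
        return int(np.flatnonzero(self.lambdas == self.lambda_opt)[0])


def _argmin_prefer_larger_lambda(lambdas, crit) -> int:
    """Grid minimizer; exact ties resolve to the larger lambda (sparser fit)."""
    best = np.min(crit)
    return int(np.flatnonzero(crit == best)[0])  # grid is descending


def tune_cv(
    design, y, alpha: float, K: int = 10, seed: int = 0,
    lambdas=None, weights=None, loss: str = "logistic", rule: str = "min",
) -> TuningResult:
    """K-fold (default tenfold) cross-validated mean held-out deviance.

    ``rule="min"`` picks the grid minimizer; ``rule="1se"`` the largest
    lambda whose criterion stays within one fold-SE of the minimum (sparser,
    used by the adaptive-lasso stage).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    X = _as_matrix(design)
    y = np.asarray(y, float)
    if lambdas is None:
        lambdas = compute_lambda_grid(design, y, alpha, weights=weights, loss=loss)
    folds = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    dev = np.zeros((K, len(lambdas)))
    for k, (tr, te) in enumerate(folds.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {k} has a single-class outcome")
        fits = fit_path(X[tr], y[tr], lambdas, alpha, weights=weights, loss=loss)
        for i, f in enumerate(fits):
            if loss == "squared":
                dev[k, i] = float(np.mean((y[te] - f.linear_predictor(X[te])) ** 2))
            else:
                dev[k, i] = binomial_deviance(y[te], f.predict_proba(X[te])) / len(te)
    crit = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(K)
    i = _argmin_prefer_larger_lambda(lambdas, crit)
    if rule == "1se":
        i = int(np.flatnonzero(crit <= crit[i] + se[i])[0])
    elif rule != "min":
        raise ValueError(f"unknown CV rule {rule!r}")
    return TuningResult(np.asarray(lambdas), crit, float(lambdas[i]), f"cv{K}",
                        criterion_se=se)


def tune_bic(design, y, alpha: float, lambdas=None, weights=None, loss: str = "logistic"):
    """BIC(lambda) = training deviance + (nonzero slopes + 1) * ln n."""
    X = _as_matrix(design)
    y = np.asarray(y, float)
    if lambdas is None:
        lambdas = compute_lambda_grid(design, y, alpha, weights=weights, loss=loss)
    n = len(y)
    fits = fit_path(X, y, lambdas, alpha, weights=weights, loss=loss)
    crit = np.zeros(len(lambdas))
    for i, f in enumerate(fits):
        if loss == "squared":
            dev = float(np.sum((y - f.linear_predictor(X)) ** 2))
        else:
            dev = binomial_deviance(y, f.predict_proba(X))
        k = len(f.nonzero) + 1
        crit[i] = dev + k * np.log(n)
    i = _argmin_prefer_larger_lambda(lambdas, crit)
    return TuningResult(np.asarray(lambdas), crit, float(lambdas[i]), "minbic")


def fit_adaptive_lasso(
    design, y, gamma: float = 1.0, seed: int = 0, K: int = 10, loss: str = "logistic",
) -> PenalizedFit:
    """Adaptive lasso: weights 1/|ridge slope|^gamma, lambda tuned by CV.

    Slopes the CV-tuned ridge initializer estimates as zero get infinite
    weight and can never enter.  If every initial slope is zero the fit
    degenerates to intercept-only with a warning.  The lasso stage uses the
    one-standard-error CV rule: the minimum-CV lambda systematically
    overselects, which defeats the selection-consistency purpose of the
    adaptive weights.
    """
    X = _as_matrix(design)
    y = np.asarray(y, float)
    ridge = tune_cv(X, y, alpha=1.0, K=K, seed=seed, loss=loss)
    init = fit_path(X, y, ridge.lambdas[: ridge.index_opt + 1], 1.0, loss=loss)[-1]
    b = np.abs(init.coef_std)
    if not np.any(b > 0):
        logger.warning("all initial ridge slopes zero; adaptive lasso is intercept-only")
        pen = PenaltySpec(lam=1.0, alpha=0.0, weights=np.full(X.shape[1], np.inf), loss=loss)
        f = fit_penalized(design, y, pen)
        f.converged = True
        return f
    with np.errstate(divide="ignore"):
        w = np.where(b > 0, 1.0 / b**gamma, np.inf)
    lambdas = compute_lambda_grid(X, y, 0.0, weights=w, loss=loss)
    tuned = tune_cv(X, y, alpha=0.0, K=K, seed=seed, lambdas=lambdas, weights=w,
                    loss=loss, rule="1se")
    path = fit_path(design, y, lambdas[: tuned.index_opt + 1], 0.0, weights=w, loss=loss)
    return path[-1]


# ---------------------------------------------------------------------------
# held-out evaluation and selection


@dataclass
class TestEvaluation:
    deviance: float
    null_deviance: float

    @property
    def deviance_ratio(self) -> float:
        return 1.0 - self.deviance / self.null_deviance


def test_deviance(fit: PenalizedFit, test_design, test_y) -> TestEvaluation:
    """Binomial deviance on held-out data and the deviance ratio
    ``1 - dev / dev_null``, with the null from the training intercept."""
    y = np.asarray(test_y, float)
    prob = fit.predict_proba(test_design)
    dev = binomial_deviance(y, prob)
    p0 = np.full_like(y, np.clip(fit.train_outcome_mean, P_CLIP, 1 - P_CLIP))
    return TestEvaluation(deviance=dev, null_deviance=binomial_deviance(y, p0))


def select_variables(fit: PenalizedFit, design: DesignMatrix | None = None) -> list[str]:
    """Variables with at least one nonzero design-column slope."""
    cmap = fit.column_map if fit.column_map is not None else design.column_map
    if cmap is None:
        raise ValueError("no column map available on the fit or design")
    selected, seen = [], set()
    for j in fit.nonzero:
        var = cmap[j][0]
        if var not in seen:
            seen.add(var)
            selected.append(var)
    return selected


# ---------------------------------------------------------------------------
# sklearn estimator


class PenalizedLogisticRegression(BaseEstimator, ClassifierMixin):
    """Elastic-net penalized logistic regression classifier.

    Parameters
    ----------
    alpha : float, default 0.0
        Penalty mix; 1 = pure ridge, 0 = pure lasso (set
        ``alpha_convention="glmnet"`` for the opposite reading).
    lam : float or {"cv", "bic", "adaptive"}, default "cv"
        Fixed regularization strength or a tuning rule.  ``"adaptive"``
        runs the adaptive lasso (ignores ``alpha``).
    cv : int, default 10
        Folds for the cross-validation rules.
    gamma : float, default 1.0
        Adaptive-lasso weight exponent.
    random_state : int, default 0
        Seed for fold assignment.
    """

    def __init__(self, alpha=0.0, lam="cv", cv=10, gamma=1.0,
                 alpha_convention="paper", random_state=0):
        self.alpha = alpha
        self.lam = lam
        self.cv = cv
        self.gamma = gamma
        self.alpha_convention = alpha_convention
        self.random_state = random_state

    def _alpha_internal(self) -> float:
        if self.alpha_convention == "paper":
            return self.alpha
        if self.alpha_convention == "glmnet":
            return 1.0 - self.alpha
        raise ValueError(f"unknown alpha_convention {self.alpha_convention!r}")

    def fit(self, X, y):
        y = np.asarray(y, float)
        self.classes_ = np.unique(y)
        a = self._alpha_internal()
        if self.lam == "adaptive":
            fit = fit_adaptive_lasso(X, y, gamma=self.gamma, seed=self.random_state, K=self.cv)
            self.tuning_ = None
        elif self.lam in ("cv", "bic"):
            tuner = tune_cv if self.lam == "cv" else tune_bic
            kw = {"K": self.cv, "seed": self.random_state} if self.lam == "cv" else {}
            res = tuner(X, y, a, **kw)
            fit = fit_path(X, y, res.lambdas[: res.index_opt + 1], a)[-1]
            self.tuning_ = res
        else:
            fit = fit_penalized(X, y, PenaltySpec(lam=float(self.lam), alpha=a))
            self.tuning_ = None
        self.fit_ = fit
        self.coef_ = fit.coef
        self.intercept_ = fit.intercept
        self.lambda_ = fit.penalty.lam
        self.n_features_in_ = len(fit.coef)
        if fit.column_map is not None:
            self.selected_ = select_variables(fit)
        return self

    def decision_function(self, X):
        return self.fit_.linear_predictor(X)

    def predict_proba(self, X):
        p = self.fit_.predict_proba(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.fit_.predict_proba(X) >= 0.5).astype(float)
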