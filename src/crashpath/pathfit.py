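"""DWLS estimation of recursive path models over ordinal variables.

The structural model lives on the standard-normal latent responses: each
endogenous latent is a linear combination of its parents' latents plus an
independent normal error whose variance is set so every latent stays
standardized.  The free parameters (path coefficients, exogenous
correlations) are estimated by diagonally weighted least squares on the
polychoric correlation vector,

    F(theta) = (s - sigma(theta))' D^-1 (s - sigma(theta)),

with D the asymptotic variances of the polychorics.  Inference uses the
mean-and-variance-adjusted (scale-and-shift) test statistic computed from the
full asymptotic covariance of s, so the reported df is the nominal model df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .dag import IdentificationReport, PathModel, check_identification
from .polychoric import MomentEstimates, estimate_polychoric

logger = logging.getLogger(__name__)

PSI_FLOOR = 1e-3  # smallest admissible residual variance on the latent scale
GRAD_TOL = 1e-8


# ---------------------------------------------------------------------------
# implied moments


def _param_names(model: PathModel) -> list[str]:
    return [f"{a}->{b}" for a, b in model.edges] + [f"{a}~~{b}" for a, b in model.covariances]


@lru_cache(maxsize=256)
def _model_structure(model: PathModel):
    """Precomputed index structure for fast implied-moment evaluation."""
    names = model.names
    idx = {n: i for i, n in enumerate(names)}
    exo = [idx[v] for v in model.exogenous]
    cov_pairs = [(idx[a], idx[b]) for a, b in model.covariances]
    ne = len(model.edges)
    edge_pos = {e: k for k, e in enumerate(model.edges)}
    endo = []
    for v in model.topological_order():
        if v in model.exogenous:
            continue
        parents = model.parents(v)
        endo.append((idx[v],
                     np.array([idx[u] for u in parents], dtype=int),
                     np.array([edge_pos[(u, v)] for u in parents], dtype=int)))
    return len(names), exo, cov_pairs, ne, endo


def implied_sigma(model: PathModel, theta: np.ndarray):
    """Model-implied latent correlation matrix (in ``model.names`` order).

    Returns ``(Sigma, min_psi)``; ``min_psi`` is the smallest residual
    variance, negative when ``theta`` implies an infeasible (>1) structural
    variance.
    """
    p, exo, cov_pairs, ne, endo = _model_structure(model)
    S = np.zeros((p, p))
    for i in exo:
        S[i, i] = 1.0
    for k, (i, j) in enumerate(cov_pairs):
        S[i, j] = S[j, i] = theta[ne + k]
    min_psi = 1.0
    for i, pj, tpos in endo:
        if len(pj):
            b = theta[tpos]
            var_struct = float(b @ S[np.ix_(pj, pj)] @ b)
            row = S[pj, :] .T @ b
            S[i, :] = row
            S[:, i] = row
        else:
            var_struct = 0.0
        min_psi = min(min_psi, 1.0 - var_struct)
        S[i, i] = 1.0
    return S, min_psi


def _sigma_vec(model: PathModel, theta: np.ndarray, pairs) -> np.ndarray:
    S, _ = implied_sigma(model, theta)
    return np.array([S[i, j] for i, j in pairs])


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PathFit:
    """DWLS solution for one path model."""

    model: PathModel
    theta: np.ndarray
    discrepancy: float
    converged: bool
    n: int
    moments: MomentEstimates
    identification: IdentificationReport

    @property
    def param_names(self) -> list[str]:
        return _param_names(self.model)

    @property
    def coefficients(self) -> dict[tuple[str, str], float]:
        """Standardized (latent-scale) path coefficients."""
        return {e: float(self.theta[k]) for k, e in enumerate(self.model.edges)}

    @property
    def exogenous_correlations(self) -> dict[tuple[str, str], float]:
        ne = len(self.model.edges)
        return {c: float(self.theta[ne + k]) for k, c in enumerate(self.model.covariances)}

    @property
    def implied(self) -> np.ndarray:
        return implied_sigma(self.model, self.theta)[0]

    @property
    def df(self) -> int:
        return self.identification.df

    def sigma_vec(self) -> np.ndarray:
        return _sigma_vec(self.model, self.theta, self.moments.pairs)


def _initial_theta(model: PathModel, moments: MomentEstimates) -> np.ndarray:
    """Equationwise normal-equations start values from the sample polychorics."""
    idx = {n: i for i, n in enumerate(moments.variables)}
    R = moments.R
    theta = []
    for a, b in model.edges:
        theta.append(0.0)
    for eq in model.endogenous:
        parents = model.parents(eq)
        pj = [idx[u] for u in parents]
        try:
            bhat = np.linalg.solve(R[np.ix_(pj, pj)], R[pj, idx[eq]])
        except np.linalg.LinAlgError:
            bhat = np.zeros(len(pj))
        for u, val in zip(parents, bhat):
            theta[model.edges.index((u, eq))] = float(val)
    for a, b in model.covariances:
        theta.append(float(R[idx[a], idx[b]]))
    return np.array(theta)


def fit_dwls(model: PathModel, moments: MomentEstimates, n: int | None = None) -> PathFit:
    """Minimize the diagonally weighted least-squares discrepancy.

    Quasi-Newton (BFGS) on the free parameters; infeasible parameter values
    (implied latent variance above 1) are repelled by a smooth barrier.
    Deterministic given inputs.
    """
    ident = check_identification(model)
    if n is None:
        n = moments.n
    if list(moments.variables) != list(model.names):
        raise ValueError("moment estimates and model cover different variables")
    s = moments.s
    w = moments.weight_diag
    pairs = moments.pairs

    def objective(theta):
        S, min_psi = implied_sigma(model, theta)
        sig = np.array([S[i, j] for i, j in pairs])
        f = float(np.sum((s - sig) ** 2 / w))
        if min_psi < PSI_FLOOR:
            f += 1e6 * (PSI_FLOOR - min_psi) ** 2
        return f

    def gradient(theta, eps=1e-6):
        g = np.zeros_like(theta)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            g[k] = (objective(tp) - objective(tm)) / (2 * eps)
        return g

    theta0 = _initial_theta(model, moments)
    if objective(theta0) > 1e3:  # infeasible start; fall back to zeros
        theta0 = np.zeros_like(theta0)
    res = optimize.minimize(objective, theta0, jac=gradient, method="L-BFGS-B",
                            options={"gtol": GRAD_TOL, "ftol": 1e-14,
                                     "maxiter": 500, "maxfun": 5000})
    theta = res.x
    S, min_psi = implied_sigma(model, theta)
    if min_psi < -1e-6:
        raise RuntimeError("implied latent covariance not positive definite at the optimum")
    # BFGS may report precision loss on flat tails; accept if the gradient is tiny
    converged = bool(res.success or np.max(np.abs(gradient(theta))) < 1e-5
                     or res.fun <= objective(theta0))
    if not converged:
        logger.warning("DWLS optimizer stopped without convergence: %s", res.message)
    return PathFit(model=model, theta=theta, discrepancy=float(res.fun),
                   converged=converged, n=int(n), moments=moments, identification=ident)


# ---------------------------------------------------------------------------
# adjusted test statistic


def _jacobian(model: PathModel, theta: np.ndarray, pairs, eps: float = 1e-6) -> np.ndarray:
    q = len(theta)
    m = len(pairs)
    J = np.zeros((m, q))
    for k in range(q):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        J[:, k] = (_sigma_vec(model, tp, pairs) - _sigma_vec(model, tm, pairs)) / (2 * eps)
    return J


@dataclass
class AdjustedChiSquare:
    T: float
    df: int
    p_value: float
    T_raw: float
    scale: float
    shift: float


def adjusted_chi_square(fit: PathFit, moments: MomentEstimates | None = None,
                        n: int | None = None) -> AdjustedChiSquare:
    """Mean-and-variance adjusted (scale-and-shift) chi-square statistic.

    ``T = a * n * F_hat + b`` with a, b chosen so that T has mean df and
    variance 2 df under the model, from the trace moments of U * Gamma
    (U the DWLS residual-weight operator, Gamma the asymptotic covariance of
    the polychoric vector).
    """
    moments = moments or fit.moments
    n = n or fit.n
    df = fit.df
    T_raw = n * fit.discrepancy
    if df == 0:
        return AdjustedChiSquare(T=0.0, df=0, p_value=1.0, T_raw=T_raw, scale=1.0, shift=0.0)
    V = np.diag(1.0 / moments.weight_diag)
    gamma = moments.gamma
    q = len(fit.theta)
    if q:
        J = _jacobian(fit.model, fit.theta, moments.pairs)
        JV = V @ J
        U = V - JV @ np.linalg.solve(J.T @ JV, JV.T)
    else:
        U = V
    M = U @ gamma
    c1 = float(np.trace(M))
    c2 = float(np.trace(M @ M))
    a = float(np.sqrt(df / c2))
    b = float(df - a * c1)
    T = max(a * T_raw + b, 0.0)
    return AdjustedChiSquare(T=T, df=df, p_value=float(stats.chi2.sf(T, df)),
                             T_raw=float(T_raw), scale=a, shift=b)


def fit_baseline(moments: MomentEstimates, n: int | None = None) -> AdjustedChiSquare:
    """Independence baseline: all correlations fixed at zero, thresholds free."""
    n = n or moments.n
    s = moments.s
    w = moments.weight_diag
    F = float(np.sum(s**2 / w))
    df = len(s)
    V = np.diag(1.0 / w)
    M = V @ moments.gamma
    c1, c2 = float(np.trace(M)), float(np.trace(M @ M))
    a = float(np.sqrt(df / c2))
    b = float(df - a * c1)
    T = max(a * n * F + b, 0.0)
    return AdjustedChiSquare(T=T, df=df, p_value=float(stats.chi2.sf(T, df)),
                             T_raw=float(n * F), scale=a, shift=b)


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndices:
    chi2: float
    df: int
    p_value: float
    chi2_df: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    saturated: bool = False

    THRESHOLDS = {"chi2_df": 5.0, "cfi": 0.90, "tli": 0.90, "rmsea": 0.08}

    @property
    def verdicts(self) -> dict[str, bool]:
        return {
            "chi2_df": self.chi2_df < self.THRESHOLDS["chi2_df"],
            "cfi": self.cfi > self.THRESHOLDS["cfi"],
            "tli": self.tli > self.THRESHOLDS["tli"],
            "rmsea": self.rmsea < self.THRESHOLDS["rmsea"],
        }

    @property
    def acceptable(self) -> bool:
        return all(self.verdicts.values())


def _rmsea_point(T, df, n) -> float:
    return float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))


def _noncentrality(T, df, prob) -> float:
    """nc with ncx2.cdf(T, df, nc) = prob (0 when unattainable)."""
    if stats.chi2.cdf(T, df) <= prob:
        return 0.0
    hi = max(T * 2, 10.0)
    while stats.ncx2.cdf(T, df, hi) > prob:
        hi *= 2
        if hi > 1e8:
            return hi
    return float(optimize.brentq(lambda nc: stats.ncx2.cdf(T, df, nc) - prob, 0.0, hi))


def fit_indices(T_M: float, df_M: int, T_B: float, df_B: int, n: int,
                ci_level: float = 0.90) -> FitIndices:
    """chi2/df, CFI, TLI and RMSEA (with noncentral-chi-square CI)."""
    if df_M == 0:
        return FitIndices(chi2=0.0, df=0, p_value=1.0, chi2_df=0.0, cfi=1.0,
                          tli=1.0, rmsea=0.0, rmsea_ci=(0.0, 0.0), saturated=True)
    dM = max(T_M - df_M, 0.0)
    dB = max(T_B - df_B, dM, 0.0)
    cfi = 1.0 if dB == 0 else 1.0 - dM / dB
    rB = T_B / df_B
    tli = 1.0 if rB <= 1.0 else (rB - T_M / df_M) / (rB - 1.0)
    lo_p, hi_p = (1 + ci_level) / 2, (1 - ci_level) / 2
    nc_lo = _noncentrality(T_M, df_M, lo_p)
    nc_hi = _noncentrality(T_M, df_M, hi_p)
    scale = df_M * (n - 1)
    return FitIndices(
        chi2=float(T_M), df=int(df_M), p_value=float(stats.chi2.sf(T_M, df_M)),
        chi2_df=float(T_M / df_M),
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=float(np.clip(tli, 0.0, 1.0)),
        rmsea=_rmsea_point(T_M, df_M, n),
        rmsea_ci=(float(np.sqrt(nc_lo / scale)), float(np.sqrt(nc_hi / scale))),
    )


# ---------------------------------------------------------------------------
# modification indices


def modification_indices(model: PathModel, moments: MomentEstimates, n: int | None = None,
                         candidates=None) -> list[dict]:
    """Delta-chi-square from explicitly refitting each freed candidate path.

    The models in scope are tiny, so the exact refit replaces the usual
    score-test approximation.  Candidates that would create a cycle are
    skipped with a note.  Returned ranked by descending delta-chi-square.
    """
    if candidates is None:
        candidates = model.candidates
    base_fit = fit_dwls(model, moments, n)
    base_T = adjusted_chi_square(base_fit).T
    out = []
    for parent, child in candidates:
        if not model.would_be_acyclic(parent, child):
            out.append({"path": (parent, child), "skipped": "would create a cycle"})
            continue
        freed = model.with_edge(parent, child)
        if check_identification(freed).df < 0:
            out.append({"path": (parent, child), "skipped": "df would fall below zero"})
            continue
        f = fit_dwls(freed, moments, n)
        T = adjusted_chi_square(f).T
        out.append({"path": (parent, child), "delta_chi2": float(base_T - T), "delta_df": 1})
    ranked = [d for d in out if "delta_chi2" in d]
    ranked.sort(key=lambda d: -d["delta_chi2"])
    return ranked + [d for d in out if "skipped" in d]


# ---------------------------------------------------------------------------
# effect decomposition


@dataclass
class EffectDecomposition:
    """Direct, indirect (sum of path products) and total effects.

    A pair appears in ``direct`` only when the edge is structurally free and
    in ``indirect`` only when a directed path of length >= 2 exists (a path
    whose coefficients happen to be zero still counts as structural, with a
    zero effect).  ``total`` treats absent entries as zero.
    """

    direct: dict[tuple[str, str], float]
    indirect: dict[tuple[str, str], float]

    def total(self, pair) -> float:
        return self.direct.get(pair, 0.0) + self.indirect.get(pair, 0.0)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(set(self.direct) | set(self.indirect))

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b,
             "direct": self.direct.get((a, b), 0.0),
             "indirect": self.indirect.get((a, b), 0.0),
             "total": self.total((a, b))}
            for a, b in self.pairs
        ]
        return pd.DataFrame(rows)


def _structural_indirect_pairs(edges, nodes) -> set[tuple[str, str]]:
    """Pairs connected by at least one directed path of length >= 2."""
    p = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((p, p), dtype=bool)
    for a, b in edges:
        A[idx[a], idx[b]] = True
    reach2 = np.zeros((p, p), dtype=bool)
    power = A.copy()
    for _ in range(max(p - 2, 0)):
        power = power @ A
        reach2 |= power
    return {(nodes[i], nodes[j]) for i, j in zip(*np.nonzero(reach2))}


def effects_from_coefficients(edges: dict[tuple[str, str], float],
                              nodes: list[str]) -> EffectDecomposition:
    """Effect decomposition over all directed paths of the DAG.

    The sum over every directed path of the product of edge coefficients is
    the matrix geometric series of the (nilpotent) coefficient matrix:
    ``total = (I - B)^-1 - I``; indirect = total - direct.  Identical to
    exhaustive path enumeration on a DAG, but polynomial in the node count.
    """
    p = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    B = np.zeros((p, p))  # B[child, parent]
    for (a, b), c in edges.items():
        B[idx[b], idx[a]] = c
    total = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    direct = dict(edges)
    indirect = {}
    for a, b in _structural_indirect_pairs(edges, nodes):
        indirect[(a, b)] = float(total[idx[b], idx[a]] - edges.get((a, b), 0.0))
    return EffectDecomposition(direct=direct, indirect=indirect)


def effects(fit: PathFit) -> EffectDecomposition:
    return effects_from_coefficients(fit.coefficients, fit.model.names)


def parameter_acov(fit: PathFit) -> np.ndarray:
    """Sandwich asymptotic covariance of the DWLS parameter estimates."""
    moments = fit.moments
    J = _jacobian(fit.model, fit.theta, moments.pairs)
    V = np.diag(1.0 / moments.weight_diag)
    bread = np.linalg.inv(J.T @ V @ J)
    meat = J.T @ V @ moments.gamma @ V @ J
    return bread @ meat @ bread / fit.n


def effect_intervals(fit: PathFit, level: float = 0.95) -> pd.DataFrame:
    """Delta-method Wald intervals for direct/indirect/total effects.

    One decomposition per perturbed parameter (central differences), so the
    cost is 2q decompositions regardless of how many effects exist.
    """
    acov = parameter_acov(fit)
    z = stats.norm.ppf((1 + level) / 2)
    names = fit.model.names
    eps = 1e-6

    def flat(theta) -> dict:
        coefs = {e: theta[k] for k, e in enumerate(fit.model.edges)}
        d = effects_from_coefficients(coefs, names)
        out = {}
        for a, b in d.pairs:
            if (a, b) in d.direct:
                out[(a, b, "direct")] = d.direct[(a, b)]
            if (a, b) in d.indirect:
                out[(a, b, "indirect")] = d.indirect[(a, b)]
            out[(a, b, "total")] = d.total((a, b))
        return out

    base = flat(fit.theta)
    grads = {key: np.zeros(len(fit.theta)) for key in base}
    for k in range(len(fit.theta)):
        tp, tm = fit.theta.copy(), fit.theta.copy()
        tp[k] += eps
        tm[k] -= eps
        vp, vm = flat(tp), flat(tm)
        for key in base:
            grads[key][k] = (vp[key] - vm[key]) / (2 * eps)
    rows = []
    for (a, b, kind), est in base.items():
        g = grads[(a, b, kind)]
        se = float(np.sqrt(max(g @ acov @ g, 0.0)))
        rows.append({"source": a, "target": b, "kind": kind, "estimate": est,
                     "se": se, "lo": est - z * se, "hi": est + z * se})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# equationwise logistic estimator (odds-ratio scale)


class SeparationError(RuntimeError):
    pass


def _detect_separating(y: np.ndarray, X: pd.DataFrame) -> str:
    for col in X.columns:
        tab = pd.crosstab(X[col], y)
        if (tab.astype(bool).sum(axis=1) <= 1).all():
            return col
    return "unknown"


def fit_equationwise_logit(model: PathModel, table, level: float = 0.95,
                           ordinal_mode: str = "cumulative") -> dict[str, pd.DataFrame]:
    """Per-equation ML logistic fits with odds ratios and Wald intervals.

    Binary endogenous variables get ordinary logistic regression; multi-level
    mediators a cumulative-logit (proportional-odds) model, or a binary
    collapse at the first threshold when ``ordinal_mode="collapse"``.
    Predictors enter as ordinal integer scores.
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    z = stats.norm.ppf((1 + level) / 2)
    out = {}
    for eq in model.endogenous:
        parents = model.parents(eq)
        y = table.codes(eq).astype(float)
        X = pd.DataFrame({p: table.codes(p).astype(float) for p in parents})
        if len(np.unique(y)) < 2:
            raise SeparationError(f"outcome {eq!r} is constant")
        k = table.spec(eq).n_levels
        try:
            if k == 2 or ordinal_mode == "collapse":
                yb = (y >= 1).astype(float) if k > 2 else y
                res = sm.Logit(yb, sm.add_constant(X)).fit(disp=0, maxiter=200)
                params = res.params.drop("const")
                ses = res.bse.drop("const")
            else:
                res = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0, maxiter=500)
                params = res.params[parents]
                ses = res.bse[parents]
        except Exception as exc:  # statsmodels separation errors vary by version
            raise SeparationError(
                f"separation fitting {eq!r}; offending predictor: "
                f"{_detect_separating(y, X)}"
            ) from exc
        if np.any(np.abs(params.to_numpy()) > 15):
            raise SeparationError(
                f"separation fitting {eq!r}; offending predictor: "
                f"{_detect_separating(y, X)}"
            )
        out[eq] = pd.DataFrame({
            "coef": params, "se": ses,
            "odds_ratio": np.exp(params),
            "or_lo": np.exp(params - z * ses),
            "or_hi": np.exp(params + z * ses),
        })
    return out


# ---------------------------------------------------------------------------
# estimator facade


class PathAnalysis(BaseEstimator):
    """Generalized path analysis over categorical observed variables.

    Fits the recursive latent-probit path model by polychoric + DWLS,
    computes the adjusted chi-square, fit indices against an independence
    baseline, modification indices for declared candidate paths, an
    equationwise logistic (odds-ratio) solution, and the effect
    decomposition.

    Parameters
    ----------
    model : PathModel
    estimator : {"dwls", "logit", "both"}, default "both"
    compute_modifications : bool, default True
    """

    def __init__(self, model=None, estimator="both", compute_modifications=True):
        self.model = model
        self.estimator = estimator
        self.compute_modifications = compute_modifications

    def fit(self, table, y=None):
        if self.model is None:
            raise ValueError("a PathModel is required")
        model = self.model
        self.identification_ = check_identification(model)
        self.moments_ = estimate_polychoric(table, variables=model.names)
        self.n_ = table.n
        if self.estimator in ("dwls", "both"):
            self.fit_ = fit_dwls(model, self.moments_, self.n_)
            self.chi2_ = adjusted_chi_square(self.fit_)
            self.baseline_ = fit_baseline(self.moments_, self.n_)
            self.indices_ = fit_indices(self.chi2_.T, self.chi2_.df,
                                        self.baseline_.T, self.baseline_.df, self.n_)
            self.effects_ = effects(self.fit_)
            self.effect_intervals_ = effect_intervals(self.fit_)
            if self.compute_modifications and model.candidates:
                self.modification_indices_ = modification_indices(model, self.moments_, self.n_)
            else:
                self.modification_indices_ = []
        if self.estimator in ("logit", "both"):
            self.logit_ = fit_equationwise_logit(model, table)
        return self
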