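"""Synthetic crash-registry data from a recursive latent-probit model.

The generator states a world: a causal block of five variables — two
correlated exogenous drivers (passenger presence, vehicle age), two ordinal
mediators (driver misconduct, collision type) and a binary fatality outcome —
plus a bank of noise predictors drawn independently with registry-style
marginal frequencies.  Latent responses are jointly normal with the
model-implied correlation matrix, every latent is standard normal, and
observed levels come from thresholding at the probit quantiles of the stated
marginals.  Consequently (i) marginal frequencies match their targets in
expectation exactly, and (ii) the polychoric/DWLS estimand equals the
generating path coefficients, which is what makes parameter-recovery tests
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .dag import PathModel, hypothesized_crash_model
from .pathfit import implied_sigma
from .specs import StudyTable, VariableSpec


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete stated world for one synthetic study."""

    model: PathModel
    coefficients: dict[tuple[str, str], float]
    exog_corr: dict[tuple[str, str], float]
    marginals: dict[str, tuple[float, ...]]       # causal-block level probabilities
    levels: dict[str, tuple[str, ...]]            # labels for every variable
    noise: tuple[tuple[str, tuple[str, ...], tuple[float, ...]], ...]
    n: int = 742
    seed: int = 0

    def theta(self) -> np.ndarray:
        t = [self.coefficients[e] for e in self.model.edges]
        t += [self.exog_corr[c] for c in self.model.covariances]
        return np.array(t)

    def implied_correlation(self) -> np.ndarray:
        S, min_psi = implied_sigma(self.model, self.theta())
        if min_psi <= 0:
            raise ValueError("implied latent covariance not positive definite")
        return S

    def thresholds(self, name: str) -> np.ndarray:
        p = np.asarray(self.marginals[name], float)
        p = p / p.sum()
        return stats.norm.ppf(np.cumsum(p)[:-1])

    def variable_specs(self) -> tuple[VariableSpec, ...]:
        roles = self.model.roles
        out = []
        for name in self.model.names:
            role = "outcome" if roles[name] == "final-endogenous" else "predictor"
            scale = "binary" if len(self.levels[name]) == 2 else "ordinal"
            out.append(VariableSpec(name, role, scale, tuple(self.levels[name])))
        for name, labels, _ in self.noise:
            scale = "binary" if len(labels) == 2 else "ordinal"
            out.append(VariableSpec(name, "predictor", scale, tuple(labels)))
        return tuple(out)

    def truth(self) -> dict:
        return {
            "coefficients": {f"{a}->{b}": c for (a, b), c in self.coefficients.items()},
            "exogenous_correlations": {f"{a}~~{b}": c for (a, b), c in self.exog_corr.items()},
            "thresholds": {v: self.thresholds(v).tolist() for v in self.model.names},
            "noise_variables": [name for name, _, _ in self.noise],
            "n": self.n,
            "seed": self.seed,
        }


def _draw_categorical(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    p = np.asarray(probs, float)
    cum = np.cumsum(p / p.sum())
    return np.searchsorted(cum[:-1], rng.random(n), side="right")


def simulate_structural(spec: GeneratorSpec, n: int | None = None,
                        seed: int | None = None) -> tuple[StudyTable, dict]:
    """Draw one synthetic study table plus the truth record."""
    n = spec.n if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    S = spec.implied_correlation()
    L = np.linalg.cholesky(S)
    Z = rng.standard_normal((n, S.shape[0])) @ L.T
    cols = {}
    for i, name in enumerate(spec.model.names):
        tau = spec.thresholds(name)
        codes = (Z[:, i][:, None] > tau[None, :]).sum(axis=1)
        cols[name] = np.asarray(spec.levels[name])[codes]
    for name, labels, probs in spec.noise:
        cols[name] = np.asarray(labels)[_draw_categorical(rng, probs, n)]
    table = StudyTable(pd.DataFrame(cols), spec.variable_specs())
    truth = spec.truth() | {"n": n, "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# the default registry-style world


_YN = ("no", "yes")

# noise-bank marginals follow the registry frequency template (counts / 742)
_NOISE: tuple = (
    ("crash_day", ("weekday", "weekend"), (0.6752, 0.3248)),
    ("lighting", ("day", "night", "twilight"), (0.6712, 0.2938, 0.0350)),
    ("clear_weather", _YN, (0.0553, 0.9447)),
    ("dry_surface", _YN, (0.0606, 0.9394)),
    ("curved_design", _YN, (0.8464, 0.1536)),
    ("vehicle_factor", _YN, (0.9852, 0.0148)),
    ("human_factor", _YN, (0.2642, 0.7358)),
    ("road_shoulder", ("unpaved", "soil", "asphalt"), (0.0472, 0.4704, 0.4824)),
    ("road_design", ("one-way", "two-way"), (0.9555, 0.0445)),
    ("road_defect", _YN, (0.9461, 0.0539)),
    ("permitted_speed", ("60-80", "80-95", "95-110", "110-120"),
     (0.1038, 0.0512, 0.7345, 0.1105)),
    ("vehicle_type", ("low", "high", "two-three-wheeler"), (0.7790, 0.2062, 0.0148)),
    ("high_risk_color", _YN, (0.7547, 0.2453)),
    ("safety_equipment", ("low-risk", "high-risk"), (0.6146, 0.3854)),
    ("vehicle_plaque", ("personal-regional", "other"), (0.8720, 0.1280)),
    ("vehicle_maneuver", ("forward", "turn", "other", "backward"),
     (0.9744, 0.0189, 0.0054, 0.0013)),
    ("fault_status", ("at-fault", "not-at-fault"), (0.9879, 0.0121)),
    ("driver_gender", ("male", "female"), (0.8989, 0.1011)),
    ("driver_education", ("illiterate", "primary", "nonacademic", "academic"),
     (0.0175, 0.0930, 0.8019, 0.0876)),
    ("driver_job", ("high-status", "middle-status", "low-status"),
     (0.8652, 0.0809, 0.0539)),
    ("driver_age", ("child", "adult", "elderly"), (0.0013, 0.9353, 0.0633)),
    ("license_type", ("class-A", "class-B", "class-C", "motorcycle", "none"),
     (0.1119, 0.3369, 0.5296, 0.0081, 0.0135)),
    ("seatbelt", ("used", "not-used"), (0.7075, 0.2925)),
    ("judiciary_cause", ("carelessness", "other"), (0.9771, 0.0229)),
)

DEFAULT_COEFFICIENTS = {
    ("passenger", "misconduct"): 0.30,
    ("passenger", "collision"): 0.25,
    ("passenger", "fatality"): 0.30,
    ("vehicle_age", "fatality"): 0.30,
    ("misconduct", "fatality"): 0.35,
    ("collision", "fatality"): 0.25,
}

_CAUSAL_MARGINALS = {
    "passenger": (0.4326, 0.5674),
    "vehicle_age": (0.3518, 0.3760, 0.2075, 0.0647),
    "misconduct": (0.4798, 0.4394, 0.0809),
    "collision": (0.2372, 0.4191, 0.2965, 0.0472),
    "fatality": (0.8639, 0.1361),
}

_CAUSAL_LEVELS = {
    "passenger": _YN,
    "vehicle_age": ("<5", "5-9", "10-14", ">=15"),
    "misconduct": ("spiral-movement", "over-speeding", "other"),
    "collision": ("head-on", "rear-end", "t-bone", "side-swipe"),
    "fatality": ("non-fatal", "fatal"),
}


def default_crash_spec(n: int = 742, seed: int = 0,
                       misconduct_to_collision: float = 0.0) -> GeneratorSpec:
    """Registry-style stated world: 28 predictors, ~13.6% fatality prevalence.

    Level frequencies follow the registry template; path coefficients are
    moderate (0.25-0.35 on the latent scale).  A nonzero
    ``misconduct_to_collision`` adds that path to the generating model (it is
    otherwise the modification candidate).
    """
    model = hypothesized_crash_model(with_misconduct_to_collision=misconduct_to_collision != 0.0)
    coefs = dict(DEFAULT_COEFFICIENTS)
    if misconduct_to_collision != 0.0:
        coefs[("misconduct", "collision")] = misconduct_to_collision
    return GeneratorSpec(
        model=model,
        coefficients=coefs,
        exog_corr={("passenger", "vehicle_age"): 0.15},
        marginals=dict(_CAUSAL_MARGINALS),
        levels=dict(_CAUSAL_LEVELS),
        noise=_NOISE,
        n=n,
        seed=seed,
    )


def mediation_chain_spec(n: int = 750, seed: int = 0,
                         b_xm: float = 0.40, b_my: float = 0.45) -> GeneratorSpec:
    """Minimal mediation world x -> m -> y for coverage studies.

    A balanced binary exposure, a three-level ordinal mediator with the
    registry misconduct margins, and a binary outcome at the registry's
    13.6% prevalence; the true indirect effect of x on y is ``b_xm * b_my``.
    """
    model = PathModel(
        nodes=(("x", "exogenous"), ("m", "mediator"), ("y", "final-endogenous")),
        edges=(("x", "m"), ("m", "y")),
    )
    return GeneratorSpec(
        model=model,
        coefficients={("x", "m"): b_xm, ("m", "y"): b_my},
        exog_corr={},
        marginals={"x": (0.5, 0.5), "m": _CAUSAL_MARGINALS["misconduct"],
                   "y": (0.8639, 0.1361)},
        levels={"x": _YN, "m": _CAUSAL_LEVELS["misconduct"], "y": ("no", "yes")},
        noise=(),
        n=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sparse-signal benchmark for the regularization stage


DEFAULT_TRUE_SLOPES = {
    "passenger": 0.80,
    "vehicle_age": 0.45,
    "misconduct": 0.60,
    "collision": 0.35,
}


def simulate_selection_benchmark(n: int = 2000, p_noise: int = 24,
                                 true_coefficients: dict[str, float] | None = None,
                                 seed: int = 0, prevalence: float = 0.1361):
    """Logistic-outcome benchmark with a known sparse truth set.

    Four true predictors with the stated score-scale log-odds slopes plus
    ``p_noise`` null predictors (28 predictors in total at the default,
    mirroring the registry's predictor count); the intercept is solved so the
    realized outcome prevalence matches the target.

    Returns ``(StudyTable, truth_set)``.
    """
    true_coefficients = dict(DEFAULT_TRUE_SLOPES if true_coefficients is None
                             else true_coefficients)
    if not true_coefficients:
        raise ValueError("at least one true coefficient required")
    rng = np.random.default_rng(seed)
    cols, specs = {}, []
    eta = np.zeros(n)
    for name, slope in true_coefficients.items():
        labels = _CAUSAL_LEVELS.get(name, ("0", "1"))
        probs = _CAUSAL_MARGINALS.get(name, (0.5, 0.5))
        codes = _draw_categorical(rng, probs, n)
        eta += slope * codes
        cols[name] = np.asarray(labels)[codes]
        scale = "binary" if len(labels) == 2 else "ordinal"
        specs.append(VariableSpec(name, "predictor", scale, tuple(labels)))
    noise_bank = [(f"noise_{i:02d}", _NOISE[i % len(_NOISE)][1], _NOISE[i % len(_NOISE)][2])
                  for i in range(p_noise)]
    for name, labels, probs in noise_bank:
        codes = _draw_categorical(rng, probs, n)
        cols[name] = np.asarray(labels)[codes]
        scale = "binary" if len(labels) == 2 else "ordinal"
        specs.append(VariableSpec(name, "predictor", scale, tuple(labels)))

    def mean_prob(b0):
        return float(np.mean(expit(b0 + eta))) - prevalence

    b0 = optimize.brentq(mean_prob, -20.0, 20.0)
    y = (rng.random(n) < expit(b0 + eta)).astype(int)
    cols["fatality"] = np.asarray(("non-fatal", "fatal"))[y]
    specs.append(VariableSpec("fatality", "outcome", "binary", ("non-fatal", "fatal")))
    table = StudyTable(pd.DataFrame(cols), tuple(specs))
    return table, set(true_coefficients)
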