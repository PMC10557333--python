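"""Bootstrap external validation of path-model effects.

Case-resampled refits give percentile confidence intervals for every direct,
indirect and total effect; the CI-width-change statistic

    P_change = 100 * (width_original - width_bootstrap) / width_bootstrap

compares them with the original model's Wald intervals, and the model is
declared externally valid when every |P_change| stays below a predetermined
threshold (15% by default, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import PathModel
from .pathfit import effect_intervals, effects, fit_dwls
from .polychoric import estimate_polychoric

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    seed: int = 0
    level: float = 0.95
    method: str = "percentile"
    max_failure_fraction: float = 0.2

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("CI level must lie in (0, 1)")


@dataclass
class BootstrapResult:
    intervals: pd.DataFrame  # source, target, kind, estimate, lo, hi
    n_resamples: int
    n_failed: int
    seed: int


def _effect_values(model: PathModel, table) -> dict:
    moments = estimate_polychoric(table, variables=model.names, full_acov=False)
    fit = fit_dwls(model, moments)
    if not fit.converged:
        raise RuntimeError("bootstrap refit did not converge")
    dec = effects(fit)
    out = {}
    for a, b in dec.pairs:
        if (a, b) in dec.direct:
            out[(a, b, "direct")] = dec.direct[(a, b)]
        if (a, b) in dec.indirect:
            out[(a, b, "indirect")] = dec.indirect[(a, b)]
        out[(a, b, "total")] = dec.total((a, b))
    return out


def bootstrap_effects(model: PathModel, table, config: BootstrapConfig) -> BootstrapResult:
    """Percentile bootstrap CIs for all effects; deterministic given the seed.

    Resamples whose refit fails are skipped and counted; more than
    ``max_failure_fraction`` failures is an error.
    """
    rng = np.random.default_rng(config.seed)
    point = _effect_values(model, table)
    keys = sorted(point)
    draws = {k: [] for k in keys}
    n = table.n
    n_failed = 0
    if config.B == 1:
        logger.warning("B=1 gives a degenerate zero-width bootstrap interval")
    for _ in range(config.B):
        rows = rng.integers(0, n, n)
        try:
            vals = _effect_values(model, table.subset(rows))
        except Exception as exc:
            n_failed += 1
            logger.debug("bootstrap refit failed: %s", exc)
            continue
        for k in keys:
            draws[k].append(vals.get(k, 0.0))
    if n_failed > config.max_failure_fraction * config.B:
        raise RuntimeError(f"{n_failed}/{config.B} bootstrap refits failed")
    lo_q = 100 * (1 - config.level) / 2
    rows = []
    for a, b, kind in keys:
        d = np.asarray(draws[(a, b, kind)])
        rows.append({
            "source": a, "target": b, "kind": kind,
            "estimate": point[(a, b, kind)],
            "lo": float(np.percentile(d, lo_q)),
            "hi": float(np.percentile(d, 100 - lo_q)),
        })
    return BootstrapResult(intervals=pd.DataFrame(rows), n_resamples=config.B,
                           n_failed=n_failed, seed=config.seed)


def p_change(width_original: float, width_bootstrap: float) -> float:
    """Percent change of CI width, sign preserved."""
    if width_bootstrap <= 0:
        raise ValueError("bootstrap CI width must be positive")
    return 100.0 * (width_original - width_bootstrap) / width_bootstrap


@dataclass
class ValidationReport:
    table: pd.DataFrame   # per effect: original/bootstrap widths, P_change, verdict
    threshold: float
    n_failed: int

    @property
    def p_change_range(self) -> tuple[float, float]:
        p = self.table["p_change"].abs()
        return float(p.min()), float(p.max())

    @property
    def overall_pass(self) -> bool:
        return bool(self.table["within_threshold"].all())


def validity_verdict(report: ValidationReport, threshold: float | None = None) -> bool:
    """Overall external-validity verdict: every |P_change| strictly below threshold."""
    if len(report.table) == 0:
        raise ValueError("no effects to validate")
    thr = report.threshold if threshold is None else threshold
    return bool((report.table["p_change"].abs() < thr).all())


def validate_model(model: PathModel, table, config: BootstrapConfig | None = None,
                   threshold: float = 15.0) -> ValidationReport:
    """Full validation pass: original Wald CIs vs bootstrap percentile CIs."""
    config = config or BootstrapConfig()
    moments = estimate_polychoric(table, variables=model.names)
    fit = fit_dwls(model, moments)
    original = effect_intervals(fit, level=config.level)
    boot = bootstrap_effects(model, table, config)
    merged = original.merge(boot.intervals, on=["source", "target", "kind"],
                            suffixes=("_orig", "_boot"))
    rows = []
    for _, r in merged.iterrows():
        w_orig = r["hi_orig"] - r["lo_orig"]
        w_boot = r["hi_boot"] - r["lo_boot"]
        pc = p_change(w_orig, w_boot) if w_boot > 0 else np.nan
        rows.append({
            "source": r["source"], "target": r["target"], "kind": r["kind"],
            "estimate": r["estimate_orig"],
            "width_original": w_orig, "width_bootstrap": w_boot,
            "p_change": pc,
            "within_threshold": bool(abs(pc) < threshold) if np.isfinite(pc) else False,
        })
    return ValidationReport(table=pd.DataFrame(rows), threshold=threshold,
                            n_failed=boot.n_failed)
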