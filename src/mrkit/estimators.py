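"""Causal-effect estimators for two-sample Mendelian randomization.

Each harmonized instrument j contributes a Wald ratio

    beta_j = Gamma_j / gamma_j,    se_j = se_out_j / |gamma_j|,

the variant-outcome effect scaled by the variant-exposure effect, with a
first-order delta-method standard error that treats gamma_j as fixed.
The estimators here combine the ratios under different assumptions about
instrument validity:

* **IVW** — inverse-variance weighted mean of the ratios. The fixed-effect
  model takes se = (sum w_j)^(-1/2); the multiplicative random-effects
  model inflates that by max(1, sqrt(Q/(J-1))), where Q is Cochran's
  heterogeneity statistic. Valid when every instrument is valid (or
  pleiotropy is balanced with InSIDE).
* **Weighted median** — the 50% point of the weight-ordered ratios;
  consistent while valid instruments carry more than half the weight.
* **Weighted mode** — the peak of a weighted Gaussian kernel density over
  the ratios; consistent while the largest cluster of ratios is valid.
* **MR-Egger** — weighted regression of Gamma on gamma with a free
  intercept; the slope is the causal estimate and a nonzero intercept is
  evidence of directional pleiotropy (requires InSIDE).

Bootstrap standard errors for median and mode are parametric: each ratio
is redrawn from Normal(beta_j, se_j) and the statistic recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedInstrument

Method = Literal["wald_ratio", "ivw_fe", "ivw_mre", "weighted_median",
                 "weighted_mode", "egger"]

MIN_INSTRUMENTS = {"wald_ratio": 1, "ivw_fe": 1, "ivw_mre": 1,
                   "weighted_median": 3, "weighted_mode": 3, "egger": 3}


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio with first-order SE and inverse-variance weight."""

    variant_id: str
    beta_ratio: float
    se_ratio: float

    def __post_init__(self) -> None:
        if not (self.se_ratio > 0):
            raise ValueError(f"{self.variant_id}: se_ratio must be > 0")
        if not math.isfinite(self.beta_ratio):
            raise ValueError(f"{self.variant_id}: ratio estimate not finite")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MRResult:
    """One method's causal estimate with CI, p-value and heterogeneity."""

    method: Method
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    ci_level: float = 0.95
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def ratio_estimates(instruments: Sequence[HarmonizedInstrument]) -> list[RatioEstimate]:
    """Wald ratios Gamma_j/gamma_j with delta-method SE se_out_j/|gamma_j|.

    Fails per-variant on gamma_j = 0 (the ratio is undefined for a null
    instrument).
    """
    out = []
    for ins in instruments:
        if ins.beta_exp == 0:
            raise ZeroDivisionError(
                f"{ins.variant_id}: exposure effect is 0; Wald ratio undefined")
        out.append(RatioEstimate(
            variant_id=ins.variant_id,
            beta_ratio=ins.beta_out / ins.beta_exp,
            se_ratio=ins.se_out / abs(ins.beta_exp),
        ))
    return out


def cochran_q(ratios: Sequence[RatioEstimate], beta: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (beta_j - beta_IVW)^2 with fixed-effect weights.

    Returns (Q, df, upper-tail chi-square p). df = J - 1.
    """
    w = np.array([r.weight for r in ratios])
    b = np.array([r.beta_ratio for r in ratios])
    if beta is None:
        beta = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def _zcrit(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


def _normal_result(method: Method, beta: float, se: float, n: int,
                   ci_level: float, **kw) -> MRResult:
    z = _zcrit(ci_level)
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MRResult(method=method, beta=beta, se=se,
                    ci_low=beta - z * se, ci_high=beta + z * se,
                    pvalue=p, n_snps=n, ci_level=ci_level, **kw)


def ivw(ratios: Sequence[RatioEstimate],
        model: Literal["fixed", "multiplicative_random"] = "fixed",
        ci_level: float = 0.95) -> MRResult:
    """Inverse-variance weighted meta-analysis of Wald ratios.

    ``fixed``: se = (sum w_j)^(-1/2). ``multiplicative_random``: the
    fixed-effect SE scaled by max(1, sqrt(Q/(J-1))) — heterogeneity
    inflates uncertainty multiplicatively, never below the fixed-effect
    SE. A single ratio degenerates to the Wald ratio (method tag
    ``wald_ratio``), with a note when a random-effects model was asked of it.
    """
    if len(ratios) == 0:
        raise ValueError("ivw requires at least one ratio estimate")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    w = np.array([r.weight for r in ratios])
    b = np.array([r.beta_ratio for r in ratios])
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if len(ratios) == 1:
        notes = []
        if model == "multiplicative_random":
            notes.append("single instrument: multiplicative random effects "
                         "undefined, fell back to Wald ratio")
        return _normal_result("wald_ratio", beta, se_fixed, 1, ci_level, notes=notes)
    q, q_df, q_p = cochran_q(ratios, beta)
    if model == "fixed":
        method: Method = "ivw_fe"
        se = se_fixed
    else:
        method = "ivw_mre"
        se = se_fixed * max(1.0, math.sqrt(q / q_df))
    return _normal_result(method, beta, se, len(ratios), ci_level,
                          q=q, q_df=q_df, q_pvalue=q_p)


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative standardized weights
    p_j = (S_j - w_j/2)/S_J over the sorted ratios, linear interpolation
    at p = 0.5 (stable sort, so ties keep input order)."""
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    if 0.5 <= p[0]:
        return float(b[0])
    if 0.5 >= p[-1]:
        return float(b[-1])
    return float(np.interp(0.5, p, b))


def weighted_median(ratios: Sequence[RatioEstimate], n_boot: int = 1000,
                    seed: int | None = None, ci_level: float = 0.95) -> MRResult:
    """Weighted median of the Wald ratios; parametric-bootstrap SE.

    Consistent when instruments carrying >50% of the weight are valid.
    """
    if len(ratios) < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    b = np.array([r.beta_ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    se_r = np.array([r.se_ratio for r in ratios])
    est = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se_r, size=(n_boot, len(ratios)))
    boots = np.array([_weighted_median(row, w) for row in draws])
    se = float(np.std(boots, ddof=1))
    return _normal_result("weighted_median", est, se, len(ratios), ci_level)


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the ratio estimates, scaled by phi."""
    sd = float(np.std(b, ddof=1))
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * len(b) ** (-0.2)


def _kde_argmax(b: np.ndarray, w: np.ndarray, h: float) -> float:
    """Argmax of the weighted Gaussian KDE: coarse grid then local refine."""
    wn = w / w.sum()

    def neg_density(x: float) -> float:
        return -float(np.sum(wn * np.exp(-0.5 * ((x - b) / h) ** 2)))

    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 1024)
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2)).sum(axis=1)
    x0 = grid[int(np.argmax(dens))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(neg_density, bracket=None,
                                   bounds=(x0 - 2 * step, x0 + 2 * step),
                                   method="bounded")
    return float(res.x) if res.fun <= neg_density(x0) else float(x0)


def weighted_mode(ratios: Sequence[RatioEstimate], bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None,
                  ci_level: float = 0.95) -> MRResult:
    """Mode of the weighted kernel density over the Wald ratios.

    Bandwidth h = phi * 0.9 * min(sd, iqr/1.34) * J^(-1/5); weights are
    normalized inverse variances, so the estimate is invariant to
    rescaling all weights. Consistent when the largest cluster of ratios
    comes from valid instruments. Parametric-bootstrap SE as in
    :func:`weighted_median`.
    """
    if len(ratios) < 3:
        raise ValueError("weighted_mode requires at least 3 instruments")
    b = np.array([r.beta_ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    se_r = np.array([r.se_ratio for r in ratios])
    h = _mode_bandwidth(b, bandwidth_factor)
    est = float(b[0]) if h == 0 else _kde_argmax(b, w, h)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se_r, size=(n_boot, len(ratios)))
    boots = np.empty(n_boot)
    for i, row in enumerate(draws):
        hb = _mode_bandwidth(row, bandwidth_factor)
        boots[i] = row[0] if hb == 0 else _kde_argmax(row, w, hb)
    se = float(np.std(boots, ddof=1))
    return _normal_result("weighted_mode", est, se, len(ratios), ci_level)


def mr_egger(instruments: Sequence[HarmonizedInstrument],
             ci_level: float = 0.95) -> MRResult:
    """MR-Egger: WLS of Gamma_j on gamma_j with intercept, weights 1/se_out^2.

    Instruments are first oriented so every gamma_j > 0 (negating both
    effects where needed), which fixes the sign convention the intercept
    depends on. The slope estimates the causal effect; the intercept is
    the average directional pleiotropy. The residual variance factor is
    floored at 1 (no shrinking below the homoskedastic model); p-values
    use t with J-2 degrees of freedom.
    """
    j = len(instruments)
    if j < 3:
        raise ValueError("mr_egger requires at least 3 instruments")
    sign = np.array([1.0 if ins.beta_exp > 0 else -1.0 for ins in instruments])
    x = sign * np.array([ins.beta_exp for ins in instruments])
    y = sign * np.array([ins.beta_out for ins in instruments])
    w = np.array([1.0 / ins.se_out**2 for ins in instruments])
    if np.allclose(x, x[0]):
        raise ValueError("all exposure effects equal after orientation: "
                         "Egger design matrix is collinear")
    X = np.column_stack([np.ones(j), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    cov = max(1.0, sigma2) * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_s = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, j - 2))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_s, j - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_i, j - 2))
    q, q_df, q_p = _egger_q(x, y, w, intercept, slope)
    return MRResult(
        method="egger", beta=slope, se=se_s,
        ci_low=slope - tcrit * se_s, ci_high=slope + tcrit * se_s,
        pvalue=p_slope, n_snps=j, ci_level=ci_level,
        q=q, q_df=q_df, q_pvalue=q_p,
        egger_intercept=intercept, egger_intercept_se=se_i,
        egger_intercept_p=p_int,
    )


def _egger_q(x, y, w, intercept, slope):
    """Rucker's Q': weighted squared residuals about the Egger fit."""
    q = float(np.sum(w * (y - intercept - slope * x) ** 2))
    df = len(x) - 2
    return q, df, float(stats.chi2.sf(q, df))


def pvalue_consistency_check(beta: float, se: float) -> float:
    """Two-sided normal p recomputed from beta/se, 2*(1 - Phi(|beta/se|)).

    Used to cross-check ingested p-values (which are stored as reported);
    rounding of the printed beta and se propagates into this value, so
    comparisons should allow a few percent of slack.
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def all_methods(instruments: Sequence[HarmonizedInstrument],
                ivw_model: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
                n_boot: int = 1000, seed: int | None = None,
                bandwidth_factor: float = 1.0,
                ci_level: float = 0.95) -> list[MRResult]:
    """Run every estimator the instrument count permits, IVW first."""
    ratios = ratio_estimates(instruments)
    results = [ivw(ratios, model=ivw_model, ci_level=ci_level)]
    if len(ratios) >= 3:
        results.append(weighted_median(ratios, n_boot=n_boot, seed=seed, ci_level=ci_level))
        results.append(weighted_mode(ratios, bandwidth_factor=bandwidth_factor,
                                     n_boot=n_boot, seed=seed, ci_level=ci_level))
        results.append(mr_egger(instruments, ci_level=ci_level))
    return results
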