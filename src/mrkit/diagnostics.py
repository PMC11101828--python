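"""Sensitivity analyses: leave-one-out, MR-PRESSO, scatter export.

Leave-one-out refits the IVW estimate J times, dropping one instrument
each time; an estimate that moves materially when a single variant is
dropped points at that variant as a pleiotropy suspect.

MR-PRESSO (pleiotropy residual sum and outlier test) compares the
observed weighted residual sum of squares about leave-one-out IVW
predictions with its parametric null distribution, simulated by
redrawing every instrument's effects from their sampling distributions
under the no-pleiotropy model. The global p tests for any horizontal
pleiotropy; per-variant contributions give empirical outlier p-values
(Bonferroni-adjusted across instruments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .estimators import MRResult, ivw, ratio_estimates
from .harmonize import HarmonizedInstrument


@dataclass
class LeaveOneOutRow:
    dropped_variant: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    model: Literal["fixed", "multiplicative_random"] = "fixed",
    ci_level: float = 0.95,
) -> list[LeaveOneOutRow]:
    """IVW estimate excluding each instrument in turn; rows follow input order."""
    if len(instruments) < 3:
        raise ValueError("leave_one_out requires at least 3 instruments")
    rows = []
    for i, ins in enumerate(instruments):
        rest = [x for j, x in enumerate(instruments) if j != i]
        res = ivw(ratio_estimates(rest), model=model, ci_level=ci_level)
        rows.append(LeaveOneOutRow(ins.variant_id, res.beta, res.se,
                                   res.ci_low, res.ci_high, res.pvalue))
    return rows


def leave_one_out_frame(rows: Sequence[LeaveOneOutRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class PressoResult:
    """MR-PRESSO global and outlier test results."""

    global_rss: float
    global_p: float
    n_sim: int
    outlier_p: dict[str, float]        # Bonferroni-adjusted, capped at 1
    outliers: list[str]
    seed: int | None
    distortion: dict = field(default_factory=dict)


def _loo_rss(gamma: np.ndarray, Gamma: np.ndarray, w_out: np.ndarray) -> np.ndarray:
    """Per-variant weighted squared residual about the leave-one-out IVW
    prediction. Inputs are (..., J) arrays; broadcasting covers both the
    observed data (1D) and the simulation matrix (2D)."""
    num = (gamma * Gamma * w_out).sum(axis=-1, keepdims=True)
    den = (gamma**2 * w_out).sum(axis=-1, keepdims=True)
    beta_loo = (num - gamma * Gamma * w_out) / (den - gamma**2 * w_out)
    return w_out * (Gamma - beta_loo * gamma) ** 2


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global test with per-variant outlier detection.

    The observed statistic is RSS = sum_j (Gamma_j - beta_(-j) gamma_j)^2
    / se_out_j^2, with beta_(-j) the IVW estimate excluding variant j.
    The null distribution redraws Gamma_j* ~ N(beta_(-j) gamma_j,
    se_out_j) and gamma_j* ~ N(gamma_j, se_exp_j) ``n_sim`` times;
    empirical p-values use the (k+1)/(n_sim+1) estimator, so
    global_p >= 1/(n_sim+1) and identical seeds are bit-reproducible.

    Also reports the distortion summary: the outlier-corrected IVW
    estimate and its percent change from the full-set estimate.
    """
    j = len(instruments)
    if j < 4:
        raise ValueError("mr_presso requires at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")

    gamma = np.array([i.beta_exp for i in instruments])
    Gamma = np.array([i.beta_out for i in instruments])
    se_exp = np.array([i.se_exp for i in instruments])
    se_out = np.array([i.se_out for i in instruments])
    w_out = 1.0 / se_out**2
    ids = [i.variant_id for i in instruments]

    obs_contrib = _loo_rss(gamma, Gamma, w_out)
    obs_rss = float(obs_contrib.sum())

    # expected outcome effects under the no-pleiotropy null
    num = float((gamma * Gamma * w_out).sum())
    den = float((gamma**2 * w_out).sum())
    beta_loo = (num - gamma * Gamma * w_out) / (den - gamma**2 * w_out)

    rng = np.random.default_rng(seed)
    g_sim = rng.normal(gamma, se_exp, size=(n_sim, j))
    y_sim = rng.normal(beta_loo * gamma, se_out, size=(n_sim, j))
    sim_contrib = _loo_rss(g_sim, y_sim, w_out)
    sim_rss = sim_contrib.sum(axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    raw_p = (np.sum(sim_contrib >= obs_contrib, axis=0) + 1) / (n_sim + 1)
    adj_p = np.minimum(raw_p * j, 1.0)
    outlier_p = dict(zip(ids, adj_p.astype(float)))
    outliers = [v for v, p in outlier_p.items() if p < outlier_alpha]

    distortion: dict = {}
    if outliers and j - len(outliers) >= 2:
        keep = [i for i in instruments if i.variant_id not in outliers]
        full = ivw(ratio_estimates(instruments), model="fixed")
        corrected = ivw(ratio_estimates(keep), model="fixed")
        distortion = {
            "beta_full": full.beta,
            "beta_corrected": corrected.beta,
            "percent_change": 100.0 * (corrected.beta - full.beta) / abs(full.beta)
            if full.beta != 0 else float("nan"),
        }
    return PressoResult(global_rss=obs_rss, global_p=global_p, n_sim=n_sim,
                        outlier_p=outlier_p, outliers=outliers, seed=seed,
                        distortion=distortion)


def scatter_export(
    instruments: Sequence[HarmonizedInstrument],
    results: Sequence[MRResult],
) -> pd.DataFrame:
    """Table from which the exposure-vs-outcome scatter can be redrawn.

    One ``point`` row per instrument (effects and SEs, so 95% whiskers
    can be drawn as +/- 1.96 SE) and one ``line`` row per method (slope
    plus intercept; the intercept is zero for every method but Egger).
    """
    if not instruments or not results:
        raise ValueError("scatter_export needs instruments and results")
    rows = [{"kind": "point", "variant_id": i.variant_id,
             "beta_exp": i.beta_exp, "se_exp": i.se_exp,
             "beta_out": i.beta_out, "se_out": i.se_out,
             "method": None, "slope": None, "intercept": None}
            for i in instruments]
    for r in results:
        rows.append({"kind": "line", "variant_id": None,
                     "beta_exp": None, "se_exp": None,
                     "beta_out": None, "se_out": None,
                     "method": r.method, "slope": r.beta,
                     "intercept": r.egger_intercept or 0.0})
    return pd.DataFrame(rows)


def plot_scatter(table: pd.DataFrame, path=None):
    """Optional cosmetic rendering of a :func:`scatter_export` table.

    Requires matplotlib; returns None (with a warning) if it is absent,
    so pipelines never fail for lack of a plotting backend.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        import logging
        logging.getLogger(__name__).warning("matplotlib unavailable: plot skipped")
        return None
    pts = table[table["kind"] == "point"]
    lines = table[table["kind"] == "line"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(pts["beta_exp"], pts["beta_out"],
                xerr=1.96 * pts["se_exp"], yerr=1.96 * pts["se_out"],
                fmt="o", color="k", ecolor="0.6", ms=4)
    xs = np.linspace(min(0, pts["beta_exp"].min()), pts["beta_exp"].max() * 1.05, 50)
    for _, row in lines.iterrows():
        ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"])
    ax.set_xlabel("variant-exposure effect")
    ax.set_ylabel("variant-outcome effect")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
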