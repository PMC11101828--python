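"""Seeded generator of two-sample GWAS summary statistics with known truth.

Data are generated directly at the summary level under the linear
instrumental-variable model: each variant j has a true exposure effect
gamma_j, an optional direct (pleiotropic) outcome effect alpha_j, and a
true outcome effect Gamma_j = theta * gamma_j + alpha_j, where theta is
the causal effect of exposure on outcome. Observed effects add
independent Gaussian noise at the stated standard errors — the exposure
and outcome samples are treated as non-overlapping, as in a two-sample
design. No LD between instruments is simulated and no individual-level
genotypes exist.

Pleiotropy options: ``none``; ``balanced`` (alpha ~ N(0, kappa),
satisfying InSIDE, under which IVW stays approximately unbiased);
``directional`` (alpha ~ N(mu, kappa), biasing IVW but detectable by the
Egger intercept); ``correlated`` (alpha correlated with gamma,
violating InSIDE, which biases Egger too).

Defaults are scaled to look like real strong-instrument summary
statistics: per-allele exposure effects of a few hundredths to tenths of
an SD with |gamma| >= 0.05 enforced by truncation (so single-variant
F-statistics clear the weak-instrument bound deterministically),
exposure SEs of 0.003 and outcome SEs of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .sumstats import SummaryAssociation

PleiotropyKind = Literal["none", "balanced", "directional", "correlated"]

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticScenario:
    """Generative parameters for a simulated two-sample MR dataset."""

    n_variants: int = 20
    theta: float = 0.0                      # causal effect, outcome per exposure unit
    gamma_sd: float = 0.1                   # spread of true exposure effects
    min_abs_gamma: float = 0.05             # instrument-strength floor (truncation)
    se_exp: float | Sequence[float] = 0.003
    se_out: float | Sequence[float] = 0.01
    pleiotropy: PleiotropyKind = "none"
    pleiotropy_mean: float = 0.0            # mu of direct effects (directional)
    pleiotropy_sd: float = 0.0              # kappa
    pleiotropy_cor: float = 0.0             # rho with gamma (correlated / InSIDE-violating)
    frac_invalid: float = 0.0
    palindromic_frac: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0 <= self.frac_invalid <= 1):
            raise ValueError("frac_invalid must be in [0, 1]")
        if not (0 <= self.palindromic_frac <= 1):
            raise ValueError("palindromic_frac must be in [0, 1]")
        for name in ("se_exp", "se_out"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v <= 0):
                raise ValueError(f"{name} scales must be > 0")


def _broadcast(value, j: int, rng: np.random.Generator) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(j, float(arr))
    if arr.shape == (2,):  # (low, high) range
        return rng.uniform(arr[0], arr[1], size=j)
    if arr.shape == (j,):
        return arr.copy()
    raise ValueError(f"se spec must be scalar, (low, high) or length-{j}")


def generate(
    scenario: SyntheticScenario,
) -> tuple[list[SummaryAssociation], list[SummaryAssociation], dict]:
    """Draw one two-sample summary dataset.

    Returns (exposure records, outcome records, truth record). The truth
    record holds every latent quantity (true gamma, alpha, Gamma, the
    invalid-variant mask and theta) so tests can score recovery.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    j = scenario.n_variants

    gamma = rng.normal(0.0, scenario.gamma_sd, size=j)
    # truncation: push effects below the strength floor outward
    small = np.abs(gamma) < scenario.min_abs_gamma
    gamma[small] = np.sign(gamma[small] + (gamma[small] == 0)) * scenario.min_abs_gamma

    alpha = np.zeros(j)
    n_invalid = int(round(scenario.frac_invalid * j))
    invalid = np.zeros(j, dtype=bool)
    if n_invalid and scenario.pleiotropy != "none":
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
        if scenario.pleiotropy == "balanced":
            alpha[invalid] = rng.normal(0.0, scenario.pleiotropy_sd, size=n_invalid)
        elif scenario.pleiotropy == "directional":
            # directional with respect to the exposure-increasing allele:
            # sign-coupling to gamma keeps the direct effects one-sided in
            # the orientation MR-Egger uses, as a shared upstream pathway
            # would be
            alpha[invalid] = np.sign(gamma[invalid]) * rng.normal(
                scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=n_invalid)
        elif scenario.pleiotropy == "correlated":
            rho = scenario.pleiotropy_cor
            noise = rng.normal(0.0, 1.0, size=n_invalid)
            g = np.abs(gamma[invalid]) / scenario.gamma_sd
            alpha[invalid] = np.sign(gamma[invalid]) * (
                scenario.pleiotropy_mean + scenario.pleiotropy_sd * (
                    rho * g + np.sqrt(max(0.0, 1 - rho**2)) * noise))

    Gamma = scenario.theta * gamma + alpha
    se_exp = _broadcast(scenario.se_exp, j, rng)
    se_out = _broadcast(scenario.se_out, j, rng)
    gamma_hat = rng.normal(gamma, se_exp)
    Gamma_hat = rng.normal(Gamma, se_out)

    n_pal = int(round(scenario.palindromic_frac * j))
    pal_idx = set(rng.choice(j, size=n_pal, replace=False).tolist()) if n_pal else set()
    eaf = rng.uniform(0.1, 0.9, size=j)
    chrom = rng.integers(1, 23, size=j)
    pos = rng.integers(1_000_000, 100_000_000, size=j)

    exposure, outcome = [], []
    for i in range(j):
        ea, oa = (_PALINDROMIC if i in pal_idx else _NONPALINDROMIC)[
            rng.integers(0, 4 if i in pal_idx else 8)]
        common = dict(variant_id=f"rs{i + 1:06d}", chrom=str(chrom[i]),
                      pos=int(pos[i]), effect_allele=ea, other_allele=oa,
                      eaf=float(eaf[i]))
        exposure.append(SummaryAssociation(
            beta=float(gamma_hat[i]), se=float(se_exp[i]),
            pvalue=float(2 * stats.norm.sf(abs(gamma_hat[i]) / se_exp[i])) or 5e-324,
            trait="simulated exposure", unit="SD per allele", **common))
        outcome.append(SummaryAssociation(
            beta=float(Gamma_hat[i]), se=float(se_out[i]),
            pvalue=float(2 * stats.norm.sf(abs(Gamma_hat[i]) / se_out[i])) or 5e-324,
            trait="simulated outcome", unit="SD per allele", **common))

    truth = {
        "scenario": asdict(scenario),
        "theta": scenario.theta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "Gamma": Gamma.tolist(),
        "invalid": invalid.tolist(),
    }
    return exposure, outcome, truth


_PRESETS: dict[str, dict] = {
    # instrument counts and SE magnitudes on the scale of the packaged
    # coffee/caffeine analyses
    "ea_coffee_like": dict(n_variants=7, theta=0.08, gamma_sd=0.1,
                           min_abs_gamma=0.06, se_exp=0.012, se_out=0.01),
    "eu_coffee_like": dict(n_variants=22, theta=0.05, gamma_sd=0.015,
                           min_abs_gamma=0.009, se_exp=0.002, se_out=0.004),
    "caffeine_pair_like": dict(n_variants=2, theta=-0.05, gamma_sd=0.065,
                               min_abs_gamma=0.06, se_exp=(0.009, 0.019),
                               se_out=(0.0004, 0.0023)),
    "single_iv_like": dict(n_variants=1, theta=-0.07, gamma_sd=0.07,
                           min_abs_gamma=0.06, se_exp=0.019, se_out=0.0023),
}


def preset(name: str, seed: int | None = None, **overrides) -> SyntheticScenario:
    """Scenario presets mirroring the dimensions of the packaged analyses."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SyntheticScenario(seed=seed, **params)


PRESET_NAMES = tuple(_PRESETS)
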