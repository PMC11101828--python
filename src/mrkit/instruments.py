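"""Instrument selection and heterogeneity-driven pruning.

Candidate instruments must be strongly and significantly associated with
the exposure (p below genome-wide significance, single-variant
F-statistic above the weak-instrument bound) and mutually independent
(pairwise LD r^2 below a ceiling, greedily pruned in order of
significance). Variants with known pleiotropic associations are removed
via explicit, documented exclusion lists — a reproducible stand-in for
interactive phenome-scan lookups — and variants with established
exposure-specific biology can be protected from automated removal.

``prune_heterogeneity`` implements the heterogeneity-driven exclusion
used to build "robust" instrument sets: repeatedly drop the instrument
contributing most to Cochran's Q until the heterogeneity test is no
longer significant. The removal trace makes every exclusion auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .estimators import cochran_q, ratio_estimates
from .harmonize import HarmonizedInstrument
from .sumstats import SummaryAssociation

logger = logging.getLogger(__name__)

#: Pleiotropy-screen presets for the packaged analyses. Exclusions are
#: variants reported as associated with non-exposure pathways (metabolic
#: loci such as GCKR, ALDH2, APOE5, MIR2113); protected variants sit in
#: core caffeine-metabolism genes (AHR, CYP1A1/1A2, PCMTD2) with no known
#: pleiotropy and are never removed by automated pruning.
PLEIOTROPY_PRESETS: dict[str, dict[str, list[str]]] = {
    "ea_coffee": {
        "manual_exclusions": ["rs1260326", "rs671", "rs12189679", "rs662799"],
        "protected_variants": ["rs4410790"],
    },
    "eu_coffee": {
        "manual_exclusions": [],
        "protected_variants": ["rs4410790", "rs2472297", "rs6062682"],
    },
}


@dataclass
class SelectionConfig:
    """Thresholds and lists governing instrument selection."""

    p_threshold: float = 5.0e-8
    f_min: float = 10.0
    ld_r2_max: float = 0.01
    exclude_palindromic: bool = False
    manual_exclusions: Mapping[str, str] | Sequence[str] = field(default_factory=dict)
    protected_variants: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must be in [0, 1]")
        if not isinstance(self.manual_exclusions, Mapping):
            self.manual_exclusions = {v: "manual exclusion" for v in self.manual_exclusions}


class LDTable:
    """Symmetric pairwise r^2 lookup; absent pairs (and cross-chromosome
    pairs, which share no entry) default to r^2 = 0; r^2(a, a) = 1."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
        key = frozenset((a, b))
        if key in self._pairs and abs(self._pairs[key] - r2) > 1e-12:
            raise ValueError(f"conflicting r2 entries for ({a},{b})")
        self._pairs[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_file(cls, path: str | Path) -> "LDTable":
        """Read a 3-column delimited table (rsid_a, rsid_b, r2)."""
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [c.lower() for c in df.columns]
        table = cls()
        for _, row in df.iterrows():
            table.add(str(row.iloc[0]), str(row.iloc[1]), float(row.iloc[2]))
        return table


def f_statistic(assoc: SummaryAssociation) -> float:
    """Single-variant instrument-strength F = (beta/se)^2.

    F > 10 is the conventional weak-instrument bound.
    """
    return (assoc.beta / assoc.se) ** 2


@dataclass
class ExclusionRecord:
    variant_id: str
    stage: str
    reason: str
    statistic: float | None = None


def select_instruments(
    exposure: Sequence[SummaryAssociation],
    config: SelectionConfig | None = None,
    ld: LDTable | None = None,
) -> tuple[list[SummaryAssociation], list[ExclusionRecord]]:
    """Apply significance, strength, manual-exclusion, palindrome and LD
    filters; return (retained, exclusion log).

    LD pruning is greedy in ascending p order: a variant is kept only if
    its r^2 against every already-kept variant is below ``ld_r2_max``.
    The result is independent of input ordering (ties broken by rsID).
    An empty retained set is legal.
    """
    config = config or SelectionConfig()
    if ld is None:
        ld = LDTable()
        logger.info("no LD table supplied: no LD pruning will occur")
    log: list[ExclusionRecord] = []
    survivors: list[SummaryAssociation] = []
    for a in exposure:
        if a.variant_id in config.manual_exclusions:
            log.append(ExclusionRecord(a.variant_id, "manual",
                                       config.manual_exclusions[a.variant_id]))
        elif a.pvalue >= config.p_threshold:
            log.append(ExclusionRecord(
                a.variant_id, "significance",
                f"p = {a.pvalue:.3g} >= {config.p_threshold:.3g}", a.pvalue))
        elif f_statistic(a) <= config.f_min:
            log.append(ExclusionRecord(
                a.variant_id, "strength",
                f"F = {f_statistic(a):.2f} <= {config.f_min:g}", f_statistic(a)))
        elif config.exclude_palindromic and a.is_palindromic:
            log.append(ExclusionRecord(a.variant_id, "palindrome",
                                       f"{a.effect_allele}/{a.other_allele} pair"))
        else:
            survivors.append(a)

    # greedy LD pruning, most significant first; rsID tiebreak for
    # order-independence
    survivors.sort(key=lambda a: (a.pvalue, a.variant_id))
    kept: list[SummaryAssociation] = []
    for a in survivors:
        clash = next((k for k in kept
                      if ld.r2(a.variant_id, k.variant_id) >= config.ld_r2_max), None)
        if clash is None:
            kept.append(a)
        else:
            log.append(ExclusionRecord(
                a.variant_id, "ld",
                f"r2 = {ld.r2(a.variant_id, clash.variant_id):.3g} with {clash.variant_id}",
                ld.r2(a.variant_id, clash.variant_id)))
    return kept, log


def exclusion_log_frame(log: Sequence[ExclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variant_id, r.stage, r.reason, r.statistic) for r in log],
        columns=["rsid", "stage", "reason", "statistic"])


def prune_heterogeneity(
    instruments: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
    protected: Sequence[str] = (),
    max_removals: int | None = None,
) -> tuple[list[HarmonizedInstrument], list[tuple[str, float]]]:
    """Greedily remove instruments driving Cochran's Q until the
    heterogeneity test is non-significant.

    At each step the non-protected instrument with the largest Q
    contribution w_j (beta_j - beta_IVW)^2 is removed and the IVW fit
    recomputed; removal stops when the Q p-value reaches ``alpha``, when
    ``max_removals`` is hit, or when fewer than 3 instruments would
    remain. Returns (surviving set, ordered removal trace of
    (rsID, Q contribution at removal)). Q decreases at every step.

    With fewer than 3 instruments to start, refuses to prune and returns
    the input unchanged.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    current = list(instruments)
    removed: list[tuple[str, float]] = []
    if len(current) < 3:
        logger.warning("fewer than 3 instruments: heterogeneity pruning skipped")
        return current, removed
    if max_removals is None:
        max_removals = len(current) - 3
    protected_set = set(protected)
    while len(current) > 2 and len(removed) < max_removals:
        ratios = ratio_estimates(current)
        q, df, p = cochran_q(ratios)
        if p >= alpha:
            break
        w = [r.weight for r in ratios]
        b = [r.beta_ratio for r in ratios]
        beta_ivw = sum(wi * bi for wi, bi in zip(w, b)) / sum(w)
        contrib = [wi * (bi - beta_ivw) ** 2 for wi, bi in zip(w, b)]
        candidates = [(c, i) for i, c in enumerate(contrib)
                      if current[i].variant_id not in protected_set]
        if not candidates:
            logger.warning("all remaining instruments protected: pruning stopped")
            break
        worst_c, worst_i = max(candidates)
        removed.append((current[worst_i].variant_id, worst_c))
        del current[worst_i]
    return current, removed
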