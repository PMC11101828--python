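"""Align exposure and outcome summary statistics to a shared effect allele.

Two-sample MR combines a variant-exposure effect (gamma) and a
variant-outcome effect (Gamma) for the same variant, but the two source
GWAS need not report effects for the same allele or even the same
strand. Harmonization joins the two sets on rsID, re-signs the outcome
effect where its alleles are reversed, resolves strand flips by
complementing, and applies a policy to palindromic (A/T, C/G) variants,
whose orientation cannot be decided from alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .sumstats import SummaryAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PalindromePolicy = Literal["drop_all", "drop_ambiguous", "keep_infer_by_eaf"]


@dataclass
class HarmonizedInstrument:
    """A variant carrying exposure and outcome effects for one shared allele.

    ``flipped`` records that the outcome record's alleles were swapped
    (and its beta negated) during alignment.
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    palindromic: bool = False
    flipped: bool = False
    effect_allele: str = ""
    other_allele: str = ""

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


class HarmonizationError(ValueError):
    pass


def _index_unique(records: Iterable[SummaryAssociation], label: str):
    out: dict[str, SummaryAssociation] = {}
    order: list[str] = []
    for r in records:
        if r.variant_id in out:
            raise HarmonizationError(
                f"duplicate variant_id {r.variant_id!r} in {label} set: join is ambiguous")
        out[r.variant_id] = r
        order.append(r.variant_id)
    return out, order


def harmonize_pair(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    palindrome_policy: PalindromePolicy = "drop_all",
    eaf_ambiguity_threshold: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Join exposure and outcome records on rsID and align effect alleles.

    Alignment order per variant: exact allele match; swapped alleles
    (outcome beta negated, eaf complemented); strand-complement match;
    strand-complement swapped. Irreconcilable allele sets are dropped
    with a logged reason. ``chrom:pos`` disagreement between the two
    records warns but never drops.

    Palindromic variants are handled per policy: ``drop_all`` removes
    them; ``drop_ambiguous`` removes only those whose minor-allele
    frequency is within ``eaf_ambiguity_threshold`` of 0.5 (default
    0.08, i.e. a variant is ambiguous when its MAF exceeds 0.42);
    ``keep_infer_by_eaf`` orients by frequency agreement between the
    cohorts.
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous", "keep_infer_by_eaf"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    exp_by_id, order = _index_unique(exposure, "exposure")
    out_by_id, _ = _index_unique(outcome, "outcome")

    instruments: list[HarmonizedInstrument] = []
    for vid in order:
        if vid not in out_by_id:
            logger.info("%s: absent from outcome set, dropped", vid)
            continue
        e, o = exp_by_id[vid], out_by_id[vid]
        if (e.chrom, e.pos) != (o.chrom, o.pos):
            logger.warning("%s: chrom:pos mismatch between files (%s:%s vs %s:%s)",
                           vid, e.chrom, e.pos, o.chrom, o.pos)

        palindromic = e.is_palindromic
        ea, oa = e.effect_allele, e.other_allele
        o_ea, o_oa = o.effect_allele, o.other_allele
        comp_ea, comp_oa = o_ea.translate(_COMPLEMENT), o_oa.translate(_COMPLEMENT)

        if (o_ea, o_oa) == (ea, oa):
            flipped = False
        elif (o_ea, o_oa) == (oa, ea):
            flipped = True
        elif not palindromic and (comp_ea, comp_oa) == (ea, oa):
            logger.info("%s: outcome on opposite strand, complemented", vid)
            flipped = False
        elif not palindromic and (comp_ea, comp_oa) == (oa, ea):
            logger.info("%s: outcome on opposite strand, complemented and swapped", vid)
            flipped = True
        else:
            logger.warning("%s: alleles irreconcilable (%s/%s vs %s/%s), dropped",
                           vid, ea, oa, o_ea, o_oa)
            continue

        beta_out = -o.beta if flipped else o.beta
        eaf_out = 1.0 - o.eaf if flipped else o.eaf

        if palindromic:
            if palindrome_policy == "drop_all":
                logger.info("%s: palindromic, dropped (policy=drop_all)", vid)
                continue
            ambiguous = 0.5 - min(e.eaf, 1.0 - e.eaf) <= eaf_ambiguity_threshold
            if palindrome_policy == "drop_ambiguous":
                if ambiguous:
                    logger.info("%s: palindromic with eaf %.3f too close to 0.5, dropped",
                                vid, e.eaf)
                    continue
            else:  # keep_infer_by_eaf: flip if the frequencies disagree in side
                if ambiguous:
                    logger.warning("%s: palindromic with eaf %.3f near 0.5 kept by "
                                   "frequency inference; orientation uncertain", vid, e.eaf)
                if (e.eaf - 0.5) * (eaf_out - 0.5) < 0:
                    beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped

        instruments.append(HarmonizedInstrument(
            variant_id=vid,
            beta_exp=e.beta, se_exp=e.se,
            beta_out=beta_out, se_out=o.se,
            eaf_exp=e.eaf, eaf_out=eaf_out,
            palindromic=palindromic, flipped=flipped,
            effect_allele=ea, other_allele=oa,
        ))
    return instruments
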