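"""Reading, validating and writing GWAS summary statistics.

A summary-statistic record is one variant's association with one trait:
the per-allele effect size (beta), its standard error, the effect and
other alleles, the effect-allele frequency and the reported p-value.
Records are the raw material of two-sample Mendelian randomization:
variant-exposure associations supply the instrument strengths and
variant-outcome associations supply the effects to be scaled.

The module also houses packaged instrument tables for the coffee /
caffeine / kidney-function analyses (East Asian and European ancestry
GWAS). Positions are 1-based GRCh37. Source cohort sizes are reported
inconsistently at the source (47,070 vs 47,000 for the ToMMo eGFR GWAS;
564,470 vs 567,460 for CKDGen) and are carried as metadata only.

P-values are stored exactly as ingested and never recomputed here;
cross-checking a p-value against beta/se is a separate diagnostic
(:func:`mrkit.estimators.pvalue_consistency_check`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: accepted (lower-cased) header spellings for each canonical column
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "rs_id", "markername", "id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "ea", "allele1"),
    "other_allele": ("other_allele", "a2", "oa", "nea", "allele2", "non_effect_allele"),
    "eaf": ("eaf", "freq", "af", "effect_allele_frequency", "maf", "af(a1)"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "se": ("se", "stderr", "standard_error"),
    "pvalue": ("pvalue", "p", "pval", "p_value"),
    "n": ("n", "samplesize", "sample_size"),
    "trait": ("trait", "phenotype"),
    "unit": ("unit", "units"),
    "gene": ("gene", "nearest_gene"),
}

REQUIRED_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue",
)


class SumstatsError(ValueError):
    """Malformed summary statistics or configuration."""


@dataclass
class SummaryAssociation:
    """One variant's association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` in the declared
    ``unit``; ``eaf`` is the effect-allele frequency. Only biallelic SNVs
    are accepted: every allele must be a single A/C/G/T base.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float | None = None
    trait: str = ""
    unit: str = ""
    gene: str = ""
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumstatsError(
                f"{self.variant_id}: alleles must be single A/C/G/T bases "
                f"(got {self.effect_allele!r}/{self.other_allele!r})"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise SumstatsError(f"{self.variant_id}: se must be > 0 (got {self.se})")
        if not (0 < self.eaf < 1):
            raise SumstatsError(f"{self.variant_id}: eaf must be in (0,1) (got {self.eaf})")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.variant_id}: pvalue must be in (0,1] (got {self.pvalue})")
        if not math.isfinite(self.beta):
            raise SumstatsError(f"{self.variant_id}: beta must be finite")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pair: strand unresolvable from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical names -> actual file columns, honouring user overrides."""
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon, aliases in DEFAULT_COLUMN_ALIASES.items():
        if canon in column_map:
            if column_map[canon] not in header:
                raise SumstatsError(
                    f"column {column_map[canon]!r} (mapped to {canon!r}) not in header"
                )
            resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise SumstatsError(f"required column(s) not resolvable: {', '.join(missing)}")
    return resolved


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
    unit: str | None = None,
    strict: bool = False,
) -> list[SummaryAssociation]:
    """Read delimited summary statistics (TSV default; comma autodetected;
    gzip transparent).

    Rows violating record invariants are dropped with a logged count
    (``strict=True`` raises instead). Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True, comment="#")
    cols = _resolve_columns(list(df.columns), column_map)
    known = set(cols.values())
    records: list[SummaryAssociation] = []
    n_rejected = 0
    for i, row in df.iterrows():
        try:
            rec = SummaryAssociation(
                variant_id=str(row[cols["variant_id"]]).strip(),
                chrom=str(row[cols["chrom"]]).strip(),
                pos=int(float(row[cols["pos"]])),
                effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row[cols["other_allele"]]).strip().upper(),
                eaf=float(row[cols["eaf"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pvalue=float(row[cols["pvalue"]]),
                n=float(row[cols["n"]]) if "n" in cols and pd.notna(row[cols["n"]]) else None,
                trait=trait if trait is not None else (
                    str(row[cols["trait"]]) if "trait" in cols and pd.notna(row[cols["trait"]]) else ""),
                unit=unit if unit is not None else (
                    str(row[cols["unit"]]) if "unit" in cols and pd.notna(row[cols["unit"]]) else ""),
                gene=str(row[cols["gene"]]) if "gene" in cols and pd.notna(row[cols["gene"]]) else "",
                extra={c: row[c] for c in df.columns if c not in known},
            )
            rec.validate()
        except (SumstatsError, ValueError, TypeError) as exc:
            if strict:
                raise SumstatsError(f"row {i}: {exc}") from exc
            n_rejected += 1
            logger.warning("rejected row %d: %s", i, exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.info("read %d records from %s (%d rows rejected)",
                    len(records), path, n_rejected)
    return records


def write_sumstats(records: Iterable[SummaryAssociation], path: str | Path) -> None:
    """Write records as TSV; ``read_sumstats`` round-trips them field-for-field.

    Duplicated variant ids are written verbatim -- duplication is a
    harmonization-time error, not an I/O one.
    """
    rows = []
    for rec in records:
        d = asdict(rec)
        d.pop("extra")
        d["n"] = "" if d["n"] is None else repr(d["n"])
        for k in ("eaf", "beta", "se", "pvalue"):
            d[k] = repr(d[k])
        rows.append(d)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged instrument tables

_FIXTURE_FILES = {
    "ea_coffee_exposure_11": "ea_coffee_exposure_11.tsv",
    "ea_coffee_exposure_robust7": "ea_coffee_exposure_11.tsv",
    "eu_coffee_exposure_28": "eu_coffee_exposure_28.tsv",
    "eu_coffee_exposure_robust22": "eu_coffee_exposure_28.tsv",
    "ea_caffeine_pair": "ea_caffeine_pair.tsv",
    "eu_caffeine_pair": "eu_caffeine_pair.tsv",
}

FIXTURE_NAMES = tuple(_FIXTURE_FILES)


def load_fixture(name: str) -> list[SummaryAssociation]:
    """Load a packaged instrument table by name.

    ``*_robust*`` names return only the rows that survived the published
    heterogeneity-driven exclusion (the bold rows of the source tables,
    flagged ``robust`` in the packaged files).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    ref = resources.files("mrkit.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as p:
        records = read_sumstats(p, strict=True)
    if "robust" in name:
        records = [r for r in records if str(r.extra.get("robust", "1")).strip() == "1"]
    return records
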