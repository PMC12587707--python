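"""Rare-variant filtering and case-vs-control allele burden.

The filter keeps a germline variant when it is rare in the reference
population (control minor-allele frequency ≤ 0.1%) and predicted damaging:
loss-of-function classes (frameshift, stop-gain, canonical splice site,
start loss) unconditionally, missense only with REVEL > 0.644. Everything
else is dropped. Kept case alleles (heterozygous carriers, one allele each)
are then compared to the control allele frequency with a two-sided Fisher
exact test on the 2×2 allele table; the odds ratio uses the
Haldane–Anscombe 0.5 correction when any cell is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io import LOF_CLASSES, VariantRecord

logger = logging.getLogger(__name__)

REVEL_THRESHOLD = 0.644
MAF_THRESHOLD_PCT = 0.1


@dataclass
class BurdenResult:
    case_ac: int
    case_an: int
    control_ac: int
    control_an: int
    case_maf_pct: float
    control_maf_pct: float
    odds_ratio: float
    fisher_p: float


def filter_variants(
    records: list[VariantRecord],
    revel_threshold: float = REVEL_THRESHOLD,
    maf_threshold_pct: float = MAF_THRESHOLD_PCT,
) -> list[VariantRecord]:
    """Apply the rarity and damage filters; idempotent and order-preserving."""
    kept = []
    for rec in records:
        if rec.control_maf_pct > maf_threshold_pct:
            continue
        if rec.consequence_class in LOF_CLASSES:
            kept.append(rec)
        elif rec.consequence_class == "missense":
            if rec.revel is None:
                logger.warning(
                    "missense variant %s without REVEL score dropped", rec.identifier
                )
            elif rec.revel > revel_threshold:
                kept.append(rec)
        # class "other" is never considered
    return kept


def allele_frequency(
    alleles: int, n_individuals: int, ploidy: int = 2
) -> tuple[float, float]:
    """Allele frequency as a percentage: (rounded to 2 dp, full precision).

    ``alleles`` counts variant alleles directly; heterozygous carriers map to
    alleles one-to-one, so a carrier count can be passed unchanged.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    if alleles < 0:
        raise ValueError("allele count must be >= 0")
    full = 100.0 * alleles / (ploidy * n_individuals)
    return round(full, 2), full


def burden_compare(
    case_ac: int, case_an: int, control_ac: int, control_an: int
) -> BurdenResult:
    """Case vs control allele-frequency comparison on a 2×2 allele table."""
    if case_an <= 0 or control_an <= 0:
        raise ValueError("allele numbers must be > 0")
    if not 0 <= case_ac <= case_an or not 0 <= control_ac <= control_an:
        raise ValueError("allele counts must satisfy 0 <= AC <= AN")
    table = [
        [case_ac, case_an - case_ac],
        [control_ac, control_an - control_ac],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = float(case_ac), float(case_an - case_ac)
    c, d = float(control_ac), float(control_an - control_ac)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a / b) / (c / d)
    return BurdenResult(
        case_ac=case_ac,
        case_an=case_an,
        control_ac=control_ac,
        control_an=control_an,
        case_maf_pct=100.0 * case_ac / case_an,
        control_maf_pct=100.0 * control_ac / control_an,
        odds_ratio=odds_ratio,
        fisher_p=float(p),
    )


def burden_from_records(
    records: list[VariantRecord], case_n_individuals: int, ploidy: int = 2
) -> tuple[list[VariantRecord], BurdenResult]:
    """Filter a variant table and compare pooled case vs control alleles.

    Case alleles are summed carrier counts (heterozygous assumption) over the
    kept variants; control alleles are summed control ACs over the same
    variants against the maximum control AN (one shared reference cohort).
    """
    kept = filter_variants(records)
    case_ac = sum(r.case_carriers for r in kept)
    case_an = ploidy * case_n_individuals
    control_ac = sum(r.control_ac for r in kept)
    control_an = max((r.control_an for r in kept), default=0)
    if control_an == 0:
        raise ValueError("no variants kept; burden comparison undefined")
    return kept, burden_compare(case_ac, case_an, control_ac, control_an)
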