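"""Cohort-level distributions and diagnostic-yield summaries.

Percentages are rounded half-up to one decimal, which reproduces every
recomputable printed cohort statistic (e.g. 74/129 -> 57.4, 22/32 ->
68.8).  Mode-of-inheritance categories per diagnosed case follow the
cohort-reporting partition: a case is counted as X-linked when its
diagnostic variant lies in a gene on chromosome X, as "both AD and AR"
when the gene has dominant and recessive disease forms, otherwise as AD
(heterozygous, dominant gene) or AR (biallelic, recessive gene); for
multi-variant cases the AD > AR > XL > both precedence applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .panel import GeneEntry, InheritanceMode, Panel, SuspicionCategory
from .variant_io import AgeGroup, VARIANT_CLASSES
from .inheritance import BIALLELIC, BiallelicStatus, Zygosity
from .classify import ClassTier
from .report import CaseReport, OUTCOME_DIAGNOSED, ReportedVariant


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (22/32 -> 68.8)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    value = Decimal(numerator) * Decimal(100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class CountPct(NamedTuple):
    count: int
    pct: float


MOI_AD = "AD"
MOI_AR = "AR"
MOI_XL = "XL"
MOI_BOTH = "AD_AR"
_MOI_PRECEDENCE = (MOI_AD, MOI_AR, MOI_XL, MOI_BOTH)

REPORTED_CLASSES = ("missense", "nonsense", "frameshift", "indel", "splice", "CNV")
REPORTED_TIERS = ("C5", "C4", "C3")


def _variant_moi_bucket(rv: ReportedVariant, gene: GeneEntry) -> str | None:
    """Cohort MoI bucket of one diagnostic variant, or None if undecidable."""
    if gene.on_x:
        return MOI_XL
    declared = gene.compatible_modes
    if {InheritanceMode.AD, InheritanceMode.AR} <= declared:
        return MOI_BOTH
    if (
        InheritanceMode.AR in declared
        and rv.cv.biallelic_status in BIALLELIC
    ):
        return MOI_AR
    if InheritanceMode.AD in declared:
        return MOI_AD
    return None


def case_moi_category(report: CaseReport, panel: Panel) -> str | None:
    """MoI category of a diagnosed case from its diagnostic variants."""
    buckets = set()
    for rv in report.reported:
        if not rv.diagnostic:
            continue
        gene = panel.entries.get(rv.cv.gene)
        if gene is None:
            continue
        b = _variant_moi_bucket(rv, gene)
        if b is not None:
            buckets.add(b)
    for b in _MOI_PRECEDENCE:
        if b in buckets:
            return b
    return None


@dataclass
class CohortSummary:
    """All cohort-level distributions, counts alongside percentages."""

    n_eligible: int
    n_diagnosed: int
    yield_pct: float
    yield_by_age_group: dict[str, CountPct]
    moi_distribution: dict[str, CountPct]
    class_distribution: dict[str, CountPct]
    tier_distribution: dict[str, CountPct]
    per_suspicion: dict[str, tuple[int, int, float]]  # (n, n_diagnosed, pct)
    n_variants: int
    n_genes: int
    n_multi_variant_patients: int
    n_recurrent_variants: int

    def to_dict(self) -> dict:
        return {
            "n_eligible": self.n_eligible,
            "n_diagnosed": self.n_diagnosed,
            "yield_pct": self.yield_pct,
            "yield_by_age_group": {
                k: {"count": v.count, "pct": v.pct}
                for k, v in self.yield_by_age_group.items()
            },
            "moi_distribution": {
                k: {"count": v.count, "pct": v.pct}
                for k, v in self.moi_distribution.items()
            },
            "class_distribution": {
                k: {"count": v.count, "pct": v.pct}
                for k, v in self.class_distribution.items()
            },
            "tier_distribution": {
                k: {"count": v.count, "pct": v.pct}
                for k, v in self.tier_distribution.items()
            },
            "per_suspicion": {
                k: {"n": n, "n_diagnosed": d, "pct": p}
                for k, (n, d, p) in self.per_suspicion.items()
            },
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "n_multi_variant_patients": self.n_multi_variant_patients,
            "n_recurrent_variants": self.n_recurrent_variants,
        }


def reported_variant_index(
    reports: Sequence[CaseReport],
) -> list[tuple[str, str]]:
    """(case_id, variant key) for every reported variant occurrence."""
    return [
        (r.case_id, rv.cv.key) for r in reports for rv in r.reported
    ]


def recurrent_variants(
    occurrences: Iterable[tuple[str, str]],
) -> list[tuple[str, int]]:
    """Variant keys reported in >= 2 distinct patients.

    Sorted by patient count descending, then key ascending.
    """
    carriers: dict[str, set[str]] = {}
    for case_id, key in occurrences:
        carriers.setdefault(key, set()).add(case_id)
    hits = [(k, len(c)) for k, c in carriers.items() if len(c) >= 2]
    return sorted(hits, key=lambda kv: (-kv[1], kv[0]))


def summarize_cohort(
    reports: Sequence[CaseReport], panel: Panel
) -> CohortSummary:
    """Aggregate per-case reports into the cohort summary.

    Permutation-invariant in the report order; raises on an empty cohort.
    """
    if not reports:
        raise ValueError("summarize_cohort() requires a non-empty cohort")
    n_eligible = len(reports)
    diagnosed = [r for r in reports if r.outcome == OUTCOME_DIAGNOSED]
    n_diagnosed = len(diagnosed)

    yield_by_age: dict[str, CountPct] = {}
    for ag in AgeGroup:
        group = [r for r in reports if r.age_group == ag]
        if not group:
            continue
        d = sum(1 for r in group if r.outcome == OUTCOME_DIAGNOSED)
        yield_by_age[ag.value] = CountPct(d, pct(d, len(group)))

    moi_counts = {b: 0 for b in _MOI_PRECEDENCE}
    for r in diagnosed:
        bucket = case_moi_category(r, panel)
        if bucket is not None:
            moi_counts[bucket] += 1
    moi_distribution = {
        b: CountPct(c, pct(c, n_diagnosed)) for b, c in moi_counts.items()
    } if n_diagnosed else {b: CountPct(0, 0.0) for b in _MOI_PRECEDENCE}

    all_reported = [rv for r in reports for rv in r.reported]
    n_variants = len(all_reported)
    class_counts = {c: 0 for c in REPORTED_CLASSES}
    tier_counts = {t: 0 for t in REPORTED_TIERS}
    genes: set[str] = set()
    for rv in all_reported:
        vclass = rv.cv.variant.variant_class
        if vclass in class_counts:
            class_counts[vclass] += 1
        if rv.cv.tier.name in tier_counts:
            tier_counts[rv.cv.tier.name] += 1
        genes.add(rv.cv.gene)
    class_distribution = {
        c: CountPct(n, pct(n, n_variants) if n_variants else 0.0)
        for c, n in class_counts.items()
    }
    tier_distribution = {
        t: CountPct(n, pct(n, n_variants) if n_variants else 0.0)
        for t, n in tier_counts.items()
    }

    per_suspicion: dict[str, tuple[int, int, float]] = {}
    for cat in SuspicionCategory:
        group = [r for r in reports if r.suspicion == cat]
        if not group:
            continue  # categories with no cases are omitted
        d = sum(1 for r in group if r.outcome == OUTCOME_DIAGNOSED)
        per_suspicion[cat.value] = (len(group), d, pct(d, len(group)))

    multi = sum(1 for r in reports if len(r.reported) >= 2)
    recurrent = recurrent_variants(reported_variant_index(list(reports)))

    return CohortSummary(
        n_eligible=n_eligible,
        n_diagnosed=n_diagnosed,
        yield_pct=pct(n_diagnosed, n_eligible),
        yield_by_age_group=yield_by_age,
        moi_distribution=moi_distribution,
        class_distribution=class_distribution,
        tier_distribution=tier_distribution,
        per_suspicion=per_suspicion,
        n_variants=n_variants,
        n_genes=len(genes),
        n_multi_variant_patients=multi,
        n_recurrent_variants=len(recurrent),
    )


def detection_rate_by_suspicion(
    reports: Sequence[CaseReport],
) -> pd.DataFrame:
    """Per-suspicion case counts and detection rates as a table."""
    rows = []
    for cat in SuspicionCategory:
        group = [r for r in reports if r.suspicion == cat]
        if not group:
            continue
        d = sum(1 for r in group if r.outcome == OUTCOME_DIAGNOSED)
        rows.append(
            {
                "suspicion": cat.value,
                "n_cases": len(group),
                "n_diagnosed": d,
                "detection_pct": pct(d, len(group)),
            }
        )
    return pd.DataFrame(rows, columns=["suspicion", "n_cases", "n_diagnosed", "detection_pct"])
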