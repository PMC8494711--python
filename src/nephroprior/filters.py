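"""The sequential inclusion/exclusion cascade and the two-pass strategy.

Four per-variant predicates, applied in fixed order for a reproducible
audit trail:

1. reportable class — synonymous (and unclassifiable) variants are
   filtered out; missense, nonsense, frameshift, in-frame indel, splice
   and CNV calls proceed;
2. call quality — proband coverage >= 20x and alt read fraction >= 0.3
   (inclusive bounds);
3. rarity — overall population frequency <= 1% in every population
   database that reports the variant; a variant absent from all
   databases counts as rare;
4. panel membership — the gene is in the active gene set.

Variants are first run against the suspicion-tailored gene list; if that
pass yields a pathogenic (C5) or likely pathogenic (C4) variant the
analysis stops, otherwise the full panel is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

from .panel import (
    BROAD_CATEGORIES,
    GeneEntry,
    Panel,
    genes_for_suspicion,
)
from .variant_io import AnnotatedVariant, Case, GenotypeCall, Pedigree
from .classify import AcmgConfig, ClassTier, ClassifiedVariant, classify_case_variants


class FilterReason(str, Enum):
    SYNONYMOUS_OR_NONREPORTABLE_CLASS = "SYNONYMOUS_OR_NONREPORTABLE_CLASS"
    LOW_COVERAGE = "LOW_COVERAGE"
    LOW_ALT_FRACTION = "LOW_ALT_FRACTION"
    COMMON_POLYMORPHISM = "COMMON_POLYMORPHISM"
    OFF_PANEL = "OFF_PANEL"


DEFAULT_REPORTABLE_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "indel", "splice", "CNV"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Cascade thresholds; defaults follow the published pipeline."""

    min_depth: int = 20
    min_alt_fraction: float = 0.3
    max_pop_freq: float = 0.01
    reportable_classes: frozenset[str] = DEFAULT_REPORTABLE_CLASSES


@dataclass(frozen=True)
class FilterOutcome:
    """Audit record for one variant in one pass."""

    key: str
    passed: bool
    reasons: tuple[FilterReason, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold iff reasons is empty")


def passes_quality(
    genotype: GenotypeCall | None,
    min_depth: int = 20,
    min_alt_fraction: float = 0.3,
) -> tuple[bool, list[FilterReason]]:
    """Coverage and alt-read-fraction check on the proband call.

    Bounds are inclusive; missing depth or fraction fails with the
    corresponding reason.
    """
    reasons: list[FilterReason] = []
    if genotype is None or genotype.depth is None or genotype.depth < min_depth:
        reasons.append(FilterReason.LOW_COVERAGE)
    fraction = genotype.alt_fraction if genotype is not None else None
    if fraction is None or fraction < min_alt_fraction:
        reasons.append(FilterReason.LOW_ALT_FRACTION)
    return not reasons, reasons


def is_rare(variant: AnnotatedVariant, max_pop_freq: float = 0.01) -> bool:
    """True iff every reported population frequency is <= the bound.

    Absence from all databases counts as rare: novel pathogenic variants
    are by definition unreported.
    """
    for db, f in variant.pop_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{variant.key}: {db} frequency {f} outside [0,1]")
    if not variant.pop_freqs:
        return True
    return max(variant.pop_freqs.values()) <= max_pop_freq


def is_reportable_class(
    variant: AnnotatedVariant,
    reportable_classes: frozenset[str] = DEFAULT_REPORTABLE_CLASSES,
) -> bool:
    """Synonymous and unclassifiable calls are filtered out."""
    return variant.variant_class in reportable_classes


def filter_cascade(
    variants: Sequence[AnnotatedVariant],
    proband_id: str,
    gene_set: Iterable[str],
    config: FilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], list[FilterOutcome]]:
    """Apply the four predicates; return survivors and the full audit.

    Every input variant appears exactly once in the audit; the survivor
    set equals the intersection of the four per-predicate survivor sets
    and is independent of input order.
    """
    genes = frozenset(gene_set)
    if not genes:
        raise ValueError("filter_cascade() requires a non-empty gene set")
    cfg = config or FilterConfig()
    survivors: list[AnnotatedVariant] = []
    audit: list[FilterOutcome] = []
    for v in variants:
        reasons: list[FilterReason] = []
        if not is_reportable_class(v, cfg.reportable_classes):
            reasons.append(FilterReason.SYNONYMOUS_OR_NONREPORTABLE_CLASS)
        ok, quality_reasons = passes_quality(
            v.genotype(proband_id), cfg.min_depth, cfg.min_alt_fraction
        )
        reasons.extend(quality_reasons)
        if not is_rare(v, cfg.max_pop_freq):
            reasons.append(FilterReason.COMMON_POLYMORPHISM)
        if v.gene not in genes:
            reasons.append(FilterReason.OFF_PANEL)
        outcome = FilterOutcome(
            key=v.key, passed=not reasons, reasons=tuple(reasons)
        )
        audit.append(outcome)
        if outcome.passed:
            survivors.append(v)
    return survivors, audit


PASS_TAILORED = "TAILORED"
PASS_FULL = "FULL"


@dataclass(frozen=True)
class AuditRecord:
    pass_name: str
    outcome: FilterOutcome


@dataclass
class PrioritizationResult:
    """Outcome of the two-pass prioritization for one case."""

    case_id: str
    pass_used: str
    survivors: list[ClassifiedVariant]
    audit: list[AuditRecord]
    tailored_gene_count: int = 0
    full_gene_count: int = 0

    @property
    def stopped_at_tailored(self) -> bool:
        return self.pass_used == PASS_TAILORED


def two_pass_prioritize(
    case: Case,
    panel: Panel,
    variants: Sequence[AnnotatedVariant],
    pedigree: Pedigree | None = None,
    config: FilterConfig | None = None,
    acmg_config: AcmgConfig | None = None,
    force_full_pass: bool = False,
) -> PrioritizationResult:
    """Suspicion-tailored pass with a stop rule, then full-panel fallback.

    The tailored pass classifies only variants in genes tagged with the
    case's clinical suspicion.  If it yields a C4/C5 variant the analysis
    stops there; otherwise all panel genes are tested.  Unknown-origin
    and "other" suspicions have no tailored list and run a single
    full-panel pass.
    """
    cfg = config or FilterConfig()
    tailored = genes_for_suspicion(panel, case.suspicion)
    tailored_symbols = frozenset(e.symbol for e in tailored)
    full_symbols = panel.symbols
    audit: list[AuditRecord] = []

    degenerate = (
        case.suspicion in BROAD_CATEGORIES
        or not tailored_symbols
        or tailored_symbols == full_symbols
    )
    if not degenerate and not force_full_pass:
        t_survivors, t_audit = filter_cascade(
            variants, case.proband, tailored_symbols, cfg
        )
        audit.extend(AuditRecord(PASS_TAILORED, o) for o in t_audit)
        t_classified = classify_case_variants(
            t_survivors, panel, case, pedigree, acmg_config, cfg.min_depth
        )
        if any(cv.tier >= ClassTier.C4 for cv in t_classified):
            return PrioritizationResult(
                case_id=case.case_id,
                pass_used=PASS_TAILORED,
                survivors=t_classified,
                audit=audit,
                tailored_gene_count=len(tailored_symbols),
                full_gene_count=len(full_symbols),
            )
    elif not degenerate and force_full_pass:
        t_survivors, t_audit = filter_cascade(
            variants, case.proband, tailored_symbols, cfg
        )
        audit.extend(AuditRecord(PASS_TAILORED, o) for o in t_audit)

    f_survivors, f_audit = filter_cascade(
        variants, case.proband, full_symbols, cfg
    )
    audit.extend(AuditRecord(PASS_FULL, o) for o in f_audit)
    f_classified = classify_case_variants(
        f_survivors, panel, case, pedigree, acmg_config, cfg.min_depth
    )
    return PrioritizationResult(
        case_id=case.case_id,
        pass_used=PASS_FULL,
        survivors=f_classified,
        audit=audit,
        tailored_gene_count=len(tailored_symbols),
        full_gene_count=len(full_symbols),
    )
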