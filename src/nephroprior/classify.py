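"""Reduced ACMG-style evidence gathering and C1-C5 tier assignment.

The classifier operationalises a 9-criterion subset of the ACMG/AMP
sequence-variant framework that is computable from variant annotations
alone:

===========  =============  ====================================================
criterion    strength       trigger (defaults; all thresholds configurable)
===========  =============  ====================================================
PVS1         very strong    null variant (nonsense, frameshift, canonical
                            splice site, CNV loss) in a gene where loss of
                            function is a known disease mechanism
PS1          strong         same change asserted pathogenic in a clinical DB
PS2          strong         confirmed de novo in the trio
PM2          moderate       absent from population DBs or below 0.01%
PM3          moderate       biallelic in a recessive gene, in trans with a
                            known-pathogenic allele
PP3          supporting     in-silico deleterious votes exceed tolerated by >= 2
BP4          supporting(b)  tolerated votes exceed deleterious by >= 2
BS1          strong(b)      population frequency above the rare-disease bound
BA1          stand-alone    population frequency >= 5%
===========  =============  ====================================================

Combining follows the published ACMG table, with one documented
extension: a very-strong criterion alone classifies as likely pathogenic
rather than remaining a VUS.  Benign and pathogenic evidence together is
conflicting and yields a VUS (C3), except that nothing outranks BA1 when
it is the only evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from functools import total_ordering
from typing import Iterable, Mapping, Sequence

from .panel import GeneEntry, InheritanceMode, Panel
from .variant_io import (
    AnnotatedVariant,
    CANONICAL_SPLICE_TERMS,
    Case,
    Pedigree,
)
from .inheritance import (
    BIALLELIC,
    BiallelicStatus,
    SegregationResult,
    Zygosity,
    ZygosityCall,
    assign_zygosity,
    detect_compound_het,
    trio_segregations,
)


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    SUPPORTING_BENIGN = "supporting_benign"
    STRONG_BENIGN = "strong_benign"
    STAND_ALONE_BENIGN = "stand_alone_benign"


class EvidenceCriterion(str, Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PM2 = "PM2"
    PM3 = "PM3"
    PP3 = "PP3"
    BP4 = "BP4"
    BS1 = "BS1"
    BA1 = "BA1"

    @property
    def strength(self) -> Strength:
        return _STRENGTH[self]

    @property
    def benign_side(self) -> bool:
        return self in (
            EvidenceCriterion.BP4,
            EvidenceCriterion.BS1,
            EvidenceCriterion.BA1,
        )


_STRENGTH = {
    EvidenceCriterion.PVS1: Strength.VERY_STRONG,
    EvidenceCriterion.PS1: Strength.STRONG,
    EvidenceCriterion.PS2: Strength.STRONG,
    EvidenceCriterion.PM2: Strength.MODERATE,
    EvidenceCriterion.PM3: Strength.MODERATE,
    EvidenceCriterion.PP3: Strength.SUPPORTING,
    EvidenceCriterion.BP4: Strength.SUPPORTING_BENIGN,
    EvidenceCriterion.BS1: Strength.STRONG_BENIGN,
    EvidenceCriterion.BA1: Strength.STAND_ALONE_BENIGN,
}


@total_ordering
class ClassTier(Enum):
    """Five-tier classification: C1 benign ... C5 pathogenic."""

    C1 = 1
    C2 = 2
    C3 = 3
    C4 = 4
    C5 = 5

    def __lt__(self, other: "ClassTier") -> bool:
        return self.value < other.value

    @property
    def label(self) -> str:
        return {
            ClassTier.C1: "benign",
            ClassTier.C2: "likely benign",
            ClassTier.C3: "VUS",
            ClassTier.C4: "likely pathogenic",
            ClassTier.C5: "pathogenic",
        }[self]


@dataclass(frozen=True)
class AcmgConfig:
    """Thresholds behind the reduced criteria."""

    pm2_max_freq: float = 1e-4
    insilico_margin: int = 2
    ba1_min_freq: float = 0.05
    bs1_min_freq: float = 0.01


def gather_evidence(
    variant: AnnotatedVariant,
    gene: GeneEntry,
    zygosity: Zygosity,
    segregation: SegregationResult,
    biallelic_status: BiallelicStatus | None = None,
    partner_known_pathogenic: bool = False,
    config: AcmgConfig | None = None,
) -> frozenset[EvidenceCriterion]:
    """Evaluate the nine reduced criteria for one filtered variant."""
    cfg = config or AcmgConfig()
    ev: set[EvidenceCriterion] = set()
    vclass = variant.variant_class
    is_null = (
        vclass in ("nonsense", "frameshift")
        or variant.consequence in CANONICAL_SPLICE_TERMS
        or (variant.is_cnv and variant.cnv_type == "loss")
    )
    if is_null and gene.lof_mechanism:
        ev.add(EvidenceCriterion.PVS1)
    if variant.known_pathogenic_same_change:
        ev.add(EvidenceCriterion.PS1)
    if segregation == SegregationResult.DE_NOVO:
        ev.add(EvidenceCriterion.PS2)
    freqs = list(variant.pop_freqs.values())
    if not freqs or max(freqs) < cfg.pm2_max_freq:
        ev.add(EvidenceCriterion.PM2)
    if (
        biallelic_status in BIALLELIC
        and InheritanceMode.AR in gene.compatible_modes
        and partner_known_pathogenic
    ):
        ev.add(EvidenceCriterion.PM3)
    votes = list(variant.insilico.values())
    deleterious = votes.count("deleterious")
    tolerated = votes.count("tolerated")
    if deleterious - tolerated >= cfg.insilico_margin:
        ev.add(EvidenceCriterion.PP3)
    if tolerated - deleterious >= cfg.insilico_margin:
        ev.add(EvidenceCriterion.BP4)
    if freqs and max(freqs) >= cfg.ba1_min_freq:
        ev.add(EvidenceCriterion.BA1)
    elif freqs and max(freqs) > cfg.bs1_min_freq:
        ev.add(EvidenceCriterion.BS1)
    return frozenset(ev)


def combine(evidence: Iterable[EvidenceCriterion]) -> ClassTier:
    """Combine evidence criteria into a tier per the ACMG rule table.

    Pathogenic and benign evidence are scored separately; if both sides
    reach a non-VUS conclusion the call is conflicting and drops to C3.
    """
    ev = frozenset(evidence)
    counts = {s: 0 for s in Strength}
    for c in ev:
        counts[c.strength] += 1
    vs = counts[Strength.VERY_STRONG]
    s = counts[Strength.STRONG]
    m = counts[Strength.MODERATE]
    p = counts[Strength.SUPPORTING]
    ba = counts[Strength.STAND_ALONE_BENIGN]
    sb = counts[Strength.STRONG_BENIGN]
    pb = counts[Strength.SUPPORTING_BENIGN]

    path_tier = ClassTier.C3
    if (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or vs >= 2
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    ):
        path_tier = ClassTier.C5
    elif (
        (vs >= 1 and m <= 1)  # includes the VS-alone extension
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    ):
        path_tier = ClassTier.C4

    benign_tier = ClassTier.C3
    if ba >= 1 or sb >= 2:
        benign_tier = ClassTier.C1
    elif (sb == 1 and pb >= 1) or pb >= 2:
        benign_tier = ClassTier.C2

    if path_tier != ClassTier.C3 and benign_tier != ClassTier.C3:
        return ClassTier.C3  # conflicting evidence
    if benign_tier != ClassTier.C3:
        return benign_tier
    return path_tier


def _rationale(evidence: frozenset[EvidenceCriterion], tier: ClassTier) -> str:
    codes = "+".join(sorted(c.value for c in evidence)) or "no criteria met"
    return f"{codes} -> {tier.name} ({tier.label})"


@dataclass(frozen=True)
class ClassifiedVariant:
    """A filtered variant with its evidence, tier and inheritance context."""

    variant: AnnotatedVariant
    zygosity: Zygosity
    evidence: frozenset[EvidenceCriterion]
    tier: ClassTier
    segregation: SegregationResult
    rationale: str
    biallelic_status: BiallelicStatus = BiallelicStatus.MONOALLELIC
    zygosity_warning: str | None = None

    def __post_init__(self) -> None:
        expected = combine(self.evidence)
        if expected != self.tier:
            raise ValueError(
                f"{self.variant.key}: tier {self.tier.name} inconsistent with "
                f"evidence (expected {expected.name})"
            )

    @property
    def gene(self) -> str:
        return self.variant.gene

    @property
    def key(self) -> str:
        return self.variant.key


def make_classified(
    variant: AnnotatedVariant,
    zygosity: Zygosity,
    evidence: Iterable[EvidenceCriterion],
    segregation: SegregationResult = SegregationResult.UNKNOWN,
    biallelic_status: BiallelicStatus = BiallelicStatus.MONOALLELIC,
    zygosity_warning: str | None = None,
) -> ClassifiedVariant:
    ev = frozenset(evidence)
    tier = combine(ev)
    return ClassifiedVariant(
        variant=variant,
        zygosity=zygosity,
        evidence=ev,
        tier=tier,
        segregation=segregation,
        rationale=_rationale(ev, tier),
        biallelic_status=biallelic_status,
        zygosity_warning=zygosity_warning,
    )


def classify_case_variants(
    survivors: Sequence[AnnotatedVariant],
    panel: Panel,
    case: Case,
    pedigree: Pedigree | None = None,
    config: AcmgConfig | None = None,
    min_parent_depth: int = 20,
) -> list[ClassifiedVariant]:
    """Classify all filter survivors of one case.

    Variants are grouped per gene so that compound-heterozygote state and
    trans-pathogenic partners (PM3) are evaluated within the gene, then
    each variant is classified independently.
    """
    cfg = config or AcmgConfig()
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in survivors:
        by_gene.setdefault(v.gene, []).append(v)

    out: list[ClassifiedVariant] = []
    for gene_symbol in sorted(by_gene):
        gene = panel.entries.get(gene_symbol)
        if gene is None:
            continue  # cascade guarantees on-panel genes; defensive
        group = sorted(by_gene[gene_symbol], key=lambda v: (v.chrom, v.pos))
        zyg_calls: list[ZygosityCall] = []
        for v in group:
            zyg_calls.append(
                assign_zygosity(v.genotype(case.proband), v.chrom, case.sex)
            )
        segs = trio_segregations(group, case.proband, pedigree, min_parent_depth)
        status = detect_compound_het([z.zygosity for z in zyg_calls], segs)
        for i, v in enumerate(group):
            if zyg_calls[i].zygosity in (Zygosity.HOM, Zygosity.HEMI):
                partner_known = v.known_pathogenic_same_change
            else:
                partner_known = any(
                    w.known_pathogenic_same_change
                    for j, w in enumerate(group)
                    if j != i
                )
            ev = gather_evidence(
                v,
                gene,
                zyg_calls[i].zygosity,
                segs[i],
                biallelic_status=status,
                partner_known_pathogenic=partner_known,
                config=cfg,
            )
            out.append(
                make_classified(
                    v,
                    zyg_calls[i].zygosity,
                    ev,
                    segregation=segs[i],
                    biallelic_status=status,
                    zygosity_warning=zyg_calls[i].warning,
                )
            )
    return out


def reclassify_with_segregation(
    classified: ClassifiedVariant,
    segregation: SegregationResult,
    gene: GeneEntry,
    partner_known_pathogenic: bool = False,
    config: AcmgConfig | None = None,
) -> ClassifiedVariant:
    """Re-run evidence gathering once trio segregation becomes available.

    UNKNOWN segregation is a no-op.  Because the combining table is
    monotone in pathogenic-side evidence, a tier never decreases from
    newly added de-novo/trans support.
    """
    if segregation == SegregationResult.UNKNOWN:
        return classified
    ev = gather_evidence(
        classified.variant,
        gene,
        classified.zygosity,
        segregation,
        biallelic_status=classified.biallelic_status,
        partner_known_pathogenic=partner_known_pathogenic
        or EvidenceCriterion.PM3 in classified.evidence,
        config=config,
    )
    # retain evidence that came from context not recomputable here
    ev = frozenset(ev | {c for c in classified.evidence if not c.benign_side})
    tier = combine(ev)
    if tier < classified.tier:
        tier = classified.tier
        ev = classified.evidence
    return replace(
        classified,
        evidence=ev,
        tier=tier,
        segregation=segregation,
        rationale=_rationale(ev, tier),
    )
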