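"""Zygosity, mode-of-inheritance compatibility and trio segregation.

Implements the inheritance step of the prioritization cascade: assigning
het/hom/hemizygous state, checking candidate genotypes against a gene's
declared inheritance modes, resolving compound heterozygotes in cis/trans
from trio phase, re-checking monoallelic recessive hits against digenic
partner genes, and classifying trio segregation (de novo, maternal,
paternal, biparental, Mendelian-inconsistent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .panel import GeneEntry, InheritanceMode, Panel
from .variant_io import AnnotatedVariant, GenotypeCall, Pedigree, Sex


class Zygosity(str, Enum):
    HET = "HET"
    HOM = "HOM"
    HEMI = "HEMI"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ZygosityCall:
    """Zygosity plus an optional data-quality warning."""

    zygosity: Zygosity
    warning: str | None = None


def assign_zygosity(
    genotype: GenotypeCall, chrom: str, sex: Sex
) -> ZygosityCall:
    """Assign zygosity given the chromosome and proband sex.

    Autosomes follow diploid rules.  Any alt call on X or Y in a male is
    hemizygous; an apparently heterozygous X call in a male is coerced to
    HEMI with a warning (common genotyping artifact).  Pseudoautosomal
    regions are not modelled.
    """
    if genotype is None or genotype.is_missing:
        return ZygosityCall(Zygosity.UNKNOWN, "missing genotype")
    alt_count = genotype.alt_allele_count
    called = genotype.called_allele_count
    if alt_count == 0:
        return ZygosityCall(Zygosity.UNKNOWN, "no alt allele called")
    sex_chrom = chrom in {"X", "Y"}
    if sex_chrom and sex == Sex.MALE:
        warning = None
        if called == 2 and alt_count == 1:
            warning = "heterozygous X call in male coerced to hemizygous"
        return ZygosityCall(Zygosity.HEMI, warning)
    if called == 1:
        # haploid call outside male X/Y: treat single alt as HOM-equivalent
        return ZygosityCall(Zygosity.HOM, "haploid call treated as homozygous")
    return ZygosityCall(Zygosity.HET if alt_count == 1 else Zygosity.HOM)


class BiallelicStatus(str, Enum):
    HOM = "HOM"
    COMPOUND_HET_CONFIRMED = "COMPOUND_HET_CONFIRMED"
    COMPOUND_HET_PUTATIVE = "COMPOUND_HET_PUTATIVE"
    MONOALLELIC = "MONOALLELIC"


BIALLELIC = frozenset(
    {
        BiallelicStatus.HOM,
        BiallelicStatus.COMPOUND_HET_CONFIRMED,
        BiallelicStatus.COMPOUND_HET_PUTATIVE,
    }
)


class SegregationResult(str, Enum):
    DE_NOVO = "DE_NOVO"
    INHERITED_MATERNAL = "INHERITED_MATERNAL"
    INHERITED_PATERNAL = "INHERITED_PATERNAL"
    BIPARENTAL = "BIPARENTAL"
    INCONSISTENT = "INCONSISTENT"
    UNKNOWN = "UNKNOWN"


def segregate(
    proband: GenotypeCall,
    mother: GenotypeCall | None,
    father: GenotypeCall | None,
    min_parent_depth: int = 20,
) -> SegregationResult:
    """Classify trio segregation of a variant carried by the proband.

    De novo calls require both parents homozygous reference at adequate
    depth (mirror of the proband coverage rule).  A homozygous proband
    with a confidently non-carrier parent is Mendelian-inconsistent.
    Anything with insufficient parental data is UNKNOWN.
    """
    if proband is None or not proband.carries_alt:
        raise ValueError("segregate() requires a proband carrying the variant")

    def genotyped(gt: GenotypeCall | None) -> bool:
        return gt is not None and not gt.is_missing

    def at_depth(gt: GenotypeCall) -> bool:
        return gt.depth is not None and gt.depth >= min_parent_depth

    proband_hom = (
        proband.alt_allele_count >= 2
        or (proband.called_allele_count == 1 and proband.alt_allele_count == 1)
    )
    # Mendelian inconsistency: both proband alleles are alt, yet a genotyped
    # parent confidently carries no alt allele.
    if proband.alt_allele_count >= 2:
        for parent in (mother, father):
            if genotyped(parent) and parent.is_hom_ref and at_depth(parent):
                return SegregationResult.INCONSISTENT
    if not (genotyped(mother) and genotyped(father)):
        return SegregationResult.UNKNOWN
    m_carries, f_carries = mother.carries_alt, father.carries_alt
    if m_carries and f_carries:
        return SegregationResult.BIPARENTAL
    if m_carries:
        return SegregationResult.INHERITED_MATERNAL
    if f_carries:
        return SegregationResult.INHERITED_PATERNAL
    # neither parent carries
    if at_depth(mother) and at_depth(father):
        return SegregationResult.DE_NOVO
    return SegregationResult.UNKNOWN


def detect_compound_het(
    zygosities: Sequence[Zygosity],
    segregations: Sequence[SegregationResult] | None = None,
) -> BiallelicStatus:
    """Biallelic status for the surviving variants of one gene.

    A homozygous (or hemizygous) call dominates.  With trio phase, two
    heterozygous variants inherited from different parents are a confirmed
    compound heterozygote; variants all inherited from the same parent are
    in cis and collapse to monoallelic.  Without phase, >= 2 heterozygous
    variants are a putative compound heterozygote.
    """
    if not zygosities:
        raise ValueError("detect_compound_het() requires at least one variant")
    if any(z in (Zygosity.HOM, Zygosity.HEMI) for z in zygosities):
        return BiallelicStatus.HOM
    het_idx = [i for i, z in enumerate(zygosities) if z == Zygosity.HET]
    if len(het_idx) < 2:
        return BiallelicStatus.MONOALLELIC
    if segregations is not None:
        origins = [
            segregations[i]
            for i in het_idx
            if i < len(segregations)
            and segregations[i]
            in (
                SegregationResult.INHERITED_MATERNAL,
                SegregationResult.INHERITED_PATERNAL,
            )
        ]
        has_m = SegregationResult.INHERITED_MATERNAL in origins
        has_p = SegregationResult.INHERITED_PATERNAL in origins
        if has_m and has_p:
            return BiallelicStatus.COMPOUND_HET_CONFIRMED
        if len(origins) == len(het_idx) and (has_m != has_p):
            # full phase, all alleles from the same parent: cis
            return BiallelicStatus.MONOALLELIC
    return BiallelicStatus.COMPOUND_HET_PUTATIVE


@dataclass(frozen=True)
class CandidateSet:
    """All surviving variants of one gene in one proband."""

    gene: str
    zygosities: tuple[Zygosity, ...]
    biallelic_status: BiallelicStatus
    variants: tuple[AnnotatedVariant, ...] = ()


def build_candidate_set(
    gene: str,
    zygosities: Sequence[Zygosity],
    segregations: Sequence[SegregationResult] | None = None,
    variants: Sequence[AnnotatedVariant] = (),
) -> CandidateSet:
    return CandidateSet(
        gene=gene,
        zygosities=tuple(zygosities),
        biallelic_status=detect_compound_het(zygosities, segregations),
        variants=tuple(variants),
    )


def moi_compatible(
    candidate: CandidateSet, gene: GeneEntry, sex: Sex
) -> frozenset[InheritanceMode]:
    """Inheritance modes the candidate genotypes can satisfy for this gene.

    AD needs any alt call; AR needs biallelic state (hom or compound het);
    X-linked needs a hemizygous male or a homozygous female — a female
    heterozygote is a carrier only and does not satisfy XL.  The result is
    intersected with the gene's declared modes (AD_AR expands).
    """
    zygs = set(candidate.zygosities)
    satisfied: set[InheritanceMode] = set()
    if zygs & {Zygosity.HET, Zygosity.HOM, Zygosity.HEMI}:
        satisfied.add(InheritanceMode.AD)
    if candidate.biallelic_status in BIALLELIC:
        satisfied.add(InheritanceMode.AR)
    if gene.on_x:
        if sex == Sex.MALE and Zygosity.HEMI in zygs:
            satisfied.add(InheritanceMode.XL)
        elif sex == Sex.FEMALE and Zygosity.HOM in zygs:
            satisfied.add(InheritanceMode.XL)
    return frozenset(satisfied) & gene.compatible_modes


def digenic_recheck(
    monoallelic_genes: Iterable[str], panel: Panel
) -> list[tuple[str, str]]:
    """Candidate digenic pairs among genes carrying a monoallelic AR het.

    Returns each unordered pair (g1, g2), sorted, where both genes carry a
    surviving heterozygous variant and one lists the other as a digenic
    partner.  An empty partner table yields an empty result.
    """
    genes = sorted(set(monoallelic_genes) & panel.symbols)
    pairs: set[tuple[str, str]] = set()
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            e1, e2 = panel.entries[g1], panel.entries[g2]
            if g2 in e1.digenic_partners or g1 in e2.digenic_partners:
                pairs.add((g1, g2))
    return sorted(pairs)


def trio_segregations(
    variants: Sequence[AnnotatedVariant],
    proband_id: str,
    pedigree: Pedigree | None,
    min_parent_depth: int = 20,
) -> list[SegregationResult]:
    """Per-variant segregation for a proband, UNKNOWN without trio data."""
    results: list[SegregationResult] = []
    father_id = mother_id = None
    if pedigree is not None:
        father_id, mother_id = pedigree.parents_of(proband_id)
    for v in variants:
        proband_gt = v.genotype(proband_id)
        if proband_gt is None or not proband_gt.carries_alt:
            results.append(SegregationResult.UNKNOWN)
            continue
        mother_gt = v.genotype(mother_id) if mother_id else None
        father_gt = v.genotype(father_id) if father_id else None
        if mother_gt is None and father_gt is None:
            results.append(SegregationResult.UNKNOWN)
            continue
        results.append(
            segregate(proband_gt, mother_gt, father_gt, min_parent_depth)
        )
    return results
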