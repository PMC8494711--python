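"""Report-inclusion rules, case outcome and panel-update re-analysis.

Inclusion mirrors the clinical reporting policy: pathogenic (C5) and
likely pathogenic (C4) variants are always reported; VUS (C3) are
reported in genes with autosomal dominant disease, in X-linked genes for
male probands, and in autosomal-recessive-only genes only when the
finding is in line with the clinical phenotype.  Benign and likely
benign calls (C1/C2) are classified but never reported.

A case counts as DIAGNOSED when at least one reported variant is both
phenotype-compatible and compatible with the gene's inheritance mode;
an incidental C4 in a phenotype-mismatched gene is reported but does not
diagnose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .panel import (
    BROAD_CATEGORIES,
    GeneEntry,
    InheritanceMode,
    Panel,
    SuspicionCategory,
    panel_diff,
)
from .variant_io import AgeGroup, AnnotatedVariant, Case, GenotypeCall, Pedigree, Sex
from .inheritance import (
    BIALLELIC,
    BiallelicStatus,
    CandidateSet,
    SegregationResult,
    Zygosity,
    moi_compatible,
)
from .classify import (
    AcmgConfig,
    ClassTier,
    ClassifiedVariant,
    EvidenceCriterion,
    make_classified,
)

OUTCOME_DIAGNOSED = "DIAGNOSED"
OUTCOME_NOT_DIAGNOSED = "NOT_DIAGNOSED"


def phenotype_match(
    gene: GeneEntry,
    case: Case,
    biallelic_status: BiallelicStatus = BiallelicStatus.MONOALLELIC,
) -> bool:
    """Is a finding in this gene in line with the clinical phenotype?

    The suspicion must be among the gene's disease categories
    (unknown-origin and "other" presentations match any panel gene), and
    when the gene is recessive-only a monoallelic finding cannot explain
    the phenotype.
    """
    if case.suspicion not in BROAD_CATEGORIES:
        if case.suspicion not in gene.categories:
            return False
    if gene.ar_only and biallelic_status == BiallelicStatus.MONOALLELIC:
        return False
    return True


def include_in_report(
    cv: ClassifiedVariant,
    gene: GeneEntry,
    sex: Sex,
    biallelic_status: BiallelicStatus,
    phenotype_match: bool,
) -> tuple[bool, str]:
    """Apply the report-inclusion policy; returns (decision, rationale)."""
    modes = gene.compatible_modes
    if cv.tier >= ClassTier.C4:
        return True, f"{cv.tier.name} ({cv.tier.label}) variants are always reported"
    if cv.tier <= ClassTier.C2:
        return False, f"{cv.tier.name} ({cv.tier.label}) variants are never reported"
    # C3 / VUS clauses
    if InheritanceMode.AD in modes:
        return True, "C3 in a gene with autosomal dominant disease"
    if InheritanceMode.XL in gene.modes and sex == Sex.MALE:
        return True, "C3 in an X-linked gene, male proband"
    if InheritanceMode.AR in modes:
        if phenotype_match:
            return True, "C3 in a recessive gene, in line with the clinical phenotype"
        return False, "C3 in a recessive gene, not in line with the clinical phenotype"
    return False, "C3 with no reportable inheritance clause"


@dataclass(frozen=True)
class ReportedVariant:
    """A classified variant plus the reporting decision context."""

    cv: ClassifiedVariant
    inclusion_rationale: str
    phenotype_match: bool
    moi_compatible: frozenset[InheritanceMode]

    @property
    def diagnostic(self) -> bool:
        return self.phenotype_match and bool(self.moi_compatible)


@dataclass(frozen=True)
class ExcludedVariant:
    cv: ClassifiedVariant
    exclusion_reason: str


@dataclass
class CaseReport:
    """Per-case genetic report with a complete audit of decisions."""

    case_id: str
    suspicion: SuspicionCategory
    age_group: AgeGroup
    sex: Sex
    reported: list[ReportedVariant]
    excluded: list[ExcludedVariant]
    outcome: str
    pass_used: str
    panel_version: str
    previous_panel_version: str | None = None
    reanalysis_of_diagnosed: bool = False
    created: str | None = None

    def body_dict(self) -> dict:
        """Report content without volatile fields (timestamps)."""
        d = report_to_dict(self)
        d.pop("created", None)
        return d


def case_outcome(report: CaseReport) -> str:
    """DIAGNOSED iff a reported variant is phenotype- and MoI-compatible."""
    if any(rv.diagnostic for rv in report.reported):
        return OUTCOME_DIAGNOSED
    return OUTCOME_NOT_DIAGNOSED


def build_case_report(
    case: Case,
    prioritization,
    panel: Panel,
    created: str | None = None,
    previous_panel_version: str | None = None,
) -> CaseReport:
    """Assemble the genetic report from a prioritization result.

    Every classified survivor appears exactly once, either reported or
    excluded with the clause that excluded it.
    """
    reported: list[ReportedVariant] = []
    excluded: list[ExcludedVariant] = []
    # per-gene candidate sets for MoI compatibility
    by_gene: dict[str, list[ClassifiedVariant]] = {}
    for cv in prioritization.survivors:
        by_gene.setdefault(cv.gene, []).append(cv)
    for gene_symbol in sorted(by_gene):
        gene = panel.entries[gene_symbol]
        group = by_gene[gene_symbol]
        candidate = CandidateSet(
            gene=gene_symbol,
            zygosities=tuple(cv.zygosity for cv in group),
            biallelic_status=group[0].biallelic_status,
            variants=tuple(cv.variant for cv in group),
        )
        modes = moi_compatible(candidate, gene, case.sex)
        for cv in group:
            match = phenotype_match(gene, case, cv.biallelic_status)
            include, rationale = include_in_report(
                cv, gene, case.sex, cv.biallelic_status, match
            )
            if include:
                reported.append(
                    ReportedVariant(
                        cv=cv,
                        inclusion_rationale=rationale,
                        phenotype_match=match,
                        moi_compatible=modes,
                    )
                )
            else:
                excluded.append(ExcludedVariant(cv=cv, exclusion_reason=rationale))
    report = CaseReport(
        case_id=case.case_id,
        suspicion=case.suspicion,
        age_group=case.age_group,
        sex=case.sex,
        reported=reported,
        excluded=excluded,
        outcome=OUTCOME_NOT_DIAGNOSED,
        pass_used=prioritization.pass_used,
        panel_version=panel.version,
        previous_panel_version=previous_panel_version,
        created=created,
    )
    report.outcome = case_outcome(report)
    return report


def reanalyze(
    case: Case,
    variants: Sequence[AnnotatedVariant],
    old_report: CaseReport,
    new_panel: Panel,
    pedigree: Pedigree | None = None,
    filter_config=None,
    acmg_config: AcmgConfig | None = None,
    created: str | None = None,
) -> CaseReport:
    """Re-run the pipeline against an updated panel, without re-sequencing.

    The archived variant table is re-prioritized against the new panel;
    the resulting report records both panel versions.  Re-analysing an
    already diagnosed case is permitted but flagged (the routine policy
    re-analyses negative reports).
    """
    from .filters import two_pass_prioritize

    result = two_pass_prioritize(
        case,
        new_panel,
        variants,
        pedigree=pedigree,
        config=filter_config,
        acmg_config=acmg_config,
    )
    report = build_case_report(
        case,
        result,
        new_panel,
        created=created,
        previous_panel_version=old_report.panel_version,
    )
    report.reanalysis_of_diagnosed = old_report.outcome == OUTCOME_DIAGNOSED
    return report


# ---------------------------------------------------------------------------
# JSON (de)serialization — versioned report schema + archives
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "1"


def _genotype_to_dict(g: GenotypeCall) -> dict:
    return {
        "sample_id": g.sample_id,
        "alleles": list(g.alleles),
        "depth": g.depth,
        "alt_depth": g.alt_depth,
        "quality": g.quality,
    }


def _genotype_from_dict(d: Mapping) -> GenotypeCall:
    alleles = tuple(d["alleles"])
    return GenotypeCall(
        sample_id=d["sample_id"],
        alleles=(alleles[0], alleles[1]),
        depth=d.get("depth"),
        alt_depth=d.get("alt_depth"),
        quality=d.get("quality"),
    )


def variant_to_dict(v: AnnotatedVariant) -> dict:
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "consequence": v.consequence,
        "transcript": v.transcript,
        "hgvs_c": v.hgvs_c,
        "hgvs_p": v.hgvs_p,
        "pop_freqs": dict(v.pop_freqs),
        "insilico": dict(v.insilico),
        "known_pathogenic_same_change": v.known_pathogenic_same_change,
        "is_cnv": v.is_cnv,
        "cnv_type": v.cnv_type,
        "genotypes": {s: _genotype_to_dict(g) for s, g in v.genotypes.items()},
    }


def variant_from_dict(d: Mapping) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=d["chrom"],
        pos=d["pos"],
        ref=d["ref"],
        alt=d["alt"],
        gene=d.get("gene", ""),
        consequence=d.get("consequence", "unknown"),
        transcript=d.get("transcript", ""),
        hgvs_c=d.get("hgvs_c", ""),
        hgvs_p=d.get("hgvs_p", ""),
        pop_freqs=dict(d.get("pop_freqs", {})),
        insilico=dict(d.get("insilico", {})),
        known_pathogenic_same_change=d.get("known_pathogenic_same_change", False),
        is_cnv=d.get("is_cnv", False),
        cnv_type=d.get("cnv_type", "none"),
        genotypes={
            s: _genotype_from_dict(g) for s, g in d.get("genotypes", {}).items()
        },
    )


def classified_to_dict(cv: ClassifiedVariant) -> dict:
    return {
        "variant": variant_to_dict(cv.variant),
        "zygosity": cv.zygosity.value,
        "evidence": sorted(c.value for c in cv.evidence),
        "tier": cv.tier.name,
        "segregation": cv.segregation.value,
        "rationale": cv.rationale,
        "biallelic_status": cv.biallelic_status.value,
        "zygosity_warning": cv.zygosity_warning,
    }


def classified_from_dict(d: Mapping) -> ClassifiedVariant:
    return make_classified(
        variant=variant_from_dict(d["variant"]),
        zygosity=Zygosity(d["zygosity"]),
        evidence=[EvidenceCriterion(c) for c in d["evidence"]],
        segregation=SegregationResult(d["segregation"]),
        biallelic_status=BiallelicStatus(d["biallelic_status"]),
        zygosity_warning=d.get("zygosity_warning"),
    )


def report_to_dict(report: CaseReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "case_id": report.case_id,
        "suspicion": report.suspicion.value,
        "age_group": report.age_group.value,
        "sex": report.sex.value,
        "outcome": report.outcome,
        "pass_used": report.pass_used,
        "panel_version": report.panel_version,
        "previous_panel_version": report.previous_panel_version,
        "reanalysis_of_diagnosed": report.reanalysis_of_diagnosed,
        "created": report.created,
        "reported": [
            {
                "classified": classified_to_dict(rv.cv),
                "inclusion_rationale": rv.inclusion_rationale,
                "phenotype_match": rv.phenotype_match,
                "moi_compatible": sorted(m.value for m in rv.moi_compatible),
            }
            for rv in report.reported
        ],
        "excluded": [
            {
                "classified": classified_to_dict(ev.cv),
                "exclusion_reason": ev.exclusion_reason,
            }
            for ev in report.excluded
        ],
    }


def report_from_dict(d: Mapping) -> CaseReport:
    return CaseReport(
        case_id=d["case_id"],
        suspicion=SuspicionCategory(d["suspicion"]),
        age_group=AgeGroup(d["age_group"]),
        sex=Sex(d["sex"]),
        reported=[
            ReportedVariant(
                cv=classified_from_dict(rv["classified"]),
                inclusion_rationale=rv["inclusion_rationale"],
                phenotype_match=rv["phenotype_match"],
                moi_compatible=frozenset(
                    InheritanceMode(m) for m in rv["moi_compatible"]
                ),
            )
            for rv in d.get("reported", [])
        ],
        excluded=[
            ExcludedVariant(
                cv=classified_from_dict(ev["classified"]),
                exclusion_reason=ev["exclusion_reason"],
            )
            for ev in d.get("excluded", [])
        ],
        outcome=d["outcome"],
        pass_used=d["pass_used"],
        panel_version=d["panel_version"],
        previous_panel_version=d.get("previous_panel_version"),
        reanalysis_of_diagnosed=d.get("reanalysis_of_diagnosed", False),
        created=d.get("created"),
    )


def write_report(report: CaseReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")


def read_report(path: str | Path) -> CaseReport:
    return report_from_dict(json.loads(Path(path).read_text()))
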