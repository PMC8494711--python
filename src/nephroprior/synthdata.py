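"""Seed-deterministic synthetic cohorts and the printed-marginals fixture.

Two generators live here:

* :func:`simulate_cohort` writes a complete synthetic study — per-case
  annotated VCFs, a sidecar annotation table, pedigrees, a case table
  and a truth table — in which every planted causal variant passes the
  filter cascade by construction and every decoy fails exactly its
  designated filter.  Defaults emulate the reference cohort: 138 cases,
  the recruited suspicion mix, 56.5% of cases carrying a causal variant,
  tier and inheritance mixes matching the reported distributions, and
  trios for a subset of paediatric cases.

* :func:`make_reference_cohort` builds, without randomness, a cohort of 138
  case reports carrying 129 reported variants in 65 genes whose marginal
  statistics (diagnostic yield, variant classes, tiers, inheritance
  categories, per-suspicion detection rates, multi-variant and recurrent
  counts) equal the published cohort values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import (
    BROAD_CATEGORIES,
    GeneEntry,
    InheritanceMode,
    Panel,
    SuspicionCategory,
    fixture_panel,
    genes_for_suspicion,
)
from .variant_io import (
    AgeGroup,
    AnnotatedVariant,
    AnnotationSpec,
    Case,
    EligibilityCategory,
    GenotypeCall,
    Sex,
    read_case_table,
    read_pedigree,
    read_vcf,
    write_case_table,
)
from .inheritance import BiallelicStatus, CandidateSet, SegregationResult, Zygosity
from .classify import (
    AcmgConfig,
    ClassTier,
    ClassifiedVariant,
    EvidenceCriterion,
    make_classified,
)
from .filters import FilterConfig, PASS_FULL, PASS_TAILORED, two_pass_prioritize
from .report import (
    CaseReport,
    OUTCOME_DIAGNOSED,
    OUTCOME_NOT_DIAGNOSED,
    ReportedVariant,
    build_case_report,
    case_outcome,
    phenotype_match,
)
from .inheritance import moi_compatible


class SimConfigError(ValueError):
    """Raised for impossible or inconsistent simulation configurations."""


MOI_BUCKETS = ("AD", "AR", "XL", "BOTH")
DECOY_KINDS = (
    "synonymous",
    "common",
    "low_coverage",
    "low_alt_fraction",
    "off_panel",
)

# Eligible-cohort suspicion mix (paediatric, adult case counts).
_COHORT_SUSPICIONS: dict[SuspicionCategory, tuple[int, int]] = {
    SuspicionCategory.CAKUT: (3, 0),
    SuspicionCategory.TUBULAR: (5, 6),
    SuspicionCategory.CILIOPATHY: (13, 19),
    SuspicionCategory.NEPHROLITHIASIS_NEPHROCALCINOSIS: (1, 1),
    SuspicionCategory.GLOMERULAR: (9, 12),
    SuspicionCategory.HUS: (1, 3),
    SuspicionCategory.UNKNOWN_ORIGIN: (18, 42),
    SuspicionCategory.OTHER: (2, 3),
}


@dataclass(frozen=True)
class PlantSpec:
    """Explicit planted-causal request for one case."""

    case_index: int
    moi: str
    tier: ClassTier
    sex: Sex | None = None
    suspicion: SuspicionCategory | None = None


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reference study's structure: cohort size and
    suspicion mix from the eligible cohort, causal-carrier fraction equal
    to the diagnostic yield, tier and inheritance mixes equal to the
    reported variant-level distributions, trios for roughly half of the
    paediatric probands.
    """

    n_cases: int = 138
    suspicion_mix: dict[SuspicionCategory, float] = field(
        default_factory=lambda: {
            cat: (p + a) / 138.0 for cat, (p, a) in _COHORT_SUSPICIONS.items()
        }
    )
    paediatric_fraction: float = 52 / 138
    trio_fraction_paediatric: float = 23 / 52
    trio_fraction_adult: float = 0.0
    causal_fraction: float = 78 / 138
    tier_mix: dict[ClassTier, float] = field(
        default_factory=lambda: {
            ClassTier.C5: 27 / 129,
            ClassTier.C4: 35 / 129,
            ClassTier.C3: 67 / 129,
        }
    )
    moi_mix: dict[str, float] = field(
        default_factory=lambda: {
            "AD": 43 / 78,
            "AR": 16 / 78,
            "XL": 11 / 78,
            "BOTH": 8 / 78,
        }
    )
    compound_het_fraction: float = 0.5
    de_novo_fraction_c5: float = 0.2
    decoys_per_case: dict[str, int] = field(
        default_factory=lambda: {
            "synonymous": 2,
            "common": 2,
            "low_coverage": 1,
            "low_alt_fraction": 1,
            "off_panel": 2,
        }
    )
    forced_plants: tuple[PlantSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise SimConfigError("n_cases must be positive")
        for name, mix in (
            ("suspicion_mix", self.suspicion_mix),
            ("tier_mix", self.tier_mix),
            ("moi_mix", self.moi_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise SimConfigError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise SimConfigError(f"{name} contains a negative probability")
        if any(n < 0 for n in self.decoys_per_case.values()):
            raise SimConfigError("decoy counts must be non-negative")
        unknown = set(self.decoys_per_case) - set(DECOY_KINDS)
        if unknown:
            raise SimConfigError(f"unknown decoy kinds {sorted(unknown)}")
        for spec in self.forced_plants:
            if not 0 <= spec.case_index < self.n_cases:
                raise SimConfigError(
                    f"forced plant case_index {spec.case_index} out of range"
                )
            if spec.moi not in MOI_BUCKETS:
                raise SimConfigError(f"unknown MoI bucket {spec.moi!r}")
            if spec.moi == "XL" and spec.sex == Sex.FEMALE:
                raise SimConfigError(
                    "cannot plant an X-linked hemizygous variant in a female proband"
                )


@dataclass(frozen=True)
class PlantedVariant:
    """Truth-table row for one simulated variant."""

    case_id: str
    key: str
    gene: str
    role: str  # "causal" or "decoy"
    expected_tier: str = ""
    expected_zygosity: str = ""
    expected_segregation: str = ""
    designated_reason: str = ""


@dataclass
class SimulatedCohort:
    out_dir: Path
    panel: Panel
    cases: list[Case]
    vcf_paths: dict[str, Path]
    annotation_path: Path
    ped_path: Path
    case_table_path: Path
    truth: list[PlantedVariant]
    truth_path: Path
    seed: int


# ---------------------------------------------------------------------------
# variant templates
# ---------------------------------------------------------------------------

_GT_HET = ("0/1", 60, 28)  # genotype string, depth, alt depth
_GT_HOM = ("1/1", 55, 53)
_GT_HEMI = ("1", 48, 46)  # haploid: male X
_GT_REF = ("0/0", 40, 0)
_GT_REF_HAPLOID = ("0", 40, 0)
_GT_PARENT_HET = ("0/1", 40, 19)


def _template_for(tier: ClassTier, rng: np.random.Generator) -> dict:
    """Variant template (class, alleles, annotations) realising a tier.

    C5 uses a null variant with a database-asserted pathogenic match
    (PVS1+PS1+PM2); C4 either a novel null variant (PVS1+PM2) or a
    known-pathogenic missense (PS1+PM2); C3 a novel rare missense (PM2).
    """
    lof_classes = (
        ("stop_gained", "C", "T"),
        ("frameshift_variant", "AC", "A"),
        ("splice_donor_variant", "G", "A"),
    )
    if tier == ClassTier.C5:
        cons, ref, alt = lof_classes[int(rng.integers(len(lof_classes)))]
        return {"consequence": cons, "ref": ref, "alt": alt, "known": True}
    if tier == ClassTier.C4:
        if rng.random() < 0.5:
            cons, ref, alt = lof_classes[int(rng.integers(len(lof_classes)))]
            return {"consequence": cons, "ref": ref, "alt": alt, "known": False}
        return {"consequence": "missense_variant", "ref": "A", "alt": "G", "known": True}
    return {"consequence": "missense_variant", "ref": "A", "alt": "G", "known": False}


def _gene_pool(
    panel: Panel, suspicion: SuspicionCategory, bucket: str
) -> list[GeneEntry]:
    genes = sorted(genes_for_suspicion(panel, suspicion), key=lambda g: g.symbol)
    both = frozenset({InheritanceMode.AD, InheritanceMode.AR})
    if bucket == "XL":
        return [g for g in genes if g.on_x and InheritanceMode.XL in g.modes]
    if bucket == "BOTH":
        return [g for g in genes if not g.on_x and both <= g.compatible_modes]
    if bucket == "AR":
        return [g for g in genes if not g.on_x and g.ar_only]
    return [
        g
        for g in genes
        if not g.on_x
        and InheritanceMode.AD in g.compatible_modes
        and not both <= g.compatible_modes
    ]


def _draw(rng: np.random.Generator, mix: Mapping) -> object:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


@dataclass
class _SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    freqs: dict[str, float]
    known: bool
    genotypes: dict[str, tuple[str, int, int]]  # sample -> (gt, dp, alt_dp)


def simulate_cohort(
    config: SimConfig, out_dir: str | Path, panel: Panel | None = None
) -> SimulatedCohort:
    """Generate a synthetic cohort on disk; identical seeds give identical files."""
    config.validate()
    panel = panel or fixture_panel()
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    forced = {s.case_index: s for s in config.forced_plants}
    cases: list[Case] = []
    truth: list[PlantedVariant] = []
    sim_variants_per_case: dict[str, list[_SimVariant]] = {}
    trio_of: dict[str, tuple[str, str] | None] = {}
    pos_counter = 100_000  # global, so annotation keys never collide

    ann_rows: list[dict] = []

    for i in range(config.n_cases):
        case_id = f"SIM{i:04d}"
        proband = f"{case_id}-P"
        spec = forced.get(i)
        suspicion = (
            spec.suspicion
            if spec is not None and spec.suspicion is not None
            else _draw(rng, config.suspicion_mix)
        )
        paediatric = rng.random() < config.paediatric_fraction
        causal = spec is not None or rng.random() < config.causal_fraction
        bucket = None
        if causal:
            bucket = spec.moi if spec is not None else _draw(rng, config.moi_mix)
        if spec is not None and spec.sex is not None:
            sex = spec.sex
        elif bucket == "XL":
            sex = Sex.MALE
        else:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        trio_frac = (
            config.trio_fraction_paediatric
            if paediatric
            else config.trio_fraction_adult
        )
        has_trio = rng.random() < trio_frac
        father = f"{case_id}-F" if has_trio else None
        mother = f"{case_id}-M" if has_trio else None
        trio_of[case_id] = (father, mother) if has_trio else None
        case = Case(
            case_id=case_id,
            proband=proband,
            sex=sex,
            age_group=AgeGroup.PAEDIATRIC if paediatric else AgeGroup.ADULT,
            suspicion=suspicion,
            family_history=bool(rng.random() < 0.48),
            eligibility_category=(
                EligibilityCategory.NO_DIAGNOSIS
                if suspicion in BROAD_CATEGORIES
                else EligibilityCategory.CONFIRM_DIAGNOSIS
            ),
        )
        cases.append(case)
        variants: list[_SimVariant] = []

        if causal:
            tier = spec.tier if spec is not None else _draw(rng, config.tier_mix)
            pool = _gene_pool(panel, suspicion, bucket)
            if not pool:
                # suspicion has no gene with that inheritance; fall back
                for alt_bucket in MOI_BUCKETS:
                    pool = _gene_pool(panel, suspicion, alt_bucket)
                    if pool:
                        bucket = alt_bucket
                        break
            if bucket == "XL" and sex == Sex.FEMALE:
                raise SimConfigError(
                    f"case {case_id}: X-linked hemizygous plant in a female proband"
                )
            gene = pool[int(rng.integers(len(pool)))]
            n_alleles = 1
            compound = False
            if bucket == "AR" and rng.random() < config.compound_het_fraction:
                compound = True
                n_alleles = 2
            planted_templates = [_template_for(tier, rng)]
            if compound:
                planted_templates.append(
                    {"consequence": "missense_variant", "ref": "A", "alt": "G", "known": False}
                )
            de_novo = (
                tier == ClassTier.C5
                and has_trio
                and not compound
                and bucket in ("AD", "BOTH", "XL")
                and rng.random() < config.de_novo_fraction_c5
            )
            for vi, tpl in enumerate(planted_templates):
                pos_counter += int(rng.integers(50, 500))
                if bucket in ("AD", "BOTH"):
                    gt, zyg = _GT_HET, Zygosity.HET
                elif bucket == "XL":
                    gt, zyg = _GT_HEMI, Zygosity.HEMI
                elif compound:
                    gt, zyg = _GT_HET, Zygosity.HET
                else:
                    gt, zyg = _GT_HOM, Zygosity.HOM
                genotypes = {proband: gt}
                father_ref = _GT_REF_HAPLOID if bucket == "XL" else _GT_REF
                seg = SegregationResult.UNKNOWN
                if has_trio:
                    if de_novo:
                        genotypes[father] = father_ref
                        genotypes[mother] = _GT_REF
                        seg = SegregationResult.DE_NOVO
                    elif compound:
                        carrier = mother if vi == 0 else father
                        other = father if vi == 0 else mother
                        genotypes[carrier] = _GT_PARENT_HET
                        genotypes[other] = _GT_REF
                        seg = (
                            SegregationResult.INHERITED_MATERNAL
                            if carrier == mother
                            else SegregationResult.INHERITED_PATERNAL
                        )
                    elif bucket == "AR":
                        genotypes[father] = _GT_PARENT_HET
                        genotypes[mother] = _GT_PARENT_HET
                        seg = SegregationResult.BIPARENTAL
                    elif bucket == "XL":
                        # an X-linked allele in a male comes from the mother
                        genotypes[mother] = _GT_PARENT_HET
                        genotypes[father] = _GT_REF_HAPLOID
                        seg = SegregationResult.INHERITED_MATERNAL
                    else:
                        carrier = mother if rng.random() < 0.5 else father
                        other = father if carrier == mother else mother
                        genotypes[carrier] = _GT_PARENT_HET
                        genotypes[other] = _GT_REF
                        seg = (
                            SegregationResult.INHERITED_MATERNAL
                            if carrier == mother
                            else SegregationResult.INHERITED_PATERNAL
                        )
                sv = _SimVariant(
                    chrom=gene.chromosome,
                    pos=pos_counter,
                    ref=tpl["ref"],
                    alt=tpl["alt"],
                    gene=gene.symbol,
                    consequence=tpl["consequence"],
                    freqs={},
                    known=tpl["known"],
                    genotypes=genotypes,
                )
                variants.append(sv)
                expected_tier = tier if vi == 0 else ClassTier.C3
                truth.append(
                    PlantedVariant(
                        case_id=case_id,
                        key=f"{sv.chrom}:{sv.pos}:{sv.ref}:{sv.alt}",
                        gene=gene.symbol,
                        role="causal",
                        expected_tier=expected_tier.name,
                        expected_zygosity=zyg.value,
                        expected_segregation=seg.value,
                    )
                )

        # decoys, each failing exactly its designated filter
        tailored = sorted(
            genes_for_suspicion(panel, suspicion), key=lambda g: g.symbol
        )
        for kind in DECOY_KINDS:
            for _ in range(config.decoys_per_case.get(kind, 0)):
                pos_counter += int(rng.integers(50, 500))
                gene_entry = tailored[int(rng.integers(len(tailored)))]
                gene_symbol = gene_entry.symbol
                chrom = gene_entry.chromosome
                consequence = "missense_variant"
                freqs: dict[str, float] = {"1KG": 0.001}
                gt = ("0/1", 60, 30)
                if kind == "synonymous":
                    consequence = "synonymous_variant"
                elif kind == "common":
                    freqs = {"ExAC": 0.02}
                elif kind == "low_coverage":
                    gt = ("0/1", 10, 5)
                elif kind == "low_alt_fraction":
                    gt = ("0/1", 40, 8)
                elif kind == "off_panel":
                    gene_symbol = "OFFPANEL1"
                    chrom = "1"
                genotypes = {proband: gt}
                if has_trio:
                    genotypes[father] = _GT_REF
                    genotypes[mother] = _GT_REF
                reason = {
                    "synonymous": "SYNONYMOUS_OR_NONREPORTABLE_CLASS",
                    "common": "COMMON_POLYMORPHISM",
                    "low_coverage": "LOW_COVERAGE",
                    "low_alt_fraction": "LOW_ALT_FRACTION",
                    "off_panel": "OFF_PANEL",
                }[kind]
                sv = _SimVariant(
                    chrom=chrom,
                    pos=pos_counter,
                    ref="A",
                    alt="G",
                    gene=gene_symbol,
                    consequence=consequence,
                    freqs=freqs,
                    known=False,
                    genotypes=genotypes,
                )
                variants.append(sv)
                truth.append(
                    PlantedVariant(
                        case_id=case_id,
                        key=f"{sv.chrom}:{sv.pos}:{sv.ref}:{sv.alt}",
                        gene=gene_symbol,
                        role="decoy",
                        designated_reason=reason,
                    )
                )
        sim_variants_per_case[case_id] = variants
        for sv in variants:
            ann_rows.append(
                {
                    "chrom": sv.chrom,
                    "pos": sv.pos,
                    "ref": sv.ref,
                    "alt": sv.alt,
                    "gene": sv.gene,
                    "consequence": sv.consequence,
                    "transcript": f"NM_{sv.pos:07d}.1",
                    "hgvs_c": ".",
                    "hgvs_p": ".",
                    "freq_1kg": sv.freqs.get("1KG", ""),
                    "freq_exac": sv.freqs.get("ExAC", ""),
                    "insilico": ".",
                    "known_pathogenic": "true" if sv.known else "false",
                    "is_cnv": "false",
                    "cnv_type": ".",
                }
            )

    # ---------------- write files ----------------
    vcf_paths: dict[str, Path] = {}
    chrom_order = [str(c) for c in range(1, 23)] + ["X", "Y"]
    for case in cases:
        samples = [case.proband]
        trio = trio_of[case.case_id]
        if trio is not None:
            samples += [trio[0], trio[1]]
        lines = [
            "##fileformat=VCFv4.2",
            f"##source=nephroprior-sim seed={config.seed}",
        ]
        lines += [f"##contig=<ID={c}>" for c in chrom_order]
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples),
        ]
        for sv in sorted(
            sim_variants_per_case[case.case_id],
            key=lambda v: (chrom_order.index(v.chrom), v.pos),
        ):
            cols = [sv.chrom, str(sv.pos), ".", sv.ref, sv.alt, "100", "PASS", ".", "GT:DP:AD"]
            for s in samples:
                gt, dp, ad_alt = sv.genotypes.get(s, _GT_REF)
                cols.append(f"{gt}:{dp}:{dp - ad_alt},{ad_alt}")
            lines.append("\t".join(cols))
        path = out / "vcf" / f"{case.case_id}.vcf"
        path.write_text("\n".join(lines) + "\n")
        vcf_paths[case.case_id] = path

    ann_path = out / "annotations.tsv"
    header = [
        "chrom", "pos", "ref", "alt", "gene", "consequence", "transcript",
        "hgvs_c", "hgvs_p", "freq_1kg", "freq_exac", "insilico",
        "known_pathogenic", "is_cnv", "cnv_type",
    ]
    ann_lines = ["\t".join(header)]
    for row in ann_rows:
        ann_lines.append("\t".join(str(row[c]) if row[c] != "" else "." for c in header))
    ann_path.write_text("\n".join(ann_lines) + "\n")

    ped_path = out / "cohort.ped"
    ped_lines = []
    for case in cases:
        trio = trio_of[case.case_id]
        sex_code = "1" if case.sex == Sex.MALE else "2"
        if trio is None:
            ped_lines.append(f"{case.case_id} {case.proband} 0 0 {sex_code} 2")
        else:
            father, mother = trio
            ped_lines.append(
                f"{case.case_id} {case.proband} {father} {mother} {sex_code} 2"
            )
            ped_lines.append(f"{case.case_id} {father} 0 0 1 1")
            ped_lines.append(f"{case.case_id} {mother} 0 0 2 1")
    ped_path.write_text("\n".join(ped_lines) + "\n")

    case_table_path = out / "cases.tsv"
    write_case_table(cases, case_table_path)

    truth_path = out / "truth.tsv"
    t_header = [
        "case_id", "key", "gene", "role", "expected_tier",
        "expected_zygosity", "expected_segregation", "designated_reason",
    ]
    t_lines = ["\t".join(t_header)]
    for t in truth:
        t_lines.append(
            "\t".join(
                [
                    t.case_id, t.key, t.gene, t.role, t.expected_tier,
                    t.expected_zygosity, t.expected_segregation,
                    t.designated_reason,
                ]
            )
        )
    truth_path.write_text("\n".join(t_lines) + "\n")

    return SimulatedCohort(
        out_dir=out,
        panel=panel,
        cases=cases,
        vcf_paths=vcf_paths,
        annotation_path=ann_path,
        ped_path=ped_path,
        case_table_path=case_table_path,
        truth=truth,
        truth_path=truth_path,
        seed=config.seed,
    )


def run_pipeline_on_cohort(
    cohort: SimulatedCohort,
    filter_config: FilterConfig | None = None,
    acmg_config: AcmgConfig | None = None,
) -> list[CaseReport]:
    """Ingest the simulated files and prioritize every case."""
    spec = AnnotationSpec(sidecar=cohort.annotation_path)
    pedigree = read_pedigree(cohort.ped_path)
    cases = read_case_table(cohort.case_table_path)
    reports: list[CaseReport] = []
    for case in cases:
        variants = read_vcf(cohort.vcf_paths[case.case_id], spec)
        result = two_pass_prioritize(
            case,
            cohort.panel,
            variants,
            pedigree=pedigree,
            config=filter_config,
            acmg_config=acmg_config,
        )
        reports.append(build_case_report(case, result, cohort.panel))
    return reports


# ---------------------------------------------------------------------------
# The printed-marginals fixture cohort
# ---------------------------------------------------------------------------

# per suspicion: (paediatric cases, adult cases, paediatric diagnosed,
# adult diagnosed) — consistent with every published marginal.
_FIXTURE_PLAN: list[tuple[SuspicionCategory, int, int, int, int]] = [
    (SuspicionCategory.CAKUT, 3, 0, 0, 0),
    (SuspicionCategory.TUBULAR, 5, 6, 1, 3),
    (SuspicionCategory.CILIOPATHY, 13, 19, 11, 11),
    (SuspicionCategory.NEPHROLITHIASIS_NEPHROCALCINOSIS, 1, 1, 1, 0),
    (SuspicionCategory.GLOMERULAR, 9, 12, 6, 8),
    (SuspicionCategory.HUS, 1, 3, 0, 1),
    (SuspicionCategory.UNKNOWN_ORIGIN, 18, 42, 10, 22),
    (SuspicionCategory.OTHER, 2, 3, 1, 3),
]

# per suspicion: diagnosed-case inheritance buckets with their gene lists
# (cycled when shorter than the count).
_FIXTURE_MOI: dict[SuspicionCategory, list[tuple[str, int, list[str]]]] = {
    SuspicionCategory.TUBULAR: [
        ("AD", 1, ["UMOD"]),
        ("AR", 2, ["SLC12A3", "CTNS"]),
        ("XL", 1, ["CLCN5"]),
    ],
    SuspicionCategory.CILIOPATHY: [
        ("AD", 16, ["PKD1", "PKD2", "GANAB", "DNAJB11", "HNF1B"]),
        ("AR", 5, ["PKHD1", "NPHP1", "CEP290", "TMEM67", "IFT140"]),
        ("XL", 1, ["OFD1"]),
    ],
    SuspicionCategory.NEPHROLITHIASIS_NEPHROCALCINOSIS: [
        ("AR", 1, ["AGXT"]),
    ],
    SuspicionCategory.GLOMERULAR: [
        ("AD", 6, ["WT1", "INF2", "TRPC6", "ACTN4", "LMX1B", "PAX2"]),
        ("AR", 2, ["NPHS1", "NPHS2"]),
        ("XL", 2, ["COL4A5"]),
        ("BOTH", 4, ["COL4A3", "COL4A4"]),
    ],
    SuspicionCategory.HUS: [
        ("BOTH", 1, ["CFH"]),
    ],
    SuspicionCategory.UNKNOWN_ORIGIN: [
        ("AD", 16, [
            "RET", "ROBO2", "SOX17", "UPK3A", "DSTYK", "CHD7", "REN",
            "SEC61A1", "CFI", "CFB", "C3", "THBD", "GREB1L", "TBX18",
            "PAX8", "NRIP1",
        ]),
        ("AR", 6, ["NPHP3", "NPHP4", "INVS", "IQCB1", "BBS1", "NPHP1"]),
        ("XL", 7, ["OCRL", "AVPR2", "ANOS1", "COL4A5", "CLCN5", "OFD1", "OCRL"]),
        ("BOTH", 3, ["CD2AP", "SLC7A9", "CASR"]),
    ],
    SuspicionCategory.OTHER: [
        ("AD", 4, ["SALL1", "GATA3", "EYA1", "SIX1"]),
    ],
}

# non-CNV diagnostic (tier, class, count) schedule; together with the four
# CNV slots this realises 27 C5 / 35 C4 / 25 C3 diagnostic variants in
# classes 32 missense / 10 nonsense / 19 frameshift / 7 indel / 15 splice.
_DIAG_SCHEDULE: list[tuple[str, str, int]] = [
    ("C5", "nonsense", 6),
    ("C5", "frameshift", 9),
    ("C5", "splice", 6),
    ("C5", "missense", 4),
    ("C4", "nonsense", 4),
    ("C4", "frameshift", 10),
    ("C4", "splice", 9),
    ("C4", "indel", 4),
    ("C4", "missense", 6),
    ("C3", "indel", 3),
    ("C3", "missense", 22),
]

_CLASS_FIELDS = {
    "missense": ("missense_variant", "A", "G"),
    "nonsense": ("stop_gained", "C", "T"),
    "frameshift": ("frameshift_variant", "AC", "A"),
    "indel": ("inframe_deletion", "AGGG", "A"),
    "splice": ("splice_donor_variant", "G", "A"),
}

# additional reported-but-incidental VUS genes; the first six are not used
# by any diagnostic variant, bringing the distinct gene total to 65.
_EXTRA_NEW_GENES = ["TNXB", "HNF4A", "MYH9", "FN1", "COL4A1", "AQP2"]
_EXTRA_REUSE_GENES = [
    "PKD1", "PKD2", "WT1", "UMOD", "RET", "INF2", "TRPC6", "ACTN4",
    "LMX1B", "EYA1", "GATA3", "SALL1", "CHD7", "REN",
]
_EXTRA_COUNTS = [3] * 8 + [2] * 7 + [1] * 4  # 42 extras over 19 patients


@dataclass
class ReferenceCohort:
    panel: Panel
    reports: list[CaseReport]


def _evidence_for(tier: str, vclass: str) -> tuple[frozenset, bool, SegregationResult]:
    """(evidence, known_pathogenic, segregation) realising a tier."""
    E = EvidenceCriterion
    lof = vclass in ("nonsense", "frameshift", "splice", "CNV")
    if tier == "C5":
        if lof:
            return frozenset({E.PVS1, E.PS1, E.PM2}), True, SegregationResult.UNKNOWN
        return frozenset({E.PS1, E.PS2, E.PM2}), True, SegregationResult.DE_NOVO
    if tier == "C4":
        if lof:
            return frozenset({E.PVS1, E.PM2}), False, SegregationResult.UNKNOWN
        return frozenset({E.PS1, E.PM2}), True, SegregationResult.UNKNOWN
    return frozenset({E.PM2}), False, SegregationResult.UNKNOWN


def make_reference_cohort() -> ReferenceCohort:
    """Deterministic 138-case cohort reproducing the printed marginals."""
    panel = fixture_panel()
    pos_of: dict[str, int] = {}

    gene_base = {
        sym: 1_000_000 * (i + 1) for i, sym in enumerate(sorted(panel.entries))
    }  # distinct position ranges per gene, so keys never collide

    def next_pos(gene: str) -> int:
        pos_of[gene] = pos_of.get(gene, gene_base[gene]) + 500
        return pos_of[gene]

    def build_variant(
        gene: GeneEntry,
        vclass: str,
        tier: str,
        zygosity: Zygosity,
        proband: str,
        biallelic: BiallelicStatus,
        pos: int | None = None,
        ref: str | None = None,
        alt: str | None = None,
    ) -> ClassifiedVariant:
        if vclass == "CNV":
            consequence, vref, valt = "cnv", "N", "<DEL>"
            is_cnv, cnv_type = True, "loss"
        else:
            consequence, vref, valt = _CLASS_FIELDS[vclass]
            is_cnv, cnv_type = False, "none"
        evidence, known, seg = _evidence_for(tier, vclass)
        gt = {
            Zygosity.HET: (0, 1, 60, 28),
            Zygosity.HOM: (1, 1, 55, 53),
            Zygosity.HEMI: (1, None, 48, 46),
        }[zygosity]
        position = pos if pos is not None else next_pos(gene.symbol)
        variant = AnnotatedVariant(
            chrom=gene.chromosome,
            pos=position,
            ref=ref or vref,
            alt=alt or valt,
            gene=gene.symbol,
            consequence=consequence,
            known_pathogenic_same_change=known,
            is_cnv=is_cnv,
            cnv_type=cnv_type,
            genotypes={
                proband: GenotypeCall(
                    sample_id=proband,
                    alleles=(gt[0], gt[1]),
                    depth=gt[2],
                    alt_depth=gt[3],
                )
            },
        )
        return make_classified(
            variant, zygosity, evidence, segregation=seg, biallelic_status=biallelic
        )

    # deal the non-CNV diagnostic (tier, class) pairs
    schedule: list[tuple[str, str]] = []
    for tier, vclass, n in _DIAG_SCHEDULE:
        schedule.extend([(tier, vclass)] * n)

    def pop_schedule(allow_c5_missense: bool) -> tuple[str, str]:
        for idx, (tier, vclass) in enumerate(schedule):
            if tier == "C5" and vclass == "missense" and not allow_c5_missense:
                continue
            return schedule.pop(idx)
        raise AssertionError("diagnostic schedule exhausted")

    reports: list[CaseReport] = []
    case_counter = 0
    ad_case_ids: list[str] = []  # candidates for incidental extras
    ar_counter = 0  # global over AR-bucket cases: first 9 compound het

    for suspicion, n_ped, n_adult, d_ped, d_adult in _FIXTURE_PLAN:
        n_total = n_ped + n_adult
        n_diag = d_ped + d_adult
        moi_slots: list[tuple[str, GeneEntry]] = []
        for bucket, count, gene_list in _FIXTURE_MOI.get(suspicion, []):
            for k in range(count):
                symbol = gene_list[k % len(gene_list)]
                moi_slots.append((bucket, panel.entries[symbol]))
        assert len(moi_slots) == n_diag, (suspicion, len(moi_slots), n_diag)

        # designated CNV slots within this suspicion's ordering
        for local_idx in range(n_total):
            case_id = f"PF{case_counter:03d}"
            proband = f"{case_id}-P"
            case_counter += 1
            diagnosed = local_idx < n_diag
            if diagnosed:
                paediatric = local_idx < d_ped
            else:
                paediatric = (local_idx - n_diag) < (n_ped - d_ped)
            bucket, gene = moi_slots[local_idx] if diagnosed else (None, None)
            sex = Sex.MALE if (bucket == "XL" or local_idx % 2 == 1) else Sex.FEMALE

            reported: list[ReportedVariant] = []
            if diagnosed:
                is_cnv_slot = (
                    (suspicion == SuspicionCategory.CILIOPATHY and bucket == "AD"
                     and gene.symbol == "HNF1B" and local_idx == 4)
                    or (suspicion == SuspicionCategory.GLOMERULAR and bucket == "XL"
                        and local_idx == 6 + 2)  # first GLOM XL case (AD 6, AR 2)
                    or (suspicion == SuspicionCategory.UNKNOWN_ORIGIN and bucket == "XL"
                        and local_idx == 16 + 6)  # first UNK XL case
                    or (suspicion == SuspicionCategory.UNKNOWN_ORIGIN and bucket == "AR"
                        and local_idx == 16 + 5)  # last UNK AR case (NPHP1)
                )
                cvs: list[ClassifiedVariant] = []
                if bucket == "AR":
                    compound = (not is_cnv_slot) and ar_counter < 9
                    ar_counter += 1
                    if is_cnv_slot:
                        cvs.append(
                            build_variant(
                                gene, "CNV", "C5", Zygosity.HOM, proband,
                                BiallelicStatus.HOM,
                            )
                        )
                    elif compound:
                        for _ in range(2):
                            tier, vclass = pop_schedule(allow_c5_missense=False)
                            cvs.append(
                                build_variant(
                                    gene, vclass, tier, Zygosity.HET, proband,
                                    BiallelicStatus.COMPOUND_HET_PUTATIVE,
                                )
                            )
                    else:
                        tier, vclass = pop_schedule(allow_c5_missense=False)
                        cvs.append(
                            build_variant(
                                gene, vclass, tier, Zygosity.HOM, proband,
                                BiallelicStatus.HOM,
                            )
                        )
                elif bucket == "XL":
                    if is_cnv_slot:
                        cvs.append(
                            build_variant(
                                gene, "CNV", "C4", Zygosity.HEMI, proband,
                                BiallelicStatus.HOM,
                            )
                        )
                    else:
                        tier, vclass = pop_schedule(allow_c5_missense=False)
                        cvs.append(
                            build_variant(
                                gene, vclass, tier, Zygosity.HEMI, proband,
                                BiallelicStatus.HOM,
                            )
                        )
                else:  # AD or BOTH, heterozygous
                    if is_cnv_slot:
                        cvs.append(
                            build_variant(
                                gene, "CNV", "C5", Zygosity.HET, proband,
                                BiallelicStatus.MONOALLELIC,
                            )
                        )
                    else:
                        tier, vclass = pop_schedule(allow_c5_missense=True)
                        cvs.append(
                            build_variant(
                                gene, vclass, tier, Zygosity.HET, proband,
                                BiallelicStatus.MONOALLELIC,
                            )
                        )
                candidate = CandidateSet(
                    gene=gene.symbol,
                    zygosities=tuple(cv.zygosity for cv in cvs),
                    biallelic_status=cvs[0].biallelic_status,
                )
                case_stub = Case(
                    case_id=case_id,
                    proband=proband,
                    sex=sex,
                    age_group=AgeGroup.PAEDIATRIC if paediatric else AgeGroup.ADULT,
                    suspicion=suspicion,
                )
                modes = moi_compatible(candidate, gene, sex)
                for cv in cvs:
                    match = phenotype_match(gene, case_stub, cv.biallelic_status)
                    assert match and modes, (case_id, gene.symbol, bucket)
                    reported.append(
                        ReportedVariant(
                            cv=cv,
                            inclusion_rationale=(
                                f"{cv.tier.name} diagnostic finding"
                                if cv.tier >= ClassTier.C4
                                else "C3 in line with phenotype and inheritance"
                            ),
                            phenotype_match=True,
                            moi_compatible=modes,
                        )
                    )
                if bucket == "AD":
                    ad_case_ids.append(case_id)
            stopped_early = (
                suspicion not in BROAD_CATEGORIES
                and any(rv.cv.tier >= ClassTier.C4 for rv in reported)
            )
            report = CaseReport(
                case_id=case_id,
                suspicion=suspicion,
                age_group=AgeGroup.PAEDIATRIC if paediatric else AgeGroup.ADULT,
                sex=sex,
                reported=reported,
                excluded=[],
                outcome=OUTCOME_DIAGNOSED if diagnosed else OUTCOME_NOT_DIAGNOSED,
                pass_used=PASS_TAILORED if stopped_early else PASS_FULL,
                panel_version=panel.version,
            )
            reports.append(report)
    assert not schedule, f"{len(schedule)} diagnostic slots undealt"

    # incidental C3 extras: 42 across the first 19 AD-bucket patients, with
    # three variants shared by two patients each (the recurrent variants).
    by_id = {r.case_id: r for r in reports}
    extra_slots: list[str] = []  # case id per extra slot
    for case_id, n in zip(ad_case_ids, _EXTRA_COUNTS):
        extra_slots.extend([case_id] * n)
    assert len(extra_slots) == 42

    extra_genes = _EXTRA_NEW_GENES + [
        _EXTRA_REUSE_GENES[i % len(_EXTRA_REUSE_GENES)] for i in range(33)
    ]  # 39 unique descriptors
    descriptors: list[ClassifiedVariant] = []
    gi = 0
    for slot, case_id in enumerate(extra_slots):
        if slot in (21, 22, 23):
            cv = descriptors[slot - 21]  # recurrent: same variant, 2nd patient
            src = cv.variant
            cv = build_variant(
                panel.entries[src.gene], "missense", "C3", Zygosity.HET,
                f"{case_id}-P", BiallelicStatus.MONOALLELIC,
                pos=src.pos, ref=src.ref, alt=src.alt,
            )
        else:
            gene = panel.entries[extra_genes[gi]]
            gi += 1
            cv = build_variant(
                gene, "missense", "C3", Zygosity.HET, f"{case_id}-P",
                BiallelicStatus.MONOALLELIC,
            )
            if slot < 3:
                descriptors.append(cv)
        report = by_id[case_id]
        gene_entry = panel.entries[cv.gene]
        case_stub = Case(
            case_id=case_id,
            proband=f"{case_id}-P",
            sex=report.sex,
            age_group=report.age_group,
            suspicion=report.suspicion,
        )
        match = phenotype_match(gene_entry, case_stub, cv.biallelic_status)
        candidate = CandidateSet(
            gene=cv.gene, zygosities=(Zygosity.HET,),
            biallelic_status=BiallelicStatus.MONOALLELIC,
        )
        report.reported.append(
            ReportedVariant(
                cv=cv,
                inclusion_rationale="C3 in a gene with autosomal dominant disease",
                phenotype_match=match,
                moi_compatible=moi_compatible(candidate, gene_entry, report.sex),
            )
        )

    # integrity checks on the assembled cohort
    all_rv = [rv for r in reports for rv in r.reported]
    genes = {rv.cv.gene for rv in all_rv}
    assert len(all_rv) == 129, len(all_rv)
    assert len(genes) == 65, len(genes)
    assert sum(1 for r in reports if r.outcome == OUTCOME_DIAGNOSED) == 78
    assert sum(1 for r in reports if len(r.reported) >= 2) == 28
    for r in reports:
        r.outcome = case_outcome(r)
    return ReferenceCohort(panel=panel, reports=reports)
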