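"""Readers for annotated VCF, PED pedigrees and case tables.

VCF records are decomposed to one alt allele per record, trimmed to a
minimal representation and joined with a sidecar annotation table (gene,
consequence, population frequencies, in-silico votes, clinical-database
assertions, CNV flags).  Coordinates are 1-based VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import SuspicionCategory, normalize_chromosome

log = logging.getLogger(__name__)


class VariantIOError(ValueError):
    """Raised for malformed VCF/PED/annotation inputs."""


# ---------------------------------------------------------------------------
# Genotype and variant model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """A single sample's call at one site.

    ``alleles`` holds allele indices (0 = ref, 1 = alt, ``None`` = missing)
    after decomposition; haploid calls carry a single index plus ``None``.
    """

    sample_id: str
    alleles: tuple[int | None, int | None]
    depth: int | None = None
    alt_depth: int | None = None
    quality: float | None = None

    def __post_init__(self) -> None:
        if (
            self.depth is not None
            and self.alt_depth is not None
            and not 0 <= self.alt_depth <= self.depth
        ):
            raise VariantIOError(
                f"{self.sample_id}: alt_depth {self.alt_depth} outside "
                f"[0, depth={self.depth}]"
            )

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def alt_allele_count(self) -> int:
        return sum(1 for a in self.alleles if a is not None and a > 0)

    @property
    def called_allele_count(self) -> int:
        return sum(1 for a in self.alleles if a is not None)

    @property
    def carries_alt(self) -> bool:
        return self.alt_allele_count > 0

    @property
    def is_hom_ref(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return bool(called) and all(a == 0 for a in called)

    @property
    def alt_fraction(self) -> float | None:
        """Alt-supporting read fraction; ``None`` when depth is 0/unknown."""
        if self.depth is None or self.depth == 0 or self.alt_depth is None:
            return None
        return self.alt_depth / self.depth


VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "indel",
    "splice",
    "CNV",
    "synonymous",
    "other",
)

#: Reportable classes never include synonymous/other (see filters module).
DEFAULT_CLASS_MAP: dict[str, str] = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "frameshift_variant": "frameshift",
    "inframe_insertion": "indel",
    "inframe_deletion": "indel",
    "splice_donor_variant": "splice",
    "splice_acceptor_variant": "splice",
    "splice_region_variant": "splice",
    "synonymous_variant": "synonymous",
    "start_lost": "nonsense",
    "stop_lost": "other",
}

#: Consequence terms counted as canonical (±1-2) splice-site disruption.
CANONICAL_SPLICE_TERMS = frozenset(
    {"splice_donor_variant", "splice_acceptor_variant"}
)


def classify_variant_class(
    consequence: str,
    is_cnv: bool = False,
    ref: str = "",
    alt: str = "",
    class_map: Mapping[str, str] | None = None,
) -> str:
    """Map an annotation consequence term to one of the 8 variant classes.

    Total and deterministic: the CNV flag dominates any consequence term;
    generic insertion/deletion terms fall back to indel length (frame
    preserved → indel, otherwise frameshift); everything unmapped → other.
    """
    if is_cnv:
        return "CNV"
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    term = (consequence or "unknown").strip().lower()
    if term in cmap:
        return cmap[term]
    if term in {"insertion", "deletion", "indel"} and ref and alt:
        return "indel" if (len(ref) - len(alt)) % 3 == 0 else "frameshift"
    return "other"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized variant call (single alt) plus its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "unknown"
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    insilico: Mapping[str, str] = field(default_factory=dict)
    known_pathogenic_same_change: bool = False
    is_cnv: bool = False
    cnv_type: str = "none"
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"position must be >= 1, got {self.pos}")
        for db, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise VariantIOError(
                    f"{self.key}: {db} frequency {f} outside [0, 1]"
                )
        if self.cnv_type not in {"loss", "gain", "none"}:
            raise VariantIOError(f"invalid cnv_type {self.cnv_type!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def variant_class(self) -> str:
        return classify_variant_class(
            self.consequence, self.is_cnv, self.ref, self.alt
        )

    def genotype(self, sample_id: str) -> GenotypeCall | None:
        return self.genotypes.get(sample_id)


def minimal_representation(
    pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base each.

    Left-alignment proper requires the reference sequence; suffix/prefix
    trimming yields the minimal representation for already-normalised
    inputs and is idempotent.
    """
    ref, alt = ref.upper(), alt.upper()
    if alt.startswith("<"):  # symbolic allele, leave untouched
        return pos, ref, alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Sidecar annotation table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "freq_1kg",
    "freq_exac",
    "insilico",
    "known_pathogenic",
    "is_cnv",
    "cnv_type",
]


@dataclass
class AnnotationSpec:
    """Where variant annotations come from and how terms map to classes."""

    sidecar: Path | None = None
    class_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )


def _parse_insilico(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    raw = (raw or "").strip()
    if not raw or raw == ".":
        return out
    for tok in raw.split(","):
        if ":" not in tok:
            continue
        tool, vote = tok.split(":", 1)
        vote = vote.strip().lower()
        if vote not in {"deleterious", "tolerated", "unknown"}:
            vote = "unknown"
        out[tool.strip()] = vote
    return out


def read_annotation_sidecar(path: str | Path) -> dict[str, dict]:
    """Read a sidecar annotation TSV keyed by ``chrom:pos:ref:alt``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(".")
    missing = [c for c in ANNOTATION_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise VariantIOError(f"{path}: annotation table missing {missing}")
    table: dict[str, dict] = {}
    for _, row in df.iterrows():
        chrom = normalize_chromosome(str(row["chrom"]))
        key = f"{chrom}:{row['pos']}:{row['ref']}:{row['alt']}"
        if key in table:
            raise VariantIOError(f"{path}: annotation key collision at {key}")
        freqs: dict[str, float] = {}
        for col, db in (("freq_1kg", "1KG"), ("freq_exac", "ExAC")):
            raw = str(row.get(col, ".")).strip()
            if raw not in {".", "", "nan"}:
                freqs[db] = float(raw)
        table[key] = {
            "gene": "" if row["gene"] == "." else str(row["gene"]),
            "consequence": (
                "unknown" if row["consequence"] == "." else str(row["consequence"])
            ),
            "transcript": "" if row["transcript"] == "." else str(row["transcript"]),
            "hgvs_c": "" if str(row.get("hgvs_c", ".")) == "." else str(row["hgvs_c"]),
            "hgvs_p": "" if str(row.get("hgvs_p", ".")) == "." else str(row["hgvs_p"]),
            "pop_freqs": freqs,
            "insilico": _parse_insilico(str(row.get("insilico", "."))),
            "known_pathogenic_same_change": str(row.get("known_pathogenic", "false"))
            .strip()
            .lower()
            in {"true", "1", "yes"},
            "is_cnv": str(row.get("is_cnv", "false")).strip().lower()
            in {"true", "1", "yes"},
            "cnv_type": (
                str(row["cnv_type"])
                if str(row.get("cnv_type", ".")) not in {".", "", "nan"}
                else "none"
            ),
        }
    return table


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2)
# ---------------------------------------------------------------------------


def _int_or_none(value) -> int | None:
    try:
        v = int(value)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def read_vcf(
    path: str | Path,
    annotation_spec: AnnotationSpec | None = None,
) -> list[AnnotatedVariant]:
    """Read a VCF (v4.2, plain or bgzipped) into annotated variants.

    Multi-allelic records are decomposed into one variant per alt allele;
    for each decomposed alt, other alt alleles in a genotype are recoded
    as ref.  Per-sample depth/alt-depth come from DP/AD.  Records absent
    from the sidecar annotation table keep consequence ``unknown`` and are
    logged, never dropped.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = annotation_spec or AnnotationSpec()
    ann_table: dict[str, dict] = {}
    if spec.sidecar is not None:
        ann_table = read_annotation_sidecar(spec.sidecar)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VariantIOError(f"{path}: VCF has no sample columns / GT field")
    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        chrom = normalize_chromosome(rec.CHROM)
        alts = rec.ALT or []
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        gq = None
        try:
            gq = rec.format("GQ")
        except KeyError:
            pass
        for alt_idx, alt in enumerate(alts):
            alt_code = alt_idx + 1
            genotypes: dict[str, GenotypeCall] = {}
            for si, sample in enumerate(samples):
                raw = rec.genotypes[si]
                allele_idxs = [a for a in raw[:-1]]
                coded: list[int | None] = []
                for a in allele_idxs:
                    if a is None or a < 0:
                        coded.append(None)
                    elif a == alt_code:
                        coded.append(1)
                    else:
                        coded.append(0)
                while len(coded) < 2:
                    coded.append(None)
                depth = _int_or_none(dp[si][0]) if dp is not None else None
                alt_depth = None
                if ad is not None:
                    row = ad[si]
                    if len(row) > alt_code:
                        alt_depth = _int_or_none(row[alt_code])
                if (
                    depth is not None
                    and alt_depth is not None
                    and alt_depth > depth
                ):
                    alt_depth = depth
                quality = None
                if gq is not None:
                    try:
                        quality = float(gq[si][0])
                    except (TypeError, ValueError):
                        quality = None
                genotypes[sample] = GenotypeCall(
                    sample_id=sample,
                    alleles=(coded[0], coded[1]),
                    depth=depth,
                    alt_depth=alt_depth,
                    quality=quality,
                )
            pos, ref, alt_n = minimal_representation(rec.POS, rec.REF, alt)
            key = f"{chrom}:{pos}:{ref}:{alt_n}"
            ann = ann_table.get(key)
            if ann is None and spec.sidecar is not None:
                log.warning("no annotation for %s; marking consequence unknown", key)
            ann = ann or {}
            variants.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    genotypes=genotypes,
                    **{
                        k: ann.get(k, default)
                        for k, default in (
                            ("gene", ""),
                            ("consequence", "unknown"),
                            ("transcript", ""),
                            ("hgvs_c", ""),
                            ("hgvs_p", ""),
                            ("pop_freqs", {}),
                            ("insilico", {}),
                            ("known_pathogenic_same_change", False),
                            ("is_cnv", False),
                            ("cnv_type", "none"),
                        )
                    },
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Pedigrees (6-column PED)
# ---------------------------------------------------------------------------


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affected(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Affected


@dataclass
class Pedigree:
    members: dict[str, PedigreeMember]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.members

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        """(father_id, mother_id); ids not present as members become None."""
        m = self.members.get(sample_id)
        if m is None:
            return None, None
        father = m.father_id if m.father_id in self.members else None
        mother = m.mother_id if m.mother_id in self.members else None
        return father, mother

    def _check_acyclic(self) -> None:
        for start in self.members:
            seen: set[str] = set()
            stack = list(p for p in self.parents_of(start) if p is not None)
            while stack:
                cur = stack.pop()
                if cur == start:
                    raise VariantIOError(f"pedigree cycle involving {start!r}")
                if cur in seen:
                    continue
                seen.add(cur)
                stack.extend(p for p in self.parents_of(cur) if p is not None)


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PED_AFFECTED = {"2": Affected.YES, "1": Affected.NO, "0": Affected.UNKNOWN}


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Parent ids not present as individuals are kept but treated as missing
    when resolving trios (real clinical pedigrees often lack genotyped
    parents).  Self-parentage or ancestry cycles are hard errors.
    """
    members: dict[str, PedigreeMember] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise VariantIOError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        _fam, sid, father, mother, sex, aff = cols[:6]
        if sid in {father, mother}:
            raise VariantIOError(f"{path}:{lineno}: {sid!r} is its own parent")
        if sid in members:
            raise VariantIOError(f"{path}:{lineno}: duplicate individual {sid!r}")
        members[sid] = PedigreeMember(
            sample_id=sid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_PED_SEX.get(sex, Sex.UNKNOWN),
            affected=_PED_AFFECTED.get(aff, Affected.UNKNOWN),
        )
    ped = Pedigree(members=members)
    ped._check_acyclic()
    for m in members.values():
        for parent in (m.father_id, m.mother_id):
            if parent is not None and parent not in members:
                log.warning(
                    "pedigree parent %r of %r not genotyped; treated as missing",
                    parent,
                    m.sample_id,
                )
    return ped


# ---------------------------------------------------------------------------
# Case table
# ---------------------------------------------------------------------------


class AgeGroup(str, Enum):
    PAEDIATRIC = "paediatric"
    ADULT = "adult"


class EligibilityCategory(str, Enum):
    FAMILY_HISTORY = "FAMILY_HISTORY"
    CONFIRM_DIAGNOSIS = "CONFIRM_DIAGNOSIS"
    NO_DIAGNOSIS = "NO_DIAGNOSIS"


@dataclass(frozen=True)
class Case:
    """One recruited proband and its clinical context."""

    case_id: str
    proband: str
    sex: Sex
    age_group: AgeGroup
    suspicion: SuspicionCategory
    family_history: bool = False
    eligibility_category: EligibilityCategory = EligibilityCategory.NO_DIAGNOSIS

    def __post_init__(self) -> None:
        if self.sex not in (Sex.MALE, Sex.FEMALE):
            raise VariantIOError(f"{self.case_id}: proband sex must be male/female")


CASE_COLUMNS = [
    "case_id",
    "proband",
    "sex",
    "age_group",
    "suspicion",
    "family_history",
    "eligibility_category",
]


def read_case_table(path: str | Path) -> list[Case]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in CASE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise VariantIOError(f"{path}: case table missing columns {missing}")
    cases = []
    for _, row in df.iterrows():
        cases.append(
            Case(
                case_id=str(row["case_id"]),
                proband=str(row["proband"]),
                sex=Sex(str(row["sex"]).lower()),
                age_group=AgeGroup(str(row["age_group"]).lower()),
                suspicion=SuspicionCategory(str(row["suspicion"])),
                family_history=str(row.get("family_history", "false")).lower()
                in {"true", "1", "yes"},
                eligibility_category=EligibilityCategory(
                    str(row.get("eligibility_category", "NO_DIAGNOSIS"))
                ),
            )
        )
    return cases


def write_case_table(cases: Sequence[Case], path: str | Path) -> None:
    rows = [
        {
            "case_id": c.case_id,
            "proband": c.proband,
            "sex": c.sex.value,
            "age_group": c.age_group.value,
            "suspicion": c.suspicion.value,
            "family_history": str(c.family_history).lower(),
            "eligibility_category": c.eligibility_category.value,
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, sep="\t", index=False)
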