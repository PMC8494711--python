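"""Shared fixtures: panels, variant factories, hypothesis settings."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from nephroprior.panel import (
    GeneEntry,
    InheritanceMode,
    Panel,
    SuspicionCategory,
    fixture_panel,
)
from nephroprior.variant_io import AnnotatedVariant, Case, GenotypeCall, Sex, AgeGroup


@pytest.fixture(scope="session")
def panel() -> Panel:
    return fixture_panel()


def make_genotype(
    sample="P1",
    alleles=(0, 1),
    depth=60,
    alt_depth=28,
):
    return GenotypeCall(
        sample_id=sample, alleles=alleles, depth=depth, alt_depth=alt_depth
    )


def make_variant(
    gene="PKD1",
    chrom="16",
    pos=1000,
    ref="A",
    alt="G",
    consequence="missense_variant",
    pop_freqs=None,
    insilico=None,
    known=False,
    is_cnv=False,
    cnv_type="none",
    proband="P1",
    alleles=(0, 1),
    depth=60,
    alt_depth=28,
    extra_genotypes=None,
) -> AnnotatedVariant:
    genotypes = {
        proband: make_genotype(proband, alleles, depth, alt_depth)
    }
    if extra_genotypes:
        genotypes.update(extra_genotypes)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        pop_freqs=pop_freqs or {},
        insilico=insilico or {},
        known_pathogenic_same_change=known,
        is_cnv=is_cnv,
        cnv_type=cnv_type,
        genotypes=genotypes,
    )


def make_case(
    case_id="CASE1",
    proband="P1",
    sex=Sex.FEMALE,
    age_group=AgeGroup.ADULT,
    suspicion=SuspicionCategory.CILIOPATHY,
) -> Case:
    return Case(
        case_id=case_id,
        proband=proband,
        sex=sex,
        age_group=age_group,
        suspicion=suspicion,
    )


def make_gene(
    symbol="GENE1",
    chromosome="1",
    modes=frozenset({InheritanceMode.AD}),
    categories=frozenset({SuspicionCategory.GLOMERULAR}),
    digenic_partners=frozenset(),
    lof_mechanism=True,
) -> GeneEntry:
    return GeneEntry(
        symbol=symbol,
        chromosome=chromosome,
        modes=frozenset(modes),
        categories=frozenset(categories),
        digenic_partners=frozenset(digenic_partners),
        lof_mechanism=lof_mechanism,
    )
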