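"""Zygosity, compound-het phase, digenic pairs and trio segregation."""

import itertools

import pytest

from nephroprior.inheritance import (
    BiallelicStatus,
    CandidateSet,
    SegregationResult,
    Zygosity,
    assign_zygosity,
    build_candidate_set,
    detect_compound_het,
    digenic_recheck,
    moi_compatible,
    segregate,
)
from nephroprior.panel import InheritanceMode, Panel, SuspicionCategory
from nephroprior.variant_io import GenotypeCall, Sex

from conftest import make_gene, make_genotype


def gt(alleles, depth=30):
    alt = sum(1 for a in alleles if a == 1)
    ad = 0 if alt == 0 else depth // 2 if alt == 1 else depth
    return GenotypeCall("S", alleles, depth=depth, alt_depth=min(ad, depth))


class TestAssignZygosity:
    @pytest.mark.parametrize(
        "alleles,chrom,sex,expected",
        [
            ((0, 1), "7", Sex.FEMALE, Zygosity.HET),
            ((1, 1), "7", Sex.FEMALE, Zygosity.HOM),
            ((1, 1), "X", Sex.MALE, Zygosity.HEMI),
            ((1, None), "X", Sex.MALE, Zygosity.HEMI),
            ((0, 1), "X", Sex.FEMALE, Zygosity.HET),
            ((1, 1), "X", Sex.FEMALE, Zygosity.HOM),
        ],
    )
    def test_rules(self, alleles, chrom, sex, expected):
        assert assign_zygosity(gt(alleles), chrom, sex).zygosity == expected

    def test_het_x_in_male_coerced_to_hemi_with_warning(self):
        call = assign_zygosity(gt((0, 1)), "X", Sex.MALE)
        assert call.zygosity == Zygosity.HEMI
        assert call.warning is not None

    def test_missing_genotype_yields_unknown(self):
        call = assign_zygosity(
            GenotypeCall("S", (None, None)), "7", Sex.FEMALE
        )
        assert call.zygosity == Zygosity.UNKNOWN


# ---------------------------------------------------------------------------
# segregation truth-table oracle, coded independently of the implementation
# ---------------------------------------------------------------------------

PARENT_GTS = [None, (0, 0), (0, 1), (1, 1)]
DEPTHS = [10, 30]  # below / at-or-above the 20x de novo gate


def oracle_segregation(proband_alleles, mother, father, min_depth=20):
    """Nested-if reference built from Mendelian first principles."""

    def carries(p):
        return p is not None and any(a == 1 for a in p[0])

    def hom_ref(p):
        return p is not None and all(a == 0 for a in p[0])

    def deep(p):
        return p is not None and p[1] >= min_depth

    proband_hom = all(a == 1 for a in proband_alleles if a is not None) and (
        sum(1 for a in proband_alleles if a == 1) >= 2
    )
    if proband_hom:
        if (hom_ref(mother) and deep(mother)) or (hom_ref(father) and deep(father)):
            return SegregationResult.INCONSISTENT
    if mother is None or father is None:
        return SegregationResult.UNKNOWN
    if carries(mother) and carries(father):
        return SegregationResult.BIPARENTAL
    if carries(mother):
        return SegregationResult.INHERITED_MATERNAL
    if carries(father):
        return SegregationResult.INHERITED_PATERNAL
    if deep(mother) and deep(father):
        return SegregationResult.DE_NOVO
    return SegregationResult.UNKNOWN


class TestSegregate:
    @pytest.mark.parametrize("proband_alleles", [(0, 1), (1, 1)])
    def test_matches_exhaustive_trio_truth_table(self, proband_alleles):
        """All parental genotype x depth combinations, het and hom proband."""
        proband = gt(proband_alleles, depth=50)
        for (mg, md), (fg, fd) in itertools.product(
            itertools.product(PARENT_GTS, DEPTHS), repeat=2
        ):
            mother = None if mg is None else gt(mg, md)
            father = None if fg is None else gt(fg, fd)
            expected = oracle_segregation(
                proband_alleles,
                None if mg is None else (mg, md),
                None if fg is None else (fg, fd),
            )
            got = segregate(proband, mother, father)
            assert got == expected, (proband_alleles, mg, md, fg, fd)

    def test_de_novo_requires_parental_depth(self):
        proband = gt((0, 1), 60)
        assert (
            segregate(proband, gt((0, 0), 30), gt((0, 0), 25))
            == SegregationResult.DE_NOVO
        )
        assert (
            segregate(proband, gt((0, 0), 10), gt((0, 0), 25))
            == SegregationResult.UNKNOWN
        )

    def test_hom_proband_with_confident_noncarrier_parent_is_inconsistent(self):
        got = segregate(gt((1, 1), 60), gt((0, 1), 40), gt((0, 0), 40))
        assert got == SegregationResult.INCONSISTENT

    def test_missing_parent_is_unknown(self):
        assert (
            segregate(gt((0, 1), 60), gt((0, 1), 40), None)
            == SegregationResult.UNKNOWN
        )

    def test_requires_a_carrier_proband(self):
        with pytest.raises(ValueError):
            segregate(gt((0, 0), 60), gt((0, 1), 40), gt((0, 0), 40))


SEG = SegregationResult


class TestDetectCompoundHet:
    def test_trans_pair_is_confirmed(self):
        status = detect_compound_het(
            [Zygosity.HET, Zygosity.HET],
            [SEG.INHERITED_MATERNAL, SEG.INHERITED_PATERNAL],
        )
        assert status == BiallelicStatus.COMPOUND_HET_CONFIRMED

    def test_cis_pair_collapses_to_monoallelic(self):
        status = detect_compound_het(
            [Zygosity.HET, Zygosity.HET],
            [SEG.INHERITED_MATERNAL, SEG.INHERITED_MATERNAL],
        )
        assert status == BiallelicStatus.MONOALLELIC

    def test_two_hets_without_pedigree_are_putative(self):
        assert (
            detect_compound_het([Zygosity.HET, Zygosity.HET])
            == BiallelicStatus.COMPOUND_HET_PUTATIVE
        )

    def test_hom_dominates_mixed_calls(self):
        assert (
            detect_compound_het([Zygosity.HET, Zygosity.HOM])
            == BiallelicStatus.HOM
        )

    def test_single_het_is_monoallelic(self):
        assert detect_compound_het([Zygosity.HET]) == BiallelicStatus.MONOALLELIC

    def test_never_confirmed_without_phase(self):
        """Enumerate all origin pairs: CONFIRMED needs both parents."""
        origins = [SEG.INHERITED_MATERNAL, SEG.INHERITED_PATERNAL,
                   SEG.UNKNOWN, SEG.BIPARENTAL, SEG.DE_NOVO]
        for s1, s2 in itertools.product(origins, repeat=2):
            status = detect_compound_het([Zygosity.HET, Zygosity.HET], [s1, s2])
            informative = {s1, s2} & {SEG.INHERITED_MATERNAL, SEG.INHERITED_PATERNAL}
            if status == BiallelicStatus.COMPOUND_HET_CONFIRMED:
                assert informative == {
                    SEG.INHERITED_MATERNAL,
                    SEG.INHERITED_PATERNAL,
                }

    def test_requires_at_least_one_variant(self):
        with pytest.raises(ValueError):
            detect_compound_het([])


def candidate(zygosities, status):
    return CandidateSet(gene="G", zygosities=tuple(zygosities), biallelic_status=status)


class TestMoiCompatible:
    def test_single_het_in_dominant_gene(self):
        g = make_gene(modes={InheritanceMode.AD})
        got = moi_compatible(
            candidate([Zygosity.HET], BiallelicStatus.MONOALLELIC), g, Sex.FEMALE
        )
        assert got == {InheritanceMode.AD}

    def test_putative_compound_het_in_recessive_gene(self):
        g = make_gene(modes={InheritanceMode.AR})
        got = moi_compatible(
            candidate(
                [Zygosity.HET, Zygosity.HET],
                BiallelicStatus.COMPOUND_HET_PUTATIVE,
            ),
            g,
            Sex.FEMALE,
        )
        assert got == {InheritanceMode.AR}

    def test_single_het_in_recessive_only_gene_is_incompatible(self):
        g = make_gene(modes={InheritanceMode.AR})
        got = moi_compatible(
            candidate([Zygosity.HET], BiallelicStatus.MONOALLELIC), g, Sex.FEMALE
        )
        assert got == frozenset()

    def test_xl_male_hemizygote(self):
        g = make_gene(chromosome="X", modes={InheritanceMode.XL})
        got = moi_compatible(
            candidate([Zygosity.HEMI], BiallelicStatus.HOM), g, Sex.MALE
        )
        assert got == {InheritanceMode.XL}

    def test_xl_female_het_is_carrier_only(self):
        g = make_gene(chromosome="X", modes={InheritanceMode.XL})
        got = moi_compatible(
            candidate([Zygosity.HET], BiallelicStatus.MONOALLELIC), g, Sex.FEMALE
        )
        assert got == frozenset()

    def test_xl_female_homozygote_is_compatible(self):
        g = make_gene(chromosome="X", modes={InheritanceMode.XL})
        got = moi_compatible(
            candidate([Zygosity.HOM], BiallelicStatus.HOM), g, Sex.FEMALE
        )
        assert got == {InheritanceMode.XL}

    def test_output_is_subset_of_expanded_gene_modes(self):
        g = make_gene(modes={InheritanceMode.AD_AR})
        got = moi_compatible(
            candidate([Zygosity.HOM], BiallelicStatus.HOM), g, Sex.FEMALE
        )
        assert got <= g.compatible_modes
        assert got == {InheritanceMode.AD, InheritanceMode.AR}


class TestDigenicRecheck:
    def _panel(self, partner_map):
        entries = {}
        for sym, partners in partner_map.items():
            entries[sym] = make_gene(
                sym, modes={InheritanceMode.AR}, digenic_partners=frozenset(partners)
            )
        return Panel(entries=entries, version="v1")

    def test_mutual_partners_reported_once(self):
        p = self._panel({"A": {"B"}, "B": {"A"}})
        assert digenic_recheck({"A", "B"}, p) == [("A", "B")]

    def test_unrelated_genes_yield_nothing(self):
        p = self._panel({"A": set(), "B": set()})
        assert digenic_recheck({"A", "B"}, p) == []

    def test_three_pairwise_partners_give_three_pairs(self):
        p = self._panel({"A": {"B", "C"}, "B": {"A", "C"}, "C": {"A", "B"}})
        assert digenic_recheck({"A", "B", "C"}, p) == [
            ("A", "B"),
            ("A", "C"),
            ("B", "C"),
        ]

    def test_empty_partner_table_is_always_empty(self, panel):
        genes_without_partners = [
            s for s, e in panel.entries.items() if not e.digenic_partners
        ]
        assert digenic_recheck(genes_without_partners, panel) == []

    def test_one_sided_partner_listing_still_pairs(self):
        p = self._panel({"A": {"B"}, "B": set()})
        assert digenic_recheck({"A", "B"}, p) == [("A", "B")]
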