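"""Report-inclusion policy, case outcome and panel-update re-analysis."""

import itertools

import pytest

from nephroprior.classify import ClassTier, EvidenceCriterion, make_classified
from nephroprior.inheritance import BiallelicStatus, Zygosity
from nephroprior.panel import (
    GeneEntry,
    InheritanceMode,
    Panel,
    SuspicionCategory,
)
from nephroprior.report import (
    OUTCOME_DIAGNOSED,
    OUTCOME_NOT_DIAGNOSED,
    build_case_report,
    case_outcome,
    include_in_report,
    phenotype_match,
    read_report,
    reanalyze,
    report_from_dict,
    report_to_dict,
)
from nephroprior.variant_io import Sex
from nephroprior.filters import two_pass_prioritize

from conftest import make_case, make_gene, make_variant

E = EvidenceCriterion

_EVIDENCE_FOR_TIER = {
    ClassTier.C5: {E.PVS1, E.PS1, E.PM2},
    ClassTier.C4: {E.PVS1, E.PM2},
    ClassTier.C3: {E.PM2},
    ClassTier.C2: {E.BS1, E.BP4},
    ClassTier.C1: {E.BA1},
}


def classified(tier, zygosity=Zygosity.HET, status=BiallelicStatus.MONOALLELIC):
    kwargs = {}
    if tier in (ClassTier.C5, ClassTier.C4):
        kwargs = dict(consequence="stop_gained", ref="C", alt="T")
        if tier == ClassTier.C5:
            kwargs["known"] = True
    if tier == ClassTier.C1:
        kwargs = dict(pop_freqs={"1KG": 0.06})
    if tier == ClassTier.C2:
        kwargs = dict(
            pop_freqs={"1KG": 0.02},
            insilico={"SIFT": "tolerated", "PolyPhen2": "tolerated"},
        )
    v = make_variant(**kwargs)
    return make_classified(v, zygosity, _EVIDENCE_FOR_TIER[tier],
                           biallelic_status=status)


MODE_SETS = [
    frozenset({InheritanceMode.AD}),
    frozenset({InheritanceMode.AR}),
    frozenset({InheritanceMode.XL}),
    frozenset({InheritanceMode.AD_AR}),
    frozenset({InheritanceMode.AR, InheritanceMode.XL}),
]


def oracle_include(tier, modes, sex, match):
    """Clause-by-clause transcription of the reporting policy sentence."""
    if tier in (ClassTier.C5, ClassTier.C4):
        return True  # always included
    if tier in (ClassTier.C1, ClassTier.C2):
        return False  # never reported
    # C3 clauses
    expanded = set()
    for m in modes:
        expanded |= m.expand()
    if InheritanceMode.AD in expanded:
        return True  # AD genes: always
    if InheritanceMode.XL in modes and sex == Sex.MALE:
        return True  # X-linked recessive, males only
    if expanded == {InheritanceMode.AR} or InheritanceMode.AR in expanded:
        return match  # recessive: only in line with the phenotype
    return False


class TestIncludeInReport:
    def test_exhaustive_truth_table(self):
        """Every tier x mode-set x sex x phenotype-match combination."""
        for tier, modes, sex, match in itertools.product(
            ClassTier, MODE_SETS, (Sex.MALE, Sex.FEMALE), (True, False)
        ):
            chrom = "X" if InheritanceMode.XL in modes else "1"
            gene = make_gene("G", chrom, modes=modes)
            cv = classified(tier)
            got, rationale = include_in_report(
                cv, gene, sex, cv.biallelic_status, match
            )
            expected = oracle_include(tier, modes, sex, match)
            assert got == expected, (tier, sorted(m.value for m in modes), sex, match)
            assert rationale

    @pytest.mark.parametrize("tier", [ClassTier.C5, ClassTier.C4])
    def test_pathogenic_always_included(self, tier):
        gene = make_gene(modes={InheritanceMode.AR})
        included, _ = include_in_report(
            classified(tier), gene, Sex.FEMALE, BiallelicStatus.MONOALLELIC, False
        )
        assert included

    def test_c3_in_xl_gene_excluded_for_female_proband(self):
        gene = make_gene("OCRL", "X", modes={InheritanceMode.XL})
        included, _ = include_in_report(
            classified(ClassTier.C3), gene, Sex.FEMALE,
            BiallelicStatus.MONOALLELIC, True,
        )
        assert not included

    def test_c3_in_ar_gene_needs_phenotype_match(self):
        gene = make_gene(modes={InheritanceMode.AR})
        cv = classified(ClassTier.C3, Zygosity.HOM, BiallelicStatus.HOM)
        yes, _ = include_in_report(cv, gene, Sex.FEMALE, BiallelicStatus.HOM, True)
        no, _ = include_in_report(cv, gene, Sex.FEMALE, BiallelicStatus.HOM, False)
        assert yes and not no


class TestPhenotypeMatch:
    def test_category_and_biallelic_requirements(self):
        gene = make_gene(
            modes={InheritanceMode.AR},
            categories={SuspicionCategory.CILIOPATHY},
        )
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        assert phenotype_match(gene, case, BiallelicStatus.HOM)
        assert not phenotype_match(gene, case, BiallelicStatus.MONOALLELIC)

    def test_mismatched_category(self):
        gene = make_gene(categories={SuspicionCategory.CILIOPATHY})
        case = make_case(suspicion=SuspicionCategory.GLOMERULAR)
        assert not phenotype_match(gene, case, BiallelicStatus.MONOALLELIC)

    def test_unknown_origin_matches_any_gene_but_keeps_ar_rule(self):
        ar_gene = make_gene("A", modes={InheritanceMode.AR},
                            categories={SuspicionCategory.TUBULAR})
        case = make_case(suspicion=SuspicionCategory.UNKNOWN_ORIGIN)
        assert phenotype_match(ar_gene, case, BiallelicStatus.HOM)
        assert not phenotype_match(ar_gene, case, BiallelicStatus.MONOALLELIC)


class TestCaseReportAssembly:
    def test_diagnosed_case_with_one_pathogenic_matched_variant(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        v = make_variant(gene="PKD1", chrom="16", consequence="stop_gained",
                         ref="C", alt="T", known=True)
        result = two_pass_prioritize(case, panel, [v])
        report = build_case_report(case, result, panel)
        assert report.outcome == OUTCOME_DIAGNOSED
        assert len(report.reported) == 1

    def test_included_but_mismatched_variant_does_not_diagnose(self, panel):
        # C3 in an AD CAKUT gene, ciliopathy case: included, not diagnostic
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        v = make_variant(gene="EYA1", chrom="8", pos=50)
        result = two_pass_prioritize(case, panel, [v])
        report = build_case_report(case, result, panel)
        assert len(report.reported) == 1
        assert not report.reported[0].phenotype_match
        assert report.outcome == OUTCOME_NOT_DIAGNOSED

    def test_empty_report_is_not_diagnosed(self, panel):
        case = make_case()
        result = two_pass_prioritize(case, panel, [])
        report = build_case_report(case, result, panel)
        assert report.outcome == OUTCOME_NOT_DIAGNOSED
        assert case_outcome(report) == OUTCOME_NOT_DIAGNOSED

    def test_every_survivor_reported_or_excluded_exactly_once(self, panel):
        case = make_case(suspicion=SuspicionCategory.UNKNOWN_ORIGIN)
        variants = [
            make_variant(gene="PKD1", chrom="16", pos=1),
            # monoallelic C3 in an AR-only gene: classified then excluded
            make_variant(gene="PKHD1", chrom="6", pos=2),
        ]
        result = two_pass_prioritize(case, panel, variants)
        report = build_case_report(case, result, panel)
        keys = sorted(
            [rv.cv.key for rv in report.reported]
            + [ev.cv.key for ev in report.excluded]
        )
        assert keys == sorted(cv.key for cv in result.survivors)
        assert len(report.excluded) == 1
        assert report.excluded[0].cv.gene == "PKHD1"


class TestReanalyze:
    def _small_panel(self, with_gene_b):
        entries = {
            "GENEA": make_gene("GENEA", "1",
                               categories={SuspicionCategory.GLOMERULAR}),
        }
        if with_gene_b:
            entries["GENEB"] = make_gene(
                "GENEB", "2", categories={SuspicionCategory.GLOMERULAR}
            )
        return Panel(entries=entries, version="v2" if with_gene_b else "v1")

    def test_panel_update_turns_a_negative_case_positive(self):
        case = make_case(suspicion=SuspicionCategory.GLOMERULAR)
        # likely pathogenic variant in a gene absent from the old panel
        v = make_variant(gene="GENEB", chrom="2", consequence="stop_gained",
                         ref="C", alt="T")
        old_panel = self._small_panel(with_gene_b=False)
        result = two_pass_prioritize(case, old_panel, [v])
        old_report = build_case_report(case, result, old_panel)
        assert old_report.outcome == OUTCOME_NOT_DIAGNOSED

        new_panel = self._small_panel(with_gene_b=True)
        new_report = reanalyze(case, [v], old_report, new_panel)
        assert new_report.outcome == OUTCOME_DIAGNOSED
        assert new_report.previous_panel_version == "v1"
        assert new_report.panel_version == "v2"
        assert not new_report.reanalysis_of_diagnosed

    def test_identical_panel_reanalysis_is_idempotent(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        v = make_variant(gene="PKD1", chrom="16", consequence="stop_gained",
                         ref="C", alt="T", known=True)
        result = two_pass_prioritize(case, panel, [v])
        first = build_case_report(case, result, panel)
        second = reanalyze(case, [v], first, panel)
        body1, body2 = first.body_dict(), second.body_dict()
        body1.pop("previous_panel_version")
        body2.pop("previous_panel_version")
        body1.pop("reanalysis_of_diagnosed")
        body2.pop("reanalysis_of_diagnosed")
        assert body1 == body2

    def test_reanalysing_a_diagnosed_case_is_flagged(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        v = make_variant(gene="PKD1", chrom="16", consequence="stop_gained",
                         ref="C", alt="T", known=True)
        result = two_pass_prioritize(case, panel, [v])
        first = build_case_report(case, result, panel)
        assert first.outcome == OUTCOME_DIAGNOSED
        again = reanalyze(case, [v], first, panel)
        assert again.reanalysis_of_diagnosed


class TestSerialization:
    def test_report_json_round_trip(self, panel, tmp_path):
        from nephroprior.report import write_report

        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        v = make_variant(gene="PKD1", chrom="16", consequence="stop_gained",
                         ref="C", alt="T", known=True)
        result = two_pass_prioritize(case, panel, [v])
        report = build_case_report(case, result, panel, created="2020-01-01T00:00:00")
        path = tmp_path / "r.json"
        write_report(report, path)
        back = read_report(path)
        assert report_to_dict(back) == report_to_dict(report)
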