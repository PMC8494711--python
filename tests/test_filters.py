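"""Filter cascade predicates, audit trail and the two-pass stop rule."""

import numpy as np
import pytest

from nephroprior.filters import (
    DEFAULT_REPORTABLE_CLASSES,
    FilterConfig,
    FilterReason,
    PASS_FULL,
    PASS_TAILORED,
    filter_cascade,
    is_rare,
    is_reportable_class,
    passes_quality,
    two_pass_prioritize,
)
from nephroprior.classify import ClassTier
from nephroprior.panel import SuspicionCategory
from nephroprior.variant_io import Sex

from conftest import make_case, make_genotype, make_variant


class TestPassesQuality:
    @pytest.mark.parametrize(
        "depth,alt_depth,expected_reasons",
        [
            (20, 6, ()),  # 20x and 0.30 exactly: inclusive bounds pass
            (19, 10, (FilterReason.LOW_COVERAGE,)),
            (100, 29, (FilterReason.LOW_ALT_FRACTION,)),
            (10, 2, (FilterReason.LOW_COVERAGE, FilterReason.LOW_ALT_FRACTION)),
        ],
    )
    def test_inclusive_thresholds(self, depth, alt_depth, expected_reasons):
        ok, reasons = passes_quality(make_genotype(depth=depth, alt_depth=alt_depth))
        assert ok == (not expected_reasons)
        assert tuple(reasons) == expected_reasons

    def test_missing_depth_fails_with_both_reasons(self):
        from nephroprior.variant_io import GenotypeCall

        gt = GenotypeCall("P1", (0, 1), depth=None, alt_depth=None)
        ok, reasons = passes_quality(gt)
        assert not ok
        assert FilterReason.LOW_COVERAGE in reasons


class TestIsRare:
    def test_max_over_databases(self):
        v = make_variant(pop_freqs={"1KG": 0.005, "ExAC": 0.012})
        assert not is_rare(v)

    def test_one_percent_bound_is_inclusive(self):
        assert is_rare(make_variant(pop_freqs={"1KG": 0.01}))
        assert not is_rare(make_variant(pop_freqs={"1KG": 0.0101}))

    def test_absent_from_all_databases_counts_as_rare(self):
        assert is_rare(make_variant(pop_freqs={}))

    def test_frequency_outside_unit_interval_is_an_error(self):
        v = make_variant()
        object.__setattr__(v, "pop_freqs", {"1KG": 1.5})
        with pytest.raises(ValueError):
            is_rare(v)


class TestIsReportableClass:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("synonymous_variant", False),
            ("frameshift_variant", True),
            ("missense_variant", True),
            ("splice_donor_variant", True),
            ("inframe_deletion", True),
            ("unknown", False),
        ],
    )
    def test_class_policy(self, consequence, expected):
        assert is_reportable_class(make_variant(consequence=consequence)) == expected

    def test_cnv_calls_are_reportable(self):
        assert is_reportable_class(make_variant(is_cnv=True, cnv_type="loss"))


def _random_variants(rng, n, genes=("PKD1", "WT1", "OFFPANEL")):
    consequences = [
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "unknown",
    ]
    out = []
    for i in range(n):
        out.append(
            make_variant(
                gene=str(rng.choice(genes)),
                pos=1000 + i,
                consequence=str(rng.choice(consequences)),
                pop_freqs={"1KG": float(rng.choice([0.0, 0.005, 0.01, 0.02, 0.2]))},
                depth=int(rng.choice([5, 19, 20, 60])),
                alt_depth=0,
            )
        )
        v = out[-1]
        depth = v.genotype("P1").depth
        frac = float(rng.choice([0.1, 0.29, 0.3, 0.5]))
        object.__setattr__(
            v.genotypes["P1"], "alt_depth", int(round(depth * frac))
        )
    return out


def _oracle_survivors(variants, gene_set, cfg):
    """Independent set-intersection reference for the cascade."""
    reportable = {
        v.key for v in variants if v.variant_class in cfg.reportable_classes
    }
    quality = set()
    for v in variants:
        gt = v.genotype("P1")
        if (
            gt.depth is not None
            and gt.depth >= cfg.min_depth
            and gt.alt_fraction is not None
            and gt.alt_fraction >= cfg.min_alt_fraction
        ):
            quality.add(v.key)
    rare = {
        v.key
        for v in variants
        if not v.pop_freqs or max(v.pop_freqs.values()) <= cfg.max_pop_freq
    }
    on_panel = {v.key for v in variants if v.gene in gene_set}
    return reportable & quality & rare & on_panel


class TestFilterCascade:
    def test_six_planted_variants_example(self):
        """Four distinct single-failure decoys plus two clean survivors."""
        variants = [
            make_variant(gene="PKD1", pos=1, consequence="missense_variant"),
            make_variant(gene="PKD2", pos=2, consequence="stop_gained"),
            make_variant(gene="PKD1", pos=3, consequence="synonymous_variant"),
            make_variant(gene="PKD1", pos=4, depth=10, alt_depth=5),
            make_variant(gene="PKD1", pos=5, pop_freqs={"ExAC": 0.02}),
            make_variant(gene="NOTONPANEL", pos=6),
        ]
        gene_set = {"PKD1", "PKD2"}
        survivors, audit = filter_cascade(variants, "P1", gene_set)
        cfg = FilterConfig()
        assert {v.key for v in survivors} == _oracle_survivors(
            variants, gene_set, cfg
        )
        assert len(survivors) == 2
        failed = {o.key: o.reasons for o in audit if not o.passed}
        assert len(failed) == 4
        assert all(len(r) == 1 for r in failed.values())
        assert {r[0] for r in failed.values()} == {
            FilterReason.SYNONYMOUS_OR_NONREPORTABLE_CLASS,
            FilterReason.LOW_COVERAGE,
            FilterReason.COMMON_POLYMORPHISM,
            FilterReason.OFF_PANEL,
        }

    def test_empty_gene_set_is_a_precondition_error(self):
        with pytest.raises(ValueError):
            filter_cascade([make_variant()], "P1", set())

    def test_all_passing_audit(self):
        variants = [make_variant(pos=i) for i in range(1, 4)]
        survivors, audit = filter_cascade(variants, "P1", {"PKD1"})
        assert len(survivors) == 3
        assert all(o.passed and not o.reasons for o in audit)

    def test_every_variant_audited_exactly_once(self):
        rng = np.random.default_rng(1)
        variants = _random_variants(rng, 50)
        _, audit = filter_cascade(variants, "P1", {"PKD1"})
        assert sorted(o.key for o in audit) == sorted(v.key for v in variants)

    def test_matches_independent_predicate_intersection(self):
        rng = np.random.default_rng(42)
        variants = _random_variants(rng, 300)
        gene_set = {"PKD1", "WT1"}
        cfg = FilterConfig()
        survivors, _ = filter_cascade(variants, "P1", gene_set, cfg)
        assert {v.key for v in survivors} == _oracle_survivors(
            variants, gene_set, cfg
        )

    def test_survivor_set_is_order_independent(self):
        rng = np.random.default_rng(3)
        variants = _random_variants(rng, 40)
        s1, _ = filter_cascade(variants, "P1", {"PKD1", "WT1"})
        s2, _ = filter_cascade(list(reversed(variants)), "P1", {"PKD1", "WT1"})
        assert {v.key for v in s1} == {v.key for v in s2}

    def test_permissive_thresholds_reduce_to_the_class_filter(self):
        rng = np.random.default_rng(9)
        variants = _random_variants(rng, 100)
        cfg = FilterConfig(min_depth=0, min_alt_fraction=0.0, max_pop_freq=1.0)
        genes = {v.gene for v in variants}
        survivors, _ = filter_cascade(variants, "P1", genes, cfg)
        assert {v.key for v in survivors} == {
            v.key for v in variants if v.variant_class in DEFAULT_REPORTABLE_CLASSES
        }


class TestTwoPassPrioritize:
    def _tailored_hit(self):
        # C5: known-pathogenic nonsense in a LoF ciliopathy gene
        return make_variant(
            gene="PKD1", chrom="16", pos=10, ref="C", alt="T",
            consequence="stop_gained", known=True,
        )

    def _off_category(self):
        return make_variant(gene="WT1", chrom="11", pos=20, known=True,
                            consequence="stop_gained")

    def test_tailored_c5_stops_the_analysis(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        result = two_pass_prioritize(
            case, panel, [self._tailored_hit(), self._off_category()]
        )
        assert result.pass_used == PASS_TAILORED
        assert any(cv.tier == ClassTier.C5 for cv in result.survivors)
        # the off-category gene was never classified
        assert all(cv.gene != "WT1" for cv in result.survivors)
        assert all(rec.pass_name == PASS_TAILORED for rec in result.audit)

    def test_all_c3_tailored_pass_triggers_the_full_panel(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        c3 = make_variant(gene="PKD1", chrom="16", pos=10)  # novel missense
        off = make_variant(gene="WT1", chrom="11", pos=20)
        result = two_pass_prioritize(case, panel, [c3, off])
        assert result.pass_used == PASS_FULL
        assert {cv.gene for cv in result.survivors} == {"PKD1", "WT1"}

    def test_unknown_origin_runs_a_single_full_pass(self, panel):
        case = make_case(suspicion=SuspicionCategory.UNKNOWN_ORIGIN)
        result = two_pass_prioritize(case, panel, [self._tailored_hit()])
        assert result.pass_used == PASS_FULL
        assert {rec.pass_name for rec in result.audit} == {PASS_FULL}

    def test_tailored_survivors_subset_of_full_pass(self, panel):
        case = make_case(suspicion=SuspicionCategory.CILIOPATHY)
        variants = [self._tailored_hit(), self._off_category()]
        tailored = two_pass_prioritize(case, panel, variants)
        full = two_pass_prioritize(case, panel, variants, force_full_pass=True)
        assert {cv.key for cv in tailored.survivors} <= {
            cv.key for cv in full.survivors
        }

    def test_never_classifies_outside_the_active_gene_set(self, panel):
        case = make_case(suspicion=SuspicionCategory.GLOMERULAR)
        off = make_variant(gene="NOTAPANELGENE", pos=30, known=True,
                           consequence="stop_gained")
        result = two_pass_prioritize(case, panel, [off])
        assert result.survivors == []
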