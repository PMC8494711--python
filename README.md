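# nephroprior

Phenotype-tailored clinical-exome variant prioritization for monogenic
kidney disease.

A considerable fraction of chronic kidney disease is monogenic, yet many
patients — including candidates for transplantation — reach end-stage
disease without a molecular diagnosis.  Clinical-exome sequencing
followed by *in silico* analysis of a kidney-disease gene panel can
resolve a large share of these cases, provided the analysis is
disciplined: a phenotype-to-genotype gene list tailored to the clinical
suspicion, hard quality and frequency filters, explicit inheritance-mode
logic, and conservative reporting rules.  `nephroprior` implements that
workflow as a reusable Python library and CLI for nephrology-genetics
analysts and for anyone studying diagnostic-yield methodology.

## The pipeline

For a proband with suspicion *s*, annotated variants *V* and optional
trio pedigree:

1. **Tailored pass** over the genes G(s) of the panel tagged with *s*
   (unknown-origin cases use the full panel).  Each variant must satisfy
   all four predicates — reportable consequence class (synonymous calls
   are removed), coverage ≥ 20× and alt read fraction ≥ 0.3 (inclusive),
   population frequency ≤ 1% in 1KG/ExAC-style databases (absence counts
   as rare), and gene ∈ G(s).
2. **Classification** of survivors with a reduced, annotation-computable
   ACMG criterion set (PVS1, PS1, PS2, PM2, PM3, PP3, BP4, BS1, BA1)
   combined into tiers C1 (benign) … C5 (pathogenic).  Zygosity,
   compound-heterozygote phase from the trio, digenic partner re-checks
   of monoallelic recessive hits and trio segregation (de novo /
   maternal / paternal / inconsistent) feed the criteria.
3. **Stop rule**: a C4/C5 variant in the tailored pass ends the
   analysis; otherwise all panel genes are tested.
4. **Reporting**: C5/C4 always; C3 in dominant genes, in X-linked genes
   for males, and in recessive-only genes only when in line with the
   phenotype.  A case is diagnosed when a reported variant is both
   phenotype-compatible and inheritance-compatible.
5. **Cohort summaries** (diagnostic yield overall / by age group / by
   suspicion, variant class / tier / inheritance distributions) and
   **panel-update re-analysis** of archived negative cases without
   re-sequencing.

Every filtering decision is recorded in a per-variant, per-pass audit
trail.  See `docs/methods.md` for the full rule tables and modelling
choices.

## Worked example

```python
from nephroprior import fixture_panel, two_pass_prioritize, build_case_report
from nephroprior.variant_io import Case, Sex, AgeGroup, GenotypeCall, AnnotatedVariant
from nephroprior.panel import SuspicionCategory

panel = fixture_panel()
case = Case(case_id="DEMO-01", proband="P1", sex=Sex.FEMALE,
            age_group=AgeGroup.ADULT, suspicion=SuspicionCategory.CILIOPATHY)
variants = [
    # known-pathogenic PKD1 nonsense call, well covered
    AnnotatedVariant(chrom="16", pos=2185690, ref="C", alt="T", gene="PKD1",
                     consequence="stop_gained", known_pathogenic_same_change=True,
                     genotypes={"P1": GenotypeCall("P1", (0, 1), depth=62, alt_depth=29)}),
    # synonymous PKD1 call: filtered by class
    AnnotatedVariant(chrom="16", pos=2186000, ref="A", alt="G", gene="PKD1",
                     consequence="synonymous_variant",
                     genotypes={"P1": GenotypeCall("P1", (0, 1), depth=55, alt_depth=26)}),
    # common WT1 missense, off the ciliopathy list: filtered twice over
    AnnotatedVariant(chrom="11", pos=32413566, ref="A", alt="G", gene="WT1",
                     consequence="missense_variant", pop_freqs={"ExAC": 0.02},
                     genotypes={"P1": GenotypeCall("P1", (0, 1), depth=48, alt_depth=22)}),
]
result = two_pass_prioritize(case, panel, variants)
report = build_case_report(case, result, panel)
print("pass used:", result.pass_used)
for rv in report.reported:
    print(f"reported: {rv.cv.variant.key} {rv.cv.variant.gene} "
          f"{rv.cv.tier.name} [{rv.cv.rationale}] diagnostic={rv.diagnostic}")
print("outcome:", report.outcome)
```

prints:

```
pass used: TAILORED
reported: 16:2185690:C:T PKD1 C5 [PM2+PS1+PVS1 -> C5 (pathogenic)] diagnostic=True
outcome: DIAGNOSED
```

The nonsense variant earns PVS1 (null variant, loss-of-function gene),
PS1 (database-asserted pathogenic change) and PM2 (absent from
population databases), combining to C5; being in a ciliopathy gene for a
ciliopathy case with a compatible dominant genotype, it diagnoses the
case, and the tailored pass stops there.  The audit trail records the
synonymous call (`SYNONYMOUS_OR_NONREPORTABLE_CLASS`) and the common
off-list call (`COMMON_POLYMORPHISM`, `OFF_PANEL`).

The same workflow is available from the shell:

```bash
nephroprior panel validate my_panel.tsv
nephroprior prioritize --case-id C1 --cases cases.tsv --panel my_panel.tsv \
    --vcf c1.vcf --ann annotations.tsv --ped trio.ped --out reports/
nephroprior cohort-summary --reports reports/ --panel my_panel.tsv --out summary.json
nephroprior simulate --seed 17 --out simdir/        # synthetic cohort
nephroprior simulate --reference-cohort --out fixture/ # printed-marginals cohort
```

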