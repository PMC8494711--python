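# Methods

## The procedure

`nephroprior` implements a clinical-exome variant-prioritization workflow
for monogenic kidney disease as a deterministic, auditable pipeline.  One
case is a proband with a clinical-suspicion category (CAKUT, tubular
disease, ciliopathy, nephrolithiasis/nephrocalcinosis, glomerular
disease, haemolytic uraemic syndrome, organ failure of unknown origin,
or other), an annotated variant call set, and optionally a trio
pedigree.  The workflow proceeds in fixed stages:

1. **Phenotype-to-genotype tailoring.**  A versioned gene panel maps
   each gene to its inheritance modes, disease categories, optional
   digenic partners and a loss-of-function mechanism flag.  The first
   pass restricts analysis to the genes tagged with the case's
   suspicion; unknown-origin and "other" cases have no tailored list and
   use the full panel directly.
2. **Sequential inclusion/exclusion filters.**  Four pure per-variant
   predicates, audited per variant per pass: reportable consequence
   class (synonymous and unclassifiable calls are removed; missense,
   nonsense, frameshift, in-frame indel, splice and pre-called CNV calls
   proceed), proband call quality (coverage ≥ 20×, alt read fraction
   ≥ 0.3, both inclusive), population rarity (frequency ≤ 1% in every
   database reporting the variant, with absence counting as rare), and
   panel membership.  The survivor set equals the intersection of the
   four per-predicate survivor sets, so audit order never changes
   results.
3. **Inheritance.**  Zygosity assignment (het / hom / hemizygous, with
   male X heterozygote calls coerced to hemizygous and flagged),
   compound-heterozygote resolution (trio phase distinguishes cis from
   trans; without phase two heterozygotes are "putative"), a digenic
   re-check of monoallelic recessive hits against the panel's partner
   table, and trio segregation (de novo, maternal, paternal, biparental,
   Mendelian-inconsistent, unknown).
4. **Classification.**  A reduced, annotation-computable subset of the
   ACMG/AMP criteria (PVS1, PS1, PS2, PM2, PM3, PP3, BP4, BS1, BA1) is
   gathered per variant and combined into tiers C1–C5 by the published
   combination table.  The tailored pass stops the analysis when it
   yields a C4/C5 variant; otherwise all panel genes are tested.
5. **Reporting.**  C5/C4 findings are always reported; C3 findings are
   reported in genes with dominant disease, in X-linked genes for male
   probands, and in recessive-only genes only when in line with the
   phenotype (matching category and biallelic state).  C1/C2 calls are
   classified but never reported.  A case is DIAGNOSED when at least one
   reported variant is both phenotype-compatible and compatible with the
   gene's inheritance mode; an incidental C4 in a mismatched gene is
   reported but does not diagnose.
6. **Cohort summaries and re-analysis.**  Per-case reports aggregate
   into diagnostic yield (overall, by age group, by suspicion), variant
   class / tier / inheritance-mode distributions, multi-variant and
   recurrent-variant counts.  Archived variant tables can be re-run
   against an updated panel without re-ingesting sequence data; the new
   report records both panel versions.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 20× | minimum proband coverage at the site |
| `min_alt_fraction` | 0.30 | minimum alt-supporting read fraction (AD/DP) |
| `max_pop_freq` | 0.01 | maximum population frequency in 1KG/ExAC-style databases |
| `pm2_max_freq` | 1×10⁻⁴ | PM2 rarity bound (absence also qualifies) |
| `insilico_margin` | 2 | deleterious-minus-tolerated vote margin for PP3/BP4 |
| `ba1_min_freq` | 0.05 | stand-alone benign frequency |
| `bs1_min_freq` | 0.01 | strong-benign frequency bound (reachable only with a relaxed rarity filter) |
| `min_parent_depth` | 20× | parental coverage required for de-novo and inconsistency calls |

All bounds are inclusive as written.  The alt-fraction threshold applies
to the per-sample read fraction, not any population quantity.  Quality
thresholds gate the proband call only; parents enter through the
segregation rules with their own depth requirement, chosen to mirror the
proband rule because no separate parental QC convention exists for this
workflow.

## Classification details

Criterion strengths are fixed: PVS1 very strong; PS1/PS2 strong;
PM2/PM3 moderate; PP3 supporting; BA1 stand-alone benign; BS1 strong
benign; BP4 supporting benign.  "Null variant" for PVS1 means nonsense,
frameshift, canonical ±1–2 splice-site disruption, or a pre-called copy
number loss, and requires the gene's loss-of-function mechanism flag.
PM3 requires a biallelic state in a recessive gene with the trans allele
carrying a clinical-database pathogenic assertion (the variant's own
assertion when homozygous).  The combining table follows the published
rules, scored separately for the pathogenic and benign sides; any
non-VUS conclusion on both sides is conflicting and yields C3.  One
documented extension: a very-strong criterion alone classifies as C4
(likely pathogenic) rather than remaining a VUS, which matches common
diagnostic practice for novel null variants in established disease
genes.  Classification is deterministic — identical inputs give
bit-identical evidence sets, tiers and rationale strings.

Re-classification after segregation re-gathers evidence with the new
phase information; because the combining table is monotone in
pathogenic-side evidence, a tier never decreases from newly added
de-novo or trans support, and the implementation additionally clamps the
tier at its previous value as a guard.

## Numerical and formatting choices

* Percentages are rounded half-up to one decimal (22/32 → 68.8,
  1/3 → 33.3).  This is fixed, not configurable, because it is the
  convention under which the summary statistics are reported.
* Coordinates are 1-based VCF convention.  Multi-allelic records are
  decomposed per alt allele; alleles are reduced to a minimal
  representation by suffix/prefix trimming.  True left-alignment against
  a reference sequence is out of scope; inputs are expected to be
  normalised upstream.
* Variant keys are `chrom:pos:ref:alt`; recurrence counts distinct
  patients per key.
* A diagnosed case's inheritance-mode category uses the reporting
  partition X-linked = gene on chromosome X; "both" = gene with dominant
  and recessive forms; otherwise AD (heterozygous, dominant gene) or AR
  (biallelic, recessive gene), with AD > AR > XL > both precedence for
  multi-variant cases.
* Degenerate inputs: zero-depth genotypes have an undefined alt fraction
  and fail quality with the corresponding reason; dangling PED parents
  are kept as missing with a warning; suspicion categories with no
  tagged panel gene yield an empty tailored pass that falls through to
  the full panel.

## The gene panel

The shipped panel (`data/fixture_panel.tsv`, ~90 genes) is an
illustrative set of canonical kidney-disease genes with plausible
inheritance modes and disease categories.  It exists to exercise the
pipeline and the synthetic cohorts and is **not** a clinically curated
resource; any user panel in the documented TSV/JSON schema is accepted.
Digenic partner pairs (NPHP1–NPHP4, CFH–CD46) illustrate the digenic
re-check and default to empty in user panels.  The loss-of-function
mechanism flag defaults to true in the fixture — a modelling choice, not
a clinical assertion.

## What the synthetic data emulates — and what it does not

`simulate_cohort` reproduces the *structure* of a clinical-exome study:
the recruited suspicion mix, paediatric/adult split, a causal-carrier
fraction equal to the observed diagnostic yield, tier and
inheritance-mode mixes matching the reported distributions, trios for
roughly half of paediatric probands, and per-case decoys each designed
to fail exactly one filter (synonymous class, >1% frequency, low
coverage, low alt fraction, off-panel gene).  Planted variants pass the
cascade by construction and decoys fail it by construction, so full
recall and full decoy rejection on simulated cohorts demonstrate the
*internal consistency* of the filters, inheritance logic and reporting
rules — not performance on real exomes.  The simulator does not model
sequencing error, coverage variation along genes, linkage, population
structure, annotation disagreement between databases, or CNV calling;
CNVs enter only as pre-called records.  Genomic coordinates are
synthetic (each gene owns a disjoint position range), and no reference
genome is required.

`make_reference_cohort` is a curated, fully deterministic cohort of 138
case reports carrying 129 reported variants in 65 genes whose marginal
statistics equal the published cohort values exactly: 78 diagnosed
(56.5%; 30/52 paediatric, 48/86 adult), class counts 74 missense / 10
nonsense / 19 frameshift / 7 indel / 15 splice / 4 CNV, tiers 27 C5 /
35 C4 / 67 C3, diagnosed-case inheritance categories 43 AD / 16 AR / 11
X-linked / 8 both, per-suspicion detection rates (22/32 ciliopathy,
14/21 glomerular, 32/60 unknown-origin, 4/11 tubular, 1/4 HUS, 1/2
nephrolithiasis, 4/8 across CAKUT and other), 28 multi-variant patients
and 3 recurrent variants.  The fixture reproduces marginals, not
individual patients; per-variant evidence sets are chosen per tier so
that the tier-equals-combined-evidence invariant holds exactly.  The
paediatric/adult split within most suspicion categories is
underdetermined by the published totals; the fixture uses one split
consistent with every published marginal (unknown-origin: 10 of 18
paediatric diagnosed; CAKUT: all three cases paediatric and
undiagnosed).

## Problem sizes

The test suite and the acceptance script run the fixture cohort (138
cases / 129 variants) and simulated cohorts of 200–400 cases with ~8
variants per case — sizes chosen so a full run completes in well under
a minute per suite component while still exercising every pipeline
branch, including trios, compound heterozygotes, hemizygous males,
CNV records and every decoy failure mode.

## Known limitations

* The nine-criterion classifier is an approximation of the full
  28-criterion framework; criteria requiring functional data, allele
  counts in affected cohorts, or segregation across extended pedigrees
  are out of scope.
* Pseudoautosomal regions, X-inactivation skew, mosaicism and imprinting
  are not modelled; male X heterozygote calls are treated as genotyping
  artifacts.
* Phenotype matching is category-level (suspicion ∈ gene categories),
  not HPO-term based.
* The stop rule is evaluated per case: any C4/C5 among tailored-pass
  survivors halts the analysis, so secondary findings in off-category
  genes are not examined unless `force_full_pass` is set.
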