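# cgprofiler

Cohort-level profiling of germline variation in cancer-susceptibility genes.

Whole-genome sequencing of healthy people routinely reveals dozens of
protein-affecting variants in genes causally implicated in cancer, almost all
of unknown clinical significance. Interpreting them requires knowing what the
background variation in these genes looks like in a general, ancestrally
diverse population: how many variants a healthy person carries, how they are
distributed over genes, and how allele frequencies differ between ancestry
groups — including sites where the *minor* allele in one population is the
*major* allele in another, so that variant calls against a single reference
sequence mean different things for different ancestries.

`cgprofiler` implements that analysis as a tested, reusable pipeline for
geneticists working with multi-sample VCFs of a gene panel:

1. **Quality filtering** (`cgprofiler.qc`) — a two-stage reliability filter:
   sites are excluded when the cohort call rate is < 80% or the average
   fractional allele depth is ≤ 0.295; individual calls are masked when the
   minimum carried-allele depth is ≤ 11. Post-filter error rates are estimated
   by stratified k-fold cross-validation against validated genotypes.
2. **Consequence annotation** (`cgprofiler.effects`, `cgprofiler.genes`) —
   each variant is classified per transcript by translating the reference and
   variant coding sequences (frameshift / nonsense / splice-site / missense /
   in-frame indel / synonymous); the gene-level category is the most severe
   effect on any transcript. Variants are assigned to three nonexclusive
   classes: HGMD-listed, deleterious (frameshift, nonsense, splice-site), and
   VUS (all other nonsynonymous); "novel" means absent from the known-variant
   table.
3. **Ancestry assignment** (`cgprofiler.ancestry`) — supervised admixture:
   per-subject coefficients **q** over six fixed ancestral populations
   (African, European, Native American, East Asian, Central Asian, Oceanic)
   maximise the binomial likelihood

   L(q) = Σₗ [ xₗ log(Σₖ qₖ fₖₗ) + (2 − xₗ) log(Σₖ qₖ (1 − fₖₗ)) ]

   over the simplex by EM, where xₗ is the alt-allele dosage at panel marker l
   and fₖₗ the ancestral frequency. Subjects are clustered into labelled
   subpopulations by explicit thresholds (dominant ancestry ≥ 0.78;
   African-European and Hispanic admixture rules); clusters under 20 members
   merge into "Other".
4. **Population statistics** (`cgprofiler.popstats`) — ancestry-stratified
   allele counts (males hemizygous at non-PAR X sites), chi-squared tests when
   all expected cells are > 1 and otherwise Fisher's exact test with simulated
   p-values, and the composite allele-flip criterion: minimum group frequency
   < 0.5 < maximum, the two extremes differing from each other (one-sided
   Fisher) and each from 0.5 (one-sided exact binomial), all at α = 0.05.
5. **Variant-load profiling** (`cgprofiler.profiles`) — per-individual and
   per-gene summaries, the regression of per-gene variant count on coding
   length (variants per kb), one-way ANOVA of per-person counts across
   ancestry groups, and ANCOVA for the gene-type effect.
6. **Synthetic cohort generator** (`cgprofiler.simulate`) — first-class,
   fully seeded generator of a 681-subject admixed cohort (genotypes, read
   depths, toy genome and transcripts, annotation tables, ancestral panel)
   with truth tables for every planted feature, so the whole pipeline is
   testable end-to-end without any external data.

## Worked example

The numbered scripts under `analysis/` run the pipeline end-to-end on the
default synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quality_filter.py
python analysis/03_annotate_variants.py
python analysis/04_ancestry_assignment.py
python analysis/05_frequency_analysis.py
python analysis/06_variant_load_profiles.py
```

Output of the last three steps (seed 2014):

```
subpopulation sizes:
European            331
Hispanic            118
EastAsian            62
CentralAsian         50
African-European     45
African              43
Other                32
agreement with generating groups: 99.9%

443 variants common (>5%) in at least one group
  399 with significant between-group frequency differences (p < 0.05)
  21 major/minor allele flips detected
  57 common variants specific to a single group (57 in low-admixture groups)
  14 positions with the nonreference allele >50% in every group

mean variants per person: 68.11 (range [50, 92])
variants per kb of coding sequence: 6.17 (r^2 = 0.778)
ANOVA (totals by group): p = 7.86e-19; ANCOVA (gene type): p = 5.92e-16
```

Reading the numbers: the supervised-admixture clustering recovers the seven
generating subpopulations almost perfectly; the flip detector finds exactly
the 21 planted major/minor-allele flips and the 14 planted reference-minor
positions; each subject carries on average ≈ 68 nonsynonymous variant sites
across the 158 genes; and per-gene variant counts grow with coding length at
≈ 6 variants per kb, with predisposition genes more variable than tumor
suppressors and oncogenes (the ANCOVA gene-type effect).

The same pipeline runs from files via the CLI:

```sh
cgprofiler run-all --seed 7 --outdir out/
cgprofiler filter --vcf cohort.vcf --min-call-rate 0.80 \
    --min-frac-depth 0.295 --min-allele-depth 12 --outdir out/
```

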