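# Methods

This note documents the statistical models, parameter choices, numerical
details and limitations of `cgprofiler`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is a
claim about real cohorts.

## Quality filtering

The filter has two fixed stages applied in order. The **position filter**
excludes a site when the cohort call rate is below 0.80 or the average
fractional allele depth is at most 0.295 (boundary inclusive: 0.295 fails).
Call rate is computed on raw calls, before any genotype masking. The
**genotype filter** then masks calls whose minimum carried-allele depth is at
most 11 (so 12 reads is the smallest passing depth). The thresholds are
published constants of an upstream decision-tree model; no training happens
here, and re-deriving them is out of scope.

Two definitions in this stage are not fully specified by their source and are
documented assumptions, both configurable:

* **Minimum allele depth** is taken over the alleles the genotype actually
  carries — both alleles of a het, the single allele of a hom. Taking the
  minimum over both VCF alleles would give every hom call a zero on the
  uncarried allele and mask it, which is the only reading we can rule out.
* **Fractional allele depth** of a call is the depth of its less-supported
  carried allele divided by the total depth; for hom calls it is the carried
  allele's fraction (near 1 for clean data). A clean het therefore sits near
  0.5 and a clean hom near 1.0, so ordinary sites clear the 0.295 site-average
  threshold comfortably and the threshold catches sites with systematically
  unbalanced support.

`estimate_error_rates` evaluates the fixed filters on held-out folds of a
labelled validation set (stratified k-fold, k = 10 by default, seeded). Since
no parameters are fit, cross-validation here is an honest hold-out error
estimate rather than model selection. False negatives are truth-positive
genotypes that are masked or called non-variant; false positives are
truth-negative genotypes passing as variant. Intervals are Clopper-Pearson at
95%.

## Gene models and consequence annotation

Coordinates are 0-based half-open internally; VCF positions convert on
ingest. A gene's **coding length** is the union over its transcripts of
exonic bases inside each transcript's CDS bounds, so shared exons count once.
Variants are normalized (shared-suffix trim, left-alignment, minimal
representation) before any table lookup or classification.

Consequences are computed per transcript by rebuilding the coding sequence
with the variant applied in CDS coordinates and translating both sequences
with the standard genetic code. Category rules: CDS length change not a
multiple of 3 → frameshift; a stop before the reference stop → nonsense;
amino-acid substitution → missense; identical protein → synonymous; in-frame
length change → inframe_indel. A variant whose reference span intersects
coding bases is classified through translation even if it also touches the
splice window (coding context takes precedence); otherwise a span touching
the first or last 2 intronic bases of an intron is a splice-site variant. The
window of 2 matches the canonical donor/acceptor dinucleotides and is
configurable; wider windows are defensible and unimplemented choices of the
original analysis. Stop-loss is reported as missense-like rather than as its
own category. The gene-level category is the most severe effect on any
transcript (frameshift > nonsense > splice_site > missense > inframe_indel >
synonymous).

Class flags are nonexclusive: deleterious iff the gene-level category is
frameshift, nonsense or splice-site; HGMD iff listed in the HGMD-like table;
VUS iff nonsynonymous and neither of the above; novel iff absent from the
known-variant table. Synonymous and noncoding variants carry no flags and are
excluded from all variant-load analyses. PolyPhen-like scores bin at > 0.85
(probably damaging), [0.15, 0.85] (possibly damaging, boundaries assigned to
the middle bin), < 0.15 (benign).

## Supervised admixture and subpopulations

Each subject is modelled independently: given fixed ancestral alt-allele
frequencies f (6 populations × L markers) and dosages x ∈ {0,1,2}, the
coefficients q maximise Σₗ xₗ log(qᵀf·ₗ) + (2−xₗ) log(qᵀ(1−f·ₗ)) on the
simplex. The EM update multiplies each qₖ by its expected share of allele
ancestries and renormalises; the log-likelihood is non-decreasing (asserted
per iteration in tests). Numerical details: panel frequencies are clipped to
[1e−6, 1−1e−6]; iteration starts uniform and stops when the per-subject
log-likelihood change drops below `tol` (default 1e−4, which on the default
panel changes estimates by < 1e−3 relative to much tighter tolerances) or at
`max_iter` = 1000; subjects need at least 100 called panel markers. The
unsupervised problem (re-estimating f) is out of scope.

Clustering uses explicit thresholds rather than a generic algorithm because
the reported group boundaries are breakpoint-like: dominant coefficient
≥ 0.78 forms one cluster per ancestry; African + European ≥ 0.95 with African
in [0.13, 0.75] forms African-European; Native American ≥ 0.05 with European
≥ 0.05 and African ≤ 0.50 forms Hispanic. The Hispanic rule's "nonzero"
Native American component becomes a 0.05 floor because EM estimates are never
exactly zero. Unassigned subjects and clusters under 20 members merge into
"Other". A k-means alternative exists behind `method="kmeans"` for
sensitivity analysis. Optional relabelling by majority birth region excludes
US-born subjects and falls back to the ancestry label on ties or empty votes.

## Frequency statistics

Allele counts per subpopulation exclude "Other" (not an ancestry-based
population) and masked genotypes. Autosomes contribute 2 alleles per called
subject; chromosome-X sites outside the pseudoautosomal regions contribute 1
for males.

Test selection follows the expected-count rule: Pearson chi-squared (no
continuity correction, df = groups − 1) when every expected cell exceeds 1
(strictly), otherwise Fisher's exact test with simulated p-values:
Monte-Carlo tables with the observed margins (10,000 draws by default), with
p = (1 + #{simulated table probability ≤ observed}) / (n_sim + 1) so p > 0;
probability comparisons use a 1e−9 log-scale tolerance against ties.

The **allele-flip criterion** is composite: the minimum and maximum group
frequencies must straddle 0.5; the min-vs-max 2×2 allele table must be
significant by a one-sided Fisher's exact test; and each extreme must differ
from 0.5. The test "against 0.5" is implemented as a one-sided exact binomial
test on the group's allele count (a Fisher test against 0.5 is not a standard
two-sample construction; a pseudo-sample Fisher variant would be an
equivalent design). The direction of each one-sided test is the observed
side; all use α = 0.05 with no multiple-testing correction, matching the
original raw-p convention (a Benjamini-Hochberg option exists, off by
default). Tests on allele counts, not carrier counts.

When validating the criterion against the 21 published flip rows, integer
counts are reconstructed from the printed two-decimal frequencies as
round(freq × total alleles), with group sizes from the published table and a
50% male fraction for the one X-linked row. All 21 rows pass the frequency
component; 19 of 21 also pass the significance component — the two borderline
rows (minimum-frequency groups at 0.42 and 0.44 in groups of ≤ 62 subjects)
fall on the wrong side of the binomial test once frequencies are rounded, so
the test asserts ≥ 19 rather than 21. Exact reconstruction of the published
p-values from rounded frequencies is not possible.

Single-group common variants are sites with frequency > 5% in at least one
group and alt alleles observed in exactly one group; reference-minor
positions have alt frequency > 0.5 in every group.

## Variant-load profiling

A carried site (het or hom-alt, unmasked) counts once per subject; an
allele-counting mode is available but per-site counting is the default
reading of per-person totals. Rarity is classified from the cohort MAF of
the filtered genotypes (< 1% rare, > 5% common). The variants-per-kb rate is
the OLS slope of per-gene variant count on coding length (intercept
included), reported per kb with r². Group comparisons use one-way
fixed-effects ANOVA on untransformed counts with "Other" excluded; the
gene-type analysis is an ANCOVA — OLS of count on coding length plus a
gene-type factor — reporting the factor's partial F-test.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs. Group sizes are 43 African, 46 African-European, 50 Central Asian, 62
East Asian, 331 European, 118 Hispanic, 31 Other (681 subjects); 158 genes
split 60 tumor-suppressor / 60 oncogene / 38 predisposition with lognormal
coding lengths (mean 2,975 bases, σ = 0.6 on the log scale) and
nonsynonymous site counts drawn Poisson at 5 / 5 / 8 sites per kb by type, so
the cohort-wide rate is ≈ 6 per kb and the gene-type contrast is present by
construction.

Admixture vectors are Dirichlet per group around documented mean vectors
(e.g. African: 92% African ancestry at concentration 300; Hispanic: 35%
Native American, 50% European at concentration 60; "Other" subjects are
three-way Eurasian admixtures matching no cluster rule). Sites fall into
strata:

* **Rare stratum** — 65% of nonsynonymous sites are singletons and 10%
  doubletons by direct carrier assignment (het carriers drawn uniformly),
  because the calibration targets are empirical proportions, not a
  population-genetic model; no coalescent is simulated.
* **Common stratum** — global frequencies from Beta(0.7, 18), diverged across
  the six ancestral populations by a Balding-Nichols model with Fst = 0.08,
  floored at 0.01 per population so the stratum stays genuinely polymorphic
  and the rare spectrum is exactly the planted one.
* **Planted features** — 21 flips (one ancestral population at 0.78–0.92,
  the rest at 0.10–0.22, rotating the high population), 14 reference-minor
  sites (0.78–0.92 in all six populations), and 58 single-group common sites
  (49 African, 2 Central Asian, 6 East Asian, 1 European; carriers assigned
  directly within the group at 5.5–10% frequency, since admixture leakage
  would otherwise spread them across groups).

Genotypes at common-stratum sites are Binomial(2, qᵀf) per subject.  The
common-stratum frequency scale is then calibrated by a one-dimensional root
find so the expected post-masking nonsynonymous load is 68 sites per subject
(the 1% planted genotype-mask rate is compensated analytically); an
infeasible configuration (planted load exceeding the target, or no scale in
[0.001, 6] reaching it) raises an error rather than silently degrading.

Consequence truth is fixed by codon surgery: the generator writes specific
reference codons into the toy genome and derives each alt allele
constructively (AAA→TAA nonsense, AAA→GAA missense, GGA→GGG synonymous,
single-base deletion for frameshift, whole-codon deletion for in-frame,
donor-site SNVs for splice). Deleterious counts default to 22 nonsense, 42
frameshift, 16 splice-site, with 21 of the 80 placed on common sites so
per-person deleterious counts land near 2. HGMD-like flags attach to 21% of
common and 9.2% of rare sites (≈ 12% of sites overall, ≈ 14 per person);
rare sites are "known" with probability 0.427, making ≈ 43% of sites novel.
Class-flag rates and per-person HGMD/VUS means are plausibility features, not
calibration targets. Read depths are Poisson (mean 58) with binomial allele
split; planted low-quality material comprises 30 extra low-call-rate sites
(~25% no-calls), 30 extra low-fractional-depth sites, and 1% of genotypes
with a carried-allele depth ≤ 11. About 5% extra synonymous sites exercise
the exclusion path.

All randomness flows from one mandatory seed through `numpy.random.SeedSequence`
spawns, so stages are independently reproducible and regeneration is
byte-identical.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: linkage disequilibrium (sites are independent), real
gene sequences and mutational signatures, relatedness between subjects,
X-linked variant sites (the hemizygote counting rule is exercised by unit
tests and the published-table reconstruction instead), batch effects in
depth, and any correlation between consequence class and allele frequency
beyond the configured rates. Calibration conclusions transfer to real
cohorts only to the extent these assumptions hold.

## Problem sizes and determinism

The calibration check and acceptance script generate 20 cohorts of 681
subjects (~2,900 sites each) and run filtering, annotation and profiling on
each — about two minutes on one CPU. The default panel is 2,000 markers
(the original panel had 16,443; 2,000 informative markers already put the
EM's mean absolute error near 0.01, comfortably inside the 0.05 recovery
contract). Pipeline outputs round floating-point text to 12 significant
digits so reruns are bit-identical; simulated-Fisher seeds derive from the
pipeline seed.

## Known limitations

* The fractional-allele-depth and minimum-allele-depth definitions are
  reconstructions of an under-specified published filter (flagged above).
* The flip criterion's "different from 0.5" test is an exact binomial; other
  one-sided constructions could differ on borderline sites.
* Multi-allelic sites are decomposed to biallelic records; haplotype-aware
  effects (two variants in one codon) are not composed.
* The per-gene analyses use each gene's transcripts as given; no transcript
  prioritisation (canonical vs others) is applied beyond the any-transcript
  severity rule.
* Per-person totals count variant sites, not alleles; the alternative
  allele-counting mode changes hom-alt weighting.
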