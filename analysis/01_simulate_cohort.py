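#!/usr/bin/env python
"""Generate the default synthetic cohort and write every pipeline input.

Emulates the study conditions: 681 subjects in seven ancestry-based groups
(43/46/50/62/331/118/31), 158 cancer genes, a rare-heavy spectrum (65%
singletons, 75% of sites in <=2 carriers), ancestry-dependent common-variant
frequencies with 21 planted allele flips, 14 reference-minor sites and 58
single-group common variants, and read depths around 58x with planted
low-quality positions and genotypes.

Outputs: results/cohort/ (VCF, toy genome FASTA, transcript and gene tables,
annotation tables, ancestral panel, truth tables).
"""

from pathlib import Path

from cgprofiler.simulate import GeneratorConfig, generate_cohort

SEED = 2014
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    syn = generate_cohort(GeneratorConfig(seed=SEED))
    paths = syn.write(OUT)
    t = syn.truth.sites
    print(f"cohort: {syn.cohort.n_subjects} subjects, {syn.cohort.n_sites} variant sites")
    print(f"  nonsynonymous sites: {(t.category_truth != 'synonymous').sum()}")
    print(f"  planted flips: {t.flip.sum()}, reference-minor: {t.reference_minor.sum()}, "
          f"group-specific: {t.group_specific.sum()}")
    print(f"  planted low-quality sites: {t.low_quality.sum()}, "
          f"low-depth genotypes: {syn.truth.planted_low_depth.sum()}")
    print(f"wrote {len(paths)} files under {OUT}")


if __name__ == "__main__":
    main()
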