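#!/usr/bin/env python
"""Per-individual and per-gene variant-load profiles and their models.

Summarises carried nonsynonymous sites per subject (total and by class),
per-gene burden and prevalence, the regression of per-gene variant count on
coding length (variants per kb), one-way ANOVA of per-person totals across
ancestry groups, and the ANCOVA for the gene-type effect on variability.

Reads results/filter/, results/annotation/, results/ancestry/, results/cohort/;
writes results/profiles/.
"""

import json
from pathlib import Path

import pandas as pd

from cgprofiler.cohort import read_vcf
from cgprofiler.genes import coding_length, gene_models_from_frames
from cgprofiler.profiles import (
    ancova_gene_type,
    anova_by_group,
    gene_profiles,
    individual_profiles,
    variability_rate,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    filtered = read_vcf(ROOT / "filter" / "filtered.vcf")
    classes = pd.read_csv(ROOT / "annotation" / "annotated_sites.tsv", sep="\t")
    subpop = pd.read_csv(ROOT / "ancestry" / "subpopulations.tsv", sep="\t")
    tx = pd.read_csv(ROOT / "cohort" / "transcripts.tsv", sep="\t")
    genes = pd.read_csv(ROOT / "cohort" / "gene_list.tsv", sep="\t")
    models, _ = gene_models_from_frames(tx, genes)
    lengths = {m.gene_symbol: coding_length(m) for m in models}

    prof = individual_profiles(filtered, classes)
    gprof = gene_profiles(filtered, classes, lengths)
    gprof["gene_type"] = gprof.gene.map(genes.set_index("gene_symbol")["gene_type"])
    out = ROOT / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    prof.to_csv(out / "individual_profiles.tsv", sep="\t", index=False)
    gprof.to_csv(out / "gene_profiles.tsv", sep="\t", index=False, float_format="%.12g")

    rate = variability_rate(gprof)
    f_tot, p_tot = anova_by_group(prof, subpop, "n_total")
    f_gt, p_gt = ancova_gene_type(gprof)
    by_group = prof.merge(subpop, on="subject")
    group_means = (
        by_group[by_group.subpopulation != "Other"]
        .groupby("subpopulation")[["n_total", "n_deleterious", "n_hgmd", "n_novel"]]
        .mean()
        .round(2)
    )
    summary = {
        "mean_variants_per_person": round(float(prof.n_total.mean()), 2),
        "range_variants_per_person": [int(prof.n_total.min()), int(prof.n_total.max())],
        "median_genes_with_variant": float(prof.n_genes_with_variant.median()),
        "variants_per_kb": round(rate.slope_per_kb, 2),
        "r_squared": round(rate.r_squared, 3),
        "anova_total_by_group_p": p_tot,
        "ancova_gene_type_p": p_gt,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"mean variants per person: {summary['mean_variants_per_person']} "
          f"(range {summary['range_variants_per_person']})")
    print(f"median genes with a variant per person: {summary['median_genes_with_variant']:.0f}")
    print("per-person means by ancestry group:")
    print(group_means.to_string())
    print(f"variants per kb of coding sequence: {summary['variants_per_kb']} "
          f"(r^2 = {summary['r_squared']})")
    print(f"ANOVA (totals by group): p = {p_tot:.3g}; ANCOVA (gene type): p = {p_gt:.3g}")


if __name__ == "__main__":
    main()
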