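#!/usr/bin/env python
"""Annotate the filtered variants with predicted protein consequences and
assign the three nonexclusive variant classes.

Each variant is classified against its gene's transcripts by translating the
reference and variant coding sequences; the gene-level category is the most
severe effect on any transcript.  Classes: HGMD-listed, deleterious
(frameshift/nonsense/splice-site), and VUS (all other nonsynonymous).
Novelty means absence from the known-variant table.

Reads results/cohort/ and results/filter/; writes results/annotation/.
"""

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from cgprofiler.annotate import annotate_cohort
from cgprofiler.cohort import read_vcf
from cgprofiler.genes import gene_models_from_frames

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    filtered = read_vcf(ROOT / "filter" / "filtered.vcf")
    tx = pd.read_csv(ROOT / "cohort" / "transcripts.tsv", sep="\t")
    genes = pd.read_csv(ROOT / "cohort" / "gene_list.tsv", sep="\t")
    ann_tables = pd.read_csv(ROOT / "cohort" / "annotations.tsv", sep="\t")
    genome = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(ROOT / "cohort" / "genome.fa"), "fasta")
    }
    models, missing = gene_models_from_frames(tx, genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classes = annotate_cohort(filtered, models, genome, ann_tables)
    out = ROOT / "annotation"
    out.mkdir(parents=True, exist_ok=True)
    classes.to_csv(out / "annotated_sites.tsv", sep="\t", index=False, float_format="%.12g")
    nonsyn = classes[classes.nonsynonymous]
    print(f"{len(classes)} sites annotated across {classes.gene.nunique()} genes")
    print(f"  nonsynonymous: {len(nonsyn)}")
    print(f"  by category: {classes.category.value_counts().to_dict()}")
    print(
        f"  classes: deleterious {nonsyn.deleterious.sum()}, HGMD {nonsyn.hgmd.sum()}, "
        f"VUS {nonsyn.vus.sum()}, novel {nonsyn.novel.sum()}"
    )
    print(f"  rare (cohort MAF < 1%): {nonsyn.rare.sum()}")


if __name__ == "__main__":
    main()
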