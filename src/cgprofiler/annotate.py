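"""Cohort-level consequence annotation: map sites to transcripts, classify, and
assemble the per-site class table used by profiling and popstats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes
from .effects import (
    NONSYNONYMOUS_CATEGORIES,
    VariantRecord,
    aggregate_gene_category,
    assign_classes,
    bin_polyphen,
    classify_consequence,
)
from .genes import GeneModel


def annotate_cohort(
    cohort: CohortGenotypes,
    gene_models: list[GeneModel],
    genome: dict[str, str],
    annotations: pd.DataFrame | None = None,
    splice_window: int = 2,
) -> pd.DataFrame:
    """One row per cohort site: gene, gene-level category, class flags, rarity.

    Sites are matched to transcripts by overlap with the transcript span; the
    gene-level category is the most severe consequence over the gene's
    transcripts.  ``annotations`` supplies known-variant ids, HGMD-like flags
    and PolyPhen-like scores keyed on (chrom, pos, ref, alt); absent keys mean
    unknown/unlisted/unscored.  Rarity is classified from the observed cohort
    MAF of the (filtered) genotypes.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    if annotations is not None:
        akey = annotations.set_index(["chrom", "pos", "ref", "alt"])
    else:
        akey = None

    called = cohort.called()
    alt_counts = np.where(called, cohort.dosage, 0).sum(axis=0)
    totals = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(totals > 0, alt_counts / np.maximum(totals, 1), 0.0)
    maf = np.minimum(af, 1 - af)

    rows = []
    for j, site in enumerate(cohort.sites.itertuples(index=False)):
        v = VariantRecord(site.chrom, int(site.pos), site.ref, site.alt)
        start0, end0 = v.pos - 1, v.pos - 1 + len(v.ref)
        gene_symbol, category, protein_change = "unassigned", "noncoding", ""
        for g in by_chrom.get(v.chrom, []):
            hits = [
                t
                for t in g.transcripts
                if t.exons and start0 < t.exons[-1].end and end0 > t.exons[0].start
            ]
            if not hits:
                continue
            anns = [
                classify_consequence(v, t, genome, splice_window=splice_window) for t in hits
            ]
            cat = aggregate_gene_category(anns)
            if cat != "noncoding" or gene_symbol == "unassigned":
                gene_symbol = g.gene_symbol
                category = cat
                for a in anns:
                    if a.category == cat:
                        protein_change = a.protein_change
                        break
            if cat != "noncoding":
                break
        in_hgmd, known, pp = False, False, None
        if akey is not None and (v.chrom, v.pos, v.ref, v.alt) in akey.index:
            rec = akey.loc[(v.chrom, v.pos, v.ref, v.alt)]
            in_hgmd = bool(rec.get("hgmd", False))
            kid = rec.get("known_id", ".")
            known = bool(pd.notna(kid) and str(kid) not in (".", ""))
            score = rec.get("polyphen_score", np.nan)
            pp = None if pd.isna(score) else float(score)
        vc = assign_classes(category, in_hgmd, known, pp)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": gene_symbol,
                "category": category,
                "protein_change": protein_change,
                "nonsynonymous": category in NONSYNONYMOUS_CATEGORIES,
                "deleterious": vc.deleterious,
                "hgmd": vc.hgmd,
                "vus": vc.vus,
                "novel": vc.novel,
                "polyphen_bin": vc.polyphen_bin,
                "maf": float(maf[j]),
                "rare": bool(maf[j] < 0.01),
            }
        )
    return pd.DataFrame(rows)
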