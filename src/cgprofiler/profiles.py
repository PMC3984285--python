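"""Per-individual and per-gene variant-load profiles and their models.

A carried variant site (het or hom-alt, unmasked) counts once per subject; the
nonexclusive class flags (deleterious / HGMD / VUS / novel) tally the same
sites.  Per-gene burden is summarised as distinct variant sites, individuals
carrying any, and variants per kilobase of coding sequence; the cohort-level
variability rate is the slope of the ordinary least-squares regression of
per-gene variant count on coding length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortGenotypes


def individual_profiles(
    cohort: CohortGenotypes,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject variant-load profile over nonsynonymous sites.

    ``classes`` has one row per site of ``cohort`` (positionally aligned) with
    boolean columns nonsynonymous, deleterious, hgmd, vus, novel, rare and a
    ``gene`` column.  Synonymous/noncoding sites are excluded from every count.

    Returns columns: subject, n_total, n_hgmd, n_deleterious, n_vus, n_novel,
    n_rare, n_genes_with_variant.
    """
    if len(classes) != cohort.n_sites:
        raise ValueError("classes must align with cohort sites")
    carried = cohort.dosage > 0  # (n, s)
    nonsyn = classes["nonsynonymous"].to_numpy(dtype=bool)
    carried = carried & nonsyn

    def tally(flag: str) -> np.ndarray:
        return (carried & classes[flag].to_numpy(dtype=bool)).sum(axis=1)

    genes = classes["gene"].to_numpy()
    gene_codes, _ = pd.factorize(genes)
    n_genes_with = np.zeros(cohort.n_subjects, dtype=int)
    for i in range(cohort.n_subjects):
        n_genes_with[i] = len(np.unique(gene_codes[carried[i]]))

    return pd.DataFrame(
        {
            "subject": cohort.subjects,
            "n_total": carried.sum(axis=1),
            "n_hgmd": tally("hgmd"),
            "n_deleterious": tally("deleterious"),
            "n_vus": tally("vus"),
            "n_novel": tally("novel"),
            "n_rare": tally("rare"),
            "n_genes_with_variant": n_genes_with,
        }
    )


def gene_profiles(
    cohort: CohortGenotypes,
    classes: pd.DataFrame,
    coding_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-gene burden over nonsynonymous sites.

    Genes in ``coding_lengths`` with no variants appear with zero counts.
    Sites whose gene is not in ``coding_lengths`` are tallied under
    "unassigned" with a warning from the caller's perspective (NaN lengths).
    """
    if len(classes) != cohort.n_sites:
        raise ValueError("classes must align with cohort sites")
    nonsyn = classes["nonsynonymous"].to_numpy(dtype=bool)
    rare = classes["rare"].to_numpy(dtype=bool)
    carried = cohort.dosage > 0
    genes = classes["gene"].where(classes["gene"].isin(coding_lengths), "unassigned")

    rows = []
    n_cohort = cohort.n_subjects
    for gene in list(coding_lengths) + (
        ["unassigned"] if (genes == "unassigned").any() else []
    ):
        in_g = (genes == gene).to_numpy() & nonsyn
        n_var = int(in_g.sum())
        any_carried = carried[:, in_g].any(axis=1)
        rare_carried = carried[:, in_g & rare].any(axis=1)
        length = coding_lengths.get(gene, np.nan)
        rows.append(
            {
                "gene": gene,
                "n_variants": n_var,
                "n_individuals": int(any_carried.sum()),
                "n_individuals_rare": int(rare_carried.sum()),
                "prevalence": any_carried.sum() / n_cohort,
                "prevalence_rare": rare_carried.sum() / n_cohort,
                "coding_length": length,
                "variants_per_kb": n_var / (length / 1000.0) if length == length else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariabilityRate:
    slope_per_kb: float
    intercept: float
    r_squared: float


def variability_rate(profiles: pd.DataFrame) -> VariabilityRate:
    """OLS regression of per-gene variant count on coding length (bases),
    intercept included; the slope is reported per kilobase."""
    sub = profiles.dropna(subset=["coding_length"])
    if len(sub) < 3:
        raise ValueError("need >= 3 genes with coding lengths")
    x = sub["coding_length"].to_numpy(dtype=float)
    y = sub["n_variants"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in coding length")
    res = stats.linregress(x, y)
    return VariabilityRate(
        slope_per_kb=res.slope * 1000.0,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
    )


def anova_by_group(
    profiles: pd.DataFrame,
    subpop: pd.DataFrame,
    response: str = "n_total",
    exclude: tuple[str, ...] = ("Other",),
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a per-individual count across ancestry
    groups ("Other" excluded).  Returns (F, p)."""
    merged = profiles.merge(subpop, on="subject")
    merged = merged[~merged.subpopulation.isin(exclude)]
    groups = [g[response].to_numpy(dtype=float) for _, g in merged.groupby("subpopulation")]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 subjects")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def ancova_gene_type(profiles: pd.DataFrame) -> tuple[float, float]:
    """Gene-type effect on variant count adjusting for coding length.

    Fits n_variants ~ coding_length + C(gene_type) by OLS and returns the
    partial F-test (F, p) for the gene-type factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = profiles.dropna(subset=["coding_length", "gene_type"])
    types = sub["gene_type"].unique()
    if len(types) < 2:
        raise ValueError("need >= 2 gene types")
    if (sub["gene_type"].value_counts() < 3).any():
        raise ValueError("need >= 3 genes per type")
    model = smf.ols("n_variants ~ coding_length + C(gene_type)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(gene_type)"]
    return float(row["F"]), float(row["PR(>F)"])
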