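"""Ancestry-stratified allele frequencies and between-group statistics.

Allele counts are computed per subpopulation from quality-filtered genotypes
("Other" is excluded: it is a catch-all, not an ancestry-based population).
Autosomal sites contribute 2 alleles per called subject; chromosome-X sites
outside the pseudoautosomal regions contribute 1 allele for males.

Between-group frequency differences use the chi-squared test when every
expected cell count exceeds 1 and otherwise Fisher's exact test with simulated
p-values (Monte-Carlo over tables with the observed margins).  A major/minor
allele flip is a site where the minimum group frequency is below 0.5 and the
maximum above, with the difference between the two groups and each group's
difference from 0.5 statistically supported at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import CohortGenotypes

#: subpopulations entering allele-frequency statistics, in reporting order
FREQ_GROUPS = (
    "African",
    "African-European",
    "CentralAsian",
    "EastAsian",
    "European",
    "Hispanic",
)


def _is_x(chrom: str) -> bool:
    c = chrom.lower().removeprefix("chr")
    return c == "x"


def group_allele_counts(
    cohort: CohortGenotypes,
    subpop: pd.DataFrame,
    groups: tuple[str, ...] = FREQ_GROUPS,
    par_regions: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-site, per-group alt allele counts, totals and frequencies.

    ``subpop`` maps subject -> subpopulation; subjects in groups outside
    ``groups`` (e.g. "Other") are excluded.  Masked/no-call genotypes are
    excluded from the denominator.  At chromosome-X sites outside
    ``par_regions`` males contribute one allele (their stored dosage must be
    0 or 1); everywhere else each called subject contributes two.

    Returns a long-format frame: chrom, pos, ref, alt, group, alt_count,
    total_alleles, frequency, plus per-site overall_maf.
    """
    lab = subpop.set_index("subject")["subpopulation"]
    member = np.array([lab.get(s, "Other") for s in cohort.subjects])
    sexes = cohort.sex if cohort.sex is not None else np.full(cohort.n_subjects, "F")
    is_male = np.asarray(sexes) == "M"

    x_site = np.array([_is_x(c) for c in cohort.sites.chrom])
    if par_regions:
        in_par = np.zeros(cohort.n_sites, dtype=bool)
        pos = cohort.sites.pos.to_numpy()
        for s, t in par_regions:
            in_par |= x_site & (pos >= s) & (pos <= t)
        hemi_site = x_site & ~in_par
    else:
        hemi_site = x_site

    called = cohort.called()
    dosage = np.where(called, cohort.dosage, 0)
    # ploidy per genotype: 1 for male on hemizygous X, else 2
    ploidy = np.where(np.outer(is_male, hemi_site), 1, 2)
    rows = []
    for g in groups:
        in_g = member == g
        alt = (dosage[in_g]).sum(axis=0)
        tot = (called[in_g] * ploidy[in_g]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": cohort.sites.chrom,
                    "pos": cohort.sites.pos,
                    "ref": cohort.sites.ref,
                    "alt": cohort.sites.alt,
                    "group": g,
                    "alt_count": alt,
                    "total_alleles": tot,
                    "frequency": freq,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    # overall MAF over the included groups
    tot = out.groupby(["chrom", "pos", "ref", "alt"], sort=False).agg(
        alt=("alt_count", "sum"), n=("total_alleles", "sum")
    )
    af = (tot.alt / tot.n.where(tot.n > 0)).fillna(0.0)
    maf = np.minimum(af, 1 - af)
    out = out.merge(
        maf.rename("overall_maf").reset_index(), on=["chrom", "pos", "ref", "alt"], how="left"
    )
    return out


def counts_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long group-frequency table to one row per site."""
    wide = table.pivot_table(
        index=["chrom", "pos", "ref", "alt"],
        columns="group",
        values=["alt_count", "total_alleles", "frequency"],
        sort=False,
    )
    return wide


def classify_rarity(maf: float) -> str:
    """Rare: MAF < 1%; common: MAF > 5%; otherwise intermediate."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]; pass the minor allele frequency")
    if maf < 0.01:
        return "rare"
    if maf > 0.05:
        return "common"
    return "intermediate"


def _contingency(alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    """groups x 2 table of (alt, ref) allele counts, dropping zero-total groups."""
    alt = np.asarray(alt, dtype=int)
    total = np.asarray(total, dtype=int)
    keep = total > 0
    return np.column_stack([alt[keep], total[keep] - alt[keep]])


def select_test(table: np.ndarray) -> str:
    """Choose chi_squared iff every expected cell count under independence
    exceeds 1; otherwise fisher_simulated."""
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2:
        raise ValueError("need >= 2 groups with nonzero totals")
    col = table.sum(axis=0)
    if (col == 0).any():
        warnings.warn("degenerate table: a column is all zero; using fisher_simulated")
        return "fisher_simulated"
    expected = np.outer(table.sum(axis=1), col) / table.sum()
    return "chi_squared" if (expected > 1).all() else "fisher_simulated"


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of an R x C table under the fixed-margins null
    (multivariate hypergeometric)."""
    table = np.asarray(table, dtype=float)
    r, c = table.sum(axis=1), table.sum(axis=0)
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(table.sum() + 1)
        - gammaln(table + 1).sum()
    )


@dataclass(frozen=True)
class FreqTestResult:
    test_used: str
    p_value: float
    n_simulations: int = 0
    statistic: float = float("nan")


def test_freq_difference(
    table: np.ndarray,
    n_sim: int = 10_000,
    seed: int | None = None,
    force_test: str | None = None,
) -> FreqTestResult:
    """Test for between-group allele-frequency differences.

    chi_squared: Pearson statistic without continuity correction,
    df = groups - 1.  fisher_simulated: Monte-Carlo sample of tables with the
    observed margins; p = (1 + #{simulated prob <= observed prob}) / (n_sim + 1).
    """
    table = np.asarray(table, dtype=int)
    choice = force_test or select_test(table)
    if choice == "chi_squared":
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return FreqTestResult("chi_squared", float(p), 0, float(stat))
    if n_sim < 1000:
        warnings.warn(f"n_sim={n_sim} < 1000 gives a coarse simulated p-value")
    rng = np.random.default_rng(seed)
    row, col = table.sum(axis=1), table.sum(axis=0)
    nz = col > 0
    lp_obs = _log_table_prob(table[:, nz])
    dist = stats.random_table(row, col[nz])
    sims = dist.rvs(n_sim, random_state=rng)
    lp = dist.logpmf(sims)
    count = int((lp <= lp_obs + 1e-9).sum())
    p = (1 + count) / (n_sim + 1)
    return FreqTestResult("fisher_simulated", float(p), n_sim, float("nan"))


@dataclass(frozen=True)
class FlipResult:
    is_flip: bool
    min_group: str
    max_group: str
    min_freq: float
    max_freq: float
    p_pairwise: float
    p_min_vs_half: float
    p_max_vs_half: float


def detect_flip(
    alt: np.ndarray,
    total: np.ndarray,
    groups: tuple[str, ...] = FREQ_GROUPS,
    alpha: float = 0.05,
) -> FlipResult:
    """Composite major/minor allele-flip criterion for one site.

    The minimum- and maximum-frequency groups are located (groups with zero
    total alleles are excluded); the site is a flip iff min < 0.5 < max, a
    one-sided Fisher's exact test on the min-vs-max 2x2 allele table is
    significant, and each extreme frequency differs from 0.5 by a one-sided
    exact binomial test, all at ``alpha``.
    """
    alt = np.asarray(alt, dtype=int)
    total = np.asarray(total, dtype=int)
    ok = total > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 groups with nonzero totals")
    freq = np.where(ok, alt / np.maximum(total, 1), np.nan)
    i_min = int(np.nanargmin(freq))
    i_max = int(np.nanargmax(freq))
    fmin, fmax = freq[i_min], freq[i_max]
    candidate = fmin < 0.5 < fmax
    pair_table = [
        [alt[i_max], total[i_max] - alt[i_max]],
        [alt[i_min], total[i_min] - alt[i_min]],
    ]
    p_pair = float(stats.fisher_exact(pair_table, alternative="greater").pvalue)
    p_min = float(
        stats.binomtest(int(alt[i_min]), int(total[i_min]), 0.5, alternative="less").pvalue
    )
    p_max = float(
        stats.binomtest(int(alt[i_max]), int(total[i_max]), 0.5, alternative="greater").pvalue
    )
    is_flip = bool(candidate and p_pair < alpha and p_min < alpha and p_max < alpha)
    return FlipResult(
        is_flip=is_flip,
        min_group=groups[i_min],
        max_group=groups[i_max],
        min_freq=float(fmin),
        max_freq=float(fmax),
        p_pairwise=p_pair,
        p_min_vs_half=p_min,
        p_max_vs_half=p_max,
    )


LOW_ADMIXTURE_GROUPS = frozenset({"African", "CentralAsian", "EastAsian", "European"})


def group_specific_common(table: pd.DataFrame) -> pd.DataFrame:
    """Variants common (>5%) in some group whose alt alleles occur in exactly
    one group.

    Returns one row per qualifying site with the carrying group and whether it
    is one of the four low-admixture ancestry groups.
    """
    rows = []
    for key, sub in table.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        sub = sub[sub.total_alleles > 0]
        if sub.empty or sub.frequency.max() <= 0.05:
            continue
        carrying = sub[sub.alt_count > 0]
        if len(carrying) != 1:
            continue
        g = carrying.iloc[0].group
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "group": g,
                "frequency": float(carrying.iloc[0].frequency),
                "low_admixture_group": g in LOW_ADMIXTURE_GROUPS,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "group", "frequency", "low_admixture_group"],
    )


def reference_minor_positions(table: pd.DataFrame) -> pd.DataFrame:
    """Sites whose alt frequency exceeds 0.5 in every group — positions where
    the reference assembly likely carries the minor allele."""
    rows = []
    for key, sub in table.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        sub = sub[sub.total_alleles > 0]
        if len(sub) and (sub.frequency > 0.5).all():
            rows.append(dict(zip(["chrom", "pos", "ref", "alt"], key)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def reconstruct_allele_counts(
    freqs: np.ndarray,
    group_sizes: np.ndarray,
    chrom: str = "chr1",
    male_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild integer allele counts from published rounded frequencies and
    group sizes.

    Autosomes: total alleles = 2n per group.  Chromosome X (non-PAR): males are
    hemizygous, total = 2n - round(male_fraction * n).  Alt counts are
    round(freq * total).
    """
    n = np.asarray(group_sizes, dtype=int)
    if _is_x(chrom):
        males = np.round(male_fraction * n).astype(int)
        total = 2 * n - males
    else:
        total = 2 * n
    alt = np.round(np.asarray(freqs, dtype=float) * total).astype(int)
    return alt, total
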