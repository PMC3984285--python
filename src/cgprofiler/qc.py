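"""Two-stage genotype reliability filtering and cross-validated error rates.

The position filter excludes whole sites with a cohort call rate below 80% or
an average fractional allele depth of at most 0.295; the genotype filter masks
individual calls whose minimum carried-allele depth is at most 11.  The
thresholds are published constants of the upstream decision-tree model; no
re-training happens here.

"Minimum allele depth" is taken over the alleles actually carried by the
genotype (both alleles of a het, the single allele of a hom), and "fractional
allele depth" of a call is the depth of its less-supported carried allele
divided by the total depth (for hom calls, the carried allele's fraction).
Both definitions are configurable assumptions; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import NO_CALL, CohortGenotypes

#: published filter constants
DEFAULT_MIN_CALL_RATE = 0.80
DEFAULT_MIN_FRAC_DEPTH = 0.295  # exclusive: sites with avg frac depth <= this fail
DEFAULT_MIN_ALLELE_DEPTH = 11  # inclusive: calls with min carried depth <= this masked


@dataclass(frozen=True)
class FilterThresholds:
    min_call_rate: float = DEFAULT_MIN_CALL_RATE
    min_frac_depth: float = DEFAULT_MIN_FRAC_DEPTH
    min_allele_depth: int = DEFAULT_MIN_ALLELE_DEPTH


@dataclass(frozen=True)
class SiteQuality:
    call_rate: float
    avg_fractional_allele_depth: float  # NaN when no called genotype has depth


@dataclass
class FilterOutcome:
    site_keep: np.ndarray  # bool per site
    genotype_mask: np.ndarray  # bool (n_subjects, n_kept_sites); True = masked
    site_quality: pd.DataFrame
    mask_report: pd.DataFrame  # subject, chrom, pos, ref, alt, reason


def _carried_min_depth(dosage: np.ndarray, ref_d: np.ndarray, alt_d: np.ndarray) -> np.ndarray:
    """Minimum depth over the alleles carried by each called genotype."""
    out = np.where(
        dosage == 1,
        np.minimum(ref_d, alt_d),
        np.where(dosage >= 2, alt_d, ref_d),
    )
    return out


def _fractional_depth(dosage: np.ndarray, ref_d: np.ndarray, alt_d: np.ndarray) -> np.ndarray:
    """Less-supported carried allele depth / total depth; NaN for no-calls or zero depth."""
    total = (ref_d + alt_d).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.minimum(ref_d, alt_d) / total
        hom_ref = ref_d / total
        hom_alt = alt_d / total
    frac = np.where(dosage == 1, het, np.where(dosage >= 2, hom_alt, hom_ref))
    frac = np.where((dosage == NO_CALL) | (total == 0), np.nan, frac)
    return frac


def site_quality(cohort: CohortGenotypes) -> pd.DataFrame:
    """Per-site call rate and average fractional allele depth, on raw calls."""
    called = cohort.called()
    call_rate = called.mean(axis=0)
    frac = _fractional_depth(cohort.dosage, cohort.ref_depth, cohort.alt_depth)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        avg_frac = np.nanmean(np.where(called, frac, np.nan), axis=0)
    return pd.DataFrame(
        {"call_rate": call_rate, "avg_fractional_allele_depth": avg_frac}
    )


def apply_position_filter(
    quality: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> np.ndarray:
    """Keep mask per site: fails on call rate < 80% or avg fractional depth <= 0.295.

    Sites whose fractional depth is undefined (no called genotype with reads)
    fail the filter.
    """
    cr = quality["call_rate"].to_numpy()
    fd = quality["avg_fractional_allele_depth"].to_numpy()
    keep = (cr >= thresholds.min_call_rate) & (fd > thresholds.min_frac_depth)
    keep &= ~np.isnan(fd)
    return keep


def apply_genotype_filter(
    cohort: CohortGenotypes, thresholds: FilterThresholds = FilterThresholds()
) -> np.ndarray:
    """Mask (True) called genotypes whose minimum carried-allele depth is <= 11."""
    called = cohort.called()
    min_depth = _carried_min_depth(cohort.dosage, cohort.ref_depth, cohort.alt_depth)
    return called & (min_depth <= thresholds.min_allele_depth)


def filter_cohort(
    cohort: CohortGenotypes, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[CohortGenotypes, FilterOutcome]:
    """Apply the position filter then the genotype filter.

    Returns the filtered cohort (failed sites dropped, masked genotypes set to
    no-call) and a FilterOutcome describing what was removed.
    """
    quality = site_quality(cohort)
    keep = apply_position_filter(quality, thresholds)
    kept = cohort.subset_sites(keep)
    gmask = apply_genotype_filter(kept, thresholds)
    filtered = kept.with_mask(gmask)

    subj_idx, site_idx = np.nonzero(gmask)
    report = pd.DataFrame(
        {
            "subject": [kept.subjects[i] for i in subj_idx],
            "chrom": kept.sites.chrom.to_numpy()[site_idx],
            "pos": kept.sites.pos.to_numpy()[site_idx],
            "ref": kept.sites.ref.to_numpy()[site_idx],
            "alt": kept.sites.alt.to_numpy()[site_idx],
            "reason": f"min_allele_depth<={thresholds.min_allele_depth}",
        }
    )
    return filtered, FilterOutcome(
        site_keep=keep, genotype_mask=gmask, site_quality=quality, mask_report=report
    )


def estimate_error_rates(
    labeled: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> dict:
    """Estimate post-filter false-negative and false-positive rates by
    stratified k-fold cross-validation against validated genotypes.

    ``labeled`` needs columns: dosage, ref_depth, alt_depth, truth_variant
    (bool: validation says a non-reference genotype is present), called_variant
    (bool: the pipeline called a non-reference genotype).  The filters are fixed
    constants, so cross-validation here estimates hold-out error honestly
    without any fitting step: each fold is evaluated with the published
    thresholds.

    FN = truth-positive calls that are filtered out or called non-variant;
    FP = truth-negative calls that pass the filters as variant.
    Returns rates with binomial (Clopper-Pearson) 95% intervals.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    y = labeled["truth_variant"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both truth classes must be present")
    if min((~y).sum(), y.sum()) < k:
        raise ValueError(f"need >= {k} entries per class for {k}-fold CV")

    dosage = labeled["dosage"].to_numpy()
    min_depth = _carried_min_depth(
        dosage, labeled["ref_depth"].to_numpy(), labeled["alt_depth"].to_numpy()
    )
    masked = (dosage != NO_CALL) & (min_depth <= thresholds.min_allele_depth)
    called_variant = labeled["called_variant"].to_numpy(dtype=bool) & ~masked
    called_variant &= dosage != NO_CALL

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fn = fp = n_pos = n_neg = 0
    for _, test_idx in skf.split(np.zeros(len(y)), y):
        yt, ct = y[test_idx], called_variant[test_idx]
        fn += int((yt & ~ct).sum())
        fp += int((~yt & ct).sum())
        n_pos += int(yt.sum())
        n_neg += int((~yt).sum())
    fn_lo, fn_hi = proportion_confint(fn, n_pos, alpha=0.05, method="beta")
    fp_lo, fp_hi = proportion_confint(fp, n_neg, alpha=0.05, method="beta")
    return {
        "false_negative_rate": fn / n_pos,
        "false_negative_ci": (fn_lo, fn_hi),
        "false_positive_rate": fp / n_neg,
        "false_positive_ci": (fp_lo, fp_hi),
        "n_truth_positive": n_pos,
        "n_truth_negative": n_neg,
        "k": k,
    }
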