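"""Packaged reference tables from the published cohort study.

``subpopulation_sizes``: the seven ancestry-based subpopulation sizes of the
681-subject reference cohort.  ``reported_flip_sites``: the 21 sites reported
with ancestry-dependent major alleles — per-group nonreference allele
frequencies as printed, used to validate the flip criterion against in-study
data (genotype-level data are not public, so integer allele counts are
reconstructed from the rounded frequencies and group sizes).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .popstats import FREQ_GROUPS, reconstruct_allele_counts

_FREQ_COLS = [
    "f_African",
    "f_AfricanEuropean",
    "f_CentralAsian",
    "f_EastAsian",
    "f_European",
    "f_Hispanic",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("cgprofiler.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def subpopulation_sizes() -> pd.DataFrame:
    """Subpopulation sizes of the reference cohort (columns: subpopulation,
    n_individuals)."""
    return _read("subpopulation_sizes.tsv")


def reported_flip_sites() -> pd.DataFrame:
    """The 21 reported major/minor-allele-flip sites with per-group
    nonreference allele frequencies."""
    return _read("reported_flip_sites.tsv")


def reconstructed_flip_counts(male_fraction: float = 0.5) -> list[dict]:
    """Integer (alt, total) allele counts per group for each reported flip site.

    Autosomal sites use 2 alleles per subject; the X-linked site uses the
    hemizygote ploidy rule with the given male fraction.  Returns one dict per
    site with keys gene, chrom, freqs, alt, total.
    """
    flips = reported_flip_sites()
    sizes = subpopulation_sizes().set_index("subpopulation")["n_individuals"]
    group_n = np.array([sizes[g] for g in FREQ_GROUPS])
    out = []
    for row in flips.itertuples(index=False):
        chrom = row.position.split(":")[0]
        freqs = np.array([getattr(row, c) for c in _FREQ_COLS], dtype=float)
        alt, total = reconstruct_allele_counts(
            freqs, group_n, chrom=chrom, male_fraction=male_fraction
        )
        out.append(
            {
                "gene": row.gene,
                "chrom": chrom,
                "position": row.position,
                "freqs": freqs,
                "alt": alt,
                "total": total,
            }
        )
    return out
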