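#!/usr/bin/env python
"""Ancestry-stratified allele-frequency statistics for the common variants.

Computes per-group allele counts (Other excluded), tests between-group
frequency differences for every variant common (>5%) in at least one group
(chi-squared when all expected cells exceed 1, otherwise Fisher's exact test
with simulated p-values), and reports major/minor allele flips, single-group
common variants, and positions where the reference carries the minor allele.

Reads results/filter/ and results/ancestry/; writes results/popstats/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cgprofiler import popstats
from cgprofiler.cohort import read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2014
ALPHA = 0.05


def main() -> None:
    filtered = read_vcf(ROOT / "filter" / "filtered.vcf")
    subpop = pd.read_csv(ROOT / "ancestry" / "subpopulations.tsv", sep="\t")
    table = popstats.group_allele_counts(filtered, subpop)
    out = ROOT / "popstats"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "group_frequencies.tsv", sep="\t", index=False, float_format="%.12g")

    rng = np.random.default_rng(SEED)
    common, tests, flips = 0, [], []
    for key, sub in table.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        if sub.frequency.max() <= 0.05:
            continue
        common += 1
        alt, tot = sub.alt_count.to_numpy(), sub.total_alleles.to_numpy()
        ct = popstats._contingency(alt, tot)
        res = popstats.test_freq_difference(ct, seed=int(rng.integers(2**31 - 1)))
        tests.append({"key": key, "test": res.test_used, "p": res.p_value})
        fr = popstats.detect_flip(alt, tot, groups=tuple(sub.group), alpha=ALPHA)
        if fr.is_flip:
            flips.append(
                {
                    "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                    "min_group": fr.min_group, "max_group": fr.max_group,
                    "min_freq": fr.min_freq, "max_freq": fr.max_freq,
                }
            )
    tests_df = pd.DataFrame(tests)
    flips_df = pd.DataFrame(flips)
    flips_df.to_csv(out / "allele_flips.tsv", sep="\t", index=False, float_format="%.12g")
    gs = popstats.group_specific_common(table)
    gs.to_csv(out / "group_specific_common.tsv", sep="\t", index=False, float_format="%.12g")
    rm = popstats.reference_minor_positions(table)
    rm.to_csv(out / "reference_minor_positions.tsv", sep="\t", index=False)

    n_sig = int((tests_df.p < ALPHA).sum()) if len(tests_df) else 0
    print(f"{common} variants common (>5%) in at least one group")
    print(f"  {n_sig} with significant between-group frequency differences (p < {ALPHA})")
    print(f"  {len(flips_df)} major/minor allele flips detected")
    print(f"  {len(gs)} common variants specific to a single group "
          f"({gs.low_admixture_group.sum()} in low-admixture groups)")
    print(f"  {len(rm)} positions with the nonreference allele >50% in every group")


if __name__ == "__main__":
    main()
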