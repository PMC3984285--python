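#!/usr/bin/env python
"""Apply the two-stage genotype reliability filter to the simulated cohort.

Position filter: drop sites with cohort call rate < 80% or average fractional
allele depth <= 0.295.  Genotype filter: mask calls whose minimum carried-allele
depth is <= 11.  A validation subset of 341 labelled genotypes is used to
estimate post-filter error rates by 10-fold cross-validation.

Reads results/cohort/; writes results/filter/ (filtered VCF, site quality,
mask report, error-rate estimates).
"""

import json
from pathlib import Path

from cgprofiler.cohort import read_vcf, write_vcf
from cgprofiler.qc import estimate_error_rates, filter_cohort
from cgprofiler.simulate import GeneratorConfig, emit_validation_set, generate_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2014


def main() -> None:
    cohort = read_vcf(ROOT / "cohort" / "cohort.vcf")
    filtered, outcome = filter_cohort(cohort)
    out = ROOT / "filter"
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(filtered, out / "filtered.vcf")
    outcome.site_quality.assign(kept=outcome.site_keep).to_csv(
        out / "site_quality.tsv", sep="\t", index=False, float_format="%.12g"
    )
    outcome.mask_report.to_csv(out / "genotype_mask.tsv", sep="\t", index=False)
    print(f"position filter excluded {(~outcome.site_keep).sum()} of {cohort.n_sites} sites")
    print(f"genotype filter masked {outcome.genotype_mask.sum()} calls")

    # error-rate estimation on a labelled validation subset (errors planted at
    # low depth, where the genotype filter operates)
    syn = generate_cohort(GeneratorConfig(seed=SEED))
    labeled = emit_validation_set(syn, n=341, fp_rate=0.05, fn_rate=0.02, seed=SEED)
    rates = estimate_error_rates(labeled, k=10, seed=SEED)
    with open(out / "error_rates.json", "w") as fh:
        json.dump({k: v for k, v in rates.items() if k != "k"}, fh, indent=1, default=list)
    print(
        f"10-fold CV error rates: FN {rates['false_negative_rate']:.3f} "
        f"(95% CI {rates['false_negative_ci'][1]:.3f} upper), "
        f"FP {rates['false_positive_rate']:.3f} "
        f"(95% CI {rates['false_positive_ci'][1]:.3f} upper)"
    )


if __name__ == "__main__":
    main()
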