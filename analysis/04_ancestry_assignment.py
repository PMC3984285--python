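#!/usr/bin/env python
"""Estimate admixture coefficients and assign ancestry-based subpopulations.

Per-subject coefficients over six ancestral populations are estimated by
supervised EM against the fixed marker panel; subjects are then clustered with
the dominant-ancestry / African-European / Hispanic threshold rules, and
clusters below 20 members are aggregated into "Other".

Reads results/cohort/; writes results/ancestry/.
"""

from pathlib import Path

import pandas as pd

from cgprofiler.ancestry import (
    AncestralPanel,
    assign_subpopulations,
    cluster_subjects,
    estimate_admixture,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = AncestralPanel.from_tsv(ROOT / "cohort" / "panel.tsv")
    dosage_df = pd.read_csv(ROOT / "cohort" / "panel_dosage.tsv", sep="\t", index_col=0)
    res = estimate_admixture(dosage_df.to_numpy(), panel, subjects=list(dosage_df.index))
    labels = cluster_subjects(res.q)
    subpop = assign_subpopulations(res.subjects, labels)
    out = ROOT / "ancestry"
    out.mkdir(parents=True, exist_ok=True)
    res.to_frame().to_csv(out / "admixture.tsv", sep="\t", index=False, float_format="%.12g")
    subpop.to_csv(out / "subpopulations.tsv", sep="\t", index=False)
    sizes = subpop.subpopulation.value_counts()
    print("subpopulation sizes:")
    print(sizes.to_string())
    truth = pd.read_csv(ROOT / "cohort" / "subjects.tsv", sep="\t")
    agree = (subpop.subpopulation.to_numpy() == truth.group.to_numpy()).mean()
    print(f"agreement with generating groups: {agree:.1%}")


if __name__ == "__main__":
    main()
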