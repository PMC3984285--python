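"""End-to-end generator calibration metrics.

Runs the full pipeline on a synthetic cohort — quality filtering, consequence
annotation, per-individual profiling — and measures the quantities the
generator is calibrated to reproduce: the rare-heavy site-frequency spectrum
(fraction of segregating nonsynonymous sites carried by one, and by at most
two, individuals) and the mean nonsynonymous variant load per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import annotate_cohort
from .genes import gene_models_from_frames
from .profiles import individual_profiles
from .qc import filter_cohort
from .simulate import GeneratorConfig, SyntheticCohort, generate_cohort


def cohort_metrics(syn: SyntheticCohort) -> dict:
    """Filter, annotate and profile one synthetic cohort; return its summary."""
    filtered, outcome = filter_cohort(syn.cohort)
    models, _ = gene_models_from_frames(syn.transcripts, syn.gene_list)
    classes = annotate_cohort(filtered, models, syn.genome, syn.annotations)
    nonsyn = classes["nonsynonymous"].to_numpy(dtype=bool)

    carriers = (filtered.dosage > 0).sum(axis=0)
    segregating = nonsyn & (carriers > 0)
    n_seg = int(segregating.sum())
    singleton = int((carriers[segregating] == 1).sum())
    le2 = int((carriers[segregating] <= 2).sum())

    prof = individual_profiles(filtered, classes)
    return {
        "n_sites_segregating": n_seg,
        "pct_singleton": 100.0 * singleton / n_seg,
        "pct_le2_carriers": 100.0 * le2 / n_seg,
        "mean_load": float(prof.n_total.mean()),
        "mean_hgmd": float(prof.n_hgmd.mean()),
        "mean_deleterious": float(prof.n_deleterious.mean()),
        "mean_vus": float(prof.n_vus.mean()),
        "n_sites_excluded": int((~outcome.site_keep).sum()),
        "n_genotypes_masked": int(outcome.genotype_mask.sum()),
        "profiles": prof,
        "classes": classes,
        "filtered": filtered,
    }


def calibration_summary(
    seeds: list[int], config_kwargs: dict | None = None
) -> pd.DataFrame:
    """Per-seed calibration metrics for a list of generator seeds."""
    rows = []
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, **(config_kwargs or {}))
        syn = generate_cohort(cfg)
        m = cohort_metrics(syn)
        rows.append(
            {
                "seed": seed,
                "n_sites_segregating": m["n_sites_segregating"],
                "pct_singleton": m["pct_singleton"],
                "pct_le2_carriers": m["pct_le2_carriers"],
                "mean_load": m["mean_load"],
                "mean_hgmd": m["mean_hgmd"],
                "mean_deleterious": m["mean_deleterious"],
                "mean_vus": m["mean_vus"],
            }
        )
    return pd.DataFrame(rows)


def seeds_from(master_seed: int, n: int = 20) -> list[int]:
    """Derive ``n`` independent generator seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
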