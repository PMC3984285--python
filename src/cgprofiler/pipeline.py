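"""End-to-end pipeline: simulate (optional) -> filter -> annotate -> ancestry
-> popstats -> profiling, with per-stage TSV outputs and a JSON summary.

Every published threshold is a config key with its published default; the log
records the thresholds and seed for provenance.  Stage outputs are pure
functions of (inputs, config, seed); floating-point text is rounded to 12
significant digits so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import popstats
from .annotate import annotate_cohort
from .cohort import read_vcf
from .genes import coding_length, gene_models_from_frames
from .profiles import (
    ancova_gene_type,
    anova_by_group,
    gene_profiles,
    individual_profiles,
    variability_rate,
)
from .qc import FilterThresholds, filter_cohort
from .simulate import GeneratorConfig, generate_cohort

log = logging.getLogger("cgprofiler")

FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    vcf: str | None = None
    transcripts: str | None = None
    gene_list: str | None = None
    annotations: str | None = None
    genome: str | None = None
    panel: str | None = None
    panel_dosage: str | None = None
    subjects: str | None = None  # TSV with subject, sex
    # published thresholds
    min_call_rate: float = 0.80
    min_frac_depth: float = 0.295
    min_allele_depth: int = 11
    maf_rare: float = 0.01
    maf_common: float = 0.05
    alpha: float = 0.05
    min_cluster_size: int = 20
    n_sim: int = 10_000
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_call_rate=self.min_call_rate,
            min_frac_depth=self.min_frac_depth,
            min_allele_depth=self.min_allele_depth,
        )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _load_genome(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the JSON-ready summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "thresholds": asdict(config.thresholds())}
    t0 = time.time()
    try:
        # ---------------------------------------------------------- inputs
        if config.simulate:
            gen_cfg = GeneratorConfig(seed=config.seed, **config.generator)
            syn = generate_cohort(gen_cfg)
            cohort = syn.cohort
            tx_df, gene_df = syn.transcripts, syn.gene_list
            annotations = syn.annotations
            genome = syn.genome
            panel, panel_dosage = syn.panel, syn.panel_dosage
            syn.write(out / "inputs")
            log.info("stage simulate: %d subjects, %d sites", cohort.n_subjects, cohort.n_sites)
        else:
            for name in ("vcf", "transcripts", "gene_list", "annotations", "genome"):
                if getattr(config, name) is None:
                    raise ValueError(f"simulate=False requires input path {name!r}")
            sex = None
            if config.subjects:
                subj = pd.read_csv(config.subjects, sep="\t")
                sex = subj.set_index("subject")["sex"]
            cohort = read_vcf(config.vcf)
            if sex is not None:
                cohort.sex = np.array([sex.get(s, "F") for s in cohort.subjects])
            tx_df = pd.read_csv(config.transcripts, sep="\t")
            gene_df = pd.read_csv(config.gene_list, sep="\t")
            annotations = pd.read_csv(config.annotations, sep="\t")
            genome = _load_genome(config.genome)
            panel = anc.AncestralPanel.from_tsv(config.panel) if config.panel else None
            panel_dosage = (
                pd.read_csv(config.panel_dosage, sep="\t", index_col=0).to_numpy()
                if config.panel_dosage
                else None
            )

        # ---------------------------------------------------------- filter
        filtered, outcome = filter_cohort(cohort, config.thresholds())
        _write(outcome.site_quality.assign(kept=outcome.site_keep), out / "site_quality.tsv")
        _write(outcome.mask_report, out / "genotype_mask.tsv")
        summary["filter"] = {
            "n_sites_in": cohort.n_sites,
            "n_sites_excluded": int((~outcome.site_keep).sum()),
            "n_genotypes_masked": int(outcome.genotype_mask.sum()),
        }
        log.info("stage filter: %s", summary["filter"])

        # -------------------------------------------------------- annotate
        models, missing_genes = gene_models_from_frames(tx_df, gene_df)
        classes = annotate_cohort(filtered, models, genome, annotations)
        _write(classes, out / "annotated_sites.tsv")
        nonsyn = classes["nonsynonymous"]
        summary["annotate"] = {
            "n_genes": len(models),
            "n_genes_missing": len(missing_genes),
            "n_sites": int(len(classes)),
            "n_nonsynonymous": int(nonsyn.sum()),
            "n_deleterious": int(classes.deleterious.sum()),
            "n_hgmd": int(classes.hgmd.sum()),
            "n_vus": int(classes.vus.sum()),
            "n_novel": int(classes.novel.sum()),
        }
        log.info("stage annotate: %s", summary["annotate"])

        # -------------------------------------------------------- ancestry
        if panel is not None and panel_dosage is not None:
            adm = anc.estimate_admixture(panel_dosage, panel, subjects=filtered.subjects)
            labels = anc.cluster_subjects(adm.q)
            subpop = anc.assign_subpopulations(
                filtered.subjects, labels, min_cluster_size=config.min_cluster_size
            )
            _write(adm.to_frame(), out / "admixture.tsv")
            _write(subpop, out / "subpopulations.tsv")
            sizes = subpop.subpopulation.value_counts().to_dict()
            summary["ancestry"] = {"group_sizes": sizes}
            log.info("stage ancestry: %s", sizes)
        else:
            subpop = pd.DataFrame(
                {"subject": filtered.subjects, "subpopulation": "Other"}
            )
            summary["ancestry"] = {"group_sizes": {"Other": filtered.n_subjects}}
            log.info("stage ancestry: skipped (no panel)")

        # -------------------------------------------------------- popstats
        freq_groups = [
            g for g in popstats.FREQ_GROUPS
            if (subpop.subpopulation == g).sum() > 0
        ]
        if not freq_groups:
            summary["popstats"] = "skipped: no ancestry-based subpopulation of sufficient size"
            log.info("stage popstats: skipped, all subjects in Other")
        else:
            table = popstats.group_allele_counts(
                filtered, subpop, groups=tuple(freq_groups)
            )
            _write(table, out / "group_frequencies.tsv")
            rng = np.random.default_rng(config.seed + 1)
            common_keys = (
                table[table.frequency > config.maf_common]
                .loc[:, ["chrom", "pos", "ref", "alt"]]
                .drop_duplicates()
            )
            tests, flips = [], []
            grouped = table.set_index(["chrom", "pos", "ref", "alt"])
            for key in common_keys.itertuples(index=False):
                sub = table[
                    (table.chrom == key.chrom)
                    & (table.pos == key.pos)
                    & (table.ref == key.ref)
                    & (table.alt == key.alt)
                ]
                alt = sub.alt_count.to_numpy()
                tot = sub.total_alleles.to_numpy()
                ct = popstats._contingency(alt, tot)
                if len(ct) < 2:
                    continue
                res = popstats.test_freq_difference(
                    ct, n_sim=config.n_sim, seed=int(rng.integers(2**31 - 1))
                )
                tests.append(
                    {
                        **key._asdict(),
                        "test_used": res.test_used,
                        "p_value": res.p_value,
                        "significant": res.p_value < config.alpha,
                    }
                )
                fr = popstats.detect_flip(alt, tot, groups=tuple(sub.group), alpha=config.alpha)
                if fr.is_flip:
                    flips.append(
                        {
                            **key._asdict(),
                            "min_group": fr.min_group,
                            "max_group": fr.max_group,
                            "min_freq": fr.min_freq,
                            "max_freq": fr.max_freq,
                            "p_pairwise": fr.p_pairwise,
                        }
                    )
            tests_df = pd.DataFrame(tests)
            flips_df = pd.DataFrame(flips)
            _write(tests_df, out / "frequency_tests.tsv")
            _write(flips_df, out / "allele_flips.tsv")
            gs = popstats.group_specific_common(table)
            _write(gs, out / "group_specific_common.tsv")
            rm = popstats.reference_minor_positions(table)
            _write(rm, out / "reference_minor_positions.tsv")
            summary["popstats"] = {
                "n_common": int(len(common_keys)),
                "n_significant": int(tests_df.significant.sum()) if len(tests_df) else 0,
                "n_flips": int(len(flips_df)),
                "n_group_specific": int(len(gs)),
                "n_reference_minor": int(len(rm)),
            }
            log.info("stage popstats: %s", summary["popstats"])

        # ------------------------------------------------------- profiling
        lengths = {m.gene_symbol: coding_length(m) for m in models}
        prof = individual_profiles(filtered, classes)
        _write(prof, out / "individual_profiles.tsv")
        gprof = gene_profiles(filtered, classes, lengths)
        gtypes = gene_df.set_index("gene_symbol")["gene_type"]
        gprof["gene_type"] = gprof.gene.map(gtypes)
        _write(gprof, out / "gene_profiles.tsv")
        rate = variability_rate(gprof)
        summary["profiling"] = {
            "mean_variants_per_person": float(prof.n_total.mean()),
            "range_variants_per_person": [int(prof.n_total.min()), int(prof.n_total.max())],
            "mean_hgmd": float(prof.n_hgmd.mean()),
            "mean_deleterious": float(prof.n_deleterious.mean()),
            "mean_vus": float(prof.n_vus.mean()),
            "variants_per_kb": rate.slope_per_kb,
            "r_squared": rate.r_squared,
        }
        if isinstance(summary["popstats"], dict):
            try:
                f, p = anova_by_group(prof, subpop, "n_total")
                summary["profiling"]["anova_total_p"] = p
            except ValueError as exc:
                log.info("anova skipped: %s", exc)
            try:
                f, p = ancova_gene_type(gprof)
                summary["profiling"]["ancova_gene_type_p"] = p
            except ValueError as exc:
                log.info("ancova skipped: %s", exc)
        log.info("stage profiling: %s", summary["profiling"])

        summary["runtime_s"] = round(time.time() - t0, 2)
        with open(out / "summary.json", "w") as fh:
            json.dump(_round_floats(summary, 12), fh, indent=1, sort_keys=True)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _round_floats(obj, sig: int):
    if isinstance(obj, float):
        return float(f"%.{sig}g" % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj
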