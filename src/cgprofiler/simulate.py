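"""Synthetic admixed cohort generator with full truth tables.

Generates everything the pipeline consumes — genotypes with read depths, a toy
genome and transcript set, annotation tables, an ancestral marker panel — with
the statistical structure the analysis assumes:

* 681 subjects in 7 ancestry-based groups (sizes 43 / 46 / 50 / 62 / 331 /
  118 / 31), each subject an admixture of 6 ancestral populations drawn from a
  group-specific Dirichlet;
* a rare-heavy site-frequency spectrum: 65% of segregating nonsynonymous sites
  are singletons and 10% doubletons, planted by direct carrier assignment;
* a common stratum with Balding-Nichols group-divergent frequencies whose
  scale is calibrated so the expected nonsynonymous variant load is 68 sites
  per subject after genotype masking;
* planted major/minor-allele flips, reference-minor sites (alt frequency
  >0.5 in every ancestral population) and single-group common variants;
* read depths around a mean coverage of 58x, with configurable fractions of
  planted low-call-rate sites, low-fractional-depth sites and low-depth
  genotypes for the quality filters to catch.

Variant alleles are constructed by explicit codon surgery (e.g. AAA->TAA for a
nonsense site), so consequence truth is fixed independently of the annotation
code under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ancestry import POPULATIONS, AncestralPanel
from .cohort import NO_CALL, CohortGenotypes, write_vcf
from .effects import normalize_variant

GROUP_SIZES_DEFAULT = {
    "African": 43,
    "African-European": 46,
    "CentralAsian": 50,
    "EastAsian": 62,
    "European": 331,
    "Hispanic": 118,
    "Other": 31,
}

#: mean ancestry vector (order: African, European, NativeAmerican, EastAsian,
#: CentralAsian, Oceanic) and Dirichlet concentration per group
DIRICHLET_PARAMS: dict[str, tuple[list[float], float]] = {
    "African": ([0.92, 0.06, 0.002, 0.006, 0.006, 0.006], 300.0),
    "African-European": ([0.45, 0.54, 0.002, 0.003, 0.003, 0.002], 150.0),
    "CentralAsian": ([0.005, 0.05, 0.002, 0.02, 0.915, 0.008], 300.0),
    "EastAsian": ([0.003, 0.02, 0.002, 0.92, 0.045, 0.01], 300.0),
    "European": ([0.01, 0.93, 0.003, 0.007, 0.045, 0.005], 300.0),
    "Hispanic": ([0.08, 0.50, 0.35, 0.04, 0.02, 0.01], 60.0),
    "Other": ([0.0, 0.40, 0.0, 0.30, 0.25, 0.05], 50.0),
}

GROUP_SPECIFIC_DEFAULT = {"African": 49, "CentralAsian": 2, "EastAsian": 6, "European": 1}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# codon surgery options: (reference codon, offset within codon, alt base)
_MISSENSE_OPS = [("AAA", 0, "G"), ("CGT", 1, "A"), ("GAC", 2, "A")]
_NONSENSE_OPS = [("AAA", 0, "T"), ("TGC", 2, "A"), ("CAG", 0, "T")]
_SYNONYMOUS_OPS = [("GGA", 2, "G"), ("CTA", 2, "G"), ("GTT", 2, "C")]

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES_DEFAULT))
    n_genes: int = 158
    gene_type_counts: dict[str, int] = field(
        default_factory=lambda: {"tumor_suppressor": 60, "oncogene": 60, "predisposition": 38}
    )
    #: nonsynonymous variant sites per kb of coding sequence, by gene type
    variants_per_kb: dict[str, float] = field(
        default_factory=lambda: {"tumor_suppressor": 5.0, "oncogene": 5.0, "predisposition": 8.0}
    )
    mean_coding_length: float = 2975.0  # bases; lognormal across genes
    coding_length_sigma: float = 0.6
    singleton_frac: float = 0.65
    doubleton_frac: float = 0.10
    n_flips: int = 21
    n_reference_minor: int = 14
    group_specific_counts: dict[str, int] = field(
        default_factory=lambda: dict(GROUP_SPECIFIC_DEFAULT)
    )
    target_mean_load: float = 68.0
    #: deleterious-category site counts; the "common" share is placed on
    #: common-stratum sites so per-person deleterious counts are realistic
    n_nonsense: int = 22
    n_frameshift: int = 42
    n_splice: int = 16
    n_inframe: int = 5
    n_deleterious_common: int = 21
    synonymous_extra_frac: float = 0.05
    depth_mean: float = 58.0
    n_low_callrate_sites: int = 30
    n_low_fracdepth_sites: int = 30
    low_depth_genotype_rate: float = 0.01
    hgmd_rate_common: float = 0.21
    hgmd_rate_rare: float = 0.092
    known_rate_rare: float = 0.427
    male_fraction: float = 337 / 681
    panel_markers: int = 2000
    panel_missing_rate: float = 0.01
    balding_nichols_fst: float = 0.08
    filler_beta: tuple[float, float] = (0.7, 18.0)

    def validate(self) -> None:
        for name in (
            "singleton_frac",
            "doubleton_frac",
            "low_depth_genotype_rate",
            "hgmd_rate_common",
            "hgmd_rate_rare",
            "known_rate_rare",
            "male_fraction",
            "panel_missing_rate",
            "synonymous_extra_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.singleton_frac + self.doubleton_frac >= 1.0:
            raise ValueError("singleton + doubleton fractions must leave a common stratum")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")


@dataclass
class TruthTables:
    """Ground truth for every emitted subject, site and genotype."""

    subjects: pd.DataFrame  # subject, group, sex, q_<pop> columns
    sites: pd.DataFrame  # aligned with the cohort sites; stratum/category/flags
    planted_low_depth: np.ndarray  # bool (n_subjects, n_sites)
    q_true: np.ndarray  # (n_subjects, 6)


@dataclass
class SyntheticCohort:
    cohort: CohortGenotypes
    truth: TruthTables
    genome: dict[str, str]
    transcripts: pd.DataFrame  # knownGene-style rows
    gene_list: pd.DataFrame  # gene_symbol, gene_type, census_reason
    annotations: pd.DataFrame  # chrom,pos,ref,alt,known_id,hgmd,polyphen_score
    panel: AncestralPanel
    panel_dosage: np.ndarray  # (n_subjects, n_markers), -1 missing
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF, FASTA, TSVs and the truth JSON; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "genome": out / "genome.fa",
            "transcripts": out / "transcripts.tsv",
            "gene_list": out / "gene_list.tsv",
            "annotations": out / "annotations.tsv",
            "panel": out / "panel.tsv",
            "panel_dosage": out / "panel_dosage.tsv",
            "subjects": out / "subjects.tsv",
            "truth_sites": out / "truth_sites.tsv",
            "truth": out / "truth.json",
        }
        write_vcf(self.cohort, paths["vcf"])
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.transcripts.to_csv(paths["transcripts"], sep="\t", index=False)
        self.gene_list.to_csv(paths["gene_list"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.panel.to_tsv(paths["panel"])
        pd.DataFrame(
            self.panel_dosage,
            index=pd.Index(self.cohort.subjects, name="subject"),
        ).to_csv(paths["panel_dosage"], sep="\t")
        self.truth.subjects.to_csv(paths["subjects"], sep="\t", index=False)
        self.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": self.config.seed,
                    "n_subjects": self.cohort.n_subjects,
                    "n_sites": self.cohort.n_sites,
                    "planted_low_depth_count": int(self.truth.planted_low_depth.sum()),
                },
                fh,
                indent=1,
            )
        return paths


def _chrom_sort_key(chrom: str) -> int:
    c = chrom.removeprefix("chr")
    return int(c) if c.isdigit() else 100


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_gene, rng_site, rng_admix, rng_geno, rng_depth, rng_panel, rng_annot, rng_qc = (
        np.random.default_rng(s) for s in streams
    )

    # ------------------------------------------------------------------ subjects
    groups, sizes = zip(*config.group_sizes.items())
    group_of = np.repeat(groups, sizes)
    n_subjects = len(group_of)
    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    sex = np.where(rng_admix.random(n_subjects) < config.male_fraction, "M", "F")
    q_true = np.zeros((n_subjects, len(POPULATIONS)))
    for g in groups:
        idx = np.flatnonzero(group_of == g)
        mean, conc = DIRICHLET_PARAMS[g]
        mean = np.asarray(mean)
        nz = mean > 0
        draws = rng_admix.dirichlet(mean[nz] * conc, size=len(idx))
        q = np.zeros((len(idx), len(POPULATIONS)))
        q[:, nz] = draws
        q_true[idx] = q

    # ------------------------------------------------------------------ genes
    genome: dict[str, str] = {}
    gene_rows, tx_rows = [], []
    type_labels = np.repeat(
        list(config.gene_type_counts), list(config.gene_type_counts.values())
    )
    if len(type_labels) < config.n_genes:
        type_labels = np.concatenate(
            [type_labels, np.repeat("tumor_suppressor", config.n_genes - len(type_labels))]
        )
    type_labels = type_labels[: config.n_genes]
    rng_gene.shuffle(type_labels)
    mu = np.log(config.mean_coding_length) - config.coding_length_sigma**2 / 2
    lengths = rng_gene.lognormal(mu, config.coding_length_sigma, size=config.n_genes)
    lengths = np.maximum(300, (np.round(lengths / 3).astype(int) * 3))

    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    gene_layout = {}  # symbol -> dict with coords
    for i in range(config.n_genes):
        symbol = f"GENE{i + 1:03d}"
        chrom = f"chr{(i % 22) + 1}"
        strand = "+" if rng_gene.random() < 0.5 else "-"
        L = int(lengths[i])
        n_codons = L // 3
        codons = ["ATG"] + [
            _NONSTOP_CODONS[j]
            for j in rng_gene.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        exon1_codons = max(1, n_codons // 2)
        gene_layout[symbol] = {
            "chrom": chrom,
            "strand": strand,
            "codons": codons,
            "exon1_len": exon1_codons * 3,
            "gene_type": type_labels[i],
        }

    # ------------------------------------------------------------------ sites
    # number of nonsynonymous sites per gene ~ Poisson(rate * kb)
    sites: list[dict] = []
    for symbol, lay in gene_layout.items():
        rate = config.variants_per_kb[lay["gene_type"]]
        kb = len(lay["codons"]) * 3 / 1000.0
        n_sites = rng_site.poisson(rate * kb)
        lay["n_sites"] = int(n_sites)

    total_nonsyn = sum(lay["n_sites"] for lay in gene_layout.values())
    n_single = int(round(config.singleton_frac * total_nonsyn))
    n_double = int(round(config.doubleton_frac * total_nonsyn))
    n_gs = sum(config.group_specific_counts.values())
    n_planted_common = config.n_flips + config.n_reference_minor + n_gs
    n_filler = total_nonsyn - n_single - n_double - n_planted_common
    if n_filler <= 0:
        raise ValueError(
            "infeasible config: planted and rare sites exceed the drawn site count "
            f"({total_nonsyn})"
        )

    strata = np.concatenate(
        [
            np.repeat("singleton", n_single),
            np.repeat("doubleton", n_double),
            np.repeat("flip", config.n_flips),
            np.repeat("reference_minor", config.n_reference_minor),
            np.concatenate(
                [np.repeat(g, n) for g, n in config.group_specific_counts.items()]
            ).astype("U32")
            if n_gs
            else np.array([], dtype="U32"),
            np.repeat("filler", n_filler),
        ]
    )
    rng_site.shuffle(strata)

    # consequence categories: deleterious sites split between rare and common
    categories = np.repeat("missense", total_nonsyn).astype("U16")
    rare_idx = np.flatnonzero(np.isin(strata, ["singleton", "doubleton"]))
    filler_idx = np.flatnonzero(strata == "filler")
    del_cats = np.concatenate(
        [
            np.repeat("nonsense", config.n_nonsense),
            np.repeat("frameshift", config.n_frameshift),
            np.repeat("splice_site", config.n_splice),
        ]
    )
    rng_site.shuffle(del_cats)
    n_del_common = min(config.n_deleterious_common, len(del_cats), len(filler_idx))
    common_del = rng_site.choice(filler_idx, size=n_del_common, replace=False)
    rare_del = rng_site.choice(
        rare_idx, size=len(del_cats) - n_del_common, replace=False
    )
    categories[common_del] = del_cats[:n_del_common]
    categories[rare_del] = del_cats[n_del_common:]
    free_rare = np.setdiff1d(rare_idx, rare_del)
    inframe_pick = rng_site.choice(
        free_rare, size=min(config.n_inframe, len(free_rare)), replace=False
    )
    categories[inframe_pick] = "inframe_indel"

    # extra synonymous sites (excluded from every nonsynonymous analysis)
    n_syn = int(round(config.synonymous_extra_frac * total_nonsyn))
    strata = np.concatenate([strata, np.repeat("synonymous_extra", n_syn)])
    categories = np.concatenate([categories, np.repeat("synonymous", n_syn)])

    # planted low-quality sites are extra missense sites on top of the spectrum
    n_badcr, n_badfd = config.n_low_callrate_sites, config.n_low_fracdepth_sites
    strata = np.concatenate(
        [strata, np.repeat("low_callrate", n_badcr), np.repeat("low_fracdepth", n_badfd)]
    )
    categories = np.concatenate([categories, np.repeat("missense", n_badcr + n_badfd)])
    n_total_sites = len(strata)

    # assign each site to a gene: nonsynonymous quota first, extras at random
    gene_assign = np.concatenate(
        [np.repeat(sym, lay["n_sites"]) for sym, lay in gene_layout.items()]
    ).astype("U16")
    symbols = list(gene_layout)
    extra = rng_site.choice(symbols, size=n_total_sites - total_nonsyn, replace=True)
    gene_assign = np.concatenate([gene_assign, extra])
    # splice sites need one intron each and at most one per gene
    splice_sites = np.flatnonzero(categories == "splice_site")
    splice_genes = rng_site.choice(symbols, size=len(splice_sites), replace=False)
    gene_assign[splice_sites] = splice_genes

    # ------------------------------------------------------- codon allocation
    # even codon indices only, so indel anchors never collide with SNV codons
    codon_slot: dict[str, list[int]] = {}
    for sym, lay in gene_layout.items():
        n_codons = len(lay["codons"])
        slots = [c for c in range(2, n_codons - 1, 2)]
        rng_site.shuffle(slots)
        codon_slot[sym] = slots

    site_codon = np.full(n_total_sites, -1, dtype=int)
    for j in range(n_total_sites):
        if categories[j] == "splice_site":
            continue
        sym = gene_assign[j]
        if not codon_slot[sym]:
            # gene saturated; spill to a random other gene with room
            candidates = [s for s in symbols if codon_slot[s]]
            sym = rng_site.choice(candidates)
            gene_assign[j] = sym
        site_codon[j] = codon_slot[sym].pop()

    # codon surgery: force reference codons, record CDS-space edits
    site_edit: list[tuple] = [None] * n_total_sites
    for j in range(n_total_sites):
        cat = categories[j]
        sym = gene_assign[j]
        lay = gene_layout[sym]
        c = site_codon[j]
        if cat == "splice_site":
            site_edit[j] = ("splice",)
            continue
        if cat in ("missense",):
            ref_codon, off, alt_base = _MISSENSE_OPS[rng_site.integers(len(_MISSENSE_OPS))]
        elif cat == "nonsense":
            ref_codon, off, alt_base = _NONSENSE_OPS[rng_site.integers(len(_NONSENSE_OPS))]
        elif cat == "synonymous":
            ref_codon, off, alt_base = _SYNONYMOUS_OPS[rng_site.integers(len(_SYNONYMOUS_OPS))]
        elif cat == "frameshift":
            ref_codon, off, alt_base = "ACT", 1, None  # delete the middle base
        elif cat == "inframe_indel":
            ref_codon, off, alt_base = "ACT", 0, None  # delete the whole codon
        else:  # pragma: no cover
            raise AssertionError(cat)
        lay["codons"][c] = ref_codon
        site_edit[j] = (cat, c, off, alt_base)

    # ------------------------------------------------------------ build genome
    flank = 100
    intron_len = 120
    tx_meta = {}
    for i, (sym, lay) in enumerate(gene_layout.items()):
        chrom = lay["chrom"]
        cds = "".join(lay["codons"])
        genomic_cds = cds if lay["strand"] == "+" else cds.translate(_COMPLEMENT)[::-1]
        e1 = lay["exon1_len"] if lay["strand"] == "+" else len(cds) - lay["exon1_len"]
        exon1_seq, exon2_seq = genomic_cds[:e1], genomic_cds[e1:]
        intron = "".join(rng_gene.choice(list("ACGT"), size=intron_len))
        flank5 = "".join(rng_gene.choice(list("ACGT"), size=flank))
        flank3 = "".join(rng_gene.choice(list("ACGT"), size=flank))
        cursor = chrom_cursor.get(chrom, 0)
        tx_start = cursor + flank
        exon1 = (tx_start, tx_start + len(exon1_seq))
        exon2 = (exon1[1] + intron_len, exon1[1] + intron_len + len(exon2_seq))
        tx_end = exon2[1]
        chrom_parts.setdefault(chrom, []).append(flank5 + exon1_seq + intron + exon2_seq + flank3)
        chrom_cursor[chrom] = tx_end + flank
        lay.update(
            {"tx_start": tx_start, "tx_end": tx_end, "exon1": exon1, "exon2": exon2,
             "cds_len": len(cds)}
        )
        tx_meta[sym] = lay
        tx_rows.append(
            {
                "name": f"TX{i + 1:03d}",
                "chrom": chrom,
                "strand": lay["strand"],
                "txStart": tx_start,
                "txEnd": tx_end,
                "cdsStart": tx_start,
                "cdsEnd": tx_end,
                "exonCount": 2,
                "exonStarts": f"{exon1[0]},{exon2[0]},",
                "exonEnds": f"{exon1[1]},{exon2[1]},",
                "geneSymbol": sym,
            }
        )
        gene_rows.append(
            {"gene_symbol": sym, "gene_type": lay["gene_type"], "census_reason": "Mis; F; N; S"}
        )
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}

    def cds_to_genomic(lay: dict, i: int) -> int:
        """0-based genomic position of CDS index i (coding-strand order)."""
        if lay["strand"] == "-":
            i = lay["cds_len"] - 1 - i
        e1_len = lay["exon1"][1] - lay["exon1"][0]
        if i < e1_len:
            return lay["exon1"][0] + i
        return lay["exon2"][0] + (i - e1_len)

    # ------------------------------------------------------------ VCF records
    recs = []
    for j in range(n_total_sites):
        sym = gene_assign[j]
        lay = tx_meta[sym]
        chrom, strand = lay["chrom"], lay["strand"]
        edit = site_edit[j]
        if edit[0] == "splice":
            g0 = lay["exon1"][1] if strand == "+" else lay["exon2"][0] - 1
            ref = genome[chrom][g0]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            recs.append((chrom, g0 + 1, ref, alt))
            continue
        cat, c, off, alt_base = edit
        if alt_base is not None:  # SNV
            i = 3 * c + off
            g0 = cds_to_genomic(lay, i)
            ref = genome[chrom][g0]
            alt = alt_base if strand == "+" else alt_base.translate(_COMPLEMENT)
            assert ref != alt, (sym, cat, ref, alt)
            recs.append((chrom, g0 + 1, ref, alt))
        elif cat == "frameshift":  # delete CDS base 3c+1
            g0 = cds_to_genomic(lay, 3 * c + 1)
            v = normalize_variant(chrom, g0, genome[chrom][g0 - 1 : g0 + 1],
                                  genome[chrom][g0 - 1], genome)
            recs.append((chrom, v.pos, v.ref, v.alt))
        else:  # inframe deletion of the whole codon
            gpos = sorted(cds_to_genomic(lay, 3 * c + k) for k in range(3))
            g0 = gpos[0]
            v = normalize_variant(chrom, g0, genome[chrom][g0 - 1 : g0 + 3],
                                  genome[chrom][g0 - 1], genome)
            recs.append((chrom, v.pos, v.ref, v.alt))

    sites_df = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    sites_df["gene"] = gene_assign
    sites_df["stratum"] = strata
    sites_df["category_truth"] = categories
    keys = list(zip(sites_df.chrom, sites_df.pos, sites_df.ref, sites_df.alt))
    if len(set(keys)) != len(keys):
        raise AssertionError("generated duplicate variant keys")

    # --------------------------------------------------------- frequencies
    K = len(POPULATIONS)
    fst = config.balding_nichols_fst
    site_pop_freq = np.zeros((n_total_sites, K))  # ancestral freqs; 0 for direct strata

    flip_idx = np.flatnonzero(strata == "flip")
    high_pops = ["African", "EastAsian", "CentralAsian", "European"]
    flip_high = [high_pops[k % 4] for k in range(len(flip_idx))]
    for j, hp in zip(flip_idx, flip_high):
        f = rng_geno.uniform(0.10, 0.22, size=K)
        f[POPULATIONS.index(hp)] = rng_geno.uniform(0.78, 0.92)
        site_pop_freq[j] = f

    rm_idx = np.flatnonzero(strata == "reference_minor")
    site_pop_freq[rm_idx] = rng_geno.uniform(0.78, 0.92, size=(len(rm_idx), K))

    fill_like = np.flatnonzero(np.isin(strata, ["filler", "low_callrate", "low_fracdepth",
                                                "synonymous_extra"]))
    a, b = config.filler_beta
    p_global = np.clip(rng_geno.beta(a, b, size=len(fill_like)), 0.008, 0.6)
    shape1 = p_global * (1 - fst) / fst
    shape2 = (1 - p_global) * (1 - fst) / fst
    bn = rng_geno.beta(shape1[:, None], shape2[:, None], size=(len(fill_like), K))
    # floor keeps the common stratum genuinely polymorphic in every ancestry,
    # so the rare spectrum is exactly the directly assigned singletons/doubletons
    site_pop_freq[fill_like] = np.clip(bn, 0.01, 0.95)

    # --------------------------------------------------- load calibration
    filler_only = np.flatnonzero(strata == "filler")
    load_rare = (n_single + 2 * n_double) / n_subjects

    def expected_load(idx: np.ndarray, scale: float = 1.0) -> float:
        if len(idx) == 0:
            return 0.0
        P = q_true @ np.clip(scale * site_pop_freq[idx].T, 0.01, 0.98)
        return float((1.0 - (1.0 - P) ** 2).sum(axis=1).mean())

    load_flip = expected_load(flip_idx)
    load_rm = expected_load(rm_idx)
    group_arr = np.asarray(group_of)
    load_gs = 0.0
    gs_plan: dict[int, int] = {}
    for g, n_sites_g in config.group_specific_counts.items():
        n_g = int(config.group_sizes.get(g, 0))
        for j in np.flatnonzero(strata == g):
            u = rng_geno.uniform(0.055, 0.10)
            k_alleles = max(int(np.ceil(0.055 * 2 * n_g)), int(round(u * 2 * n_g)))
            gs_plan[j] = min(k_alleles, n_g)
            load_gs += gs_plan[j] / n_subjects

    mask_rate = config.low_depth_genotype_rate
    target_pre = config.target_mean_load / (1.0 - mask_rate)
    need = target_pre - load_rare - load_flip - load_rm - load_gs
    if need <= 0:
        raise ValueError("infeasible config: planted site load exceeds the target mean load")

    def gap(c: float) -> float:
        return expected_load(filler_only, c) - need

    lo, hi = 1e-3, 6.0
    if gap(hi) < 0 or gap(lo) > 0:
        raise ValueError("infeasible config: cannot calibrate common-site frequencies")
    scale = brentq(gap, lo, hi, xtol=1e-4)
    site_pop_freq[fill_like] = np.clip(scale * site_pop_freq[fill_like], 0.01, 0.98)

    # --------------------------------------------------------- genotypes
    dosage = np.zeros((n_subjects, n_total_sites), dtype=np.int8)
    binom_idx = np.concatenate([flip_idx, rm_idx, fill_like])
    P = q_true @ site_pop_freq[binom_idx].T
    dosage[:, binom_idx] = rng_geno.binomial(2, np.clip(P, 0, 1)).astype(np.int8)

    single_idx = np.flatnonzero(strata == "singleton")
    carriers = rng_geno.integers(0, n_subjects, size=len(single_idx))
    dosage[carriers, single_idx] = 1
    double_idx = np.flatnonzero(strata == "doubleton")
    for j in double_idx:
        c1, c2 = rng_geno.choice(n_subjects, size=2, replace=False)
        dosage[c1, j] = 1
        dosage[c2, j] = 1
    for j, k_alleles in gs_plan.items():
        g = strata[j]
        members = np.flatnonzero(group_arr == g)
        chosen = rng_geno.choice(members, size=k_alleles, replace=False)
        dosage[chosen, j] = 1

    # --------------------------------------------------------- depths & QC
    DP = rng_depth.poisson(config.depth_mean, size=(n_subjects, n_total_sites))
    DP = np.maximum(DP, 1)
    err = rng_depth.binomial(DP, 0.005)
    het_ref = rng_depth.binomial(DP, 0.5)
    ref_d = np.where(dosage == 0, DP - err, np.where(dosage == 1, het_ref, err))
    alt_d = DP - ref_d

    badcr_idx = np.flatnonzero(strata == "low_callrate")
    nocall = rng_qc.random((n_subjects, len(badcr_idx))) < 0.25
    d = dosage[:, badcr_idx]
    d[nocall] = NO_CALL
    dosage[:, badcr_idx] = d

    badfd_idx = np.flatnonzero(strata == "low_fracdepth")
    frac = rng_qc.uniform(0.05, 0.25, size=(n_subjects, len(badfd_idx)))
    dp_b = DP[:, badfd_idx]
    minority = np.round(frac * dp_b).astype(np.int64)
    dos_b = dosage[:, badfd_idx]
    # hets: minority side is the smaller depth; homs: carried allele gets the
    # minority share so the carried fraction is low
    ref_b = np.where(dos_b == 0, minority, np.where(dos_b == 1, minority, dp_b - minority))
    ref_d[:, badfd_idx] = ref_b
    alt_d[:, badfd_idx] = dp_b - ref_b

    called = dosage != NO_CALL
    planted_low = (rng_qc.random((n_subjects, n_total_sites)) < mask_rate) & called
    good_cols = np.isin(np.arange(n_total_sites), np.concatenate([badcr_idx, badfd_idx]))
    planted_low[:, good_cols] = False
    low_val = rng_qc.integers(0, 12, size=int(planted_low.sum()))
    li, lj = np.nonzero(planted_low)
    dlow = dosage[li, lj]
    # put the low depth on a carried allele so the genotype filter must fire
    ref_low = np.where(dlow == 2, DP[li, lj] - low_val, low_val)
    ref_d[li, lj] = ref_low
    alt_d[li, lj] = DP[li, lj] - ref_low

    ref_d = np.maximum(ref_d, 0).astype(np.int32)
    alt_d = np.maximum(alt_d, 0).astype(np.int32)
    ref_d[~called] = 0
    alt_d[~called] = 0

    # --------------------------------------------------------- annotations
    is_rare_stratum = np.isin(strata, ["singleton", "doubleton"])
    known = np.where(
        is_rare_stratum,
        rng_annot.random(n_total_sites) < config.known_rate_rare,
        True,
    )
    hgmd = np.where(
        is_rare_stratum,
        rng_annot.random(n_total_sites) < config.hgmd_rate_rare,
        rng_annot.random(n_total_sites) < config.hgmd_rate_common,
    )
    polyphen = np.full(n_total_sites, np.nan)
    mis = np.flatnonzero(categories == "missense")
    u = rng_annot.random(len(mis))
    score = np.where(
        u < 0.25,
        rng_annot.uniform(0.86, 1.0, len(mis)),
        np.where(
            u < 0.60,
            rng_annot.uniform(0.15, 0.85, len(mis)),
            rng_annot.uniform(0.0, 0.149, len(mis)),
        ),
    )
    score[rng_annot.random(len(mis)) < 0.1] = np.nan
    polyphen[mis] = score

    sites_df["known"] = known
    sites_df["hgmd"] = hgmd
    sites_df["polyphen_score"] = polyphen
    sites_df["flip"] = strata == "flip"
    sites_df["reference_minor"] = strata == "reference_minor"
    gs_names = list(config.group_specific_counts)
    sites_df["group_specific"] = np.isin(strata, gs_names)
    sites_df["group_specific_group"] = np.where(np.isin(strata, gs_names), strata, "")
    sites_df["low_quality"] = np.isin(strata, ["low_callrate", "low_fracdepth"])
    sites_df["id"] = [
        f"rs{9_000_000 + j}" if known[j] else "." for j in range(n_total_sites)
    ]

    # ------------------------------------------------------------- ordering
    order = sites_df.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
    ).index.to_numpy()
    sites_df = sites_df.loc[order].reset_index(drop=True)
    dosage = dosage[:, order]
    ref_d = ref_d[:, order]
    alt_d = alt_d[:, order]
    planted_low = planted_low[:, order]

    cohort = CohortGenotypes(
        subjects=subjects,
        sites=sites_df[["chrom", "pos", "id", "ref", "alt"]].copy(),
        dosage=dosage,
        ref_depth=ref_d,
        alt_depth=alt_d,
        sex=sex,
    )

    subj_df = pd.DataFrame({"subject": subjects, "group": group_of, "sex": sex})
    for k, p in enumerate(POPULATIONS):
        subj_df[f"q_{p}"] = q_true[:, k]

    annotations = sites_df.loc[
        :, ["chrom", "pos", "ref", "alt", "id", "hgmd", "polyphen_score"]
    ].rename(columns={"id": "known_id"})

    # ------------------------------------------------------------- panel
    n_mark = config.panel_markers
    panel_freqs = np.clip(rng_panel.beta(0.5, 0.5, size=(n_mark, K)), 0.02, 0.98)
    bases = np.array(list("ACGT"))
    ra = bases[rng_panel.integers(0, 4, size=n_mark)]
    aa = np.array([
        rng_panel.choice([b for b in "ACGT" if b != r]) for r in ra
    ])
    panel = AncestralPanel(
        markers=pd.DataFrame(
            {
                "chrom": "chrPanel",
                "pos": np.arange(1, n_mark + 1) * 100,
                "ref": ra,
                "alt": aa,
            }
        ),
        freqs=panel_freqs,
    )
    Pm = q_true @ panel_freqs.T
    panel_dosage = rng_panel.binomial(2, Pm).astype(np.int8)
    miss = rng_panel.random(panel_dosage.shape) < config.panel_missing_rate
    panel_dosage[miss] = -1

    truth = TruthTables(
        subjects=subj_df,
        sites=sites_df,
        planted_low_depth=planted_low,
        q_true=q_true,
    )
    return SyntheticCohort(
        cohort=cohort,
        truth=truth,
        genome=genome,
        transcripts=pd.DataFrame(tx_rows),
        gene_list=pd.DataFrame(gene_rows),
        annotations=annotations,
        panel=panel,
        panel_dosage=panel_dosage,
        config=config,
    )


def emit_validation_set(
    syn: SyntheticCohort,
    n: int = 341,
    fp_rate: float = 0.05,
    fn_rate: float = 0.02,
    seed: int | None = None,
    low_depth_fraction: float = 1.0,
    positive_fraction: float = 0.5,
) -> pd.DataFrame:
    """Labeled genotype calls emulating an orthogonally validated subset.

    Samples ``n`` called genotypes — ``positive_fraction`` of them carrying a
    variant, mirroring a validation set selected around called variants — then
    plants false-positive and false-negative calls at the given rates,
    concentrating ``low_depth_fraction`` of the planted errors at depths the
    genotype filter should catch.  Columns: subject, chrom, pos, ref, alt,
    dosage, ref_depth, alt_depth, truth_variant, called_variant, planted_error.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    co = syn.cohort
    called = co.called()
    pos_i, pos_j = np.nonzero(called & (co.dosage > 0))
    neg_i, neg_j = np.nonzero(called & (co.dosage == 0))
    n_pos = min(int(round(positive_fraction * n)), len(pos_i))
    n_neg = n - n_pos
    if n_neg > len(neg_i):
        raise ValueError(f"n={n} exceeds the available called genotypes")
    pick_p = rng.choice(len(pos_i), size=n_pos, replace=False)
    pick_n = rng.choice(len(neg_i), size=n_neg, replace=False)
    ii = np.concatenate([pos_i[pick_p], neg_i[pick_n]])
    jj = np.concatenate([pos_j[pick_p], neg_j[pick_n]])
    perm = rng.permutation(n)
    ii, jj = ii[perm], jj[perm]
    dosage = co.dosage[ii, jj].astype(int)
    ref_d = co.ref_depth[ii, jj].astype(int)
    alt_d = co.alt_depth[ii, jj].astype(int)
    truth = dosage > 0
    called_variant = truth.copy()
    planted = np.zeros(n, dtype=bool)

    n_fp = int(round(fp_rate * n))
    neg = np.flatnonzero(~truth)
    fp_pick = rng.choice(neg, size=min(n_fp, len(neg)), replace=False)
    called_variant[fp_pick] = True
    dosage[fp_pick] = 1
    planted[fp_pick] = True
    low = rng.random(len(fp_pick)) < low_depth_fraction
    alt_d[fp_pick[low]] = rng.integers(1, 12, size=low.sum())
    # miscalls planted at credible depth must survive the genotype filter
    alt_d[fp_pick[~low]] = rng.integers(15, 30, size=(~low).sum())

    n_fn = int(round(fn_rate * n))
    pos = np.flatnonzero(truth & ~planted)
    fn_pick = rng.choice(pos, size=min(n_fn, len(pos)), replace=False)
    called_variant[fn_pick] = False
    dosage[fn_pick] = 0
    planted[fn_pick] = True

    return pd.DataFrame(
        {
            "subject": np.asarray(co.subjects)[ii],
            "chrom": co.sites.chrom.to_numpy()[jj],
            "pos": co.sites.pos.to_numpy()[jj],
            "ref": co.sites.ref.to_numpy()[jj],
            "alt": co.sites.alt.to_numpy()[jj],
            "dosage": dosage,
            "ref_depth": ref_d,
            "alt_depth": alt_d,
            "truth_variant": truth,
            "called_variant": called_variant,
            "planted_error": planted,
        }
    )
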