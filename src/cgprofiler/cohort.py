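"""Cohort genotype container and VCF v4.1 input/output.

Genotypes for the whole cohort are held as dense arrays: an alt-allele dosage
matrix (``-1`` marks a no-call) plus per-allele read depth matrices matching the
VCF ``AD`` field.  Multi-allelic sites are decomposed into biallelic records on
ingest, so each row of ``sites`` is one allelic variant keyed by
(chrom, pos, ref, alt).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SITE_KEY = ["chrom", "pos", "ref", "alt"]

NO_CALL = -1


@dataclass
class CohortGenotypes:
    """Dense genotype matrix for ``n_subjects`` x ``n_sites``.

    dosage: int8, number of alt alleles carried (0..ploidy), NO_CALL for missing.
    ref_depth/alt_depth: reads supporting each allele (VCF AD).
    sex: 'M'/'F' per subject; used for chromosome-X allele counting.
    ploidy: per-site ploidy applied to males at non-pseudoautosomal X sites is
    handled at counting time, not here; stored dosage for a hemizygous call is
    0 or 1.
    """

    subjects: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, s = len(self.subjects), len(self.sites)
        for name in ("dosage", "ref_depth", "alt_depth"):
            arr = getattr(self, name)
            if arr.shape != (n, s):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, {s})")
        if list(self.sites.index) != list(range(s)):
            self.sites = self.sites.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def called(self) -> np.ndarray:
        return self.dosage != NO_CALL

    def site_keys(self) -> pd.Index:
        return pd.Index(
            list(zip(self.sites.chrom, self.sites.pos, self.sites.ref, self.sites.alt))
        )

    def subset_sites(self, mask: np.ndarray) -> "CohortGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortGenotypes(
            subjects=self.subjects,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            sex=self.sex,
        )

    def with_mask(self, genotype_mask: np.ndarray) -> "CohortGenotypes":
        """Return a copy with masked genotypes set to no-call."""
        dosage = self.dosage.copy()
        dosage[genotype_mask] = NO_CALL
        return CohortGenotypes(
            self.subjects, self.sites, dosage, self.ref_depth, self.alt_depth, self.sex
        )


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as an uncompressed multi-sample VCF v4.1 with GT:AD:DP."""
    sites = cohort.sites
    n, s = cohort.n_subjects, cohort.n_sites
    dosage, rd, ad = cohort.dosage, cohort.ref_depth, cohort.alt_depth
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.1\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
    )
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
    for chrom in pd.unique(sites.chrom):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.subjects)
        + "\n"
    )
    gt_strings = np.empty((n, s), dtype=object)
    gt_strings[dosage == 0] = "0/0"
    gt_strings[dosage == 1] = "0/1"
    gt_strings[dosage == 2] = "1/1"
    gt_strings[dosage == NO_CALL] = "./."
    ids = sites["id"] if "id" in sites.columns else pd.Series(["."] * s)
    for j in range(s):
        row = sites.iloc[j]
        cols = [
            f"{gt_strings[i, j]}:{rd[i, j]},{ad[i, j]}:{rd[i, j] + ad[i, j]}"
            for i in range(n)
        ]
        buf.write(
            f"{row.chrom}\t{row.pos}\t{ids.iloc[j] or '.'}\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
            "GT:AD:DP\t" + "\t".join(cols) + "\n"
        )
    Path(path).write_text(buf.getvalue())


def read_vcf(path: str | Path, sex: np.ndarray | None = None) -> CohortGenotypes:
    """Read a multi-sample VCF into a CohortGenotypes, decomposing multi-allelic
    sites into biallelic records.

    Per-allele depths are taken from AD; at a decomposed site the row for alt k
    keeps the reference depth and the depth of alt k.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    n = len(subjects)
    rows = []
    dosages, rds, ads = [], [], []
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            ad = np.zeros((n, len(rec.ALT) + 1), dtype=np.int32)
        ad = np.where(ad < 0, 0, ad).astype(np.int32)
        gts = np.array(rec.genotypes, dtype=object)
        for k, alt in enumerate(rec.ALT, start=1):
            dos = np.full(n, NO_CALL, dtype=np.int8)
            for i, g in enumerate(rec.genotypes):
                alleles = [a for a in g[:-1] if a is not None and a >= 0]
                if not alleles:
                    continue
                dos[i] = sum(a == k for a in alleles)
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "id": rec.ID or ".",
                    "ref": rec.REF,
                    "alt": alt,
                }
            )
            dosages.append(dos)
            rds.append(ad[:, 0])
            ads.append(ad[:, k] if ad.shape[1] > k else np.zeros(n, dtype=np.int32))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return CohortGenotypes(
        subjects=subjects,
        sites=sites,
        dosage=np.array(dosages, dtype=np.int8).T.reshape(n, -1)
        if dosages
        else np.zeros((n, 0), dtype=np.int8),
        ref_depth=np.array(rds, dtype=np.int32).T.reshape(n, -1)
        if rds
        else np.zeros((n, 0), dtype=np.int32),
        alt_depth=np.array(ads, dtype=np.int32).T.reshape(n, -1)
        if ads
        else np.zeros((n, 0), dtype=np.int32),
        sex=sex,
    )
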