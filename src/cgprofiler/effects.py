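"""Predicted protein consequences of variants and nonexclusive variant classes.

A variant's effect on one transcript is determined by translating the reference
coding sequence and the variant-substituted coding sequence with the standard
genetic code and comparing the proteins.  Gene-level categories take the most
severe effect over all annotated transcripts.  Variants are then assigned to
three nonexclusive classes: listed in an HGMD-like table, predicted deleterious
(frameshift / nonsense / splice-site), or otherwise a variant of unknown
significance (VUS); novelty is absence from a known-variant (dbSNP-like) table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genes import GeneModelError, Transcript, locate

CATEGORIES = (
    "frameshift",
    "nonsense",
    "splice_site",
    "missense",
    "inframe_indel",
    "synonymous",
    "noncoding",
)
#: most severe first; used for gene-level aggregation over transcripts
SEVERITY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}

DELETERIOUS_CATEGORIES = frozenset({"frameshift", "nonsense", "splice_site"})
#: categories counted as protein-affecting ("nonsynonymous") in all analyses
NONSYNONYMOUS_CATEGORIES = frozenset(
    {"frameshift", "nonsense", "splice_site", "missense", "inframe_indel"}
)

_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic, normalized variant (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if not (_BASES.issuperset(self.ref) and _BASES.issuperset(self.alt)):
            raise ValueError(f"{self.chrom}:{self.pos} alleles must be over ACGT")

    @property
    def variant_type(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    transcript_id: str
    category: str
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.category not in SEVERITY_ORDER:
            raise ValueError(f"unknown category {self.category!r}")
        no_protein = self.category in ("splice_site", "noncoding")
        if no_protein != (self.protein_change == ""):
            raise ValueError(
                f"protein_change must be empty iff splice_site/noncoding "
                f"(got {self.category}, {self.protein_change!r})"
            )


@dataclass(frozen=True)
class VariantClass:
    """Nonexclusive class flags for one (nonsynonymous) variant."""

    deleterious: bool
    hgmd: bool
    vus: bool
    novel: bool
    polyphen_bin: str = "none"


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str, genome: Mapping[str, str]
) -> VariantRecord:
    """Left-align and trim to the minimal representation against the reference.

    Standard variant normalization: trim shared suffix bases, shift indels left
    while the representation permits, then trim shared prefix bases.
    """
    seq = genome[chrom]
    ref, alt = ref.upper(), alt.upper()
    if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref:
        raise ValueError(f"{chrom}:{pos} ref allele {ref!r} does not match reference")
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(f"{chrom}:{pos} cannot left-align at contig start")
                pos -= 1
                base = seq[pos - 1].upper()
                ref, alt = base + ref, base + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return VariantRecord(chrom, pos, ref, alt)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _translate(cds: str) -> str:
    """Translate through the first stop; returns protein with trailing '*' if found."""
    n = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:n]).translate())
    stop = prot.find("*")
    return prot[: stop + 1] if stop >= 0 else prot


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def classify_consequence(
    v: VariantRecord,
    transcript: Transcript,
    genome: Mapping[str, str],
    splice_window: int = 2,
) -> ConsequenceAnnotation:
    """Classify one variant against one transcript by re-translation.

    Builds the reference CDS and the variant CDS, translates both, and applies
    the category rules: CDS length change not a multiple of 3 is a frameshift;
    a stop introduced before the reference stop is nonsense; an amino-acid
    substitution is missense; an identical protein is synonymous; a variant in
    the splice region (first/last ``splice_window`` intronic bases) is
    splice_site; an in-frame length change is an inframe_indel.
    """
    if v.chrom != transcript.chrom:
        raise GeneModelError(
            f"variant on {v.chrom}, transcript {transcript.transcript_id} on {transcript.chrom}"
        )
    start0 = v.pos - 1
    context = locate(v.chrom, start0, start0 + len(v.ref), transcript, splice_window)
    if context == "splice_region":
        return ConsequenceAnnotation(transcript.transcript_id, "splice_site", "")
    if context != "coding" or not transcript.is_coding:
        return ConsequenceAnnotation(transcript.transcript_id, "noncoding", "")

    seq = genome[v.chrom].upper()
    cds_pos: list[int] = []
    for s, t in transcript.cds_exon_intervals():
        cds_pos.extend(range(s, t))
    index = {p: i for i, p in enumerate(cds_pos)}
    ref_cds = "".join(seq[p] for p in cds_pos)

    k = 0
    while k < min(len(v.ref), len(v.alt)) and v.ref[k] == v.alt[k]:
        k += 1
    alt_chars = list(ref_cds)
    if len(v.ref) == len(v.alt):
        for i in range(len(v.ref)):
            p = start0 + i
            if p in index:
                alt_chars[index[p]] = v.alt[i]
        alt_cds = "".join(alt_chars)
    else:
        deleted = {start0 + i for i in range(k, len(v.ref))}
        ins_seq = v.alt[k:]
        anchor = start0 + k - 1
        # if the anchor base is not coding, attach the insertion just before the
        # first deleted coding base instead
        ins_before = None
        if ins_seq and anchor not in index:
            coding_deleted = [index[p] for p in deleted if p in index]
            ins_before = min(coding_deleted) if coding_deleted else None
        pieces: list[str] = []
        for i, p in enumerate(cds_pos):
            if ins_before is not None and i == ins_before:
                pieces.append(ins_seq)
            if p not in deleted:
                pieces.append(ref_cds[i])
            if ins_seq and p == anchor:
                pieces.append(ins_seq)
        alt_cds = "".join(pieces)

    if alt_cds == ref_cds:
        # touched only non-coding bases of the span (e.g. MNV straddling a boundary)
        return ConsequenceAnnotation(transcript.transcript_id, "noncoding", "")

    if transcript.strand == "-":
        ref_cds, alt_cds = _revcomp(ref_cds), _revcomp(alt_cds)

    if not ref_cds.startswith("ATG"):
        warnings.warn(f"{transcript.transcript_id}: CDS does not start with ATG")
    ref_prot = _translate(ref_cds)
    alt_prot = _translate(alt_cds)
    if not ref_prot.endswith("*"):
        warnings.warn(f"{transcript.transcript_id}: CDS lacks a stop codon")

    if (len(alt_cds) - len(ref_cds)) % 3 != 0:
        i = _first_diff(ref_prot, alt_prot)
        aa = ref_prot[i] if i < len(ref_prot) else "?"
        return ConsequenceAnnotation(
            transcript.transcript_id, "frameshift", f"p.{_aa3(aa)}{i + 1}fs"
        )
    if alt_prot == ref_prot:
        i = _first_codon_diff(ref_cds, alt_cds)
        return ConsequenceAnnotation(
            transcript.transcript_id, "synonymous", f"p.{_aa3(ref_prot[i])}{i + 1}="
        )
    if len(alt_cds) == len(ref_cds):
        i = _first_diff(ref_prot, alt_prot)
        ref_aa = ref_prot[i] if i < len(ref_prot) else "?"
        alt_aa = alt_prot[i] if i < len(alt_prot) else "?"
        change = f"p.{_aa3(ref_aa)}{i + 1}{_aa3(alt_aa)}"
        if alt_aa == "*":
            return ConsequenceAnnotation(transcript.transcript_id, "nonsense", change)
        # stop-loss and plain substitutions are both reported as missense-like
        return ConsequenceAnnotation(transcript.transcript_id, "missense", change)
    # in-frame indel; a new early stop still counts as nonsense
    i = _first_diff(ref_prot, alt_prot)
    if i < len(alt_prot) and alt_prot[i] == "*":
        ref_aa = ref_prot[i] if i < len(ref_prot) else "?"
        return ConsequenceAnnotation(
            transcript.transcript_id, "nonsense", f"p.{_aa3(ref_aa)}{i + 1}Ter"
        )
    ref_aa = ref_prot[i] if i < len(ref_prot) else "?"
    kind = "del" if len(alt_cds) < len(ref_cds) else "ins"
    return ConsequenceAnnotation(
        transcript.transcript_id, "inframe_indel", f"p.{_aa3(ref_aa)}{i + 1}{kind}"
    )


def _first_diff(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _first_codon_diff(a: str, b: str) -> int:
    for i in range(0, min(len(a), len(b)), 3):
        if a[i : i + 3] != b[i : i + 3]:
            return i // 3
    return 0


def aggregate_gene_category(annotations: Sequence[ConsequenceAnnotation]) -> str:
    """Gene-level category: the most severe predicted effect on any transcript."""
    if not annotations:
        raise ValueError("aggregate_gene_category needs >=1 annotation")
    return min((a.category for a in annotations), key=SEVERITY_ORDER.__getitem__)


def bin_polyphen(score: float | None) -> str:
    """Bin a PolyPhen-2 score: >0.85 probably damaging, [0.15, 0.85] possibly
    damaging, <0.15 benign; missing scores map to 'none'."""
    if score is None:
        return "none"
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen score {score} outside [0, 1]")
    if score > 0.85:
        return "probably_damaging"
    if score >= 0.15:
        return "possibly_damaging"
    return "benign"


def assign_classes(
    gene_category: str,
    in_hgmd: bool,
    is_known: bool,
    polyphen_score: float | None = None,
) -> VariantClass:
    """Assign the nonexclusive variant classes from the gene-level category.

    Synonymous and noncoding variants are excluded from the protein-affecting
    variant set entirely and receive no class flags.
    """
    if gene_category not in NONSYNONYMOUS_CATEGORIES:
        return VariantClass(False, False, False, False, bin_polyphen(polyphen_score))
    deleterious = gene_category in DELETERIOUS_CATEGORIES
    vus = not deleterious and not in_hgmd
    return VariantClass(deleterious, in_hgmd, vus, not is_known, bin_polyphen(polyphen_score))
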