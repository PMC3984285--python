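"""Transcript and gene models: coding-region geometry for annotation and per-gene statistics.

Transcripts are ingested from a UCSC knownGene-style TSV (name, chrom, strand,
txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds, geneSymbol).
All internal coordinates are 0-based half-open; VCF positions are converted from
1-based on ingest elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

GENE_TYPES = {"oncogene", "tumor_suppressor", "predisposition", "unknown"}


class GeneModelError(ValueError):
    """Malformed or inconsistent transcript/gene definition."""


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GeneModelError("chrom must be non-empty")
        if not self.start < self.end:
            raise GeneModelError(f"empty interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Transcript:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise GeneModelError(
                    f"{self.transcript_id}: overlapping exons [{a.start},{a.end}) [{b.start},{b.end})"
                )
        self.exons = ex
        if ex and self.cds_start < self.cds_end:
            if self.cds_start < ex[0].start or self.cds_end > ex[-1].end:
                raise GeneModelError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) outside exon span"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end and len(self.cds_exon_intervals()) > 0

    def cds_exon_intervals(self) -> list[tuple[int, int]]:
        """Exonic sub-intervals (genomic order) that fall within the CDS bounds."""
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s < t:
                out.append((s, t))
        return out

    def cds_length(self) -> int:
        return sum(t - s for s, t in self.cds_exon_intervals())

    def introns(self) -> list[tuple[int, int]]:
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:]) if a.end < b.start]


@dataclass
class GeneModel:
    gene_symbol: str
    transcripts: list[Transcript]
    gene_type: str = "unknown"
    census_reason: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GeneModelError(f"{self.gene_symbol}: gene model needs >=1 transcript")
        for t in self.transcripts:
            if t.gene_symbol != self.gene_symbol:
                raise GeneModelError(
                    f"transcript {t.transcript_id} labeled {t.gene_symbol}, expected {self.gene_symbol}"
                )
        if self.gene_type not in GENE_TYPES:
            raise GeneModelError(f"{self.gene_symbol}: unknown gene_type {self.gene_type!r}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, t in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], t)
        else:
            out.append([s, t])
    return [(s, t) for s, t in out]


def coding_length(gene: GeneModel) -> int:
    """Number of distinct genomic bases translated in any transcript of the gene.

    The union over transcripts of exonic bases within each transcript's CDS
    bounds, so shared exons are not double-counted.
    """
    ivals: list[tuple[int, int]] = []
    for t in gene.transcripts:
        ivals.extend(t.cds_exon_intervals())
    return sum(t - s for s, t in _merge_intervals(ivals))


def locate(chrom: str, start: int, end: int, transcript: Transcript, splice_window: int = 2) -> str:
    """Site context of a reference-allele span [start, end) against one transcript.

    Returns one of ``coding``, ``splice_region``, ``intronic``, ``noncoding``.
    ``splice_region`` is the first/last ``splice_window`` intronic bases of each
    intron (canonical donor/acceptor dinucleotides at the default of 2).
    """
    if chrom != transcript.chrom:
        raise GeneModelError(
            f"chromosome mismatch: variant on {chrom}, transcript on {transcript.chrom}"
        )
    for s, t in transcript.cds_exon_intervals():
        if start < t and end > s:
            return "coding"
    for istart, iend in transcript.introns():
        w = min(splice_window, iend - istart)
        if (start < istart + w and end > istart) or (start < iend and end > iend - w):
            return "splice_region"
    for istart, iend in transcript.introns():
        if start < iend and end > istart:
            return "intronic"
    return "noncoding"


KNOWNGENE_COLUMNS = [
    "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds", "geneSymbol",
]


def _parse_csl(text: str) -> list[int]:
    return [int(x) for x in str(text).rstrip(",").split(",") if x != ""]


def transcripts_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[Transcript]:
    """Build Transcript objects from a knownGene-style DataFrame."""
    missing = set(KNOWNGENE_COLUMNS) - set(df.columns)
    if missing:
        raise GeneModelError(f"transcript table missing columns: {sorted(missing)}")
    out = []
    transcript_table = source
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            starts = _parse_csl(row.exonStarts)
            ends = _parse_csl(row.exonEnds)
            if len(starts) != len(ends) or len(starts) != int(row.exonCount):
                raise GeneModelError("exonStarts/exonEnds/exonCount disagree")
            exons = [GenomeInterval(row.chrom, s, e, row.strand) for s, e in zip(starts, ends)]
            out.append(
                Transcript(
                    transcript_id=row.name,
                    gene_symbol=row.geneSymbol,
                    chrom=row.chrom,
                    strand=row.strand,
                    exons=exons,
                    cds_start=int(row.cdsStart),
                    cds_end=int(row.cdsEnd),
                )
            )
        except (ValueError, GeneModelError) as exc:
            raise GeneModelError(f"{transcript_table} line {i}: {exc}") from exc
    return out


def load_transcripts(transcript_table: str) -> list[Transcript]:
    """Parse a knownGene-style TSV into Transcript objects."""
    df = pd.read_csv(transcript_table, sep="\t", dtype=str)
    return transcripts_from_frame(df, source=str(transcript_table))


def gene_models_from_frames(
    tx_df: pd.DataFrame, gene_df: pd.DataFrame
) -> tuple[list[GeneModel], list[str]]:
    """Build one GeneModel per listed gene that has at least one transcript.

    The gene frame needs columns (gene_symbol, gene_type[, census_reason]).
    Genes absent from the transcript table are returned in the second element
    as warning records rather than silently dropped.
    """
    transcripts = transcripts_from_frame(tx_df)
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_symbol, []).append(t)

    genes = gene_df
    if "gene_symbol" not in genes.columns or "gene_type" not in genes.columns:
        raise GeneModelError("gene list needs columns gene_symbol, gene_type")
    models: list[GeneModel] = []
    missing: list[str] = []
    for row in genes.itertuples(index=False):
        sym = row.gene_symbol
        if sym not in by_gene:
            missing.append(sym)
            continue
        models.append(
            GeneModel(
                gene_symbol=sym,
                transcripts=by_gene[sym],
                gene_type=getattr(row, "gene_type", "unknown") or "unknown",
                census_reason=getattr(row, "census_reason", "") or "",
            )
        )
    if missing:
        warnings.warn(f"{len(missing)} listed genes have no transcript: {missing[:10]}")
    return models, missing


def load_gene_models(
    transcript_table: str, gene_list: str
) -> tuple[list[GeneModel], list[str]]:
    """TSV-path wrapper around :func:`gene_models_from_frames`."""
    tx_df = pd.read_csv(transcript_table, sep="\t", dtype=str)
    gene_df = pd.read_csv(gene_list, sep="\t", dtype=str)
    return gene_models_from_frames(tx_df, gene_df)
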