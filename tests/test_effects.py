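import pytest
from Bio.Seq import Seq

from cgprofiler.effects import (
    ConsequenceAnnotation,
    VariantRecord,
    aggregate_gene_category,
    assign_classes,
    bin_polyphen,
    classify_consequence,
    normalize_variant,
)
from cgprofiler.genes import GenomeInterval, Transcript

import oracles


def single_exon_tx(cds, chrom="chrT", strand="+", offset=10):
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    seq = "C" * offset + genomic + "G" * 10
    t = Transcript(
        transcript_id="tx1",
        gene_symbol="G1",
        chrom=chrom,
        strand=strand,
        exons=[GenomeInterval(chrom, offset, offset + len(cds), strand)],
        cds_start=offset,
        cds_end=offset + len(cds),
    )
    return t, {chrom: seq}


class TestClassifyConsequence:
    def test_stop_gain(self):
        t, genome = single_exon_tx("ATGAAATAA")
        ann = classify_consequence(VariantRecord("chrT", 14, "A", "T"), t, genome)
        assert ann.category == "nonsense"
        assert ann.protein_change == "p.Lys2Ter"

    def test_missense(self):
        t, genome = single_exon_tx("ATGAAATAA")
        ann = classify_consequence(VariantRecord("chrT", 14, "A", "G"), t, genome)
        assert ann.category == "missense"
        assert ann.protein_change == "p.Lys2Glu"

    def test_single_base_deletion_is_frameshift(self):
        t, genome = single_exon_tx("ATGAAATAA")
        v = normalize_variant("chrT", 13, "GA", "G", genome)
        ann = classify_consequence(v, t, genome)
        assert ann.category == "frameshift"

    def test_synonymous_third_position(self):
        t, genome = single_exon_tx("ATGGGATAA")  # GGA -> GGG both Gly
        ann = classify_consequence(VariantRecord("chrT", 16, "A", "G"), t, genome)
        assert ann.category == "synonymous"

    def test_outside_transcript_is_noncoding(self):
        t, genome = single_exon_tx("ATGAAATAA")
        ann = classify_consequence(VariantRecord("chrT", 2, "C", "A"), t, genome)
        assert ann.category == "noncoding"
        assert ann.protein_change == ""

    def test_agrees_with_bruteforce_rebuild(self, rng):
        """1,000 random variants against the whole-chromosome rebuild oracle."""
        n_checked = 0
        while n_checked < 1000:
            tx, genome = oracles.random_toy_transcript(rng)
            seq = genome[tx.chrom]
            kind = rng.choice(["snv", "del", "ins", "mnv"], p=[0.5, 0.2, 0.2, 0.1])
            if kind in ("snv", "mnv"):
                width = 1 if kind == "snv" else int(rng.integers(2, 4))
                p0 = int(rng.integers(5, len(seq) - width - 5))
                ref = seq[p0 : p0 + width]
                alt = "".join(rng.choice(list("ACGT"), size=width))
                if ref == alt:
                    continue
                raw = (p0 + 1, ref, alt)
            else:
                # keep indels interior to one exon or deep in the intron
                regions = [(e.start + 8, e.end - 8) for e in tx.exons]
                regions.append((tx.exons[0].end + 8, tx.exons[1].start - 8))
                lo, hi = regions[int(rng.integers(len(regions)))]
                if hi - lo < 10:
                    continue
                p0 = int(rng.integers(lo, hi - 5))
                if kind == "del":
                    w = int(rng.integers(1, 4))
                    raw = (p0, seq[p0 - 1 : p0 + w], seq[p0 - 1])
                else:
                    ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                    raw = (p0, seq[p0 - 1], seq[p0 - 1] + ins)
            try:
                v = normalize_variant(tx.chrom, raw[0], raw[1], raw[2], genome)
            except ValueError:
                continue
            # skip indels whose normalized span left the sampled safe region
            if v.variant_type in ("insertion", "deletion"):
                span = (v.pos - 1, v.pos - 1 + len(v.ref))
                boundary_zones = [
                    (tx.exons[0].end - 3, tx.exons[0].end + 3),
                    (tx.exons[1].start - 3, tx.exons[1].start + 3),
                ]
                if any(span[0] < z2 and span[1] > z1 for z1, z2 in boundary_zones):
                    continue
            got = classify_consequence(v, tx, genome).category
            want = oracles.bruteforce_category(v, tx, genome)
            assert got == want, (v, tx.strand, got, want)
            n_checked += 1

    def test_minus_strand_equals_mirrored_plus_strand(self, rng):
        """Classifying on a minus-strand transcript equals classifying the
        reverse-complement construction on the plus strand."""
        for _ in range(100):
            tx_minus, genome_minus = oracles.random_toy_transcript(rng, strand="-")
            seq = genome_minus[tx_minus.chrom]
            L = len(seq)
            mirror_seq = str(Seq(seq).reverse_complement())
            ex = [
                GenomeInterval("chrM", L - e.end, L - e.start, "+")
                for e in reversed(tx_minus.exons)
            ]
            tx_plus = Transcript(
                transcript_id="TOY1",
                gene_symbol="TOY",
                chrom="chrM",
                strand="+",
                exons=ex,
                cds_start=L - tx_minus.cds_end,
                cds_end=L - tx_minus.cds_start,
            )
            genome_plus = {"chrM": mirror_seq}
            p0 = int(rng.integers(5, L - 6))
            ref = seq[p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v_minus = VariantRecord(tx_minus.chrom, p0 + 1, ref, alt)
            v_plus = VariantRecord(
                "chrM",
                L - p0,
                str(Seq(ref).reverse_complement()),
                str(Seq(alt).reverse_complement()),
            )
            a = classify_consequence(v_minus, tx_minus, genome_minus)
            b = classify_consequence(v_plus, tx_plus, genome_plus)
            assert a.category == b.category
            assert a.protein_change == b.protein_change


class TestNormalization:
    def test_left_align_deletion_in_repeat(self):
        genome = {"c": "GCATATATG"}
        v = normalize_variant("c", 6, "TAT", "T", genome)
        assert (v.pos, v.ref, v.alt) == (2, "CAT", "C")

    def test_trim_shared_suffix_and_prefix(self):
        genome = {"c": "GACGTACGT"}
        v = normalize_variant("c", 2, "ACG", "ATG", genome)
        assert (v.pos, v.ref, v.alt) == (3, "C", "T")

    def test_idempotent(self, rng):
        genome = {"c": "".join(rng.choice(list("ACGT"), size=200))}
        for _ in range(200):
            p0 = int(rng.integers(2, 190))
            w = int(rng.integers(1, 4))
            ref = genome["c"][p0 - 1 : p0 - 1 + w]
            alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            if ref == alt:
                continue
            try:
                v1 = normalize_variant("c", p0, ref, alt, genome)
            except ValueError:
                continue
            v2 = normalize_variant("c", v1.pos, v1.ref, v1.alt, genome)
            assert v1 == v2

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            normalize_variant("c", 1, "A", "T", {"c": "GGGG"})


class TestAggregateAndClasses:
    def test_any_transcript_rule(self):
        anns = [
            ConsequenceAnnotation("t1", "missense", "p.Ala2Val"),
            ConsequenceAnnotation("t2", "nonsense", "p.Lys2Ter"),
        ]
        assert aggregate_gene_category(anns) == "nonsense"

    def test_single_synonymous(self):
        assert aggregate_gene_category(
            [ConsequenceAnnotation("t1", "synonymous", "p.Gly2=")]
        ) == "synonymous"

    def test_splice_beats_missense(self):
        anns = [
            ConsequenceAnnotation("t5", "splice_site", ""),
            ConsequenceAnnotation("t1", "missense", "p.Val2Ala"),
        ]
        assert aggregate_gene_category(anns) == "splice_site"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_gene_category([])

    @pytest.mark.parametrize(
        "category,in_hgmd,known,expect",
        [
            ("frameshift", False, False, dict(deleterious=True, vus=False, novel=True)),
            ("missense", True, True, dict(deleterious=False, hgmd=True, vus=False)),
            ("missense", False, True, dict(vus=True, deleterious=False, hgmd=False)),
        ],
    )
    def test_class_assignment(self, category, in_hgmd, known, expect):
        vc = assign_classes(category, in_hgmd, known)
        for k, v in expect.items():
            assert getattr(vc, k) == v

    def test_synonymous_gets_no_class_flags(self):
        vc = assign_classes("synonymous", True, False)
        assert not (vc.deleterious or vc.hgmd or vc.vus or vc.novel)


class TestPolyphenBinning:
    @pytest.mark.parametrize(
        "score,expect",
        [
            (0.9, "probably_damaging"),
            (0.10, "benign"),
            (0.85, "possibly_damaging"),
            (0.15, "possibly_damaging"),
            (None, "none"),
        ],
    )
    def test_bins(self, score, expect):
        assert bin_polyphen(score) == expect

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bin_polyphen(1.2)
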