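"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route available —
rebuilding whole mutated chromosomes, enumerating contingency tables, grid
searches — so they share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from cgprofiler.genes import GenomeInterval, Transcript


# --------------------------------------------------------------- consequences
def random_toy_transcript(rng, chrom="chrT", strand=None, n_codons=None):
    """A 2-exon fully coding toy transcript embedded in a random chromosome."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_codons = n_codons or int(rng.integers(12, 40))
    codons = ["ATG"]
    stops = {"TAA", "TAG", "TGA"}
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    genomic_cds = cds if strand == "+" else str(Seq(cds).reverse_complement())
    e1 = 3 * (n_codons // 2)
    if strand == "-":
        e1 = len(cds) - e1
    intron = "".join(rng.choice(list("ACGT"), size=60))
    flank5 = "".join(rng.choice(list("ACGT"), size=50))
    flank3 = "".join(rng.choice(list("ACGT"), size=50))
    seq = flank5 + genomic_cds[:e1] + intron + genomic_cds[e1:] + flank3
    ex1 = GenomeInterval(chrom, 50, 50 + e1, strand)
    ex2 = GenomeInterval(chrom, 50 + e1 + 60, 50 + len(genomic_cds) + 60, strand)
    tx = Transcript(
        transcript_id="TOY1",
        gene_symbol="TOY",
        chrom=chrom,
        strand=strand,
        exons=[ex1, ex2],
        cds_start=ex1.start,
        cds_end=ex2.end,
    )
    return tx, {chrom: seq}


def _translate_to_stop(cds: str) -> str:
    n = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:n]).translate())
    i = prot.find("*")
    return prot[: i + 1] if i >= 0 else prot


def bruteforce_category(v, tx: Transcript, genome: dict[str, str]) -> str:
    """Re-derive the consequence category by rebuilding the mutated chromosome
    and re-extracting the CDS with shifted coordinates.

    Assumes the edit does not straddle an exon/intron boundary (the samplers
    guarantee this); SNVs/MNVs may fall anywhere.
    """
    seq = genome[tx.chrom]
    s0, e0 = v.pos - 1, v.pos - 1 + len(v.ref)
    delta = len(v.alt) - len(v.ref)

    cds_ivals = tx.cds_exon_intervals()
    touches_cds = any(s0 < t and e0 > s for s, t in cds_ivals)
    if not touches_cds:
        # splice context: span intersects the first/last 2 bases of the intron
        for (istart, iend) in [(tx.exons[0].end, tx.exons[1].start)]:
            for ws, we in [(istart, istart + 2), (iend - 2, iend)]:
                if s0 < we and e0 > ws:
                    return "splice_site"
    if len(v.ref) == len(v.alt):
        # substitution may straddle boundaries; only coding bases matter
        changed = [
            s0 + i
            for i in range(len(v.ref))
            if v.ref[i] != v.alt[i]
            and any(s <= s0 + i < t for s, t in cds_ivals)
        ]
        if not changed:
            return "noncoding"
    elif not touches_cds:
        k = 0
        while k < min(len(v.ref), len(v.alt)) and v.ref[k] == v.alt[k]:
            k += 1
        ins_anchor = s0 + k - 1
        if not (len(v.alt) > len(v.ref) and any(s <= ins_anchor < t for s, t in cds_ivals)):
            return "noncoding"

    mutated = seq[:s0] + v.alt + seq[e0:]

    def shift(c: int) -> int:
        return c + delta if c > s0 else c

    new_ivals = [(shift(s), shift(t)) for s, t in cds_ivals]
    ref_cds = "".join(seq[s:t] for s, t in cds_ivals)
    alt_cds = "".join(mutated[s:t] for s, t in new_ivals)
    if tx.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    if alt_cds == ref_cds:
        return "noncoding"
    if (len(alt_cds) - len(ref_cds)) % 3 != 0:
        return "frameshift"
    rp, ap = _translate_to_stop(ref_cds), _translate_to_stop(alt_cds)
    if rp == ap:
        return "synonymous"
    i = 0
    while i < min(len(rp), len(ap)) and rp[i] == ap[i]:
        i += 1
    if i < len(ap) and ap[i] == "*":
        return "nonsense"
    if len(alt_cds) == len(ref_cds):
        return "missense"
    return "inframe_indel"


# ----------------------------------------------------------- contingency tables
def enumerate_tables(row_sums, col_sums):
    """All R x 2 tables with the given margins (col_sums length 2)."""
    assert len(col_sums) == 2
    R = len(row_sums)
    tables = []

    def rec(i, remaining_c0, acc):
        if i == R:
            if remaining_c0 == 0:
                tables.append(list(acc))
            return
        for a in range(0, row_sums[i] + 1):
            if a > remaining_c0:
                break
            rec(i + 1, remaining_c0 - a, acc + [a])

    rec(0, col_sums[0], [])
    out = []
    for t in tables:
        tbl = np.array([[a, r - a] for a, r in zip(t, row_sums)])
        if (tbl >= 0).all():
            out.append(tbl)
    return out


def exact_prob_based_p(table) -> float:
    """Exact Fisher-style p: total probability of all fixed-margin tables no
    more probable than the observed one (multivariate hypergeometric)."""
    from math import lgamma

    table = np.asarray(table, dtype=int)

    def logp(t):
        r, c = t.sum(axis=1), t.sum(axis=0)
        val = sum(lgamma(x + 1) for x in r) + sum(lgamma(x + 1) for x in c)
        val -= lgamma(t.sum() + 1) + sum(lgamma(x + 1) for x in t.ravel())
        return val

    lp_obs = logp(table)
    total = 0.0
    for t in enumerate_tables(list(table.sum(axis=1)), list(table.sum(axis=0))):
        lp = logp(t)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


# ------------------------------------------------------------------ admixture
def grid_search_q2(dosage: np.ndarray, freqs2: np.ndarray, step: float = 0.01) -> float:
    """1-D grid maximum-likelihood mixing proportion for a 2-population panel.

    Returns the weight on population 0 maximising the binomial log-likelihood.
    """
    f = np.clip(freqs2, 1e-6, 1 - 1e-6)
    called = dosage >= 0
    x = np.where(called, dosage, 0).astype(float)
    x2 = np.where(called, 2 - dosage, 0.0)
    best_q, best_ll = 0.0, -np.inf
    for q in np.arange(0.0, 1.0 + step / 2, step):
        p = np.clip(q * f[:, 0] + (1 - q) * f[:, 1], 1e-12, 1 - 1e-12)
        ll = float((x * np.log(p) + x2 * np.log(1 - p)).sum())
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q


# ------------------------------------------------------------------ regression
def normal_equation_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS (slope, intercept) from the normal equations."""
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    return float(beta[1]), float(beta[0])
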