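"""Per-gene codon-usage metrics against per-genome backgrounds.

Four quantities feed the horizontal-gene-transfer screen: GC content,
a scalar RSCU deviation, Wright's effective number of codons (ENC) and the
codon adaptation index (CAI).  All are computed under the bacterial genetic
code; Met, Trp and stop codons carry no synonymous-choice information and
are excluded from RSCU/ENC/CAI.

RSCU is a 59-element vector per gene; the screen needs one number, so we
scalarize it as the mean absolute deviation of the gene's RSCU from the
genome-wide RSCU over the degenerate-family codons of amino acids the gene
actually uses (``rscu_deviation``).  High values mean atypical synonymous
choices relative to the host genome.

CAI uses the whole genome's coding sequences as the reference pool by
default (no curated highly-expressed set is assumed), with a +1 pseudocount
on reference counts so unseen codons do not zero the geometric mean.

GC is computed over the full CDS, not the third codon position only.

Degenerate inputs yield ``nan`` ("undefined") rather than errors: ENC when
a required degeneracy class is unobserved, CAI when the gene has no codons
in degenerate families.  Downstream flagging treats ``nan`` conservatively.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome_io import Genome
from .synthetic_data import (
    SENSE_CODONS,
    STOP_CODONS,
    _AA_TO_CODONS as AA_TO_CODONS,
    _CODON_TO_AA as CODON_TO_AA,
)

# amino acids with >= 2 synonymous codons (table 11): Met/Trp excluded
DEGENERATE_AA = sorted(
    aa for aa, codons in AA_TO_CODONS.items() if len(codons) >= 2
)
DEGENERACY_CLASS = {aa: len(AA_TO_CODONS[aa]) for aa in DEGENERATE_AA}
# class sizes in the standard/bacterial code: 9 two-fold, 1 three-fold,
# 5 four-fold, 3 six-fold amino acids
_CLASS_COUNT = Counter(DEGENERACY_CLASS.values())
assert _CLASS_COUNT == {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCounts:
    """Codon tally of one gene (or a pooled gene set)."""

    gene_id: str
    counts: dict[str, int]

    @classmethod
    def from_cds(cls, gene_id: str, cds_nt: str) -> "CodonCounts":
        cds = cds_nt.upper()
        counts: Counter[str] = Counter()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if codon in CODON_TO_AA or codon in STOP_CODONS:
                counts[codon] += 1
        return cls(gene_id=gene_id, counts=dict(counts))

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(gene_id="pool", counts=dict(merged))


def pool_counts(counts_list: list[CodonCounts]) -> CodonCounts:
    merged: Counter[str] = Counter()
    for c in counts_list:
        merged.update(c.counts)
    return CodonCounts(gene_id="pool", counts=dict(merged))


@dataclass
class CodonProfile:
    """The four screened metrics for one gene; ``nan`` marks undefined."""

    gene_id: str
    gc: float
    rscu_dev: float
    enc: float
    cai: float


def gc_content(cds_nt: str) -> float:
    """GC fraction of a sequence; ambiguous bases excluded from both sides."""
    if not cds_nt:
        raise ValueError("empty sequence")
    seq = cds_nt.upper()
    unambiguous = sum(seq.count(b) for b in "ACGT")
    if unambiguous == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / unambiguous


def rscu(counts: CodonCounts) -> dict[str, float]:
    """Relative synonymous codon usage of a gene set.

    For codon *j* of amino acid *i* with family size *n*:
    ``RSCU = X_ij / (mean_k X_ik)``.  Families with zero total usage are
    omitted; single-codon families (Met, Trp) and stops never appear.
    """
    out: dict[str, float] = {}
    for aa in DEGENERATE_AA:
        family = AA_TO_CODONS[aa]
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            continue
        expected = total / len(family)
        for c in family:
            out[c] = counts.counts.get(c, 0) / expected
    return out


def rscu_deviation(gene: CodonCounts, genome_pool: CodonCounts) -> float:
    """Mean |RSCU_gene − RSCU_genome| over codons of the gene's amino acids.

    Only degenerate families the gene actually uses contribute; returns
    ``nan`` when the gene has no degenerate-family codons.
    """
    gene_rscu = rscu(gene)
    pool_rscu = rscu(genome_pool)
    codons = sorted(gene_rscu)
    if not codons:
        return math.nan
    return float(np.mean([
        abs(gene_rscu[c] - pool_rscu.get(c, 0.0)) for c in codons
    ]))


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, capped at 61.

    Homozygosity ``F = (n * sum p_i^2 - 1) / (n - 1)`` per amino acid with
    n >= 2 observations, averaged within degeneracy classes {2,3,4,6};
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.  A missing three-fold class
    (Ile unobserved) is imputed as ``(F2 + F4)/2``; any other missing class
    makes the estimate undefined (``nan``).  Amino acids whose F estimate
    is zero are skipped, as in the usual implementations.
    """
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa in DEGENERATE_AA:
        family = AA_TO_CODONS[aa]
        ns = [counts.counts.get(c, 0) for c in family]
        n = sum(ns)
        if n < 2:
            continue
        p2 = sum((x / n) ** 2 for x in ns)
        f_hat = (n * p2 - 1) / (n - 1)
        if f_hat > 0:
            f_by_class[len(family)].append(f_hat)
    fbar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_by_class.items() if v
    }
    if 2 not in fbar or 4 not in fbar or 6 not in fbar:
        return math.nan
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    value = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(value, 61.0)


def cai(counts: CodonCounts, reference_pool: CodonCounts) -> float:
    """Codon adaptation index versus a reference usage pool.

    Relative adaptiveness ``w_ij = (X_ij + 1) / (X_imax + 1)`` (pseudocount
    1); CAI is the geometric mean of ``w`` over the gene's codons in
    degenerate families.  ``nan`` when the gene has none.
    """
    if not reference_pool.counts:
        raise ValueError("empty reference pool")
    w: dict[str, float] = {}
    for aa in DEGENERATE_AA:
        family = AA_TO_CODONS[aa]
        x_max = max(reference_pool.counts.get(c, 0) for c in family)
        for c in family:
            w[c] = (reference_pool.counts.get(c, 0) + 1) / (x_max + 1)
    log_sum = 0.0
    n = 0
    for c, x in counts.counts.items():
        if c in w:
            log_sum += x * math.log(w[c])
            n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def profile_genome(genome: Genome,
                   reference_pool: CodonCounts | None = None
                   ) -> list[CodonProfile]:
    """Compute all four metrics for every intact gene of a genome.

    Frameshifted/pseudogenized records are excluded both from profiling and
    from the genome pool used for RSCU deviation and (by default) CAI.
    """
    usable = [g for g in genome.genes
              if not g.frameshifted and not g.pseudogenized]
    if len(usable) < 2:
        raise ValueError("need >= 2 intact genes to define a genome background")
    per_gene = {g.gene_id: CodonCounts.from_cds(g.gene_id, g.cds_nt)
                for g in usable}
    genome_pool = pool_counts(list(per_gene.values()))
    ref = reference_pool if reference_pool is not None else genome_pool
    profiles = []
    for g in usable:
        counts = per_gene[g.gene_id]
        profiles.append(CodonProfile(
            gene_id=g.gene_id,
            gc=gc_content(g.cds_nt),
            rscu_dev=rscu_deviation(counts, genome_pool),
            enc=enc(counts),
            cai=cai(counts, ref),
        ))
    return profiles
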