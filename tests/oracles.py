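"""Naive, formula-level re-implementations of the codon-usage metrics.

These are deliberately written with plain loops and dictionaries, straight
from the textbook definitions, as an independent cross-check of the package
implementations.  They share the package's documented conventions
(bacterial code; Met/Trp/stops excluded; CAI pseudocount 1; Wright's ENC
with F3 imputation, undefined on other missing classes, zero-F amino acids
skipped) but none of its code.
"""

import math

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
FAMILIES = {}
for codon, aa in _CODE.items():
    if aa != "*":
        FAMILIES.setdefault(aa, []).append(codon)
DEGENERATE = {aa: sorted(cs) for aa, cs in FAMILIES.items() if len(cs) >= 2}


def count_codons(cds):
    counts = {}
    for i in range(0, len(cds) - len(cds) % 3, 3):
        c = cds[i:i + 3]
        counts[c] = counts.get(c, 0) + 1
    return counts


def naive_gc(seq):
    num = sum(1 for b in seq if b in "GC")
    den = sum(1 for b in seq if b in "ACGT")
    return num / den


def naive_rscu(counts):
    out = {}
    for aa, codons in DEGENERATE.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        for c in codons:
            out[c] = counts.get(c, 0) * len(codons) / total
    return out

def naive_rscu_dev(gene_counts, pool_counts):
    gene = naive_rscu(gene_counts)
    pool = naive_rscu(pool_counts)
    if not gene:
        return math.nan
    devs = [abs(gene[c] - pool.get(c, 0.0)) for c in gene]
    return sum(devs) / len(devs)


def naive_enc(counts):
    per_class = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE.items():
        xs = [counts.get(c, 0) for c in codons]
        n = sum(xs)
        if n < 2:
            continue
        s = sum((x / n) ** 2 for x in xs)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            per_class[len(codons)].append(f)
    fbar = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if 2 not in fbar or 4 not in fbar or 6 not in fbar:
        return math.nan
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    return min(2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6],
               61.0)


def naive_cai(counts, ref_counts):
    w = {}
    for aa, codons in DEGENERATE.items():
        xmax = max(ref_counts.get(c, 0) for c in codons)
        for c in codons:
            w[c] = (ref_counts.get(c, 0) + 1) / (xmax + 1)
    total_log, n = 0.0, 0
    for c, x in counts.items():
        if c in w:
            total_log += x * math.log(w[c])
            n += x
    if n == 0:
        return math.nan
    return math.exp(total_log / n)
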