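import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    count_codons,
    naive_cai,
    naive_enc,
    naive_gc,
    naive_rscu,
    naive_rscu_dev,
)
from piliscan.codon_metrics import (
    AA_TO_CODONS,
    CodonCounts,
    cai,
    enc,
    gc_content,
    profile_genome,
    rscu,
    rscu_deviation,
)
from piliscan.synthetic_data import SENSE_CODONS, SimulationConfig, \
    simulate_genomes


def _random_cds(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS, size=n_codons)) + "TAA"


# ---------------------------------------------------------------------------
# GC content

@pytest.mark.parametrize("seq,expected", [
    ("GGGCCC", 1.0),
    ("AAATTT", 0.0),
    ("GCGGCA", 5 / 6),
])
def test_gc_direct(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_ignores_ambiguous_bases():
    assert gc_content("GCNN") == 1.0


def test_gc_empty_raises():
    with pytest.raises(ValueError):
        gc_content("")


# ---------------------------------------------------------------------------
# RSCU and its scalarization

def test_rscu_uniform_fourfold_is_one():
    c = CodonCounts("g", {k: 3 for k in AA_TO_CODONS["A"]})
    assert all(v == pytest.approx(1.0) for v in rscu(c).values())


def test_rscu_single_codon_twofold():
    c = CodonCounts("g", {"TTT": 5, "TTC": 0})
    vals = rscu(c)
    assert vals["TTT"] == 2.0 and vals["TTC"] == 0.0


def test_rscu_hand_computed_alanine():
    c = CodonCounts("g", {"GCT": 2, "GCC": 1, "GCA": 1, "GCG": 0})
    vals = rscu(c)
    assert [vals[k] for k in ("GCT", "GCC", "GCA", "GCG")] == \
        [2.0, 1.0, 1.0, 0.0]


def test_rscu_family_sums_equal_family_size():
    rng = np.random.default_rng(5)
    c = CodonCounts.from_cds("g", _random_cds(rng, 300))
    vals = rscu(c)
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) < 2 or not any(k in vals for k in codons):
            continue
        assert sum(vals[k] for k in codons) == pytest.approx(len(codons))


def test_rscu_deviation_identity_is_zero():
    rng = np.random.default_rng(7)
    c = CodonCounts.from_cds("g", _random_cds(rng, 200))
    assert rscu_deviation(c, c) == pytest.approx(0.0)


def test_rscu_deviation_hand_computed():
    gene = CodonCounts("g", {"GCG": 4})
    pool = CodonCounts("p", {k: 10 for k in AA_TO_CODONS["A"]})
    # gene RSCU (0,0,0,4) vs pool (1,1,1,1): (1+1+1+3)/4
    assert rscu_deviation(gene, pool) == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# ENC

def test_enc_maximal_bias_is_twenty():
    counts = {codons[0]: 50 for codons in AA_TO_CODONS.values()}
    assert enc(CodonCounts("g", counts)) == pytest.approx(20.0)


def test_enc_uniform_usage_caps_at_61():
    counts = {c: 5000 for c in SENSE_CODONS}
    assert enc(CodonCounts("g", counts)) == 61.0


def test_enc_fixed_toy_gene_matches_bruteforce():
    rng = np.random.default_rng(11)
    cds = _random_cds(rng, 100)
    c = CodonCounts.from_cds("g", cds)
    assert enc(c) == pytest.approx(naive_enc(count_codons(cds)), abs=1e-9)


def test_enc_undefined_when_twofold_class_missing():
    # only four-fold and six-fold families observed
    counts = {"GCT": 3, "GCC": 2, "CTT": 2, "CTC": 2, "GGT": 2, "GGA": 1,
              "CCT": 2, "CCA": 1, "TCT": 2, "TCA": 1, "CGT": 2}
    assert math.isnan(enc(CodonCounts("g", counts)))


def test_enc_monotone_under_increasing_bias():
    # deterministic gradient: skew every family toward its first codon
    values = []
    for skew in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        counts = {}
        for codons in AA_TO_CODONS.values():
            if len(codons) == 1:
                continue
            n = 600
            major = int(n * (1 + skew * (len(codons) - 1)) / len(codons))
            rest = (n - major) // (len(codons) - 1)
            counts[codons[0]] = major
            for c in codons[1:]:
                counts[c] = rest
        values.append(enc(CodonCounts("g", counts)))
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# CAI

def test_cai_all_preferred_is_one():
    ref = CodonCounts("r", {"TTT": 99, "TTC": 9})
    gene = CodonCounts("g", {"TTT": 30})
    assert cai(gene, ref) == pytest.approx(1.0)


def test_cai_half_preferred_closed_form():
    # w(TTT)=1, w(TTC)=(9+1)/(19+1)=0.5; equal use -> exp(0.5*ln 0.5)
    ref = CodonCounts("r", {"TTT": 19, "TTC": 9})
    gene = CodonCounts("g", {"TTT": 10, "TTC": 10})
    assert cai(gene, ref) == pytest.approx(math.exp(0.5 * math.log(0.5)))


def test_cai_met_trp_only_is_undefined():
    ref = CodonCounts("r", {c: 5 for c in SENSE_CODONS})
    assert math.isnan(cai(CodonCounts("g", {"ATG": 3, "TGG": 2}), ref))


def test_cai_reference_concatenation_beats_random_genes():
    rng = np.random.default_rng(13)
    # biased reference pool
    pool_counts = {}
    for codons in AA_TO_CODONS.values():
        for i, c in enumerate(codons):
            pool_counts[c] = 400 if i == 0 else 10
    ref = CodonCounts("r", pool_counts)
    self_cai = cai(ref, ref)
    wins = sum(
        self_cai >= cai(CodonCounts.from_cds("g", _random_cds(rng, 150)),
                        ref)
        for _ in range(50)
    )
    assert wins == 50


# ---------------------------------------------------------------------------
# oracle agreement across all four metrics

def test_all_metrics_match_naive_oracle_on_random_genes():
    rng = np.random.default_rng(17)
    pool_cds = _random_cds(rng, 2000)
    pool = CodonCounts.from_cds("pool", pool_cds)
    naive_pool = count_codons(pool_cds)
    for _ in range(20):
        cds = _random_cds(rng, int(rng.integers(80, 400)))
        c = CodonCounts.from_cds("g", cds)
        nc = count_codons(cds)
        assert gc_content(cds) == pytest.approx(naive_gc(cds), abs=1e-9)
        mine, naive = rscu(c), naive_rscu(nc)
        assert set(mine) == set(naive)
        for k in mine:
            assert mine[k] == pytest.approx(naive[k], abs=1e-9)
        assert rscu_deviation(c, pool) == pytest.approx(
            naive_rscu_dev(nc, naive_pool), abs=1e-9)
        assert enc(c) == pytest.approx(naive_enc(nc), abs=1e-9)
        assert cai(c, pool) == pytest.approx(naive_cai(nc, naive_pool),
                                             abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rscu_mean_per_family_is_one(seed):
    rng = np.random.default_rng(seed)
    c = CodonCounts.from_cds("g", _random_cds(rng, 200))
    vals = rscu(c)
    for codons in AA_TO_CODONS.values():
        if len(codons) >= 2 and codons[0] in vals:
            assert np.mean([vals[k] for k in codons]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# genome profiling

@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimulationConfig(seed=4, n_genomes=1, n_background_genes=60,
                           n_alien_genes=0, loci_to_embed=[],
                           n_core_families=2)
    return simulate_genomes(cfg)


def test_profile_genome_counts_and_finiteness(small_cohort):
    genomes, _ = small_cohort
    profiles = profile_genome(genomes[0])
    assert len(profiles) == len(genomes[0].genes)
    for p in profiles:
        assert 0 <= p.gc <= 1
        assert p.rscu_dev >= 0
        assert 20 <= p.enc <= 61
        assert 0 < p.cai <= 1


def test_profile_excludes_frameshifted_genes(small_cohort):
    genomes, _ = small_cohort
    g = genomes[0]
    broken = g.genes[0]
    broken.frameshifted = True
    try:
        profiles = profile_genome(g)
        assert broken.gene_id not in {p.gene_id for p in profiles}
    finally:
        broken.frameshifted = False


def test_profile_order_invariance(small_cohort):
    genomes, _ = small_cohort
    g = genomes[0]
    shuffled_genes = list(reversed(g.genes))
    from piliscan.genome_io import Genome
    g2 = Genome(genome_id=g.genome_id, contigs=g.contigs,
                genes=shuffled_genes)
    p1 = {(p.gene_id, p.gc, p.rscu_dev, p.enc, p.cai)
          for p in profile_genome(g)}
    p2 = {(p.gene_id, p.gc, p.rscu_dev, p.enc, p.cai)
          for p in profile_genome(g2)}
    assert p1 == p2
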