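import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj as skbio_nj

from conftest import genome_from_proteins, random_protein
from piliscan.genome_io import GeneRecord
from piliscan.locus_scan import FamilyAssignment, LocusMember, LocusModel
from piliscan.pangenome_phylo import (
    DistanceMatrix,
    OrthologClusterSet,
    cluster_orthologs,
    core_distances,
    core_families,
    flank_conservation,
    nj_tree,
)
from piliscan.synthetic_data import mutate_protein


def _cohort(rng, shared=None, extras=None, n_genomes=3):
    """Genomes sharing `shared` proteins plus per-genome unique extras."""
    shared = shared or {}
    genomes = []
    for i in range(n_genomes):
        named = [(f"G{i}_{name}", prot) for name, prot in shared.items()]
        for j in range(extras or 0):
            named.append((f"G{i}_u{j}", random_protein(rng, 200)))
        genomes.append(genome_from_proteins(f"G{i}", named, rng))
    return genomes


def test_identical_protein_clusters_across_genomes():
    rng = np.random.default_rng(41)
    prot = random_protein(rng, 240)
    genomes = _cohort(rng, shared={"s": prot}, extras=2)
    ocs = cluster_orthologs(genomes)
    sizes = sorted(len(m) for m in ocs.clusters.values())
    assert sizes == [1] * 6 + [3]
    big = next(m for m in ocs.clusters.values() if len(m) == 3)
    assert {g for g, _ in big} == {"G0", "G1", "G2"}


def test_half_identity_pair_stays_split():
    rng = np.random.default_rng(43)
    prot = random_protein(rng, 240)
    far = "M" + mutate_protein(rng, prot[1:], 0.5)
    g0 = genome_from_proteins("G0", [("a", prot)], rng)
    g1 = genome_from_proteins("G1", [("b", far)], rng)
    ocs = cluster_orthologs([g0, g1])
    assert all(len(m) == 1 for m in ocs.clusters.values())


def test_planted_family_clusters_at_high_identity():
    rng = np.random.default_rng(47)
    ref = random_protein(rng, 260)
    genomes = []
    for i in range(10):
        variant = "M" + mutate_protein(rng, ref[1:], 0.95)
        genomes.append(genome_from_proteins(f"G{i}", [("fam", variant)],
                                            rng))
    ocs = cluster_orthologs(genomes)
    assert sorted(len(m) for m in ocs.clusters.values()) == [10]


def test_clustering_invariant_to_genome_order():
    rng = np.random.default_rng(53)
    prot = random_protein(rng, 220)
    genomes = _cohort(rng, shared={"s": prot}, extras=1)
    a = cluster_orthologs(genomes)
    b = cluster_orthologs(list(reversed(genomes)))
    assert a.clusters == b.clusters


def test_core_family_rules():
    ocs = OrthologClusterSet(clusters={
        "c_all": [("G0", "a"), ("G1", "b"), ("G2", "c")],
        "c_missing": [("G0", "d"), ("G1", "e")],
        "c_paralog": [("G0", "f"), ("G0", "g"), ("G1", "h"), ("G2", "i")],
    })
    class _G:
        def __init__(self, gid):
            self.genome_id = gid
    genomes = [_G("G0"), _G("G1"), _G("G2")]
    assert core_families(ocs, genomes) == ["c_all"]


def test_core_distances_identical_and_single_family():
    rng = np.random.default_rng(59)
    prot = random_protein(rng, 200)
    genomes = _cohort(rng, shared={"s": prot}, extras=0, n_genomes=3)
    ocs = cluster_orthologs(genomes)
    assert len(ocs.core_ids) == 1
    dm = core_distances(ocs, genomes)
    assert np.allclose(dm.d, 0.0)


def test_core_distances_mean_over_families():
    rng = np.random.default_rng(61)
    refs = {f"f{k}": random_protein(rng, 300) for k in range(3)}
    genomes = []
    for i, ident in enumerate((1.0, 0.9)):
        named = [(f"G{i}_{k}", "M" + mutate_protein(rng, p[1:], ident))
                 for k, p in refs.items()]
        genomes.append(genome_from_proteins(f"G{i}", named, rng))
    ocs = cluster_orthologs(genomes)
    assert len(ocs.core_ids) == 3
    dm = core_distances(ocs, genomes)
    # hand-average of the three per-family p-distances
    from piliscan.align import global_identity
    expected = np.mean([
        1 - global_identity(genomes[0].genes[k].protein_aa,
                            genomes[1].genes[k].protein_aa)[0]
        for k in range(3)
    ])
    assert dm.d[0, 1] == pytest.approx(expected)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 1], [2, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=["a", "b"], d=np.array([[1, 2], [2, 0]]))


# ---------------------------------------------------------------------------
# neighbor joining

def test_three_taxon_closed_form():
    dm = DistanceMatrix(taxa=["A", "B", "C"],
                        d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                   dtype=float))
    tree = TreeNode.read(io.StringIO(nj_tree(dm)))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx(1.0, abs=1e-12)
    assert lengths["B"] == pytest.approx(1.0, abs=1e-12)
    assert lengths["C"] == pytest.approx(3.0, abs=1e-12)


def test_two_taxa_split_evenly():
    dm = DistanceMatrix(taxa=["A", "B"], d=np.array([[0.0, 2.0],
                                                     [2.0, 0.0]]))
    assert nj_tree(dm) == "(A:2,B:2);".replace("2", "1")


def test_four_taxon_additive_exact_recovery():
    # tree ((A:1,B:2):1,(C:3,D:4)); path-length distances
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float)
    dm = DistanceMatrix(taxa=list("ABCD"), d=d)
    tree = TreeNode.read(io.StringIO(nj_tree(dm)))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
    # A+B form a cherry
    parent_names = {tuple(sorted(t.name for t in n.tips()))
                    for n in tree.non_tips()}
    assert ("A", "B") in parent_names or ("C", "D") in parent_names


def _random_additive_tree(rng, n_taxa):
    taxa = [f"t{i}" for i in range(n_taxa)]
    newicks = {name: name for name in taxa}
    active = list(taxa)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]   # pop higher index first
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = f"({newicks[a]}:{la:.6f},{newicks[b]}:{lb:.6f})"
        active.remove(a)
        active.remove(b)
        key = f"n{len(newicks)}"
        newicks[key] = merged
        active.append(key)
    la, lb = rng.uniform(0.05, 1.0, size=2)
    final = (f"({newicks[active[0]]}:{la:.6f},"
             f"{newicks[active[1]]}:{lb:.6f});")
    return TreeNode.read(io.StringIO(final))


def test_nj_recovers_random_additive_trees():
    """50 random 6-taxon trees: additive distances give exact topology."""
    rng = np.random.default_rng(67)
    for _ in range(50):
        true_tree = _random_additive_tree(rng, 6)
        dm_sk = true_tree.tip_tip_distances()
        taxa = list(dm_sk.ids)
        dm = DistanceMatrix(taxa=taxa, d=dm_sk.data)
        mine = TreeNode.read(io.StringIO(nj_tree(dm)))
        rf = true_tree.compare_rfd(mine, rooted=False)
        assert rf == 0.0


def test_nj_matches_reference_implementation_topology():
    rng = np.random.default_rng(71)
    n = 7
    base = rng.uniform(0.2, 1.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    taxa = [f"s{i}" for i in range(n)]
    mine = TreeNode.read(io.StringIO(
        nj_tree(DistanceMatrix(taxa=taxa, d=d))))
    ref = skbio_nj(SkbioDM(d, ids=taxa))
    assert mine.compare_rfd(ref, rooted=False) == 0.0


def test_outgroup_rooting():
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float)
    nwk = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=d), outgroup="D")
    tree = TreeNode.read(io.StringIO(nwk))
    children = tree.children
    assert {c.name for c in children if c.is_tip()} == {"D"}
    out_edge = next(c for c in children if c.is_tip())
    other = next(c for c in children if not c.is_tip())
    assert out_edge.length == pytest.approx(other.length)


def test_unknown_outgroup_raises():
    dm = DistanceMatrix(taxa=["A", "B", "C"],
                        d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                   dtype=float))
    with pytest.raises(ValueError):
        nj_tree(dm, outgroup="Z")


# ---------------------------------------------------------------------------
# flank conservation

def _locus_for(genome, member_gene_ids, system="T4cP"):
    members = []
    for gid in member_gene_ids:
        gene = genome.gene(gid)
        fam = "tadZ"
        members.append(LocusMember(
            assignment=FamilyAssignment(gene_id=gid, family_name=fam,
                                        identity=0.9, coverage=1.0,
                                        pseudo=False),
            gene=gene))
    return LocusModel(locus_id=f"{genome.genome_id}_L",
                      genome_id=genome.genome_id, members=members,
                      system=system)


def test_all_genomes_share_flank_pair():
    rng = np.random.default_rng(73)
    up, down, mid = (random_protein(rng, 220) for _ in range(3))
    genomes, loci = [], []
    for i in range(4):
        g = genome_from_proteins(
            f"G{i}",
            [("up", "M" + mutate_protein(rng, up[1:], 0.95)),
             ("locus", random_protein(rng, 220)),
             ("down", "M" + mutate_protein(rng, down[1:], 0.95))],
            rng)
        genomes.append(g)
        loci.append(_locus_for(g, ["locus"]))
    ocs = cluster_orthologs(genomes)
    report = flank_conservation(loci, ocs, genomes)
    assert report.conservation == 1.0


def test_locus_at_contig_start_counts_none_flank():
    rng = np.random.default_rng(79)
    down = random_protein(rng, 220)
    genomes, loci = [], []
    for i in range(3):
        g = genome_from_proteins(
            f"G{i}",
            [("locus", random_protein(rng, 220)),
             ("down", "M" + mutate_protein(rng, down[1:], 0.95))],
            rng)
        genomes.append(g)
        loci.append(_locus_for(g, ["locus"]))
    report = flank_conservation(loci, cluster_orthologs(genomes), genomes)
    assert all(pair[0] == "none" for pair in report.pairs.values())
    assert report.conservation == 1.0
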