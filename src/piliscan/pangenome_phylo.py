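"""Pangenome ortholog clustering, core-genome phylogeny and locus context.

Orthologs are clustered across genomes from an all-against-all protein
identity graph (edges at >= 80% global identity by default, with a shared
4-mer prefilter to skip obviously unrelated pairs) using Markov clustering
(MCL: expansion 2, configurable inflation, pruning 1e-6).  Core families
are clusters with exactly one member in every genome — the strict
single-copy reading of "shared by all genomes".

The core-genome tree is built by Saitou–Nei neighbor joining on a distance
matrix of per-family protein p-distances (1 − identity) averaged across
core families — an alignment-free stand-in for concatenated multiple
alignment that yields the same additive signal at this scale.  Negative NJ
branch lengths are clamped to zero with the excess moved to the sister
branch; an optional outgroup roots the tree at the midpoint of its pendant
edge.

Flanking-gene conservation around detected pilus loci maps the nearest
non-locus gene on each side of a locus to its ortholog cluster (COG) and
reports the fraction of genomes sharing the modal (upstream, downstream)
pair, orientation-normalized so minus-strand loci swap their flanks.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import global_identity, kmer_set
from .genome_io import Genome
from .locus_scan import LocusModel

GeneKey = tuple[str, str]   # (genome_id, gene_id)


@dataclass
class OrthologClusterSet:
    clusters: dict[str, list[GeneKey]]
    core_ids: list[str] = field(default_factory=list)

    def cluster_of(self) -> dict[GeneKey, str]:
        return {
            key: cid for cid, members in self.clusters.items()
            for key in members
        }


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class NeighborhoodReport:
    pairs: dict[str, tuple[str, str]]      # genome_id -> (up COG, down COG)
    modal_pair: tuple[str, str]
    conservation: float


# ---------------------------------------------------------------------------
# ortholog clustering

def _mcl(adj: np.ndarray, inflation: float, prune: float = 1e-6,
         tol: float = 1e-8, max_iter: int = 100) -> list[set[int]]:
    """Markov clustering on a weighted adjacency matrix (self-loops added)."""
    n = adj.shape[0]
    m = adj + np.eye(n)
    m /= m.sum(axis=0)
    for _ in range(max_iter):
        previous = m
        m = m @ m                       # expansion 2
        m = np.power(m, inflation)      # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - previous).max() < tol:
            break
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [set(c) for c in nx.connected_components(g)]


def _candidate_pairs(proteins: list[str], min_shared: int = 10
                     ) -> set[tuple[int, int]]:
    """Pairs of proteins sharing enough 4-mers to merit alignment."""
    buckets: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(proteins):
        for kmer in kmer_set(p):
            buckets[kmer].append(i)
    shared: Counter[tuple[int, int]] = Counter()
    for members in buckets.values():
        if len(members) < 2 or len(members) > 200:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                shared[(members[a], members[b])] += 1
    return {pair for pair, count in shared.items() if count >= min_shared}


def cluster_orthologs(
    genomes: list[Genome],
    min_identity: float = 0.8,
    inflation: float = 2.0,
) -> OrthologClusterSet:
    """All-against-all identity graph plus MCL; singletons kept as clusters."""
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes for ortholog clustering")
    keys: list[GeneKey] = []
    proteins: list[str] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for gene in genome.genes:
            prot = gene.protein_aa.split("*", 1)[0]
            if len(prot) < 20:
                continue
            keys.append((genome.genome_id, gene.gene_id))
            proteins.append(prot)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(keys)))
    for i, j in sorted(_candidate_pairs(proteins)):
        ident, _ = global_identity(proteins[i], proteins[j])
        if ident >= min_identity:
            graph.add_edge(i, j, weight=ident)

    clusters: list[list[GeneKey]] = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            clusters.append([keys[nodes[0]]])
            continue
        adj = np.zeros((len(nodes), len(nodes)))
        pos = {n: i for i, n in enumerate(nodes)}
        for a, b, data in graph.subgraph(nodes).edges(data=True):
            adj[pos[a], pos[b]] = adj[pos[b], pos[a]] = data["weight"]
        for part in _mcl(adj, inflation):
            clusters.append(sorted(keys[nodes[i]] for i in part))

    clusters.sort(key=lambda members: members[0])
    ocs = OrthologClusterSet(clusters={
        f"COG{i:05d}": members for i, members in enumerate(clusters)
    })
    ocs.core_ids = core_families(ocs, genomes)
    return ocs


def core_families(ocs: OrthologClusterSet,
                  genomes: list[Genome]) -> list[str]:
    """Clusters with exactly one member in every genome (single-copy core)."""
    genome_ids = {g.genome_id for g in genomes}
    core = []
    for cid, members in ocs.clusters.items():
        counts = Counter(genome_id for genome_id, _ in members)
        if set(counts) == genome_ids and all(v == 1 for v in counts.values()):
            core.append(cid)
    return sorted(core)


# ---------------------------------------------------------------------------
# core-genome distances and neighbor joining

def core_distances(ocs: OrthologClusterSet,
                   genomes: list[Genome]) -> DistanceMatrix:
    """Mean per-core-family protein p-distance between every genome pair."""
    if not ocs.core_ids:
        raise ValueError("no core families")
    taxa = sorted(g.genome_id for g in genomes)
    by_id = {g.genome_id: g for g in genomes}
    n = len(taxa)
    total = np.zeros((n, n))
    for cid in ocs.core_ids:
        member_of = dict(ocs.clusters[cid])
        prots = {
            gid: by_id[gid].gene(member_of[gid]).protein_aa.split("*", 1)[0]
            for gid in taxa
        }
        for i in range(n):
            for j in range(i + 1, n):
                ident, _ = global_identity(prots[taxa[i]], prots[taxa[j]])
                total[i, j] += 1 - ident
                total[j, i] += 1 - ident
    return DistanceMatrix(taxa=taxa, d=total / len(ocs.core_ids))


def _clamp(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to zero, excess moved to the sister
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string.

    Unrooted by default (trifurcating at the last join); when an outgroup
    is given the tree is rooted at the midpoint of the outgroup's pendant
    edge.  Ties in the Q criterion break on the smallest taxon-index pair,
    making the output deterministic.
    """
    taxa = list(dm.taxa)
    if outgroup is not None and outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    if len(taxa) == 2:
        half = dm.d[0, 1] / 2
        newick = f"({taxa[0]}:{_fmt(half)},{taxa[1]}:{_fmt(half)});"
        return newick

    # adjacency of the growing unrooted tree
    edges: dict[str, dict[str, float]] = defaultdict(dict)

    def connect(a: str, b: str, length: float) -> None:
        edges[a][b] = edges[b][a] = max(length, 0.0)

    active = list(taxa)
    d = dm.d.copy()
    next_internal = 0
    while len(active) > 3:
        n = len(active)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, lj)
        node = f"_nj{next_internal}"
        next_internal += 1
        connect(active[i], node, li)
        connect(active[j], node, lj)
        new_row = np.array([
            (d[i, k] + d[j, k] - d[i, j]) / 2
            for k in range(n) if k not in (i, j)
        ])
        keep = [k for k in range(n) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        active = [active[k] for k in keep] + [node]

    # final trifurcation: branch of each remaining node to the center
    a, b, c = active
    da = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    db = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    dc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    center = f"_nj{next_internal}"
    connect(a, center, da)
    connect(b, center, db)
    connect(c, center, dc)

    def subtree(node: str, parent: str) -> str:
        children = [k for k in edges[node] if k != parent]
        if not children:
            return node
        inner = ",".join(
            f"{subtree(child, node)}:{_fmt(edges[node][child])}"
            for child in sorted(children)
        )
        return f"({inner})"

    if outgroup is None:
        return subtree(center, parent="") + ";"
    parent = next(iter(edges[outgroup]))
    half = edges[outgroup][parent] / 2
    rest = subtree(parent, parent=outgroup)
    return f"({outgroup}:{_fmt(half)},{rest}:{_fmt(half)});"


# ---------------------------------------------------------------------------
# locus neighborhood conservation

def flank_conservation(
    loci: list[LocusModel],
    ocs: OrthologClusterSet,
    genomes: list[Genome],
    system: str = "T4cP",
) -> NeighborhoodReport:
    """Conservation of the (upstream, downstream) COG pair around loci.

    Uses each genome's first locus of the requested system.  The locus
    span is its contiguous members (a distal tadV does not extend it); the
    nearest non-member gene on each side is mapped to its COG, ``"none"``
    at contig edges.  Minus-strand loci have their flanks swapped so that
    "upstream" is always on the 5' side of the locus reading direction.
    """
    cluster_of = ocs.cluster_of()
    by_id = {g.genome_id: g for g in genomes}
    pairs: dict[str, tuple[str, str]] = {}
    for genome_id in sorted(by_id):
        genome = by_id[genome_id]
        locus = next(
            (l for l in loci
             if l.genome_id == genome_id and l.system == system
             and l.members),
            None,
        )
        if locus is None:
            continue
        member_ids = {m.gene.gene_id for m in locus.members}
        core_members = [m for m in locus.members
                        if not (m.assignment.family_name == "tadV"
                                and locus.tadV_distal)]
        contig_id = core_members[0].gene.contig_id
        contig_genes = [g for g in genome.genes if g.contig_id == contig_id]
        positions = [i for i, g in enumerate(contig_genes)
                     if g.gene_id in {m.gene.gene_id for m in core_members}]
        lo, hi = min(positions), max(positions)

        def flank_cog(direction: int) -> str:
            pos = (lo if direction < 0 else hi) + direction
            while 0 <= pos < len(contig_genes):
                gene = contig_genes[pos]
                if gene.gene_id not in member_ids:
                    return cluster_of.get(
                        (genome_id, gene.gene_id), "none"
                    )
                pos += direction
            return "none"

        up, down = flank_cog(-1), flank_cog(+1)
        strands = [m.gene.strand for m in core_members]
        if strands.count("-") * 2 > len(strands):
            up, down = down, up
        pairs[genome_id] = (up, down)

    if not pairs:
        raise ValueError(f"no {system} loci found in any genome")
    counts = Counter(pairs.values())
    top = max(counts.values())
    modal = min(p for p, c in counts.items() if c == top)
    conservation = counts[modal] / len(pairs)
    return NeighborhoodReport(pairs=pairs, modal_pair=modal,
                              conservation=conservation)
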