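"""Synthetic annotated genomes with ground-truth manifests.

The generator emulates the statistical and syntenic structure the pipeline
assumes in real bacterial genomes:

* per-genome background codon usage — a biased 61-codon table tilted to a
  target GC content (bifidobacteria-like, ~60%), from which background genes
  are drawn codon by codon;
* a minority of "alien" genes drawn from a compositionally distinct table
  (near-uniform synonymous usage, GC shifted upward) — the planted signal
  for the codon-usage HGT screen;
* embedded multi-gene type IV pilus loci following the tight-adherence
  (Tad/T4cP) and T4aP architectures, with each member mutated to a
  controlled protein identity versus its family reference, plus optional
  gene deletion, sub-cluster inversion and frameshift edits;
* single-copy "core" families shared by every genome (for ortholog
  clustering and the core-genome tree) and locus-flanking genes that are
  conserved in a configured fraction of genomes.

Locus genes are back-translated with the host genome's own codon table, so
by default an embedded locus does *not* look alien to the HGT screen; a
per-family option plants alien codon usage in chosen locus genes to emulate
horizontally acquired pilin genes.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .align import global_identity
from .genome_io import Genome, GeneRecord, write_genome

# ---------------------------------------------------------------------------
# family and template definitions

TAD_FAMILIES = ["tadZ", "tadA", "tadB", "tadC", "flp", "tadE", "tadF", "tadV"]
PIL_FAMILIES = [
    "pilT", "pilB", "pilV", "pilW", "pilE", "pilC",
    "pilX", "pilD", "pilM", "pilN", "pilO",
]

T4CP_TEMPLATES = {"T4cP_canonical", "T4cP_deltaC_inverted", "T4cP_deltaV"}
T4AP_TEMPLATES = {"T4aP_functional", "T4aP_nonfunctional"}
TEMPLATE_NAMES = sorted(T4CP_TEMPLATES | T4AP_TEMPLATES)

# (family, strand) in chromosomal order; tadV is handled separately because
# it sits outside the cluster (>= 10 genes away) in the Tad architecture.
_T4CP_CLUSTER = [("tadZ", "+"), ("tadA", "+"), ("tadB", "+"), ("tadC", "+"),
                 ("flp", "+"), ("tadE", "+"), ("tadF", "+")]
# the prepilin/pseudopilin sub-cluster {flp,tadE,tadF} inverted (order and
# strand) relative to {tadZ,tadA,tadB}, with tadC deleted
_T4CP_DELTA_C = [("tadZ", "+"), ("tadA", "+"), ("tadB", "+"),
                 ("tadF", "-"), ("tadE", "-"), ("flp", "-")]
# pilB+pilT on one strand, the remaining nine genes on the opposite strand
_T4AP_CLUSTER = [("pilB", "+"), ("pilT", "+"),
                 ("pilE", "-"), ("pilV", "-"), ("pilW", "-"), ("pilX", "-"),
                 ("pilC", "-"), ("pilD", "-"), ("pilM", "-"), ("pilN", "-"),
                 ("pilO", "-")]
T4AP_FRAMESHIFT_TARGET = "pilC"

AA = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("TCAG", repeat=3)
    if "".join(c) not in STOP_CODONS
)
_CODON_TO_AA = {
    c: str(Seq(c).translate(table=11)) for c in SENSE_CODONS
}
_AA_TO_CODONS = {
    aa: [c for c in SENSE_CODONS if _CODON_TO_AA[c] == aa] for aa in AA
}
_GC_COUNT = {c: c.count("G") + c.count("C") for c in SENSE_CODONS}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration and manifest

@dataclass
class SimulationConfig:
    """Parameters of one simulated genome cohort.

    ``loci_to_embed`` lists ``(template_name, target_identity)`` pairs; each
    listed locus is embedded in every genome.  ``alien_locus_families`` maps
    a family name to the fraction of genomes in which that family's locus
    gene is emitted with alien codon usage.  ``n_scattered_pilE`` plants
    extra prepilin genes far away from any T4aP locus;
    ``scattered_alien_fraction`` controls how often those look alien.
    """

    seed: int = 0
    n_genomes: int = 20
    n_background_genes: int = 200
    gene_length_codons: tuple[int, int] = (100, 400)
    background_gc: float = 0.60
    codon_bias_concentration: float = 0.35
    n_alien_genes: int = 5
    alien_gc_shift: float = 0.15
    loci_to_embed: list[tuple[str, float]] = field(
        default_factory=lambda: [("T4cP_canonical", 0.8)]
    )
    flank_conservation: float = 0.7
    n_core_families: int = 12
    core_identity: float = 0.95
    alien_locus_families: dict[str, float] = field(default_factory=dict)
    n_scattered_pilE: int = 0
    scattered_alien_fraction: float = 0.0
    contig_prefix: str = "chr"
    spacer_nt: int = 50

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        lo, hi = self.gene_length_codons
        if not (10 <= lo <= hi):
            raise ConfigError("gene_length_codons must satisfy 10 <= lo <= hi")
        for name, ident in self.loci_to_embed:
            if name not in T4CP_TEMPLATES | T4AP_TEMPLATES:
                raise ConfigError(f"unknown locus template {name!r}")
            if not 0 < ident <= 1:
                raise ConfigError("target_identity must be in (0, 1]")
        if not 0 <= self.flank_conservation <= 1:
            raise ConfigError("flank_conservation must be in [0, 1]")
        target = self.background_gc + self.alien_gc_shift
        if not 0.02 < target < 0.98:
            raise ConfigError(
                f"alien GC target {target:.3f} is outside the achievable range"
            )
        if self.n_background_genes < 30:
            raise ConfigError("need >= 30 background genes to place loci")


@dataclass
class LocusTruth:
    template: str
    gene_families: dict[str, str]          # gene_id -> family name
    start: int                             # locus extent, 1-based nt
    end: int
    deleted_families: list[str]
    inverted: bool
    frameshifted_gene_ids: list[str]
    tadV_gene_id: str | None = None        # distal peptidase gene, if any


@dataclass
class GenomeTruth:
    genome_id: str
    alien_gene_ids: list[str]
    loci: list[LocusTruth]
    flank_conserved: bool
    flank_pair: tuple[str, str]            # (upstream, downstream) family label
    core_gene_ids: dict[str, str]          # core family -> gene_id
    scattered_pilE_ids: list[str]
    alien_usage_gene_ids: list[str]        # locus/scattered genes with alien usage


@dataclass
class TruthManifest:
    seed: int
    genomes: dict[str, GenomeTruth]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# reference families

@dataclass(frozen=True)
class ReferenceFamily:
    name: str
    system: str            # "T4cP" or "T4aP"
    protein: str
    cds: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA), size=length - 1))


def _back_translate(rng: np.random.Generator, protein: str,
                    codon_probs: dict[str, float] | None = None) -> str:
    """Back-translate, sampling synonymous codons (uniform if no table)."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        if codon_probs is None:
            p = None
        else:
            w = np.array([codon_probs[c] for c in options])
            p = w / w.sum() if w.sum() > 0 else None
        codons.append(rng.choice(options, p=p))
    return "".join(codons)


def make_reference_families(seed: int) -> dict[str, ReferenceFamily]:
    """Generate the 19 reference families (8 tad, 11 pil).

    Proteins are 80–500 aa and mutually dissimilar (< 30% pairwise global
    identity, re-drawn on violation); deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    names = [(n, "T4cP") for n in TAD_FAMILIES] + \
            [(n, "T4aP") for n in PIL_FAMILIES]
    proteins: dict[str, str] = {}
    for name, _ in names:
        length = int(rng.integers(80, 501))
        proteins[name] = _random_protein(rng, length)
    # enforce mutual dissimilarity; random 20-letter sequences essentially
    # always satisfy this, the loop is a guarantee not an expectation
    for _ in range(20):
        clash = None
        for a, b in itertools.combinations(proteins, 2):
            ident, _ = global_identity(proteins[a], proteins[b])
            if ident >= 0.30:
                clash = b
                break
        if clash is None:
            break
        proteins[clash] = _random_protein(
            rng, int(rng.integers(80, 501))
        )
    else:  # pragma: no cover
        raise RuntimeError("could not generate dissimilar reference families")
    return {
        name: ReferenceFamily(
            name=name, system=system, protein=proteins[name],
            cds="ATG" + _back_translate(rng, proteins[name][1:]) + "TAA",
        )
        for name, system in names
    }


# ---------------------------------------------------------------------------
# codon tables

def _tilt_to_gc(base: dict[str, float], target_gc: float) -> dict[str, float]:
    """Exponentially tilt a codon table so its expected GC hits ``target_gc``."""
    codons = sorted(base)
    p = np.array([base[c] for c in codons])
    g = np.array([_GC_COUNT[c] / 3 for c in codons])

    def expected_gc(lam: float) -> float:
        w = p * np.exp(lam * g)
        w /= w.sum()
        return float(w @ g)

    lo, hi = -80.0, 80.0
    if not expected_gc(lo) <= target_gc <= expected_gc(hi):
        raise ConfigError(f"GC target {target_gc:.3f} unreachable by tilting")
    for _ in range(200):  # bisection; expected_gc is monotone in lambda
        mid = (lo + hi) / 2
        if expected_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2
    w = p * np.exp(lam * g)
    w /= w.sum()
    return dict(zip(codons, w.tolist()))


def _background_codon_table(rng: np.random.Generator,
                            cfg: SimulationConfig) -> dict[str, float]:
    """Strongly biased per-genome synonymous usage at the target GC.

    A small Dirichlet concentration puts most of each family's weight on one
    or two codons, giving the low effective-number-of-codons background the
    alien genes must stand out against.
    """
    table: dict[str, float] = {}
    for aa in AA:
        options = _AA_TO_CODONS[aa]
        if len(options) == 1:
            weights = np.array([1.0])
        else:
            weights = rng.dirichlet(
                [cfg.codon_bias_concentration] * len(options)
            )
        for c, w in zip(options, weights):
            table[c] = float(w) / len(AA)   # uniform amino-acid frequencies
    return _tilt_to_gc(table, cfg.background_gc)


def _alien_codon_table(cfg: SimulationConfig,
                       background: dict[str, float]) -> dict[str, float]:
    """Near-uniform usage tilted to background GC plus the configured shift."""
    bg_gc = sum(background[c] * _GC_COUNT[c] / 3 for c in background)
    uniform = {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}
    return _tilt_to_gc(uniform, bg_gc + cfg.alien_gc_shift)


def _sample_gene(rng: np.random.Generator, table: dict[str, float],
                 n_codons: int) -> str:
    codons = sorted(table)
    p = np.array([table[c] for c in codons])
    p /= p.sum()
    body = rng.choice(codons, size=n_codons - 2, p=p)
    return "ATG" + "".join(body) + "TAA"


def mutate_protein(rng: np.random.Generator, protein: str,
                   identity: float) -> str:
    """Substitute residues at rate ``1 - identity`` (uniform replacement)."""
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < 1 - identity:
            choices = [a for a in AA if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# genome assembly

@dataclass
class _GeneSpec:
    kind: str                  # background | alien | core | flank | locus | scattered
    cds: str
    strand: str = "+"
    family: str | None = None  # reference/core/flank family label
    locus_idx: int | None = None


def _locus_layout(template: str) -> list[tuple[str, str]]:
    if template in ("T4cP_canonical", "T4cP_deltaV"):
        return list(_T4CP_CLUSTER)
    if template == "T4cP_deltaC_inverted":
        return list(_T4CP_DELTA_C)
    return list(_T4AP_CLUSTER)


def _frameshift(cds: str) -> str:
    # single-nt deletion ~70% into the gene: the intact prefix still aligns
    # to the family reference (so the broken gene is assigned, not lost)
    # while the shifted tail garbles the product
    cut = (len(cds) * 7 // 10) // 3 * 3
    return cds[:cut] + cds[cut + 1 :]


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[list[Genome], TruthManifest]:
    """Generate the cohort of annotated genomes plus its truth manifest."""
    config.validate()
    # child stream: must be independent of the one used for the reference
    # families, or generated proteins correlate with the references
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    families = make_reference_families(config.seed)

    # cohort-level shared proteins: core families and the modal flank pair
    core_refs = {
        f"core{i:02d}": _random_protein(rng, int(rng.integers(150, 351)))
        for i in range(config.n_core_families)
    }
    flank_refs = {
        "flankU": _random_protein(rng, int(rng.integers(150, 351))),
        "flankD": _random_protein(rng, int(rng.integers(150, 351))),
    }

    n_conserved = round(config.flank_conservation * config.n_genomes)
    conserved_mask = np.zeros(config.n_genomes, dtype=bool)
    conserved_mask[
        rng.permutation(config.n_genomes)[:n_conserved]
    ] = True

    # which genomes carry alien codon usage in which locus family
    alien_family_mask: dict[str, np.ndarray] = {}
    for fam, frac in config.alien_locus_families.items():
        mask = np.zeros(config.n_genomes, dtype=bool)
        mask[rng.permutation(config.n_genomes)[
            : round(frac * config.n_genomes)
        ]] = True
        alien_family_mask[fam] = mask
    scattered_alien_mask = np.zeros(
        (config.n_genomes, config.n_scattered_pilE), dtype=bool
    )
    if config.n_scattered_pilE:
        total = config.n_genomes * config.n_scattered_pilE
        flat = np.zeros(total, dtype=bool)
        flat[rng.permutation(total)[
            : round(config.scattered_alien_fraction * total)
        ]] = True
        scattered_alien_mask = flat.reshape(
            config.n_genomes, config.n_scattered_pilE
        )

    genomes: list[Genome] = []
    truths: dict[str, GenomeTruth] = {}
    for gi in range(config.n_genomes):
        genome_id = f"g{gi:03d}"
        bg_table = _background_codon_table(rng, config)
        alien_table = _alien_codon_table(config, bg_table)
        lo, hi = config.gene_length_codons

        specs: list[_GeneSpec] = []
        for _ in range(config.n_background_genes):
            specs.append(_GeneSpec(
                kind="background",
                cds=_sample_gene(rng, bg_table, int(rng.integers(lo, hi + 1))),
            ))
        for _ in range(config.n_alien_genes):
            specs.append(_GeneSpec(
                kind="alien",
                cds=_sample_gene(rng, alien_table,
                                 int(rng.integers(lo, hi + 1))),
            ))
        for fam, ref in core_refs.items():
            prot = "M" + mutate_protein(rng, ref[1:], config.core_identity)
            specs.append(_GeneSpec(
                kind="core", family=fam,
                cds="ATG" + _back_translate(rng, prot[1:], bg_table) + "TAA",
            ))
        order = rng.permutation(len(specs))
        specs = [specs[i] for i in order]

        # embed loci as contiguous blocks bracketed by flanking genes
        locus_edits: list[dict] = []
        n_loci = len(config.loci_to_embed)
        for li, (template, target_ident) in enumerate(config.loci_to_embed):
            layout = _locus_layout(template)
            block: list[_GeneSpec] = []

            def _flank_spec(which: str) -> _GeneSpec:
                if conserved_mask[gi]:
                    prot = "M" + mutate_protein(
                        rng, flank_refs[which][1:], config.core_identity)
                    fam = which
                else:
                    prot = _random_protein(rng, int(rng.integers(150, 351)))
                    fam = f"{which}_alt_{genome_id}"
                return _GeneSpec(
                    kind="flank", family=fam,
                    cds="ATG" + _back_translate(rng, prot[1:], bg_table)
                        + "TAA",
                )

            block.append(_flank_spec("flankU"))
            frameshifted_fams: list[str] = []
            for fam, strand in layout:
                prot = "M" + mutate_protein(
                    rng, families[fam].protein[1:], target_ident)
                table = bg_table
                if fam in alien_family_mask and alien_family_mask[fam][gi]:
                    table = alien_table
                cds = "ATG" + _back_translate(rng, prot[1:], table) + "TAA"
                if (template == "T4aP_nonfunctional"
                        and fam == T4AP_FRAMESHIFT_TARGET):
                    cds = _frameshift(cds)
                    frameshifted_fams.append(fam)
                block.append(_GeneSpec(kind="locus", family=fam,
                                       strand=strand, cds=cds,
                                       locus_idx=li))
            block.append(_flank_spec("flankD"))

            # insert the block at a position that leaves >= 15 gene slots
            # downstream (distal tadV) and does not split or abut a
            # previously embedded locus
            pos = None
            for _ in range(200):
                cand = int(rng.integers(5, len(specs) - 16 * n_loci))
                window = specs[max(0, cand - 8): cand + 8]
                if not any(s.kind == "locus" for s in window):
                    pos = cand
                    break
            if pos is None:  # pragma: no cover
                raise ConfigError(
                    "could not place locus block; increase n_background_genes"
                )
            specs[pos:pos] = block

            deleted = []
            if template == "T4cP_deltaC_inverted":
                deleted.append("tadC")
            needs_tadv = template in ("T4cP_canonical", "T4cP_deltaC_inverted")
            if template == "T4cP_deltaV":
                deleted.append("tadV")
            tadv_spec = None
            if needs_tadv:
                prot = "M" + mutate_protein(
                    rng, families["tadV"].protein[1:], target_ident)
                tadv_spec = _GeneSpec(
                    kind="locus", family="tadV", strand="+",
                    cds="ATG" + _back_translate(rng, prot[1:], bg_table)
                        + "TAA",
                    locus_idx=li,
                )
                # >= 10 intervening genes downstream of the cluster
                tadv_pos = pos + len(block) + 10 + int(rng.integers(0, 4))
                specs.insert(min(tadv_pos, len(specs)), tadv_spec)
            locus_edits.append({
                "template": template,
                "deleted": deleted,
                "inverted": template == "T4cP_deltaC_inverted",
                "frameshifted_fams": frameshifted_fams,
                "idx": li,
            })

        # scattered prepilin (pilE) genes, far from any T4aP locus
        scattered_specs: list[_GeneSpec] = []
        for si in range(config.n_scattered_pilE):
            prot = "M" + mutate_protein(rng, families["pilE"].protein[1:], 0.8)
            table = (alien_table if scattered_alien_mask[gi, si] else bg_table)
            spec = _GeneSpec(
                kind="scattered", family="pilE", strand="+",
                cds="ATG" + _back_translate(rng, prot[1:], table) + "TAA",
            )
            spec._alien = bool(scattered_alien_mask[gi, si])  # type: ignore
            scattered_specs.append(spec)
        for spec in scattered_specs:
            # keep >= 8 gene slots clear of every locus gene
            for _ in range(100):
                pos = int(rng.integers(0, len(specs)))
                window = specs[max(0, pos - 8): pos + 8]
                if not any(s.kind == "locus" for s in window):
                    specs.insert(pos, spec)
                    break
            else:  # pragma: no cover
                specs.append(spec)

        # lay the genes on one contig with fixed-length random spacers
        contig_id = f"{config.contig_prefix}1"
        seq_parts: list[str] = []
        pos_nt = 0
        records: list[GeneRecord] = []
        spec_records: list[tuple[_GeneSpec, GeneRecord]] = []
        for idx, spec in enumerate(specs):
            spacer = "".join(rng.choice(list("ACGT"), size=config.spacer_nt))
            seq_parts.append(spacer)
            pos_nt += config.spacer_nt
            start = pos_nt + 1
            end = pos_nt + len(spec.cds)
            on_contig = spec.cds
            if spec.strand == "-":
                on_contig = str(Seq(spec.cds).reverse_complement())
            seq_parts.append(on_contig)
            pos_nt = end
            rec = GeneRecord(
                gene_id=f"{genome_id}_g{idx:04d}",
                genome_id=genome_id,
                contig_id=contig_id,
                start=start, end=end, strand=spec.strand,
                cds_nt=spec.cds,
            )
            records.append(rec)
            spec_records.append((spec, rec))
        seq_parts.append("".join(rng.choice(list("ACGT"),
                                            size=config.spacer_nt)))
        contig = "".join(seq_parts)
        genome = Genome(genome_id=genome_id,
                        contigs={contig_id: contig}, genes=records)
        genomes.append(genome)

        # manifest bookkeeping
        alien_ids = [r.gene_id for s, r in spec_records if s.kind == "alien"]
        core_ids = {s.family: r.gene_id for s, r in spec_records
                    if s.kind == "core"}
        scattered_ids = [r.gene_id for s, r in spec_records
                         if s.kind == "scattered"]
        alien_usage_ids = [
            r.gene_id for s, r in spec_records
            if (s.kind == "locus" and s.family in alien_family_mask
                and alien_family_mask[s.family][gi])
            or (s.kind == "scattered" and getattr(s, "_alien", False))
        ]
        loci_truth: list[LocusTruth] = []
        for edit in locus_edits:
            li = edit["idx"]
            members = [(s, r) for s, r in spec_records
                       if s.kind == "locus" and s.locus_idx == li]
            cluster = [(s, r) for s, r in members if s.family != "tadV"] \
                if edit["template"] in T4CP_TEMPLATES else members
            tadv = next((r for s, r in members if s.family == "tadV"), None)
            loci_truth.append(LocusTruth(
                template=edit["template"],
                gene_families={r.gene_id: s.family for s, r in members},
                start=min(r.start for _, r in cluster),
                end=max(r.end for _, r in cluster),
                deleted_families=edit["deleted"],
                inverted=edit["inverted"],
                frameshifted_gene_ids=[
                    r.gene_id for s, r in members
                    if s.family in edit["frameshifted_fams"]
                ],
                tadV_gene_id=tadv.gene_id if tadv is not None else None,
            ))
        flank_fams = [s.family for s, _ in spec_records if s.kind == "flank"]
        truths[genome_id] = GenomeTruth(
            genome_id=genome_id,
            alien_gene_ids=alien_ids,
            loci=loci_truth,
            flank_conserved=bool(conserved_mask[gi]),
            flank_pair=(flank_fams[0], flank_fams[1]) if flank_fams
            else ("none", "none"),
            core_gene_ids=core_ids,
            scattered_pilE_ids=scattered_ids,
            alien_usage_gene_ids=alien_usage_ids,
        )

    return genomes, TruthManifest(seed=config.seed, genomes=truths)


def write_cohort(genomes: list[Genome], manifest: TruthManifest,
                 out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for g in genomes:
        write_genome(g, out_dir)
    with open(os.path.join(str(out_dir), "truth_manifest.json"), "w") as fh:
        fh.write(manifest.to_json() + "\n")
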