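"""Genetic-map rendering and end-to-end pipeline orchestration.

Maps follow the usual comparative-genomics convention: one row per locus,
one arrow per ORF with horizontal extent proportional to ORF length and
direction given by strand, colored by gene family, with percent-identity
labels versus a reference locus beneath each arrow.  Output is SVG so test
assertions can be structural (element counts, geometry) rather than
pixel-based, and reruns are byte-identical.
"""

from __future__ import annotations

import json
import os
import sys
import time
from dataclasses import dataclass, field

import yaml

from . import __version__
from .align import global_identity
from .genome_io import Genome, read_genome, write_genome
from .synthetic_data import (
    ReferenceFamily,
    SimulationConfig,
    TruthManifest,
    make_reference_families,
    simulate_genomes,
    write_cohort,
)
from .codon_metrics import profile_genome
from .hgt_screen import acquisition_rates, composite_call, percentile_flags
from .locus_scan import LocusModel, scan_genome
from .pangenome_phylo import (
    cluster_orthologs,
    core_distances,
    flank_conservation,
    nj_tree,
)

_PALETTE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f", "#edc948",
    "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac", "#86bcb6", "#d37295",
    "#fabfd2", "#b6992d", "#499894", "#79706e", "#ffbe7d", "#8cd17d",
    "#a0cbe8",
]


@dataclass
class MapSpec:
    loci: list[LocusModel]
    reference_locus_id: str | None = None
    scale: float = 20.0                   # nucleotides per SVG unit
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        systems = {l.system for l in self.loci}
        if len(systems) > 1:
            raise ValueError("all loci in one map must share a system")
        fams = sorted({f for l in self.loci for f in l.families})
        for i, fam in enumerate(fams):
            self.colors.setdefault(fam, _PALETTE[i % len(_PALETTE)])


def _arrow_points(x0: float, x1: float, y: float, height: float,
                  forward: bool) -> str:
    head = min(abs(x1 - x0) * 0.3, height)
    ym, yt, yb = y, y - height / 2, y + height / 2
    if forward:
        pts = [(x0, yt), (x1 - head, yt), (x1, ym), (x1 - head, yb),
               (x0, yb)]
    else:
        pts = [(x1, yt), (x0 + head, yt), (x0, ym), (x0 + head, yb),
               (x1, yb)]
    return " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)


def render_map(spec: MapSpec) -> str:
    """Render one locus-per-row SVG genetic map; deterministic output."""
    if not spec.loci:
        raise ValueError("no loci to render")
    reference = None
    if spec.reference_locus_id is not None:
        reference = next(
            l for l in spec.loci if l.locus_id == spec.reference_locus_id
        )
    row_h, gene_h, margin = 60.0, 18.0, 10.0
    width = margin * 2 + max(
        (l.end - l.start + 1) / spec.scale for l in spec.loci
    )
    height = row_h * len(spec.loci) + margin
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="0 0 {width:.2f} {height:.2f}">',
    ]
    for row, locus in enumerate(spec.loci):
        y = margin + row_h * row + gene_h
        parts.append(
            f'<text x="{margin:.2f}" y="{y - gene_h:.2f}" '
            f'font-size="9" class="locus-label">'
            f"{locus.locus_id} [{locus.classification or locus.system}]"
            f"</text>"
        )
        ref_by_family = {}
        if reference is not None and locus is not reference:
            for m in reference.members:
                ref_by_family.setdefault(
                    m.assignment.family_name, m.gene.protein_aa)
        for m in locus.members:
            x0 = margin + (m.gene.start - locus.start) / spec.scale
            x1 = margin + (m.gene.end - locus.start + 1) / spec.scale
            fam = m.assignment.family_name
            pts = _arrow_points(x0, x1, y, gene_h,
                                forward=m.gene.strand == "+")
            parts.append(
                f'<polygon class="gene-arrow" points="{pts}" '
                f'fill="{spec.colors[fam]}" stroke="#333" '
                f'stroke-width="0.5"><title>{fam}</title></polygon>'
            )
            label = fam
            if fam in ref_by_family:
                ident, _ = global_identity(
                    m.gene.protein_aa.split("*", 1)[0],
                    ref_by_family[fam].split("*", 1)[0],
                )
                label = f"{fam} {round(ident * 100)}"
            elif reference is not None and locus is reference:
                label = f"{fam} 100"
            parts.append(
                f'<text x="{(x0 + x1) / 2:.2f}" y="{y + gene_h:.2f}" '
                f'font-size="8" text-anchor="middle" class="identity-label">'
                f"{label}</text>"
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# pipeline

class PipelineConfigError(ValueError):
    """A required pipeline configuration field is missing or invalid."""


def _log(stage: str, started: float) -> None:
    print(f"[piliscan] {stage}: {time.perf_counter() - started:.2f}s",
          file=sys.stderr)


def _load_families(cfg: dict) -> dict[str, ReferenceFamily]:
    fam_cfg = cfg.get("families")
    if fam_cfg is None:
        raise PipelineConfigError(
            "config field 'families' is required (families.seed or "
            "families.fasta)"
        )
    if "seed" in fam_cfg:
        return make_reference_families(int(fam_cfg["seed"]))
    if "fasta" in fam_cfg:
        from Bio import SeqIO
        out = {}
        for rec in SeqIO.parse(str(fam_cfg["fasta"]), "fasta"):
            system = "T4cP" if rec.id.startswith(("tad", "flp")) else "T4aP"
            out[rec.id] = ReferenceFamily(
                name=rec.id, system=system, protein=str(rec.seq), cds="")
        if not out:
            raise PipelineConfigError(f"no sequences in {fam_cfg['fasta']}")
        return out
    raise PipelineConfigError("families needs a 'seed' or 'fasta' key")


def _loci_record(locus: LocusModel) -> dict:
    return {
        "locus_id": locus.locus_id,
        "genome_id": locus.genome_id,
        "system": locus.system,
        "classification": locus.classification,
        "classification_reasons": locus.classification_reasons,
        "start": locus.start if locus.members else None,
        "end": locus.end if locus.members else None,
        "tadV_distal": locus.tadV_distal,
        "extra_pilE_in_locus": locus.extra_pilE_in_locus,
        "scattered_prepilins": locus.scattered_prepilins,
        "members": [
            {
                "gene_id": m.gene.gene_id,
                "family": m.assignment.family_name,
                "identity": round(m.assignment.identity, 4),
                "coverage": round(m.assignment.coverage, 4),
                "pseudo": m.assignment.pseudo,
                "start": m.gene.start,
                "end": m.gene.end,
                "strand": m.gene.strand,
            }
            for m in locus.members
        ],
    }


def run_pipeline(config_path: str | os.PathLike) -> dict:
    """Execute the full analysis from a YAML config; returns a summary.

    Stages: simulate (optional) -> genome IO -> codon metrics -> HGT screen
    -> locus scan -> ortholog clustering -> core NJ tree -> neighborhood
    conservation -> genetic maps.  All outputs are a pure function of
    (inputs, config, seed); a run manifest records versions and parameters.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a YAML mapping")
    out_dir = cfg.get("out_dir")
    if not out_dir:
        raise PipelineConfigError("config field 'out_dir' is required")
    os.makedirs(out_dir, exist_ok=True)
    maps_dir = os.path.join(out_dir, "maps")
    os.makedirs(maps_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    families = _load_families(cfg)

    t0 = time.perf_counter()
    manifest_truth: TruthManifest | None = None
    if "simulate" in cfg:
        sim_cfg = SimulationConfig(seed=seed, **cfg["simulate"])
        genomes, manifest_truth = simulate_genomes(sim_cfg)
        genome_dir = os.path.join(out_dir, "genomes")
        write_cohort(genomes, manifest_truth, genome_dir)
        # read back through the same IO path as external data
        genomes = [
            read_genome(os.path.join(genome_dir, f"{g.genome_id}.fna"),
                        os.path.join(genome_dir, f"{g.genome_id}.gff3"))
            for g in genomes
        ]
    elif "genomes_dir" in cfg:
        genome_dir = cfg["genomes_dir"]
        fastas = sorted(f for f in os.listdir(genome_dir)
                        if f.endswith((".fna", ".fa", ".fasta")))
        genomes = [
            read_genome(os.path.join(genome_dir, f),
                        os.path.join(genome_dir,
                                     os.path.splitext(f)[0] + ".gff3"))
            for f in fastas
        ]
    else:
        raise PipelineConfigError(
            "config needs either 'simulate' or 'genomes_dir'")
    _log("load", t0)

    # codon metrics + HGT screen
    t0 = time.perf_counter()
    min_flags = int(cfg.get("min_flags", 3))
    rows = []
    calls_by_genome = {}
    for genome in genomes:
        profiles = profile_genome(genome)
        calls = composite_call(percentile_flags(profiles), k=min_flags)
        calls_by_genome[genome.genome_id] = calls
        by_id = {p.gene_id: p for p in profiles}
        for call in calls:
            p = by_id[call.gene_id]
            rows.append((genome.genome_id, call, p))
    with open(os.path.join(out_dir, "metrics.tsv"), "w") as fh:
        fh.write("genome_id\tgene_id\tgc\trscu_dev\tenc\tcai\n")
        for genome_id, call, p in rows:
            fh.write(f"{genome_id}\t{p.gene_id}\t{p.gc:.6f}\t"
                     f"{p.rscu_dev:.6f}\t{p.enc:.4f}\t{p.cai:.6f}\n")
    with open(os.path.join(out_dir, "hgt_calls.tsv"), "w") as fh:
        fh.write("genome_id\tgene_id\tflag_gc\tflag_rscu\tflag_enc\t"
                 "flag_cai\tn_flags\tis_hgt\n")
        for genome_id, call, _ in rows:
            fh.write(
                f"{genome_id}\t{call.gene_id}\t{int(call.flag_gc)}\t"
                f"{int(call.flag_rscu)}\t{int(call.flag_enc)}\t"
                f"{int(call.flag_cai)}\t{call.n_flags}\t{int(call.is_hgt)}\n"
            )
    _log("metrics+hgt", t0)

    # locus scan
    t0 = time.perf_counter()
    min_id = float(cfg.get("min_id", 0.4))
    min_cov = float(cfg.get("min_cov", 0.6))
    max_gap = int(cfg.get("max_gap_genes", 5))
    all_loci: list[LocusModel] = []
    family_by_gene: dict[str, dict[str, str]] = {}
    for genome in genomes:
        assignments, loci = scan_genome(genome, families, min_id, min_cov,
                                        max_gap)
        all_loci.extend(loci)
        in_locus = {m.gene.gene_id for l in loci for m in l.members}
        family_by_gene[genome.genome_id] = {
            a.gene_id: (a.family_name if a.gene_id in in_locus
                        else f"{a.family_name}_scattered")
            for a in assignments
        }
    with open(os.path.join(out_dir, "loci.json"), "w") as fh:
        json.dump([_loci_record(l) for l in all_loci], fh, indent=1,
                  sort_keys=True)
        fh.write("\n")
    rates = acquisition_rates(calls_by_genome, family_by_gene)
    with open(os.path.join(out_dir, "acquisition_rates.tsv"), "w") as fh:
        fh.write("family\tn_genomes_with_family\tn_flagged\trate\n")
        for r in rates:
            fh.write(f"{r.family_name}\t{r.n_genomes_with_family}\t"
                     f"{r.n_flagged}\t{r.rate:.4f}\n")
    _log("locus_scan", t0)

    # pangenome, tree, neighborhood
    t0 = time.perf_counter()
    summary: dict = {"n_genomes": len(genomes)}
    ocs = cluster_orthologs(
        genomes,
        min_identity=float(cfg.get("min_identity", 0.8)),
        inflation=float(cfg.get("inflation", 2.0)),
    )
    with open(os.path.join(out_dir, "clusters.tsv"), "w") as fh:
        fh.write("cluster_id\tis_core\tgenome_id\tgene_id\n")
        for cid in sorted(ocs.clusters):
            core = int(cid in ocs.core_ids)
            for genome_id, gene_id in ocs.clusters[cid]:
                fh.write(f"{cid}\t{core}\t{genome_id}\t{gene_id}\n")
    summary["n_clusters"] = len(ocs.clusters)
    summary["n_core_families"] = len(ocs.core_ids)
    if ocs.core_ids and len(genomes) >= 3:
        dm = core_distances(ocs, genomes)
        newick = nj_tree(dm, outgroup=cfg.get("outgroup"))
        with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
    flank_system = cfg.get("flank_system", "T4cP")
    try:
        report = flank_conservation(all_loci, ocs, genomes,
                                    system=flank_system)
    except ValueError:
        report = None
    with open(os.path.join(out_dir, "neighborhood.tsv"), "w") as fh:
        fh.write("genome_id\tupstream_cog\tdownstream_cog\tmatches_modal\n")
        if report is not None:
            for genome_id in sorted(report.pairs):
                up, down = report.pairs[genome_id]
                fh.write(f"{genome_id}\t{up}\t{down}\t"
                         f"{int((up, down) == report.modal_pair)}\n")
    if report is not None:
        summary["flank_conservation"] = report.conservation
    _log("pangenome", t0)

    # genetic maps, one per system
    t0 = time.perf_counter()
    for system in ("T4cP", "T4aP"):
        system_loci = [l for l in all_loci
                       if l.system == system and l.members]
        if not system_loci:
            continue
        spec = MapSpec(loci=system_loci,
                       reference_locus_id=system_loci[0].locus_id)
        with open(os.path.join(maps_dir, f"{system}.svg"), "w") as fh:
            fh.write(render_map(spec))
    _log("maps", t0)

    run_manifest = {
        "piliscan_version": __version__,
        "seed": seed,
        "parameters": {
            k: cfg[k] for k in sorted(cfg) if k not in ("out_dir",)
        },
        "n_genomes": len(genomes),
        "outputs": sorted(
            os.path.relpath(os.path.join(root, f), out_dir)
            for root, _, fs in os.walk(out_dir) for f in fs
            if f != "manifest.json"
        ),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    summary["loci"] = [_loci_record(l) for l in all_loci]
    return summary
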