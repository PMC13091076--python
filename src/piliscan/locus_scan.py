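"""Type IV pilus locus detection and architecture classification.

Genes are assigned to one of 19 reference families (8 tight-adherence/T4cP
families: tadZ, tadA, tadB, tadC, flp, tadE, tadF, tadV; 11 T4aP families:
pilT, pilB, pilV, pilW, pilE/pilA, pilC, pilX, pilD, pilM, pilN, pilO) by
exact global protein alignment — with only 19 references, all-vs-all
alignment is cheap and no heuristic seeding is needed.  Same-system
assignments close together on a contig are grouped into loci, and each
locus is classified against the architectures observed in bifidobacteria:

* ``T4cP_canonical`` — tadZ-tadA-tadB-tadC plus the flp-tadE-tadF
  prepilin/pseudopilin cluster in tandem; the prepilin peptidase tadV sits
  outside the cluster and is attached to the locus as a distal member.
* ``T4cP_deltaC_inverted`` — tadC lost and the prepilin/pseudopilin
  sub-cluster inverted relative to tadZ-tadA-tadB.
* ``T4cP_deltaV`` — no tadV homolog anywhere in the genome.
* ``T4aP_functional`` — all 11 pil families intact, pilB+pilT on one
  strand and the remaining nine genes on the opposite strand.
* ``T4aP_nonfunctional`` — any missing, pseudogenized or strand-scrambled
  member; reasons are reported.

Prepilin (pilE) genes far from any T4aP locus are counted as scattered
prepilins; extra pilE copies inside a locus are counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import global_identity, shares_kmers
from .genome_io import Genome, GeneRecord
from .synthetic_data import PIL_FAMILIES, TAD_FAMILIES, ReferenceFamily

T4CP_CLUSTER_FAMILIES = ["tadZ", "tadA", "tadB", "tadC", "flp", "tadE", "tadF"]
T4CP_MOTOR_SUB = ("tadZ", "tadA", "tadB")
T4CP_PILIN_SUB = ("flp", "tadE", "tadF")
T4AP_SAME_STRAND = ("pilB", "pilT")

_SYSTEM_OF = {f: "T4cP" for f in TAD_FAMILIES}
_SYSTEM_OF.update({f: "T4aP" for f in PIL_FAMILIES})


@dataclass
class FamilyAssignment:
    gene_id: str
    family_name: str
    identity: float
    coverage: float
    pseudo: bool

    @property
    def system(self) -> str:
        return _SYSTEM_OF[self.family_name]


@dataclass
class LocusMember:
    assignment: FamilyAssignment
    gene: GeneRecord


@dataclass
class LocusModel:
    locus_id: str
    genome_id: str
    members: list[LocusMember]            # sorted by start coordinate
    system: str
    classification: str | None = None
    classification_reasons: list[str] = field(default_factory=list)
    tadV_distal: bool = False
    delta_c: bool = False
    delta_v: bool = False
    inverted_pilin_cluster: bool = False
    extra_pilE_in_locus: int = 0
    scattered_prepilins: int = 0

    @property
    def families(self) -> list[str]:
        return [m.assignment.family_name for m in self.members]

    @property
    def start(self) -> int:
        return min(m.gene.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.gene.end for m in self.members)

    @property
    def strand(self) -> str:
        """Reference orientation of the locus: strand of its first member."""
        return self.members[0].gene.strand


def assign_families(
    genome: Genome,
    families: dict[str, ReferenceFamily],
    min_id: float = 0.4,
    min_cov: float = 0.6,
) -> list[FamilyAssignment]:
    """Best-hit family assignment for every gene of a genome.

    Each gene is aligned globally (affine gaps, BLOSUM62) against every
    family reference after a shared-4-mer prefilter; the best-scoring
    family is kept when identity >= ``min_id`` and reference coverage >=
    ``min_cov``.  Proteins are truncated at the first internal stop before
    alignment, so frameshifted/pseudogenized genes are still recognized by
    their intact prefix; such assignments carry ``pseudo=True`` (as do
    assignments covering < 50% of the reference).
    """
    if not families:
        raise ValueError("empty family reference set")
    out: list[FamilyAssignment] = []
    for gene in genome.genes:
        prot = gene.protein_aa.split("*", 1)[0]
        if len(prot) < 20:
            continue
        best: tuple[float, str, float] | None = None   # identity, fam, cov
        for fam in sorted(families):
            ref = families[fam].protein
            if not shares_kmers(prot, ref):
                continue
            ident, cov = global_identity(prot, ref)
            if ident >= min_id and cov >= min_cov:
                if best is None or ident > best[0]:
                    best = (ident, fam, cov)
        if best is not None:
            ident, fam, cov = best
            out.append(FamilyAssignment(
                gene_id=gene.gene_id, family_name=fam,
                identity=ident, coverage=cov,
                pseudo=(gene.frameshifted or gene.pseudogenized
                        or cov < 0.5),
            ))
    return out


def _gene_index(genome: Genome) -> dict[str, int]:
    return {g.gene_id: i for i, g in enumerate(genome.genes)}


def group_loci(
    assignments: list[FamilyAssignment],
    genome: Genome,
    max_gap_genes: int = 5,
) -> list[LocusModel]:
    """Group family assignments into loci by contig proximity.

    Same-system assignments with at most ``max_gap_genes`` unassigned genes
    between them merge into one locus.  tadV is exempt from proximity: it
    attaches to the nearest T4cP locus on its contig, with ``tadV_distal``
    recording whether it lies beyond the gap limit.  pilE assignments
    beyond the gap limit from every T4aP locus are tallied as scattered
    prepilins on the genome's T4aP loci.
    """
    idx = _gene_index(genome)
    by_gene = {a.gene_id: a for a in assignments}
    loci: list[LocusModel] = []
    counter = 0

    for contig_id in sorted({g.contig_id for g in genome.genes}):
        contig_genes = [g for g in genome.genes if g.contig_id == contig_id]
        # seed runs per system; tadV and distal pilE handled afterwards
        runs: dict[str, list[list[GeneRecord]]] = {"T4cP": [], "T4aP": []}
        last_pos: dict[str, int] = {}
        for pos, gene in enumerate(contig_genes):
            a = by_gene.get(gene.gene_id)
            if a is None or a.family_name == "tadV":
                continue
            system = a.system
            if (system in last_pos
                    and pos - last_pos[system] - 1 <= max_gap_genes):
                runs[system][-1].append(gene)
            else:
                runs[system].append([gene])
            last_pos[system] = pos

        contig_loci: list[LocusModel] = []
        for system in ("T4cP", "T4aP"):
            for run in runs[system]:
                counter += 1
                members = [LocusMember(assignment=by_gene[g.gene_id], gene=g)
                           for g in run]
                members.sort(key=lambda m: m.gene.start)
                contig_loci.append(LocusModel(
                    locus_id=f"{genome.genome_id}_locus{counter:02d}",
                    genome_id=genome.genome_id,
                    members=members, system=system,
                ))

        # attach each tadV to the nearest T4cP locus on this contig
        tadv_assignments = [
            a for a in assignments
            if a.family_name == "tadV"
            and genome.gene(a.gene_id).contig_id == contig_id
        ]
        t4cp_loci = [l for l in contig_loci if l.system == "T4cP"]
        for a in tadv_assignments:
            gene = genome.gene(a.gene_id)
            if not t4cp_loci:
                counter += 1
                contig_loci.append(LocusModel(
                    locus_id=f"{genome.genome_id}_locus{counter:02d}",
                    genome_id=genome.genome_id,
                    members=[LocusMember(assignment=a, gene=gene)],
                    system="T4cP",
                ))
                continue
            gpos = idx[gene.gene_id]

            def gap_to(locus: LocusModel) -> int:
                positions = [idx[m.gene.gene_id] for m in locus.members]
                if gpos < min(positions):
                    return min(positions) - gpos - 1
                if gpos > max(positions):
                    return gpos - max(positions) - 1
                return 0

            nearest = min(t4cp_loci, key=gap_to)
            nearest.tadV_distal = gap_to(nearest) > max_gap_genes
            nearest.members.append(LocusMember(assignment=a, gene=gene))
            nearest.members.sort(key=lambda m: m.gene.start)

        # scattered prepilins: pilE runs far from any multi-family T4aP locus
        main_t4ap = [l for l in contig_loci
                     if l.system == "T4aP"
                     and len(set(l.families) - {"pilE"}) > 0]
        scattered = 0
        for locus in list(contig_loci):
            if (locus.system == "T4aP" and locus not in main_t4ap
                    and set(locus.families) == {"pilE"}):
                scattered += len(locus.members)
                contig_loci.remove(locus)
        for locus in main_t4ap:
            locus.scattered_prepilins = scattered
        if scattered and not main_t4ap:
            # keep the count visible even without a main locus
            counter += 1
            contig_loci.append(LocusModel(
                locus_id=f"{genome.genome_id}_locus{counter:02d}",
                genome_id=genome.genome_id, members=[], system="T4aP",
                scattered_prepilins=scattered,
            ))
        loci.extend(l for l in contig_loci if l.members
                    or l.scattered_prepilins)

    loci.sort(key=lambda l: (l.members[0].gene.contig_id if l.members else "",
                             l.start if l.members else 0))
    return loci


def _majority_strand(members: list[LocusMember]) -> str:
    plus = sum(1 for m in members if m.gene.strand == "+")
    return "+" if plus * 2 >= len(members) else "-"


def classify_t4cp(locus: LocusModel) -> str:
    """Classify a tight-adherence (T4cP) locus; sets flags on the model.

    tadV absence is judged from the locus model: every tadV homolog in the
    genome is attached to its nearest T4cP locus during grouping, so a
    locus without a tadV member implies genome-wide absence.
    """
    if locus.system != "T4cP":
        raise ValueError(f"not a T4cP locus: {locus.locus_id}")
    fams = set(locus.families)
    locus.delta_c = "tadC" not in fams
    locus.delta_v = "tadV" not in fams

    motor = [m for m in locus.members
             if m.assignment.family_name in T4CP_MOTOR_SUB]
    pilin = [m for m in locus.members
             if m.assignment.family_name in T4CP_PILIN_SUB]
    if motor and pilin:
        locus.inverted_pilin_cluster = (
            _majority_strand(motor) != _majority_strand(pilin)
        )

    if locus.delta_c and locus.inverted_pilin_cluster:
        locus.classification = "T4cP_deltaC_inverted"
    elif locus.delta_v:
        locus.classification = "T4cP_deltaV"
    elif set(T4CP_CLUSTER_FAMILIES) <= fams:
        locus.classification = "T4cP_canonical"
    else:
        locus.classification = "T4cP_partial"
        locus.classification_reasons = [
            f"missing:{f}" for f in T4CP_CLUSTER_FAMILIES if f not in fams
        ]
    return locus.classification


def classify_t4ap(locus: LocusModel) -> str:
    """Classify a T4aP locus as functional or nonfunctional.

    Functional requires all 11 families present and intact, with pilB+pilT
    on one strand and the remaining nine genes on the opposite strand.
    """
    if locus.system != "T4aP":
        raise ValueError(f"not a T4aP locus: {locus.locus_id}")
    fams = locus.families
    reasons: list[str] = []
    for f in PIL_FAMILIES:
        if f not in fams:
            reasons.append(f"missing:{f}")
    for m in locus.members:
        if m.assignment.pseudo:
            reasons.append(f"pseudo:{m.assignment.family_name}")
    motor = [m for m in locus.members
             if m.assignment.family_name in T4AP_SAME_STRAND]
    others = [m for m in locus.members
              if m.assignment.family_name not in T4AP_SAME_STRAND]
    if motor and others:
        motor_strands = {m.gene.strand for m in motor}
        other_strands = {m.gene.strand for m in others}
        if (len(motor_strands) != 1 or len(other_strands) != 1
                or motor_strands == other_strands):
            reasons.append("strand_layout")
    locus.extra_pilE_in_locus = max(0, fams.count("pilE") - 1)
    locus.classification_reasons = sorted(set(reasons))
    locus.classification = ("T4aP_functional" if not reasons
                            else "T4aP_nonfunctional")
    return locus.classification


def classify(locus: LocusModel) -> str:
    return (classify_t4cp(locus) if locus.system == "T4cP"
            else classify_t4ap(locus))


def scan_genome(
    genome: Genome,
    families: dict[str, ReferenceFamily],
    min_id: float = 0.4,
    min_cov: float = 0.6,
    max_gap_genes: int = 5,
) -> tuple[list[FamilyAssignment], list[LocusModel]]:
    """Assign families, group into loci and classify, in one pass."""
    assignments = assign_families(genome, families, min_id, min_cov)
    loci = group_loci(assignments, genome, max_gap_genes)
    for locus in loci:
        if locus.members:
            classify(locus)
    return assignments, loci
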