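"""Reading and writing annotated genomes.

All coordinates are 1-based inclusive (GFF3 convention) throughout the
package; no half-open intervals are used internally.  Coding sequences are
stored in coding orientation, i.e. minus-strand CDS are reverse-complemented
on extraction.  Translation uses the bacterial/archaeal genetic code
(NCBI table 11); a terminal stop codon is dropped from the protein, while an
internal stop is retained as ``*`` and flags the record as pseudogenized.

CDS whose length is not a multiple of three are not rejected: they are
flagged ``frameshifted`` and translated up to the last complete codon.
Broken genes must be representable because downstream locus classification
distinguishes functional from frameshift-disrupted pilus loci.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

TRANSLATION_TABLE = 11


class CoordinateError(ValueError):
    """A gene interval falls outside its contig."""


@dataclass
class GeneRecord:
    """One coding sequence of one genome.

    ``start``/``end`` are 1-based inclusive with ``end >= start`` regardless
    of strand.  ``cds_nt`` is always in coding orientation.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds_nt: str
    protein_aa: str = ""
    frameshifted: bool = False
    pseudogenized: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if not self.protein_aa:
            self.protein_aa = self._translate()

    def _translate(self) -> str:
        nt = self.cds_nt
        trimmed_len = len(nt) - len(nt) % 3
        if trimmed_len != len(nt):
            self.frameshifted = True
        prot = str(Seq(nt[:trimmed_len]).translate(table=TRANSLATION_TABLE))
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            self.pseudogenized = True
        return prot

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """An annotated genome: contig sequences plus coordinate-sorted genes."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.contig_id, g.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise CoordinateError(
                    f"{g.gene_id}: contig {g.contig_id!r} not in genome"
                )
            if g.start < 1 or g.end > len(self.contigs[g.contig_id]):
                raise CoordinateError(
                    f"{g.gene_id}: interval {g.start}..{g.end} outside contig "
                    f"{g.contig_id} (length {len(self.contigs[g.contig_id])})"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def extract_cds(contig_seq: str, start: int, end: int, strand: str) -> str:
    """Return the coding-orientation CDS for a 1-based inclusive interval."""
    sub = contig_seq[start - 1 : end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def read_genome(fasta_path: str | os.PathLike, gff3_path: str | os.PathLike,
                genome_id: str | None = None) -> Genome:
    """Load a genome from a nucleotide FASTA plus a GFF3 of CDS features.

    Only CDS features are used; each must carry an ``ID=`` (or
    ``locus_tag=``) attribute.  Phase is assumed 0.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(fasta_path)))[0]
    contigs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    genes: list[GeneRecord] = []
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "CDS":
                continue
            contig_id, _, _, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag")
            if gid is None:
                raise ValueError(f"CDS without ID attribute: {line!r}")
            if contig_id not in contigs:
                raise CoordinateError(
                    f"{gid}: contig {contig_id!r} absent from FASTA"
                )
            s, e = int(start), int(end)
            if s < 1 or e > len(contigs[contig_id]):
                raise CoordinateError(
                    f"{gid}: CDS {s}..{e} outside contig {contig_id}"
                )
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=s,
                    end=e,
                    strand=strand,
                    cds_nt=extract_cds(contigs[contig_id], s, e, strand),
                )
            )
    return Genome(genome_id=genome_id, contigs=contigs, genes=genes)


def write_genome(genome: Genome, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write ``<genome_id>.fna`` and ``<genome_id>.gff3``; returns the paths.

    Round-trips with :func:`read_genome` gene-for-gene.
    """
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(str(out_dir), f"{genome.genome_id}.fna")
    gff3_path = os.path.join(str(out_dir), f"{genome.genome_id}.gff3")
    with open(fasta_path, "w") as fh:
        for contig_id, seq in genome.contigs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "piliscan",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
    return fasta_path, gff3_path
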