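import numpy as np
import pytest

from piliscan.genome_io import Genome, GeneRecord
from piliscan.synthetic_data import _back_translate, make_reference_families


@pytest.fixture(scope="session")
def families():
    return make_reference_families(1)


def genome_from_proteins(genome_id, named_proteins, rng=None, strands=None,
                         spacer=30):
    """Build a single-contig Genome from (gene_id, protein) pairs.

    Proteins must start with M; CDS are uniform back-translations with an
    ATG...TAA frame, laid head-to-tail with random spacers.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    parts, genes, pos = [], [], 0
    for i, (gene_id, prot) in enumerate(named_proteins):
        strand = strands[i] if strands else "+"
        cds = "ATG" + _back_translate(rng, prot[1:]) + "TAA"
        sp = "".join(rng.choice(list("ACGT"), size=spacer))
        parts.append(sp)
        pos += spacer
        start, end = pos + 1, pos + len(cds)
        on_contig = cds
        if strand == "-":
            from Bio.Seq import Seq
            on_contig = str(Seq(cds).reverse_complement())
        parts.append(on_contig)
        pos = end
        genes.append(GeneRecord(
            gene_id=gene_id, genome_id=genome_id, contig_id="c1",
            start=start, end=end, strand=strand, cds_nt=cds,
        ))
    parts.append("ACGT" * 10)
    return Genome(genome_id=genome_id, contigs={"c1": "".join(parts)},
                  genes=genes)


def random_protein(rng, length):
    return "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                    size=length - 1))
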