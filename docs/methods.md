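# Methods

This note documents the models and procedures implemented in piliscan, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coordinate and sequence conventions

All coordinates are 1-based inclusive (the GFF3 convention), everywhere; no
half-open intervals are used internally. Coding sequences are stored in
coding orientation (minus-strand CDS reverse-complemented on extraction)
and translated with the bacterial/archaeal genetic code (NCBI table 11,
phase 0 assumed). A terminal stop is dropped from the protein; an internal
stop is kept as `*` and flags the record *pseudogenized*; a CDS whose
length is not a multiple of three is flagged *frameshifted* and translated
up to the last complete codon rather than rejected. Broken genes must be
representable because the T4aP classifier distinguishes functional loci
from loci disrupted by frameshifts.

## Codon-usage metrics

Metrics use only sense codons; Met, Trp and stop codons carry no
synonymous information and are excluded from RSCU, ENC and CAI.

- **GC** is computed over the full CDS, not the third codon position;
  ambiguous bases are excluded from numerator and denominator alike.
- **RSCU deviation.** RSCU is a 59-element vector, but the screen needs a
  per-gene scalar. We use the mean absolute deviation of the gene's RSCU
  from the genome-wide RSCU, restricted to codons of degenerate families
  the gene actually uses. This measures synonymous-choice atypicality
  relative to the host, which is what a compositional HGT screen needs;
  genes with no degenerate-family codons are undefined.
- **ENC** is Wright's estimator: per amino acid with at least two
  observations, the codon homozygosity F̂ = (nΣp² − 1)/(n − 1); F̂ values
  are averaged within degeneracy classes {2, 3, 4, 6} and combined as
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. A missing
  three-fold class (Ile unobserved) is imputed as (F̄₂ + F̄₄)/2; a missing
  two-, four- or six-fold class makes the estimate undefined, and amino
  acids with F̂ = 0 are skipped (their reciprocal is unusable), as in the
  common ENc implementations. For genes of ≥ 100 codons drawn from any
  non-degenerate usage all classes are observed in practice.
- **CAI** uses the genome's own pooled CDS usage as the reference set —
  no curated highly-expressed gene set is assumed; the reference is
  configurable. A pseudocount of 1 on reference counts keeps relative
  adaptiveness w strictly positive for codons unseen in the reference.

Undefined values are `nan`, never errors, and never contribute an HGT flag.

## HGT screen

Thresholds are dynamic per genome: for each gene and metric the comparison
set is the metric values of all *other* profiled genes of the same genome
(leave-one-out). GC, RSCU deviation and ENC flag above the 90th percentile;
CAI flags below the 10th. The percentile is the nearest-rank empirical
quantile (`numpy` method `"higher"`, or `"lower"` for the low tail) with a
strict inequality at the threshold. With linear interpolation the
leave-one-out construction flags about N/10 + 1 genes on tie-free values;
the nearest-rank form keeps the screen calibrated at ≤ ⌈0.1 N⌉ flags per
metric, which is the property the rest of the analysis relies on.
Frameshifted/pseudogenized genes are excluded from both profiling and the
genome background pool. A floor of 20 profiled genes (configurable) guards
against meaningless percentiles.

The rule for combining the four per-metric flags into one verdict is a free
parameter; the default composite call requires ≥ 3 of 4 flags (`k`,
exposed as `--min-flags`). k = 3 keeps single-metric noise out while not
demanding that all four signals co-occur.

Per-family acquisition rates count, for each gene family across a cohort,
the fraction of family-carrying genomes in which at least one family member
is called HGT. Family members outside any detected locus are tallied
separately (suffix `_scattered`), so extra prepilin copies outside the main
locus get their own rate.

## Locus detection and classification

Family assignment aligns every translated gene against each of the 19
reference proteins with one aligner configuration used package-wide
(global, BLOSUM62, gap open −11 / extend −1). With only 19 references,
exact all-vs-all alignment is desk-scale and no heuristic seeding is
needed; a shared-4-mer prefilter merely skips pairs that cannot reach the
thresholds. Identity is matches over alignment columns excluding terminal
gaps; coverage is the fraction of the reference inside that region. The
best-scoring family is kept when identity ≥ 0.4 and coverage ≥ 0.6 (both
configurable; the defaults tolerate genus-level divergence). Proteins are
truncated at the first internal stop before alignment so pseudogenes are
still recognized by their intact prefix; an assignment is marked *pseudo*
when the record is frameshifted/pseudogenized or covers < 50% of the
reference.

Loci are maximal runs of same-system assignments on one contig with at
most `max_gap_genes` = 5 intervening unassigned genes ("locus" has no
standard numeric definition; 5 is the package's operational one, exposed
in config). Two exemptions reflect T4P biology: tadV (the prepilin
peptidase) is attached to the nearest Tad locus regardless of distance,
with `tadV_distal` recording whether it lies beyond the gap limit, because
in the Tad architecture the peptidase characteristically sits outside the
cluster; and pilE-only runs far from any T4aP locus are counted as
scattered prepilins rather than loci of their own. pilE and pilA are
treated as a single family.

Classification rules:

- `T4cP_canonical` — tadZ, tadA, tadB, tadC, flp, tadE, tadF all present.
- `T4cP_deltaC_inverted` — tadC absent and the {flp, tadE, tadF}
  prepilin/pseudopilin sub-cluster inverted (majority strand opposite to
  the {tadZ, tadA, tadB} sub-cluster).
- `T4cP_deltaV` — no tadV genome-wide (every tadV homolog is attached to
  its nearest Tad locus during grouping, so absence from the locus model
  is genome-wide absence). Loss of tadC and loss of tadV can co-occur;
  both are reported as flags and the tadC variant takes the primary label.
- `T4aP_functional` — all 11 pil families present, none pseudo, with
  pilB + pilT on one strand and the remaining nine genes on the opposite
  strand; anything else is `T4aP_nonfunctional` with reasons listed
  (`missing:*`, `pseudo:*`, `strand_layout`). Extra pilE copies inside
  the locus are counted as `extra_pilE_in_locus`.
- Tad loci matching none of the rules get the fallback label
  `T4cP_partial` with the missing families listed.

## Pangenome, core genome, tree

Ortholog clustering builds an all-against-all protein identity graph
(edges at ≥ 80% identity by default, after the 4-mer prefilter, which at
that threshold cannot lose genuine edges) and runs Markov clustering per
connected component: expansion 2, inflation 2.0 (configurable; the value
is conventional, not derived), pruning 1e-6, convergence when the matrix
changes < 1e-8 or after 100 iterations. Singletons are their own clusters.
Cluster ids are assigned from sorted membership, so clustering is
invariant to genome and gene input order.

Core families are clusters with *exactly one* member in every genome — the
strict single-copy reading of "shared by all genomes", the standard
pangenome convention that guarantees unambiguous per-genome
representatives for the tree.

The core-genome distance between two genomes is the mean over core
families of protein p-distance (1 − identity) from pairwise global
alignment. This replaces multiple alignment plus concatenation: at these
scales averaged pairwise p-distances carry the same additive signal
without a progressive aligner, and the neighbor-joining input remains a
proper distance matrix. The tree is Saitou–Nei NJ with the standard Q
criterion; ties break on the smallest taxon-index pair for determinism;
negative branch lengths are clamped to zero with the excess moved to the
sister branch; with an outgroup the tree is rooted at the midpoint of the
outgroup's pendant edge. On additive matrices the topology is recovered
exactly.

Flank conservation maps the nearest non-member gene on each side of a
locus to its ortholog cluster ("none" at contig edges), swaps the pair for
minus-strand loci so "upstream" is always 5′ of the locus reading
direction, and reports the fraction of genomes sharing the modal pair
(ties broken lexicographically). One locus per genome (the first of the
queried system) enters the statistic. The locus span used here is its
contiguous run — a distal tadV does not stretch the span, otherwise the
"flanks" would be genes unrelated to the cluster context.

## Synthetic genomes

The generator emulates exactly the structure the pipeline assumes:

- **Background codon usage.** Per genome, synonymous codon weights are
  drawn from a sparse Dirichlet (concentration 0.35 — strongly biased,
  low-ENC usage, as in real high-GC actinobacteria) with uniform amino
  acid frequencies, exponentially tilted so the expected GC hits the
  target (default 0.60, bifidobacteria-like). Background genes are drawn
  codon-by-codon from this table; lengths are uniform in 100–400 codons;
  every emitted CDS is forced to `ATG … TAA` except deliberately
  frameshifted ones. Genes sit on a single contig separated by fixed
  50-nt random spacers.
- **Alien genes** are drawn from a near-uniform codon table tilted to the
  background GC plus a configured shift (default +0.15). Near-uniform
  usage gives the planted genes high ENC and high RSCU deviation as well
  as shifted GC and low CAI, i.e. a four-metric signal, mirroring genes
  acquired from a compositionally different donor. A configuration error
  is raised when the tilt target is unreachable.
- **Reference families and embedded loci.** The 19 family proteins are
  random sequences of 80–500 aa, re-drawn until all pairs are < 30%
  identical; each family also gets a back-translated CDS. Locus templates
  place family genes in architecture order and strand layout; each member
  protein is mutated to a target identity by per-residue substitution at
  rate (1 − identity), uniform over the other 19 amino acids, then
  back-translated with the *host genome's* codon table — embedded loci do
  not look alien to the HGT screen by default. A per-family option plants
  alien codon usage in chosen locus genes (and in scattered pilE copies)
  in a configured fraction of genomes, emulating horizontally acquired
  pilin genes. Edits per template: delete tadC and invert the pilin
  sub-cluster; delete tadV genome-wide; or frameshift pilC by a
  single-nucleotide deletion ~70% into the gene (so the intact prefix
  still aligns and the broken gene is assigned, not lost). The distal
  tadV is placed ≥ 10 genes downstream of the Tad cluster.
- **Shared families.** A configurable number of single-copy core families
  and one modal flanking pair are planted across genomes at 0.95 identity
  to a cohort-level reference (pairwise ~0.90 between genomes, safely
  above the 0.8 clustering threshold); non-conserved genomes get unique
  random flank genes, so exactly the configured fraction of genomes share
  the modal flank pair. Random number streams for the reference families
  and for genome content are kept independent (spawned seeds), which
  matters: a shared stream makes generated proteins correlated
  subsequences of the references.

Determinism is end-to-end: one seeded generator drives everything, and
identical configs produce byte-identical FASTA/GFF3/manifest files.

What the generator does **not** emulate: realistic intergenic or
regulatory sequence, rRNA/tRNA genes, insertion sequences, amino-acid
composition bias, genome rearrangements beyond the scripted locus edits,
or phylogenetic correlation structure among genomes (core-family
divergence is independent per genome, so simulated trees are star-like).
Passing tests therefore demonstrate correctness of the bookkeeping,
calibration and classification logic under the planted statistical
structure, not performance on real genomes with gene-length, composition
and phylogenetic confounders.

## Problem sizes and defaults

Worked examples run on single genomes of ~200 genes; the classifier check
uses 25 genomes per template at 60 background genes; the HGT recovery
check uses 20 genomes × 200 background + 5 alien genes; the flank
analysis uses 20–26 genomes; NJ recovery uses 50 random 6-taxon additive
trees; the demo pipeline uses 5 genomes × 200 genes. These sizes exercise
every code path at desk scale while keeping the whole suite and the
acceptance script in the low minutes on one CPU.

## Known limitations

- The RSCU scalarization and the 3-of-4 composite rule are package
  choices; other reductions (e.g. chi-square codon deviation, 2-of-4
  voting) would shift per-gene flags.
- Acquisition rates inherit the screen's per-gene detection noise; they
  equal the planted fractions only because the planted compositional
  signal is strong.
- The p-distance NJ tree is not a substitution-model phylogeny; for real
  data one would want model-corrected distances or a likelihood tree.
- Family assignment is best-hit by score with fixed thresholds; profile
  (HMM) search would be more sensitive for remote homologs.
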