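# Methods

## Scope and overall design

`seldscope` re-implements, as a reusable library, the comparative-genomics
workflow used to characterise a distant selenophosphate-synthetase homolog
family in archaea: occurrence searches for Se-utilization marker genes,
bidirectional-best-hit orthology, genomic-context analysis around an anchor
gene, an exclusive co-occurrence screen between positive and negative
genome sets, conserved-residue checks on a family alignment, and
distance-based phylogenetics with bootstrap support. Genome-scale inputs
are replaced by a synthetic-data generator that plants every feature the
pipeline is meant to detect, so all claims the test suite makes are about
recovery of known ground truth at stated divergences — not about real
archaeal genomes.

## Homology model

Pairwise search uses exact Smith–Waterman local alignment instead of a
heuristic seeded search: at desk scale (tens of genomes, tens of proteins
each) exact dynamic programming is affordable, removes an external binary,
and makes results bit-reproducible. Alignment is executed through
Biopython's `PairwiseAligner` (C implementation) under BLOSUM62 with affine
gap costs `open=11, extend=1` (a gap of length k costs `11 + k`).
Selenocysteine (`U`) is preserved in storage but scored as `C`, so a
Sec/Cys correspondence counts as identity — the convention used when
comparing SelD with its Cys-containing homologs.

Statistical significance uses the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with fixed gapped-BLOSUM62/11/1 parameters
`λ = 0.267`, `K = 0.041`, where `n` is the summed length of the database
searched. Fixed parameters (rather than per-query estimation) keep results
deterministic; the cutoffs used downstream are coarse enough (0.1, 1e−07)
that this approximation does not change presence/absence calls at the
simulated divergences. Identity is computed over the full alignment length
(gap columns in the denominator) and query coverage as the aligned query
span over query length — both BLAST reporting conventions.

Two named criteria sets are built in, matching the wording of the original
procedures exactly: the occurrence search accepts `E ≤ 0.1` (inclusive),
while the profiling screen requires `E < 1e−07` (strict), alignment
extending over half the query length (strict `>`), and identity at least
30% (inclusive `≥`). Best-hit ranking breaks ties by E-value, then
bitscore, then lexicographic subject id, which makes BBH orthology
deterministic when paralogs are equidistant.

A score-only pass (no traceback) bounds each pair's E-value first;
tracebacks run only for pairs that can pass the E cutoff. This is a pure
optimisation: scores, and therefore decisions, are unchanged.

## Trait rules

Marker genes: SelD, SelA, archaeal SecS, SelB, YbbB, YqeB, YqeC, plus the
SelD-like family tracked alongside. Traits are conjunctions over marker
presence — Sec requires SelD, a Sec synthase (SelA **or** SecS, covering
both the bacterial and archaeal enzymes) and SelB; SeU requires SelD and
YbbB; the Se cofactor requires SelD, YqeB and YqeC. SelC (the tRNA) and
PSTK are not part of the default rule: detection is protein-level only. A
genome with SelD but no complete trait is an orphan-SelD genome.
Percentages in clade summaries are rounded half-up to one decimal.

For synthetic marker calling the panel uses stricter criteria than the
plain occurrence search (`E ≤ 1e−5`, coverage > 0.5, identity ≥ 0.30):
random unrelated proteins can reach E ≈ 0.1 by chance (that is what an
E-value of 0.1 means), and the stricter rule keeps the negative-control
false-positive rate effectively zero while planted homologs — full-length,
≥ 70% identity at the default divergence — pass with enormous margin.

## Neighborhood and fusion analysis

The context window (default 10,000 nt) is measured from the anchor gene's
outermost coordinates, and any locus overlapping the window on the same
contig is a member (partial overlap counts; membership is therefore
symmetric between genes for a fixed window). Distances are signed gap
lengths, zero for overlap, negative upstream. Strand is recorded but never
filters membership. Domain fusions on one protein are called when at least
two domain queries hit with criteria-passing alignments whose spans on the
protein overlap by less than 20% of the shorter span; the 20% tolerance
admits ragged hit ends while rejecting two hits to one domain.

## Exclusive co-occurrence screen

Every protein of a designated reference genome is searched against target
genomes under the strict profiling criteria, producing a boolean
presence/absence matrix (criteria recorded for provenance). Candidates are
genes absent from **every** negative genome and present in **all** positive
genomes; the dismissal-on-negatives rule is applied first, mirroring the
original procedure's step order, though the final set is order-independent.
A `min_positive_fraction` parameter relaxes the all-positives rule when
wanted; the strict rule is the default. Candidates are then annotated per
outgroup clade as present in `all`, `some` or `none` of its genomes
(single-genome clades report `all` when present). Criteria are applied to
the single best local alignment per subject protein.

## Conservation checks

Functional sites are configuration, not code: a residue spec names a
reference row, a 1-based ungapped position and the allowed letters (e.g.
catalytic Sec/Cys accepting `C` or `U`); a motif spec is an ordered pattern
such as `[CU]xx[K]`. Positions map through the alignment to a column and
back (a bijection per row between ungapped positions and non-gap columns).
Motifs are evaluated on each row's ungapped residues starting from the
anchor column — residue-space spacing, since a functional site sits "three
residues downstream" regardless of alignment gaps; rows with a gap at the
anchor, or too few remaining residues, evaluate false. The packaged
alignment under `tests/data/` is a synthetic stand-in constructed to carry
the documented sites (catalytic Sec/Cys, Cys-X-X-Lys, four Asp positions,
a conserved Asn) in both SelD and SelD-like rows.

## Phylogenetics

Distances are p-distances with pairwise deletion (a pair sharing no
gap-free column is an error naming the pair). Trees come from the
Saitou–Nei neighbor-joining algorithm with the standard Q-matrix selection
and branch-length formulas; negative length estimates are clamped to zero
and ties in Q are broken by the smallest (i, j) index pair, making the
topology deterministic. Trees are unrooted `dendropy` objects,
newick-serializable with supports as internal node labels. NJ rather than
maximum likelihood carries the topology claims here: at fixture
divergences, distance methods recover the generating topology exactly
(verified against random additive matrices), and ML would add heavy
dependencies without changing what the tests can demonstrate.

Bootstrap support resamples alignment columns with replacement (seeded
numpy generator; a replicate that leaves some pair without comparable
columns is redrawn), rebuilds the NJ tree per replicate, and scores each
internal edge of the original tree by the percentage of replicates
containing the same leaf bipartition. The majority-rule consensus contains
exactly the bipartitions with support > 50% (such bipartitions are pairwise
compatible, so they nest greedily from the best supported). Monophyly of a
leaf set means some edge of the unrooted tree separates exactly that set;
singleton sets, the full set and its complements of size one are trivially
monophyletic.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions:

* **Shape** — the default configuration mirrors the study design: one
  reference genome among 9 SelD-like-positive Thermoproteales, 3
  SelD-like-negative Thermoproteales, a 4-genome Sulfolobales outgroup
  carrying SelD-like, a 3-genome Methanococcales clade planted with
  {SelD, SelA, SelB, YbbB} (Sec + SeU) and a 2-genome Halobacteriales clade
  with {SelD, YqeB, YqeC}, 50 background families present everywhere, one
  gene planted exclusively in the positives, SirA-like/Prx-like partner
  genes clustered with the anchor inside the 10,000 nt window, and the
  SelD-like–acylphosphatase fusion in all positive Thermoproteales.
* **Evolution model** — each family has a random seed sequence drawn from
  approximate natural amino-acid frequencies; a clade ancestor derives from
  the seed and each genome copy from its ancestor with i.i.d. substitutions
  at a per-branch rate (default 0.05, so within-clade homologs differ by
  roughly 10%), uniform over the other 19 residues. No indels in this
  version: family members stay equal-length, which keeps alignment columns
  trivially mappable and lets family blocks serve directly as MSAs. The
  SelD and SelD-like families carry an invariant catalytic Cys at position
  17 and Lys at position 20 (the [CU]-X-X-K site), modelling purifying
  selection on the active site.
* **Layout** — one contig per genome, genes laid left to right with
  intergenic gaps uniform in 200–1500 nt (20–120 nt inside the planted
  cluster), random strands. Protein lengths are uniform in 80–160 residues
  — shorter than the ~280-residue average of real archaeal proteins, a
  deliberate desk-scale choice that leaves all detection margins
  (identity, coverage, E-value) qualitatively unchanged.
* **Determinism** — everything derives from one numpy generator seeded by
  the config; identical seeds produce byte-identical output files.
* **Ground truth** — planted marker maps, the exclusive gene, the full
  ortholog correspondence, neighborhood memberships, fusion protein ids and
  the expected screen outcome are recorded and checkable against the
  emitted files by independent readers.

What the generator does **not** emulate: insertions/deletions, gene
duplication and loss, horizontal transfer, rearrangements, codon-level
evolution, compositional bias and annotation noise. Passing tests
therefore demonstrate correctness of the pipeline's logic and statistics
under a clean divergence model, not robustness to the full messiness of
real genomes.

## Numerical and interface choices

* Coordinates are 1-based inclusive at every public boundary.
* Gene tables are a fixed 8-column TSV rather than full GFF3 — the context
  analysis needs only coordinates, strand and labels, and this avoids GFF3
  attribute-dialect ambiguity. Domain labels are taken as given annotation;
  profile-based domain assignment is out of scope.
* The E-value cutoff inside BBH defaults to the occurrence-search value
  (0.1) and is configurable; the screen's criteria are strict as worded
  above.
* Alignments are consumed (aligned FASTA or Clustal), never built — except
  pairwise; families in the simulator are alignment-free by construction.
* The survey-scale trait-distribution computation in
  `scripts/acceptance.py` reconstructs a 215-genome marker table from the
  published distribution constraints (26 SelD-positive; 15 Sec / 14 SeU /
  10 Se-cofactor organisms; SeU confined to Methanococcales where it
  overlaps Sec; the cofactor trait confined to Halobacteriales; one orphan
  SelD). Those constraints determine the overlap structure uniquely
  (all 14 SeU genomes also decode Sec), and the classifier recomputes the
  headline numbers from that table.
* Problem sizes in the default test run (genome counts, 50 background
  families, 80–160-residue proteins, 100 bootstrap replicates, 20 screen
  seeds) are the package's chosen study conditions; they keep the whole
  suite to a few minutes on one CPU while leaving every detection margin
  wide.

## Known limitations

* Karlin–Altschul parameters are the fixed gapped-BLOSUM62 constants;
  E-values for other matrices/penalties would need their own (λ, K).
* Pairwise identity of distant homologs depends on gap parameters; small
  deviations from any particular BLAST parameterisation are expected.
* The representative-sequence checks in the acceptance suite require real
  published SelD/SelD-like sequences, which are not bundled; those two
  tests fail unless the fixture is supplied
  (`tests/data/seld_representatives.fasta`).
* NJ stands in for the maximum-likelihood and Bayesian analyses of the
  original workflow; supports are NJ-bootstrap by construction.
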