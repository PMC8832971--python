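# Methods

## The mining procedure and its assumptions

`panta` predicts toxin–antitoxin (TA) operons anchored on a seed antitoxin
domain (Panacea/DUF4065-like) by conservation of gene neighborhoods rather
than by toxin homology, because the toxin side of these systems is
hyperpromiscuous — one antitoxin domain family pairs with many unrelated
toxin folds.  The underlying assumptions are:

- the seed domain is detectable in every genome of interest (by profile
  scan or injected HMMER hits, one best hit per protein);
- a genuine TA pair is operonic: co-oriented, immediately adjacent genes
  separated by at most `max_gap_nt` (default 100 nt);
- a genuine architecture recurs: the same partner homology family on the
  same transcriptional side of the seed in at least `min_species` distinct
  species (species, not genomes, are the conservation unit — a corpus is
  assumed to be roughly one representative assembly per species, and where
  it is not, equal species strings collapse);
- TA operons are short: a conserved architecture of more than
  `max_operon_genes` (default 3) genes is evidence the seed sits inside a
  longer, non-TA operon and the pair is rejected; exactly three conserved
  genes mark the third as an *accessory* gene;
- a genuine partner family is *reciprocally* seed-associated: most of its
  corpus-wide homologs also sit in operons with seed genes.  Mobile and
  housekeeping families violate this and are flagged spurious.

## Stage-by-stage choices

### Seed detection

The internal scanner is an ungapped position-specific scoring matrix,
deliberately simpler than a profile HMM: per column,
`score(aa) = log2(((count + τ·bg) / (n_eff + τ)) / bg)` bits with
pseudocount weight τ = 1 and a uniform background by default.  Columns with
more than 50% gaps are dropped.  The best-scoring window is accepted when
it reaches the profile's gathering threshold, by default 60% of the score
of the profile's own consensus — a calibrated stand-in for curated
gathering cutoffs, which cannot be derived from an alignment alone.
Unknown residues (X) score 0 bits.  This scanner is exact for the
simulator's indel-free families; for real proteomes the intended route is
an external HMMER run injected via `parse_domain_table`, which produces
identical hit records.

### Flank clustering

All-vs-all global alignment (Biopython `PairwiseAligner`, BLOSUM62, gap
open −11 / extend −1, a gap of length *g* costing 11 + (*g* − 1)), then
single-linkage connected components over edges with identity ≥ 0.3 and
coverage ≥ 0.6.  Identity is identical pairs over alignment columns
excluding terminal gaps; coverage is both-aligned columns over the shorter
length.  Single linkage mirrors the transitivity of iterative profile
search; its known chaining risk is accepted at this scale.  Two prefilters
bound cost: pairs with length ratio < 0.5 are skipped, and pairs whose
edlib edit distance exceeds 0.6 of the shorter length are skipped before
scored alignment.  The second is a speed heuristic: on indel-free families
diverged ≤ ~20% it is loss-free, but for real, distantly homologous pairs
in the 0.3–0.45 identity band it can suppress edges; set
`max_edit_fraction=None` to recover pure threshold semantics.

### Locus calling

Candidates are seed genes with a rank-adjacent, co-oriented gene within the
gap limit (up to one candidate per side).  Co-orientation is required
because these are operonic loci; `require_same_strand=False` relaxes it,
labelling anti-parallel pairs `mixed_strand`.  Gene order
(antitoxin-first / toxin-first) is transcriptional: on `+` the seed is
first when it has the smaller start, mirrored on `−`.  The conservation
unit is `(partner cluster, order)`, so the same family antitoxin-first in
one species and toxin-first in another forms two architectures, each
needing its own support.  The operon-length check walks outward from the
pair chaining same-strand genes with gaps ≤ `max_gap_nt`; a chained gene is
conserved when its cluster co-occurs with the architecture in
≥ `min_species` species.  Chained genes outside every seed neighborhood
window (beyond `neighborhood_k` = 4 genes per side) carry no cluster and
count as non-conserved.  Neighborhoods never cross replicon/contig
boundaries.

### Reciprocity filter

For each surviving partner (and accessory) cluster the representative
member (longest, ties by smallest id) is aligned against every corpus
protein; hits passing the clustering thresholds are ranked by score and the
best `top_n` (20) kept.  The *context fraction* is the fraction of these
homologs (plus the representative) that are operonically linked to a seed
gene — reachable through a chain of same-strand adjacencies, each gap
≤ `max_gap_nt`, within the operon-length limit.  Operonic linkage rather
than raw distance-to-seed is used so that accessory genes, which are
separated from the seed by the toxin gene, are judged by the same rule as
direct partners; for direct partners the two definitions coincide.
Clusters with fraction < 0.5 are spurious; a cluster whose only detectable
homologs are its own members is retained (absence of evidence).  A
spurious partner cluster voids its loci (`spurious_partner`); a spurious
accessory cluster strips the accessory but keeps the locus.  Product-
keyword tallies (transposase / integrase / ATPase) are diagnostics only —
product strings are never used to filter.

### Annotation

- **N-terminal extensions**: residues preceding the seed-domain envelope,
  recorded when ≥ 40 aa (long enough to hold a ~50–60 aa HTH domain).
- **HTH two-pass remodelling**: scan extensions with an initial HTH
  profile; rebuild a profile from the pass-1 hit envelopes (an ungapped
  alignment, all envelopes having profile length); rescan.  Final flags
  are the union of both passes, which makes "remodelling never loses a
  pass-1 hit" true by construction rather than by hope — a rebuilt
  profile's own gathering threshold could otherwise exclude a marginal
  pass-1 hit.
- **PAD1-style discovery**: extensions with no HTH flag are clustered with
  the flank-clustering machinery; families with ≥ 5 members spanning ≥ 2
  species are reported as candidate novel domains.
- **Transmembrane segments**: Kyte–Doolittle sliding-window hydropathy,
  window 19, threshold 1.6 — the standard settings.  Overlapping
  qualifying windows merge; each segment reports merged bounds and its
  mean hydropathy.  This is a stand-in for a dedicated TM predictor; the
  `read_tm_predictions_tsv` injection path accepts external predictions.
- **Conservation**: per alignment column, `1 − H / log2(20)` with `H` the
  Shannon entropy of non-gap residues; columns under 50% occupancy score
  0.  Sufficient to rank invariant motif columns (GPV-like) at the top;
  it is not a phylogeny-aware score.

## The simulator: what it emulates and what it does not

`simulate_pangenome` emulates the statistical structure the pipeline
assumes: `n_species` species × `genomes_per_species` genomes, each genome
one chromosome of `genes_per_replicon` genes.  Species *j* carries toxin
family *j* mod `n_toxin_families`, so every family recurs in ≥ 2 species
whenever `n_species ≥ 2 · n_toxin_families`.  Default study conditions:
10 species × 3 genomes, 5 toxin families, seed domain 80 aa, per-site
substitution probability 0.05, operon gaps uniform on [0, 80] nt,
toxin-first fraction 0.25, 40% of families with an accessory third gene,
a decoy family with 2 seed-adjacent and 18 background placements, 30%/20%
of antitoxins with HTH/PAD1 N-terminal extensions, 40% of toxin families
transmembrane (a spliced 25-Leu block).  Background genes are 60–200 aa,
i.i.d. from the uniform residue background, with intergenic gaps drawn
from [150, 400] nt so that only planted architectures can satisfy the
100-nt criterion.

Generator design points:

- **No indels.**  Families evolve star-like from an ancestor by per-site
  substitution only.  This keeps the ungapped scanner and the identity
  computations exact and is the key simplification relative to real data:
  passing tests demonstrate correct logic and geometry, not robustness to
  indels, domain fusions or fragmented assemblies.
- **Order fixed per family**, so the conserved-architecture criterion is
  well-posed in the truth tables.  Consequently planted loci are clustered
  observations: with the minimal two species × one genome per family, an
  order fraction over N loci has the sampling variance of N/2 independent
  draws, and statistical checks of the order fraction are calibrated at
  the number of families, the independent unit.
- **Accessory genes flank the toxin**, never the seed, so an accessory
  cannot itself form a second seed-adjacent candidate pair.
- **Decoy adjacent placements target one family without an accessory**,
  always on the antitoxin's side opposite the toxin, so the seed–decoy
  architecture is consistent across species, survives the conservation
  filter, and genuinely exercises the reciprocity filter (a decoy that
  never survives conservation would never be tested).
- **Planted 4-gene cassettes** (`n_long_operon_families`) provide
  rejected-operon controls: a second seed gene in a conserved four-gene
  architecture that the pipeline must reject.
- Coordinates are laid left-to-right with drawn gaps; nucleotide sequences
  are never generated (gene length = 3 × aa length).  Equal configs give
  byte-identical output trees.

## Numerical and degenerate-input conventions

- Intergenic distance clamps to 0 for overlapping or book-ended genes,
  keeping the gap criterion monotone.  The 100-nt limit is inclusive.
- Window and cluster tie-breaks are deterministic: leftmost best window;
  cluster ids by descending size then smallest member id; T-numbers by
  descending distinct-partner count then smallest partner id.
- Scanner scores are float64 sums; co-optimal windows may differ from a
  reference enumeration by summation order at ~1e-15, so exactness is
  asserted at 1e-9.
- Proteins shorter than a profile, empty neighborhoods, comment-only
  domain tables, and extension sets with zero pass-1 hits all degrade to
  empty results, never errors; infeasible simulation configs and malformed
  input files raise before any output is written.

## Problem sizes used in validation

The shipped validation runs use the default 30-genome corpus for
end-to-end recovery, five seeded replicates of it for the reciprocity
rates, and a flat 500-genome corpus (250 families × 2 species, 6 genes per
genome) for order statistics — sizes chosen to exercise every code path at
desk scale while the conservation, decoy and accessory structures remain
non-trivial.

## Known limitations

- The PSSM scanner is not a profile HMM: no insert/delete states, no
  local/glocal modes, no E-values.  Real corpora should inject HMMER
  results.
- Single-linkage clustering can chain distinct families through
  intermediates; the identity/coverage thresholds and the planted-truth
  tests bound this only at simulation divergences.
- The edit-distance prefilter trades remote-homology sensitivity for
  speed (see above).
- The reciprocity context fraction treats all homolog placements equally;
  no weighting by similarity or taxonomic spread.
- Entropy conservation ignores phylogeny and residue similarity.
- Copy-number statistics count at species level; strain-level resolution
  collapses to the representative genome with the most features.
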