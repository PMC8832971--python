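# panta

Gene-neighborhood mining of **Pan**acea-linked **t**oxin–**a**ntitoxin loci
in annotated prokaryotic genomes.

Panacea (the Pfam DUF4065 domain) is an antitoxin domain found across
bacteria, archaea and bacteriophages, remarkable for pairing in operons with
dozens of unrelated toxin folds.  Because the domain itself is the only
stable signature, new toxin–antitoxin (TA) systems of this class are found
by *comparative gene-neighborhood analysis*: detect every seed-domain
protein, cluster the proteins encoded around it into homologous families
across genomes, and keep the pairings that look like conserved operons.
`panta` is a reusable, deterministic implementation of that procedure for
bioinformaticians studying TA systems, mobile genetic elements, or operon
conservation generally, together with a synthetic-pangenome simulator that
plants ground-truth loci so every stage can be scored.

## The method

A candidate locus is a seed (antitoxin) gene *a* and an immediately adjacent
co-oriented gene *t*.  The pair is called a putative TA (pTA) locus when

1. **gap criterion** — the intergenic distance satisfies
   `d(a, t) ≤ 100 nt`;
2. **conservation criterion** — the same architecture (the same partner
   homology cluster on the same transcriptional side of the seed) occurs in
   ≥ 2 species;
3. **operon-length criterion** — the conserved neighborhood does not
   suggest an operon longer than 3 genes.  A conserved chain of exactly 3
   records the third gene as an *accessory* gene instead.

Flank families come from all-vs-all global alignment (BLOSUM62, affine
gaps 11/1) with single-linkage components over edges with identity ≥ 0.3
and coverage ≥ 0.6.  Surviving partner families then face a
**reciprocity filter**: the family representative is searched against every
proteome, and the fraction of its best homologs that sit in an operon with
a seed gene is measured.  Mobile or housekeeping families (transposases,
integrases, ATPases) that are seed-adjacent only occasionally score a low
context fraction (< 0.5) and are flagged spurious.  Final toxin clusters
are T-numbered (T1, T2, …) by descending size.

Antitoxins are further annotated with N-terminal helix-turn-helix (HTH)
domains via a two-pass profile-remodelling scan, and remaining conserved
extensions are clustered to surface novel domains (the PAD1-discovery
route).  Toxins get Kyte–Doolittle hydropathy transmembrane segments
(window 19, threshold 1.6).  Seed detection itself uses either a built-in
ungapped log-odds profile (PSSM) with a gathering-style bit threshold, or
injected HMMER3 `--domtblout` results for real corpora.

## Worked example

`python examples/01_simulate_and_mine.py` simulates the default synthetic
pangenome (10 species × 3 genomes, 5 cognate toxin families, one mobile
decoy family present in 20 copies of which only 2 are seed-adjacent), mines
it, and prints:

```
Corpus: 30 genomes, 10 species
Seed-domain proteins: 30
Copy number (homologs per taxon): 10 taxa with 1
Replicon localization (complete genomes): 30 chromosomal, 0 plasmid, 0 other
pTA loci: 32 preliminary, 2 removed as spurious, 30 final in 5 toxin clusters
Gene order: antitoxin first 18 vs toxin first 12

recall    1.00   (fraction of planted loci recovered)
precision 1.00   (fraction of calls that are planted)
reciprocity: a genuine partner's homologs sit next to seed genes
(fraction ~1.0); a mobile decoy's mostly do not (fraction < 0.5):
  cluster 1: retained  context fraction 1.00
  ...
  cluster 3: spurious  context fraction 0.10
```

All 30 planted loci are recovered; the two decoy-adjacent pairs are the
"2 removed as spurious" — their partner family's corpus-wide context
fraction is 2/20 = 0.10, far below the 0.5 threshold.  Further examples
show the HMMER injection path (`02_inject_hmmer_hits.py`) and the
annotation operations (`03_annotate_features.py`).

The same workflow is available from the shell:

```bash
panta simulate --seed 1 --out sim/
panta run --corpus sim/ --seed-alignment sim/seed_alignment.afa --out out/
panta evaluate --pred out/loci.tsv --truth sim/
```

## Layout

- `src/panta/genome.py` — genome/feature data model, GFF3/GenBank/FASTA
  I/O, intergenic geometry, neighborhoods
- `src/panta/profile_scan.py` — PSSM construction and scanning, HMMER
  table injection
- `src/panta/clustering.py` — pairwise similarity and flank clustering
- `src/panta/loci.py` — the three pTA criteria, accessory genes, gene
  order, T-numbering
- `src/panta/reciprocity.py` — spurious-partner filtering
- `src/panta/annotate.py` — HTH remodelling, PAD1 discovery, TM segments,
  conservation profiles
- `src/panta/summarize.py` — corpus-level statistics
- `src/panta/simulate.py` — synthetic pangenomes, ground truth, scoring
- `docs/methods.md` — model, assumptions, parameter defaults, limitations
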