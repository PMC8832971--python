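"""Corpus-level descriptive statistics over seed hits and called loci.

The taxon unit for copy-number counting is the species string: where several
genomes share a species, the representative with the most features stands in
for the species (mirroring a one-proteome-per-species corpus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genome import Genome
from .loci import PTALocus, ANTITOXIN_FIRST, TOXIN_FIRST, VERDICT_PTA, VERDICT_SPURIOUS
from .profile_scan import SeedHit

__all__ = [
    "CorpusSummary",
    "representative_genomes",
    "copy_number_table",
    "replicon_localization",
    "order_counts",
    "build_corpus_summary",
    "write_summary_tsv",
    "render_report",
]


@dataclass(frozen=True)
class CorpusSummary:
    n_genomes: int
    n_species: int
    n_seed_hits: int
    copy_number_histogram: dict[int, int] = field(default_factory=dict)
    n_chromosomal: int = 0
    n_plasmid: int = 0
    n_unknown_replicon: int = 0
    n_antitoxin_first: int = 0
    n_toxin_first: int = 0
    n_pta: int = 0
    n_spurious: int = 0
    n_final: int = 0
    n_toxin_clusters: int = 0


def representative_genomes(genomes: Sequence[Genome]) -> dict[str, Genome]:
    """species -> representative genome (most features, ties by genome id)."""
    best: dict[str, Genome] = {}
    for g in sorted(genomes, key=lambda g: g.genome_id):
        cur = best.get(g.species)
        if cur is None or len(g.features) > len(cur.features):
            best[g.species] = g
    return best


def copy_number_table(
    genomes: Sequence[Genome], seed_hits: Sequence[SeedHit]
) -> dict[int, int]:
    """Histogram: seed homologs per taxon -> number of taxa.

    Counted on one representative genome per species; species without hits
    are absent from the histogram.
    """
    hits_per_genome: dict[str, int] = {}
    for h in seed_hits:
        hits_per_genome[h.genome_id] = hits_per_genome.get(h.genome_id, 0) + 1
    hist: dict[int, int] = {}
    for _species, genome in sorted(representative_genomes(genomes).items()):
        n = hits_per_genome.get(genome.genome_id, 0)
        if n > 0:
            hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


def replicon_localization(
    genomes: Sequence[Genome], seed_hits: Sequence[SeedHit]
) -> tuple[int, int, int]:
    """(chromosomal, plasmid, other/unknown) seed-gene counts.

    Restricted to genomes flagged complete, where replicon assignment is
    meaningful; phage and unknown replicons fall in the third bucket.
    """
    genome_by_id = {g.genome_id: g for g in genomes}
    n_chr = n_pla = n_unk = 0
    for h in seed_hits:
        genome = genome_by_id.get(h.genome_id)
        if genome is None or not genome.is_complete:
            continue
        for f in genome.features:
            if f.protein_id != h.protein_id:
                continue
            kind = genome.replicon(f.replicon_id).kind
            if kind == "chromosome":
                n_chr += 1
            elif kind == "plasmid":
                n_pla += 1
            else:
                n_unk += 1
    return n_chr, n_pla, n_unk


def order_counts(loci: Sequence[PTALocus]) -> tuple[int, int]:
    """(antitoxin_first, toxin_first) tallies over final pTA loci."""
    n_af = sum(
        1 for l in loci if l.verdict == VERDICT_PTA and l.order == ANTITOXIN_FIRST
    )
    n_tf = sum(1 for l in loci if l.verdict == VERDICT_PTA and l.order == TOXIN_FIRST)
    return n_af, n_tf


def build_corpus_summary(
    genomes: Sequence[Genome],
    seed_hits: Sequence[SeedHit],
    loci: Sequence[PTALocus],
    t_ids: Mapping[int, str],
) -> CorpusSummary:
    n_af, n_tf = order_counts(loci)
    n_chr, n_pla, n_unk = replicon_localization(genomes, seed_hits)
    n_spurious = sum(1 for l in loci if l.verdict == VERDICT_SPURIOUS)
    n_final = sum(1 for l in loci if l.verdict == VERDICT_PTA)
    return CorpusSummary(
        n_genomes=len(genomes),
        n_species=len({g.species for g in genomes}),
        n_seed_hits=len(seed_hits),
        copy_number_histogram=copy_number_table(genomes, seed_hits),
        n_chromosomal=n_chr,
        n_plasmid=n_pla,
        n_unknown_replicon=n_unk,
        n_antitoxin_first=n_af,
        n_toxin_first=n_tf,
        n_pta=n_final + n_spurious,
        n_spurious=n_spurious,
        n_final=n_final,
        n_toxin_clusters=len(t_ids),
    )


def write_summary_tsv(summary: CorpusSummary, path) -> None:
    rows = [
        ("n_genomes", summary.n_genomes),
        ("n_species", summary.n_species),
        ("n_seed_hits", summary.n_seed_hits),
        ("n_chromosomal", summary.n_chromosomal),
        ("n_plasmid", summary.n_plasmid),
        ("n_unknown_replicon", summary.n_unknown_replicon),
        ("n_antitoxin_first", summary.n_antitoxin_first),
        ("n_toxin_first", summary.n_toxin_first),
        ("n_pta", summary.n_pta),
        ("n_spurious", summary.n_spurious),
        ("n_final", summary.n_final),
        ("n_toxin_clusters", summary.n_toxin_clusters),
    ]
    with open(path, "w") as fh:
        fh.write("quantity\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")
        for copies, taxa in summary.copy_number_histogram.items():
            fh.write(f"copy_number_{copies}\t{taxa}\n")


def render_report(summary: CorpusSummary) -> str:
    lines = [
        f"Corpus: {summary.n_genomes} genomes, {summary.n_species} species",
        f"Seed-domain proteins: {summary.n_seed_hits}",
        "Copy number (homologs per taxon): "
        + (
            ", ".join(
                f"{taxa} taxa with {copies}"
                for copies, taxa in summary.copy_number_histogram.items()
            )
            or "none"
        ),
        f"Replicon localization (complete genomes): "
        f"{summary.n_chromosomal} chromosomal, {summary.n_plasmid} plasmid, "
        f"{summary.n_unknown_replicon} other",
        f"pTA loci: {summary.n_pta} preliminary, {summary.n_spurious} removed as "
        f"spurious, {summary.n_final} final in {summary.n_toxin_clusters} toxin clusters",
        f"Gene order: antitoxin first {summary.n_antitoxin_first} vs "
        f"toxin first {summary.n_toxin_first}",
    ]
    return "\n".join(lines) + "\n"
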