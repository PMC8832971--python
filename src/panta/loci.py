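"""Calling putative toxin-antitoxin (pTA) loci from seed neighborhoods.

A candidate locus is a seed-domain (antitoxin) gene plus an immediately
adjacent, co-oriented gene within ``max_gap_nt`` (default 100 nt).  A
candidate is accepted as a pTA locus when

1. the gap between the two genes is at most ``max_gap_nt``,
2. the same architecture — the same partner homology cluster on the same
   transcriptional side of the seed — is conserved in at least
   ``min_species`` distinct species, and
3. the conserved gene neighborhood does not suggest an operon longer than
   ``max_operon_genes`` (default 3) genes.

A conserved chain of exactly three genes marks the third gene as an
accessory candidate rather than rejecting the locus.  Co-orientation is
required because these are operonic loci; a config flag relaxes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .genome import GeneFeature, Genome, intergenic_distance

__all__ = [
    "PTALocus",
    "ToxinClusterSummary",
    "classify_order",
    "call_candidate_pairs",
    "filter_conserved",
    "filter_operon_length",
    "detect_accessory",
    "assign_toxin_cluster_ids",
    "toxin_cluster_summaries",
]

ANTITOXIN_FIRST = "antitoxin_first"
TOXIN_FIRST = "toxin_first"

VERDICT_CANDIDATE = "candidate"
VERDICT_PTA = "pTA"
VERDICT_SPURIOUS = "spurious_partner"
VERDICT_REJECTED_OPERON = "rejected_operon_length"
VERDICT_REJECTED_SUPPORT = "rejected_support"


@dataclass(frozen=True)
class PTALocus:
    """A called antitoxin-partner pair in one genome."""

    genome_id: str
    species: str
    antitoxin: GeneFeature
    partner: GeneFeature
    gap_nt: int
    order: str
    partner_cluster: int
    support_species: int = 0
    accessory: tuple[GeneFeature, int] | None = None
    verdict: str = VERDICT_CANDIDATE

    @property
    def architecture(self) -> tuple[int, str]:
        """Conservation unit: (partner cluster, transcriptional side)."""
        return (self.partner_cluster, self.order)


@dataclass(frozen=True)
class ToxinClusterSummary:
    t_id: str
    cluster_id: int
    member_count: int
    n_genomes: int
    n_species: int
    example_protein_id: str


def classify_order(antitoxin: GeneFeature, partner: GeneFeature) -> str:
    """Which gene is transcribed first, on either strand.

    On '+' the upstream gene has the smaller start; on '-' the larger.
    """
    if antitoxin.strand != partner.strand:
        raise ValueError(
            "gene order is undefined for genes on different strands "
            f"({antitoxin.feature_id} vs {partner.feature_id})"
        )
    if antitoxin.strand == "+":
        return ANTITOXIN_FIRST if antitoxin.start_nt < partner.start_nt else TOXIN_FIRST
    return ANTITOXIN_FIRST if antitoxin.start_nt > partner.start_nt else TOXIN_FIRST


def seed_features(
    genome: Genome, seed_proteins: frozenset[str] | set[str]
) -> list[GeneFeature]:
    return [f for f in genome.features if f.protein_id in seed_proteins]


def call_candidate_pairs(
    genomes: Sequence[Genome],
    seed_proteins: set[str] | frozenset[str],
    cluster_of: Mapping[str, int],
    max_gap_nt: int = 100,
    *,
    require_same_strand: bool = True,
) -> list[PTALocus]:
    """Unfiltered candidate pairs: seed gene + rank-adjacent partner.

    Each seed may yield up to two candidates (one per side).  Adjacent genes
    that are themselves seed genes, or that carry no homology cluster, are
    skipped.
    """
    loci: list[PTALocus] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for seed in seed_features(genome, seed_proteins):
            feats = genome.features_on(seed.replicon_id)
            for neighbor_rank in (seed.rank - 1, seed.rank + 1):
                if not (0 <= neighbor_rank < len(feats)):
                    continue
                partner = feats[neighbor_rank]
                if partner.protein_id in seed_proteins:
                    continue
                if require_same_strand and partner.strand != seed.strand:
                    continue
                gap = intergenic_distance(seed, partner)
                if gap > max_gap_nt:
                    continue
                cluster = cluster_of.get(partner.protein_id)
                if cluster is None:
                    continue
                # order is undefined for anti-parallel pairs (relaxed mode only)
                order = (
                    classify_order(seed, partner)
                    if partner.strand == seed.strand
                    else "mixed_strand"
                )
                loci.append(
                    PTALocus(
                        genome_id=genome.genome_id,
                        species=genome.species,
                        antitoxin=seed,
                        partner=partner,
                        gap_nt=gap,
                        order=order,
                        partner_cluster=cluster,
                    )
                )
    loci.sort(key=lambda l: (l.genome_id, l.antitoxin.feature_id, l.partner.feature_id))
    return loci


def filter_conserved(
    candidates: Sequence[PTALocus], min_species: int = 2
) -> list[PTALocus]:
    """Keep architectures seen in >= min_species distinct species.

    The architecture is (partner cluster, transcriptional side of the seed):
    the same partner cluster observed antitoxin-first in one species and
    toxin-first in another counts as two independent architectures.
    """
    support: dict[tuple[int, str], set[str]] = {}
    for loc in candidates:
        support.setdefault(loc.architecture, set()).add(loc.species)
    out = []
    for loc in candidates:
        n = len(support[loc.architecture])
        verdict = loc.verdict if n >= min_species else VERDICT_REJECTED_SUPPORT
        out.append(replace(loc, support_species=n, verdict=verdict))
    return out


def _operon_chain(
    genome: Genome, loc: PTALocus, max_gap_nt: int
) -> list[GeneFeature]:
    """Genes chained to the pair by same-strand gaps <= max_gap_nt."""
    feats = genome.features_on(loc.antitoxin.replicon_id)
    strand = loc.antitoxin.strand
    lo = min(loc.antitoxin.rank, loc.partner.rank)
    hi = max(loc.antitoxin.rank, loc.partner.rank)
    chain = list(feats[lo : hi + 1])
    rank = lo - 1
    while rank >= 0:
        gene = feats[rank]
        if gene.strand != strand or intergenic_distance(gene, chain[0]) > max_gap_nt:
            break
        chain.insert(0, gene)
        rank -= 1
    rank = hi + 1
    while rank < len(feats):
        gene = feats[rank]
        if gene.strand != strand or intergenic_distance(chain[-1], gene) > max_gap_nt:
            break
        chain.append(gene)
        rank += 1
    return chain


def filter_operon_length(
    candidates: Sequence[PTALocus],
    genomes: Sequence[Genome],
    cluster_of: Mapping[str, int],
    max_gap_nt: int = 100,
    max_operon_genes: int = 3,
    min_species: int = 2,
) -> list[PTALocus]:
    """Reject pairs whose conserved operonic context exceeds 3 genes.

    Walk outward from the pair chaining same-strand genes with gaps <=
    ``max_gap_nt``.  A chained gene is conserved when its homology cluster
    co-occurs with the pair's architecture in >= ``min_species`` species.  A
    conserved chain longer than ``max_operon_genes`` rejects the pair; a
    chain of exactly three records the third gene as an accessory candidate.
    Chained genes without a cluster assignment (outside all neighborhoods)
    are treated as non-conserved.
    """
    genome_by_id = {g.genome_id: g for g in genomes}
    pair_ids: dict[int, set[str]] = {}
    extras: list[list[tuple[GeneFeature, int | None]]] = []
    for i, loc in enumerate(candidates):
        pair_ids[i] = {loc.antitoxin.feature_id, loc.partner.feature_id}
        if loc.verdict != VERDICT_CANDIDATE:
            extras.append([])
            continue
        chain = _operon_chain(genome_by_id[loc.genome_id], loc, max_gap_nt)
        extras.append(
            [
                (g, cluster_of.get(g.protein_id))
                for g in chain
                if g.feature_id not in pair_ids[i]
            ]
        )

    # cluster co-occurrence with each architecture, counted in species
    co_support: dict[tuple[tuple[int, str], int], set[str]] = {}
    for loc, chain_extras in zip(candidates, extras):
        for _gene, cluster in chain_extras:
            if cluster is not None:
                co_support.setdefault((loc.architecture, cluster), set()).add(loc.species)

    out = []
    for loc, chain_extras in zip(candidates, extras):
        if loc.verdict != VERDICT_CANDIDATE:
            out.append(loc)
            continue
        conserved = [
            (gene, cluster)
            for gene, cluster in chain_extras
            if cluster is not None
            and len(co_support[(loc.architecture, cluster)]) >= min_species
        ]
        total = 2 + len(conserved)
        if total > max_operon_genes:
            out.append(replace(loc, verdict=VERDICT_REJECTED_OPERON))
        elif total == 3:
            gene, cluster = conserved[0]
            out.append(
                replace(loc, verdict=VERDICT_PTA, accessory=(gene, int(cluster)))
            )
        else:
            out.append(replace(loc, verdict=VERDICT_PTA))
    return out


def assign_toxin_cluster_ids(loci: Sequence[PTALocus]) -> dict[int, str]:
    """Deterministic T-numbering of partner (toxin) clusters.

    T1, T2, ... by descending number of distinct partner proteins in final
    loci; ties broken by the lexicographically smallest partner protein id.
    """
    members: dict[int, set[str]] = {}
    for loc in loci:
        if loc.verdict == VERDICT_PTA:
            members.setdefault(loc.partner_cluster, set()).add(loc.partner.protein_id)
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    return {cluster: f"T{i}" for i, (cluster, _m) in enumerate(ordered, start=1)}


def toxin_cluster_summaries(
    loci: Sequence[PTALocus], t_ids: Mapping[int, str]
) -> list[ToxinClusterSummary]:
    rows = []
    by_cluster: dict[int, list[PTALocus]] = {}
    for loc in loci:
        if loc.verdict == VERDICT_PTA:
            by_cluster.setdefault(loc.partner_cluster, []).append(loc)
    for cluster, group in by_cluster.items():
        proteins = {l.partner.protein_id for l in group}
        rows.append(
            ToxinClusterSummary(
                t_id=t_ids[cluster],
                cluster_id=cluster,
                member_count=len(proteins),
                n_genomes=len({l.genome_id for l in group}),
                n_species=len({l.species for l in group}),
                example_protein_id=min(proteins),
            )
        )
    rows.sort(key=lambda r: int(r.t_id[1:]))
    return rows


def detect_accessory(
    loci: Sequence[PTALocus], t_ids: Mapping[int, str]
) -> list[tuple[str, int, int]]:
    """Aggregate accessory third genes per toxin cluster.

    Returns (t_id, accessory cluster id, number of species carrying the
    accessory) rows, one per (toxin cluster, accessory cluster) combination.
    """
    acc: dict[tuple[str, int], set[str]] = {}
    for loc in loci:
        if loc.verdict == VERDICT_PTA and loc.accessory is not None:
            t_id = t_ids[loc.partner_cluster]
            acc.setdefault((t_id, loc.accessory[1]), set()).add(loc.species)
    rows = [
        (t_id, cluster, len(species)) for (t_id, cluster), species in acc.items()
    ]
    rows.sort(key=lambda r: (int(r[0][1:]), r[1]))
    return rows
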