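"""Reciprocal genomic-context filter for spurious partner clusters.

Some gene families — transposases, integrases, well-conserved ATPases — sit
next to seed-domain genes in a handful of genomes purely because they are
mobile or ubiquitous, and would otherwise be called toxins.  The filter asks
the reciprocal question: across ALL proteomes, how often do a putative
partner family's homologs actually sit in an operon with a seed-domain gene?
A genuine cognate partner is seed-adjacent essentially everywhere it occurs;
a mobile-element family is seed-adjacent only occasionally.

``context_fraction`` is the fraction of the representative member's best
corpus-wide homologs (plus the representative itself) that are operonically
linked to a seed gene — linked meaning reachable through a chain of
same-strand adjacencies, each gap <= ``max_gap_nt``, within the operon-length
limit.  Clusters below ``min_context_fraction`` are flagged spurious.  A
cluster whose only detectable homologs are its own members is retained: it
cannot be convicted on absence of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .clustering import FlankCluster, ProteinRecord, candidate_pair, pairwise_similarity
from .genome import Genome, intergenic_distance

__all__ = [
    "ReciprocityVerdict",
    "seed_context_proteins",
    "reciprocal_context_test",
    "run_reciprocity",
    "annotate_spurious_classes",
    "write_verdicts_tsv",
]

STATUS_RETAINED = "retained"
STATUS_SPURIOUS = "spurious"


@dataclass(frozen=True)
class ReciprocityVerdict:
    cluster_id: int
    status: str
    context_fraction: float
    n_homologs_examined: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.context_fraction <= 1.0):
            raise ValueError("context_fraction must lie in [0, 1]")


def seed_context_proteins(
    genomes: Sequence[Genome],
    seed_proteins: set[str] | frozenset[str],
    max_gap_nt: int = 100,
    max_operon_genes: int = 3,
) -> frozenset[str]:
    """Protein ids of genes operonically linked to a seed-domain gene.

    Includes the seed genes themselves and any gene reachable from a seed
    through at most ``max_operon_genes - 1`` same-strand adjacencies with
    gaps <= ``max_gap_nt``.
    """
    linked: set[str] = set()
    for genome in genomes:
        for replicon in genome.replicons:
            feats = genome.features_on(replicon.replicon_id)
            for i, seed in enumerate(feats):
                if seed.protein_id not in seed_proteins:
                    continue
                linked.add(seed.protein_id)
                for step in (-1, 1):
                    prev = seed
                    j = i + step
                    hops = 0
                    while 0 <= j < len(feats) and hops < max_operon_genes - 1:
                        gene = feats[j]
                        pair = (gene, prev) if step == -1 else (prev, gene)
                        if (
                            gene.strand != seed.strand
                            or intergenic_distance(*pair) > max_gap_nt
                        ):
                            break
                        linked.add(gene.protein_id)
                        prev = gene
                        j += step
                        hops += 1
    return frozenset(linked)


def reciprocal_context_test(
    cluster: FlankCluster,
    corpus_proteins: Mapping[str, ProteinRecord],
    seed_context: frozenset[str] | set[str],
    *,
    min_identity: float = 0.3,
    min_coverage: float = 0.6,
    min_context_fraction: float = 0.5,
    top_n: int = 20,
    min_length_ratio: float | None = 0.5,
    max_edit_fraction: float | None = 0.6,
) -> ReciprocityVerdict:
    """Context-reciprocity verdict for one partner cluster.

    The representative member (longest sequence, ties by lexicographically
    smallest protein id) is searched against every corpus protein; hits
    passing the clustering thresholds are ranked by alignment score (ties by
    protein id) and the best ``top_n`` kept.
    """
    member_ids = cluster.protein_ids
    rep_id = min(
        member_ids,
        key=lambda pid: (-len(corpus_proteins[pid].seq), pid),
    )
    rep_seq = corpus_proteins[rep_id].seq

    scored: list[tuple[float, str]] = []
    for pid in sorted(corpus_proteins):
        if pid == rep_id:
            continue
        seq = corpus_proteins[pid].seq
        if not candidate_pair(
            rep_seq,
            seq,
            min_length_ratio=min_length_ratio,
            max_edit_fraction=max_edit_fraction,
        ):
            continue
        edge = pairwise_similarity(rep_seq, seq, id_a=rep_id, id_b=pid)
        if edge.identity >= min_identity and edge.coverage >= min_coverage:
            scored.append((edge.score, pid))
    scored.sort(key=lambda t: (-t[0], t[1]))
    homologs = [pid for _score, pid in scored[:top_n]]

    examined = homologs + [rep_id]
    n_adjacent = sum(1 for pid in examined if pid in seed_context)
    fraction = n_adjacent / len(examined)
    outside = [pid for pid in homologs if pid not in member_ids]
    if not outside:
        return ReciprocityVerdict(
            cluster_id=cluster.cluster_id,
            status=STATUS_RETAINED,
            context_fraction=fraction,
            n_homologs_examined=cluster.size,
        )
    status = STATUS_SPURIOUS if fraction < min_context_fraction else STATUS_RETAINED
    return ReciprocityVerdict(
        cluster_id=cluster.cluster_id,
        status=status,
        context_fraction=fraction,
        n_homologs_examined=len(examined),
    )


def run_reciprocity(
    clusters: Iterable[FlankCluster],
    corpus_proteins: Mapping[str, ProteinRecord],
    seed_context: frozenset[str] | set[str],
    **kwargs,
) -> dict[int, ReciprocityVerdict]:
    out = {}
    for cluster in sorted(clusters, key=lambda c: c.cluster_id):
        out[cluster.cluster_id] = reciprocal_context_test(
            cluster, corpus_proteins, seed_context, **kwargs
        )
    return out


def annotate_spurious_classes(
    verdicts: Mapping[int, ReciprocityVerdict],
    cluster_products: Mapping[int, str],
    keywords: Sequence[str] = ("transposase", "integrase", "ATPase"),
) -> dict[str, dict[str, int]]:
    """Product-keyword tallies among spurious vs retained clusters.

    Case-insensitive substring matching; purely diagnostic — annotations
    never feed back into the filter, because product strings are unreliable.
    """
    tally: dict[str, dict[str, int]] = {}
    lowered = [(kw, kw.lower()) for kw in keywords]
    for cid in sorted(verdicts):
        status = verdicts[cid].status
        product = (cluster_products.get(cid) or "").lower()
        bucket = tally.setdefault(status, {})
        matched = False
        for kw, kw_lower in lowered:
            if kw_lower in product:
                bucket[kw] = bucket.get(kw, 0) + 1
                matched = True
                break
        if not matched:
            bucket["other"] = bucket.get("other", 0) + 1
    return tally


def write_verdicts_tsv(
    verdicts: Mapping[int, ReciprocityVerdict],
    t_ids: Mapping[int, str],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tt_id\tstatus\tcontext_fraction\tn_homologs_examined\n")
        for cid in sorted(verdicts):
            v = verdicts[cid]
            fh.write(
                f"{cid}\t{t_ids.get(cid, '')}\t{v.status}\t"
                f"{v.context_fraction:.4f}\t{v.n_homologs_examined}\n"
            )
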