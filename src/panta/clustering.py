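"""Homology clustering of flanking proteins across genomes.

Mirrors the FlaGs step of neighborhood analysis in a simplified, fully
deterministic form: all-vs-all global alignment (BLOSUM62, affine gaps)
followed by single-linkage connected components over edges that pass
identity and coverage thresholds.  Single linkage is the natural analogue of
iterative profile search, which is transitive by construction; the usual
chaining caveat applies and is documented in the methods note.

Two prefilters bound the all-vs-all cost: pairs whose length ratio is below
``min_length_ratio`` are skipped outright, and pairs whose edit distance
(edlib) exceeds ``max_edit_fraction`` of the shorter length are skipped
before the expensive scored alignment.  On indel-free synthetic families the
edit-distance cut is loss-free; set ``max_edit_fraction=None`` to recover the
pure threshold semantics.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

__all__ = [
    "ProteinRecord",
    "SimilarityEdge",
    "FlankCluster",
    "pairwise_similarity",
    "cluster_flanks",
    "cluster_map",
    "write_clusters_tsv",
    "similarity_graph_dot",
]


class ProteinRecord(NamedTuple):
    protein_id: str
    genome_id: str
    species: str
    seq: str


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity between two proteins (ids in canonical order)."""

    protein_a: str
    protein_b: str
    score: float
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


@dataclass(frozen=True)
class FlankCluster:
    """A homologous family of flanking proteins with a stable integer id."""

    cluster_id: int
    members: tuple[tuple[str, str], ...]  # (protein_id, genome_id), sorted
    n_species: int

    @property
    def protein_ids(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


@functools.lru_cache(maxsize=1)
def _aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_BLOSUM_OK = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


def _sanitize(seq: str) -> str:
    s = seq.upper()
    if all(c in _BLOSUM_OK for c in s):
        return s
    return "".join(c if c in _BLOSUM_OK else "X" for c in s)


def pairwise_similarity(
    a: str, b: str, *, id_a: str = "a", id_b: str = "b"
) -> SimilarityEdge:
    """Global alignment statistics between two protein sequences.

    identity = identical aligned pairs / alignment columns excluding terminal
    gaps; coverage = columns where both sequences have a residue / length of
    the shorter sequence.  Gap of length g scores -(11 + (g - 1)).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sa, sb = _sanitize(a), _sanitize(b)
    aligner = _aligner()
    aln = aligner.align(sa, sb)[0]
    blocks_a, blocks_b = aln.aligned
    if id_b < id_a:
        id_a, id_b = id_b, id_a
    if len(blocks_a) == 0:
        return SimilarityEdge(id_a, id_b, float(aln.score), 0.0, 0.0)
    aligned_pairs = int(sum(e - s for s, e in blocks_a))
    matches = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        matches += sum(1 for x, y in zip(sa[s1:e1], sb[s2:e2]) if x == y)
    core = (int(blocks_a[-1][1]) - int(blocks_a[0][0])) + (
        int(blocks_b[-1][1]) - int(blocks_b[0][0])
    ) - aligned_pairs
    identity = matches / core if core else 0.0
    coverage = aligned_pairs / min(len(sa), len(sb))
    return SimilarityEdge(id_a, id_b, float(aln.score), identity, min(coverage, 1.0))


def _edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, task="distance")["editDistance"]


def candidate_pair(
    a: str,
    b: str,
    *,
    min_length_ratio: float | None = 0.5,
    max_edit_fraction: float | None = 0.6,
) -> bool:
    """Cheap prefilter: could (a, b) plausibly pass the edge thresholds?"""
    la, lb = len(a), len(b)
    if min_length_ratio is not None and min(la, lb) < min_length_ratio * max(la, lb):
        return False
    if max_edit_fraction is not None:
        if _edit_distance(a, b) > max_edit_fraction * min(la, lb):
            return False
    return True


def cluster_flanks(
    records: Sequence[ProteinRecord],
    min_identity: float = 0.3,
    min_coverage: float = 0.6,
    *,
    min_length_ratio: float | None = 0.5,
    max_edit_fraction: float | None = 0.6,
) -> list[FlankCluster]:
    """Single-linkage homology clusters over a set of proteins.

    Edges require ``identity >= min_identity`` and ``coverage >=
    min_coverage``; clusters are connected components.  Cluster ids are
    assigned by descending member count, ties broken by the lexicographically
    smallest member protein id, so the partition and the ids are invariant
    under permutation of the input.
    """
    if not records:
        raise ValueError("no proteins to cluster")
    import networkx as nx

    by_id: dict[str, ProteinRecord] = {}
    for rec in records:
        by_id.setdefault(rec.protein_id, rec)
    ids = sorted(by_id)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, pid_a in enumerate(ids):
        seq_a = by_id[pid_a].seq
        for pid_b in ids[i + 1 :]:
            seq_b = by_id[pid_b].seq
            if not candidate_pair(
                seq_a,
                seq_b,
                min_length_ratio=min_length_ratio,
                max_edit_fraction=max_edit_fraction,
            ):
                continue
            edge = pairwise_similarity(seq_a, seq_b, id_a=pid_a, id_b=pid_b)
            if edge.identity >= min_identity and edge.coverage >= min_coverage:
                graph.add_edge(pid_a, pid_b)

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for cid, comp in enumerate(components, start=1):
        members = tuple(sorted((pid, by_id[pid].genome_id) for pid in comp))
        n_species = len({by_id[pid].species for pid in comp})
        clusters.append(FlankCluster(cluster_id=cid, members=members, n_species=n_species))
    return clusters


def cluster_map(clusters: Sequence[FlankCluster]) -> dict[str, int]:
    """protein_id -> cluster_id lookup."""
    out: dict[str, int] = {}
    for cl in clusters:
        for pid, _gid in cl.members:
            out[pid] = cl.cluster_id
    return out


def write_clusters_tsv(
    clusters: Sequence[FlankCluster],
    species_of_genome: Mapping[str, str],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tprotein_id\tgenome_id\tspecies\n")
        for cl in clusters:
            for pid, gid in cl.members:
                fh.write(
                    f"{cl.cluster_id}\t{pid}\t{gid}\t{species_of_genome.get(gid, '')}\n"
                )


def similarity_graph_dot(edges: Sequence[SimilarityEdge]) -> str:
    """Render similarity edges as a DOT graph (diagnostic export)."""
    lines = ["graph similarity {"]
    for e in sorted(edges, key=lambda e: (e.protein_a, e.protein_b)):
        lines.append(
            f'  "{e.protein_a}" -- "{e.protein_b}" [label="{e.identity:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
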