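"""End-to-end orchestration: corpus -> seed hits -> clusters -> loci -> report.

The pipeline is a thin, deterministic composition of the per-stage library
functions; every stage's output is exposed on the result object and written
as TSV, and all orderings are canonical so that equal inputs give
byte-identical outputs regardless of input file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import (
    conservation_profile,
    discover_conserved_extensions,
    extract_nterm_extensions,
    predict_tm_segments,
    remodel_and_detect_hth,
)
from .clustering import (
    FlankCluster,
    ProteinRecord,
    cluster_flanks,
    cluster_map,
    write_clusters_tsv,
)
from .genome import Genome, neighborhood, read_genome, read_metadata_tsv
from .loci import (
    PTALocus,
    VERDICT_PTA,
    VERDICT_SPURIOUS,
    assign_toxin_cluster_ids,
    call_candidate_pairs,
    detect_accessory,
    filter_conserved,
    filter_operon_length,
    toxin_cluster_summaries,
)
from .profile_scan import ProfileModel, SeedHit, scan_proteins, write_hits_tsv
from .reciprocity import (
    annotate_spurious_classes,
    run_reciprocity,
    seed_context_proteins,
    write_verdicts_tsv,
)
from .summarize import build_corpus_summary, render_report, write_summary_tsv

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_corpus"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the locus-mining pipeline."""

    neighborhood_k: int = 4  # genes per side around each seed
    max_gap_nt: int = 100  # operon gap criterion
    min_species: int = 2  # conservation criterion
    max_operon_genes: int = 3  # longest allowed conserved architecture
    require_same_strand: bool = True
    min_identity: float = 0.3
    min_coverage: float = 0.6
    min_length_ratio: float | None = 0.5
    max_edit_fraction: float | None = 0.6
    min_context_fraction: float = 0.5  # reciprocity threshold
    top_n_homologs: int = 20
    ext_min_len: int = 40  # N-terminal extension minimum
    tm_window: int = 19
    tm_threshold: float = 1.6
    pad1_min_members: int = 5
    pad1_min_species: int = 2


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: tuple[Genome, ...]
    seed_hits: tuple[SeedHit, ...]
    clusters: tuple[FlankCluster, ...]
    cluster_of: dict[str, int]
    loci: tuple[PTALocus, ...]
    reciprocity: dict
    tested_cluster_members: dict[int, frozenset]
    t_ids: dict[int, str]
    accessory_rows: list[tuple[str, int, int]]
    annotations: pd.DataFrame
    seed_conservation: object = None
    summary: object = None
    spurious_classes: dict = field(default_factory=dict)

    def loci_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            rows.append(
                {
                    "genome_id": l.genome_id,
                    "species": l.species,
                    "antitoxin_feature": l.antitoxin.feature_id,
                    "antitoxin_protein": l.antitoxin.protein_id,
                    "partner_feature": l.partner.feature_id,
                    "partner_protein": l.partner.protein_id,
                    "t_id": self.t_ids.get(l.partner_cluster, ""),
                    "partner_cluster": l.partner_cluster,
                    "gap_nt": l.gap_nt,
                    "order": l.order,
                    "support_species": l.support_species,
                    "accessory_feature": l.accessory[0].feature_id if l.accessory else "",
                    "accessory_cluster": l.accessory[1] if l.accessory else 0,
                    "verdict": l.verdict,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "genome_id", "species", "antitoxin_feature", "antitoxin_protein",
                "partner_feature", "partner_protein", "t_id", "partner_cluster",
                "gap_nt", "order", "support_species", "accessory_feature",
                "accessory_cluster", "verdict",
            ],
        )
        return frame.sort_values(
            ["genome_id", "antitoxin_feature", "partner_feature"],
            kind="mergesort",
            ignore_index=True,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        species_of = {g.genome_id: g.species for g in self.genomes}
        write_hits_tsv(self.seed_hits, outdir / "seed_hits.tsv")
        write_clusters_tsv(self.clusters, species_of, outdir / "clusters.tsv")
        self.loci_frame().to_csv(outdir / "loci.tsv", sep="\t", index=False)
        write_verdicts_tsv(self.reciprocity, self.t_ids, outdir / "reciprocity.tsv")
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        with open(outdir / "accessory.tsv", "w") as fh:
            fh.write("t_id\taccessory_cluster\tn_species_with_accessory\n")
            for t_id, cluster, n in self.accessory_rows:
                fh.write(f"{t_id}\t{cluster}\t{n}\n")
        with open(outdir / "toxin_clusters.tsv", "w") as fh:
            fh.write("t_id\tcluster_id\tmember_count\tn_genomes\tn_species\texample_protein_id\n")
            for s in toxin_cluster_summaries(self.loci, self.t_ids):
                fh.write(
                    f"{s.t_id}\t{s.cluster_id}\t{s.member_count}\t{s.n_genomes}\t"
                    f"{s.n_species}\t{s.example_protein_id}\n"
                )
        if self.seed_conservation is not None:
            with open(outdir / "seed_conservation.tsv", "w") as fh:
                fh.write("column\tscore\toccupancy\n")
                for i, (s, o) in enumerate(
                    zip(self.seed_conservation.scores, self.seed_conservation.occupancy),
                    start=1,
                ):
                    fh.write(f"{i}\t{s:.6f}\t{o:.4f}\n")
        write_summary_tsv(self.summary, outdir / "summary.tsv")
        (outdir / "report.txt").write_text(render_report(self.summary))


def load_corpus(indir: str | Path) -> list[Genome]:
    """Load every genome listed in ``metadata.tsv`` from a corpus directory."""
    indir = Path(indir)
    metadata = read_metadata_tsv(indir / "metadata.tsv")
    genomes = []
    for gid in sorted(metadata):
        genomes.append(
            read_genome(
                indir / f"{gid}.gff3",
                indir / f"{gid}.faa",
                genome_id=gid,
                metadata=metadata[gid],
            )
        )
    return genomes


def _corpus_proteins(genomes: Sequence[Genome]) -> dict[str, ProteinRecord]:
    out: dict[str, ProteinRecord] = {}
    for g in genomes:
        for f in g.features:
            out.setdefault(
                f.protein_id,
                ProteinRecord(f.protein_id, g.genome_id, g.species, f.aa_seq),
            )
    return out


def run_pipeline(
    genomes: Sequence[Genome],
    profile: ProfileModel | None = None,
    *,
    seed_hits: Sequence[SeedHit] | None = None,
    hth_profile: ProfileModel | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full locus-mining pipeline over a genome corpus.

    Seed hits come either from scanning every protein with ``profile`` or
    from an injected ``seed_hits`` list (e.g. parsed HMMER output); exactly
    one of the two must be provided.
    """
    if (profile is None) == (seed_hits is None):
        raise ValueError("provide either a profile to scan with or injected seed hits")
    genomes = tuple(sorted(genomes, key=lambda g: g.genome_id))
    proteins = _corpus_proteins(genomes)

    if seed_hits is None:
        records = [
            (f.protein_id, g.genome_id, f.aa_seq)
            for g in genomes
            for f in g.features
        ]
        seed_hits = scan_proteins(records, profile)
    seed_hits = tuple(
        sorted(seed_hits, key=lambda h: (h.genome_id, h.protein_id))
    )
    seed_proteins = frozenset(h.protein_id for h in seed_hits)

    # flanking proteins of every seed neighborhood
    flank_records: dict[str, ProteinRecord] = {}
    for g in genomes:
        for f in g.features:
            if f.protein_id not in seed_proteins:
                continue
            hood = neighborhood(g, f, config.neighborhood_k)
            for flank in hood.flanks():
                if flank.protein_id in seed_proteins:
                    continue
                flank_records.setdefault(
                    flank.protein_id,
                    ProteinRecord(flank.protein_id, g.genome_id, g.species, flank.aa_seq),
                )

    if flank_records:
        clusters = tuple(
            cluster_flanks(
                [flank_records[p] for p in sorted(flank_records)],
                config.min_identity,
                config.min_coverage,
                min_length_ratio=config.min_length_ratio,
                max_edit_fraction=config.max_edit_fraction,
            )
        )
    else:
        clusters = ()
    cluster_of = cluster_map(clusters)

    loci = call_candidate_pairs(
        genomes,
        seed_proteins,
        cluster_of,
        config.max_gap_nt,
        require_same_strand=config.require_same_strand,
    )
    loci = filter_conserved(loci, config.min_species)
    loci = filter_operon_length(
        loci,
        genomes,
        cluster_of,
        config.max_gap_nt,
        config.max_operon_genes,
        config.min_species,
    )

    # reciprocity filter over partner + accessory clusters of surviving loci
    to_test_ids = sorted(
        {l.partner_cluster for l in loci if l.verdict == VERDICT_PTA}
        | {l.accessory[1] for l in loci if l.verdict == VERDICT_PTA and l.accessory}
    )
    cluster_by_id = {c.cluster_id: c for c in clusters}
    seed_context = seed_context_proteins(
        genomes, seed_proteins, config.max_gap_nt, config.max_operon_genes
    )
    reciprocity = run_reciprocity(
        [cluster_by_id[c] for c in to_test_ids],
        proteins,
        seed_context,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        min_context_fraction=config.min_context_fraction,
        top_n=config.top_n_homologs,
        min_length_ratio=config.min_length_ratio,
        max_edit_fraction=config.max_edit_fraction,
    )
    spurious = {c for c, v in reciprocity.items() if v.status == "spurious"}
    final: list[PTALocus] = []
    for l in loci:
        if l.verdict == VERDICT_PTA and l.partner_cluster in spurious:
            final.append(replace(l, verdict=VERDICT_SPURIOUS))
        elif l.verdict == VERDICT_PTA and l.accessory and l.accessory[1] in spurious:
            final.append(replace(l, accessory=None))
        else:
            final.append(l)
    loci = tuple(final)

    t_ids = assign_toxin_cluster_ids(loci)
    accessory_rows = detect_accessory(loci, t_ids)

    # diagnostics: product keywords among spurious vs retained clusters
    product_of: dict[int, str] = {}
    for cid in to_test_ids:
        members = cluster_by_id[cid].members
        rep_pid = min(p for p, _g in members)
        for g in genomes:
            for f in g.features:
                if f.protein_id == rep_pid:
                    product_of[cid] = f.product
                    break
    spurious_classes = annotate_spurious_classes(reciprocity, product_of)

    # annotations: antitoxin extensions (HTH / PAD1), toxin TM segments
    seqs = {pid: rec.seq for pid, rec in proteins.items()}
    extensions = extract_nterm_extensions(seed_hits, seqs, config.ext_min_len)
    hth_flags: dict[str, bool] = {}
    if hth_profile is not None and extensions:
        _updated, hth_flags = remodel_and_detect_hth(extensions, hth_profile)
    species_of_protein = {pid: rec.species for pid, rec in proteins.items()}
    genome_of_protein = {pid: rec.genome_id for pid, rec in proteins.items()}
    non_hth = [e for e in extensions if not hth_flags.get(e.protein_id, False)]
    pad1_clusters = (
        discover_conserved_extensions(
            non_hth,
            species_of_protein,
            genome_of_protein,
            config.pad1_min_members,
            config.pad1_min_species,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            min_length_ratio=config.min_length_ratio,
            max_edit_fraction=config.max_edit_fraction,
        )
        if non_hth
        else []
    )
    pad1_of: dict[str, int] = {}
    for cl in pad1_clusters:
        for pid, _gid in cl.members:
            pad1_of[pid] = cl.cluster_id

    final_partner_ids = sorted(
        {l.partner.protein_id for l in loci if l.verdict == VERDICT_PTA}
    )
    ann_rows = []
    ext_len_of = {e.protein_id: e.ext_len for e in extensions}
    for h in seed_hits:
        ann_rows.append(
            {
                "protein_id": h.protein_id,
                "genome_id": h.genome_id,
                "role": "antitoxin",
                "ext_len": ext_len_of.get(h.protein_id, 0),
                "hth": bool(hth_flags.get(h.protein_id, False)),
                "pad1_cluster": pad1_of.get(h.protein_id, 0),
                "n_tm_segments": 0,
                "tm_coords": "",
            }
        )
    for pid in final_partner_ids:
        segments = predict_tm_segments(
            seqs[pid], config.tm_window, config.tm_threshold
        )
        ann_rows.append(
            {
                "protein_id": pid,
                "genome_id": genome_of_protein[pid],
                "role": "toxin",
                "ext_len": 0,
                "hth": False,
                "pad1_cluster": 0,
                "n_tm_segments": len(segments),
                "tm_coords": ";".join(f"{s.start_aa}-{s.end_aa}" for s in segments),
            }
        )
    annotations = pd.DataFrame(
        ann_rows,
        columns=[
            "protein_id", "genome_id", "role", "ext_len", "hth",
            "pad1_cluster", "n_tm_segments", "tm_coords",
        ],
    ).sort_values(["role", "protein_id"], kind="mergesort", ignore_index=True)

    # conservation over seed-domain envelopes (equal-length, ungapped)
    seed_conservation = None
    env_lengths = {h.env_end - h.env_start + 1 for h in seed_hits}
    if len(seed_hits) >= 2 and len(env_lengths) == 1:
        envelopes = [
            seqs[h.protein_id][h.env_start - 1 : h.env_end] for h in seed_hits
        ]
        seed_conservation = conservation_profile(envelopes)

    summary = build_corpus_summary(genomes, seed_hits, loci, t_ids)
    tested_members = {
        cid: cluster_by_id[cid].protein_ids for cid in to_test_ids
    }
    return PipelineResult(
        config=config,
        genomes=genomes,
        seed_hits=seed_hits,
        clusters=clusters,
        cluster_of=cluster_of,
        loci=loci,
        reciprocity=reciprocity,
        tested_cluster_members=tested_members,
        t_ids=t_ids,
        accessory_rows=accessory_rows,
        annotations=annotations,
        seed_conservation=seed_conservation,
        summary=summary,
        spurious_classes=spurious_classes,
    )
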