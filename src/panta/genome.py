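"""Data model and I/O for annotated prokaryotic genomes.

A genome is a set of replicons (chromosome / plasmid / phage) carrying CDS
features with 1-based inclusive nucleotide coordinates (GenBank convention;
GFF3 coordinates map directly).  Every feature carries its translated protein
sequence, because all downstream analysis (domain scanning, flank clustering)
is protein-level; the nucleotide sequence itself is never needed, only the
coordinate geometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Replicon",
    "GeneFeature",
    "Genome",
    "GenomeMetadata",
    "LoadReport",
    "Neighborhood",
    "GenomeFormatError",
    "read_genome",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_gff3",
    "write_protein_fasta",
    "intergenic_distance",
    "neighborhood",
    "mirror_genome",
]

REPLICON_KINDS = ("chromosome", "plasmid", "phage", "unknown")


class GenomeFormatError(ValueError):
    """Raised when an annotation or protein file cannot be interpreted."""


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    genome_id: str
    kind: str = "unknown"
    length_nt: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REPLICON_KINDS:
            raise ValueError(f"unknown replicon kind {self.kind!r}")
        if self.length_nt < 1:
            raise ValueError("replicon length must be >= 1")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated protein-coding gene.

    ``start_nt <= end_nt`` regardless of strand; ``rank`` is the 0-based
    index of the gene along its replicon ordered by start coordinate.
    """

    feature_id: str
    replicon_id: str
    start_nt: int
    end_nt: int
    strand: str
    rank: int
    protein_id: str
    product: str = ""
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start_nt <= self.end_nt):
            raise ValueError(
                f"{self.feature_id}: invalid coordinates "
                f"{self.start_nt}..{self.end_nt}"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt + 1


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping for features discarded while loading a genome."""

    n_features: int = 0
    n_dropped_no_translation: int = 0
    dropped_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    species: str
    phylum: str = ""
    superkingdom: str = "bacteria"
    is_complete: bool = True
    replicon_kinds: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Genome:
    genome_id: str
    species: str
    phylum: str = ""
    superkingdom: str = "bacteria"
    is_complete: bool = True
    replicons: tuple[Replicon, ...] = ()
    features: tuple[GeneFeature, ...] = ()
    load_report: LoadReport = field(default=LoadReport(), compare=False)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"{self.genome_id}: species must be non-empty")
        known = {r.replicon_id for r in self.replicons}
        for f in self.features:
            if f.replicon_id not in known:
                raise ValueError(
                    f"{self.genome_id}: feature {f.feature_id} references "
                    f"unknown replicon {f.replicon_id}"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def features_on(self, replicon_id: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.replicon_id == replicon_id)

    def feature(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


@dataclass(frozen=True)
class Neighborhood:
    """A focal gene plus up to k genes either side on the same replicon.

    ``upstream``/``downstream`` refer to the coordinate axis (lower / higher
    start), both ordered by increasing distance from the focal gene.
    Neighborhoods never wrap around or cross replicon (contig) boundaries.
    """

    focal: GeneFeature
    upstream: tuple[GeneFeature, ...]
    downstream: tuple[GeneFeature, ...]

    def flanks(self) -> tuple[GeneFeature, ...]:
        return self.upstream + self.downstream


def build_genome(
    genome_id: str,
    replicons: Iterable[Replicon],
    features: Iterable[GeneFeature],
    metadata: GenomeMetadata | None = None,
    load_report: LoadReport = LoadReport(),
) -> Genome:
    """Assemble a Genome, (re)assigning ranks by start coordinate."""
    ranked: list[GeneFeature] = []
    replicons = tuple(replicons)
    by_replicon: dict[str, list[GeneFeature]] = {r.replicon_id: [] for r in replicons}
    for f in features:
        by_replicon.setdefault(f.replicon_id, []).append(f)
    for rid in sorted(by_replicon):
        feats = sorted(by_replicon[rid], key=lambda f: (f.start_nt, f.end_nt, f.feature_id))
        for rank, f in enumerate(feats):
            ranked.append(replace(f, rank=rank))
    meta = metadata or GenomeMetadata(genome_id=genome_id, species=genome_id)
    return Genome(
        genome_id=genome_id,
        species=meta.species,
        phylum=meta.phylum,
        superkingdom=meta.superkingdom,
        is_complete=meta.is_complete,
        replicons=replicons,
        features=tuple(ranked),
        load_report=load_report,
    )


# ---------------------------------------------------------------------------
# geometry


def intergenic_distance(a: GeneFeature, b: GeneFeature) -> int:
    """Nucleotides strictly between two genes on one replicon.

    Symmetric in its arguments; overlapping or book-ended genes clamp to 0 so
    that the <=100 nt operon criterion is monotone in the gap.
    """
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"features {a.feature_id} and {b.feature_id} are on different replicons"
        )
    if a.feature_id == b.feature_id and a.start_nt == b.start_nt:
        raise ValueError("intergenic distance of a feature with itself is undefined")
    earlier, later = (a, b) if a.start_nt <= b.start_nt else (b, a)
    return max(0, later.start_nt - earlier.end_nt - 1)


def neighborhood(genome: Genome, focal: GeneFeature, k: int) -> Neighborhood:
    """Up to ``k`` genes either side of ``focal`` by rank, truncated at ends."""
    if k < 1:
        raise ValueError("k must be positive")
    feats = genome.features_on(focal.replicon_id)
    if focal.rank >= len(feats) or feats[focal.rank].feature_id != focal.feature_id:
        raise ValueError(f"{focal.feature_id} does not belong to {genome.genome_id}")
    lo = max(0, focal.rank - k)
    upstream = tuple(reversed(feats[lo : focal.rank]))
    downstream = feats[focal.rank + 1 : focal.rank + 1 + k]
    return Neighborhood(focal=focal, upstream=upstream, downstream=downstream)


def mirror_genome(genome: Genome) -> Genome:
    """Reverse-complement the coordinate system of every replicon.

    Coordinates are mirrored (start' = L - end + 1) and strands flipped;
    protein content is untouched.  Pipeline output must be invariant under
    this transformation (strand-flip symmetry).
    """
    mirrored = []
    for f in genome.features:
        length = genome.replicon(f.replicon_id).length_nt
        mirrored.append(
            replace(
                f,
                start_nt=length - f.end_nt + 1,
                end_nt=length - f.start_nt + 1,
                strand="-" if f.strand == "+" else "+",
            )
        )
    meta = GenomeMetadata(
        genome_id=genome.genome_id,
        species=genome.species,
        phylum=genome.phylum,
        superkingdom=genome.superkingdom,
        is_complete=genome.is_complete,
    )
    return build_genome(genome.genome_id, genome.replicons, mirrored, metadata=meta,
                        load_report=genome.load_report)


# ---------------------------------------------------------------------------
# readers


def _read_protein_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            dupes.append(rec.id)
        seqs[rec.id] = str(rec.seq)
    if dupes:
        raise GenomeFormatError(
            f"{path}: duplicate protein ids: {', '.join(sorted(set(dupes)))}"
        )
    return seqs


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
        return "genbank"
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("##gff-version"):
                return "gff3"
            if line.startswith("LOCUS"):
                return "genbank"
            break
    raise GenomeFormatError(f"{path}: cannot determine annotation format")


def _validate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            ncol = len(stripped.split("\t"))
            if ncol != 9:
                raise GenomeFormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {ncol}"
                )


def _parse_gff3(
    path: Path,
) -> tuple[dict[str, int], list[dict]]:
    """Return (replicon lengths from ##sequence-region, raw CDS rows)."""
    import gffutils

    _validate_gff3(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feat.attributes
        fid = (attrs.get("ID") or attrs.get("protein_id") or [None])[0]
        pid = (attrs.get("protein_id") or attrs.get("ID") or [None])[0]
        if fid is None:
            raise GenomeFormatError(
                f"{path}: CDS at {feat.seqid}:{feat.start}..{feat.end} has no "
                "ID or protein_id attribute"
            )
        rows.append(
            dict(
                feature_id=fid,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                protein_id=pid,
                product=(attrs.get("product") or [""])[0],
                translation=None,
            )
        )
    return lengths, rows


def _parse_genbank(path: Path) -> tuple[dict[str, int], list[dict]]:
    from Bio import SeqIO

    lengths: dict[str, int] = {}
    rows = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:  # Biopython reports the offending content
        raise GenomeFormatError(f"{path}: {exc}") from exc
    for rec in records:
        lengths[rec.id] = len(rec.seq)
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            quals = feat.qualifiers
            pid = (quals.get("protein_id") or quals.get("locus_tag") or [None])[0]
            fid = (quals.get("locus_tag") or quals.get("protein_id") or [f"cds{n}"])[0]
            rows.append(
                dict(
                    feature_id=fid,
                    replicon_id=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    protein_id=pid,
                    product=(quals.get("product") or [""])[0],
                    translation=(quals.get("translation") or [None])[0],
                )
            )
    return lengths, rows


def read_genome(
    annotation_path: str | Path,
    proteins_path: str | Path | None = None,
    *,
    genome_id: str | None = None,
    metadata: GenomeMetadata | None = None,
) -> Genome:
    """Load a genome from GFF3 (+ protein FASTA) or a GenBank flat file.

    Every CDS must resolve a protein sequence, either from a ``/translation``
    qualifier (GenBank) or from the FASTA record matching its protein id.
    Features without a translation are dropped, not fatal (real annotations
    contain pseudogenes); the count is recorded on ``genome.load_report``.
    """
    path = Path(annotation_path)
    fmt = _sniff_format(path)
    if fmt == "gff3":
        lengths, rows = _parse_gff3(path)
    else:
        lengths, rows = _parse_genbank(path)

    seqs = _read_protein_fasta(proteins_path) if proteins_path else {}

    gid = genome_id or (metadata.genome_id if metadata else path.stem)
    kinds = dict(metadata.replicon_kinds) if metadata else {}

    features: list[GeneFeature] = []
    dropped: list[str] = []
    max_end: dict[str, int] = {}
    for row in rows:
        aa = row["translation"]
        if aa is None and row["protein_id"] is not None:
            aa = seqs.get(row["protein_id"])
        if not aa:
            dropped.append(row["feature_id"])
            continue
        max_end[row["replicon_id"]] = max(max_end.get(row["replicon_id"], 0), row["end"])
        features.append(
            GeneFeature(
                feature_id=row["feature_id"],
                replicon_id=row["replicon_id"],
                start_nt=row["start"],
                end_nt=row["end"],
                strand=row["strand"],
                rank=0,
                protein_id=row["protein_id"] or row["feature_id"],
                product=row["product"],
                aa_seq=aa,
            )
        )
    replicon_ids = sorted(set(lengths) | set(max_end))
    replicons = tuple(
        Replicon(
            replicon_id=rid,
            genome_id=gid,
            kind=kinds.get(rid, "unknown"),
            length_nt=max(lengths.get(rid, 0), max_end.get(rid, 0)) or 1,
        )
        for rid in replicon_ids
    )
    report = LoadReport(
        n_features=len(features),
        n_dropped_no_translation=len(dropped),
        dropped_ids=tuple(dropped),
    )
    return build_genome(gid, replicons, features, metadata=metadata, load_report=report)


# ---------------------------------------------------------------------------
# writers


def write_gff3(genome: Genome, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for r in genome.replicons:
        buf.write(f"##sequence-region {r.replicon_id} 1 {r.length_nt}\n")
    for f in genome.features:
        attrs = f"ID={f.feature_id};protein_id={f.protein_id};product={f.product}"
        buf.write(
            f"{f.replicon_id}\tpanta\tCDS\t{f.start_nt}\t{f.end_nt}\t.\t"
            f"{f.strand}\t0\t{attrs}\n"
        )
    Path(path).write_text(buf.getvalue())


def write_protein_fasta(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in genome.features:
            fh.write(f">{f.protein_id}\n{f.aa_seq}\n")


# ---------------------------------------------------------------------------
# metadata sidecar


def write_metadata_tsv(genomes: Sequence[Genome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies\tphylum\tsuperkingdom\tis_complete\treplicons\n")
        for g in genomes:
            reps = ";".join(
                f"{r.replicon_id}:{r.kind}:{r.length_nt}" for r in g.replicons
            )
            fh.write(
                f"{g.genome_id}\t{g.species}\t{g.phylum}\t{g.superkingdom}\t"
                f"{int(g.is_complete)}\t{reps}\n"
            )


def read_metadata_tsv(path: str | Path) -> dict[str, GenomeMetadata]:
    import csv

    out: dict[str, GenomeMetadata] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            kinds = {}
            for item in (row.get("replicons") or "").split(";"):
                if item:
                    rid, kind, _length = item.split(":")
                    kinds[rid] = kind
            out[row["genome_id"]] = GenomeMetadata(
                genome_id=row["genome_id"],
                species=row["species"],
                phylum=row.get("phylum", ""),
                superkingdom=row.get("superkingdom", "bacteria"),
                is_complete=bool(int(row.get("is_complete", "1"))),
                replicon_kinds=kinds,
            )
    return out
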