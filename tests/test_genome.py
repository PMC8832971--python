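"""Genome model, readers/writers and intergenic geometry."""

import pytest
from hypothesis import given, settings, strategies as st

from panta.genome import (
    GenomeFormatError,
    GeneFeature,
    GenomeMetadata,
    intergenic_distance,
    mirror_genome,
    neighborhood,
    read_genome,
    read_metadata_tsv,
    write_gff3,
    write_metadata_tsv,
    write_protein_fasta,
)

from conftest import make_genome

GFF3 = """##gff-version 3
##sequence-region contig1 1 5000
contig1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=gA;protein_id=pA;product=alpha
contig1\tsrc\tCDS\t500\t900\t.\t-\t0\tID=gB;protein_id=pB;product=beta
contig1\tsrc\tCDS\t1000\t1300\t.\t+\t0\tID=gC;protein_id=pC;product=gamma
"""

FASTA = ">pA\nMKLVINW\n>pB\nMAACDEF\n>pC\nMWYHKRT\n"


@pytest.fixture
def gff3_paths(tmp_path):
    gff = tmp_path / "toy.gff3"
    faa = tmp_path / "toy.faa"
    gff.write_text(GFF3)
    faa.write_text(FASTA)
    return gff, faa


def test_read_gff3_assigns_ranks(gff3_paths):
    genome = read_genome(*gff3_paths, genome_id="toy",
                         metadata=GenomeMetadata("toy", "toy sp."))
    assert [f.feature_id for f in genome.features] == ["gA", "gB", "gC"]
    assert [f.rank for f in genome.features] == [0, 1, 2]
    assert genome.features[1].strand == "-"
    assert genome.features[0].aa_seq == "MKLVINW"
    assert genome.replicons[0].length_nt == 5000


def test_genbank_equals_gff3_load(gff3_paths, tmp_path):
    """The same fixture encoded as GenBank yields field-identical features."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    via_gff = read_genome(*gff3_paths, genome_id="toy",
                          metadata=GenomeMetadata("toy", "toy sp."))
    record = SeqRecord(Seq("N" * 5000), id="contig1", name="contig1",
                       description="", annotations={"molecule_type": "DNA"})
    for f in via_gff.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start_nt - 1, f.end_nt,
                                strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [f.feature_id],
                    "protein_id": [f.protein_id],
                    "product": [f.product],
                    "translation": [f.aa_seq],
                },
            )
        )
    gb = tmp_path / "toy.gb"
    SeqIO.write([record], str(gb), "genbank")
    via_gb = read_genome(gb, genome_id="toy",
                         metadata=GenomeMetadata("toy", "toy sp."))
    assert [
        (f.feature_id, f.start_nt, f.end_nt, f.strand, f.rank, f.protein_id,
         f.product, f.aa_seq)
        for f in via_gb.features
    ] == [
        (f.feature_id, f.start_nt, f.end_nt, f.strand, f.rank, f.protein_id,
         f.product, f.aa_seq)
        for f in via_gff.features
    ]


def test_missing_translation_dropped_and_counted(tmp_path):
    gff = tmp_path / "toy.gff3"
    faa = tmp_path / "toy.faa"
    gff.write_text(GFF3)
    faa.write_text(">pA\nMKLVINW\n>pC\nMWYHKRT\n")  # pB absent
    genome = read_genome(gff, faa, genome_id="toy",
                         metadata=GenomeMetadata("toy", "toy sp."))
    assert len(genome.features) == 2
    assert genome.load_report.n_dropped_no_translation == 1
    assert genome.load_report.dropped_ids == ("gB",)


def test_duplicate_protein_ids_rejected(tmp_path):
    gff = tmp_path / "toy.gff3"
    faa = tmp_path / "toy.faa"
    gff.write_text(GFF3)
    faa.write_text(">pA\nMKLV\n>pA\nMKLV\n>pB\nMAAC\n>pC\nMWYH\n")
    with pytest.raises(GenomeFormatError, match="pA"):
        read_genome(gff, faa, genome_id="toy")


def test_malformed_gff3_names_line(tmp_path):
    gff = tmp_path / "bad.gff3"
    gff.write_text("##gff-version 3\ncontig1\tsrc\tCDS\t100\n")
    with pytest.raises(GenomeFormatError, match="line 2"):
        read_genome(gff)


def test_roundtrip_gff3(tmp_path, default_sim):
    """Write-then-reload reproduces identical feature tuples."""
    genome = default_sim.genomes[0]
    gff = tmp_path / "g.gff3"
    faa = tmp_path / "g.faa"
    write_gff3(genome, gff)
    write_protein_fasta(genome, faa)
    meta = GenomeMetadata(
        genome.genome_id, genome.species, genome.phylum, genome.superkingdom,
        genome.is_complete, {r.replicon_id: r.kind for r in genome.replicons},
    )
    again = read_genome(gff, faa, genome_id=genome.genome_id, metadata=meta)
    assert again.features == genome.features
    assert again.replicons == genome.replicons


def test_metadata_tsv_roundtrip(tmp_path, default_sim):
    path = tmp_path / "metadata.tsv"
    write_metadata_tsv(default_sim.genomes, path)
    meta = read_metadata_tsv(path)
    g = default_sim.genomes[0]
    assert meta[g.genome_id].species == g.species
    assert meta[g.genome_id].replicon_kinds == {
        r.replicon_id: r.kind for r in g.replicons
    }


@pytest.mark.parametrize(
    "a_coords,b_coords,expected",
    [
        ((1, 100), (131, 400), 30),
        ((1, 100), (101, 400), 0),  # book-ended genes
        ((1, 200), (150, 400), 0),  # overlap clamps to zero
    ],
)
def test_intergenic_distance_cases(a_coords, b_coords, expected):
    g = make_genome("t", [("a", *a_coords, "+", "MA"), ("b", *b_coords, "+", "MB")])
    a, b = g.features
    assert intergenic_distance(a, b) == expected
    assert intergenic_distance(b, a) == expected


def test_intergenic_distance_requires_same_replicon():
    a = GeneFeature("a", "r1", 1, 10, "+", 0, "a", aa_seq="M")
    b = GeneFeature("b", "r2", 1, 10, "+", 0, "b", aa_seq="M")
    with pytest.raises(ValueError, match="different replicons"):
        intergenic_distance(a, b)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 5000), st.integers(1, 300)),
                min_size=2, max_size=8))
def test_intergenic_distance_symmetric_nonnegative(raw):
    genes = []
    for i, (start, length) in enumerate(sorted(set(raw))):
        genes.append((f"g{i}", start, start + length, "+", "M"))
    g = make_genome("t", genes, length_nt=10_000)
    feats = g.features
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            d = intergenic_distance(feats[i], feats[j])
            assert d == intergenic_distance(feats[j], feats[i])
            assert d >= 0


@pytest.mark.parametrize(
    "focal_rank,k,n_up,n_down",
    [(0, 4, 0, 4), (4, 4, 4, 4), (1, 1, 1, 1)],
)
def test_neighborhood_window(focal_rank, k, n_up, n_down):
    genes = [(f"g{i}", 1 + 500 * i, 300 + 500 * i, "+", "M") for i in range(9)]
    g = make_genome("t", genes)
    hood = neighborhood(g, g.features[focal_rank], k)
    assert len(hood.upstream) == n_up
    assert len(hood.downstream) == n_down
    # ordered by increasing distance from focal
    if hood.upstream:
        assert hood.upstream[0].rank == focal_rank - 1
    if hood.downstream:
        assert hood.downstream[0].rank == focal_rank + 1


def test_neighborhood_invariant_to_input_order():
    genes = [(f"g{i}", 1 + 500 * i, 300 + 500 * i, "+", "M") for i in range(5)]
    fwd = make_genome("t", genes)
    rev = make_genome("t", list(reversed(genes)))
    assert fwd.features == rev.features
    for a, b in zip(fwd.features, rev.features):
        na = neighborhood(fwd, a, 2)
        nb = neighborhood(rev, b, 2)
        assert [f.feature_id for f in na.flanks()] == [f.feature_id for f in nb.flanks()]


def test_mirror_genome_is_involution(default_sim):
    g = default_sim.genomes[0]
    assert mirror_genome(mirror_genome(g)).features == g.features
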