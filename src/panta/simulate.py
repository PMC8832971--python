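"""Seeded synthetic pangenomes with planted ground truth.

The generator emulates the statistical structure the locus-mining pipeline
assumes: multiple species, one representative set of genomes per species, a
seed antitoxin family whose members sit in tight operons (gap <= 100 nt)
with cognate toxin families, accessory third genes in a subset of species,
a mobile-element decoy family that is seed-adjacent in only a couple of
genomes but present in many, and optional N-terminal extensions (HTH- or
PAD1-derived) on the antitoxins plus transmembrane blocks in some toxin
families.

Protein families evolve star-like from an ancestor drawn i.i.d. from the
background: each member substitutes every site independently with
probability ``p_sub`` and there are no indels — the key simplification that
keeps the ungapped profile scanner and identity computations exact.
Nucleotide sequences are never generated; gene length in nt is 3x the
protein length and genes are laid left-to-right with drawn intergenic gaps,
which is all the pipeline's geometry needs.  Planted operon gaps come from
``gap_distribution``; all background adjacencies draw gaps from
``background_gap`` (default 150-400 nt) so that only planted architectures
satisfy the operon criterion.

Everything derives from one ``numpy`` Generator seeded by the config, and
the emitted file tree is byte-identical for equal configs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneFeature,
    Genome,
    GenomeMetadata,
    Replicon,
    build_genome,
    write_gff3,
    write_metadata_tsv,
    write_protein_fasta,
)
from .profile_scan import ALPHABET

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedPangenome",
    "SimulationError",
    "simulate_pangenome",
    "parse_sim_config",
    "evaluate_loci",
    "evaluate_spurious_flags",
    "evaluate_annotations",
]


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic pangenome."""

    rng_seed: int = 1
    n_species: int = 10
    genomes_per_species: int = 3
    genes_per_replicon: int = 30
    background_gene_len: tuple[int, int] = (60, 200)  # aa
    seed_profile_len: int = 80  # aa length of the seed-domain family
    p_sub: float = 0.05  # per-site substitution probability
    n_toxin_families: int = 5
    gap_distribution: tuple[int, int] = (0, 80)  # nt, planted operon gaps
    frac_toxin_first: float = 0.25
    frac_with_accessory: float = 0.4
    decoy_adjacent: int = 2  # seed-adjacent decoy placements
    decoy_background: int = 18  # decoy copies away from seeds
    frac_hth_extension: float = 0.3
    frac_pad1_extension: float = 0.2
    frac_tm_toxins: float = 0.4
    n_long_operon_families: int = 0  # planted 4-gene conserved cassettes
    background_gap: tuple[int, int] = (150, 400)  # nt between background genes
    hth_len: int = 55
    pad1_len: int = 60

    def __post_init__(self) -> None:
        for name in (
            "frac_toxin_first",
            "frac_with_accessory",
            "frac_hth_extension",
            "frac_pad1_extension",
            "frac_tm_toxins",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.p_sub < 0.5):
            raise SimulationError("p_sub must lie in [0, 0.5)")
        if self.gap_distribution[0] > self.gap_distribution[1]:
            raise SimulationError("gap_distribution must be (min, max)")
        if self.background_gap[0] <= 100:
            raise SimulationError(
                "background_gap minimum must exceed 100 nt so that only "
                "planted architectures satisfy the operon criterion"
            )
        if self.frac_hth_extension + self.frac_pad1_extension > 1.0:
            raise SimulationError("extension fractions must sum to <= 1")


@dataclass
class GroundTruth:
    """Planted-truth tables used to score every pipeline stage."""

    loci: pd.DataFrame
    decoys: pd.DataFrame
    extensions: pd.DataFrame
    tm: pd.DataFrame

    _FILES = {
        "loci": "truth_loci.tsv",
        "decoys": "truth_decoys.tsv",
        "extensions": "truth_extensions.tsv",
        "tm": "truth_tm.tsv",
    }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(outdir / fname, sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "GroundTruth":
        indir = Path(indir)
        frames = {
            attr: pd.read_csv(
                indir / fname, sep="\t", dtype={"genome_id": str},
                keep_default_na=False,
            )
            for attr, fname in cls._FILES.items()
        }
        return cls(**frames)


@dataclass
class SimulatedPangenome:
    config: SimConfig
    genomes: tuple[Genome, ...]
    truth: GroundTruth
    seed_alignment: tuple[str, ...]
    hth_alignment: tuple[str, ...]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata_tsv(self.genomes, outdir / "metadata.tsv")
        for g in self.genomes:
            write_gff3(g, outdir / f"{g.genome_id}.gff3")
            write_protein_fasta(g, outdir / f"{g.genome_id}.faa")
        self.truth.write(outdir)
        _write_alignment(self.seed_alignment, "seed", outdir / "seed_alignment.afa")
        _write_alignment(self.hth_alignment, "hth", outdir / "hth_seed.afa")
        with open(outdir / "sim_config.cfg", "w") as fh:
            for f_ in dataclasses.fields(self.config):
                value = getattr(self.config, f_.name)
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{f_.name}={value}\n")


def _write_alignment(seqs: Sequence[str], stem: str, path: Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs, start=1):
            fh.write(f">{stem}{i}\n{seq}\n")


# ---------------------------------------------------------------------------
# sequence evolution


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution to a uniformly drawn other residue."""
    if p_sub == 0.0:
        return seq
    out = list(seq)
    mask = rng.random(len(seq)) < p_sub
    for i in np.nonzero(mask)[0]:
        cur = ALPHABET.index(out[i]) if out[i] in ALPHABET else 0
        r = int(rng.integers(0, 19))
        out[i] = ALPHABET[r if r < cur else r + 1]
    return "".join(out)


# ---------------------------------------------------------------------------
# generator


def simulate_pangenome(config: SimConfig) -> SimulatedPangenome:
    rng = np.random.default_rng(config.rng_seed)
    n_fam = config.n_toxin_families
    lo_len, hi_len = config.background_gene_len

    def gene_len() -> int:
        return int(rng.integers(lo_len, hi_len + 1))

    def operon_gap() -> int:
        return int(rng.integers(config.gap_distribution[0], config.gap_distribution[1] + 1))

    def bg_gap() -> int:
        return int(rng.integers(config.background_gap[0], config.background_gap[1] + 1))

    # --- ancestors (drawn in fixed order) ---
    seed_anc = _random_seq(config.seed_profile_len, rng)
    hth_anc = _random_seq(config.hth_len, rng)
    pad1_anc = _random_seq(config.pad1_len, rng)

    n_tm = round(config.frac_tm_toxins * n_fam)
    n_acc = round(config.frac_with_accessory * n_fam)
    toxin_anc: list[str] = []
    for fam in range(n_fam):
        anc = _random_seq(gene_len(), rng)
        if fam < n_tm:  # transmembrane toxin family: splice a poly-Leu block
            mid = len(anc) // 2
            anc = anc[:mid] + "L" * 25 + anc[mid:]
        toxin_anc.append(anc)
    acc_anc = {fam: _random_seq(gene_len(), rng) for fam in range(n_acc)}
    long_anc = [
        (_random_seq(gene_len(), rng), _random_seq(gene_len(), rng), _random_seq(gene_len(), rng))
        for _ in range(config.n_long_operon_families)
    ]
    decoy_anc = _random_seq(gene_len(), rng)

    fam_order = [
        "toxin_first" if rng.random() < config.frac_toxin_first else "antitoxin_first"
        for _ in range(n_fam)
    ]
    long_order = [
        "toxin_first" if rng.random() < config.frac_toxin_first else "antitoxin_first"
        for _ in range(config.n_long_operon_families)
    ]

    # emitted model alignments (the Pfam-seed stand-ins)
    seed_alignment = tuple(_mutate(seed_anc, config.p_sub, rng) for _ in range(8))
    hth_alignment = tuple(_mutate(hth_anc, 0.1, rng) for _ in range(6))

    # --- placement plan ---
    fam_species = {
        fam: [j for j in range(config.n_species) if j % n_fam == fam]
        for fam in range(n_fam)
    }
    long_species = {
        l: [s % config.n_species for s in (2 * l, 2 * l + 1)]
        for l in range(config.n_long_operon_families)
    }

    decoy_adjacent_targets: set[tuple[int, int]] = set()
    if config.decoy_adjacent > 0:
        decoy_fam = next((f for f in range(n_fam) if f >= n_acc), None)
        if decoy_fam is None:
            raise SimulationError(
                "decoy placement needs at least one toxin family without an "
                "accessory gene"
            )
        slots = [
            (sp, g)
            for g in range(config.genomes_per_species)
            for sp in fam_species[decoy_fam]
        ]
        if config.decoy_adjacent > len(slots):
            raise SimulationError("not enough genomes for adjacent decoy placements")
        decoy_adjacent_targets = set(slots[: config.decoy_adjacent])

    all_slots = [
        (sp, g)
        for sp in range(config.n_species)
        for g in range(config.genomes_per_species)
    ]
    bg_eligible = [s for s in all_slots if s not in decoy_adjacent_targets]
    decoy_bg_count: dict[tuple[int, int], int] = {s: 0 for s in all_slots}
    if config.decoy_background > 0:
        if not bg_eligible:
            raise SimulationError("no genomes available for background decoys")
        for i in range(config.decoy_background):
            decoy_bg_count[bg_eligible[i % len(bg_eligible)]] += 1

    # --- per-genome assembly ---
    genomes: list[Genome] = []
    loci_rows: list[dict] = []
    decoy_rows: list[dict] = []
    ext_rows: list[dict] = []
    tm_rows: list[dict] = []

    for sp in range(config.n_species):
        species = f"species{sp:03d}"
        fam = sp % n_fam
        for g in range(config.genomes_per_species):
            genome_id = f"G{sp:03d}_{g}"
            replicon_id = f"{genome_id}_chr"

            units: list[dict] = []  # each: {"genes": [spec...], "gaps": [int...]}

            # main operon block, genes listed in transcription order
            u = rng.random()
            if u < config.frac_hth_extension:
                ext_label, ext_seq = "hth", _mutate(hth_anc, config.p_sub, rng)
            elif u < config.frac_hth_extension + config.frac_pad1_extension:
                ext_label, ext_seq = "pad1", _mutate(pad1_anc, config.p_sub, rng)
            else:
                ext_label, ext_seq = "none", ""
            anti = {
                "seq": ext_seq + _mutate(seed_anc, config.p_sub, rng),
                "role": "antitoxin",
                "product": "Panacea-domain antitoxin",
            }
            toxin = {
                "seq": _mutate(toxin_anc[fam], config.p_sub, rng),
                "role": "toxin",
                "product": "hypothetical protein",
            }
            block = [anti, toxin] if fam_order[fam] == "antitoxin_first" else [toxin, anti]
            pair_gap = operon_gap()
            gaps = [pair_gap]
            accessory_spec = None
            if fam < n_acc:
                accessory_spec = {
                    "seq": _mutate(acc_anc[fam], config.p_sub, rng),
                    "role": "accessory",
                    "product": "accessory protein",
                }
                # the accessory flanks the toxin, never the seed, so it cannot
                # itself become a second seed-adjacent candidate pair
                if fam_order[fam] == "antitoxin_first":
                    block.append(accessory_spec)
                    gaps.append(operon_gap())
                else:
                    block.insert(0, accessory_spec)
                    gaps.insert(0, operon_gap())
            decoy_adj_spec = None
            if (sp, g) in decoy_adjacent_targets:
                decoy_adj_spec = {
                    "seq": _mutate(decoy_anc, config.p_sub, rng),
                    "role": "decoy",
                    "product": "transposase",
                }
                # always on the antitoxin's side away from the toxin, so the
                # seed-decoy architecture is consistent across species
                if fam_order[fam] == "antitoxin_first":
                    block.insert(0, decoy_adj_spec)
                    gaps.insert(0, operon_gap())
                else:
                    block.append(decoy_adj_spec)
                    gaps.append(operon_gap())
            strand = "+" if rng.random() < 0.5 else "-"
            units.append({"genes": block, "gaps": gaps, "strand": strand})

            # planted 4-gene conserved cassette (rejected-operon control)
            long_here = [
                l for l, specs in long_species.items() if sp in specs
            ]
            for l in long_here:
                anti2 = {
                    "seq": _mutate(seed_anc, config.p_sub, rng),
                    "role": "long_antitoxin",
                    "product": "Panacea-domain antitoxin",
                }
                t_l = {
                    "seq": _mutate(long_anc[l][0], config.p_sub, rng),
                    "role": "long_toxin",
                    "product": "hypothetical protein",
                }
                x1 = {
                    "seq": _mutate(long_anc[l][1], config.p_sub, rng),
                    "role": "long_extra",
                    "product": "hypothetical protein",
                }
                x2 = {
                    "seq": _mutate(long_anc[l][2], config.p_sub, rng),
                    "role": "long_extra",
                    "product": "hypothetical protein",
                }
                lblock = (
                    [anti2, t_l] if long_order[l] == "antitoxin_first" else [t_l, anti2]
                ) + [x1, x2]
                lgaps = [operon_gap() for _ in range(3)]
                lstrand = "+" if rng.random() < 0.5 else "-"
                units.append({"genes": lblock, "gaps": lgaps, "strand": lstrand})
                loci_rows.append(
                    {
                        "_anti": anti2,
                        "_toxin": t_l,
                        "_acc": None,
                        "genome_id": genome_id,
                        "species": species,
                        "family": f"long{l}",
                        "gap_nt": lgaps[0],
                        "order": long_order[l],
                        "accessory_present": 0,
                        "expect_called": 0,
                    }
                )

            n_block_genes = sum(len(unit["genes"]) for unit in units)
            n_decoy_bg = decoy_bg_count[(sp, g)]
            n_bg = config.genes_per_replicon - n_block_genes - n_decoy_bg
            if n_bg < 0:
                raise SimulationError(
                    f"{genome_id}: operons and decoys need {n_block_genes + n_decoy_bg} "
                    f"gene slots but genes_per_replicon={config.genes_per_replicon}"
                )

            single_units: list[dict] = []
            for _ in range(n_bg):
                single_units.append(
                    {
                        "genes": [
                            {
                                "seq": _random_seq(gene_len(), rng),
                                "role": "background",
                                "product": "hypothetical protein",
                            }
                        ],
                        "gaps": [],
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
            for _ in range(n_decoy_bg):
                spec = {
                    "seq": _mutate(decoy_anc, config.p_sub, rng),
                    "role": "decoy_background",
                    "product": "transposase",
                }
                single_units.append(
                    {
                        "genes": [spec],
                        "gaps": [],
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
            # deterministic shuffle of background slots, then insert blocks
            order_idx = rng.permutation(len(single_units))
            layout = [single_units[i] for i in order_idx]
            for unit in reversed(units):  # insert main block last => first drawn pos
                pos = int(rng.integers(0, len(layout) + 1))
                layout.insert(pos, unit)

            # left-to-right coordinate layout
            pos = 1 + int(rng.integers(0, 200))
            placed: list[tuple[dict, int, int, str]] = []
            for unit in layout:
                genes = unit["genes"]
                if unit["strand"] == "-":
                    coord_genes = list(reversed(genes))
                    coord_gaps = list(reversed(unit["gaps"]))
                else:
                    coord_genes = list(genes)
                    coord_gaps = list(unit["gaps"])
                for i, spec in enumerate(coord_genes):
                    length_nt = 3 * len(spec["seq"])
                    placed.append((spec, pos, pos + length_nt - 1, unit["strand"]))
                    pos += length_nt
                    if i < len(coord_gaps):
                        pos += coord_gaps[i]
                pos += bg_gap()
            replicon_len = pos + bg_gap()

            features = []
            for k, (spec, start, end, strand_) in enumerate(placed):
                fid = f"{genome_id}_g{k:03d}"
                pid = f"{genome_id}_p{k:03d}"
                spec["feature_id"] = fid
                spec["protein_id"] = pid
                features.append(
                    GeneFeature(
                        feature_id=fid,
                        replicon_id=replicon_id,
                        start_nt=start,
                        end_nt=end,
                        strand=strand_,
                        rank=0,
                        protein_id=pid,
                        product=spec["product"],
                        aa_seq=spec["seq"],
                    )
                )
            meta = GenomeMetadata(
                genome_id=genome_id,
                species=species,
                phylum=f"phylum{sp % 3}",
                superkingdom="bacteria",
                is_complete=True,
                replicon_kinds={replicon_id: "chromosome"},
            )
            genome = build_genome(
                genome_id,
                (
                    Replicon(
                        replicon_id=replicon_id,
                        genome_id=genome_id,
                        kind="chromosome",
                        length_nt=replicon_len,
                    ),
                ),
                features,
                metadata=meta,
            )
            genomes.append(genome)

            # --- truth rows for this genome ---
            loci_rows.append(
                {
                    "_anti": anti,
                    "_toxin": toxin,
                    "_acc": accessory_spec,
                    "genome_id": genome_id,
                    "species": species,
                    "family": f"fam{fam}",
                    "gap_nt": pair_gap,
                    "order": fam_order[fam],
                    "accessory_present": int(accessory_spec is not None),
                    "expect_called": 1,
                }
            )
            if decoy_adj_spec is not None:
                decoy_rows.append(
                    {
                        "genome_id": genome_id,
                        "feature_id": decoy_adj_spec["feature_id"],
                        "protein_id": decoy_adj_spec["protein_id"],
                        "adjacent_to_seed": 1,
                    }
                )
            for spec, _s, _e, _st in placed:
                if spec["role"] == "decoy_background":
                    decoy_rows.append(
                        {
                            "genome_id": genome_id,
                            "feature_id": spec["feature_id"],
                            "protein_id": spec["protein_id"],
                            "adjacent_to_seed": 0,
                        }
                    )
            ext_rows.append(
                {
                    "protein_id": anti["protein_id"],
                    "genome_id": genome_id,
                    "label": ext_label,
                    "ext_len": len(ext_seq),
                }
            )
            tm_rows.append(
                {
                    "protein_id": toxin["protein_id"],
                    "genome_id": genome_id,
                    "family": f"fam{fam}",
                    "is_tm": int(fam < n_tm),
                }
            )

    # resolve planted ids now that every gene has one
    resolved = []
    for row in loci_rows:
        anti, toxin, acc = row.pop("_anti"), row.pop("_toxin"), row.pop("_acc")
        row["antitoxin_feature"] = anti["feature_id"]
        row["antitoxin_protein"] = anti["protein_id"]
        row["toxin_feature"] = toxin["feature_id"]
        row["toxin_protein"] = toxin["protein_id"]
        row["accessory_feature"] = acc["feature_id"] if acc else ""
        row["accessory_protein"] = acc["protein_id"] if acc else ""
        resolved.append(row)
    loci_cols = [
        "genome_id", "species", "family",
        "antitoxin_feature", "antitoxin_protein",
        "toxin_feature", "toxin_protein",
        "gap_nt", "order", "accessory_present",
        "accessory_feature", "accessory_protein", "expect_called",
    ]
    truth = GroundTruth(
        loci=pd.DataFrame(resolved, columns=loci_cols).sort_values(
            ["genome_id", "antitoxin_feature"], kind="mergesort", ignore_index=True
        ),
        decoys=pd.DataFrame(
            decoy_rows,
            columns=["genome_id", "feature_id", "protein_id", "adjacent_to_seed"],
        ).sort_values(["genome_id", "feature_id"], kind="mergesort", ignore_index=True),
        extensions=pd.DataFrame(
            ext_rows, columns=["protein_id", "genome_id", "label", "ext_len"]
        ).sort_values("protein_id", kind="mergesort", ignore_index=True),
        tm=pd.DataFrame(
            tm_rows, columns=["protein_id", "genome_id", "family", "is_tm"]
        ).sort_values("protein_id", kind="mergesort", ignore_index=True),
    )
    genomes.sort(key=lambda g: g.genome_id)
    return SimulatedPangenome(
        config=config,
        genomes=tuple(genomes),
        truth=truth,
        seed_alignment=seed_alignment,
        hth_alignment=hth_alignment,
    )


def parse_sim_config(path: str | Path) -> SimConfig:
    """Read a flat key=value config file into a SimConfig."""
    kwargs: dict = {}
    types = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise SimulationError(f"unknown simulation parameter {key!r}")
            if "tuple" in str(types[key]):
                parts = [int(p) for p in raw.split(",")]
                kwargs[key] = tuple(parts)
            elif "float" in str(types[key]):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# scoring against planted truth


def _require_ids(frame: pd.DataFrame, cols: Sequence[str], label: str) -> None:
    bad = []
    for col in cols:
        if col not in frame.columns:
            raise ValueError(f"{label}: missing column {col!r}")
        null = frame[col].isna() | (frame[col].astype(str) == "")
        bad.extend(f"{col}[{i}]" for i in frame.index[null])
    if bad:
        raise ValueError(f"{label}: unresolvable ids: {', '.join(bad)}")


def evaluate_loci(predicted: pd.DataFrame, truth_loci: pd.DataFrame) -> dict:
    """Precision / recall / F1 of final called loci against planted truth.

    A prediction is a true positive iff its (genome, antitoxin feature,
    partner feature) triple matches a planted locus expected to be called.
    Undefined ratios (empty denominators) are reported as None.
    """
    final = predicted[predicted["verdict"] == "pTA"]
    if len(final):
        _require_ids(final, ["genome_id", "antitoxin_feature", "partner_feature"], "predictions")
    positives = truth_loci[truth_loci["expect_called"] == 1]
    truth_keys = {
        (r.genome_id, r.antitoxin_feature, r.toxin_feature)
        for r in positives.itertuples()
    }
    pred_keys = {
        (r.genome_id, r.antitoxin_feature, r.partner_feature)
        for r in final.itertuples()
    }
    tp = len(pred_keys & truth_keys)
    precision = tp / len(pred_keys) if pred_keys else None
    recall = tp / len(truth_keys) if truth_keys else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "tp": tp,
        "n_predicted": len(pred_keys),
        "n_truth": len(truth_keys),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def evaluate_spurious_flags(
    tested_clusters: Mapping[int, frozenset],
    statuses: Mapping[int, str],
    truth: GroundTruth,
) -> dict:
    """Sensitivity of the spurious flag on decoys; false-flag rate on cognates.

    ``tested_clusters`` maps cluster id -> member protein ids for every
    cluster the reciprocity filter examined.
    """
    decoy_ids = set(truth.decoys["protein_id"])
    cognate_ids = set(
        truth.loci.loc[truth.loci["expect_called"] == 1, "toxin_protein"]
    )
    decoy_clusters = [c for c, m in tested_clusters.items() if m & decoy_ids]
    cognate_clusters = [c for c, m in tested_clusters.items() if m & cognate_ids]
    decoy_flagged = (
        sum(statuses[c] == "spurious" for c in decoy_clusters) / len(decoy_clusters)
        if decoy_clusters
        else None
    )
    cognate_flagged = (
        sum(statuses[c] == "spurious" for c in cognate_clusters)
        / len(cognate_clusters)
        if cognate_clusters
        else None
    )
    return {
        "n_decoy_clusters_tested": len(decoy_clusters),
        "n_cognate_clusters_tested": len(cognate_clusters),
        "decoy_spurious_rate": decoy_flagged,
        "cognate_false_spurious_rate": cognate_flagged,
    }


def evaluate_annotations(annotations: pd.DataFrame, truth: GroundTruth) -> dict:
    """Accuracy of HTH / PAD1 / TM labels against planted labels."""
    ann = annotations.set_index("protein_id")

    def _acc(truth_frame, truth_col, pred_col, positive) -> float | None:
        total = correct = 0
        for row in truth_frame.itertuples():
            if row.protein_id not in ann.index:
                continue
            pred = ann.loc[row.protein_id, pred_col]
            total += 1
            correct += int(bool(pred) == positive(getattr(row, truth_col)))
        return correct / total if total else None

    hth_acc = _acc(truth.extensions, "label", "hth", lambda v: v == "hth")
    pad1_acc = _acc(
        truth.extensions, "label", "pad1_cluster", lambda v: v == "pad1"
    )
    tm_acc = _acc(truth.tm, "is_tm", "n_tm_segments", lambda v: bool(v))
    return {"hth_accuracy": hth_acc, "pad1_accuracy": pad1_acc, "tm_accuracy": tm_acc}
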