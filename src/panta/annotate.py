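"""Feature annotation of called antitoxins and toxins.

Antitoxin side: many seed-domain antitoxins carry N-terminal extensions
ahead of the domain envelope.  Extensions matching a helix-turn-helix (HTH)
profile are flagged through a two-pass remodelling procedure (scan with an
initial model, rebuild a sharper model from the hits, rescan); extensions
with no HTH hit are clustered to surface novel conserved domains (the
PAD1-discovery route).

Toxin side: putative membrane-targeting toxins are annotated with a
Kyte-Doolittle sliding-window hydropathy scan (window 19, threshold 1.6 —
the standard settings for transmembrane-segment prediction).  This is a
deliberate stand-in for a dedicated TM predictor such as TMHMM; external
predictions can be injected as a TSV instead.

Alignment columns are scored for conservation as 1 - H / log2(20) with H the
Shannon entropy of the non-gap residues, which ranks invariant motif columns
(GPV-like) at the top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import FlankCluster, ProteinRecord, cluster_flanks
from .profile_scan import ProfileModel, SeedHit, build_profile, scan_protein

__all__ = [
    "KYTE_DOOLITTLE",
    "NTermExtension",
    "TMSegment",
    "ConservationProfile",
    "extract_nterm_extensions",
    "remodel_and_detect_hth",
    "discover_conserved_extensions",
    "predict_tm_segments",
    "read_tm_predictions_tsv",
    "conservation_profile",
]

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class NTermExtension:
    """Residues preceding the seed-domain envelope on an antitoxin."""

    protein_id: str
    ext_seq: str
    ext_len: int


@dataclass(frozen=True)
class TMSegment:
    start_aa: int  # 1-based inclusive
    end_aa: int
    mean_hydropathy: float


@dataclass(frozen=True)
class ConservationProfile:
    scores: np.ndarray
    occupancy: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


def extract_nterm_extensions(
    seed_hits: Sequence[SeedHit],
    proteins: Mapping[str, str],
    min_len: int = 40,
) -> list[NTermExtension]:
    """One extension per protein whose envelope starts >= min_len + 1."""
    out = []
    for hit in sorted(seed_hits, key=lambda h: h.protein_id):
        ext_len = hit.env_start - 1
        if ext_len < min_len:
            continue
        seq = proteins[hit.protein_id]
        out.append(
            NTermExtension(
                protein_id=hit.protein_id, ext_seq=seq[:ext_len], ext_len=ext_len
            )
        )
    return out


def remodel_and_detect_hth(
    extensions: Sequence[NTermExtension],
    initial_profile: ProfileModel,
    *,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> tuple[ProfileModel, dict[str, bool]]:
    """Two-pass HTH detection with profile remodelling.

    Pass 1 scans every extension with the initial HTH profile.  Pass 2
    rebuilds a profile from the pass-1 hit envelopes (an ungapped alignment,
    since every envelope has profile length) and rescans.  Final flags are
    the union of the two passes, so remodelling can only gain hits — a
    pass-1 hit is never lost.  With zero pass-1 hits the initial profile is
    returned unchanged with all-false flags.
    """
    pass1: dict[str, SeedHit | None] = {
        ext.protein_id: scan_protein(
            ext.ext_seq, initial_profile, protein_id=ext.protein_id
        )
        for ext in extensions
    }
    hit_exts = [
        (pid, hit) for pid, hit in sorted(pass1.items()) if hit is not None
    ]
    if not hit_exts:
        return initial_profile, {ext.protein_id: False for ext in extensions}

    by_id = {ext.protein_id: ext for ext in extensions}
    segments = [
        by_id[pid].ext_seq[hit.env_start - 1 : hit.env_end] for pid, hit in hit_exts
    ]
    if len(segments) >= 2:
        updated = build_profile(
            segments,
            name=f"{initial_profile.name}-remodelled",
            pseudocount=pseudocount,
            background=background,
        )
    else:
        updated = initial_profile
    flags = {}
    for ext in extensions:
        pass2 = scan_protein(ext.ext_seq, updated, protein_id=ext.protein_id)
        flags[ext.protein_id] = (pass1[ext.protein_id] is not None) or (
            pass2 is not None
        )
    return updated, flags


def discover_conserved_extensions(
    extensions: Sequence[NTermExtension],
    species_of_protein: Mapping[str, str],
    genome_of_protein: Mapping[str, str] | None = None,
    min_members: int = 5,
    min_species: int = 2,
    **cluster_kwargs,
) -> list[FlankCluster]:
    """Cluster HTH-free extensions; report widely conserved families.

    This is the route by which a novel N-terminal domain (a PAD1-like
    family) surfaces: a cluster of >= ``min_members`` extensions spanning
    >= ``min_species`` species with no known-domain hit.
    """
    if not extensions:
        return []
    records = [
        ProteinRecord(
            protein_id=ext.protein_id,
            genome_id=(genome_of_protein or {}).get(ext.protein_id, ""),
            species=species_of_protein.get(ext.protein_id, ""),
            seq=ext.ext_seq,
        )
        for ext in extensions
    ]
    clusters = cluster_flanks(records, **cluster_kwargs)
    return [
        c for c in clusters if c.size >= min_members and c.n_species >= min_species
    ]


def predict_tm_segments(
    seq: str, window: int = 19, threshold: float = 1.6
) -> list[TMSegment]:
    """Kyte-Doolittle hydropathy segments.

    Windows whose mean hydropathy reaches ``threshold`` are merged when they
    overlap; each merged segment reports its bounds and the mean hydropathy
    over the merged span.  Sequences shorter than the window yield nothing.
    Unknown residues contribute 0 to the scale.
    """
    if len(seq) < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.upper()])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    hits = np.nonzero(means >= threshold)[0]
    if hits.size == 0:
        return []
    segments: list[list[int]] = []
    for i in hits:
        start, end = int(i), int(i) + window - 1  # 0-based inclusive
        if segments and start <= segments[-1][1]:
            segments[-1][1] = end
        else:
            segments.append([start, end])
    return [
        TMSegment(
            start_aa=s + 1,
            end_aa=e + 1,
            mean_hydropathy=float(values[s : e + 1].mean()),
        )
        for s, e in segments
    ]


def read_tm_predictions_tsv(path) -> dict[str, list[TMSegment]]:
    """Injection path for external TM predictions (protein_id, start, end)."""
    import csv

    out: dict[str, list[TMSegment]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["protein_id"], []).append(
                TMSegment(
                    start_aa=int(row["start"]),
                    end_aa=int(row["end"]),
                    mean_hydropathy=float(row.get("mean_hydropathy", "nan")),
                )
            )
    return out


def conservation_profile(alignment: Sequence[str]) -> ConservationProfile:
    """Normalized-entropy conservation score per alignment column.

    score = 1 - H / log2(20), H the Shannon entropy (bits) of the non-gap
    residues; columns with occupancy < 0.5 score 0.  An invariant column
    scores 1.0, a column uniform over the 20 residues scores 0.0.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("ragged alignment: sequences differ in gapped length")
    n = len(alignment)
    scores = np.zeros(width)
    occupancy = np.zeros(width)
    max_h = np.log2(20.0)
    for c in range(width):
        residues = [s[c].upper() for s in alignment if s[c] not in "-."]
        occupancy[c] = len(residues) / n
        if occupancy[c] < 0.5 or not residues:
            scores[c] = 0.0
            continue
        _unique, counts = np.unique(np.array(residues), return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log2(p)).sum())
        scores[c] = min(1.0, max(0.0, 1.0 - h / max_h))
    return ConservationProfile(scores=scores, occupancy=occupancy)
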