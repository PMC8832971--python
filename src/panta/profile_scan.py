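"""Position-specific profile construction and seed-domain scanning.

The seed (Panacea-like antitoxin) domain is detected with an ungapped
position-specific scoring matrix (PSSM) slid along each protein: adequate for
synthetic families generated without indels, and deliberately simpler than a
full profile HMM.  Real-world scans run HMMER externally and inject their
per-domain table through :func:`parse_domain_table` — the two entry points
produce the same :class:`SeedHit` records, so the rest of the pipeline is
agnostic to which scanner produced them.

Scores are log-odds in bits: ``score_c(a) = log2(P_c(a) / bg(a))`` with
``P_c(a) = (count_c(a) + tau * bg(a)) / (n_c + tau)`` for pseudocount weight
``tau``.  A profile accepts a hit when the best window's summed score reaches
the profile's gathering threshold, by default 60% of the score of the
profile's own consensus sequence (a calibrated stand-in for Pfam gathering
cutoffs, which are not derivable from an alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "ProfileModel",
    "SeedHit",
    "build_profile",
    "scan_protein",
    "scan_proteins",
    "parse_domain_table",
    "read_alignment",
    "write_hits_tsv",
    "read_hits_tsv",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP_CHARS = frozenset("-.")

_ENCODE = np.full(128, 20, dtype=np.int64)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a protein string to alphabet indices; X/unknown -> 20."""
    raw = np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)
    return _ENCODE[np.minimum(raw, 127)]


@dataclass(frozen=True)
class SeedHit:
    """A seed-domain match on one protein (best window only)."""

    protein_id: str
    genome_id: str
    bits: float
    env_start: int  # 1-based inclusive
    env_end: int


@dataclass(frozen=True)
class ProfileModel:
    """Ungapped log-odds profile over the 20-letter amino-acid alphabet."""

    name: str
    log_odds: np.ndarray = field(repr=False)  # (length, 20) bits
    background: np.ndarray = field(repr=False)  # (20,)
    gathering_bits: float = 0.0
    consensus: str = ""

    def __post_init__(self) -> None:
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise ValueError("log_odds must have shape (length, 20)")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds must be finite")
        if self.background.shape != (20,) or np.any(self.background <= 0):
            raise ValueError("background must be 20 strictly positive frequencies")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def scores_with_unknown(self) -> np.ndarray:
        """(length, 21) score table where index 20 (X/unknown) scores 0 bits."""
        return np.concatenate(
            [self.log_odds, np.zeros((self.length, 1))], axis=1
        )

    def score_sequence(self, seq: str) -> float:
        """Score an ungapped sequence of exactly profile length."""
        if len(seq) != self.length:
            raise ValueError("sequence length must equal profile length")
        table = self.scores_with_unknown()
        return float(table[np.arange(self.length), encode(seq)].sum())


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def build_profile(
    alignment: Sequence[str],
    *,
    name: str = "profile",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
    gathering_fraction: float = 0.6,
    gathering_bits: float | None = None,
) -> ProfileModel:
    """Build a PSSM from a gapped alignment.

    Columns with gap occupancy above ``max_gap_fraction`` are discarded.
    ``gathering_bits`` defaults to ``gathering_fraction`` times the score of
    the alignment's own consensus sequence.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("ragged alignment: sequences differ in gapped length")
    bg = uniform_background() if background is None else np.asarray(background, float)

    columns: list[np.ndarray] = []
    consensus: list[str] = []
    for c in range(width):
        chars = [s[c].upper() for s in alignment]
        n_gap = sum(ch in GAP_CHARS for ch in chars)
        if n_gap / len(chars) > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for ch in chars:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        n_eff = counts.sum()
        if n_eff == 0:
            scores = np.zeros(20)
            consensus.append("A")
        else:
            probs = (counts + pseudocount * bg) / (n_eff + pseudocount)
            scores = np.log2(probs / bg)
            consensus.append(ALPHABET[int(np.argmax(counts))])
        columns.append(scores)
    if not columns:
        raise ValueError("all alignment columns are gap-majority")
    log_odds = np.vstack(columns)
    cons = "".join(consensus)
    model = ProfileModel(
        name=name, log_odds=log_odds, background=bg, gathering_bits=0.0, consensus=cons
    )
    if gathering_bits is None:
        gathering_bits = gathering_fraction * model.score_sequence(cons)
    return ProfileModel(
        name=name,
        log_odds=log_odds,
        background=bg,
        gathering_bits=float(gathering_bits),
        consensus=cons,
    )


def scan_protein(
    seq: str,
    profile: ProfileModel,
    *,
    protein_id: str = "",
    genome_id: str = "",
) -> SeedHit | None:
    """Best ungapped placement of the full profile within ``seq``.

    Returns the highest-scoring window (leftmost on ties) if its score
    reaches the gathering threshold, else None.  Proteins shorter than the
    profile never hit.
    """
    L = profile.length
    if len(seq) < L:
        return None
    enc = encode(seq)
    table = profile.scores_with_unknown()
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = table[np.arange(L), windows].sum(axis=1)
    best = int(np.argmax(scores))
    bits = float(scores[best])
    if bits < profile.gathering_bits:
        return None
    return SeedHit(
        protein_id=protein_id,
        genome_id=genome_id,
        bits=bits,
        env_start=best + 1,
        env_end=best + L,
    )


def scan_proteins(
    proteins: Iterable[tuple[str, str, str]],
    profile: ProfileModel,
) -> list[SeedHit]:
    """Scan (protein_id, genome_id, seq) records; one best hit per protein."""
    hits = []
    for protein_id, genome_id, seq in proteins:
        hit = scan_protein(seq, profile, protein_id=protein_id, genome_id=genome_id)
        if hit is not None:
            hits.append(hit)
    return sorted(hits, key=lambda h: (h.genome_id, h.protein_id))


def read_alignment(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read an aligned FASTA or Stockholm file into gapped strings."""
    from Bio import AlignIO

    if fmt is None:
        fmt = "stockholm" if Path(path).suffix in {".sto", ".stk"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in aln]


def parse_domain_table(
    path: str | Path,
    *,
    min_bits: float | None = None,
    genome_of: Mapping[str, str] | None = None,
) -> list[SeedHit]:
    """Parse a HMMER3 per-domain table (``--domtblout`` dialect).

    Whitespace-delimited; target name in column 1, full-sequence bit score in
    column 8, envelope from/to in columns 20-21; ``#`` lines are comments.
    ``genome_of`` maps protein ids to genome ids (defaults to empty string).
    Rows below ``min_bits`` are dropped.
    """
    hits: list[SeedHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 21:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=21 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                bits = float(fields[7])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score or envelope field"
                ) from exc
            if min_bits is not None and bits < min_bits:
                continue
            pid = fields[0]
            hits.append(
                SeedHit(
                    protein_id=pid,
                    genome_id=(genome_of or {}).get(pid, ""),
                    bits=bits,
                    env_start=env_start,
                    env_end=env_end,
                )
            )
    return hits


def write_hits_tsv(hits: Sequence[SeedHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgenome_id\tbits\tenv_start\tenv_end\n")
        for h in sorted(hits, key=lambda h: (h.genome_id, h.protein_id)):
            fh.write(
                f"{h.protein_id}\t{h.genome_id}\t{h.bits:.4f}\t{h.env_start}\t{h.env_end}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SeedHit]:
    import csv

    hits = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hits.append(
                SeedHit(
                    protein_id=row["protein_id"],
                    genome_id=row["genome_id"],
                    bits=float(row["bits"]),
                    env_start=int(row["env_start"]),
                    env_end=int(row["env_end"]),
                )
            )
    return hits
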