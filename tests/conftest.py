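"""Shared fixtures: hand-built mini genomes and session-scoped simulations.

The expensive end-to-end pipeline runs (default study conditions, the
reordered and mirrored variants, the large order-statistics corpus) are
session-scoped so that unit, property and acceptance tests share them.
"""

from __future__ import annotations

import pytest

from panta.genome import GeneFeature, Genome, GenomeMetadata, Replicon, build_genome
from panta.pipeline import PipelineConfig, run_pipeline
from panta.profile_scan import build_profile
from panta.simulate import SimConfig, simulate_pangenome

DEFAULT_SEED = 1
REPLICATE_SEEDS = (1, 2, 3, 4, 5)
ORDER_STATS_SEED = 7  # fixed up front for the stochastic order-fraction check


def make_genome(
    genome_id: str,
    genes: list[tuple[str, int, int, str, str]],
    *,
    species: str | None = None,
    length_nt: int = 100_000,
    kind: str = "chromosome",
    is_complete: bool = True,
) -> Genome:
    """Build a one-replicon genome from (name, start, end, strand, aa_seq)."""
    rid = f"{genome_id}_chr"
    features = [
        GeneFeature(
            feature_id=f"{genome_id}_{name}",
            replicon_id=rid,
            start_nt=start,
            end_nt=end,
            strand=strand,
            rank=0,
            protein_id=f"{genome_id}_{name}",
            product=name,
            aa_seq=seq,
        )
        for name, start, end, strand, seq in genes
    ]
    meta = GenomeMetadata(
        genome_id=genome_id,
        species=species or genome_id,
        is_complete=is_complete,
        replicon_kinds={rid: kind},
    )
    return build_genome(
        genome_id,
        (Replicon(replicon_id=rid, genome_id=genome_id, kind=kind, length_nt=length_nt),),
        features,
        metadata=meta,
    )


@pytest.fixture(scope="session")
def default_sim():
    return simulate_pangenome(SimConfig(rng_seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_profile(default_sim):
    return build_profile(list(default_sim.seed_alignment), name="seed")


@pytest.fixture(scope="session")
def hth_profile(default_sim):
    return build_profile(list(default_sim.hth_alignment), name="hth")


@pytest.fixture(scope="session")
def default_result(default_sim, default_profile, hth_profile):
    return run_pipeline(
        default_sim.genomes, default_profile, hth_profile=hth_profile
    )


@pytest.fixture(scope="session")
def reordered_result(default_sim, default_profile, hth_profile):
    return run_pipeline(
        tuple(reversed(default_sim.genomes)), default_profile, hth_profile=hth_profile
    )


@pytest.fixture(scope="session")
def mirrored_result(default_sim, default_profile, hth_profile):
    from panta.genome import mirror_genome

    return run_pipeline(
        [mirror_genome(g) for g in default_sim.genomes],
        default_profile,
        hth_profile=hth_profile,
    )


@pytest.fixture(scope="session")
def replicate_runs():
    """Five seeded replicates of the default conditions, scored lazily."""
    runs = []
    for seed in REPLICATE_SEEDS:
        sim = simulate_pangenome(SimConfig(rng_seed=seed))
        profile = build_profile(list(sim.seed_alignment), name="seed")
        runs.append((sim, run_pipeline(sim.genomes, profile)))
    return runs


@pytest.fixture(scope="session")
def order_stats_run():
    """Large flat corpus for gene-order statistics: 250 families x 2 species."""
    cfg = SimConfig(
        rng_seed=ORDER_STATS_SEED,
        n_species=500,
        genomes_per_species=1,
        n_toxin_families=250,
        genes_per_replicon=6,
        frac_toxin_first=0.25,
        frac_with_accessory=0.0,
        frac_hth_extension=0.0,
        frac_pad1_extension=0.0,
        decoy_adjacent=0,
        decoy_background=0,
    )
    sim = simulate_pangenome(cfg)
    profile = build_profile(list(sim.seed_alignment), name="seed")
    return cfg, sim, run_pipeline(sim.genomes, profile)
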