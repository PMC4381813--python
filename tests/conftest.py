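"""Shared fixtures: small synthetic communities and libraries.

The heavyweight three-species end-to-end run is session-scoped so the
acceptance-style checks (community recovery, purity, 3D separation) share
one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from meta3c import (HPAII, BinningScheme, LibraryConfig, binning, contact_map,
                    digest_genome, make_bins, simulate, structure3d)
from meta3c.simulate import three_species_default


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_community():
    """Two small species (120 kb + 80 kb), enough for fast graph tests."""
    cfg = simulate.CommunityConfig(
        species=(
            simulate.SpeciesSpec(
                "spA", (simulate.RepliconSpec("spA_chr", 120_000, True),)),
            simulate.SpeciesSpec(
                "spB", (simulate.RepliconSpec("spB_chr", 80_000, True),)),
        ),
        seed=7,
    )
    return simulate.simulate_genomes(cfg)


@pytest.fixture(scope="session")
def three_species_run():
    """Full-scale three-species mix: 2e6 pairs, cross-species background at
    the observed 0.37% level; everything downstream shares this run."""
    community = simulate.simulate_genomes(three_species_default(seed=42))
    contigs, truth = simulate.simulate_contigs(community, target_n50=20_000,
                                               p_chimeric_join=0.0, seed=43)
    lib = LibraryConfig(n_pairs=2_000_000, p_regular=0.8, alpha=1.0,
                        p_trans_replicon=0.2, p_chimera=0.0037)
    pairs = simulate.simulate_pairs(community, lib, seed=44)
    return {"community": community, "contigs": contigs, "truth": truth,
            "pairs": pairs, "lib": lib}


@pytest.fixture(scope="session")
def three_species_partition(three_species_run):
    """Chunk graph + Louvain partition of the shared three-species run."""
    run = three_species_run
    on_contigs = simulate.map_pairs_to_contigs(run["pairs"], run["truth"])
    lengths = run["truth"].groupby("contig")["c_end"].max().to_dict()
    chunks = binning.chunk_contigs(lengths, binning.ChunkParams(2500))
    graph, rejected = binning.build_graph(on_contigs, chunks)
    partition = binning.louvain_partition(
        graph, binning.PartitionParams(resolution=0.3, repeats=3, seed=5))
    table = binning.assign_contigs(partition, chunks)
    return {"chunks": chunks, "graph": graph, "partition": partition,
            "table": table, "rejected": rejected}


@pytest.fixture(scope="session")
def three_species_scn(three_species_run):
    """SCN-normalized 10 kb contact map of the shared run."""
    run = three_species_run
    frag_map = digest_genome(run["community"].replicons.values(), HPAII)
    bins = make_bins(frag_map, BinningScheme("basepairs", 10_000))
    cm = contact_map.build_matrix(run["pairs"], bins)
    return contact_map.scn_normalize(cm)


@pytest.fixture(scope="session")
def three_species_structure(three_species_scn):
    structures = structure3d.embed_contact_map(three_species_scn)
    assert structures, "joint contact map should embed"
    return structures[0]
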