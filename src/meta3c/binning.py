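"""Species deconvolution of contigs from 3C contact data.

Because contacts are overwhelmingly intra-cellular, the weighted graph of
3C contacts between contigs decomposes into densely connected groups — one
per genome in the mixture.  The steps:

1. :func:`chunk_contigs` — contigs longer than a threshold (2.5 kb by
   default) are split into equal-sized chunks so that long contigs, which
   accumulate more contacts simply by being long, do not dominate the
   clustering;
2. :func:`build_graph` — chunk-level contact graph, edge weight = number of
   pairs joining the two chunks;
3. :func:`louvain_partition` — modularity-based community detection
   (Louvain) with a resolution parameter and best-of-``repeats`` restarts;
4. :func:`assign_contigs` — chunk communities reconciled into per-contig
   calls by length-weighted majority;
5. :func:`filter_communities` — size filter and summary of the significant
   communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChunkParams:
    """Contig splitting rule: a contig of length L > ``split_threshold``
    becomes ``floor(L / split_threshold)`` equal-sized chunks (lengths
    within 1 bp); shorter contigs stay whole."""

    split_threshold: int = 2500


@dataclass(frozen=True)
class PartitionParams:
    """Louvain parameters: ``resolution`` scales the null-model term of
    modularity (higher -> more, smaller communities); ``repeats`` restarts
    with distinct sub-seeds keep the best-modularity partition."""

    resolution: float = 1.0
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class Partition:
    """Community assignment of chunk nodes."""

    membership: dict[str, int]
    modularity: Optional[float]      # None for an edgeless graph
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def members(self, community: int) -> list[str]:
        return [n for n, c in self.membership.items() if c == community]


def chunk_contigs(contig_lengths: Mapping[str, int],
                  params: ChunkParams = ChunkParams()) -> pd.DataFrame:
    """Split contigs into chunks; returns a table with one row per chunk:
    ``chunk, contig, chunk_index, start, end, length``.  Chunks tile each
    contig exactly and differ by at most 1 bp within a contig."""
    rows = []
    th = params.split_threshold
    for contig, L in contig_lengths.items():
        if L < 1:
            raise ValueError(f"contig {contig!r} has non-positive length")
        k = max(L // th, 1) if L > th else 1
        bounds = np.linspace(0, L, k + 1).round().astype(int)
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            rows.append((f"{contig}|{i}", contig, i, int(a), int(b),
                         int(b - a)))
    return pd.DataFrame(rows, columns=["chunk", "contig", "chunk_index",
                                       "start", "end", "length"])


def chunk_of_positions(chunks: pd.DataFrame, refs: np.ndarray,
                       positions: np.ndarray) -> np.ndarray:
    """Vectorized (contig, position) -> chunk name lookup; unknown contigs
    map to None."""
    out = np.full(len(refs), None, dtype=object)
    per_contig = {c: g for c, g in chunks.groupby("contig", sort=False)}
    refs = np.asarray(refs)
    positions = np.asarray(positions, dtype=np.int64)
    for name in pd.unique(refs):
        if name not in per_contig:
            continue
        g = per_contig[name]
        starts = g["start"].to_numpy()
        sel = refs == name
        i = np.searchsorted(starts, positions[sel], side="right") - 1
        i = np.clip(i, 0, len(starts) - 1)
        out[sel] = g["chunk"].to_numpy()[i]
    return out


def build_graph(pairs: pd.DataFrame, chunks: pd.DataFrame
                ) -> tuple[nx.Graph, int]:
    """Chunk-level contact graph.

    Edge weight = number of pairs joining the two chunks; pairs within one
    chunk carry no inter-chunk information and are discarded; chunks with no
    inter-chunk contact remain as isolated nodes.  Returns the graph and the
    count of pairs rejected for naming unknown contigs.
    """
    g = nx.Graph()
    g.add_nodes_from(chunks["chunk"])
    c1 = chunk_of_positions(chunks, pairs["ref1"].to_numpy(),
                            pairs["pos1"].to_numpy())
    c2 = chunk_of_positions(chunks, pairs["ref2"].to_numpy(),
                            pairs["pos2"].to_numpy())
    known = np.array([a is not None and b is not None
                      for a, b in zip(c1, c2)])
    rejected = int((~known).sum())
    if rejected:
        logger.warning("build_graph: rejected %d pairs on unknown contigs",
                       rejected)
    inter = known & (c1 != c2)
    edges = pd.DataFrame({"u": c1[inter], "v": c2[inter]})
    # canonical orientation so (u,v) and (v,u) pool together
    swap = edges["u"] > edges["v"]
    edges.loc[swap, ["u", "v"]] = edges.loc[swap, ["v", "u"]].to_numpy()
    counts = edges.groupby(["u", "v"], sort=False).size()
    g.add_weighted_edges_from((u, v, int(w)) for (u, v), w in counts.items())
    return g, rejected


def louvain_partition(g: nx.Graph,
                      params: PartitionParams = PartitionParams()
                      ) -> Partition:
    """Louvain modularity optimization on the weighted contact graph.

    Runs ``repeats`` times with sub-seeds derived from ``seed`` and keeps
    the partition with the highest modularity (at the same resolution).
    An edgeless graph degenerates to one community per node with undefined
    modularity (reported as None).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        logger.warning("louvain_partition: graph has no edges; "
                       "every node is its own community")
        return Partition({n: i for i, n in enumerate(g.nodes)}, None,
                         params.resolution, params.seed)
    best: Optional[tuple[float, list[set]]] = None
    for r in range(params.repeats):
        sub_seed = (params.seed + 1_000_003 * r) % (2 ** 31)
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=params.resolution, seed=sub_seed)
        q = nx.community.modularity(g, comms, weight="weight",
                                    resolution=params.resolution)
        if best is None or q > best[0]:
            best = (q, comms)
    q, comms = best
    membership = {n: i for i, c in enumerate(comms) for n in c}
    return Partition(membership, float(q), params.resolution, params.seed)


def assign_contigs(partition: Partition, chunks: pd.DataFrame,
                   agreement_threshold: float = 0.5) -> pd.DataFrame:
    """Reconcile chunk communities into per-contig calls.

    Each contig goes to the community holding the majority of its chunk
    length; the agreement fraction is reported.  Ties and agreement below
    ``agreement_threshold`` leave the contig unattributed (community -1).
    Returns ``contig, community, agreement, length, unattributed``.
    """
    df = chunks.copy()
    df["community"] = df["chunk"].map(partition.membership)
    if df["community"].isna().any():
        raise ValueError("partition does not cover all chunks")
    rows = []
    for contig, g in df.groupby("contig", sort=False):
        by_c = g.groupby("community")["length"].sum().sort_values(
            ascending=False)
        total = int(g["length"].sum())
        top = float(by_c.iloc[0])
        tie = len(by_c) > 1 and by_c.iloc[1] == by_c.iloc[0]
        agreement = top / total
        unattributed = tie or agreement < agreement_threshold
        rows.append((contig, -1 if unattributed else int(by_c.index[0]),
                     agreement, total, unattributed))
    return pd.DataFrame(rows, columns=["contig", "community", "agreement",
                                       "length", "unattributed"])


def filter_communities(contig_table: pd.DataFrame, min_length: int = 0
                       ) -> pd.DataFrame:
    """Community summary with a significance flag by total contig length.

    Returns ``community, n_contigs, total_length, significant`` (the
    unattributed pseudo-community -1 is excluded).  The log records the
    count, total and median size of the significant communities.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    attributed = contig_table[contig_table["community"] >= 0]
    if len(attributed) == 0:
        logger.info("filter_communities: no attributed contigs")
        return pd.DataFrame(columns=["community", "n_contigs", "total_length",
                                     "significant"])
    summary = (attributed.groupby("community")
               .agg(n_contigs=("contig", "size"),
                    total_length=("length", "sum"))
               .reset_index())
    summary["significant"] = summary["total_length"] >= min_length
    sig = summary[summary["significant"]]
    if len(sig):
        logger.info("filter_communities: %d significant communities, "
                    "total %.3g bp, median %.3g bp", len(sig),
                    sig["total_length"].sum(),
                    float(sig["total_length"].median()))
    return summary


# ---------------------------------------------------------------------------
# exports for force-directed visualization (Gephi-style workflows)


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v, w in g.edges(data="weight", default=1):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_weighted_edges_from(df.itertuples(index=False, name=None))
    return g


def write_graphml(g: nx.Graph, path: str | Path,
                  partition: Optional[Partition] = None) -> None:
    if partition is not None:
        g = g.copy()
        nx.set_node_attributes(g, partition.membership, "community")
    nx.write_graphml(g, str(path))
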