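"""End-to-end orchestration of a synthetic meta3C analysis.

Stages (in dependency order): ``simulate`` -> ``digest`` ->
``pairs2matrix`` -> ``normalize`` -> ``bin`` -> ``structure`` ->
``features`` -> ``evaluate``.  Each stage reads the plain-text artifacts of
its predecessors from the output directory, writes its own (TSV/FASTA
only), and records a manifest (parameters, sub-seed, output checksums).
Re-running a completed stage with an unchanged configuration is a no-op;
re-running the whole pipeline with the same seed reproduces the outputs
byte for byte.  Every stochastic stage derives its sub-seed
deterministically from the global seed and the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import binning, contact_map, evaluation, features, simulate, structure3d
from .genome_digest import (ENZYMES, BinningScheme, BinTable, digest_genome,
                            make_bins, read_fasta)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "digest", "pairs2matrix", "normalize", "bin",
          "structure", "features", "evaluate"]


@dataclass
class RunConfig:
    """All pipeline parameters; one global seed rules every stage."""

    outdir: str = "meta3c_run"
    seed: int = 0
    # simulate
    n_pairs: int = 2_000_000
    p_regular: float = 0.8
    alpha: float = 1.0
    p_trans_replicon: float = 0.2
    p_chimera: float = 0.0037
    target_n50: int = 20_000
    p_chimeric_join: float = 0.0
    community: str = "three_species"     # or "fprime"
    # digest / binning scheme
    enzyme: str = "HpaII"
    bin_mode: str = "basepairs"
    bin_width: int = 10_000
    # normalize
    scn_tol: float = 1e-6
    scn_max_iter: int = 100
    # bin (community detection); resolution below 1 because polymer decay
    # makes intra-genome contact graphs locally dense and modularity at
    # r = 1 splits genomes into arc-shaped sub-communities — the species
    # level is a broad plateau (r ~ 0.05-0.5 on the default mix)
    chunk_size: int = 2500
    resolution: float = 0.3
    repeats: int = 3
    min_community_length: int = 100_000
    # features
    dup_ratio_threshold: float = 1.6
    dup_min_bins: int = 3
    # structure
    mask: tuple = ()                     # ((replicon, start, end), ...)

    def sub_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mask"] = [list(m) for m in self.mask]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data["mask"] = tuple(tuple(m) for m in data.get("mask", ()))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class MissingArtifact(RuntimeError):
    """An upstream stage has not been run yet."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig, stage: str) -> str:
    payload = {"stage": stage, **config.to_dict()}
    payload.pop("outdir", None)       # runs must be relocatable
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"manifest_{stage}.json"


def _write_manifest(outdir: Path, stage: str, config: RunConfig,
                    outputs: Sequence[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config, stage),
        "sub_seed": config.sub_seed(stage),
        "parameters": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _manifest_path(outdir, stage).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_done(outdir: Path, stage: str, config: RunConfig) -> bool:
    mp = _manifest_path(outdir, stage)
    if not mp.exists():
        return False
    try:
        manifest = json.loads(mp.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("config_hash") != _config_hash(config, stage):
        return False
    outputs = manifest.get("outputs", {})
    return all((outdir / name).exists()
               and _sha256(outdir / name) == digest
               for name, digest in outputs.items())


def _require(outdir: Path, name: str, stage_needed: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise MissingArtifact(
            f"missing {name}: run the {stage_needed!r} stage first")
    return p


def _community(config: RunConfig) -> simulate.CommunityConfig:
    seed = config.sub_seed("simulate")
    if config.community == "three_species":
        return simulate.three_species_default(seed)
    if config.community == "fprime":
        return simulate.fprime_community(seed)
    raise ValueError(f"unknown community preset {config.community!r}")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    com_cfg = _community(config)
    rng = np.random.default_rng(config.sub_seed("simulate"))
    community = simulate.simulate_genomes(com_cfg, rng)
    contigs, truth = simulate.simulate_contigs(
        community, config.target_n50, config.p_chimeric_join, rng=rng)
    lib = simulate.LibraryConfig(
        n_pairs=config.n_pairs, p_regular=config.p_regular,
        alpha=config.alpha, p_trans_replicon=config.p_trans_replicon,
        p_chimera=config.p_chimera)
    pairs = simulate.simulate_pairs(community, lib, rng=rng)
    community.write_fasta(outdir / "genomes.fasta")
    simulate.write_contigs_fasta(contigs, outdir / "contigs.fasta")
    simulate.write_pairs(pairs, outdir / "pairs.tsv")
    simulate.write_truth(truth, outdir / "contig_truth.tsv")
    meta = {"replicons": {n: {"length": len(r), "circular": r.circular,
                              "species": community.species_of[n]}
                          for n, r in community.replicons.items()},
            "duplication": dataclasses.asdict(community.duplication)
            if community.duplication else None}
    (outdir / "community.json").write_text(json.dumps(meta, indent=2,
                                                      sort_keys=True) + "\n")
    _write_manifest(outdir, "simulate", config,
                    [outdir / f for f in ("genomes.fasta", "contigs.fasta",
                                          "pairs.tsv", "contig_truth.tsv",
                                          "community.json")])


def _load_community_meta(outdir: Path) -> dict:
    return json.loads(_require(outdir, "community.json", "simulate")
                      .read_text())


def _load_bin_table(config: RunConfig, outdir: Path) -> BinTable:
    meta = _load_community_meta(outdir)
    circ = {n: v["circular"] for n, v in meta["replicons"].items()}
    replicons = read_fasta(_require(outdir, "genomes.fasta", "simulate"),
                           circular=circ)
    frag_map = digest_genome(replicons, ENZYMES[config.enzyme])
    scheme = BinningScheme(config.bin_mode, config.bin_width)
    return make_bins(frag_map, scheme)


def stage_digest(config: RunConfig, outdir: Path) -> None:
    bin_table = _load_bin_table(config, outdir)
    bin_table.frag_map.to_tsv(outdir / "fragments.tsv")
    bin_table.bins.to_csv(outdir / "bins.tsv", sep="\t", index=False)
    _write_manifest(outdir, "digest", config,
                    [outdir / "fragments.tsv", outdir / "bins.tsv"])


def stage_pairs2matrix(config: RunConfig, outdir: Path) -> None:
    pairs = simulate.read_pairs(_require(outdir, "pairs.tsv", "simulate"))
    pairs, n_dup = contact_map.dedup_pairs(pairs)
    bin_table = _load_bin_table(config, outdir)
    cm = contact_map.build_matrix(pairs, bin_table)
    contact_map.write_matrix_tsv(cm, outdir / "matrix_raw.tsv")
    (outdir / "pairs_stats.json").write_text(json.dumps(
        {"n_pairs": len(pairs), "duplicates_removed": n_dup,
         "rejected": cm.rejected_pairs}, sort_keys=True) + "\n")
    _write_manifest(outdir, "pairs2matrix", config,
                    [outdir / "matrix_raw.tsv", outdir / "pairs_stats.json"])


def stage_normalize(config: RunConfig, outdir: Path) -> None:
    cm = contact_map.read_matrix_tsv(
        _require(outdir, "matrix_raw.tsv", "pairs2matrix"))
    scn = contact_map.scn_normalize(cm, tol=config.scn_tol,
                                    max_iter=config.scn_max_iter)
    contact_map.write_matrix_tsv(scn, outdir / "matrix_scn.tsv")
    _write_manifest(outdir, "normalize", config, [outdir / "matrix_scn.tsv"])


def stage_bin(config: RunConfig, outdir: Path) -> None:
    pairs = simulate.read_pairs(_require(outdir, "pairs.tsv", "simulate"))
    truth = simulate.read_truth(
        _require(outdir, "contig_truth.tsv", "simulate"))
    on_contigs = simulate.map_pairs_to_contigs(pairs, truth)
    lengths = truth.groupby("contig")["c_end"].max().to_dict()
    chunks = binning.chunk_contigs(lengths,
                                   binning.ChunkParams(config.chunk_size))
    graph, _ = binning.build_graph(on_contigs, chunks)
    partition = binning.louvain_partition(
        graph, binning.PartitionParams(config.resolution, config.repeats,
                                       config.sub_seed("bin")))
    table = binning.assign_contigs(partition, chunks)
    summary = binning.filter_communities(table, config.min_community_length)
    binning.write_edge_list(graph, outdir / "graph.tsv")
    binning.write_graphml(graph, outdir / "graph.graphml", partition)
    table.to_csv(outdir / "contig_communities.tsv", sep="\t", index=False,
                 float_format="%.6g")
    summary.to_csv(outdir / "community_summary.tsv", sep="\t", index=False)
    _write_manifest(outdir, "bin", config,
                    [outdir / f for f in ("graph.tsv", "graph.graphml",
                                          "contig_communities.tsv",
                                          "community_summary.tsv")])


def stage_structure(config: RunConfig, outdir: Path) -> None:
    cm = contact_map.read_matrix_tsv(
        _require(outdir, "matrix_scn.tsv", "normalize"))
    if config.mask:
        cm = contact_map.mask_regions(cm, config.mask)
    structures = structure3d.embed_contact_map(cm)
    reports = []
    for i, s in enumerate(structures):
        structure3d.write_structure_tsv(s, outdir / f"structure_{i}.tsv")
        structure3d.write_structure_xyz(s, outdir / f"structure_{i}.xyz")
        reports.append({"component": i, "n_bins": s.n,
                        "stress": round(s.stress, 6),
                        "eigenvalues": [round(float(v), 6)
                                        for v in s.eigenvalues]})
    (outdir / "structure_report.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True) + "\n")
    outputs = [outdir / "structure_report.json"]
    outputs += [outdir / f"structure_{i}.{ext}"
                for i in range(len(structures)) for ext in ("tsv", "xyz")]
    _write_manifest(outdir, "structure", config, outputs)


def stage_features(config: RunConfig, outdir: Path) -> None:
    pairs = simulate.read_pairs(_require(outdir, "pairs.tsv", "simulate"))
    bin_table = _load_bin_table(config, outdir)
    cov = features.coverage_track(pairs, bin_table)
    calls = features.detect_duplications(cov, config.dup_ratio_threshold,
                                         config.dup_min_bins)
    features.write_track_tsv(cov, outdir / "coverage.tsv")
    features.write_duplications_bed(calls, outdir / "duplications.tsv")
    _write_manifest(outdir, "features", config,
                    [outdir / "coverage.tsv", outdir / "duplications.tsv"])


def stage_evaluate(config: RunConfig, outdir: Path) -> None:
    truth = simulate.read_truth(
        _require(outdir, "contig_truth.tsv", "simulate"))
    table = pd.read_csv(_require(outdir, "contig_communities.tsv", "bin"),
                        sep="\t")
    meta = _load_community_meta(outdir)
    lengths = {n: v["length"] for n, v in meta["replicons"].items()}
    species = {n: v["species"] for n, v in meta["replicons"].items()}
    report = evaluation.evaluate_run(table, truth, lengths, species)
    report.to_tsv(outdir / "eval_report.tsv")
    _write_manifest(outdir, "evaluate", config, [outdir / "eval_report.tsv"])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "digest": stage_digest,
    "pairs2matrix": stage_pairs2matrix,
    "normalize": stage_normalize,
    "bin": stage_bin,
    "structure": stage_structure,
    "features": stage_features,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig,
                 stages: Optional[Sequence[str]] = None,
                 force: bool = False) -> Path:
    """Run the selected stages (default: all, in order) into
    ``config.outdir``.  Completed stages with matching manifests are
    skipped unless ``force``."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for stage in stages:
        if not force and _stage_done(outdir, stage, config):
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running (sub-seed %d)", stage,
                    config.sub_seed(stage))
        _STAGE_FUNCS[stage](config, outdir)
    return outdir
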