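"""Synthetic meta3C community simulator.

Generates everything a desk-scale meta3C analysis needs, with ground truth:

* :func:`simulate_genomes` — a mixed community of random genomes, optionally
  with a planted segmental duplication (e.g. a chromosomal interval carried a
  second time by an F'-like plasmid) and shared repeats across species;
* :func:`simulate_contigs` — contigs as contiguous genome slices (standing in
  for a shotgun assembly), optionally with chimeric joins between species;
* :func:`simulate_pairs` — a paired contact library with the statistical
  structure of a real meta3C experiment: ~80% "regular" short-insert
  shotgun-like pairs, religation pairs whose genomic separation s follows a
  polymer-like power law P(s) ~ s**-alpha, intra-cell inter-replicon
  contacts, and a small cross-species chimeric-pair background
  (0.37% by default, the level observed in a controlled three-species mix).

Every draw is taken from a single :class:`numpy.random.Generator`, so a seed
fixes all outputs byte-for-byte.  Truth labels (source species / replicon /
interval for every contig and pair end) ride along in separate columns and
are never consulted by the inference modules; they replace the
reference-genome comparisons one would run on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_digest import Replicon, write_fasta

PAIR_COLUMNS = ["readid", "ref1", "pos1", "strand1", "ref2", "pos2", "strand2"]
LABEL_COLUMNS = ["species1", "species2", "kind"]

_DNA = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# community configuration


@dataclass(frozen=True)
class RepliconSpec:
    name: str
    length: int
    circular: bool = True


@dataclass(frozen=True)
class DuplicationSpec:
    """Plant a copy of ``[start, end)`` of ``source`` at ``target_pos`` of
    ``target`` (overwriting, so replicon lengths are preserved)."""

    source: str
    start: int
    end: int
    target: str
    target_pos: int


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat of ``length`` bp planted ``copies`` times in every species."""

    length: int
    copies: int


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    replicons: tuple[RepliconSpec, ...]
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError(f"species {self.name!r}: abundance must be > 0")


@dataclass(frozen=True)
class CommunityConfig:
    species: tuple[SpeciesSpec, ...]
    duplication: Optional[DuplicationSpec] = None
    shared_repeat: Optional[RepeatSpec] = None
    seed: int = 0


def three_species_default(seed: int = 0) -> CommunityConfig:
    """The default controlled mix: three ~equal-abundance bacteria, one of
    which carries two replicons sharing a cell (a Vibrio-like arrangement)."""
    return CommunityConfig(
        species=(
            SpeciesSpec("sp1", (RepliconSpec("sp1_chr", 1_000_000, True),)),
            SpeciesSpec("sp2", (RepliconSpec("sp2_chr1", 1_000_000, True),
                                RepliconSpec("sp2_chr2", 500_000, True))),
            SpeciesSpec("sp3", (RepliconSpec("sp3_chr", 1_000_000, True),)),
        ),
        seed=seed,
    )


def fprime_community(seed: int = 0,
                     chrom_length: int = 1_000_000,
                     plasmid_length: int = 200_000,
                     dup_start: int = 240_000,
                     dup_end: int = 380_000,
                     plasmid_insert: int = 30_000) -> CommunityConfig:
    """One species carrying an F'-like plasmid: a ~140 kb chromosomal interval
    is duplicated onto the plasmid, so reads from either copy map to the same
    chromosomal reference interval (2x coverage + plasmid-chromosome
    contact enrichment)."""
    return CommunityConfig(
        species=(
            SpeciesSpec("host", (RepliconSpec("host_chr", chrom_length, True),
                                 RepliconSpec("host_plasmid", plasmid_length,
                                              True),)),
        ),
        duplication=DuplicationSpec("host_chr", dup_start, dup_end,
                                    "host_plasmid", plasmid_insert),
        seed=seed,
    )


class Community:
    """A simulated community: replicons grouped by species, plus truth."""

    def __init__(self, config: CommunityConfig):
        self.config = config
        self.replicons: dict[str, Replicon] = {}
        self.species_of: dict[str, str] = {}
        self.duplication = config.duplication
        self.repeat_loci: list[tuple[str, int, int]] = []

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.config.species]

    def replicons_of(self, species: str) -> list[Replicon]:
        return [self.replicons[r.name] for s in self.config.species
                if s.name == species for r in s.replicons]

    def lengths(self) -> dict[str, int]:
        return {name: len(rep) for name, rep in self.replicons.items()}

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.replicons.values(), path)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _DNA[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_genomes(config: CommunityConfig,
                     rng: np.random.Generator | None = None) -> Community:
    """Draw i.i.d.-uniform random genomes and plant the configured features."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    com = Community(config)
    seqs: dict[str, list[str]] = {}
    for sp in config.species:
        for rep in sp.replicons:
            if rep.name in seqs:
                raise ValueError(f"duplicate replicon name {rep.name!r}")
            seqs[rep.name] = list(_random_seq(rng, rep.length))
            com.species_of[rep.name] = sp.name
    dup = config.duplication
    if dup is not None:
        if dup.source not in seqs or dup.target not in seqs:
            raise ValueError("duplication names an unknown replicon")
        seg = seqs[dup.source][dup.start:dup.end]
        if dup.target_pos + len(seg) > len(seqs[dup.target]):
            raise ValueError("duplicated segment does not fit in target")
        seqs[dup.target][dup.target_pos:dup.target_pos + len(seg)] = seg
    if config.shared_repeat is not None:
        rpt = list(_random_seq(rng, config.shared_repeat.length))
        for sp in config.species:
            rep = sp.replicons[0]
            L = rep.length
            for _ in range(config.shared_repeat.copies):
                pos = int(rng.integers(0, L - len(rpt)))
                seqs[rep.name][pos:pos + len(rpt)] = rpt
                com.repeat_loci.append((rep.name, pos, pos + len(rpt)))
    for sp in config.species:
        for rep in sp.replicons:
            com.replicons[rep.name] = Replicon(rep.name, "".join(seqs[rep.name]),
                                               rep.circular)
    return com


# ---------------------------------------------------------------------------
# contigs


def simulate_contigs(community: Community,
                     target_n50: int = 20_000,
                     p_chimeric_join: float = 0.0,
                     tile_length: Optional[int] = None,
                     rng: np.random.Generator | None = None,
                     seed: Optional[int] = None,
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Slice the genomes into contigs with ground-truth source intervals.

    Contig lengths are drawn uniformly in [0.5, 1.5] x ``target_n50`` (or
    exactly ``tile_length`` when given), walking each replicon left to right
    so the slices tile the community exactly.  With probability
    ``p_chimeric_join`` a contig is chimeric: it concatenates its slice with
    an equally sized slice taken from another species' walk.

    Returns ``(contigs, truth)`` where ``contigs`` maps contig name to
    sequence and ``truth`` has one row per source segment:
    ``contig, segment, species, replicon, g_start, g_end, c_start, c_end,
    chimeric``.
    """
    if target_n50 < 1000:
        raise ValueError("target_n50 must be >= 1 kb")
    if rng is None:
        rng = np.random.default_rng(community.config.seed + 1
                                    if seed is None else seed)
    cursors = {name: 0 for name in community.replicons}
    remaining = list(community.replicons)
    contigs: dict[str, str] = {}
    rows = []
    n_ct = 0

    def take(rep_name: str, want: int) -> tuple[str, int, int]:
        rep = community.replicons[rep_name]
        a = cursors[rep_name]
        b = min(a + want, len(rep))
        cursors[rep_name] = b
        if b >= len(rep):
            remaining.remove(rep_name)
        return rep.seq[a:b], a, b

    while remaining:
        # draw from the replicon with most sequence left so species deplete
        # evenly and chimera partners stay available throughout
        rep_name = max(remaining,
                       key=lambda r: len(community.replicons[r]) - cursors[r])
        want = (tile_length if tile_length is not None
                else int(rng.uniform(0.5, 1.5) * target_n50))
        want = max(want, 1000)
        others = [r for r in remaining if r != rep_name and
                  community.species_of[r] != community.species_of[rep_name]]
        chimeric = bool(others) and rng.random() < p_chimeric_join
        name = f"contig_{n_ct:05d}"
        n_ct += 1
        if chimeric:
            half = max(want // 2, 500)
            other = others[int(rng.integers(0, len(others)))]
            s1, a1, b1 = take(rep_name, half)
            s2, a2, b2 = take(other, half)
            contigs[name] = s1 + s2
            rows.append((name, 0, community.species_of[rep_name], rep_name,
                         a1, b1, 0, len(s1), True))
            rows.append((name, 1, community.species_of[other], other,
                         a2, b2, len(s1), len(s1) + len(s2), True))
        else:
            s1, a1, b1 = take(rep_name, want)
            contigs[name] = s1
            rows.append((name, 0, community.species_of[rep_name], rep_name,
                         a1, b1, 0, len(s1), False))
    truth = pd.DataFrame(rows, columns=["contig", "segment", "species",
                                        "replicon", "g_start", "g_end",
                                        "c_start", "c_end", "chimeric"])
    return contigs, truth


def write_contigs_fasta(contigs: dict[str, str], path: str | Path) -> None:
    write_fasta([Replicon(n, s, False) for n, s in contigs.items()], path)


# ---------------------------------------------------------------------------
# pair library


@dataclass(frozen=True)
class LibraryConfig:
    """Statistical description of a meta3C pair library.

    ``p_regular`` — fraction of shotgun-like short-insert pairs (~0.8 in the
    source libraries, since meta3C skips the religation enrichment of Hi-C).
    ``alpha`` — contact-decay exponent of religation pairs, P(s) ~ s**-alpha.
    ``p_trans_replicon`` — fraction of a species' religation pairs joining
    two of its replicons (only meaningful for multi-replicon species).
    ``p_chimera`` — cross-species ligation background (0.37% default).
    ``min_separation`` — decay floor; religation cannot be resolved below
    roughly one restriction fragment, so s is drawn above this (bp).
    """

    n_pairs: int = 1_000_000
    p_regular: float = 0.8
    alpha: float = 1.0
    p_trans_replicon: float = 0.2
    p_chimera: float = 0.0037
    insert_mean: float = 600.0
    insert_sd: float = 100.0
    read_length: int = 100
    min_separation: float = 500.0
    p_duplicate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_regular, self.p_trans_replicon, self.p_chimera,
                  self.p_duplicate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("contact-decay exponent alpha must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def _sample_power_law(rng: np.random.Generator, alpha: float,
                      s_min: np.ndarray, s_max: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw from density ~ s**-alpha on [s_min, s_max]."""
    u = rng.random(len(s_min))
    s_max = np.maximum(s_max, s_min + 1.0)
    if abs(alpha - 1.0) < 1e-12:
        s = s_min * (s_max / s_min) ** u
    else:
        a = 1.0 - alpha
        s = (s_min ** a + u * (s_max ** a - s_min ** a)) ** (1.0 / a)
    return s


def simulate_pairs(community: Community, lib: LibraryConfig,
                   rng: np.random.Generator | None = None,
                   seed: Optional[int] = None,
                   collapse_duplication: bool = True) -> pd.DataFrame:
    """Simulate a meta3C pair library on the community's replicons.

    Each row is a mapped pair: (ref1, pos1, strand1, ref2, pos2, strand2)
    plus truth columns ``species1, species2, kind`` with kind in
    {regular, religation, trans, chimera}.

    With ``collapse_duplication`` (the default) and a planted duplication,
    ends falling inside the plasmid-borne copy are remapped onto the
    chromosomal source interval — emulating a mapper that cannot tell the
    two identical copies apart.  This is what produces the 2x coverage of
    the duplicated region and the plasmid-chromosome contact enrichment.
    """
    if not community.replicons:
        raise ValueError("empty genome set")
    rng = (rng if rng is not None
           else np.random.default_rng(community.config.seed + 2
                                      if seed is None else seed))
    n = lib.n_pairs
    cfg = community.config

    rep_names = np.array(list(community.replicons))
    rep_len = np.array([len(community.replicons[r]) for r in rep_names],
                       dtype=np.int64)
    rep_circ = np.array([community.replicons[r].circular for r in rep_names])
    rep_species = np.array([community.species_of[r] for r in rep_names])
    sp_names = np.array([s.name for s in cfg.species])
    sp_abund = np.array([s.abundance for s in cfg.species], dtype=float)
    sp_abund /= sp_abund.sum()
    # replicon draw weight: abundance x length (copy number x molecule size)
    sp_w = {s: w for s, w in zip(sp_names, sp_abund)}
    rep_w = np.array([sp_w[s] for s in rep_species]) * rep_len
    rep_w /= rep_w.sum()

    # pair class
    u = rng.random(n)
    is_chimera = u < lib.p_chimera
    is_regular = (~is_chimera) & (rng.random(n) < lib.p_regular)
    is_relig = ~(is_chimera | is_regular)

    ref1 = np.empty(n, dtype=np.int64)   # replicon index of end 1
    ref2 = np.empty(n, dtype=np.int64)
    pos1 = np.zeros(n, dtype=np.int64)
    pos2 = np.zeros(n, dtype=np.int64)
    strand1 = rng.choice(np.array(["+", "-"]), size=n)
    strand2 = rng.choice(np.array(["+", "-"]), size=n)
    kind = np.empty(n, dtype=object)

    home = rng.choice(len(rep_names), size=n, p=rep_w)

    # --- regular shotgun pairs: both ends one short insert, inward
    m = int(is_regular.sum())
    if m:
        idx = np.flatnonzero(is_regular)
        r = home[idx]
        L = rep_len[r]
        insert = np.clip(rng.normal(lib.insert_mean, lib.insert_sd, m),
                         2 * lib.read_length, None).astype(np.int64)
        p1 = (rng.random(m) * L).astype(np.int64)
        p2 = p1 + insert
        circ = rep_circ[r]
        p2 = np.where(circ, p2 % L, np.minimum(p2, L - 1))
        ref1[idx] = r
        ref2[idx] = r
        pos1[idx] = p1
        pos2[idx] = p2
        strand1[idx] = "+"
        strand2[idx] = "-"
        kind[idx] = "regular"

    # --- religation pairs: cis with power-law separation, or trans-replicon
    m = int(is_relig.sum())
    if m:
        idx = np.flatnonzero(is_relig)
        r = home[idx]
        sp = rep_species[r]
        multi = np.array([np.sum(rep_species == s) > 1 for s in sp])
        trans = multi & (rng.random(m) < lib.p_trans_replicon)

        # cis religation
        cis = idx[~trans]
        rc = r[~trans]
        L = rep_len[rc].astype(float)
        s_max = np.where(rep_circ[rc], L / 2.0, L - 1.0)
        s_min = np.full(len(cis), float(lib.min_separation))
        s = _sample_power_law(rng, lib.alpha, s_min, s_max).astype(np.int64)
        s = np.maximum(s, 1)
        Li = rep_len[rc]
        p1 = (rng.random(len(cis)) * Li).astype(np.int64)
        sign = np.where(rng.random(len(cis)) < 0.5, 1, -1)
        p2 = p1 + sign * s
        circ = rep_circ[rc]
        p2m = np.mod(p2, Li)
        # linear replicons: reflect out-of-range separations back inside
        p2l = np.where(p2 < 0, p1 + s, np.where(p2 >= Li, p1 - s, p2))
        p2l = np.clip(p2l, 0, Li - 1)
        ref1[cis] = rc
        ref2[cis] = rc
        pos1[cis] = p1
        pos2[cis] = np.where(circ, p2m, p2l)
        kind[cis] = "religation"

        # trans-replicon religation (same cell, different molecule)
        tr = idx[trans]
        if len(tr):
            rt1 = r[trans]
            rt2 = np.empty(len(tr), dtype=np.int64)
            for s_name in np.unique(rep_species[rt1]):
                sel = np.flatnonzero(rep_species[rt1] == s_name)
                cand = np.flatnonzero(rep_species == s_name)
                w = rep_len[cand].astype(float)
                w /= w.sum()
                # partner replicon != home, length-weighted (vectorized
                # rejection sampling)
                draw = rng.choice(cand, size=len(sel), p=w)
                bad = draw == rt1[sel]
                while bad.any():
                    draw[bad] = rng.choice(cand, size=int(bad.sum()), p=w)
                    bad = draw == rt1[sel]
                rt2[sel] = draw
            p1 = (rng.random(len(tr)) * rep_len[rt1]).astype(np.int64)
            p2 = (rng.random(len(tr)) * rep_len[rt2]).astype(np.int64)
            ref1[tr] = rt1
            ref2[tr] = rt2
            pos1[tr] = p1
            pos2[tr] = p2
            kind[tr] = "trans"

    # --- chimeric cross-species pairs
    m = int(is_chimera.sum())
    if m:
        idx = np.flatnonzero(is_chimera)
        if len(sp_names) < 2:
            # single-species community cannot produce cross-species pairs;
            # fold them back into cis religation background
            r = home[idx]
            L = rep_len[r]
            p1 = (rng.random(m) * L).astype(np.int64)
            p2 = (rng.random(m) * L).astype(np.int64)
            ref1[idx] = r
            ref2[idx] = r
            pos1[idx] = p1
            pos2[idx] = p2
            kind[idx] = "religation"
        else:
            sp1 = rng.choice(len(sp_names), size=m, p=sp_abund)
            shift = rng.integers(1, len(sp_names), size=m)
            sp2 = (sp1 + shift) % len(sp_names)

            def draw_rep(sp_idx: np.ndarray) -> np.ndarray:
                out = np.empty(len(sp_idx), dtype=np.int64)
                for si in np.unique(sp_idx):
                    sel = sp_idx == si
                    cand = np.flatnonzero(rep_species == sp_names[si])
                    w = rep_len[cand].astype(float)
                    w /= w.sum()
                    out[sel] = rng.choice(cand, size=int(sel.sum()), p=w)
                return out

            r1 = draw_rep(sp1)
            r2 = draw_rep(sp2)
            ref1[idx] = r1
            ref2[idx] = r2
            pos1[idx] = (rng.random(m) * rep_len[r1]).astype(np.int64)
            pos2[idx] = (rng.random(m) * rep_len[r2]).astype(np.int64)
            kind[idx] = "chimera"

    pairs = pd.DataFrame({
        "readid": [f"read_{i:08d}" for i in range(n)],
        "ref1": rep_names[ref1],
        "pos1": pos1,
        "strand1": strand1,
        "ref2": rep_names[ref2],
        "pos2": pos2,
        "strand2": strand2,
        "species1": rep_species[ref1],
        "species2": rep_species[ref2],
        "kind": kind,
    })

    if collapse_duplication and community.duplication is not None:
        pairs = collapse_duplication_mapping(pairs, community.duplication)

    if lib.p_duplicate > 0:
        dup_n = int(round(lib.p_duplicate * n))
        if dup_n:
            take = rng.integers(0, n, size=dup_n)
            dups = pairs.iloc[take].copy()
            dups["readid"] = [f"dup_{i:08d}" for i in range(dup_n)]
            pairs = pd.concat([pairs, dups], ignore_index=True)

    return pairs


def collapse_duplication_mapping(pairs: pd.DataFrame,
                                 dup: DuplicationSpec) -> pd.DataFrame:
    """Remap ends inside the planted copy back onto the source interval.

    Models read mapping against a reference that carries the duplicated
    sequence once: reads from the second (plasmid-borne) copy align to the
    chromosomal source coordinates.
    """
    pairs = pairs.copy()
    seg_len = dup.end - dup.start
    for ref_col, pos_col in (("ref1", "pos1"), ("ref2", "pos2")):
        inside = ((pairs[ref_col] == dup.target)
                  & (pairs[pos_col] >= dup.target_pos)
                  & (pairs[pos_col] < dup.target_pos + seg_len))
        pairs.loc[inside, pos_col] = (pairs.loc[inside, pos_col]
                                      - dup.target_pos + dup.start)
        pairs.loc[inside, ref_col] = dup.source
    return pairs


# ---------------------------------------------------------------------------
# mapping genome-coordinate pairs onto contigs (the "realignment" step)


def map_pairs_to_contigs(pairs: pd.DataFrame,
                         contig_truth: pd.DataFrame) -> pd.DataFrame:
    """Translate pair ends from genome coordinates to contig coordinates.

    Stands in for realigning the library against the assembly.  Uses the
    contigs' truth intervals; ends falling outside any contig slice (possible
    only if the slices do not tile the genome) are dropped.
    """
    seg = contig_truth.sort_values(["replicon", "g_start"])
    per_rep = {name: g for name, g in seg.groupby("replicon", sort=False)}

    def translate(refs: pd.Series, poss: pd.Series):
        out_ref = np.empty(len(refs), dtype=object)
        out_pos = np.full(len(refs), -1, dtype=np.int64)
        refs_a = refs.to_numpy()
        poss_a = poss.to_numpy()
        for name in pd.unique(refs_a):
            sel = refs_a == name
            if name not in per_rep:
                continue
            g = per_rep[name]
            starts = g["g_start"].to_numpy()
            ends = g["g_end"].to_numpy()
            p = poss_a[sel]
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, None)])
            i = np.clip(i, 0, None)
            c_pos = g["c_start"].to_numpy()[i] + (p - starts[i])
            ctg = g["contig"].to_numpy()[i]
            out_ref[sel] = np.where(ok, ctg, None)
            out_pos[sel] = np.where(ok, c_pos, -1)
        return out_ref, out_pos

    r1, p1 = translate(pairs["ref1"], pairs["pos1"])
    r2, p2 = translate(pairs["ref2"], pairs["pos2"])
    keep = np.array([(a is not None) and (b is not None)
                     for a, b in zip(r1, r2)])
    out = pairs.copy()
    out["ref1"], out["pos1"] = r1, p1
    out["ref2"], out["pos2"] = r2, p2
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def write_pairs(pairs: pd.DataFrame, path: str | Path,
                labels: bool = True) -> None:
    cols = PAIR_COLUMNS + [c for c in LABEL_COLUMNS if labels and c in pairs]
    pairs[cols].to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
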