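"""Sequence and coordinate model for 3C contact maps.

A 3C/Hi-C library measures contacts between *restriction fragments*: the
intervals between consecutive cut sites of the enzyme used to digest the
cross-linked chromatin.  Everything downstream of read mapping is expressed
in fragment coordinates, so this module provides

* :class:`Replicon` — a chromosome or plasmid, possibly circular;
* :class:`Enzyme` — a restriction enzyme as (recognition site, cut offset);
* :func:`digest` / :func:`digest_genome` — in-silico digestion into a
  :class:`FragmentMap`;
* :class:`BinningScheme` / :func:`make_bins` — grouping of fragments into
  the fixed-size bins used for contact matrices (units of N fragments, or
  fixed genomic width in bp applied to fragment start coordinates).

All coordinates are 0-based, half-open.  Circular replicons are first-class:
a cut-site layout with at least one cut on a circle produces a fragment that
wraps the origin, and position lookup handles the wrap transparently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_SITE = re.compile(r"^[ACGT]+$")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Replicon:
    """A single DNA molecule (chromosome or plasmid)."""

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"replicon {self.name!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        if not _VALID_SEQ.match(self.seq):
            raise ValueError(f"replicon {self.name!r}: sequence must be over ACGTN")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition ``site`` cut after ``cut_offset`` bases.

    HpaII (C^CGG) is ``Enzyme("HpaII", "CCGG", 1)``.  Matching is on the
    given strand only; the classic 3C enzymes (HpaII, DpnII, HaeIII) have
    palindromic sites so this loses nothing.  ``N`` in the subject sequence
    never matches.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", self.site.upper())
        if not _VALID_SITE.match(self.site):
            raise ValueError(f"enzyme {self.name!r}: site must be non-empty over ACGT")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"enzyme {self.name!r}: cut offset outside site")


HPAII = Enzyme("HpaII", "CCGG", 1)
DPNII = Enzyme("DpnII", "GATC", 1)
HAEIII = Enzyme("HaeIII", "GGCC", 2)

ENZYMES: Mapping[str, Enzyme] = {e.name: e for e in (HPAII, DPNII, HAEIII)}


@dataclass(frozen=True)
class Fragment:
    """Restriction fragment ``[start, end)`` on ``replicon``.

    For the origin-spanning fragment of a circular replicon, ``end`` exceeds
    the replicon length and the fragment covers ``[start, L) + [0, end - L)``.
    """

    replicon: str
    start: int
    end: int
    wraps: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int, replicon_length: int) -> bool:
        if not self.wraps:
            return self.start <= position < self.end
        return position >= self.start or position < self.end - replicon_length


class FragmentMap:
    """Ordered restriction fragments of one or more replicons.

    Fragments tile each replicon exactly; global fragment indices are
    contiguous and follow the replicon order given at construction.
    """

    def __init__(self, replicon_fragments: Mapping[str, Sequence[Fragment]],
                 replicon_lengths: Mapping[str, int],
                 circular: Mapping[str, bool]):
        self.replicon_names: list[str] = list(replicon_fragments)
        self.lengths: dict[str, int] = dict(replicon_lengths)
        self.circular: dict[str, bool] = dict(circular)
        self.fragments: list[Fragment] = []
        self._offset: dict[str, int] = {}
        self._starts: dict[str, np.ndarray] = {}
        for name in self.replicon_names:
            frags = list(replicon_fragments[name])
            if not frags:
                raise ValueError(f"replicon {name!r} has no fragments")
            self._offset[name] = len(self.fragments)
            self.fragments.extend(frags)
            # Starts are sorted except that a wrap fragment owns the head of
            # the replicon as well; searchsorted on starts plus a wrap check
            # gives O(log n) position lookup.
            self._starts[name] = np.array([f.start for f in frags], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.fragments)

    def n_fragments(self, replicon: str) -> int:
        i = self._offset[replicon]
        j = i + len(self._starts[replicon])
        return j - i

    def fragments_of(self, replicon: str) -> list[Fragment]:
        i = self._offset[replicon]
        return self.fragments[i:i + len(self._starts[replicon])]

    def locate(self, replicon: str, position: int) -> int:
        """Global index of the fragment containing ``position``."""
        return int(self.locate_many(np.array([replicon]), np.array([position]))[0])

    def locate_many(self, replicons: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`locate`; returns global fragment indices."""
        replicons = np.asarray(replicons)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=np.int64)
        for name in np.unique(replicons):
            if name not in self._offset:
                raise KeyError(f"unknown replicon {name!r}")
            sel = replicons == name
            pos = positions[sel]
            L = self.lengths[name]
            if ((pos < 0) | (pos >= L)).any():
                raise ValueError(f"position out of range on replicon {name!r}")
            starts = self._starts[name]
            idx = np.searchsorted(starts, pos, side="right") - 1
            # Positions before the first start belong to the wrap fragment
            # (circular replicon whose last fragment spans the origin).
            frags = self.fragments_of(name)
            if idx.min() < 0 or frags[-1].wraps:
                head = pos < starts[0]
                idx = np.where(head, len(starts) - 1, idx)
                if head.any() and not frags[-1].wraps:
                    raise ValueError(f"position before first fragment on {name!r}")
            out[sel] = idx + self._offset[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(f.replicon, i, f.start, f.end, f.length, f.wraps)
                for i, f in enumerate(self.fragments)]
        return pd.DataFrame(rows, columns=["replicon", "frag_index", "start",
                                           "end", "length", "wraps"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @property
    def median_fragment_length(self) -> float:
        return float(np.median([f.length for f in self.fragments]))


def find_sites(seq: str, enzyme: Enzyme, circular: bool) -> list[int]:
    """Start positions of every site occurrence (overlaps included).

    On a circular sequence, occurrences wrapping the origin are found by
    scanning the sequence extended with its first ``|site|-1`` bases.
    """
    pattern = re.compile(f"(?={re.escape(enzyme.site)})")
    subject = seq + seq[: len(enzyme.site) - 1] if circular else seq
    return [m.start() for m in pattern.finditer(subject) if m.start() < len(seq)]


def digest(replicon: Replicon, enzyme: Enzyme) -> FragmentMap:
    """Digest a single replicon into a :class:`FragmentMap`.

    Cut positions are ``site start + cut_offset``.  A linear replicon with k
    internal cuts yields k+1 fragments; a circular replicon with k >= 1 cuts
    yields k fragments, the last of which wraps the origin (unless a cut
    falls exactly at position 0).  With no cut the whole replicon is one
    fragment.
    """
    L = len(replicon)
    cuts = sorted({(s + enzyme.cut_offset) % L if replicon.circular
                   else s + enzyme.cut_offset
                   for s in find_sites(replicon.seq, enzyme, replicon.circular)})
    if not replicon.circular:
        cuts = [c for c in cuts if 0 < c < L]
    frags: list[Fragment]
    if not cuts:
        frags = [Fragment(replicon.name, 0, L)]
    elif replicon.circular:
        frags = [Fragment(replicon.name, a, b)
                 for a, b in zip(cuts[:-1], cuts[1:])]
        # last fragment runs from the final cut around the origin to the first
        last = Fragment(replicon.name, cuts[-1], cuts[0] + L, wraps=cuts[0] != 0)
        if last.length > 0:
            frags.append(last)
        frags.sort(key=lambda f: f.start)
    else:
        bounds = [0] + cuts + [L]
        frags = [Fragment(replicon.name, a, b)
                 for a, b in zip(bounds[:-1], bounds[1:])]
    return FragmentMap({replicon.name: frags}, {replicon.name: L},
                       {replicon.name: replicon.circular})


def digest_genome(replicons: Iterable[Replicon], enzyme: Enzyme) -> FragmentMap:
    """Digest several replicons into one globally indexed fragment map."""
    frag_lists, lengths, circ = {}, {}, {}
    for rep in replicons:
        if rep.name in frag_lists:
            raise ValueError(f"duplicate replicon name {rep.name!r}")
        single = digest(rep, enzyme)
        frag_lists[rep.name] = single.fragments
        lengths[rep.name] = len(rep)
        circ[rep.name] = rep.circular
    return FragmentMap(frag_lists, lengths, circ)


locate = FragmentMap.locate  # documented free-function alias


@dataclass(frozen=True)
class BinningScheme:
    """How fragments are grouped into matrix bins.

    ``fragments`` mode groups ``width`` consecutive fragments; ``basepairs``
    mode groups fragments by ``floor(start / width)`` so each bin covers a
    fixed genomic window.  Bins never span replicons.
    """

    mode: Literal["fragments", "basepairs"]
    width: int

    def __post_init__(self) -> None:
        if self.mode not in ("fragments", "basepairs"):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if self.width <= 0:
            raise ValueError("bin width must be positive")


class BinTable:
    """Bins of a fragment map under a binning scheme.

    Carries the fragment->bin assignment and bin labels
    (replicon, [start, end)); the currency shared by the contact-map,
    features and 3D modules.
    """

    def __init__(self, frag_map: FragmentMap, scheme: BinningScheme):
        self.frag_map = frag_map
        self.scheme = scheme
        frame = frag_map.to_frame()
        if scheme.mode == "fragments":
            local = frame.groupby("replicon", sort=False).cumcount() // scheme.width
        else:
            local = frame["start"] // scheme.width
        key = pd.DataFrame({"replicon": frame["replicon"], "local": local})
        # stable bin order: replicon order of the map, then local bin index
        uniq = (key.drop_duplicates()
                .sort_values(["replicon", "local"],
                             key=lambda s: (s.map({n: i for i, n in
                                                   enumerate(frag_map.replicon_names)})
                                            if s.name == "replicon" else s))
                .reset_index(drop=True))
        bin_id = {(r, l): i for i, (r, l) in enumerate(zip(uniq["replicon"],
                                                           uniq["local"]))}
        self.fragment_bin = np.array([bin_id[(r, l)] for r, l in
                                      zip(key["replicon"], key["local"])],
                                     dtype=np.int64)
        starts, ends, nfrags = [], [], []
        for i in range(len(uniq)):
            sel = frame[self.fragment_bin == i]
            starts.append(int(sel["start"].min()))
            ends.append(int(sel["end"].max()))
            nfrags.append(len(sel))
        self.bins = pd.DataFrame({
            "bin": np.arange(len(uniq)),
            "replicon": uniq["replicon"].to_numpy(),
            "start": starts,
            "end": ends,
            "n_frags": nfrags,
        })

    def __len__(self) -> int:
        return len(self.bins)

    def bin_of(self, replicons: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized position -> bin via the fragment assignment."""
        frag = self.frag_map.locate_many(replicons, positions)
        return self.fragment_bin[frag]

    def labels(self) -> list[str]:
        return [f"{r}:{s}-{e}" for r, s, e in
                zip(self.bins["replicon"], self.bins["start"], self.bins["end"])]

    def bins_of_replicon(self, replicon: str) -> np.ndarray:
        return self.bins.loc[self.bins["replicon"] == replicon, "bin"].to_numpy()


def make_bins(frag_map: FragmentMap, scheme: BinningScheme) -> BinTable:
    """Group the fragments of ``frag_map`` into bins under ``scheme``."""
    return BinTable(frag_map, scheme)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, circular: Mapping[str, bool] | bool = False
               ) -> list[Replicon]:
    """Read replicons from FASTA. ``circular`` is a flag or per-name mapping."""
    reps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = circular if isinstance(circular, bool) else bool(
            circular.get(rec.id, False))
        reps.append(Replicon(rec.id, str(rec.seq), circ))
    return reps


def write_fasta(replicons: Iterable[Replicon], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.name, description="")
               for r in replicons]
    SeqIO.write(records, str(path), "fasta")
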