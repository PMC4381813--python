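"""Contact matrices from pair tables.

The pipeline here is the classic 3C one: collapse PCR duplicates, assign
each pair end to a restriction fragment, pool fragments into bins, count
pairs per bin pair into a symmetric raw matrix, then balance it with SCN —
sequential component normalization, the iterative column-then-row division
that drives every non-empty row and column sum to 1.  A Pearson-correlation
map of the normalized matrix and bin-level masking (e.g. to remove a
duplicated region from the analysis) round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_digest import BinTable

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric bin x bin contact matrix with bin labels.

    ``state`` is one of ``raw`` (integer counts), ``scn`` (balanced
    frequencies) or ``pearson`` (row-row correlations).
    """

    matrix: np.ndarray
    bins: pd.DataFrame            # columns: bin, replicon, start, end
    state: str = "raw"
    empty_bins: np.ndarray = field(default_factory=lambda: np.array([], int))
    scn_deviation: Optional[float] = None
    scn_iterations: Optional[int] = None
    rejected_pairs: int = 0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if len(self.bins) != m.shape[0]:
            raise ValueError("bin table does not match matrix size")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def labels(self) -> list[str]:
        return [f"{r}:{s}-{e}" for r, s, e in
                zip(self.bins["replicon"], self.bins["start"], self.bins["end"])]

    def bins_of_replicon(self, replicon: str) -> np.ndarray:
        return np.flatnonzero((self.bins["replicon"] == replicon).to_numpy())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.matrix.copy(), self.bins.copy(), self.state,
                             self.empty_bins.copy(), self.scn_deviation,
                             self.scn_iterations, self.rejected_pairs)


# ---------------------------------------------------------------------------
# pair-level operations


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair's two ends canonically: (ref, pos, strand) of end 1
    lexicographically <= end 2.  Contacts are unordered, so this makes
    (i, j) and (j, i) representations identical."""
    a = list(zip(pairs["ref1"], pairs["pos1"], pairs["strand1"]))
    b = list(zip(pairs["ref2"], pairs["pos2"], pairs["strand2"]))
    swap = np.array([x > y for x, y in zip(a, b)])
    out = pairs.copy()
    for c in ("ref", "pos", "strand"):
        c1, c2 = f"{c}1", f"{c}2"
        tmp = out.loc[swap, c1].to_numpy()
        out.loc[swap, c1] = out.loc[swap, c2].to_numpy()
        out.loc[swap, c2] = tmp
    sp = [c for c in ("species1", "species2") if c in out.columns]
    if len(sp) == 2:
        tmp = out.loc[swap, "species1"].to_numpy()
        out.loc[swap, "species1"] = out.loc[swap, "species2"].to_numpy()
        out.loc[swap, "species2"] = tmp
    return out


def dedup_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse PCR duplicates: rows identical on both (ref, pos, strand)
    ends after canonical end ordering keep one representative.  Returns the
    deduplicated table and the number of rows removed."""
    canon = canonicalize_pairs(pairs)
    key_cols = ["ref1", "pos1", "strand1", "ref2", "pos2", "strand2"]
    out = canon.drop_duplicates(subset=key_cols, keep="first")
    removed = len(pairs) - len(out)
    if removed:
        logger.info("dedup_pairs: removed %d duplicate pairs", removed)
    return out.reset_index(drop=True), removed


def interspecies_fraction(pairs: pd.DataFrame) -> float:
    """Fraction of pairs whose ends carry different species truth labels."""
    if "species1" not in pairs or "species2" not in pairs:
        raise ValueError("pair table carries no species labels")
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    return float((pairs["species1"] != pairs["species2"]).mean())


# ---------------------------------------------------------------------------
# matrix construction


def build_matrix(pairs: pd.DataFrame, bin_table: BinTable) -> ContactMatrix:
    """Count pairs into a symmetric raw contact matrix.

    Each pair contributes once: off-diagonal contacts populate both
    triangles, self-bin contacts the diagonal, so the matrix mass
    (upper triangle + diagonal) equals the number of accepted pairs.  Pairs
    naming a replicon unknown to the fragment map are rejected and counted.
    """
    known = set(bin_table.frag_map.replicon_names)
    ok = pairs["ref1"].isin(known) & pairs["ref2"].isin(known)
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("build_matrix: rejected %d pairs on unknown replicons",
                       rejected)
    sub = pairs[ok]
    n = len(bin_table)
    m = np.zeros((n, n), dtype=np.int64)
    if len(sub):
        b1 = bin_table.bin_of(sub["ref1"].to_numpy(), sub["pos1"].to_numpy())
        b2 = bin_table.bin_of(sub["ref2"].to_numpy(), sub["pos2"].to_numpy())
        np.add.at(m, (b1, b2), 1)
        m = m + m.T
        # diagonal was doubled by the transpose sum
        np.fill_diagonal(m, np.diag(m) // 2)
    return ContactMatrix(m, bin_table.bins.copy(), "raw",
                         rejected_pairs=rejected)


def matrix_mass(cm: ContactMatrix) -> float:
    """Upper triangle + diagonal — the accepted pair count of a raw matrix."""
    return float(np.triu(cm.matrix).sum())


# ---------------------------------------------------------------------------
# SCN normalization


def scn_normalize(cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 100,
                  drop_empty: bool = True) -> ContactMatrix:
    """Sequential component normalization.

    Iteratively divides each column by its sum, then each row by its sum,
    until the largest deviation of any row or column sum from 1 is below
    ``tol``; the result is then symmetrized by averaging with its transpose.
    Empty (all-zero) rows/columns cannot be normalized: they are dropped
    from the matrix (``drop_empty``, the default) and recorded in
    ``empty_bins``.  Non-convergence within ``max_iter`` is reported via the
    ``scn_deviation`` diagnostic and a warning, not an exception.
    """
    if cm.state != "raw":
        logger.info("scn_normalize: input state is %r, renormalizing", cm.state)
    m = cm.matrix.astype(float)
    if (m < 0).any():
        raise ValueError("contact matrix must be non-negative")
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix must be symmetric")
    sums = m.sum(axis=0)
    empty = np.flatnonzero(sums == 0)
    if len(empty) == m.shape[0]:
        raise ValueError("all-zero contact matrix cannot be normalized")
    bins = cm.bins
    if drop_empty and len(empty):
        logger.info("scn_normalize: dropping %d empty bins", len(empty))
        keep = np.setdiff1d(np.arange(m.shape[0]), empty)
        m = m[np.ix_(keep, keep)]
        bins = bins.iloc[keep].reset_index(drop=True)
        # dropping bins can empty further rows; iterate until support stable
        while True:
            sums = m.sum(axis=0)
            still = np.flatnonzero(sums == 0)
            if not len(still):
                break
            empty = np.union1d(empty, keep[still])
            keep = np.delete(keep, still)
            m = np.delete(np.delete(m, still, axis=0), still, axis=1)
            bins = bins.drop(bins.index[still]).reset_index(drop=True)

    deviation = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        m = m / m.sum(axis=0, keepdims=True)
        m = m / m.sum(axis=1, keepdims=True)
        # restore symmetry every pass so the convergence criterion is
        # measured on the matrix actually returned
        m = (m + m.T) / 2.0
        deviation = max(np.abs(m.sum(axis=0) - 1).max(),
                        np.abs(m.sum(axis=1) - 1).max())
        if deviation < tol:
            break
    if deviation >= tol:
        logger.warning("scn_normalize: not converged after %d iterations "
                       "(max deviation %.3g)", iterations, deviation)
    return ContactMatrix(m, bins.reset_index(drop=True), "scn",
                         empty_bins=np.asarray(empty, dtype=int),
                         scn_deviation=float(deviation),
                         scn_iterations=iterations,
                         rejected_pairs=cm.rejected_pairs)


# ---------------------------------------------------------------------------
# Pearson map


def pearson_map(cm: ContactMatrix, exclude_diagonal: bool = False
                ) -> ContactMatrix:
    """Row-row Pearson correlation matrix of a normalized contact map.

    Entry (i, j) is the correlation of rows i and j; the diagonal is 1.
    With ``exclude_diagonal`` the self-contact columns i and j are left out
    of each pairwise correlation (pairwise-complete).  Constant rows have
    undefined correlation: their entries are set to 0 and the bins flagged.
    """
    if cm.state != "scn":
        raise ValueError("pearson_map expects an SCN-normalized matrix")
    m = cm.matrix
    n = m.shape[0]
    flagged = np.flatnonzero(m.std(axis=1) == 0)
    if not exclude_diagonal:
        with np.errstate(invalid="ignore"):
            p = np.corrcoef(m)
        p = np.nan_to_num(p, nan=0.0)
    else:
        p = np.zeros((n, n))
        cols = np.arange(n)
        for i in range(n):
            for j in range(i + 1, n):
                sel = (cols != i) & (cols != j)
                x, y = m[i, sel], m[j, sel]
                if x.std() == 0 or y.std() == 0:
                    continue
                p[i, j] = p[j, i] = float(np.corrcoef(x, y)[0, 1])
    np.fill_diagonal(p, 1.0)
    p[flagged, :] = 0.0
    p[:, flagged] = 0.0
    p[flagged, flagged] = 1.0
    if len(flagged):
        logger.warning("pearson_map: %d constant rows set to 0", len(flagged))
    out = ContactMatrix(np.clip(p, -1.0, 1.0), cm.bins.copy(), "pearson",
                        empty_bins=cm.empty_bins.copy())
    return out


# ---------------------------------------------------------------------------
# masking


def mask_regions(cm: ContactMatrix,
                 regions: Sequence[tuple[str, int, int]]) -> ContactMatrix:
    """Remove all bins overlapping any (replicon, start, end) region.

    The matrix shrinks; surviving bins keep their labels.  A region naming
    an unknown replicon or lying wholly outside it is an error.
    """
    bins = cm.bins
    drop = np.zeros(len(bins), dtype=bool)
    for rep, start, end in regions:
        if rep not in set(bins["replicon"]):
            raise ValueError(f"mask region on unknown replicon {rep!r}")
        hit = ((bins["replicon"] == rep)
               & (bins["start"] < end) & (bins["end"] > start)).to_numpy()
        if not hit.any():
            raise ValueError(f"mask region {rep}:{start}-{end} covers no bin")
        drop |= hit
    keep = np.flatnonzero(~drop)
    out = ContactMatrix(cm.matrix[np.ix_(keep, keep)],
                        bins.iloc[keep].reset_index(drop=True), cm.state,
                        empty_bins=cm.empty_bins.copy(),
                        scn_deviation=cm.scn_deviation,
                        scn_iterations=cm.scn_iterations,
                        rejected_pairs=cm.rejected_pairs)
    return out


# ---------------------------------------------------------------------------
# matrix I/O (dense TSV and sparse COO TSV; lossless round trips)


def write_matrix_tsv(cm: ContactMatrix, path: str | Path) -> None:
    labels = cm.labels()
    df = pd.DataFrame(cm.matrix, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(f"# state={cm.state}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        state = header.split("state=")[1] if "state=" in header else "raw"
        df = pd.read_csv(fh, sep="\t", index_col=0)
    bins = _labels_to_bins(df.index)
    m = df.to_numpy(dtype=float)
    if state == "raw":
        m = m.astype(np.int64)
    return ContactMatrix(m, bins, state)


def write_matrix_coo(cm: ContactMatrix, path: str | Path) -> None:
    i, j = np.nonzero(np.triu(cm.matrix != 0))
    df = pd.DataFrame({"bin1": i, "bin2": j, "value": cm.matrix[i, j]})
    with open(path, "w") as fh:
        fh.write(f"# state={cm.state} n_bins={cm.n_bins}\n")
        fh.write("# labels=" + ",".join(cm.labels()) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_matrix_coo(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        meta = fh.readline().strip().lstrip("# ").split()
        state = meta[0].split("=")[1]
        n = int(meta[1].split("=")[1])
        labels = fh.readline().strip().split("labels=")[1].split(",")
        df = pd.read_csv(fh, sep="\t")
    m = np.zeros((n, n))
    m[df["bin1"], df["bin2"]] = df["value"]
    m = np.triu(m) + np.triu(m, 1).T
    if state == "raw":
        m = m.astype(np.int64)
    return ContactMatrix(m, _labels_to_bins(labels), state)


def _labels_to_bins(labels: Iterable[str]) -> pd.DataFrame:
    rows = []
    for i, lab in enumerate(labels):
        rep, interval = lab.rsplit(":", 1)
        start, end = interval.split("-")
        rows.append((i, rep, int(start), int(end)))
    return pd.DataFrame(rows, columns=["bin", "replicon", "start", "end"])


# ---------------------------------------------------------------------------
# optional SAM ingestion


def pairs_from_sam(path: str | Path) -> pd.DataFrame:
    """Read a name-sorted SAM of independently mapped mates into a pair
    table (requires pysam).  Mates are matched by query name; secondary and
    unmapped records are ignored."""
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SAM ingestion requires pysam") from exc
    ends: dict[str, tuple[str, int, str]] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            end = (rec.reference_name, int(rec.reference_start),
                   "-" if rec.is_reverse else "+")
            if rec.query_name in ends:
                other = ends.pop(rec.query_name)
                rows.append((rec.query_name, *other, *end))
            else:
                ends[rec.query_name] = end
    return pd.DataFrame(rows, columns=["readid", "ref1", "pos1", "strand1",
                                       "ref2", "pos2", "strand2"])
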