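"""Coverage and contact-profile analyses: segmental duplications and
plasmid-chromosome relationships.

A segmental duplication collapsed onto a single-copy reference shows up as
a contiguous run of bins at ~2x the median read coverage.  A plasmid
carrying one copy of such a duplication (an F'-like episome) additionally
shows contact enrichment with the duplicated chromosomal interval, and the
correlation between the plasmid's contact profile and each chromosomal
bin's contact row shifts sharply at the duplication boundaries — which
localizes the breakpoints without any sequence comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contact_map import ContactMatrix
from .genome_digest import BinTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage


def coverage_track(pairs: pd.DataFrame, bin_table: BinTable) -> pd.DataFrame:
    """Per-bin pair-end counts, normalized by the genome-wide median.

    Both ends of every pair increment their bin.  Normalization divides by
    the median count over non-empty bins, so the median reported normalized
    coverage is exactly 1; empty bins stay at 0 and are excluded from the
    median.  Returns ``bin, replicon, start, end, count, norm``.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to compute coverage from")
    n = len(bin_table)
    counts = np.zeros(n, dtype=np.int64)
    for ref_col, pos_col in (("ref1", "pos1"), ("ref2", "pos2")):
        b = bin_table.bin_of(pairs[ref_col].to_numpy(),
                             pairs[pos_col].to_numpy())
        counts += np.bincount(b, minlength=n)
    nonempty = counts > 0
    med = float(np.median(counts[nonempty]))
    out = bin_table.bins.copy()
    out["count"] = counts
    out["norm"] = np.where(nonempty, counts / med, 0.0)
    return out


def detect_duplications(coverage: pd.DataFrame, ratio_threshold: float = 1.6,
                        min_bins: int = 3) -> pd.DataFrame:
    """Call duplicated regions as runs of elevated normalized coverage.

    A call is a maximal run of >= ``min_bins`` consecutive bins (within one
    replicon) with normalized coverage >= ``ratio_threshold`` (default 1.6,
    between single copy and the 2x expected for a clean duplication).
    Returns ``replicon, start, end, first_bin, last_bin, n_bins,
    mean_ratio`` — BED-like, one row per call.
    """
    rows = []
    for rep, g in coverage.groupby("replicon", sort=False):
        g = g.sort_values("start")
        hot = (g["norm"] >= ratio_threshold).to_numpy()
        i = 0
        while i < len(hot):
            if not hot[i]:
                i += 1
                continue
            j = i
            while j < len(hot) and hot[j]:
                j += 1
            if j - i >= min_bins:
                run = g.iloc[i:j]
                rows.append((rep, int(run["start"].iloc[0]),
                             int(run["end"].iloc[-1]),
                             int(run["bin"].iloc[0]), int(run["bin"].iloc[-1]),
                             j - i, float(run["norm"].mean())))
            i = j
    return pd.DataFrame(rows, columns=["replicon", "start", "end",
                                       "first_bin", "last_bin", "n_bins",
                                       "mean_ratio"])


# ---------------------------------------------------------------------------
# contact profiles


def contact_profile(cm: ContactMatrix, query_bins: Sequence[int]
                    ) -> pd.DataFrame:
    """Mean normalized contact of the query region with every other bin.

    ``profile[j]`` = mean over query bins i of m[i, j]; the query bins
    themselves (self-contacts) are excluded from the output support.
    Returns ``bin, replicon, start, end, value`` over non-query bins.
    """
    if cm.state != "scn":
        raise ValueError("contact_profile expects an SCN-normalized matrix")
    query = np.asarray(sorted(set(int(q) for q in query_bins)))
    if len(query) == 0:
        raise ValueError("empty query")
    if query.min() < 0 or query.max() >= cm.n_bins:
        raise ValueError("query bins outside matrix")
    others = np.setdiff1d(np.arange(cm.n_bins), query)
    values = cm.matrix[np.ix_(query, others)].mean(axis=0)
    out = cm.bins.iloc[others].reset_index(drop=True).copy()
    out["value"] = values
    return out


@dataclass(frozen=True)
class CorrelationShift:
    """Correlation curve of a query region along the genome, with the
    change-point segment of elevated correlation (if significant)."""

    curve: pd.DataFrame                     # bin, replicon, start, end, r
    change_start: Optional[int]             # first bin of the elevated run
    change_end: Optional[int]               # last bin (inclusive)
    contrast: float                         # mean(inside) - mean(outside)
    flagged_bins: tuple[int, ...]           # constant rows, r forced to 0


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Standardize by median and MAD (falls back to SD for zero MAD)."""
    center = np.median(values)
    mad = np.median(np.abs(values - center))
    scale = 1.4826 * mad if mad > 0 else values.std()
    if scale == 0:
        return np.zeros_like(values)
    return (values - center) / scale


def correlation_shift(cm: ContactMatrix, query_bins: Sequence[int],
                      window: int = 5, alpha: float = 0.01,
                      n_permutations: int = 200,
                      seed: int = 0) -> CorrelationShift:
    """Correlation of the query's contact profile with each bin's contacts.

    For each non-query bin j, computes the Pearson correlation between the
    query's mean contact profile and bin j's contact row, over all bins
    outside the query and outside a ``window``-bin guard around j (local
    contacts are excluded so the short-range decay around j does not
    dominate).  Bins whose contacts mirror the query's — e.g. a chromosomal
    region whose second copy rides on the query plasmid — score high, the
    rest near 0.

    Breakpoints are localized on a composite score: the robust z-scores of
    the correlation curve and of the query's contact profile, added.  The
    correlation shift marks the region qualitatively but smears over a few
    bins through shared distance decay; the profile step at the boundary of
    a duplicated region is bin-sharp; the sum inherits both.  The segment
    maximizing the balanced mean-shift statistic is called a change-point
    only if its score exceeds the (1 - ``alpha``) quantile of the same
    maximum under ``n_permutations`` random permutations of the composite
    curve (circular structure destroyed, so the null is "no contiguous
    elevated segment").
    """
    if cm.state != "scn":
        raise ValueError("correlation_shift expects an SCN-normalized matrix")
    if window < 3:
        raise ValueError("window must be >= 3")
    query = np.asarray(sorted(set(int(q) for q in query_bins)))
    others = np.setdiff1d(np.arange(cm.n_bins), query)
    profile_full = cm.matrix[query].mean(axis=0)
    flagged = []
    r = np.zeros(len(others))
    for k, j in enumerate(others):
        support = others[np.abs(others - j) > window]
        x = profile_full[support]
        y = cm.matrix[j, support]
        if len(support) < 3 or x.std() == 0 or y.std() == 0:
            flagged.append(int(j))
            continue
        r[k] = float(np.corrcoef(x, y)[0, 1])
    curve = cm.bins.iloc[others].reset_index(drop=True).copy()
    curve["r"] = r
    curve["profile"] = profile_full[others]

    # winsorize the z-scores: the profile step at a duplication boundary is
    # tens of MADs high, and unclipped heavy tails let single bins dominate
    # both the scan and its permutation null
    composite = (np.clip(_robust_z(r), -5, 5)
                 + np.clip(_robust_z(profile_full[others]), -5, 5))
    start, end, contrast, score = _best_segment(composite)
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_permutations)
    for b in range(n_permutations):
        null_scores[b] = _best_segment(rng.permutation(composite))[3]
    threshold = float(np.quantile(null_scores, 1.0 - alpha))
    if score > threshold:
        change = (int(others[start]), int(others[end]))
    else:
        change = (None, None)
    r_contrast = _segment_contrast(r, start, end)
    if flagged:
        logger.warning("correlation_shift: %d constant rows set to 0",
                       len(flagged))
    return CorrelationShift(curve, change[0], change[1], float(r_contrast),
                            tuple(flagged))


def _segment_contrast(values: np.ndarray, a: int, b: int) -> float:
    inside = values[a:b + 1]
    outside = np.concatenate([values[:a], values[b + 1:]])
    if len(outside) == 0:
        return 0.0
    return float(inside.mean() - outside.mean())


def _best_segment(values: np.ndarray, min_len: int = 3
                  ) -> tuple[int, int, float, float]:
    """Exhaustive two-boundary scan for a mean shift.

    Selects the contiguous segment [a, b] (>= ``min_len`` bins, by curve
    position) maximizing the balanced mean-shift score
    (mean_in - mean_out) * sqrt(n_in * n_out / n) — the likelihood-ratio
    statistic for a step in the mean, which prefers the full plateau over a
    narrow peak.  Returns (a, b, contrast, score).  Vectorized over all
    O(n^2) segments via prefix sums; n is a bin count, so this is cheap.
    """
    n = len(values)
    if n < min_len + 1:
        return 0, n - 1, 0.0, 0.0
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    total = prefix[-1]
    a_idx, b_idx = np.triu_indices(n, k=min_len - 1)
    keep = (b_idx - a_idx + 1) < n
    a_idx, b_idx = a_idx[keep], b_idx[keep]
    inside = (b_idx - a_idx + 1).astype(float)
    seg_sum = prefix[b_idx + 1] - prefix[a_idx]
    mean_in = seg_sum / inside
    mean_out = (total - seg_sum) / (n - inside)
    contrast = mean_in - mean_out
    score = contrast * np.sqrt(inside * (n - inside) / n)
    k = int(np.argmax(score))
    return int(a_idx[k]), int(b_idx[k]), float(contrast[k]), float(score[k])


# ---------------------------------------------------------------------------
# I/O


def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_duplications_bed(calls: pd.DataFrame, path: str | Path) -> None:
    cols = ["replicon", "start", "end", "mean_ratio"]
    calls[cols].to_csv(path, sep="\t", index=False, float_format="%.4g")
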