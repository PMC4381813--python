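"""3D genome reconstruction from a normalized contact map.

The reconstruction follows the shortest-path distance-geometry recipe used
for single-genome 3C maps: the normalized contact matrix becomes a graph
whose edge weights are inverse contact frequencies (frequent contact =
short), all-pairs shortest-path lengths turn that graph into a metric
(triangle inequality holds by construction), and classical
multidimensional scaling — double-center the squared distances, take the
three leading non-negative eigenpairs — yields bead coordinates per bin.

Circular chromosomes come out as closed rings; a ring-closure diagnostic
quantifies that.  Disconnected contact maps (after masking, or with no
cross-species contacts at all) are embedded one component at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components, shortest_path

from .contact_map import ContactMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path distances; inf marks disconnected pairs."""

    d: np.ndarray
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def components(self) -> np.ndarray:
        finite = np.isfinite(self.d)
        _, labels = connected_components(scipy.sparse.csr_matrix(finite),
                                         directed=False)
        return labels


@dataclass
class Structure3D:
    """Embedded bead coordinates with labels and diagnostics."""

    coords: np.ndarray                      # (n, 3)
    bins: pd.DataFrame
    eigenvalues: np.ndarray                 # top 3 used for the embedding
    stress: float                           # normalized RMS distance error
    negative_eigenvalue_magnitude: float    # |most negative eigenvalue|
    track: Optional[np.ndarray] = None
    track_name: Optional[str] = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def contacts_to_graph(cm: ContactMatrix) -> np.ndarray:
    """Inverse-contact weighted adjacency: w[i, j] = 1 / m[i, j] for every
    off-diagonal m[i, j] > 0, else 0 (= no edge).  Isolated bins (all-zero
    rows) are reported."""
    m = cm.matrix
    if (m < 0).any():
        raise ValueError("contact matrix must be non-negative")
    w = np.zeros_like(m, dtype=float)
    nz = m > 0
    np.fill_diagonal(nz, False)
    w[nz] = 1.0 / m[nz]
    isolated = np.flatnonzero(w.sum(axis=0) == 0)
    if len(isolated):
        logger.warning("contacts_to_graph: %d isolated bins", len(isolated))
    return w


def shortest_path_distances(adjacency: np.ndarray,
                            bins: Optional[pd.DataFrame] = None
                            ) -> DistanceMatrix:
    """All-pairs shortest-path lengths over a non-negative weighted graph.

    Zero entries in ``adjacency`` mean "no edge".  Disconnected pairs stay
    at inf and are reported; structures are then computed per component.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if (adjacency < 0).any():
        raise ValueError("edge weights must be non-negative")
    sparse = scipy.sparse.csr_matrix(adjacency)
    d = shortest_path(sparse, method="auto", directed=False)
    np.fill_diagonal(d, 0.0)
    n_inf = int(np.isinf(d).sum())
    if n_inf:
        logger.info("shortest_path_distances: %d disconnected pairs", n_inf // 2)
    if bins is None:
        bins = pd.DataFrame({"bin": np.arange(d.shape[0])})
    return DistanceMatrix(d, bins)


def embed_3d(dm: DistanceMatrix) -> Structure3D:
    """Classical distance-geometry embedding (Torgerson scaling) in 3D.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are the three leading
    non-negative eigenpairs scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are truncated to zero and their
    magnitude reported.  Axes are ordered by eigenvalue and each axis is
    flipped so its third moment is non-negative, making the output
    reproducible up to the inherent rigid-motion ambiguity.  Stress is the
    normalized RMS deviation between input and embedded distances.
    """
    d = dm.d
    if d.shape[0] < 3:
        raise ValueError("embedding needs at least 3 points")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix must be finite on one component")
    if np.all(d == 0):
        raise ValueError("all distances are zero")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mag = float(max(0.0, -evals.min()))
    top = np.clip(evals[:3], 0.0, None)
    # eigenvalues that are zero at machine precision give spurious ~1e-9
    # coordinates through the square root; truncate them exactly
    top[top < 1e-12 * max(evals.max(), 1e-300)] = 0.0
    coords = evecs[:, :3] * np.sqrt(top)
    # canonical orientation: non-negative third moment on every axis
    for a in range(3):
        if np.sum(coords[:, a] ** 3) < 0:
            coords[:, a] = -coords[:, a]
    emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    stress = float(np.sqrt(np.sum((d - emb) ** 2) / np.sum(d ** 2)))
    return Structure3D(coords, dm.bins.copy(), evals[:3], stress, neg_mag)


def embed_contact_map(cm: ContactMatrix, min_component: int = 3
                      ) -> list[Structure3D]:
    """Full recipe on a normalized map: inverse-contact graph, shortest
    paths, one embedding per connected component of >= ``min_component``
    bins (largest first).  Smaller components are reported and skipped."""
    adj = contacts_to_graph(cm)
    sparse = scipy.sparse.csr_matrix(adj)
    n_comp, labels = connected_components(sparse, directed=False)
    structures = []
    sizes = np.bincount(labels)
    for comp in np.argsort(sizes)[::-1]:
        members = np.flatnonzero(labels == comp)
        if len(members) < max(min_component, 3):
            logger.info("embed_contact_map: skipping component of %d bins",
                        len(members))
            continue
        sub = adj[np.ix_(members, members)]
        dm = shortest_path_distances(
            sub, cm.bins.iloc[members].reset_index(drop=True))
        structures.append(embed_3d(dm))
    if n_comp > 1:
        logger.warning("embed_contact_map: contact map has %d components",
                       n_comp)
    return structures


def attach_track(s: Structure3D, track: Sequence[float],
                 name: str = "track") -> Structure3D:
    """Attach a per-bin scalar (e.g. read coverage) for coloring.

    The track must match the structure's bins — i.e. be computed after any
    masking that shaped the embedding."""
    track = np.asarray(track, dtype=float)
    if track.shape != (s.n,):
        raise ValueError(f"track length {track.shape} does not match "
                         f"{s.n} bins")
    return Structure3D(s.coords, s.bins, s.eigenvalues, s.stress,
                       s.negative_eigenvalue_magnitude, track, name)


@dataclass(frozen=True)
class RingReport:
    """Circularity diagnostics of an embedded replicon."""

    max_over_median_gap: float
    closure_over_median_gap: float
    median_gap: float
    n_bins: int


def ring_diagnostics(s: Structure3D, order: Optional[np.ndarray] = None,
                     circular: bool = True) -> RingReport:
    """Gap statistics along the genomic bin order.

    Reports the ratio of the largest to the median Euclidean gap between
    genomically adjacent beads (including the wrap pair when ``circular``)
    and the closure gap |x_first - x_last| relative to the median gap.  A
    well-reconstructed circular chromosome closes: closure gap comparable
    to the median adjacent gap; a linear one leaves a large closure gap.
    """
    if s.n < 4:
        raise ValueError("ring diagnostics need at least 4 bins")
    coords = s.coords if order is None else s.coords[np.asarray(order)]
    adjacent = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    closure = float(np.linalg.norm(coords[0] - coords[-1]))
    gaps = np.append(adjacent, closure) if circular else adjacent
    median = float(np.median(gaps))
    if median == 0:
        raise ValueError("degenerate embedding: zero median gap")
    return RingReport(float(gaps.max() / median), closure / median,
                      median, s.n)


# ---------------------------------------------------------------------------
# export


def write_structure_tsv(s: Structure3D, path: str | Path) -> None:
    df = s.bins.copy()
    df["x"], df["y"], df["z"] = s.coords.T
    if s.track is not None:
        df[s.track_name or "track"] = s.track
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_structure_xyz(s: Structure3D, path: str | Path,
                        element: str = "C") -> None:
    """Minimal XYZ file for molecular viewers (one pseudo-atom per bin)."""
    with open(path, "w") as fh:
        fh.write(f"{s.n}\n3C reconstruction\n")
        for (x, y, z) in s.coords:
            fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")
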