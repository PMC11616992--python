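"""Local spatial pattern (LSP) comparison of Cα–Cβ vector sets.

Every pair of nodes within a distance cutoff is described by four internal
coordinates that fix the relative pose of two oriented vectors up to global
rotation/translation:

* ``d`` — distance between the two anchors (Å);
* ``alpha_i`` — angle between node i's direction vector and the i→j axis;
* ``alpha_j`` — angle between node j's direction vector and the j→i axis;
* ``tau`` — torsion of the two direction vectors about the inter-anchor
  axis, in (−180°, 180°].

Two frames *match* on a pair when the pair is within the candidate cutoff in
both frames and all four descriptors agree within the tolerances.  Averaging
the binary match matrices over all unordered frame pairs of a time window
yields the window's weighted adjacency matrix: entry (i, j) is the fraction
of frame comparisons in which the local pattern of i and j was conserved.
Ordered regions, whose Cα–Cβ vectors move cohesively, therefore acquire
edge weights near 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensembles import NodeVectorFrame, WindowedEnsemble, check_identical_node_sets
from .errors import ComparisonError, ConfigError, DegenerateInputError, InputError

__all__ = [
    "LSPTolerances",
    "PairDescriptor",
    "AdjacencyMatrix",
    "pair_descriptors",
    "frame_pair_match",
    "build_window_adjacency",
    "write_adjacency_tsv",
    "read_adjacency_tsv",
]


@dataclass(frozen=True)
class LSPTolerances:
    """Candidate cutoff and per-descriptor match tolerances.

    Defaults (12 Å cutoff, 1 Å distance, 15° angles) keep same-rigid-body
    adjacency dense while letting the match fraction degrade smoothly with
    positional/orientational noise; all four are configuration, not claims
    about any published threshold set.
    """

    candidate_cutoff: float = 12.0  # Å
    delta_d: float = 1.0  # Å
    delta_angle: float = 15.0  # degrees, applies to alpha_i and alpha_j
    delta_tau: float = 15.0  # degrees, periodic

    def __post_init__(self) -> None:
        for name in ("candidate_cutoff", "delta_d", "delta_angle", "delta_tau"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"LSP tolerance {name} must be strictly positive")


@dataclass(frozen=True)
class PairDescriptor:
    """Internal-coordinate description of one node pair in one frame."""

    i: int
    j: int
    d: float  # Å
    alpha_i: float  # degrees in [0, 180]
    alpha_j: float  # degrees in [0, 180]
    tau: float  # degrees in (-180, 180]


@dataclass
class AdjacencyMatrix:
    """Per-window node×node LSP match-fraction matrix.

    ``matrix`` holds fractions in [0, 1]; ``match_counts`` the underlying
    integer match tallies over ``n_comparisons`` unordered frame pairs.
    """

    window_id: int
    labels: tuple[str, ...]
    matrix: np.ndarray  # (n, n) float, symmetric, zero diagonal
    match_counts: np.ndarray  # (n, n) int
    n_comparisons: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise InputError("adjacency matrix must be square")
        if not np.allclose(m, m.T):
            raise InputError("adjacency matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise InputError("adjacency matrix must have a zero diagonal")
        if m.min() < 0 or m.max() > 1:
            raise InputError("adjacency entries must lie in [0, 1]")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _descriptor_arrays(frame: NodeVectorFrame, iu: np.ndarray, ju: np.ndarray):
    """Vectorized descriptors for the listed (i, j) pairs.

    Returns ``(d, alpha_i, alpha_j, tau)`` arrays (Å / degrees).
    """
    a = frame.anchors
    v = frame.directions
    sep = a[ju] - a[iu]  # i -> j
    d = np.linalg.norm(sep, axis=1)
    if np.any(d < 1e-9):
        raise InputError("coincident node anchors")
    e = sep / d[:, None]
    vi = v[iu]
    vj = v[ju]
    cos_i = np.clip(np.einsum("ij,ij->i", vi, e), -1.0, 1.0)
    cos_j = np.clip(np.einsum("ij,ij->i", vj, -e), -1.0, 1.0)
    alpha_i = np.degrees(np.arccos(cos_i))
    alpha_j = np.degrees(np.arccos(cos_j))
    # torsion of vi vs vj about the axis e: signed angle between their
    # components perpendicular to e
    pi_ = vi - np.einsum("ij,ij->i", vi, e)[:, None] * e
    pj_ = vj - np.einsum("ij,ij->i", vj, e)[:, None] * e
    x = np.einsum("ij,ij->i", pi_, pj_)
    y = np.einsum("ij,ij->i", np.cross(e, pi_), pj_)
    tau = np.degrees(np.arctan2(y, x))
    # wrap -180 -> +180 so the range is (-180, 180]
    tau = np.where(tau <= -180.0 + 1e-12, 180.0, tau)
    return d, alpha_i, alpha_j, tau


def pair_descriptors(frame: NodeVectorFrame, candidate_cutoff: float = 12.0) -> list[PairDescriptor]:
    """Descriptors for all unordered node pairs within ``candidate_cutoff``."""
    if frame.n_nodes < 2:
        raise InputError("need at least 2 nodes")
    if candidate_cutoff <= 0:
        raise ConfigError("candidate_cutoff must be positive")
    iu, ju = _pair_indices(frame.n_nodes)
    d, ai, aj, tau = _descriptor_arrays(frame, iu, ju)
    keep = d <= candidate_cutoff
    return [
        PairDescriptor(int(iu[k]), int(ju[k]), float(d[k]), float(ai[k]), float(aj[k]), float(tau[k]))
        for k in np.nonzero(keep)[0]
    ]


def _periodic_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def _match_mask(desc_a, desc_b, tol: LSPTolerances) -> np.ndarray:
    da, aia, aja, ta = desc_a
    db, aib, ajb, tb = desc_b
    return (
        (da <= tol.candidate_cutoff)
        & (db <= tol.candidate_cutoff)
        & (np.abs(da - db) <= tol.delta_d)
        & (np.abs(aia - aib) <= tol.delta_angle)
        & (np.abs(aja - ajb) <= tol.delta_angle)
        & (_periodic_diff_deg(ta, tb) <= tol.delta_tau)
    )


def frame_pair_match(
    frame_a: NodeVectorFrame,
    frame_b: NodeVectorFrame,
    tol: LSPTolerances = LSPTolerances(),
) -> np.ndarray:
    """Binary symmetric match matrix between two frames of one node set.

    Entry (i, j) is 1 iff the pair is within the candidate cutoff in *both*
    frames and all four descriptor differences are within tolerance.
    """
    if frame_a.labels != frame_b.labels:
        raise ComparisonError("frames do not share a node set")
    n = frame_a.n_nodes
    iu, ju = _pair_indices(n)
    desc_a = _descriptor_arrays(frame_a, iu, ju)
    desc_b = _descriptor_arrays(frame_b, iu, ju)
    hits = _match_mask(desc_a, desc_b, tol)
    m = np.zeros((n, n), dtype=np.int8)
    m[iu[hits], ju[hits]] = 1
    m[ju[hits], iu[hits]] = 1
    return m


def build_window_adjacency(
    window: WindowedEnsemble,
    tol: LSPTolerances = LSPTolerances(),
) -> AdjacencyMatrix:
    """All-to-all LSP comparison of a window's frames, averaged to fractions.

    With F frames every one of the F·(F−1)/2 unordered frame pairs is
    compared (F=100 → 4950 comparisons) and entry (i, j) is the fraction of
    comparisons in which pair (i, j) matched.  Cost is O(F²·P) for P
    candidate pairs; pairs never within the cutoff in any frame are pruned.
    """
    frames = window.frames
    if len(frames) < 2:
        raise DegenerateInputError("window adjacency needs at least 2 frames")
    labels = check_identical_node_sets(frames)
    n = frames[0].n_nodes
    iu, ju = _pair_indices(n)
    F = len(frames)

    descs = [_descriptor_arrays(f, iu, ju) for f in frames]
    d_all = np.stack([desc[0] for desc in descs])  # (F, P)
    active = (d_all <= tol.candidate_cutoff).any(axis=0)
    cols = np.nonzero(active)[0]
    stacked = [
        np.stack([desc[q] for desc in descs])[:, cols] for q in range(4)
    ]  # each (F, P_active)

    counts = np.zeros(len(cols), dtype=np.int64)
    for a in range(F - 1):
        desc_a = tuple(s[a] for s in stacked)
        desc_rest = tuple(s[a + 1 :] for s in stacked)
        counts += _match_mask(desc_a, desc_rest, tol).sum(axis=0)

    n_comp = F * (F - 1) // 2
    count_mat = np.zeros((n, n), dtype=np.int64)
    count_mat[iu[cols], ju[cols]] = counts
    count_mat[ju[cols], iu[cols]] = counts
    return AdjacencyMatrix(
        window_id=window.window_id,
        labels=labels,
        matrix=count_mat / n_comp,
        match_counts=count_mat,
        n_comparisons=n_comp,
    )


def write_adjacency_tsv(adj: AdjacencyMatrix, path: str | Path) -> Path:
    """Serialize an adjacency matrix as a labeled dense TSV."""
    path = Path(path)
    df = pd.DataFrame(adj.matrix, index=list(adj.labels), columns=list(adj.labels))
    df.to_csv(path, sep="\t", float_format="%.6f")
    return path


def read_adjacency_tsv(path: str | Path, window_id: int = 0) -> AdjacencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.to_numpy(dtype=float)
    m = (m + m.T) / 2.0  # undo serialization rounding asymmetry
    np.fill_diagonal(m, 0.0)
    return AdjacencyMatrix(
        window_id=window_id,
        labels=tuple(str(c) for c in df.columns),
        matrix=m,
        match_counts=np.zeros_like(m, dtype=np.int64),
        n_comparisons=0,
    )
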