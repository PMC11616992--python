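"""Principal component analysis of Cα fluctuations and free-energy landscapes.

The covariance of the Cα coordinates over an ensemble,

    C_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩,

is diagonalized to extract collective modes; frames are first superposed onto
the iteratively refined mean structure so rigid-body tumbling does not
dominate the fluctuations.  Projecting each frame onto the first two
principal components and binning gives an empirical free-energy surface

    G_i = −k_B·T·ln(N_i / N_m),

where N_i is the population of bin i and N_m that of the most populated bin,
so G ≥ 0 with its minimum (exactly 0) at the most visited state.  Empty bins
are undefined (NaN), not zero.  Basins are counted by persistence-style
watershed: local minima merged when the barrier between them is shallower
than a depth threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError, InputError

__all__ = [
    "BOLTZMANN_KCAL",
    "SuperposedEnsemble",
    "PCModel",
    "FELGrid",
    "superpose",
    "pca",
    "fel",
    "basin_count",
    "plot_fel",
]

#: Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_FEL_BINS = 50


@dataclass
class SuperposedEnsemble:
    """Cα coordinate sets after removal of global rotation/translation."""

    coords: np.ndarray  # (F, N, 3), Å
    reference: np.ndarray  # (N, 3) mean structure the frames are fitted to
    n_iterations: int
    mean_shift: float  # final RMS change of the mean structure (Å)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class PCModel:
    """Eigendecomposition of the 3N×3N Cα covariance matrix."""

    mean: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # (k,) Å², descending
    eigenvectors: np.ndarray  # (3N, k), orthonormal columns
    projections: np.ndarray  # (F, k), centered
    covariance_trace: float  # Å²

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class FELGrid:
    """2D free-energy surface over (PC1, PC2) bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) int
    free_energy: np.ndarray  # (nx, ny) kcal/mol, NaN where counts == 0
    temperature: float  # K

    @property
    def max_count(self) -> int:
        return int(self.counts.max())


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares fit of ``mobile`` onto ``target`` (both centered copies)."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, mc)
    return rot.apply(mc) + target.mean(axis=0)


def superpose(frames: np.ndarray, max_iter: int = 20, tol: float = 1e-6) -> SuperposedEnsemble:
    """Iterative mean-structure superposition.

    Every frame is least-squares fitted to the running mean structure until
    the RMS change of the mean falls below ``tol`` (Å) or ``max_iter`` is
    reached.  The fixed point makes the mean structure itself invariant
    under a further round of fitting.
    """
    coords = np.asarray(frames, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise InputError("frames must be an (F, N, 3) array")
    if coords.shape[0] < 2:
        raise InputError("superposition needs at least 2 frames")
    spread = coords[0] - coords[0].mean(axis=0)
    if np.linalg.matrix_rank(spread) < 2:
        raise InputError("degenerate (collinear) coordinates cannot be fitted")

    ref = coords[0] - coords[0].mean(axis=0)
    fitted = coords.copy()
    shift = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        for f in range(coords.shape[0]):
            fitted[f] = _kabsch(coords[f], ref)
        new_mean = fitted.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - ref) ** 2)))
        ref = new_mean
        if shift < tol:
            break
    return SuperposedEnsemble(coords=fitted, reference=ref, n_iterations=it, mean_shift=shift)


def pca(ens: SuperposedEnsemble, n_components: int | None = None) -> PCModel:
    """Diagonalize the Cα coordinate covariance matrix.

    The covariance is over frames of the flattened (3N,) coordinate vectors:
    C_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩ with the population (1/F)
    normalization.  Eigenvalues are returned in descending order (Å²);
    projections of every frame on the retained components are centered.
    """
    X = ens.coords.reshape(ens.n_frames, -1)
    if X.shape[0] < 2:
        raise InputError("PCA needs at least 2 frames")
    dim = X.shape[1]
    if n_components is None:
        n_components = dim
    if not (1 <= n_components <= dim):
        raise ConfigError(f"n_components must lie in [1, {dim}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proj = Xc @ evecs[:, :n_components]
    return PCModel(
        mean=mean,
        eigenvalues=evals[:n_components],
        eigenvectors=evecs[:, :n_components],
        projections=proj,
        covariance_trace=float(np.trace(cov)),
    )


def fel(
    projections: np.ndarray,
    bins: int = DEFAULT_FEL_BINS,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    margin_bins: int = 1,
) -> FELGrid:
    """Bin (PC1, PC2) projections and convert populations to free energies.

    G_i = −k_B·T·ln(N_i/N_m) in kcal/mol; the most populated bin sits at
    exactly G = 0 and empty bins are NaN.  The grid spans the data range
    plus ``margin_bins`` empty bins on each side.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise InputError("projections must be (F, >=2)")
    if P.shape[0] < 1:
        raise InputError("need at least one frame")
    if bins < 2:
        raise ConfigError("need at least 2 bins per axis")
    if temperature_K <= 0:
        raise ConfigError("temperature must be positive")
    x, y = P[:, 0], P[:, 1]

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 0.5, hi + 0.5
        width = (hi - lo) / bins
        return np.linspace(lo - margin_bins * width, hi + margin_bins * width, bins + 2 * margin_bins + 1)

    xe, ye = _edges(x), _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    counts = counts.astype(int)
    nm = counts.max()
    with np.errstate(divide="ignore"):
        g = -BOLTZMANN_KCAL * temperature_K * np.log(counts / nm)
    g[counts == 0] = np.nan
    return FELGrid(x_edges=xe, y_edges=ye, counts=counts, free_energy=g, temperature=temperature_K)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def basin_count(
    grid: FELGrid,
    depth_threshold: float = 0.75,
    min_count: int = 5,
) -> tuple[int, np.ndarray]:
    """Count free-energy basins separated by barriers above a depth threshold.

    Watershed by persistence: bins are flooded in order of increasing G;
    when two growing basins meet, the shallower one is merged into the
    deeper unless its persistence (barrier G minus its minimum G) exceeds
    ``depth_threshold`` (kcal/mol), in which case both survive as distinct
    basins.  Unsampled bins, and bins holding fewer than ``min_count``
    frames (whose free energy is statistically undefined), are flooded as
    high ground at the landscape ceiling so that isolated tail fluctuations
    never register as basins.  Returns the basin count and an integer
    assignment map (−1 on unsampled bins).
    """
    g = grid.free_energy
    if np.all(np.isnan(g)):
        return 0, np.full(g.shape, -1, dtype=int)
    # unsampled and under-sampled bins are high-free-energy ground, not
    # holes: flooding them at the ceiling merges spuriously isolated tail
    # bins into the landscape
    eff_min = min(int(min_count), int(grid.counts.max()))  # sparse data: keep the mode
    undefined = np.isnan(g) | (grid.counts < eff_min)
    if np.all(undefined):
        return 0, np.full(g.shape, -1, dtype=int)
    ceiling = float(np.nanmax(np.where(undefined, np.nan, g)))
    g = np.where(undefined, ceiling, np.maximum(g, 0.0))
    g = np.minimum(g, ceiling)
    cells = np.argwhere(np.isfinite(g))
    order = cells[np.argsort(g[cells[:, 0], cells[:, 1]], kind="stable")]
    index_of = {}
    uf = _UnionFind(len(order))
    min_g = np.empty(len(order))
    is_root_basin: dict[int, bool] = {}
    assignment = np.full(g.shape, -1, dtype=int)
    cell_to_id = {}
    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    survivors = 0
    for idx, (i, j) in enumerate(order):
        index_of[(i, j)] = idx
        min_g[idx] = g[i, j]
        cell_to_id[(i, j)] = idx
        touching = set()
        for di, dj in neighbors:
            key = (i + di, j + dj)
            if key in index_of:
                touching.add(uf.find(index_of[key]))
        if not touching:
            is_root_basin[idx] = True  # new local minimum seeds a basin
            survivors += 1
            continue
        roots = sorted(touching, key=lambda r: min_g[r])
        # attach this cell to the deepest adjacent basin
        target = roots[0]
        uf.union(target, idx)
        # merging event: shallow basins meeting here die unless persistent
        for r in roots[1:]:
            persistence = g[i, j] - min_g[r]
            if persistence <= depth_threshold:
                if is_root_basin.get(r, False):
                    survivors -= 1
                    is_root_basin[r] = False
                uf.union(target, r)
            # else: r remains a separate basin; do not merge its membership
    for (i, j), idx in cell_to_id.items():
        assignment[i, j] = uf.find(idx)
    assignment[np.isnan(grid.free_energy)] = -1
    return survivors, assignment


def projections_to_frame(model: PCModel, times: np.ndarray | None = None) -> pd.DataFrame:
    cols = {f"pc{k + 1}": model.projections[:, k] for k in range(model.projections.shape[1])}
    df = pd.DataFrame(cols)
    if times is not None:
        df.insert(0, "time_ns", np.asarray(times, dtype=float))
    return df


def plot_fel(grid: FELGrid, path: str | Path, title: str = "Free energy landscape") -> Path:
    """Render the FEL as a filled-contour image (kcal/mol color scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    fig, ax = plt.subplots(figsize=(5, 4))
    pcm = ax.pcolormesh(xc, yc, grid.free_energy.T, shading="auto", cmap="viridis")
    fig.colorbar(pcm, ax=ax, label="G (kcal/mol)")
    ax.set_xlabel("PC1 (Å)")
    ax.set_ylabel("PC2 (Å)")
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
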