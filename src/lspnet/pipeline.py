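"""High-level orchestration: windows → adjacency → networks → statistics.

These functions tie the stage modules together for the standard workflow
(per-window LSP adjacency, replicate centralities, wild-type vs mutant
comparison, PCA/FEL) and are what the CLI and the example scripts call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensembles import (
    DEFAULT_WINDOW_LENGTH,
    DEFAULT_WINDOW_STARTS,
    DEFAULT_WINDOW_STRIDE,
    NodeVectorFrame,
    select_windows,
)
from .errors import InputError
from .landscape import (
    DEFAULT_FEL_BINS,
    DEFAULT_TEMPERATURE_K,
    FELGrid,
    PCModel,
    basin_count,
    fel,
    pca,
    superpose,
)
from .lsp import AdjacencyMatrix, LSPTolerances, build_window_adjacency
from .networks import (
    CentralityProfile,
    DeltaCentrality,
    ResidueNetwork,
    adjacency_to_network,
    centrality_stats,
    delta_centrality,
)

__all__ = ["PRNResult", "FELResult", "run_prn", "run_compare", "run_fel"]


@dataclass
class PRNResult:
    """Everything the PRN stage produces for one ensemble."""

    adjacencies: list[AdjacencyMatrix]
    networks: list[ResidueNetwork]
    profile: CentralityProfile
    tolerances: LSPTolerances
    weight_threshold: float
    length_transform: str

    @property
    def mean_adjacency(self) -> np.ndarray:
        return np.mean([a.matrix for a in self.adjacencies], axis=0)


@dataclass
class FELResult:
    model: PCModel
    grid: FELGrid
    n_basins: int
    basin_map: np.ndarray = field(repr=False)


def run_prn(
    vector_frames: Sequence[NodeVectorFrame],
    window_starts: Sequence[float] = DEFAULT_WINDOW_STARTS,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    stride: float = DEFAULT_WINDOW_STRIDE,
    tolerances: LSPTolerances = LSPTolerances(),
    weight_threshold: float = 0.0,
    length_transform: str = "reciprocal",
) -> PRNResult:
    """Window the trajectory, build per-window adjacency and centralities."""
    windows = select_windows(vector_frames, window_starts, window_length, stride)
    adjacencies = [build_window_adjacency(w, tolerances) for w in windows]
    networks = [adjacency_to_network(a, weight_threshold) for a in adjacencies]
    profile = centrality_stats(networks, length_transform)
    return PRNResult(
        adjacencies=adjacencies,
        networks=networks,
        profile=profile,
        tolerances=tolerances,
        weight_threshold=weight_threshold,
        length_transform=length_transform,
    )


def run_compare(wt: PRNResult, mut: PRNResult) -> DeltaCentrality:
    """Per-node Δ (mutant − wild type) for both centralities."""
    return delta_centrality(wt.profile, mut.profile)


def run_fel(
    ca_coords: np.ndarray,
    bins: int = DEFAULT_FEL_BINS,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    depth_threshold: float = 0.75,
    n_components: int = 10,
) -> FELResult:
    """Superpose Cα frames, run PCA, bin (PC1, PC2) into a free-energy grid."""
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 3:
        raise InputError("ca_coords must be (F, N, 3)")
    ens = superpose(coords)
    n_components = min(n_components, coords.shape[1] * 3)
    model = pca(ens, n_components=max(2, n_components))
    grid = fel(model.projections[:, :2], bins=bins, temperature_K=temperature_K)
    n_basins, basin_map = basin_count(grid, depth_threshold=depth_threshold)
    return FELResult(model=model, grid=grid, n_basins=n_basins, basin_map=basin_map)
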