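"""Weighted protein residue networks and their centrality statistics.

The adjacency matrices produced by the LSP comparison become undirected
weighted graphs whose edge weight is the pattern match fraction.  Two node
centralities carry the biological signal:

* **Degree centrality (DC)** — the sum of a node's incident edge weights.
  High-DC residues are local hubs, i.e. the most ordered parts of the
  molecule.
* **Betweenness centrality (BC)** — the number of shortest paths between
  all other node pairs passing through the node (Brandes algorithm,
  fractional credit under ties, unnormalized).  High-BC residues are global
  connectors between hubs, e.g. the bottlenecks that carry allosteric
  communication between the kinase lobes.

Replicate centralities from several time windows are summarized as mean ±
standard error (sample sd / √n), and two ensembles (wild type vs mutant) are
compared node-by-node as Δ = mutant − wt, split into positive and negative
channels for mapping onto structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ComparisonError, ConfigError, DegenerateInputError, InputError
from .lsp import AdjacencyMatrix

__all__ = [
    "ResidueNetwork",
    "CentralityProfile",
    "DeltaCentrality",
    "adjacency_to_network",
    "degree_centrality",
    "betweenness_centrality",
    "centrality_stats",
    "delta_centrality",
    "export_network",
    "write_centrality_tsv",
    "write_delta_tsv",
    "write_bfactor_pdb",
]

LENGTH_TRANSFORMS = ("reciprocal", "neglog", "unit")


@dataclass
class ResidueNetwork:
    """Undirected weighted graph over residue (and optional ligand) nodes."""

    graph: nx.Graph
    labels: tuple[str, ...]
    weight_threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CentralityProfile:
    """Per-node DC/BC with per-window replicates, means and standard errors.

    ``dc_replicates``/``bc_replicates`` have shape (n_windows, n_nodes);
    the standard error is sample sd (n−1 denominator) divided by √n_windows.
    """

    labels: tuple[str, ...]
    dc_replicates: np.ndarray
    bc_replicates: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.dc_replicates.shape[0]

    @property
    def dc_mean(self) -> np.ndarray:
        return self.dc_replicates.mean(axis=0)

    @property
    def bc_mean(self) -> np.ndarray:
        return self.bc_replicates.mean(axis=0)

    @property
    def dc_se(self) -> np.ndarray:
        return self.dc_replicates.std(axis=0, ddof=1) / math.sqrt(self.n_windows)

    @property
    def bc_se(self) -> np.ndarray:
        return self.bc_replicates.std(axis=0, ddof=1) / math.sqrt(self.n_windows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"node": list(self.labels)})
        for w in range(self.n_windows):
            df[f"dc_w{w}"] = self.dc_replicates[w]
        for w in range(self.n_windows):
            df[f"bc_w{w}"] = self.bc_replicates[w]
        df["dc_mean"] = self.dc_mean
        df["dc_se"] = self.dc_se
        df["bc_mean"] = self.bc_mean
        df["bc_se"] = self.bc_se
        return df


@dataclass
class DeltaCentrality:
    """Per-node centrality changes, mutant minus wild type.

    The positive and negative channels are exact partitions:
    ``delta = positive + negative`` with ``positive ≥ 0`` and
    ``negative ≤ 0`` elementwise.
    """

    labels: tuple[str, ...]
    delta_dc: np.ndarray
    delta_bc: np.ndarray

    @property
    def delta_dc_positive(self) -> np.ndarray:
        return np.clip(self.delta_dc, 0.0, None)

    @property
    def delta_dc_negative(self) -> np.ndarray:
        return np.clip(self.delta_dc, None, 0.0)

    @property
    def delta_bc_positive(self) -> np.ndarray:
        return np.clip(self.delta_bc, 0.0, None)

    @property
    def delta_bc_negative(self) -> np.ndarray:
        return np.clip(self.delta_bc, None, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.labels),
                "delta_dc": self.delta_dc,
                "delta_dc_pos": self.delta_dc_positive,
                "delta_dc_neg": self.delta_dc_negative,
                "delta_bc": self.delta_bc,
                "delta_bc_pos": self.delta_bc_positive,
                "delta_bc_neg": self.delta_bc_negative,
            }
        )


def adjacency_to_network(adj: AdjacencyMatrix, weight_threshold: float = 0.0) -> ResidueNetwork:
    """Turn a match-fraction matrix into a weighted graph.

    Edges with weight strictly above ``weight_threshold`` are kept; isolated
    nodes remain in the node set so that node sets stay comparable across
    ensembles.
    """
    if not (0.0 <= weight_threshold < 1.0):
        raise ConfigError("weight_threshold must lie in [0, 1)")
    n = adj.n_nodes
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    w = adj.matrix[iu, ju]
    keep = w > weight_threshold
    g.add_weighted_edges_from(
        (int(i), int(j), float(x)) for i, j, x in zip(iu[keep], ju[keep], w[keep])
    )
    return ResidueNetwork(graph=g, labels=adj.labels, weight_threshold=weight_threshold)


def degree_centrality(net: ResidueNetwork) -> np.ndarray:
    """DC(v) = sum of incident edge weights (neighbor count on unit graphs)."""
    deg = net.graph.degree(weight="weight")
    return np.array([deg[i] for i in range(net.n_nodes)], dtype=float)


def _edge_length(w: float, transform: str) -> float:
    if transform == "reciprocal":
        return 1.0 / w
    if transform == "neglog":
        return -math.log(w) if w < 1.0 else 0.0
    if transform == "unit":
        return 1.0
    raise ConfigError(f"unknown length transform {transform!r}; choose from {LENGTH_TRANSFORMS}")


def betweenness_centrality(net: ResidueNetwork, length_transform: str = "reciprocal") -> np.ndarray:
    """Unnormalized Brandes betweenness on transformed edge lengths.

    Strong edges (weight near 1) are short under the default ``reciprocal``
    transform, so shortest paths prefer well-conserved contacts.  With unit
    lengths and unique shortest paths this reduces to the literal count of
    shortest paths through the node; ties receive fractional credit.
    """
    if length_transform not in LENGTH_TRANSFORMS:
        raise ConfigError(
            f"unknown length transform {length_transform!r}; choose from {LENGTH_TRANSFORMS}"
        )
    g = net.graph.copy()
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        if w <= 0:
            raise InputError("edge weights must be positive")
        data["length"] = _edge_length(w, length_transform)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)], dtype=float)


def centrality_stats(
    per_window_networks: Sequence[ResidueNetwork],
    length_transform: str = "reciprocal",
) -> CentralityProfile:
    """Window-replicate DC/BC with mean and standard error of the mean.

    Each window's averaged adjacency yields one DC and one BC value per
    node; the replicates are then summarized as mean ± sd/√n (sample sd).
    """
    if len(per_window_networks) < 2:
        raise DegenerateInputError("need at least 2 windows for replicate statistics")
    labels = per_window_networks[0].labels
    for net in per_window_networks[1:]:
        if net.labels != labels:
            raise ComparisonError("window networks do not share a node set")
    dc = np.stack([degree_centrality(net) for net in per_window_networks])
    bc = np.stack([betweenness_centrality(net, length_transform) for net in per_window_networks])
    return CentralityProfile(labels=labels, dc_replicates=dc, bc_replicates=bc)


def delta_centrality(wt: CentralityProfile, mut: CentralityProfile) -> DeltaCentrality:
    """Δ = mutant mean − wild-type mean, per node and per centrality."""
    if wt.labels != mut.labels:
        raise ComparisonError("profiles do not share a node set")
    return DeltaCentrality(
        labels=wt.labels,
        delta_dc=mut.dc_mean - wt.dc_mean,
        delta_bc=mut.bc_mean - wt.bc_mean,
    )


def export_network(
    net: ResidueNetwork,
    profile: CentralityProfile | None,
    path: str | Path,
    edge_list_path: str | Path | None = None,
) -> Path:
    """Write the network as GEXF (plus optional TSV edge list).

    DC/BC means are attached as node attributes and the match fraction as
    edge weight, ready for force-directed layout in an external viewer
    (e.g. Gephi's ForceAtlas2).
    """
    if profile is not None and profile.labels != net.labels:
        raise ComparisonError("profile does not match the network node set")
    g = nx.Graph()
    for i, label in enumerate(net.labels):
        attrs = {"label": label}
        if profile is not None:
            attrs["dc"] = float(profile.dc_mean[i])
            attrs["bc"] = float(profile.bc_mean[i])
        g.add_node(i, **attrs)
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, weight=float(data.get("weight", 1.0)))
    path = Path(path)
    nx.write_gexf(g, str(path))
    if edge_list_path is not None:
        rows = [
            {"source": net.labels[u], "target": net.labels[v], "weight": data.get("weight", 1.0)}
            for u, v, data in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            edge_list_path, sep="\t", index=False, float_format="%.6f"
        )
    return path


def write_centrality_tsv(profile: CentralityProfile, path: str | Path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_delta_tsv(delta: DeltaCentrality, path: str | Path) -> Path:
    path = Path(path)
    delta.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_bfactor_pdb(
    frame,
    values_by_resid: dict[int, float],
    path: str | Path,
) -> Path:
    """Write a single-model PDB with per-residue values in the B-factor column.

    Intended for coloring structures by ΔDC/ΔBC in external viewers; residues
    absent from ``values_by_resid`` get 0.
    """
    import MDAnalysis as mda
    import warnings

    from .ensembles import write_multimodel_pdb

    path = Path(path)
    write_multimodel_pdb([frame], path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        u.add_TopologyAttr("tempfactors", np.zeros(u.atoms.n_atoms))
        for res in u.residues:
            res.atoms.tempfactors = float(values_by_resid.get(int(res.resid), 0.0))
        with mda.Writer(str(path)) as w:
            w.write(u.atoms)
    return path
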