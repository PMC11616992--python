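# lspnet

Local-spatial-pattern (LSP) protein residue networks, centrality statistics
and free-energy landscapes for conformational ensembles.

## The problem

Protein kinases — and many other allosteric proteins — transmit information
between sites that never touch. Backbone structures barely change, so the
signal lives in *dynamics*: which regions move as cohesive units, and which
residues connect those units. `lspnet` is for computational structural
biologists who have a conformational ensemble (an MD trajectory or a
multi-model PDB) and want a residue-level map of local order and global
connectivity, plus how that map changes upon a mutation or a change in
ligation state.

## The method

Every residue is represented by its Cα→Cβ unit vector (glycine gets a
tetrahedral pseudo-Cβ; a ligand such as ATP can join the network through an
N1→C8 vector). For each pair of residues within a candidate cutoff, four
internal coordinates fix the relative pose of the two oriented vectors:

* `d` — inter-Cα distance,
* `α_i`, `α_j` — the angles each Cα-Cβ vector makes with the inter-Cα axis,
* `τ` — the torsion of the two vectors about that axis.

Two snapshots *match* on a pair when all four agree within tolerance. Time
windows are cut from the trajectory (by default five 10 ns windows of 100
frames each) and every window is compared all-to-all: with F frames, each of
the F(F−1)/2 snapshot pairs yields a binary match matrix, and their average
is the window's weighted adjacency matrix — entry (i, j) is the fraction of
comparisons in which residues i and j kept their mutual geometry. That
matrix defines a weighted, undirected protein residue network (PRN) on which
two centralities carry the biology:

* **Degree centrality** `DC(v) = Σ_u w(v,u)` — local hubs, the most ordered
  regions;
* **Betweenness centrality** `BC(v)` — the number of shortest paths through
  `v` (Brandes, unnormalized, edge length 1/w by default) — the global
  connectors carrying communication between hubs.

Per-window replicates give mean ± SEM (sample sd/√n) per residue, and two
ensembles are compared node-by-node as Δ = mutant − wild type, split into
positive/negative channels for structure mapping.

Companion analyses: PCA of superposed Cα fluctuations
(`C_ij = ⟨(x_i−⟨x_i⟩)(x_j−⟨x_j⟩)⟩`) with free-energy landscapes
`G_i = −k_B T ln(N_i/N_m)` over (PC1, PC2) bins and persistence-based basin
counting; and side-chain atom-pair distance series with kernel-density
curves and hydrogen-bond-style occupancies.

A fully seeded synthetic generator (`lspnet.synthetic`) builds two-lobe
ensembles with a flexible linker loop, a hinge motion, and a
catalytic-interface contact, so every stage of the pipeline is testable
against planted ground truth without any simulation data.

## Worked example

`examples/02_wildtype_vs_mutant_prn.py` generates a 200-frame synthetic
two-lobe ensemble and its "mutant" (linker σ × 0.2, active-site σ × 3), runs
the windowed LSP pipeline on both and prints:

```
wild-type top-BC node: 0 (active-site patch = nodes 108-119, its lobe-1 contact = node 0)
mutant top-8 BC nodes: [50, 51, 52, 53, 54, 55, 56, 57] (linker = nodes 50-57)
mean linker  ΔBC:     +3124   ΔDC:  +1.63
mean active  ΔBC:      -769   ΔDC:  -3.30
```

In the wild type, inter-lobe shortest paths run through the catalytic
interface contact (node 0), so it tops the betweenness ranking. Rigidifying
the linker makes its eight nodes the cheapest — and only — route between the
lobes: they take over the top eight betweenness ranks, their ΔBC/ΔDC are
positive, and the loosened active-site patch loses both degree (order) and
betweenness (its connector role). The other examples cover toy-graph
centralities, the free-energy landscape, distance distributions, and (with
network access) K105–E107/E121 measurements on the deposited kinase
structure 1ATP.

A thin CLI wraps the same pipeline for shell use:
`lspnet simulate|prn|compare|fel|sidechain --help`.

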