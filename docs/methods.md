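# Methods

This note records the models, conventions and numerical choices behind
`lspnet`, and what the synthetic test system does and does not establish
about real data.

## Node vectors

A residue's local orientation is its normalized Cα→Cβ bond. Glycine has no
Cβ, so a pseudo-Cβ is constructed from the backbone N, Cα and C atoms by the
tetrahedral rule: the direction is a combination of the inverted N/C-bond
bisector and the normal of the N–Cα–C plane, with the mixing angle chosen so
that the pseudo-bond makes 109.47° with both the Cα–N and Cα–C bonds; the
bond length is 1.53 Å and the normal's sign follows L-amino-acid chirality.
Ligands join the network through a configurable atom pair (ATP: anchor N1,
direction N1→C8). Missing atoms are an error rather than a silent drop —
networks compared across ensembles must share an identical node set.

## Pair descriptors and matching

The relative pose of two oriented vectors, up to global rotation and
translation, has four degrees of freedom once each vector's position along
itself is fixed at the anchor: the anchor distance `d`, the polar angles
`α_i` and `α_j` of each direction vector against the inter-anchor axis, and
the torsion `τ` of one transverse component against the other, wrapped to
(−180°, 180°]. Two frames match on a pair when the pair lies within the
candidate cutoff in *both* frames (symmetric gating keeps the matrix
symmetric by construction) and |Δd|, |Δα_i|, |Δα_j| and the periodic |Δτ|
are all within tolerance. The comparison is binary per frame pair; averaging
over all unordered frame pairs of a window yields the match-fraction
adjacency. Defaults — cutoff 12 Å, Δd ≤ 1 Å, angles ≤ 15° — are
configuration, not a claim about any published threshold set; they keep
same-rigid-body adjacency dense while degrading smoothly with thermal noise.
Matching costs O(F²·P) per window (F frames, P candidate pairs); pairs never
within the cutoff in any frame are pruned, and a 100-frame, 120-node window
runs in about a second.

Note that `τ` becomes ill-conditioned when a direction vector is nearly
parallel to the inter-anchor axis (its transverse component vanishes);
such pairs simply match less reproducibly, which is the intended behavior
of a conservation measure.

## Centralities and statistics

Degree centrality is the weighted degree. Betweenness uses Brandes'
algorithm, unnormalized (so toy-graph values match literal path counts),
with fractional credit under ties and edge length = 1/weight by default
(strong, well-conserved contacts are short); −log(w) and unit lengths are
selectable. Edges are kept above a weight threshold of 0 by default —
any conserved fraction counts; sparsification is opt-in. Window replicates
are summarized as mean and standard error with the sample (n−1) standard
deviation over n windows; at least two windows are required. Δ-centrality is
mutant minus wild type on matched node sets, with exact positive/negative
channel decomposition for structure mapping (GEXF export carries DC/BC as
node attributes; a B-factor writer maps per-residue values onto PDB files).

## PCA and free-energy landscapes

Frames are superposed by iterative least-squares fitting to the running mean
structure (Kabsch via SVD) until the mean moves less than 10⁻⁶ Å RMS —
without this, the coordinate covariance is dominated by rigid-body tumbling.
The 3N×3N covariance over frames uses the population (1/F) normalization and
is diagonalized exactly (`eigh`); eigenvalue sum equals the trace to
round-off. Landscapes bin the (PC1, PC2) projections on a 50×50 grid by
default with a one-bin empty margin, and convert populations to
G = −k_B T ln(N_i/N_m) with k_B = 0.0019872041 kcal/(mol·K) and T = 300 K by
default. Empty bins are undefined (NaN), never zero.

Basins are counted by a persistence watershed: bins flood in order of
increasing G, and when two growing basins meet, the shallower survives only
if its depth below the meeting point exceeds a threshold (default
0.75 kcal/mol ≈ 1.25 k_BT at 300 K). Unsampled bins — and bins holding
fewer than 5 frames, whose free energy is statistically meaningless — are
flooded as high ground at the landscape ceiling, so isolated tail
fluctuations never register as basins; on very sparse grids the minimum
population is capped at the modal count so the mode always survives.

## Side-chain analyses

Hydrogen bonds are operationalized as heavy-atom donor–acceptor distance ≤
3.5 Å, with no angular term, because the interactions of interest are
reported as single atom-pair distances; the cutoff is configurable.
Carboxylate and amide oxygens are chemically equivalent, so single-structure
measurements can take the nearer of OE1/OE2 (or OD1/OD2), while trajectory
series use exactly the named atoms. Density curves use a Gaussian KDE with
Scott's-rule bandwidth by default, renormalized on their grid.

## The synthetic two-lobe system

The generator emulates the architecture the pipeline is meant to resolve: a
bilobal enzyme whose N- and C-lobe analogs move as rigid bodies, joined by
(a) an eight-node linker loop arcing over the top and (b) a single
catalytic-interface contact reaching across the inter-lobe cleft from an
active-site patch on the second lobe. Geometry: Cα nodes on self-avoiding
coarse chains (3.8 Å spacing, 4 Å excluded volume, ~110 Å³ of lobe volume
per node); lobes 8 Å apart at closest approach; the interface tip fixed at
5.9–6.1 Å from its lobe-1 anchor; the linker attached 4 Å above the centroid
of three lobe nodes on each side, with every interior linker node kept
beyond 6.2 Å of any lobe node and non-consecutive linker nodes likewise
separated (validated, with regrowth on failure). Direction vectors are
random but transverse to the local chain tangent, as real Cβ atoms point
away from the backbone.

Each frame applies a hinge rotation about an axis through the middle linker
node (amplitude 10°, 10 ns period, sinusoidal): the second lobe and its
patch rotate fully, linker node i by the fraction (i+1)/9 — a distributed
hinge — and the first lobe not at all. Per-region i.i.d. Gaussian noise is
then added to positions (rigid lobes σ = 0.2 Å, linker σ = 1.5 Å by
default), with matched orientational jitter: each direction vector receives
a small random rotation with per-axis standard deviation 10°/Å × σ, so
positional and orientational disorder co-vary. All randomness flows from one
`default_rng(seed)` stream in a fixed draw order; wild-type and mutant
ensembles from the same seed share the underlying standard-normal draws, so
their comparison is paired.

The mechanism of the planted signal: the interface contact is short but
decohered by the hinge swing (its tip sits ~17 Å from the hinge axis, so the
±10° swing modulates the contact distance by ±~1.7 Å), giving it a modest
but usable match fraction, while the floppy linker (σ = 1.5 Å against a 1 Å
distance tolerance) conserves almost nothing. Wild-type inter-lobe shortest
paths therefore run through the interface — the catalytic contact is the
wild-type connector. The "mutant" edit (linker σ × 0.2, active-site σ × 3)
makes the linker chain strongly conserved and further decoheres the
interface: every inter-lobe path re-routes through the linker, whose eight
nodes then hold the top eight betweenness ranks, with positive linker
ΔBC/ΔDC and negative active-site ΔDC/ΔBC. Note the corollary, which shaped
this design: a *sole* bridge cannot gain betweenness by rigidifying (it
already carries every path), so a competing wild-type channel is a
structural requirement for the Δ signature, not a decoration.

The planted-recovery suite analyzes this system at a 6 Å candidate cutoff
(`recovery_tolerances()`): with 3.8 Å chain spacing, a 12 Å cutoff admits
i→i+2/i+3 "skip" contacts along the linker, so shortest paths would visit
only a subset of its nodes; at 6 Å the chain is traversed node-by-node and
the bottleneck is resolved at single-node granularity. The 12 Å default
remains the recommendation for real proteins, where node-resolved bridge
coverage is not the question being asked. Suite problem sizes are five 10 ns
windows of 40 frames (0.25 ns stride) per ensemble — the generator's own
defaults keep the full five-window, 0.1 ns-stride protocol on a 200 ns
grid. Across 30 generator seeds the full signature (all four checks)
reproduces in 28; the residual failure mode is a near-tie in which a single
lobe node captures almost all linker traffic and edges out the lowest-ranked
linker node by a few tens of paths.

What passing these tests does *not* show: the generator has no force field,
no excluded-volume dynamics, no solvent, and its noise is i.i.d. Gaussian
rather than collectively correlated, so recovery here demonstrates that the
pipeline's statistics identify planted cohesion and connectivity structure —
not that any particular real protein's centrality map is correct, and no
attempt is made to reproduce real ΔDC/ΔBC magnitudes.

## Known limitations

* The LSP match is binary per comparison; graded similarity scores are out
  of scope by design (the averaged fraction is the graded quantity).
* Betweenness on weighted graphs depends on the length transform; rankings
  are stable under weight rescaling for the reciprocal transform, but
  reciprocal and −log transforms can order mid-rank nodes differently.
* The FEL is strictly two-dimensional (PC1, PC2); higher components are
  available from the PCA model but not binned.
* Multi-model PDB is the only writable ensemble format; DCD/XTC are
  read-only through MDAnalysis.
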