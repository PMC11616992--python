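"""Synthetic conformational ensembles and toy graphs with planted structure.

The generator emulates the coarse architecture of a bilobal kinase: two
internally cohesive rigid bodies (an N-lobe-like and a C-lobe-like cluster of
Cα nodes) joined by a flexible linker loop arcing over the top, plus an
``active_site`` patch on the second lobe whose tip reaches across the
inter-lobe cleft to a single contact with the first lobe (the analog of the
catalytic interface).  Each frame applies a hinge rotation (slow collective
opening/closing about an axis through the linker midpoint; the rotation is
distributed along the linker and full on the second lobe) and adds
per-region Gaussian positional noise with matched small-angle jitter of the
Cα→Cβ direction vectors.

Two communication channels therefore compete, exactly as in the kinase:

* the *catalytic-interface contact* — geometrically short but decohered by
  the hinge swing, the dominant connector while the linker is floppy
  (wild-type-like conditions);
* the *linker loop* — eight nodes in series; floppy (high σ) in the
  wild type, it carries almost no conserved pattern, but once rigidified by
  the "mutant" edit it becomes the cheap route and takes over all
  inter-lobe shortest paths.

The planted ground truth the pipeline is expected to recover: intra-lobe
edge weights exceed lobe-to-lobe weights; after the mutant edit the linker
nodes hold the top betweenness ranks, linker ΔBC/ΔDC are positive, and the
loosened active-site patch shows negative ΔDC (and loses its connector
role, negative ΔBC) — the centrality signature of a mutation that shifts
inter-lobe communication from the catalytic area to a rigidified loop.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
with a fixed draw order (reference geometry first, then per-frame noise), so
ensembles are bit-reproducible per seed.  Wild-type and mutant ensembles
built from the same seed share the underlying standard-normal draws; the
mutant only rescales them, which makes Δ comparisons paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .ensembles import NodeVectorFrame, StructureFrame, WindowedEnsemble, select_windows
from .errors import ConfigError, InputError
from .lsp import AdjacencyMatrix
from .networks import ResidueNetwork
from .sidechains import DistanceSeries

__all__ = [
    "SyntheticRegion",
    "SyntheticEnsembleSpec",
    "MutantEdit",
    "SyntheticEnsemble",
    "default_two_lobe_spec",
    "default_mutant_edit",
    "apply_mutant",
    "generate_ensemble",
    "generate_toy_graph",
    "generate_distance_series",
    "region_pair_mean_weight",
]

#: Direction-vector jitter scale: degrees of angular noise per Å of
#: positional noise, so positional and orientational disorder co-vary.
ANGLE_NOISE_DEG_PER_A = 10.0

CA_SPACING = 3.8  # Å along the coarse chain
EXCLUDED_VOLUME = 4.0  # Å minimum distance between non-consecutive nodes
LOBE_GAP = 8.0  # Å between the lobes' bounding spheres (the cleft width)


def recovery_tolerances() -> "LSPTolerances":
    """LSP tolerances for planted-structure recovery on the coarse chain.

    A 6 Å candidate cutoff resolves the linker bottleneck node-by-node:
    with 3.8 Å node spacing it admits consecutive-node contacts but not
    i→i+2 "skips" (7.6 Å), so every inter-lobe shortest path must traverse
    the full linker chain.  Match tolerances are the package defaults.
    """
    from .lsp import LSPTolerances

    return LSPTolerances(candidate_cutoff=6.0)


@dataclass(frozen=True)
class SyntheticRegion:
    """A contiguous node range with a structural role and noise level."""

    name: str
    start: int  # inclusive
    stop: int  # exclusive
    role: str  # rigid_body | linker | loop
    sigma: float  # Å positional noise

    def __post_init__(self) -> None:
        if self.role not in ("rigid_body", "linker", "loop"):
            raise ConfigError(f"unknown region role {self.role!r}")
        if self.sigma < 0:
            raise ConfigError("sigma must be nonnegative")
        if self.stop <= self.start:
            raise ConfigError("empty region")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Full recipe for one synthetic two-lobe ensemble."""

    regions: tuple[SyntheticRegion, ...]
    hinge_amplitude_deg: float = 10.0
    hinge_period_ns: float = 10.0
    n_frames: int = 2000
    stride_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hinge_amplitude_deg < 0:
            raise ConfigError("hinge amplitude must be nonnegative")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be positive")
        spans = sorted((r.start, r.stop) for r in self.regions)
        pos = 0
        for start, stop in spans:
            if start != pos:
                raise ConfigError("regions must partition the node range without gaps/overlaps")
            pos = stop

    @property
    def n_nodes(self) -> int:
        return max(r.stop for r in self.regions)

    def region(self, name: str) -> SyntheticRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise ConfigError(f"no region named {name!r}")

    def region_of_nodes(self) -> np.ndarray:
        out = np.empty(self.n_nodes, dtype=object)
        for r in self.regions:
            out[r.start : r.stop] = r.name
        return out


@dataclass(frozen=True)
class MutantEdit:
    """Per-region noise rescaling emulating a point-mutation phenotype.

    The default edit rigidifies the linker (σ × 0.2) and loosens the
    active-site patch (σ × 3), the qualitative signature of a mutation that
    turns a flexible inter-lobe loop into a dominant connector while
    destabilizing the catalytic region.
    """

    sigma_multipliers: dict = field(default_factory=dict)
    hinge_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.hinge_multiplier <= 0:
            raise ConfigError("hinge multiplier must be positive")
        for name, m in self.sigma_multipliers.items():
            if m <= 0:
                raise ConfigError(f"sigma multiplier for {name!r} must be positive")


def default_two_lobe_spec(seed: int = 0, n_frames: int = 2000, stride_ns: float = 0.1) -> SyntheticEnsembleSpec:
    """The standard 120-node system: 50-node lobe, 8-node linker, 62-node lobe.

    The second lobe contains a 12-node ``active_site`` patch grown on its
    linker-facing surface.  Rigid lobes jitter at σ = 0.2 Å, the linker at
    σ = 1.5 Å; the hinge swings the second lobe by ±10° with a 10 ns period.
    """
    regions = (
        SyntheticRegion("n_lobe", 0, 50, "rigid_body", 0.2),
        SyntheticRegion("linker", 50, 58, "linker", 1.5),
        SyntheticRegion("c_lobe", 58, 108, "rigid_body", 0.2),
        SyntheticRegion("active_site", 108, 120, "loop", 0.2),
    )
    return SyntheticEnsembleSpec(regions=regions, seed=seed, n_frames=n_frames, stride_ns=stride_ns)


def default_mutant_edit() -> MutantEdit:
    return MutantEdit(sigma_multipliers={"linker": 0.2, "active_site": 3.0})


def apply_mutant(spec: SyntheticEnsembleSpec, edit: MutantEdit) -> SyntheticEnsembleSpec:
    """Return a new spec with per-region σ and hinge amplitude rescaled."""
    for name in edit.sigma_multipliers:
        spec.region(name)  # raises on unknown region
    new_regions = tuple(
        replace(r, sigma=r.sigma * edit.sigma_multipliers.get(r.name, 1.0)) for r in spec.regions
    )
    return replace(
        spec,
        regions=new_regions,
        hinge_amplitude_deg=spec.hinge_amplitude_deg * edit.hinge_multiplier,
    )


@dataclass
class SyntheticEnsemble:
    """Generated frames plus the ground truth they were built from."""

    spec: SyntheticEnsembleSpec
    frames: list[NodeVectorFrame]
    ref_anchors: np.ndarray  # (n, 3) reference geometry
    ref_directions: np.ndarray  # (n, 3) unit
    hinge_angles_deg: np.ndarray  # (F,)
    hinge_pivot: np.ndarray  # (3,)
    hinge_axis: np.ndarray  # (3,) unit
    hinge_fractions: np.ndarray  # (n,) per-node share of the hinge angle

    @property
    def moving_nodes(self) -> np.ndarray:
        return np.nonzero(self.hinge_fractions > 0)[0]

    def windows(self, window_starts, window_length, stride) -> list[WindowedEnsemble]:
        return select_windows(self.frames, window_starts, window_length, stride)

    def _hinge_apply(self, frame_idx: int, pos: np.ndarray, dirs: np.ndarray | None = None):
        angle = np.radians(self.hinge_angles_deg[frame_idx])
        for frac in np.unique(self.hinge_fractions):
            if frac == 0.0:
                continue
            idx = np.nonzero(self.hinge_fractions == frac)[0]
            rot = Rotation.from_rotvec(frac * angle * self.hinge_axis)
            pos[idx] = rot.apply(pos[idx] - self.hinge_pivot) + self.hinge_pivot
            if dirs is not None:
                dirs[idx] = rot.apply(dirs[idx])
        return pos, dirs

    def transformed_reference(self, frame_idx: int) -> np.ndarray:
        """Reference anchors after the frame's hinge rotation (no noise)."""
        pos, _ = self._hinge_apply(frame_idx, self.ref_anchors.copy())
        return pos

    def noise_residuals(self) -> np.ndarray:
        """Per-frame anchor deviations from the hinge-transformed reference."""
        return np.stack(
            [f.anchors - self.transformed_reference(i) for i, f in enumerate(self.frames)]
        )

    def to_structure_frames(self) -> list[StructureFrame]:
        """Represent each node as an ALA residue with CA and CB atoms."""
        n = self.spec.n_nodes
        chains = np.array(["A"] * (2 * n), dtype=object)
        resids = np.repeat(np.arange(1, n + 1), 2)
        resnames = np.array(["ALA"] * (2 * n), dtype=object)
        names = np.array(["CA", "CB"] * n, dtype=object)
        out = []
        for f in self.frames:
            coords = np.empty((2 * n, 3))
            coords[0::2] = f.anchors
            coords[1::2] = f.anchors + 1.53 * f.directions
            out.append(
                StructureFrame(
                    frame_index=f.frame_index,
                    time=f.time,
                    chains=chains.copy(),
                    resids=resids.copy(),
                    resnames=resnames.copy(),
                    names=names.copy(),
                    coords=coords,
                )
            )
        return out


def _grow_chain(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    start: np.ndarray | None,
    existing: list[np.ndarray],
    exclude: tuple[np.ndarray, float] | None = None,
    end_zone: tuple[np.ndarray, float] | None = None,
    max_tries: int = 300,
) -> list[np.ndarray]:
    """Self-avoiding coarse chain of ``n`` nodes inside a sphere.

    ``exclude`` reserves a spherical zone the chain must stay out of (a
    fixed ``start`` is exempt, so it can serve as a deliberate contact).
    ``end_zone`` forces the final node into a target sphere; steps are
    biased toward it once the remaining contour length gets tight.
    """
    for _ in range(60):  # restarts
        placed: list[np.ndarray] = []
        if start is None:
            placed.append(center + rng.normal(0.0, 1.0, 3) * 0.1)
        else:
            placed.append(np.asarray(start, float))
        ok = True
        while len(placed) < n:
            prev = placed[-1]
            remaining = n - len(placed)
            bias = None
            if end_zone is not None:
                gap_to_zone = np.linalg.norm(end_zone[0] - prev)
                slack = remaining * CA_SPACING - gap_to_zone
                if slack < 2.5 * CA_SPACING:
                    bias = (end_zone[0] - prev) / max(gap_to_zone, 1e-9)
            for _try in range(max_tries):
                step = rng.normal(0.0, 1.0, 3)
                step /= np.linalg.norm(step)
                if bias is not None:
                    step = bias + 0.45 * step
                    step /= np.linalg.norm(step)
                cand = prev + CA_SPACING * step
                if np.linalg.norm(cand - center) > radius:
                    continue
                if exclude is not None and np.linalg.norm(cand - exclude[0]) < exclude[1]:
                    continue
                if (
                    end_zone is not None
                    and remaining == 1
                    and np.linalg.norm(cand - end_zone[0]) > end_zone[1]
                ):
                    continue
                near = placed[:-1] + existing
                if near and min(np.linalg.norm(cand - p) for p in near) < EXCLUDED_VOLUME:
                    continue
                placed.append(cand)
                break
            else:
                ok = False
                break
        if ok:
            return placed
    raise InputError("could not grow a self-avoiding chain; region too dense")


def _lobe_radius(n_nodes: int) -> float:
    # ~110 Å³ of sphere volume per node keeps the chain growable
    return 3.0 * n_nodes ** (1.0 / 3.0)


def _arc_linker(n: int, a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    """Planar arc of ``n`` interior nodes from a to b, ~CA_SPACING apart.

    The arc length is (n+1)·spacing over the chord |b−a|; solving the
    chord/arc relation gives the bulge.  The loop bows out of the lobe-lobe
    axis in +y.
    """
    chord = float(np.linalg.norm(b - a))
    arc_len = (n + 1) * CA_SPACING
    if chord >= arc_len / 1.02:
        # no room for a bulge: straight polyline (spacing stretches a bit)
        return [a + (b - a) * k / (n + 1) for k in range(1, n + 1)]
    # solve arc/chord = (theta/2)/sin(theta/2) for the subtended angle
    ratio = arc_len / chord
    lo, hi = 1e-6, math.pi - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mid / math.sin(mid) < ratio:
            lo = mid
        else:
            hi = mid
    half = 0.5 * (lo + hi)
    R = chord / (2.0 * math.sin(half))
    x_hat = (b - a) / chord
    y_hat = np.array([0.0, 1.0, 0.0])
    y_hat = y_hat - np.dot(y_hat, x_hat) * x_hat
    if np.linalg.norm(y_hat) < 1e-6:
        y_hat = np.array([0.0, 0.0, 1.0]) - np.dot(np.array([0.0, 0.0, 1.0]), x_hat) * x_hat
    y_hat /= np.linalg.norm(y_hat)
    mid_pt = 0.5 * (a + b)
    center = mid_pt - math.sqrt(max(R * R - (chord / 2) ** 2, 0.0)) * y_hat
    ang0 = math.atan2(np.dot(a - center, y_hat), np.dot(a - center, x_hat))
    ang1 = math.atan2(np.dot(b - center, y_hat), np.dot(b - center, x_hat))
    # sweep the short way over the +y bulge (decreasing angle)
    if ang1 > ang0:
        ang1 -= 2 * math.pi
    pts = []
    for k in range(1, n + 1):
        ang = ang0 + (ang1 - ang0) * k / (n + 1)
        pts.append(center + R * (math.cos(ang) * x_hat + math.sin(ang) * y_hat))
    return pts


def _reference_geometry(spec: SyntheticEnsembleSpec, rng: np.random.Generator):
    """Build the bilobal reference: lobes, cleft patch, linker arc, hinge.

    Architecture (x = lobe-lobe axis, y = "up", all Å):

    * lobe 1 in a sphere at the origin, its chain *starting* 1.2 Å beneath
      the cleft-facing (+x) pole — the guaranteed catalytic-interface
      contact;
    * loop patches (the active-site analog) as a chain whose fixed first
      node protrudes into the cleft to within ~5.4 Å of lobe 1's start
      node (the single interface contact) and whose remainder coils into
      lobe 2's cleft-side volume; an exclusion shell keeps every other
      patch node ≥ 4.8 Å away from lobe 1 so the contact stays
      node-resolved;
    * lobe 2 mirrored around its own center;
    * the linker as a shallow planar arc over the top, anchored just above
      each lobe's topmost node, node spacing CA_SPACING;
    * the hinge axis z through the middle linker node; per frame lobe 2 and
      the patches rotate by the full hinge angle, linker node i by the
      fraction (i+1)/(n_linker+1) (a distributed hinge), lobe 1 not at all.

    Because the lobes' bounding spheres stay ≥ ``LOBE_GAP`` apart, direct
    lobe-lobe contacts are impossible at short candidate cutoffs: the only
    communication channels are the cleft contact (hinge-decohered) and the
    linker arc.
    """
    lobes = [r for r in spec.regions if r.role == "rigid_body"]
    linkers = [r for r in spec.regions if r.role == "linker"]
    if len(lobes) != 2 or len(linkers) != 1:
        raise ConfigError("the generator expects exactly two rigid bodies and one linker")
    lobe1, lobe2 = sorted(lobes, key=lambda r: r.start)
    linker = linkers[0]
    loops = [r for r in spec.regions if r.role == "loop"]

    r1 = _lobe_radius(lobe1.size)
    r2 = _lobe_radius(lobe2.size)
    c1 = np.zeros(3)
    c2 = np.array([r1 + LOBE_GAP + r2, 0.0, 0.0])
    x_hat = np.array([1.0, 0.0, 0.0])
    attach_clearance = 4.0  # Å from the anchor centroid to the first/last linker node
    free_clearance = 6.2  # Å minimum lobe distance for interior linker nodes

    for _attempt in range(30):
        anchors = np.zeros((spec.n_nodes, 3))
        body1 = _grow_chain(
            rng,
            lobe1.size,
            c1,
            r1,
            start=c1 + (r1 - 1.2) * x_hat,
            existing=[],
        )
        anchors[lobe1.start : lobe1.stop] = body1

        # cleft patch(es): fixed tip protruding into the cleft, remainder
        # coiled into lobe 2's cleft-side volume; the exclusion shell keeps
        # every non-tip patch node beyond candidate reach of lobe 1
        tip = c1 + (r1 + 4.9) * x_hat
        body2_existing: list[np.ndarray] = []
        for loop in loops:
            patch = _grow_chain(
                rng,
                loop.size,
                c2 - 0.75 * r2 * x_hat,
                0.62 * r2 + 2.0,
                start=tip,
                existing=body2_existing,
                exclude=(c1, r1 + free_clearance),
            )
            anchors[loop.start : loop.stop] = patch
            body2_existing = body2_existing + patch

        body2 = _grow_chain(
            rng,
            lobe2.size,
            c2,
            r2,
            start=None,
            existing=body2_existing,
        )
        anchors[lobe2.start : lobe2.stop] = body2

        # linker: attachment nodes above each lobe's upper-inner pole,
        # joined by a high arc bulging upward over the cleft; each
        # attachment sits over the centroid of THREE lobe nodes so that no
        # single lobe node funnels all of the linker's traffic
        def _attach(body: list[np.ndarray], center: np.ndarray, aim: np.ndarray) -> np.ndarray:
            arr = np.array(body)
            k1 = int(np.argmin(np.linalg.norm(arr - aim, axis=1)))
            d_to_k1 = np.linalg.norm(arr - arr[k1], axis=1)
            d_to_k1[k1] = np.inf
            k2, k3 = np.argsort(d_to_k1)[:2]
            mid = (arr[k1] + arr[k2] + arr[k3]) / 3.0
            u = (mid - center) / np.linalg.norm(mid - center)
            return mid + attach_clearance * u

        aim1 = c1 + r1 * np.array([0.42, 0.91, 0.0])
        aim2 = c2 + r2 * np.array([-0.42, 0.91, 0.0])
        l_first = _attach(body1, c1, aim1)
        l_last = _attach(body2, c2, aim2)
        chord = np.linalg.norm(l_last - l_first)
        if chord >= (linker.size - 1) * CA_SPACING * 0.98:
            continue  # anchors too far apart for a proper arc; regrow
        arc = [l_first] + _arc_linker(linker.size - 2, l_first, l_last) + [l_last]
        anchors[linker.start : linker.stop] = arc

        # validity: interior linker nodes must be out of candidate reach of
        # every lobe/patch node (entry only via the attachment nodes), the
        # attachments must not touch the opposite lobe, and non-consecutive
        # linker nodes must stay apart (the chain cannot short-circuit)
        others = np.array(body1 + body2_existing + body2)
        interior = np.array(arc[1:-1])
        d_int = np.linalg.norm(interior[:, None, :] - others[None, :, :], axis=2)
        d1 = np.linalg.norm(np.array(body2 + body2_existing) - l_first, axis=1)
        d2 = np.linalg.norm(np.array(body1) - l_last, axis=1)
        arc_arr = np.array(arc)
        d_skip = np.array(
            [
                np.linalg.norm(arc_arr[i] - arc_arr[j])
                for i in range(len(arc))
                for j in range(i + 2, len(arc))
            ]
        )
        if (
            d_int.min() > free_clearance
            and d1.min() > free_clearance
            and d2.min() > free_clearance
            and d_skip.min() > free_clearance
        ):
            break
    else:
        raise InputError("could not assemble a valid two-lobe reference geometry")

    # Cβ-like direction vectors: random but transverse to the local chain
    # tangent, as real side chains point away from the backbone.  Transverse
    # orientations also keep the pair torsion well-defined along the chain.
    directions = np.empty((spec.n_nodes, 3))
    for region in spec.regions:
        pts = anchors[region.start : region.stop]
        for i in range(region.size):
            lo = max(i - 1, 0)
            hi = min(i + 1, region.size - 1)
            tangent = pts[hi] - pts[lo]
            tnorm = np.linalg.norm(tangent)
            tangent = tangent / tnorm if tnorm > 1e-9 else np.array([1.0, 0.0, 0.0])
            while True:
                raw = rng.normal(0.0, 1.0, 3)
                raw -= np.dot(raw, tangent) * tangent
                if np.linalg.norm(raw) > 1e-6:
                    break
            directions[region.start + i] = raw / np.linalg.norm(raw)

    pivot = np.asarray(arc[linker.size // 2])
    axis = np.array([0.0, 0.0, 1.0])
    fractions = np.zeros(spec.n_nodes)
    fractions[lobe2.start : lobe2.stop] = 1.0
    for loop in loops:
        fractions[loop.start : loop.stop] = 1.0
    for i in range(linker.size):
        fractions[linker.start + i] = (i + 1) / (linker.size + 1)
    return anchors, directions, pivot, axis, fractions


def generate_ensemble(spec: SyntheticEnsembleSpec) -> SyntheticEnsemble:
    """Build the reference geometry and sample the frames.

    Draw order (fixed for reproducibility): reference geometry, then per
    frame a (n, 3) standard-normal block for positional noise and a (n, 3)
    standard-normal block for direction rotation vectors.  Positional noise
    scales by the region σ; direction jitter by σ_angle = 10°/Å · σ.
    """
    rng = np.random.default_rng(spec.seed)
    ref_anchors, ref_dirs, pivot, axis, fractions = _reference_geometry(spec, rng)
    n = spec.n_nodes
    sigma = np.zeros(n)
    for r in spec.regions:
        sigma[r.start : r.stop] = r.sigma
    sigma_angle_rad = np.radians(ANGLE_NOISE_DEG_PER_A * sigma)

    times = np.arange(spec.n_frames) * spec.stride_ns
    if spec.hinge_period_ns > 0:
        angles = spec.hinge_amplitude_deg * np.sin(2.0 * math.pi * times / spec.hinge_period_ns)
    else:
        angles = np.zeros_like(times)

    skeleton = SyntheticEnsemble(
        spec=spec,
        frames=[],
        ref_anchors=ref_anchors,
        ref_directions=ref_dirs,
        hinge_angles_deg=angles,
        hinge_pivot=pivot,
        hinge_axis=axis,
        hinge_fractions=fractions,
    )

    labels = tuple(f"N{i}" for i in range(n))
    frames: list[NodeVectorFrame] = []
    for f_idx in range(spec.n_frames):
        pos, dirs = skeleton._hinge_apply(f_idx, ref_anchors.copy(), ref_dirs.copy())
        pos_noise = rng.normal(0.0, 1.0, (n, 3))
        rotvec_noise = rng.normal(0.0, 1.0, (n, 3))
        pos = pos + pos_noise * sigma[:, None]
        jitter = Rotation.from_rotvec(rotvec_noise * sigma_angle_rad[:, None])
        dirs = jitter.apply(dirs)
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        frames.append(
            NodeVectorFrame(
                frame_index=f_idx,
                time=float(times[f_idx]),
                labels=labels,
                anchors=pos,
                directions=dirs,
            )
        )
    skeleton.frames = frames
    return skeleton


def region_pair_mean_weight(
    adj: AdjacencyMatrix,
    spec: SyntheticEnsembleSpec,
    region_a: str,
    region_b: str,
) -> float:
    """Mean adjacency entry between two regions (diagonal excluded)."""
    ia = spec.region(region_a).indices
    ib = spec.region(region_b).indices
    block = adj.matrix[np.ix_(ia, ib)]
    if region_a == region_b:
        mask = ~np.eye(len(ia), dtype=bool)
        return float(block[mask].mean())
    return float(block.mean())


def generate_toy_graph(kind: str, **params) -> ResidueNetwork:
    """Deterministic unit-weight toy graphs for centrality illustrations.

    ``hub_star(n_leaves=8)``: one hub connected to ``n_leaves`` leaves — the
    hub's DC equals the leaf count.  ``bridged_cliques(k1=3, k2=3)``: two
    cliques joined by a single bridge edge — each bridge endpoint carries
    all cross-clique shortest paths.  ``path(n)`` and ``complete(n)`` are
    the usual toys.
    """
    if kind == "hub_star":
        n_leaves = int(params.get("n_leaves", 8))
        g = nx.star_graph(n_leaves)
    elif kind == "bridged_cliques":
        k1 = int(params.get("k1", 3))
        k2 = int(params.get("k2", 3))
        g = nx.complete_graph(k1)
        g = nx.disjoint_union(g, nx.complete_graph(k2))
        g.add_edge(0, k1)  # bridge between one vertex of each clique
    elif kind == "path":
        g = nx.path_graph(int(params.get("n", 3)))
    elif kind == "complete":
        g = nx.complete_graph(int(params.get("n", 4)))
    else:
        raise ConfigError(f"unknown toy graph kind {kind!r}")
    nx.set_edge_attributes(g, 1.0, "weight")
    labels = tuple(f"n{i}" for i in range(g.number_of_nodes()))
    return ResidueNetwork(graph=g, labels=labels, weight_threshold=0.0)


def generate_distance_series(
    mode: str,
    n: int,
    seed: int = 0,
    stride_ns: float = 0.1,
    **params,
) -> DistanceSeries:
    """Sampled atom-pair distance series with a known distribution.

    ``unimodal(mu, sigma)`` — Gaussian about one contact distance;
    ``bimodal(mu1, sigma1, mu2, sigma2, w)`` — a two-state toggle with
    weight ``w`` on the first state; ``drifting(start, end, sigma)`` — a
    linear mean drift with Gaussian noise.  Distances are clipped to stay
    positive (at 0.5 Å).
    """
    if n < 1:
        raise InputError("n must be positive")
    rng = np.random.default_rng(seed)
    if mode == "unimodal":
        mu = float(params.get("mu", 2.8))
        sigma = float(params.get("sigma", 0.1))
        x = rng.normal(mu, sigma, n)
    elif mode == "bimodal":
        mu1 = float(params.get("mu1", 2.8))
        sigma1 = float(params.get("sigma1", 0.15))
        mu2 = float(params.get("mu2", 6.0))
        sigma2 = float(params.get("sigma2", 0.15))
        w = float(params.get("w", 0.5))
        if not (0.0 < w < 1.0):
            raise ConfigError("mixture weight must lie in (0, 1)")
        pick = rng.random(n) < w
        x = np.where(pick, rng.normal(mu1, sigma1, n), rng.normal(mu2, sigma2, n))
    elif mode == "drifting":
        start = float(params.get("start", 3.0))
        end = float(params.get("end", 6.0))
        sigma = float(params.get("sigma", 0.2))
        x = np.linspace(start, end, n) + rng.normal(0.0, sigma, n)
    else:
        raise ConfigError(f"unknown series mode {mode!r}")
    x = np.clip(x, 0.5, None)
    times = np.arange(n) * stride_ns
    label = params.get("label", f"{mode}_series")
    return DistanceSeries(label=label, times=times, distances=x)
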