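"""Reading conformational ensembles and turning frames into node/vector sets.

The analyses in this package operate on *oriented point clouds*: one anchor
position and one unit direction vector per node and per frame.  For amino-acid
residues the anchor is the Cα atom and the direction is the normalized Cα→Cβ
bond; glycine gets a pseudo-Cβ built from its backbone (tetrahedral
construction); a ligand such as ATP can be added as an extra node with a
configurable atom pair (default N1→C8).

File reading and writing is delegated to MDAnalysis, which handles multi-model
PDB files (models become trajectory frames) and DCD/XTC trajectories with a
PDB topology.  Frame times are expressed in nanoseconds throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ComparisonError,
    DataError,
    FormatError,
    InputError,
    RangeError,
    SelectionError,
)

__all__ = [
    "StructureFrame",
    "NodeSpec",
    "NodeVectorFrame",
    "WindowedEnsemble",
    "load_ensemble",
    "write_multimodel_pdb",
    "build_node_specs",
    "extract_node_vectors",
    "select_windows",
    "default_window_starts",
    "fetch_pdb",
    "glycine_pseudo_cb",
]

#: Ideal Cα–Cβ bond length (Å), used for the glycine pseudo-Cβ.
CA_CB_LENGTH = 1.53
#: Ideal tetrahedral angle (degrees) between the pseudo-Cβ bond and each of
#: the N–Cα and C–Cα bonds.
TETRAHEDRAL_ANGLE_DEG = 109.47

#: The five default analysis windows (start times in ns).
DEFAULT_WINDOW_STARTS = (0.0, 50.0, 90.0, 130.0, 170.0)
DEFAULT_WINDOW_LENGTH = 10.0
DEFAULT_WINDOW_STRIDE = 0.1


@dataclass
class StructureFrame:
    """One snapshot of a structure: a flat table of atom records.

    Coordinates are in Å.  Atom records must be unique per
    ``(chain, resid, name)``.
    """

    frame_index: int
    time: float  # ns
    chains: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int
    resnames: np.ndarray  # (n,) str
    names: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, Å

    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in frame")
        n = len(self.coords)
        if not (len(self.chains) == len(self.resids) == len(self.resnames) == len(self.names) == n):
            raise InputError("atom attribute arrays have inconsistent lengths")
        self._index = {}
        for i in range(n):
            key = (str(self.chains[i]), int(self.resids[i]), str(self.names[i]))
            if key in self._index:
                raise FormatError(f"duplicate atom record {key}")
            self._index[key] = i

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        try:
            return self._index[(str(chain), int(resid), str(name))]
        except KeyError:
            raise DataError(f"atom {chain}:{resid}:{name} not found in frame {self.frame_index}") from None

    def has_atom(self, chain: str, resid: int, name: str) -> bool:
        return (str(chain), int(resid), str(name)) in self._index

    def position(self, chain: str, resid: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(chain, resid, name)]

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique ``(chain, resid, resname)`` triples in first-seen order."""
        seen: dict[tuple[str, int], str] = {}
        for i in range(self.n_atoms):
            key = (str(self.chains[i]), int(self.resids[i]))
            if key not in seen:
                seen[key] = str(self.resnames[i])
        return [(c, r, n) for (c, r), n in seen.items()]


@dataclass(frozen=True)
class NodeSpec:
    """How one network node is anchored and oriented within a structure.

    Residue nodes use Cα as anchor and Cβ as direction atom; glycine sets
    ``pseudo_direction`` and builds a tetrahedral pseudo-Cβ from N, Cα, C.
    Ligand nodes name arbitrary atoms (ATP default: N1 anchor, C8 direction).
    """

    node_id: int
    label: str
    chain: str
    resid: int
    anchor_atom: str = "CA"
    direction_atom: str = "CB"
    pseudo_direction: bool = False


@dataclass
class NodeVectorFrame:
    """Per-frame anchors and unit direction vectors for a fixed node set."""

    frame_index: int
    time: float  # ns
    labels: tuple[str, ...]
    anchors: np.ndarray  # (n, 3) Å
    directions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InputError("direction vectors must have unit norm")

    @property
    def n_nodes(self) -> int:
        return len(self.anchors)


@dataclass
class WindowedEnsemble:
    """Frames falling in one half-open time window ``[start, start+length)``."""

    window_id: int
    start: float  # ns
    length: float  # ns
    frames: list  # ordered; NodeVectorFrame or StructureFrame

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def span(self) -> tuple[float, float]:
        return (self.start, self.start + self.length)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InputError("zero-length vector cannot be normalized")
    return v / n


def glycine_pseudo_cb(n_pos: np.ndarray, ca_pos: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    """Place a pseudo-Cβ for glycine from its backbone N, Cα, C atoms.

    Tetrahedral rule: the Cβ direction is a combination of the inverted
    N/C-bond bisector and the normal of the N–Cα–C plane, with the mixing
    angle chosen so the pseudo-bond makes the ideal 109.47° angle with both
    the Cα–N and Cα–C bonds.  The normal's sign follows the L-amino-acid
    convention (pseudo-Cβ on the same side as a real Cβ would sit).
    Returns the pseudo-Cβ *position* (Å), at 1.53 Å from Cα.
    """
    n1 = _unit(np.asarray(n_pos, float) - ca_pos)
    n2 = _unit(np.asarray(c_pos, float) - ca_pos)
    bis = _unit(n1 + n2)
    perp = _unit(np.cross(n1, n2))
    cos_gamma = float(np.dot(bis, n1))  # half the N-Ca-C angle
    target = math.cos(math.radians(TETRAHEDRAL_ANGLE_DEG))  # negative
    cos_a = min(1.0, -target / cos_gamma)
    a = math.acos(cos_a)
    direction = -math.cos(a) * bis + math.sin(a) * perp
    return np.asarray(ca_pos, float) + CA_CB_LENGTH * _unit(direction)


def build_node_specs(
    frame: StructureFrame,
    ligands: Sequence[NodeSpec] | None = None,
    ligand_resnames: Iterable[str] = ("ATP",),
    include_ligands: bool = False,
) -> list[NodeSpec]:
    """Derive the node list from a frame: one node per amino-acid residue.

    Residues are taken in file order.  Glycine nodes get the pseudo-Cβ flag.
    Ligand residues (by residue name) are skipped unless ``include_ligands``
    is set, in which case they become N1→C8 nodes (the ATP convention), or
    explicit ``ligands`` specs are appended.
    """
    ligand_resnames = set(ligand_resnames)
    specs: list[NodeSpec] = []
    for chain, resid, resname in frame.residues():
        if resname in ligand_resnames:
            if include_ligands and ligands is None:
                specs.append(
                    NodeSpec(
                        node_id=len(specs),
                        label=f"{resname}{resid}",
                        chain=chain,
                        resid=resid,
                        anchor_atom="N1",
                        direction_atom="C8",
                    )
                )
            continue
        if not frame.has_atom(chain, resid, "CA"):
            continue  # not an amino acid (waters, ions)
        specs.append(
            NodeSpec(
                node_id=len(specs),
                label=f"{resname}{resid}",
                chain=chain,
                resid=resid,
                pseudo_direction=(resname == "GLY"),
            )
        )
    if ligands is not None:
        for lig in ligands:
            specs.append(
                NodeSpec(
                    node_id=len(specs),
                    label=lig.label,
                    chain=lig.chain,
                    resid=lig.resid,
                    anchor_atom=lig.anchor_atom,
                    direction_atom=lig.direction_atom,
                )
            )
    if len(specs) < 2:
        raise SelectionError("node selection resolves to fewer than 2 nodes")
    return specs


def extract_node_vectors(frame: StructureFrame, nodes: Sequence[NodeSpec]) -> NodeVectorFrame:
    """Compute per-node anchor positions and unit direction vectors.

    Residue nodes: anchor = Cα, direction = normalized Cα→Cβ.  Glycine
    (``pseudo_direction``): direction toward the tetrahedral pseudo-Cβ.
    Ligand nodes: anchor→direction atoms as configured.
    """
    n = len(nodes)
    anchors = np.empty((n, 3))
    directions = np.empty((n, 3))
    for k, spec in enumerate(nodes):
        if spec.node_id != k:
            raise InputError("node_ids must be contiguous from 0 and in order")
        anchor = frame.position(spec.chain, spec.resid, spec.anchor_atom)
        if spec.pseudo_direction:
            n_pos = frame.position(spec.chain, spec.resid, "N")
            c_pos = frame.position(spec.chain, spec.resid, "C")
            target = glycine_pseudo_cb(n_pos, anchor, c_pos)
        else:
            if not frame.has_atom(spec.chain, spec.resid, spec.direction_atom):
                raise DataError(
                    f"node {spec.label}: direction atom {spec.direction_atom} missing "
                    f"in frame {frame.frame_index}"
                )
            target = frame.position(spec.chain, spec.resid, spec.direction_atom)
        anchors[k] = anchor
        directions[k] = _unit(target - anchor)
    return NodeVectorFrame(
        frame_index=frame.frame_index,
        time=frame.time,
        labels=tuple(s.label for s in nodes),
        anchors=anchors,
        directions=directions,
    )


def load_ensemble(
    coordinate_source: str | Path,
    topology: str | Path | None = None,
    selection: str = "all",
    t0: float = 0.0,
    stride: float | None = None,
) -> list[StructureFrame]:
    """Read an ensemble into a list of :class:`StructureFrame`.

    ``coordinate_source`` may be a multi-model PDB (models become frames) or
    a DCD/XTC trajectory, in which case ``topology`` names a PDB/PSF-style
    topology.  ``selection`` is an MDAnalysis selection string.  Frame times
    (ns) are ``t0 + i*stride`` when ``stride`` is given, otherwise taken from
    trajectory metadata (ps converted to ns) when present.

    When alternate locations exist, only the first conformer (altLoc '' or
    'A') is kept.
    """
    import MDAnalysis as mda

    src = Path(coordinate_source)
    if not src.exists():
        raise InputError(f"coordinate source not found: {src}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology is not None:
                u = mda.Universe(str(topology), str(src))
            else:
                u = mda.Universe(str(src))
        except Exception as exc:  # MDA raises a zoo of types for bad files
            raise InputError(f"could not read {src}: {exc}") from exc
        ag = u.select_atoms(selection)
        if hasattr(ag, "altLocs"):
            keep = np.isin(ag.altLocs, ("", "A"))
            ag = ag[keep]
        if ag.n_atoms == 0:
            raise SelectionError(f"selection {selection!r} matches zero atoms")
        n_res = len(np.unique(ag.resindices))
        if n_res < 2:
            raise SelectionError("selection must cover at least 2 residues")

        chains = np.array([(s if s else "A") for s in _segids(ag)], dtype=object)
        resids = ag.resids.astype(int)
        resnames = np.array([str(x) for x in ag.resnames], dtype=object)
        names = np.array([str(x) for x in ag.names], dtype=object)

        frames: list[StructureFrame] = []
        n_atoms = ag.n_atoms
        for i, ts in enumerate(u.trajectory):
            if ag.n_atoms != n_atoms:
                raise FormatError("inconsistent atom counts across frames")
            if stride is not None:
                t = t0 + i * stride
            else:
                t = t0 + (float(ts.time) / 1000.0 if ts.time is not None else float(i))
            frames.append(
                StructureFrame(
                    frame_index=i,
                    time=t,
                    chains=chains.copy(),
                    resids=resids.copy(),
                    resnames=resnames.copy(),
                    names=names.copy(),
                    coords=ag.positions.astype(float).copy(),
                )
            )
    if not frames:
        raise InputError(f"no frames found in {src}")
    return frames


def _segids(ag):
    try:
        out = []
        for a in ag:
            sid = str(getattr(a, "chainID", "") or getattr(a, "segid", "") or "A")
            out.append(sid.strip() or "A")
        return out
    except Exception:
        return ["A"] * ag.n_atoms


def write_multimodel_pdb(frames: Sequence[StructureFrame], path: str | Path) -> Path:
    """Write frames as a multi-model PDB (one MODEL per frame) via MDAnalysis."""
    import MDAnalysis as mda

    if not frames:
        raise InputError("no frames to write")
    f0 = frames[0]
    resid_keys = [(c, r) for c, r, _ in f0.residues()]
    key_to_resindex = {k: i for i, k in enumerate(resid_keys)}
    atom_resindex = np.array(
        [key_to_resindex[(str(f0.chains[i]), int(f0.resids[i]))] for i in range(f0.n_atoms)]
    )
    u = mda.Universe.empty(
        n_atoms=f0.n_atoms,
        n_residues=len(resid_keys),
        n_segments=len(set(c for c, _ in resid_keys)),
        atom_resindex=atom_resindex,
        residue_segindex=_residue_segindex(resid_keys),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in f0.names])
    u.add_TopologyAttr("resnames", [rn for _, _, rn in f0.residues()])
    u.add_TopologyAttr("resids", [r for _, r in resid_keys])
    seg_order = sorted(set(c for c, _ in resid_keys))
    u.add_TopologyAttr("segids", seg_order)
    u.add_TopologyAttr("chainIDs", [str(c) for c in f0.chains])
    u.add_TopologyAttr("elements", [_guess_element(str(n)) for n in f0.names])

    coords = np.stack([f.coords for f in frames])
    u.load_new(coords, order="fac")
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=f0.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return path


def _residue_segindex(resid_keys):
    seg_order = sorted(set(c for c, _ in resid_keys))
    seg_idx = {s: i for i, s in enumerate(seg_order)}
    return np.array([seg_idx[c] for c, _ in resid_keys])


def _guess_element(name: str) -> str:
    name = name.strip()
    return name[0] if name else "C"


def default_window_starts() -> tuple[float, ...]:
    return DEFAULT_WINDOW_STARTS


def select_windows(
    frames: Sequence,
    window_starts: Sequence[float] = DEFAULT_WINDOW_STARTS,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    stride: float = DEFAULT_WINDOW_STRIDE,
) -> list[WindowedEnsemble]:
    """Cut half-open time windows ``[t0, t0+L)`` out of an ordered frame list.

    Each window contains the frames at times ``t0, t0+stride, …,
    t0+L−stride``; the defaults give five 10 ns windows of 100 frames each
    (0.1 ns stride).  Works on any frame objects carrying a ``time``
    attribute (ns).
    """
    if window_length <= 0 or stride <= 0:
        raise RangeError("window length and stride must be positive")
    n_per = window_length / stride
    if abs(n_per - round(n_per)) > 1e-9 * max(1.0, n_per):
        raise RangeError("stride must divide the window length")
    n_per = int(round(n_per))

    times = np.array([f.time for f in frames], dtype=float)
    if len(times) < 1:
        raise InputError("no frames supplied")
    if np.any(np.diff(times) <= 0):
        raise InputError("frame times must be strictly increasing")
    dt = float(np.median(np.diff(times))) if len(times) > 1 else stride
    step = stride / dt
    if abs(step - round(step)) > 1e-6 * max(1.0, step) or round(step) < 1:
        raise RangeError(
            f"stride {stride} ns is finer than or incommensurate with the "
            f"source sampling interval {dt} ns"
        )
    step = int(round(step))

    windows: list[WindowedEnsemble] = []
    for wid, t_start in enumerate(window_starts):
        i0 = (t_start - times[0]) / dt
        if abs(i0 - round(i0)) > 1e-6 * max(1.0, abs(i0)):
            raise RangeError(f"window start {t_start} ns does not align with the sampling grid")
        i0 = int(round(i0))
        last = i0 + (n_per - 1) * step
        if i0 < 0 or last >= len(frames):
            raise RangeError(
                f"window [{t_start}, {t_start + window_length}) ns extends past the trajectory"
            )
        sel = [frames[i0 + k * step] for k in range(n_per)]
        for f, k in zip(sel, range(n_per)):
            expected = t_start + k * stride
            if abs(f.time - expected) > 1e-6 * max(1.0, abs(expected)):
                raise RangeError("frame times do not match the requested window grid")
        windows.append(
            WindowedEnsemble(window_id=wid, start=float(t_start), length=float(window_length), frames=sel)
        )
    return windows


def check_identical_node_sets(frames: Sequence[NodeVectorFrame]) -> tuple[str, ...]:
    """Return the common label tuple or raise :class:`ComparisonError`."""
    if not frames:
        raise InputError("no frames")
    labels = frames[0].labels
    for f in frames[1:]:
        if f.labels != labels:
            raise ComparisonError("frames do not share a node set")
    return labels


def fetch_pdb(pdb_id: str, dest: str | Path) -> Path:
    """Download a PDB entry from the RCSB (network required) to ``dest``."""
    import urllib.request

    pdb_id = pdb_id.strip().lower()
    if len(pdb_id) != 4:
        raise InputError(f"invalid PDB id {pdb_id!r}")
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    try:
        urllib.request.urlretrieve(url, dest)
    except Exception as exc:
        raise InputError(f"could not fetch {pdb_id} from RCSB: {exc}") from exc
    return dest
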