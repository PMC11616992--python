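"""Ensemble I/O: PDB round trips, node-vector extraction, time windows."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lspnet.ensembles import (
    CA_CB_LENGTH,
    NodeSpec,
    StructureFrame,
    TETRAHEDRAL_ANGLE_DEG,
    build_node_specs,
    extract_node_vectors,
    glycine_pseudo_cb,
    load_ensemble,
    select_windows,
    write_multimodel_pdb,
)
from lspnet.errors import DataError, FormatError, InputError, RangeError

from conftest import apply_rigid, make_vector_frame, random_rigid_transform


def _toy_frame(coords_by_atom, frame_index=0, time=0.0):
    chains, resids, resnames, names, coords = [], [], [], [], []
    for (chain, resid, resname, name), xyz in coords_by_atom.items():
        chains.append(chain)
        resids.append(resid)
        resnames.append(resname)
        names.append(name)
        coords.append(xyz)
    return StructureFrame(
        frame_index=frame_index,
        time=time,
        chains=np.array(chains, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        names=np.array(names, dtype=object),
        coords=np.array(coords, dtype=float),
    )


class TestStructureFrame:
    def test_duplicate_atom_records_rejected(self):
        with pytest.raises(FormatError):
            StructureFrame(
                frame_index=0,
                time=0.0,
                chains=np.array(["A", "A"], dtype=object),
                resids=np.array([1, 1]),
                resnames=np.array(["ALA", "ALA"], dtype=object),
                names=np.array(["CA", "CA"], dtype=object),
                coords=np.zeros((2, 3)),
            )

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InputError):
            _toy_frame({("A", 1, "ALA", "CA"): (np.nan, 0, 0)})


class TestNodeVectors:
    def test_alanine_direction_is_normalized_ca_cb(self):
        frame = _toy_frame(
            {
                ("A", 1, "ALA", "CA"): (0.0, 0.0, 0.0),
                ("A", 1, "ALA", "CB"): (1.5, 0.0, 0.0),
                ("A", 2, "ALA", "CA"): (3.8, 0.0, 0.0),
                ("A", 2, "ALA", "CB"): (3.8, 1.5, 0.0),
            }
        )
        nodes = build_node_specs(frame)
        nv = extract_node_vectors(frame, nodes)
        assert np.allclose(nv.directions[0], [1.0, 0.0, 0.0])
        assert np.allclose(nv.directions[1], [0.0, 1.0, 0.0])
        assert np.allclose(nv.anchors[0], [0.0, 0.0, 0.0])

    def test_glycine_pseudo_cb_tetrahedral_angles(self):
        # ideal-ish backbone: N and C at standard bond lengths, ~111° apart
        ca = np.zeros(3)
        n_pos = np.array([1.458, 0.0, 0.0])
        c_pos = 1.525 * np.array([math.cos(math.radians(111.0)), math.sin(math.radians(111.0)), 0.0])
        cb = glycine_pseudo_cb(n_pos, ca, c_pos)
        assert np.linalg.norm(cb - ca) == pytest.approx(CA_CB_LENGTH, abs=1e-9)

        def angle(u, v):
            return math.degrees(
                math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            )

        a_n = angle(cb - ca, n_pos - ca)
        a_c = angle(cb - ca, c_pos - ca)
        assert a_n == pytest.approx(TETRAHEDRAL_ANGLE_DEG, abs=0.1)
        assert a_c == pytest.approx(TETRAHEDRAL_ANGLE_DEG, abs=0.1)
        assert cb[2] != 0.0  # out of the backbone plane

    def test_ligand_node_uses_anchor_to_direction_atoms(self):
        frame = _toy_frame(
            {
                ("A", 1, "ALA", "CA"): (0.0, 0.0, 0.0),
                ("A", 1, "ALA", "CB"): (1.5, 0.0, 0.0),
                ("A", 2, "ALA", "CA"): (3.8, 0.0, 0.0),
                ("A", 2, "ALA", "CB"): (3.8, 1.5, 0.0),
                ("A", 400, "ATP", "N1"): (10.0, 0.0, 0.0),
                ("A", 400, "ATP", "C8"): (10.0, 0.0, 4.4),
            }
        )
        nodes = build_node_specs(frame, include_ligands=True)
        assert nodes[-1].label == "ATP400"
        nv = extract_node_vectors(frame, nodes)
        assert np.allclose(nv.anchors[-1], [10.0, 0.0, 0.0])
        assert np.allclose(nv.directions[-1], [0.0, 0.0, 1.0])
        assert np.linalg.norm(nv.directions[-1]) == pytest.approx(1.0)

    def test_missing_direction_atom_raises(self):
        frame = _toy_frame(
            {
                ("A", 1, "ALA", "CA"): (0.0, 0.0, 0.0),
                ("A", 2, "ALA", "CA"): (3.8, 0.0, 0.0),
                ("A", 2, "ALA", "CB"): (3.8, 1.5, 0.0),
            }
        )
        nodes = [
            NodeSpec(0, "ALA1", "A", 1),
            NodeSpec(1, "ALA2", "A", 2),
        ]
        with pytest.raises(DataError):
            extract_node_vectors(frame, nodes)

    def test_extraction_is_rigid_equivariant(self):
        rng = np.random.default_rng(11)
        coords = {}
        for r in range(1, 6):
            ca = rng.uniform(-5, 5, 3)
            cb = ca + 1.53 * _unit(rng.normal(0, 1, 3))
            coords[("A", r, "ALA", "CA")] = tuple(ca)
            coords[("A", r, "ALA", "CB")] = tuple(cb)
        frame = _toy_frame(coords)
        nodes = build_node_specs(frame)
        nv = extract_node_vectors(frame, nodes)
        rot, shift = random_rigid_transform(rng)
        moved = _toy_frame(
            {k: tuple(rot.apply(np.array(v)) + shift) for k, v in coords.items()}
        )
        nv2 = extract_node_vectors(moved, nodes)
        assert np.allclose(nv2.anchors, rot.apply(nv.anchors) + shift, atol=1e-9)
        assert np.allclose(nv2.directions, rot.apply(nv.directions), atol=1e-9)
        assert np.allclose(np.linalg.norm(nv2.directions, axis=1), 1.0, atol=1e-9)


def _unit(v):
    return v / np.linalg.norm(v)


class TestPDBRoundTrip:
    def test_write_then_load_preserves_coordinates(self, tmp_path, small_ensemble):
        frames = small_ensemble.to_structure_frames()[:3]
        path = write_multimodel_pdb(frames, tmp_path / "toy.pdb")
        loaded = load_ensemble(path, stride=0.1)
        assert len(loaded) == 3
        for orig, back in zip(frames, loaded):
            assert back.n_atoms == orig.n_atoms
            assert np.allclose(back.coords, orig.coords, atol=1.1e-3)

    def test_loading_twice_is_deterministic(self, tmp_path, small_ensemble):
        frames = small_ensemble.to_structure_frames()[:2]
        path = write_multimodel_pdb(frames, tmp_path / "toy.pdb")
        a = load_ensemble(path)
        b = load_ensemble(path)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.coords, fb.coords)

    def test_unreadable_file_raises_input_error(self, tmp_path):
        with pytest.raises(InputError):
            load_ensemble(tmp_path / "nope.pdb")


class _TimedFrame:
    def __init__(self, i, t):
        self.frame_index = i
        self.time = t


class TestWindows:
    def test_ten_ns_window_at_tenth_ns_stride_has_100_frames(self):
        frames = [_TimedFrame(i, i * 0.1) for i in range(2000)]
        windows = select_windows(frames, window_starts=[0.0], window_length=10.0, stride=0.1)
        assert windows[0].n_frames == 100
        assert windows[0].frames[0].time == 0.0
        assert windows[0].frames[-1].time == pytest.approx(9.9)

    def test_window_equal_to_stride_is_single_frame(self):
        frames = [_TimedFrame(i, i * 0.1) for i in range(100)]
        (w,) = select_windows(frames, window_starts=[1.0], window_length=0.1, stride=0.1)
        assert w.n_frames == 1

    def test_five_default_windows_are_disjoint_and_match_brute_force(self):
        frames = [_TimedFrame(i, i * 0.01) for i in range(20000)]
        windows = select_windows(frames)  # the five standard windows
        assert len(windows) == 5
        assert all(w.n_frames == 100 for w in windows)
        seen = set()
        for w in windows:
            idx = {f.frame_index for f in w.frames}
            assert not (idx & seen)
            seen |= idx
            # brute force: times in [t0, t0+L) that are multiples of stride
            expect = [
                f.frame_index
                for f in frames
                if w.start - 1e-9 <= f.time < w.start + w.length - 1e-9
                and abs((f.time - w.start) / 0.1 - round((f.time - w.start) / 0.1)) < 1e-6
            ]
            assert sorted(idx) == expect

    def test_window_past_trajectory_end_raises(self):
        frames = [_TimedFrame(i, i * 0.1) for i in range(50)]
        with pytest.raises(RangeError):
            select_windows(frames, window_starts=[0.0], window_length=10.0, stride=0.1)

    def test_stride_finer_than_sampling_raises(self):
        frames = [_TimedFrame(i, i * 0.5) for i in range(100)]
        with pytest.raises(RangeError):
            select_windows(frames, window_starts=[0.0], window_length=10.0, stride=0.1)
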