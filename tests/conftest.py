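from __future__ import annotations

import numpy as np
import pytest

from lspnet.ensembles import NodeVectorFrame


def make_vector_frame(rng: np.random.Generator, n_nodes: int, frame_index: int = 0, time: float = 0.0, scale: float = 10.0) -> NodeVectorFrame:
    """Random oriented point cloud with unit direction vectors."""
    anchors = rng.uniform(-scale, scale, (n_nodes, 3))
    directions = rng.normal(0.0, 1.0, (n_nodes, 3))
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    return NodeVectorFrame(
        frame_index=frame_index,
        time=time,
        labels=tuple(f"N{i}" for i in range(n_nodes)),
        anchors=anchors,
        directions=directions,
    )


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-30.0, 30.0, 3)
    return rot, shift


def apply_rigid(frame: NodeVectorFrame, rot, shift) -> NodeVectorFrame:
    return NodeVectorFrame(
        frame_index=frame.frame_index,
        time=frame.time,
        labels=frame.labels,
        anchors=rot.apply(frame.anchors) + shift,
        directions=rot.apply(frame.directions),
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """A small wild-type synthetic ensemble shared across tests."""
    from lspnet.synthetic import default_two_lobe_spec, generate_ensemble

    spec = default_two_lobe_spec(seed=7, n_frames=60, stride_ns=0.1)
    return generate_ensemble(spec)
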