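import numpy as np
import pytest
import trimesh

from anthroscan import (
    AvatarSpec,
    TriMesh,
    detect_landmarks,
    make_avatar,
    measure_all,
    segment_body,
)


@pytest.fixture(scope="session")
def avatar():
    """Default synthetic A-pose avatar with analytic ground truth."""
    return make_avatar(AvatarSpec())


@pytest.fixture(scope="session")
def avatar_landmarks(avatar):
    mesh, _ = avatar
    return detect_landmarks(mesh)


@pytest.fixture(scope="session")
def avatar_segments(avatar, avatar_landmarks):
    mesh, _ = avatar
    return segment_body(mesh, avatar_landmarks)


@pytest.fixture(scope="session")
def avatar_measurements(avatar, avatar_landmarks, avatar_segments):
    mesh, _ = avatar
    return measure_all(mesh, lm=avatar_landmarks, segments=avatar_segments)


@pytest.fixture(scope="session")
def small_avatar():
    """Coarse, fast avatar for I/O and CLI tests."""
    return make_avatar(AvatarSpec(ring_resolution=48))


@pytest.fixture()
def cube():
    """Unit cube as a TriMesh (8 vertices, 12 faces)."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    v = np.asarray(box.vertices) - np.asarray(box.vertices).min(axis=0)
    return TriMesh(v, np.asarray(box.faces))


def mirror_x(mesh: TriMesh) -> TriMesh:
    """Reflect a mesh across the sagittal plane, keeping outward winding."""
    v = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    f = mesh.faces[:, ::-1]
    return TriMesh(v, f, mesh.frame)
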