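import numpy as np
import pytest

from corticoh.geometry import CorticalMesh
from corticoh.synthdata import make_sphere_mesh


@pytest.fixture(scope="session")
def sphere_mesh():
    """Icosphere at human-head cortical radius (1280 triangles)."""
    return make_sphere_mesh(3, 8.0)


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    """Unit-radius icosphere: total area ~ 4*pi cm^2."""
    return make_sphere_mesh(2, 1.0)


def make_strip_mesh(n_quads: int, width_mm: float = 10.0) -> CorticalMesh:
    """Flat strip of n_quads squares, each split into two triangles.

    All normals point +z (consistent winding). Useful for path-topology
    and coplanar-orientation tests.
    """
    w = width_mm
    verts = []
    for i in range(n_quads + 1):
        verts.append([i * w, 0.0, 0.0])
        verts.append([i * w, w, 0.0])
    verts = np.array(verts)
    tris = []
    for i in range(n_quads):
        a, b = 2 * i, 2 * i + 1
        c, d = 2 * i + 2, 2 * i + 3
        tris.append([a, c, b])   # +z normal
        tris.append([b, c, d])
    hemi = np.array(["right"] * len(verts))
    return CorticalMesh(vertices=verts, triangles=np.array(tris),
                        hemisphere=hemi)


@pytest.fixture
def strip_mesh():
    return make_strip_mesh(6)
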