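import numpy as np
import pytest

import meshkit as mk
from meshkit import synth


@pytest.fixture
def single_tet() -> mk.Mesh:
    """Unit right-corner tetrahedron, volume 1/6, tag 7."""
    return mk.Mesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        np.array([[0, 1, 2, 3]]),
        np.array([4]),
        np.array([7]),
    )


@pytest.fixture(scope="session")
def box3() -> mk.Mesh:
    return synth.box_tet_mesh(3, 3, 3)


@pytest.fixture(scope="session")
def two_label_box() -> mk.Mesh:
    """4x4x4 box split by the plane x = 2 into tags 1 and 2."""
    return synth.box_tet_mesh(4, 4, 4, label_planes=[(0, 2.0)])


@pytest.fixture(scope="session")
def shell() -> mk.Mesh:
    """Two-label ball: cavity (tag 1) inside tissue (tag 2)."""
    return synth.shell_with_cavity(1.0, 0.5, refinement=4)


@pytest.fixture(scope="session")
def ico4() -> mk.Mesh:
    return synth.icosphere(1.0, 4)


def brute_force_boundary_faces(mesh: mk.Mesh, tag_set) -> set:
    """Oracle: faces appearing exactly once among the selected tets."""
    from collections import Counter

    counts: Counter = Counter()
    ti, tc = mesh.tets()
    for row, tag in zip(tc, mesh.tags[ti]):
        if tag in tag_set:
            a, b, c, d = row
            for f in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                counts[tuple(sorted(f))] += 1
    return {f for f, n in counts.items() if n == 1}
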