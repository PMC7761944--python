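import numpy as np
import pytest
import trimesh as _trimesh

from toothwear.core import TriangleMesh
from toothwear.synthetic import build_case


def to_mesh(tm: "_trimesh.Trimesh") -> TriangleMesh:
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


@pytest.fixture()
def cube() -> TriangleMesh:
    """Unit cube [0,1]^3, outward oriented, 8 vertices / 12 faces."""
    tm = _trimesh.creation.box(extents=(1, 1, 1))
    m = to_mesh(tm)
    m.vertices = m.vertices + 0.5
    return m


@pytest.fixture()
def icosphere() -> TriangleMesh:
    return to_mesh(_trimesh.creation.icosphere(subdivisions=3, radius=1.0))


@pytest.fixture(scope="session")
def case_noisefree():
    """Noise-free 1 mm symmetric incisor case (retainer applied)."""
    return build_case(
        "nf1", tooth_type="incisor", loss=1.0, pattern="symmetric",
        seed=42, resolution=1500, noise=None,
    )


@pytest.fixture(scope="session")
def case_noisy():
    """Default-noise 1 mm asymmetric canine case."""
    return build_case(
        "ny1", tooth_type="canine", loss=1.0, pattern="asymmetric",
        seed=43, resolution=1500,
    )


@pytest.fixture(scope="session")
def unchanged_pair():
    """A case with zero wear and no retainer: T1 is a re-posed copy of T0."""
    return build_case(
        "uc1", tooth_type="incisor", loss=0.0, pattern="symmetric",
        seed=44, resolution=1200, noise=None, retainer=None,
    )
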