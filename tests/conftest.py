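import numpy as np
import pytest

import craniofea as cf


@pytest.fixture
def unit_tet() -> cf.TetMesh:
    """Single positively oriented unit reference tet (volume 1/6)."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    mesh = cf.TetMesh(nodes, [[0, 1, 2, 3]], ["bone"])
    mesh.normalize_orientation()
    return mesh


@pytest.fixture
def unit_cube() -> cf.TetMesh:
    """Unit cube split into 6 tets (volume 1, surface area 6)."""
    return cf.make_beam(1.0, 1.0, 1.0, 1, 1, 1)


@pytest.fixture(scope="session")
def toy_skull() -> cf.TetMesh:
    return cf.make_toy_skull()


@pytest.fixture(scope="session")
def materials() -> dict[str, cf.Material]:
    return {"bone": cf.BONE, "teeth": cf.TEETH}


@pytest.fixture(scope="session")
def toy_muscles() -> list[cf.MuscleLoad]:
    """Symmetric two-muscle-per-side table aimed at a ventral jaw insertion."""
    muscles = []
    for side, sx in (("L", -1.0), ("R", 1.0)):
        muscles.append(
            cf.MuscleLoad("mAME", side, f"m_AME_origin_{side}", (sx * 8.0, 12.0, -8.0), 120.0)
        )
        muscles.append(
            cf.MuscleLoad("mAMP", side, f"m_AMP_origin_{side}", (sx * 8.0, 10.0, -6.0), 80.0)
        )
    return muscles


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
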