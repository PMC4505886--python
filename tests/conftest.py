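import numpy as np
import pytest

from vdomgeom.cuboid_geometry import EulerTriple
from vdomgeom.pipeline import build_templates, extract_geometries
from vdomgeom.synthetic_fixtures import (
    SyntheticSpec,
    planted_ensemble,
    synth_complex,
    toy_domain,
)


@pytest.fixture(scope="session")
def toy_alpha():
    return toy_domain(0, "alpha", "A")


@pytest.fixture(scope="session")
def toy_beta():
    return toy_domain(1, "beta", "B")


@pytest.fixture(scope="session")
def reference_complex(toy_alpha, toy_beta):
    return synth_complex(toy_alpha, toy_beta, EulerTriple(0, 0, 0), pdb_id="ref0")


@pytest.fixture(scope="session")
def small_pipeline(toy_alpha, toy_beta, reference_complex):
    """Reference + two rotated complexes with templates and extracted records."""
    cx1 = synth_complex(toy_alpha, toy_beta, EulerTriple(10, -20, 30), pdb_id="syn1")
    cx2 = synth_complex(toy_alpha, toy_beta, EulerTriple(-5, 15, 40), pdb_id="syn2")
    complexes = [reference_complex, cx1, cx2]
    templates = build_templates(complexes, reference_pdb_id="ref0")
    records, poses = extract_geometries(complexes, templates)
    return complexes, templates, records, poses


@pytest.fixture(scope="session")
def planted_three_clusters():
    spec = SyntheticSpec(
        n_structures=18,
        n_clusters=3,
        cluster_center_angles=((0, 0, 0), (30, 0, 0), (0, 30, 0)),
        intra_cluster_spread=0.5,
        coordinate_noise=0.0,
        seed=7,
    )
    complexes, labels = planted_ensemble(spec)
    return spec, complexes, labels


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.RandomState(rng.integers(2**31))).as_matrix()
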