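import numpy as np
import pytest

from lesionsf.asymmetry import asymmetry_curves, build_feature_vector
from lesionsf.config import PipelineConfig
from lesionsf.imaging import segment_lesion
from lesionsf.sfcore import SFDiagram, SizeGraph
from lesionsf.synthlesion import LesionSpec, generate_lesion


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def disk_image():
    img, mask = generate_lesion(LesionSpec())
    return img, mask


@pytest.fixture(scope="session")
def disk_seg(disk_image):
    return segment_lesion(disk_image[0])


@pytest.fixture(scope="session")
def disk_curves(disk_image, disk_seg, config):
    return asymmetry_curves(disk_image[0], disk_seg, config)


@pytest.fixture(scope="session")
def asym_lesion(config):
    spec = LesionSpec(
        boundary_harmonics=[(3, 0.15, 0.3), (2, 0.05, 1.0)],
        boundary_asym=0.8,
        color_asym=0.7,
        mass_asym=0.6,
        noise_sd=2.0,
        seed=7,
    )
    img, mask = generate_lesion(spec)
    vec, details = build_feature_vector(img, config, return_details=True)
    return {"spec": spec, "image": img, "mask": mask, "vector": vec, **details}


def random_graph(rng, max_vertices=30, phi_digits=2):
    n = int(rng.integers(1, max_vertices + 1))
    verts = list(range(n))
    edges = set()
    for _ in range(int(rng.integers(0, 2 * n + 1))):
        a, b = rng.integers(0, n, 2)
        if a != b:
            edges.add((int(a), int(b)))
    phi = {v: float(np.round(rng.normal(), phi_digits)) for v in verts}
    return SizeGraph(vertices=verts, edges=edges, phi=phi)


def random_diagram(rng, max_proper=4, max_lines=3):
    proper = []
    for _ in range(int(rng.integers(0, max_proper + 1))):
        x = float(rng.normal())
        proper.append((x, x + float(rng.uniform(0.05, 2.0))))
    lines = [float(rng.normal()) for _ in range(int(rng.integers(1, max_lines + 1)))]
    return SFDiagram(proper=proper, cornerlines=lines)
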