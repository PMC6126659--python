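import numpy as np
import pytest

from phytogeom.structure_io import AtomRecord, Residue, StructureModel
from phytogeom.synthetic import DimerSpec, make_synthetic_dimer


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from a random axis and angle."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0, np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def poly_ala_model(n: int = 10, chain: str = "A", identifier: str = "polyala") -> StructureModel:
    """Synthetic poly-ALA chain with one CA per residue along x."""
    residues = []
    for i in range(1, n + 1):
        atom = AtomRecord(chain, i, "", "ALA", "CA", np.array([3.8 * i, 0.0, 0.0]), 20.0, 1.0, False, "C")
        residues.append(Residue(i, "", "ALA", [atom], False))
    return StructureModel(identifier, {chain: residues})


@pytest.fixture(scope="session")
def reference_dimer():
    """Full-size noise-free synthetic dimer at the wild-type PCM geometry."""
    spec = DimerSpec(phi=46.0, d_centroids=30.0, omega=54.0, seed=11)
    model, truth = make_synthetic_dimer(spec)
    return spec, model, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
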