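import numpy as np
import pytest

from rinmut.structure_io import Atom, Residue, StructureModel
from rinmut.synthetic import FixtureSpec, make_benchmark


def chain_of_points(positions, coords, names=None):
    """Minimal structure: one CA atom per residue at the given coordinates."""
    residues = []
    for i, (pos, xyz) in enumerate(zip(positions, coords)):
        name = (names or ["ALA"] * len(positions))[i]
        residues.append(
            Residue(
                legacy_position=pos,
                name=name,
                atoms=[Atom("CA", "C", tuple(float(c) for c in xyz))],
            )
        )
    return StructureModel(chain_id="A", residues=residues)


def nerf_place(a, b, c, bond, angle_deg, torsion_deg):
    """Place a fourth atom from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_extended_peptide(names):
    """Ideal fully-extended backbone (phi=psi=omega=180) with CB side chains."""
    residues = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = nerf_place(np.array([-1.0, 1.0, 0.0]), N, CA, 1.525, 111.2, 180.0)
    for i, name in enumerate(names):
        atoms = [
            Atom("N", "N", tuple(N)),
            Atom("CA", "C", tuple(CA)),
            Atom("C", "C", tuple(C)),
        ]
        if name != "GLY":
            atoms.append(
                Atom("CB", "C", tuple(nerf_place(C, N, CA, 1.521, 110.4, -122.0)))
            )
        N2 = nerf_place(N, CA, C, 1.329, 116.2, 180.0)
        CA2 = nerf_place(CA, C, N2, 1.458, 121.7, 180.0)
        C2 = nerf_place(C, N2, CA2, 1.525, 111.2, 180.0)
        atoms.append(Atom("O", "O", tuple(nerf_place(N2, CA, C, 1.231, 120.5, 180.0))))
        residues.append(Residue(legacy_position=i + 1, name=name, atoms=atoms))
        N, CA, C = N2, CA2, C2
    return StructureModel(chain_id="A", residues=residues)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small end-to-end bundle shared by unit tests (fast to build)."""
    spec = FixtureSpec(n_residues=70, n_instances=56, label_noise=0.1, seed=11)
    return make_benchmark(spec)


@pytest.fixture(scope="session")
def clean_benchmark():
    """Noise-free planted bundle: labels follow the burial/conservation rule."""
    spec = FixtureSpec(n_residues=90, n_instances=70, label_noise=0.0, seed=5)
    return make_benchmark(spec)
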