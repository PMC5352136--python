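import numpy as np
import pytest

from mgfold import EnergyParams, SystemState
from mgfold.structure import NativeTopology
from mgfold.synthetic import make_hairpin


@pytest.fixture(scope="session")
def hairpin10():
    """Coarse 10-residue hairpin fixture: model, topology, truth table."""
    return make_hairpin(10, seed=0)


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


def point_topology(coords, phosphate_idx=(), res_per_atom=True):
    """Topology of free point particles (no local terms, no contacts):
    handy for isolating single energy terms."""
    coords = np.asarray(coords, float)
    n = len(coords)
    empty = lambda *s: np.empty(s, dtype=int)
    ridx = np.arange(n) if res_per_atom else np.zeros(n, int)
    return NativeTopology(
        n_atoms=n, bonds=empty(0, 2), bond_r0=np.empty(0),
        angles=empty(0, 3), angle_t0=np.empty(0),
        dihedrals=empty(0, 4), dihedral_p0=np.empty(0),
        impropers=empty(0, 4), improper_p0=np.empty(0),
        contacts=empty(0, 2), contact_r0=np.empty(0), contact_labels=[],
        phosphate_idx=np.asarray(phosphate_idx, dtype=int),
        is_ligand=np.zeros(n, bool), residue_index=ridx,
        res_ids=ridx + 1, native_coords=coords.copy())


def place_ions(rng, coords, n, d_min=5.0, d_max=18.0):
    """Uniform ion positions in a shell around the molecule, rejected until
    every ion clears the hard cores (keeps energies moderate)."""
    out = []
    center = coords.mean(axis=0)
    while len(out) < n:
        cand = center + rng.uniform(-d_max, d_max, 3)
        if np.linalg.norm(coords - cand, axis=1).min() >= d_min:
            out.append(cand)
    return np.asarray(out)


@pytest.fixture()
def perturbed_state(hairpin10, params):
    """Hairpin state with jittered coordinates, a few Mg ions and
    interior theta values — a generic configuration for force checks."""
    _, topo, _ = hairpin10
    rng = np.random.default_rng(1)
    return SystemState(
        coords=topo.native_coords + 0.05 * rng.standard_normal(
            (topo.n_atoms, 3)),
        mg=place_ions(rng, topo.native_coords, 4),
        theta=rng.uniform(0.2, 0.8, len(topo.phosphate_idx)),
        box=100.0)
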