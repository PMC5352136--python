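"""Small topology helpers shared by the acceptance script."""

import numpy as np

from mgfold.structure import NativeTopology


def point_topology(coords, phosphate_idx=()):
    """Free point particles: no local terms, no contacts."""
    coords = np.asarray(coords, float)
    n = len(coords)
    empty = lambda *s: np.empty(s, dtype=int)
    ridx = np.arange(n)
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
    """Uniform ion positions around the molecule, clearing hard cores."""
    out = []
    center = coords.mean(axis=0)
    while len(out) < n:
        cand = center + rng.uniform(-d_max, d_max, 3)
        if np.linalg.norm(coords - cand, axis=1).min() >= d_min:
            out.append(cand)
    return np.asarray(out)


def bond_topology(r0=5.0):
    """Two atoms joined by one harmonic bond at rest length r0."""
    topo = point_topology(np.array([[0.0, 0, 0], [r0, 0, 0]]))
    topo.bonds = np.array([[0, 1]])
    topo.bond_r0 = np.array([float(r0)])
    return topo
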