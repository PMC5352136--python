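"""Native-structure parsing and structure-based topology construction.

An all-atom structure-based ("Go-type") model takes a single experimentally
determined conformation as the global minimum of the energy function.  This
module turns a PDB file into that reference: an :class:`AtomModel` of heavy
atoms, a native contact map, and a :class:`NativeTopology` holding every local
geometry term (bonds, angles, dihedrals, impropers) with its native value, the
native contact set with per-contact secondary-structure labels, and the
phosphate atoms that carry the RNA's negative charge.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

__all__ = [
    "AtomModel",
    "SegmentMap",
    "NativeTopology",
    "load_structure",
    "build_contact_map",
    "build_topology",
    "classify_contacts",
    "covalent_bonds",
]

#: heavy-atom covalent templates for the standard ribonucleotides; the sugar
#: and phosphate backbone is shared, base rings differ.
_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"),
    ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "O4'"), ("C4'", "C3'"),
    ("C3'", "O3'"), ("C3'", "C2'"), ("C2'", "O2'"), ("C2'", "C1'"),
    ("C1'", "O4'"),
]
_BASE_BONDS = {
    "A": [("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "N6"), ("C6", "N1"), ("N1", "C2"),
          ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C4", "N9")],
    "G": [("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "O6"), ("C6", "N1"), ("N1", "C2"),
          ("C2", "N2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C4", "N9")],
    "C": [("C1'", "N1"), ("N1", "C2"), ("C2", "O2"), ("C2", "N3"),
          ("N3", "C4"), ("C4", "N4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1")],
    "U": [("C1'", "N1"), ("N1", "C2"), ("C2", "O2"), ("C2", "N3"),
          ("N3", "C4"), ("C4", "O4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1")],
}
_RNA_RESNAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC", "SYN"}
_COVALENT_CUTOFF = 1.8  # Angstrom, distance fallback for unknown residues


@dataclass
class AtomModel:
    """Heavy-atom model of one RNA chain plus optional ligand heteroatoms.

    Residue numbers are kept exactly as in the source PDB (1-based,
    possibly with gaps); array indices are 0-based.
    """

    names: list[str]
    elements: list[str]
    res_names: list[str]
    res_ids: np.ndarray          # author residue numbers, per atom
    chain_ids: list[str]
    coords: np.ndarray           # (N, 3) Angstrom
    is_ligand: np.ndarray        # bool per atom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_index(self) -> np.ndarray:
        """Ordinal residue index (0-based, dense) per atom, ligand last."""
        keys = list(zip(self.chain_ids, self.res_ids.tolist()))
        order: dict[tuple, int] = {}
        for k in keys:
            if k not in order:
                order[k] = len(order)
        return np.array([order[k] for k in keys], dtype=int)

    def atom_index(self, res_id: int, name: str) -> int:
        """Index of atom `name` in author residue `res_id` (RNA chain)."""
        hits = np.nonzero((self.res_ids == res_id)
                          & ~self.is_ligand
                          & np.array([n == name for n in self.names]))[0]
        if len(hits) == 0:
            raise KeyError(f"atom {name} of residue {res_id} not found")
        return int(hits[0])

    def phosphate_indices(self) -> np.ndarray:
        """Indices of backbone P atoms (one per nucleotide, 5'-P optional)."""
        return np.nonzero(np.array([n == "P" for n in self.names])
                          & ~self.is_ligand)[0]

    def to_pdb(self) -> str:
        lines = []
        for i in range(self.n_atoms):
            record = "HETATM" if self.is_ligand[i] else "ATOM  "
            name = self.names[i]
            pad = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = self.coords[i]
            lines.append(
                f"{record}{i + 1:5d} {pad} {self.res_names[i]:>3s} "
                f"{self.chain_ids[i]:1s}{self.res_ids[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {self.elements[i]:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def _is_nucleotide(residue) -> bool:
    name = residue.get_resname().strip()
    if name in _RNA_RESNAMES:
        return True
    # fall back on composition: a ribose C4' marks a nucleotide
    return any(a.get_name() == "C4'" for a in residue)


def load_structure(pdb_text: str, include_ligand: bool = True) -> AtomModel:
    """Parse PDB text into a heavy-atom :class:`AtomModel`.

    Model 1 only; hydrogens are dropped; alternate locations are resolved to
    the highest-occupancy conformer (Biopython's default selection).  Ligand
    heteroatoms (e.g. SAM) are kept with ``is_ligand=True`` when
    ``include_ligand``; waters are always discarded.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration as exc:
        raise ValueError("no model in PDB input") from exc

    names, elements, res_names, res_ids, chain_ids, coords, lig = \
        [], [], [], [], [], [], []
    n_rna_res = 0
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in ("HOH", "WAT"):
                continue
            is_nt = _is_nucleotide(residue)
            if not is_nt and not include_ligand:
                continue
            if is_nt:
                n_rna_res += 1
            atoms = [a for a in residue
                     if a.element not in ("H", "D") and
                     not a.get_name().startswith("H")]
            if not atoms:
                continue
            first = len(names)
            for atom in atoms:
                names.append(atom.get_name())
                elements.append(atom.element if atom.element
                                else atom.get_name()[0])
                res_names.append(resname)
                res_ids.append(residue.get_id()[1])
                chain_ids.append(chain.get_id() if chain.get_id().strip()
                                 else "A")
                coords.append(atom.get_coord())
                lig.append(not is_nt)
            if is_nt:
                present = {names[k] for k in range(first, len(names))}
                if resname in _BASE_BONDS and "C1'" not in present:
                    raise ValueError(
                        f"residue {resname}{residue.get_id()[1]} misses "
                        "ribose atom C1'")
    if n_rna_res == 0:
        raise ValueError("no nucleic acid chain in input")

    out = AtomModel(names, elements, res_names, np.array(res_ids),
                    chain_ids, np.array(coords), np.array(lig))
    _check_phosphates(out)
    return out


def _check_phosphates(model: AtomModel) -> None:
    """Every nucleotide carries one P except a 5'-terminal residue."""
    ridx = model.residue_index()
    rna = ~model.is_ligand
    for chain in sorted(set(model.chain_ids)):
        in_chain = np.array([c == chain for c in model.chain_ids]) & rna
        if not in_chain.any():
            continue
        res_in_chain = np.unique(ridx[in_chain])
        for pos, r in enumerate(res_in_chain):
            sel = ridx == r
            n_p = sum(1 for k in np.nonzero(sel)[0] if model.names[k] == "P")
            if n_p == 0 and pos > 0:
                rid = int(model.res_ids[sel][0])
                raise ValueError(
                    f"residue {rid} in chain {chain} lacks a backbone P "
                    "but is not 5'-terminal")
            if n_p > 1:
                rid = int(model.res_ids[sel][0])
                raise ValueError(f"residue {rid} has {n_p} P atoms")


def covalent_bonds(model: AtomModel) -> np.ndarray:
    """Covalent bond list (pairs of atom indices, i<j) of the RNA chain.

    Standard ribonucleotides use the chemical template; unknown residues fall
    back on a 1.8-Angstrom distance rule within the residue.  Consecutive
    residues of a chain are linked O3'(i)->P(i+1) (C4' fallback for
    coarse residues lacking O3').  Ligand-internal bonds are NOT generated
    here — the ligand is handled as a rigid block by the topology builder.
    """
    ridx = model.residue_index()
    bonds: set[tuple[int, int]] = set()
    by_res: dict[int, dict[str, int]] = {}
    for i in range(model.n_atoms):
        if model.is_ligand[i]:
            continue
        by_res.setdefault(int(ridx[i]), {})[model.names[i]] = i

    for r, atoms in by_res.items():
        resname = model.res_names[atoms[next(iter(atoms))]].strip()
        base = _BASE_BONDS.get(resname[-1] if resname in _RNA_RESNAMES
                               else resname)
        if resname in _BASE_BONDS or (len(resname) == 2 and base):
            template = _BACKBONE_BONDS + base
            for a, b in template:
                if a in atoms and b in atoms:
                    i, j = atoms[a], atoms[b]
                    bonds.add((min(i, j), max(i, j)))
        else:
            idx = sorted(atoms.values())
            xyz = model.coords[idx]
            if len(idx) > 1:
                d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        if d[a, b] < _COVALENT_CUTOFF:
                            bonds.add((idx[a], idx[b]))
    # inter-residue backbone link
    res_sorted = sorted(by_res)
    for r0, r1 in zip(res_sorted[:-1], res_sorted[1:]):
        a0, a1 = by_res[r0], by_res[r1]
        chain0 = model.chain_ids[next(iter(a0.values()))]
        chain1 = model.chain_ids[next(iter(a1.values()))]
        if chain0 != chain1 or "P" not in a1:
            continue
        donor = a0.get("O3'", a0.get("C4'"))
        if donor is not None:
            i, j = donor, a1["P"]
            bonds.add((min(i, j), max(i, j)))
    return np.array(sorted(bonds), dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# segment map

@dataclass
class SegmentMap:
    """Residue ranges of the secondary-structure elements.

    ``ranges`` maps element name (P1, P2a, P2b, L1, L3) to a list of
    inclusive 1-based ``[start, end]`` author-residue ranges.  The five
    primary elements must not overlap; derived interaction classes
    (L3-P1 pseudoknot, L1-P2b triplex) are inferred, not stored.
    """

    ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    PRIMARY = ("P1", "P2a", "P2b", "L1", "L3")

    def __post_init__(self) -> None:
        self.ranges = {k: [tuple(r) for r in v] for k, v in self.ranges.items()}
        seen: set[int] = set()
        for name in self.PRIMARY:
            for a, b in self.ranges.get(name, []):
                if b < a:
                    raise ValueError(f"range {a}-{b} of {name} inverted")
                block = set(range(a, b + 1))
                if block & seen:
                    raise ValueError(f"segment {name} overlaps another")
                seen |= block

    def segment_of(self, res_id: int) -> str | None:
        for name, rr in self.ranges.items():
            for a, b in rr:
                if a <= res_id <= b:
                    return name
        return None

    def covers(self, res_ids) -> bool:
        return all(self.segment_of(int(r)) is not None for r in res_ids)

    @classmethod
    def from_yaml(cls, text: str) -> "SegmentMap":
        return cls(ranges=yaml.safe_load(text)["segments"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"segments": {k: [list(r) for r in v]
                          for k, v in self.ranges.items()}},
            sort_keys=True)

    @classmethod
    def default_sam2(cls) -> "SegmentMap":
        """Editable default layout for the 52-nt SAM-II pseudoknot,
        shipped as package data (``data/segments_sam2.yaml``).

        An H-type pseudoknot: hairpin P1 whose loop L1 docks into the major
        groove of P2b (triplex), P2a/P2b formed with the 3' tail, L3
        pseudoknotted back onto P1 and carrying the Shine-Dalgarno stretch
        at the 3' end.
        """
        from importlib.resources import files
        text = files("mgfold").joinpath(
            "data/segments_sam2.yaml").read_text()
        return cls.from_yaml(text)


# ---------------------------------------------------------------------------
# contact map

def build_contact_map(model: AtomModel, method: str = "cutoff",
                      cutoff: float = 4.0, min_seq_sep: int = 3,
                      shadow_radius: float = 1.0,
                      include_ligand: bool = True) -> np.ndarray:
    """Native contact pairs (i<j) between heavy atoms.

    Pairs must join residues at least ``min_seq_sep`` apart in sequence
    (author residue numbering), or an RNA atom with a ligand atom.
    ``method='shadow'`` additionally drops pairs whose connecting segment
    passes within ``shadow_radius`` of a third atom (a light-shadowing
    occlusion criterion).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ridx = model.res_ids
    tree = cKDTree(model.coords)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    keep = []
    for i, j in raw:
        li, lj = model.is_ligand[i], model.is_ligand[j]
        if li and lj:
            continue
        if li or lj:
            if include_ligand:
                keep.append((min(i, j), max(i, j)))
            continue
        if abs(int(ridx[i]) - int(ridx[j])) >= min_seq_sep:
            keep.append((min(i, j), max(i, j)))
    pairs = np.array(sorted(keep), dtype=int).reshape(-1, 2)
    if method == "cutoff":
        return pairs
    if method != "shadow":
        raise ValueError(f"unknown contact method {method!r}")

    xyz = model.coords
    out = []
    for i, j in pairs:
        a, b = xyz[i], xyz[j]
        ab = b - a
        L2 = float(ab @ ab)
        occluded = False
        for k in range(model.n_atoms):
            if k == i or k == j:
                continue
            t = float((xyz[k] - a) @ ab) / L2
            if 0.05 < t < 0.95:
                perp = xyz[k] - (a + t * ab)
                if perp @ perp < shadow_radius ** 2:
                    occluded = True
                    break
        if not occluded:
            out.append((i, j))
    return np.array(out, dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# topology

_CONTACT_CLASSES = ("P1", "P2a", "P2b", "L1", "L3",
                    "L3-P1 pseudoknot", "L1-P2b triplex", "RNA-ligand",
                    "other")


@dataclass
class NativeTopology:
    """All terms of the structure-based energy function with native values."""

    n_atoms: int
    bonds: np.ndarray            # (nb, 2)
    bond_r0: np.ndarray
    angles: np.ndarray           # (na, 3)
    angle_t0: np.ndarray
    dihedrals: np.ndarray        # (nd, 4)
    dihedral_p0: np.ndarray
    impropers: np.ndarray        # (ni, 4)
    improper_p0: np.ndarray
    contacts: np.ndarray         # (nc, 2), i<j
    contact_r0: np.ndarray
    contact_labels: list[str]
    phosphate_idx: np.ndarray
    is_ligand: np.ndarray
    residue_index: np.ndarray
    res_ids: np.ndarray
    native_coords: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))
    ligand_bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int))
    ligand_bond_r0: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def excluded_pairs(self) -> set[int]:
        """Flattened i*n+j keys excluded from non-native repulsion:
        bonded 1-2/1-3/1-4 neighbours, same-residue pairs, native contacts."""
        n = self.n_atoms
        excl: set[int] = set()

        def add(i, j):
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            excl.add(i * n + j)

        for i, j in self.bonds:
            add(i, j)
        for i, _, k in self.angles:
            add(i, k)
        for i, _, _, l in self.dihedrals:
            add(i, l)
        for i, j in self.contacts:
            add(i, j)
        for i, j in self.ligand_bonds:
            add(i, j)
        ridx = self.residue_index
        for r in np.unique(ridx):
            members = np.nonzero(ridx == r)[0]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    add(members[a], members[b])
        return excl

    def to_json(self) -> str:
        payload = {
            "n_atoms": self.n_atoms,
            "bonds": self.bonds.tolist(), "bond_r0": self.bond_r0.tolist(),
            "angles": self.angles.tolist(),
            "angle_t0": self.angle_t0.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "dihedral_p0": self.dihedral_p0.tolist(),
            "impropers": self.impropers.tolist(),
            "improper_p0": self.improper_p0.tolist(),
            "contacts": self.contacts.tolist(),
            "contact_r0": self.contact_r0.tolist(),
            "contact_labels": self.contact_labels,
            "phosphate_idx": self.phosphate_idx.tolist(),
            "is_ligand": self.is_ligand.astype(int).tolist(),
            "residue_index": self.residue_index.tolist(),
            "res_ids": self.res_ids.tolist(),
            "ligand_bonds": self.ligand_bonds.tolist(),
            "ligand_bond_r0": self.ligand_bond_r0.tolist(),
            "native_coords": self.native_coords.tolist(),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NativeTopology":
        d = json.loads(text)
        arr = lambda k, dt=float: np.asarray(d[k], dtype=dt)
        return cls(
            n_atoms=d["n_atoms"],
            bonds=arr("bonds", int).reshape(-1, 2), bond_r0=arr("bond_r0"),
            angles=arr("angles", int).reshape(-1, 3),
            angle_t0=arr("angle_t0"),
            dihedrals=arr("dihedrals", int).reshape(-1, 4),
            dihedral_p0=arr("dihedral_p0"),
            impropers=arr("impropers", int).reshape(-1, 4),
            improper_p0=arr("improper_p0"),
            contacts=arr("contacts", int).reshape(-1, 2),
            contact_r0=arr("contact_r0"),
            contact_labels=list(d["contact_labels"]),
            phosphate_idx=arr("phosphate_idx", int),
            is_ligand=arr("is_ligand", int).astype(bool),
            residue_index=arr("residue_index", int),
            res_ids=arr("res_ids", int),
            ligand_bonds=arr("ligand_bonds", int).reshape(-1, 2),
            ligand_bond_r0=arr("ligand_bond_r0"),
            native_coords=arr("native_coords").reshape(-1, 3),
        )


def _dihedral_angle(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.arctan2(y, x)


def _angle(p0, p1, p2):
    a, b = p0 - p1, p2 - p1
    cos = np.einsum("...i,...i->...", a, b) / (
        np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1))
    return np.arccos(np.clip(cos, -1.0, 1.0))


def label_contact(ri: int, rj: int, lig_i: bool, lig_j: bool,
                  segments: SegmentMap) -> str:
    if lig_i or lig_j:
        return "RNA-ligand"
    si, sj = segments.segment_of(ri), segments.segment_of(rj)
    if si is None or sj is None:
        return "other"
    if si == sj:
        return si
    pair = {si, sj}
    if pair == {"L1", "P2b"}:
        return "L1-P2b triplex"
    if pair == {"L3", "P1"}:
        return "L3-P1 pseudoknot"
    return "other"


def build_topology(model: AtomModel, contacts: np.ndarray,
                   segments: SegmentMap,
                   include_ligand: bool = False) -> NativeTopology:
    """Measure native values of every term and assemble the topology.

    In apo mode (``include_ligand=False``) ligand atoms and RNA-ligand
    contacts are removed.  In holo mode the ligand enters as a rigid block of
    heavy atoms: stiff all-pair internal restraints (no angle/dihedral terms)
    plus its native contacts to the RNA — its modelling role is to bridge
    the L1-P2b gap, not to flex internally.
    """
    ridx_full = model.residue_index()
    lig = model.is_ligand
    if not include_ligand and lig.any():
        keep = np.nonzero(~lig)[0]
        remap = -np.ones(model.n_atoms, dtype=int)
        remap[keep] = np.arange(len(keep))
        model = AtomModel(
            [model.names[i] for i in keep],
            [model.elements[i] for i in keep],
            [model.res_names[i] for i in keep],
            model.res_ids[keep], [model.chain_ids[i] for i in keep],
            model.coords[keep], model.is_ligand[keep])
        mapped = []
        for i, j in contacts:
            if remap[i] >= 0 and remap[j] >= 0:
                mapped.append((remap[i], remap[j]))
        contacts = np.array(mapped, dtype=int).reshape(-1, 2)
        ridx_full = model.residue_index()
        lig = model.is_ligand

    xyz = model.coords
    bonds = covalent_bonds(model)

    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(int(i), []).append(int(j))
        adj.setdefault(int(j), []).append(int(i))
    for v in adj.values():
        v.sort()

    angles = []
    for j, nbrs in sorted(adj.items()):
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    angles = np.array(sorted(angles), dtype=int).reshape(-1, 3)
    if len(angles):
        # a harmonic angle about an exactly straight native geometry is
        # ill-conditioned (arccos loses smoothness at pi); drop those terms
        t0 = _angle(xyz[angles[:, 0]], xyz[angles[:, 1]], xyz[angles[:, 2]])
        angles = angles[(t0 > 0.05) & (t0 < np.pi - 0.05)]

    def well_defined(quads: np.ndarray) -> np.ndarray:
        """Drop torsions whose native geometry is (near-)collinear."""
        if len(quads) == 0:
            return quads
        p = [xyz[quads[:, k]] for k in range(4)]
        n1 = np.cross(p[1] - p[0], p[2] - p[1])
        n2 = np.cross(p[2] - p[1], p[3] - p[2])
        ok = (np.linalg.norm(n1, axis=1) > 1e-2) \
            & (np.linalg.norm(n2, axis=1) > 1e-2)
        return quads[ok]

    dihedrals = set()
    for j, k in bonds:
        for i in adj.get(int(j), []):
            if i == k:
                continue
            for l in adj.get(int(k), []):
                if l == j or l == i:
                    continue
                quad = (i, int(j), int(k), l)
                dihedrals.add(min(quad, quad[::-1]))
    dihedrals = well_defined(
        np.array(sorted(dihedrals), dtype=int).reshape(-1, 4))

    impropers = []
    for j, nbrs in sorted(adj.items()):
        if len(nbrs) >= 3:
            a, b, c = nbrs[:3]
            impropers.append((j, a, b, c))
    impropers = well_defined(
        np.array(sorted(impropers), dtype=int).reshape(-1, 4))

    # warn-and-other for contacts outside the segment map, never fail
    labels = []
    warned = False
    for i, j in contacts:
        lab = label_contact(int(model.res_ids[i]), int(model.res_ids[j]),
                            bool(lig[i]), bool(lig[j]), segments)
        if lab == "other" and not warned and not (lig[i] or lig[j]):
            si = segments.segment_of(int(model.res_ids[i]))
            sj = segments.segment_of(int(model.res_ids[j]))
            if si is None or sj is None:
                warnings.warn("segment map does not cover all contact "
                              "residues; labelling as 'other'")
                warned = True
        labels.append(lab)

    lig_bonds, lig_r0 = [], []
    lig_idx = np.nonzero(lig)[0]
    for a in range(len(lig_idx)):
        for b in range(a + 1, len(lig_idx)):
            i, j = int(lig_idx[a]), int(lig_idx[b])
            lig_bonds.append((i, j))
            lig_r0.append(float(np.linalg.norm(xyz[i] - xyz[j])))

    d = lambda p: np.linalg.norm(xyz[p[:, 0]] - xyz[p[:, 1]], axis=1) \
        if len(p) else np.empty(0)
    return NativeTopology(
        n_atoms=model.n_atoms,
        bonds=bonds, bond_r0=d(bonds),
        angles=angles,
        angle_t0=_angle(xyz[angles[:, 0]], xyz[angles[:, 1]],
                        xyz[angles[:, 2]]) if len(angles) else np.empty(0),
        dihedrals=dihedrals,
        dihedral_p0=_dihedral_angle(
            xyz[dihedrals[:, 0]], xyz[dihedrals[:, 1]],
            xyz[dihedrals[:, 2]], xyz[dihedrals[:, 3]])
        if len(dihedrals) else np.empty(0),
        impropers=impropers,
        improper_p0=_dihedral_angle(
            xyz[impropers[:, 0]], xyz[impropers[:, 1]],
            xyz[impropers[:, 2]], xyz[impropers[:, 3]])
        if len(impropers) else np.empty(0),
        contacts=contacts, contact_r0=d(contacts),
        contact_labels=labels,
        phosphate_idx=model.phosphate_indices(),
        is_ligand=lig.copy(),
        residue_index=ridx_full,
        res_ids=model.res_ids.copy(),
        ligand_bonds=np.array(lig_bonds, dtype=int).reshape(-1, 2),
        ligand_bond_r0=np.array(lig_r0),
        native_coords=xyz.copy(),
    )


def classify_contacts(topo: NativeTopology) -> dict[str, np.ndarray]:
    """Disjoint contact-index lists per structural class."""
    out: dict[str, list[int]] = {c: [] for c in _CONTACT_CLASSES}
    for k, lab in enumerate(topo.contact_labels):
        out[lab].append(k)
    return {c: np.array(v, dtype=int) for c, v in out.items()}
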