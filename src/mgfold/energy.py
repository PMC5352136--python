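"""Potential energy and analytic gradients of the hybrid structure-based model.

The total potential is

    Phi = Phi_SBM + Phi_MgSize + Phi_ion

* ``Phi_SBM`` — the structure-based part: harmonic bonds/angles/impropers and
  periodic dihedrals restraining local geometry and chirality to their native
  values (``Phi_local``), plus a 12-6 well per native contact and an r^-12
  excluded volume between all other atom pairs (``Phi_nonlocal``).
* ``Phi_MgSize`` — r^-12 excluded volume of the explicit, hydrated Mg2+ ions
  against RNA atoms and each other.
* ``Phi_ion`` — the electrostatics.  Explicit Mg2+ (+2e) and phosphates (-1e)
  interact through a Debye-Hueckel potential screened by the implicit
  monovalent salt.  Each phosphate i additionally carries a Manning
  condensation variable theta_i in [0,1]: the fraction of its charge
  neutralised by locally condensed monovalent counterions, modelled as a
  two-width Gaussian cloud centred on the P atom.  theta rescales the
  phosphate's effective charge to -(1-theta_i)e, gains the cloud-phosphate
  attraction, and pays an ideal-mixing entropy relative to the bulk salt.
  theta_i is a dynamical degree of freedom with its own generalised force.

Energies are in reduced units (the native-contact well depth eps_contact is
the unit); lengths in Angstrom; charges in elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure import NativeTopology

__all__ = ["EnergyParams", "ManningState", "SystemState", "Forces",
           "energy_local", "energy_contacts", "energy_mg_size",
           "energy_ion_effect", "condensed_density", "total_energy",
           "total_forces", "energy_and_forces", "debye_kappa"]

#: ions per cubic Angstrom for a 1 mM solution
_MM_TO_DENSITY = 6.02214076e-7 * 1e-3 * 1e3  # = 6.022e-7

_THETA_EPS = 1e-8


@dataclass
class EnergyParams:
    """Parameters of the hybrid model, in reduced units and Angstrom."""

    eps_contact: float = 1.0       # native-contact well depth (energy unit)
    k_bond: float = 100.0          # eps / A^2
    k_angle: float = 20.0          # eps / rad^2
    k_dihedral: float = 1.0        # eps
    k_improper: float = 10.0       # eps / rad^2
    eps_rep: float = 1.0           # excluded-volume strength
    sigma_rep: float = 2.5         # atom-atom hard-core diameter, A
    eps_mg: float = 1.0
    r_mg: float = 3.5              # hydrated Mg2+ radius, A
    q_phos: float = 1.0            # phosphate charge magnitude, e
    z_mg: float = 2.0
    bjerrum: float = 7.1           # A (water, 298 K)
    c_mono_mm: float = 100.0       # monovalent salt, mM
    sigma_cond: tuple[float, float] = (3.0, 6.0)   # condensed-cloud widths, A
    entropy_scale: float = 1.0
    theta_ref_half_mm: float = 100.0
    rep_cutoff_factor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("eps_contact", "k_bond", "k_angle", "k_dihedral",
                     "k_improper", "eps_rep", "sigma_rep", "eps_mg", "r_mg",
                     "q_phos", "z_mg", "bjerrum", "entropy_scale",
                     "theta_ref_half_mm", "rep_cutoff_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c_mono_mm < 0:
            raise ValueError("c_mono_mm must be non-negative")
        if any(s <= 0 for s in self.sigma_cond):
            raise ValueError("condensed-cloud widths must be positive")

    @property
    def theta_ref(self) -> float:
        """Baseline condensation fraction set by the bulk salt: high salt
        already screens well, so less condensation is favoured.  Clamped
        away from the degenerate endpoints of the mixing entropy."""
        raw = 1.0 / (1.0 + self.c_mono_mm / self.theta_ref_half_mm)
        return float(np.clip(raw, 0.01, 0.99))

    def replace(self, **kw) -> "EnergyParams":
        return replace(self, **kw)


def debye_kappa(params: EnergyParams, box: float | None = None,
                n_rna_atoms: int = 0) -> float:
    """Inverse Debye length (1/A) of the free monovalent salt.

    When a box is given, the continuum screening ions are removed from the
    volume the RNA occupies: the free-ion concentration is rescaled by
    (V_box - V_RNA)/V_box, with V_RNA the summed hard-core volume.
    """
    c = params.c_mono_mm
    if box is not None and n_rna_atoms > 0:
        v_box = float(box) ** 3
        v_rna = n_rna_atoms * (4.0 / 3.0) * np.pi * (params.sigma_rep / 2) ** 3
        c = c * max(v_box - v_rna, 0.0) / v_box
    n = c * _MM_TO_DENSITY  # per-species number density, A^-3
    return float(np.sqrt(8.0 * np.pi * params.bjerrum * n))


@dataclass
class ManningState:
    """Per-phosphate condensation fractions and their auxiliary velocities."""

    theta: np.ndarray
    v_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < -1e-12) or np.any(self.theta > 1 + 1e-12):
            raise ValueError("theta outside [0, 1]")
        self.theta = np.clip(self.theta, 0.0, 1.0)
        if self.v_theta is None:
            self.v_theta = np.zeros_like(self.theta)


@dataclass
class SystemState:
    """RNA coordinates, explicit Mg2+ ions, condensation variables."""

    coords: np.ndarray                       # (N, 3) A
    mg: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    v_coords: np.ndarray | None = None
    v_mg: np.ndarray | None = None
    v_theta: np.ndarray | None = None
    box: float | None = None                 # cubic box side, A
    temperature: float = 1.0                 # reduced

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.mg = np.asarray(self.mg, dtype=float).reshape(-1, 3)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.v_coords is None:
            self.v_coords = np.zeros_like(self.coords)
        if self.v_mg is None:
            self.v_mg = np.zeros_like(self.mg)
        if self.v_theta is None:
            self.v_theta = np.zeros_like(self.theta)

    @property
    def n_mg(self) -> int:
        return len(self.mg)

    def copy(self) -> "SystemState":
        return SystemState(self.coords.copy(), self.mg.copy(),
                           self.theta.copy(), self.v_coords.copy(),
                           self.v_mg.copy(), self.v_theta.copy(),
                           self.box, self.temperature)


@dataclass
class Forces:
    """Negative gradients: Cartesian on atoms and ions, generalised on theta."""

    atoms: np.ndarray
    mg: np.ndarray
    theta: np.ndarray

    def __iadd__(self, other: "Forces") -> "Forces":
        self.atoms += other.atoms
        self.mg += other.mg
        self.theta += other.theta
        return self


def _zero_forces(state: SystemState) -> Forces:
    return Forces(np.zeros_like(state.coords), np.zeros_like(state.mg),
                  np.zeros_like(state.theta))


def _check_coords(state: SystemState) -> None:
    if not (np.all(np.isfinite(state.coords)) and np.all(np.isfinite(state.mg))
            and np.all(np.isfinite(state.theta))):
        raise ValueError("non-finite coordinates in state")


# ---------------------------------------------------------------------------
# Phi_local

def _bond_energy(x, pairs, r0, k, grad):
    if len(pairs) == 0:
        return 0.0
    rij = x[pairs[:, 1]] - x[pairs[:, 0]]
    r = np.linalg.norm(rij, axis=1)
    dr = r - r0
    if grad is not None:
        g = (k * dr / r)[:, None] * rij        # dE/dx_j
        np.add.at(grad, pairs[:, 1], g)
        np.add.at(grad, pairs[:, 0], -g)
    return float(0.5 * k * np.sum(dr * dr))


def _angle_energy(x, triples, t0, k, grad):
    if len(triples) == 0:
        return 0.0
    i, j, l = triples[:, 0], triples[:, 1], triples[:, 2]
    u = x[i] - x[j]
    v = x[l] - x[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0 + 1e-12, 1.0 - 1e-12)
    theta = np.arccos(cos)
    dt = theta - t0
    if grad is not None:
        sin = np.sqrt(1.0 - cos * cos)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        dti = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dtl = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        coef = (k * dt)[:, None]
        np.add.at(grad, i, coef * dti)
        np.add.at(grad, l, coef * dtl)
        np.add.at(grad, j, -coef * (dti + dtl))
    return float(0.5 * k * np.sum(dt * dt))


def _dihedral_geometry(x, quads):
    p0, p1, p2, p3 = (x[quads[:, k]] for k in range(4))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                     np.einsum("ij,ij->i", n1, n2))
    return phi, b1, b2, b3, n1, n2, nb2


def _dihedral_grad_accumulate(grad, quads, dEdphi, b1, b2, b3, n1, n2, nb2):
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # signs match the atan2(m1.n2, n1.n2) angle convention used above
    dphi_d0 = (nb2 / n1sq)[:, None] * n1
    dphi_d3 = -(nb2 / n2sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    dphi_d1 = -(1.0 + c12) * dphi_d0 + c32 * dphi_d3
    dphi_d2 = -(1.0 + c32) * dphi_d3 + c12 * dphi_d0
    coef = dEdphi[:, None]
    np.add.at(grad, quads[:, 0], coef * dphi_d0)
    np.add.at(grad, quads[:, 1], coef * dphi_d1)
    np.add.at(grad, quads[:, 2], coef * dphi_d2)
    np.add.at(grad, quads[:, 3], coef * dphi_d3)


def _dihedral_energy(x, quads, p0, k, grad):
    """Periodic SBM dihedral K[1-cos(dphi)] + K/2 [1-cos(3 dphi)]."""
    if len(quads) == 0:
        return 0.0
    phi, b1, b2, b3, n1, n2, nb2 = _dihedral_geometry(x, quads)
    d = phi - p0
    energy = float(np.sum(k * (1 - np.cos(d)) + 0.5 * k * (1 - np.cos(3 * d))))
    if grad is not None:
        dEdphi = k * np.sin(d) + 1.5 * k * np.sin(3 * d)
        _dihedral_grad_accumulate(grad, quads, dEdphi, b1, b2, b3, n1, n2, nb2)
    return energy


def _improper_energy(x, quads, p0, k, grad):
    if len(quads) == 0:
        return 0.0
    phi, b1, b2, b3, n1, n2, nb2 = _dihedral_geometry(x, quads)
    d = np.mod(phi - p0 + np.pi, 2 * np.pi) - np.pi
    energy = float(0.5 * k * np.sum(d * d))
    if grad is not None:
        _dihedral_grad_accumulate(grad, quads, k * d, b1, b2, b3, n1, n2, nb2)
    return energy


def energy_local(state: SystemState, topo: NativeTopology,
                 params: EnergyParams, _forces: Forces | None = None) -> float:
    """Phi_local: bonds, angles, dihedrals, impropers; zero at the native
    configuration.  Stiff ligand-internal restraints (rigid SAM) included."""
    _check_coords(state)
    grad = None
    if _forces is not None:
        grad = np.zeros_like(state.coords)
    x = state.coords
    e = _bond_energy(x, topo.bonds, topo.bond_r0, params.k_bond, grad)
    e += _bond_energy(x, topo.ligand_bonds, topo.ligand_bond_r0,
                      params.k_bond, grad)
    e += _angle_energy(x, topo.angles, topo.angle_t0, params.k_angle, grad)
    e += _dihedral_energy(x, topo.dihedrals, topo.dihedral_p0,
                          params.k_dihedral, grad)
    e += _improper_energy(x, topo.impropers, topo.improper_p0,
                          params.k_improper, grad)
    if _forces is not None:
        _forces.atoms -= grad
    return e


# ---------------------------------------------------------------------------
# Phi_nonlocal

def _get_exclusions(topo: NativeTopology) -> np.ndarray:
    cached = getattr(topo, "_excl_cache", None)
    if cached is None:
        cached = np.fromiter(topo.excluded_pairs(), dtype=np.int64)
        cached.sort()
        topo._excl_cache = cached
    return cached


def energy_contacts(state: SystemState, topo: NativeTopology,
                    params: EnergyParams,
                    _forces: Forces | None = None) -> float:
    """Phi_nonlocal: 12-6 wells on native pairs (depth eps_contact at r0)
    plus truncated-shifted r^-12 repulsion on all other non-bonded pairs."""
    _check_coords(state)
    x = state.coords
    e = 0.0
    grad = np.zeros_like(x) if _forces is not None else None

    pairs = topo.contacts
    if len(pairs):
        rij = x[pairs[:, 1]] - x[pairs[:, 0]]
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("hard-core violation: coincident contact atoms")
        s6 = (topo.contact_r0 / r) ** 6
        e += params.eps_contact * float(np.sum(s6 * s6 - 2.0 * s6))
        if grad is not None:
            dudr = -12.0 * params.eps_contact * (s6 * s6 - s6) / r
            g = (dudr / r)[:, None] * rij
            np.add.at(grad, pairs[:, 1], g)
            np.add.at(grad, pairs[:, 0], -g)

    # non-native excluded volume
    rc = params.rep_cutoff_factor * params.sigma_rep
    tree = cKDTree(x)
    cand = tree.query_pairs(rc, output_type="ndarray")
    if len(cand):
        keys = cand[:, 0].astype(np.int64) * topo.n_atoms + cand[:, 1]
        excl = _get_exclusions(topo)
        mask = ~np.isin(keys, excl, assume_unique=False)
        cand = cand[mask]
    if len(cand):
        rij = x[cand[:, 1]] - x[cand[:, 0]]
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("hard-core violation: coincident atoms")
        s12 = (params.sigma_rep / r) ** 12
        shift = (params.sigma_rep / rc) ** 12
        e += params.eps_rep * float(np.sum(s12 - shift))
        if grad is not None:
            dudr = -12.0 * params.eps_rep * s12 / r
            g = (dudr / r)[:, None] * rij
            np.add.at(grad, cand[:, 1], g)
            np.add.at(grad, cand[:, 0], -g)

    if _forces is not None:
        _forces.atoms -= grad
    return e


def energy_mg_size(state: SystemState, params: EnergyParams,
                   _forces: Forces | None = None) -> float:
    """Phi_MgSize: hydrated-Mg excluded volume against RNA atoms and Mg."""
    _check_coords(state)
    if state.n_mg == 0:
        return 0.0
    e = 0.0
    gx = np.zeros_like(state.coords) if _forces is not None else None
    gm = np.zeros_like(state.mg) if _forces is not None else None

    def rep(rij, sigma, eps):
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("hard-core violation involving Mg2+")
        rc = params.rep_cutoff_factor * sigma
        inside = r < rc
        s12 = np.where(inside, (sigma / np.maximum(r, 1e-12)) ** 12
                       - (sigma / rc) ** 12, 0.0)
        dudr = np.where(inside,
                        -12.0 * eps * (sigma / np.maximum(r, 1e-12)) ** 12 / r,
                        0.0)
        return eps * float(np.sum(s12)), (dudr / np.maximum(r, 1e-12))[:, None] * rij

    # Mg - RNA
    sigma_ma = params.r_mg + 0.5 * params.sigma_rep
    tree = cKDTree(state.coords)
    lists = tree.query_ball_point(state.mg,
                                  params.rep_cutoff_factor * sigma_ma)
    pairs = [(m, a) for m, lst in enumerate(lists) for a in lst]
    if pairs:
        pairs = np.array(pairs, dtype=int)
        rij = state.coords[pairs[:, 1]] - state.mg[pairs[:, 0]]
        de, g = rep(rij, sigma_ma, params.eps_mg)
        e += de
        if _forces is not None:
            np.add.at(gx, pairs[:, 1], g)
            np.add.at(gm, pairs[:, 0], -g)

    # Mg - Mg
    if state.n_mg > 1:
        iu, ju = np.triu_indices(state.n_mg, k=1)
        rij = state.mg[ju] - state.mg[iu]
        de, g = rep(rij, 2.0 * params.r_mg, params.eps_mg)
        e += de
        if _forces is not None:
            np.add.at(gm, ju, g)
            np.add.at(gm, iu, -g)

    if _forces is not None:
        _forces.atoms -= gx
        _forces.mg -= gm
    return e


# ---------------------------------------------------------------------------
# Phi_ion

def condensed_density(theta: np.ndarray, phosphate_xyz: np.ndarray,
                      points: np.ndarray,
                      sigma: tuple[float, float] = (3.0, 6.0)) -> np.ndarray:
    """Number density of condensed counterions at ``points``.

    Each phosphate carries an equal-weight mixture of two normalised
    isotropic Gaussians (widths ``sigma``) centred on its P atom, integrating
    to theta_i over all space.
    """
    if any(s <= 0 for s in sigma):
        raise ValueError("sigma must be positive")
    points = np.atleast_2d(points)
    d2 = np.sum((points[:, None, :] - phosphate_xyz[None, :, :]) ** 2, axis=2)
    rho = np.zeros(len(points))
    for s in sigma:
        norm = (2.0 * np.pi * s * s) ** -1.5
        rho += 0.5 * norm * np.sum(theta[None, :] * np.exp(-d2 / (2 * s * s)),
                                   axis=1)
    return rho


def _cloud_inv_r(params: EnergyParams) -> float:
    """<1/r> of a unit two-Gaussian cloud about its centre."""
    return 0.5 * float(np.sqrt(2.0 / np.pi)
                       * (1.0 / params.sigma_cond[0]
                          + 1.0 / params.sigma_cond[1]))


def _screened_pairs(xi, xj, qi, qj, kappa, lb, grad_i, grad_j,
                    dq_i=None, dtheta_i=None, dq_j=None, dtheta_j=None):
    """Sum of lb qi qj exp(-kappa r)/r over the cross product of two charge
    sets, with position gradients and optional dE/dtheta accumulation."""
    rij = xj[None, :, :] - xi[:, None, :]
    r = np.linalg.norm(rij, axis=2)
    if np.any(r < 1e-9):
        raise ValueError("overlapping point charges")
    scr = np.exp(-kappa * r) / r
    qq = qi[:, None] * qj[None, :]
    e = lb * float(np.sum(qq * scr))
    # dU/dr = lb qq (-kappa r - 1) exp(-kappa r)/r^2
    dudr = lb * qq * (-(kappa * r + 1.0)) * scr / r
    gvec = (dudr / r)[:, :, None] * rij          # gradient wrt xj
    if grad_j is not None:
        grad_j += np.sum(gvec, axis=0)
    if grad_i is not None:
        grad_i += -np.sum(gvec, axis=1)
    if dtheta_i is not None:
        dtheta_i += lb * dq_i * np.sum(qj[None, :] * scr, axis=1)
    if dtheta_j is not None:
        dtheta_j += lb * dq_j * np.sum(qi[:, None] * scr, axis=0)
    return e


def energy_ion_effect(state: SystemState, topo: NativeTopology,
                      params: EnergyParams,
                      _forces: Forces | None = None) -> float:
    """Phi_ion: screened electrostatics plus the Manning free energy.

    Pair terms over phosphate-phosphate, phosphate-Mg and Mg-Mg with the
    phosphate charge renormalised by its condensation fraction; per
    phosphate, the condensed-cloud self attraction and the ideal-mixing
    entropy of condensed counterions relative to the bulk reservoir.
    """
    _check_coords(state)
    pidx = topo.phosphate_idx
    n_p = len(pidx)
    if len(state.theta) != n_p:
        raise ValueError("theta length does not match phosphate count")
    theta = np.clip(state.theta, 0.0, 1.0)
    lb = params.bjerrum
    kappa = debye_kappa(params, state.box, topo.n_atoms)

    xp = state.coords[pidx]
    qp = -params.q_phos * (1.0 - theta)
    dq_dtheta = params.q_phos            # d(qp_i)/d(theta_i)

    gx = np.zeros_like(state.coords) if _forces is not None else None
    gm = np.zeros_like(state.mg) if _forces is not None else None
    gt = np.zeros(n_p) if _forces is not None else None
    gp = np.zeros_like(xp) if _forces is not None else None

    e = 0.0
    # phosphate-phosphate (each unordered pair once)
    if n_p > 1:
        iu, ju = np.triu_indices(n_p, k=1)
        rij = xp[ju] - xp[iu]
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("overlapping point charges")
        scr = np.exp(-kappa * r) / r
        qq = qp[iu] * qp[ju]
        e += lb * float(np.sum(qq * scr))
        if _forces is not None:
            dudr = lb * qq * (-(kappa * r + 1.0)) * scr / r
            g = (dudr / r)[:, None] * rij
            np.add.at(gp, ju, g)
            np.add.at(gp, iu, -g)
            np.add.at(gt, iu, lb * dq_dtheta * qp[ju] * scr)
            np.add.at(gt, ju, lb * dq_dtheta * qp[iu] * scr)

    if state.n_mg:
        qm = np.full(state.n_mg, params.z_mg)
        e += _screened_pairs(xp, state.mg, qp, qm, kappa, lb, gp, gm,
                             dq_i=dq_dtheta, dtheta_i=gt)
        if state.n_mg > 1:
            iu, ju = np.triu_indices(state.n_mg, k=1)
            rij = state.mg[ju] - state.mg[iu]
            r = np.linalg.norm(rij, axis=1)
            if np.any(r < 1e-9):
                raise ValueError("overlapping point charges")
            scr = np.exp(-kappa * r) / r
            e += lb * params.z_mg ** 2 * float(np.sum(scr))
            if _forces is not None:
                dudr = lb * params.z_mg ** 2 * (-(kappa * r + 1.0)) * scr / r
                g = (dudr / r)[:, None] * rij
                np.add.at(gm, ju, g)
                np.add.at(gm, iu, -g)

    # condensed-cloud self attraction: cloud (+q theta) with bare P (-q)
    inv_r = _cloud_inv_r(params)
    e += -lb * params.q_phos ** 2 * inv_r * float(np.sum(theta))
    if _forces is not None:
        gt += -lb * params.q_phos ** 2 * inv_r

    # ideal-mixing entropy of condensation vs the bulk reservoir
    tref = params.theta_ref
    th = np.clip(theta, _THETA_EPS, 1.0 - _THETA_EPS)
    s = th * np.log(th / tref) + (1 - th) * np.log((1 - th) / (1 - tref))
    e += params.entropy_scale * state.temperature * float(np.sum(s))
    if _forces is not None:
        gt += params.entropy_scale * state.temperature * (
            np.log(th / tref) - np.log((1 - th) / (1 - tref)))
        np.add.at(gx, pidx, gp)
        _forces.atoms -= gx
        _forces.mg -= gm
        _forces.theta -= gt
    return e


# ---------------------------------------------------------------------------
# totals

def total_energy(state: SystemState, topo: NativeTopology,
                 params: EnergyParams) -> float:
    return (energy_local(state, topo, params)
            + energy_contacts(state, topo, params)
            + energy_mg_size(state, params)
            + energy_ion_effect(state, topo, params))


def energy_and_forces(state: SystemState, topo: NativeTopology,
                      params: EnergyParams) -> tuple[float, Forces]:
    f = _zero_forces(state)
    e = energy_local(state, topo, params, f)
    e += energy_contacts(state, topo, params, f)
    e += energy_mg_size(state, params, f)
    e += energy_ion_effect(state, topo, params, f)
    return e, f


def total_forces(state: SystemState, topo: NativeTopology,
                 params: EnergyParams) -> Forces:
    return energy_and_forces(state, topo, params)[1]
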