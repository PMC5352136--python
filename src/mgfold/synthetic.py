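"""Seed-deterministic synthetic fixtures for every pipeline stage.

Miniature hairpin structures with known contact counts, two-state Q
trajectories with prescribed populations, dilute Debye-Hueckel ion gases,
noisy two-state CEST profiles and exact Boltzmann umbrella samples from an
analytic double well.  Every generator takes an explicit seed and returns
its ground-truth parameters next to the data, so recovery tests close the
loop without any external input.
"""

from __future__ import annotations

import numpy as np

from .cest import CESTExperiment, CESTModel, simulate_profile
from .energy import EnergyParams
from .structure import (AtomModel, NativeTopology, SegmentMap,
                        build_contact_map, build_topology)
from .wham import UmbrellaWindow

__all__ = ["make_hairpin", "make_two_state_q", "make_dh_gas", "make_cest",
           "make_double_well_samples", "double_well_potential",
           "pair_correlation"]

_RISE = 3.0        # A per residue along a strand
_BOND = 1.5        # backbone step P -> C4'
_BRANCH = 1.4      # C4' -> C1' -> N1 toward the partner strand
_STRAND_SEP = 9.1  # places paired N1-N1 at 3.5 A


def make_hairpin(n_residues: int, seed: int = 0
                 ) -> tuple[AtomModel, NativeTopology, dict]:
    """Idealised coarse hairpin: two straight strands of paired residues
    joined by a short loop, four heavy atoms per residue (P, C4', C1', N1)
    with the base nitrogen pointing into the duplex.

    Paired residues put their N1 atoms 3.5 A apart, giving one native
    contact per stem pair under the default 4 A cutoff.  Returns the model,
    the built topology, and a hand-checkable truth table (atom, bond and
    stem-contact counts).
    """
    if n_residues < 6:
        raise ValueError("hairpin needs at least 6 residues")
    n_stem = (n_residues - 2) // 2
    n_loop = n_residues - 2 * n_stem

    def residue(origin, branch, rise_sign):
        # slight pucker keeps all torsions away from collinearity
        px, py, pz = origin
        bx, by = branch
        cz = pz + rise_sign * _BOND   # C4' continues toward the next P
        return [("P", (px, py, pz)),
                ("C4'", (px, py, cz)),
                ("C1'", (px + bx * _BRANCH, py + by * _BRANCH,
                         cz + 0.3 * rise_sign)),
                ("N1", (px + 2 * bx * _BRANCH, py + 2 * by * _BRANCH, cz))]

    placements = []
    for i in range(n_stem):                       # 5' strand, ascending
        placements.append(residue((0.0, 0.0, _RISE * i), (+1, 0), +1))
    top = _RISE * n_stem + 5.0                    # loop kept clear of stem
    for m in range(n_loop):
        x = _STRAND_SEP * (m + 1) / (n_loop + 1)
        placements.append(residue((x, 2.0, top), (0, +1), +1))
    for m in range(n_stem):                       # 3' strand, descending
        z = _RISE * (n_stem - 1 - m) + _RISE      # C4' level matches partner
        placements.append(residue((_STRAND_SEP, 0.0, z), (-1, 0), -1))

    names, elements, res_names, res_ids, chains, coords = \
        [], [], [], [], [], []
    for r, atoms in enumerate(placements):
        for name, xyz in atoms:
            names.append(name)
            elements.append(name[0])
            res_names.append("SYN")
            res_ids.append(r + 1)
            chains.append("A")
            coords.append(xyz)
    model = AtomModel(names, elements, res_names, np.array(res_ids), chains,
                      np.array(coords, float),
                      np.zeros(len(names), dtype=bool))

    segments = SegmentMap(ranges={
        "P1": [(1, n_stem), (n_stem + n_loop + 1, n_residues)],
        "L1": [(n_stem + 1, n_stem + n_loop)],
    })
    contacts = build_contact_map(model, method="cutoff", cutoff=4.0)
    topo = build_topology(model, contacts, segments)
    truth = {
        "seed": seed, "n_residues": n_residues, "n_stem_pairs": n_stem,
        "n_atoms": 4 * n_residues,
        # 3 intra-residue bonds per residue + one backbone link per junction
        "n_bonds": 4 * n_residues - 1,
        "min_stem_contacts": n_stem,
    }
    return model, topo, truth


def make_two_state_q(p_high: float, q_lo: float = 0.7, q_hi: float = 0.9,
                     n: int = 10000, sigma: float = 0.02, seed: int = 0,
                     k_flip: float = 0.02) -> tuple[np.ndarray, dict]:
    """Markov two-state Q series with Gaussian jitter.

    Switching probabilities per step are k_flip*p_high (up) and
    k_flip*(1-p_high) (down), so the stationary occupancy of the high-Q
    (bound-like) state is exactly p_high.  Defaults place the modes at the
    open (Q~0.7) and bound-like (Q~0.9) states.
    """
    if not 0.0 < p_high < 1.0:
        raise ValueError("p_high must be in (0, 1)")
    rng = np.random.default_rng(seed)
    up = k_flip * p_high
    down = k_flip * (1.0 - p_high)
    state = np.empty(n, dtype=bool)
    state[0] = rng.random() < p_high
    u = rng.random(n)
    for t in range(1, n):
        if state[t - 1]:
            state[t] = u[t] >= down
        else:
            state[t] = u[t] < up
    q = np.where(state, q_hi, q_lo) + sigma * rng.standard_normal(n)
    truth = {"p_high": p_high, "q_lo": q_lo, "q_hi": q_hi, "sigma": sigma,
             "k_flip": k_flip, "seed": seed}
    return q, truth


def make_dh_gas(n_ions: int, box: float, kappa: float,
                n_samples: int = 200, n_sweeps_between: int = 5,
                step: float | None = None, seed: int = 0,
                charge: float = 1.0, bjerrum: float = 7.1,
                temperature: float = 1.0
                ) -> tuple[np.ndarray, dict]:
    """Metropolis samples of a gas of like point charges interacting through
    the screened Coulomb (Debye-Hueckel) pair potential in a cubic box.

    At low density the pair correlation approaches
    g(r) = exp(-u(r)/k_BT); in the strong-screening limit the gas is ideal.
    Returns an (n_samples, n_ions, 3) array of configurations.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, box, size=(n_ions, 3))
    step = step or box / 10.0
    pref = bjerrum * charge * charge

    def pair_energy(xi, others):
        if len(others) == 0:
            return 0.0
        r = np.linalg.norm(others - xi, axis=1)
        r = np.maximum(r, 1e-9)
        return float(pref * np.sum(np.exp(-kappa * r) / r))

    samples = np.empty((n_samples, n_ions, 3))
    accepted = tried = 0
    for s in range(n_samples):
        for _ in range(n_sweeps_between):
            for i in range(n_ions):
                old = x[i].copy()
                others = np.delete(x, i, axis=0)
                e_old = pair_energy(old, others)
                new = old + rng.uniform(-step, step, size=3)
                if np.any(new < 0) or np.any(new > box):
                    tried += 1
                    continue
                e_new = pair_energy(new, others)
                tried += 1
                if e_new <= e_old or \
                        rng.random() < np.exp(-(e_new - e_old) / temperature):
                    x[i] = new
                    accepted += 1
        samples[s] = x
    truth = {"n_ions": n_ions, "box": box, "kappa": kappa,
             "bjerrum": bjerrum, "charge": charge, "seed": seed,
             "acceptance": accepted / max(tried, 1)}
    return samples, truth


def pair_correlation(samples: np.ndarray, box: float,
                     r_max: float, n_bins: int = 30, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """g(r) of gas configurations in a closed (non-periodic) box.

    The ideal-gas denominator is estimated by Monte Carlo with uniform
    configurations of the same size, which accounts exactly for the
    boundary geometry.  Returns (r, g, sigma_g) with per-bin counting
    uncertainties.
    """
    edges = np.linspace(0.0, r_max, n_bins + 1)
    n_frames, n_ions, _ = samples.shape
    iu = np.triu_indices(n_ions, k=1)

    def histogram(frames):
        counts = np.zeros(n_bins)
        for f in range(len(frames)):
            d = np.linalg.norm(frames[f][:, None] - frames[f][None, :],
                               axis=2)
            h, _ = np.histogram(d[iu], bins=edges)
            counts += h
        return counts

    counts = histogram(samples)
    rng = np.random.default_rng(seed)
    n_ref = max(4 * n_frames, 400)
    ref = rng.uniform(0.0, box, size=(n_ref, n_ions, 3))
    ref_counts = histogram(ref) * (n_frames / n_ref)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = counts / np.maximum(ref_counts, 1e-300)
    sigma = g * np.sqrt(1.0 / np.maximum(counts, 1.0)
                        + 1.0 / np.maximum(ref_counts * n_ref / n_frames,
                                           1.0))
    return centers, g, sigma


def make_cest(truth: CESTModel, b1_fields=(17.5, 27.9, 37.8),
              t_sat: float = 0.3, offsets: np.ndarray | None = None,
              sigma: float = 0.01, seed: int = 0
              ) -> tuple[list[CESTExperiment], dict]:
    """Noisy two-state CEST profiles at several B1 fields.

    Profiles are simulated from ``truth``, normalised by the mean of three
    reference (no-saturation) points, and perturbed with Gaussian noise of
    width ``sigma``; the truth parameters ride along for recovery tests.
    """
    from .cest import default_offsets
    offsets = default_offsets() if offsets is None else np.asarray(offsets)
    rng = np.random.default_rng(seed)
    experiments = []
    for b1 in b1_fields:
        exp = CESTExperiment(b1_hz=float(b1), t_sat=t_sat,
                             offsets_hz=offsets, sigma=sigma)
        clean = simulate_profile(truth, exp)
        refs = 1.0 + sigma * rng.standard_normal(3)
        noisy = (clean + sigma * rng.standard_normal(len(clean))) \
            / float(np.mean(refs))
        exp.intensities = np.clip(noisy, -0.2, 1.2)
        experiments.append(exp)
    meta = {"p_minor": truth.p_minor, "k_ex": truth.k_ex,
            "dw_hz": truth.dw_hz, "r1": truth.r1, "r2": truth.r2,
            "sigma": sigma, "t_sat": t_sat,
            "b1_fields": list(b1_fields), "seed": seed}
    return experiments, meta


def double_well_potential(x, barrier: float = 3.0):
    """Quartic double well U(x) = barrier * (x^2 - 1)^2: minima at x = +-1,
    barrier height exactly ``barrier`` at x = 0."""
    x = np.asarray(x, float)
    return barrier * (x * x - 1.0) ** 2


def make_double_well_samples(barrier: float = 3.0,
                             centers: np.ndarray | None = None,
                             k_q: float = 20.0, n_per_window: int = 4000,
                             seed: int = 0, temperature: float = 1.0,
                             domain: tuple[float, float] = (-1.8, 1.8)
                             ) -> tuple[list[UmbrellaWindow], dict]:
    """Exact Boltzmann samples (rejection sampling) from the biased quartic
    double well, one umbrella window per centre — the independent oracle for
    the WHAM reconstruction."""
    if centers is None:
        centers = np.arange(-1.4, 1.401, 0.2)
    rng = np.random.default_rng(seed)
    lo, hi = domain
    grid = np.linspace(lo, hi, 2001)
    windows = []
    for c in centers:
        logp = -(double_well_potential(grid, barrier)
                 + 0.5 * k_q * (grid - c) ** 2) / temperature
        m = logp.max()
        samples = np.empty(n_per_window)
        filled = 0
        while filled < n_per_window:
            batch = max(4 * (n_per_window - filled), 1000)
            x = rng.uniform(lo, hi, size=batch)
            lp = -(double_well_potential(x, barrier)
                   + 0.5 * k_q * (x - c) ** 2) / temperature
            keep = x[rng.random(batch) < np.exp(lp - m)]
            take = min(len(keep), n_per_window - filled)
            samples[filled:filled + take] = keep[:take]
            filled += take
        windows.append(UmbrellaWindow(q0=float(c), k=k_q, q_samples=samples,
                                      temperature=temperature))
    truth = {"barrier": barrier, "k_q": k_q, "centers": list(map(float,
                                                                 centers)),
             "n_per_window": n_per_window, "seed": seed,
             "temperature": temperature}
    return windows, truth
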