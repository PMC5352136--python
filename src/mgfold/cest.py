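"""Two-state chemical exchange saturation transfer (CEST): simulation and
fitting with the 7x7 Bloch-McConnell formalism.

A sparsely populated minor state (population p_minor) exchanging with the
major state at total rate k_ex = k_AB + k_BA imprints a second dip on the
saturation profile at the minor-state resonance, offset by the chemical
shift difference Delta-omega.  The magnetisation vector
[1, MxA, MyA, MzA, MxB, MyB, MzB] evolves under a 7x7 generator combining
rotating-frame precession, RF nutation about x, relaxation (with the
constant first column returning Mz to its equilibrium p_A, p_B) and
two-site exchange; the profile is the major-state Mz after the spin-lock
period, normalised by the no-saturation reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = ["CESTModel", "CESTExperiment", "CESTFit", "bm_matrix",
           "simulate_profile", "fit_cest", "population_compare",
           "default_offsets"]

_TWO_PI = 2.0 * np.pi


@dataclass
class CESTModel:
    """Exchange parameter set; Delta-omega is stored in Hz (reported unit)."""

    p_minor: float = 0.05
    k_ex: float = 200.0            # 1/s, total exchange rate
    dw_hz: float = 300.0           # minor minus major resonance, Hz
    r1: float = 1.5                # 1/s, shared longitudinal rate
    r2: float = 20.0               # 1/s, shared transverse rate
    major_offset_hz: float = 0.0   # major-state resonance position
    r1_minor: float | None = None  # per-state values when not shared
    r2_minor: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_minor < 0.5):
            raise ValueError("p_minor must be in [0, 0.5)")
        if self.k_ex <= 0 or self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("rates must be positive")

    @property
    def rates(self) -> tuple[float, float, float, float]:
        r1b = self.r1 if self.r1_minor is None else self.r1_minor
        r2b = self.r2 if self.r2_minor is None else self.r2_minor
        return self.r1, self.r2, r1b, r2b


@dataclass
class CESTExperiment:
    """One saturation profile: B1 amplitude, spin-lock time and offsets."""

    b1_hz: float
    t_sat: float
    offsets_hz: np.ndarray
    intensities: np.ndarray | None = None
    sigma: float | np.ndarray = 0.01
    temperature_k: float = 298.0
    n_references: int = 3

    def __post_init__(self) -> None:
        self.offsets_hz = np.asarray(self.offsets_hz, float)
        if not np.all(np.isfinite(self.offsets_hz)):
            raise ValueError("offsets must be finite")
        if self.t_sat < 0:
            raise ValueError("saturation time must be non-negative")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, float)
            if np.any(self.intensities < -0.2) or \
                    np.any(self.intensities > 1.2):
                raise ValueError("intensities outside the physical band "
                                 "[-0.2, 1.2]")


def default_offsets(step_hz: float = 15.0) -> np.ndarray:
    """-600..600 Hz grid as acquired in the interleaved CEST scheme."""
    return np.arange(-600.0, 600.0 + step_hz / 2, step_hz)


def bm_matrix(model: CESTModel, offset_hz: float, b1_hz: float) -> np.ndarray:
    """7x7 two-state Bloch-McConnell generator at one spin-lock offset.

    Basis [1, MxA, MyA, MzA, MxB, MyB, MzB]; the first row is zero and the
    first column carries R1*p_eq so that Mz relaxes to its equilibrium.
    """
    p_b = model.p_minor
    p_a = 1.0 - p_b
    k_ab = p_b * model.k_ex
    k_ba = p_a * model.k_ex
    r1a, r2a, r1b, r2b = model.rates
    w1 = _TWO_PI * b1_hz
    oa = _TWO_PI * (model.major_offset_hz - offset_hz)
    ob = _TWO_PI * (model.major_offset_hz + model.dw_hz - offset_hz)

    k = np.zeros((7, 7))
    # state A block
    k[1, 1], k[1, 2] = -r2a - k_ab, -oa
    k[2, 1], k[2, 2], k[2, 3] = oa, -r2a - k_ab, -w1
    k[3, 2], k[3, 3] = w1, -r1a - k_ab
    k[3, 0] = r1a * p_a
    # state B block
    k[4, 4], k[4, 5] = -r2b - k_ba, -ob
    k[5, 4], k[5, 5], k[5, 6] = ob, -r2b - k_ba, -w1
    k[6, 5], k[6, 6] = w1, -r1b - k_ba
    k[6, 0] = r1b * p_b
    # exchange coupling
    for d in range(3):
        k[1 + d, 4 + d] += k_ba
        k[4 + d, 1 + d] += k_ab
    return k


def _batched_generators(model: CESTModel, offsets: np.ndarray,
                        b1_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """6x6 homogeneous blocks A and constant vectors b over all offsets."""
    n = len(offsets)
    a = np.zeros((n, 6, 6))
    b = np.zeros((n, 6))
    for m, off in enumerate(offsets):
        k = bm_matrix(model, float(off), b1_hz)
        a[m] = k[1:, 1:]
        b[m] = k[1:, 0]
    return a, b


def simulate_profile(model: CESTModel, experiment: CESTExperiment
                     ) -> np.ndarray:
    """I(t_sat)/I(0): start from thermal z-magnetisation, propagate through
    the spin-lock period, report major-state Mz over the reference."""
    offsets = experiment.offsets_hz
    t = experiment.t_sat
    p_a = 1.0 - model.p_minor
    if t == 0.0:
        return np.ones(len(offsets))
    a, b = _batched_generators(model, offsets, experiment.b1_hz)
    m0 = np.zeros(6)
    m0[2] = p_a
    m0[5] = model.p_minor
    # M(t) = Mss + exp(A t) (M0 - Mss) with Mss = -A^-1 b
    mss = np.linalg.solve(a, -b[..., None])[..., 0]
    lam, vec = np.linalg.eig(a)
    c = np.linalg.solve(vec, (m0[None, :] - mss).astype(complex)[..., None]
                        )[..., 0]
    mt = np.einsum("nij,nj->ni", vec, c * np.exp(lam * t))
    mz_a = np.real(mt[:, 2]) + mss[:, 2]
    return mz_a / p_a


def _simulate_all(model: CESTModel, experiments) -> np.ndarray:
    return np.concatenate([simulate_profile(model, e) for e in experiments])


@dataclass
class CESTFit:
    model: CESTModel
    covariance: np.ndarray           # over (p_minor, k_ex, dw_hz, r1, r2)
    residuals: np.ndarray
    chi2: float
    p_minor_se: float
    dw_se: float
    at_bound: bool = False
    param_names: tuple[str, ...] = ("p_minor", "k_ex", "dw_hz", "r1", "r2")


_BOUNDS = (np.array([1e-6, 1e-2, -3000.0, 1e-3, 1e-3]),
           np.array([0.499, 1e5, 3000.0, 1e3, 1e4]))


def fit_cest(experiments, init: CESTModel | None = None,
             extra_dw_starts=(150.0, 300.0, 500.0)) -> CESTFit:
    """Global nonlinear least squares of one two-state model across all B1
    fields simultaneously.

    Multi-starts over the sign and magnitude of Delta-omega avoid the mirror
    minimum at -Delta-omega.  Each experiment needs measured intensities;
    at least 10 offsets in total are required.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")
    if sum(len(e.offsets_hz) for e in experiments) < 10:
        raise ValueError("need at least 10 offsets for a stable fit")
    for e in experiments:
        if e.intensities is None:
            raise ValueError("experiments must carry measured intensities")
    init = init or CESTModel()
    y = np.concatenate([e.intensities for e in experiments])
    sig = np.concatenate([np.broadcast_to(np.asarray(e.sigma, float),
                                          e.offsets_hz.shape)
                          for e in experiments])
    sig = np.where(sig > 0, sig, 1.0)

    def residual(x):
        m = replace(init, p_minor=float(x[0]), k_ex=float(x[1]),
                    dw_hz=float(x[2]), r1=float(x[3]), r2=float(x[4]),
                    r1_minor=None, r2_minor=None)
        return (_simulate_all(m, experiments) - y) / sig

    starts = []
    base = [init.p_minor, init.k_ex, init.dw_hz, init.r1, init.r2]
    for dw in {init.dw_hz, -init.dw_hz,
               *(s for mag in extra_dw_starts for s in (mag, -mag))}:
        if abs(dw) < 1e-9:
            continue
        starts.append([base[0], base[1], dw, base[3], base[4]])

    best = None
    for x0 in starts:
        x0 = np.clip(x0, *_BOUNDS)
        try:
            sol = least_squares(residual, x0, bounds=_BOUNDS,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("CEST fit failed from every start")

    dof = max(len(y) - 5, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = np.full((5, 5), np.nan)
    x = best.x
    at_bound = bool(np.any(np.isclose(x, _BOUNDS[0]))
                    or np.any(np.isclose(x, _BOUNDS[1])))
    fitted = replace(init, p_minor=float(x[0]), k_ex=float(x[1]),
                     dw_hz=float(x[2]), r1=float(x[3]), r2=float(x[4]),
                     r1_minor=None, r2_minor=None)
    return CESTFit(model=fitted, covariance=cov,
                   residuals=best.fun * sig,
                   chi2=float(np.sum(best.fun ** 2)),
                   p_minor_se=float(np.sqrt(max(cov[0, 0], 0.0))),
                   dw_se=float(np.sqrt(max(cov[2, 2], 0.0))),
                   at_bound=at_bound)


def population_compare(fit_low: CESTFit, fit_high: CESTFit,
                       labels: tuple[str, str] = ("low Mg", "high Mg"),
                       alpha: float = 0.05) -> dict:
    """Tabulate minor-state populations of two fits and z-test their
    difference (does pre-organized population grow with Mg2+?)."""
    from scipy.stats import norm

    for f in (fit_low, fit_high):
        if not np.isfinite(f.p_minor_se) or f.p_minor_se == 0.0:
            raise ValueError("fit lacks a parameter uncertainty")
    d = fit_high.model.p_minor - fit_low.model.p_minor
    se = float(np.hypot(fit_low.p_minor_se, fit_high.p_minor_se))
    z = d / se if se > 0 else 0.0
    p_val = float(2.0 * (1.0 - norm.cdf(abs(z))))
    inconclusive = fit_low.at_bound or fit_high.at_bound
    return {
        labels[0]: {"p_minor": fit_low.model.p_minor,
                    "se": fit_low.p_minor_se},
        labels[1]: {"p_minor": fit_high.model.p_minor,
                    "se": fit_high.p_minor_se},
        "difference": d, "se": se, "z": z, "p_value": p_val,
        "significant": bool((p_val < alpha) and not inconclusive),
        "inconclusive": bool(inconclusive),
    }
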