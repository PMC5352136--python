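"""Umbrella sampling along the fraction of native contacts Q, WHAM
reconstruction of free-energy surfaces, basin free-energy differences and
ion-titration sigmoid fits.

Q is the canonical folding reaction coordinate for structure-based models:
the fraction of native contact pairs formed in a conformation.  The biased
coordinate is a smooth (differentiable) version of Q so that the umbrella
restraint exerts well-defined forces; analyses may use either the smooth or
the hard-count definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

from .energy import EnergyParams, Forces, SystemState
from .structure import NativeTopology

__all__ = ["UmbrellaWindow", "FreeEnergySurface", "BasinSet", "QBias",
           "q_smooth", "q_smooth_grad", "q_hard", "run_umbrella", "wham_1d",
           "wham_2d", "basin_delta_g", "fit_sigmoid", "estimate_tf",
           "SigmoidFit"]

#: switching steepness: the logistic turns over within ~0.4 A, narrow
#: against the 0.2*r0 margin separating native from cut distances, so the
#: smooth and hard contact counts track each other closely
_SWITCH_STEEPNESS = 10.0  # 1/A
_SWITCH_SCALE = 1.2       # switching midpoint at 1.2 * native distance


def q_smooth(coords: np.ndarray, topo: NativeTopology,
             steepness: float = _SWITCH_STEEPNESS) -> float:
    """Smooth fraction of native contacts, in [0, ~1.05].

    Each native pair contributes a logistic switching function centred at
    1.2 r0 so that formed contacts count ~1 and broken ones ~0, with a
    gradient defined everywhere.
    """
    if topo.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    i, j = topo.contacts[:, 0], topo.contacts[:, 1]
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    f = 1.0 / (1.0 + np.exp(steepness * (r - _SWITCH_SCALE * topo.contact_r0)))
    return float(np.mean(f))


def q_smooth_grad(coords: np.ndarray, topo: NativeTopology,
                  steepness: float = _SWITCH_STEEPNESS
                  ) -> tuple[float, np.ndarray]:
    i, j = topo.contacts[:, 0], topo.contacts[:, 1]
    rij = coords[j] - coords[i]
    r = np.linalg.norm(rij, axis=1)
    z = steepness * (r - _SWITCH_SCALE * topo.contact_r0)
    f = 1.0 / (1.0 + np.exp(z))
    dfdr = -steepness * f * (1.0 - f)
    grad = np.zeros_like(coords)
    g = (dfdr / (topo.n_contacts * r))[:, None] * rij
    np.add.at(grad, j, g)
    np.add.at(grad, i, -g)
    return float(np.mean(f)), grad


def q_hard(coords: np.ndarray, topo: NativeTopology,
           factor: float = 1.2) -> float:
    """Hard-count Q: a native pair is formed when r < factor * r0."""
    i, j = topo.contacts[:, 0], topo.contacts[:, 1]
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    return float(np.mean(r < factor * topo.contact_r0))


class QBias:
    """Harmonic umbrella restraint 0.5 k (Q_smooth - q0)^2."""

    def __init__(self, topo: NativeTopology, q0: float, k: float,
                 steepness: float = _SWITCH_STEEPNESS):
        if k <= 0:
            raise ValueError("umbrella force constant must be positive")
        self.topo = topo
        self.q0 = q0
        self.k = k
        self.steepness = steepness

    def __call__(self, state: SystemState, forces: Forces | None) -> float:
        q, grad = q_smooth_grad(state.coords, self.topo, self.steepness)
        if forces is not None:
            forces.atoms -= self.k * (q - self.q0) * grad
        return 0.5 * self.k * (q - self.q0) ** 2

    def bias_energy(self, q: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(q, float) - self.q0) ** 2


@dataclass
class UmbrellaWindow:
    """Samples of one biased window: bias centre/strength and Q series."""

    q0: float
    k: float
    q_samples: np.ndarray
    temperature: float = 1.0
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        self.q_samples = np.asarray(self.q_samples, dtype=float)
        if not np.all(np.isfinite(self.q_samples)):
            raise ValueError("non-finite umbrella samples")

    def bias_energy(self, q: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(q, float) - self.q0) ** 2


@dataclass
class FreeEnergySurface:
    """G on a grid over one or two coordinates, in k_BT, minimum at 0.

    Bins that received no samples are NaN and are never extrapolated.
    """

    centers: tuple[np.ndarray, ...]
    g: np.ndarray
    counts: np.ndarray
    error: np.ndarray
    names: tuple[str, ...] = ("Q",)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.g)
        if finite.any():
            self.g = self.g - np.nanmin(self.g)

    def to_dataframe(self):
        import pandas as pd
        if len(self.centers) == 1:
            return pd.DataFrame({self.names[0]: self.centers[0],
                                 "G_kT": self.g, "error_kT": self.error,
                                 "count": self.counts})
        xx, yy = np.meshgrid(self.centers[0], self.centers[1], indexing="ij")
        return pd.DataFrame({self.names[0]: xx.ravel(),
                             self.names[1]: yy.ravel(),
                             "G_kT": self.g.ravel(),
                             "error_kT": self.error.ravel(),
                             "count": self.counts.ravel()})


@dataclass
class BasinSet:
    """Ordered, non-overlapping Q intervals naming conformational basins."""

    intervals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a0, b0), (a1, b1) in zip(spans[:-1], spans[1:]):
            if b0 > a1:
                raise ValueError("basin intervals overlap")
            if b0 < a0 or b1 < a1:
                raise ValueError("inverted basin interval")

    @classmethod
    def default_sam2(cls) -> "BasinSet":
        """U unfolded, O open, PO partially open, PC partially closed
        (pre-organized, bound-like), C ligand-bound closed."""
        return cls({"U": (0.0, 0.35), "O": (0.35, 0.60),
                    "PO": (0.60, 0.80), "PC": (0.80, 0.95),
                    "C": (0.95, 1.05)})


# ---------------------------------------------------------------------------
# umbrella sampling driver

def default_windows(q_min: float = 0.1, q_max: float = 1.0,
                    spacing: float = 0.05) -> np.ndarray:
    return np.round(np.arange(q_min, q_max + spacing / 2, spacing), 10)


def check_overlap(windows: list[UmbrellaWindow], n_bins: int = 60,
                  min_overlap: float = 0.01) -> list[tuple[int, int, float]]:
    """Pairwise histogram overlap of adjacent windows (ordered by centre).
    Raises with the offending gaps when any overlap is below threshold."""
    order = np.argsort([w.q0 for w in windows])
    lo = min(w.q_samples.min() for w in windows)
    hi = max(w.q_samples.max() for w in windows)
    edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    hists = []
    for w in windows:
        h, _ = np.histogram(w.q_samples, bins=edges)
        hists.append(h / max(h.sum(), 1))
    report, gaps = [], []
    for a, b in zip(order[:-1], order[1:]):
        ov = float(np.minimum(hists[a], hists[b]).sum())
        report.append((int(a), int(b), ov))
        if ov < min_overlap:
            gaps.append((windows[a].q0, windows[b].q0, ov))
    if gaps:
        raise ValueError(
            "umbrella histograms do not overlap between centres: "
            + ", ".join(f"{a:.3f}-{b:.3f} ({ov:.4f})" for a, b, ov in gaps))
    return report


def run_umbrella(topo: NativeTopology, params: EnergyParams, config,
                 centers, k_q: float, n_equil: int | None = None,
                 aux_funcs=None, check: bool = True,
                 min_overlap: float = 0.01) -> list[UmbrellaWindow]:
    """One biased Langevin window per centre, started from the native state.

    ``aux_funcs`` maps observable names to callables ``f(coords, mg, theta)``
    evaluated on each saved frame.  Equilibration defaults to 20% of the
    production length and is discarded.
    """
    from .dynamics import SimulationConfig, run, setup_system

    n_equil = n_equil if n_equil is not None else config.n_steps // 5
    windows = []
    for w_idx, q0 in enumerate(centers):
        cfg = SimulationConfig(**{**asdict(config),
                                  "seed": config.seed + 1000 * w_idx})
        state = setup_system(topo, cfg, params)
        bias = QBias(topo, float(q0), k_q)
        total = SimulationConfig(**{**asdict(cfg),
                                    "n_steps": cfg.n_steps + n_equil})
        traj = run(state, topo, params, total, bias=bias)
        n_skip = int(np.searchsorted(traj.time,
                                     n_equil * cfg.timestep, side="right"))
        qs = np.array([q_smooth(traj.coords[f], topo)
                       for f in range(n_skip, traj.n_frames)])
        aux = {}
        for name, fn in (aux_funcs or {}).items():
            aux[name] = np.array([fn(*traj.frame(f))
                                  for f in range(n_skip, traj.n_frames)])
        windows.append(UmbrellaWindow(q0=float(q0), k=k_q, q_samples=qs,
                                      temperature=cfg.temperature, aux=aux))
    if check and len(windows) > 1:
        check_overlap(windows, min_overlap=min_overlap)
    return windows


# ---------------------------------------------------------------------------
# WHAM

def _wham_weights(windows: list[UmbrellaWindow], tol: float,
                  max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent window free energies; returns (f_k, per-sample
    unbiasing weights, normalised)."""
    T = windows[0].temperature
    q_all = np.concatenate([w.q_samples for w in windows])
    n_k = np.array([len(w.q_samples) for w in windows], dtype=float)
    # Boltzmann factor of every sample in every window's bias potential,
    # precomputed once: the iteration is then two mat-vec products
    boltz = np.exp(-np.stack([w.bias_energy(q_all) / T
                              for w in windows]))     # (K, S)
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        w_s = 1.0 / ((n_k * np.exp(f)) @ boltz)
        f_new = -np.log(boltz @ w_s)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations "
            f"(residual {delta:.2e})")
    w_s = 1.0 / ((n_k * np.exp(f)) @ boltz)
    return f, w_s / w_s.sum()


def _block_resample(rng: np.random.Generator, x: np.ndarray,
                    block: int) -> np.ndarray:
    n = len(x)
    if n == 0 or block >= n:
        return x[rng.integers(0, n, size=n)] if n else x
    starts = rng.integers(0, n - block + 1, size=int(np.ceil(n / block)))
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
    return x[idx]


def _autocorr_block(x: np.ndarray) -> int:
    """Block length from the integrated autocorrelation time of x."""
    n = len(x)
    if n < 8:
        return 1
    y = x - x.mean()
    var = float(y @ y) / n
    if var == 0:
        return 1
    tau = 1.0
    for lag in range(1, min(n // 4, 200)):
        c = float(y[:-lag] @ y[lag:]) / ((n - lag) * var)
        if c < 0.05:
            break
        tau += 2.0 * c
    return max(1, int(np.ceil(tau)))


def wham_1d(windows: list[UmbrellaWindow], n_bins: int = 50,
            q_range: tuple[float, float] | None = None, tol: float = 1e-7,
            max_iter: int = 100000, n_bootstrap: int = 20,
            seed: int = 0) -> FreeEnergySurface:
    """Unbiased G(Q) in k_BT from umbrella windows by binned WHAM, with
    moving-block bootstrap uncertainties (>= 20 resamples)."""
    if not windows:
        raise ValueError("no umbrella windows")
    q_all = np.concatenate([w.q_samples for w in windows])
    if q_range is None:
        q_range = (float(q_all.min()), float(q_all.max()) + 1e-9)
    edges = np.linspace(*q_range, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def surface(wins) -> tuple[np.ndarray, np.ndarray]:
        _, w_s = _wham_weights(wins, tol, max_iter)
        qs = np.concatenate([w.q_samples for w in wins])
        p, _ = np.histogram(qs, bins=edges, weights=w_s)
        cnt, _ = np.histogram(qs, bins=edges)
        with np.errstate(divide="ignore"):
            g = np.where(cnt > 0, -np.log(np.where(p > 0, p, np.nan)), np.nan)
        return g, cnt

    g, counts = surface(windows)
    rng = np.random.default_rng(seed)
    blocks = [_autocorr_block(w.q_samples) for w in windows]
    boots = []
    for _ in range(max(n_bootstrap, 20)):
        resampled = [UmbrellaWindow(w.q0, w.k,
                                    _block_resample(rng, w.q_samples, blk),
                                    w.temperature)
                     for w, blk in zip(windows, blocks)]
        gb, _ = surface(resampled)
        boots.append(gb - np.nanmin(gb))
    err = np.nanstd(np.stack(boots), axis=0)
    return FreeEnergySurface(centers=(centers,), g=g, counts=counts,
                             error=err, names=("Q",))


def wham_2d(windows: list[UmbrellaWindow], aux_pair: tuple[str, str],
            n_bins: tuple[int, int] = (40, 40), tol: float = 1e-7,
            max_iter: int = 100000, n_bootstrap: int = 20,
            seed: int = 0) -> FreeEnergySurface:
    """Reweight the Q-biased samples onto two auxiliary coordinates
    (e.g. total contacts vs Mg-bridged phosphate contacts, or Q vs a
    regional Q); the bias acts on Q only."""
    ax, ay = aux_pair
    for w in windows:
        if ax not in w.aux or ay not in w.aux:
            raise ValueError(f"windows lack auxiliary series {aux_pair}")
    _, w_s = _wham_weights(windows, tol, max_iter)
    x = np.concatenate([w.aux[ax] for w in windows]).astype(float)
    y = np.concatenate([w.aux[ay] for w in windows]).astype(float)
    ex = np.linspace(x.min(), x.max() + 1e-9, n_bins[0] + 1)
    ey = np.linspace(y.min(), y.max() + 1e-9, n_bins[1] + 1)
    p, _, _ = np.histogram2d(x, y, bins=(ex, ey), weights=w_s)
    cnt, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    with np.errstate(divide="ignore"):
        g = np.where(cnt > 0, -np.log(np.where(p > 0, p, np.nan)), np.nan)
    # bootstrap over joint (q, x, y) blocks per window
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(max(n_bootstrap, 20)):
        ws, xs, ys = [], [], []
        for w in windows:
            blk = _autocorr_block(w.q_samples)
            n = len(w.q_samples)
            idx = _block_resample(rng, np.arange(n), blk)
            ws.append(UmbrellaWindow(w.q0, w.k, w.q_samples[idx],
                                     w.temperature))
            xs.append(w.aux[ax][idx])
            ys.append(w.aux[ay][idx])
        _, w_sb = _wham_weights(ws, tol, max_iter)
        pb, _, _ = np.histogram2d(np.concatenate(xs).astype(float),
                                  np.concatenate(ys).astype(float),
                                  bins=(ex, ey), weights=w_sb)
        with np.errstate(divide="ignore"):
            gb = -np.log(np.where(pb > 0, pb, np.nan))
        boots.append(gb - np.nanmin(gb))
    err = np.nanstd(np.stack(boots), axis=0)
    return FreeEnergySurface(
        centers=(0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:])),
        g=g, counts=cnt, error=err, names=(ax, ay))


def basin_delta_g(surface: FreeEnergySurface, basins: BasinSet,
                  pair: tuple[str, str]) -> float:
    """G_A - G_B in k_BT from population-weighted basin free energies:
    Delta G = -ln sum_A e^-G + ln sum_B e^-G."""
    if len(surface.centers) != 1:
        raise ValueError("basin analysis requires a 1D surface")
    q = surface.centers[0]
    out = []
    for name in pair:
        lo, hi = basins.intervals[name]
        sel = (q >= lo) & (q < hi) & np.isfinite(surface.g)
        if not sel.any():
            raise ValueError(f"basin {name} contains no defined bins")
        out.append(-np.log(np.sum(np.exp(-surface.g[sel]))))
    return float(out[0] - out[1])


# ---------------------------------------------------------------------------
# titration sigmoid and folding temperature

@dataclass
class SigmoidFit:
    midpoint: float           # e.g. Mg_1/2 in mM
    steepness: float
    y_lo: float
    y_hi: float
    midpoint_ci: float        # 1.96 sigma from the covariance
    defined: bool
    residual: float


def _sigmoid(x, y_lo, y_hi, x_half, s):
    return y_lo + (y_hi - y_lo) / (1.0 + np.exp((x - x_half) / s))


def fit_sigmoid(x, y) -> SigmoidFit:
    """Least-squares sigmoid fit of a titration curve; the midpoint is the
    half-transition concentration (Mg_1/2, K_1/2, Ca_1/2...).

    Data that a constant model explains at least as well (by AIC) are
    flagged and the midpoint reported as undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 titration points")
    span = x.max() - x.min()
    p0 = [float(y[np.argmax(x)]), float(y[np.argmin(x)]),
          float(np.median(x)), max(span / 10, 1e-6)]
    try:
        popt, pcov = curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
        rss = float(np.sum((_sigmoid(x, *popt) - y) ** 2))
        ok = True
    except RuntimeError:
        popt, pcov = p0, np.full((4, 4), np.inf)
        rss, ok = float(np.sum((y - y.mean()) ** 2)), False
    n = len(x)
    rss_const = float(np.sum((y - y.mean()) ** 2))
    aic_sig = n * np.log(max(rss, 1e-300) / n) + 2 * 4
    aic_const = n * np.log(max(rss_const, 1e-300) / n) + 2 * 1
    defined = ok and aic_sig < aic_const and popt[3] > 0 \
        and x.min() <= popt[2] <= x.max()
    ci = 1.96 * float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) \
        else np.inf
    return SigmoidFit(
        midpoint=float(popt[2]) if defined else float("nan"),
        steepness=float(popt[3]), y_lo=float(popt[0]), y_hi=float(popt[1]),
        midpoint_ci=ci, defined=bool(defined), residual=rss)


def folded_fraction(surface: FreeEnergySurface, q_split: float = 0.5) -> float:
    q = surface.centers[0]
    ok = np.isfinite(surface.g)
    w = np.exp(-surface.g[ok])
    folded = float(np.sum(w[q[ok] >= q_split]))
    return folded / float(np.sum(w))


def estimate_tf(temperatures, surfaces, q_split: float = 0.5) -> float:
    """Folding temperature: where folded and unfolded basin weights cross.

    ``surfaces`` are G(Q) at each temperature (in that temperature's k_BT).
    Interpolates the zero of Delta G(T) = -ln(w_folded/w_unfolded);
    raises when the crossover is not bracketed.
    """
    temps = np.asarray(temperatures, float)
    order = np.argsort(temps)
    temps = temps[order]
    dg = []
    for k in order:
        frac = folded_fraction(surfaces[k], q_split)
        frac = min(max(frac, 1e-12), 1 - 1e-12)
        dg.append(-np.log(frac / (1.0 - frac)))
    dg = np.asarray(dg)
    sign = np.sign(dg)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        if np.any(dg == 0):
            return float(temps[np.argmin(np.abs(dg))])
        raise ValueError("temperatures do not bracket the folding crossover")
    a = crossings[0]
    t0, t1, g0, g1 = temps[a], temps[a + 1], dg[a], dg[a + 1]
    return float(t0 + (0.0 - g0) * (t1 - t0) / (g1 - g0))
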