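"""Polarity landscapes: occupancy quasipotentials and velocity fields.

The four-variable PAR model is projected onto the two concentration
differences (Aa-Pa, Ap-Pp).  A stochastic ensemble (Euler–Maruyama with
additive noise and reflection at zero) is binned on this plane; the
quasipotential is U = -ln(occupancy density), shifted so its minimum is
zero.  Wells mark attractors and barrier heights measure resistance to
state switching.  Deterministic quiver fields show how initial states
evolve; since the 2D projection of a 4D flow is degenerate, each bin is
lifted back to representative 4D states by an explicit lift rule.

For the one-species model the state space is already 2D, so the
stationary Fokker–Planck equation can be solved directly (finite-volume
Scharfetter–Gummel discretization, zero-flux boundaries) and cross-checked
against the sampled histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .ode import (
    CONSTANT_SCHEDULE,
    NO_CUE,
    Cue,
    FeedbackSchedule,
    OdeParams,
    _multipliers,
    _rhs_values,
    find_steady_states,
)
from .wavepin import WavePinParams, _rhs_raw as _wavepin_rhs_raw

__all__ = [
    "LandscapeConfig",
    "LandscapeGrid",
    "euler_maruyama_ensemble",
    "euler_maruyama_wavepin",
    "build_landscape",
    "velocity_field",
    "fokker_planck_stationary",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Sampling and binning configuration for occupancy landscapes.

    ``sigma`` is the additive noise amplitude (a.u. per sqrt(time)); the
    default is small enough that wells of the high-feedback regime are
    resolved rather than washed out, yet large enough that each attractor's
    neighbourhood is populated within ``t_sample``.
    """

    sigma: float = 0.05
    n_trajectories: int = 200
    t_burn: float = 20.0
    t_sample: float = 500.0
    dt_sde: float = 0.005
    seed: int = 0
    grid_bounds: tuple[tuple[float, float], tuple[float, float]] = ((-2.5, 2.5), (-2.5, 2.5))
    grid_bins: tuple[int, int] = (61, 61)
    sample_every: int = 20  # record every k-th step after burn-in

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dt_sde <= 0:
            raise ValueError("dt_sde must be > 0")
        if min(self.grid_bins) < 2:
            raise ValueError("need at least 2 bins per axis")


@dataclass
class LandscapeGrid:
    """Binned occupancy density, quasipotential and velocity on the
    difference-coordinate plane."""

    x_centers: np.ndarray  # Aa - Pa axis
    y_centers: np.ndarray  # Ap - Pp axis
    density: np.ndarray  # (ny, nx), sums to 1 over occupied bins
    quasipotential: np.ndarray  # -ln density, min-shifted; NaN where unoccupied
    velocity: np.ndarray | None = None  # (2, ny, nx) projected deterministic velocity

    def minima(self) -> list[tuple[float, float]]:
        """Bin centers of local quasipotential minima (4-neighbourhood)."""
        U = self.quasipotential
        ny, nx = U.shape
        out = []
        for j in range(ny):
            for i in range(nx):
                u = U[j, i]
                if not np.isfinite(u):
                    continue
                neigh = []
                for dj, di in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    jj, ii = j + dj, i + di
                    if 0 <= jj < ny and 0 <= ii < nx and np.isfinite(U[jj, ii]):
                        neigh.append(U[jj, ii])
                if neigh and all(u <= v for v in neigh) and any(u < v for v in neigh):
                    out.append((float(self.x_centers[i]), float(self.y_centers[j])))
        return out


def _em_sample(drift, y0s: np.ndarray, config: LandscapeConfig, rng: np.random.Generator):
    """Vectorized Euler–Maruyama over an ensemble; reflection at zero.

    ``drift`` maps an (n, d) state block to an (n, d) derivative block.
    Returns collected post-burn-in samples, shape (m, d).
    """
    y = np.array(y0s, dtype=float)
    n, d = y.shape
    dt = config.dt_sde
    n_burn = int(round(config.t_burn / dt))
    n_samp = int(round(config.t_sample / dt))
    noise_scale = config.sigma * np.sqrt(dt)
    samples = []
    scale = max(1.0, float(np.max(np.abs(y))))
    checked = False
    for step in range(n_burn + n_samp):
        f = drift(y)
        if not checked:
            mx = float(np.max(np.abs(f))) * dt
            if mx > 0.2 * scale:
                warnings.warn(
                    f"drift per step ({mx:.3g}) exceeds 20% of state scale; "
                    "reduce dt_sde", stacklevel=2)
            checked = True
        y = y + f * dt
        if config.sigma > 0:
            y = y + noise_scale * rng.standard_normal((n, d))
        np.abs(y, out=y)  # reflecting boundary at zero
        if step >= n_burn and (step - n_burn) % config.sample_every == 0:
            samples.append(y.copy())
    return np.concatenate(samples, axis=0)


def _default_initials(params: OdeParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Trajectories start spread over the stable attractors (round-robin),
    so every well of a multistable landscape is populated."""
    stable = [fp.state for fp in find_steady_states(params) if fp.is_stable]
    if not stable:
        stable = [np.full(4, params.uniform_balance_A)]
    reps = int(np.ceil(n / len(stable)))
    y0 = np.vstack([np.tile(s, (reps, 1)) for s in stable])[:n]
    return y0


def euler_maruyama_ensemble(
    params: OdeParams,
    schedule: FeedbackSchedule = CONSTANT_SCHEDULE,
    cue: Cue = NO_CUE,
    config: LandscapeConfig = LandscapeConfig(),
    initials: np.ndarray | None = None,
) -> np.ndarray:
    """Sampled 4D states of the stochastic two-compartment model.

    X_{t+dt} = X_t + f(X_t) dt + sigma sqrt(dt) xi with per-component
    standard-normal xi and reflection at zero.  The schedule/cue are
    evaluated at the current time, so a frozen (constant) schedule gives a
    stationary ensemble.  Reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if initials is None:
        initials = _default_initials(params, config.n_trajectories, rng)
    t_holder = {"t": 0.0}
    dt = config.dt_sde

    def drift(block):
        s_kAP, s_kPA = _multipliers(schedule, t_holder["t"])
        c = cue.active_rate(t_holder["t"])
        t_holder["t"] += dt
        return _rhs_block(block, params, s_kAP, s_kPA, c)

    return _em_sample(drift, initials, config, rng)


def _rhs_block(y: np.ndarray, params: OdeParams, s_kAP: float, s_kPA: float,
               cue_rate: float) -> np.ndarray:
    """Vectorized two-compartment RHS over an (n, 4) state block."""
    Aa, Ap, Pa, Pp = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    Acyto = params.rhoA - params.psi * (Aa + Ap) / 2.0
    Pcyto = params.rhoP - params.psi * (Pa + Pp) / 2.0
    D, kon, koff = params.Dtilde, params.kon, params.koff
    kAP = s_kAP * params.kAP
    kPA = s_kPA * params.kPA
    out = np.empty_like(y)
    out[:, 0] = D * (Ap - Aa) + kon * Acyto - koff * Aa - kAP * Pa**params.alpha * Aa + cue_rate * Ap
    out[:, 1] = D * (Aa - Ap) + kon * Acyto - koff * Ap - kAP * Pp**params.alpha * Ap - cue_rate * Ap
    out[:, 2] = D * (Pp - Pa) + kon * Pcyto - koff * Pa - kPA * Aa**params.beta * Pa
    out[:, 3] = D * (Pa - Pp) + kon * Pcyto - koff * Pp - kPA * Ap**params.beta * Pp
    return out


def euler_maruyama_wavepin(
    params: WavePinParams,
    config: LandscapeConfig = LandscapeConfig(),
    gamma_multiplier: float = 1.0,
    cue_rate: float = 0.0,
    initials: np.ndarray | None = None,
) -> np.ndarray:
    """Sampled 2D states (Xa, Xp) of the stochastic one-species model."""
    rng = np.random.default_rng(config.seed)
    if initials is None:
        u = params.uniform_balance
        initials = np.tile([u, u], (config.n_trajectories, 1))
        initials = initials + 0.1 * rng.standard_normal(initials.shape)
        initials = np.abs(initials)

    def drift(block):
        Xa, Xp = block[:, 0], block[:, 1]
        Xcyto = params.rhoX - params.psi * (Xa + Xp) / 2.0
        g = gamma_multiplier * params.gamma
        D, kon, koff = params.Dtilde, params.kon, params.koff
        Kn = params.K ** params.n
        ha = Xa**params.n / (Kn + Xa**params.n)
        hp = Xp**params.n / (Kn + Xp**params.n)
        out = np.empty_like(block)
        out[:, 0] = D * (Xp - Xa) + kon * Xcyto - koff * Xa + g * Xcyto * ha + cue_rate * Xp
        out[:, 1] = D * (Xa - Xp) + kon * Xcyto - koff * Xp + g * Xcyto * hp - cue_rate * Xp
        return out

    return _em_sample(drift, initials, config, rng)


def project_differences(samples: np.ndarray) -> np.ndarray:
    """(n, 4) states -> (n, 2) difference coordinates (Aa-Pa, Ap-Pp)."""
    return np.column_stack([samples[:, 0] - samples[:, 2], samples[:, 1] - samples[:, 3]])


def build_landscape(
    samples: np.ndarray,
    config: LandscapeConfig = LandscapeConfig(),
    min_samples: int = 100,
) -> LandscapeGrid:
    """Histogram samples on the difference plane and derive U = -ln(density).

    4-column samples are projected to difference coordinates first;
    2-column samples (the one-species model) are binned directly.
    Unoccupied bins carry NaN quasipotential rather than a fabricated
    barrier height.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(samples)}")
    pts = project_differences(samples) if samples.shape[1] == 4 else samples
    (xlo, xhi), (ylo, yhi) = config.grid_bounds
    nx, ny = config.grid_bins
    H, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=config.grid_bins,
        range=[[xlo, xhi], [ylo, yhi]],
    )
    H = H.T  # (ny, nx) with rows = y bins
    density = H / H.sum()
    with np.errstate(divide="ignore"):
        U = -np.log(np.where(density > 0, density, np.nan))
    U = U - np.nanmin(U)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    return LandscapeGrid(xc, yc, density, U)


def velocity_field(
    params: OdeParams,
    schedule_value: float = 1.0,
    cue_value: float = 0.0,
    grid: LandscapeGrid | None = None,
    config: LandscapeConfig = LandscapeConfig(),
    lift_samples: np.ndarray | None = None,
    apply_to_kPA: bool = False,
) -> LandscapeGrid:
    """Instantaneous deterministic velocity projected on the difference plane.

    Default lift rule: a bin at (u, v) maps to the 4D state on the
    symmetric section Aa+Pa = Ap+Pp = S, with S the mean compartment sum
    over the stable attractors; concentrations are clipped at zero.  If
    ``lift_samples`` is given, the velocity in each bin is instead the mean
    projected velocity over the samples that fall in it (the degeneracy of
    the projection is then resolved empirically).
    """
    if grid is None:
        (xlo, xhi), (ylo, yhi) = config.grid_bounds
        nx, ny = config.grid_bins
        xe = np.linspace(xlo, xhi, nx + 1)
        ye = np.linspace(ylo, yhi, ny + 1)
        xc, yc = 0.5 * (xe[:-1] + xe[1:]), 0.5 * (ye[:-1] + ye[1:])
        empty = np.full((ny, nx), np.nan)
        grid = LandscapeGrid(xc, yc, empty, empty)
    s_kPA = schedule_value if apply_to_kPA else 1.0
    nx, ny = len(grid.x_centers), len(grid.y_centers)
    V = np.full((2, ny, nx), np.nan)

    if lift_samples is not None:
        pts = project_differences(lift_samples)
        ix = np.digitize(pts[:, 0], _edges(grid.x_centers)) - 1
        iy = np.digitize(pts[:, 1], _edges(grid.y_centers)) - 1
        acc = np.zeros((2, ny, nx))
        cnt = np.zeros((ny, nx))
        for p, i, j in zip(lift_samples, ix, iy):
            if 0 <= i < nx and 0 <= j < ny:
                f = _rhs_values(p, params, schedule_value, s_kPA, cue_value)
                acc[0, j, i] += f[0] - f[2]
                acc[1, j, i] += f[1] - f[3]
                cnt[j, i] += 1
        nzero = cnt > 0
        V[0][nzero] = acc[0][nzero] / cnt[nzero]
        V[1][nzero] = acc[1][nzero] / cnt[nzero]
    else:
        stable = [fp.state for fp in find_steady_states(params) if fp.is_stable]
        if stable:
            S = float(np.mean([s[0] + s[2] for s in stable]))
        else:
            S = params.uniform_balance_A + params.uniform_balance_P
        for j, v in enumerate(grid.y_centers):
            for i, u in enumerate(grid.x_centers):
                Aa = max((S + u) / 2.0, 0.0)
                Pa = max((S - u) / 2.0, 0.0)
                Ap = max((S + v) / 2.0, 0.0)
                Pp = max((S - v) / 2.0, 0.0)
                f = _rhs_values(np.array([Aa, Ap, Pa, Pp]), params, schedule_value, s_kPA, cue_value)
                V[0, j, i] = f[0] - f[2]
                V[1, j, i] = f[1] - f[3]
    return LandscapeGrid(grid.x_centers, grid.y_centers, grid.density, grid.quasipotential, V)


def _edges(centers: np.ndarray) -> np.ndarray:
    d = centers[1] - centers[0]
    return np.concatenate([centers - d / 2, [centers[-1] + d / 2]])


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the Scharfetter–Gummel weight."""
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def fokker_planck_stationary(
    params: WavePinParams,
    sigma: float,
    x_max: float | None = None,
    n_grid: int = 64,
    gamma_multiplier: float = 1.0,
    cue_rate: float = 0.0,
):
    """Stationary density of the one-species model's Fokker–Planck equation.

    Solves 0 = -div(f p) + (sigma^2/2) laplacian(p) on [0, x_max]^2 with
    zero-flux (reflecting) boundaries, using a finite-volume
    Scharfetter–Gummel scheme (exact for linear drift in 1D, hence the
    Boltzmann closed form is reproduced on gradient systems).  Returns
    ``(x_centers, density, quasipotential)`` with density summing to 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0 for a stationary density")
    if x_max is None:
        x_max = 2.0 * params.rhoX / params.psi
    h = x_max / n_grid
    xc = (np.arange(n_grid) + 0.5) * h
    D = sigma**2 / 2.0

    # drift on cell centers
    FX = np.zeros((n_grid, n_grid))
    FY = np.zeros((n_grid, n_grid))
    for j, xp in enumerate(xc):
        for i, xa in enumerate(xc):
            f = _wavepin_rhs_raw(np.array([xa, xp]), params, gamma_multiplier, cue_rate)
            FX[j, i], FY[j, i] = f[0], f[1]

    N = n_grid * n_grid
    idx = lambda j, i: j * n_grid + i
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    # Scharfetter–Gummel interface fluxes; zero-flux outer boundaries.
    for j in range(n_grid):
        for i in range(n_grid):
            r = idx(j, i)
            # x-direction neighbour (i, i+1)
            if i + 1 < n_grid:
                v = 0.5 * (FX[j, i] + FX[j, i + 1])  # interface drift
                pe = v * h / D
                bm, bp = _bernoulli(np.array([-pe, pe]))
                # flux F = (D/h) * (B(-pe) p_i - B(pe) p_{i+1}) leaving cell i
                cfl = D / h**2
                add(r, r, -cfl * bm)
                add(r, idx(j, i + 1), cfl * bp)
                rr = idx(j, i + 1)
                add(rr, r, cfl * bm)
                add(rr, rr, -cfl * bp)
            # y-direction neighbour (j, j+1)
            if j + 1 < n_grid:
                v = 0.5 * (FY[j, i] + FY[j + 1, i])
                pe = v * h / D
                bm, bp = _bernoulli(np.array([-pe, pe]))
                cfl = D / h**2
                add(r, r, -cfl * bm)
                add(r, idx(j + 1, i), cfl * bp)
                rr = idx(j + 1, i)
                add(rr, r, cfl * bm)
                add(rr, rr, -cfl * bp)

    L = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    # stationary: L p = 0 with sum(p) = 1; replace one equation
    A = L.tolil()
    A[0, :] = 1.0
    b = np.zeros(N)
    b[0] = 1.0
    p = spla.spsolve(A.tocsr(), b)
    res = float(np.max(np.abs(L @ p)))
    if not np.all(np.isfinite(p)) or res > 1e-6 * max(1.0, float(np.max(np.abs(p)))):
        raise RuntimeError(f"Fokker–Planck solve did not converge (residual {res:.3g})")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    dens = p.reshape(n_grid, n_grid)  # rows = Xp bins, cols = Xa bins
    with np.errstate(divide="ignore"):
        U = -np.log(np.where(dens > 0, dens, np.nan))
    U = U - np.nanmin(U)
    return xc, dens, U


def fokker_planck_stationary_1d(drift_fn, x_lo: float, x_hi: float, sigma: float,
                                n_grid: int = 256):
    """1D zero-flux stationary Fokker–Planck solver (Scharfetter–Gummel).

    Returns ``(x_centers, density)`` with the density normalized so that
    sum(density) * dx = 1.  For gradient drift f = -V'(x) the result
    matches exp(-2 V / sigma^2) up to normalization.
    """
    h = (x_hi - x_lo) / n_grid
    xc = x_lo + (np.arange(n_grid) + 0.5) * h
    D = sigma**2 / 2.0
    F = np.array([drift_fn(x) for x in xc], dtype=float)
    N = n_grid
    Lm = sp.lil_matrix((N, N))
    for i in range(N - 1):
        v = 0.5 * (F[i] + F[i + 1])
        pe = v * h / D
        bm, bp = _bernoulli(np.array([-pe, pe]))
        cfl = D / h**2
        Lm[i, i] -= cfl * bm
        Lm[i, i + 1] += cfl * bp
        Lm[i + 1, i] += cfl * bm
        Lm[i + 1, i + 1] -= cfl * bp
    A = Lm.tolil()
    A[0, :] = 1.0
    b = np.zeros(N)
    b[0] = 1.0
    p = spla.spsolve(A.tocsr(), b)
    p = np.clip(p, 0.0, None)
    p = p / (p.sum() * h)
    return xc, p
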