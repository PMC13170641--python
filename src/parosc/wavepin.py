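"""One-species polarity model with Hill-type positive feedback.

A single polarity species X occupies two membrane compartments (``Xa``,
``Xp``) and a shared cytoplasmic pool.  Besides linear attachment and
detachment, membrane-bound X recruits cytoplasmic X cooperatively through
a Hill function — the wave-pinning mechanism.  For sufficiently strong
feedback the two-compartment reduction is bistable: a pair of mirror-image
polarized states coexists with an unstable symmetric state, so the model
reproduces the polarity phenomenology of the four-variable PAR system with
only two degrees of freedom (which makes the Fokker–Planck quasipotential
tractable).

The detachment term enters with a negative sign (first-order removal from
the membrane); the feedback multiplier of a :class:`~parosc.ode.FeedbackSchedule`
acts on the recruitment strength ``gamma``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .ode import Cue, FeedbackSchedule, CONSTANT_SCHEDULE, NO_CUE, InadmissibleParameters

__all__ = [
    "WavePinParams",
    "WavePinFixedPoint",
    "wavepin_cyto",
    "wavepin_rhs",
    "wavepin_jacobian",
    "wavepin_fixed_points",
    "wavepin_simulate",
    "WavePinTrajectory",
]


@dataclass(frozen=True)
class WavePinParams:
    """Rates, pool and Hill parameters of the one-species model.

    Defaults are calibrated to the bistable regime: two mirror-image
    polarized attractors plus an unstable symmetric state.
    """

    Dtilde: float = 0.01
    kon: float = 0.1
    koff: float = 1.0
    gamma: float = 2.0
    K: float = 2.0
    n: int = 2
    rhoX: float = 3.0
    psi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Dtilde", "kon", "koff", "gamma", "rhoX"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.psi <= 0:
            raise ValueError("psi must be > 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    @property
    def uniform_balance(self) -> float:
        """Feedback-free uniform state kon*rhoX/(koff + kon*psi)."""
        return self.kon * self.rhoX / (self.koff + self.kon * self.psi)


def wavepin_cyto(state, params: WavePinParams) -> float:
    """Cytoplasmic concentration rhoX - psi*(Xa+Xp)/2 (mass conservation)."""
    Xa, Xp = np.asarray(state, dtype=float)
    Xcyto = params.rhoX - params.psi * (Xa + Xp) / 2.0
    if Xcyto < -1e-12:
        raise InadmissibleParameters(f"negative cytoplasmic pool (Xcyto={Xcyto:.3g})")
    return float(max(Xcyto, 0.0))


def _hill(x: np.ndarray, K: float, n: int) -> np.ndarray:
    xn = np.power(x, n)
    return xn / (K**n + xn)


def wavepin_rhs(state, params: WavePinParams, gamma_multiplier: float = 1.0,
                cue_rate: float = 0.0) -> np.ndarray:
    """(dXa/dt, dXp/dt) with optional feedback multiplier and cue.

    The cue redistributes membrane X from the posterior to the anterior
    compartment at a first-order rate, mirroring the aPAR cue of the
    four-variable model.
    """
    wavepin_cyto(state, params)  # admissibility check
    return _rhs_raw(state, params, gamma_multiplier, cue_rate)


def _rhs_raw(state, params: WavePinParams, gamma_multiplier: float,
             cue_rate: float) -> np.ndarray:
    # No pool-admissibility check: used by root finders that may probe
    # inadmissible intermediate states.
    Xa, Xp = np.asarray(state, dtype=float)
    Xcyto = params.rhoX - params.psi * (Xa + Xp) / 2.0
    g = gamma_multiplier * params.gamma
    D, kon, koff = params.Dtilde, params.kon, params.koff
    dXa = D * (Xp - Xa) + kon * Xcyto - koff * Xa + g * Xcyto * _hill(Xa, params.K, params.n) + cue_rate * Xp
    dXp = D * (Xa - Xp) + kon * Xcyto - koff * Xp + g * Xcyto * _hill(Xp, params.K, params.n) - cue_rate * Xp
    return np.array([dXa, dXp])


def wavepin_jacobian(state, params: WavePinParams, gamma_multiplier: float = 1.0,
                     cue_rate: float = 0.0) -> np.ndarray:
    Xa, Xp = np.asarray(state, dtype=float)
    Xcyto = params.rhoX - params.psi * (Xa + Xp) / 2.0
    g = gamma_multiplier * params.gamma
    D, kon, koff, psi = params.Dtilde, params.kon, params.koff, params.psi
    K, n = params.K, params.n
    h_a, h_p = _hill(Xa, K, n), _hill(Xp, K, n)

    def dhill(x):
        if x == 0.0:
            return 0.0 if n > 1 else 1.0 / K
        return n * K**n * x ** (n - 1) / (K**n + x**n) ** 2

    half = psi / 2.0
    J = np.empty((2, 2))
    J[0, 0] = -D - kon * half - koff + g * (-half * h_a + Xcyto * dhill(Xa))
    J[0, 1] = D - kon * half - g * half * h_a + cue_rate
    J[1, 0] = D - kon * half - g * half * h_p
    J[1, 1] = -D - kon * half - koff + g * (-half * h_p + Xcyto * dhill(Xp)) - cue_rate
    return J


@dataclass(frozen=True)
class WavePinFixedPoint:
    state: np.ndarray
    stability: str
    eigenvalue_real_parts: np.ndarray
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def is_symmetric(self) -> bool:
        return abs(self.state[0] - self.state[1]) < 1e-6


def wavepin_fixed_points(
    params: WavePinParams,
    gamma_multiplier: float = 1.0,
    cue_rate: float = 0.0,
    grid_density: int = 12,
    tol: float = 1e-9,
    dedupe_tol: float = 1e-6,
    tol_eig: float = 1e-8,
) -> list[WavePinFixedPoint]:
    """Multi-start enumeration of fixed points with stability labels."""
    cmax = 2.0 * params.rhoX / params.psi

    def fun(y):
        return _rhs_raw(np.clip(y, 0, None), params, gamma_multiplier, cue_rate)

    grid = np.linspace(0.0, 0.98 * cmax, grid_density)
    found: list[np.ndarray] = []
    for Xa, Xp in itertools.product(grid, grid):
        if params.psi * (Xa + Xp) / 2.0 > params.rhoX:
            continue
        sol = root(fun, np.array([Xa, Xp]), method="hybr", tol=1e-12)
        # keep any root whose residual passes; hybr can report failure
        # (xtol unreachable) at an already-converged point
        y = np.clip(sol.x, 0.0, None)
        if params.rhoX - params.psi * (y[0] + y[1]) / 2.0 < -1e-9:
            continue
        if np.max(np.abs(fun(y))) > tol:
            continue
        if any(np.linalg.norm(y - f) < dedupe_tol for f in found):
            continue
        found.append(y)

    out = []
    for y in found:
        re = np.sort(np.real(np.linalg.eigvals(
            wavepin_jacobian(y, params, gamma_multiplier, cue_rate))))
        if np.all(re < -tol_eig):
            lab = "stable"
        elif np.all(re > tol_eig):
            lab = "unstable"
        elif np.any(re > tol_eig):
            lab = "saddle"
        else:
            lab = "stable"
        out.append(WavePinFixedPoint(y, lab, re, float(np.max(np.abs(fun(y))))))
    out.sort(key=lambda f: round(f.state[0] - f.state[1], 6))
    return out


@dataclass
class WavePinTrajectory:
    times: np.ndarray
    states: np.ndarray  # (n, 2)
    params: WavePinParams

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def cyto(self) -> np.ndarray:
        return self.params.rhoX - self.params.psi * (self.states[:, 0] + self.states[:, 1]) / 2.0


def wavepin_simulate(
    initial,
    params: WavePinParams,
    t_span: tuple[float, float],
    schedule: FeedbackSchedule = CONSTANT_SCHEDULE,
    cue: Cue = NO_CUE,
    n_out: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> WavePinTrajectory:
    """Integrate the one-species model; the schedule multiplier scales gamma."""
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (2,):
        raise ValueError("initial state must have 2 components (Xa, Xp)")
    wavepin_cyto(y0, params)

    edges = sorted({t_span[0], t_span[1]}
                   | {t for t in schedule.times() if t_span[0] < t < t_span[1]}
                   | {t for t in (cue.t_on, cue.t_off)
                      if np.isfinite(t) and t_span[0] < t < t_span[1]})
    t_eval = np.linspace(t_span[0], t_span[1], n_out)
    all_t, all_y = [], []
    y = y0
    for a, b in zip(edges, edges[1:]):
        seg_cue = cue.active_rate((a + b) / 2.0)

        def rhs(t, yy, seg_cue=seg_cue):
            return wavepin_rhs(yy, params, float(schedule(t)), seg_cue)

        def jac(t, yy, seg_cue=seg_cue):
            return wavepin_jacobian(yy, params, float(schedule(t)), seg_cue)

        te = np.unique(np.concatenate([[a], t_eval[(t_eval >= a) & (t_eval <= b)], [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=te, rtol=rtol, atol=atol, jac=jac)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        all_t.append(sol.t)
        all_y.append(sol.y.T)
    t = np.concatenate(all_t)
    ys = np.vstack(all_y)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return WavePinTrajectory(t[keep], np.clip(ys[keep], 0.0, None), params)
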