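"""Two-compartment, four-ODE PAR polarity model.

The cell is coarse-grained into an anterior and a posterior membrane
compartment, each carrying an aPAR concentration (``Aa``, ``Ap``) and a
pPAR concentration (``Pa``, ``Pp``).  Membrane species exchange between
compartments at a diffusion-like rate, bind from and unbind to shared
cytoplasmic pools (mass conservation), and remove each other through
mutual antagonism (the P→A coefficient ``kAP`` acting on A, the A→P
coefficient ``kPA`` acting on P).  Cell-cycle entrainment enters as a
time-dependent multiplier on ``kAP`` (optionally also ``kPA``), and a
symmetry-breaking cue as a first-order redistribution of aPAR from the
posterior to the anterior compartment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "OdeParams",
    "FeedbackSchedule",
    "Cue",
    "FixedPoint",
    "Trajectory",
    "InadmissibleParameters",
    "param_set",
    "cytoplasmic_pools",
    "ode_rhs",
    "ode_jacobian",
    "simulate",
    "find_steady_states",
    "classify_stability",
    "classify_quadrant",
    "default_dead_zone",
    "run_state_switching_matrix",
    "QUADRANT_LABELS",
]

QUADRANT_LABELS = (
    "UNIFORM_A",
    "UNIFORM_P",
    "POLARIZED_AP",
    "POLARIZED_PA",
    "UNDEFINED",
)


class InadmissibleParameters(ValueError):
    """Raised when a state/parameter combination exhausts a cytoplasmic pool."""


@dataclass(frozen=True)
class OdeParams:
    """Rate constants, pools and exponents of the two-compartment model.

    Units are nondimensional: concentrations in arbitrary units, rates per
    unit time.  ``psi`` is the surface-to-volume ratio coupling membrane
    concentrations to cytoplasmic pool depletion.
    """

    Dtilde: float = 0.1
    kon: float = 1.0
    koff: float = 1.0
    kAP: float = 1.0
    kPA: float = 1.0
    alpha: int = 2
    beta: int = 2
    rhoA: float = 2.0
    rhoP: float = 2.0
    psi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Dtilde", "kon", "koff", "kAP", "kPA", "rhoA", "rhoP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.psi <= 0:
            raise ValueError("psi must be > 0")
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("antagonism exponents must be >= 1")

    @property
    def uniform_balance_A(self) -> float:
        """Feedback-free uniform steady state kon*rhoA/(koff + kon*psi)."""
        return self.kon * self.rhoA / (self.koff + self.kon * self.psi)

    @property
    def uniform_balance_P(self) -> float:
        return self.kon * self.rhoP / (self.koff + self.kon * self.psi)


#: Behaviour-calibrated named parameter regimes.  ``high_feedback`` sits in
#: the multistable region (four stable polarity states plus a central
#: unstable state); ``low_feedback`` lowers the P→A coefficient until only
#: the uniform-A-high state survives.
_PARAM_SETS = {
    "high_feedback": OdeParams(kAP=20.0, kPA=20.0),
    "low_feedback": OdeParams(kAP=0.1, kPA=20.0),
}


def param_set(name: str) -> OdeParams:
    """Return a shipped named parameter regime (``high_feedback``/``low_feedback``)."""
    try:
        return _PARAM_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {sorted(_PARAM_SETS)}"
        ) from None


@dataclass(frozen=True)
class FeedbackSchedule:
    """Time-dependent multiplier on the P→A antagonism coefficient.

    ``breakpoints`` is an ordered sequence of ``(time, multiplier)`` pairs;
    the multiplier is piecewise-linear between breakpoints and constant
    outside them.  A single breakpoint is a constant schedule.  With
    ``apply_to_kPA`` the same multiplier also scales the A→P coefficient
    (the co-oscillation variant).
    """

    breakpoints: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    apply_to_kPA: bool = False

    def __post_init__(self) -> None:
        times = [t for t, _ in self.breakpoints]
        mults = [m for _, m in self.breakpoints]
        if not times:
            raise ValueError("schedule needs at least one breakpoint")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(m < 0 for m in mults):
            raise ValueError("multipliers must be >= 0")
        object.__setattr__(self, "breakpoints", tuple((float(t), float(m)) for t, m in self.breakpoints))

    @classmethod
    def constant(cls, multiplier: float = 1.0, apply_to_kPA: bool = False) -> "FeedbackSchedule":
        return cls(((0.0, float(multiplier)),), apply_to_kPA=apply_to_kPA)

    @classmethod
    def low_window(
        cls,
        t_low_on: float,
        t_low_off: float,
        low: float,
        high: float = 1.0,
        ramp: float = 1.0,
        apply_to_kPA: bool = False,
    ) -> "FeedbackSchedule":
        """High→low→high trapezoid: a transient low-feedback excursion.

        Mimics the CDK-1 cycle seen from one cell birth: feedback drops over
        ``ramp`` time units at ``t_low_on``, stays low until ``t_low_off``,
        then ramps back up to ``high``.
        """
        return cls(
            (
                (t_low_on - ramp, high),
                (t_low_on, low),
                (t_low_off, low),
                (t_low_off + ramp, high),
            ),
            apply_to_kPA=apply_to_kPA,
        )

    def __call__(self, t) -> np.ndarray | float:
        times = np.array([b[0] for b in self.breakpoints])
        mults = np.array([b[1] for b in self.breakpoints])
        return np.interp(t, times, mults)

    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.breakpoints)


CONSTANT_SCHEDULE = FeedbackSchedule.constant(1.0)


@dataclass(frozen=True)
class Cue:
    """First-order redistribution of aPAR from posterior to anterior.

    While ``t_on <= t < t_off`` a flux ``rate * Ap`` leaves the posterior
    aPAR compartment and enters the anterior one; total aPAR is conserved
    exactly.  ``rate=0`` disables the cue.
    """

    rate: float = 0.0
    t_on: float = 0.0
    t_off: float = np.inf

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("cue rate must be >= 0")
        if self.rate > 0 and not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")

    def active_rate(self, t: float) -> float:
        if self.rate > 0 and self.t_on <= t < self.t_off:
            return self.rate
        return 0.0


NO_CUE = Cue(0.0)


def cytoplasmic_pools(state, params: OdeParams) -> tuple[float, float]:
    """Cytoplasmic concentrations implied by mass conservation.

    Acyto = rhoA - psi*(Aa+Ap)/2 and the pPAR analogue.  Raises
    :class:`InadmissibleParameters` if either pool would be negative.
    """
    Aa, Ap, Pa, Pp = np.asarray(state, dtype=float)
    Acyto = params.rhoA - params.psi * (Aa + Ap) / 2.0
    Pcyto = params.rhoP - params.psi * (Pa + Pp) / 2.0
    if Acyto < -1e-12 or Pcyto < -1e-12:
        raise InadmissibleParameters(
            f"negative cytoplasmic pool (Acyto={Acyto:.3g}, Pcyto={Pcyto:.3g})"
        )
    return float(max(Acyto, 0.0)), float(max(Pcyto, 0.0))


def _rhs_values(y, params: OdeParams, s_kAP: float, s_kPA: float, cue_rate: float):
    Aa, Ap, Pa, Pp = y
    Acyto = params.rhoA - params.psi * (Aa + Ap) / 2.0
    Pcyto = params.rhoP - params.psi * (Pa + Pp) / 2.0
    D, kon, koff = params.Dtilde, params.kon, params.koff
    kAP = s_kAP * params.kAP
    kPA = s_kPA * params.kPA
    dAa = D * (Ap - Aa) + kon * Acyto - koff * Aa - kAP * Pa**params.alpha * Aa + cue_rate * Ap
    dAp = D * (Aa - Ap) + kon * Acyto - koff * Ap - kAP * Pp**params.alpha * Ap - cue_rate * Ap
    dPa = D * (Pp - Pa) + kon * Pcyto - koff * Pa - kPA * Aa**params.beta * Pa
    dPp = D * (Pa - Pp) + kon * Pcyto - koff * Pp - kPA * Ap**params.beta * Pp
    return np.array([dAa, dAp, dPa, dPp])


def _multipliers(schedule: FeedbackSchedule, t: float) -> tuple[float, float]:
    s = float(schedule(t))
    return s, (s if schedule.apply_to_kPA else 1.0)


def ode_rhs(
    state,
    t: float,
    params: OdeParams,
    schedule: FeedbackSchedule = CONSTANT_SCHEDULE,
    cue: Cue = NO_CUE,
) -> np.ndarray:
    """Time derivatives (dAa, dAp, dPa, dPp) of the two-compartment model."""
    cytoplasmic_pools(state, params)  # admissibility check
    s_kAP, s_kPA = _multipliers(schedule, t)
    return _rhs_values(np.asarray(state, dtype=float), params, s_kAP, s_kPA, cue.active_rate(t))


def ode_jacobian(
    state,
    params: OdeParams,
    s_kAP: float = 1.0,
    s_kPA: float = 1.0,
    cue_rate: float = 0.0,
) -> np.ndarray:
    """Analytic Jacobian of the right-hand side at fixed feedback multipliers."""
    Aa, Ap, Pa, Pp = np.asarray(state, dtype=float)
    D, kon, koff, psi = params.Dtilde, params.kon, params.koff, params.psi
    kAP = s_kAP * params.kAP
    kPA = s_kPA * params.kPA
    a, b = params.alpha, params.beta
    half = kon * psi / 2.0
    J = np.zeros((4, 4))
    # dAa
    J[0, 0] = -D - half - koff - kAP * Pa**a
    J[0, 1] = D - half + cue_rate
    J[0, 2] = -kAP * a * Pa ** (a - 1) * Aa
    # dAp
    J[1, 0] = D - half
    J[1, 1] = -D - half - koff - kAP * Pp**a - cue_rate
    J[1, 3] = -kAP * a * Pp ** (a - 1) * Ap
    # dPa
    J[2, 0] = -kPA * b * Aa ** (b - 1) * Pa
    J[2, 2] = -D - half - koff - kPA * Aa**b
    J[2, 3] = D - half
    # dPp
    J[3, 1] = -kPA * b * Ap ** (b - 1) * Pp
    J[3, 2] = D - half
    J[3, 3] = -D - half - koff - kPA * Ap**b
    return J


@dataclass
class Trajectory:
    """Time-resolved solution of the two-compartment model."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 4): Aa, Ap, Pa, Pp
    params: OdeParams
    schedule: FeedbackSchedule = CONSTANT_SCHEDULE
    cue: Cue = NO_CUE

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def pools(self) -> np.ndarray:
        """(n, 2) array of (Acyto, Pcyto) along the trajectory."""
        A = self.params.rhoA - self.params.psi * (self.states[:, 0] + self.states[:, 1]) / 2.0
        P = self.params.rhoP - self.params.psi * (self.states[:, 2] + self.states[:, 3]) / 2.0
        return np.column_stack([A, P])

    def to_dataframe(self):
        import pandas as pd

        pools = self.pools()
        mult = np.asarray(self.schedule(self.times), dtype=float)
        cue_on = np.array([self.cue.active_rate(t) > 0 for t in self.times])
        return pd.DataFrame(
            {
                "time": self.times,
                "Aa": self.states[:, 0],
                "Ap": self.states[:, 1],
                "Pa": self.states[:, 2],
                "Pp": self.states[:, 3],
                "Acyto": pools[:, 0],
                "Pcyto": pools[:, 1],
                "kAP_multiplier": mult,
                "cue_active": cue_on,
            }
        )


def _segment_times(t0: float, t1: float, schedule: FeedbackSchedule, cue: Cue) -> list[float]:
    pts = {t0, t1}
    for t in schedule.times():
        if t0 < t < t1:
            pts.add(t)
    for t in (cue.t_on, cue.t_off):
        if np.isfinite(t) and t0 < t < t1:
            pts.add(t)
    return sorted(pts)


def simulate(
    initial,
    params: OdeParams,
    t_span: tuple[float, float],
    schedule: FeedbackSchedule = CONSTANT_SCHEDULE,
    cue: Cue = NO_CUE,
    n_out: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``t_span``.

    The integration is segmented at schedule breakpoints and at cue
    on/off times so the stiff integrator never steps across a kink.
    """
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (4,):
        raise ValueError("initial state must have 4 components (Aa, Ap, Pa, Pp)")
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    cytoplasmic_pools(y0, params)

    t_eval = np.linspace(t_span[0], t_span[1], n_out)
    seg_edges = _segment_times(t_span[0], t_span[1], schedule, cue)
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    y = y0
    for a, b in zip(seg_edges, seg_edges[1:]):
        # The cue is constant within a segment (segments split at t_on/t_off),
        # so evaluate it once at the midpoint; the schedule multiplier is
        # continuous piecewise-linear and is evaluated pointwise.
        seg_cue = cue.active_rate((a + b) / 2.0)

        def rhs(t, yy, seg_cue=seg_cue):
            s_kAP, s_kPA = _multipliers(schedule, t)
            return _rhs_values(yy, params, s_kAP, s_kPA, seg_cue)

        def jac(t, yy, seg_cue=seg_cue):
            s_kAP, s_kPA = _multipliers(schedule, t)
            return ode_jacobian(yy, params, s_kAP, s_kPA, seg_cue)

        te = t_eval[(t_eval >= a) & (t_eval <= b)]
        te = np.unique(np.concatenate([[a], te, [b]]))
        sol = solve_ivp(
            rhs, (a, b), y, method=method, t_eval=te, rtol=rtol, atol=atol, jac=jac
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        all_t.append(sol.t)
        all_y.append(sol.y.T)

    t = np.concatenate(all_t)
    ys = np.vstack(all_y)
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, ys = t[keep], ys[keep]
    ys = np.clip(ys, 0.0, None)
    for row in ys[:: max(1, len(ys) // 16)]:
        cytoplasmic_pools(row, params)
    return Trajectory(t, ys, params, schedule, cue)


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the model at frozen feedback/cue values."""

    state: np.ndarray
    stability: str  # "stable" | "unstable" | "saddle"
    eigenvalue_real_parts: np.ndarray
    residual: float = 0.0

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def classify_stability(
    fp_state,
    params: OdeParams,
    schedule_value: float = 1.0,
    cue_value: float = 0.0,
    tol_eig: float = 1e-8,
    apply_to_kPA: bool = False,
) -> tuple[str, np.ndarray]:
    """Linearize at a fixed point and classify by eigenvalue real parts.

    Returns ``(label, real_parts)`` with label ``stable`` (all real parts
    < -tol), ``unstable`` (all > tol), or ``saddle`` (mixed signs).
    """
    s_kPA = schedule_value if apply_to_kPA else 1.0
    J = ode_jacobian(fp_state, params, schedule_value, s_kPA, cue_value)
    re = np.sort(np.real(np.linalg.eigvals(J)))
    n_pos = int(np.sum(re > tol_eig))
    n_neg = int(np.sum(re < -tol_eig))
    if n_neg == len(re):
        label = "stable"
    elif n_pos == len(re):
        label = "unstable"
    elif n_pos > 0:
        label = "saddle" if n_neg > 0 else "unstable"
    else:
        label = "stable"  # marginal within tolerance treated as stable
    return label, re


def find_steady_states(
    params: OdeParams,
    schedule_value: float = 1.0,
    cue_value: float = 0.0,
    grid_density: int = 4,
    tol: float = 1e-9,
    dedupe_tol: float = 1e-6,
    apply_to_kPA: bool = False,
) -> list[FixedPoint]:
    """Enumerate steady states by multi-start root finding.

    Starts are a deterministic grid over [0, max concentration]^4; roots
    with residual below ``tol`` are kept, deduplicated within
    ``dedupe_tol`` (Euclidean distance), and classified for stability.
    """
    s_kPA = schedule_value if apply_to_kPA else 1.0
    cmaxA = 2.0 * params.rhoA / params.psi
    cmaxP = 2.0 * params.rhoP / params.psi

    def fun(y):
        return _rhs_values(y, params, schedule_value, s_kPA, cue_value)

    def jac(y):
        return ode_jacobian(y, params, schedule_value, s_kPA, cue_value)

    gA = np.linspace(0.0, 0.95 * cmaxA, grid_density)
    gP = np.linspace(0.0, 0.95 * cmaxP, grid_density)
    found: list[np.ndarray] = []
    for Aa, Ap, Pa, Pp in itertools.product(gA, gA, gP, gP):
        # skip starts with exhausted pools
        if params.psi * (Aa + Ap) / 2.0 > params.rhoA or params.psi * (Pa + Pp) / 2.0 > params.rhoP:
            continue
        sol = root(fun, np.array([Aa, Ap, Pa, Pp]), jac=jac, method="hybr", tol=1e-12)
        # acceptance is by residual below; hybr may flag success=False at
        # an already-converged point when xtol is unreachable
        y = sol.x
        if np.any(y < -1e-9):
            continue
        y = np.clip(y, 0.0, None)
        if params.rhoA - params.psi * (y[0] + y[1]) / 2 < -1e-9:
            continue
        if params.rhoP - params.psi * (y[2] + y[3]) / 2 < -1e-9:
            continue
        if np.max(np.abs(fun(y))) > tol:
            continue
        if any(np.linalg.norm(y - f) < dedupe_tol for f in found):
            continue
        found.append(y)

    fps = []
    for y in found:
        label, re = classify_stability(
            y, params, schedule_value, cue_value, apply_to_kPA=apply_to_kPA
        )
        fps.append(
            FixedPoint(state=y, stability=label, eigenvalue_real_parts=re,
                       residual=float(np.max(np.abs(fun(y)))))
        )
    # deterministic ordering: by (Aa-Pa, Ap-Pp) quadrant coordinates
    fps.sort(key=lambda f: (round(f.state[0] - f.state[2], 6), round(f.state[1] - f.state[3], 6)))
    return fps


def default_dead_zone(params: OdeParams) -> float:
    """1% of the larger feedback-free uniform balance concentration."""
    return 0.01 * max(params.uniform_balance_A, params.uniform_balance_P)


def classify_quadrant(state, dead_zone: float) -> str:
    """Polarity class from the signs of (Aa-Pa) and (Ap-Pp).

    Differences inside ``±dead_zone`` yield ``UNDEFINED`` (prevents sign
    flicker at near-symmetric states).
    """
    Aa, Ap, Pa, Pp = np.asarray(state, dtype=float)
    da = Aa - Pa
    dp = Ap - Pp
    if abs(da) <= dead_zone or abs(dp) <= dead_zone:
        return "UNDEFINED"
    if da > 0 and dp > 0:
        return "UNIFORM_A"
    if da < 0 and dp < 0:
        return "UNIFORM_P"
    if da > 0 and dp < 0:
        return "POLARIZED_AP"
    return "POLARIZED_PA"


def quadrant_attractors(params: OdeParams, **kwargs) -> dict[str, np.ndarray]:
    """Map quadrant label -> stable fixed-point state under frozen feedback."""
    dz = default_dead_zone(params)
    out: dict[str, np.ndarray] = {}
    for fp in find_steady_states(params, **kwargs):
        if fp.is_stable:
            lab = classify_quadrant(fp.state, dz)
            if lab != "UNDEFINED":
                out[lab] = fp.state
    return out


def run_state_switching_matrix(
    params: OdeParams,
    cue: Cue | None = None,
    low_multiplier: float = 0.02,
    t_low: tuple[float, float] = (5.0, 35.0),
    t_end: float = 200.0,
    regimes: tuple[str, ...] = ("constant_high", "constant_low", "oscillating"),
) -> dict[str, dict[str, str]]:
    """Cue-induced state switching under constant vs oscillating feedback.

    For each regime and each of the four polarity attractors of the
    high-feedback model, simulate with a transient posterior→anterior cue
    (active during the low-feedback window of the oscillating regime) and
    classify the final state after the system relaxes back at high
    feedback.  Returns ``{regime: {initial_label: final_label}}``.
    """
    if cue is None:
        # the cue spans the low-feedback window and persists through the
        # ramp back to high feedback, locking in the cue-aligned state
        cue = Cue(rate=0.5, t_on=t_low[0], t_off=t_low[1] + 10.0)
    attractors = quadrant_attractors(params)
    if len(attractors) != 4:
        raise RuntimeError(
            f"expected 4 quadrant attractors under high feedback, found {len(attractors)}"
        )
    schedules = {
        "constant_high": FeedbackSchedule.constant(1.0),
        "constant_low": FeedbackSchedule.constant(low_multiplier),
        "oscillating": FeedbackSchedule.low_window(t_low[0], t_low[1], low_multiplier),
    }
    dz = default_dead_zone(params)
    table: dict[str, dict[str, str]] = {}
    for regime in regimes:
        sched = schedules[regime]
        row: dict[str, str] = {}
        for label, y0 in attractors.items():
            traj = simulate(y0, params, (0.0, t_end), schedule=sched, cue=cue)
            row[label] = classify_quadrant(traj.final_state, dz)
        table[regime] = row
    return table
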