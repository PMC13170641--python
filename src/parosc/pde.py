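"""Spatially resolved 1D PAR model with time-varying P→A feedback.

Membrane concentrations A(x), P(x) live on the anterior–posterior axis,
diffuse laterally, exchange with well-mixed cytoplasmic pools (mass
conservation through the membrane means), and antagonize each other.
Unlike the two-compartment reduction, reaction rates need not be
symmetric between the species.  Integration is explicit forward Euler
with central finite differences (default dt = 0.01), which resolves the
kinks introduced by the dynamic ``kAP`` schedule.

The module also carries the P-lineage polarization scenarios: P1 (de novo
polarization from a uniformly pPAR-loaded membrane) and P2 (cue-induced
reversal of an inherited, oppositely polarized state), with domain-count
and asymmetry-index diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ode import FeedbackSchedule, CONSTANT_SCHEDULE, InadmissibleParameters, classify_quadrant

__all__ = [
    "PdeParams",
    "SpatialProfile",
    "ScenarioSpec",
    "ScenarioResult",
    "pde_step",
    "run_pde",
    "run_scenario",
    "count_domains",
    "asi_of_profile",
    "kap_schedule_from_trace",
    "default_scenario",
]


@dataclass(frozen=True)
class PdeParams:
    """Rates, pools, geometry and discretization of the spatial model."""

    DA: float = 0.1
    DP: float = 0.1
    konA: float = 1.0
    konP: float = 1.0
    koffA: float = 1.0
    koffP: float = 1.0
    kAP: float = 20.0
    kPA: float = 20.0
    kAP_schedule: FeedbackSchedule = CONSTANT_SCHEDULE
    alpha: int = 2
    beta: int = 2
    rhoA: float = 2.0
    rhoP: float = 2.0
    psi: float = 1.0
    L: float = 10.0
    N: int = 128
    dt: float = 0.01
    boundary: str = "no_flux"  # or "periodic"

    def __post_init__(self) -> None:
        if self.boundary not in ("no_flux", "periodic"):
            raise ValueError("boundary must be 'no_flux' or 'periodic'")
        if self.N < 16:
            raise ValueError("N must be >= 16")
        dx = self.L / self.N
        dmax = max(self.DA, self.DP)
        if dmax > 0 and self.dt > dx**2 / (2.0 * dmax):
            raise ValueError(
                f"dt={self.dt} violates diffusive stability bound "
                f"{dx**2 / (2 * dmax):.4g} (dx={dx:.4g})"
            )

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def x(self) -> np.ndarray:
        """Cell-centered grid positions."""
        return (np.arange(self.N) + 0.5) * self.dx


@dataclass
class SpatialProfile:
    """Membrane concentration profiles A(x), P(x) plus derived pools."""

    x: np.ndarray
    A: np.ndarray
    P: np.ndarray
    rhoA: float
    rhoP: float
    psi: float

    @property
    def Abar(self) -> float:
        return float(self.A.mean())

    @property
    def Pbar(self) -> float:
        return float(self.P.mean())

    @property
    def Acyto(self) -> float:
        return self.rhoA - self.psi * self.Abar

    @property
    def Pcyto(self) -> float:
        return self.rhoP - self.psi * self.Pbar

    def check_admissible(self) -> None:
        if self.Acyto < -1e-9 or self.Pcyto < -1e-9:
            raise InadmissibleParameters(
                f"negative pool (Acyto={self.Acyto:.3g}, Pcyto={self.Pcyto:.3g})"
            )

    def total_mass(self) -> tuple[float, float]:
        """(total A, total P) per unit cytoplasmic volume: psi*mean + cyto."""
        return (self.psi * self.Abar + self.Acyto, self.psi * self.Pbar + self.Pcyto)

    def coarse_state(self) -> np.ndarray:
        """Two-compartment reduction (Aa, Ap, Pa, Pp) by half-domain means."""
        n = len(self.A) // 2
        return np.array([
            self.A[:n].mean(), self.A[n:].mean(),
            self.P[:n].mean(), self.P[n:].mean(),
        ])


def _laplacian(u: np.ndarray, dx: float, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return (np.roll(u, -1) - 2 * u + np.roll(u, 1)) / dx**2
    out = np.empty_like(u)
    out[1:-1] = (u[2:] - 2 * u[1:-1] + u[:-2]) / dx**2
    # zero-flux: ghost cells mirror the boundary cell
    out[0] = (u[1] - u[0]) / dx**2
    out[-1] = (u[-2] - u[-1]) / dx**2
    return out


def pde_step(profile: SpatialProfile, params: PdeParams, t: float,
             cue_rate: np.ndarray | float = 0.0) -> SpatialProfile:
    """One forward-Euler step of length ``params.dt`` at time ``t``.

    ``cue_rate`` may be a per-position array: a positive local rate removes
    aPAR from the membrane there and returns it to the cytoplasmic pool
    (local inhibition of aPAR, the generic guise of polarity cues).
    """
    A, P = profile.A, profile.P
    dx, dt = params.dx, params.dt
    Acyto = params.rhoA - params.psi * A.mean()
    Pcyto = params.rhoP - params.psi * P.mean()
    s = float(params.kAP_schedule(t))
    kAP = s * params.kAP
    dA = (params.DA * _laplacian(A, dx, params.boundary)
          + params.konA * Acyto - params.koffA * A
          - kAP * P**params.alpha * A
          - np.asarray(cue_rate) * A)
    dP = (params.DP * _laplacian(P, dx, params.boundary)
          + params.konP * Pcyto - params.koffP * P
          - params.kPA * A**params.beta * P)
    A2 = A + dt * dA
    P2 = P + dt * dP
    if np.any(A2 < 0) or np.any(P2 < 0):
        A2 = np.clip(A2, 0.0, None)
        P2 = np.clip(P2, 0.0, None)
    out = SpatialProfile(profile.x, A2, P2, params.rhoA, params.rhoP, params.psi)
    out.check_admissible()
    return out


def count_domains(values: np.ndarray, threshold: float | None = None,
                  min_width: int | None = None, periodic: bool = False) -> int:
    """Number of contiguous runs above threshold with length >= min_width.

    Defaults: threshold is half the spatial maximum, min_width 5% of the
    grid.  With ``periodic`` a run wrapping the boundary counts once.
    """
    values = np.asarray(values, dtype=float)
    if threshold is None:
        threshold = 0.5 * values.max()
    if min_width is None:
        min_width = max(1, int(0.05 * len(values)))
    above = values > threshold
    if not above.any():
        return 0
    if above.all():
        return 1
    if periodic:
        shift = int(np.argmin(above))  # rotate so a below-threshold cell starts
        above = np.roll(above, -shift)
    runs = []
    length = 0
    for a in above:
        if a:
            length += 1
        elif length:
            runs.append(length)
            length = 0
    if length:
        runs.append(length)
    return sum(1 for r in runs if r >= min_width)


def asi_of_profile(values: np.ndarray) -> float:
    """Asymmetry index (A - P) / [2 (A + P)] over the two half-domains.

    A is the summed signal over the anterior half (first half of the
    grid), P over the posterior half.  Ranges over [-0.5, 0.5].
    """
    values = np.asarray(values, dtype=float)
    n = len(values) // 2
    a = float(values[:n].sum())
    p = float(values[n:].sum())
    if a + p == 0:
        raise ZeroDivisionError("ASI undefined: total signal is zero")
    return (a - p) / (2.0 * (a + p))


def kap_schedule_from_trace(times, levels, floor: float = 0.05,
                            apply_to_kPA: bool = False) -> FeedbackSchedule:
    """Feedback schedule from a measured (or synthetic) pPAR effector trace.

    The trace is rescaled affinely so its maximum maps to multiplier 1
    (full kAP) and its minimum to ``floor``; breakpoints are the trace
    samples, linearly interpolated.  A constant trace maps to multiplier 1.
    """
    times = np.asarray(times, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(levels < 0):
        raise ValueError("levels must be >= 0")
    lo, hi = float(levels.min()), float(levels.max())
    if hi == lo:
        mult = np.ones_like(levels)
    else:
        mult = floor + (1.0 - floor) * (levels - lo) / (hi - lo)
    return FeedbackSchedule(tuple(zip(times, mult)), apply_to_kPA=apply_to_kPA)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named polarization scenario: initial condition, cue, schedule."""

    name: str  # "P1", "P2" or "zygote"
    initial: SpatialProfile
    schedule: FeedbackSchedule
    cue_rate: float = 0.0
    cue_window: tuple[float, float] = (0.0, 0.0)
    cue_profile: np.ndarray | None = None  # spatial weight in [0, 1]


@dataclass
class ScenarioResult:
    """Output cadence frames plus per-frame diagnostics."""

    times: np.ndarray
    profiles: list[SpatialProfile]
    asi_A: np.ndarray
    asi_P: np.ndarray
    n_domains_A: np.ndarray
    n_domains_P: np.ndarray

    @property
    def final(self) -> SpatialProfile:
        return self.profiles[-1]

    def final_class(self, dead_zone: float) -> str:
        return classify_quadrant(self.final.coarse_state(), dead_zone)

    def to_diagnostics_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times,
            "ASI_A": self.asi_A,
            "ASI_P": self.asi_P,
            "n_domains_A": self.n_domains_A,
            "n_domains_P": self.n_domains_P,
        })

    def to_profiles_frame(self):
        import pandas as pd

        rows = []
        for t, pr in zip(self.times, self.profiles):
            rows.append(pd.DataFrame({
                "time": t, "x": pr.x, "A": pr.A, "P": pr.P,
            }))
        return pd.concat(rows, ignore_index=True)


def run_pde(profile: SpatialProfile, params: PdeParams, t_end: float,
            cue_rate: float = 0.0, cue_window: tuple[float, float] = (0.0, 0.0),
            cue_profile: np.ndarray | None = None,
            output_every: float = 1.0) -> ScenarioResult:
    """Integrate to ``t_end`` recording frames every ``output_every`` time units."""
    profile.check_admissible()
    periodic = params.boundary == "periodic"
    n_steps = int(round(t_end / params.dt))
    rec_every = max(1, int(round(output_every / params.dt)))
    weight = np.ones(params.N) if cue_profile is None else np.asarray(cue_profile, dtype=float)

    times = [0.0]
    profiles = [profile]
    t = 0.0
    cur = profile
    for step in range(n_steps):
        rate = cue_rate * weight if (cue_rate > 0 and cue_window[0] <= t < cue_window[1]) else 0.0
        cur = pde_step(cur, params, t, cue_rate=rate)
        t += params.dt
        if (step + 1) % rec_every == 0 or step == n_steps - 1:
            times.append(t)
            profiles.append(cur)

    asi_A = np.array([asi_of_profile(p.A) if p.A.sum() > 0 else np.nan for p in profiles])
    asi_P = np.array([asi_of_profile(p.P) if p.P.sum() > 0 else np.nan for p in profiles])
    ndA = np.array([count_domains(p.A, periodic=periodic) for p in profiles])
    ndP = np.array([count_domains(p.P, periodic=periodic) for p in profiles])
    return ScenarioResult(np.array(times), profiles, asi_A, asi_P, ndA, ndP)


def run_scenario(spec: ScenarioSpec, params: PdeParams, t_end: float,
                 output_every: float = 1.0) -> ScenarioResult:
    """Run a named scenario (its schedule overrides the one in ``params``)."""
    params = replace(params, kAP_schedule=spec.schedule)
    return run_pde(spec.initial, params, t_end, cue_rate=spec.cue_rate,
                   cue_window=spec.cue_window, cue_profile=spec.cue_profile,
                   output_every=output_every)


def default_scenario(name: str, params: PdeParams,
                     oscillating: bool = True) -> ScenarioSpec:
    """Shipped P1 / P2 scenario constructors.

    P1: pPAR enriched throughout the membrane, aPAR mostly cytoplasmic with
    a small anterior contact bump; polarization requires a transient
    low-feedback window for aPARs to load.

    P2: inherited reversed polarity (aPAR domain at the prospective
    posterior); a cue at the contact end (x = L) locally suppresses
    aPAR membrane binding.  Under constant high feedback the old and new
    pPAR domains transiently coexist.
    """
    from .synth import make_scenario_profile

    low, t_lo, t_hi = 0.02, 0.0, 30.0
    if oscillating:
        sched = FeedbackSchedule(((t_lo, low), (t_hi, low), (t_hi + 5.0, 1.0)))
    else:
        sched = FeedbackSchedule.constant(1.0)
    if name == "P1":
        # birth state: pPAR everywhere, small aPAR bump at the anterior
        # contact; a posterior cue reinforces the initial bias
        initial = make_scenario_profile("uniform_P_high", params)
        return ScenarioSpec(name="P1", initial=initial, schedule=sched,
                            cue_rate=0.5, cue_window=(0.0, 40.0),
                            cue_profile=_posterior_weight(params))
    if name == "P2":
        # inherited reversed polarity; the EMS-contact cue at x = L must
        # re-orient the pattern
        initial = make_scenario_profile("reversed_polarized", params)
        return ScenarioSpec(name="P2", initial=initial, schedule=sched,
                            cue_rate=2.0, cue_window=(0.0, 40.0),
                            cue_profile=_posterior_weight(params))
    raise ValueError(f"unknown scenario {name!r}")


def _posterior_weight(params: PdeParams, width_frac: float = 0.2) -> np.ndarray:
    """Cue weight suppressing aPAR near the prospective posterior x = L."""
    x = params.x
    return np.exp(-0.5 * ((x - params.L) / (width_frac * params.L)) ** 2)
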