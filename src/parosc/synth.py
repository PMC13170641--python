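"""Synthetic data with known ground truth.

Everything the package quantifies can be generated here: embryo images
with a ring-like membrane of known cross-sectional Gaussian amplitude over
a cytoplasmic step and constant background; punctate cluster images with
known blob positions and intensities; cell-cycle-phased membrane-level
traces of pPAR effectors (low early, rising after mitotic entry, peaking
at NEBD, dropping at anaphase onset); and initial spatial profiles for the
P-lineage polarization scenarios.  All generators are pure functions of
their parameters and a seed, and every truth quantity is returned
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbryoTruth",
    "OscillationTruth",
    "anterior_high_amplitude",
    "make_embryo_image",
    "make_cluster_image",
    "make_oscillation_trace",
    "make_scenario_profile",
]


@dataclass(frozen=True)
class EmbryoTruth:
    """Geometry, intensity and noise ground truth for a synthetic embryo.

    The membrane is a Gaussian ridge along an ellipse; its height varies
    with the contour polar angle theta through ``amplitude_fn`` (a callable
    theta -> amplitude, or a constant).  Intensities are arbitrary units;
    lengths are pixels.  The default ellipse is 50 x 30 um at 0.155 um/px.
    """

    semi_a: float = 161.0  # px (25 um)
    semi_b: float = 97.0  # px (15 um)
    center: tuple[float, float] | None = None  # (row, col); default image center
    amplitude: object = 100.0  # constant or callable theta -> a.u.
    cyto: float = 30.0
    bg: float = 10.0
    membrane_sigma: float = 2.0  # ridge cross-section width, px
    edge_sigma: float = 2.0  # smoothness of the cytoplasmic step, px
    noise_sigma: float = 0.0
    seed: int = 0
    margin: float = 70.0  # px of padding beyond the ellipse
    pixel_size: float = 0.155  # um/px

    def amplitude_at(self, theta: np.ndarray) -> np.ndarray:
        if callable(self.amplitude):
            return np.asarray(self.amplitude(theta), dtype=float)
        return np.full_like(np.asarray(theta, dtype=float), float(self.amplitude))


@dataclass(frozen=True)
class OscillationTruth:
    """Phase landmarks and levels of a pPAR effector membrane trace."""

    t_condensation: float = 8.0
    t_nebd: float = 14.0
    t_anaphase: float = 18.0
    t_end: float = 24.0
    baseline: float = 1.0
    peak: float = 5.0
    decline_duration: float = 1.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_condensation < self.t_nebd < self.t_anaphase <= self.t_end):
            raise ValueError("phase times must be increasing and positive")


def _ellipse_contour(truth: EmbryoTruth, n: int) -> np.ndarray:
    """(n, 2) array of (row, col) points on the ellipse, anticlockwise in
    image coordinates, starting at theta=0 (the +col axis)."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    if truth.center is None:
        c = (truth.semi_b + truth.margin, truth.semi_a + truth.margin)
    else:
        c = truth.center
    rows = c[0] + truth.semi_b * np.sin(theta)
    cols = c[1] + truth.semi_a * np.cos(theta)
    return np.column_stack([rows, cols])


def make_embryo_image(truth: EmbryoTruth, roi_points: int = 200):
    """Render a synthetic embryo image.

    Returns ``(image, roi, amplitude_truth)``: the 2D float image, an
    (roi_points, 2) closed (row, col) polyline tracing the membrane ridge
    center, and the ground-truth Gaussian ridge amplitude at each ROI
    vertex.  Image model per pixel: ``bg + cyto * inside`` (an erf-smoothed
    indicator) ``+ amplitude(theta) * exp(-d^2 / (2 sigma_m^2))`` plus
    i.i.d. Gaussian noise, where d is the distance to the ridge center.
    """
    from matplotlib.path import Path as MplPath
    from scipy.spatial import cKDTree

    if truth.center is None:
        center = (truth.semi_b + truth.margin, truth.semi_a + truth.margin)
    else:
        center = truth.center
    h = int(np.ceil(center[0] + truth.semi_b + truth.margin))
    w = int(np.ceil(center[1] + truth.semi_a + truth.margin))
    if (center[0] - truth.semi_b < 5) or (center[1] - truth.semi_a < 5):
        raise ValueError("ellipse does not fit in the frame with margin")

    dense = _ellipse_contour(truth, 4096)
    tree = cKDTree(dense)
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    dist, nearest = tree.query(pts, workers=-1)
    theta_near = np.arctan2(dense[nearest, 0] - center[0], dense[nearest, 1] - center[1])
    inside = MplPath(dense[::8]).contains_points(pts)
    signed = np.where(inside, dist, -dist)

    from scipy.special import erf

    cyto_step = 0.5 * (1.0 + erf(signed / (np.sqrt(2) * truth.edge_sigma)))
    ridge = truth.amplitude_at(theta_near) * np.exp(-dist**2 / (2 * truth.membrane_sigma**2))
    img = truth.bg + truth.cyto * cyto_step + ridge
    img = img.reshape(h, w)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        img = img + truth.noise_sigma * rng.standard_normal(img.shape)

    roi = _ellipse_contour(truth, roi_points)
    theta_roi = np.arctan2(roi[:, 0] - center[0], roi[:, 1] - center[1])
    amp_truth = truth.amplitude_at(theta_roi)
    return img, roi, amp_truth


def anterior_high_amplitude(amp_high: float = 100.0, amp_low: float = 0.0,
                            softness: float = 8.0):
    """Angular amplitude function: high on the anterior half (|theta| > pi/2,
    i.e. the -col side), smoothly dropping to ``amp_low`` posteriorly."""

    def fn(theta):
        # anterior = cos(theta) < 0
        s = 1.0 / (1.0 + np.exp(softness * np.cos(theta)))
        return amp_low + (amp_high - amp_low) * s

    return fn


def make_cluster_image(
    n: int,
    shape: tuple[int, int] = (256, 256),
    positions: np.ndarray | None = None,
    intensities: np.ndarray | float = 50.0,
    sizes: np.ndarray | float = 2.0,
    bg: float = 10.0,
    noise_sigma: float = 5.0,
    min_separation: float = 15.0,
    border: float = 12.0,
    seed: int = 0,
):
    """Image of 2D Gaussian spots plus constant background and noise.

    Returns ``(image, truth)`` where truth is a dict of arrays with keys
    ``row``, ``col``, ``sigma``, ``peak`` and ``integrated`` (the analytic
    2 pi sigma^2 peak).  Random positions are rejection-sampled to honour
    ``min_separation`` (the well-separated benchmark geometry).
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        pos = []
        attempts = 0
        while len(pos) < n:
            cand = border + rng.random(2) * (np.array(shape) - 2 * border)
            if all(np.hypot(*(cand - p)) >= min_separation for p in pos):
                pos.append(cand)
            attempts += 1
            if attempts > 10000 * max(n, 1):
                raise RuntimeError("could not place spots with requested separation")
        positions = np.array(pos).reshape(-1, 2)
    else:
        positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        n = len(positions)
    peaks = np.broadcast_to(np.asarray(intensities, dtype=float), (n,)).copy()
    sig = np.broadcast_to(np.asarray(sizes, dtype=float), (n,)).copy()

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, float(bg))
    for (r0, c0), pk, s in zip(positions, peaks, sig):
        img += pk * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2))
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(shape)
    truth = {
        "row": positions[:, 0],
        "col": positions[:, 1],
        "sigma": sig,
        "peak": peaks,
        "integrated": 2 * np.pi * sig**2 * peaks,
    }
    return img, truth


def make_oscillation_trace(truth: OscillationTruth, dt: float = 0.25):
    """Cell-cycle-phased membrane-level trace of a pPAR effector.

    Piecewise-linear: baseline until chromosome condensation, rise to the
    peak at NEBD, held through metaphase, sharp decline at anaphase onset
    back to baseline.  Returns ``(times, levels, marks)`` where marks is a
    dict of the phase times (so schedules derived from the trace can be
    validated against the generator's landmarks).
    """
    times = np.arange(0.0, truth.t_end + dt / 2, dt)
    knots_t = [0.0, truth.t_condensation, truth.t_nebd, truth.t_anaphase,
               min(truth.t_anaphase + truth.decline_duration, truth.t_end), truth.t_end]
    knots_v = [truth.baseline, truth.baseline, truth.peak, truth.peak,
               truth.baseline, truth.baseline]
    levels = np.interp(times, knots_t, knots_v)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        levels = np.clip(levels + truth.noise_sigma * rng.standard_normal(levels.shape), 0.0, None)
    marks = {
        "condensation": truth.t_condensation,
        "nebd": truth.t_nebd,
        "anaphase": truth.t_anaphase,
    }
    return times, levels, marks


def make_scenario_profile(kind: str, params, p_high: float = 1.5,
                          bump_amp: float = 0.3, bump_width_frac: float = 0.1,
                          a_high: float = 1.5):
    """Initial spatial profiles for the P-lineage scenarios.

    ``uniform_P_high``: pPAR enriched throughout the membrane with a small
    aPAR bump at the contact end x=0 (the P1 birth state).
    ``contact_A_bump``: only the aPAR contact bump.
    ``reversed_polarized``: inherited reversed polarity — aPAR high toward
    x=L, pPAR high toward x=0 (the P2 birth state; the EMS cue then acts
    at x=L).
    """
    from .pde import SpatialProfile

    x = params.x
    L = params.L
    w = bump_width_frac * L
    bump = bump_amp * np.exp(-0.5 * (x / w) ** 2)
    if kind == "uniform_P_high":
        A = bump
        P = np.full_like(x, p_high)
    elif kind == "contact_A_bump":
        A = bump
        P = np.zeros_like(x)
    elif kind == "reversed_polarized":
        s = 1.0 / (1.0 + np.exp(-(x - 0.5 * L) / (0.05 * L)))
        A = a_high * s
        P = p_high * (1.0 - s)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    prof = SpatialProfile(x, A, P, params.rhoA, params.rhoP, params.psi)
    prof.check_admissible()
    return prof
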