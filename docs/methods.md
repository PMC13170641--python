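# Methods

Model equations, default parameters, numerical choices and limitations of
`parosc`.

## Two-compartment ODE model (`parosc.ode`)

Two membrane species A (anterior, aPAR) and P (posterior, pPAR) occupy an
anterior and a posterior membrane compartment and exchange with
well-mixed cytoplasmic pools. States are the four membrane concentrations
(Aa, Ap, Pa, Pp):

```
dAa/dt = D̃ (Ap − Aa) + kon Acyto − koff Aa − kAP Pa^α Aa  [+ cue Ap]
dAp/dt = D̃ (Aa − Ap) + kon Acyto − koff Ap − kAP Pp^α Ap  [− cue Ap]
dPa/dt = D̃ (Pp − Pa) + kon Pcyto − koff Pa − kPA Aa^β Pa
dPp/dt = D̃ (Pa − Pp) + kon Pcyto − koff Pp − kPA Ap^β Pp
```

with mass-conserving pools `Acyto = ρA − ψ (Aa + Ap)/2` and likewise for
P. The antagonism terms knock the opposing species off the membrane into
its pool, so total A and total P are conserved separately. A
`FeedbackSchedule` is a piecewise-linear multiplier on `kAP` (optionally
also on `kPA`), modeling cell-cycle-dependent pPAR-side feedback; a `Cue`
redistributes A from the posterior to the anterior compartment at a
first-order rate over a time window — it conserves A and represents a
generic, weak, A-favoring spatial signal.

**Defaults** (all rates in arbitrary reciprocal time units): `D̃ = 0.1`,
`kon = koff = 1`, `α = β = 2`, `ρA = ρP = 2`, `ψ = 1`. Two shipped
regimes: `high_feedback` (`kAP = kPA = 20`) and `low_feedback`
(`kAP = 0.1, kPA = 20`). The high-feedback values were calibrated, once,
by a numerical sweep to the smallest symmetric antagonism strength at
which the model is robustly multistable with exactly four stable
states — uniform-A, uniform-P and the two polarized states — plus a
central unstable coexistence state; the stable count decreases
monotonically as `kAP` is lowered, reaching a single uniform-A state in
the `low_feedback` regime. These are behavior-calibrated study
conditions, not fitted quantities.

Steady states are enumerated by multi-start root finding (`scipy` hybrid
Powell) from a deterministic grid; roots are kept by residual (not by the
solver's success flag, which can be false at an already-converged point),
deduplicated, and classified by the eigenvalues of the analytic Jacobian.
Polarity classes are quadrants of the difference plane
(Aa − Pa, Ap − Pp) with a dead zone of 1 % of the feedback-free uniform
balance `kon ρ / (koff + kon ψ)`; states inside the dead zone are
`UNDEFINED`. Trajectories use LSODA (`rtol 1e-8`, `atol 1e-10`) with the
time axis segmented at schedule breakpoints and cue edges so the
integrator never steps across a kink.

The switching matrix (`run_state_switching_matrix`) runs a transient cue
against all four initial attractors under three regimes: constant high
feedback, constant low feedback, and an oscillating schedule whose
low-feedback window overlaps the cue. The cue deliberately persists a few
time units past the feedback ramp-up so the restored antagonism locks in
the cue-selected state.

## One-species wave-pinning model (`parosc.wavepin`)

A single species X in two compartments with cooperative self-recruitment:

```
dXa/dt = D̃ (Xp − Xa) + kon Xcyto − koff Xa + γ Xcyto Xa^n / (K^n + Xa^n)
```

(mirrored for Xp), `Xcyto = ρX − ψ (Xa + Xp)/2`. The membrane detachment
term enters with a negative sign (first-order removal). **Defaults**
`D̃ = 0.01, kon = 0.1, koff = 1, γ = 2, K = 2, n = 2, ρX = 3, ψ = 1` were
calibrated, once, to the bistable regime: two mirror-image polarized
attractors and an unstable symmetric state (the antisymmetric mode of the
symmetric state is unstable when `γ Xcyto h′(X*) > koff + 2 D̃`). The
feedback-schedule multiplier scales `γ`; the cue moves X from Xp to Xa.

## Landscapes and Fokker–Planck (`parosc.landscape`)

Stochastic dynamics are simulated with Euler–Maruyama: additive noise of
amplitude σ per component, reflection at zero (absolute value), default
`dt = 0.005` with a drift-per-step sanity warning. Ensembles start
round-robin on the stable attractors so every well is populated. Sampled
4D states are projected onto (Aa − Pa, Ap − Pp) and binned; the
quasipotential is `U = −ln(density)`, shifted to minimum zero, with NaN
(not a fabricated barrier) in unoccupied bins. The default
`sigma = 0.05` resolves the high-feedback wells without washing them out.

Quiver fields need a lift from the 2D plane back to 4D because the
projection is degenerate. The default lift evaluates the deterministic
velocity on the symmetric section `Aa + Pa = Ap + Pp = S` with S the mean
compartment sum over the stable attractors (clipped at zero); optionally
the lift is resolved empirically by averaging projected velocities of
supplied samples per bin.

For the one-species model the stationary Fokker–Planck equation
`0 = −∇·(f p) + (σ²/2) Δp` is solved directly on `[0, 2ρX/ψ]²` with a
finite-volume Scharfetter–Gummel discretization and zero-flux boundaries;
the singular system is closed by a normalization row. The scheme
reproduces the Boltzmann density `exp(−2V/σ²)` exactly for 1D gradient
drift, and its 2D output is validated against the sampled histogram in
total variation.

## Spatial PDE model (`parosc.pde`)

On `x ∈ [0, L]` (cell-centered grid, no-flux or periodic boundaries):

```
∂t A = DA ∂x²A + konA Acyto − koffA A − kAP(t) P^α A  [− cue(x, t) A]
∂t P = DP ∂x²P + konP Pcyto − koffP P − kPA A^β P
```

with well-mixed pools `Acyto = ρA − ψ Ā` (Ā the spatial mean). The cue is
a per-position first-order removal of membrane A returning it to the
pool — local inhibition of aPAR membrane binding, the generic form of both
germline cues. `kAP(t)` follows a `FeedbackSchedule`; a schedule can also
be derived from a measured or synthetic effector trace
(`kap_schedule_from_trace`, affine rescaling of the trace to multiplier
`[floor, 1]`).

**Defaults** `DA = DP = 0.1`, rates as in the ODE model with
`kAP = kPA = 20`, `L = 10`, `N = 128`, `dt = 0.01`. Integration is
explicit forward Euler with central differences; the constructor enforces
the diffusive stability bound `dt ≤ dx²/(2 max(DA, DP))`. Forward Euler
is first order (verified by dt-halving self-convergence) and is chosen
because the dynamic schedule introduces kinks that defeat higher-order
smoothness assumptions, and the stable dt needed for accuracy is cheap at
this grid size.

Diagnostics: per-frame domain count (contiguous runs above half the
spatial maximum, minimum width 5 % of the grid, with wrap-around handling
for periodic domains), asymmetry index over half-domains, and a
coarse-grained polarity class from half-domain means.

Shipped scenarios: **P1** starts from a uniformly pPAR-loaded membrane
with a small aPAR contact bump and a posterior cue — polarization requires
the low-feedback window for aPARs to load. **P2** starts from an
inherited, reversed polarized profile with a strong cue at the contact
end `x = L` — under constant high feedback the old and the cue-induced
pPAR domains transiently coexist (a two-domain frame), while the
oscillating schedule reverses cleanly. The oscillating schedule holds the
multiplier at 0.02 until t = 30 and ramps to 1 by t = 35; cue windows are
(0, 40) with rates 0.5 (P1) and 2.0 (P2), Gaussian-weighted (width 0.2 L)
at the cue pole. These were calibrated once to exhibit the qualitative
regime difference and then frozen.

## Image quantification (`parosc.imaging`)

The membrane pipeline straightens a 100-pixel-wide (15.5 µm at
0.155 µm/px) band following a closed contour: the contour is resampled at
1 px arc length, outward normals come from a circularly smoothed tangent,
and the band is sampled with cubic spline interpolation — bilinear
interpolation visibly attenuates a ridge only ~2 px wide (median
amplitude error ~2 % versus ~0.06 % for cubic on noise-free synthetic
embryos). Profiles are smoothed with a circular 20-sample rolling average
along the contour, and each cross-membrane profile is fit
(`scipy.optimize.curve_fit`) to

```
bg + cyto · ½(1 + erf((i − µ)/(√2 σ))) + amplitude · exp(−(i − µ)²/2σ²)
```

— constant background, an error-function step rising toward the
cytoplasmic side, and a Gaussian membrane peak (widths shared by
default). The Gaussian amplitude is the membrane concentration.
Non-convergent fits yield NaN rather than raising.

ASI is `(A − P) / [2 (A + P)]` over half-contours, ranging over
[−0.5, 0.5]. Alignment of repeated profiles uses FFT circular
cross-correlation of mean-subtracted profiles against the running mean,
accepting only non-worsening moves (so the recorded MSE history is
non-increasing); between-embryo alignment additionally tries both
traversal orientations, with orientation meaningful relative to the
consensus frame. Cluster quantification applies difference-of-Gaussians
background subtraction followed by multiscale Laplacian-of-Gaussian
detection (`skimage.feature.blob_log`, relative threshold 0.2 calibrated
on seeded synthetic benchmarks for precision = recall = 1 at SNR 5);
per-cluster intensity integrates the background-subtracted image over a
disk of radius twice the blob scale, and the summary statistic is summed
intensity per cell area.

## Synthetic generators (`parosc.synth`)

Pure functions of parameters and a seed; every truth quantity is returned
with the data. Embryo images: Gaussian ridge (σ = 2 px) along an ellipse
(default 50 × 30 µm at 0.155 µm/px) with angle-dependent amplitude, an
erf-smoothed cytoplasmic step and constant background, plus i.i.d.
Gaussian noise; SNR is defined as membrane amplitude over noise σ.
Cluster images: well-separated (≥ 15 px) Gaussian spots with analytic
integrated intensity `2π σ² · peak`. Effector traces: piecewise-linear
cell-cycle phase logic (baseline → rise from chromosome condensation →
peak at nuclear-envelope breakdown → held → sharp decline at anaphase
onset), with the phase landmarks returned for schedule validation.
Scenario profiles: the P1 and P2 initial conditions described above.

## Limitations

- Parameters are behavior-calibrated defaults in arbitrary units, not
  fits to measured rate constants; quantitative time scales are not
  comparable to experiments.
- The two-compartment reduction has no notion of domain boundaries; the
  1D PDE has no membrane flow/advection term and uses well-mixed pools.
- The stochastic model uses additive noise with reflection at zero, not a
  chemical Langevin or particle-level description; quasipotentials are
  occupancy-based and depend on σ and sampling, not on a
  Freidlin–Wentzell action.
- The quiver lift on the symmetric section is a visualization convention;
  off-section states project onto the same bins.
- Synthetic images use Gaussian noise without a PSF or shot-noise model,
  sufficient for the stated recovery claims only.
- The imaging pipeline assumes a closed, star-shaped, non-self-intersecting
  contour traced well inside the image frame.
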