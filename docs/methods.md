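# Methods

This note documents the model, the numerical scheme, the parameter
choices and their rationale, and what the synthetic landscape does and
does not establish about the real molecule.

## Units

Energies in eV, lengths in Å, times in fs, linear masses in amu and
angular inertias in amu·Å²; angles are degrees at every interface and
radians internally. One constants module holds the conversions:
1 amu·Å²/fs² = 103.6427 eV and ħ = 0.6582120 eV·fs. Engine-internal
masses are pre-multiplied by the kinetic-energy conversion so forces in
eV/Å divide by mass to give accelerations directly.

## The model landscape

Coordinates are `(r_CC, φ_OOCC, φ_CCCC, b₁…b_m)` with m = 3 harmonic
bath modes by default. The electronic basis holds 4 singlets and 4
triplets × 3 S_z sublevels (16 states), ordered singlets-first and then
sublevels grouped by S_z — the ordering of published transition-count
tables for this system.

Every state shares a common nuclear profile: a C–C Morse well (depth
0.8 eV at r₀ = 1.55 Å, range parameter tuned so the well-bottom period is
40 fs, matching the observed C–C oscillation), torsional potentials
`k(1 − cos(φ − φ₀))` weak enough that the dihedrals are nearly free
rotors on the simulation timescale, harmonic bath modes, and an
exothermic logistic tail that lowers all surfaces by 1.5 eV past
r_CC ≈ 2.25 Å. The tail encodes that the decomposition is strongly
exothermic: the committed point of the ground-state exit lies at
r ≈ 1.96 Å, *before* the 2.4 Å van der Waals distance used for product
labeling, so a trajectory that crosses 2.4 Å always carries large outward
momentum and can never be recaptured. Without the tail (a plain Morse
exit) recrossings at ~10 meV margins occasionally relabeled products
after the fact, which the real system's phenomenology forbids.

On top of the shared profile each state adds:

* **In-trap offsets.** Inside a logistic window (center 1.95 Å, width
  0.08 Å) the eight parent states are nearly degenerate, spread over
  30 meV and modulated by ±15 meV sinusoids of φ_OOCC with per-parent
  phases. The modulation makes the levels sweep through avoided
  crossings as the dihedral drifts — this is what renders the trap
  "entropic": hopping is promiscuous there (tens of hops per trajectory)
  because the diagonal basis keeps rotating. The window itself depends
  only on r_CC.
* **Asymptotic offsets.** Outside the trap the states split to their
  product energies: S1 +0.20, T1 +0.12, T2 +0.90 eV, while S2/S3/T3/T4
  sit 2.0–3.5 eV up so their dissociation channels are closed at the
  3.96 eV launch energy (their yields are zero, as observed; T3/T4 are
  additionally excluded as hop targets). Triplet sublevels differ by
  0.5 meV per S_z unit — resolvable but far inside the guaranteed
  degeneracy bound ε_z = 2 meV.
* **Dissociation ridges.** Every excited state carries a Gaussian bump
  (height 0.35 eV, σ = 0.12 Å) centered at 2.16 Å, the crossing geometry
  observed for the real surfaces. Combined with the exothermic tail this
  puts exactly one interior barrier maximum on each excited surface near
  2.09 Å (inside the required [2.0, 2.3] window), while the ground
  singlet has none between 2.1 and 2.4 Å.
* **Couplings.** Spin–orbit matrix elements are constants: 10 meV
  between singlets and S_z = ±1 triplet sublevels, 2 meV between
  sublevels of unequal S_z. The singlet–triplet block is damped to zero
  at 2.2 Å — intersystem crossing is a biradical-region interaction and
  must be extinct before the labeling distance — while the intra-triplet
  mixing survives to 3.55 Å, so sublevel hops continue after the bond
  cleaves but can never change the collapsed product label. Nonadiabatic
  couplings act between adjacent states of equal multiplicity and S_z,
  Gaussian-localized in r_CC (amplitude 0.5 Å⁻¹, center 1.95 Å,
  σ = 0.18 Å), which funnels outgoing excited-singlet population
  downward across the exit region.
* **Intramolecular energy flow.** The bath modes couple bilinearly to
  the stretch through g(r) = (r − r₀)·exp(−((r − r₀)/0.35 Å)²) with
  strength 3.0 eV/Å² and periods 38/44/52 fs bracketing the C–C
  resonance. Without this, the C–C kinetic energy would be frozen at its
  sampled value and most trajectories could never dissociate; with it,
  ~95 % dissociate within 2000 fs and the ensemble half-time lands near
  190 fs, the regime reported for the real molecule. The Gaussian
  localization makes the coupling vanish outside the well, so the
  asymptotic region is clean.

The magnitudes of the spin–orbit couplings are order-of-magnitude
choices (none are published for this molecule) and are configurable, as
is every number above.

## Initial conditions

All trajectories start from one geometry (r_CC = 1.60 Å,
φ_OOCC = 135.8°, φ_CCCC = 180°, baths at rest) — the surrogate for the
rate-controlling O–O transition state. Velocities are sampled per
coordinate from the Boltzmann distribution at 300 K, rescaled globally so
the kinetic energy is exactly 3.96 eV (treated as a plain input; its
decomposition into zero-point and correlation parts is out of scope), and
the component along the designated reaction mode (the first bath
coordinate, standing in for the O–O product direction) is made positive
by sign flip — mirroring preserves the forward marginal and wastes no
samples; rejection is available by flag. Rescaling is global rather than
per-mode, matching the single-energy statement of the protocol.

## The propagation scheme

Per 0.5 fs step: (1) velocity-Verlet on the active eigensurface, with the
gradient from central differences (step 10⁻⁴) of the batch-diagonalized
eigenvalues — the surfaces are analytic in the spin-free basis but not in
the diagonal one; (2) eigendecomposition at the new geometry with phases
aligned to the previous step; (3) coefficients advanced in the diagonal
basis under `H_eff(τ) = diag(E(τ)) − iħT` with
`T = (S − Sᵀ)/2Δt + U†(v·d)U` from the overlap matrix S and the model's
coupling vectors, using 25 split-operator substeps (exact phase factors
interleaved with the constant orthogonal rotation `exp(−T δt)`; unitary
to machine precision); (4) fewest-switches hop probabilities accumulated
over substeps as `max(0, 2 Re(c_a* T_ak c_k) δt)/|c_a|²`, hop targets
masked when their dominant spin-free character is T3/T4; (5) accepted
hops rescale the velocity along the nonadiabatic-coupling direction when
one exists for the state pair (full-velocity fallback otherwise,
recorded), conserving total energy exactly; insufficient directed kinetic
energy frustrates the hop (no velocity reversal by default); (6)
energy-based decoherence with `τ_k = ħ/|ΔE_k|·(1 + C/E_kin)`,
C = 2.72 eV.

**Trivial crossings.** When two essentially uncoupled surfaces cross
between samples, the energy-sorted active index silently changes
character and the delta-like coupling spike cannot be resolved at finite
Δt. The engine detects this through the overlap matrix (active-state
self-overlap² < 1/2) and follows the diabatic character deterministically,
provided the two sorted energies agree to 0.05 eV; no stochastic hop is
rolled on such a step. Without this guard, a zero-SOC ensemble leaked
singlet population into triplets at every exact S/T crossing — a pure
discretization artifact that would break spin conservation.

A trajectory fails (`failed_energy`) if its total energy drifts more than
0.2 eV from launch; the published protocol's failure criterion is also
energy conservation, and the surrogate's failure rate stays below the
few-percent level reported there. The electronic-integrator substep count
and the drift threshold are assumptions (the protocol does not state
them) and are configurable.

## Analysis conventions

* Dissociation time: first *sample* with r_CC strictly above 2.4 Å; no
  interpolation — this quantization is what makes half-fs dissociation
  times and quarter-fs medians possible.
* Product label: collapsed spin-free label at that sample. The engine
  records (rather than enforces) that the collapsed label never changes
  afterwards; the test suite asserts it over whole ensembles.
* Transition counts: an N-sample state series yields N − 1 transitions;
  residence = diagonal + off-diagonal column sum (destination
  convention: the first sample belongs to no state), times Δt.
* Frustrated dissociations: strict interior maxima of r_CC(t) with
  prominence ≥ 0.05 Å (suppresses integrator jitter; the published count
  was visual), windowed to before dissociation. The mean oscillation
  period is window/peaks.
* Dihedral unwrapping: successive differences mapped to (−180°, 180°];
  the angle variation is |unwrapped final − initial|.
* Half-time: sample median with the even-count midpoint convention — the
  only definition consistent with quarter-fs printed values.
* Populations: per time-grid point, the fraction of completed
  trajectories whose active state maps to each basis state
  (collapsed-MCH, full-MCH or diagonal); after a trajectory terminates
  its state is frozen at the product label, so the late-time collapsed
  populations equal the quantum yields by construction. The freezing
  convention is an assumption.
* Equilibrium detection: earliest grid time from which every state stays
  within tolerance of its final value, required to hold for a trailing
  window; persistently fluctuating series (the triplet S_z sublevels)
  return none.
* 2-D histograms: right-open bins, last bin closed, shared-edge points
  to the higher bin. Default bins (100 fs × 10°; 0.5 °/fs for angular
  velocities) are configurable; none were published.
* RLSE: closed global ranges; a state touching an endpoint has zero
  empty length there.

## Problem sizes

The test suite exercises ensembles of 10–40 trajectories at 400–800 fs
horizons and validates the integrators against closed forms (harmonic
period to 0.5 %, Rabi transfer to 10⁻⁶, norm to 10⁻⁸ over 10⁴ steps,
quadratic drift scaling); ensemble-level claims about the real molecule
(absolute yields, 4200 fs equilibration) are represented by structural
invariants, not numerical matches. A full 310-trajectory run at a
2000 fs horizon completes in roughly a quarter hour on one CPU via
`dioxhop simulate`.

## What the surrogate shows — and does not

Passing tests establish that the surface-hopping machinery is correct
(energy/norm conservation, exact-limit behavior, spin conservation
without spin–orbit coupling, determinism) and that the analysis
operations reproduce every printed worked number from its printed
inputs. They do not establish quantitative fidelity to the CASSCF
surfaces: the surrogate's yields (~50–60 % S0, ~25–50 % T1, few-percent
S1) and time scales are in the reported regime by construction of the
landscape, not by fit, and its reduced dimensionality omits
anharmonic-mode coupling, rotational effects and geometry-dependent
spin–orbit couplings of the real biradical.

## Known limitations

* The diagonal-basis gradient is obtained from eigenvalue differences;
  at near-degeneracies inside the trap it is only piecewise smooth, which
  is the main source of the residual energy drift.
* Post-cleavage S_z-sublevel hopping is present but rarer than in the
  real system, where geometry-dependent couplings keep mixing the
  sublevels along the whole exit path.
* Timeouts (trajectories still trapped at t_max) are counted as failures
  in the binary ensemble bookkeeping but are censoring, not integrator
  errors; yields condition on completion.
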