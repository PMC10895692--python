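"""Fewest-switches surface hopping with spin-orbit coupling.

Dynamics run in the *diagonal* representation: at every geometry the total
electronic Hamiltonian H_total = H_MCH + H_SOC is diagonalized and the
nuclei move on one of its eigensurfaces.  Electronic coefficients are
propagated in that basis with time-derivative couplings obtained from
successive eigenvector overlaps (local-diabatization flavor) plus the
declared nonadiabatic-coupling terms; stochastic hops follow the
fewest-switches prescription, momenta are adjusted along the projected
coupling direction at accepted hops, and an energy-based decoherence
correction damps coherences between surfaces.

Numerical scheme per nuclear time step (default 0.5 fs):

1. velocity-Verlet update of the nuclei on the active eigensurface, with
   the gradient from central differences of the eigenvalues;
2. eigendecomposition at the new geometry, phase-aligned to the previous
   step; the overlap matrix gives the time-derivative coupling
   T = (S - S^T) / (2 dt), augmented with v . d terms from the model's
   NAC vectors transformed into the diagonal basis;
3. sub-stepped unitary propagation of the coefficients under
   H_eff(tau) = diag(E(tau)) - i hbar T (split-operator: exact phases
   interleaved with the constant orthogonal rotation exp(-T dt_sub)),
   accumulating fewest-switches hop probabilities along the way;
4. hop decision, momentum rescaling (hops with insufficient kinetic
   energy along the rescaling direction are *frustrated* and rejected);
5. energy-based decoherence correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .constants import HBAR
from .model import ConfigurationError, ModelSystem
from .sampling import InitialConditions, SamplingParams, sample_initial_conditions
from .states import SpinStateLabel, parse_label


class PropagationError(RuntimeError):
    """Non-finite gradient or electronic norm loss during propagation."""


class DegenerateStateError(ValueError):
    """The active state carries no population."""


@dataclass(frozen=True)
class EngineParams:
    """Integrator and protocol parameters (times fs, energies eV, lengths A)."""

    dt: float = 0.5
    electronic_substeps: int = 25
    t_max: float = 2000.0
    r_dissoc: float = 2.4
    r_terminate: float = 3.7
    decoherence_c: float = 2.72          # 0.1 hartree, energy-based decoherence
    energy_drift_tolerance: float = 0.2
    frustrated_reversal: bool = False
    gradient_step: float = 1.0e-4
    hop_mask: tuple[str, ...] | None = None   # None -> model default (T3/T4 off)

    @classmethod
    def from_dict(cls, data: Mapping[str, object] | None) -> "EngineParams":
        data = dict(data or {})
        known = {f.name for f in dc_fields(cls)}
        for key in data:
            if key not in known:
                raise ConfigurationError(f"unknown engine parameter: {key!r}")
        if "hop_mask" in data and data["hop_mask"] is not None:
            data["hop_mask"] = tuple(str(x) for x in data["hop_mask"])  # type: ignore[arg-type]
        params = cls(**data)  # type: ignore[arg-type]
        if params.dt <= 0:
            raise ConfigurationError("engine parameter 'dt' must be > 0")
        if params.electronic_substeps < 1:
            raise ConfigurationError("engine parameter 'electronic_substeps' must be >= 1")
        if params.r_terminate <= params.r_dissoc:
            raise ConfigurationError("'r_terminate' must exceed 'r_dissoc'")
        return params


@dataclass(frozen=True)
class HopEvent:
    t: float
    from_diag: int
    to_diag: int
    from_mch: SpinStateLabel
    to_mch: SpinStateLabel
    frustrated: bool
    used_fallback_direction: bool = False


@dataclass
class TrajectoryRecord:
    """Per-step time series plus hop events and termination status.

    ``steps`` columns are stored as parallel numpy arrays of equal length;
    ``active_mch`` holds indices into ``labels``.
    """

    labels: list[SpinStateLabel]
    t: np.ndarray
    q: np.ndarray                # (n, d)
    v: np.ndarray                # (n, d)
    active_diag: np.ndarray      # (n,) int
    active_mch: np.ndarray       # (n,) int index into labels
    e_active: np.ndarray         # (n,) eV
    e_total: np.ndarray          # (n,) eV
    r_cc: np.ndarray
    phi_oocc: np.ndarray
    phi_cccc: np.ndarray
    hops: list[HopEvent]
    status: str                  # 'dissociated' | 'timed_out' | 'failed_energy'
    product_mch: SpinStateLabel | None
    dissociation_time: float | None
    initial: InitialConditions | None = None
    label_consistent: bool = True
    dt: float = 0.5

    @property
    def n_steps(self) -> int:
        return len(self.t)

    @property
    def mch_series(self) -> list[SpinStateLabel]:
        return [self.labels[i] for i in self.active_mch]


# --- elementary operations -------------------------------------------------

def propagate_nuclei(q, v, gradient, masses, dt):
    """One velocity-Verlet position half: returns the predicted position.

    ``gradient`` is dV/dq of the active surface at ``q`` (eV per coordinate
    unit); ``masses`` are engine-unit masses.  The velocity update needs the
    gradient at the new position and is completed by
    :func:`complete_velocity_step`.
    """
    gradient = np.asarray(gradient, dtype=float)
    if not np.all(np.isfinite(gradient)):
        raise PropagationError("non-finite gradient on the active surface")
    a = -gradient / masses
    return q + v * dt + 0.5 * a * dt * dt, a


def complete_velocity_step(v, a_old, gradient_new, masses, dt):
    gradient_new = np.asarray(gradient_new, dtype=float)
    if not np.all(np.isfinite(gradient_new)):
        raise PropagationError("non-finite gradient on the active surface")
    a_new = -gradient_new / masses
    return v + 0.5 * (a_old + a_new) * dt, a_new


def verlet_step(q, v, grad_fn, masses, dt):
    """One full velocity-Verlet step on a surface with gradient ``grad_fn(q)``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    q_new, a = propagate_nuclei(q, v, grad_fn(q), masses, dt)
    v_new, _ = complete_velocity_step(v, a, grad_fn(q_new), masses, dt)
    return q_new, v_new


def propagate_electronic(coeffs, h_start, h_end, dt, substeps=25):
    """Advance coefficients under the linearly interpolated Hamiltonian.

    ``h_start``/``h_end`` are complex Hermitian matrices in the propagation
    basis (they may contain -i*hbar*T nonadiabatic terms, which keep them
    Hermitian for antisymmetric real T).  Each substep applies the exact
    exponential of the midpoint-interpolated matrix.
    """
    c = np.asarray(coeffs, dtype=complex).copy()
    norm0 = float(np.vdot(c, c).real)
    if abs(norm0 - 1.0) > 1e-8:
        raise ValueError(f"coefficients must be normalized, got |c|^2 = {norm0}")
    h0 = np.asarray(h_start, dtype=complex)
    h1 = np.asarray(h_end, dtype=complex)
    dts = dt / substeps
    for j in range(substeps):
        frac = (j + 0.5) / substeps
        h = (1.0 - frac) * h0 + frac * h1
        w, u = np.linalg.eigh(h)
        phases = np.exp(-1j * w * dts / HBAR)
        c = u @ (phases * (u.conj().T @ c))
    norm = float(np.vdot(c, c).real)
    if abs(norm - 1.0) > 1e-6:
        raise PropagationError(f"electronic norm drifted to {norm}")
    return c


def hop_probabilities(coeffs, flux_terms, active, dt, mask=None):
    """Fewest-switches hop probabilities out of ``active``.

    ``flux_terms`` is the time-derivative coupling matrix T (1/fs) in the
    propagation basis; the outflow of population from the active state to
    state k over ``dt`` is 2 Re(c_a* T[a,k] c_k) dt, and the hop
    probability is that outflow divided by the active population, clipped
    at zero.  Masked targets get probability zero; the total is clipped
    at one.
    """
    c = np.asarray(coeffs, dtype=complex)
    t_mat = np.asarray(flux_terms)
    pop_a = float(abs(c[active]) ** 2)
    if pop_a == 0.0:
        raise DegenerateStateError("active state holds no population")
    flux = 2.0 * np.real(np.conj(c[active]) * t_mat[active, :] * c) * dt
    g = np.clip(flux, 0.0, None) / pop_a
    g[active] = 0.0
    if mask is not None:
        g[list(mask)] = 0.0
    total = g.sum()
    if total > 1.0:
        g = g / total
    return g


def attempt_hop(v, direction, masses, delta_e, frustrated_reversal=False):
    """Adjust velocities along ``direction`` so total energy is conserved
    across a hop with potential-energy change ``delta_e``.

    Solves 0.5 * sum m (v + lambda*u)^2 = KE - delta_e for lambda and picks
    the smaller-|lambda| root.  Returns ``(v_new, accepted)``; when the
    kinetic energy along the direction cannot cover an uphill gap the hop
    is frustrated: velocities are returned unchanged (or with the directed
    component reversed when ``frustrated_reversal``).
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(direction, dtype=float)
    mu2 = float(np.dot(masses, u * u))
    if mu2 == 0.0:
        raise ValueError("zero rescaling direction")
    a = 0.5 * mu2
    b = float(np.dot(masses * v, u))
    disc = b * b - 4.0 * a * delta_e
    if disc < 0.0:
        if frustrated_reversal:
            return v - 2.0 * (b / mu2) * u, False
        return v.copy(), False
    root = math.sqrt(disc)
    lam1 = (-b + root) / (2.0 * a)
    lam2 = (-b - root) / (2.0 * a)
    lam = lam1 if abs(lam1) <= abs(lam2) else lam2
    return v + lam * u, True


def apply_decoherence(coeffs, diag_energies, active, kinetic_energy, dt, c_param=2.72):
    """Energy-based decoherence: damp non-active amplitudes with lifetime
    tau_k = hbar / |E_k - E_active| * (1 + C / E_kin) and restore the norm
    through the active amplitude."""
    c = np.asarray(coeffs, dtype=complex).copy()
    if kinetic_energy <= 0.0:
        return c
    e = np.asarray(diag_energies, dtype=float)
    gaps = np.abs(e - e[active])
    damp = np.ones_like(e)
    nz = gaps > 0.0
    tau = np.empty_like(e)
    tau[nz] = HBAR / gaps[nz] * (1.0 + c_param / kinetic_energy)
    damp[nz] = np.exp(-dt / tau[nz])
    damp[active] = 1.0
    c = c * damp
    pop_a = float(abs(c[active]) ** 2)
    others = float(np.sum(np.abs(c) ** 2)) - pop_a
    if pop_a > 0.0:
        c[active] = c[active] * math.sqrt(max(1.0 - others, 0.0) / pop_a)
    return c


# --- trajectory driver -----------------------------------------------------

def _aligned_eigh(h, u_prev=None):
    """Ascending eigendecomposition with column signs matched to ``u_prev``
    (or the deterministic largest-component-positive phase when first)."""
    w, u = np.linalg.eigh(h)
    if u_prev is None:
        idx = np.argmax(np.abs(u), axis=0)
        signs = np.sign(u[idx, np.arange(u.shape[1])])
        signs[signs == 0] = 1.0
    else:
        diag = np.einsum("ij,ij->j", u_prev, u)
        signs = np.where(diag < 0, -1.0, 1.0)
    return w, u * signs


class _SurfaceCache:
    """Eigenvalues of H_total at q and at the 2d central-difference points,
    so the gradient of *any* eigensurface at q is available at no extra
    diagonalization cost (needed when a hop changes the active surface)."""

    def __init__(self, model: ModelSystem, q: np.ndarray, step: float, u_prev=None):
        self.q = q
        d = model.d
        pts = np.tile(q, (2 * d + 1, 1))
        for i in range(d):
            pts[2 * i, i] += step
            pts[2 * i + 1, i] -= step
        stack = model.h_total_batch(pts)
        self.energies, self.u = _aligned_eigh(stack[2 * d], u_prev)
        evals = np.linalg.eigvalsh(stack[: 2 * d])   # (2d, K)
        self._eplus = evals[0::2]
        self._eminus = evals[1::2]
        self._step = step

    def gradient(self, surface: int) -> np.ndarray:
        return (self._eplus[:, surface] - self._eminus[:, surface]) / (2.0 * self._step)


def _mch_assignment(u: np.ndarray, surface: int) -> int:
    """MCH label index of a diagonal state by maximal squared overlap;
    ties resolve to the lowest label in the canonical order (first argmax)."""
    return int(np.argmax(np.abs(u[:, surface]) ** 2))


def _electronic_step(c, e_start, e_end, t_mat, dt, substeps, active):
    """Split-operator substep propagation under diag(E(tau)) - i hbar T with
    constant T; accumulates fewest-switches hop probabilities."""
    dts = dt / substeps
    rot = expm(-t_mat * dts)          # orthogonal: T is antisymmetric
    fracs = (np.arange(substeps) + 0.5) / substeps
    halves = np.exp(
        -1j * (np.outer(1.0 - fracs, e_start) + np.outer(fracs, e_end)) * dts / (2.0 * HBAR))
    t_row = t_mat[active, :]
    g = np.zeros(len(c))
    for j in range(substeps):
        pop_a = abs(c[active]) ** 2
        if pop_a > 0.0:
            flux = 2.0 * np.real(np.conj(c[active]) * t_row * c) * dts
            np.maximum(flux, 0.0, out=flux)
            g += flux / pop_a
        half = halves[j]
        c = half * (rot @ (half * c))
    g[active] = 0.0
    return c, g


def run_trajectory(
        model: ModelSystem,
        initial: InitialConditions,
        params: EngineParams,
        rng: np.random.Generator) -> TrajectoryRecord:
    """Propagate one surface-hopping trajectory to termination.

    Termination: the C-C distance exceeding ``r_terminate`` (status
    ``dissociated``), the time budget ``t_max`` (``timed_out``), or total
    energy drifting beyond tolerance (``failed_energy``).  The dissociation
    time is the first sample with r_CC > ``r_dissoc`` and the product label
    is the collapsed MCH label frozen at that sample; subsequent sz hops
    are allowed but a change of the collapsed label is recorded as an
    inconsistency rather than enforced away.
    """
    p = params
    dt = p.dt
    masses = model.masses
    ke0 = model.kinetic_energy(initial.v0)
    if abs(ke0 - initial.kinetic_energy) > 1e-9:
        raise ValueError("initial kinetic energy inconsistent with its record")

    if p.hop_mask is None:
        masked = set(model.hop_mask)
    else:
        masked_labels = {parse_label(s) for s in p.hop_mask}
        masked = {i for i, l in enumerate(model.labels)
                  if l in masked_labels or
                  (l.multiplicity == 3 and any(m.multiplicity == 3 and m.index == l.index
                                               for m in masked_labels))}

    n_max = int(round(p.t_max / dt)) + 1
    d = model.d
    t_arr = np.empty(n_max)
    q_arr = np.empty((n_max, d))
    v_arr = np.empty((n_max, d))
    diag_arr = np.empty(n_max, dtype=np.int64)
    mch_arr = np.empty(n_max, dtype=np.int64)
    eact_arr = np.empty(n_max)
    etot_arr = np.empty(n_max)

    q = initial.q0.astype(float).copy()
    v = initial.v0.astype(float).copy()
    cache = _SurfaceCache(model, q, p.gradient_step)
    s0_idx = model.labels.index(SpinStateLabel(1, 0, 0))
    active = int(np.argmax(np.abs(cache.u[s0_idx, :])))
    c = cache.u.conj().T[:, s0_idx].astype(complex)
    a = -cache.gradient(active) / masses

    hops: list[HopEvent] = []
    status = "timed_out"
    product: SpinStateLabel | None = None
    dissociation_time: float | None = None
    label_consistent = True
    e_total_0: float | None = None
    n = 0

    for step_idx in range(n_max):
        t = step_idx * dt
        mch_idx = _mch_assignment(cache.u, active)
        e_act = float(cache.energies[active])
        e_tot = e_act + model.kinetic_energy(v)
        if e_total_0 is None:
            e_total_0 = e_tot
        t_arr[n] = t
        q_arr[n] = q
        v_arr[n] = v
        diag_arr[n] = active
        mch_arr[n] = mch_idx
        eact_arr[n] = e_act
        etot_arr[n] = e_tot
        n += 1

        r = q[0]
        if dissociation_time is None and r > p.r_dissoc:
            dissociation_time = t
            product = model.labels[mch_idx]
        elif dissociation_time is not None:
            if model.labels[mch_idx].collapsed != product.collapsed:  # type: ignore[union-attr]
                label_consistent = False
        if abs(e_tot - e_total_0) > p.energy_drift_tolerance:
            status = "failed_energy"
            break
        if r > p.r_terminate:
            status = "dissociated"
            break
        if step_idx == n_max - 1:
            status = "timed_out"
            break

        # --- velocity Verlet -------------------------------------------
        q_new = q + v * dt + 0.5 * a * dt * dt
        try:
            new_cache = _SurfaceCache(model, q_new, p.gradient_step, u_prev=cache.u)
            grad_new = new_cache.gradient(active)
            if not np.all(np.isfinite(grad_new)):
                raise PropagationError("non-finite gradient")
        except (PropagationError, np.linalg.LinAlgError):
            status = "failed_energy"
            break
        a_new = -grad_new / masses
        v_new = v + 0.5 * (a + a_new) * dt

        # --- electronic propagation ------------------------------------
        overlap = cache.u.T @ new_cache.u
        t_ov = (overlap - overlap.T) / (2.0 * dt)
        d_dot = model.nac_r_matrix(q_new) * v_new[0]
        t_mat = t_ov + new_cache.u.T @ d_dot @ new_cache.u
        c, g = _electronic_step(
            c, cache.energies, new_cache.energies, t_mat, dt,
            p.electronic_substeps, active)
        norm = float(np.vdot(c, c).real)
        if abs(norm - 1.0) > 1e-6:
            status = "failed_energy"
            break

        # --- trivial-crossing detection --------------------------------
        # When the active surface's character migrates to another sorted
        # index (overlap with itself below 1/2), two uncoupled surfaces
        # crossed between samples; follow the diabatic character
        # deterministically instead of rolling a stochastic hop.  True
        # crossings are (near-)degenerate, so no momentum adjustment is
        # needed; the gap guard keeps this from firing in genuinely
        # coupled regions.
        s_row2 = overlap[active, :] ** 2
        if s_row2[active] < 0.5:
            j = int(np.argmax(s_row2))
            if j != active and abs(new_cache.energies[j]
                                   - new_cache.energies[active]) < 0.05:
                active = j
                a_new = -new_cache.gradient(active) / masses
                v_new = v + 0.5 * (a + a_new) * dt
            ke = model.kinetic_energy(v_new)
            c = apply_decoherence(c, new_cache.energies, active, ke, dt,
                                  p.decoherence_c)
            q, v, a, cache = q_new, v_new, a_new, new_cache
            continue

        # --- hop decision ----------------------------------------------
        for k in masked:
            # mask by MCH character of the candidate diagonal surface
            g[k] = 0.0
        for k in range(len(g)):
            if k not in masked and g[k] > 0.0:
                if _mch_assignment(new_cache.u, k) in masked:
                    g[k] = 0.0
        total_g = g.sum()
        if total_g > 1.0:
            g = g / total_g
        xi = rng.random()
        target = -1
        acc = 0.0
        for k in range(len(g)):
            if g[k] <= 0.0:
                continue
            acc += g[k]
            if xi < acc:
                target = k
                break
        if target >= 0:
            from_mch = model.labels[_mch_assignment(new_cache.u, active)]
            to_mch = model.labels[_mch_assignment(new_cache.u, target)]
            delta_e = float(new_cache.energies[target] - new_cache.energies[active])
            direction = None
            used_fallback = False
            if (from_mch.multiplicity == to_mch.multiplicity and from_mch.sz == to_mch.sz):
                pair = (min(from_mch, to_mch), max(from_mch, to_mch))
                ia, ib = model.labels.index(pair[0]), model.labels.index(pair[1])
                key = (min(ia, ib), max(ia, ib))
                vecs = model.nac(q_new)
                if key in vecs and np.linalg.norm(vecs[key]) > 0:
                    direction = vecs[key]
            if direction is None:
                vnorm = np.linalg.norm(v_new)
                if vnorm == 0.0:
                    direction = np.zeros(d); direction[0] = 1.0
                else:
                    direction = v_new / vnorm
                used_fallback = True
            v_try, accepted = attempt_hop(
                v_new, direction, masses, delta_e, p.frustrated_reversal)
            hops.append(HopEvent(
                t=t + dt, from_diag=active, to_diag=target,
                from_mch=from_mch, to_mch=to_mch,
                frustrated=not accepted, used_fallback_direction=used_fallback))
            if accepted:
                v_new = v_try
                active = target
                a_new = -new_cache.gradient(active) / masses
            else:
                v_new = v_try  # unchanged unless reversal was requested

        # --- decoherence ------------------------------------------------
        ke = model.kinetic_energy(v_new)
        c = apply_decoherence(c, new_cache.energies, active, ke, dt, p.decoherence_c)

        q, v, a, cache = q_new, v_new, a_new, new_cache

    obs_deg = np.degrees(q_arr[:n, 1:3])
    from .model import wrap_degrees
    rec = TrajectoryRecord(
        labels=model.labels,
        t=t_arr[:n].copy(), q=q_arr[:n].copy(), v=v_arr[:n].copy(),
        active_diag=diag_arr[:n].copy(), active_mch=mch_arr[:n].copy(),
        e_active=eact_arr[:n].copy(), e_total=etot_arr[:n].copy(),
        r_cc=q_arr[:n, 0].copy(),
        phi_oocc=wrap_degrees(obs_deg[:, 0]),
        phi_cccc=wrap_degrees(obs_deg[:, 1]),
        hops=hops, status=status, product_mch=product,
        dissociation_time=dissociation_time, initial=initial,
        label_consistent=label_consistent, dt=dt)
    return rec


def run_ensemble(
        model: ModelSystem,
        n: int,
        params: EngineParams,
        master_seed: int,
        sampling: SamplingParams | None = None) -> list[TrajectoryRecord]:
    """Run ``n`` independent trajectories with per-trajectory seeds derived
    deterministically from ``master_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampling = sampling or SamplingParams()
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=(n, 2))
    records = []
    for i in range(n):
        ic = sample_initial_conditions(model, sampling, int(seeds[i, 0]))
        rng = np.random.default_rng(int(seeds[i, 1]))
        try:
            rec = run_trajectory(model, ic, params, rng)
        except (PropagationError, np.linalg.LinAlgError):
            rec = TrajectoryRecord(
                labels=model.labels, t=np.array([0.0]),
                q=ic.q0[None, :], v=ic.v0[None, :],
                active_diag=np.array([0]), active_mch=np.array([0]),
                e_active=np.array([np.nan]), e_total=np.array([np.nan]),
                r_cc=np.array([ic.q0[0]]),
                phi_oocc=np.array([0.0]), phi_cccc=np.array([0.0]),
                hops=[], status="failed_energy", product_mch=None,
                dissociation_time=None, initial=ic, dt=params.dt)
        records.append(rec)
    return records
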