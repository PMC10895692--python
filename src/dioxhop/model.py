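"""Analytic multi-state model of a dioxetane-like dissociation landscape.

The model stands in for ab initio excited-state surfaces.  It is built in a
reduced set of internal coordinates

    q = (r_CC, phi_OOCC, phi_CCCC, b_1 ... b_m)

with r_CC the breaking C-C distance in angstrom, the two dihedral angles in
radians internally (degrees at every interface) and ``m`` harmonic bath
modes.  The spin-free (MCH) electronic basis holds ``n_singlets`` singlet
states and ``3 * n_triplets`` triplet sublevels.  The landscape realizes
the qualitative features that control the dynamics of this reaction class:

* a bound C-C Morse well whose bottom frequency gives a ~40 fs vibrational
  period (the C-C oscillation seen as "frustrated dissociations");
* an "entropic trap": for r_CC below a logistic window all electronic
  states are nearly degenerate, so trajectories hop promiscuously;
* on every excited surface a Gaussian "ridge" near r_CC = 2.16 A that must
  be surmounted for excited-state dissociation, while the ground singlet
  has no interior barrier at all between 2.1 and 2.4 A;
* weak constant spin-orbit couplings (singlet-triplet and intra-triplet
  S_z mixing) damped to zero at large r_CC, and Gaussian-localized
  nonadiabatic couplings between adjacent states of equal multiplicity
  and S_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np

from .constants import KE_TO_EV
from .states import SpinStateLabel, state_labels


class ConfigurationError(ValueError):
    """A configuration field is missing, unknown or has an invalid value."""


class ModelConstructionError(ValueError):
    """Parameters violate a topological invariant of the landscape."""


class DomainError(ValueError):
    """A configuration point lies outside the model domain."""


def wrap_degrees(angle):
    """Wrap an angle in degrees into (-180, 180], with -180 mapped to +180."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


@dataclass(frozen=True)
class ModelParams:
    """All tunable parameters of the surrogate landscape (energies eV,
    lengths A, times fs, masses amu / amu*A^2, angles degrees)."""

    n_singlets: int = 4
    n_triplets: int = 4
    bath_modes: int = 3

    # inertial parameters
    mass_r: float = 22.0              # reduced mass of the two fragments, amu
    inertia_oocc: float = 10.0        # amu*A^2
    inertia_cccc: float = 20.0        # amu*A^2
    bath_masses: tuple[float, ...] = (8.0, 8.0, 8.0)

    # C-C Morse well (the trap region oscillator)
    morse_depth: float = 0.8          # eV
    morse_r0: float = 1.55            # A
    well_period: float = 40.0         # fs, small-amplitude period at the well bottom

    # exothermic exit: past the biradical region every surface plunges by
    # exo_depth (the chemiluminescent decomposition releases heat into the
    # fragments), so a trajectory that clears the barrier is committed and
    # never recrosses the labeling distance
    exo_depth: float = 1.5            # eV
    exo_center: float = 2.25          # A
    exo_width: float = 0.10           # A

    # excited-state dissociation ridge
    ridge_center: float = 2.16        # A
    ridge_width: float = 0.12         # A (Gaussian sigma)
    ridge_height: float = 0.35        # eV

    # entropic-trap degeneracy window (logistic in r_CC)
    trap_r: float = 1.95              # A, window center
    trap_width: float = 0.08          # A, logistic width
    trap_spread: float = 0.03         # eV, residual in-trap state spread
    trap_modulation: float = 0.015    # eV, dihedral-driven in-trap level sweep
    trap_energy_window: float = 0.15  # eV, asserted max pairwise diag gap in the trap

    # asymptotic state offsets outside the trap (product-state splittings)
    singlet_offsets: tuple[float, ...] = (0.0, 0.20, 2.00, 2.40)
    triplet_offsets: tuple[float, ...] = (0.12, 0.90, 3.20, 3.50)
    sz_splitting: float = 0.0005      # eV per unit sz, keeps sublevels resolvable
    epsilon_z: float = 0.002          # eV, guaranteed max sublevel gap

    # spin-orbit coupling; the singlet-triplet (intersystem-crossing)
    # channel lives in the biradical region and is damped out before the
    # C-C van der Waals distance, while the weak intra-triplet sz mixing
    # persists almost to the termination distance (sublevel hops continue
    # after the bond cleaves, but can never relabel the collapsed product)
    soc_singlet_triplet: float = 0.010   # eV
    soc_intra_triplet: float = 0.002     # eV
    soc_st_cutoff: float = 2.2           # A
    soc_st_cutoff_width: float = 0.08    # A
    soc_tt_cutoff: float = 3.55          # A
    soc_tt_cutoff_width: float = 0.08    # A

    # nonadiabatic coupling (adjacent equal-multiplicity, equal-sz states)
    nac_amplitude: float = 0.5           # 1/A
    nac_center: float = 1.95             # A
    nac_width: float = 0.18              # A

    # torsional potentials, V = k * (1 - cos(phi - phi0))
    torsion_k_oocc: float = 0.05         # eV
    torsion_phi0_oocc: float = 180.0     # deg
    torsion_k_cccc: float = 0.05         # eV
    torsion_phi0_cccc: float = 180.0     # deg

    bath_periods: tuple[float, ...] = (38.0, 44.0, 52.0)  # fs
    # bilinear bath / C-C stretch coupling: strengths (eV/A^2) and the
    # gaussian localization length (A) of the coupling function
    # g(r) = (r - r0) exp(-((r - r0)/l)^2); these set the pace of
    # intramolecular energy redistribution into the breaking bond, and the
    # localization guarantees the bath decouples once the bond has broken
    bath_coupling: tuple[float, ...] = (3.0, 3.0, 3.0)
    ivr_length: float = 0.35

    r_min: float = 0.5
    r_max: float = 6.0

    @classmethod
    def from_dict(cls, data: Mapping[str, object] | None) -> "ModelParams":
        data = dict(data or {})
        known = {f.name for f in dc_fields(cls)}
        for key in data:
            if key not in known:
                raise ConfigurationError(f"unknown model parameter: {key!r}")
        for key in ("bath_masses", "bath_periods", "bath_coupling",
                    "singlet_offsets", "triplet_offsets"):
            if key in data:
                data[key] = tuple(float(x) for x in data[key])  # type: ignore[arg-type]
        try:
            params = cls(**data)  # type: ignore[arg-type]
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        params.validate()
        return params

    def validate(self) -> None:
        def positive(name: str) -> None:
            if not (float(getattr(self, name)) > 0):
                raise ConfigurationError(f"model parameter {name!r} must be > 0")

        for name in ("mass_r", "inertia_oocc", "inertia_cccc", "morse_depth",
                     "well_period", "ridge_width", "trap_width",
                     "soc_st_cutoff_width", "soc_tt_cutoff_width",
                     "nac_width", "epsilon_z", "ivr_length", "exo_width"):
            positive(name)
        if self.n_singlets < 1 or self.n_triplets < 0:
            raise ConfigurationError("n_singlets must be >= 1 and n_triplets >= 0")
        if (len(self.bath_masses) < self.bath_modes
                or len(self.bath_periods) < self.bath_modes
                or len(self.bath_coupling) < self.bath_modes):
            raise ConfigurationError(
                "bath_masses/bath_periods/bath_coupling must provide one entry "
                "per bath mode")
        if len(self.singlet_offsets) < self.n_singlets:
            raise ConfigurationError("singlet_offsets must cover all singlet states")
        if len(self.triplet_offsets) < self.n_triplets:
            raise ConfigurationError("triplet_offsets must cover all triplet states")
        if self.ridge_height <= 0:
            raise ModelConstructionError(
                "ridge_height must be > 0: excited surfaces need a dissociation ridge")
        if self.trap_spread < 0 or self.trap_spread > self.trap_energy_window:
            raise ModelConstructionError(
                "trap_spread must lie in [0, trap_energy_window]")
        if abs(self.sz_splitting) > self.epsilon_z / 2:
            raise ModelConstructionError(
                "sz_splitting too large: triplet sublevels must stay within epsilon_z")

    # derived quantities -------------------------------------------------

    @property
    def morse_a(self) -> float:
        """Morse range parameter tuned so the well-bottom period is ``well_period``."""
        omega = 2.0 * math.pi / self.well_period
        m_eng = self.mass_r * KE_TO_EV
        return omega * math.sqrt(m_eng / (2.0 * self.morse_depth))


@dataclass(frozen=True)
class TotalHamiltonianAtPoint:
    """Eigendecomposition of H_total = H_MCH + H_SOC at one geometry."""

    h_mch: np.ndarray          # (K,) MCH energies, eV
    h_soc: np.ndarray          # (K, K) Hermitian SOC matrix, eV
    h_total: np.ndarray        # (K, K)
    u: np.ndarray              # (K, K) columns = diagonal states, phase-fixed
    diag_energies: np.ndarray  # (K,) ascending


class ModelSystem:
    """Callable bundle of surfaces, couplings and observables.

    Coordinates are ``(r_CC [A], phi_OOCC [rad], phi_CCCC [rad],
    b_1 ... b_m [A])``; masses are stored in engine units (amu * KE_TO_EV)
    so kinetic energies and forces come out in eV directly.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        p = params
        self.labels: list[SpinStateLabel] = state_labels(p.n_singlets, p.n_triplets)
        self.n_states = len(self.labels)
        self.coordinate_names = ["r_cc", "phi_oocc", "phi_cccc"] + [
            f"bath_{j + 1}" for j in range(p.bath_modes)]
        self.d = len(self.coordinate_names)
        self.masses_amu = np.array(
            [p.mass_r, p.inertia_oocc, p.inertia_cccc, *p.bath_masses[: p.bath_modes]])
        self.masses = self.masses_amu * KE_TO_EV

        # per-state static data -------------------------------------------
        self._is_singlet = np.array([l.multiplicity == 1 for l in self.labels])
        self._sz = np.array([l.sz for l in self.labels])
        self._parent_index = np.array([l.index for l in self.labels])
        # in-trap residual offsets: parents ordered S0..S(n-1), T1..Tn share
        # an even ladder across trap_spread so the trap is near-degenerate
        parents = [(1, i) for i in range(p.n_singlets)] + [(3, i) for i in range(p.n_triplets)]
        n_par = max(len(parents) - 1, 1)
        trap_of_parent = {par: p.trap_spread * k / n_par for k, par in enumerate(parents)}
        self._trap_offsets = np.array(
            [trap_of_parent[(l.multiplicity, l.index)] for l in self.labels])
        # per-parent phase of the dihedral-driven level sweep inside the trap;
        # identical for sz sublevels so triplet near-degeneracy is preserved
        phase_of_parent = {par: 2.0 * math.pi * k / max(len(parents), 1)
                           for k, par in enumerate(parents)}
        self._trap_phases = np.array(
            [phase_of_parent[(l.multiplicity, l.index)] for l in self.labels])
        self._asym_offsets = np.array(
            [p.singlet_offsets[l.index] if l.multiplicity == 1 else p.triplet_offsets[l.index]
             for l in self.labels])
        self._ridge_heights = np.where(
            (self._is_singlet) & (self._parent_index == 0), 0.0, p.ridge_height)
        self._sz_terms = np.where(self._is_singlet, 0.0, p.sz_splitting * self._sz)

        self._soc_st, self._soc_tt = self._build_soc_patterns()
        self._nac_pairs = self._build_nac_pairs()
        self._nac_base = self._build_nac_pattern()
        self._bath_k = np.array(
            [p.bath_masses[j] * KE_TO_EV * (2.0 * math.pi / p.bath_periods[j]) ** 2
             for j in range(p.bath_modes)])
        self._bath_c = np.array(p.bath_coupling[: p.bath_modes])
        self.hop_mask: frozenset[int] = frozenset(
            i for i, l in enumerate(self.labels)
            if l.multiplicity == 3 and l.index >= 2)  # T3, T4 sublevels

    # construction helpers ------------------------------------------------

    def _build_soc_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Constant parts of the SOC matrix (before the r_CC damping).

        Singlet states (sz = 0) couple to triplet sublevels with sz = +/-1;
        triplet sublevels of unequal sz mix among themselves.  The two
        blocks are damped on different r_CC scales.
        """
        p = self.params
        K = self.n_states
        soc_st = np.zeros((K, K))
        soc_tt = np.zeros((K, K))
        for a in range(K):
            for b in range(a + 1, K):
                la, lb = self.labels[a], self.labels[b]
                if la.multiplicity != lb.multiplicity and la.sz != lb.sz:
                    soc_st[a, b] = soc_st[b, a] = p.soc_singlet_triplet
                elif la.multiplicity == 3 and lb.multiplicity == 3 and la.sz != lb.sz:
                    soc_tt[a, b] = soc_tt[b, a] = p.soc_intra_triplet
        return soc_st, soc_tt

    def _build_nac_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for a in range(self.n_states):
            for b in range(a + 1, self.n_states):
                la, lb = self.labels[a], self.labels[b]
                if (la.multiplicity == lb.multiplicity and la.sz == lb.sz
                        and abs(la.index - lb.index) == 1):
                    pairs.append((a, b))
        return pairs

    def _build_nac_pattern(self) -> np.ndarray:
        K = self.n_states
        base = np.zeros((K, K))
        for a, b in self._nac_pairs:
            base[a, b] = self.params.nac_amplitude
            base[b, a] = -self.params.nac_amplitude
        return base

    # point evaluations ---------------------------------------------------

    def check_domain(self, q: np.ndarray) -> None:
        q = np.asarray(q, dtype=float)
        if q.shape != (self.d,):
            raise DomainError(f"configuration must have length {self.d}, got {q.shape}")
        if not np.all(np.isfinite(q)):
            raise DomainError("configuration contains non-finite values")
        if not (self.params.r_min <= q[0] <= self.params.r_max):
            raise DomainError(
                f"r_CC = {q[0]:.4f} A outside domain "
                f"[{self.params.r_min}, {self.params.r_max}] A")

    def _trap_window(self, r: float) -> float:
        """Logistic switch: 0 deep in the trap, 1 outside (large r)."""
        return 1.0 / (1.0 + math.exp(-(r - self.params.trap_r) / self.params.trap_width))

    def _soc_damp_st(self, r: float) -> float:
        p = self.params
        return 1.0 / (1.0 + math.exp((r - p.soc_st_cutoff) / p.soc_st_cutoff_width))

    def _soc_damp_tt(self, r: float) -> float:
        p = self.params
        return 1.0 / (1.0 + math.exp((r - p.soc_tt_cutoff) / p.soc_tt_cutoff_width))

    def _shared_potential(self, q: np.ndarray) -> float:
        """State-independent part: Morse + torsions + bath."""
        p = self.params
        r, phi1, phi2 = q[0], q[1], q[2]
        x = 1.0 - math.exp(-p.morse_a * (r - p.morse_r0))
        v = p.morse_depth * x * x
        v -= p.exo_depth / (1.0 + math.exp(-(r - p.exo_center) / p.exo_width))
        v += p.torsion_k_oocc * (1.0 - math.cos(phi1 - math.radians(p.torsion_phi0_oocc)))
        v += p.torsion_k_cccc * (1.0 - math.cos(phi2 - math.radians(p.torsion_phi0_cccc)))
        b = q[3:]
        v += 0.5 * float(np.dot(self._bath_k, b * b))
        # bilinear IVR coupling, localized inside the C-C well
        dr = r - p.morse_r0
        g = dr * math.exp(-((dr / p.ivr_length) ** 2))
        v += g * float(np.dot(self._bath_c, b))
        return v

    def mch_potential(self, q: np.ndarray) -> np.ndarray:
        """Per-MCH-state energies (K,) in eV."""
        q = np.asarray(q, dtype=float)
        r = q[0]
        s = self._trap_window(r)
        shared = self._shared_potential(q)
        # inside the trap the nearly degenerate levels sweep with the
        # O-O-C-C dihedral, producing the avoided crossings that drive the
        # promiscuous hopping of the entropic-trap region
        sweep = self.params.trap_modulation * np.sin(q[1] + self._trap_phases)
        offsets = (self._trap_offsets + sweep) * (1.0 - s) + self._asym_offsets * s
        p = self.params
        ridge = self._ridge_heights * math.exp(
            -0.5 * ((r - p.ridge_center) / p.ridge_width) ** 2)
        return shared + offsets + ridge + self._sz_terms

    def soc(self, q: np.ndarray) -> np.ndarray:
        """Hermitian (real symmetric) SOC matrix (K, K) in eV, zero diagonal."""
        q = np.asarray(q, dtype=float)
        return (self._soc_st * self._soc_damp_st(q[0])
                + self._soc_tt * self._soc_damp_tt(q[0]))

    def h_total(self, q: np.ndarray) -> np.ndarray:
        h = self.soc(q).copy()
        h[np.diag_indices(self.n_states)] = self.mch_potential(q)
        return h

    def mch_potential_batch(self, qs: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`mch_potential` over (n, d) points -> (n, K)."""
        qs = np.asarray(qs, dtype=float)
        p = self.params
        r = qs[:, 0]
        phi1 = qs[:, 1]
        phi2 = qs[:, 2]
        b = qs[:, 3:]
        x = 1.0 - np.exp(-p.morse_a * (r - p.morse_r0))
        shared = p.morse_depth * x * x
        shared -= p.exo_depth / (1.0 + np.exp(-(r - p.exo_center) / p.exo_width))
        shared += p.torsion_k_oocc * (1.0 - np.cos(phi1 - math.radians(p.torsion_phi0_oocc)))
        shared += p.torsion_k_cccc * (1.0 - np.cos(phi2 - math.radians(p.torsion_phi0_cccc)))
        shared += 0.5 * (b * b) @ self._bath_k
        dr = r - p.morse_r0
        shared += dr * np.exp(-((dr / p.ivr_length) ** 2)) * (b @ self._bath_c)
        s = 1.0 / (1.0 + np.exp(-(r - p.trap_r) / p.trap_width))
        sweep = p.trap_modulation * np.sin(phi1[:, None] + self._trap_phases[None, :])
        offsets = ((self._trap_offsets[None, :] + sweep) * (1.0 - s)[:, None]
                   + self._asym_offsets[None, :] * s[:, None])
        ridge = self._ridge_heights[None, :] * np.exp(
            -0.5 * ((r - p.ridge_center) / p.ridge_width) ** 2)[:, None]
        return shared[:, None] + offsets + ridge + self._sz_terms[None, :]

    def h_total_batch(self, qs: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`h_total` over (n, d) points -> (n, K, K)."""
        qs = np.asarray(qs, dtype=float)
        p = self.params
        r = qs[:, 0]
        damp_st = 1.0 / (1.0 + np.exp((r - p.soc_st_cutoff) / p.soc_st_cutoff_width))
        damp_tt = 1.0 / (1.0 + np.exp((r - p.soc_tt_cutoff) / p.soc_tt_cutoff_width))
        h = (damp_st[:, None, None] * self._soc_st[None, :, :]
             + damp_tt[:, None, None] * self._soc_tt[None, :, :])
        e = self.mch_potential_batch(qs)
        k = np.arange(self.n_states)
        h[:, k, k] = e
        return h

    def nac_r_matrix(self, q: np.ndarray) -> np.ndarray:
        """Antisymmetric (K, K) matrix of the r_CC components of the NAC vectors."""
        q = np.asarray(q, dtype=float)
        p = self.params
        g = math.exp(-0.5 * ((q[0] - p.nac_center) / p.nac_width) ** 2)
        return self._nac_base * g

    def nac(self, q: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
        """Coupling vectors (length d) for each coupled equal-multiplicity,
        equal-sz MCH state pair, keyed by the ordered index pair."""
        mat = self.nac_r_matrix(q)
        out: dict[tuple[int, int], np.ndarray] = {}
        for a, b in self._nac_pairs:
            vec = np.zeros(self.d)
            vec[0] = mat[a, b]
            out[(a, b)] = vec
        return out

    def observables(self, q: np.ndarray) -> dict[str, float]:
        """Geometric observables: r_CC in A, dihedrals in (-180, 180] degrees."""
        self.check_domain(q)
        return {
            "r_cc": float(q[0]),
            "phi_oocc": float(wrap_degrees(math.degrees(q[1]))),
            "phi_cccc": float(wrap_degrees(math.degrees(q[2]))),
        }

    def kinetic_energy(self, v: np.ndarray) -> float:
        """Kinetic energy in eV of velocities (A/fs, rad/fs)."""
        v = np.asarray(v, dtype=float)
        return 0.5 * float(np.dot(self.masses, v * v))


def build_model(config: Mapping[str, object] | ModelParams | None = None) -> ModelSystem:
    """Construct a :class:`ModelSystem` from a configuration mapping.

    Raises :class:`ConfigurationError` naming the offending field for
    unknown or invalid keys and :class:`ModelConstructionError` when
    parameters break a topological invariant (e.g. a non-positive ridge).
    """
    if isinstance(config, ModelParams):
        config.validate()
        return ModelSystem(config)
    return ModelSystem(ModelParams.from_dict(config))


def fix_eigenvector_phases(u: np.ndarray) -> np.ndarray:
    """Deterministic phase: largest-magnitude component of each column made
    real and positive."""
    u = np.array(u)
    idx = np.argmax(np.abs(u), axis=0)
    for j in range(u.shape[1]):
        comp = u[idx[j], j]
        if comp != 0:
            u[:, j] = u[:, j] * (np.conj(comp) / abs(comp))
    return u


def evaluate_total_hamiltonian(model: ModelSystem, q: np.ndarray) -> TotalHamiltonianAtPoint:
    """MCH energies, SOC and the diagonal-basis eigendecomposition at ``q``.

    Eigenvalues are ascending; eigenvector phases are fixed so the
    largest-magnitude component of each column is real positive.
    """
    model.check_domain(q)
    h_mch = model.mch_potential(q)
    h_soc = model.soc(q)
    h_total = h_soc.copy()
    h_total[np.diag_indices(model.n_states)] = h_mch
    energies, u = np.linalg.eigh(h_total)
    u = fix_eigenvector_phases(u)
    return TotalHamiltonianAtPoint(
        h_mch=h_mch, h_soc=h_soc, h_total=h_total, u=u, diag_energies=energies)


def geometric_observables(model: ModelSystem, q: np.ndarray) -> dict[str, float]:
    """Convenience wrapper for :meth:`ModelSystem.observables`."""
    return model.observables(q)
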