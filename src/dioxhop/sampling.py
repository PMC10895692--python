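"""Initial-condition generation for trajectories launched at the O-O
bond-breaking transition state.

Following the Sellner-Barbatti-Lischka recipe, every trajectory starts
from the same geometry; velocities are drawn coordinate-wise from a
Boltzmann distribution (default 300 K), rescaled globally so the total
kinetic energy matches a fixed launch energy (default 3.96 eV, the
transition-state vibrational zero-point energy plus a correlation
correction taken as a plain input), and the component along the reaction
mode is constrained to point toward products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import KB
from .model import ConfigurationError, ModelSystem


class ResampleNeeded(RuntimeError):
    """Raised when the reaction-mode projection is exactly zero; the caller
    should redraw the velocities."""


@dataclass(frozen=True)
class SamplingParams:
    """Initial-condition parameters (temperature K, energies eV, angles deg)."""

    temperature: float = 300.0
    kinetic_energy: float = 3.96
    r_cc0: float = 1.60
    phi_oocc0: float = 135.8
    phi_cccc0: float = 180.0
    reaction_mode: str = "bath_1"   # surrogate O-O product-direction mode
    backward_policy: str = "flip"   # 'flip' or 'reject'

    @classmethod
    def from_dict(cls, data: Mapping[str, object] | None) -> "SamplingParams":
        data = dict(data or {})
        known = {f for f in cls.__dataclass_fields__}
        for key in data:
            if key not in known:
                raise ConfigurationError(f"unknown sampling parameter: {key!r}")
        params = cls(**data)  # type: ignore[arg-type]
        if params.temperature < 0:
            raise ConfigurationError("sampling parameter 'temperature' must be >= 0")
        if params.kinetic_energy <= 0:
            raise ConfigurationError("sampling parameter 'kinetic_energy' must be > 0")
        if params.backward_policy not in ("flip", "reject"):
            raise ConfigurationError("sampling parameter 'backward_policy' must be "
                                     "'flip' or 'reject'")
        return params


@dataclass(frozen=True)
class InitialConditions:
    """One accepted launch condition."""

    q0: np.ndarray               # internal coordinates
    v0: np.ndarray               # A/fs and rad/fs
    kinetic_energy: float        # eV, equals the configured target
    seed: int
    features: dict[str, float] = field(default_factory=dict)


def initial_geometry(model: ModelSystem, params: SamplingParams) -> np.ndarray:
    """The fixed launch geometry (surrogate O-O transition state)."""
    q0 = np.zeros(model.d)
    q0[0] = params.r_cc0
    q0[1] = math.radians(params.phi_oocc0)
    q0[2] = math.radians(params.phi_cccc0)
    return q0


def reaction_mode_vector(model: ModelSystem, params: SamplingParams) -> np.ndarray:
    """Unit vector along the designated product-direction coordinate."""
    try:
        idx = model.coordinate_names.index(params.reaction_mode)
    except ValueError:
        raise ConfigurationError(
            f"unknown reaction_mode coordinate: {params.reaction_mode!r}") from None
    mode = np.zeros(model.d)
    mode[idx] = 1.0
    return mode


def sample_boltzmann_velocities(
        model: ModelSystem, temperature: float, rng: np.random.Generator) -> np.ndarray:
    """Coordinate-wise Maxwell-Boltzmann velocities at ``temperature``.

    Each component is an independent zero-mean Gaussian with variance
    kT / m_i (engine-unit masses, so the per-mode kinetic energy averages
    kT/2 in eV).
    """
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0, got {temperature}")
    sigma = np.sqrt(KB * temperature / model.masses)
    return rng.normal(0.0, 1.0, model.d) * sigma


def rescale_to_energy(model: ModelSystem, velocities: np.ndarray, target: float) -> np.ndarray:
    """Scale all velocities by a common factor so the kinetic energy equals
    ``target`` (eV)."""
    if target <= 0:
        raise ValueError(f"target kinetic energy must be > 0, got {target}")
    ke = model.kinetic_energy(velocities)
    if ke == 0.0:
        raise ValueError("cannot rescale an all-zero velocity vector")
    return np.asarray(velocities, dtype=float) * math.sqrt(target / ke)


def select_forward(velocities: np.ndarray, reaction_mode: np.ndarray) -> np.ndarray:
    """Force the velocity component along ``reaction_mode`` to be positive.

    A negative projection is sign-flipped (mirror through the plane normal
    to the mode), leaving the orthogonal part and the norm untouched; a
    zero projection raises :class:`ResampleNeeded`.
    """
    v = np.asarray(velocities, dtype=float)
    mode = np.asarray(reaction_mode, dtype=float)
    if not math.isclose(float(np.dot(mode, mode)), 1.0, rel_tol=0, abs_tol=1e-10):
        raise ValueError("reaction_mode must have unit norm")
    proj = float(np.dot(v, mode))
    if proj == 0.0:
        raise ResampleNeeded("zero projection on the reaction mode; redraw velocities")
    if proj < 0:
        return v - 2.0 * proj * mode
    return v.copy()


def compute_initial_features(
        model: ModelSystem, q0: np.ndarray, v0: np.ndarray) -> dict[str, float]:
    """Scalar features of a launch condition.

    Angular velocities of the two dihedrals in deg/fs and the surrogate
    bond-rate velocities in A/fs; these are the time derivatives of the
    geometric observables at t = 0 (exact, since each observable is a
    single internal coordinate here).
    """
    v0 = np.asarray(v0, dtype=float)
    feats = {
        "omega0_1234": math.degrees(v0[1]),
        "omega0_3456": math.degrees(v0[2]),
        "v0_34": float(v0[0]),
    }
    # surrogate bond-rate features carried by the first two bath modes
    if model.d > 3:
        feats["v0_12"] = float(v0[3])
    if model.d > 4:
        feats["v0_56"] = float(v0[4])
    return feats


def sample_initial_conditions(
        model: ModelSystem, params: SamplingParams, seed: int,
        max_redraws: int = 100) -> InitialConditions:
    """Draw one accepted launch condition with the full SBL pipeline."""
    rng = np.random.default_rng(seed)
    q0 = initial_geometry(model, params)
    mode = reaction_mode_vector(model, params)
    for _ in range(max_redraws):
        v = sample_boltzmann_velocities(model, params.temperature, rng)
        if model.kinetic_energy(v) == 0.0:
            continue
        v = rescale_to_energy(model, v, params.kinetic_energy)
        proj = float(np.dot(v, mode))
        if proj == 0.0:
            continue
        if proj < 0:
            if params.backward_policy == "reject":
                continue
            v = select_forward(v, mode)
        feats = compute_initial_features(model, q0, v)
        return InitialConditions(
            q0=q0, v0=v, kinetic_energy=model.kinetic_energy(v),
            seed=seed, features=feats)
    raise RuntimeError("failed to draw an acceptable initial condition "
                       f"after {max_redraws} attempts")
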