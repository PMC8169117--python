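"""Core hormone-network model: parameters, state, regulatory functions, drift and noise.

The model couples abscisic acid (ABA), gibberellin (GA), a lumped germination
inhibitor ("Integrator", I) and a sowing signal (Z) through Hill-type
regulatory functions.  ABA promotes Integrator production, GA promotes
Integrator degradation, the Integrator feeds back positively on ABA and
negatively on GA, and Z ramps up GA production after sowing.  Germination is
the first-passage of I below a threshold.

All units are arbitrary (concentration, time); the effective system volume
``V`` sets the inverse noise intensity of the chemical Langevin equations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "ExogenousDose",
    "hill_increasing",
    "hill_decreasing",
    "drift",
    "diffusion_amplitude",
    "noise_prefactor",
    "production_degradation_terms",
]

#: order of the dynamical variables in every array-valued quantity
STATE_VARS = ("ABA", "GA", "I", "Z")


@dataclass(frozen=True)
class ModelParameters:
    """Rate, threshold and coefficient constants of the germination switch.

    Defaults are the model's reference parameterization.  ``beta_*`` are
    basal production rates, ``v_*`` degradation rates, ``theta_X_Y`` the
    concentration of Y at which its regulatory effect on X is half-maximal,
    ``C_X_Y`` the maximal value of that regulatory function, ``h`` the Hill
    exponent shared by all four regulatory functions and ``V`` the effective
    system volume (noise intensity is 1/V).

    Instances are immutable; use :meth:`replace` to derive variants.
    """

    beta_ABA: float = 1.0
    beta_GA: float = 0.3
    beta_GA_Z: float = 0.01
    beta_Z: float = 39.0
    beta_I: float = 0.3
    v_ABA: float = 1.0
    v_GA: float = 1.0
    v_Z: float = 0.1
    v_I: float = 0.4
    theta_ABA_I: float = 3.7
    theta_GA_I: float = 1.2
    theta_I_ABA: float = 6.5
    theta_I_GA: float = 6.0
    C_ABA_I: float = 10.0
    C_GA_I: float = 4.0
    C_I_ABA: float = 10.0
    C_I_GA: float = 6.0
    h: float = 4.0
    V: float = 30.0

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if name == "beta_GA_Z":
                if value < 0:
                    raise ValueError(f"beta_GA_Z must be >= 0, got {value!r}")
            elif value <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value!r}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ModelParameters":
        """Build parameters from a (possibly partial) mapping.

        Unknown keys raise ``KeyError`` (typo protection); missing keys fall
        back to the defaults.
        """
        known = set(cls.field_names())
        unknown = sorted(set(values) - known)
        if unknown:
            raise KeyError(f"unknown parameter key(s): {', '.join(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the four dynamical variables at time ``t``."""

    ABA: float
    GA: float
    I: float
    Z: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"concentration {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"concentration {name} must be >= 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ABA, self.GA, self.I, self.Z], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, t: float = 0.0) -> "SystemState":
        a, g, i, z = (float(x) for x in values)
        return cls(ABA=a, GA=g, I=i, Z=z, t=float(t))


@dataclass(frozen=True)
class ExogenousDose:
    """Constant exogenous hormone concentrations applied to the medium.

    Doses enter only the Integrator equation (production sensing ABA + ABA_exo,
    degradation sensing GA + GA_exo); they never add to the endogenous ABA/GA
    dynamics themselves.
    """

    ABA_exo: float = 0.0
    GA_exo: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ABA_exo", "GA_exo"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


ZERO_DOSE = ExogenousDose()


def _check_input(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("regulatory-function input must be finite")
    if np.any(arr < 0):
        raise ValueError("regulatory-function input must be >= 0")
    return arr


def _hill_inc(y, C: float, theta: float, h: float):
    # internal, unvalidated; y >= 0 assumed
    yh = np.power(y, h)
    return C * yh / (theta**h + yh)


def _hill_dec(y, C: float, theta: float, h: float):
    return C / (1.0 + np.power(np.asarray(y, dtype=float) / theta, h))


def hill_increasing(y, C: float, theta: float, h: float):
    """Increasing Hill regulatory function ``C * y^h / (theta^h + y^h)``.

    Half-maximal at ``y == theta``, bounded in ``[0, C)``.  Accepts scalars
    or arrays of non-negative concentrations.
    """
    if C <= 0 or theta <= 0 or h <= 0:
        raise ValueError("C, theta and h must be > 0")
    arr = _check_input(y)
    out = _hill_inc(arr, C, theta, h)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def hill_decreasing(y, C: float, theta: float, h: float):
    """Decreasing Hill regulatory function ``C / (1 + (y/theta)^h)``.

    Equals ``C`` at ``y == 0`` and is half-maximal at ``y == theta``.
    Complements :func:`hill_increasing`: for identical arguments the two sum
    to ``C`` exactly.
    """
    if C <= 0 or theta <= 0 or h <= 0:
        raise ValueError("C, theta and h must be > 0")
    arr = _check_input(y)
    out = _hill_dec(arr, C, theta, h)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def _terms_cols(S: np.ndarray, p: ModelParameters, dose: ExogenousDose):
    """Production and degradation magnitudes for a batch of states.

    ``S`` has shape (n, 4) with columns ordered as :data:`STATE_VARS`.
    Returns ``(production, degradation)`` arrays of the same shape; the
    drift is their difference and the Langevin noise intensity their sum.
    """
    A, G, I, Z = S[..., 0], S[..., 1], S[..., 2], S[..., 3]
    h = p.h
    prod = np.empty_like(S)
    deg = np.empty_like(S)
    prod[..., 0] = p.beta_ABA + _hill_inc(I, p.C_ABA_I, p.theta_ABA_I, h)
    deg[..., 0] = p.v_ABA * A
    prod[..., 1] = p.beta_GA + p.beta_GA_Z * Z + _hill_dec(I, p.C_GA_I, p.theta_GA_I, h)
    deg[..., 1] = p.v_GA * G
    prod[..., 2] = p.beta_I + _hill_inc(A + dose.ABA_exo, p.C_I_ABA, p.theta_I_ABA, h)
    deg[..., 2] = (p.v_I + _hill_inc(G + dose.GA_exo, p.C_I_GA, p.theta_I_GA, h)) * I
    prod[..., 3] = p.beta_Z
    deg[..., 3] = p.v_Z * Z
    return prod, deg


def production_degradation_terms(
    state: SystemState, p: ModelParameters, dose: ExogenousDose | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable (production, degradation) magnitudes at ``state``."""
    dose = dose or ZERO_DOSE
    S = state.as_array()[np.newaxis, :]
    prod, deg = _terms_cols(S, p, dose)
    return prod[0], deg[0]


def drift(
    state: SystemState, p: ModelParameters, dose: ExogenousDose | None = None
) -> np.ndarray:
    """Deterministic right-hand side d(ABA, GA, I, Z)/dt at ``state``."""
    prod, deg = production_degradation_terms(state, p, dose)
    return prod - deg


def noise_prefactor(V: float) -> float:
    """Langevin noise prefactor: squared amplitude = (prod + deg) * prefactor.

    Isolated so the convention (1/(2V) here) is a one-line change; the
    1/sqrt(V) scaling of amplitudes holds regardless.
    """
    if V <= 0:
        raise ValueError(f"V must be > 0, got {V!r}")
    return 1.0 / (2.0 * V)


def diffusion_amplitude(
    state: SystemState, p: ModelParameters, dose: ExogenousDose | None = None
) -> np.ndarray:
    """Multipliers of the unit-intensity Gaussian white noises, per variable.

    ``sqrt((production + degradation) / (2 V))`` component-wise; vanishes as
    ``V -> inf`` (deterministic limit of the chemical Langevin equations).
    """
    prod, deg = production_degradation_terms(state, p, dose)
    return np.sqrt(noise_prefactor(p.V) * (prod + deg))
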