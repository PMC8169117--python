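"""Stochastic (chemical Langevin) integration of seed ensembles.

Each seed is an independent realization of the four-variable Langevin system,
integrated with the stochastic Heun scheme under the Ito interpretation with
an absorptive barrier at zero.  A seed is tagged germinated at the end of the
first step at which its Integrator concentration lies below the germination
threshold; seeds that never cross by the final time are censored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ZERO_DOSE,
    ExogenousDose,
    ModelParameters,
    SystemState,
    _terms_cols,
    noise_prefactor,
)
from .steady import solve_fixed_points

__all__ = [
    "SimulationSettings",
    "EnsembleResult",
    "initial_state",
    "heun_step",
    "simulate_seed",
    "simulate_ensemble",
    "deterministic_crossing_time",
]

CENSORED = None  # sentinel returned by simulate_seed for non-germinating seeds


@dataclass(frozen=True)
class SimulationSettings:
    """Integration and ensemble settings.

    ``dt`` and ``t_final`` default to the reference numerical protocol
    (dt = 0.1, stop at time 1000).  ``germination_threshold`` is the
    Integrator level below which a seed counts as germinated; the default 1.0
    sits between the post-rise germination branch and the pre-rise dormant
    state of the reference parameterization (see
    :func:`check_threshold_bracketing`).
    """

    dt: float = 0.1
    t_final: float = 1000.0
    n_seeds: int = 1000
    germination_threshold: float = 1.0
    rng_seed: int = 0
    record_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_final <= self.dt:
            raise ValueError("t_final must exceed dt")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.germination_threshold <= 0:
            raise ValueError("germination_threshold must be > 0")

    def replace(self, **overrides) -> "SimulationSettings":
        import dataclasses

        return dataclasses.replace(self, **overrides)


@dataclass
class EnsembleResult:
    """Per-seed germination times for one stochastic ensemble.

    ``times_per_seed`` holds one entry per seed, NaN for censored seeds.
    ``trajectories`` (present only when requested) has shape
    (n_steps + 1, n_seeds, 4) and ``trajectory_times`` (n_steps + 1,).
    """

    times_per_seed: np.ndarray
    n_seeds: int
    provenance: dict = field(repr=False)
    trajectories: np.ndarray | None = field(default=None, repr=False)
    trajectory_times: np.ndarray | None = field(default=None, repr=False)

    @property
    def germination_times(self) -> np.ndarray:
        """Times of germinated seeds only, in seed order."""
        return self.times_per_seed[~np.isnan(self.times_per_seed)]

    @property
    def n_censored(self) -> int:
        return int(np.isnan(self.times_per_seed).sum())

    @property
    def fraction_germinated(self) -> float:
        return 1.0 - self.n_censored / self.n_seeds

    def to_csv(self, path, write_provenance: bool = True) -> None:
        """Write (seed_id, germination_time-or-NA) CSV plus a JSON sidecar."""
        path = Path(path)
        frame = pd.DataFrame(
            {
                "seed_id": np.arange(self.n_seeds),
                "germination_time": self.times_per_seed,
            }
        )
        frame.to_csv(path, index=False, na_rep="NA")
        if write_provenance:
            sidecar = path.with_suffix(path.suffix + ".provenance.json")
            sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))


def initial_state(p: ModelParameters, tol: float = 1e-10) -> SystemState:
    """Pre-sowing initial condition shared by every seed of an ensemble.

    The ABA/GA/I components sit at the pre-rise stable fixed point with the
    highest Integrator value; Z starts at 0 so that it relaxes toward
    beta_Z / v_Z during the run, producing the sowing-induced rise in GA
    production.  Exogenous doses do not alter the initial state (treatments
    start at sowing).
    """
    pre = [fp for fp in solve_fixed_points(p, z_value=0.0, tol=tol) if fp.is_stable]
    if not pre:
        raise ValueError("no stable pre-rise fixed point: cannot set initial state")
    top = max(pre, key=lambda fp: fp.state.I)
    return SystemState(ABA=top.state.ABA, GA=top.state.GA, I=top.state.I, Z=0.0, t=0.0)


def _heun_update(
    S: np.ndarray,
    p: ModelParameters,
    dose: ExogenousDose,
    dt: float,
    dW: np.ndarray,
    prefactor: float,
) -> np.ndarray:
    """One stochastic Heun step for a batch of states, absorbing at 0.

    The same Wiener increment ``dW`` multiplies the diffusion amplitude
    evaluated at the *current* state in both stages (Ito); only the drift is
    averaged between the current and predictor states.  Negative components
    are clamped to zero after each stage.
    """
    prod, deg = _terms_cols(S, p, dose)
    f0 = prod - deg
    noise = np.sqrt(prefactor * (prod + deg)) * dW
    pred = S + f0 * dt + noise
    np.maximum(pred, 0.0, out=pred)
    prod_p, deg_p = _terms_cols(pred, p, dose)
    out = S + 0.5 * (f0 + (prod_p - deg_p)) * dt + noise
    np.maximum(out, 0.0, out=out)
    return out


def heun_step(
    state: SystemState,
    p: ModelParameters,
    dose: ExogenousDose | None,
    dt: float,
    noise_increments: np.ndarray,
) -> SystemState:
    """Advance one state by ``dt`` using the stochastic Heun scheme.

    ``noise_increments`` are the four Wiener increments for this step (mean
    0, variance dt).  Pass zeros to obtain the deterministic (second-order
    Heun) ODE step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dose = dose or ZERO_DOSE
    dW = np.asarray(noise_increments, dtype=float).reshape(1, 4)
    S = state.as_array()[np.newaxis, :]
    out = _heun_update(S, p, dose, dt, dW, noise_prefactor(p.V))[0]
    if not np.all(np.isfinite(out)):
        bad = [name for name, v in zip(("ABA", "GA", "I", "Z"), out) if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite update in component(s): {', '.join(bad)}")
    return SystemState.from_array(out, t=state.t + dt)


def _resolve_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_ensemble(
    p: ModelParameters,
    dose: ExogenousDose | None = None,
    settings: SimulationSettings | None = None,
) -> EnsembleResult:
    """Integrate ``settings.n_seeds`` independent seeds and collect crossing times.

    All seeds share the deterministic initial state; randomness comes from a
    generator seeded by ``settings.rng_seed`` alone, so results are exactly
    reproducible.  Germinated seeds are removed from the active set (their
    trajectories are no longer advanced) unless trajectories are recorded.
    The crossing time is the end time of the first step with I below the
    germination threshold (no within-step interpolation).
    """
    dose = dose or ZERO_DOSE
    settings = settings or SimulationSettings()
    p0 = initial_state(p)
    n = settings.n_seeds
    dt = settings.dt
    n_steps = int(round(settings.t_final / dt))
    prefactor = noise_prefactor(p.V)
    rng = np.random.default_rng(np.random.SeedSequence(settings.rng_seed))

    S = np.tile(p0.as_array(), (n, 1))
    times = np.full(n, np.nan)
    alive = np.arange(n)

    record = settings.record_trajectories
    if record:
        traj = np.empty((n_steps + 1, n, 4))
        traj[0] = S
        traj_t = dt * np.arange(n_steps + 1)

    sqrt_dt = np.sqrt(dt)
    threshold = settings.germination_threshold
    for step in range(1, n_steps + 1):
        if alive.size == 0 and not record:
            break
        dW = rng.standard_normal((S.shape[0], 4)) * sqrt_dt
        S = _heun_update(S, p, dose, dt, dW, prefactor)
        if not np.all(np.isfinite(S)):
            raise FloatingPointError(f"non-finite state at step {step}")
        t = step * dt
        if record:
            traj[step] = S
            crossed = (S[:, 2] < threshold) & np.isnan(times)
            times[crossed] = t
        else:
            crossed = S[:, 2] < threshold
            if crossed.any():
                times[alive[crossed]] = t
                keep = ~crossed
                alive = alive[keep]
                S = S[keep]

    provenance = {
        "parameters": p.to_dict(),
        "dose": asdict(dose),
        "settings": asdict(settings),
    }
    return EnsembleResult(
        times_per_seed=times,
        n_seeds=n,
        provenance=provenance,
        trajectories=traj if record else None,
        trajectory_times=traj_t if record else None,
    )


def simulate_seed(
    p: ModelParameters,
    dose: ExogenousDose | None,
    settings: SimulationSettings,
    rng_stream=None,
) -> float | None:
    """Simulate a single seed; returns its germination time or ``None`` if censored.

    ``rng_stream`` may be an int seed, a ``SeedSequence`` or a ``Generator``;
    when omitted, ``settings.rng_seed`` is used.
    """
    dose = dose or ZERO_DOSE
    p0 = initial_state(p)
    dt = settings.dt
    n_steps = int(round(settings.t_final / dt))
    prefactor = noise_prefactor(p.V)
    rng = _resolve_rng(settings.rng_seed if rng_stream is None else rng_stream)
    S = p0.as_array()[np.newaxis, :]
    sqrt_dt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        dW = rng.standard_normal((1, 4)) * sqrt_dt
        S = _heun_update(S, p, dose, dt, dW, prefactor)
        if S[0, 2] < settings.germination_threshold:
            return step * dt
    return CENSORED


def deterministic_crossing_time(
    p: ModelParameters,
    dose: ExogenousDose | None = None,
    settings: SimulationSettings | None = None,
) -> float | None:
    """Threshold-crossing time of the noiseless (ODE) dynamics, or ``None``.

    Uses the same Heun stepping and step-end crossing convention as the
    stochastic path, so it is the exact V -> infinity limit of
    :func:`simulate_seed`.
    """
    dose = dose or ZERO_DOSE
    settings = settings or SimulationSettings(n_seeds=1)
    p0 = initial_state(p)
    dt = settings.dt
    n_steps = int(round(settings.t_final / dt))
    S = p0.as_array()[np.newaxis, :]
    dW = np.zeros((1, 4))
    for step in range(1, n_steps + 1):
        S = _heun_update(S, p, dose, dt, dW, 0.0)
        if S[0, 2] < settings.germination_threshold:
            return step * dt
    return CENSORED


def check_threshold_bracketing(
    p: ModelParameters, threshold: float = 1.0, tol: float = 1e-10
) -> bool:
    """True when ``threshold`` separates germination from dormancy.

    Verifies that the lowest post-rise stable Integrator level lies below the
    threshold and the highest pre-rise stable level above it — the bracketing
    a meaningful germination threshold must satisfy.
    """
    from .steady import post_rise_z

    pre = [f.state.I for f in solve_fixed_points(p, 0.0, tol=tol) if f.is_stable]
    post = [
        f.state.I for f in solve_fixed_points(p, post_rise_z(p), tol=tol) if f.is_stable
    ]
    if not pre or not post:
        return False
    return min(post) < threshold < max(pre)
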