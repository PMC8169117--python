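"""Deterministic fixed points, stability and dynamical-regime classification.

At steady state ABA and GA are slaved to the Integrator level, reducing the
fixed-point problem to one scalar equation in I.  Roots are bracketed on a
geometric grid and refined with Brent's method; stability follows from the
sign of the reduced dI/dt on either side of each root.

"Pre-rise" evaluates the system with the Z-driven GA production term absent
(before the sowing signal has risen); "post-rise" uses the relaxed value
Z = beta_Z / v_Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    ZERO_DOSE,
    ExogenousDose,
    ModelParameters,
    SystemState,
    _hill_dec,
    _hill_inc,
)

__all__ = [
    "FixedPoint",
    "RegimeReport",
    "solve_fixed_points",
    "classify_regime",
    "nullcline_sections",
    "post_rise_z",
    "regime_report_frame",
]

STABLE = "stable"
UNSTABLE = "unstable"

#: default bracketing grid for the Integrator variable
GRID_LO = 1e-6
GRID_HI = 1e4
POINTS_PER_DECADE = 50


def post_rise_z(p: ModelParameters) -> float:
    """Relaxed sowing-signal level beta_Z / v_Z."""
    return p.beta_Z / p.v_Z


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the deterministic dynamics with its stability label."""

    state: SystemState
    stability: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == STABLE


@dataclass(frozen=True)
class RegimeReport:
    """Regime label and biological-relevance flags for one parameter set."""

    n_stable_post_rise: int
    regime: str
    flag_instantaneous_germination: bool
    flag_deterministic_non_germination: bool
    flag_germinates_without_rise: bool
    threshold: float
    pre_rise: tuple[FixedPoint, ...] = field(repr=False, default=())
    post_rise: tuple[FixedPoint, ...] = field(repr=False, default=())

    @property
    def biologically_relevant(self) -> bool:
        return not (
            self.flag_instantaneous_germination
            or self.flag_deterministic_non_germination
            or self.flag_germinates_without_rise
        )

    def to_row(self) -> dict:
        return {
            "regime": self.regime,
            "n_stable_post_rise": self.n_stable_post_rise,
            "flag_instantaneous_germination": int(self.flag_instantaneous_germination),
            "flag_deterministic_non_germination": int(
                self.flag_deterministic_non_germination
            ),
            "flag_germinates_without_rise": int(self.flag_germinates_without_rise),
            "biologically_relevant": int(self.biologically_relevant),
            "threshold": self.threshold,
        }


_REGIME_BY_COUNT = {1: "monostable", 2: "bistable", 3: "tristable"}


def _slaved_aba(I, p: ModelParameters):
    return (p.beta_ABA + _hill_inc(I, p.C_ABA_I, p.theta_ABA_I, p.h)) / p.v_ABA


def _slaved_ga(I, p: ModelParameters, z_value: float):
    return (
        p.beta_GA + p.beta_GA_Z * z_value + _hill_dec(I, p.C_GA_I, p.theta_GA_I, p.h)
    ) / p.v_GA


def integrator_rate(I, p: ModelParameters, z_value: float, dose: ExogenousDose):
    """Reduced dI/dt with ABA and GA slaved to their steady-state values."""
    aba = _slaved_aba(I, p) + dose.ABA_exo
    ga = _slaved_ga(I, p, z_value) + dose.GA_exo
    return (
        p.beta_I
        + _hill_inc(aba, p.C_I_ABA, p.theta_I_ABA, p.h)
        - (p.v_I + _hill_inc(ga, p.C_I_GA, p.theta_I_GA, p.h)) * I
    )


def nullcline_rhs(I, p: ModelParameters, z_value: float, dose: ExogenousDose):
    """Right-hand side of the scalar fixed-point equation I = rhs(I)."""
    aba = _slaved_aba(I, p) + dose.ABA_exo
    ga = _slaved_ga(I, p, z_value) + dose.GA_exo
    return (p.beta_I + _hill_inc(aba, p.C_I_ABA, p.theta_I_ABA, p.h)) / (
        p.v_I + _hill_inc(ga, p.C_I_GA, p.theta_I_GA, p.h)
    )


def _stability_label(p, z_value, dose, root: float) -> str:
    eps = max(1e-9, 1e-5 * root)
    below = integrator_rate(max(root - eps, 0.0), p, z_value, dose)
    above = integrator_rate(root + eps, p, z_value, dose)
    return STABLE if (below > 0 and above < 0) else UNSTABLE


def solve_fixed_points(
    p: ModelParameters,
    z_value: float,
    dose: ExogenousDose | None = None,
    tol: float = 1e-10,
    grid_lo: float = GRID_LO,
    grid_hi: float = GRID_HI,
    points_per_decade: int = POINTS_PER_DECADE,
) -> list[FixedPoint]:
    """Find all steady states of the reduced scalar Integrator equation.

    Sign changes of ``I - rhs(I)`` are bracketed on a geometric grid in I and
    refined with Brent's method to ``|I - rhs(I)| < tol``.  Returned in
    increasing I order; stable and unstable roots alternate.

    Parameters
    ----------
    z_value:
        Sowing-signal level to use in the GA balance: 0 for pre-rise,
        :func:`post_rise_z` for post-rise, or any caller-supplied value.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    dose = dose or ZERO_DOSE
    if z_value < 0:
        raise ValueError("z_value must be >= 0")

    n_decades = np.log10(grid_hi / grid_lo)
    grid = np.geomspace(grid_lo, grid_hi, int(np.ceil(n_decades * points_per_decade)) + 1)
    f_vals = grid - nullcline_rhs(grid, p, z_value, dose)

    def f(I: float) -> float:
        return I - float(nullcline_rhs(I, p, z_value, dose))

    roots: list[float] = []
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], f_vals[:-1], f_vals[1:]):
        if flo == 0.0:
            roots.append(float(lo))
        elif flo * fhi < 0:
            roots.append(brentq(f, float(lo), float(hi), xtol=1e-14, rtol=1e-15))
    if f_vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    if not roots:
        warnings.warn(
            "no fixed point detected on the bracketing grid "
            "(degenerate parameterization)",
            stacklevel=2,
        )
        return []

    out = []
    for root in sorted(roots):
        residual = abs(f(root))
        if residual >= tol:
            raise RuntimeError(
                f"root refinement failed: residual {residual:.3e} >= tol {tol:.3e}"
            )
        state = SystemState(
            ABA=float(_slaved_aba(root, p)),
            GA=float(_slaved_ga(root, p, z_value)),
            I=float(root),
            Z=float(z_value),
        )
        out.append(
            FixedPoint(
                state=state,
                stability=_stability_label(p, z_value, dose, root),
                residual=residual,
            )
        )
    return out


def _stable_levels(points: list[FixedPoint]) -> list[float]:
    return [fp.state.I for fp in points if fp.is_stable]


def classify_regime(
    p: ModelParameters,
    dose: ExogenousDose | None = None,
    threshold: float = 1.0,
    check_no_rise_germination="deterministic",
    tol: float = 1e-10,
) -> RegimeReport:
    """Classify a parameter set into mono-/bi-/tristable and relevance flags.

    The regime counts stable steady states *after* the rise of GA production
    (Z = beta_Z / v_Z).  Flags:

    - instantaneous germination: highest pre-rise stable I already below the
      germination threshold (seed would germinate at sowing);
    - deterministic non-germination: lowest post-rise stable I above the
      threshold (germination only via fluctuations);
    - germinates without rise: per ``check_no_rise_germination`` —
      ``"deterministic"`` uses the proxy "lowest pre-rise stable I below the
      threshold"; a callable ``(p, dose) -> bool`` may implement the
      stochastic check (simulate with beta_GA_Z = 0 and flag any
      germination); ``"none"`` skips the check.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dose = dose or ZERO_DOSE

    pre = solve_fixed_points(p, z_value=0.0, dose=dose, tol=tol)
    post = solve_fixed_points(p, z_value=post_rise_z(p), dose=dose, tol=tol)
    if not pre:
        raise ValueError("pre-rise fixed-point equation has no detected root")
    if not post:
        raise ValueError("post-rise fixed-point equation has no detected root")

    pre_stable = _stable_levels(pre)
    post_stable = _stable_levels(post)
    if not pre_stable or not post_stable:
        raise ValueError("no stable fixed point found (degenerate parameterization)")

    n_stable = len(post_stable)
    regime = _REGIME_BY_COUNT.get(n_stable)
    if regime is None:
        raise ValueError(f"unexpected number of stable post-rise states: {n_stable}")

    if check_no_rise_germination == "deterministic":
        no_rise = min(pre_stable) < threshold
    elif check_no_rise_germination == "none":
        no_rise = False
    elif callable(check_no_rise_germination):
        no_rise = bool(check_no_rise_germination(p, dose))
    else:
        raise ValueError(
            "check_no_rise_germination must be 'deterministic', 'none' or a callable"
        )

    return RegimeReport(
        n_stable_post_rise=n_stable,
        regime=regime,
        flag_instantaneous_germination=max(pre_stable) < threshold,
        flag_deterministic_non_germination=min(post_stable) > threshold,
        flag_germinates_without_rise=no_rise,
        threshold=threshold,
        pre_rise=tuple(pre),
        post_rise=tuple(post),
    )


def nullcline_sections(
    p: ModelParameters,
    z_value: float,
    dose: ExogenousDose | None = None,
    I_grid=None,
) -> pd.DataFrame:
    """Tabulate both sides of the scalar fixed-point equation along a grid.

    Crossings of ``lhs`` (= I) and ``rhs`` bracket the fixed points returned
    by :func:`solve_fixed_points`; useful for plotting the graphical solution.
    """
    dose = dose or ZERO_DOSE
    if I_grid is None:
        I_grid = np.geomspace(GRID_LO, GRID_HI, 2001)
    grid = np.asarray(I_grid, dtype=float)
    if grid.ndim != 1 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("I_grid must be 1-D, positive and strictly increasing")
    rhs = nullcline_rhs(grid, p, z_value, dose)
    return pd.DataFrame({"I": grid, "lhs": grid, "rhs": rhs})


def regime_report_frame(reports: dict | list) -> pd.DataFrame:
    """Tidy one-row-per-parameter-set export of regime reports.

    Accepts a list of (label, RegimeReport) pairs or a dict mapping labels to
    reports; flags are written as 0/1.
    """
    items = reports.items() if isinstance(reports, dict) else reports
    rows = []
    for label, report in items:
        row = {"label": label}
        row.update(report.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
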