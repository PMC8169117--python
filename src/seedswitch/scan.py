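"""1D/2D parameter scans and exogenous hormone dose-response experiments.

Every grid point is classified into its deterministic regime, screened for
biological relevance (no germination without the sowing-induced GA rise, no
instantaneous germination, no deterministic non-germination) and then
simulated with replicate stochastic ensembles.  Per-point RNG seeds are
derived deterministically from (master seed, point index, replicate index),
so scans are order-independent and safely parallelizable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExogenousDose, ModelParameters
from .simulate import SimulationSettings, simulate_ensemble
from .stats import TraitSummary, summarize_times
from .steady import RegimeReport, classify_regime

__all__ = [
    "ScanPoint",
    "geometric_grid",
    "scan",
    "scan_frame",
    "dose_response",
    "derive_seed",
    "no_rise_germination_check",
]

logger = logging.getLogger(__name__)


def geometric_grid(lo: float, hi: float, per_decade: int = 4) -> np.ndarray:
    """Logarithmically spaced values, ``per_decade`` per order of magnitude.

    The sequence starts at ``lo`` with ratio ``10**(1/per_decade)`` and is
    clipped to include ``hi`` as its last element.
    """
    if lo <= 0 or hi <= 0:
        raise ValueError("grid bounds must be > 0")
    if hi < lo:
        raise ValueError("hi must be >= lo")
    if per_decade < 1:
        raise ValueError("per_decade must be >= 1")
    if hi == lo:
        return np.array([lo], dtype=float)
    n = int(np.floor(per_decade * np.log10(hi / lo) + 1e-9))
    values = lo * 10.0 ** (np.arange(n + 1) / per_decade)
    if not np.isclose(values[-1], hi, rtol=1e-12):
        values = np.append(values, hi)
    values[-1] = hi
    return values


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed for (master, point, replicate, ...) keys."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


def no_rise_germination_check(
    p: ModelParameters,
    dose: ExogenousDose | None,
    settings: SimulationSettings,
    n_seeds: int,
    rng_seed: int,
) -> bool:
    """Stochastic pre-sowing check: does anything germinate with beta_GA_Z = 0?

    Simulates ``n_seeds`` seeds with the sowing-induced GA production term
    removed and reports whether any crossed the germination threshold —
    such parameterizations would allow germination before sowing and are not
    biologically relevant.
    """
    p_no_rise = p.replace(beta_GA_Z=0.0)
    check_settings = settings.replace(
        n_seeds=n_seeds, rng_seed=rng_seed, record_trajectories=False
    )
    result = simulate_ensemble(p_no_rise, dose, check_settings)
    return result.germination_times.size > 0


def _min_reportable(n_seeds: int, min_fraction: float) -> int:
    # >= 1% of sown, the 10-of-1000 boundary inclusive
    return max(1, math.ceil(min_fraction * n_seeds - 1e-9))


@dataclass
class ScanPoint:
    """Result bundle for one grid point of a parameter scan."""

    index: int
    overrides: dict[str, float]
    regime: RegimeReport
    traits: list[TraitSummary] = field(default_factory=list)
    replicate_seeds: list[int] = field(default_factory=list)

    @property
    def biologically_relevant(self) -> bool:
        return self.regime.biologically_relevant


def scan(
    base: ModelParameters,
    axes: list[tuple[str, np.ndarray]],
    settings: SimulationSettings,
    n_replicates: int = 3,
    no_rise_check_seeds: int = 40,
    min_report_fraction: float = 0.01,
    progress: bool = False,
) -> list[ScanPoint]:
    """Scan 1-2 parameters over grids, classifying and simulating each point.

    For each point of the (product) grid the deterministic regime is
    computed, the stochastic no-rise germination check run with
    ``no_rise_check_seeds`` seeds, and ``n_replicates`` independent
    ensembles of ``settings.n_seeds`` seeds simulated and summarized.
    Excluded (non-relevant) points keep their regime data; trait values are
    reported but flagged unreportable when germination is below
    ``min_report_fraction``.
    """
    if not 1 <= len(axes) <= 2:
        raise ValueError("scan supports 1 or 2 axes")
    valid = set(ModelParameters.field_names())
    for name, _ in axes:
        if name not in valid:
            raise ValueError(f"unknown parameter name: {name!r}")

    names = [name for name, _ in axes]
    grids = [np.asarray(grid, dtype=float) for _, grid in axes]
    combos = list(itertools.product(*grids))
    min_germ = _min_reportable(settings.n_seeds, min_report_fraction)

    points: list[ScanPoint] = []
    for index, values in enumerate(combos):
        overrides = dict(zip(names, map(float, values)))
        p = base.replace(**overrides)
        check_seed = derive_seed(settings.rng_seed, index, n_replicates)
        regime = classify_regime(
            p,
            threshold=settings.germination_threshold,
            check_no_rise_germination=lambda pp, dd: no_rise_germination_check(
                pp, dd, settings, no_rise_check_seeds, check_seed
            ),
        )
        point = ScanPoint(index=index, overrides=overrides, regime=regime)
        for rep in range(n_replicates):
            seed = derive_seed(settings.rng_seed, index, rep)
            result = simulate_ensemble(p, None, settings.replace(rng_seed=seed))
            point.traits.append(
                summarize_times(
                    result.germination_times,
                    n_sown=settings.n_seeds,
                    min_germinated=min_germ,
                )
            )
            point.replicate_seeds.append(seed)
        points.append(point)
        if progress:
            logger.info(
                "point %d/%d %s -> %s", index + 1, len(combos), overrides, regime.regime
            )
    n_excluded = sum(not pt.biologically_relevant for pt in points)
    if n_excluded:
        logger.info(
            "%d of %d scan points flagged not biologically relevant",
            n_excluded,
            len(points),
        )
    return points


def scan_frame(points: list[ScanPoint]) -> pd.DataFrame:
    """Tidy export: one row per point x replicate, flags as 0/1.

    CV/mean/mode are masked (NaN) for replicates failing the reporting
    filter; percentage germination is always present.
    """
    rows = []
    for pt in points:
        base = {"point": pt.index}
        base.update(pt.overrides)
        base.update(pt.regime.to_row())
        for rep, (summary, seed) in enumerate(zip(pt.traits, pt.replicate_seeds)):
            row = dict(base)
            row["replicate"] = rep
            row["rng_seed"] = seed
            masked = summary.reportable
            row["cv"] = summary.cv if masked else np.nan
            row["mean"] = summary.mean if masked else np.nan
            row["mode"] = summary.mode if masked else np.nan
            row["pct_germination"] = summary.pct_germination
            row["reportable"] = int(summary.reportable)
            rows.append(row)
    return pd.DataFrame(rows)


def dose_response(
    p_low: ModelParameters,
    p_high: ModelParameters,
    hormone: str,
    dose_grid,
    settings: SimulationSettings,
    n_replicates: int = 5,
    control_check_seeds: int = 4000,
    min_report_fraction: float = 0.01,
) -> pd.DataFrame:
    """Exogenous-hormone dose response for a low- and a high-variability class.

    ``hormone`` is ``"ABA"`` or ``"GA"``; ``dose_grid`` must contain 0 (the
    vehicle-control analogue).  For each class the control is required to be
    biologically valid — it must not fall in the spontaneous (instantaneous)
    germination region, must not germinate without the GA rise (stochastic
    check on ``control_check_seeds`` seeds), and must not fall in the
    deterministic non-germination region; violations raise ``ValueError``.
    Applied doses are checked the same way deterministically and flagged,
    not rejected.

    Returns a tidy frame with one row per class x dose x replicate.
    """
    if hormone not in ("ABA", "GA"):
        raise ValueError("hormone must be 'ABA' or 'GA'")
    doses = np.asarray(dose_grid, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if not np.any(doses == 0):
        raise ValueError("dose_grid must include 0 (control)")

    def make_dose(level: float) -> ExogenousDose:
        if hormone == "ABA":
            return ExogenousDose(ABA_exo=level)
        return ExogenousDose(GA_exo=level)

    min_germ = _min_reportable(settings.n_seeds, min_report_fraction)
    rows = []
    for class_index, (line_class, p) in enumerate(
        [("low_variability", p_low), ("high_variability", p_high)]
    ):
        control_seed = derive_seed(settings.rng_seed, class_index, 10**6)
        control_report = classify_regime(
            p,
            dose=make_dose(0.0),
            threshold=settings.germination_threshold,
            check_no_rise_germination=lambda pp, dd: no_rise_germination_check(
                pp, dd, settings, control_check_seeds, control_seed
            ),
        )
        violations = []
        if control_report.flag_instantaneous_germination:
            violations.append("spontaneous (instantaneous) germination region")
        if control_report.flag_germinates_without_rise:
            violations.append("germination without the rise of GA production")
        if control_report.flag_deterministic_non_germination:
            violations.append("deterministic non-germination region")
        if violations:
            raise ValueError(
                f"{line_class} control fails validity check(s): "
                + "; ".join(violations)
            )

        for dose_index, level in enumerate(doses):
            dose = make_dose(float(level))
            report = classify_regime(
                p,
                dose=dose,
                threshold=settings.germination_threshold,
                check_no_rise_germination="none",
            )
            for rep in range(n_replicates):
                seed = derive_seed(settings.rng_seed, class_index, dose_index, rep)
                result = simulate_ensemble(p, dose, settings.replace(rng_seed=seed))
                summary = summarize_times(
                    result.germination_times,
                    n_sown=settings.n_seeds,
                    min_germinated=min_germ,
                )
                row = {
                    "line_class": line_class,
                    "hormone": hormone,
                    "dose": float(level),
                    "replicate": rep,
                    "rng_seed": seed,
                    "regime": report.regime,
                    "flag_instantaneous_germination": int(
                        report.flag_instantaneous_germination
                    ),
                    "flag_deterministic_non_germination": int(
                        report.flag_deterministic_non_germination
                    ),
                }
                masked = summary.reportable
                row["cv"] = summary.cv if masked else np.nan
                row["mean"] = summary.mean if masked else np.nan
                row["mode"] = summary.mode if masked else np.nan
                row["pct_germination"] = summary.pct_germination
                row["reportable"] = int(summary.reportable)
                rows.append(row)
    return pd.DataFrame(rows)
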