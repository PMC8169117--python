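"""Germination-time trait statistics: CV, mean, mode, percentage germination.

Works both on simulated first-passage times and on experimental-style
day-binned germination count tables, applying the study filters: plates with
fewer than 10 germinated seeds are excluded, and simulated CV/mode are only
reported when at least 1% of the sown seeds germinated.  CV, mean and mode
are computed over germinated seeds only; censored seeds contribute to the
sown total and hence to the germination percentage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TraitSummary",
    "GerminationCountTable",
    "summarize_times",
    "summarize_counts",
    "aggregate_line",
    "aggregate_lines",
    "trait_correlation",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("line_id", "replicate_id", "plate_id", "day", "n_germinated", "n_sown")

#: minimum germinated seeds for a plate / simulated ensemble to be reportable
MIN_GERMINATED = 10


@dataclass(frozen=True)
class TraitSummary:
    """Trait values for one sample of germination times.

    ``cv``, ``mean`` and ``mode`` are NaN when undefined (no, or too few,
    germinated seeds); ``reportable`` records whether the sample passed the
    minimum-germination filter.
    """

    cv: float
    mean: float
    mode: float
    pct_germination: float
    n_germinated: int
    n_sown: int
    reportable: bool

    def to_row(self) -> dict:
        return {
            "cv": self.cv,
            "mean": self.mean,
            "mode": self.mode,
            "pct_germination": self.pct_germination,
            "n_germinated": self.n_germinated,
            "n_sown": self.n_sown,
            "reportable": self.reportable,
        }


def _mode_of_times(times: np.ndarray, bin_width: float) -> float:
    # bins (0, w], (w, 2w], ... labelled by their right edge; ties -> earliest
    idx = np.ceil(times / bin_width - 1e-12).astype(int)
    counts = np.bincount(idx)
    return float(np.argmax(counts) * bin_width)


def summarize_times(
    times,
    n_sown: int,
    bin_width: float = 1.0,
    min_germinated: int = MIN_GERMINATED,
) -> TraitSummary:
    """Summarize a sample of germination times against the number sown.

    CV uses the sample (n-1) standard deviation.  The mode is the label
    (right edge) of the most populated histogram bin of width ``bin_width``
    anchored at 0, with ties broken toward the earliest bin; with daily
    scoring (integer day values, bin width 1) this is simply the most common
    day.  The summary is reportable when at least ``min_germinated`` seeds
    germinated (default 10, i.e. >= 1% of 1000 sown).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and > 0")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_germ = t.size
    if n_sown < n_germ:
        raise ValueError("n_sown must be >= number of germination times")

    pct = 100.0 * n_germ / n_sown
    if n_germ == 0:
        return TraitSummary(
            cv=math.nan,
            mean=math.nan,
            mode=math.nan,
            pct_germination=0.0,
            n_germinated=0,
            n_sown=n_sown,
            reportable=False,
        )
    mean = float(t.mean())
    sd = float(t.std(ddof=1)) if n_germ > 1 else math.nan
    return TraitSummary(
        cv=sd / mean if n_germ > 1 else math.nan,
        mean=mean,
        mode=_mode_of_times(t, bin_width),
        pct_germination=pct,
        n_germinated=n_germ,
        n_sown=n_sown,
        reportable=n_germ >= min_germinated,
    )


@dataclass
class GerminationCountTable:
    """Day-binned germination counts per (line, replicate, plate).

    Thin wrapper over a tidy DataFrame with columns ``line_id,
    replicate_id, plate_id, day, n_germinated, n_sown`` — one row per
    scoring day with at least one newly germinated seed.  ``n_sown`` is a
    per-plate constant.
    """

    frame: pd.DataFrame

    PLATE_KEY = ["line_id", "replicate_id", "plate_id"]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            return
        if (df["day"] < 1).any() or (df["day"] != df["day"].astype(int)).any():
            raise ValueError("day must be an integer >= 1")
        if (df["n_germinated"] < 0).any():
            raise ValueError("n_germinated must be >= 0")
        for key, grp in df.groupby(self.PLATE_KEY, sort=False):
            if grp["n_sown"].nunique() != 1:
                raise ValueError(f"plate {key}: n_sown must be constant within a plate")
            if not grp["day"].is_monotonic_increasing or grp["day"].duplicated().any():
                raise ValueError(f"plate {key}: days must be strictly increasing")
            if grp["n_germinated"].sum() > grp["n_sown"].iloc[0]:
                raise ValueError(f"plate {key}: germinated seeds exceed seeds sown")

    @classmethod
    def from_records(cls, records) -> "GerminationCountTable":
        return cls(pd.DataFrame.from_records(records, columns=list(COUNT_COLUMNS)))

    @classmethod
    def read_csv(cls, path) -> "GerminationCountTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plates(self):
        """Iterate (key-tuple, per-plate sub-frame) pairs."""
        yield from self.frame.groupby(self.PLATE_KEY, sort=False)


def summarize_counts(
    table: GerminationCountTable, min_plate_germinated: int = MIN_GERMINATED
) -> pd.DataFrame:
    """Per-plate trait summaries from a day-binned count table.

    Each plate's counts are expanded to one integer day value per germinated
    seed and passed through :func:`summarize_times` with 1-day bins.  Plates
    with fewer than ``min_plate_germinated`` germinated seeds are marked
    ``reportable = False`` and are skipped by :func:`aggregate_line`.
    """
    rows = []
    for (line_id, replicate_id, plate_id), grp in table.plates():
        days = np.repeat(grp["day"].to_numpy(), grp["n_germinated"].to_numpy())
        summary = summarize_times(
            days,
            n_sown=int(grp["n_sown"].iloc[0]),
            bin_width=1.0,
            min_germinated=min_plate_germinated,
        )
        row = {"line_id": line_id, "replicate_id": replicate_id, "plate_id": plate_id}
        row.update(summary.to_row())
        rows.append(row)
    out = pd.DataFrame(rows)
    n_excluded = int((~out["reportable"]).sum()) if len(out) else 0
    if n_excluded:
        logger.info(
            "excluded %d of %d plates with < %d germinated seeds",
            n_excluded,
            len(out),
            min_plate_germinated,
        )
    return out


TRAITS = ("cv", "mean", "mode", "pct_germination")


def aggregate_line(per_plate: pd.DataFrame) -> pd.Series | None:
    """Line-level traits: unweighted mean of the reportable per-plate values.

    Returns ``None`` (with a logged reason) when no plate is reportable.
    """
    kept = per_plate[per_plate["reportable"]]
    if len(kept) == 0:
        line = per_plate["line_id"].iloc[0] if len(per_plate) else "<empty>"
        logger.info("line %s excluded: no plate passed the germination filter", line)
        return None
    values = {trait: float(kept[trait].mean()) for trait in TRAITS}
    values["n_plates"] = int(len(kept))
    return pd.Series(values)


def aggregate_lines(per_plate: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`aggregate_line` per line; excluded lines are dropped."""
    rows = {}
    for line_id, grp in per_plate.groupby("line_id", sort=False):
        agg = aggregate_line(grp)
        if agg is not None:
            rows[line_id] = agg
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "line_id"
    return out


def trait_correlation(
    line_summaries: pd.DataFrame, trait_x: str, trait_y: str
) -> tuple[float, int]:
    """Spearman rank correlation between two line-level traits.

    NaN lines are excluded pairwise; at least 3 complete pairs are required.
    Returns ``(rho, n_lines_used)``.
    """
    x = line_summaries[trait_x].to_numpy(dtype=float)
    y = line_summaries[trait_y].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 lines with both traits defined")
    rho, _ = sps.spearmanr(x[keep], y[keep])
    return float(rho), int(keep.sum())
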