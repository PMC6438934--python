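"""Z-score reference tables on the EFW scale.

The growth model lives on the sqrt-gram scale, where the posterior
predictive distribution of a new fetus-visit is (approximately) normal
with week-specific mean ``m_w`` and sd ``s_w``.  A reference table cell at
week ``w`` and Z-score ``z`` is the EFW quantile at level Phi(z), obtained
either empirically from a predictive sample (squared, then quantile) or in
closed form as ``(m_w + z*s_w)**2``; the two agree because squaring is
monotone on the positive axis.

Cells are rounded half-up to integer grams for presentation; the unrounded
values remain available.  Percentile labels attached to Z levels are
``100*Phi(z)`` truncated (not rounded) to two decimals — truncation is the
rule that reproduces the conventional label set 2.27 / 6.68 / 50.00 /
93.31 / 97.72 for z in {-2, -1.5, 0, 1.5, 2}.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_Z_LEVELS: tuple[float, ...] = (-2.0, -1.5, 0.0, 1.5, 2.0)
DEFAULT_WEEK_GRID: tuple[int, ...] = tuple(range(16, 38))

#: EFW Z-score below which a measurement is flagged as a fetal growth
#: restriction candidate (the Japanese diagnostic threshold).
FGR_Z_THRESHOLD = -1.5


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, ties away from zero-half upward."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def z_to_percentile(z: float) -> float:
    """100*Phi(z) truncated (floored) to two decimals.

    Truncation, not rounding: Phi(-2) = 2.275...% must print as 2.27.
    """
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return math.floor(100.0 * stats.norm.cdf(z) * 100.0) / 100.0


def percentile_label(z: float) -> str:
    """Two-decimal percentile string for a Z level, e.g. -1.5 -> '6.68'."""
    return f"{z_to_percentile(z):.2f}"


@dataclass
class PredictiveMoments:
    """Week-indexed mean and sd of the sqrt-EFW predictive distribution."""

    weeks: np.ndarray  # int weeks
    m: np.ndarray  # predictive mean, sqrt-grams
    s: np.ndarray  # predictive sd, sqrt-grams

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks)
        self.m = np.asarray(self.m, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if not (len(self.weeks) == len(self.m) == len(self.s)):
            raise ValueError("weeks, m, s must have equal length")
        if np.any(self.s <= 0):
            raise ValueError("predictive sd must be positive at every week")
        if np.any(np.diff(self.m) <= 0):
            raise ValueError("predictive mean must be strictly increasing in week")

    def at_week(self, week: float, interpolate: bool = False) -> tuple[float, float]:
        idx = np.nonzero(self.weeks == week)[0]
        if idx.size:
            i = int(idx[0])
            return float(self.m[i]), float(self.s[i])
        if not interpolate:
            raise ValueError(f"week {week} not on the reference grid {list(self.weeks)}")
        if not (self.weeks.min() <= week <= self.weeks.max()):
            raise ValueError(f"week {week} outside the reference grid")
        return (
            float(np.interp(week, self.weeks, self.m)),
            float(np.interp(week, self.weeks, self.s)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ga_weeks": self.weeks, "mean_sqrt": self.m, "sd_sqrt": self.s})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PredictiveMoments":
        return cls(
            weeks=frame["ga_weeks"].to_numpy(),
            m=frame["mean_sqrt"].to_numpy(),
            s=frame["sd_sqrt"].to_numpy(),
        )


class ReferenceTable:
    """Weeks x Z-levels table of integer-gram EFW reference values.

    Invariants (validated on construction): every row strictly increasing
    in z, every column strictly increasing in week, all cells positive.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        unrounded: pd.DataFrame | None = None,
        validate: bool = True,
    ):
        frame = frame.copy()
        frame.columns = [float(c) for c in frame.columns]
        frame = frame.sort_index().sort_index(axis=1)
        self.frame = frame
        self.unrounded = unrounded
        if validate:
            self._validate()

    def _validate(self) -> None:
        values = self.frame.to_numpy(dtype=float)
        if np.any(values <= 0):
            raise ValueError("reference table cells must all be positive")
        if np.any(np.diff(values, axis=1) <= 0):
            raise ValueError("reference table rows must be strictly increasing in z")
        if np.any(np.diff(values, axis=0) <= 0):
            raise ValueError("reference table columns must be strictly increasing in week")

    @property
    def weeks(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def z_levels(self) -> np.ndarray:
        return np.asarray(self.frame.columns, dtype=float)

    def cell(self, week: int, z: float) -> float:
        return float(self.frame.loc[week, float(z)])

    def column(self, z: float) -> np.ndarray:
        return self.frame[float(z)].to_numpy(dtype=float)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.columns = [f"z_{c}" for c in out.columns]
        out.index.name = "ga_weeks"
        out.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path)
        df = df.set_index("ga_weeks")
        df.columns = [float(c.removeprefix("z_")) for c in df.columns]
        return cls(df)

    def to_json(self, path: str | Path, metadata: Mapping | None = None) -> None:
        payload = {
            "metadata": dict(metadata or {}),
            "z_levels": [float(z) for z in self.z_levels],
            "weeks": [int(w) for w in self.weeks],
            "cells": {str(int(w)): [float(v) for v in self.frame.loc[w]] for w in self.weeks},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferenceTable) and self.frame.equals(other.frame)


def build_reference_table(
    samples_by_week: Mapping[int, np.ndarray],
    z_levels: Sequence[float] = DEFAULT_Z_LEVELS,
    validate: bool = True,
) -> ReferenceTable:
    """Empirical reference table from sqrt-scale predictive samples.

    For each grid week the predictive sample is squared back to grams and
    the cell at level z is the empirical quantile at Phi(z), rounded
    half-up to integer grams.  Warns when a sample is too small to resolve
    an extreme quantile (n * tail mass < 10).
    """
    z = np.asarray(z_levels, dtype=float)
    levels = stats.norm.cdf(z)
    rows, raw_rows = {}, {}
    for week, sample in samples_by_week.items():
        sample = np.asarray(sample, dtype=float)
        tail = min(levels.min(), 1.0 - levels.max())
        if sample.size * tail < 10:
            warnings.warn(
                f"predictive sample at week {week} too small (n={sample.size}) "
                f"for extreme quantiles",
                stacklevel=2,
            )
        q = np.quantile(sample**2, levels)
        raw_rows[week] = q
        rows[week] = round_half_up(q)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = list(z)
    frame.index.name = "ga_weeks"
    raw = pd.DataFrame.from_dict(raw_rows, orient="index")
    raw.columns = list(z)
    return ReferenceTable(frame, unrounded=raw, validate=validate)


def table_row_from_moments(
    m: float, s: float, z_levels: Sequence[float] = DEFAULT_Z_LEVELS
) -> np.ndarray:
    """Closed-form integer-gram row from sqrt-scale moments: round((m+z*s)^2)."""
    if s <= 0:
        raise ValueError("s must be positive")
    z = np.asarray(z_levels, dtype=float)
    q = m + z * s
    if np.any(q < 0):
        raise ValueError("m + z*s < 0: non-physical sqrt-scale quantile")
    return round_half_up(q**2)


def table_from_moments(
    moments: PredictiveMoments, z_levels: Sequence[float] = DEFAULT_Z_LEVELS
) -> ReferenceTable:
    """Closed-form reference table from week-indexed moments."""
    rows = {
        int(w): table_row_from_moments(mi, si, z_levels)
        for w, mi, si in zip(moments.weeks, moments.m, moments.s)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [float(z) for z in z_levels]
    frame.index.name = "ga_weeks"
    return ReferenceTable(frame)


def reconstruct_moments_from_table(table: ReferenceTable) -> PredictiveMoments:
    """Invert the table construction: m_w = sqrt(cell(w,0)),
    s_w = (sqrt(cell(w,+2)) - sqrt(cell(w,-2))) / 4.

    The +/-2 columns give the widest lever arm; the +/-1.5 columns are a
    cross-check only because printed tables carry ~1 g rounding noise.
    """
    for needed in (-2.0, 0.0, 2.0):
        if needed not in table.z_levels:
            raise ValueError(f"table lacks required Z column {needed}")
    m = np.sqrt(table.column(0.0))
    s = (np.sqrt(table.column(2.0)) - np.sqrt(table.column(-2.0))) / 4.0
    return PredictiveMoments(weeks=table.weeks, m=m, s=s)


class ZScoreResult(NamedTuple):
    z: float
    percentile: float
    fgr_candidate: bool


def efw_z_score(
    efw_g: float,
    week: float,
    moments: PredictiveMoments,
    interpolate: bool = False,
) -> ZScoreResult:
    """Clinical Z-score of a measured EFW against the reference.

    z = (sqrt(efw) - m_w) / s_w; values below -1.5 are flagged as fetal
    growth restriction candidates.  Off-grid weeks raise unless
    ``interpolate`` (linear in m and s) is enabled.
    """
    if efw_g <= 0:
        raise ValueError("efw_g must be positive")
    m, s = moments.at_week(week, interpolate=interpolate)
    z = (math.sqrt(efw_g) - m) / s
    return ZScoreResult(z=z, percentile=z_to_percentile(z), fgr_candidate=z < FGR_Z_THRESHOLD)
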