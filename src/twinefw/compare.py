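"""Twin-vs-singleton comparison and DC-vs-MC mean-EFW curves.

The singleton reference is always user-supplied (as a Z-score table CSV or
a sqrt-scale moments CSV); no singleton values are bundled with the
package.  Comparisons:

* ``ratio_curve`` — per-week percent ratio of twin to singleton EFW at a
  common Z level (growth of twins relative to singletons).
* ``z_crosswalk`` — which singleton Z-score a twin Z-score corresponds to
  at each week (relevant to growth-restriction thresholds).
* ``chorionicity_spline`` — smoothed mean-EFW curves for dichorionic and
  monochorionic subgroups, a cubic smoothing spline on per-week group
  means weighted by observation counts (smoothing chosen by generalized
  cross-validation unless given).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .cohort import ExamRecord, Pregnancy
from .reference import PredictiveMoments, ReferenceTable, reconstruct_moments_from_table


def load_singleton_reference(path: str | Path) -> PredictiveMoments:
    """Load a user-supplied singleton reference.

    Accepts either the moments layout (``ga_weeks, mean_sqrt, sd_sqrt``)
    or the Z-score table layout (``ga_weeks, z_-2.0, ..., z_2.0``), in
    which case moments are reconstructed from the 0 and +/-2 columns.
    """
    df = pd.read_csv(path)
    if {"mean_sqrt", "sd_sqrt"}.issubset(df.columns):
        return PredictiveMoments.from_frame(df)
    return reconstruct_moments_from_table(ReferenceTable.from_csv(path))


def ratio_curve(
    twin: ReferenceTable, singleton: ReferenceTable | PredictiveMoments, z: float = 0.0
) -> pd.DataFrame:
    """Per-week twin/singleton EFW ratio in percent (one decimal) at Z=z."""
    twin_weeks = set(int(w) for w in twin.weeks)
    if isinstance(singleton, PredictiveMoments):
        single_weeks = set(int(w) for w in singleton.weeks)
    else:
        single_weeks = set(int(w) for w in singleton.weeks)
    weeks = sorted(twin_weeks & single_weeks)
    if not weeks:
        raise ValueError("twin and singleton week grids do not overlap")
    rows = []
    for w in weeks:
        t = twin.cell(w, z)
        if isinstance(singleton, PredictiveMoments):
            m, s = singleton.at_week(w)
            sv = (m + z * s) ** 2
        else:
            sv = singleton.cell(w, z)
        rows.append({"ga_weeks": w, "ratio_percent": round(100.0 * t / sv, 1)})
    return pd.DataFrame(rows)


def ratio_band(ratios: pd.DataFrame, week_min: int, week_max: int) -> str:
    """Min-max summary of the ratio over a week range, e.g. '90.0-93.0%'."""
    sel = ratios[(ratios.ga_weeks >= week_min) & (ratios.ga_weeks <= week_max)]
    if sel.empty:
        raise ValueError("no weeks in the requested range")
    return f"{sel.ratio_percent.min():.1f}–{sel.ratio_percent.max():.1f}%"


def z_crosswalk(
    twin: PredictiveMoments,
    singleton: PredictiveMoments,
    z_twin: float,
    weeks: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Equivalent singleton Z-score of the twin Z=z_twin curve, per week."""
    if weeks is None:
        weeks = sorted(set(int(w) for w in twin.weeks) & set(int(w) for w in singleton.weeks))
    if not weeks:
        raise ValueError("no common weeks between twin and singleton references")
    rows = []
    for w in weeks:
        mt, st = twin.at_week(w)
        ms, ss = singleton.at_week(w)
        rows.append({"ga_weeks": w, "z_singleton": (mt + z_twin * st - ms) / ss})
    return pd.DataFrame(rows)


def chorionicity_spline(
    exams: Iterable[ExamRecord],
    pregnancies: Iterable[Pregnancy],
    smoothing: float | None = None,
    grid_step: float = 0.25,
) -> pd.DataFrame:
    """Smoothed mean-EFW curves for DC and MC twins on a fine week grid.

    Per-week group means of EFW are fit with a cubic smoothing spline
    weighted by per-week observation counts; ``smoothing`` is the penalty
    lambda (0 interpolates; None selects by generalized cross-validation).
    Returns columns ``ga_weeks, efw_dc, efw_mc``.
    """
    chor = {p.pregnancy_id: p.chorionicity for p in pregnancies}
    df = pd.DataFrame(
        {
            "chorionicity": [chor[e.pregnancy_id] for e in exams],
            "ga_weeks": [e.ga_weeks for e in exams],
            "efw_g": [e.efw_g for e in exams],
        }
    )
    curves = {}
    lo, hi = None, None
    for group in ("DC", "MC"):
        sub = df[df.chorionicity == group]
        agg = sub.groupby("ga_weeks")["efw_g"].agg(["mean", "count"]).reset_index()
        if len(agg) < 4:
            raise ValueError(f"{group} group has fewer than 4 distinct weeks")
        x = agg.ga_weeks.to_numpy(dtype=float)
        if len(agg) == 4:  # too few points for a penalized fit: interpolate
            from scipy.interpolate import CubicSpline

            spl = CubicSpline(x, agg["mean"].to_numpy())
        else:
            spl = make_smoothing_spline(
                x, agg["mean"].to_numpy(), w=agg["count"].to_numpy(dtype=float), lam=smoothing
            )
        curves[group] = spl
        lo = x.min() if lo is None else max(lo, x.min())
        hi = x.max() if hi is None else min(hi, x.max())
    grid = np.arange(lo, hi + 1e-9, grid_step)
    return pd.DataFrame(
        {
            "ga_weeks": grid,
            "efw_dc": curves["DC"](grid),
            "efw_mc": curves["MC"](grid),
        }
    )


def plot_reference(table: ReferenceTable, observations: pd.DataFrame | None = None, ax=None):
    """Reference-chart plot: one curve per Z level, optional raw points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if observations is not None:
        ax.plot(observations["ga_weeks"], observations["efw_g"], ".", ms=2, alpha=0.3,
                color="grey")
    for z in table.z_levels:
        ax.plot(table.weeks, table.column(z), label=f"Z={z:g}")
    ax.set_xlabel("gestational age (weeks)")
    ax.set_ylabel("EFW (g)")
    ax.legend()
    return ax
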