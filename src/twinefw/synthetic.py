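"""Synthetic twin-cohort generator.

Emulates the longitudinal structure the growth analysis assumes: each
pregnancy i carries a bivariate-normal random intercept/slope (u0i, u1i)
on the sqrt-gram scale, shared by both co-twins; every fetus-visit at week
w yields

    sqrt(EFW) = (beta0 + u0i) + (beta1 + u1i) * w + eps,   eps ~ N(0, sigma2_e)

and EFW is emitted as the square, floored at a small positive minimum.
Visit weeks follow the antenatal protocol of the reference study:
from 16 weeks, dichorionic (DC) pregnancies are scanned every 4 weeks and
monochorionic (MC) every 2 weeks until 24 weeks, both every 2 weeks from
24 to 36 weeks, and weekly from 36 weeks until delivery.  Delivery
gestational age is a clipped normal parameterized by a median and IQR
(early-term planned delivery around 37 weeks).

Truth parameters can be set directly or calibrated from a printed
reference table (:func:`derive_truth_from_reference`): the population line
comes from OLS of sqrt(Z=0 column) on week, and the random-effect
covariance plus residual variance from a quadratic least-squares fit to
the squared per-week predictive sd.  A small configurable fraction of
pregnancies receives planted exclusion flags so the eligibility filter is
exercised end-to-end; the generator records its plan in a ledger that
downstream tests use as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .cohort import EXCLUSION_FLAGS, REASON_ORDER, ExamRecord, Pregnancy

_NORMAL_IQR_WIDTH = 1.3489795003921634  # Phi^-1(0.75) - Phi^-1(0.25)


@dataclass(frozen=True)
class DeliverySpec:
    """Delivery gestational age: normal from median/IQR, clipped."""

    median: float = 37.1
    iqr: tuple[float, float] = (36.7, 37.4)
    clip: tuple[float, float] = (33.0, 38.5)

    @property
    def sd(self) -> float:
        return (self.iqr[1] - self.iqr[0]) / _NORMAL_IQR_WIDTH


def _default_violation_rates() -> dict[str, float]:
    return {flag: 0.01 for flag in EXCLUSION_FLAGS}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of the generator (sqrt-gram scale)."""

    beta0: float
    beta1: float
    Sigma_u: np.ndarray  # 2x2 random-effect covariance
    sigma2_e: float
    mc_fraction: float = 0.478
    delivery: DeliverySpec = field(default_factory=DeliverySpec)
    violation_rates: Mapping[str, float] = field(default_factory=_default_violation_rates)
    efw_floor_g: float = 1.0
    first_visit_week: int = 16

    def __post_init__(self) -> None:
        self.Sigma_u = np.asarray(self.Sigma_u, dtype=float)
        if self.Sigma_u.shape != (2, 2):
            raise ValueError("Sigma_u must be 2x2")
        if not np.allclose(self.Sigma_u, self.Sigma_u.T):
            raise ValueError("Sigma_u must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma_u) < -1e-10):
            raise ValueError("Sigma_u must be positive semidefinite")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if not (0.0 <= self.mc_fraction <= 1.0):
            raise ValueError("mc_fraction must lie in [0, 1]")

    def mean_sqrt(self, week: float) -> float:
        return self.beta0 + self.beta1 * week

    def predictive_sd_sqrt(self, week: float) -> float:
        v = (
            self.Sigma_u[0, 0]
            + 2 * week * self.Sigma_u[0, 1]
            + week**2 * self.Sigma_u[1, 1]
            + self.sigma2_e
        )
        return float(np.sqrt(v))

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "var_u0": float(self.Sigma_u[0, 0]),
            "var_u1": float(self.Sigma_u[1, 1]),
            "cov_u01": float(self.Sigma_u[0, 1]),
            "sigma2_e": self.sigma2_e,
            "mc_fraction": self.mc_fraction,
            "delivery_median": self.delivery.median,
            "delivery_iqr": list(self.delivery.iqr),
            "delivery_clip": list(self.delivery.clip),
            "violation_rates": dict(self.violation_rates),
            "efw_floor_g": self.efw_floor_g,
            "first_visit_week": self.first_visit_week,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            Sigma_u=np.array(
                [
                    [d["var_u0"], d["cov_u01"]],
                    [d["cov_u01"], d["var_u1"]],
                ]
            ),
            sigma2_e=float(d["sigma2_e"]),
            mc_fraction=float(d.get("mc_fraction", 0.478)),
            delivery=DeliverySpec(
                median=float(d.get("delivery_median", 37.1)),
                iqr=tuple(d.get("delivery_iqr", (36.7, 37.4))),
                clip=tuple(d.get("delivery_clip", (33.0, 38.5))),
            ),
            violation_rates=dict(d.get("violation_rates", _default_violation_rates())),
            efw_floor_g=float(d.get("efw_floor_g", 1.0)),
            first_visit_week=int(d.get("first_visit_week", 16)),
        )


def visit_weeks(chorionicity: str, delivery_ga: float, start: int = 16) -> list[int]:
    """Integer scan weeks under the protocol schedule, stopping at delivery."""
    if chorionicity not in ("DC", "MC"):
        raise ValueError(f"chorionicity must be 'DC' or 'MC', got {chorionicity!r}")
    early_step = 2 if chorionicity == "MC" else 4
    weeks: list[int] = []
    w = start
    while w < 24:
        weeks.append(w)
        w += early_step
    w = 24
    while w < 36:
        weeks.append(w)
        w += 2
    w = 36
    while w <= delivery_ga:
        weeks.append(w)
        w += 1
    return [w for w in weeks if w <= delivery_ga]


def derive_truth_from_reference(
    table,
    week_range: tuple[int, int] = (16, 36),
    residual_fraction: float = 0.5,
    **overrides,
) -> SyntheticTruth:
    """Calibrate generator truth from a printed Z-score reference table.

    * beta0, beta1: OLS of sqrt(Z=0 column) on week over ``week_range``.
    * per-week predictive sd: s(w) = (sqrt(cell(w,+2)) - sqrt(cell(w,-2)))/4.
    * (Sigma_u, sigma2_e): least-squares fit of
      s(w)^2 = var_u0 + 2w cov + w^2 var_u1 + sigma2_e.  The intercept of
      that quadratic only identifies the *sum* var_u0 + sigma2_e, so the
      split is a calibration rule: sigma2_e = residual_fraction times the
      largest residual variance still compatible with a positive
      semidefinite Sigma_u.

    ``table`` is a :class:`~twinefw.reference.ReferenceTable` or a
    DataFrame indexed by week with Z-level columns including -2, 0, +2.
    """
    frame = getattr(table, "frame", table)
    frame = frame.loc[(frame.index >= week_range[0]) & (frame.index <= week_range[1])]
    for col in (-2.0, 0.0, 2.0):
        if float(col) not in [float(c) for c in frame.columns]:
            raise ValueError(f"reference table lacks Z column {col}")
    frame = frame.copy()
    frame.columns = [float(c) for c in frame.columns]
    if np.any(np.diff(frame.to_numpy(dtype=float), axis=0) <= 0):
        raise ValueError("reference table must be strictly increasing in week")

    w = frame.index.to_numpy(dtype=float)
    y = np.sqrt(frame[0.0].to_numpy(dtype=float))
    X = np.vstack([np.ones_like(w), w]).T
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    s = (np.sqrt(frame[2.0].to_numpy(dtype=float)) - np.sqrt(frame[-2.0].to_numpy(dtype=float))) / 4.0
    Q = np.vstack([np.ones_like(w), w, w**2]).T
    (a, b, c), *_ = np.linalg.lstsq(Q, s**2, rcond=None)
    var_u1 = float(c)
    cov = float(b) / 2.0
    if var_u1 < 1e-9:
        # flat sd profile: no identifiable slope heterogeneity
        var_u1, cov = 0.0, 0.0
        a = float(np.mean(s**2))
        sigma2_max = a
    else:
        sigma2_max = float(a) - cov**2 / var_u1
    if sigma2_max <= 0:
        raise ValueError("reference table variance profile admits no PSD split")
    if not (0.0 < residual_fraction < 1.0):
        raise ValueError("residual_fraction must lie in (0, 1)")
    sigma2_e = residual_fraction * sigma2_max
    var_u0 = float(a) - sigma2_e
    Sigma_u = np.array([[var_u0, cov], [cov, var_u1]])
    return SyntheticTruth(
        beta0=float(beta[0]), beta1=float(beta[1]), Sigma_u=Sigma_u, sigma2_e=sigma2_e, **overrides
    )


class GeneratedCohort(NamedTuple):
    pregnancies: list[Pregnancy]
    exams: list[ExamRecord]
    ledger: dict


def generate_cohort(truth: SyntheticTruth, n_pregnancies: int, seed: int) -> GeneratedCohort:
    """Simulate a twin cohort; same truth + seed is bit-identical.

    Returns the pregnancy list, fetus-visit exam records, and a ledger
    recording every planted eligibility violation (per-pregnancy flags,
    per-reason counts under the documented precedence, and expected
    included/excluded totals) for use as a downstream test oracle.
    """
    if n_pregnancies < 0:
        raise ValueError("n_pregnancies must be >= 0")
    rng = np.random.Generator(np.random.Philox(seed))
    L = np.linalg.cholesky(truth.Sigma_u + 1e-12 * np.eye(2))

    pregnancies: list[Pregnancy] = []
    exams: list[ExamRecord] = []
    planted: dict[str, list[str]] = {}
    reason_counts: dict[str, int] = {}

    flags_order = [f for f in EXCLUSION_FLAGS if truth.violation_rates.get(f, 0.0) > 0]
    for i in range(n_pregnancies):
        pid = f"P{i:04d}"
        chorionicity = "MC" if rng.random() < truth.mc_fraction else "DC"
        delivery_ga = float(
            np.clip(
                rng.normal(truth.delivery.median, truth.delivery.sd),
                truth.delivery.clip[0],
                truth.delivery.clip[1],
            )
        )
        u = L @ rng.standard_normal(2)
        flags = frozenset(
            f for f in flags_order if rng.random() < truth.violation_rates[f]
        )
        pregnancies.append(
            Pregnancy(
                pregnancy_id=pid,
                chorionicity=chorionicity,
                ga_first_visit_weeks=float(truth.first_visit_week),
                ga_delivery_weeks=delivery_ga,
                live_born=True,
                flags=flags,
            )
        )
        planted[pid] = sorted(flags)
        if flags:
            first = next(r for r in REASON_ORDER if r in flags)
            reason_counts[first] = reason_counts.get(first, 0) + 1

        weeks = visit_weeks(chorionicity, delivery_ga, start=truth.first_visit_week)
        for fetus in (1, 2):
            eps = rng.normal(0.0, np.sqrt(truth.sigma2_e), size=len(weeks))
            for wk, e in zip(weeks, eps):
                sq = (truth.beta0 + u[0]) + (truth.beta1 + u[1]) * wk + e
                efw = max(sq * sq if sq > 0 else 0.0, truth.efw_floor_g)
                exams.append(
                    ExamRecord(
                        pregnancy_id=pid, fetus_index=fetus, ga_weeks=float(wk), efw_g=float(efw)
                    )
                )

    excluded = sum(reason_counts.values())
    ledger = {
        "n_pregnancies": n_pregnancies,
        "seed": seed,
        "planted_flags": planted,
        "reason_counts": reason_counts,
        "expected_excluded": excluded,
        "expected_included": n_pregnancies - excluded,
        "n_exams": len(exams),
    }
    return GeneratedCohort(pregnancies=pregnancies, exams=exams, ledger=ledger)


def exams_to_frame(exams: list[ExamRecord]) -> pd.DataFrame:
    """Long-format view of exam records (one fetus-visit per row)."""
    return pd.DataFrame(
        {
            "pregnancy_id": [e.pregnancy_id for e in exams],
            "fetus_index": [e.fetus_index for e in exams],
            "ga_weeks": [e.ga_weeks for e in exams],
            "efw_g": [e.efw_g for e in exams],
        }
    )
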