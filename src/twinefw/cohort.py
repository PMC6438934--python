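"""Cohort data model, CSV I/O, biometry-to-EFW conversion and eligibility.

A twin-pregnancy ultrasound cohort is stored in two CSV files:

``exams.csv``
    one row per fetus-visit: ``pregnancy_id, fetus_index, ga_weeks, efw_g,
    bpd_cm, ac_cm, fl_cm`` (the three biometry columns are optional).
``pregnancies.csv``
    one row per pregnancy: ``pregnancy_id, chorionicity, live_born,
    ga_first_visit_weeks, ga_delivery_weeks`` plus one 0/1 column per
    exclusion flag.

Eligibility follows the cohort-selection rules of the reference study: a
pregnancy enters the analysis set iff the twins were live-born at >= 22
completed weeks, antenatal care started by 16 weeks, and none of the
clinical exclusion flags (oocyte donation, fetal reduction, ... TTTS,
fetal therapy) is set.  A pregnancy failing several criteria is counted
once, under the first matching reason in a fixed documented order
(:data:`REASON_ORDER`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

#: Clinical exclusion flags, in the precedence order used for reporting.
EXCLUSION_FLAGS: tuple[str, ...] = (
    "oocyte_donation",
    "fetal_reduction",
    "non_japanese_parent",
    "maternal_complication",
    "mcma",
    "fetal_death",
    "congenital_anomaly",
    "aneuploidy",
    "ttts",
    "fetal_therapy",
)

#: Full reason precedence: inclusion criteria first, then the clinical
#: flags, then late entry to antenatal care.
REASON_ORDER: tuple[str, ...] = (
    "not_live_born",
    "delivery_before_22_weeks",
    *EXCLUSION_FLAGS,
    "late_first_visit",
)

EXAM_COLUMNS = ("pregnancy_id", "fetus_index", "ga_weeks", "efw_g")
BIOMETRY_COLUMNS = ("bpd_cm", "ac_cm", "fl_cm")
PREGNANCY_COLUMNS = (
    "pregnancy_id",
    "chorionicity",
    "live_born",
    "ga_first_visit_weeks",
    "ga_delivery_weeks",
)


@dataclass(frozen=True)
class FetalBiometry:
    """Single-visit biometry: BPD, AC, FL, all in centimetres."""

    bpd: float
    ac: float
    fl: float

    def __post_init__(self) -> None:
        for name in ("bpd", "ac", "fl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"biometry field {name!r} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class JsumCoefficients:
    """Coefficients of the JSUM-style EFW formula (cm in, grams out).

    EFW = c1 * BPD^3 + c2 * AC^2 * FL.  The defaults follow the standard
    Japanese formula; they are configuration, not ground truth.
    """

    c1: float = 1.07
    c2: float = 0.30


@dataclass(frozen=True)
class ExamRecord:
    """One fetus at one ultrasound visit."""

    pregnancy_id: str
    fetus_index: int
    ga_weeks: float
    efw_g: float
    biometry: FetalBiometry | None = None

    def __post_init__(self) -> None:
        if self.fetus_index not in (1, 2):
            raise ValueError(f"fetus_index must be 1 or 2, got {self.fetus_index}")
        if not (10.0 <= self.ga_weeks <= 43.0):
            raise ValueError(f"ga_weeks out of range [10, 43]: {self.ga_weeks}")
        if not (self.efw_g > 0):
            raise ValueError(f"efw_g must be positive, got {self.efw_g}")


@dataclass(frozen=True)
class Pregnancy:
    """Pregnancy-level metadata used by the eligibility engine."""

    pregnancy_id: str
    chorionicity: str
    ga_first_visit_weeks: float
    ga_delivery_weeks: float
    live_born: bool = True
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.chorionicity not in ("DC", "MC"):
            raise ValueError(f"chorionicity must be 'DC' or 'MC', got {self.chorionicity!r}")
        if self.ga_first_visit_weeks > self.ga_delivery_weeks:
            raise ValueError("ga_first_visit_weeks must be <= ga_delivery_weeks")
        unknown = set(self.flags) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")


class RejectedRow(NamedTuple):
    source: str
    row_number: int  # 1-based data-row number (header not counted)
    reason: str


@dataclass
class CohortData:
    pregnancies: list[Pregnancy]
    exams: list[ExamRecord]
    rejects: list[RejectedRow] = field(default_factory=list)


@dataclass
class EligibilityCriteria:
    """Inclusion thresholds; 'after 16 weeks' is strict (> 16.0 excludes)."""

    min_delivery_ga_weeks: float = 22.0
    max_first_visit_ga_weeks: float = 16.0
    exclusion_flags: Sequence[str] = EXCLUSION_FLAGS


@dataclass
class ExclusionLog:
    """Outcome of an eligibility run, mirroring a selection flowchart."""

    decisions: dict[str, str | None]  # pregnancy_id -> None (included) or reason
    reason_counts: Counter
    recruited: int
    excluded: int
    included: int

    def __post_init__(self) -> None:
        if self.recruited != self.excluded + self.included:
            raise ValueError("conservation violated: recruited != excluded + included")

    @property
    def exclusion_rate_percent(self) -> float:
        """Excluded / recruited, in percent (one decimal)."""
        if self.recruited == 0:
            return 0.0
        return round(100.0 * self.excluded / self.recruited, 1)

    def included_ids(self) -> list[str]:
        return [pid for pid, reason in self.decisions.items() if reason is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pregnancy_id": list(self.decisions),
                "decision": [
                    "included" if r is None else "excluded" for r in self.decisions.values()
                ],
                "reason": [r or "" for r in self.decisions.values()],
            }
        )

    def summary(self) -> str:
        lines = [
            f"recruited: {self.recruited}",
            f"excluded:  {self.excluded} ({self.exclusion_rate_percent}%)",
        ]
        for reason in REASON_ORDER:
            if self.reason_counts.get(reason):
                lines.append(f"  - {reason}: {self.reason_counts[reason]}")
        lines.append(f"included:  {self.included}")
        return "\n".join(lines)


def efw_from_biometry(
    biometry: FetalBiometry, coeffs: JsumCoefficients = JsumCoefficients()
) -> float:
    """Estimated fetal weight in grams from BPD/AC/FL in centimetres.

    Uses the parameterized cubic formula EFW = c1*BPD^3 + c2*AC^2*FL.
    """
    return coeffs.c1 * biometry.bpd**3 + coeffs.c2 * biometry.ac**2 * biometry.fl


def measurements_per_fetus(n_measurements: int, n_fetuses: int) -> float:
    """Average number of EFW measurements per fetus, one decimal."""
    if n_fetuses <= 0:
        raise ValueError("n_fetuses must be positive")
    return round(n_measurements / n_fetuses, 1)


def apply_eligibility(
    pregnancies: Iterable[Pregnancy],
    criteria: EligibilityCriteria | None = None,
) -> ExclusionLog:
    """Classify every pregnancy as included or excluded with one reason.

    The first matching reason in :data:`REASON_ORDER` is recorded;
    eligibility never defaults to included when a field is missing
    (dataclass construction already enforces presence).
    """
    criteria = criteria or EligibilityCriteria()
    decisions: dict[str, str | None] = {}
    counts: Counter = Counter()
    for p in pregnancies:
        reason = _first_reason(p, criteria)
        decisions[p.pregnancy_id] = reason
        if reason is not None:
            counts[reason] += 1
    excluded = sum(counts.values())
    return ExclusionLog(
        decisions=decisions,
        reason_counts=counts,
        recruited=len(decisions),
        excluded=excluded,
        included=len(decisions) - excluded,
    )


def _first_reason(p: Pregnancy, criteria: EligibilityCriteria) -> str | None:
    for reason in REASON_ORDER:
        if reason == "not_live_born":
            if not p.live_born:
                return reason
        elif reason == "delivery_before_22_weeks":
            if p.ga_delivery_weeks < criteria.min_delivery_ga_weeks:
                return reason
        elif reason == "late_first_visit":
            if p.ga_first_visit_weeks > criteria.max_first_visit_ga_weeks:
                return reason
        elif reason in criteria.exclusion_flags and reason in p.flags:
            return reason
    return None


# ---------------------------------------------------------------------------
# CSV I/O


def write_cohort(
    pregnancies: Sequence[Pregnancy],
    exams: Sequence[ExamRecord],
    exams_path: str | Path,
    pregnancies_path: str | Path,
) -> None:
    """Write the two-file cohort layout (UTF-8, comma-separated)."""
    exam_rows = []
    for e in exams:
        row: dict[str, object] = {
            "pregnancy_id": e.pregnancy_id,
            "fetus_index": e.fetus_index,
            "ga_weeks": e.ga_weeks,
            "efw_g": e.efw_g,
        }
        if e.biometry is not None:
            row.update(bpd_cm=e.biometry.bpd, ac_cm=e.biometry.ac, fl_cm=e.biometry.fl)
        exam_rows.append(row)
    cols = list(EXAM_COLUMNS) + [
        c for c in BIOMETRY_COLUMNS if any(c in r for r in exam_rows)
    ]
    pd.DataFrame(exam_rows, columns=cols).to_csv(exams_path, index=False)

    preg_rows = []
    for p in pregnancies:
        row = {
            "pregnancy_id": p.pregnancy_id,
            "chorionicity": p.chorionicity,
            "live_born": int(p.live_born),
            "ga_first_visit_weeks": p.ga_first_visit_weeks,
            "ga_delivery_weeks": p.ga_delivery_weeks,
        }
        for flag in EXCLUSION_FLAGS:
            row[flag] = int(flag in p.flags)
        preg_rows.append(row)
    pd.DataFrame(preg_rows, columns=list(PREGNANCY_COLUMNS) + list(EXCLUSION_FLAGS)).to_csv(
        pregnancies_path, index=False
    )


def read_cohort(exams_path: str | Path, pregnancies_path: str | Path) -> CohortData:
    """Read the two-file cohort layout.

    Malformed rows (non-numeric GA/EFW, out-of-range values) are collected
    in ``CohortData.rejects`` rather than silently dropped; a missing
    required column raises ``ValueError`` naming the column.
    """
    exams_df = pd.read_csv(exams_path, dtype=str, keep_default_na=False)
    preg_df = pd.read_csv(pregnancies_path, dtype=str, keep_default_na=False)
    for col in EXAM_COLUMNS:
        if col not in exams_df.columns:
            raise ValueError(f"exams file missing required column {col!r}")
    for col in list(PREGNANCY_COLUMNS) + list(EXCLUSION_FLAGS):
        if col not in preg_df.columns:
            raise ValueError(f"pregnancies file missing required column {col!r}")

    rejects: list[RejectedRow] = []
    exams: list[ExamRecord] = []
    has_biometry = all(c in exams_df.columns for c in BIOMETRY_COLUMNS)
    for i, row in enumerate(exams_df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            biometry = None
            if has_biometry and d["bpd_cm"] != "":
                biometry = FetalBiometry(
                    bpd=float(d["bpd_cm"]), ac=float(d["ac_cm"]), fl=float(d["fl_cm"])
                )
            exams.append(
                ExamRecord(
                    pregnancy_id=d["pregnancy_id"],
                    fetus_index=int(d["fetus_index"]),
                    ga_weeks=float(d["ga_weeks"]),
                    efw_g=float(d["efw_g"]),
                    biometry=biometry,
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(source="exams", row_number=i, reason=str(exc)))

    pregnancies: list[Pregnancy] = []
    for i, row in enumerate(preg_df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            flags = frozenset(f for f in EXCLUSION_FLAGS if _parse_bool(d[f]))
            pregnancies.append(
                Pregnancy(
                    pregnancy_id=d["pregnancy_id"],
                    chorionicity=d["chorionicity"],
                    live_born=_parse_bool(d["live_born"]),
                    ga_first_visit_weeks=float(d["ga_first_visit_weeks"]),
                    ga_delivery_weeks=float(d["ga_delivery_weeks"]),
                    flags=flags,
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(source="pregnancies", row_number=i, reason=str(exc)))

    return CohortData(pregnancies=pregnancies, exams=exams, rejects=rejects)


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in ("1", "true", "t", "yes"):
        return True
    if t in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {token!r}")
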