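"""Psoriasis Area and Severity Index (PASI) and Local Inflammation Severity.

PASI grades four body regions (head, upper limbs, trunk, lower limbs).
For each region, erythema (redness), induration (thickness) and scaling
are graded 0-4 and summed to a severity of 0-12; the involved-area grade
0-6 multiplies the severity to a region score of 0-72.  The total is the
area-weighted sum over regions using the standard body-surface weights
(head 0.1, upper limbs 0.2, trunk 0.3, lower limbs 0.4), which keeps the
total in [0, 72].  Scores below 10 indicate mild psoriasis; 10 and above,
moderate to severe.

LIS is a clinician-assigned 1-10 grade of the imaged lesion from
photographs; it is validated here but never computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import OutOfCohortRangeWarning, ValidationError

__all__ = [
    "REGIONS",
    "STANDARD_WEIGHTS",
    "RegionAssessment",
    "PasiRecord",
    "region_severity",
    "region_score",
    "pasi_total",
    "pasi_band",
    "combined_band",
    "validate_lis",
    "records_to_dataframe",
    "records_from_dataframe",
]

REGIONS = ("head", "upper_limbs", "trunk", "lower_limbs")
STANDARD_WEIGHTS = {
    "head": 0.1,
    "upper_limbs": 0.2,
    "trunk": 0.3,
    "lower_limbs": 0.4,
}

#: PASI bands as used for the severity split: low = [1, 9], high = [10, 29].
PASI_BAND_THRESHOLD = 10
PASI_COHORT_RANGE = (1, 29)


def _check_grade(value: int, name: str, lo: int, hi: int) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise ValidationError(f"{name} must lie in [{lo}, {hi}], got {value}")
    return value


def region_severity(redness: int, thickness: int, scaling: int) -> int:
    """Sum of the three 0-4 grades; ranges over 0-12."""
    return (
        _check_grade(redness, "redness", 0, 4)
        + _check_grade(thickness, "thickness", 0, 4)
        + _check_grade(scaling, "scaling", 0, 4)
    )


def region_score(area_grade: int, severity: int) -> int:
    """Area grade (0-6) times severity (0-12); ranges over 0-72."""
    return _check_grade(area_grade, "area_grade", 0, 6) * _check_grade(
        severity, "severity", 0, 12
    )


@dataclass(frozen=True)
class RegionAssessment:
    region: str
    redness: int
    thickness: int
    scaling: int
    area_grade: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown body region {self.region!r}")
        self.severity  # triggers grade validation

    @property
    def severity(self) -> int:
        return region_severity(self.redness, self.thickness, self.scaling)

    @property
    def score(self) -> int:
        return region_score(self.area_grade, self.severity)


def pasi_total(
    regions: dict[str, RegionAssessment] | list[RegionAssessment],
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted sum of region scores over all four body regions.

    ``weights`` defaults to the standard body-surface weights and must sum
    to 1, which bounds the total to [0, 72].
    """
    if not isinstance(regions, dict):
        regions = {r.region: r for r in regions}
    missing = [r for r in REGIONS if r not in regions]
    if missing:
        raise ValidationError(f"missing region assessments: {missing}")
    weights = dict(weights or STANDARD_WEIGHTS)
    if set(weights) != set(REGIONS):
        raise ValidationError("weights must cover exactly the four regions")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValidationError("region weights must sum to 1")
    if any(w < 0 for w in weights.values()):
        raise ValidationError("region weights must be non-negative")
    return float(sum(weights[r] * regions[r].score for r in REGIONS))


def pasi_band(pasi: float) -> str:
    """Band a PASI total: ``"low"`` for [1, 9], ``"high"`` for [10, 29].

    Values outside the cohort range [1, 29] trigger an
    ``OutOfCohortRangeWarning`` but are still banded by the threshold of
    10.
    """
    lo, hi = PASI_COHORT_RANGE
    if not lo <= pasi <= hi:
        warnings.warn(
            f"PASI {pasi} outside the banded cohort range [{lo}, {hi}]",
            OutOfCohortRangeWarning,
            stacklevel=2,
        )
    return "high" if pasi >= PASI_BAND_THRESHOLD else "low"


def validate_lis(lis: int) -> int:
    """Validate a clinician-assigned LIS grade (integer 1-10)."""
    return _check_grade(lis, "LIS", 1, 10)


def combined_band(
    pasi: float,
    lis: int | None,
    pasi_threshold: int = PASI_BAND_THRESHOLD,
    lis_threshold: int = 7,
) -> str:
    """Band severity on PASI and LIS jointly: high if either exceeds its
    threshold.

    There is no canonical definition of a combined PASI+LIS grouping;
    this default (high iff PASI >= 10 or LIS >= 7) treats a strongly
    inflamed imaged lesion as high-severity even when the whole-body PASI
    is mild.  Both thresholds are configurable.
    """
    if lis is not None:
        validate_lis(lis)
    if pasi >= pasi_threshold or (lis is not None and lis >= lis_threshold):
        return "high"
    return "low"


@dataclass(frozen=True)
class PasiRecord:
    """Four region assessments plus the derived total and optional LIS."""

    regions: tuple[RegionAssessment, ...]
    lis: int | None = None

    def __post_init__(self) -> None:
        pasi_total(list(self.regions))  # validates completeness
        if self.lis is not None:
            validate_lis(self.lis)

    @property
    def total(self) -> float:
        return pasi_total(list(self.regions))

    @property
    def band(self) -> str:
        return pasi_band(self.total)


def records_to_dataframe(records: dict[str, PasiRecord]):
    """Flatten subject-keyed records to a table (one row per subject)."""
    import pandas as pd

    rows = []
    for subject_id, rec in records.items():
        row: dict[str, object] = {"subject_id": subject_id}
        for region in rec.regions:
            for grade in ("redness", "thickness", "scaling", "area_grade"):
                row[f"{region.region}_{grade}"] = getattr(region, grade)
        row["pasi_total"] = rec.total
        row["lis"] = rec.lis
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_dataframe(df) -> dict[str, PasiRecord]:
    """Rebuild validated records from a table written by
    :func:`records_to_dataframe`; derived totals are recomputed and
    checked."""
    records = {}
    for _, row in df.iterrows():
        regions = tuple(
            RegionAssessment(
                region,
                int(row[f"{region}_redness"]),
                int(row[f"{region}_thickness"]),
                int(row[f"{region}_scaling"]),
                int(row[f"{region}_area_grade"]),
            )
            for region in REGIONS
        )
        lis = row.get("lis")
        rec = PasiRecord(
            regions, lis=None if lis is None or lis != lis else int(lis)
        )
        if "pasi_total" in row and abs(rec.total - row["pasi_total"]) > 1e-9:
            raise ValidationError(
                f"{row['subject_id']}: stored pasi_total "
                f"{row['pasi_total']} inconsistent with grades ({rec.total})"
            )
        records[str(row["subject_id"])] = rec
    return records
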