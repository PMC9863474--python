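"""The PAPVR ratio and binary surgical classification.

The score is the normalised position of the most cranial anomalous pulmonary
vein between the sinus venosus defect and the azygos vein::

    ratio = d_pv_svd / (d_pv_svd + d_pv_azygos)

It is dimensionless, confined to [0, 1], and invariant under uniform scaling
of the anatomy — so it applies across patient sizes without body-surface-area
adjustment. High ratios (vein far from the defect, close to the azygos) favour
the Warden procedure; low ratios favour single/double patch repair. The
published decision rule is WARDEN iff ratio > 0.68, strictly: a ratio exactly
at the cutoff is classified PATCH.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geometry import MeasurementSet

__all__ = [
    "SurgicalProcedure",
    "BinaryLabel",
    "ScoredPatient",
    "DEFAULT_CUTOFF",
    "COHORT_COLUMNS",
    "papvr_ratio",
    "classify",
    "to_binary",
    "score_measurements",
    "read_cohort_table",
    "write_cohort_table",
    "measurements_from_table",
    "score_table",
]

#: Published decision threshold: ratio > 0.68 predicts the Warden procedure.
DEFAULT_CUTOFF = 0.68


class SurgicalProcedure(str, enum.Enum):
    """The three repair techniques for right PAPVR with sinus venosus defect."""

    SINGLE_PATCH = "SINGLE_PATCH"
    DOUBLE_PATCH = "DOUBLE_PATCH"
    WARDEN = "WARDEN"


class BinaryLabel(str, enum.Enum):
    """Warden-vs-patch dichotomy used by the cutoff analysis.

    PATCH pools single- and double-patch repairs, which the score does not
    attempt to distinguish.
    """

    WARDEN = "WARDEN"
    PATCH = "PATCH"


def to_binary(procedure: SurgicalProcedure) -> BinaryLabel:
    """Collapse a procedure label onto the Warden-vs-patch dichotomy."""
    procedure = SurgicalProcedure(procedure)
    if procedure is SurgicalProcedure.WARDEN:
        return BinaryLabel.WARDEN
    return BinaryLabel.PATCH


@dataclass(frozen=True)
class ScoredPatient:
    """A patient's ratio with predicted and (optionally) actual procedure."""

    patient_id: str
    ratio: float
    predicted_procedure: BinaryLabel | None = None
    actual_procedure: SurgicalProcedure | None = None

    def __post_init__(self) -> None:
        r = float(self.ratio)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"ratio must lie in [0, 1], got {r}")
        object.__setattr__(self, "ratio", r)
        if self.predicted_procedure is not None:
            object.__setattr__(
                self, "predicted_procedure", BinaryLabel(self.predicted_procedure)
            )
        if self.actual_procedure is not None:
            object.__setattr__(
                self, "actual_procedure", SurgicalProcedure(self.actual_procedure)
            )

    @property
    def actual_binary(self) -> BinaryLabel | None:
        if self.actual_procedure is None:
            return None
        return to_binary(self.actual_procedure)


def papvr_ratio(m: MeasurementSet) -> float:
    """Compute the PAPVR ratio from a measurement set.

    ratio = d_pv_svd / (d_pv_svd + d_pv_azygos), in [0, 1]. A zero
    denominator is impossible for a valid :class:`MeasurementSet` (its
    invariant requires d_pv_svd + d_pv_azygos > 0) but is re-checked here.
    """
    total = m.d_pv_svd + m.d_pv_azygos
    if total <= 0:
        raise ValueError(
            f"patient {m.patient_id!r}: d_pv_svd + d_pv_azygos = 0, ratio undefined"
        )
    return m.d_pv_svd / total


def classify(ratio: float, cutoff: float = DEFAULT_CUTOFF) -> BinaryLabel:
    """Predict the procedure: WARDEN iff ratio > cutoff (strict), else PATCH."""
    ratio = float(ratio)
    cutoff = float(cutoff)
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie strictly in (0, 1), got {cutoff}")
    return BinaryLabel.WARDEN if ratio > cutoff else BinaryLabel.PATCH


def score_measurements(
    measurements: Iterable[MeasurementSet],
    cutoff: float | None = DEFAULT_CUTOFF,
    actual: Sequence[SurgicalProcedure | None] | None = None,
) -> list[ScoredPatient]:
    """Score a sequence of measurements, optionally attaching actual labels."""
    measurements = list(measurements)
    if actual is None:
        actual = [None] * len(measurements)
    if len(actual) != len(measurements):
        raise ValueError("actual labels and measurements differ in length")
    out = []
    for m, lab in zip(measurements, actual):
        ratio = papvr_ratio(m)
        out.append(
            ScoredPatient(
                patient_id=m.patient_id,
                ratio=ratio,
                predicted_procedure=None if cutoff is None else classify(ratio, cutoff),
                actual_procedure=lab,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort tables — delimited text, strict header:
#   patient_id, d_pv_svd_mm, d_pv_azygos_mm, actual_procedure
# actual_procedure may be empty when unknown.
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("patient_id", "d_pv_svd_mm", "d_pv_azygos_mm", "actual_procedure")


class CohortTableError(ValueError):
    """Raised for a malformed cohort table (header or row level)."""


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort table (CSV or TSV by extension), enforcing the header."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    if tuple(df.columns) != COHORT_COLUMNS:
        raise CohortTableError(
            f"{path}: expected columns {list(COHORT_COLUMNS)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise CohortTableError(f"{path}: cohort table is empty")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.loc[:, list(COHORT_COLUMNS)].to_csv(path, sep=sep, index=False)
    return path


def measurements_from_table(
    df: pd.DataFrame, strict: bool = True
) -> tuple[list[MeasurementSet], list[SurgicalProcedure | None], list[str]]:
    """Convert cohort-table rows to measurements plus actual labels.

    Returns ``(measurements, labels, warnings)``. In strict mode the first
    malformed row aborts with a :class:`CohortTableError` naming the row; in
    lenient mode malformed rows are skipped and reported in ``warnings``.
    """
    measurements: list[MeasurementSet] = []
    labels: list[SurgicalProcedure | None] = []
    warnings: list[str] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        try:
            m = MeasurementSet(
                patient_id=str(row["patient_id"]),
                d_pv_svd=float(row["d_pv_svd_mm"]),
                d_pv_azygos=float(row["d_pv_azygos_mm"]),
            )
            raw_label = row["actual_procedure"]
            label: SurgicalProcedure | None
            if pd.isna(raw_label) or str(raw_label).strip() == "":
                label = None
            else:
                label = SurgicalProcedure(str(raw_label).strip())
        except (ValueError, TypeError) as exc:
            msg = f"row {rowno}: {exc}"
            if strict:
                raise CohortTableError(msg) from exc
            warnings.append(msg)
            continue
        measurements.append(m)
        labels.append(label)
    return measurements, labels, warnings


def score_table(
    df: pd.DataFrame,
    cutoff: float | None = DEFAULT_CUTOFF,
    strict: bool = True,
) -> tuple[list[ScoredPatient], list[str]]:
    """Score every row of a cohort table. Returns (scored, row warnings)."""
    measurements, labels, warnings = measurements_from_table(df, strict=strict)
    return score_measurements(measurements, cutoff=cutoff, actual=labels), warnings
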