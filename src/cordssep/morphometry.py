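"""Cord morphometry: CCR, MSCC and the 0-3 MRI compression grade.

Works on measured scalars from sagittal/axial T2-weighted MRI (diameters in
mm, a CSF occlusion fraction and two radiological flags); no image handling.

Quantities
----------
CCR (cord compression ratio)
    Anteroposterior over transverse cord diameter at the level of maximal
    compression. A flatter (more compressed) cord has a lower CCR.
MSCC (maximum spinal cord compression, %)
    Percent reduction of the AP diameter relative to the mean of the normal
    levels above and below: ``(1 - d_i / ((d_a + d_b)/2)) * 100``. Zero when
    the compressed level matches the adjacent mean; negative values (cord
    wider than its neighbours) are kept unless ``clamp_negative`` is set.
Grade
    3 if the cord is deformed and the intramedullary signal changed; 2 if
    deformed without signal change; 1 if not deformed but the subarachnoid
    CSF space is >= 50% occluded; 0 otherwise. Deformation takes precedence
    over the occlusion criterion, since the deformation-defined grades do not
    reference the CSF space. Exactly 50% occlusion is assigned to grade 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CordMorphometry",
    "GradeResult",
    "compute_ccr",
    "compute_mscc",
    "assign_grade",
    "grade_table",
    "read_morphometry_csv",
    "write_grades_csv",
]


@dataclass(frozen=True)
class CordMorphometry:
    """Measured descriptors for one patient at the maximal-compression level."""

    ap_diameter: float  # mm, anteroposterior at maximal compression (d_i)
    transverse_diameter: float  # mm, same level
    ap_above: float  # mm, normal level above (d_a)
    ap_below: float  # mm, normal level below (d_b)
    csf_occlusion_fraction: float  # 0-1
    deformation: bool
    signal_change: bool
    patient_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("ap_diameter", "transverse_diameter", "ap_above", "ap_below"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if not 0.0 <= self.csf_occlusion_fraction <= 1.0:
            raise ValueError("csf_occlusion_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GradeResult:
    grade: int
    ccr: float
    mscc: float

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be 0-3, got {self.grade!r}")
        if not self.ccr > 0:
            raise ValueError("ccr must be positive")


def compute_ccr(m: CordMorphometry) -> float:
    """AP / transverse diameter ratio (dimensionless, lower = flatter)."""
    return m.ap_diameter / m.transverse_diameter


def compute_mscc(m: CordMorphometry, clamp_negative: bool = False) -> float:
    """Percent AP-diameter reduction against the adjacent-level mean.

    ``clamp_negative=True`` floors the result at 0 for workflows that treat
    any widening as "no compression".
    """
    mscc = (1.0 - m.ap_diameter / ((m.ap_above + m.ap_below) / 2.0)) * 100.0
    if clamp_negative and mscc < 0:
        return 0.0
    return mscc


def assign_grade(m: CordMorphometry, clamp_negative_mscc: bool = False) -> GradeResult:
    """Assign the 0-3 compression grade from the radiological descriptors."""
    if m.deformation and m.signal_change:
        grade = 3
    elif m.deformation:
        grade = 2
    elif m.csf_occlusion_fraction >= 0.5:
        grade = 1
    else:
        grade = 0
    return GradeResult(grade, compute_ccr(m), compute_mscc(m, clamp_negative_mscc))


# --------------------------------------------------------------------------
# tabular interface
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "patient_id",
    "ap_diameter",
    "transverse_diameter",
    "ap_above",
    "ap_below",
    "csf_occlusion_fraction",
    "deformation",
    "signal_change",
)


def _row_to_morphometry(row: pd.Series) -> CordMorphometry:
    return CordMorphometry(
        ap_diameter=float(row["ap_diameter"]),
        transverse_diameter=float(row["transverse_diameter"]),
        ap_above=float(row["ap_above"]),
        ap_below=float(row["ap_below"]),
        csf_occlusion_fraction=float(row["csf_occlusion_fraction"]),
        deformation=bool(row["deformation"]),
        signal_change=bool(row["signal_change"]),
        patient_id=str(row["patient_id"]),
    )


def grade_table(morphometry: pd.DataFrame, clamp_negative_mscc: bool = False) -> pd.DataFrame:
    """Grade every row of a morphometry table.

    Returns a frame with ``patient_id, ccr, mscc, grade`` in input order.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in morphometry.columns]
    if missing:
        raise ValueError(f"morphometry table missing columns: {missing}")
    records = []
    for _, row in morphometry.iterrows():
        m = _row_to_morphometry(row)
        res = assign_grade(m, clamp_negative_mscc)
        records.append(
            {"patient_id": m.patient_id, "ccr": res.ccr, "mscc": res.mscc, "grade": res.grade}
        )
    return pd.DataFrame.from_records(records)


def read_morphometry_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_grades_csv(grades: pd.DataFrame, path: str | Path) -> None:
    grades.to_csv(path, index=False)
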