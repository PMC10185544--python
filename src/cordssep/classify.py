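"""Threshold-based neuro-abnormality classification against control references.

A patient's evoked-potential features are judged as percent changes against
the control group's per-side *mean* feature values (the reference statistic
is deliberately the mean with its standard error, not the median used for
descriptive tables):

* amplitude reduction = 1 − amplitude / reference mean amplitude;
  abnormal when ≥ 50% (inclusive);
* TFA power loss = 1 − power / reference mean power; abnormal when ≥ 30%
  (inclusive);
* latency delay = latency / reference mean latency − 1; abnormal when ≥ 10%
  (inclusive — the delay criterion is stated inconsistently in the clinical
  literature; the inclusive reading matches the amplitude criterion).

Negative changes (patient better than control) are kept as negative
fractions and always classify as normal. The amplitude/power flag pair maps
to four categories:

====  =================  ==============
code  amplitude          TFA power
====  =================  ==============
A     normal             normal
B     abnormal           normal
C     abnormal           lost
D     normal             lost
====  =================  ==============

Category D is fully representable and counted even though compression
cohorts typically show power loss only after amplitude abnormality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import SsepFeatureSet
from .stats import ContingencyTable2x2

__all__ = [
    "ThresholdConfig",
    "SideReference",
    "ControlReference",
    "AbnormalityCall",
    "GradeTable",
    "build_control_reference",
    "classify_patient",
    "category_from_flags",
    "tabulate_by_grade",
    "calls_frame",
]

CATEGORY_ORDER = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ThresholdConfig:
    amplitude_reduction_cut: float = 0.50
    power_loss_cut: float = 0.30
    latency_delay_cut: float = 0.10

    def __post_init__(self) -> None:
        for name in ("amplitude_reduction_cut", "power_loss_cut", "latency_delay_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class SideReference:
    """Control-group means (and SEMs) for one side."""

    mean_amplitude_uv: float
    mean_tfa_power: float
    mean_latency_ms: float
    n_controls: int
    sem_amplitude_uv: float = math.nan
    sem_tfa_power: float = math.nan
    sem_latency_ms: float = math.nan

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("need at least one control")
        for name in ("mean_amplitude_uv", "mean_tfa_power", "mean_latency_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ControlReference:
    sides: Mapping[str, SideReference]

    def for_side(self, side: str) -> SideReference:
        if side not in self.sides:
            raise ValueError(f"no control reference for side {side!r}")
        return self.sides[side]


@dataclass(frozen=True)
class AbnormalityCall:
    patient_id: str
    side: str
    amplitude_reduction: float
    power_loss: float
    latency_delay: float
    amplitude_abnormal: bool
    power_abnormal: bool
    latency_abnormal: bool
    category: str

    def __post_init__(self) -> None:
        if self.category != category_from_flags(self.amplitude_abnormal, self.power_abnormal):
            raise ValueError("category inconsistent with the flag pair")


def category_from_flags(amplitude_abnormal: bool, power_abnormal: bool) -> str:
    """Pure mapping of the amplitude/power flag pair onto A/B/C/D."""
    if amplitude_abnormal:
        return "C" if power_abnormal else "B"
    return "D" if power_abnormal else "A"


def build_control_reference(control_features: Iterable[SsepFeatureSet]) -> ControlReference:
    """Per-side arithmetic means and standard errors of the control features.

    With a single control per side the mean is that patient's value and the
    SEM is flagged as NaN.
    """
    by_side: dict[str, list[SsepFeatureSet]] = {}
    for f in control_features:
        by_side.setdefault(f.side, []).append(f)
    if not by_side:
        raise ValueError("control feature set is empty")
    sides = {}
    for side, feats in by_side.items():
        amp = np.array([f.amplitude_uv for f in feats])
        pwr = np.array([f.tfa_power for f in feats])
        lat = np.array([f.latency_ms for f in feats])
        n = len(feats)

        def sem(v: np.ndarray) -> float:
            return float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan

        sides[side] = SideReference(
            mean_amplitude_uv=float(amp.mean()),
            mean_tfa_power=float(pwr.mean()),
            mean_latency_ms=float(lat.mean()),
            n_controls=n,
            sem_amplitude_uv=sem(amp),
            sem_tfa_power=sem(pwr),
            sem_latency_ms=sem(lat),
        )
    return ControlReference(sides)


def classify_patient(
    features: SsepFeatureSet,
    reference: ControlReference,
    thresholds: ThresholdConfig | None = None,
) -> AbnormalityCall:
    """Percent changes against the side-matched control means, with flags.

    Cuts are inclusive: a reduction of exactly 50% (or loss of exactly 30%,
    delay of exactly 10%) classifies as abnormal.
    """
    thresholds = thresholds or ThresholdConfig()
    ref = reference.for_side(features.side)
    amplitude_reduction = 1.0 - features.amplitude_uv / ref.mean_amplitude_uv
    power_loss = 1.0 - features.tfa_power / ref.mean_tfa_power
    latency_delay = features.latency_ms / ref.mean_latency_ms - 1.0
    # the cuts are inclusive; a small relative guard keeps values that are
    # mathematically at the cut from being demoted by float rounding
    def _at_least(value: float, cut: float) -> bool:
        return value >= cut * (1.0 - 1e-9)

    amp_abn = _at_least(amplitude_reduction, thresholds.amplitude_reduction_cut)
    pow_abn = _at_least(power_loss, thresholds.power_loss_cut)
    lat_abn = _at_least(latency_delay, thresholds.latency_delay_cut)
    return AbnormalityCall(
        patient_id=features.patient_id,
        side=features.side,
        amplitude_reduction=amplitude_reduction,
        power_loss=power_loss,
        latency_delay=latency_delay,
        amplitude_abnormal=bool(amp_abn),
        power_abnormal=bool(pow_abn),
        latency_abnormal=bool(lat_abn),
        category=category_from_flags(bool(amp_abn), bool(pow_abn)),
    )


_ROW_LABELS = ("power_loss<cut", "power_loss>=cut")
_COL_LABELS = ("amplitude_reduction<cut", "amplitude_reduction>=cut")


@dataclass(frozen=True)
class GradeTable:
    """Per-grade 2×2 cross-classification and category proportions.

    ``table`` is ``None`` for an empty stratum (all-zero counts, NaN
    percentages) — the exact-test container requires at least one
    observation, and an empty grade has nothing to test.
    """

    grade: int
    table: ContingencyTable2x2 | None  # rows: power loss < / >= cut; cols: reduction < / >= cut
    n: int
    category_counts: Mapping[str, int]
    category_pct: Mapping[str, float]  # NaN when the stratum is empty

    def as_dict(self) -> dict:
        counts = self.table.as_array().tolist() if self.table is not None else [[0, 0], [0, 0]]
        return {
            "grade": self.grade,
            "counts": counts,
            "row_labels": list(_ROW_LABELS),
            "col_labels": list(_COL_LABELS),
            "n": self.n,
            "empty": self.table is None,
            "category_counts": dict(self.category_counts),
            "category_pct": {
                k: (None if math.isnan(v) else v) for k, v in self.category_pct.items()
            },
        }


def tabulate_by_grade(
    calls: Sequence[AbnormalityCall],
    grades: Mapping[str, int],
    grades_to_tabulate: Sequence[int] = (1, 2, 3),
) -> dict[int, GradeTable]:
    """Cross-count amplitude reduction × power loss per MRI grade.

    Every call must have a grade in ``grades``; counts per grade conserve
    that grade's patient count. Empty strata yield zero tables with NaN
    percentages.
    """
    counts: dict[int, dict[str, int]] = {g: {c: 0 for c in CATEGORY_ORDER} for g in grades_to_tabulate}
    for call in calls:
        if call.patient_id not in grades:
            raise ValueError(f"patient {call.patient_id!r} has a call but no grade")
        g = int(grades[call.patient_id])
        if g in counts:
            counts[g][call.category] += 1

    out: dict[int, GradeTable] = {}
    for g in grades_to_tabulate:
        c = counts[g]
        n = sum(c.values())
        if n == 0:
            out[g] = GradeTable(
                grade=g,
                table=None,
                n=0,
                category_counts=dict(c),
                category_pct={c_: math.nan for c_ in CATEGORY_ORDER},
            )
            continue
        # Table layout: rows = power loss (< cut, >= cut), cols = amplitude
        # reduction (< cut, >= cut): [[A, B], [D, C]]
        table = ContingencyTable2x2(
            c["A"], c["B"], c["D"], c["C"], row_labels=_ROW_LABELS, col_labels=_COL_LABELS
        )
        pct = {c_: 100.0 * c[c_] / n for c_ in CATEGORY_ORDER}
        out[g] = GradeTable(grade=g, table=table, n=n, category_counts=dict(c), category_pct=pct)
    return out


def calls_frame(calls: Sequence[AbnormalityCall]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "patient_id": c.patient_id,
                "side": c.side,
                "amplitude_reduction": c.amplitude_reduction,
                "power_loss": c.power_loss,
                "latency_delay": c.latency_delay,
                "amplitude_abnormal": c.amplitude_abnormal,
                "power_abnormal": c.power_abnormal,
                "latency_abnormal": c.latency_abnormal,
                "category": c.category,
            }
            for c in calls
        ]
    )
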