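"""Abnormality classification against control references and per-grade tables."""

import math

import numpy as np
import pytest

from cordssep.classify import (
    ThresholdConfig,
    build_control_reference,
    calls_frame,
    category_from_flags,
    classify_patient,
    tabulate_by_grade,
)
from cordssep.features import SsepFeatureSet


def _f(pid="p", side="right", amp=2.58, lat=40.0, power=6.37):
    return SsepFeatureSet(patient_id=pid, side=side, amplitude_uv=amp, latency_ms=lat, tfa_power=power)


def _ref(amp=2.58, power=6.37, lat=40.0, n=10):
    feats = [_f(pid=f"c{i}", amp=amp, power=power, lat=lat) for i in range(n)]
    return build_control_reference(feats)


# --------------------------------------------------------------------------
# reference construction
# --------------------------------------------------------------------------

def test_reference_two_point_mean():
    ref = build_control_reference([_f(pid="a", amp=2.0), _f(pid="b", amp=3.0)])
    side = ref.for_side("right")
    assert side.mean_amplitude_uv == pytest.approx(2.5)
    assert side.n_controls == 2


def test_reference_single_control_flags_sem():
    side = build_control_reference([_f()]).for_side("right")
    assert side.mean_amplitude_uv == pytest.approx(2.58)
    assert math.isnan(side.sem_amplitude_uv)


def test_reference_empty_is_error():
    with pytest.raises(ValueError):
        build_control_reference([])


def test_reference_missing_side_is_error():
    ref = build_control_reference([_f(side="right")])
    with pytest.raises(ValueError, match="left"):
        ref.for_side("left")


# --------------------------------------------------------------------------
# per-patient classification
# --------------------------------------------------------------------------

def test_hand_arithmetic_reductions():
    ref = _ref()
    call = classify_patient(_f(amp=1.00, power=4.70), ref)
    assert call.amplitude_reduction == pytest.approx(1 - 1.00 / 2.58, abs=1e-12)  # ~0.612
    assert call.power_loss == pytest.approx(1 - 4.70 / 6.37, abs=1e-12)  # ~0.262
    assert call.amplitude_abnormal and not call.power_abnormal
    assert call.category == "B"


def test_self_comparison_is_category_a():
    call = classify_patient(_f(), _ref())
    assert call.amplitude_reduction == pytest.approx(0.0)
    assert call.power_loss == pytest.approx(0.0)
    assert call.latency_delay == pytest.approx(0.0)
    assert call.category == "A"


def test_cuts_are_inclusive():
    ref = _ref(amp=2.58, power=6.0, lat=40.0)
    call = classify_patient(_f(amp=1.29, power=4.2, lat=44.0), ref)
    assert call.amplitude_reduction == pytest.approx(0.5)
    assert call.power_loss == pytest.approx(0.3)
    assert call.latency_delay == pytest.approx(0.1)
    assert call.amplitude_abnormal and call.power_abnormal and call.latency_abnormal
    assert call.category == "C"


def test_negative_changes_stay_negative_and_normal():
    call = classify_patient(_f(amp=3.5, power=9.0, lat=35.0), _ref())
    assert call.amplitude_reduction < 0
    assert call.power_loss < 0
    assert call.latency_delay < 0
    assert call.category == "A"


def test_classification_scale_invariant():
    thresholds = ThresholdConfig()
    ref1 = _ref(amp=2.58, power=6.37)
    ref2 = _ref(amp=2.58 * 3.7, power=6.37 * 0.01)
    for amp_frac, pow_frac in [(0.9, 0.9), (0.45, 0.8), (0.4, 0.6), (0.7, 0.2)]:
        c1 = classify_patient(_f(amp=2.58 * amp_frac, power=6.37 * pow_frac), ref1, thresholds)
        c2 = classify_patient(
            _f(amp=2.58 * 3.7 * amp_frac, power=6.37 * 0.01 * pow_frac), ref2, thresholds
        )
        assert c1.category == c2.category
        assert c1.amplitude_reduction == pytest.approx(c2.amplitude_reduction, abs=1e-12)


def test_category_mapping_covers_all_flag_pairs():
    assert category_from_flags(False, False) == "A"
    assert category_from_flags(True, False) == "B"
    assert category_from_flags(True, True) == "C"
    assert category_from_flags(False, True) == "D"


def test_category_d_is_representable():
    call = classify_patient(_f(amp=2.5, power=1.0), _ref())
    assert call.category == "D"


def test_threshold_validation():
    with pytest.raises(ValueError):
        ThresholdConfig(amplitude_reduction_cut=0.0)
    with pytest.raises(ValueError):
        ThresholdConfig(power_loss_cut=1.0)


# --------------------------------------------------------------------------
# per-grade tabulation
# --------------------------------------------------------------------------

def _calls_for_counts(counts_by_cat, grade, grades, start=0):
    """Engineer calls whose categories realise the requested counts."""
    ref = _ref()
    specs = {
        "A": dict(amp=2.5, power=6.0),
        "B": dict(amp=1.0, power=6.0),
        "C": dict(amp=1.0, power=2.0),
        "D": dict(amp=2.5, power=2.0),
    }
    calls = []
    i = start
    for cat, k in counts_by_cat.items():
        for _ in range(k):
            pid = f"p{i}"
            calls.append(classify_patient(_f(pid=pid, **specs[cat]), ref))
            assert calls[-1].category == cat
            grades[pid] = grade
            i += 1
    return calls


def test_tabulate_reproduces_printed_grade1_structure():
    grades = {}
    calls = _calls_for_counts({"A": 27, "B": 4, "C": 4, "D": 0}, grade=1, grades=grades)
    tables = tabulate_by_grade(calls, grades)
    t1 = tables[1]
    assert t1.table.as_array().tolist() == [[27, 4], [0, 4]]
    assert t1.category_pct["A"] == pytest.approx(77.1, abs=0.05)
    assert t1.category_pct["B"] == pytest.approx(11.4, abs=0.05)
    assert t1.category_pct["C"] == pytest.approx(11.4, abs=0.05)
    assert t1.category_pct["D"] == 0.0


def test_tabulate_conserves_counts_and_flags_empty():
    grades = {}
    calls = _calls_for_counts({"A": 5}, grade=2, grades=grades)
    tables = tabulate_by_grade(calls, grades)
    assert tables[2].table.as_array().tolist() == [[5, 0], [0, 0]]
    assert tables[2].n == 5
    assert tables[1].n == 0 and tables[1].table is None
    assert all(math.isnan(v) for v in tables[1].category_pct.values())
    assert tables[1].as_dict()["counts"] == [[0, 0], [0, 0]]


def test_tabulate_missing_grade_is_error():
    calls = [classify_patient(_f(pid="x"), _ref())]
    with pytest.raises(ValueError, match="no grade"):
        tabulate_by_grade(calls, {})


def test_calls_frame_columns():
    grades = {}
    calls = _calls_for_counts({"A": 1, "C": 1}, grade=1, grades=grades)
    df = calls_frame(calls)
    assert list(df["category"]) == ["A", "C"]
    assert set(df.columns) >= {"patient_id", "amplitude_reduction", "power_loss", "category"}


# --------------------------------------------------------------------------
# integration with the synthetic cohort
# --------------------------------------------------------------------------

def test_default_cohort_reference_near_configured_control_mean(default_cohort_features):
    cfg, truths, feats = default_cohort_features
    controls = [f for f, t in zip(feats, truths) if t.grade == 0]
    ref = build_control_reference(controls).for_side("right")
    # §-style control mean: the generator targets a 2.39 uV control median,
    # whose log-normal mean sits near the printed 2.58 uV reference
    assert ref.mean_amplitude_uv == pytest.approx(2.58, rel=0.15)
    assert ref.n_controls == 10


def test_default_cohort_calls_match_truth_categories(default_cohort_features):
    cfg, truths, feats = default_cohort_features
    ref = build_control_reference([f for f, t in zip(feats, truths) if t.grade == 0])
    calls = [classify_patient(f, ref) for f in feats]
    agree = sum(c.category == t.category for c, t in zip(calls, truths) if t.grade > 0)
    n = sum(1 for t in truths if t.grade > 0)
    assert agree / n >= 0.95
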