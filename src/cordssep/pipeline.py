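"""Seeded, configured, logged pipeline: simulate → extract → grade → classify → analyze → report.

Stages communicate exclusively through on-disk artifacts (CSV/JSON) inside a
run directory, so each stage can be re-run or replaced independently and
externally produced epoch/morphometry files can substitute for simulation
with no code change:

========  =========================================  =============================
stage     reads                                      writes
========  =========================================  =============================
simulate  config                                     manifest.csv, morphometry.csv,
                                                     epochs/<pid>_<side>.{tsv,json}
extract   epochs/                                    features.csv
grade     morphometry.csv                            grades.csv
classify  features.csv, grades.csv                   calls.csv, tables.json
analyze   features.csv, grades.csv, tables.json      stats.json
report    all of the above                           report.json, summary.txt
========  =========================================  =============================

The report is deterministic for identical (config, seed): it embeds the
config hash and package version but no timestamps or absolute paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ControlReference,
    SideReference,
    ThresholdConfig,
    build_control_reference,
    calls_frame,
    classify_patient,
    tabulate_by_grade,
)
from .cohort import (
    CohortConfig,
    cohort_manifest,
    epoch_seed,
    generate_cohort,
    generate_epoch_set,
    morphometry_frame,
)
from .features import (
    SsepFeatureSet,
    extract_features,
    read_epochs,
    read_features_csv,
    write_epochs,
    write_features_csv,
)
from .morphometry import grade_table, read_morphometry_csv, write_grades_csv
from .stats import ContingencyTable2x2, fisher_exact_2x2, grade_association_summary

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "run_pipeline",
    "render_report",
    "stage_simulate",
    "stage_extract",
    "stage_grade",
    "stage_classify",
    "stage_analyze",
    "stage_report",
]

logger = logging.getLogger("cordssep.pipeline")

_STAGES = ("simulate", "extract", "grade", "classify", "analyze", "report")


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the failing stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Composition of all stage configurations."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    analysis_window_ms: tuple[float, float] = (0.0, 100.0)
    sides: tuple[str, ...] = ("right", "left")
    clamp_negative_mscc: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.sides or any(s not in ("left", "right") for s in self.sides):
            raise ValueError("sides must be a non-empty subset of {'left','right'}")
        if self.cohort.analysis_side not in self.sides:
            raise ValueError("the analysis side must be among the simulated sides")

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "thresholds": {
                "amplitude_reduction_cut": self.thresholds.amplitude_reduction_cut,
                "power_loss_cut": self.thresholds.power_loss_cut,
                "latency_delay_cut": self.thresholds.latency_delay_cut,
            },
            "analysis_window_ms": list(self.analysis_window_ms),
            "sides": list(self.sides),
            "clamp_negative_mscc": self.clamp_negative_mscc,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        if "cohort" in d:
            kwargs["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "thresholds" in d:
            kwargs["thresholds"] = ThresholdConfig(**d["thresholds"])
        if "analysis_window_ms" in d:
            kwargs["analysis_window_ms"] = tuple(d["analysis_window_ms"])
        if "sides" in d:
            kwargs["sides"] = tuple(d["sides"])
        for key in ("clamp_negative_mscc", "log_level"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


@dataclass(frozen=True)
class RunReport:
    """Machine-readable result of one pipeline run."""

    provenance: dict
    cohort: dict
    control_reference: dict
    table1: dict
    table2: dict
    table3: dict
    figure4: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "cohort": self.cohort,
            "control_reference": self.control_reference,
            "table1": self.table1,
            "table2": self.table2,
            "table3": self.table3,
            "figure4": self.figure4,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunReport":
        return cls(**{k: d[k] for k in (
            "provenance", "cohort", "control_reference", "table1", "table2", "table3", "figure4"
        )})


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_stage(stage: str, outputs: Sequence[Path]) -> None:
    hashes = {p.name: _sha256(p) for p in outputs if p.exists()}
    logger.info("stage=%s outputs=%s", stage, json.dumps(hashes, sort_keys=True))


def _mark_failure(out_dir: Path, stage: str, err: Exception) -> None:
    (out_dir / f"FAILED_{stage}.txt").write_text(f"{type(err).__name__}: {err}\n")


def _nan_to_none(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: Path) -> list[Path]:
    cohort = config.cohort
    truths = generate_cohort(cohort)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(truths)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    morph = morphometry_frame(truths)
    morph_path = out_dir / "morphometry.csv"
    morph.to_csv(morph_path, index=False)
    epochs_dir = out_dir / "epochs"
    epochs_dir.mkdir(exist_ok=True)
    for truth in truths:
        for side in config.sides:
            ep = generate_epoch_set(
                truth,
                cohort.protocol,
                epoch_seed(cohort.seed, truth, side),
                side=side,
                noise_sd_uv=cohort.noise_sd_uv,
                carrier_hz=cohort.carrier_hz,
            )
            write_epochs(ep, epochs_dir / f"{truth.patient_id}_{side}")
    config.save(out_dir / "config.yaml")
    return [manifest_path, morph_path]


def stage_extract(config: PipelineConfig, out_dir: Path) -> list[Path]:
    epochs_dir = out_dir / "epochs"
    if not epochs_dir.is_dir():
        raise FileNotFoundError(f"no epochs directory at {epochs_dir}")
    feats: list[SsepFeatureSet] = []
    for sidecar in sorted(epochs_dir.glob("*.json")):
        ep = read_epochs(sidecar.with_suffix(""))
        feats.append(
            extract_features(
                ep,
                window=config.analysis_window_ms,
                stft_params=config.cohort.stft,
                region=config.cohort.region,
            )
        )
    if not feats:
        raise FileNotFoundError(f"no epoch files found in {epochs_dir}")
    from .features import features_frame

    df = features_frame(feats)
    provenance = {
        "stft": config.cohort.stft.__dict__,
        "region": [list(config.cohort.region[0]), list(config.cohort.region[1])],
        "analysis_window_ms": list(config.analysis_window_ms),
    }
    path = out_dir / "features.csv"
    write_features_csv(df, path, provenance)
    return [path]


def stage_grade(config: PipelineConfig, out_dir: Path) -> list[Path]:
    morph = read_morphometry_csv(out_dir / "morphometry.csv")
    grades = grade_table(morph, clamp_negative_mscc=config.clamp_negative_mscc)
    path = out_dir / "grades.csv"
    write_grades_csv(grades, path)
    return [path]


def _features_by_patient(features: pd.DataFrame, side: str) -> list[SsepFeatureSet]:
    rows = features[features["side"] == side]
    return [
        SsepFeatureSet(
            patient_id=str(r.patient_id),
            side=side,
            amplitude_uv=float(r.amplitude_uV),
            latency_ms=float(r.latency_ms),
            tfa_power=float(r.tfa_power),
        )
        for r in rows.itertuples()
    ]


def _configured_reference(config: PipelineConfig, side: str) -> SideReference:
    """Fallback reference from the configured grade-0 expectations, used when
    the cohort has no control patients."""
    cohort = config.cohort
    disp = cohort.dispersion_scale
    sig_a = cohort.amplitude_sigma[0] * disp
    sig_p = cohort.tfa_sigma * disp
    return SideReference(
        mean_amplitude_uv=cohort.amplitude_medians(side)[0] * math.exp(sig_a**2 / 2),
        mean_tfa_power=cohort.tfa_medians(side)[0] * math.exp(sig_p**2 / 2),
        mean_latency_ms=cohort.latency_medians(side)[0],
        n_controls=1,
    )


def stage_classify(config: PipelineConfig, out_dir: Path) -> list[Path]:
    features = read_features_csv(out_dir / "features.csv")
    grades = pd.read_csv(out_dir / "grades.csv")
    grade_of = dict(zip(grades["patient_id"].astype(str), grades["grade"].astype(int)))
    side = config.cohort.analysis_side

    side_feats = _features_by_patient(features, side)
    controls = [f for f in side_feats if grade_of.get(f.patient_id) == 0]
    if controls:
        reference = build_control_reference(controls)
        ref_source = "cohort grade-0 means"
    else:
        reference = ControlReference({side: _configured_reference(config, side)})
        ref_source = "configured grade-0 expectations (no controls in cohort)"

    calls = [classify_patient(f, reference, config.thresholds) for f in side_feats]
    missing = [c.patient_id for c in calls if c.patient_id not in grade_of]
    if missing:
        raise ValueError(f"calls without grades: {missing[:5]}")
    tables = tabulate_by_grade(calls, grade_of)

    calls_path = out_dir / "calls.csv"
    calls_frame(calls).to_csv(calls_path, index=False)

    ref = reference.for_side(side)
    tables_payload = {
        "analysis_side": side,
        "thresholds": {
            "amplitude_reduction_cut": config.thresholds.amplitude_reduction_cut,
            "power_loss_cut": config.thresholds.power_loss_cut,
            "latency_delay_cut": config.thresholds.latency_delay_cut,
        },
        "control_reference": {
            "source": ref_source,
            "mean_amplitude_uv": ref.mean_amplitude_uv,
            "mean_tfa_power": ref.mean_tfa_power,
            "mean_latency_ms": ref.mean_latency_ms,
            "n_controls": ref.n_controls,
            "sem_amplitude_uv": _nan_to_none(ref.sem_amplitude_uv),
            "sem_tfa_power": _nan_to_none(ref.sem_tfa_power),
            "sem_latency_ms": _nan_to_none(ref.sem_latency_ms),
        },
        "grade_tables": {str(g): t.as_dict() for g, t in tables.items()},
    }
    tables_path = out_dir / "tables.json"
    tables_path.write_text(json.dumps(tables_payload, indent=2, sort_keys=True) + "\n")
    return [calls_path, tables_path]


def _wide_feature_table(features: pd.DataFrame, grades: pd.DataFrame) -> pd.DataFrame:
    wide = grades[["patient_id", "ccr", "mscc", "grade"]].copy()
    wide["patient_id"] = wide["patient_id"].astype(str)
    for side in ("left", "right"):
        sub = features[features["side"] == side]
        if sub.empty:
            continue
        sub = sub[["patient_id", "amplitude_uV", "latency_ms", "tfa_power"]].rename(
            columns={
                "amplitude_uV": f"{side}_amplitude_uV",
                "latency_ms": f"{side}_latency_ms",
                "tfa_power": f"{side}_tfa_power",
            }
        )
        sub["patient_id"] = sub["patient_id"].astype(str)
        wide = wide.merge(sub, on="patient_id", how="left")
    return wide


def stage_analyze(config: PipelineConfig, out_dir: Path) -> list[Path]:
    features = read_features_csv(out_dir / "features.csv")
    grades = pd.read_csv(out_dir / "grades.csv")
    tables = json.loads((out_dir / "tables.json").read_text())

    wide = _wide_feature_table(features, grades)
    variables = [c for c in wide.columns if c not in ("patient_id", "grade")]
    grade_tables = {}
    for g_str, payload in tables["grade_tables"].items():
        if payload.get("empty"):
            continue
        (a, b), (c, d) = payload["counts"]
        grade_tables[int(g_str)] = ContingencyTable2x2(a, b, c, d)
    summary = grade_association_summary(
        wide.dropna(subset=variables),
        grade_col="grade",
        variables=variables,
        grade_tables=grade_tables,
    )
    path = out_dir / "stats.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [path]


def _table1_block(wide: pd.DataFrame, summary: dict) -> dict:
    variables = [c for c in wide.columns if c not in ("patient_id", "grade")]
    block: dict = {"quartile_convention": "linear interpolation", "by_variable": {}}
    for v in variables:
        per_grade = {}
        for g in range(4):
            vals = wide.loc[wide["grade"] == g, v].dropna().to_numpy()
            if vals.size == 0:
                per_grade[str(g)] = {"n": 0, "empty": True}
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            per_grade[str(g)] = {
                "n": int(vals.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }
        kw = summary["kruskal_wallis"].get(v, {})
        block["by_variable"][v] = {"per_grade": per_grade, "kruskal_wallis": kw}
    return block


def stage_report(config: PipelineConfig, out_dir: Path) -> RunReport:
    features = read_features_csv(out_dir / "features.csv")
    grades = pd.read_csv(out_dir / "grades.csv")
    tables = json.loads((out_dir / "tables.json").read_text())
    summary = json.loads((out_dir / "stats.json").read_text())

    wide = _wide_feature_table(features, grades)
    counts = {str(g): int((grades["grade"] == g).sum()) for g in range(4)}

    table3 = {"thresholds": tables["thresholds"], "analysis_side": tables["analysis_side"], "per_grade": {}}
    figure4 = {}
    for g_str, payload in tables["grade_tables"].items():
        entry = dict(payload)
        if not payload.get("empty"):
            (a, b), (c, d) = payload["counts"]
            res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            entry["fisher_p"] = res.p_value
        else:
            entry["fisher_p"] = None
        table3["per_grade"][g_str] = entry
        figure4[g_str] = payload["category_pct"]

    report = RunReport(
        provenance={
            "package": "cordssep",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        cohort={"counts_by_grade": counts, "n_total": int(len(grades))},
        control_reference=tables["control_reference"],
        table1=_table1_block(wide, summary),
        table2={
            "variables": summary["variables"],
            "kendall_tau_b": summary["kendall_tau_b"],
            "band_rule": summary["band_rule"],
        },
        table3=table3,
        figure4=figure4,
    )
    render_report(report, out_dir)
    return report


# --------------------------------------------------------------------------
# orchestration and rendering
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage in order; identical (config, seed) gives an
    identical report. A stage failure aborts with the stage named and leaves
    a ``FAILED_<stage>.txt`` marker next to any partial outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage_fns = {
        "simulate": stage_simulate,
        "extract": stage_extract,
        "grade": stage_grade,
        "classify": stage_classify,
        "analyze": stage_analyze,
    }
    for name in ("simulate", "extract", "grade", "classify", "analyze"):
        try:
            outputs = stage_fns[name](config, out_dir)
            _log_stage(name, outputs)
        except Exception as err:
            _mark_failure(out_dir, name, err)
            raise PipelineError(f"stage '{name}' failed: {err}") from err
    try:
        report = stage_report(config, out_dir)
        _log_stage("report", [out_dir / "report.json", out_dir / "summary.txt"])
    except Exception as err:
        _mark_failure(out_dir, "report", err)
        raise PipelineError(f"stage 'report' failed: {err}") from err
    return report


def render_report(report: RunReport, out_dir: str | Path, formats: Sequence[str] = ("json", "text")) -> list[Path]:
    """Emit the report as machine-readable JSON and/or a human summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            path = out_dir / "report.json"
            path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        elif fmt == "text":
            path = out_dir / "summary.txt"
            path.write_text(_text_summary(report))
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(path)
    return written


def _text_summary(report: RunReport) -> str:
    lines = []
    prov = report.provenance or {}
    lines.append(
        f"cordssep {prov.get('version', '?')} run report "
        f"(seed={prov.get('seed', '?')}, config={prov.get('config_hash', '?')})"
    )
    lines.append("")
    counts = (report.cohort or {}).get("counts_by_grade", {})
    if counts:
        lines.append("Cohort: " + ", ".join(f"grade {g}: n={counts.get(str(g), 0)}" for g in range(4)))
    ref = report.control_reference or {}
    if "mean_amplitude_uv" in ref:
        lines.append(
            f"Control reference ({ref.get('source')}): amplitude {ref['mean_amplitude_uv']:.3f} uV, "
            f"TFA power {ref['mean_tfa_power']:.3f}, latency {ref['mean_latency_ms']:.2f} ms"
        )
    thr = (report.table3 or {}).get("thresholds")
    if thr:
        lines.append(
            f"Thresholds: amplitude reduction >= {thr['amplitude_reduction_cut']:.0%}, "
            f"power loss >= {thr['power_loss_cut']:.0%}, latency delay >= {thr['latency_delay_cut']:.0%}"
        )
    if report.figure4:
        lines.append("")
        lines.append("Per-grade abnormality distribution (category: % of grade):")
        lines.append("  A: no amplitude/power abnormality, B: amplitude only,")
        lines.append("  C: amplitude + power loss, D: power only")
        for g_str in sorted(report.figure4):
            pct = report.figure4[g_str]
            entry = (report.table3 or {}).get("per_grade", {}).get(g_str, {})
            if entry.get("empty"):
                lines.append(f"  grade {g_str}: empty stratum")
                continue
            pcts = ", ".join(
                f"{c}: {pct[c]:.1f}%" if pct.get(c) is not None else f"{c}: n/a" for c in "ABCD"
            )
            p = entry.get("fisher_p")
            suffix = f"; Fisher exact p = {p:.3f}" if p is not None else ""
            lines.append(f"  grade {g_str} (n={entry.get('n', 0)}): {pcts}{suffix}")
    lines.append("")
    return "\n".join(lines) + "\n"
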