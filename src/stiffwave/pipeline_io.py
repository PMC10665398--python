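"""Tabular I/O and end-to-end orchestration of the analysis stages.

Reads and writes the plain-CSV interchange formats (waveform samples,
beat onsets, stimulation events, per-beat sBP, per-beat K estimates,
cohort tables), validates them against named schemas, and chains the
stages: waveform -> per-beat K -> MEC_K -> ROC_BP for one subject, and
cohort table -> statistical validation for a study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import beat_mechanics, mec_detection, rocbp as rocbp_mod
from .beat_mechanics import KSeries, WaveformRecord
from .cohort_stats import CohortStatsResult, SubjectRecord, run_cohort_analysis
from .mec_detection import OUT_OF_RANGE, MecResult, StimulusEvent
from .rocbp import RocBpResult

logger = logging.getLogger(__name__)

#: Column schemas for the interchange CSVs.
SCHEMAS: dict[str, list[str]] = {
    "waveform": ["time_s", "abp_mmhg", "ppg_pct"],
    "onsets": ["onset_index"],
    "events": ["stim_time_s", "intensity_ma", "duration_s"],
    "sbp": ["beat_time_s", "sbp_mmhg"],
    "kseries": ["beat_time_s", "k"],
    "beats": ["beat_time_s", "k", "b", "r_squared", "valid",
              "exclusion_reason"],
    "cohort": ["subject_id", "meck_ma", "rocbp_pct", "group"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Numeric columns are parsed locale-independently by pandas; in cohort
    tables the literal token ``OOR`` is honored in ``meck_ma`` and empty
    ``rocbp_pct``/``group`` cells become missing values.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    df = df[SCHEMAS[schema]]
    numeric_cols = {
        "waveform": ["time_s", "abp_mmhg", "ppg_pct"],
        "onsets": ["onset_index"],
        "events": ["stim_time_s", "intensity_ma", "duration_s"],
        "sbp": ["beat_time_s", "sbp_mmhg"],
        "kseries": ["beat_time_s", "k"],
        "beats": ["beat_time_s", "k", "b", "r_squared"],
        "cohort": ["rocbp_pct"],
    }[schema]
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} is not numeric") from exc
    if schema == "cohort":
        def _parse_meck(v: Any) -> int | str:
            if isinstance(v, str) and v.strip().upper() == OUT_OF_RANGE:
                return OUT_OF_RANGE
            return int(v)
        try:
            df["meck_ma"] = df["meck_ma"].map(_parse_meck)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column 'meck_ma' must be integer mA or 'OOR'"
            ) from exc
    return df


def write_waveform(record: WaveformRecord, out_dir: str | Path,
                   stem: str = "waveform") -> tuple[Path, Path]:
    """Write a waveform record as waveform + onsets CSVs; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wpath = out_dir / f"{stem}.csv"
    opath = out_dir / f"{stem}_onsets.csv"
    pd.DataFrame({
        "time_s": record.time_s,
        "abp_mmhg": record.abp_mmhg,
        "ppg_pct": record.ppg_pct,
    }).to_csv(wpath, index=False)
    pd.DataFrame({"onset_index": record.beat_onsets}).to_csv(opath, index=False)
    return wpath, opath


def write_kseries(kseries: KSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"beat_time_s": kseries.beat_time_s,
                  "k": kseries.k}).to_csv(path, index=False)
    return path


def write_events(events: list[StimulusEvent], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "stim_time_s": [e.onset_s for e in events],
        "intensity_ma": [e.intensity_ma for e in events],
        "duration_s": [e.duration_s for e in events],
    }).to_csv(path, index=False)
    return path


def write_cohort(subjects: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "meck_ma": [s.meck_ma for s in subjects],
        "rocbp_pct": [s.rocbp_pct if s.rocbp_pct is not None else ""
                      for s in subjects],
        "group": [s.group if s.group is not None else ""
                  for s in subjects],
    }).to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    df = read_table(path, "cohort")
    subjects = []
    for row in df.itertuples(index=False):
        rocbp = None if pd.isna(row.rocbp_pct) else float(row.rocbp_pct)
        group = None if (pd.isna(row.group) or row.group == "") else str(row.group)
        subjects.append(SubjectRecord(
            subject_id=str(row.subject_id), meck_ma=row.meck_ma,
            rocbp_pct=rocbp, group=group))
    return subjects


@dataclass
class PipelineConfig:
    """File paths and stage parameters for a subject-level run."""

    waveform_csv: str | None = None
    onsets_csv: str | None = None
    events_csv: str | None = None
    sbp_csv: str | None = None
    cohort_csv: str | None = None
    incision_time_s: float | None = None
    out_dir: str = "stiffwave_out"
    r2_min: float = beat_mechanics.DEFAULT_R2_MIN
    threshold: float = mec_detection.DEFAULT_THRESHOLD
    pre_window_s: float = mec_detection.DEFAULT_PRE_WINDOW_S
    post_window_s: float = mec_detection.DEFAULT_POST_WINDOW_S
    rule: str = "suffix"
    anchor: str = "offset"
    rocbp_post_window_s: float = rocbp_mod.DEFAULT_POST_WINDOW_S
    alpha: float = 0.05
    external_slope: float | None = None
    external_intercept: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if extra:
            logger.warning("ignoring unknown config keys: %s", sorted(extra))
        return cls(**kwargs, extra=extra)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    """Round floats recursively so JSON reports are byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_manifest(config: PipelineConfig, out_dir: Path) -> None:
    """Record the effective configuration and package version with a run."""
    from . import __version__
    payload = {k: v for k, v in vars(config).items() if k != "extra"}
    payload["stiffwave_version"] = __version__
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True,
                  default=_json_default)


def run_subject(
    config: PipelineConfig,
) -> tuple[KSeries, MecResult, RocBpResult | None]:
    """Run beat fitting, MEC_K detection and ROC_BP for one subject.

    Reads the waveform/onsets/events/sBP CSVs named in the config, chains
    the stages, writes a JSON subject report plus per-beat and
    per-stimulus CSVs under ``out_dir``, and logs exclusion counts.
    """
    if not (config.waveform_csv and config.onsets_csv and config.events_csv):
        raise ValueError("waveform_csv, onsets_csv and events_csv are required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, out_dir)

    try:
        wdf = read_table(config.waveform_csv, "waveform")
        odf = read_table(config.onsets_csv, "onsets")
        t = wdf["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        record = WaveformRecord(
            time_s=t, abp_mmhg=wdf["abp_mmhg"].to_numpy(),
            ppg_pct=wdf["ppg_pct"].to_numpy(), sample_rate_hz=fs,
            beat_onsets=odf["onset_index"].to_numpy(dtype=int))
        kseries, estimates = beat_mechanics.estimate_k_series(
            record, r2_min=config.r2_min)
    except Exception as exc:
        raise RuntimeError(
            f"beat_mechanics stage failed on {config.waveform_csv}: {exc}"
        ) from exc
    logger.info("beat fitting: %d valid beats, exclusions %s",
                len(kseries), kseries.exclusion_counts)
    pd.DataFrame({
        "beat_time_s": [e.beat_time_s for e in estimates],
        "k": [e.k for e in estimates],
        "b": [e.b for e in estimates],
        "r_squared": [e.r_squared for e in estimates],
        "valid": [e.valid for e in estimates],
        "exclusion_reason": [e.reason or "" for e in estimates],
    }).to_csv(out_dir / "beats.csv", index=False)

    try:
        edf = read_table(config.events_csv, "events")
        events = [StimulusEvent(onset_s=float(r.stim_time_s),
                                intensity_ma=int(r.intensity_ma),
                                duration_s=float(r.duration_s))
                  for r in edf.itertuples(index=False)]
        mec = mec_detection.detect_meck_from_series(
            kseries, events, pre_window_s=config.pre_window_s,
            post_window_s=config.post_window_s, threshold=config.threshold,
            rule=config.rule, anchor=config.anchor)
    except Exception as exc:
        raise RuntimeError(
            f"mec_detection stage failed on {config.events_csv}: {exc}"
        ) from exc
    for i in mec.rejected_as_noise:
        logger.info("stimulus at %d mA rejected as noise", i)
    pd.DataFrame({
        "intensity_ma": [r.intensity_ma for r in mec.responses],
        "pre_k": [r.pre_k for r in mec.responses],
        "post_k": [r.post_k for r in mec.responses],
        "rise": [r.rise for r in mec.responses],
        "responded": [r.responded for r in mec.responses],
    }).to_csv(out_dir / "stimuli.csv", index=False)

    roc: RocBpResult | None = None
    if config.sbp_csv and config.incision_time_s is not None:
        try:
            sdf = read_table(config.sbp_csv, "sbp")
            roc = rocbp_mod.compute_rocbp(
                sdf["beat_time_s"].to_numpy(), sdf["sbp_mmhg"].to_numpy(),
                config.incision_time_s,
                post_window_s=config.rocbp_post_window_s)
        except Exception as exc:
            raise RuntimeError(
                f"rocbp stage failed on {config.sbp_csv}: {exc}") from exc

    report = {
        "meck_ma": mec.meck_ma,
        "rejected_as_noise": mec.rejected_as_noise,
        "responses": [{
            "intensity_ma": r.intensity_ma, "pre_k": r.pre_k,
            "post_k": r.post_k, "rise": r.rise, "responded": r.responded,
        } for r in mec.responses],
        "n_valid_beats": len(kseries),
        "beat_exclusions": kseries.exclusion_counts,
        "rocbp": None if roc is None else {
            "pre_sbp_mmhg": roc.pre_sbp_mmhg,
            "post_sbp_mmhg": roc.post_sbp_mmhg,
            "rocbp_pct": roc.rocbp_pct,
            "ratio": roc.ratio,
        },
    }
    with open(out_dir / "subject.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True,
                  default=_json_default)
    return kseries, mec, roc


def run_cohort(config: PipelineConfig) -> CohortStatsResult:
    """Run the cohort-level statistical validation from a cohort CSV.

    Writes a JSON result plus a tidy residual/difference CSV under
    ``out_dir``.
    """
    if not config.cohort_csv:
        raise ValueError("cohort_csv is required")
    subjects = read_cohort(config.cohort_csv)
    external = None
    if (config.external_slope is not None
            and config.external_intercept is not None):
        external = (config.external_slope, config.external_intercept)
    result = run_cohort_analysis(subjects, external_equation=external,
                                 alpha=config.alpha)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, out_dir)
    in_range = [s for s in subjects if s.in_range and s.rocbp_pct is not None]
    tidy = pd.DataFrame({
        "subject_id": [s.subject_id for s in in_range],
        "meck_ma": [s.meck_ma for s in in_range],
        "rocbp_pct": [s.rocbp_pct for s in in_range],
        "predicted_pct": result.predictions,
    })
    tidy["residual_pct"] = tidy["predicted_pct"] - tidy["rocbp_pct"]
    if external is not None:
        tidy["external_predicted_pct"] = (
            external[0] * tidy["meck_ma"].astype(float) + external[1])
        tidy["ba_difference_pct"] = (
            tidy["external_predicted_pct"] - tidy["rocbp_pct"])
    tidy.to_csv(out_dir / "residuals.csv", index=False)

    payload = {
        "n_analyzed": result.n_analyzed,
        "n_out_of_range": result.n_out_of_range,
        "r": result.r, "p_r": result.p_r,
        "slope": result.slope, "intercept": result.intercept,
        "residual_sd": result.residual_sd,
        "grubbs_outliers": result.grubbs_outliers,
        "p_parallel_slope": result.p_parallel_slope,
        "p_parallel_intercept": result.p_parallel_intercept,
        "group_r": {k: list(v) for k, v in result.group_r.items()},
        "bland_altman": None if result.bland_altman is None else {
            "bias": result.bland_altman.bias,
            "sd": result.bland_altman.sd,
            "loa_low": result.bland_altman.loa_low,
            "loa_high": result.bland_altman.loa_high,
            "precision": result.bland_altman.precision,
        },
    }
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True,
                  default=_json_default)
    return result
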