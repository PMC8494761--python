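"""End-to-end orchestration: records -> features -> cohort statistics.

Per-subject failures (too few beats, degenerate geometry) are logged with
subject id and stage and reported in the feature table's ``status`` column;
they never abort a batch.  Every output is a deterministic function of the
inputs, the configuration and the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import raix, segment, sharpness, stats
from .io import RunConfig, read_cohort_table, read_waveform
from .sharpness import PulseGeometryError
from .synth import RawPulseRecord

__all__ = ["extract_features", "features_table", "run_pipeline"]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "hr",
    "psi",
    "epa_deg",
    "vh",
    "w_s",
    "raix",
    "raix75",
    "tidal_quality",
    "excluded",
    "n_beats",
    "flags",
    "status",
]


def extract_features(record: RawPulseRecord, config: RunConfig | None = None) -> dict:
    """Compute the full feature row of one record.

    Always returns a row; on failure the ``status`` column carries the stage
    and message while the numeric features are NaN.
    """
    config = config or RunConfig()
    config.validate()
    row: dict = {c: np.nan for c in FEATURE_COLUMNS}
    row.update(
        subject_id=record.subject_id,
        age=record.age,
        sex=record.sex,
        status="ok",
        flags="",
        excluded=True,
        tidal_quality="absent",
    )
    try:
        pulse = segment.extract_ensemble(
            record,
            henderson_terms=config.henderson_terms,
            bp_low_hz=config.bp_low_hz,
            bp_high_hz=config.bp_high_hz,
            bp_order=config.bp_order,
            refine_threshold=config.refine_threshold,
            denoise=config.denoise,
        )
    except (ValueError, PulseGeometryError) as exc:
        log.warning("subject %s: segmentation failed: %s", record.subject_id, exc)
        row["status"] = f"segmentation: {exc}"
        return row
    hr = pulse.source_hr if pulse.source_hr is not None else record.heart_rate
    row["hr"] = hr
    row["n_beats"] = pulse.n_beats_averaged
    try:
        sf = sharpness.extract_sharpness(
            pulse,
            r_threshold=config.r_threshold,
            aspect=config.aspect,
            vh_reference=config.vh_reference,
        )
        row.update(psi=sf.psi, epa_deg=sf.epa_deg, vh=sf.vh, w_s=sf.w_s, flags=";".join(sf.flags))
    except PulseGeometryError as exc:
        log.warning("subject %s: sharpness failed at stage %s: %s", record.subject_id, exc.stage, exc)
        row["status"] = f"sharpness[{exc.stage}]: {exc}"
        return row
    ax = raix.extract_aix(pulse, hr=hr, hr_slope=config.hr_slope)
    row["tidal_quality"] = ax.tidal_quality
    row["excluded"] = ax.tidal_quality != "clear"
    if ax.raix is not None:
        row["raix"] = ax.raix
        row["raix75"] = ax.raix75 if ax.raix75 is not None else np.nan
    if row["excluded"]:
        log.info("subject %s: rAIx excluded (tidal wave %s)", record.subject_id, ax.tidal_quality)
    return row


def features_table(records: list[RawPulseRecord], config: RunConfig | None = None) -> pd.DataFrame:
    """Feature rows for a batch of records; failures logged, never raised."""
    config = config or RunConfig()
    rows = [extract_features(rec, config) for rec in records]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def run_pipeline(config: RunConfig) -> dict:
    """File-level pipeline: read waveforms, extract features, run statistics.

    Reads every ``*.txt``/``*.tsv`` waveform in ``config.input_dir``
    (optionally joining metadata from ``config.cohort_table`` on
    ``subject_id``), writes ``features.csv`` and ``report.json`` into
    ``config.output_dir`` and returns the report.
    """
    config.validate()
    if not config.input_dir:
        raise ValueError("config.input_dir is required")
    in_dir = Path(config.input_dir)
    paths = sorted(list(in_dir.glob("*.txt")) + list(in_dir.glob("*.tsv")))
    if not paths:
        raise ValueError(f"no waveform files (*.txt, *.tsv) in {in_dir}")
    meta = None
    if config.cohort_table:
        meta = read_cohort_table(config.cohort_table).set_index("subject_id")
    records = []
    for p in paths:
        try:
            rec = read_waveform(p)
        except (ValueError, OSError) as exc:
            log.warning("skipping unreadable waveform %s: %s", p, exc)
            continue
        if meta is not None and rec.subject_id in meta.index:
            m = meta.loc[rec.subject_id]
            for col, attr in (("age", "age"), ("sex", "sex"), ("hr", "heart_rate")):
                if col in meta.columns and pd.notna(m[col]):
                    setattr(rec, attr, float(m[col]))
        records.append(rec)
    table = features_table(records, config)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "features.csv", index=False)

    report: dict = {
        "n_records": len(records),
        "n_ok": int((table["status"] == "ok").sum()),
        "n_excluded_raix": int(table["excluded"].astype(bool).sum()),
        "config_seed": config.seed,
    }
    analysable = table[(table["status"] == "ok") & table["age"].notna()]
    if len(analysable) >= 3 * (4 + 1):
        try:
            report["stats"] = stats.cohort_report(analysable, k=config.k, seed=config.seed)
        except ValueError as exc:
            log.warning("cohort statistics skipped: %s", exc)
            report["stats_error"] = str(exc)
    else:
        log.info("cohort statistics skipped: too few analysable subjects with ages")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
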