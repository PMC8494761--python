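"""Delimited-text waveform I/O and run configuration.

Waveforms are stored as plain delimited text: `# key=value` header lines
(``fs_hz`` mandatory) followed by one row per sample with one column per
channel.  Plain text keeps records inspectable and versionable; an import
shim for device-specific binary formats can be layered on
:func:`read_waveform` later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .synth import RawPulseRecord, write_waveform

__all__ = ["RunConfig", "read_waveform", "write_waveform", "read_cohort_table"]

log = logging.getLogger(__name__)

_META_KEYS = {"age": float, "sex": int, "heart_rate": float, "sbp": float, "dbp": float}


def read_waveform(path: str | Path) -> RawPulseRecord:
    """Read a delimited-text waveform written by :func:`write_waveform`.

    Header lines are ``# key=value``; ``fs_hz`` is mandatory and must be
    positive.  Data rows may have one column (single channel) or several
    (multichannel, e.g. the six-sensor array layout).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            parts = line.replace(",", "\t").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric sample row: {line!r}") from exc
            if n_cols is None:
                n_cols = len(vals)
            elif len(vals) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, got {len(vals)}")
            rows.append(vals)
    if "fs_hz" not in header:
        raise ValueError(f"{path}: missing mandatory '# fs_hz=' header line")
    fs = float(header["fs_hz"])
    if fs <= 0.0:
        raise ValueError(f"{path}: sampling rate must be positive, got {fs}")
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    samples = np.asarray(rows, dtype=float)
    if samples.shape[1] == 1:
        samples = samples[:, 0]
    meta = {}
    for key, cast in _META_KEYS.items():
        if key in header:
            meta[key] = cast(float(header[key]))
    return RawPulseRecord(
        samples=samples,
        sampling_rate=fs,
        subject_id=header.get("subject_id", path.stem),
        **meta,
    )


def read_cohort_table(path: str | Path):
    """Read a delimited cohort metadata table (CSV) as a DataFrame."""
    import pandas as pd

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one validated place.

    Defaults follow the reference processing chain: correlation threshold
    0.99 for intersecting-tangent line growth, 0.8-s / 800-sample pulse
    template, 1000-Hz nominal sampling, width measured at 2/3 pulse height,
    heart-rate correction to 75 bpm and tenfold cross-validation.  The
    remaining values (band edges, Henderson length, refinement threshold,
    aspect, drift/noise knobs) are this tool's own documented choices.
    """

    # preprocessing
    henderson_terms: int = 13
    bp_low_hz: float = 0.005
    bp_high_hz: float = 30.0
    bp_order: int = 4
    denoise: bool = True
    # segmentation
    refine_threshold: float = 0.95
    # sharpness geometry
    r_threshold: float = 0.99
    aspect: float = 1.0
    vh_reference: str = "peak"
    w_level: float = 2.0 / 3.0
    # augmentation index
    hr_slope: float = 0.48
    # statistics
    k: int = 10
    seed: int = 0
    # paths
    input_dir: str | None = None
    cohort_table: str | None = None
    output_dir: str = "out"

    def validate(self) -> None:
        if self.henderson_terms % 2 == 0 or self.henderson_terms < 5:
            raise ValueError("henderson_terms must be odd and >= 5")
        if not (0.0 < self.bp_low_hz < self.bp_high_hz):
            raise ValueError("need 0 < bp_low_hz < bp_high_hz")
        if self.bp_order < 1:
            raise ValueError("bp_order must be >= 1")
        if not (0.0 < self.refine_threshold <= 1.0):
            raise ValueError("refine_threshold must lie in (0, 1]")
        if not (0.0 < self.r_threshold <= 1.0):
            raise ValueError(f"r_threshold must lie in (0, 1], got {self.r_threshold}")
        if self.aspect <= 0.0:
            raise ValueError("aspect must be positive")
        if self.vh_reference not in ("peak", "foot"):
            raise ValueError("vh_reference must be 'peak' or 'foot'")
        if not (0.0 < self.w_level < 1.0):
            raise ValueError("w_level must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must lie in [0, 2^31)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
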