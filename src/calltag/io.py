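"""Readers and writers: selection tables, call tables, WAV audio, metadata.

Two annotation dialects are understood. Raven-style selection tables are
tab-separated with at least "Begin Time (s)" and "End Time (s)" columns (the
header identifies the dialect); the package's own CSV schema uses the
column names of the unified call table (t_start_s, t_end_s, rl_db, ...).
Extra columns are always preserved. All times are seconds on the group's
shared clock.

WAV audio is read and written as 16-bit PCM or float through
``scipy.io.wavfile``; full-scale digital amplitude maps to 1.0 V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .exceptions import InvalidParameterError, SchemaError
from .scene import WhaleSpec

__all__ = [
    "GroupMetadata",
    "read_selection_table",
    "write_selection_table",
    "read_wav",
    "write_wav",
    "filter_to_analysis_window",
    "write_scene",
]

logger = logging.getLogger("calltag")

RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
_RAVEN_RENAME = {
    RAVEN_BEGIN: "t_start_s",
    RAVEN_END: "t_end_s",
    "Low Freq (Hz)": "low_hz",
    "High Freq (Hz)": "high_hz",
}

FULL_SCALE = 32767  # int16 full scale == 1.0 V


@dataclass
class GroupMetadata:
    """Who was tagged in a group and when the analysis window ran."""

    group_id: str
    date: str
    whales: list[WhaleSpec]
    analysis_window: tuple[float, float]

    def __post_init__(self):
        if not 2 <= len(self.whales) <= 3:
            raise InvalidParameterError("groups contain 2-3 tagged whales")
        w0, w1 = self.analysis_window
        if not w1 > w0:
            raise InvalidParameterError("analysis window must have positive length")
        tags = [w.tag_id for w in self.whales]
        if len(set(tags)) != len(tags):
            raise InvalidParameterError("tag_ids must be unique within a group")

    @classmethod
    def from_yaml(cls, path) -> "GroupMetadata":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        whales = [WhaleSpec(**w) for w in raw["whales"]]
        return cls(
            group_id=str(raw["group_id"]),
            date=str(raw.get("date", "")),
            whales=whales,
            analysis_window=tuple(raw["analysis_window"]),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "group_id": self.group_id,
            "date": self.date,
            "whales": [
                {"whale_id": w.whale_id, "age_class": w.age_class, "sex": w.sex,
                 "role": w.role, "tag_id": w.tag_id}
                for w in self.whales
            ],
            "analysis_window": list(self.analysis_window),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_selection_table(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a Raven selection table (TSV) or schema CSV into a detections frame.

    The Raven dialect is recognized by its "Begin Time (s)" header. The
    returned frame always has t_start_s and t_end_s columns; all other
    columns are preserved as annotations.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if dialect == "auto":
        dialect = "raven" if RAVEN_BEGIN in header and "\t" in header else "csv"
    if dialect == "raven":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in (RAVEN_BEGIN, RAVEN_END) if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing Raven columns {missing}")
        df = df.rename(columns=_RAVEN_RENAME)
    elif dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in ("t_start_s", "t_end_s") if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing columns {missing}")
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    for col in ("t_start_s", "t_end_s"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path.name}: non-numeric {col} at line {int(bad[0]) + 2}"
            )
        df[col] = parsed
    logger.info("read %d selections from %s (%s dialect)", len(df), path.name, dialect)
    return df


def write_selection_table(df: pd.DataFrame, path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "raven":
        out = df.rename(columns={v: k for k, v in _RAVEN_RENAME.items()})
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "csv":
        df.to_csv(path, index=False)
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file; returns (volts, sample_rate_hz)."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        volts = data.astype(float) / FULL_SCALE
    elif data.dtype == np.int32:
        volts = data.astype(float) / 2147483647
    else:
        volts = data.astype(float)
    if volts.ndim > 1:
        volts = volts[:, 0]
    return volts, float(rate)


def write_wav(path, volts: np.ndarray, sample_rate_hz: float) -> None:
    """Write volts as 16-bit PCM (full scale 1.0 V), clipping if needed."""
    clipped = np.clip(volts, -1.0, 1.0)
    n_clip = int(np.sum(clipped != volts))
    if n_clip:
        logger.warning("%s: %d samples clipped at full scale", path, n_clip)
    wavfile.write(path, int(sample_rate_hz), (clipped * FULL_SCALE).astype(np.int16))


def filter_to_analysis_window(
    detections: pd.DataFrame, window: tuple[float, float]
) -> pd.DataFrame:
    """Keep detections whose spans lie within the window (boundaries included)."""
    w0, w1 = window
    keep = (detections["t_start_s"] >= w0) & (detections["t_end_s"] <= w1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "analysis window [%s, %s]: kept %d, dropped %d detections",
            w0, w1, int(keep.sum()), dropped,
        )
    return detections[keep].reset_index(drop=True)


def write_scene(result, out_dir, audio: bool = False) -> dict[str, Path]:
    """Write a simulated scene: per-tag annotation CSVs, ground truth, WAVs."""
    from .scene import render_audio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gt_path = out_dir / "ground_truth.csv"
    result.ground_truth.to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path
    for tag_id, det in result.detections.items():
        p = out_dir / f"{tag_id}.csv"
        det.to_csv(p, index=False)
        paths[f"annotations:{tag_id}"] = p
    meta = GroupMetadata(
        group_id=result.config.group_id,
        date="",
        whales=list(result.config.whales),
        analysis_window=(0.0, float(result.config.duration_s)),
    )
    meta_path = out_dir / "group.yaml"
    meta.to_yaml(meta_path)
    paths["metadata"] = meta_path
    if audio:
        waves = render_audio(result)
        for tag_id, wave in waves.items():
            p = out_dir / f"{tag_id}.wav"
            write_wav(p, wave, result.config.sample_rate_hz)
            paths[f"audio:{tag_id}"] = p
    return paths
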