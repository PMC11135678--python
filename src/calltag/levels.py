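"""90%-energy-window RMS received levels from calibrated tag audio.

A call's received level is measured on the time window containing the
central 90% of its cumulative squared-pressure energy: the window opens at
the first sample where cumulative energy reaches 5% of the total and closes
at the first sample where it reaches 95% (both inclusive), so the window
always holds at least 90% of the energy. The RMS of the in-window samples,
interpreted as volts, is converted to dB re 1 uPa through the hydrophone
sensitivity (nominally -171 dB re 1 V/uPa for Dtag v2 hardware):

    RL = 20 log10(V_rms) - sensitivity_db

Full-scale digital amplitude maps to 1.0 V unless a gain is configured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidWindowError, ZeroEnergyError

__all__ = [
    "CalibratedSegment",
    "LevelResult",
    "energy_window_90",
    "rms_received_level",
    "measure_segment",
    "measure_calls",
]

NOMINAL_SENSITIVITY_DB = -171.0


@dataclass
class CalibratedSegment:
    """A clip of pressure-proportional samples with its calibration."""

    samples: np.ndarray  # volts (full scale = 1.0 V + gain)
    sample_rate_hz: float
    sensitivity_db: float = NOMINAL_SENSITIVITY_DB
    t_start_s: float = 0.0
    gain_db: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidWindowError("segment needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidWindowError("segment contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise InvalidWindowError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class LevelResult:
    rl_db: float
    t5_s: float
    t95_s: float
    window_energy_fraction: float


def energy_window_90(segment: CalibratedSegment) -> tuple[int, int]:
    """Sample indices (inclusive) of the 90% cumulative-energy window.

    The window start is the first index where cumulative squared-sample
    energy reaches 5% of the total, the end the first index where it reaches
    95%; the enclosed energy fraction is therefore always >= 0.90.
    """
    e = np.cumsum(segment.samples**2)
    total = e[-1]
    if total <= 0:
        raise ZeroEnergyError("segment has zero energy")
    i5 = int(np.searchsorted(e, 0.05 * total))
    i95 = int(np.searchsorted(e, 0.95 * total))
    return i5, i95


def rms_received_level(segment: CalibratedSegment, window: tuple[int, int]) -> float:
    """RMS level of the in-window samples in dB re 1 uPa."""
    i5, i95 = window
    if not (0 <= i5 <= i95 < segment.samples.size):
        raise InvalidWindowError(f"window {window} outside segment")
    v = segment.samples[i5 : i95 + 1] * 10.0 ** (-segment.gain_db / 20.0)
    v_rms = np.sqrt(np.mean(v**2))
    if v_rms <= 0:
        raise ZeroEnergyError("window has zero energy")
    return float(20.0 * np.log10(v_rms) - segment.sensitivity_db)


def measure_segment(segment: CalibratedSegment) -> LevelResult:
    """90%-window RMS received level of one clip."""
    i5, i95 = energy_window_90(segment)
    e = np.cumsum(segment.samples**2)
    frac = (e[i95] - (e[i5 - 1] if i5 > 0 else 0.0)) / e[-1]
    fs = segment.sample_rate_hz
    return LevelResult(
        rl_db=rms_received_level(segment, (i5, i95)),
        t5_s=segment.t_start_s + i5 / fs,
        t95_s=segment.t_start_s + (i95 + 1) / fs,
        window_energy_fraction=float(frac),
    )


def measure_calls(
    wave: np.ndarray,
    sample_rate_hz: float,
    detections: pd.DataFrame,
    sensitivity_db: float = NOMINAL_SENSITIVITY_DB,
    gain_db: float = 0.0,
) -> pd.DataFrame:
    """Measure every detection's RL from a tag waveform.

    ``detections`` needs t_start_s / t_end_s columns; returns a copy with
    rl_db, t5_s, t95_s and window_energy_fraction columns filled in.
    Detections whose clip has zero energy get NaN levels.
    """
    out = detections.copy()
    rl, t5, t95, frac = [], [], [], []
    for row in out.itertuples(index=False):
        i0 = max(0, int(round(row.t_start_s * sample_rate_hz)))
        i1 = min(len(wave), int(round(row.t_end_s * sample_rate_hz)))
        if i1 - i0 < 2:
            rl.append(np.nan), t5.append(np.nan), t95.append(np.nan), frac.append(np.nan)
            continue
        seg = CalibratedSegment(
            wave[i0:i1], sample_rate_hz, sensitivity_db, i0 / sample_rate_hz, gain_db
        )
        try:
            res = measure_segment(seg)
        except ZeroEnergyError:
            rl.append(np.nan), t5.append(np.nan), t95.append(np.nan), frac.append(np.nan)
            continue
        rl.append(res.rl_db), t5.append(res.t5_s), t95.append(res.t95_s)
        frac.append(res.window_energy_fraction)
    out["rl_db"] = rl
    out["t5_s"] = t5
    out["t95_s"] = t95
    out["window_energy_fraction"] = frac
    return out
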