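"""Synthetic multi-tag acoustic scenes with known ground truth.

Emulates a group of 2-3 suction-cup-tagged whales recorded simultaneously:
each whale produces calls whose inter-call intervals follow a two-process
(fast/slow) exponential mixture, call subtypes are drawn from age-class
repertoire proportions, and every call is received on every tag at a level
set by spherical spreading loss from a drawn source level, plus optional
Gaussian level jitter. Because a whale's own tag sits far closer than any
other whale (``tag_offset_m`` << inter-whale distance), the caller's own tag
always records the highest true level — the geometric assumption behind
relative-level caller assignment, which these scenes exist to validate.

Optionally renders per-tag audio: tonal calls as frequency-modulated sweeps
with harmonics, pulsed calls as pulse trains, each scaled so its analytic
RMS voltage matches the target received level under the configured
hydrophone sensitivity, embedded in Gaussian ambient noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from . import repertoire as rep
from .reference import default_repertoire
from .exceptions import (
    InvalidConfigError,
    InvalidGeometryError,
    InvalidParameterError,
)

__all__ = [
    "WhaleSpec",
    "BoutProcess",
    "SceneConfig",
    "SceneResult",
    "simulate_call_schedule",
    "render_received_levels",
    "render_audio",
    "simulate_scene",
]

REFERENCE_DISTANCE_M = 1.0


@dataclass(frozen=True)
class WhaleSpec:
    whale_id: str
    age_class: str = "adult"  # calf | adult
    sex: str = "unknown"
    role: str = "adult"  # mother | calf | escort/adult
    tag_id: str | None = None

    def __post_init__(self):
        if self.age_class not in ("calf", "adult"):
            raise InvalidParameterError(f"age_class must be calf/adult, got {self.age_class!r}")
        if self.tag_id is None:
            object.__setattr__(self, "tag_id", f"tag_{self.whale_id}")


@dataclass(frozen=True)
class BoutProcess:
    """Two-process exponential mixture governing inter-call intervals.

    A gap is fast (within-bout) with probability ``p_fast`` and drawn from
    Exp(``lambda_fast``); otherwise slow (between-bout), Exp(``lambda_slow``).
    """

    p_fast: float = 0.7
    lambda_fast: float = 2.0  # s^-1
    lambda_slow: float = 0.05  # s^-1

    def __post_init__(self):
        vals = (self.p_fast, self.lambda_fast, self.lambda_slow)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("bout-process parameters must be finite")
        if not 0 < self.p_fast < 1:
            raise InvalidParameterError("p_fast must lie in (0, 1)")
        if not self.lambda_fast > self.lambda_slow > 0:
            raise InvalidParameterError("need lambda_fast > lambda_slow > 0")

    @property
    def mean_interval_s(self) -> float:
        return self.p_fast / self.lambda_fast + (1 - self.p_fast) / self.lambda_slow


@dataclass
class SceneConfig:
    """Full parameterization of one simulated tagged group."""

    whales: list[WhaleSpec]
    duration_s: float
    pairwise_distance_m: np.ndarray
    group_id: str = "sim"
    tag_offset_m: float = 2.0
    bout_process: BoutProcess | dict = field(default_factory=BoutProcess)
    call_duration_s: tuple[float, float] = (0.2, 1.5)
    source_level_db: tuple[float, float] = (155.0, 6.0)  # dB re 1 uPa @ 1 m
    noise_rl_sd_db: float = 0.0
    repertoire: dict | None = None  # age_class -> {label: proportion}
    detection_floor_db: float | None = None
    sample_rate_hz: float = 16000.0
    sensitivity_db: float = -171.0  # dB re 1 V/uPa
    ambient_rl_db: float = 95.0
    seed: int = 0

    def __post_init__(self):
        if not 2 <= len(self.whales) <= 3:
            raise InvalidParameterError("scenes model groups of 2-3 tagged whales")
        if not (np.isfinite(self.duration_s) and self.duration_s > 0):
            raise InvalidParameterError("duration_s must be positive and finite")
        d = np.asarray(self.pairwise_distance_m, dtype=float)
        n = len(self.whales)
        if d.shape != (n, n):
            raise InvalidGeometryError(f"distance matrix must be {n}x{n}")
        if not np.allclose(d, d.T):
            raise InvalidGeometryError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise InvalidGeometryError("distance matrix diagonal must be zero")
        off = d[~np.eye(n, dtype=bool)]
        if np.any(off <= 0) or not np.all(np.isfinite(off)):
            raise InvalidGeometryError("off-diagonal distances must be positive and finite")
        if not 0 < self.tag_offset_m < off.min():
            raise InvalidGeometryError("tag_offset_m must be positive and below the closest inter-whale distance")
        self.pairwise_distance_m = d
        lo, hi = self.call_duration_s
        if not 0 < lo <= hi:
            raise InvalidParameterError("call_duration_s must satisfy 0 < min <= max")
        if self.repertoire is None:
            self.repertoire = {
                "adult": default_repertoire("adult"),
                "calf": default_repertoire("calf"),
            }
        for cls, props in self.repertoire.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"repertoire proportions for {cls!r} sum to {total}, not 1"
                )

    def process_for(self, whale_id: str) -> BoutProcess:
        if isinstance(self.bout_process, dict):
            return self.bout_process[whale_id]
        return self.bout_process


@dataclass
class SceneResult:
    """Ground truth plus the per-tag annotation tables a real analysis sees."""

    config: SceneConfig
    ground_truth: pd.DataFrame  # one row per true call, with per-tag true RLs
    detections: dict[str, pd.DataFrame]  # tag_id -> per-tag detection table
    schedule_intervals: dict[str, np.ndarray]  # whale_id -> raw mixture draws

    @property
    def call_table(self) -> pd.DataFrame:
        """Ground-truth calls as a unified caller-attributed call table."""
        whales = {w.whale_id: w for w in self.config.whales}
        gt = self.ground_truth
        return pd.DataFrame(
            {
                "call_id": gt["call_id"],
                "group_id": self.config.group_id,
                "caller_id": gt["caller_id"],
                "age_class": [whales[c].age_class for c in gt["caller_id"]],
                "t_start_s": gt["onset_s"],
                "t_end_s": gt["offset_s"],
                "rl_db": [
                    gt.loc[i, f"rl_true_{whales[gt.loc[i, 'caller_id']].tag_id}"]
                    for i in gt.index
                ],
                "focal_label": "focal",
                "subtype_label": gt["label"],
            }
        )


def simulate_call_schedule(
    p_fast: float,
    lambda_fast: float,
    lambda_slow: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw call onsets whose gaps are i.i.d. two-process mixture samples.

    Returns ``(onsets_s, intervals_s)``; the first onset is itself a mixture
    draw from time zero, and the schedule is truncated at ``duration_s``.
    """
    proc = BoutProcess(p_fast, lambda_fast, lambda_slow)  # validates
    if not (np.isfinite(duration_s) and duration_s > 0):
        raise InvalidParameterError("duration_s must be positive and finite")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # draw in blocks sized from the mean rate to avoid a python-level loop
    onsets: list[float] = []
    t = 0.0
    block = max(16, int(2 * duration_s / proc.mean_interval_s) + 16)
    while t <= duration_s:
        fast = rng.random(block) < proc.p_fast
        rates = np.where(fast, proc.lambda_fast, proc.lambda_slow)
        gaps = rng.exponential(1.0, size=block) / rates
        for g in gaps:
            t += g
            if t > duration_s:
                break
            onsets.append(t)
    onset_arr = np.asarray(onsets)
    return onset_arr, np.diff(onset_arr)


def render_received_levels(
    calls: pd.DataFrame,
    whales: list[WhaleSpec],
    pairwise_distance_m: np.ndarray,
    tag_offset_m: float,
    noise_rl_sd_db: float = 0.0,
    seed: int | np.random.Generator = 0,
    detection_floor_db: float | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Propagate every call to every tag under spherical spreading.

    ``calls`` needs columns caller_id, onset_s, offset_s, source_level_db
    (and optionally label/low_hz/high_hz, carried through). Received level on
    a tag at range r is ``SL - 20 log10(max(r, 1 m))`` plus N(0, sd) jitter;
    the caller's own tag sits at ``tag_offset_m``. Returns the ground-truth
    table augmented with per-tag true levels, and per-tag detection tables
    (optionally thresholded at ``detection_floor_db``).
    """
    d = np.asarray(pairwise_distance_m, dtype=float)
    n = len(whales)
    if d.shape != (n, n) or np.any(d[~np.eye(n, dtype=bool)] <= 0):
        raise InvalidGeometryError("invalid distance matrix")
    if tag_offset_m <= 0:
        raise InvalidGeometryError("tag_offset_m must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = {w.whale_id: i for i, w in enumerate(whales)}
    gt = calls.reset_index(drop=True).copy()
    if "call_id" not in gt.columns:
        gt.insert(0, "call_id", [f"call_{k:05d}" for k in range(len(gt))])
    detections: dict[str, pd.DataFrame] = {}
    caller_idx = gt["caller_id"].map(idx).to_numpy()
    sl = gt["source_level_db"].to_numpy(dtype=float)
    for j, w in enumerate(whales):
        r = d[caller_idx, j].copy()
        r[caller_idx == j] = tag_offset_m
        rl_true = sl - 20.0 * np.log10(np.maximum(r, REFERENCE_DISTANCE_M))
        gt[f"rl_true_{w.tag_id}"] = rl_true
        rl_obs = rl_true + rng.normal(0.0, noise_rl_sd_db, size=len(gt)) if noise_rl_sd_db > 0 else rl_true.copy()
        det = pd.DataFrame(
            {
                "tag_id": w.tag_id,
                "whale_id": w.whale_id,
                "call_id": gt["call_id"],
                "t_start_s": gt["onset_s"].to_numpy(),
                "t_end_s": gt["offset_s"].to_numpy(),
                "rl_db": rl_obs,
            }
        )
        for extra in ("label", "low_hz", "high_hz"):
            if extra in gt.columns:
                det[extra] = gt[extra].to_numpy()
        if detection_floor_db is not None:
            det = det[det["rl_db"] >= detection_floor_db].reset_index(drop=True)
        detections[w.tag_id] = det
    return gt, detections


def simulate_scene(config: SceneConfig) -> SceneResult:
    """Generate ground truth and per-tag annotation tables for one scene."""
    rng = np.random.default_rng(config.seed)
    rows = []
    intervals: dict[str, np.ndarray] = {}
    lo, hi = config.call_duration_s
    for w in config.whales:
        proc = config.process_for(w.whale_id)
        onsets, gaps = simulate_call_schedule(
            proc.p_fast, proc.lambda_fast, proc.lambda_slow, config.duration_s, rng
        )
        intervals[w.whale_id] = gaps
        props = config.repertoire[w.age_class]
        labels = list(props)
        p = np.asarray([props[k] for k in labels], dtype=float)
        drawn = rng.choice(len(labels), size=len(onsets), p=p / p.sum())
        durations = rng.uniform(lo, hi, size=len(onsets))
        # keep a caller's calls non-overlapping with its own next call
        if len(onsets) > 1:
            durations[:-1] = np.minimum(durations[:-1], 0.9 * np.diff(onsets))
        sls = rng.normal(*config.source_level_db, size=len(onsets))
        for k, t0 in enumerate(onsets):
            lab = labels[drawn[k]]
            feats = rep.features_for_label(lab, rng)
            dur_k = max(durations[k], 0.05)
            if rep.label_to_broad(lab) == "pulse":
                # a single pulse is a short transient with a tight annotation
                dur_k = min(dur_k, float(rng.uniform(0.02, 0.04)))
            rows.append(
                {
                    "caller_id": w.whale_id,
                    "onset_s": float(t0),
                    "offset_s": float(t0 + dur_k),
                    "label": lab,
                    "source_level_db": float(sls[k]),
                    "first_harmonic_hz": feats.first_harmonic_hz,
                    "structure": feats.structure,
                    "n_segments": feats.n_segments,
                    "in_paired_sequence": feats.in_paired_sequence,
                    "analyst_subtype_hint": feats.analyst_subtype_hint,
                    "segment_structures": "+".join(feats.segment_structures),
                }
            )
    if rows:
        calls = pd.DataFrame(rows).sort_values("onset_s", kind="stable").reset_index(drop=True)
    else:
        calls = pd.DataFrame(
            columns=["caller_id", "onset_s", "offset_s", "label", "source_level_db"]
        )
    gt, detections = render_received_levels(
        calls,
        config.whales,
        config.pairwise_distance_m,
        config.tag_offset_m,
        config.noise_rl_sd_db,
        rng,
        config.detection_floor_db,
    )
    feature_cols = [
        "first_harmonic_hz",
        "structure",
        "n_segments",
        "in_paired_sequence",
        "analyst_subtype_hint",
        "segment_structures",
    ]
    for tag_id, det in detections.items():
        if len(det) and len(gt):
            merged = det.merge(gt[["call_id"] + feature_cols], on="call_id", how="left")
            detections[tag_id] = merged
    return SceneResult(config, gt, detections, intervals)


# ---------------------------------------------------------------------------
# audio rendering

#: highest frequency any synthetic call type can contain, by broad type
_MAX_FREQ_HZ = {
    "HF tonal": 3400.0,
    "LF tonal": 2700.0,  # 3rd harmonic of a 900 Hz fundamental
    "LF pulsed": 1200.0,
    "pulse": 1200.0,
    "paired burst": 1200.0,
    "complex": 2700.0,
    "other": 1600.0,
}


def _volts_from_rl(rl_db: float, sensitivity_db: float) -> float:
    """RMS voltage equivalent to an RL in dB re 1 uPa at given sensitivity."""
    return 10.0 ** ((rl_db + sensitivity_db) / 20.0)


def _unit_window_rms(x: np.ndarray) -> np.ndarray:
    """Scale so the RMS over the 90% cumulative-energy window is 1.

    Levels are measured downstream on the 90%-energy window, so calls are
    calibrated in the same window to make the round trip exact.
    """
    e = np.cumsum(x**2)
    if e[-1] <= 0:
        return x
    i5 = int(np.searchsorted(e, 0.05 * e[-1]))
    i95 = int(np.searchsorted(e, 0.95 * e[-1]))
    r = np.sqrt(np.mean(x[i5 : i95 + 1] ** 2))
    return x / r if r > 0 else x


def _synth_call(label: str, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS synthetic waveform for one call of ``n`` samples."""
    broad = rep.label_to_broad(label)
    t = np.arange(n) / fs
    env = tukey(n, alpha=0.25)
    if broad in ("HF tonal", "LF tonal", "complex", "other"):
        if broad == "HF tonal":
            f0, f1, harm = 2500.0, 3200.0, (1.0,)
        else:
            f0, f1, harm = 300.0, 550.0, (1.0, 0.5, 0.25)
        f0 *= rng.uniform(0.95, 1.05)
        phase = 2 * np.pi * np.cumsum(np.linspace(f0, f1, n)) / fs
        x = sum(a * np.sin((i + 1) * phase) for i, a in enumerate(harm))
        if broad == "complex":  # pulsed onset, tonal tail
            half = n // 2
            x[:half] *= _pulse_gate(half, fs, rate_hz=45.0)
    else:  # pulsed families: gated tone bursts
        carrier = np.sin(2 * np.pi * 800.0 * rng.uniform(0.9, 1.1) * t)
        if broad == "pulse":
            gate = np.zeros(n)
            w = max(4, int(0.006 * fs))
            gate[: min(w, n)] = 1.0
        elif broad == "paired burst":
            gate = _pulse_gate(n, fs, rate_hz=45.0)
            gate[n // 3 : n // 2] = 0.0  # gap between the paired bursts
        else:
            gate = _pulse_gate(n, fs, rate_hz=45.0)
        x = carrier * gate
    x = x * env
    return _unit_window_rms(x)


def _pulse_gate(n: int, fs: float, rate_hz: float) -> np.ndarray:
    """On/off gate producing a pulse train at ``rate_hz``."""
    period = max(2, int(fs / rate_hz))
    width = max(2, period // 3)
    gate = np.zeros(n)
    for start in range(0, n, period):
        gate[start : min(start + width, n)] = 1.0
    return gate


def render_audio(result: SceneResult) -> dict[str, np.ndarray]:
    """Render per-tag waveforms (float volts, full scale 1.0 V).

    Each call is synthesized per its broad type and scaled so that its RMS
    voltage over the call equals the tag's true received level converted
    through the hydrophone sensitivity; Gaussian ambient noise at
    ``ambient_rl_db`` fills the record.
    """
    cfg = result.config
    fs = cfg.sample_rate_hz
    labels = set(result.ground_truth.get("label", pd.Series(dtype=object)).dropna())
    for lab in labels:
        fmax = _MAX_FREQ_HZ[rep.label_to_broad(lab)]
        if fs < 4.0 * fmax:
            raise InvalidConfigError(
                f"sample rate {fs} Hz is below 4x the {lab!r} max frequency {fmax} Hz"
            )
    n_total = int(round(cfg.duration_s * fs)) + 1
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xA0D10]))
    noise_v = _volts_from_rl(cfg.ambient_rl_db, cfg.sensitivity_db)
    out: dict[str, np.ndarray] = {}
    for w in cfg.whales:
        wave = rng.normal(0.0, noise_v, size=n_total)
        for row in result.ground_truth.itertuples(index=False):
            i0 = int(round(row.onset_s * fs))
            i1 = min(int(round(row.offset_s * fs)), n_total)
            if i1 - i0 < 8:
                continue
            target_v = _volts_from_rl(getattr(row, f"rl_true_{w.tag_id}"), cfg.sensitivity_db)
            wave[i0:i1] += target_v * _synth_call(row.label, i1 - i0, fs, rng)
        out[w.tag_id] = wave
    return out
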