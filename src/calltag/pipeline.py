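"""End-to-end pipeline: scene or files in, full behavioral report out.

Stages: (1) obtain per-tag detections — either by simulating a synthetic
scene or by reading per-tag selection tables plus group metadata from disk;
(2) optionally re-measure received levels from tag audio; (3) match calls
across tags and assign focal labels; (4) classify call types; (5) estimate
the bout-end criterion on pooled focal ICIs and summarize bouts; (6) count
call overlaps; (7) compute repertoire proportions; (8) fit the received-
level mixed model (full vs null, ML and REML). Deterministic given the
config and seed; each stage logs its input/output row counts, and a failed
stage aborts with the stage name while earlier outputs persist.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import FocalAssigner
from .bouts import (
    bout_statistics,
    compute_icis,
    fit_broken_stick,
    fit_mixture_mle,
    segment_bouts,
)
from .exceptions import CalltagError, InvalidConfigError
from .io import (
    GroupMetadata,
    filter_to_analysis_window,
    read_selection_table,
    read_wav,
    write_scene,
)
from .levels import measure_calls
from .overlaps import count_overlaps
from .repertoire import classify_calls, proportional_use
from .rlmodel import RandomInterceptModel, compare_aic
from .scene import BoutProcess, SceneConfig, WhaleSpec, simulate_scene

__all__ = ["run_pipeline", "scene_config_from_dict"]

logger = logging.getLogger("calltag")


def scene_config_from_dict(spec: dict, seed: int | None = None) -> SceneConfig:
    """Build a SceneConfig from a plain config mapping.

    ``whales`` is a list of whale mappings; distances come from an explicit
    ``pairwise_distance_m`` matrix or a single ``spacing_m`` (equidistant
    whales). ``seed`` overrides the config's seed when given.
    """
    spec = dict(spec)
    whales = [WhaleSpec(**w) for w in spec.pop("whales")]
    n = len(whales)
    if "pairwise_distance_m" in spec:
        d = np.asarray(spec.pop("pairwise_distance_m"), dtype=float)
        spec.pop("spacing_m", None)
    else:
        spacing = float(spec.pop("spacing_m", 50.0))
        d = spacing * (1.0 - np.eye(n))
    if "bout_process" in spec and isinstance(spec["bout_process"], dict) and (
        "p_fast" in spec["bout_process"]
    ):
        spec["bout_process"] = BoutProcess(**spec["bout_process"])
    if seed is not None:
        spec["seed"] = int(seed)
    for key in ("call_duration_s", "source_level_db"):
        if key in spec:
            spec[key] = tuple(spec[key])
    return SceneConfig(whales=whales, pairwise_distance_m=d, **spec)


def _load_group(group_dir: Path) -> tuple[dict[str, pd.DataFrame], GroupMetadata]:
    meta = GroupMetadata.from_yaml(group_dir / "group.yaml")
    per_tag = {}
    for w in meta.whales:
        for suffix in (".csv", ".txt"):
            p = group_dir / f"{w.tag_id}{suffix}"
            if p.exists():
                df = read_selection_table(p)
                df["tag_id"] = w.tag_id
                df["whale_id"] = w.whale_id
                per_tag[w.tag_id] = df
                break
        else:
            raise InvalidConfigError(f"no selection table for tag {w.tag_id!r} in {group_dir}")
    return per_tag, meta


def run_pipeline(config: dict | str | Path, out_dir=None, seed: int | None = None) -> dict:
    """Run every stage; returns a report dict and optionally writes it out."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"params": {}, "log": []}
    stage = "setup"

    def note(msg, *args):
        line = msg % args if args else msg
        logger.info("%s: %s", stage, line)
        report["log"].append(f"{stage}: {line}")

    try:
        # -- stage 1: inputs ------------------------------------------------
        stage = "input"
        if "simulate" in config:
            scfg = scene_config_from_dict(config["simulate"], seed=seed)
            result = simulate_scene(scfg)
            per_tag = result.detections
            meta = GroupMetadata(
                group_id=scfg.group_id, date="", whales=list(scfg.whales),
                analysis_window=(0.0, float(scfg.duration_s)),
            )
            report["ground_truth"] = result.ground_truth
            report["params"]["seed"] = scfg.seed
            note("simulated scene with %d whales, %d true calls",
                 len(scfg.whales), len(result.ground_truth))
            if out is not None and config.get("write_scene", False):
                write_scene(result, out / "scene", audio=config.get("audio", False))
        elif "group_dir" in config:
            group_dir = Path(config["group_dir"])
            if not group_dir.is_dir():
                raise InvalidConfigError(f"group_dir {group_dir} does not exist")
            per_tag, meta = _load_group(group_dir)
            report["params"]["seed"] = seed
            note("loaded %d tags from %s", len(per_tag), group_dir)
        else:
            raise InvalidConfigError(
                "config must name either a 'simulate' block or a 'group_dir'"
            )

        # -- stage 2: level measurement from audio --------------------------
        stage = "measure"
        audio_dir = config.get("audio_dir")
        if audio_dir:
            for tag_id in list(per_tag):
                wav_path = Path(audio_dir) / f"{tag_id}.wav"
                if wav_path.exists():
                    wave, fs = read_wav(wav_path)
                    per_tag[tag_id] = measure_calls(
                        wave, fs, per_tag[tag_id],
                        sensitivity_db=float(config.get("sensitivity_db", -171.0)),
                    )
                    note("measured %d calls on %s", len(per_tag[tag_id]), tag_id)

        # -- stage 3: caller assignment -------------------------------------
        stage = "assign"
        acfg = config.get("assign", {})
        assigner = FocalAssigner(
            tolerance_s=float(acfg.get("tolerance_s", 0.1)),
            delta_db=float(acfg.get("delta_db", 1.0)),
            strategy=acfg.get("strategy", "top_two"),
        )
        calls = assigner.transform(per_tag)
        calls["group_id"] = meta.group_id
        ages = {w.whale_id: w.age_class for w in meta.whales}
        calls["age_class"] = calls["caller_id"].map(ages)
        calls = filter_to_analysis_window(calls, meta.analysis_window)
        report["params"].update(assigner.get_params())
        note("%d detections -> %d matched calls", sum(map(len, per_tag.values())),
             calls["call_id"].nunique())
        # carry per-call features from the source tables onto focal rows
        feature_cols = [
            "first_harmonic_hz", "structure", "n_segments",
            "in_paired_sequence", "analyst_subtype_hint", "segment_structures",
        ]
        have = [c for c in feature_cols if any(c in df.columns for df in per_tag.values())]
        if have:
            frames = []
            for tag_id, df in per_tag.items():
                cols = [c for c in have if c in df.columns]
                f = df[cols].copy()
                f["tag_id"] = tag_id
                f["source_row"] = np.arange(len(df))
                frames.append(f)
            calls = calls.merge(pd.concat(frames), on=["tag_id", "source_row"], how="left")
        focal = calls[calls["focal_label"] == "focal"].sort_values("t_start_s")
        report["calls"] = calls
        note("%d focal, %d nonfocal, %d indeterminate rows",
             int((calls["focal_label"] == "focal").sum()),
             int((calls["focal_label"] == "nonfocal").sum()),
             int((calls["focal_label"] == "indeterminate").sum()))

        # -- stage 4: call classification -----------------------------------
        stage = "classify"
        if {"structure", "first_harmonic_hz"}.issubset(focal.columns):
            focal = classify_calls(focal)
            note("classified %d focal calls", len(focal))
        report["focal_calls"] = focal

        # -- stage 5: bouts --------------------------------------------------
        stage = "bouts"
        bcfg = config.get("bouts", {})
        pooled = np.concatenate(
            [
                compute_icis(g.sort_values("t_start_s")).intervals_s
                for _, g in focal.groupby("caller_id")
                if len(g) >= 2
            ]
            or [np.array([])]
        )
        min_iv = int(bcfg.get("min_intervals", 10))
        if pooled.size >= min_iv:
            method = bcfg.get("method", "mle")
            if method in ("mle", "mixture_mle"):
                fit = fit_mixture_mle(pooled, min_intervals=min_iv)
            elif method in ("broken_stick", "broken_stick_hist"):
                fit = fit_broken_stick(pooled, n_bins=int(bcfg.get("n_bins", 20)),
                                       min_intervals=min_iv)
            else:
                raise InvalidConfigError(f"unknown bout method {method!r}")
            report["bout_fit"] = fit
            note("BEC = %.3f s from %d pooled intervals (%s)",
                 fit.bec_s, fit.n_intervals, fit.method)
            bout_rows = []
            for caller, g in focal.groupby("caller_id"):
                bouts, _ = segment_bouts(g.sort_values("t_start_s").reset_index(drop=True),
                                         fit.bec_s, str(caller))
                for k, b in enumerate(bouts):
                    bout_rows.append(
                        {"caller_id": caller, "bout_id": f"{caller}_b{k:03d}",
                         "t_start_s": b.t_start_s, "t_end_s": b.t_end_s,
                         "duration_s": b.duration_s, "n_calls": b.n_calls}
                    )
            report["bouts"] = pd.DataFrame(bout_rows)
            report["bout_summary"] = bout_statistics(focal, fit.bec_s, by="age_class")
            report["bout_summary_individual"] = bout_statistics(
                focal, fit.bec_s, by="caller_id"
            )
            note("%d bouts across %d callers", len(bout_rows),
                 focal["caller_id"].nunique())
        else:
            note("only %d pooled intervals (< %d); bout stage skipped",
                 pooled.size, min_iv)

        # -- stage 6: overlaps -----------------------------------------------
        stage = "overlaps"
        instances, overlap_summary = count_overlaps(
            focal, mode=config.get("overlaps", {}).get("mode", "pairs")
        )
        report["overlaps"] = pd.DataFrame([vars(x) for x in instances])
        report["overlap_summary"] = overlap_summary
        note("%d overlap instances", len(instances))

        # -- stage 7: repertoire ---------------------------------------------
        stage = "repertoire"
        if "broad_type" in focal.columns and len(focal):
            by = config.get("repertoire", {}).get("by", "age_class")
            sub_tab, broad_tab = proportional_use(focal, by=by)
            report["subtype_proportions"] = sub_tab
            report["broad_proportions"] = broad_tab
            note("proportions over %d subtypes x %d groups", *sub_tab.shape)

        # -- stage 8: received-level model ------------------------------------
        stage = "rlstats"
        usable = focal.dropna(subset=["rl_db"])
        if usable["caller_id"].nunique() >= 2 and usable["age_class"].nunique() >= 2:
            comparison = {}
            for method in ("ML", "REML"):
                full = RandomInterceptModel("age_class", method).fit(usable)
                null = RandomInterceptModel("intercept_only", method).fit(usable)
                comparison[method] = {
                    "beta": dict(zip(full.beta_names_, full.beta_.tolist())),
                    "sigma_b2": full.sigma_b2_,
                    "sigma_e2": full.sigma_e2_,
                    "aic_full": full.aic_,
                    "aic_null": null.aic_,
                    "delta_aic": compare_aic(full, null),
                }
            report["rl_model"] = comparison
            note("delta AIC (full - null): ML %.2f, REML %.2f",
                 comparison["ML"]["delta_aic"], comparison["REML"]["delta_aic"])
        else:
            note("need >= 2 individuals and both age classes; model skipped")
    except CalltagError as err:
        report["error"] = {"stage": stage, "message": str(err)}
        if out is not None:
            _write_report(report, out)
        raise
    if out is not None:
        _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    for key in ("calls", "focal_calls", "bouts", "bout_summary",
                "bout_summary_individual", "overlaps", "overlap_summary"):
        if key in report and isinstance(report[key], pd.DataFrame):
            report[key].to_csv(out / f"{key}.csv", index=False)
    for key in ("subtype_proportions", "broad_proportions"):
        if key in report:
            report[key].to_csv(out / f"{key}.csv")
    summary = {
        "version": __version__,
        "params": report.get("params", {}),
        "log": report.get("log", []),
    }
    if "bout_fit" in report:
        summary["bout_fit"] = {
            k: v for k, v in vars(report["bout_fit"]).items() if v is not None
        }
    if "rl_model" in report:
        summary["rl_model"] = report["rl_model"]
    if "error" in report:
        summary["error"] = report["error"]
    with open(out / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
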