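"""End-to-end orchestration: synthesis -> analysis -> metrics -> models.

A :class:`RunConfig` (YAML-serializable, unknown keys rejected) drives one
reproducible run: simulate a developmental trajectory for a chosen task
and strategy, optionally render audio and re-measure it with the acoustic
pipeline, compute the trajectory metrics, and compare the realized
syllable-target assignment against the optimal-assignment and EM-mixture
accounts.  Every report bundle embeds the exact config and seed used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import analyze_waveform
from .assignment_models import (problem_from_task, qap_total, sequence_cost,
                                solve_lap)
from .em_matching import assign_by_responsibility, em_fit
from .learning_simulator import SimParams, simulate
from .song_tasks import apply_shift, task_library
from .syllable_typing import label_renditions, templates_from_dataset
from .synthetic_data import SynthConfig, render_day_audio, synth_noise_syllable, synth_syllable
from .trajectory_metrics import (daily_pitch_medians, endpoint_summary,
                                 fraction_pitch_corrected, syntax_fractions,
                                 syntax_shift_scale, syntax_spec_for_task,
                                 vacancy_histogram)

__all__ = ["RunConfig", "run_pipeline", "measure_dataset"]

log = logging.getLogger("songchairs")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimParams)}
_SYNTH_KEYS = {f.name for f in dataclasses.fields(SynthConfig)}


@dataclass
class RunConfig:
    task: str = "1"
    strategy: str = "greedy"
    seed: int = 0
    outdir: str = "songchairs_run"
    audio: bool = False
    run_metrics: bool = True
    run_assign: bool = True
    run_em: bool = True
    sim: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in task_library():
            raise ValueError(f"unknown task {self.task!r}")
        bad = set(self.sim) - _SIM_KEYS
        if bad:
            raise ValueError(f"unknown sim keys: {sorted(bad)}")
        bad = set(self.synth) - _SYNTH_KEYS
        if bad:
            raise ValueError(f"unknown synth keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def measure_dataset(task, truth, annotations: pd.DataFrame,
                    synth_cfg: SynthConfig) -> pd.DataFrame:
    """The measured path: render audio from annotations, then re-segment,
    re-track pitch, and KNN-label with truth-seeded templates.

    Returns an annotation-like table whose ``median_pitch_hz`` and
    ``label`` columns come entirely from the acoustic pipeline, suitable
    for round-trip validation against the programmed ground truth.
    """
    sr = synth_cfg.sample_rate
    waves = {int(d): render_day_audio(annotations[annotations["day"] == d],
                                      task, synth_cfg)
             for d in sorted(annotations["day"].unique())}
    # truth-seeded templates: each label at low/mid/high programmed pitch,
    # padded to >= 3 segments per label so no type is under-represented
    # in the k-nearest vote
    rng = np.random.default_rng(synth_cfg.seed + 7)
    ref = task.source.reference_freq

    def _pitch_grid(arr: np.ndarray) -> list[float]:
        ps = sorted({round(float(p), 1) for p in np.quantile(arr, [0.0, 0.5, 1.0])})
        while len(ps) < 3:
            ps = sorted(set(ps) | {ps[0] - 0.25, ps[-1] + 0.25})
        return ps

    examples: dict[str, list[np.ndarray]] = {}
    for lab, arr in truth.pitch.items():
        examples[lab] = [
            synth_syllable(apply_shift(ref, p), 100.0, synth_cfg)
            for p in _pitch_grid(arr)]
    for cid, arr in truth.call_pitch.items():
        if cid in examples:
            continue
        examples[cid] = [
            synth_syllable(apply_shift(ref, p), 80.0, synth_cfg,
                           rng=rng, call_onset=True)
            for p in _pitch_grid(arr)]
    for s in task.source.motif:
        if not s.is_harmonic:
            examples[s.label] = [
                synth_noise_syllable(s.label, s.duration, synth_cfg, rng)
                for _ in range(3)]
    templates = templates_from_dataset(examples, sr)

    frames = []
    offset = 0
    for d, wave in waves.items():
        df = analyze_waveform(wave, sr, day=d, bout_id_offset=offset)
        if not df.empty:
            offset = int(df["bout_id"].max()) + 1
        frames.append(df)
    measured = pd.concat(frames, ignore_index=True)
    measured = label_renditions(measured, lambda d: waves[d], sr, templates)
    # calls sit outside bouts: re-derive call context from bout size
    singleton = measured.groupby("bout_id")["bout_id"].transform("size") == 1
    measured["is_call"] = singleton & measured["label"].astype(str).str.startswith("call")
    return measured


@_stage("analyze")
def _measure_audio(traj, cfg: RunConfig, synth_cfg: SynthConfig) -> pd.DataFrame:
    return measure_dataset(traj.task, traj.truth, traj.renditions, synth_cfg)


@_stage("metrics")
def _compute_metrics(traj, annotations: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    task = traj.task
    ref = task.source.reference_freq
    tgt_harm = set(task.target.harmonic_labels())
    tidy = []
    summary: dict = {}
    for lab in task.shifted_source_labels():
        chosen = traj.mapping.get(lab)
        if chosen not in tgt_harm:
            continue
        src_p = task.source.pitch_of(lab)
        tgt_p = task.target.pitch_of(chosen)
        med = daily_pitch_medians(annotations, [lab], ref)
        frac = fraction_pitch_corrected(med, src_p, tgt_p)
        spec = syntax_spec_for_task(task, lab, chosen)
        syn = syntax_fractions(annotations, spec)
        shift = syntax_shift_scale(annotations, spec)
        for day, v in frac.items():
            tidy.append({"day": int(day), "metric": "pitch_correction",
                         "syllable": lab, "value": float(v)})
        for day, row in syn.iterrows():
            for m in ("converging", "diverging", "overall"):
                tidy.append({"day": int(day), "metric": f"syntax_{m}",
                             "syllable": lab, "value": float(row[m])})
        for day, v in shift.items():
            tidy.append({"day": int(day), "metric": "syntax_shift",
                         "syllable": lab, "value": float(v)})
        summary[lab] = endpoint_summary(annotations, [lab], ref, src_p, tgt_p,
                                        spec=spec)
        summary[lab]["chosen_target"] = chosen
    return pd.DataFrame(tidy), summary


@_stage("assign")
def _compare_assignments(traj) -> dict:
    task = traj.task
    call_p = {cid: float(arr[0]) for cid, arr in traj.truth.call_pitch.items()}
    problem = problem_from_task(task, call_p)
    lap = solve_lap(problem)
    seq_real = sequence_cost(traj.mapping, task.source, task.target)
    return {
        "realized_mapping": traj.mapping,
        "lap_mapping": lap.mapping,
        "lap_spectral_cost": lap.spectral_cost,
        "realized_sequence_cost": seq_real,
        "realized_total_lambda1": qap_total(problem, {
            m: t for m, t in traj.mapping.items()
            if m in problem.motor_labels and t in problem.target_labels}, task, 1.0),
    }


@_stage("em")
def _em_comparison(traj, seed: int) -> dict:
    """Fit motor-initialized Gaussian components to target-pitch samples."""
    task = traj.task
    rng = np.random.default_rng(seed)
    tgt = {lab: task.target.pitch_of(lab) for lab in task.target.harmonic_labels()}
    samples = np.concatenate([
        rng.normal(p, 0.3, 100) for p in tgt.values()])
    motor_init = {lab: task.source.pitch_of(lab)
                  for lab in task.source.harmonic_labels()}
    for cid, arr in traj.truth.call_pitch.items():
        motor_init[cid] = float(arr[0])
    state = em_fit(samples, K=len(motor_init),
                   init_means=list(motor_init.values()))
    em_map = assign_by_responsibility(state, motor_init, tgt)
    shared = [m for m in em_map if m in traj.mapping]
    agree = (sum(em_map[m] == traj.mapping[m] for m in shared) / len(shared)
             if shared else None)
    return {"em_mapping": em_map, "em_means": state.means.tolist(),
            "em_log_likelihood": state.log_likelihood,
            "agreement_with_realized": agree}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the report bundle directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("songchairs %s, seed %d, task %s, strategy %s",
                 __version__, config.seed, config.task, config.strategy)
        task = task_library()[config.task]
        params = SimParams(**{**config.sim, "seed": config.seed})
        synth_cfg = SynthConfig(**{**config.synth, "seed": config.seed})
        traj = simulate(task, config.strategy, params, synth_cfg)
        traj.renditions.to_csv(outdir / "annotations.csv", index=False)

        annotations = traj.renditions
        if config.audio:
            annotations = _measure_audio(traj, config, synth_cfg)
            annotations.to_csv(outdir / "annotations_measured.csv", index=False)

        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "mapping": traj.mapping,
            "events": traj.events,
        }
        if config.run_metrics:
            tidy, metric_summary = _compute_metrics(traj, annotations)
            tidy.to_csv(outdir / "metrics.csv", index=False)
            summary["metrics"] = metric_summary
        if config.run_assign:
            summary["assignment"] = _compare_assignments(traj)
        if config.run_em:
            summary["em"] = _em_comparison(traj, config.seed + 1)
        if config.task in ("3", "5"):
            summary["vacancy"] = _vacancy_summary(traj, annotations)

        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False))
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=_jsonable))
        log.info("report bundle written to %s", outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()


def _vacancy_summary(traj, annotations: pd.DataFrame) -> dict:
    task = traj.task
    focal = task.shifted_source_labels()[0]
    chosen = traj.mapping.get(focal)
    if chosen is None:
        return {}
    direction = task.target.pitch_of(chosen) - task.source.pitch_of(focal)
    call = next((c for c in traj.truth.call_pitch
                 if traj.mapping.get(c) is not None), None)
    endpoint_days = sorted(annotations["day"].unique())[-3:]
    tail = annotations[annotations["day"].isin(endpoint_days)]
    hists = vacancy_histogram(tail, [focal], call, task.source.reference_freq,
                              task.source.pitch_of(focal), direction)
    return {
        "recruited_call": call,
        "direction": float(np.sign(direction)),
        "histograms": {k: {"edges": e.tolist(), "counts": c.tolist()}
                       for k, (e, c) in hists.items()},
    }


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
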