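"""Generative model of developmental song trajectories under a strategy.

Implements the two-module account of song learning: a phonology module
that fixes syllable-to-target assignments at the training switch (by a
chosen strategy) and then drives each syllable's pitch toward its
assigned target by noisy exponential approach, and an independent, slower
syntax module that acquires missing target transitions one at a time and
ramps their usage while the source transitions persist.  Calls recruited
to vacant targets enter the motif after a lag.  The emitted rendition
stream feeds :mod:`songchairs.trajectory_metrics`, reproducing the
qualitative signatures of serial-tutoring experiments (pitch-before-
syntax ordering, winner-take-all target choice, call recruitment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .assignment_models import musical_chairs, problem_from_task, strategy_predict
from .song_tasks import ImitationTask, target_bigrams
from .synthetic_data import (GroundTruthTrajectory, SynthConfig,
                             generate_rendition_stream)

__all__ = ["SimParams", "LearningTrajectory", "simulate", "batch_simulate",
           "lineage_target_bigrams"]

#: similarity criterion used to declare the source song learned before the
#: switch to target training (documented constant; switch-day logic only)
SOURCE_LEARNED_SIMILARITY = 0.70


@dataclass(frozen=True)
class SimParams:
    pitch_rate: float = 0.2  # per-day exponential approach rate
    pitch_noise_sd: float = 0.05  # semitones, day-to-day trajectory noise
    occupancy_radius: float = 0.5  # semitones
    p_transition_acquire: float = 0.12  # per-day prob of acquiring one transition
    transition_ramp: float = 0.2  # per-day usage growth of an acquired transition
    recruitment_lag: int = 5  # days before a recruited call starts shifting
    n_days: int = 40
    renditions_per_day: int = 60
    n_calls: int = 1
    call_pitch_range: tuple[float, float] = (-5.0, 5.0)
    syntax_mode: str = "independent"  # or "locked" (syntax tied to pitch)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_transition_acquire <= 1):
            raise ValueError("p_transition_acquire must be a probability")
        if self.occupancy_radius <= 0:
            raise ValueError("occupancy_radius must be positive")
        if self.pitch_rate < 0 or self.pitch_noise_sd < 0:
            raise ValueError("rates must be nonnegative")
        if self.syntax_mode not in ("independent", "locked"):
            raise ValueError("syntax_mode must be 'independent' or 'locked'")


@dataclass
class LearningTrajectory:
    task: ImitationTask
    strategy: str
    params: SimParams
    mapping: dict[str, str]
    truth: GroundTruthTrajectory
    renditions: pd.DataFrame
    events: list[dict] = field(default_factory=list)


def lineage_target_bigrams(task: ImitationTask,
                           mapping: dict[str, str]) -> set[tuple[str, str]]:
    """Target bigrams expressed in the learner's own (lineage) labels.

    Each target label is replaced by the motor syllable assigned to it
    (falling back to the same name for unshifted syllables); target
    syllables left unassigned keep their target name.
    """
    reverse = {t: m for m, t in mapping.items()}
    lineage = [reverse.get(lab, lab) for lab in task.target.labels]
    pairs = {(lineage[i], lineage[i + 1]) for i in range(len(lineage) - 1)}
    pairs.add((lineage[-1], lineage[0]))
    return pairs


def _source_bigrams(task: ImitationTask) -> set[tuple[str, str]]:
    return target_bigrams(task.source)


def simulate(task: ImitationTask, strategy: str, params: SimParams,
             synth_config: Optional[SynthConfig] = None) -> LearningTrajectory:
    """One simulated bird: assignment at day 0, then daily pitch and syntax
    dynamics, emitted as an annotated rendition stream."""
    rng = np.random.default_rng(params.seed)
    n_days = params.n_days

    call_pitches = {
        f"call{i}": float(rng.uniform(*params.call_pitch_range))
        for i in range(params.n_calls)
    }
    problem = problem_from_task(task, call_pitches)
    if strategy == "greedy":
        assign = musical_chairs(problem,
                                tie_seed=int(rng.integers(2 ** 31)),
                                occupancy_radius=params.occupancy_radius)
        mapping, events = assign.mapping, list(assign.events)
    else:
        mapping = strategy_predict(task, strategy, call_pitches)
        events = [{"event": "assignment", "strategy": strategy,
                   "mapping": dict(mapping)}]

    # --- pitch dynamics -----------------------------------------------------
    tgt_harm = set(task.target.harmonic_labels())
    src_harm = list(task.source.harmonic_labels())
    pitch: dict[str, np.ndarray] = {}
    for lab in src_harm:
        p0 = task.source.pitch_of(lab)
        tgt = mapping.get(lab)
        goal = task.target.pitch_of(tgt) if tgt in tgt_harm else None
        pitch[lab] = _approach(p0, goal, n_days, params, rng, lag=0)
    call_traj: dict[str, np.ndarray] = {}
    recruited: dict[str, str] = {}
    for cid, p0 in call_pitches.items():
        tgt = mapping.get(cid)
        goal = task.target.pitch_of(tgt) if tgt in tgt_harm else None
        call_traj[cid] = _approach(p0, goal, n_days, params, rng,
                                   lag=params.recruitment_lag if goal is not None else 0)
        if goal is not None:
            recruited[cid] = tgt
            events.append({"event": "recruitment", "call": cid, "target": tgt,
                           "day": params.recruitment_lag})

    # --- syntax dynamics ----------------------------------------------------
    desired = lineage_target_bigrams(task, mapping)
    have = _source_bigrams(task)
    missing = sorted(desired - have)
    rng.shuffle(missing)
    acquired_on: dict[tuple[str, str], int] = {}
    if params.syntax_mode == "independent":
        day = 0
        queue = list(missing)
        while queue and day < n_days:
            if rng.random() < params.p_transition_acquire:
                tr = queue.pop(0)
                acquired_on[tr] = day
                events.append({"event": "transition_acquired", "day": day,
                               "bigram": list(tr)})
            day += 1
    focal_fracs = _mean_pitch_fraction(task, mapping, pitch, n_days)
    tables = [
        _day_grammar(task, desired, acquired_on, d, params, focal_fracs[d],
                     recruited)
        for d in range(n_days)
    ]

    truth_pitch = dict(pitch)
    for cid, tgt in recruited.items():
        truth_pitch[cid] = call_traj[cid]  # recruited calls join the motif pool
    truth = GroundTruthTrajectory(
        n_days=n_days, pitch=truth_pitch, transitions=tables,
        call_pitch=dict(call_traj),
        target_choice={m: t for m, t in mapping.items() if m in src_harm},
    )
    truth.validate()
    cfg = synth_config or SynthConfig()
    cfg = replace(cfg, seed=int(rng.integers(2 ** 31)),
                  renditions_per_day=params.renditions_per_day)
    stream = generate_rendition_stream(task, truth, n_days, cfg)
    return LearningTrajectory(task=task, strategy=strategy, params=params,
                              mapping=mapping, truth=truth,
                              renditions=stream, events=events)


def _approach(p0: float, goal: Optional[float], n_days: int,
              params: SimParams, rng: np.random.Generator,
              lag: int = 0) -> np.ndarray:
    traj = np.empty(n_days)
    p = p0
    for d in range(n_days):
        traj[d] = p
        if goal is not None and d >= lag:
            p = p + params.pitch_rate * (goal - p)
        if params.pitch_noise_sd > 0:
            p = p + rng.normal(0.0, params.pitch_noise_sd)
    return traj


def _mean_pitch_fraction(task: ImitationTask, mapping: dict[str, str],
                         pitch: dict[str, np.ndarray], n_days: int) -> np.ndarray:
    """Mean fraction of pitch correction across shifted motif syllables."""
    tgt_harm = set(task.target.harmonic_labels())
    fracs = []
    for lab in task.shifted_source_labels():
        tgt = mapping.get(lab)
        if tgt not in tgt_harm:
            continue
        src_p = task.source.pitch_of(lab)
        tgt_p = task.target.pitch_of(tgt)
        if tgt_p == src_p:
            continue
        fracs.append((pitch[lab] - src_p) / (tgt_p - src_p))
    if not fracs:
        return np.zeros(n_days)
    return np.clip(np.mean(fracs, axis=0), 0.0, 1.0)


def _day_grammar(task: ImitationTask, desired: set[tuple[str, str]],
                 acquired_on: dict[tuple[str, str], int], day: int,
                 params: SimParams, locked_frac: float,
                 recruited: dict[str, str]) -> dict[str, dict[str, float]]:
    """Mix source transitions with ramping acquired target transitions."""
    src = _source_bigrams(task)
    # desired successors per lineage label, with equal final shares
    succ_of: dict[str, list[str]] = {}
    for a, b in desired:
        succ_of.setdefault(a, []).append(b)
    src_succ: dict[str, list[str]] = {}
    for a, b in src:
        src_succ.setdefault(a, []).append(b)

    def usage(tr: tuple[str, str]) -> float:
        if params.syntax_mode == "locked":
            return float(locked_frac) if tr in desired and tr not in src else 0.0
        d0 = acquired_on.get(tr)
        if d0 is None or day < d0:
            return 0.0
        return min(1.0, params.transition_ramp * (day - d0 + 1))

    table: dict[str, dict[str, float]] = {}
    labels = set(src_succ) | set(succ_of)
    for a in labels:
        row: dict[str, float] = {}
        new_mass = 0.0
        targets = succ_of.get(a, [])
        share = 1.0 / len(targets) if targets else 0.0
        for b in targets:
            if (a, b) in src:
                continue  # already part of the source grammar
            w = usage((a, b)) * share
            if w > 0:
                row[b] = row.get(b, 0.0) + w
                new_mass += w
        residual = max(0.0, 1.0 - new_mass)
        olds = src_succ.get(a)
        if olds:
            for b in olds:
                row[b] = row.get(b, 0.0) + residual / len(olds)
        elif residual > 0:
            # label only exists in the target song (e.g. a recruited call):
            # spread residual over its target successors
            if targets:
                for b in targets:
                    row[b] = row.get(b, 0.0) + residual / len(targets)
        s = sum(row.values())
        if s > 0:
            table[a] = {b: v / s for b, v in row.items()}
    return table


def batch_simulate(task: ImitationTask, strategy: str, n_birds: int,
                   params: SimParams, seeds: Optional[list[int]] = None,
                   emit_renditions: bool = True
                   ) -> tuple[list[LearningTrajectory], pd.DataFrame]:
    """Independent simulated birds plus a per-bird endpoint summary table.

    With ``emit_renditions=False`` only assignments and ground-truth pitch
    trajectories are computed (fast path for large cohorts); the summary's
    endpoint pitch correction then comes from the truth trajectories.
    """
    if n_birds < 1:
        raise ValueError("n_birds must be at least 1")
    if seeds is None:
        seeds = [int(s) for s in
                 np.random.SeedSequence(params.seed).generate_state(n_birds) % (2 ** 31)]
    if len(seeds) != n_birds:
        raise ValueError("need one seed per bird")
    rows = []
    trajs: list[LearningTrajectory] = []
    for b, s in enumerate(seeds):
        p = replace(params, seed=int(s))
        if emit_renditions:
            traj = simulate(task, strategy, p)
        else:
            traj = _simulate_light(task, strategy, p)
        trajs.append(traj)
        tgt_harm = set(task.target.harmonic_labels())
        for lab in task.shifted_source_labels():
            tgt = traj.mapping.get(lab)
            row = {"bird": b, "seed": int(s), "syllable": lab,
                   "chosen_target": tgt}
            if tgt in tgt_harm:
                src_p = task.source.pitch_of(lab)
                tgt_p = task.target.pitch_of(tgt)
                endp = float(traj.truth.pitch[lab][-1])
                row["pitch_correction"] = (endp - src_p) / (tgt_p - src_p) \
                    if tgt_p != src_p else np.nan
            else:
                row["pitch_correction"] = 0.0
            rows.append(row)
    return trajs, pd.DataFrame(rows)


def _simulate_light(task: ImitationTask, strategy: str,
                    params: SimParams) -> LearningTrajectory:
    """Assignment + pitch dynamics only; no rendition stream."""
    rng = np.random.default_rng(params.seed)
    call_pitches = {f"call{i}": float(rng.uniform(*params.call_pitch_range))
                    for i in range(params.n_calls)}
    problem = problem_from_task(task, call_pitches)
    if strategy == "greedy":
        assign = musical_chairs(problem, tie_seed=int(rng.integers(2 ** 31)),
                                occupancy_radius=params.occupancy_radius)
        mapping, events = assign.mapping, list(assign.events)
    else:
        mapping = strategy_predict(task, strategy, call_pitches)
        events = []
    tgt_harm = set(task.target.harmonic_labels())
    pitch = {}
    for lab in task.source.harmonic_labels():
        goal = task.target.pitch_of(mapping[lab]) \
            if mapping.get(lab) in tgt_harm else None
        pitch[lab] = _approach(task.source.pitch_of(lab), goal,
                               params.n_days, params, rng)
    call_traj = {}
    for cid, p0 in call_pitches.items():
        goal = task.target.pitch_of(mapping[cid]) \
            if mapping.get(cid) in tgt_harm else None
        call_traj[cid] = _approach(p0, goal, params.n_days, params, rng,
                                   lag=params.recruitment_lag if goal is not None else 0)
    truth = GroundTruthTrajectory(n_days=params.n_days, pitch=pitch,
                                  transitions=[{} for _ in range(params.n_days)],
                                  call_pitch=call_traj,
                                  target_choice=dict(mapping))
    return LearningTrajectory(task=task, strategy=strategy, params=params,
                              mapping=mapping, truth=truth,
                              renditions=pd.DataFrame(), events=events)
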