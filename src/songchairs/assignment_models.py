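"""Syllable-to-target assignment models.

Matching a learned syllable repertoire to a new target song is an
assignment problem: each motor syllable (a motif syllable or a call) must
be mapped one-to-one onto target syllables so that spectral change is
small and, ideally, few new syllable transitions must be acquired.
Optimizing both simultaneously is a quadratic assignment problem (QAP);
optimizing spectral cost alone is a linear assignment problem (LAP).

This module provides:

* :func:`spectral_costs` / :func:`solve_lap` / :func:`solve_lap_bruteforce`
  — the LAP over |semitone| distances, with an exhaustive oracle;
* :func:`sequence_cost` / :func:`qap_total` — the additive spectral +
  lambda*sequence objective with an exhaustive minimizer for small motifs;
* :func:`musical_chairs` — the greedy-competitive dynamics: winner-take-all
  target selection by spectral proximity, a competition rule that prevents
  two motor syllables from converging on one target, and recruitment of
  calls to vacant targets, like a musical-chairs game ending with every
  chair occupied by one player;
* :func:`strategy_predict` — the competing strategy hypotheses (global
  positional alignment, greedy-competitive, chunk-wise bigram alignment).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .song_tasks import ImitationTask, SongModel, target_bigrams

__all__ = [
    "AssignmentProblem",
    "AssignmentResult",
    "spectral_costs",
    "solve_lap",
    "solve_lap_bruteforce",
    "sequence_cost",
    "qap_total",
    "qap_bruteforce",
    "musical_chairs",
    "strategy_predict",
    "problem_from_task",
]

TIE_TOL = 1e-9  # semitones; exact spectral ties are measure-zero under jitter


@dataclass
class AssignmentProblem:
    """Motor syllables (motif + optional call pool) vs. target syllables."""

    motor_labels: list[str]
    motor_pitches: np.ndarray  # semitones
    target_labels: list[str]
    target_pitches: np.ndarray
    motor_positions: Optional[list[int]] = None  # motif index, None for calls
    target_positions: Optional[list[int]] = None
    cost: Optional[np.ndarray] = None  # |motor| x |targets|

    def __post_init__(self) -> None:
        self.motor_pitches = np.asarray(self.motor_pitches, dtype=float)
        self.target_pitches = np.asarray(self.target_pitches, dtype=float)
        if self.cost is None:
            self.cost = spectral_costs(self.motor_pitches, self.target_pitches)
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.shape != (len(self.motor_labels), len(self.target_labels)):
            raise ValueError("cost matrix shape mismatch")
        if (self.cost < 0).any():
            raise ValueError("costs must be nonnegative")

    @property
    def n_motor(self) -> int:
        return len(self.motor_labels)

    @property
    def n_targets(self) -> int:
        return len(self.target_labels)


@dataclass
class AssignmentResult:
    """An injective motor->target mapping with its costs."""

    mapping: dict[str, str]
    spectral_cost: float
    sequence_cost: Optional[int] = None
    lam: float = 0.0
    events: list[dict] = field(default_factory=list)
    complete: bool = True  # every target matched

    @property
    def total_cost(self) -> float:
        if self.sequence_cost is None:
            return self.spectral_cost
        return self.spectral_cost + self.lam * self.sequence_cost

    def to_json(self) -> str:
        return json.dumps(
            {
                "mapping": self.mapping,
                "spectral_cost": self.spectral_cost,
                "sequence_cost": self.sequence_cost,
                "lambda": self.lam,
                "total_cost": self.total_cost,
                "complete": self.complete,
                "events": self.events,
            },
            indent=2,
        )


def spectral_costs(motor_pitches: Sequence[float],
                   target_pitches: Sequence[float]) -> np.ndarray:
    """Cost matrix of absolute semitone distances, shape |motor| x |targets|."""
    m = np.asarray(motor_pitches, dtype=float)
    t = np.asarray(target_pitches, dtype=float)
    if not (np.isfinite(m).all() and np.isfinite(t).all()):
        raise ValueError("pitches must be finite")
    return np.abs(m[:, None] - t[None, :])


def _index_result(problem: AssignmentProblem, rows: np.ndarray,
                  cols: np.ndarray) -> AssignmentResult:
    mapping = {problem.motor_labels[i]: problem.target_labels[j]
               for i, j in zip(rows, cols)}
    cost = float(problem.cost[rows, cols].sum())
    complete = len(set(cols)) == problem.n_targets
    return AssignmentResult(mapping=mapping, spectral_cost=cost, complete=complete)


def solve_lap(problem: AssignmentProblem | np.ndarray) -> AssignmentResult:
    """Optimal linear assignment minimizing total spectral cost.

    Rectangular matrices are handled directly: with more motor syllables
    than targets every target is matched (extra motors stay unassigned);
    with more targets than motors only |motor| targets can be matched and
    the result is flagged incomplete.  Among cost ties the lexicographically
    smallest index mapping is returned.
    """
    problem = _as_problem(problem)
    n, m = problem.cost.shape
    if n == 0 or m == 0:
        return AssignmentResult(mapping={}, spectral_cost=0.0, complete=(m == 0))
    # tiny lexicographic bias: strictly smaller than any real cost difference
    # it could override, makes the optimizer's tie-break deterministic
    scale = max(problem.cost.max(), 1.0)
    eps = TIE_TOL * scale / (n * m + 1)
    bias = eps * (np.arange(n)[:, None] * m + np.arange(m)[None, :])
    rows, cols = linear_sum_assignment(problem.cost + bias)
    return _index_result(problem, rows, cols)


def solve_lap_bruteforce(problem: AssignmentProblem | np.ndarray) -> AssignmentResult:
    """Exhaustive LAP minimum over all injective mappings (|targets| <= 8)."""
    problem = _as_problem(problem)
    n, m = problem.cost.shape
    k = min(n, m)
    if max(n, m) > 8:
        raise ValueError("brute force limited to 8 agents/targets")
    if n == 0 or m == 0:
        return AssignmentResult(mapping={}, spectral_cost=0.0, complete=(m == 0))
    best: Optional[tuple[float, tuple, tuple]] = None
    # choose which k rows/cols participate, then permute
    for rows in itertools.combinations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            c = float(problem.cost[list(rows), list(cols)].sum())
            key = (c, rows, cols)
            if best is None or key < best:
                best = key
    _, rows, cols = best
    return _index_result(problem, np.array(rows), np.array(cols))


def _as_problem(p: AssignmentProblem | np.ndarray) -> AssignmentProblem:
    if isinstance(p, AssignmentProblem):
        return p
    c = np.asarray(p, dtype=float)
    n, m = c.shape
    return AssignmentProblem(
        motor_labels=[f"m{i}" for i in range(n)],
        motor_pitches=np.zeros(n),
        target_labels=[f"t{j}" for j in range(m)],
        target_pitches=np.zeros(m),
        cost=c,
    )


# ---------------------------------------------------------------------------
# sequence (syntax) cost


def sequence_cost(mapping: dict[str, str], source: SongModel,
                  target: SongModel) -> int:
    """Number of target bigrams the learner must newly acquire.

    The motor motif is relabelled by the assigned targets (labels without a
    mapping entry keep their own name) and kept in source order; both the
    relabelled source and the target contribute their motif-wrap bigram,
    since motifs are sung in repetition.  The cost counts target bigrams
    not already realized by the relabelled source — syntax learning
    proceeds by acquiring those transitions one at a time.
    """
    relabelled = [mapping.get(lab, lab) for lab in source.labels]
    realized = {(relabelled[i], relabelled[i + 1])
                for i in range(len(relabelled) - 1)}
    realized.add((relabelled[-1], relabelled[0]))
    wanted = target_bigrams(target)
    return len(wanted - realized)


def qap_total(problem: AssignmentProblem, mapping: dict[str, str],
              task: ImitationTask, lam: float) -> float:
    """Spectral + lambda * sequence cost of a given mapping."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    idx_m = {lab: i for i, lab in enumerate(problem.motor_labels)}
    idx_t = {lab: j for j, lab in enumerate(problem.target_labels)}
    spectral = sum(problem.cost[idx_m[a], idx_t[b]] for a, b in mapping.items())
    seq = sequence_cost(mapping, task.source, task.target)
    return float(spectral) + lam * seq


def qap_bruteforce(problem: AssignmentProblem, task: ImitationTask,
                   lam: float) -> tuple[dict[str, str], float]:
    """Exhaustive minimizer of the quadratic objective (|targets| <= 8)."""
    n, m = problem.cost.shape
    if max(n, m) > 8:
        raise ValueError("brute force limited to 8 agents/targets")
    k = min(n, m)
    best: Optional[tuple[float, dict[str, str]]] = None
    for rows in itertools.combinations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            mapping = {problem.motor_labels[i]: problem.target_labels[j]
                       for i, j in zip(rows, cols)}
            c = qap_total(problem, mapping, task, lam)
            if best is None or c < best[0]:
                best = (c, mapping)
    assert best is not None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# greedy-competitive ("musical chairs") dynamics


def problem_from_task(task: ImitationTask,
                      call_pitches: Optional[dict[str, float]] = None
                      ) -> AssignmentProblem:
    """Assignment problem over the task's harmonic syllables.

    Motor side: harmonic syllables of the source motif, plus an optional
    call pool (pitch in semitones relative to the task reference).  Target
    side: harmonic syllables of the target motif.
    """
    motor_labels = list(task.source.harmonic_labels())
    motor_pitches = [task.source.pitch_of(l) for l in motor_labels]
    motor_positions: list[Optional[int]] = [
        list(task.source.labels).index(l) for l in motor_labels
    ]
    if call_pitches:
        for cid, p in call_pitches.items():
            motor_labels.append(cid)
            motor_pitches.append(float(p))
            motor_positions.append(None)
    target_labels = list(dict.fromkeys(task.target.harmonic_labels()))
    target_pitches = [task.target.pitch_of(l) for l in target_labels]
    target_positions = [list(task.target.labels).index(l) for l in target_labels]
    return AssignmentProblem(
        motor_labels=motor_labels,
        motor_pitches=np.asarray(motor_pitches),
        target_labels=target_labels,
        target_pitches=np.asarray(target_pitches),
        motor_positions=motor_positions,
        target_positions=target_positions,
    )


def musical_chairs(problem: AssignmentProblem, tie_seed: int = 0,
                   occupancy_radius: float = 0.5,
                   compete_on_selection: bool = True) -> AssignmentResult:
    """Greedy winner-take-all matching with a competitive occupancy constraint.

    Motif syllables ("players") repeatedly select their spectrally nearest
    unoccupied target ("chair"); exact ties are broken uniformly at random
    under ``tie_seed``.  When two players select the same chair the nearer
    one wins and the loser reselects among the remaining chairs
    (``compete_on_selection=False`` defers the conflict resolution until a
    player converges within ``occupancy_radius``; the outcome mapping is
    the same, only the event log differs).  Chairs left vacant after all
    motif players are seated recruit the nearest available call.

    Returns a target-complete injective mapping whenever
    |motor| >= |targets|; otherwise the result is flagged incomplete.
    """
    rng = np.random.default_rng(tie_seed)
    events: list[dict] = []
    is_call = [problem.motor_positions is not None
               and problem.motor_positions[i] is None
               for i in range(problem.n_motor)]
    motif_players = [i for i in range(problem.n_motor) if not is_call[i]]
    calls = [i for i in range(problem.n_motor) if is_call[i]]

    taken: dict[int, int] = {}  # target index -> motor index
    # phase 1: motif syllables compete over targets
    unseated = list(motif_players)
    guard = 0
    while unseated and len(taken) < problem.n_targets:
        guard += 1
        if guard > 10 * (problem.n_motor + 1) * (problem.n_targets + 1):
            break  # cannot happen with finite costs; safety only
        i = unseated.pop(0)
        avail = [j for j in range(problem.n_targets) if j not in taken]
        if not avail:
            break
        c = problem.cost[i, avail]
        best = c.min()
        tied = [avail[k] for k in range(len(avail)) if c[k] <= best + TIE_TOL]
        j = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
        if len(tied) > 1:
            events.append({"event": "tie_break", "motor": problem.motor_labels[i],
                           "options": [problem.target_labels[t] for t in tied],
                           "chosen": problem.target_labels[j]})
        events.append({"event": "select", "motor": problem.motor_labels[i],
                       "target": problem.target_labels[j],
                       "cost": float(problem.cost[i, j])})
        if j in taken:
            # competition: the nearer player keeps the chair
            other = taken[j]
            if problem.cost[i, j] < problem.cost[other, j] - TIE_TOL:
                winner, loser = i, other
            elif problem.cost[other, j] < problem.cost[i, j] - TIE_TOL:
                winner, loser = other, i
            else:
                winner, loser = (i, other) if rng.integers(2) else (other, i)
            taken[j] = winner
            unseated.append(loser)
            events.append({"event": "compete", "target": problem.target_labels[j],
                           "winner": problem.motor_labels[winner],
                           "loser": problem.motor_labels[loser],
                           "on": "selection" if compete_on_selection else "convergence"})
        else:
            taken[j] = i

    # phase 2: vacant chairs recruit the nearest available call
    partial = False
    seated_calls: set[int] = set()
    for j in range(problem.n_targets):
        if j in taken:
            continue
        free_calls = [i for i in calls if i not in seated_calls]
        if not free_calls:
            partial = True
            events.append({"event": "vacant", "target": problem.target_labels[j]})
            continue
        c = problem.cost[free_calls, j]
        best = c.min()
        tied = [free_calls[k] for k in range(len(free_calls))
                if c[k] <= best + TIE_TOL]
        i = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
        taken[j] = i
        seated_calls.add(i)
        events.append({"event": "recruit", "motor": problem.motor_labels[i],
                       "target": problem.target_labels[j],
                       "cost": float(problem.cost[i, j])})

    mapping = {problem.motor_labels[i]: problem.target_labels[j]
               for j, i in taken.items()}
    cost = float(sum(problem.cost[i, j] for j, i in taken.items()))
    return AssignmentResult(mapping=mapping, spectral_cost=cost,
                            events=events, complete=not partial)


# ---------------------------------------------------------------------------
# strategy hypotheses


def _syllable_pair_cost(a, b) -> float:
    """Distance between two syllable specs: |semitone| gap for harmonic pairs,
    0 for same-kind/same-label non-harmonic pairs, large penalty otherwise."""
    if a.is_harmonic and b.is_harmonic:
        return abs((a.base_pitch or 0.0) - (b.base_pitch or 0.0))
    if (not a.is_harmonic) and (not b.is_harmonic):
        return 0.0 if a.label.rstrip("0123456789+-") == b.label.rstrip("0123456789+-") else 100.0
    return 100.0


def strategy_predict(task: ImitationTask, strategy: str,
                     call_pitches: Optional[dict[str, float]] = None,
                     tie_seed: int = 0) -> dict[str, str]:
    """Predicted motor->target mapping under a named learning strategy.

    ``global``: each source syllable is matched to the target syllable at
    the same motif position (temporal correspondence, no regard to
    spectral distance).  ``greedy``: the greedy-competitive musical-chairs
    mapping.  ``chunk``: the source motif is split into its bigrams and
    each bigram is matched to the target bigram of minimal summed spectral
    cost (ties broken by earliest target position), trading off local
    spectral and sequential match.
    """
    if strategy == "greedy":
        problem = problem_from_task(task, call_pitches)
        return musical_chairs(problem, tie_seed=tie_seed).mapping
    if strategy == "global":
        src, tgt = task.source.labels, task.target.labels
        return {src[i]: tgt[i] for i in range(min(len(src), len(tgt)))}
    if strategy == "chunk":
        return _chunk_predict(task)
    raise ValueError(f"unknown strategy {strategy!r}")


def _chunk_predict(task: ImitationTask) -> dict[str, str]:
    src, tgt = task.source, task.target
    src_bigrams = [(i, i + 1) for i in range(len(src.motif) - 1)]
    tgt_bigrams = [(j, j + 1) for j in range(len(tgt.motif) - 1)]
    votes: dict[str, tuple[float, int, str]] = {}  # source label -> (cost, pos, target label)
    for i0, i1 in src_bigrams:
        best: Optional[tuple[float, int, tuple[int, int]]] = None
        for j0, j1 in tgt_bigrams:
            c = (_syllable_pair_cost(src.motif[i0], tgt.motif[j0])
                 + _syllable_pair_cost(src.motif[i1], tgt.motif[j1]))
            if best is None or (c, j0) < (best[0], best[1]):
                best = (c, j0, (j0, j1))
        assert best is not None
        c, _, (j0, j1) = best
        for si, tj in ((i0, j0), (i1, j1)):
            s, t = src.motif[si], tgt.motif[tj]
            if not s.is_harmonic:
                continue
            prev = votes.get(s.label)
            if prev is None or (c, tj) < (prev[0], prev[1]):
                votes[s.label] = (c, tj, t.label)
    return {lab: t for lab, (_, _, t) in votes.items()}
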