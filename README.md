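# songchairs

Analysis and modelling tools for **serial-tutoring song-learning
experiments** in zebra finches: a juvenile first learns an artificial
*source* song, then training is switched to a *target* song that differs
in the pitch of one or two harmonic syllables (1–2 semitones) and/or in
syllable order. Tracking how the bird corrects the mismatch reveals how a
vocal learner assigns its existing motor repertoire to new sensory
targets.

The package is aimed at researchers in computational neuroethology and
vocal-sequence learning who want to (a) compute the standard
error-correction trajectory metrics from annotated recordings, and
(b) simulate and compare competing target-assignment strategies against
those metrics.

## The core problem and models

Write the bird's motor syllables as pitches $m_1,\dots,m_n$ (semitones)
and the target syllables as $t_1,\dots,t_k$. Correcting both *phonology*
(spectral structure) and *syntax* (syllable order) optimally is a
**quadratic assignment problem**: minimize over injective mappings
$\pi$

$$\sum_i |m_i - t_{\pi(i)}| \;+\; \lambda\, S(\pi),$$

where $S(\pi)$ counts the target syllable transitions (bigrams) the bird
would still have to acquire after relabelling its motif by $\pi$.
Ignoring the sequence term reduces this to a **linear assignment problem
(LAP)** over spectral distances alone. The package implements:

- `assignment_models.solve_lap` — the optimal LAP (with an exhaustive
  brute-force oracle for cross-checking);
- `assignment_models.qap_total` / `qap_bruteforce` — the combined
  spectral + λ·sequence objective on small motifs;
- `assignment_models.musical_chairs` — the *greedy-competitive* dynamics:
  each motif syllable picks its spectrally nearest target
  (winner-take-all; exact ties at random), no two motor syllables may
  occupy one target (the nearer wins, the loser reselects), and targets
  left vacant recruit the nearest available call — like a musical-chairs
  game that ends with every chair occupied by exactly one player;
- `em_matching` — the same greedy-competitive matching viewed as EM for a
  1-D Gaussian mixture: target renditions are data, each motor syllable a
  Gaussian component initialized at its own pitch;
- `learning_simulator` — full developmental trajectories under a chosen
  strategy (greedy / positional / chunk-wise), with an independent,
  slower syntax module that acquires missing transitions one at a time;
- `acoustics` / `syllable_typing` — millisecond YIN pitch tracking,
  Wiener entropy, amplitude segmentation, bout grouping, and
  nearest-neighbour spectrogram typing for the measured path;
- `trajectory_metrics` — fraction of pitch correction
  $(p-\mathrm{src})/(\mathrm{tgt}-\mathrm{src})$, converging/diverging
  syntax fractions, the −1…+1 syntax shift scale, sliding-window binning
  (30-sample bins, 25 overlap), endpoint summaries, cohort percentages,
  and the $p = 0.5^n$ recruitment null model;
- `synthetic_data` — annotated (optionally audible) developmental
  datasets with known ground truth for validating every stage.

## Worked example

Imitation task 3 presents the source song A B C with the target
A B⁻ C B⁺: syllable B (pitch 0) faces two equidistant targets at ±2
semitones. With a call in the repertoire at −4 semitones:

```bash
$ songchairs assign --task 3 --call-pitch -4.0 --tie-seed 1
```

```json
{
  "mapping": {"B": "B-", "call0": "B+"},
  "spectral_cost": 8.0,
  "events": [
    {"event": "tie_break", "motor": "B", "options": ["B-", "B+"], "chosen": "B-"},
    {"event": "select", "motor": "B", "target": "B-", "cost": 2.0},
    {"event": "recruit", "motor": "call0", "target": "B+", "cost": 6.0}
  ]
}
optimal (LAP): {'B': 'B+', 'call0': 'B-'}  cost 4.000
```

Reading this: syllable B's two targets tie exactly, so the
winner-take-all choice is random (here B⁻); the call is then recruited to
the vacant target B⁺ at spectral cost 6, for a total of 8. The optimal
LAP would instead send B up and the call down at cost 4 — the greedy
game is efficient (both chairs occupied, one player each) but not
globally optimal, which is exactly the behavioral signature of interest.

A one-command simulated experiment (task 5, A B → A B⁺ A B⁻), ending
with the focal syllable on one target and a recruited call on the other:

```bash
$ songchairs demo --task 5 --seed 1 --out demo_out
mapping: {'B': 'B+', 'call0': 'B-'}
recruited call: call0
report bundle: demo_out
```

The bundle contains the annotation stream (`annotations.csv`), tidy
per-day metrics (`metrics.csv`), the event log, the exact config/seed,
and a `summary.json` with endpoint pitch/syntax corrections, the
LAP comparison, the EM-mixture comparison, and the endpoint
distance-from-source histograms (focal syllable / recruited call / all
other harmonic vocalizations).

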