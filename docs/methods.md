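# Methods

This note documents the models, parameter choices, and numerical
conventions behind `songchairs`, and what the synthetic validation does
and does not establish.

## Imitation tasks and the semitone scale

All pitches are expressed in semitones relative to a per-task reference
frequency (default 600 Hz, a typical zebra-finch harmonic-stack
fundamental): `semitone_offset(f, f_ref) = 12·log2(f/f_ref)`. The task
library encodes the five serial-tutoring mismatch geometries
(`song_tasks.task_library`); shift sizes that varied across experimental
birds are exposed as parameters (task 1: 1 or 2 semitones, default 2;
task 2: per-syllable shifts, default +2/+2). Per-bird model parameters
from the original training tables are not available, so defaults are
declared, not inferred. Pitch-variant labels are ASCII (`C+`, `B-1`,
`B+2`).

A motif's bigram set includes the wrap pair (last→first syllable):
motifs are performed in repetition (two per playback, several per bout),
so the wrap transition is genuinely part of the song's syntax — for the
motif ACB the set is {AC, CB, BA}.

## Assignment models

**Spectral cost** between a motor syllable and a target is the absolute
semitone distance. `solve_lap` wraps a standard rectangular
linear-assignment solver with a deterministic lexicographic tie-break;
`solve_lap_bruteforce` enumerates all injective mappings (≤ 8 units) and
serves as the oracle in tests.

**Sequence cost** of a mapping counts target bigrams (wrap included) not
realized when the motor motif is relabelled by its assigned targets and
kept in source order — the transitions the learner must still acquire.
This additive `spectral + λ·sequence` form is our reconstruction of the
combined objective; λ is exposed and `qap_bruteforce` provides the exact
minimizer on task-sized instances. Counting un-acquired transitions
(rather than, say, edit distance) matches how syntax learning proceeds
empirically: one transition at a time, mixed with the existing ones.

**Musical chairs** (`assignment_models.musical_chairs`) implements the
greedy-competitive dynamics: (1) each motif syllable selects its
spectrally nearest unoccupied target (winner-take-all; ties within 1e-9
semitones broken uniformly at random under `tie_seed` — exact ties are
measure-zero under natural jitter, so the tolerance only matters for
idealized geometries); (2) conflicts are resolved in favor of the nearer
syllable, the loser reselects; (3) occupied targets are excluded;
(4) vacant targets recruit the nearest available call. Whether the
competition acts at selection time or only at convergence is not
distinguishable behaviorally; both are implemented behind
`compete_on_selection` (default: selection) and produce the same final
mapping, differing only in the event log. The result is always injective
and target-complete when motor units ≥ targets; its spectral cost is ≥
the LAP optimum, with equality in most well-separated geometries.

**Strategy hypotheses** (`strategy_predict`): `global` matches by motif
position; `greedy` is the musical-chairs mapping; `chunk` matches source
bigrams to target bigrams minimizing summed spectral cost (non-harmonic
syllables contribute 0 when their type matches and a large penalty
otherwise; ties resolved by earliest target position).

## EM view of competitive matching

`em_matching.em_fit` is a standard 1-D Gaussian-mixture EM (E:
responsibilities; M: weights/means/variances; variance floor 1e-4
semitones², tol 1e-8 on the log-likelihood, ≤ 500 iterations).
Components are initialized at the motor repertoire's pitches — not by
k-means — because the analogy models each of the learner's own syllables
as a Gaussian whose mean migrates toward the data mode it captures, with
the shared responsibility normalization acting as soft competition.

The EM account and the musical-chairs dynamics share a testable
prediction: with target modes separated by at least ~4× the rendition
jitter sd, each target ends up captured by exactly one component — one
player per chair. This outcome-level agreement is asserted (≥ 90% over
random geometries; measured ~95%). The player-by-player map can differ:
plain EM assigns modes by proximity alone, whereas the chairs dynamics
give motif syllables priority over calls, so when a call starts between
the focal syllable and a target the two mechanisms can swap the pair.
We deliberately keep plain EM as the baseline rather than adding
priority-encoding weight constraints; the exact-map coincidence rate is
reported but not thresholded. Only 1-D pitch space is modelled — the
mismatches under study are pitch-only.

## Acoustic pipeline

The pitch tracker evaluates the cumulative-mean-normalized difference
function on 25 ms windows every 1 ms (f-band 300–4000 Hz), takes the
first lag dipping below the aperiodicity threshold 0.2, descends to the
local minimum, and refines the period by parabolic interpolation. Frames
whose CMNDF minimum stays above threshold are aperiodic and carry no f0.
On synthetic harmonic stacks across 400–1200 Hz the median error is
< 0.02 semitones.

Per-rendition **median pitch** drops the leading contiguous aperiodic
run first (the noisy onset characteristic of distance calls — no
duration bound is imposed, the run is defined by the tracker itself) and
is absent when fewer than half the remaining frames are voiced.
**Wiener entropy** is log(geometric/arithmetic spectral mean), clamped
at −15 for line spectra. **Segmentation** thresholds a 10 ms moving-RMS
log-power envelope (default −45 dB re unit RMS), merging gaps < 5 ms and
discarding runs < 20 ms; when ground-truth annotations exist the
pipeline can bypass segmentation, and both paths are tested. **Bouts**
group renditions whose inter-syllable stop is below 175 ms (configurable
within the 150–200 ms band typical of endpoint song).

**Typing** uses a nearest-neighbour classifier on 70 ms log-power STFT
segments (256-point windows, 64-sample hop) centered on the rendition
midpoint, Euclidean distance on dB matrices, k = 5 with ties broken by
mean distance then template order. Segments are RMS-normalized before
transforming so recording level cannot masquerade as type identity. On
synthetic data templates are seeded from ground truth (three examples
per type spanning its pitch range); for real data a curated template
store (matrices + JSON manifest) can be loaded. Spectrally close
variants that get lumped (e.g. two variants one semitone apart) are
pulled apart by sequential context (`refine_by_context`), falling back
to nearest expected pitch when neither context matches.

## Trajectory metrics

Fractions of pitch correction are unclamped (birds over- and
undershoot); day-level values are medians over the day's renditions.
Syntax is scored on the focal syllable's neighbors: converging =
fraction of focal renditions preceded by the target predecessor,
diverging likewise for the successor, overall = their mean. Bout-initial
(-final) renditions lack the respective neighbor and are excluded from
that fraction only — whether such edge renditions should count is
genuinely open; exclusion is our documented choice. Days with no focal
renditions yield absent values, not zeros.

The −1…+1 **shift scale** subtracts the fraction of explicitly incorrect
transitions. A retained source-context transition counts as *incorrect*
(anti-target) only when that context belongs to a competing, unchosen
target variant in the target motif — e.g. keeping A·B and B·C while B
sounds like B⁺ in a task whose target demands A·B⁻ and B⁻·C. In tasks
without a competing variant (task 1) the incorrect set is empty and the
shift scale equals the correct fraction, keeping those tasks on their
0–1 scale.

Sliding-window binning uses 30-sample bins with 25-sample overlap
(medians for pitch, means for 0/0.5/1 syntax indicators); the
pitch-vs-syntax curve summarizes mean syntax correction over bins at
45–55% pitch correction. Cohort percentages round half away from zero
(20/26 → 77%, 4/26 → 15%). The recruitment null model is
p = (1/2)^n — the chance that every bird's recruited call lands on the
vacant rather than the occupied target under independent fair choice
(0.5⁷ ≈ 0.008). "Full syntax match" for cohort flags defaults to all
target transitions ≥ 90% over the endpoint window; the threshold is
configurable and not used for any asserted number.

## Synthetic data and the simulator

`synthetic_data` generates day-indexed bouts from a first-order
syllable-transition grammar (bouts of 3 motifs, 60 motif renditions/day
by default — far fewer than a real bird sings, but enough to keep
binomial error on transition frequencies near ±6% while tests stay
fast). Rendition pitch is the day's true pitch plus Gaussian jitter in
semitone space (sd 0.25 semitones, i.e. multiplicative in Hz). Harmonic
syllables are 8-partial harmonic stacks with 0.7 amplitude rolloff and
5 ms cosine ramps; calls add a 20 ms aperiodic onset and are emitted
outside bouts with their own timing; non-harmonic syllables are fixed
band-limited noise tokens distinguishable by spectral template only — no
frequency-modulated or broadband phonology is simulated, and inter-bout
timing (uniform 0.4–1.2 s) is plausible rather than fitted. A fixed seed
reproduces the annotation CSV byte-for-byte.

The simulator fixes the assignment at day 0 by the chosen strategy, then
moves each assigned pitch by noisy exponential approach (rate 0.2/day —
chosen over constant-step drift because it produces the smooth
sigmoid-like daily-median trajectories seen in real birds; day-level
noise sd 0.05 semitones). Calls recruited to vacant targets begin
shifting after a 5-day lag and enter the motif through the grammar.
Missing target transitions are acquired one at a time (probability
0.12/day) and their usage ramps linearly (0.2/day) while source
transitions persist — new transitions are performed in combination with
the old ones, not as an instant switch. A `syntax_mode="locked"` variant
ties target-transition usage to the current pitch-correction fraction;
it exists purely as the coupled-learner contrast for the
pitch-before-syntax analysis. Age-dependent plasticity decline is out of
scope. The default call pool is one call with initial pitch uniform in
±5 semitones.

Validation sizes: the audio round trip (synthesis → segmentation →
tracking → typing → metrics) is validated at 5 days × 60 renditions,
recovering per-day median pitch within 0.1 semitone and transition
frequencies within binomial sampling error; cohort signatures use 200
simulated birds (task 3 tie split), 100 per orientation (task 4 close
targets), 8 (task 1 pitch-before-syntax cohort mean), and 10 with full
rendition streams (task 5 focal-plus-call). Note the round-trip
comparison against the *programmed* trajectory includes the generator's
own sampling noise (sd ≈ 0.04 semitones in a daily median of 60
renditions); the measured-vs-performed comparison isolates pipeline
error (≈ 0.01–0.07 semitones).

## What passing tests do and do not show

The synthetic generator produces clean harmonic stacks, stationary
within-day pitch, deterministic type templates, and first-order syntax.
Real juvenile song has drifting spectral structure within days,
non-stationary variability, imperfect segmentation under cage noise, and
higher-order sequence dependencies. Passing round-trip tests therefore
establishes the internal consistency of the pipeline (the measurement
chain recovers what the generator programmed), not field accuracy on
real recordings. Similarly, the simulator reproduces qualitative
signatures (pitch-before-syntax ordering, winner-take-all tie splits,
close-target preference, call recruitment); its cohort numbers are
model outputs, not re-derivations of any empirical cohort. Similarity
scoring of whole songs is not implemented; the 70% source-learning
criterion appears only as a documented constant
(`learning_simulator.SOURCE_LEARNED_SIMILARITY`).

## Degenerate inputs and numerical conventions

Zero-length signals yield empty feature tracks; all-zero spectra are
rejected rather than silently scored; equal source and target pitch is
an error for correction fractions (the metric is undefined); empty
truths produce empty datasets without error. EM clamps collapsed
variances to the floor with a warning and always returns normalized
responsibilities (rows sum to 1 within 1e-9). The LAP tie-break adds an
index-ordered bias smaller than 1e-9 times the cost scale, which cannot
change which mappings are optimal beyond tie resolution.
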