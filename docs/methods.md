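# Methods

This note documents the models, conventions and numerical choices behind
`topospeech`, and what the synthetic components do and do not establish
about real listeners.

## Coordinate conventions

Cells are addressed `(row, col)` with **row 0 at the bottom** (pitch increases
with row index) and **col 0 at the left** (onset time increases with column
index). All serialized artifacts (plan JSON, log CSV) use this convention.

## Trial timeline

A trial is a fixed sequence of segments: pre-delay, start beep, gap, the
contiguous word slots (one per column), gap, end beep, post-delay. The segment
sum must equal the total duration and is asserted at construction. Two presets
ship:

* **`printed`** — segment durations 5 / 10 / 10 / 50 (×3) / 10 / 10 / 5 ms,
  total 200 ms; word onsets at 25 / 75 / 125 ms for the left / central /
  right columns.
* **`paper-total`** (default) — every segment ×10, total exactly 2 s. The
  published description gives both the per-segment values and a 2-s trial
  total, which are mutually inconsistent by a factor of ten; we keep both
  readings as presets and default to the 2-s one, under which a word slot is
  500 ms — a realistic duration for a two-syllable word, whereas 50 ms is not.

## Pitch mapping

Row → note uses the published three notes "low C, low A♯, middle G♯". The
octave registers are not pinned down by that phrasing; we read them as C3,
A♯3, G♯4 (a strictly increasing map, ~10 semitones between neighbours) and
convert names to frequencies in twelve-tone equal temperament with A4 =
440 Hz (`f = 440·2^((m−69)/12)`). Both the note list and the reference pitch
are configurable. The published description calls the notes "the pentatonic
scale"; since C–A♯–G♯ with 10-semitone spacing is not a standard pentatonic
subset, the note names are taken literally and the scale label is ignored.

## Stimulus synthesis

The original stimuli were two-syllable object words sung at the three target
pitches. The packaged renderer is a **synthetic word token**: a harmonic
complex at the target f0 (first 6 harmonics; the fundamental carries the
largest weight, the remaining harmonic amplitudes are drawn once per
`(token_id, seed)` so each word has a stable timbre) under an amplitude
envelope with one raised-cosine bump per syllable (90% duty cycle, so the
inter-syllable dip is audible). The boundary beeps are pure tones with 2-ms
raised-cosine ramps at 1000 Hz (start) and 1500 Hz (end) — the source only
requires them to be "easily distinguishable"; 7 semitones separation and the
defaults are our documented choice, not an inference. A user-supplied WAV can
replace the synthetic word; it is fitted to the slot by truncation or
zero-padding (pitch-shifting natural recordings is out of scope). Segments
cannot overlap by the timeline invariant; a clip guard after mixing is purely
defensive. Audio is written as RIFF PCM-16, default rate 44.1 kHz.

## Decoding

The decoder mirrors the listener's task. Short-time energy (5-ms frames) is
thresholded at 10× the noise floor estimated from the pre-delay segment
(with a relative floor of 10⁻⁶ of the peak for digitally silent input); the
first and last supra-threshold runs are the beeps, and the word onset is the
first supra-threshold instant between them, measured on the clock anchored at
the detected start-beep onset. Column = nearest slot onset (ties toward the
lower index). The fundamental is estimated by FFT-based autocorrelation over
the word window with parabolic peak interpolation, searched in 80–600 Hz;
row = nearest pitch-map entry in log2 frequency, since pitch distance is
perceived logarithmically. A decode is labelled `clean` when the onset lands
within a quarter slot of its assigned column and the f0 within 5% (in log2)
of its assigned row. Round-trip identity holds for all 9 cells under both
presets, clean and at 20 dB SNR, and accuracy degrades monotonically along a
seeded SNR ladder.

## Session design

Test sessions present each of the 9 cells exactly 10 times (90 trials),
training sessions exactly 3 times (27 trials), in an order obtained by
shuffling the cell multiset with a seeded generator; words are then assigned
per trial uniformly among pool tokens not yet used at that cell, which
enforces the no-word-twice-at-a-location rule. Because the constraint is
per-cell only, any pool with at least `reps_per_cell` tokens is feasible and
the assignment never dead-ends; smaller pools raise an infeasibility error
naming the pigeonhole bound. Plans are fully determined by
`(pool, grid, seed)`.

The training runner replays a trial after every incorrect response (the
correct cell is passed to an optional feedback callback) until it is answered
correctly, capped at `max_replays = 10` total presentations — the published
procedure implies unbounded replays; the cap guards against non-terminating
responders and is configurable. The test runner allows at most two
presentations, denies a third listen, and records the first committed
response with no feedback. Training pools may contain spatially biased words;
test pools must not (the bias direction of training words is not matched to
trained locations, as the source leaves this unspecified).

## Synthetic observers

The observer model factorizes row and column performance — justified by the
reported absence of a row/column accuracy difference — with per-axis accuracy
following the exponential learning curve
`p(t) = p_asym − (p_asym − p_init)·exp(−(t−1)/τ)`, the simplest monotone form
matching the observed steep rise over the first ~10 trials to a plateau. On
an axis error the response is drawn from the remaining indices with adjacent
indices up-weighted `adj_weight : 1` (default 3:1 — trial-level human
confusion data are unavailable, so this is a documented assumption). Defaults
`p_init = 0.55`, `p_asym = 0.90` per axis and `τ = 4` put the plateau overall
accuracy near 0.90² ≈ 0.81, matching the observed ~80% group means with
~90% per-axis medians. Training listen counts are geometric in the current
trial accuracy (replay-until-correct implies geometric counts), reproducing
the declining repetition curve; test-phase listen counts are 1 or 2.

Parameter recovery estimates the plateaus from the last 30 trials and fits
`(p_row_init, p_col_init, τ)` jointly by least squares on the per-trial mean
accuracy curves with the plateaus held fixed; when the early-trial mean is
within 0.02 of the plateau the curve is flat and τ is flagged unidentifiable.
At the study's scale, plateau recovery is within ±0.05 with 14 simulated
subjects and τ within ±2 trials with 50.

What the simulator does **not** capture: lexical comprehension, pitch-height
associations of word meanings, attention lapses, serial position effects, or
any dependence between row and column errors. Tests passing on simulated
cohorts therefore validate the pipeline's arithmetic and interfaces, not
claims about human listeners.

## Statistics

* **Group summaries** use the sample SD (n−1 denominator; the n denominator
  does not reproduce the published values), SE = SD/√n, and the midpoint
  median for even n.
* **Outlier rule**: one pass; exclude subjects more than 2 sample SDs *below*
  the group mean, computed over all subjects including candidates.
* **Wilcoxon signed-rank** drops zero differences, mid-ranks ties, uses the
  tie-corrected variance `n(n+1)(2n+1)/24 − Σ(t³−t)/48` and a 0.5 continuity
  correction — directional for one-sided alternatives, toward the null mean
  for two-sided. This convention set reproduces the published |Z| = 3.27 for
  both conditions (3.2692 / 3.2652 at 4 decimals; without the tie correction
  the forward fixture gives 3.2643, which rounds to 3.26 instead). Exact
  enumeration over sign assignments
  (tie-safe, via doubled ranks) is available and is the default at n ≤ 12
  under `method="auto"`. When the statistic equals its null mean, Z is
  reported as 0 rather than applying the correction.
* **Rank-sum (Mann–Whitney)**, **Kruskal–Wallis** and **Friedman** follow the
  standard tie-corrected forms; small-sample exact enumeration is provided
  for the rank-sum. The chi-square approximations for Kruskal–Wallis and
  Friedman are accurate in the rejection-relevant tail at small N but can
  drift by ~0.1 from the discrete permutation null in the mid-range
  (p ≈ 0.3–0.9) — an inherent property of the approximation, cross-checked
  against permutation oracles in the tests.
* **Equivalence** follows the published procedure: Δᵢ = (fwdᵢ − bwdᵢ)/100
  paired by subject index (the groups are independent, but subject-index
  pairing exactly reproduces the published Δ median of 0.0055, so it is
  adopted); bounds ±1 SE of the forward distribution (±0.024); two one-sided
  signed-rank tests of Δ against the bounds; verdict = 95% CI of the median
  difference inside the bounds. The CI is the exact Hodges–Lehmann
  construction (order statistics of the Walsh averages at exact signed-rank
  critical values, validated against R's `wilcox.test(conf.int=TRUE)`), with
  a seeded percentile bootstrap as an alternative. **Known limitation**: the
  published 90/95% CIs ([−0.005, 0.02] / [−0.01, 0.02]) and TOST deviates
  (Z_U = −2.83, Z_L = −3.27) are not recoverable from the per-subject tables
  by any standard construction we tried — the Walsh-average CI on the table
  data is ≈ [−0.056, 0.061], under which the CI-within-bounds verdict on the
  packaged fixtures is *not equivalent*. The bounds, Δ median and the
  machinery itself reproduce; the original CI construction (likely computed
  on trial-level data unavailable here) does not.
* **Bias screen**: per word, a two-sided one-sample signed-rank test of the
  slider ratings against 0 at α = 0.05, uncorrected, flagging by the sign of
  the median — a documented assumption, as the original survey analysis is
  not described in detail.

## Problem sizes and determinism

The acceptance script and test suite run the full pipeline at the study's
own scale: 14-subject cohorts of 90-trial sessions (50 subjects for the τ
recovery check, 100 for the uniform-guessing calibration), 9 cells × 2
presets × 5 word seeds for round trips, and 22.05 kHz audio — sufficient for
the 80–600 Hz pitch band. Every stochastic component (plan shuffles, observer
draws, noise) consumes an explicit seed; `numpy.random.default_rng` streams
are keyed by `(component seed, plan seed)` so cohorts are reproducible
element-wise.
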