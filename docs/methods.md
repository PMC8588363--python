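# Methods

`xfall` re-implements, as a tested library, a laboratory-to-real-world
fall-detection analysis for waist-worn tri-axial accelerometers: scripted
lab trials train SVM / kNN / random-forest classifiers on an
impact-aligned 36-feature window representation, and the frozen models are
then evaluated on continuous real-world-style traces recorded by a
differently placed sensor. Because the real repositories this design
targets are restricted or download-only, the package ships a synthetic
data generator that reproduces their *structure* — so every stage is
testable offline — while making no claim of biomechanical fidelity.

## Synthetic data model

**ADL trials.** Each activity archetype builds a body-frame acceleration
`[h1(t), h2(t), 1 + v(t)]` (gravity along +z, in g) that is rotated into
the sensor frame and scaled per subject:

* gait archetypes (walking, jogging, stair walking): vertical oscillation
  at a cadence drawn per trial (walking 1.6–2.4 Hz, jogging 2.3–3.1 Hz,
  stairs 1.5–2.0 Hz) with one harmonic and amplitudes of 0.30 / 0.55 /
  0.35 g, plus smaller horizontal components;
* postural transitions (sitting down, standing up): a single biphasic
  magnitude excursion (±0.45 g then a smaller rebound) at a random time;
* quiet phases carry postural sway — 0.06 g at 0.18–0.35 Hz plus a
  0.4 × smaller component at 0.8–1.3 Hz. Real "still" signal is
  structured; a bare noise floor would be maximally irregular under
  sample entropy and is deliberately avoided.

Sensor noise is white with SD 0.003 g on each axis. Per-subject
variability: a fixed orientation perturbation (Euler angles ~ N(0, 6°)),
a gain in ±15 %, and a cadence factor in ±10 % — enough to make
subject-wise splitting meaningful. ADL magnitudes stay below 2.5 g.

**Fall trials.** Four phases: pre-fall ADL context (chosen from the fall
archetype's name: gait for walking/jogging falls, swaying stance
otherwise), free fall (magnitude ramping to ~0.2 g with 0.12 g flailing
noise, clipped below 0.48 g), an impact spike (raised cosine, 50 ms, apex
exactly at `impact_peak`, default 5 g), and a settling transient — white
magnitude fluctuation around 1 g with SD 0.18 × `impact_peak` decaying to
0.55 × its initial value — followed by lying rest (sway + noise). The
spike apex defines the ground-truth impact time and is the trace's
magnitude argmax.

Two modelling choices matter for the alignment stage and were made
deliberately. First, the free-fall/spike/settling span fills one whole
2.5 s window of the non-overlapping epoch grid (placement jitter ≤ 0.08 s).
Sample entropy with tolerance `r·SD(window)` is dominated by whichever
signal portion self-matches most: the spike inflates the window SD and
hence the tolerance, so *any* smooth or quiet stretch inside the impact
window would contribute a large block of predictable template matches and
mask the irregularity. An impact window that is wild end-to-end scores
SampEn ≈ 1–1.5 while gait, transitions and rest score ≈ 0.1–0.6, giving
the clean separation the threshold calibration requires. Second, the
settling noise is folded (|·|) rather than clipped at zero — clipping
would create constant runs with the same masking effect.

**Real-world-style events** are drawn from the same fall model (identical
parameter distributions, 15 s at 200 Hz, impact placed from 7.5 s onward so
the labeling convention below always applies) and pushed through a
`DomainShift`: sensor rotation, gain, extra noise, a baseline offset, and
resampling to the target rate (default 100 Hz). The `strong` preset
(25°/40°/60° rotation, gain 1.5, +0.03 g noise) is a deliberately hard
transfer problem; the added noise floor also perturbs the spectral shape
of quiet activity, which is what makes even spectral features degrade.
With the identity shift the generator is distribution-preserving by
construction; the test suite checks this with a KS test on decimated
magnitude samples (decimation reduces the serial dependence that would
otherwise miscalibrate the test).

What the generator does *not* emulate: realistic fall biomechanics,
gyroscopes, soft tissue/clothing artifacts, long free-living recordings
with confounders (vehicle rides, tooth-brushing), or class imbalance at
deployment prevalence. Passing tests therefore demonstrate that the
*pipeline machinery* is correct and sensitive to domain shift — not that
any accuracy number transfers to real patients.

## Preprocessing and labeling

Trials are epoched into fixed windows (default 500 samples = 2.5 s at
200 Hz) with 0 % or 50 % overlap; trailing partial windows are dropped.
For lab fall trials the FALL window is found by sample entropy
(Richman–Moorman: `m = 2`, tolerance `0.2 × SD` of the window, Chebyshev
distance, self-matches excluded, computed on the magnitude channel; all
three choices are exposed in `SampEnParams`). Both template sets use
`n − m` templates; `A = 0` or `B = 0` yields `inf` as the undefined
marker, which sorts above any threshold. The threshold is calibrated as
the midpoint between the largest ADL-window SampEn and the smallest
per-fall-trial maximum; overlapping ranges raise an error rather than
silently mislabeling. Windows of a fall trial other than the selected one
are discarded, not labeled ADL — they contain pre/post-fall transients.
Real-world traces are upsampled to 200 Hz (polyphase FIR; the signal mean
is removed before filtering and restored afterwards so constants survive
exactly) and labeled by the fixed convention: FALL = 1.5 s before to 1.0 s
after the known impact (2.5 s always), ADL = the 4 s before that, epoched
into window-sized sub-windows with 50 % overlap so the ADL class has more
than one member.

## Features and standardization

Nine statistics — mean, median, SD and variance (n−1), min, max, 0.25 and
0.75 quantiles (linear interpolation), spectral entropy — on each of x, y,
z and the summation channel `s(t) = |ax| + |ay| + |az|` (the literal
absolute summation; a Euclidean-norm alternative sits behind
`mode="l2"`), 36 features total in a fixed, documented order. Spectral
entropy is the Shannon entropy of the normalized one-sided power spectrum
(DC included — both that and the L1/L2 choice are auditable switches),
divided by `ln(n_bins)` to land in [0, 1]. Standardization to mean 0 / SD 1
always uses training-set statistics, also for every evaluation set;
features constant in training are mapped to zero with a warning instead of
NaN.

## Selection, tuning, evaluation

Sequential backward selection starts from all 36 features and repeatedly
removes the feature whose removal gives the best subject-grouped
cross-validated accuracy, as long as that score does not degrade by more
than `tolerance` (default 0) from the current score; ties remove the
lowest index, and the subset never drops below `min_features` (default 1).
Accepting equal-score removals means duplicated or redundant features are
pruned; on cleanly separable data the subset legitimately shrinks to a
single feature, which is itself informative — one robust feature carries
the task. The score along the accepted path is non-decreasing at
tolerance 0. SBS scores with the family's default hyperparameters (for RF
a light 15-tree forest — tree count is not tuned, and selection evaluates
hundreds of subsets) and runs before grid search.

Grid search is exhaustive with subject-grouped K-fold accuracy: SVM
`C ∈ [0.01, 10]` (7 log-spaced points, linear kernel), kNN `k ∈ [1, 10]`
(all integers), RF split features ∈ [1, 17], depth ∈ [30, 80], leaf size
∈ [1, 48] (4 log-spaced integers per range — a denser RF grid multiplies
runtime at every problem size without changing which region wins on these
data). Ties break toward the simpler model (smaller C, larger k,
shallower forest). The fitted model freezes its hyperparameters, feature
subset and standardization vectors; `predict` takes raw features and
applies the stored transform, so evaluation can never re-fit anything.

The workflow holds out `n_test_subjects` (default 6 of 23) at random,
trains on the remaining subjects' recordings of one trial index, and
evaluates on the held-out lab subjects and on the entire real-world set
(never split), repeating `n_repetitions` (default 10) times per trial
index. Per-repetition seeds derive from one experiment seed and are
recorded for replay. Metrics are accuracy, sensitivity and specificity
from the pooled fall/ADL confusion counts (real-world segments are pooled
across events before computing counts); zero-denominator metrics are
reported as undefined and excluded from aggregation. Classifier families
are compared by Kruskal–Wallis on per-run metrics with pairwise
Mann–Whitney-U post hoc tests at the Bonferroni-adjusted level; identical
constant samples are reported as test-undefined rather than crashing. A
per-family in-domain vs cross-domain Kruskal–Wallis quantifies the
generalization gap, and a 3 g magnitude-threshold oracle (FALL iff peak
Euclidean magnitude > 3 g), which is perfect on the synthetic design by
construction, bounds what any trained classifier should reach in-domain.
A window-length sweep re-runs the workflow at 250/500/750 samples for the
SVM family.

## Problem sizes and numerical choices

Default experiment parameters mirror the full study design (23 subjects,
5 trials, 10 repetitions). The acceptance script and the heavy tests run
a reduced design — 10 subjects × 2 trials × 3 repetitions, 2-fold SBS and
3-fold grid CV — chosen so a complete run finishes in minutes on one core
while leaving ≥ 6 runs per family for the rank tests. SampEn uses a
single boolean pairwise-distance matrix per window (O(n²) memory, ~1.5 ms
per 500-sample window); tests verify exact agreement with a brute-force
template counter. Windows use 0-based half-open indexing throughout. ADC
conversion is linear at ±16 g / 13 bits by default; quantization error is
bounded by half a count step, and file round-trips are tested at that
bound.

## Known limitations

* The fall phase model is a stand-in; its SampEn separation is engineered
  by construction, so alignment-recovery rates say nothing about real
  recordings.
* Backward selection on separable synthetic data collapses to very small
  feature subsets; on real, noisier data the tolerance and `min_features`
  knobs matter and the defaults here should be revisited.
* The KS-based identity-shift check is only approximately calibrated
  (serial dependence); it is used with fixed seeds and paired with a
  power check against a genuine shift.
* Per-axis SampEn, non-linear SVM kernels beyond the grid, probability
  calibration and streaming detection are out of scope.
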