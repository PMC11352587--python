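# Methods

## Sketch model

Images are binarized to 1-bit black/white; the default threshold is the
per-image median (balancing black and white mass), with a fixed-threshold
option, and the method is recorded in the image's provenance tag. All
overlapping 3×3 patches centered on pixels with a complete neighborhood
are histogrammed; borders contribute no centers, so patch statistics are
unbiased by padding. Patterns are encoded as integers in [0, 511],
row-major with the top-left pixel as the most significant bit, making file
outputs bit-exact and the code↔patch map bijective.

Feature selection maximizes Σ p·log₂(1/p) over selected patterns subject
to a capacity cap N and a bandwidth cap Σp ≤ W. This is a small knapsack
variant, and the solver is organized in two tiers:

- `select_features_exact` enumerates all subsets of the support
  (vectorized over bit masks; refused above 20 patterns) and breaks exact
  ties toward the lexicographically smallest code set. It is the oracle
  used in tests.
- `select_features_greedy` scans candidates by descending entropy
  contribution (ties by ascending code) and keeps each pattern that fits
  the remaining bandwidth. The plain scan has a classic failure mode — a
  heavy high-value pattern crowds out several lighter ones whose joint
  entropy is larger — so by default the scan is restarted under
  exclusions (every subset of the 10 heaviest feasible candidates, and
  every heavy prefix of the feasible support) and the best restarts are
  polished with destroy-and-repair local search (drop 1–2 selected
  patterns, banned from immediate re-entry, greedily refill, keep strict
  improvements). On random Dirichlet alphabets of ≤ 16 patterns the
  default selector matches the exhaustive optimum to within 1% of entropy;
  `refine=False` recovers the plain documented scan. Selection treats a
  pattern and its contrast-reversed/rotated variants as distinct, and the
  objective contains no "transmit nothing" term.

Sketches keep the center pixel's binary value wherever the local pattern
is selected and are background elsewhere (including the border ring);
`sketch_density` (retained pixels per valid center) is the realized
bandwidth, which tracks W when the feature probabilities are estimated on
the ensemble the image came from.

## Stimuli

Luminances follow the display mapping black = 7, background = 12,
white = 22 cd/m². Contrast scaling of sketches and images interpolates
linearly from the background (c = 0) to the full map (c = 1); since 12 is
not the midpoint of 7 and 22, symmetric scaling about a mean could not
reproduce both endpoint luminances, so the background-anchored convention
is used. The nominal full-contrast Michelson contrast of the black/white
pair is (22−7)/(22+7) ≈ 0.517; the luminance pair is treated as ground
truth and the Michelson value is derived, not the reverse.

Gabors are cosine carriers (cycles/deg, orientation in degrees from
vertical) under a Gaussian envelope whose σ defaults to size/6 so ±3σ
spans the stated 5° patch; drift advances the phase by 360·f_t/f_frame
degrees per frame (30°/frame for 10 Hz at 120 Hz). One static Gaussian
noise field (σ = 50 in 8-bit pixel units) is drawn per trial seed and
added identically to every frame *after* contrast scaling of the carrier,
so contrast manipulations leave noise power untouched; output is clipped
to [0, 255] and the clipped fraction is recorded on the frame stack. The
flicker adapter is a square wave between 7 and 22 cd/m² starting high
(half-period 6 frames at 10 Hz/120 Hz; non-integer half-periods are
rounded with a warning). The mask is i.i.d. black/white pixels. All
stimulus generation is deterministic given spec and seed.

## Synthetic cohort

Each observer answers 2AFC trials by a cumulative Gaussian
P(c) = 0.5 + (0.5 − λ)·Φ((c − μ)/σ) with guess rate fixed at 0.5. The
generator's defaults are the study design: 30 observers × 3 tasks × 2
conditions, 100 trials per level on the task ladders (image: 10 levels
0.02–1; motion: 12 levels 0.01–0.2; orientation: 10 levels 0.01–0.1),
6400 trials per observer. Task set points are the group thresholds the
design targets — image 0.14 → 0.29, motion 0.045 → 0.063, orientation
0.037 with no flicker effect — with the flicker effect modeled as a
multiplicative threshold shift (the simplest mechanism consistent with
group summaries; additive vs multiplicative is not identifiable from
them). σ scales with μ (default ratio 0.4, Weber-like) so the psychometric
shape is invariant on log contrast, and μ is derived from the target 75%
threshold given the task's lapse. The image task uses lapse 0.1,
reproducing the ~90% performance ceiling typical of brief
sketch-discrimination; control tasks use lapse 0. Between-observer spread
is log-normal with geometric SD 1.4. Subjects get independent substreams
spawned from the master seed, so cohorts are bit-reproducible.

What the generator does *not* emulate: adapter temporal dynamics (the
10 s/2 s top-ups enter only through the threshold multiplier), sequential
learning or attention drift, task-order effects, and cross-task
correlation of individual sensitivity. Passing tests therefore certify the
analysis chain under the assumed generative model, not the behavior of
human observers.

## Psychometric fitting

Fits maximize the binomial likelihood of per-level counts (correct for
Bernoulli trials; a least-squares-on-proportions mode exists for
sensitivity checks) over (μ, log σ) — plus a logistic-bounded lapse when
the lapse is free (ceiling 0.15, used for the image task; controls fix
λ = 0). Optimization is multi-start L-BFGS-B with analytic gradients and a
Nelder-Mead fallback; fractional success counts are accepted, which makes
noiseless self-consistency exact to ~1e-6. Degenerate data (fewer than two
levels, all-correct responses, or a solution pinned at the parameter
bounds, as happens for at-chance data) return `converged=False` rather
than a silent estimate. The 75%-correct threshold inverts the fitted curve
in closed form, T = μ + σ·Φ⁻¹((0.75 − 0.5)/(0.5 − λ)), so T = μ exactly
when λ = 0; criteria at or above the fitted asymptote raise. Thresholds
outside the tested ladder are flagged `extrapolated`, not dropped.

## Nonparametric chain

Shapiro–Wilk gates every threshold sample; if any p < 0.05 the pipeline
routes to the nonparametric branch (it computes the branch regardless and
records the gate). The paired Wilcoxon drops zero differences, uses
average ranks for ties, and computes the exact two-sided p from the
tie-aware null distribution of W⁺ (rank-sum convolution over the 2ⁿ sign
assignments) for n ≤ 25, otherwise a normal approximation with continuity
and tie corrections (within 0.01 of exact by n = 20; exact mode can be
forced). The matched-pairs rank-biserial correlation is
(R⁺ − R⁻)/(R⁺ + R⁻) with a seeded percentile bootstrap CI over pairs
(default 10,000 resamples; an analytic CI is not attempted). Friedman uses
the tie-corrected chi-square on within-row ranks, Kendall's
W = χ²/(n(k−1)), and Conover post hocs follow the textbook pooled-variance
form t = (R_i − R_j)/√(2n(A₁ − B₁)/((n−1)(k−1))) with (n−1)(k−1) df and
Bonferroni correction — other variance formulations circulate, so the
variant is fixed in code. Perfect concordance has zero residual rank
variance and produces infinite t (p = 0), which is reported as such.
Threshold elevations are put on a common scale across tasks by
100·(T_flicker − T_baseline)/max-contrast; the pipeline reports both the
mean of individual change scores and the change computed from group means
(they differ slightly, as any nonlinear summary does).

## Pipeline and problem sizes

`run_experiment` chains simulate → fit → analyze, writes CSV/JSON
artifacts plus a manifest (config hash, seed, library versions), deletes
partial outputs on stage failure, and is byte-reproducible for a fixed
config and seed. Subjects with a non-converged fit in a task are dropped
pairwise from that task's comparison and from the Friedman matrix.

Test-suite simulation sizes are chosen to keep the full run a few minutes
long while leaving calibration checks statistically meaningful: estimator
consistency uses 100 vs 10,000 trials per level; threshold recovery uses
~100 simulated observers at the study design; type-I calibration uses 200
single-task null cohorts of 30 observers (nominal 5% within two binomial
SEs); the qualitative reproduction check uses 100 full-cohort replicates.

## Known limitations

- The selector's restart/repair scheme is a heuristic; its ≤1%-of-optimal
  behavior is established empirically on random alphabets, not proven.
- The multiplicative flicker effect and log-normal subject spread are
  modeling choices; real observers include wrong-direction cases and
  session-to-session drift the generator produces only through fit noise.
- Effect sizes from the calibrated simulation (e.g. Kendall's W) are
  cleaner than human data because the generative model has no
  between-task heterogeneity beyond its set points.
- Stimulus rendering targets fidelity of the *specification* (geometry,
  timing, luminance mapping), not display hardware: no gamma model, no
  temporal response of the monitor.
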