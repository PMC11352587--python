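# fastvision

Tools for studying how the early visual system compresses images under
severe resource limits, and for the psychophysics used to probe that
mechanism: constrained maximum-entropy *sketch* extraction, stimulus
synthesis, synthetic 2AFC observers, maximum-likelihood psychometric
fitting, and the nonparametric statistical chain that turns contrast
thresholds into flicker-adaptation effect sizes.

## The science in brief

**Sketch model.** Fast vision is modeled as a pattern-matching front end
with a finite dictionary and a fixed output bandwidth: every 3×3 binary
patch of an image is matched against at most *N* stored features, and at
most a fraction *W* of patch locations may be transmitted downstream. The
dictionary that carries the most information under those constraints
maximizes the total Shannon entropy

&nbsp;&nbsp;&nbsp;&nbsp;H(S) = Σ_{i∈S} p_i log₂(1/p_i),&nbsp;&nbsp; subject to |S| ≤ N, Σ_{i∈S} p_i ≤ W,

where p_i is the probability of pattern *i* over an image ensemble. A
*sketch* keeps only pixels whose local pattern is in the selected set
(study parameters N = 50, W = 0.05) and blanks everything else.

**Experiment.** Thirty observers run three 2AFC tasks (sketch-based image
discrimination; motion direction of a drifting noisy Gabor; orientation of
a tilted Gabor), each in a baseline and a flicker-adaptation condition —
the 10 Hz uniform flicker adapter selectively desensitizes the
magnocellular pathway. Performance at each contrast level (100 trials per
level, 6400 trials per observer in total) is fitted with a cumulative
Gaussian, the 75%-correct contrast threshold *T* is extracted, and
conditions are compared with paired Wilcoxon signed-rank tests
(rank-biserial effect size), threshold relative percentage change
100·(T_flicker − T_baseline)/max-contrast, and a Friedman test across
tasks with Kendall's W and Conover post hocs.

This package implements that full chain, including a calibrated synthetic
cohort generator so every stage is testable without human data.

## Worked example

```bash
python examples/full_experiment.py
```

prints (seed 1, abridged):

```
## image task (n = 30)
- baseline T = 0.143 ± 0.047, flicker T = 0.282 ± 0.093
- Wilcoxon W = 0.0, p = 1.8e-06; rrb = -1.00, 95% CI [-1.00, -1.00]
- mean threshold change = 14.0% of max contrast
- significant threshold elevation (alpha = 0.05)
...
## orientation task (n = 30)
- Wilcoxon W = 152.0, p = 0.1; rrb = 0.35
- mean threshold change = -0.7% of max contrast
- no significant threshold elevation (alpha = 0.05)

## Across tasks
- Friedman chi2(2) = 48.07, p = 3.7e-11, Kendall's W = 0.80
```

Flicker adaptation roughly doubles the image-discrimination threshold
(~14–15% of the contrast range) and raises the motion threshold (~9%),
while the orientation threshold is untouched — the magnocellular signature
the paradigm is designed to detect. `examples/` also contains short
scripts for sketch extraction, stimulus rendering, and single-observer
threshold recovery; a thin CLI (`fastvision simulate/fit/analyze/report`,
`fastvision sketch ...`) wraps the same functions.

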