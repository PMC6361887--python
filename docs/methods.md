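# Methods

`magnotrain` simulates, end to end, a reading-intervention experiment
built around visual magnocellular (dorsal-stream) function in children
with specific reading difficulty: an adaptive coherent-motion threshold
test, saccade-cycle scoring, the four training-task engines, a
two-group longitudinal cohort with four assessment points, and the
mixed repeated-measures analysis applied to the resulting data. Nothing
here touches real participants; every input is generated by the package
itself, which is exactly what makes the statistical machinery testable
against known ground truth.

## The staircase model

Stimulus strength is expressed as attenuation `A` (dB) relative to
100 % coherence on the amplitude convention

    coherence = 100 · 10^(−A/20),

so 0 dB is 100 % coherence and 20 dB is 10 %. The dB convention for a
proportion is not uniquely determined; the amplitude convention is the
common psychophysical choice, and nothing downstream depends on it —
the equilibrium argument below is invariant to the base.

The weighted up-down rule steps 1 dB harder after a correct response
and 3 dB easier after a wrong one. In steady state the net drift is
zero, which forces

    p · 1 dB = (1 − p) · 3 dB  ⟹  p = 3/4,

i.e. the track oscillates where the observer is 75 % correct — the
definition of threshold used by the test. The package verifies this
empirically: over long simulated tracks the steady-state proportion of
correct responses is 0.750 ± 0.002 regardless of the observer's
psychometric shape, because the identity is bookkeeping, not
distributional.

A run terminates at 8 reversals (a 500-trial safety cap guards against
pathological simulated responders, flagged as `terminated_by =
"max_trials"`). The threshold estimate is the mean of the reversal
levels after discarding the first two, taken **on the dB scale** and
converted to coherence at the end (equivalently, the geometric mean of
the reversal coherences). The scale matters: the 1/3 dB sawtooth swings
roughly ±2 dB around its equilibrium and coherence is convex in dB, so
arithmetic averaging of raw coherences inflates the estimate by ~5–8 %
even for a perfectly converged track. Averaging on the step scale is
the standard estimator for staircases with logarithmic steps.

### Known bias of the short clinical protocol

Starting at 0 dB (100 % coherence — the child's first trials are easy,
which is why the clinical test starts there) and stopping after only 8
reversals leaves the track short of its equilibrium whenever the
observer's psychometric function is shallow: wrong answers during the
descent create early, easy-side reversals that the discard-2 rule does
not fully remove. Quantitatively (Monte-Carlo, 300 runs per cell): a
Weibull observer with slope 2 is overestimated by ~13–17 % relative,
slope 3 by ~8 %, slope 6 by ~3 %; a mechanistic resultant-vector
observer by ~5–7 %. This is a property of the printed protocol itself,
not of the estimator — no average of visited levels can recover a
threshold the track never reached — and it applies equally to both
groups of a cohort, so group contrasts are unaffected. The parameter-
recovery acceptance check therefore uses the mechanistic observer,
whose 75 %-point is measured independently by Monte-Carlo bisection
(≥2,000 trials per probe) before being fed to the staircase.

## Observers

*Psychometric.* A 2AFC Weibull, `p(c) = 0.5 + (0.5 − lapse)(1 −
exp(−(c/scale)^slope))`, parameterised directly by its 75 %-correct
coherence `alpha75`; the scale is solved analytically so that
`p(alpha75) = 0.75` exactly. Defaults: slope 2.0, lapse 0.02 — typical
child psychophysics values; any monotone family satisfying the anchor
would serve.

*Mechanistic.* No assumed curve: each dot displacement's heading is
perturbed by angular noise ~ N(0, `direction_noise_sd` rad) and the
panel with the larger mean resultant length of perceived unit
displacement vectors is chosen (exact ties broken by a fair coin). Its
psychometric function emerges from the stimulus; it is chance at zero
coherence and limited, even without noise, by the noise dots' sampling
variability (the resultant of n random unit vectors scales like
n^(−1/2)).

## Dot-kinematogram stimulus

Two panels; the signal panel carries exactly `round(coherence/100 · n)`
coherently moving dots per frame (half-up rounding), identities
re-drawn every frame to prevent single-dot tracking; all other dots
take independent uniform headings. Coordinates are normalised panel
units, origin top-left, x rightward, y downward, toroidal wrap-around,
unlimited dot lifetime. Defaults — 100 dots/panel, 20 frames, step 0.03
panel units — are declared, not inferred: the study reports no dot
count, speed or duration, and the 2AFC/75 % contract is the only part
the rest of the pipeline relies on.

## Training-task engines

* **Digit counting** — 10 levels; presentation time interpolates
  linearly from 560 ms (level 1) to 190 ms (level 10) (only the
  endpoints are reported; linear is the simplest monotone rule and is
  config-swappable). Level +1 on a correct answer (capped at 10), −1 on
  a wrong one (floored at 1); the session stops at 4 cumulative
  mistakes. Font size is carried as metadata only — no quantitative
  sizes are reported and nothing is rendered.
* **Dot counting** — level 1 presents 7–9 dots in 9 s, so the level-1
  inter-dot interval divides that window; each level multiplies the
  interval by 0.75 and adds 2 dots (the increment is a declared
  default; only "increased" is reported). Blocks of 10 trials; advance
  on ≥ 80 % correct (10 makes the criterion an integer: 8/10).
* **RDK with feedback** — staircase dynamics plus a per-trial feedback
  flag; stops after 4 wrong choices in total.
* **Saccade cycles** — a leftward saccade closed by the next rightward
  saccade is one cycle (strict consumption; an unmatched trailing left
  does not count), scored as cycles per minute.

## Synthetic cohort

Per child and measure: `value(s) = traj[group][s] + b_child +
e_session`, with `b_child ~ N(0, σ_between)` and `e_session ~ N(0,
σ_within)`; the three reading-error measures replace the Gaussian value
with a Poisson count at the (floored) latent rate — the simplest count
model. Groups share baseline distributions (the real groups were
matched); ages are drawn from N(9.76, 0.59) truncated to [9, 11].

The default scenario fixes the experimental group's trajectory deltas
at the published within-group mean changes (e.g. motion threshold
−14.15 / −18.39 / −17.08 points at mid/post/follow-up; saccade rate
+42.1 / +58.2 / +60.8 cycles/min; reading accuracy +13.6 / +20.1 /
+21.8; comprehension rising identically in both groups) over plausible
baselines (threshold 45 % coherence, 60 cycles/min, reading 55 and
comprehension 40 points on the reading test's abstract scale, error
rates 12/8/4 per category). The noise SDs are not reported anywhere, so
they are back-derived once from the published test statistics — e.g.
a within-group pre→mid difference of 14.15 at p = .004 with n = 13
implies sd(diff) ≈ 14.7 and hence σ_within ≈ 10 for the threshold,
while the between-group t(22) = 2.64 at mid implies a total SD ≈ 13 and
hence σ_between ≈ 8 — and documented in `cohort.py`. The scenario is a
labelled scenario, not data.

Enrolment screening is emulated by redrawing a child's whole block
until the *observed* baseline satisfies the strict cut-offs (reading
score < 71, motion threshold > 34); acceptance depends only on the
pre-session draws, so later sessions keep their marginal distributions.
The null-calibration configuration switches this off to keep the null
exactly Gaussian. `screen_inclusion` also exists as a standalone
operation on any table.

Thresholds can be produced parametrically (clipped latent value) or
mechanistically, by actually running the staircase against a
psychometric observer whose `alpha75` is the child-session latent
value. Mechanistic-mode means sit above the latent values by the
protocol bias discussed earlier (a few percent for steep observers);
the cross-mode consistency test uses slope-6 observers to isolate mode
agreement from that bias.

What the generator does *not* emulate: real Persian reading behaviour,
item-level APRA content, IQ, dropout, practice effects on the reused
test texts, or any correlation between measures beyond the shared group
trajectories. Passing tests therefore demonstrate that the machinery is
correct and calibrated, not that the published effects are true.

## Statistical analysis

The split-plot decomposition is computed from first principles
(`stats.mixed_anova`): between-subjects SS splits into group and
subjects-within-group, within-subjects SS into session, group×session
and session×subjects(group); `F_group = MS_group / MS_subj(group)`, the
two within effects are tested against `MS_session×subj(group)`, and
partial η² = SS_effect / (SS_effect + SS_error-of-that-effect) — which
reduces to the F-only identity `F·df1 / (F·df1 + df2)` used to check
the published effect sizes. SS conservation holds to machine precision
and the table agrees with `pingouin.mixed_anova` (used as an
independent cross-check in the tests, never as the implementation).

Sphericity uses Mauchly's W on the pooled within-group covariance of
orthonormal (Helmert) session contrasts — error df = N − g, the SPSS
convention; pingouin centres on the grand mean instead, which is why
only the ANOVA table, not the sphericity block, is cross-checked
against it — with the standard chi-square approximation, and
Greenhouse–Geisser ε from Box's formula on the same contrast
covariance (bounded by [1/(k−1), 1]). Policy: GG-corrected dfs are
applied when Mauchly rejects at α = .05; both corrected and uncorrected
p-values are always reported. (The source description of when the
correction applies contradicts its own fractional dfs; the fractional
dfs show corrections were applied, so the standard policy is made
explicit and configurable.) Huynh–Feldt ε is deliberately out of scope.

Follow-up tests: paired t within groups across session pairs (signed
mean difference, unadjusted p plus Bonferroni, both labelled);
pooled-variance independent t between groups (df = nA + nB − 2,
matching the reported t(22) with 13 + 11 children; a zero-pooled-
variance separation is reported as an explicit p = 0 edge); and
Mann–Whitney U, exact for nA·nB ≤ 400 without ties, otherwise the
normal approximation with tie correction. Which comparisons get U
tests is an option, not hard-wired, since the source never says.

Degenerate inputs: constant data yields all-zero SS and F reported as
missing; missing cells raise an explicit unsupported-design error (no
imputation); a single group degenerates to the pure repeated-measures
ANOVA (used to verify F = t² at two within-levels).

## Reproducibility and problem sizes

Every stochastic routine takes a seed or a `numpy` Generator. The
pipeline splits its master seed into named per-stage streams via
`SeedSequence(master, spawn_key=(crc32(stage),))`, so adding a stage
never perturbs existing streams; identical config + seed give
byte-identical outputs.

Simulation sizes used by the test suite and the analysis drivers —
200–500 staircases for equilibrium and recovery, 500 null cohorts for
type-I calibration, 40–100 scenario cohorts for the power pattern —
give Monte-Carlo standard errors comfortably inside the stated
tolerances (e.g. ±0.01 on a 0.05 rejection rate at 500 replicates).
Under the default scenario the interaction power is ≈0.87 for the
motion threshold, ≈1.0 for saccade rate and reading accuracy, and
≈0.09 for comprehension, reproducing the qualitative significance
pattern; the two error-count measures sit near 0.4–0.5 and are not
part of that contract.

## Limitations

* The staircase's short-track bias (above) means simulated *absolute*
  thresholds for shallow observers run high; all group/session
  contrasts are unaffected.
* The reading-score scale is abstract: only the cut-off (71) and the
  published deltas anchor it.
* Error counts are independent Poisson draws; real reading errors are
  likely overdispersed and correlated across categories.
* The analysis is the classical split-plot ANOVA, chosen to mirror the
  study; a multilevel model would handle unbalanced or missing data,
  which this package deliberately rejects instead.
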