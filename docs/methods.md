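# Methods

This note documents the models and numerical choices behind
`taskphenotype`: how the tasks are generated and scored, how the
generative participant simulator works, how its defaults were
calibrated, and what the package deliberately does not model.

## Task batteries and scoring

All batteries are pure functions of an integer seed, so an event log
that records its seed can always be re-scored against the exact battery
the participant saw.

**D2.** 20 pages, 42 items each (a 7 × 6 grid). An item is a target
iff it has exactly two dots and a left notch; distractors break the dot
count, the notch side, or both, in roughly equal thirds. The target
count per page is `round(42 × 0.45) = 19`. The respondent moves a
cursor (`nav_left`/`nav_right`, clamped to the page) and marks items;
marking is idempotent. Items processed on a page is `1 + max cursor
index reached`; omissions are unmarked targets within the processed
range; commissions are marked non-targets. `error_rate` is errors per
100 processed items — a rate per item, not per unit time, since logs
are the source of truth for timing and pages are fixed at 15 s.

**DMTS.** 40 trials, 10 per delay (0/1/4/12 s), prompt shown 4.5 s.
Each trial's prompt uses 4 distinct colors and 4 distinct forms from
8-element palettes. The novel distractor replaces both with colors and
forms not used by the prompt (drawn without replacement); the color
distractor combines the novel distractor's colors with the prompt's
forms; the shape distractor the converse. One randomly chosen *shared
quadrant* is identical to the prompt in all four choices, so no single
quadrant identifies the match. Only the first selection is scored
(correct / color error / shape error / both error); selection latency
is measured from choices-on to first selection. The agent (and a real
UI) must keep selecting until the match is found; selections after the
match are log errors.

**SWM.** Six trials with 4, 6, 8, 10, 12, 14 boxes. The token location
per sequence is drawn uniformly among not-yet-emptied boxes — the
adversarial placement of the classic clinical battery is intentionally
not emulated, which keeps placement testable as a uniform draw. A
within error is any re-opening of a box already opened in the current
sequence; a between error is any opening of an emptied box; an open
that is both counts toward both totals by default
(`SWMConfig.double_count_overlap`). The strategy score counts distinct
sequence-starting boxes per trial, summed over trials (range 6–54;
lower = more systematic).

## Careless-responding screens

Three per-scale screens: completion time < 1 s/item (strict), zero
response variance, and response variance more than 3 SD above the
cohort mean variance for that scale (sample variance/SD, thresholds
computed once on the full cohort, strict comparison). A participant is
removed iff any single screen flags more than two of their scales.
Exactly two flagged scales retains the participant. Honest
low-severity responders can legitimately answer a whole scale with the
same category, so some honest removals are expected in realistic
cohorts — perfect recovery is only guaranteed on fixtures where the
violations are far beyond threshold.

## Regression and metric selection

Hierarchical OLS: block 0 is age + gender (male = 1, female = 0),
block 1 the task metrics; missing data are dropped listwise. The block
contribution is ΔR² with
`ΔF = (ΔR²/m) / ((1 − R²_full)/(n − k_full − 1))`. Standardized
coefficients are `beta = B·sd(x)/sd(y)`; multicollinearity is screened
with `VIF_j = 1/(1 − R²_j)`. Both local effect-size conventions are
reported: `ΔR²/(1 − R²_full)` (Cohen) and `ΔR²/(1 − ΔR²)`.

Metric selection mirrors the validation analysis: measures that
individually improve on demographics (block F test, p < 0.05) enter a
correlation-matrix PCA; the top three components are rotated with
direct oblimin at γ = 0 (quartimin) so components may correlate. The
rotation uses the gradient-projection algorithm for oblique rotation
with Kaiser row normalization, run from the identity plus five seeded
random starts, keeping the solution with the lowest criterion — the
quartimin criterion is non-convex and a single start occasionally lands
in a local minimum. Oblique rotation preserves communalities, so
uniquenesses are computed before rotation. Each component is attributed
to the task holding the majority of its absolute pattern-loading mass
(the attribution must be one-to-one or selection fails loudly), and the
highest-loading measure per task enters the combined model.

## Generative participant model

Each simulated participant has a latent severity `s ~ N(0, 1)`.

* **PHQ-9**: graded response model; item score = number of thresholds
  `τ = (0.55, 2.0, 3.3)` passed by a logistic comparison with
  discrimination 2.0 and per-item scatter 0.3. Expected total is
  strictly increasing in severity.
* **Behavioral parameters** are logistic in
  `base + slope·s + scatter·z`, `z ~ N(0,1)` per participant:
  D2 omission and commission lapse rates (slopes +0.45/+0.5), DMTS
  memory fidelity logit (slope −0.5, decaying 0.09 logit/s of delay),
  SWM between/within per-open error propensities (+0.25/+0.6, jointly
  capped at 0.65 per step by proportional scaling so search sequences
  stay finite), strategy discipline (−0.6) and novelty preference for
  sequence starts.
* **Agents** then play the real batteries: the D2 agent paces ~21
  items per 15 s page; the DMTS agent's first selection is correct with
  the delay-dependent fidelity, errors split (0.23, 0.58, 0.19) among
  color/shape/both, then forced continuation to the match; the SWM
  agent searches with the per-open error propensities, deliberate
  sequence starts, and lognormal latencies. Perfect-agent parameters
  (zero lapses, fidelity ≈ 1) score zero errors by construction.
* **Careless responders** (optional fraction, equal style mix):
  speeders (< 1 s/item), straightliners (constant answers), and random
  clickers (maximal-variance alternation of extreme categories, clicked
  through fast — on a bounded scale the alternation variance is capped,
  so speed, not variance, is the unconditional violation).

All randomness descends from one root generator per cohort; identical
`(config, seed)` reproduce cohorts exactly.

### Calibration

Defaults were chosen so that a default cohort's metric means/SDs land
near the validation cohort's descriptive statistics (PHQ-9 ≈ 7 ± 7,
D2 total errors ≈ 43 ± 53, DMTS correct ≈ 32 ± 6.5, SWM within
≈ 20 ± 38, strategy ≈ 40 ± 8) while keeping every severity link
correctly signed. Calibration constants live in `SimConfig`, not in
code. The simulator is a test harness embodying the premise that
depression impairs attention and working memory; it is not a cognitive
process model (no drift-diffusion dynamics, no comorbidity structure).

## Recovery simulations

`simulate_from_fitted_model` is the generative twin of a fitted linear
model: predictors drawn independently (normal with recorded moments;
Bernoulli gender), outcome = linear combination + Gaussian noise with
the recorded residual SD. Refitting at n = 20,000 recovers each
published coefficient within 3 Monte-Carlo standard errors
(`scripts/acceptance.py`). Independence of predictors is a deliberate
simplification — it leaves coefficient recovery exact while ignoring
the real predictor correlations, so recovered standard errors are not
comparable to the published ones.

## Limitations

* The published human-data R² (0.344 on n = 90) is not reproducible
  without the raw data; validation is via structural constants,
  recomputation of printed statistics from printed R² values, and
  parameter recovery on simulated data.
* The SWM token placement is uniform, not adversarial; between-error
  counts are therefore somewhat lower than a clinical battery would
  produce at equal ability.
* Auxiliary scales (anxiety, affect, sleep) exist only so the
  "more than two scales" filter rule is meaningful; their content is
  not modeled.
* The χ²/normed-fit indices sometimes reported alongside PCA solutions
  are not implemented; component attribution and selection do not need
  them.
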