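# Methods

## The task and the model

`splitbelt` simulates and analyses a two-alternative forced-choice (2AFC)
experiment in which a person walking on a split-belt treadmill judges which
belt moves slower. The stimulus is the signed belt-speed difference
ΔV = V_R − V_L (mm/s at the I/O boundary, m/s internally) around a mean
speed of 1.05 m/s. Each trial yields a choice ("left"/"right" slower, or a
non-response) and a reaction time (RT, seconds from the start cue).

Two linked descriptions of behaviour are implemented:

**Psychometric (choice) level.** The probability of a "left slower" response
is logistic in the stimulus,

    p(left | ΔV) = 1 / (1 + exp(−(β0 + β1 ΔV)))

From the two coefficients follow the point of subjective equality
PSE = −β0/β1 (the stimulus judged equal, a bias measure), the
just-noticeable difference JND = ln(3)/β1 (half the distance between the
25% and 75% choice-rate stimuli), and the Weber fraction
WF = 100·JND/v̄ with v̄ the mean belt speed.

**Process (drift-diffusion) level.** Evidence x(t) accumulates as a Wiener
process with drift, dx = r·dt + σ·dw, between absorbing barriers ±a
(a ≡ 1 by scale invariance). The barrier hit determines the choice and the
hit time t_d the decision time; RT = t_d + t_nd with t_nd a
stimulus-independent non-decision latency (encoding + motor). The drift is
linear in the stimulus through r = −(σ²/2)(β0 + β1 ΔV), which makes the
barrier-choice probability exactly the logistic above and gives the mean
decision time in closed form,

    E[t_d] = (a/r)·tanh(r·a/σ²)  →  a²/σ²  as r → 0.

Because E[t_d] depends only on |r|, mean RTs across stimuli identify
(t_nd, σ, β0, β1) up to the sign of β1; fitting mean RTs alone therefore
predicts the full psychometric curve, with β1 constrained non-negative
(observers answer more accurately for larger stimuli, not less).

### Sign convention

The published closed forms for this task carry a sign ambiguity (the same
RT curve arises from ±β1, and the barrier-probability formula can be read
with either drift sign). We fix it once: the choice level
p(left) = logistic(β0 + β1 ΔV) is authoritative; the walk's drift is
r = −(σ²/2)(β0 + β1 ΔV); and in the simulator the *lower* barrier carries
the "left" label, which the walk reaches with probability exactly p(left).
RT predictions are unaffected (E[t_d] is even in r).

## Simulator

Trials are simulated by Euler–Maruyama with step dt = 1 ms (configurable),
plus the standard Brownian-bridge correction for within-step barrier
crossings: after each step an unabsorbed walker is absorbed with probability
exp(−2(a−x₀)(a−x₁)/(σ²dt)) at the upper barrier (mirrored for the lower).
Plain Euler under-absorbs with an O(√dt) bias that is visible against the
closed forms at 10⁵ trials; with the correction, hit fractions and mean
decision times at 2|r|/σ² ∈ {0, 1, 2, 4} agree with the closed forms within
3 standard errors (tested). A hard cap of 10⁶ steps guards non-termination;
when a response window is supplied, walkers still unabsorbed at the window
are censored (choice "none", RT missing).

## Protocol

A testing block presents the 12 signed non-zero stimuli
(±25, ±50, ±100, ±150, ±200, ±300 mm/s) 4× each and the null stimulus 8×,
i.e. 56 trials, built as four variants (base, mirrored, order-flipped,
both) of a seeded 14-trial pseudo-random pass; positive and negative
stimuli are balanced by construction and the stimulus order is identical
across subjects. Three blocks per subject; the first trial of each block
follows a treadmill break and is flagged `first_after_break`.

A 39-subject cohort therefore has 56 × 3 × 39 = 6,552 trials. Note a design
tension: dropping the flagged first trials while also keeping exactly 4
repetitions per magnitude would require re-presenting the first stimulus at
the block's end (57 presentations). The default keeps 56-trial blocks so
cohort-level counts are exact; `build_protocol(append_first_trial_repeat=True)`
provides the count-preserving 57-trial variant.

## Synthetic cohorts

Subjects are drawn from a Gaussian population over (β0, β1, σ, t_nd) with
β1, σ truncated positive and t_nd at zero — the same Gaussian-heterogeneity
assumption the mixed model makes. Defaults: β0 ~ N(0, 0.4²);
β1 ~ N(22.1, 8²) per m/s (mean chosen as ln 3 / 49.7 mm/s so the population
mean JND is ~50 mm/s, SD chosen to give a JND spread of roughly ±23 mm/s);
σ ~ N(0.5, 0.1²); t_nd ~ N(0.9, 0.7²) s. The response window is 8 strides
≈ 8 s.

What the generator emulates: logistic choice behaviour, chronometric RT
curves peaking at the PSE, subject heterogeneity, window censoring, and the
protocol's exact trial accounting. What it does not: stride-by-stride belt
dynamics, perceptual adaptation, lapses/guessing, or realistic non-response
rates — with the default population the first-passage tail of slow subjects
censors ~10% of trials, far more than the ~0.2% a practiced human cohort
shows. Green recovery tests therefore establish estimator correctness under
the stated model, not realism of the censoring process;
`plant_nonresponses` builds the observed 16-of-6,552 pattern on an
uncensored table for testing the removal accounting.

## Preprocessing

Choices are coded 1 = left, 0 = right; accuracy is 1 when the choice names
the truly slower belt (ΔV > 0 ⇒ left slower), undefined for null trials and
non-responses. Exclusions — non-responses and first-after-break trials —
are flagged, never dropped (row conservation is an invariant), with
`first_after_break` taking precedence so each excluded row has one reason.
The non-response percentage is quoted against the full trial count.
Summaries average within subject over included trials; per-signed-stimulus
(13 levels) and pooled-|ΔV| (7 levels) tables are both provided.

## Fitting

**Per-subject logistic.** Newton–Raphson maximum likelihood on
choice ~ ΔV. Complete separation (a deterministic observer) is detected by
the threshold criterion on the single predictor; the fit then falls back to
a weak ridge (λ = 10⁻⁴) on β1 only and is flagged. CIs are Wald. The PSE CI
propagates the β0 interval holding β1 fixed; the JND CI maps the edges of
β1's interval through ln 3 / β1 (skewed; unbounded above if the interval
touches zero).

**Mixed logistic.** Random intercept + random slope per subject,
independent Gaussian components (no correlation parameter — not
identifiable here and not assumed). The marginal likelihood is maximized
under a Laplace approximation: an inner 2-D Newton per subject finds the
random-effect mode, the outer L-BFGS-B optimizes fixed effects and log-SDs;
SEs come from the numerical Hessian of the marginal log-likelihood. The
implementation reproduces lme4::glmer (nAGQ = 1) to <0.1% on a frozen
reference dataset (tested). The exogenous-factor variant adds fixed
regressors ΔV_prev (habituation), ΔV × block₂ and ΔV × block₃ (task
learning), and |ΔV| (laterality); block-first trials are excluded from
analysis, so every fitted row has a genuine previous stimulus and no
missing-indicator is needed.

**Chronometric DDM fit.** Unweighted least squares of
t_nd + E[t_d](ΔV; σ, β0, β1) against the 13 per-signed-stimulus mean RTs
(responded trials only; nulls included — the r→0 value t_nd + 1/σ² pins σ).
Bounds: t_nd ∈ [0, min RT], σ > 0, β0 free, β1 ≥ 0. Six deterministic
multi-starts (t_nd ∈ {0, ½·min RT} × σ ∈ {0.25, 0.5, 1}) with the best-RSS
winner; trust-region-reflective least squares at tight (1e-14) tolerances.
Noiseless curves are inverted to ≤10⁻³ relative error in all four
parameters (tested); a fitted curve with no stimulus signal (range <1 ns)
pins β1 = 0 and is flagged flat. An inverse-variance weighting option
exists but is off by default. Censoring is ignored in the fit: removing
slow trials flattens the observed chronometric curve, which biases the
RT-based JND upward at the default population's ~10% censoring — visible
in the recovery study and deliberately not corrected.

## Numerical choices

- Logistic and tanh forms are evaluated in numerically stable branches;
  E[t_d] switches to its Taylor series for |ra/σ²| < 10⁻⁴ (continuity at
  r = 0 holds to <10⁻⁶).
- All randomness flows through numpy Generators seeded at the entry point;
  pipelines are byte-identical under a fixed seed (tested).
- Units: mm/s in all CSV/CLI interfaces, SI internally; Weber fractions in
  percent; α = 0.05 throughout.

## Known limitations

- No lapse/guessing parameters, biased start points, collapsing bounds, or
  across-trial drift variability; the DDM is the 4-parameter symmetric case.
- The RT-based fit uses mean RTs only (no quantile or full-distribution
  fitting), so per-subject estimates at 4–8 trials per stimulus are noisy;
  the recovery study quantifies rather than hides this.
- Wald inference throughout; no profile or bootstrap intervals.
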