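# Methods

This note documents the models, algorithms and numerical choices behind
`convkin`, and what the synthetic-data validation does and does not
establish.

## 1. The analysis model

The unit of analysis is one (utterance × articulator × 300 ms bin) feature
value. For each articulator a ∈ {torso, head, hands} and feature
f ∈ {magnitude, lateral position, A/P position, peak velocity}, we compare

- **null model**: `f ~ time_bin + duration_z + (random terms)`
- **model of interest**: `f ~ time_bin + duration_z + category + (random terms)`

both fitted by **maximum likelihood** (not REML), so the likelihood-ratio
statistic 2·(LL₁ − LL₀) is χ²-distributed under the null; with the six-level
category predictor the df is 5. Time bin is coded categorical (3 levels):
nothing forces kinematic profiles to be linear across bins. Utterance
duration is standardized internally (z-score over the analyzed rows); this
affects nothing in the tests or contrasts but keeps the optimizer
well-conditioned.

**Random structure ladder.** Candidate structures, most to least complex:

1. dyad intercept + participant-within-dyad intercept + participant×category
   component ("slope");
2. the same without the slope;
3. participant intercept + participant×category component;
4. participant intercept only.

The first rung that converges without a singular fit is retained and used
*identically* for the null and interest models of that cell, so the LRT df is
the fixed-effect difference (5). A fit is singular when any random-effect
variance falls below 1e-6 of the residual variance. Rungs 1–2 are skipped
when dyads do not contain two participants.

The "random slope" is parameterized as a single-variance
participant×category variance component — the `(1 | participant:category)`
form — rather than a full 6×6 random-slope covariance. The full covariance
adds 20 parameters that are weakly identified at desk scale and very costly
in `statsmodels`' per-group algorithm; the single-variance form captures the
phenomenon the ladder is probing (does the category effect vary by
participant?) at one parameter.

**Deliberate pseudo-replication.** Each utterance contributes three bin rows
but no utterance-level random intercept is fitted — the random terms are
exactly the dyad/participant ones. This is a fidelity choice: it mirrors the
modeling convention of the analysis this package operationalizes. Its type-I
consequences depend on the within-utterance residual correlation; see §4.

**Post-hoc contrasts.** When the omnibus p < α (default 0.05), all C(6,2)=15
pairwise contrasts of estimated marginal means are computed, covariates held
at their observed means (so a contrast reduces to the difference of category
coefficients). z-ratios use the asymptotic fixed-effect covariance; the
familywise adjustment is the studentized-range (Tukey) method with k = 6 and
infinite df, p = P(Q₆,∞ ≥ √2·|z|). With z rather than t statistics the
adjustment is asymptotic, appropriate at thousands of rows.

**Numerical optimization.** The profiled ML surface over the variance
parameters has near-boundary plateaus on which quasi-Newton optimizers
(l-bfgs, bfgs, cg) reliably stall at poor points while reporting
convergence — producing, for nested model pairs, inconsistent optima and
therefore negative or wildly inflated LRT statistics. The fitting protocol
is therefore: Powell first (derivative-free, handles the plateaus), warm
start from a related fit's variance estimates where one exists, the null
model warm-started from the interest fit, and a repair step — if a local
optimum leaves LL₀ > LL₁ (impossible at the true optima of nested models),
the interest model is refit from the null solution and the better fit kept.
This protocol was validated by null-simulation: across replicate zero-effect
corpora the omnibus p-values are uniform and the α = .05 rejection rate is
nominal (see the acceptance tests).

## 2. Feature extraction

Tracks are linearly resampled onto a uniform grid anchored at utterance
onset: with the default −300/+600 ms window and 30 Hz, 27 frames in three
half-open bins of 9 frames. Grid points outside the track span, or bridging
a gap of more than twice the nominal frame interval, are flagged invalid. A
bin is usable when ≥ 60% of its expected frames are valid; below that the
row is flagged and excluded from modeling (never silently used). Optional
smoothing (centered moving average, width 3) is off by default.

- **Magnitude** (mm): max Euclidean distance from the bin's first valid
  frame. Invariant to rotation about the bin origin and to translation;
  homogeneous of degree 1 in displacements.
- **Lateral position** (mm): max |x − x_center|. The center is the
  calibration midline when the recording provides one, otherwise the
  articulator's x at the window start (a window-local reference). Which
  convention was used is recorded per run.
- **A/P position**: per frame, proximity = position · interlocutor axis
  (unit vector toward the interlocutor; default (0,0,−1) in a
  participant-frontal device frame); the bin summary is the **maximum**
  (most proximal point), chosen for symmetry with magnitude over the
  endpoint value. Larger = closer throughout. The source convention is
  internally contradictory on this point (it describes larger values as
  closer but aggregates hands by the "minimum (most proximal)"); this
  package standardizes **larger-is-closer** everywhere and selects the more
  proximal hand.
- **Peak velocity** (cm/s): max over consecutive valid frame pairs of
  ‖Δp‖·f_s — the derivative of absolute displacement, hence nonnegative.
  Argmax ties resolve to the earliest pair.

**Hands channel**: per bin, magnitude/lateral/velocity take the max of the
two hands, A/P the more proximal (larger) value; if one hand is missing the
other carries through with a flag.

**Proximity rescaling**: within each articulator, A/P values are centered
and divided by their sample SD (ddof = 1) before modeling. Raw projections
sit near −1.9 m with millimeter-scale variance; the mean is the
participant-device distance, carries no utterance-level information, and is
absorbed by the model intercept, while the raw scale destroys optimizer
conditioning. `scale_proximity(..., center=False)` gives the divide-only
variant. Post-scaling SD is 1 by construction.

All internal units are SI (meters, seconds); conversion to mm and cm/s
happens only in the feature extractors, and annotation times are ms from
recording start. Time intervals are half-open `[start, end)` throughout.

## 3. The synthetic corpus generator

Each of `n_dyads` dyads contributes two participants; each participant's
recording holds four articulator tracks at 30 Hz (resting position +
isotropic Gaussian jitter, default SD 2 mm — the scale of consumer depth
sensor noise) and `utterances_per_participant` question utterances.

**Durations** are log-normal with the median fixed at `duration_median_ms`
(default 1114 ms) and shape σ solved in closed form from the target IQR
(default 1138 ms): with r = IQR/median, e^{zσ} − e^{−zσ} = r at z = z₀.₇₅
gives σ = ln((r + √(r²+4))/2)/z₀.₇₅ ≈ 0.728. Draws are clamped to
[99, 13145] ms. A zero IQR degenerates to the constant median. The law is
right-skewed, matching the quartile/median geometry of conversational
question durations.

**Categories** are drawn i.i.d. from `category_weights`; the default weights
are proportional to the question counts of the reference corpus the
generator emulates (693 : 365 : 360 : 246 : 126 : 161 : 74 : 53 over
InfReq…PlanAct, 2078 questions in total). SIMCO and PlanAct flow through
extraction but are flagged and excluded from modeling.

**Movement bursts.** Every utterance produces one burst per analysis
articulator (for the hands, on one hand chosen by a fair coin; the other
hand carries only baseline jitter). A burst is a Gaussian-profile
displacement g(t)·**D** with nominal duration ~ U(300, 900) ms (σ_t =
duration/6) centered uniformly in [onset − 200, onset + 400] ms, so the
analysis window catches bursts at varying phases — movements may begin
before or after speech onset. The displacement **D** sums a main component
(amplitude, random direction in the lateral-vertical plane), a lateral
component pushed away from the body midline, and an interlocutor-directed
component. Peak speed is |**D**|·e^{−1/2}/σ_t; a velocity effect is injected
by narrowing the profile to hit the target speed, leaving |**D**| unchanged.

Burst parameters are **deterministic given (category, participant, dyad)**:
parameter = articulator baseline + `effect_table[(category, articulator,
feature)]` + participant offset + dyad offset, the offsets being normal with
per-feature SDs (`participant_sd`, `dyad_sd`). Per-utterance randomness
enters only through burst timing, hand choice and frame noise. This matters:
with no utterance-level parameter noise, the within-utterance residual
correlation of bin features is small and mixed-sign (timing shifts burst
mass *between* bins), which is what keeps the bin-level model of §1 — which
has no utterance random intercept — calibrated under the null. Injecting
utterance-level amplitude noise would break that calibration, and a user who
adds it should also add an utterance-level random term to the model.

Baselines (amplitude/lateral/proximal, mm): torso 6/2/2, head 10/3/3, hands
35/8/8 — subtle postural shifts for torso and head, clearly larger free-hand
movements, in line with seated conversation where printed torso effects are
sub-millimeter. Default random-offset SDs: participant 1.5/1.0/1.0/1.0 and
dyad 0.8/0.5/0.5/0.5 (magnitude/lateral/ap/velocity; mm or cm/s).

**Effect cross-talk (by design).** An amplitude effect enlarges the whole
burst, so it also raises lateral excursion and peak speed — larger movements
are laterally larger and faster, as in real motion. Effects on lateral, A/P
and velocity are channel-specific. Tests of effect recovery therefore check
the *injected* cell, not the orthogonality of the others.

**What the generator does not emulate**: tracking drop-outs and occlusions,
sensor clock drift, utterance-to-utterance amplitude variability beyond
timing, gesture form and handedness preferences, interpersonal synchrony,
and any coupling between category and utterance duration. Passing tests
therefore show that the pipeline recovers effects *of the modeled kind* at
realistic noise levels — not that real corpora satisfy the model.

## 4. Validation design and problem sizes

The test suite validates, at desk scale chosen to keep the full suite in the
tens of minutes on one CPU:

- **Feature oracle equivalence**: all four features vs an independent
  loop-based oracle, 1000 random 9-frame trajectories, tolerance 1e-9.
- **Type-I calibration**: 300 zero-effect corpora at 20 dyads × 60
  utterances/participant; torso-magnitude LRT rejection at α = .05 must lie
  in [0.03, 0.08], and the p-values must pass a KS uniformity test. This is
  the direct check that the no-utterance-intercept model is calibrated
  against this generator (§1, §3).
- **Effect recovery**: +0.5 SD StanSem torso-magnitude effect at ~2000
  utterances, 100 replicates; the omnibus must be significant with the
  correctly-signed top StanSem contrast in ≥ 80. The injection is expressed
  on the *feature* scale: the amplitude offset is 0.5·SD(feature) divided by
  the measured amplitude→feature transfer coefficient (window capture
  attenuates amplitude offsets by roughly 3×).
- **Analytic structure**: df = 5 for every six-level comparison; 15
  contrasts per family; Tukey p ≥ unadjusted p.
- **Sync recovery**: offsets in [−3, 3] s at 16 kHz and 10 dB SNR recovered
  within one sample, 100 trials.
- **Duration law**: empirical median within 5% at n = 6778; IQR within 10%
  at n = 10⁴ against the analytic quantile solve.
- **Independent model oracle**: one LRT cell is cross-checked against
  `lme4::lmer` + `anova` through Rscript.

`scripts/acceptance.py` recomputes headline quantities from scratch at sizes
chosen for a few minutes' runtime (60-replicate calibration, 25 sync trials,
one recovery corpus); the suite's heavier versions are the authority.

## 5. Known limitations

- The Tukey adjustment uses z-ratios (infinite df); at small corpus sizes a
  Kenward-Roger or Satterthwaite t-based family would be less liberal.
- The LRT for the category effect is clean (df = 5, fixed effects only), but
  the ladder can retain a slope component whose variance is near zero; the
  comparison remains valid since both models share the structure.
- The audio-offset estimator assumes a constant offset (no drift) and mono
  streams at a common rate; sub-sample offsets are not interpolated.
- `mode="real"` expects the repo's CSV schema or time-aligned EAF tiers;
  reference (symbolic) EAF tiers are out of scope.
- Proximity values are comparable only within an articulator after SD
  scaling; cross-articulator A/P effect sizes are not interpretable.
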