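# Methods

This note documents the models, algorithms and numerical choices behind
`mrlap`, the parameters that matter, and what the synthetic validation does
and does not establish.

## The hemodynamic model

During systole a mitral-regurgitation jet carries blood from the left
ventricle (LV) into the left atrium.  The simplified Bernoulli relation maps
jet velocity `V` (m/s) to the instantaneous transvalvular pressure
difference, `ΔP = 4V²` (mmHg), so the LV pressure seen by the jet is
`P_LV = LAP + 4V²` with the left atrial pressure LAP treated as constant
over the beat.  During isovolumic relaxation, LV pressure decays
mono-exponentially (the Weiss model) with time constant τ:
`P_LV(t) = P_ref·exp(−(t−t_ref)/τ)`, with `t_ref` the instant of peak
pressure fall (−dP/dt max).  At any instant, τ = P/(−dP/dt).

On the descending branch of the CW-Doppler envelope, the crossing times
`t3 < t2 < t1` of 3, 2 and 1 m/s correspond to pressure offsets of 36, 16
and 4 mmHg above LAP, giving the two-interval system

    τ·ln[(LAP+36)/(LAP+4)] = t1 − t3
    τ·ln[(LAP+16)/(LAP+4)] = t1 − t2.

Only interval differences enter, so the time origin is arbitrary.  The
sphygmomanometer estimate is `LAP_BP = P_sys − 4·V_peak²`, substituting
arterial systolic pressure for LV systolic pressure; it is exact only when
the measured peak velocity is the true peak velocity, which fails for
eccentric jets (measured velocity scales with the cosine `c` of the
beam–jet angle).  The equation method is insensitive to a *constant*
velocity scale error only to first order — a scale factor shifts the
effective offsets to 4/c², 16/c², 36/c² — but its bias stays small: at
c = 0.9 and LAP = 10 mmHg it is ≈ −2 mmHg, against ≈ +18 mmHg for LAP_BP at
a 4.9 m/s jet.

## Solving the interval system

Dividing the two equations eliminates τ and leaves the ratio map
`g(L) = ln[(L+36)/(L+4)] / ln[(L+16)/(L+4)]`, strictly increasing on
L ≥ 0 with `g(0) = ln9/ln4 ≈ 1.58496` and supremum `8/3` (the ratio of the
offset differences).  A measured ratio `r = (t1−t3)/(t1−t2)` therefore
admits exactly one non-negative root when `r ∈ [ln9/ln4, 8/3)` and none
otherwise; infeasible ratios raise a dedicated error rather than returning
a clamped value.  The root is found by bisection (guaranteed convergence on
a bracket) with absolute tolerance 1e−8 mmHg and a 200-iteration budget.
The default bracket is [0, 200] mmHg; because `g(200) ≈ 2.549 < 8/3`, a
feasible ratio can imply a root above 200, in which case the bracket is
doubled (up to 1e7) so the operation's contract holds for every feasible
ratio.  Ratios within 1e−9 of a boundary are treated as the boundary.
τ is then recovered from the t1−t3 equation.  Round-trip accuracy against
the forward model is ≤ 1e−4 mmHg / 1e−6 s over LAP ∈ [2, 40] × τ ∈
[0.02, 0.12] (verified in the acceptance suite).

## Envelope extraction

**Detection.**  A global threshold separates jet from background — Otsu's
bimodal-histogram criterion by default, with an absolute-value policy and a
fraction-of-maximum fallback for degenerate histograms.  Per column, the
outermost above-threshold pixel on the jet side marks the coarse edge; the
edge is then localised at sub-pixel precision by interpolating where the
intensity falls through half the median jet fill level between the
bracketing rows.  On a blurred edge this recovers the edge nearly exactly;
on a hard binary edge it reduces to the bin-centre (row + ½) estimate,
which is the unbiased choice under pure quantisation.  Columns with no
signal, or whose signal reaches the grid boundary (unresolvable edge), are
flagged invalid.

**Refinement.**  The coarse trace is refined by a robust weighted
least-squares piecewise-polynomial (B-spline) fit acting on the *squared*
velocity.  The squared domain is the pressure domain (ΔP = 4V²): `v²(t)`
relaxes smoothly, whereas `v(t)` itself steepens without bound as the jet
dies out (square-root behaviour), which defeats any fixed-resolution fit in
velocity space near the end of the descent.  So that every velocity-domain
polynomial of degree ≤ `degree` is reproduced exactly, the spline order is
`2·degree` (default degree 3 → order 6), with interior knots every 6 ms
spanning the trace's full time range.  Weights `1/max(v, 0.5)²` whiten the
pixel-quantisation noise, which squaring scales by `2v`.  Outliers are
rejected over two passes at 3× the scaled MAD of the whitened residuals,
rejecting at most the worst 5 % of columns per pass — a cap that lets
isolated dropouts and spikes go while preventing structured approximation
error from cascading into wholesale rejection.  Invalid and rejected
columns receive the fitted value (bridging "fractured" columns) but stay
flagged.  Because the knot set depends only on the time axis and the fit is
a projection, refinement is exactly idempotent; beyond the observed column
range the fit is extended with its boundary value rather than extrapolated.

**Calculability rules.**  An envelope is calculable only if its peak
reaches 3 m/s and the descending branch is complete: after the global peak
it must fall through 1 m/s, and over the measured segment — from the first
downward crossing of 3 m/s to the first crossing of 1 m/s — it may never
rise more than 0.15 m/s above its running minimum.  The band absorbs
residual roughness; the region at the peak itself is exempt because
flat-top velocity plateaus are physiological.  Non-calculable envelopes
yield an error naming the violated rule, never a number.

**Timing.**  Crossing times at 3, 2, 1 m/s are the first downward crossings
after the global peak, localised by linear interpolation between bracketing
columns (sub-frame precision; earliest crossing wins on re-crossings).

## Synthetic data

The generator emulates the clinical acquisition end-to-end with exact
ground truth.  Per patient: LAP uniform on [7, 29] mmHg (the range-based
sampling the cohort configuration defines), τ uniform on [0.03, 0.08] s,
radial systolic pressure uniform on [96, 119] mmHg, true peak velocity
Bernoulli-consistent (`√(P_sys − LAP)/2`, ≈ 4.1–5.3 m/s).  The case mix is
10/28 CABG+rheumatic and 7/28 MVP A2/P2 (central jets, c = 1) and 11/28 MVP
P1/P3, whose eccentric jets scale measured velocity by c ~ U[0.85, 0.95]
(pure multiplicative model; no jet-geometry simulation).  Atrial
fibrillation (12/28 of cases) is modelled solely as ±10 % beat-to-beat
jitter of τ and the velocity cap.

The envelope rises along a half-cosine LV pressure ramp over 0.1 s (a
rendering choice only — nothing before the peak enters the method), decays
along the Weiss model until `P_LV ≤ LAP + 1` mmHg, and is sampled at
dt = 1 ms.  Rendering fills pixels (dv = 0.02 m/s/row) between baseline and
envelope, applies a 2-pixel linear edge taper centred on the true edge
(beam-spread blur), unit-mean gamma speckle with variance 0.1, and additive
Gaussian background of σ = 0.02 of full scale.  Catheter readings are
unbiased Gaussian around true LAP (σ = 2 mmHg); arterial readings likewise
(σ = 3 mmHg).  All noise levels are configurable; the defaults were chosen
to make recovery nontrivial but stable.  Randomness flows from one master
seed through per-case child seeds, so any case regenerates bit-identically
from its seed record.

"Noiseless" validation conditions switch off the stochastic components —
speckle, background, catheter/arterial noise, and the AF beat jitter —
while keeping the deterministic edge taper, which is part of image
formation.  What passing synthetic tests shows: the pipeline inverts its
own generative model to ≤ 1 mmHg (noiseless) and ~0.7 mmHg median error
(default noise).  What it does not show: robustness to scanner-specific
display processing, wall-filter artefacts, ECG overlays or genuinely
ambiguous clinical envelopes, none of which the renderer emulates.

## Comparison statistics

Paired t (classical closed form; zero-variance differences reported as
degenerate limits, not NaNs), Pearson r with Fisher-z 95 % CI
(`tanh(atanh r ± z/√(n−3))`), the consistency rule (|estimate − reference|
/ reference < 10 %, strict, reference in the denominator), Pearson χ² on
the 2×2 consistency × disease-composition table (Yates-corrected by
default, uncorrected selectable — standard at n ≈ 28 with small expected
counts), tie-corrected rank-sum tests for continuous covariates between
consistency groups, and ICC(2,1) (two-way random effects, absolute
agreement, single measure) from the mean-squares decomposition, with
degenerate grids handled explicitly.  No multiplicity correction is
applied; the significance level is 0.05.  The cohort report assembles one
section per method pair (equation vs catheter, sphygmomanometer vs
catheter).

## Numerical margins and problem sizes

Validation problem sizes were chosen to characterise the estimator
stably on a single CPU in minutes: 220-cell solver round-trip grid,
50-case noiseless and 100-case noisy cohorts for pipeline recovery,
200 draws for the eccentricity ordering, 2 000 replicates for test-size
calibration, and 20 × 100-case cohorts for the agreement study (observed:
r ≥ 0.85 in all seeds, median r ≈ 0.91).

## Known limitations

- At coarser time sampling (dt = 2 ms) worst-case noiseless recovery error
  grows to ~1–2 mmHg on hard-edged (untapered) renders: half the columns
  and no sub-pixel gradient information.
- Accuracy degrades intrinsically at high LAP with short τ: the intervals
  shrink (d12 ≈ 10 ms) while the LAP-vs-ratio sensitivity grows (~1 mmHg
  per 1 % ratio error at LAP ≈ 30), so timing errors amplify.  This is a
  property of the method, not of the implementation.
- The equation method requires a clean descending branch between 3 and
  1 m/s; envelopes failing the calculability rules are skipped by design.
- Eccentricity is a pure velocity scale factor; real eccentric jets also
  change the spectral texture, which is not modelled.
- The consistency-rule denominator and the exact test variants behind the
  subgroup statistics are conventions (documented above); alternative
  choices are selectable but not defaults.
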