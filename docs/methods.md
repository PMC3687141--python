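# Methods

`spiralfield` synthesizes the contour-in-clutter stimuli of a classic
visual-psychophysics "path paradigm" study — a spiral of collinear Gabor
micropatterns hidden in a field of distracter Gabors — simulates the
three experimental sessions (and a preliminary distracter-free
staircase) against synthetic observers, and analyzes the resulting 4AFC
records with the study's statistical chain.  This note documents the
model choices, the parameters that matter, and what the simulations do
and do not establish.

## Spiral geometry and the angular-scale calibration

The contour follows an equiangular (logarithmic) spiral

    r(t) = a · exp(b·t),   θ(t) = κ·t,   t ∈ (t_min, t_max)

with a = 1.18°, b = 0.20, t ∈ (1.25, 3).  Only the radius law is a
published stimulus constant; the mapping from the path parameter to the
polar angle is not, so the angular scale κ (rad per t-unit) is a free
parameter of the reconstruction.  We calibrate it once, on a single
condition: κ is the midpoint of the interval for which the 2λ spacing
condition (0.6°) holds exactly 26 elements, giving κ ≈ 4.815 rad/t.  The
element counts at the other three spacings — 13, 9 and 7 — then follow
from the geometry with no further freedom and hold across the entire
calibration interval ([4.725, 4.905]), so the reconstruction is not
knife-edge.

Elements are placed at equal increments of **arc length** along the
path, using the closed-form inverse of the spiral's cumulative length
(L(t₀,t) = C·(e^{bt} − e^{bt₀}), C = (a/b)·√(κ²+b²)).  We verified that
the alternative — stepping by equal Euclidean chord distance — cannot
reproduce the published element counts under any κ: the κ-interval
giving 26 elements at 2λ and the interval giving 7 at 8λ are disjoint.
The published counts are instead exactly consistent with arc-length
stepping, which is therefore what the generator does.  Chord
(center-to-center) distances sit below the nominal spacing by the
sagitta factor — under 1% at 2λ, about 10% at 8λ — and drift slowly
(a few percent) along a chain as the local curvature radius grows.

The per-trial start jitter t_j ~ Uniform(−0.1, 0.1) shifts the whole
chain along the path (first element at t_min + t_j); the element count
at 2λ then varies by ±1, matching the "approximate" published totals.
The canonical spiral is phase-aligned so its tail (outer end) lies on
the +x axis; reflections about the vertical axis produce clockwise
spirals and quarter-turn rotations permute the four response sectors
(right → up → left → down for CCW steps).  Tail labels are a
deterministic function of (reflection, rotation).  The spiral's long
axis under this calibration is ≈ 4.1°, not the published "≈ 6.9°"; that
printed value is not jointly satisfiable with the printed radius law,
parameter range and element counts under any single angular scale, and
we keep the counts, which gate the stimulus statistics.

## Distracter fill

Distracters are placed by random sequential adsorption: uniform
candidate positions in the 9.5° square are accepted iff they keep at
least d_min from every element already present (contour included), and
the fill stops after 10,000 consecutive rejections — the operational
reading of "no more elements can be placed".  Achieved densities sit at
the RSA saturation level for discs of diameter d_min (≈ 175 distracters
at d_min = 0.6°, against an RSA bulk prediction of ≈ 175 and a published
approximate total of 240; the published totals are not reachable by any
plain rejection-sampling process and are documented, not forced).  Two
empirical caveats measured here: (1) a 10k-rejection stop leaves a
residual acceptance probability of order 10⁻⁴ per fresh candidate, not
10⁻⁶ — near-saturation, not saturation; (2) mean nearest-neighbour
distances of contour vs. distracter elements differ by ~15–50%
(contour neighbours sit at the chord distance; RSA neighbours at
saturation average ≈ 1.1–1.3 d_min, more near the box edge), so the
equal-spacing configuration removes the *minimum-distance* cue, not the
full local-density profile.

The minimum distance governs every pair involving a distracter.
Contour–contour spacing is set by the chain itself; in the
reduced-distracter-spacing conditions (relative spacing > 1) distracters
may legitimately sit closer to contour elements than the contour
elements are to one another — that is the manipulation.

## Rendering

Gabors are 3.33 c/deg sine gratings (λ = 0.30°) in positive sine phase
under a circular Gaussian envelope (σ = 0.11°), 90% contrast, truncated
at 4σ.  The display model uses 66.67 px/deg — from "20 pixels per
carrier cycle" — rather than the alternative printed pixel size of
0.014° (≈ 71.4 px/deg); the two published values disagree and the cycle
statement ties directly to the rendered pattern.  Modulations sum
linearly on a 0.5 mean level, clip to [0, 1] (clipping < 0.1% of pixels
at these densities) and quantize to 8 bits, round-half-up.  Durations
map to frames at 75 Hz by round-half-up with a minimum of one frame
(0.093 s → 7 frames).  No gamma model: luminance is normalized.

## Session designs

* Experiment 1 — four spacing blocks (2/4/6/8λ) in random order; within
  each block 25 trials at each jitter level (0, ±15, ±30, ±45, ±60°),
  intermixed; 1 s stimulus; 500 trials.  The published block wording is
  ambiguous between 25 trials per block and per level; 25 per level is
  the only reading compatible with the reported precision.
* Experiment 2 — four blocks ({2λ, 6λ} × {0°, 30°}); 150 trials per
  block, 30 at each of 0.04/0.093/0.20/0.40/0.80 s, intermixed.
* Experiment 3 — two contour-spacing blocks (3λ, 6λ), order randomized;
  random-orientation backgrounds at five relative spacings plus
  iso-oriented backgrounds (σ = 5°) at relative spacings 1.0 and 2.1;
  50 trials per cell; 0.4 s.  The full crossing gives 700 trials while
  the published total is 600; both variants are explicit configuration
  (`printed_total` drops the iso cell at relative spacing 1.0).
  Relative-spacing labels are the published nominal levels paired
  positionally with the published distracter-spacing tables; exact
  ratios are stored alongside (3λ/1.5λ = 2.00 carries the nominal label
  2.1).
* Preliminary staircase — distracter-free partial contours; a
  2-down/1-up staircase (step 1 element, 12 reversals) drives the
  number of visible adjacent elements, with the segment drawn at the
  head, middle or tail of the path; the threshold is the 75% point of a
  Weibull psychometric function (γ = 0.25, lapse fixed at 0.01) fitted
  to all trials by maximum likelihood, with the reversal mean as a
  flagged fallback.  The up-down rule is not published; the ML fit
  recovers the 75% point regardless of the rule's convergence point,
  which parameter-recovery simulations confirm (true 11 → 11.1 ± 1.0
  over 100 tracks).

Trial timing metadata (0.3 s fixation flicker at 10 Hz, 0.5 s
post-stimulus blank, 1.5 s ITI) is carried verbatim into the records.
Tail labels are balanced within condition cells to the off-by-one
level where cell sizes are not divisible by four.

## Synthetic observers

The **parametric observer** gives per-condition probability correct

    pc = γ + (1 − γ − lapse) · S_J · S_space · S_dur · S_rel

with γ = 0.25 (4AFC), a Gaussian jitter link (S_J halves at
`jitter_scale`), an exponential spacing penalty per λ beyond 2λ, a
saturating-exponential duration link with time constant `duration_tau`,
and a logistic decline in relative spacing normalized to 1 at relative
spacing 1.0; iso-oriented backgrounds multiply S_rel by `iso_bonus`
(capped at 1).  Group defaults: younger {lapse 0.01, jitter_scale 45°,
spacing_penalty 0.93, τ 0.030 s, relspace mid 2.0 / slope 0.25}; older
{lapse 0.05, jitter_scale 42°, spacing_penalty 0.90, τ 0.140 s,
relspace mid 1.70 / slope 0.30}.  These encode the qualitative pattern
the analysis must detect — younger ≥ older overall, a slower duration
constant in the older group (the Age × Duration interaction), and a
steeper decline with relative spacing — at magnitudes comparable to the
published group curves.  A known structural limitation: with a purely
multiplicative S_dur, the *absolute* duration effect scales up, not
down, with static salience, so the published "duration matters only for
low-salience contours" pattern is reproduced only through the ceiling
nonlinearity, not in the salience term itself.

The **grouping observer** operates mechanistically on the element list.
Pairwise affinities combine a Gaussian proximity term (σ_d = 1.2°) and a
co-circularity term: with axial deviations u_i, u_j of the two
orientations from the chord direction, each element deviates from the
pair's co-circular ideal by (u_i + u_j)/2 (σ_θ = 25°).  The deviation
sum is deliberately not re-wrapped mod 180 — side-by-side parallel pairs
(u ≈ ±90°) support parallelism, not continuation, and re-wrapping would
alias them onto perfect co-circularity, letting chains hop between
spiral windings.  A beam search (width 8, deterministic lexicographic
tie-breaks) grows the highest-total-affinity simple chain from both
ends, rejecting links below an affinity floor (0.02) or turning more
than 75° — chance-aligned distracter chains are jagged, smooth contours
are not — and weak terminal links (< 0.5 × the chain's median edge
affinity) are trimmed.  The response is the sector of the chain endpoint
farther from the pattern centroid, measured from the extracted chain's
own centroid so the judgement tracks the perceived object rather than
the pattern's random screen offset.  The observer solves distracter-free
collinear spirals at ceiling and degrades toward the guessing floor with
orientation jitter and with distracter densification — the qualitative
orderings of the human data — but its absolute accuracies are well below
human performance in clutter and are not calibrated to match them.

## Statistical chain

Accuracy is aggregated per subject and cell; ANOVAs run on
arcsin(√p)-transformed proportions (plain arcsine, no small-sample
correction, matching the study's description).  Sensitivity uses the
independent-observations m-AFC model, pc(d′) = E_z[Φ(z + d′)³],
inverted by bisection to |Δpc| < 1e-8; chance maps to d′ = 0 and
proportions at 1 − 1e-6 are capped with a warning.

The mixed repeated-measures ANOVA takes one value per subject and
within-cell, with one between-subjects factor (group).  Within effects
are computed through orthonormal (Helmert) contrast scores, giving an
exact orthogonal SS decomposition for designs balanced within subject;
with unequal group sizes the main within effects use weighted group
means (the Type-II-style tests; Type III differs only there).  The
Greenhouse-Geisser ε̂ comes from the pooled within-group (error)
covariance of each effect's contrast scores, ε̂ = tr(Σ̃)²/(q·tr(Σ̃²)),
clamped to [1/q, 1]; this matches R's `car::Anova` mixed-design ε̂ to
machine precision (pingouin pools over groups without removing group
means and differs when group profiles differ).  Adjusted p-values use
(ε̂·df₁, ε̂·df₂).  Generalized eta-squared follows the additive recipe:
SS_effect over SS_effect plus all subject-related error SS plus the SS
of effects composed entirely of *observed* factors (age is observed by
default, stimulus factors manipulated; the classification is a
parameter, and with none observed the values match pingouin's `ng2`
exactly).  Which factors the original analysis treated as observed is
not published.

Linear trend scores contrast each subject's accuracies against centered
log-duration (or log-level) weights normalized to unit sum of squares;
the grand mean is tested against zero and the scores compared across
groups with one-way ANOVAs on the pooled within-group error.

Pipeline calibration, measured by simulation through the full chain
(binomial cell counts → accuracy table → arcsine → ANOVA): the
between-groups test rejects null data at the nominal 5% level (within
the exact binomial 99% interval over 2000 replicates).  The
GG-corrected within test is *conservative* under true sphericity — ε̂ < 1
on spherical data by construction — so its null rate is asserted only
not to exceed the interval's upper bound; the type-I guarantee is
carried by the uncorrected exact test.  With the generator defaults the
Age × Duration interaction is detected in > 80% of replicates at the
study's sample sizes (14 + 13), and removing the group difference drops
detection to the nominal rate.  Per-cell binomial draws are used in
these simulations in place of trial-by-trial response sampling; the two
are the same Bernoulli process, which is itself unit-tested.

## Problem sizes and numerics

Simulation-based tests use the study's cell sizes (25–50 trials per
cell, 12–17 subjects per group) and 200–2000 replicates depending on
the precision the claim needs; mechanistic-observer trend tests use 200
fields per level at 6λ spacing, where the fill is cheapest.  Root
finding and fitting: the arc-length step is closed-form; the Weibull
fit uses L-BFGS-B from three starts with the reversal-mean fallback
flagged in the result; d′ bisection runs to 1e-8 in pc.  Degenerate
inputs (ceiling observers, single-level trends, unbalanced tables,
unknown modes) raise or flag rather than guess.

## What the synthetic data do not show

The generators emulate the *structure* the analysis assumes —
per-condition Bernoulli responses with monotone condition effects and a
guessing floor — not the human data: no learning, fatigue, lapses
beyond a constant rate, sequential dependence, or response-time
structure.  Passing recovery and calibration tests therefore validates
the stimulus constants, the designs and the inferential machinery, not
any claim about aging or contour integration in people; the published
group means and F statistics require the original raw data and are out
of scope.
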