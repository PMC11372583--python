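# Methods

## Scoring model

Each participant-session carries 16 emotion items on a 9-point scale, mapped
to four circumplex quadrants (ND: discouraged, disappointed, fatigued,
bored; NA: uneasy, frustrated, irritated, tense, anxious, angry; PD: ease,
calm, relaxed; PA: enthusiastic, excited, happy). A session's quadrant score
is the mean of its items; the composite axes are `valence = (PA+PD) −
(NA+ND)` and `activation = (PA+NA) − (PD+ND)`, each in [−16, 16].

Person-level indices over the T = 14 sessions:

- mean levels: arithmetic mean of each quadrant's session scores;
- flux: sample SD (n−1) of each quadrant's session scores;
- pulse: sample SD of the magnitudes `m_t = sqrt(valence_t² + activation_t²)`;
- spin: circular SD `sqrt(-2 ln R̄)` of the session angles, with
  `R̄ = |Σ u_t|/n` the mean resultant length of the per-session unit vectors.

Design choices where the operationalization was genuinely open:

- **Radical in spin.** The final formula is implemented as the circular
  standard deviation `sqrt(-2 ln R̄)`, the standard "SD of angles" form; the
  non-rooted variance form `-2 ln R̄` is available via
  `spin(..., circular_sd=False)` because both appear in the applied
  literature.
- **Pulse dispersion measure.** Within-person SD of magnitudes, parallel to
  flux (both are within-person SDs, one of magnitude, four of quadrant
  level).
- **SD denominator.** n−1 everywhere (person-level estimates from a sample
  of occasions); `ddof=0` is accepted by every SD-based operation.
- **Origin sessions** (`valence = activation = 0`): the angle is undefined,
  so these sessions are excluded from the resultant (counted in
  `n_zero_magnitude`) but contribute magnitude 0 to pulse. A participant
  whose sessions all sit at the origin gets spin = NaN; one whose unit
  vectors cancel exactly gets spin = +inf with a `spin_infinite` flag. Both
  are excluded (and reported) by dataset assembly, never silently capped.
- **Raw vs. standardized axes.** Spin is computed from raw valence and
  activation; it is invariant to any common positive rescaling of the axes,
  so per-axis standardization would only matter if the two axes were scaled
  differently.
- **`R̄` slightly above 1.** Floating summation can push `|R|/n` past 1 by
  a few ulp; values within 1e-9 above 1 are snapped to 1, larger excesses
  are reported as-is (they indicate a bug, not rounding).

Game performance is `(kills/(kills+deaths) + rank_score)·100` per game,
paired games averaged into 14 session scores, sessions 1–7 / 8–14 averaged
into the pre-/post-change phase outcomes. `rank_score` is ingested directly
as a [0,1] standing (1 = first place); `rank_from_place` converts an ordinal
place among m+1 players to `(m+1−p)/m`. The exact numeric coding of rank in
the original instrument is not recoverable, which is why the column is taken
as data rather than computed. Games with kills+deaths = 0 get kill ratio 0
and are counted as degenerate. Phase outcomes are arithmetic means of the 7
session values — the simplest aggregation consistent with session-mean
scoring elsewhere.

## Screening

Careless responding is detected by long-string analysis: the longest run of
identical consecutive responses within one administration (one session's 16
emotion items in presentation order). The flagging rule — run ≥ threshold on
≥ min_administrations — defaults to a maximally conservative threshold of 16
(the full administration) on at least half the administrations, because the
original rule behind such screens is rarely reported; both knobs are
configurable. Raising the threshold can never flag more participants.

## Relative importance

All subset computations run on the correlation scale: predictors and the
outcome are z-scored with n−1 SDs on the per-outcome complete cases, so any
subset's R² is `r_xy' Rxx⁻¹ r_xy` over that subset (verified against direct
least squares to 1e-10 in tests). The all-subsets map (2^p entries, guarded
at p ≤ 20; the design here has p = 10 → 1024 subsets) feeds:

- conditional dominance: mean incremental R² of each predictor at each
  model size 0…p−1;
- general dominance: the unweighted mean over sizes (the Shapley
  decomposition of R²; sums to the full-model R²);
- pairwise complete/conditional/general dominance matrices coded 1 (row
  dominates), 0 (column dominates), 0.5 (undetermined). Complete dominance
  requires strict inequality over *every* subset excluding both predictors;
  any tie or reversal yields 0.5. Exact general-dominance ties (measure-zero
  on real data) are coded 0.5. Comparisons use a 1e-12 tolerance so floating
  noise cannot manufacture strict wins.

Relative weights use Johnson's symmetric-square-root orthogonalization (see
README for the algebra). Both RWI and general dominance are reported because
the field's "relative weight analysis" label covers both; they agree closely
in practice but are distinct estimands. Importance is flagged at RWI ≥ 0.02
(2% of outcome variance), inclusive at the boundary; the threshold is echoed
into output metadata.

Suppression diagnostics reuse the same machinery: `U_i = R²(full) −
R²(full∖i)`, `common_i = r_i² − U_i` (this per-predictor total common
variance is what gets reported one-value-per-predictor; the full 2^p−1
commonality partition is out of scope), and the incremental-variance
trajectory *is* the conditional-dominance vector (shared computation,
asserted identical in tests). The suppressor flag defaults to `common < 0`,
`|r| < 0.10`, `|β| > 0.10`; with only two predictors the size-1 companion
endpoint coincides with the full-model endpoint, so the trajectory direction
is taken from size 0.

## Mediation

Simple mediation with optional covariates, OLS path estimation
(statsmodels), indirect effect `a·b`, and a bias-corrected (BC, not BCa —
no acceleration term) bootstrap CI: participants resampled with replacement,
`z₀ = Φ⁻¹(proportion of bootstrap draws below the point estimate)`, bounds
at the adjusted percentiles `Φ(2z₀ ± z_{(1+conf)/2})`. Defaults: 10,000
draws (stable 99% endpoints), confidence 0.99, seedable. The bootstrap loop
solves the stacked normal equations for whole chunks of resamples with one
batched solve per path — verified equal to the statsmodels fit on the
identity resample. If the draw distribution is degenerate (noiseless data)
or wholly one-sided (bias correction undefined), the plain percentile
interval is substituted and flagged. Role assignment follows the study
narrative: x = an affect index, mediator = off-task attention, y =
performance, phase selectable; exact x/mediator collinearity is an error
rather than an arbitrary split of b and the direct effect.

## Synthetic data generator

The generator emulates the study design, not any particular dataset's
idiosyncrasies. Defaults (all configurable):

| parameter | default | basis |
|---|---|---|
| participants | 253 | the design's sample size |
| sessions | 14 (7 pre / 7 post), 2 games each | the design |
| person-mean (M, SD) per quadrant | ND 3.80/1.59, NA 3.44/1.68, PD 4.11/1.77, PA 3.78/1.80 | published descriptives |
| quadrant-mean correlations | ND–NA .78, ND–PD −.34, ND–PA −.52, NA–PD −.52, NA–PA −.35, PD–PA .52 | published sign structure (positive definite) |
| flux distribution | log-normal, medians 1.13/1.08/1.25/1.28, log-SD 0.45 | published flux means; log-SD puts the flux SDs near the published 0.56–0.62 |
| item noise SD | 0.75 (9-point scale, before rounding) | realistic session-level reliability |
| careless fraction | 17/253 | the design's screening yield |
| OTA coefficients | mean_nd 0.45, mean_na 0.10, mean_pa −0.15, flux_nd 0.15; noise SD 0.8 | the qualitative pattern: mean ND dominant for off-task attention; full-model R² lands near 0.35–0.45 |
| performance coefficients | mean_pa 0.40, mean_na −0.20, mean_nd −0.10, flux_na −0.10; noise SD 0.8 | mean PA dominant for performance |
| outcome instrument scales | OTA pre (2.15, 1.10) / post (2.66, 1.44); performance pre (37.51, 18.48) / post (30.11, 16.45) | published phase descriptives |

Person means are truncated to [1, 9] by resampling (no boundary point mass);
note that truncation shifts realized means above the configured locations
for quadrants whose lower tail is cut — the generator tests compare against
an independent rejection-sampling oracle, not the raw locations. Outcomes
are linear in the *observed* standardized predictors (profiles scored from
the clean generated ratings), then location/scale-mapped to the instrument
and reverse-engineered into records: attention items are integers whose mean
tracks the session value; games draw a rank score near `target/200`, a kill
ratio making up the remainder, and Poisson-scaled kill/death counts. Careless
responders are injected *after* outcome generation by overwriting every
administration with a constant string, so screening has a real signal and
retained participants' outcome links are intact.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: session-to-session autocorrelation (occasions
are independent draws; emotional inertia is absent), systematic pre/post
trajectory shapes (learning curves), item-level method variance beyond iid
noise, missingness, and any direct generative parameter for spin or pulse
(they emerge from means + within-person SDs). Parameter-recovery results
quantify estimator behaviour under the design's sampling scheme, not
real-world validity of the indices.

A measurement caveat quantified in the tests: through the full 9-point
instrument (item noise, integer rounding, clipping at the scale ends),
recovered flux correlates with the generating within-person SD at about
r ≈ 0.93–0.95 even at T = 200 — the scale ends saturate flux for high-SD
participants — while the flux estimator on latent (pre-instrument) session
scores reaches r ≈ 0.99. At the study length T = 14 the instrument
round-trip runs r ≈ 0.65–0.75. Quadrant *means* are much more robust:
r > 0.95 through the full instrument at T = 14.

## Problem sizes in the test suite

The suite exercises the pipeline at the design's native scale where that is
cheap (n = 253, T = 14; the p = 10 all-subsets analysis enumerates 1024
submodels in ~40 ms) and uses 100-replicate simulations for the stochastic
claims: dominance recovery (single-predictor generating model, n = 250) and
the bootstrap's type-I calibration (500 replications × 2,000 draws at
n = 250, conf = 0.99). The whole suite runs in about a minute on one core.

## Known limitations

- The dominance enumeration is exponential in p; the guard at p = 20 is far
  above the design's p = 10 but the method is not meant for wide predictor
  sets.
- The BC interval has no acceleration correction; for strongly skewed
  indirect-effect distributions BCa would differ.
- The commonality output is the per-predictor total common variance, not the
  full commonality partition.
- Phase boundaries (sessions 1–7 vs. 8–14) are fixed constants of the
  design; generators configured with a different session count still split
  outcomes at session 7.
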