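# Methods

This note documents the models and procedures implemented in `troopcall`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Study system and analysis units

The package is organized around a troop of 27 focal animals (12 males,
15 females, mirroring an observed macaque group of adults and
sub-adults). Four observation streams feed the analysis:

1. **Focal proximity sessions** — 600 s continuous follows logging, per
   partner, the time spent within 1 m of the focal animal.
2. **Agonistic bouts** — decided aggression–submission interactions; the
   winner is the actor.
3. **Movement logs** — per individual, the time of joining each group
   departure and the number of calls given during the event.
4. **Call recordings** — mono 44.1 kHz / 16-bit WAV, one call per file.

## Acoustic feature extraction

Frames are 30 ms with a 10 ms hop, matching common practice for
short tonal primate calls. f0 is the autocorrelation peak of the
Gaussian-windowed frame after dividing out the window's own
autocorrelation (which otherwise biases long lags downward), searched in
75–600 Hz — a band bracketing the observed 244–490 Hz call range.
Capping the corrected correlation at 1 and preferring the shortest lag
among near-best local maxima (within 85% of the frame maximum) rejects
sub-harmonic octave errors; parabolic interpolation around the peak
gives sub-sample lag resolution (< 1% f0 error on tones at 20 dB SNR,
enforced by test). Frames below 0.45 normalized correlation, or at the
numerical silence floor, are unvoiced.

Call duration is the voiced span, first to last voiced frame inclusive
of the window length. f0 statistics are over voiced frames only — an
interpretation, since summary statistics over an entire file would
differ for calls with unvoiced margins. Intensity is per-frame RMS on a
digital dB scale with a full-scale sine at 96 dB (the 16-bit
convention); absolute SPL is unrecoverable from digital recordings, so
no SPL comparability is claimed.

Classification is nearest-centroid with per-feature standardization:
each call type contributes a centroid and per-feature SD over the seven
parameters, and a call goes to the profile minimizing the quadrature sum
of standardized deviations, ties resolved by fixed profile order
(coo < leap_coo < bark). The bark class was observed once and has no
empirical SD; it borrows the pooled coo/leap-coo SD per feature — the
only variance estimate available.

## Call synthesis

Synthetic calls are 5-harmonic stacks with 1/k amplitude rolloff
(partials above the fifth fall outside the 0–5 kHz band that carries the
calls' energy; exact timbre is irrelevant to the seven features). The
f0 contour holds the type's minimum and maximum on end plateaus at least
one analysis window long (where the call duration allows) with a
monotone power ramp between, so the measured contour never leaves the
published band; the ramp exponent is solved so the frame-mean f0 equals
the type mean. The amplitude envelope is built in dB with the same
plateau–ramp family and calibrated against the package's own frame-RMS
measurement: a root solve over the internal (min, mean, max) levels
pre-compensates the inward bias of edge frames that straddle plateau and
ramp, followed by a single refinement pass against the full waveform.

One geometric limit is worth recording: for the 0.06 s bark, a 7 dB drop
at the call edge cannot coexist exactly with the published 4-frame mean
under 30 ms windows at a 10 ms hop — overlapping windows bound the mean
from above. The calibrated compromise lands within 0.7 dB of all three
amplitude targets and within 1% on min/max f0, inside the package's
acceptance bands (2% on f0 and duration, 1 dB on amplitude).

With `jitter > 0`, every feature target is perturbed multiplicatively by
`1 + jitter·N(0,1)` (seeded), with the f0 and amplitude triples re-sorted
to stay ordered. `jitter = 0` reproduces the published centroids
bit-identically for any seed.

## Association, centrality, dominance, kinship

**DAI.** For a dyad (a, b), `DAI = D_ab / (D_a + D_b − D_ab)` with
`D_a`, `D_b` the total focal time of each individual. Because a balanced
focal rotation observes each dyad from both sides, the joint term
`D_ab` is the average (half the sum) of the two directed overlap sums;
this keeps the index in [0, 1] and yields exactly 1 for a constantly
proximate pair, whereas raw summation would push the denominator to zero.
Self-pairs are excluded and the diagonal fixed at 0. A dyad with zero
combined focal time scores 0.

**Eigenvector centrality** is computed on the raw weighted DAI matrix
(no binarization) by power iteration from the uniform vector on the
largest connected component; isolates score 0. A diagonal shift of
0.1 × max row sum leaves the eigenvectors unchanged but breaks the ±λ
symmetry of bipartite graphs, which would otherwise make the iteration
oscillate. Convergence is a max-norm step below 1e−12 (default), with
the eigen-residual `‖Ax − λx‖∞` test-enforced against a dense
eigendecomposition oracle at 1e−8. Scores are normalized to unit
Euclidean norm; the downstream regression is scale-equivariant, so the
normalization convention only rescales the centrality coefficient.

**David's Score.** With `s_ij` wins of i over j in `n_ij` bouts, the
default uses raw win proportions `P_ij = s_ij/n_ij` (0 for unobserved
dyads — a deliberately non-imputing choice; 0.5 would invent data), and
`DS_i = w_i + w2_i − l_i − l2_i` with `w = Σ_j P_ij`,
`w2 = Σ_j P_ij w_j`, and `l`, `l2` the mirror-image loss terms. Under
this convention ΣDS = 0 exactly. The chance-corrected
`D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1)` variant is available as
`correction="dij"`. Ranks descend in DS with ties broken by roster
order, making the ranking deterministic.

**Relatives.** Matriline members count (matriline size − 1) relatives
each; individuals without a matriline (immigrant males) count 0.

## Movement events

An event closes when 300 s pass without a new joiner and is successful
with ≥ 3 participants (initiator included). Repeat joins are ignored.
Boundary conventions, stated once and tested at the boundaries: "over
10 m"/"over 5 m" are strict (>), "within 30 s"/"within 45°"/"within five
minutes" are inclusive (≤). Simultaneous join times keep record order,
so order indices within an event are always the exact grid
{0, 1/(N−1), …, 1}.

Percentages in the vocal tally are rounded to one decimal, with the
vocal/non-vocal pair reconciled by largest remainder so the displayed
pair always sums to 100.0. Per-individual vocal frequency is total calls
divided by events participated in; the participation count is carried
alongside so an alternative exposure convention is a one-line change —
the field convention (per movement vs. per observation time) is not
standardized, so the raw ingredients stay available. A movement counts
as vocal if any eventual participant called during the event window,
including the initiator before first displacement.

## Count model

Per-individual, per-event call counts are modeled as zero-inflated
Poisson: with probability π a structural zero, otherwise Poisson with
`log μ = Xβ + log(exposure)`. The inflation part is intercept-only; the
count part takes sex (female = 1, so a positive coefficient means
females call more), centrality, rank, relatives and joining-order
index. The likelihood is maximized by BFGS with analytic gradients for
both parts (count part starts at zero coefficients, inflation logit at
the observed zero fraction), then polished by damped Newton steps with
the observed information until the gradient max-norm is below 1e−9.
Standard errors come from the inverted observed information (central
finite differences of the analytic gradient); inference is Wald
(z = estimate/SE, two-sided normal p), matching the z-and-p reporting
convention of mixed-model count software. Non-convergence and the
all-zero boundary (π → 1, flat count likelihood) are flagged on the
results object, never silently returned.

A random-effect structure (individual-level repeated measures) is not
fitted: with 27 individuals observed repeatedly the observation-level
ZIP with an exposure offset is what is cleanly identifiable here, and
the gap is acknowledged — SEs treat observations as independent given
the covariates.

Rank tests: the Mann–Whitney U uses exact enumeration of the tie-free
null (dynamic programming over sample sizes, cached) when
`n1·n2 ≤ 400`, else the normal approximation with midrank tie correction
and 0.5 continuity correction; both U and the rank-sum form W are
reported since software conventions differ. Spearman is the Pearson
correlation of midranks with the t-approximation (n − 2 df) for p.

## Synthetic generator: what it emulates, and what not

All generators are pure functions of (config, seed), each drawing from a
named sub-seed so adding one generator never perturbs another's draws.
Latents (gregariousness, the dominance ladder, true regression
coefficients) are exported for recovery tests.

* **Roster**: sexes 12/15, three matrilines covering ~17/27 of the
  group, filled female-biased but not female-exclusively — matrilineal
  societies keep natal males in their lines and the odd female without
  resident kin, and this keeps sex and kin count from being collinear
  covariates. Migrant males carry 0 relatives.
* **Proximity**: dyadic proximity fractions proportional to the product
  of lognormal gregariousness latents (beta-jittered, capped at the
  session length), scaled so the average dyad spends 15% of a session
  within 1 m. Real proximity has temporal and spatial structure
  (feeding peaks, kin clustering) that this exchangeable model ignores.
* **Agonism**: every dyad interacts (≥ 1 bout, ~3 on average); win
  probabilities are logistic in latent strength differences with
  steepness 2 by default. Coalitions, winner effects and intransitive
  triads are not modeled.
* **Movements**: 132 events (the observed season total); participants
  drawn with gregariousness-weighted order so joining order carries
  social signal; counts ZIP with log-rate
  `−1.5 + 0.771·female + 3.361·centrality + 1.0·order_index` and π =
  0.35. The sex and centrality effects equal the fitted coefficients
  from the field study; the intercept and inflation are free parameters
  chosen once so that the effects are identifiable at the study-sized
  design (the package's recovery benchmark demands sign and significance
  recovery in ≥ 95% of simulations at these defaults). Under these
  defaults nearly every simulated movement contains some call — denser
  than the field's 39% — so the `paper_tally` preset exists separately
  to reproduce the observed sparseness (132 events, 52 vocal, 34 with a
  vocalizing initiator, exactly).

Passing tests on this generator demonstrate internal consistency and
estimator correctness, not field validity: the generator contains no
observation error, no missing data, no caller misattribution, and its
zero-inflation is exactly the fitted family.

## Problem sizes and numerical choices

The test suite runs the recovery benchmark at 20 simulations of 500
events and 100 simulations at the 132-event default, the Mann–Whitney
calibration at 10,000 null replicates (n = 20 per group, exact mode),
and the oracle comparisons at 27 individuals — sizes chosen to make
Monte-Carlo margins small relative to the asserted thresholds while the
whole suite stays interactive (~half a minute). Optimizer tolerance is
1e−8 (BFGS) with Newton polish to 1e−9; power iteration tolerance
1e−12; exact Mann–Whitney distributions are cached per (n1, n2).

## Known limitations

* The f0 tracker assumes one call per file; long recordings with
  multiple calls need prior segmentation.
* The acoustic dB scale is digital, not SPL-calibrated.
* No spatial trajectories: initiator/follower rules operate on
  already-measured displacement/bearing observations.
* The count model offers Poisson and ZIP families only (no negative
  binomial, no random effects), and no multiple-testing correction is
  applied.
* The DAI halving convention assumes balanced focal effort; strongly
  unbalanced sampling would bias dyads toward the better-sampled
  individual.
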