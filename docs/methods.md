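# Methods

This note documents the models, parameter choices and numerical
conventions behind `dynstates`, and what the synthetic-data validation
does and does not establish.

## Phase-locking state model

The analysis assumes that slow BOLD co-fluctuations can be summarised,
volume by volume, by the pattern of phase alignment among parcellated
components. Time courses are restricted to 0.04–0.07 Hz (7th-order
Butterworth, forward–backward so the phase response cancels; the
effective attenuation corresponds to order 14). The narrow band is what
makes the analytic-signal phase interpretable. The per-volume coherence
matrix `C_ij = cos(θ_i − θ_j)` equals `cc' + ss'` with `c = cos θ`,
`s = sin θ`; it therefore has rank ≤ 2, and the production path solves
a 2 × 2 eigenproblem in span{c, s} per volume instead of a dense
decomposition (the general dense routine is kept and the two are
cross-checked to 1e-8 in the tests). The sign pattern of the leading
eigenvector `V₁(t)` defines two communities whose phases are locked
against each other.

Edge handling: one full cycle of the lowest effective frequency
(0.038 Hz, set by the filter skirt) is trimmed from each end —
`ceil((1/0.038)/1.6) = 17` volumes. For a 400-volume scan the
arithmetic retains 366 volumes; a `retained_volumes` override exists
for protocols that keep a different count (e.g. 361), implemented by
dropping the surplus from the end of the series.

Sign conventions: eigenvector signs are arbitrary per volume, so the
series is aligned sequentially (flip `V₁(t)` when its inner product
with `V₁(t−1)` is negative), with the first volume oriented so its
entry sum is ≤ 0, i.e. the larger community is negative. Only `V₁` is
used downstream, so full-spectrum eigenvector matching is unnecessary.
Degenerate leading eigenvalues (gap < 1e-12) are resolved by
lexicographic comparison after sign canonicalisation; such ties are
measure-zero on real signals.

## Clustering and model selection

Pooled eigenvectors (subjects stacked in lexicographic id order) are
clustered by Lloyd k-means under the city-block (L1) metric, for which
the component-wise median is the optimal centroid; with an even row
count the lower median is taken so updates are deterministic. Each k
uses 42 random restarts (replicate r is seeded with `seed + r`, so runs
reproduce across machines), up to 5000 iterations, best total L1 cost
wins. An emptied cluster is re-seeded with the point farthest from its
assigned centroid. The within-cluster cost is asserted non-increasing
at every iteration. k is selected over 2…10 by the Davies–Bouldin
index computed with the same metric (a Euclidean mode exists and is
cross-checked against scikit-learn's implementation); ties go to the
smaller k. After selection, states are renumbered by descending pooled
occupancy so labels are stable across runs — recovered state numbers
are therefore a permutation of any planted regime numbers.

## State metrics

Runs are maximal constant segments of the label sequence; boundary runs
truncated by the scan edges count toward visits and dwell (a flag
excludes them if desired). Mean dwell time is mean run length × TR,
reported in seconds. Transition probabilities are estimated from all
consecutive pairs, self-transitions included (the inferential family
size k·k presumes the full matrix); rows of states never occupied
before the final volume are NaN, not zero-filled. Conservation
identities (occupancies sum to 1, visits × dwell accounts for every
volume, transitions equal off-diagonal pair counts) are enforced by
property tests over arbitrary sequences.

## Factor reduction

Tables are column z-scored (sample sd) and decomposed by SVD. By
default the Kaiser criterion (correlation eigenvalue > 1, minimum one)
decides how many components enter varimax rotation; the count is
overridable because published analyses rarely state it. Rotation uses
Kaiser row-normalisation by default (flaggable); the rotation matrix is
orthogonal to 1e-9 and the variance explained by the retained set is
invariant under rotation. Scores are regression scores in the rotated
basis, `Z L (L'L)^{-1}`. Two orientation rules remove rotation
ambiguity: the emotional-instability component is the one with the
largest |Neuroticism| loading, oriented Neuroticism-positive (robust to
rotation reordering); the diffusion component is the highest-variance
rotated pattern, oriented so the mean ROI coefficient is positive, so
lower white-matter values map to lower scores.

## Inferential layer

All models carry age, sex (0/1) and education (ordinal 1–7, treated as
numeric) as covariates. The response family is chosen by fitting every
admissible candidate — Gaussian with identity, square-root or log
transform (positive responses only), Poisson for counts, Gamma and
inverse Gaussian (log links, for numerical stability) for positive
responses, Binomial forced for dichotomous ones — and taking the
minimum AIC, ties toward Gaussian/identity. Transformed-Gaussian AICs
include the change-of-variables Jacobian so candidates are compared on
the original response scale; automated exhaustive AIC comparison
replaces visual histogram inspection, which is not reproducible. The
overall model test is an F-test against the intercept-only model for
Gaussian responses and a likelihood-ratio chi-square otherwise.
Diagnostics: VIF per predictor (model accepted when all < 5; perfect
collinearity reported as infinite), Shapiro–Wilk on deviance
residuals. Bonferroni families: k = 5 for state-specific measures
(threshold 0.05/5 = 0.01), k·k = 25 for specific transition
probabilities (0.05/25 = 0.002), 1 for totals; corrected
p = min(1, p·m). One unresolved naming issue upstream of this package:
"inverse gamma" is not a standard GLM family, and is implemented here
as inverse Gaussian.

## Synthetic cohort generator

The generator exists to make every stage testable against planted
truth. Per subject, a hidden Markov chain over `k_true = 5` regimes
drives which of five signed bipartitions is active; every component
emits `sin(2πf·t·TR + φ₀ + Δ·1[sign = −1]) + N(0, noise_sd²)` with the
carrier `f ~ U(0.045, 0.065)` Hz strictly inside the passband (so
filtering is near-transparent) and `Δ = π` by default (exact
anti-phase, under which the planted bipartition is exactly the leading
eigenvector of the noiseless coherence matrix).

Two design choices matter for identifiability:

* **Regime geometry.** Each regime has a minority community of 8–13 of
  the 53 components in anti-phase with the rest, mirroring empirical
  phase-locking states (a dominant negative community with a small
  positive one). Keeping minorities below a quarter of the components
  guarantees positive inner products between any two regime vectors, so
  sequential sign alignment keeps one orientation per regime across
  separated visits.
* **Dwell times.** A 0.03-Hz-wide band-pass smears each regime switch
  over roughly ±4 volumes (≈ 2.6 misassigned volumes per switch,
  independent of observation noise), so resolvability requires a switch
  rate below ~0.015 per volume. The default chain stays with
  probability 0.985 (mean dwell ≈ 67 volumes ≈ 107 s at TR 1.6 s) —
  deliberately long compared with empirical fMRI state durations,
  because the generator is an identifiability benchmark, not a fit to
  real dynamics.

Behavioural layers: Big Five tables follow a one-factor model with the
emotional-instability loading pattern (N +0.77, E −0.45, O +0.33,
A −0.13, C −0.28) scaled into plausible NEO-FFI ranges; at the default
observation noise (sd 0.5) the population correlation between PCA
scores and the latent trait is 0.869 by closed form (the optimal
estimator caps at 0.894), which the recovery tests assert. Six-month
symptom severity is a rounded, clipped (0–42, the instrument's range)
linear predictor with a negative EI × regime-3-visits interaction;
dichotomous recovery follows a logistic model on the same predictor.
Diffusion tables follow a one-factor white-matter integrity model whose
loadings peak on six injury-vulnerable ROIs (fornix, genu, anterior and
posterior corona radiata), with patients shifted along the affected
weights for FA only; the benchmark cohort sizes mirror a two-group
imaging study (tens of subjects per group).

What passing tests show — and do not. Synthetic signals are pure
sinusoids with instantaneous regime switches, white observation noise,
a shared carrier per subject and no hemodynamics, motion, scanner
drift, aperiodic background or inter-subject spatial variability.
Recovery results therefore validate the *pipeline* (that each stage
computes what it claims, and that the chain identifies structure it is
designed to detect), not the sensitivity of the method on real fMRI,
where phase relations are noisier and state durations far shorter.

## Problem sizes

The bundled benchmark uses 20 subjects × 300 volumes × 53 components
(≈ 5,300 pooled eigenvectors) over 20 seeds for state recovery, 100
null simulations at n = 200 for type-I calibration, and 200 simulations
at n = 120 for interaction coverage — sizes chosen so the whole
validation runs in minutes on a single core while keeping Monte-Carlo
error well below the asserted margins.

## Known limitations

* Sequential sign alignment can, in principle, split a state into two
  orientations if distinct states are near-orthogonal; the generator's
  minority-community construction avoids this regime, but real data are
  not guaranteed to.
* Davies–Bouldin selection is evaluated only under the planted
  conditions; no claim is made about its behaviour on real cohorts.
* AIC-based family selection is a proxy for judgement calls made per
  dataset in applied work; its selection consistency is verified only
  for clearly separated candidates.
* The GLM layer assumes complete cases and drops rows with undefined
  transition probabilities.
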