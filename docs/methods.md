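# Methods

This note documents the models and procedures implemented in `nirselect`,
the conventions chosen where the field's software leaves them ambiguous, and
what the synthetic data can and cannot establish.

## Synthetic populations

The generator emulates a harvest-season NIR study: `n_samples` (default 213)
samples from `n_cultivars` (default 3) cultivars, sampled over 8 weekly
dates so a ripening gradient spans the season. Each sample carries a
4-component latent chemistry vector (water, sugar, organic acid, phenolics):

    latents = cultivar baseline + r · trend + N(0, latent_noise_sd²),

with `r = date_index / 7` the season position. Sugar and phenolics rise with
`r`, acid falls — the sign structure that makes TA fall and TSS/pH rise with
maturity. The white-like cultivar has a markedly lower phenol baseline.

Spectra follow a Beer–Lambert mixture: absorbance is the latent vector times
a matrix of Gaussian pure-component bands (centres/widths/amplitudes in
`SimulationConfig.pure_components`, placed at plausible O–H/C–H overtone and
combination regions in 900–1700 nm), and reflectance is `R = 10^(−A)`, which
is guaranteed in (0, 1] before artifacts. Scatter is per-sample
multiplicative (slope sd 0.05) and additive (offset sd 0.01), plus i.i.d.
detector noise (sd 0.002 reflectance units). These levels give realistic
scatter-dominated variation that SNV/MSC visibly remove without swamping
the chemical signal.

Reference values are documented affine maps of the latents
(`reference_coefficients`) plus assay noise with defaults TA 2.0 g/L, TSS
0.9 °Brix, TSP 1.3 mg/g, pH 0.10 — the error level of routine oenological
assays, and the irreducible floor any calibration should approach. Physical
floors (references clipped at small positive values, pH kept inside (0, 14))
very rarely bind at the defaults.

Everything derives from one integer seed through `numpy.random.default_rng`;
the same config is bit-identical across runs. The validation split uses
round-half-up on `fraction · n`, so a one-third split of 213 reserves
exactly 71 samples.

**What the generator does not emulate:** instrument drift and wavelength
miscalibration, sample-presentation effects beyond affine scatter,
non-Gaussian reference-assay errors, correlated band noise, and any
image-formation step (the data model starts at per-sample average spectra).
Passing tests therefore show the selection/calibration machinery behaves
correctly on data with the assumed structure, not that any particular
threshold is optimal for real fruit spectra.

## Pretreatments

Codes follow the `scatter d,g,s1,s2` convention (derivative order, gap, two
smoothing segments, all in bands; `0,0,1,1` is the identity).

- SNV uses the population (1/n) row standard deviation — fixed for
  bit-stable tests; a constant row is an error.
- MSC regresses each row on the calibration column-mean spectrum and the
  reference is stored, so validation spectra are corrected against the
  calibration fit, never their own mean.
- Detrend subtracts a per-row polynomial in wavelength (degree 2, the
  SNV-detrend convention), computed against an orthonormalized basis.
- The gap-segment derivative smooths with segment `s1`, applies `d` gap
  differences `y(i+g) − y(i−g)`, then smooths with `s2`. Edge bands without
  a full window are **truncated** (no padding — no fabricated data) and the
  surviving band indices are reported; calibration and validation always end
  on the same grid. Segments must be odd so windows are centred.
- Composition order is scatter correction first, then derivative. Phrases
  like "MSC plus first derivative" do not fix an order; this one is the
  common chemometric reading and is what `apply_pretreatment` implements.
- Gap/segment units are bands, not nm; the proprietary convention is
  undocumented, and bands keep the operators grid-independent.

## Score space, H and NH

PCA is computed by SVD of the centred absorbance matrix with a deterministic
sign convention (largest-magnitude loading element positive). Score
variances use the **sample (1/(n−1)) convention**: with standardized scores
`t_j/√λ_j` and `H = (1/k) Σ_j t_j²/λ_j`, this makes the training-set mean of
H exactly `(n−1)/n`, so H sits on the scale where the conventional rules —
H > 3 is a spectral outlier, NH < 0.6 means "neighbours" — are meaningful.
NH is the same quadratic form between sample pairs; both equal the direct
covariance-inverse Mahalanobis distance divided by k (verified against that
oracle in the tests).

Outlier removal is single-pass: H is not recomputed after removal. k is the
smallest component count reaching the target explained variance (default
0.99), or a fixed k.

## Selection

The neighbourhood grouping is a greedy reconstruction (the original
CENTER/SELECT algorithms are patented and unpublished in detail): repeatedly
seed a group at the unassigned sample with the most unassigned neighbours
within the threshold, ties to the smallest index. Each group stores both its
formation seed (all members are within the threshold of it) and its centre —
the member minimizing summed NH to the rest, which is what centre-picks
return. The `√n` mode picks `round_half_up(√m)` members per group: the
centre first, then greedy maximin (farthest-from-picked) additions, so picks
spread across the group; `round(√30) = 5`.

Ward clustering runs on squared Euclidean distances over the standardized
scores (scipy's Ward linkage with heights squared onto the
error-sum-of-squares scale: two singletons merge at their squared distance,
and every height equals twice the ESS increase of the merge — verified
against an exhaustive oracle for n ≤ 8). Cuts are expressed as a percentage
of the maximum merge height; groups are connected components below the cut.
HC picks are uniformly random per group (seeded), or per
`round(√m)`-subcluster, obtained by undoing the largest merges internal to
the group's subtree. The NH-centre versus HC-random asymmetry of the two
families is deliberate and preserved.

Count-targeted selection binary-searches the observed NH values for the
smallest threshold giving the requested group count (ties can make a count
unattainable, in which case the error reports the nearest achievable counts
and the pipeline falls back to the closest one), or cuts the dendrogram to
exactly the requested number of clusters (always attainable); one central
pick per group.

## MPLS

The core is PLS1/NIPALS with the modification that, before each factor, the
X residual at each wavelength and the y residual are divided by their
current standard deviations. The per-factor scaling vectors are stored, so
prediction replays the training recursion exactly; the whole map is affine,
and the equivalent regression vector in pretreated space is recovered and
serialized. With scaling disabled the algorithm reduces to standard PLS1
(verified to 1e-8 against an independent implementation).

Conventions, each documented because the reference software leaves them
unstated: cross-validation uses 4 contiguous segments of a seeded shuffle;
SECV uses the plain N denominator (not N − f − 1); the factor count is the
arg-min of SECV; T-outlier passes are capped at 2; max factors defaults to
`min(15, N/3)` to prevent overfit on small subsets. When residuals are
exhausted before the requested factor count (noiseless, low-rank data),
factor extraction stops early — further factors would contribute nothing —
and a numerically zero SECV disables the T criterion, which is otherwise a
0/0. Calibration Min/Max estimates are the span of the calibration
predictions with negative values floored at 0 (concentrations cannot be
negative); RSQ is the cross-validated coefficient of determination, clamped
to [0, 1].

## Validation and comparison

SEP is bias-corrected with the m − 1 denominator (the NIRS convention); the
plain RMSEP is also computed since the two differ under bias. SEP% divides
by the model's applicability span (Max − Min) by default, with a
mean-of-range normalization available as a flag. The Fisher comparison is
two-sided — F is the larger SEP squared over the smaller, tested at
1 − α/2 with (m − 1, m − 1) degrees of freedom — and its type-I error is
verified by simulation. α defaults to 0.05 (an 0.0005 option exists; a
printed "α = 0.05%" is read as the conventional 5% level).

## Study sizes and runtime choices

The default study is the full design: 213 samples, 71/142 split, all eight
distance-based sets plus four count-targeted sets, 4 parameters — about
two seconds per study end to end, so the test suite can afford the
five-seed majority-vote check of the headline result and the acceptance
script runs in seconds. Count targets are computed from the post-outlier FC
population by round-half-up of n/3 and n/2.

## Known limitations

- The greedy NH grouping is a reconstruction, not the patented original;
  group counts on a given threshold scale depend on the data's score-space
  geometry and need not match any particular instrument library.
- Group-count monotonicity in the NH threshold holds empirically for the
  greedy rule but is not guaranteed for adversarial configurations.
- MPLS residual scaling follows the published description of the
  modification; the proprietary implementation may differ in detail
  (the toggle `scale_residuals=False` gives exact PLS1 for comparison).
- Fisher's test on SEPs assumes approximately normal, independent errors;
  with strongly non-normal validation errors its level is approximate.
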