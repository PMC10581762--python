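# Methods

This note documents the models, numerical choices and limitations behind
`owlfield`, in the order data flow through the package.

## Coordinate conventions and units

Azimuth is signed degrees from the median sagittal plane, positive toward
the bird's right; elevation is degrees from the horizontal through the
eyes, positive upward.  The display convention of perimeter studies (a
latitude/longitude grid with the equator aligned vertically in the median
sagittal plane) is a plotting concern only; stored data use the single
frame above.  All public interfaces are in degrees, grams and
millimetres; trigonometry is in radians internally.

## Perimetry geometry

**Viewing-point-at-infinity correction.**  The perimeter records the
angular position of the observer on an arc of radius *r* centred on the
head, but a field margin belongs to the eye, which sits ±s/2 off the
median plane (s = inter-eye separation, measured from calibrated head
photographs).  With head centre at origin, forward axis y and right axis
x, the corrected azimuth is θ′ = atan2(r sin θ ∓ s/2, r cos θ) (upper
sign for the right eye): the exact 2-D geometry of the eye-to-observer
direction, applied per elevation to the horizontal component.  It reduces
to the identity at s = 0 and as r → ∞.  The apparatus radius and eye
separations are free inputs — studies rarely publish them — with package
defaults r = 0.5 m, s = 0.02 m used by the synthetic generator.

**Binocular width.**  Both eyes' medial margins are corrected, and
width = max(0, left − right).  Negative "gaps" are clamped to zero in the
stored width but remain recoverable from the margins; the signed overlap
left − right is what the vertical-extent computation interpolates.

**Blocked elevations.**  Where the bill holder blocks the view, the width
is the arithmetic mean of the widths at the nearest measured elevations
above and below.  Measured rows are never modified.  A blocked elevation
at the grid boundary is an error: only lower-bound estimation may extend
a profile.

**Summary statistics.**  Maximum binocular overlap is the largest width
over elevations; its elevation breaks ties toward the lowest elevation,
consistent with the downward bill-tip reference.  Vertical extent is the
distance between the lower and upper zero crossings of the signed
overlap, linearly interpolated between grid rows; a profile that ends
with positive width contributes its edge elevation, so the extent is
well defined for fields clipped by the measurement range.  The bill-tip
offset is |elevation of maximum − bill-tip projection elevation|; how the
eye–bill-tip direction is quantified is outside the package, which
consumes it as an input angle.

**Lower-bound estimation.**  For profiles truncated at the bottom (the
apparatus prevents observation at the lowest elevations in some species),
the two lowest measured widths are extrapolated linearly until the width
reaches zero; added rows are flagged.  When the widths do not decrease
downward the extrapolation cannot terminate: a warning is raised and the
field is closed one grid step below.

**Species values** are arithmetic means of the per-individual summary
statistics (1–3 individuals per species), not of raw margins.

## Outline morphometrics

Outlines are closed polygons x = ±width/2, y = elevation.  Before the
transform they are resampled to k points equally spaced by arc length
(default 128) with the start point standardised to the topmost vertex
(ties toward smallest x), which removes the parameterisation phase
without rotating the shape.

The elliptic Fourier coefficients are the exact piecewise-linear
(Kuhl–Giardina) integrals over the polygonal chain; four coefficients per
harmonic (cosine/sine for x and for y).  An optional `param` argument
supplies an analytic parameterisation; the default is chord length.  Note
that an ellipse traversed by arc length is *not* a pure first harmonic —
only the uniform angular parameterisation is — a standard property of the
transform worth remembering when validating against analytic shapes.

**Normalisation.**  Translation terms are dropped, and all coefficients
are divided by the semi-major axis of the first-harmonic ellipse (the
largest singular value of the first-harmonic coefficient matrix, which is
rotation invariant).  Rotation alignment to the first ellipse is
implemented but **off by default**: a binocular field has a biologically
meaningful vertical (elevation) axis, and aligning every outline to its
own first ellipse would erase the up/down anatomy.  The fully
rotation-invariant shape definition is available via
`align_rotation=True`.

**Harmonic selection** uses the cumulative harmonic power
p(n) = (aₙ²+bₙ²+cₙ²+dₙ²)/2 with threshold 0.99 by default (the pipeline
applies it to the mean cumulative power across outlines), alongside the
reconstruction-distance curve for visual inspection.  Reconstruction
error (RMS distance to the best reconstruction at shared parameter
values) is non-increasing in the harmonic count by Parseval's identity —
but only weakly so: outlines with symmetries have entire harmonics with
zero power (a square's even harmonics, for instance), across which the
error is exactly flat.

**Shape space.**  Covariance PCA (coefficients share units after
normalisation) of the column-centred coefficient matrix; exact
zero-variance columns (e.g. entries fixed by normalisation) are dropped
with a warning and reinstated as constants on reconstruction.  A matrix
with no variation is flagged degenerate and downstream regressions are
skipped.

## Phylogenetic comparative statistics

**Covariance.**  C_ij is the shared root-to-MRCA path length.  Pagel's λ
multiplies the off-diagonal of C; λ is bounded to [0, 1], within which
C_λ remains positive semidefinite on ultrametric trees.  Non-ultrametric
trees are accepted with a warning and the same off-diagonal rule.

**PGLS.**  Full maximum likelihood (not REML) of the Gaussian model
y ~ MVN(Xβ, σ²C_λ).  β̂ and σ̂² have closed forms given λ; the λ profile
is maximised by a 101-point grid pre-scan followed by bounded scalar
refinement in the bracketing interval, so the returned optimum dominates
the grid by construction.  On ultrametric trees C_λ = λC + (1−λ)t₀I
shares C's eigenvectors, so one eigendecomposition (cached on the tree)
serves every λ evaluation; otherwise a Cholesky factorisation per λ is
used.  Standard errors use the unbiased residual variance and Student-t
with n − p degrees of freedom, which makes the λ = 0 (or star-tree) fit
agree with ordinary least squares exactly.  AIC counts the βs plus σ²
plus λ.  On a star phylogeny λ is unidentifiable (C_λ is independent of
λ); estimates there are arbitrary within the bounds and the coefficient
table is unaffected.

**Stepwise selection** starts from the intercept-only model and accepts,
per step, the single add or drop move with the lowest AIC until no move
improves it; factors move as whole blocks with treatment contrasts
(reference levels: diet = invertebrate, habitat = dense).  Singular
candidate designs are flagged and skipped.  Small-sample behaviour worth
knowing: with ML-AIC and λ re-estimated per candidate model at n ≈ 23,
each pure-noise candidate is retained roughly 20% of the time, so the
intercept-only model is the modal — not majority — outcome under a
global null.  No multiple-testing correction is applied, and the output
metadata says so.

**Phylogenetic ANOVA.**  The observed statistic is the ordinary one-way
ANOVA F on the raw tip values (the tree plays no role in it); its null
distribution comes from BM simulations on the tree with the rate
estimated from the data by ML, keeping the observed group labels.
p = (#{F_sim ≥ F_obs}+1)/(n_sims+1), with resolution 1/(n_sims+1);
defaults n_sims = 1000 and a mandatory seed.  Constant data give F = 0;
zero within-group variance with distinct means gives an infinite F,
flagged.

**Ancestral states** under BM are the joint ML states: the minimiser of
the sum over branches of squared changes divided by branch length, a
weighted-Laplacian linear system with tips clamped; the root state equals
the GLS phylogenetic mean.  Branch lengths below 10⁻⁹ are floored for
the weights.

**MCC trees.**  Clade frequencies are tallied across the sample; the
sampled tree with the highest sum of log clade frequencies wins (log sum
for numerical stability; ties go to the first).  Node heights are
replaced by the mean height of each clade across the trees containing
it; a negative branch implied by conflicting means is clamped to zero
with a warning.

**Ambiguous diet.**  A species with a 50/50 diet is handled by a pipeline
switch that runs every diet analysis twice, coding the species each way;
both tables are reported.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
a Yule tree (pure birth from two lineages, tips extended to the present,
so ultrametric), traits y = Xβ + ε with ε ~ MVN(0, σ²C_λ) on the
height-normalised tree, diet and habitat labels drawn independently of
the phylogeny, and per-individual perimeter records built from a
tent-shaped width profile peaking at the species maximum with zero
crossings half a vertical extent above and below.  One grid row past
each crossing carries the negative signed overlap, so the extent is
exactly recoverable; with zero individual noise the whole measurement
stack is an exact round trip, which the tests exploit.  Defaults are the
study conditions: 23 species, 1–3 individuals with ~2° repeatability,
intercepts/effects equal to the fitted values of the real analysis
(maximum overlap 52.6° with diet[vertebrate] −3.6°, habitat[semi-open]
−5.0°, habitat[open] −9.8°; vertical extent 97.1° with −9.7/−3.0/−9.1;
bill-tip offset 34.3°), λ = 0.97 for vertical extent and ~0 elsewhere,
BM standard deviations of 4–6° chosen to match the reported standard
errors at n = 23.  Each stage draws from its own RNG stream derived from
the master seed, so stages regenerate independently.

What it does **not** emulate: real facial-disc feather boundaries and
their asymmetries (tent profiles are symmetric, so synthetic shape
spaces are nearly two-dimensional and PC1+PC2 captures almost all
variance, more than in real outlines), eye-movement variability,
correlated diet/habitat/phylogeny structure, measurement error in the
covariates, or raptor eye anatomy.  Passing tests therefore demonstrate
the correctness of the computations and the recoverability of effects
under the assumed model — not that real owl data satisfy the model.

## Degenerate inputs and tie-breaks

Zero-variance responses are flagged and reported as intercept-only;
all-zero profiles yield a degenerate summary; identical outlines yield a
degenerate shape space; equal maximal widths resolve to the lowest
elevation; equal stepwise AICs keep the current model (moves must improve
by more than 10⁻¹⁰); λ at a bound (≤10⁻⁴ or ≥1−10⁻⁴) is reported as a
reached bound.

## Problem sizes

The test suite and the acceptance script run the study-sized synthetic
analyses (23 owls, 20 raptors, 100-tip recovery simulations, 200-replicate
parameter-recovery batches, 500×999 ANOVA calibration), sizes chosen to
give stable Monte-Carlo checks at interactive runtimes.
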