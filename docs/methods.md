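# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

An EEM is stored as an emission × excitation intensity matrix on strictly
increasing wavelength grids; a dataset stacks grid-aligned EEMs into a
three-way array (samples × emission × excitation). Cells excised during
preprocessing are carried in an explicit boolean mask and are *missing*, never
zero, for every downstream fitter.

Sample-mode unfolding uses a fixed, documented column order — emission index
fastest, excitation slowest — so a variable-wise vector (a VIP profile, a
loading) can always be refolded onto the wavelength plane. Grid cropping is
closed-interval inclusive on both ends; on a 240–800 nm grid with 5 nm steps
this yields the canonical 113 absorbance variables and, for 260–400 nm
excitation, 29 excitation points.

The analysis emission grid is defined as exactly 64 evenly spaced points on
[310, 600] nm. An instrument-style grid (242–824 nm at a 4.66 nm increment)
restricted to that window would give 62–63 points; we fix the count at 64 so
the canonical 35 × 64 × 29 array and 35 × 1856 uEEM dimensions hold exactly,
and note the discrepancy rather than resolving it.

## Preprocessing

**Inner filter effect.** With absorbance measured on the same solution in a
1 cm cell, the attenuation of excitation and re-absorption of emission is
undone multiplicatively: `F_corr(λ_ex, λ_em) = F_obs · 10^{(A(λ_ex)+A(λ_em))/2}`.
Absorbance is interpolated linearly onto the EEM grids; the correction warns
above 2 AU, where the approximation degrades. This correction never decreases
an intensity when absorbance is non-negative.

**Rayleigh scatter.** Cells with |λ_em − λ_ex| ≤ 10 nm (first order) or
|λ_em − 2λ_ex| ≤ 15 nm (second order) are excised. The halfwidths are package
defaults (removal is standard practice but widths are rarely reported). Excised cells
are masked for PARAFAC (missing-data ALS) and interpolated along the emission
axis for PCA/PLS-DA, which require complete matrices; a column fully inside a
band falls back to masking with a warning. Removal is idempotent.

**Replicates.** Three measurements per sample are averaged cell-wise after
IFE correction and scatter removal (the fixed stage order IFE → scatter →
averaging); a cell masked in any replicate is masked in the mean. Sample
dilution is treated as a preparation constant — uniform dilution cancels in
all relative analyses.

## PARAFAC

The trilinear model is fitted by alternating least squares with, by default,
non-negativity on all three modes — concentrations and spectra are physically
non-negative; an unconstrained mode is kept for comparison. Each mode update
solves its row-wise normal equations restricted to observed cells. Because
the scatter mask is shared across samples, the sample-mode Gram matrix is
common to all rows and the updates reduce to small einsum contractions; the
general per-sample-mask path is also implemented. The non-negative row
problems are solved exactly by enumerating candidate active sets of the
(small) component dimension and keeping the feasible solution with the lowest
quadratic objective; rows where an ill-conditioned Gram would produce a worse
update retain their previous value, which makes the ALS objective
non-increasing by construction (asserted at every iteration).

Defaults: tolerance 1e−8 on the relative fit change, 2000 iterations, 10
random uniform(0.1, 1) starts, seed-controlled. The best start by residual
sum of squares is kept. Emission and excitation loadings are normalised to
unit Euclidean norm with the magnitude pushed into the scores (so scores are
intensity-scaled), components are ordered by explained sum of squares, and in
the unconstrained case the sign indeterminacy is resolved by making each
loading's largest-magnitude element positive. The test suite and acceptance
script run with 2 starts, tolerance 1e−6 and 400–600 iterations: the
synthetic four-component problem is well conditioned and these settings
reach the same solution at a fraction of the cost.

**Diagnostics.** Explained variance is 100·(1 − SS_res/SS_tot) over observed
cells. CORCONDIA computes the least-squares Tucker3 core with the fitted
loadings held fixed (explicit dense regression over observed cells) and
measures its distance from the superidentity; it is 100 for exact trilinear
data and any one-component model, is scale-invariant, and collapses (or is
reported as undefined, for numerically singular loadings) when the model is
overfactored. Split-half validation partitions samples into two
class-stratified halves, fits each independently, matches components by
Hungarian assignment on combined emission/excitation Tucker congruence, and
reports 100 × the mean absolute congruence; the similarity measure a vendor
package prints may differ in detail, so ours is documented as this specific
congruence mean. Component-number selection scans a candidate range and picks
the largest candidate whose CORCONDIA stays at or above a floor (default
80%), falling back to the smallest candidate with a warning.

Class differences in component scores use the pooled-variance two-sample
Student's t-test at α = 0.05.

## PCA and PLS-DA

PCA is plain SVD on mean-centered data (autoscaling optional; centering is
the convention for same-unit spectral variables), deterministic up to a sign
fixed by the largest-loading-positive rule. Rank assessment uses a
leave-one-out predictive residual table (project the held-out, train-centered
sample on the training loadings); the table is reported without an automatic
choice.

PLS-DA regresses a two-column 0/1 dummy matrix (column order fixed:
direct, processed) on mean-centered X with NIPALS PLS2 (scikit-learn's
`PLSRegression`); a sample is assigned to the class with the larger predicted
dummy value — a simple, symmetric rule with no fitted threshold. The
latent-variable count is chosen by cross-validation (leave-one-out by
default, venetian blinds with stratification fallback available) with a
parsimony rule: the smallest count within one misclassified sample of the
minimum. Reported metrics are calibration (fitted-model) metrics with the CV
table alongside; because "class 1" is a convention, sensitivity and
specificity are reported under both positive-class choices. VIP uses the
standard weight/Y-variance formula, normalised so Σ VIP² equals the variable
count; with all latent variables retained on full-rank data the predictions
coincide with ordinary least squares (verified against a direct solver in the
tests).

## Synthetic data generator

The generator emulates the study design: 15 direct and 20
processed samples, three replicate measurements, four fluorophores with
Gaussian band profiles at the literature excitation/emission maxima
(275/345, 275/318, 305/425 and dual-excitation 270 + 365/470 nm, amplitude
ratio 0.8 : 1), and class-wise score distributions with the literature
mean ± sd for each class.

Design choices that were genuinely open:

- **Profile widths.** Only band maxima are reported in the literature; widths are free
  parameters. They are set per fluorophore (excitation sd 16/11/15/15 nm,
  emission sd 26/20/28/30 nm) on spectroscopic grounds — broad
  hydroxybenzoic-acid bands versus the narrow catechin-like band. The
  distinct widths of the two fluorophores sharing a 275 nm excitation maximum
  also keep the trilinear decomposition identifiable (identical excitation
  profiles would collapse the excitation matrix's Kruskal rank and make the
  factorisation non-unique).
- **Score distributions.** Scores are normals truncated below and re-targeted
  (by solving for the underlying location/scale) so the *post-truncation*
  mean and sd equal the configured values; empirical means converge to the
  configured ones. The truncation floor is 0 except for the browning
  component in the processed class, which is floored at 1870 (the direct
  mean + 3 sd): every pasteurized sample carries at least a thermal-treatment
  level of browning products, matching the complete class separation this
  component showed in the emulated study. Scores co-vary within class through
  a Gaussian copula (rank correlation 0.65 among the polyphenol components,
  0.3 to the browning component) — real juice fluorophores scale together
  with overall juice strength, which is what gives real uEEM data its
  PC1-dominant variance structure.
- **Absorbance model.** Gaussian bands: a UV band at 265 nm (direct) or
  275 nm (processed), anthocyanin-like visible bands at 500 nm with a 430 nm
  shoulder scaled by a per-sample pigment level, and a browning *absorption
  edge* — a sigmoid rising toward the UV, the characteristic shape of
  HMF/melanoidin absorption, not a discrete visible band — whose amplitude is
  a processed-class base level plus a term proportional to the sample's
  browning fluorophore score. Processed samples additionally draw one of
  three scenarios: unmodified, a +25 nm anthocyanin shift (addition of other
  fruits), or reduced visible amplitude (pigment decomposition). These
  choices make the visible region class-informative in the way processing
  plausibly makes it so.
- **Noise and scatter.** Replicate noise is 2% multiplicative plus an
  additive floor of 5 counts; Rayleigh ridges are Gaussian cross-sections
  (amplitudes 2000/600 counts, widths 4/6 nm) added after IFE attenuation;
  absorbance noise is 0.002 AU. IFE attenuation uses each sample's simulated
  absorbance, so correction with the measured spectrum recovers the stored
  clean EEM to within noise (the generator keeps the unattenuated truth as an
  oracle).

What the generator does **not** emulate: Raman scatter, instrument drift,
detector saturation, wavelength-dependent sensitivity, non-trilinear
class-dependent spectral shifts (real processed juices show emission extended
to longer wavelengths beyond what a common set of component profiles can
express), and any matrix effects beyond the inner filter effect. Passing
recovery tests therefore demonstrate correctness of the algorithms under the
stated statistical conditions, not instrument-level realism.

A consequence worth stating: with the literature score moments, a
least-squares dummy-response classifier places its boundary near the midpoint
of the two class means, so processed samples legitimately drawn in the lower
tail of the browning-score distribution can fall on the wrong side even when
the classes do not overlap. Zero training misclassification on unfolded EEMs
at a parsimony-chosen latent-variable count is therefore *not* a robust
property of these study conditions, even though it was observed on the real
data; the visible-absorbance block, whose class difference is a distinct
spectral shape rather than a score magnitude, reaches zero error in the large
majority of simulated studies.

## Problem sizes and determinism

All analyses run on the canonical study size (35 × 64 × 29; ~2 × 10³ uEEM
variables). Stochastic study-level checks use 20 independently seeded
generator runs. Every source of randomness — simulation draws, ALS starts,
split-half partitions, CV fold construction — derives from one master seed
via spawned `SeedSequence`s; a rerun with the same seed is numerically
identical.
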