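# Methods

This note documents the models, conventions, and numerical choices
behind craniogen, and what the synthetic-data tests do and do not
establish about real data.

## Coordinate conventions and orientation standardization

All coordinates are millimetres. Landmark files may arrive in Slicer's
LPS convention (`.fcsv`, Markups JSON); readers convert to RAS so every
dialect yields the same right-handed frame. `standardize_orientation`
then applies a rigid transform (rotation + translation, never scale):
the nasion maps to the origin, the midsagittal plane through nasion,
anterior nasal spine, and posterior nasal spine maps exactly to x = 0,
and the Frankfurt plane (both porions plus the left orbitale, the
standard cephalometric convention for the third point) defines the
vertical axis after projecting out its midsagittal component. The two
anatomical planes are not exactly orthogonal in real heads, so the
midsagittal constraint is honoured exactly and the Frankfurt constraint
up to that projection; because every one of the 21 measurement
variables is rigid-invariant, this choice affects axis labels only,
never a measured value (the test suite asserts invariance to random
rigid motions at 1e-9).

The mid-dacryon md is always recomputed as the dR/dL midpoint; a
supplied md more than 0.5 mm from that midpoint is overwritten with a
logged warning. Sided rhinion labels are merged to the midline rhi by
midpoint. "a" in the a-ba depth measurement is the cephalometric
A point.

## Measurement variables

13 distances (n-me, n-ans, a-ba, n-ba, n-s, poR-poL, sorR-sorL,
fzsR-fzsL, orR-orL, dR-dL, n-g, n-rhi, n-md), 7 angles (g-n-rhi,
md-n-g, s-n-g, s-n-rhi, s-n-md, dR-n-dL, dR-s-dL; the vertex is the
middle symbol), and the n-md/dR-dL ratio. The eight nasal-root
variables used as association outcomes are the 7 angles plus the ratio.
Angle cosines are clamped to [−1, 1] before `arccos`. Dahlberg's error
is `sqrt(Σd²/2N)` per landmark and axis; when both replicates carry
independent digitization noise of SD s, E[ME²] = s², so ME estimates
the per-measurement SD — the Monte-Carlo tests check this closed form.

## Procrustes analysis and PCA

GPA operates on the 13 upper-face landmarks (g, n, dR, dL, sorR, sorL,
fzsR, fzsL, rhi, orR, orL, ans, A, in fixed order). Each configuration
is centered, scaled to unit centroid size (scaling can be disabled via
`scale=False` for size-preserving analyses), and rotated to the running
consensus by orthogonal Procrustes with reflections forbidden
(determinant +1), preserving anatomical chirality. The consensus is
initialized from the mean of the centered/scaled configurations —
making the procedure exactly invariant to subject order — and iterated
until the RMS consensus change falls below 1e-10 (max 100 iterations).
The GPA objective (summed squared distance to the consensus) is
recorded per iteration and asserted non-increasing. Because the GPA
solution is defined only up to a global rotation, the converged
configurations are finally rotated onto the consensus' principal axes
with deterministic signs; this makes aligned coordinates a pure
function of shape content, invariant to the orientation in which
subjects were digitized.

PCA is an eigendecomposition of the covariance (not correlation) matrix
of the flattened 39-dimensional aligned coordinates, the standard
convention in geometric morphometrics. Eigenvector signs are fixed by
making the largest-magnitude loading positive so PC score signs are
reproducible; note that sign conventions are exactly the kind of
artifact that can flip the apparent direction of a PC association when
PCA is run separately per cohort, which is why the pipeline runs PCA
jointly across populations by default. Wireframe exports displace the
mean shape by ±k·SD along a chosen eigenvector (k = 3 by default).

## Two-locus phasing and LD

For two biallelic SNPs the only phase-ambiguous genotype is the double
heterozygote, so maximum-likelihood phasing reduces to a small EM under
random mating: the E-step splits double-heterozygote mass between the
cis (hAG/hGA) and trans (hAA/hGG) resolutions in proportion to the
current products of haplotype frequencies, and the M-step re-estimates
frequencies from expected gamete counts. Allele-frequency margins are
preserved exactly at every iteration, the log-likelihood is
non-decreasing (asserted), and convergence is declared when the largest
frequency change falls below 1e-10 (max 10,000 iterations; uniform
initialization, with an optional multi-restart guard). This is a
deliberate, documented substitute for coalescent-based phasing
software: with two SNPs the Bayesian prior adds nothing, and the ML
solution is the natural in-house equivalent. Tests verify that the EM
likelihood dominates a dense grid search (a 0.02-step grid over the
full frequency simplex plus a 0.001-step grid along the
margin-constrained slice that contains the MLE) and that frequencies
simulated at the published values are recovered within ±0.03 at n=500.

LD uses the closed forms D = f(hAG) − pq, D′ = D/Dmax with the
sign-dependent frequency bound, and r² = D²/(p(1−p)q(1−q)). Published
D′/r² values for the real cohorts are not recoverable from the rounded
published haplotype frequencies (the original analysis used unrounded
subject-level genotypes), so LD is validated against the closed-form
arithmetic, not against those printed values.

Haplotype copies for the regression design resolve unambiguous
genotypes by counting; double heterozygotes take the resolution with
the larger frequency product (posterior recorded), with an
expected-dosage mode for sensitivity analysis.

## Regression models and inference

All models are OLS (via statsmodels) with sex coded male = 0,
female = 1 (the coding affects only the intercept and the sex term's
sign). Age is deliberately excluded: the cohorts are adults in whom
nasal-root growth has ceased. Inference is t-based with residual
degrees of freedom — this, not normal inference, reproduces the
published single-SNP p-value of 1.4e-2 for B = −1.878, SE = 0.758 at
df = 198. Exact fits (SE = 0) report a sentinel p of 1e-15;
rank-deficient designs (monomorphic SNPs, collinear columns) are
flagged without p-values; missing data are handled by listwise deletion
with logged counts.

Cross-population comparisons screen each group with Shapiro–Wilk at
α = 0.05 and take ANOVA + Tukey HSD when all groups pass, else
Kruskal–Wallis + Dunn with tie-corrected rank variance (pairwise
p-values unadjusted by default, Holm optional); the chosen path is
always logged. Genotype-group summaries offer both omnibus families.
The Bonferroni threshold defaults to α/16 = 0.003125 for the
8 nasal-root outcomes × 2 SNPs family.

Meta-analysis is fixed-effect inverse-variance with a normal combined
p; fixed-effect arithmetic exactly reproduces the published combined
columns from the per-population coefficients, which is how that default
was validated. A DerSimonian–Laird random-effects option and Q/I²
diagnostics are provided. One numerical fine point: combining the
published 3-decimal per-population pairs for rs7559271 × md-n-g gives
p = 0.00314 at full precision, a hair above the 0.003125 threshold,
while the estimate at its reported 3-decimal precision
(−1.546/0.523) gives p = 0.00312, just below — the acceptance check
therefore evaluates the Bonferroni comparison at the reported
precision, which is also how the published claim is stated.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws two haplotypes per subject (random mating) at the
published population frequencies, giving Hardy–Weinberg genotypes whose
true phase is retained for validating the EM. Sex follows the
published cohort ratios. Landmarks start from a hand-constructed
20-landmark template in the standardized frame whose 21 measurements
match the Japanese male cohort means to within ~0.8 mm/0.5°; females
get a 0.94 global scale plus a 0.45 mm anterior nasion offset, and the
Egyptian template a 1.0 mm anterior nasion offset, reproducing the
direction of the published sex and population contrasts in the
nasal-root angles. The planted genotype effect is geometric — an
anterior nasion displacement per rs7559271 derived allele, root-found
on the noiseless template so the implied md-n-g slope equals the
configured target (default −1.8°/allele, the published Japanese
magnitude) — so the geometry and statistics modules are exercised
jointly; a direct-on-measurement mode exists for statistics-only
tests. I.i.d. Gaussian landmark noise (0.7 mm per axis) was calibrated
once so cohort md-n-g SD lands in the 7–8° range of the published
tables; repeat digitizations add 0.3 mm noise to both replicates,
matching the published 0.10–0.53 mm Dahlberg errors in order of
magnitude. All constants live in the template JSON, not in code.

Limitations: landmark noise is i.i.d. across landmarks and axes, so
the synthetic shape covariance has none of the anatomical correlation
structure of real faces — PCA variance concentrations seen in real
cohorts (e.g. a handful of PCs capturing most variance) are not
reproduced, and passing shape tests demonstrates algorithmic
correctness, not biological realism. Effects are planted only on the
nasion; real *PAX3* effects may be spatially distributed. No
population stratification, relatedness, genotyping error, or
Hardy–Weinberg violation is simulated.

## Problem sizes used in the test battery

Simulation-based checks use: 2,000 null replicates of n=150 for
single-SNP type-I error (target band 0.035–0.065 at α=0.05); 200
replicates of the full Japanese-sized cohort (n=201) for planted-slope
recovery (observed mean bias ≈ −0.06°/allele, CI coverage ≈ 0.945);
1,000 three-population replicates for meta-analysis null calibration;
500 digitization pairs for Dahlberg Monte-Carlo (±0.03 mm agreement
with the closed form); and n=500 subjects for EM frequency recovery
(±0.03). These sizes make the whole suite run in about a minute while
keeping Monte-Carlo error well inside each acceptance band.
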