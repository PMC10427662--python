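# Methods

`kernelscan` tests whether a set of SNPs has a *nonlinear* effect on a
quantitative trait, at sample sizes where the dense-kernel version of the
test is infeasible. This note describes the model, the approximations, the
numerical choices, and what the synthetic-data checks do and do not
establish.

## Model and test

For phenotypes **y** on *N* individuals, covariates **X** (N x P) and
standardized genotypes **z**_i over the *M* SNPs of a tested set, the
variance-component model is

    y ~ N(X b, sg2 * K + se2 * I),    K_ij = k(z_i, z_j),

with the radial basis function kernel k(z, z') = exp(-gamma * ||z - z'||^2 / 2).
The null hypothesis of no set effect is sg2 = 0, tested with the score
statistic

    Q = y' P K P y / se2,    P = I - X (X'X)^-1 X',

which is asymptotically a weighted sum of 1-df chi-squares, the weights
being the eigenvalues of P K P. The noise variance is the plug-in estimate
se2_hat = y'Py / (N - r), with r the achieved rank of the fixed-effect
design (rank is used, not the nominal column count, so collinear designs —
which superwindows readily produce — do not corrupt the degrees of
freedom). se2_hat is computed once per window: the null model does not
involve gamma, so it is shared across the hyperparameter grid.

The asymptotic weighted-chi-square null with a plug-in variance is used
throughout; finite-sample exact score distributions are out of scope.

## Random Fourier features

The kernel is shift-invariant, so by Bochner's theorem it is the
characteristic function of a spectral density; for this parameterization
the density is N(0, gamma * I_M). Sampling D frequencies omega_d from it
and phases b_d ~ Uniform[0, 2pi) gives features

    phi_d(z) = sqrt(2/D) * cos(omega_d' z + b_d),

whose Gram matrix K~ = Phi Phi' is an unbiased Monte Carlo estimate of K.
The cosine-with-phase variant is used (one feature per frequency), not the
paired sin/cos variant. Substituting K~ for K makes the statistic
||Phi_res' y_res||^2 / se2_hat and the null weights the squared singular
values of the projected feature matrix Phi_res = P Phi, so the approximate
path never materializes an N x N matrix; peak memory is O(N * D).

The approximation dimension is set relative to the set size: D = 50 M for
confirmatory tests, D = 10 M for the cheap genome-wide screen. D = 50 M is
the point where, in our concordance checks, the feature-space p-values
track the dense-kernel p-values closely; the residual feature-sampling
jitter shrinks like 1/sqrt(D) and is the price paid for linear-in-N cost.
Concordance also depends on the *effective dimension* of the window's
kernel: windows of mutually correlated SNPs (real LD) have concentrated
spectra that D = 50M features track tightly, while windows of independent
SNPs at gamma = 0.1 can have several hundred effective degrees of freedom
and correspondingly looser p-value correlation (~0.89-0.90 in our
desk-scale checks rather than the >= 0.9 seen with array-like LD). The
concordance harness therefore simulates array-like adjacent-SNP LD
(copying rate 0.6).

Feature maps are drawn from seeds derived deterministically from
(global seed, window index, gamma index, replicate index), so multi-seed
confirmation and reruns are bit-for-bit reproducible.

## Projection and the superwindow

Linear signal must be removed before a nonlinear test is meaningful: a SNP
in LD with the tested set but outside it carries linear effects that can
masquerade as nonlinear structure of the set. The fixed-effect design
therefore contains, besides the intercept and covariates, the standardized
genotypes of a *superwindow*: the target window plus two flanking windows
on each side (size five, clipped at chromosome ends). For gene-based
windows, flanks are taken as +/- 2x the gene span in base pairs.
Optionally the squared standardized genotypes of the target window and all
within-window pairwise products can be added, to ask whether signal
survives removal of quadratic/pairwise structure.

Projection is realized through a pivoted-QR orthonormal basis of the
nuisance columns; the N x N projector is never formed, and numerically
dependent columns are dropped and logged.

Phenotypes are inverse-rank-normalized: rank k of n maps to
Phi^-1((k - 0.5)/n), ties receiving average ranks. The symmetric offset
avoids infinite quantiles and gives an exactly order-preserving,
median-zero transform.

## Adaptive hyperparameter selection

gamma is not known a priori, so each window is tested on a grid (default
{0.01, 0.1, 1.0}, decade-spaced around the scale at which nonlinear signal
has been reported for standardized genotypes) and the minimum p-value is
the statistic. Under independence the minimum of H uniforms is
Beta(1, H); in practice the per-gamma tests share data, so a two-parameter
Beta null is fitted by maximum likelihood either to the observed
genome-wide minima (valid when most windows are null — the default for
epistasis scans) or to minima recomputed on phenotypes permuted ten times
(the default when linear effects are deliberately left in, where many
windows are non-null). Values exactly 1 are clipped to 1 - 1e-12 before
fitting (boundary likelihood degeneracy); a method-of-moments fallback is
flagged if the MLE fails. The adjusted p-value is the fitted Beta CDF at
the observed minimum. With fewer than 50 windows no stable fit exists and
the theoretical Beta(1, H) is used (logged).

The genome-wide scan is two-stage: every (trait, window) pair is screened
at D = 10M; pairs with adjusted p < 1e-5 are retested at D = 50M under
five independent feature-map seeds, and declared significant only if **all
five** adjusted p-values clear the Bonferroni threshold
0.05 / (n_windows x n_traits). Stage-2 minima are adjusted with the Beta
null fitted from the stage-1 genome-wide scan of the same trait: stage 1
is the only place a genome-wide ensemble of minima exists, and the Beta
null describes the min-over-grid selection effect, which does not change
between stages.

## Weighted-chi-square tail probabilities

p = Pr(sum_n rho_n chi2_1 > Q) is computed by numerical inversion of the
characteristic function (Imhof's integral) with adaptive quadrature at
requested absolute accuracy 1e-12; a single weight is dispatched to the
exact scaled-chi-square closed form. If the quadrature fails or returns a
value outside (0, 1], a Liu-type moment-matched noncentral-chi-square
approximation is used and flagged in the result. Realized absolute
accuracy of the inversion is ~1e-9 (verified against a Ruben-series
reference and Monte Carlo); consequently *relative* accuracy degrades for
p below ~1e-7, a known property of this formulation shared by standard
implementations. Weights below 1e-8 of the largest are discarded — they
are numerically zero directions created by the projection, not signal.

## Synthetic data

The generator produces biallelic hard calls with per-variant MAF uniform
on a configurable range (default [0.01, 0.5]), laid out so that fixed
100 kb windows hold a set number of SNPs (default 17, matching typical
array density). Three LD processes are available:

* **copying** (default): each haplotype allele copies its left neighbour
  with probability r, else is drawn fresh. Adjacent haplotype correlation
  is r; analytically transparent. Its cross-SNP conditional means are
  *exactly linear* (E[z_out | z_in] = r z_in + const per haplotype), so
  flanking-window linear effects are entirely absorbed by the target
  window's linear span — this process cannot generate the LD-driven
  miscalibration that motivates the superwindow.
* **gaussian**: thresholded latent Gaussian AR(1); mildly nonlinear
  conditional means across unequal MAFs (measured nonlinear leakage
  ~0.1-0.2 R^2 per window at r = 0.95 — too weak for a desk-scale
  stress test).
* **founder**: within blocks of consecutive sites (default three windows
  wide), haplotypes copy one of K founder haplotypes (default K = 40; the
  stress test uses K = 80) and mutate at a small rate. When K exceeds the
  window's SNP count, flanking sites are additive functions of founder
  identity that the window's linear span cannot represent but its
  quadratic span partially can — the essential feature of real haplotype
  structure. This is the model used to demonstrate that regressing out
  only the target window is insufficient while a size-five superwindow is
  calibrated.

Null phenotypes have linear architecture: round(causal_ratio x M) causal
variants drawn uniformly from a MAF bin (ALL [0.01, 0.5], COMMON
[0.05, 0.5], RARE [0.01, 0.05]), iid normal effects on standardized
genotypes, genetic component rescaled to variance h2 = 0.5 and noise to
1 - h2 (effect-size distribution on the standardized scale is a modelling
choice; nothing downstream depends on it under the null). Alternatives are
Gaussian-process draws y ~ N(0, sg2 K + se2 I) via Cholesky of the dense
covariance (with a 1e-10 jitter retry, logged) or via the feature-space
equivalent for large N.

What the synthetic data does **not** emulate: realistic allele-frequency
spectra, recombination-rate variation, population stratification and
relatedness, genotyping error, and long-range LD beyond the block/chain
structure above. Passing calibration here shows the statistical machinery
is sound under the stated generative models; it does not certify
robustness to stratification or relatedness, which the method assumes have
been handled upstream (homogeneous unrelated samples, PCs as covariates).

## Desk-scale problem sizes

The automated checks run the full pipeline at sizes chosen to keep a
complete run on one CPU short while retaining statistical resolution:

* calibration: four architectures x 350 windows (17 SNPs each), N = 2,000,
  D = 10M, exact binomial CIs at alpha in {0.05, 0.01, 1e-3};
* superwindow stress test: founder LD, N = 4,000, 200 windows, pooled
  per-gamma p-values for superwindow 1 vs 5;
* exact-vs-approximate concordance: N = 1,000-2,000, 100-200 windows,
  D = 50M, Pearson correlation of p-value vectors;
* power: N = 1,000, 120 replicate windows per setting, sg2 in
  {0, 0.02, 0.05}, gamma = 0.1.

Larger, slower configurations are a command-line flag away; nothing in the
implementation is specialized to these sizes.

## Known limitations

* The exact-kernel path is O(N^2) memory and O(N^3) time and guarded at
  N = 20,000; it exists as an oracle, not a production path.
* Deep-tail p-values (< ~1e-7) from the CF inversion have limited relative
  accuracy (see above); Bonferroni-level decisions at biobank scale are
  made on p-values where this matters only marginally, but a saddlepoint
  refinement would be the natural upgrade.
* The score test's null is asymptotic in N; no small-N exactness is
  claimed.
* Binary traits, dosage/imputed input, X-chromosome models, multi-allelic
  variants and relatedness corrections are out of scope.
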