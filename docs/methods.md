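# Methods

## Model and assumptions

`paleopca` quantifies how far the least-squares PC-score estimate of an
incompletely genotyped sample can deviate from the score the complete
sample would have received.

The reference PC space is fitted on a complete diploid panel. Genotypes
(0/1/2 copies of the reference allele) are centered per locus and scaled
by the drift unit `sqrt(p_j (1 − p_j))`, `p_j = μ_j / 2`, so that allele
frequencies that drift at the same rate contribute comparably. Loci that
are invariant in the reference (`p_j ∈ {0, 1}`) carry no direction
information and are removed; only this exclusion is applied by default
(a minor-allele-frequency cutoff is available in the CLI but off by
default). The eigenvectors live in locus space (`V ∈ R^{D×Q}`, orthonormal
columns) and are taken from the SVD of the normalized matrix; eigenvalues
are `σ_k²/(N−1)`, which makes them literally the sample variances of the
reference scores — the property the error model consumes. The stated
covariance form used throughout is the feature covariance
`XXᵀ/(N−1)`; it is the only form compatible with eigenvectors of length D.

Projection of a sample observed at `M` loci solves the normal equations
restricted to the observed eigenvector rows. The error of that estimate,
for a sample whose trailing scores are `τ_Q`, is exactly
`A τ_Q` with `A = −(V_P*ᵀV_P*)⁻¹ V_P*ᵀ V_Q*`. Two assumptions turn this
identity into a predictive distribution:

1. **Moment assumption.** `τ_Q` has mean zero and diagonal covariance
   `Λ_Q`. This holds in-sample by construction and holds for held-out
   samples from the same population distribution in aggregate: the total
   squared norm of a held-out sample matches the eigenvalue trace in
   expectation, so the part of its variance that the fitted subspace does
   not capture is compensated by the inflated in-sample eigenvalues. The
   package's calibration experiments on held-out samples confirm this
   (mean KL ≈ 0.005 across rates 0.25–0.9 under the default study
   conditions).
2. **Gaussian shape.** The error aggregates contributions from thousands
   of loci, so the central limit theorem makes the Gaussian an accurate
   shape; no heavier-tailed alternative is fitted.

The prediction depends only on the missingness mask, never on the
unobserved genotype values.

### Out-of-distribution (pseudo-haploid) samples

Pseudo-haploid calling draws one allele per locus, producing calls in
{0, 2} with per-locus variance `4p(1−p)` instead of the diploid
`2p(1−p)` — a two-fold inflation at matched frequencies. The correction
estimates per-locus variance ratios `f_in` between a target panel and the
reference panel, both on the *reference* normalization scale so that the
ratio is unit-free, and projects them into component space as
`f_out = diag(Vᵀ diag(f_in) V)` (the only reading of this quadratic form
with a length-Q output; each `f_out_k` is a convex combination of `f_in`).
The propagation then uses `f_out ⊙ Λ_Q`. With `f_in ≡ 1` the adjusted and
unadjusted predictions coincide exactly.

Sparse-locus handling: per-locus variances use observed genotypes with an
`n−1` denominator; loci with fewer than two observed genotypes on either
side, zero reference variance, or zero target variance (common when the
target panel is small) fall back to the mean of the well-defined factors.
The zero-target-variance fallback keeps `f_in` strictly positive, as the
downstream variance model requires.

## Downsampling validation

The calibration protocol takes a high-coverage sample, treats its
projection as the true embedding, omits exactly `round(r·M)` observed
genotypes uniformly at random (ties-to-even rounding; previously missing
entries untouched), re-projects, and repeats `n` times. The empirical
Gaussian uses the sample mean and the `n−1` covariance of the
discrepancies; the predicted Gaussian is centered at zero with the
per-replicate predicted covariances averaged (masks at the same rate give
near-identical predictions at these dimensions). The two are compared by
the closed-form Gaussian KL divergence, in the direction
KL(empirical ‖ predicted); the reverse direction is also stored on each
result. Replicates whose observed-row Gram matrix is numerically singular
are skipped and counted.

The replicate engine subtracts the omitted rows' contribution from
base-mask Gram/cross products rather than re-slicing the observed rows,
and batches replicates; all replicate randomness flows from one seed
through per-rate child sequences, so identical seeds give bit-identical
results regardless of chunking.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
any particular dataset: K populations diverged from a common ancestral
pool under a Balding–Nichols model (ancestral frequency uniform on
[0.05, 0.95]; population frequency Beta-distributed with mean equal to the
ancestral frequency and variance `F·p(1−p)`; diploid genotypes
Binomial(2, p)). Defaults — 3 populations × 50 samples, 2,000 loci,
F = 0.02 — put the divergence at the upper end of within-continental human
differentiation and give clearly separated populations on PC1/PC2 at a
size that runs in seconds. Pseudo-haploid and held-out diploid samples are
drawn from the same population frequencies (round-robin population
assignment), so they are in-distribution by construction.

What the generator does *not* emulate: linkage disequilibrium between
loci, genotype-calling error, contamination, reference bias, admixture
gradients, and real site-frequency spectra. Passing calibration on these
panels therefore shows the propagation machinery is correct under the
model's own assumptions; on real data, additional error sources make the
predicted ellipses a lower bound on total uncertainty.

## Numerical choices

- Components are kept up to the numerical rank (singular values above
  `1e−9` of the largest), at most `N−1`; the trailing complement `Q` of
  the error model defaults to everything beyond the visualized `P = 2`.
- Eigenvector signs follow a largest-entry-positive convention for
  reproducible orientation.
- The Gram matrix is inverted only when its reciprocal condition number
  exceeds `1e−10`; below that the projection raises a conditioning error
  unless a pseudo-inverse is explicitly requested.
- Predicted covariances are symmetrized; eigenvalues more negative than
  `−1e−10` (relative to the matrix scale) raise an error, tinier negative
  ones are clipped to zero.
- Confidence ellipses use exact chi-square(2) quantiles
  (semi-axis `sqrt(χ²_q λ_k)`), not 1σ/2σ rules, so stated bivariate
  coverage is correct; default levels 0.5/0.9/0.95/0.99 are configurable.
- A reference sample that is fully observed reprojects onto its fitted
  scores (the Gram matrix is the identity), and its predicted covariance
  is exactly zero — both used as exactness checks in the tests.
- Ploidy is inferred per sample (pseudo-haploid iff no heterozygous call
  among at least one observed genotype) and can be overridden; the
  EIGENSTRAT format itself does not encode ploidy.
- Model bundles are serialized as a single `.npz` archive (arrays plus
  scalar metadata); variance factors are persisted the same way.

## Experiment sizes

Validation experiments use 20 test samples, rates {0.25, 0.5, 0.75, 0.9}
and 2,000 replicates per rate on the default 2,000-locus panel — enough
that Monte-Carlo noise in the empirical covariance contributes KL well
below 0.01, while a full calibration sweep completes in about a minute on
one CPU. The moment-propagation check uses 100,000 latent-score draws and
3-standard-error bands.

## Known limitations

- The moment assumption calibrates against samples from the reference
  distribution; strongly diverged targets (beyond the variance-ratio
  correction) can still be under- or over-dispersed. The factor
  correction captures scale, not direction-specific variance structure.
- Empirical variance factors require a target panel of related samples;
  for a single sample the fallback degrades to a constant factor.
- Only the packed-ASCII EIGENSTRAT dialect is supported; physical
  positions are opaque metadata.
- The downsampling model treats omissions as uniform at random, which is
  the standard protocol but optimistic for coverage patterns with strong
  genomic structure.
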