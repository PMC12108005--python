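"""Gaussian uncertainty of PC-score estimates under missing genotypes.

For a sample observed at the loci selected by a mask, the error of the
least-squares score estimate is linear in the sample's unseen trailing
scores tau_Q:

    tau_P - tau_hat_P = A tau_Q,   A = -(V_P*^T V_P*)^-1 V_P*^T V_Q*,

where * selects observed rows.  Treating tau_Q as zero-mean with diagonal
covariance Lambda_Q (the trailing eigenvalues — the score variances of the
reference panel), moment propagation gives E[error] = 0 and
Cov = A Lambda_Q A^T, so the true embedding is modeled as
N(tau_hat_P, Sigma_P).  The Gaussian shape rests on the central limit
theorem: the error aggregates small contributions from thousands of loci.

Samples whose genotype variance differs from the reference panel's (e.g.
pseudo-haploid ancient calls, whose {0,2} encoding roughly doubles per-locus
variance) violate the Lambda_Q assumption.  Per-locus variance ratios f_in
between a target and the reference panel are projected onto the components,
f_out_k = sum_i V_ik^2 f_in_i, and the propagation then uses
f_out ⊙ Lambda_Q instead of Lambda_Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .panel import GenotypePanel
from .pca import PCAModel, normalize
from .projection import ProjectionScores, align_to_model, solve_gram

#: Magnitude below which a negative covariance eigenvalue is treated as
#: numerical noise and clipped to zero (relative to the matrix scale).
PSD_TOL = 1e-10


@dataclass(frozen=True)
class DiscrepancyMap:
    """Linear map A from unseen trailing scores to the estimation error."""

    a: np.ndarray
    mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape


@dataclass(frozen=True)
class GaussianEmbedding:
    """Gaussian belief over a sample's true embedding: N(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=np.float64))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        p = len(mean)
        if cov.shape != (p, p):
            raise ValidationError(f"covariance shape {cov.shape} != ({p}, {p})")
        scale = max(1.0, float(np.abs(cov).max()))
        if np.abs(cov - cov.T).max() > PSD_TOL * scale:
            raise ValidationError("covariance is not symmetric")
        if np.linalg.eigvalsh(cov)[0] < -PSD_TOL * scale:
            raise ValidationError("covariance is not positive semi-definite")

    @property
    def p(self) -> int:
        return len(self.mean)

    @property
    def is_degenerate(self) -> bool:
        """True for a zero-uncertainty (point-mass) embedding."""
        return bool(np.all(self.cov == 0.0))


@dataclass(frozen=True)
class VarianceFactors:
    """Per-locus (f_in) and per-component (f_out) variance-inflation factors.

    Each f_out_k is a convex combination of f_in (eigenvector columns have
    unit norm), hence min(f_in) <= f_out_k <= max(f_in).
    """

    f_in: np.ndarray
    f_out: np.ndarray
    n_fallback: int = 0

    def __post_init__(self) -> None:
        if (np.asarray(self.f_in) <= 0).any() or (np.asarray(self.f_out) <= 0).any():
            raise ValidationError("variance factors must be strictly positive")


def discrepancy_map(
    mask: np.ndarray,
    model: PCAModel,
    p: int = 2,
    allow_pinv: bool = False,
) -> DiscrepancyMap:
    """Compute A = -(V_P*^T V_P*)^-1 V_P*^T V_Q* for an observation mask.

    Shape P x (Q - P).  For a fully observed mask A is exactly zero by
    orthogonality of the eigenvector columns.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (model.n_loci,):
        raise IndexError("mask length must equal the model's retained loci")
    v_p = model.eigenvectors[mask, :p]
    v_q = model.eigenvectors[mask, p:]
    if mask.all():
        # orthogonality makes the cross-Gram vanish identically
        a = np.zeros((p, model.n_components - p))
    else:
        a = -solve_gram(v_p.T @ v_p, v_p.T @ v_q, allow_pinv=allow_pinv)
    return DiscrepancyMap(a=a, mask=mask)


def propagate_covariance(
    a: np.ndarray, trailing_variances: np.ndarray
) -> np.ndarray:
    """Sigma_P = A diag(v) A^T, symmetrized and PSD-repaired."""
    sigma = (a * trailing_variances) @ a.T
    sigma = 0.5 * (sigma + sigma.T)
    return _psd_repair(sigma)


def predict_covariance(
    mask: np.ndarray,
    model: PCAModel,
    p: int = 2,
    factors: VarianceFactors | None = None,
    allow_pinv: bool = False,
) -> np.ndarray:
    """Predicted covariance of the true embedding for a given mask.

    Unadjusted, the trailing score variances are the model eigenvalues
    Lambda_Q; with ``factors`` they are inflated elementwise by f_out.
    """
    dmap = discrepancy_map(mask, model, p=p, allow_pinv=allow_pinv)
    lam_q = model.eigenvalues[p:]
    if factors is not None:
        if len(factors.f_out) != model.n_components:
            raise ValidationError(
                f"f_out has {len(factors.f_out)} entries; model has "
                f"{model.n_components} components"
            )
        lam_q = lam_q * factors.f_out[p:]
    return propagate_covariance(dmap.a, lam_q)


def predict_embedding(
    scores: ProjectionScores, sigma: np.ndarray
) -> GaussianEmbedding:
    """Gaussian belief over the true embedding: mean tau_hat, covariance Sigma."""
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.shape != (scores.p, scores.p):
        raise ValidationError(
            f"covariance shape {sigma.shape} does not match P={scores.p}"
        )
    return GaussianEmbedding(mean=scores.scores.copy(), cov=sigma)


def variance_factors(
    target_panel: GenotypePanel,
    reference_panel: GenotypePanel,
    model: PCAModel,
    min_observed: int = 2,
) -> VarianceFactors:
    """Per-locus target/reference variance ratios, projected onto components.

    Both panels are aligned to the model's retained loci and normalized on
    the same scale (the model's mu and drift units), so f_in is a pure
    variance ratio.  Per-locus variances use observed genotypes with an
    n-1 denominator; loci with fewer than ``min_observed`` observed target
    genotypes (or zero/undefined reference variance) fall back to the mean
    of the well-defined factors.
    """
    if target_panel.n_samples == 0 or reference_panel.n_samples == 0:
        raise ValidationError("variance factors need non-empty panels")
    var_t, n_t = _locus_variances(target_panel, model)
    var_r, n_r = _locus_variances(reference_panel, model)
    # a zero variance on either side makes the ratio degenerate, not informative
    ok = (n_t >= min_observed) & (n_r >= min_observed) & (var_r > 0) & (var_t > 0)
    if not ok.any():
        raise ValidationError("no locus with a well-defined variance ratio")
    f_in = np.empty(model.n_loci)
    f_in[ok] = var_t[ok] / var_r[ok]
    fallback = float(f_in[ok].mean())
    f_in[~ok] = fallback
    f_out = (model.eigenvectors**2).T @ f_in
    return VarianceFactors(f_in=f_in, f_out=f_out, n_fallback=int((~ok).sum()))


def save_factors(factors: VarianceFactors, path) -> None:
    """Persist variance factors next to a model bundle (single .npz)."""
    np.savez_compressed(
        path,
        f_in=factors.f_in,
        f_out=factors.f_out,
        n_fallback=np.int64(factors.n_fallback),
    )


def load_factors(path) -> VarianceFactors:
    with np.load(path, allow_pickle=False) as z:
        return VarianceFactors(
            f_in=z["f_in"], f_out=z["f_out"], n_fallback=int(z["n_fallback"])
        )


def _locus_variances(
    panel: GenotypePanel, model: PCAModel
) -> tuple[np.ndarray, np.ndarray]:
    aligned, _ = align_to_model(panel, model)
    x = normalize(aligned, model.locus_stats)
    n_obs = np.sum(~np.isnan(x), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # all-NaN / single-observation slices are masked out below
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(x, axis=1, ddof=1)
    var[n_obs < 2] = np.nan
    return var, n_obs


def _psd_repair(sigma: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues; raise on genuinely indefinite input."""
    eigs, vecs = np.linalg.eigh(sigma)
    scale = max(1.0, float(np.abs(eigs).max()))
    if eigs[0] < -PSD_TOL * scale:
        raise ValidationError(
            f"covariance eigenvalue {eigs[0]:.3e} is negative beyond tolerance"
        )
    if eigs[0] >= 0:
        return sigma
    eigs = np.clip(eigs, 0.0, None)
    return (vecs * eigs) @ vecs.T
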