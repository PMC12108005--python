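"""Drift-scaled PCA of a reference genotype panel.

Each locus j is centered by its mean genotype mu_j and scaled by the genetic
drift unit sqrt(p_j (1 - p_j)) with p_j = mu_j / 2, so allele-frequency
change is expressed in comparable units across loci.  Invariant loci
(p_j in {0, 1}) carry no signal and are excluded.  The principal axes are
obtained from the SVD of the normalized loci x samples matrix X: the locus-
space eigenvectors are the left singular vectors and the eigenvalue of
component k is sigma_k^2 / (N - 1), i.e. exactly the sample variance of the
reference scores on that component.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneratePanelError, ValidationError
from .panel import MISSING, GenotypePanel

#: Relative singular-value cutoff defining the numerical rank.
RANK_RTOL = 1e-9


@dataclass(frozen=True)
class LocusStats:
    """Per-locus normalization statistics of the retained (variant) loci.

    ``retained_idx`` maps each retained locus back to its row in the panel
    the statistics were computed from; ``n_total`` is that panel's locus
    count, so ``n_total - len(retained_idx)`` loci were excluded as
    invariant (or as having no observed genotype).
    """

    mu: np.ndarray
    p: np.ndarray
    s: np.ndarray
    retained_idx: np.ndarray
    n_total: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_idx)

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_retained


def compute_locus_stats(panel: GenotypePanel) -> LocusStats:
    """Mean, allele fraction and drift scale per locus; drop invariant loci.

    Means are taken over observed (non-missing) genotypes.  Loci with
    p_j in {0, 1} — and loci with no observed genotype at all — are
    recorded as excluded.
    """
    g = panel.genotypes
    obs = panel.observed
    counts = obs.sum(axis=1)
    sums = np.where(obs, g, 0).sum(axis=1, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = sums / counts
    p = mu / 2.0
    keep = (counts > 0) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise DegeneratePanelError("no variant locus retained")
    mu, p = mu[keep], p[keep]
    return LocusStats(
        mu=mu,
        p=p,
        s=np.sqrt(p * (1.0 - p)),
        retained_idx=np.flatnonzero(keep),
        n_total=panel.n_loci,
    )


def normalize(values: np.ndarray, stats: LocusStats) -> np.ndarray:
    """Center and drift-scale genotype values restricted to the retained loci.

    ``values`` is a column (length n_retained) or matrix (n_retained x n)
    of raw genotypes; missing entries (9) propagate as NaN.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.shape[0] != stats.n_retained:
        raise IndexError(
            f"values have {v.shape[0]} rows; expected {stats.n_retained} "
            "retained loci"
        )
    mu = stats.mu if v.ndim == 1 else stats.mu[:, None]
    s = stats.s if v.ndim == 1 else stats.s[:, None]
    out = (v - mu) / s
    out[np.asarray(values) == MISSING] = np.nan
    return out


@dataclass
class PCAModel:
    """Fitted reference PC space.

    ``eigenvectors`` is D x Q with orthonormal columns in locus space (D =
    retained loci); ``eigenvalues`` (length Q, non-increasing) equal the
    sample variances of the reference scores.  ``ref_scores`` holds the
    reference panel's scores, samples x Q, each column mean-zero.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    locus_stats: LocusStats
    locus_ids: np.ndarray
    n_ref: int
    ref_scores: np.ndarray | None = field(default=None, repr=False)
    ref_sample_ids: np.ndarray | None = None
    ref_labels: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        v = self.eigenvectors
        gram = v.T @ v
        if not np.allclose(gram, np.eye(v.shape[1]), atol=atol):
            raise ValidationError("eigenvector columns are not orthonormal")
        lam = self.eigenvalues
        if (np.diff(lam) > atol).any() or (lam <= 0).any():
            raise ValidationError("eigenvalues must be positive, non-increasing")
        if v.shape[1] > min(v.shape[0], self.n_ref - 1):
            raise ValidationError("more components than min(D, N - 1)")

    # -- persistence --------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Serialize the model bundle to a single ``.npz`` archive."""
        payload = {
            "eigenvectors": self.eigenvectors,
            "eigenvalues": self.eigenvalues,
            "mu": self.locus_stats.mu,
            "p": self.locus_stats.p,
            "s": self.locus_stats.s,
            "retained_idx": self.locus_stats.retained_idx,
            "n_total": np.int64(self.locus_stats.n_total),
            "locus_ids": self.locus_ids.astype(str),
            "n_ref": np.int64(self.n_ref),
        }
        if self.ref_scores is not None:
            payload["ref_scores"] = self.ref_scores
        if self.ref_sample_ids is not None:
            payload["ref_sample_ids"] = self.ref_sample_ids.astype(str)
        if self.ref_labels is not None:
            payload["ref_labels"] = self.ref_labels.astype(str)
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PCAModel":
        with np.load(path, allow_pickle=False) as z:
            stats = LocusStats(
                mu=z["mu"],
                p=z["p"],
                s=z["s"],
                retained_idx=z["retained_idx"],
                n_total=int(z["n_total"]),
            )
            return cls(
                eigenvectors=z["eigenvectors"],
                eigenvalues=z["eigenvalues"],
                locus_stats=stats,
                locus_ids=z["locus_ids"].astype(object),
                n_ref=int(z["n_ref"]),
                ref_scores=z["ref_scores"] if "ref_scores" in z else None,
                ref_sample_ids=(
                    z["ref_sample_ids"].astype(object)
                    if "ref_sample_ids" in z
                    else None
                ),
                ref_labels=(
                    z["ref_labels"].astype(object) if "ref_labels" in z else None
                ),
            )


def fit_pca(
    panel: GenotypePanel,
    stats: LocusStats | None = None,
    q: int | str = "max",
) -> PCAModel:
    """Fit the PC space of a reference panel by SVD of the normalized matrix.

    Components with numerically zero singular values (below ``RANK_RTOL``
    relative to the largest) are dropped, so Q defaults to the numerical
    rank, at most min(D, N - 1).  Requesting ``q`` beyond the rank truncates
    with a warning.  Each eigenvector is oriented so its entry of largest
    magnitude is positive, for a reproducible sign convention.
    """
    if panel.n_samples < 2:
        raise DegeneratePanelError("PCA needs at least two reference samples")
    if stats is None:
        stats = compute_locus_stats(panel)
    x = normalize(panel.genotypes[stats.retained_idx], stats)
    nan = np.isnan(x)
    if nan.any():
        warnings.warn(
            f"{int(nan.sum())} missing reference entries mean-imputed to 0",
            stacklevel=2,
        )
        x[nan] = 0.0

    n = panel.n_samples
    u, sv, wt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(sv > RANK_RTOL * sv[0]))
    if q != "max":
        q = int(q)
        if q > rank:
            warnings.warn(
                f"requested {q} components but numerical rank is {rank}; "
                "truncating",
                stacklevel=2,
            )
        rank = min(q, rank)
    u, sv, wt = u[:, :rank], sv[:rank], wt[:rank]

    # sign convention: largest-magnitude loading positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(rank)])
    flip[flip == 0] = 1.0
    u *= flip
    scores = (sv[:, None] * wt * flip[:, None]).T  # samples x Q

    return PCAModel(
        eigenvectors=u,
        eigenvalues=sv**2 / (n - 1),
        locus_stats=stats,
        locus_ids=panel.locus_ids[stats.retained_idx].copy(),
        n_ref=n,
        ref_scores=scores,
        ref_sample_ids=panel.sample_ids.copy(),
        ref_labels=None if panel.sample_labels is None else panel.sample_labels.copy(),
    )
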