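"""Downsampling experiments: empirical vs predicted uncertainty.

The experiment mirrors how projection uncertainty is measured empirically:
take a high-coverage sample, record its projection tau as the reference
("true") embedding, then repeatedly omit a fraction r of its observed
genotypes at random, re-project each replicate, and collect the
discrepancies tau_hat - tau.  The empirical Gaussian fitted to the
discrepancies is compared with the model's predicted Gaussian (zero mean,
covariance propagated per realized mask and averaged over replicates) via
the closed-form Kullback-Leibler divergence for multivariate normals.

The replicate loop is vectorized: for each replicate only the *omitted*
rows are touched, and the observed-row Gram/cross products are obtained by
subtracting the omitted rows' contribution from the base-mask products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .panel import MISSING, GenotypePanel
from .pca import PCAModel, normalize
from .projection import RCOND_MIN, solve_gram
from .uncertainty import GaussianEmbedding, VarianceFactors

#: Approximate per-chunk float budget for gathered eigenvector rows.
_CHUNK_ELEMENTS = 4_000_000


def downsample(sample: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Randomly omit a fraction ``rate`` of the currently observed genotypes.

    Exactly ``round(rate * M)`` observed entries (M = observed count) are
    chosen uniformly without replacement and set to missing; entries that
    were already missing are untouched.  Deterministic for a given seed.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate {rate} outside [0, 1)")
    sample = np.asarray(sample)
    out = sample.copy()
    obs_idx = np.flatnonzero(sample != MISSING)
    k = int(np.rint(rate * len(obs_idx)))
    if k:
        rng = np.random.default_rng(seed)
        out[rng.permutation(obs_idx)[:k]] = MISSING
    return out


def kl_gaussian(g1: GaussianEmbedding, g2: GaussianEmbedding) -> float:
    """Closed-form KL(g1 || g2) between multivariate normals.

    0.5 * [tr(S2^-1 S1) + (m2-m1)^T S2^-1 (m2-m1) - P + ln(det S2 / det S1)].
    Both covariances must be strictly positive definite.
    """
    if g1.p != g2.p:
        raise ValidationError("Gaussians have different dimensions")
    p = g1.p
    try:
        l1 = np.linalg.cholesky(g1.cov)
        l2 = np.linalg.cholesky(g2.cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular covariance in KL divergence") from exc
    solved = np.linalg.solve(g2.cov, g1.cov)
    diff = g2.mean - g1.mean
    maha = diff @ np.linalg.solve(g2.cov, diff)
    logdet1 = 2.0 * np.sum(np.log(np.diag(l1)))
    logdet2 = 2.0 * np.sum(np.log(np.diag(l2)))
    return float(0.5 * (np.trace(solved) + maha - p + logdet2 - logdet1))


@dataclass
class DownsamplingResult:
    """Replicate discrepancies and their empirical vs predicted Gaussians."""

    sample_id: str | None
    rate: float
    n_reps: int
    discrepancies: np.ndarray = field(repr=False)
    empirical: GaussianEmbedding
    predicted: GaussianEmbedding
    kl: float
    kl_reverse: float
    seed: int
    n_skipped: int = 0


def run_downsampling(
    sample: np.ndarray,
    model: PCAModel,
    rates: Sequence[float] = (0.25, 0.5, 0.75, 0.9),
    n_reps: int = 2000,
    p: int = 2,
    seed: int = 0,
    factors: VarianceFactors | None = None,
    sample_id: str | None = None,
) -> list[DownsamplingResult]:
    """Run the downsampling experiment for one genotype column.

    ``sample`` holds raw genotypes aligned to the model's retained loci.
    For each rate, ``n_reps`` random omission masks are drawn, each
    replicate re-projected, and the model's covariance prediction evaluated
    on the realized mask (averaged over replicates for the summary
    Gaussian, which is centered at zero in discrepancy space).  All
    randomness derives from ``seed``; identical seeds give bit-identical
    results.  Replicates whose Gram matrix is unprojectable are skipped
    with a warning.
    """
    sample = np.asarray(sample)
    if sample.shape != (model.n_loci,):
        raise IndexError("sample length must equal the model's retained loci")
    base_idx = np.flatnonzero(sample != MISSING)
    m0 = len(base_idx)
    if m0 < p:
        raise InsufficientDataError(f"{m0} observed loci < {p} components")

    x = normalize(sample, model.locus_stats)
    x_base = x[base_idx]
    v_p = model.eigenvectors[base_idx, :p]
    v_q = model.eigenvectors[base_idx, p:]
    g0 = v_p.T @ v_p
    b0 = v_p.T @ v_q
    z0 = v_p.T @ x_base
    tau_ref = solve_gram(g0, z0)

    lam_q = model.eigenvalues[p:]
    if factors is not None:
        if len(factors.f_out) != model.n_components:
            raise ValidationError("f_out length does not match model components")
        lam_q = lam_q * factors.f_out[p:]

    children = np.random.SeedSequence(seed).spawn(len(rates))
    results = []
    for rate, child in zip(rates, children):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"rate {rate} outside [0, 1)")
        results.append(
            _run_one_rate(
                rate,
                np.random.default_rng(child),
                n_reps,
                p,
                m0,
                x_base,
                v_p,
                v_q,
                g0,
                b0,
                z0,
                tau_ref,
                lam_q,
                seed,
                sample_id,
            )
        )
    return results


def _run_one_rate(
    rate, rng, n_reps, p, m0, x_base, v_p, v_q, g0, b0, z0, tau_ref, lam_q,
    seed, sample_id,
) -> DownsamplingResult:
    k = int(np.rint(rate * m0))
    q_rest = v_q.shape[1]
    if k == 0:
        # no omission: every replicate reproduces the reference projection
        disc = np.zeros((n_reps, p))
        sigma_mean = _sigma_chunk(
            np.linalg.solve(g0[None], -b0[None]), lam_q
        )[0]
        return _summarize(
            sample_id, rate, disc, sigma_mean, tau_ref, seed, 0
        )

    if m0 - k < p:
        raise InsufficientDataError(
            f"rate {rate} leaves {m0 - k} observed loci < {p} components"
        )

    chunk = max(1, int(_CHUNK_ELEMENTS / (k * (p + q_rest) + m0)))
    disc_rows = []
    sigma_sum = np.zeros((p, p))
    n_skipped = 0
    done = 0
    while done < n_reps:
        c = min(chunk, n_reps - done)
        # c omission masks: first k entries of a random permutation each
        omit = np.argsort(rng.random((c, m0)), axis=1)[:, :k]
        vp_om = v_p[omit]  # (c, k, p)
        vq_om = v_q[omit]  # (c, k, q_rest)
        g = g0[None] - np.einsum("ckp,ckq->cpq", vp_om, vp_om, optimize=True)
        z = z0[None] - np.einsum("ckp,ck->cp", vp_om, x_base[omit], optimize=True)
        b = b0[None] - np.einsum("ckp,ckq->cpq", vp_om, vq_om, optimize=True)

        eigs = np.linalg.eigvalsh(g)
        good = (eigs[:, 0] > 0) & (eigs[:, 0] / eigs[:, -1] >= RCOND_MIN)
        if not good.all():
            n_skipped += int((~good).sum())
            g, z, b = g[good], z[good], b[good]
        if len(g):
            tau_hat = np.linalg.solve(g, z[..., None])[..., 0]
            a = -np.linalg.solve(g, b)
            disc_rows.append(tau_hat - tau_ref)
            sigma_sum += _sigma_chunk(a, lam_q).sum(axis=0)
        done += c

    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} unprojectable replicates at rate {rate}",
            stacklevel=3,
        )
    disc = np.concatenate(disc_rows) if disc_rows else np.zeros((0, p))
    if len(disc) == 0:
        raise InsufficientDataError(f"no projectable replicate at rate {rate}")
    sigma_mean = sigma_sum / len(disc)
    return _summarize(sample_id, rate, disc, sigma_mean, tau_ref, seed, n_skipped)


def _sigma_chunk(a: np.ndarray, lam_q: np.ndarray) -> np.ndarray:
    """Batched A diag(lam) A^T, symmetrized."""
    sig = np.einsum("cpq,q,crq->cpr", a, lam_q, a, optimize=True)
    return 0.5 * (sig + np.swapaxes(sig, 1, 2))


def _summarize(sample_id, rate, disc, sigma_mean, tau_ref, seed, n_skipped):
    n = len(disc)
    emp_mean = disc.mean(axis=0) if n else np.zeros(len(tau_ref))
    emp_cov = (
        np.atleast_2d(np.cov(disc.T, ddof=1))
        if n > 1
        else np.zeros((len(tau_ref), len(tau_ref)))
    )
    empirical = GaussianEmbedding(mean=emp_mean, cov=emp_cov)
    predicted = GaussianEmbedding(mean=np.zeros_like(emp_mean), cov=sigma_mean)
    try:
        kl = kl_gaussian(empirical, predicted)
        kl_rev = kl_gaussian(predicted, empirical)
    except ValidationError:
        kl = kl_rev = float("nan")
    return DownsamplingResult(
        sample_id=sample_id,
        rate=rate,
        n_reps=n,
        discrepancies=disc,
        empirical=empirical,
        predicted=predicted,
        kl=kl,
        kl_reverse=kl_rev,
        seed=seed,
        n_skipped=n_skipped,
    )


def spread_summary(results: Sequence[DownsamplingResult]) -> pd.DataFrame:
    """Per-rate, per-component spread statistics of the discrepancies.

    Long-format table with median, interquartile range and standard
    deviation, plus a per-(sample, component) flag marking whether the SD
    increases strictly with the rate.
    """
    if len({r.rate for r in results}) < 2:
        raise ValidationError("spread summary needs at least two rates")
    rows = []
    for res in results:
        for comp in range(res.discrepancies.shape[1]):
            d = res.discrepancies[:, comp]
            q25, med, q75 = np.percentile(d, [25, 50, 75])
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "rate": res.rate,
                    "component": comp + 1,
                    "median": med,
                    "iqr": q75 - q25,
                    "sd": d.std(ddof=1),
                }
            )
    table = pd.DataFrame(rows).sort_values(["sample_id", "component", "rate"])
    mono = (
        table.groupby(["sample_id", "component"], dropna=False)["sd"]
        .transform(lambda s: bool(np.all(np.diff(s.to_numpy()) > 0)))
        .astype(bool)
    )
    table["sd_monotone"] = mono
    return table.reset_index(drop=True)


def harmonize_observed(panel: GenotypePanel) -> GenotypePanel:
    """Mask every locus not observed in *all* samples (common observed set).

    Pre-step for multi-sample downsampling experiments, so that all samples
    start from an identical observed-locus set and the omission rate means
    the same thing for each of them.
    """
    common = panel.observed.all(axis=1)
    geno = panel.genotypes.copy()
    geno[~common, :] = MISSING
    return GenotypePanel(
        genotypes=geno,
        locus_ids=panel.locus_ids.copy(),
        sample_ids=panel.sample_ids.copy(),
        sample_labels=None if panel.sample_labels is None else panel.sample_labels.copy(),
        ploidy_mode=panel.ploidy_mode.copy(),
        snp_meta=panel.snp_meta,
    )
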