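"""Synthetic genotype panels with Balding-Nichols population structure.

The generator emulates the statistical shape of a modern reference panel:
K populations diverged from a common ancestral pool.  Ancestral allele
frequencies are drawn uniformly from a configurable range (bounded away
from 0/1 so invariant loci only appear via explicit injection); each
population's frequency is a Beta draw with mean equal to the ancestral
frequency and variance F * p * (1 - p), F being the divergence (FST-like)
parameter; diploid genotypes are Binomial(2, population frequency).

Ancient-like samples are *pseudo-haploid*: one allele drawn per locus and
reported homozygous, genotype = 2 * Bernoulli(p) in {0, 2}, which doubles
the per-locus variance relative to a diploid call at the same frequency
(4p(1-p) vs 2p(1-p)); missing calls are placed uniformly at a chosen rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import DIPLOID, MISSING, PSEUDO_HAPLOID, GenotypePanel


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic reference panel.

    Defaults are desk-scale study conditions: 3 populations x 50 samples at
    2,000 loci with F = 0.02, a within-continental level of divergence.
    """

    n_populations: int = 3
    n_samples_per_population: int = 50
    n_loci: int = 2000
    fst: float = 0.02
    freq_range: tuple[float, float] = (0.05, 0.95)
    n_invariant_loci: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_samples_per_population, self.n_loci) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("freq_range must satisfy 0 < lo < hi < 1")

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.n_samples_per_population


def reference_frequencies(spec: PanelSpec) -> np.ndarray:
    """Per-locus, per-population allele frequencies, shape (n_loci, K).

    Deterministic for a given spec; the same frequencies underlie
    :func:`generate_reference`, so held-out samples drawn from them are
    in-distribution for the reference panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _draw_frequencies(spec, rng)


def _draw_frequencies(spec: PanelSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.freq_range
    anc = rng.uniform(lo, hi, size=spec.n_loci)
    scale = (1.0 - spec.fst) / spec.fst
    a = anc * scale
    b = (1.0 - anc) * scale
    freqs = rng.beta(
        a[:, None], b[:, None], size=(spec.n_loci, spec.n_populations)
    )
    # Beta draws can graze 0/1 numerically; keep loci polymorphic in principle
    return np.clip(freqs, 1e-12, 1.0 - 1e-12)


def generate_reference(spec: PanelSpec) -> GenotypePanel:
    """Fully observed diploid reference panel with population labels.

    Samples are grouped by population (POP0, POP1, ...).  When
    ``spec.n_invariant_loci > 0`` that many degenerate loci (all samples
    homozygous for the same allele) are appended, to exercise
    invariant-locus exclusion.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    freqs = _draw_frequencies(spec, rng)
    assignment = np.repeat(np.arange(spec.n_populations), spec.n_samples_per_population)
    geno = rng.binomial(2, freqs[:, assignment]).astype(np.int8)

    locus_ids = np.array([f"rs{i}" for i in range(spec.n_loci)], dtype=object)
    if spec.n_invariant_loci:
        fixed_allele = rng.integers(0, 2, size=spec.n_invariant_loci)
        inv = np.repeat(fixed_allele[:, None] * 2, spec.n_samples, axis=1)
        geno = np.vstack([geno, inv.astype(np.int8)])
        inv_ids = np.array(
            [f"inv{i}" for i in range(spec.n_invariant_loci)], dtype=object
        )
        locus_ids = np.concatenate([locus_ids, inv_ids])

    labels = np.array([f"POP{k}" for k in assignment], dtype=object)
    sample_ids = np.array(
        [f"REF{j:04d}" for j in range(spec.n_samples)], dtype=object
    )
    return GenotypePanel(
        genotypes=geno,
        locus_ids=locus_ids,
        sample_ids=sample_ids,
        sample_labels=labels,
        ploidy_mode=np.full(spec.n_samples, DIPLOID, dtype=object),
    )


def generate_ancient_like(
    reference_freqs: np.ndarray,
    n_samples: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "ANC",
) -> GenotypePanel:
    """Pseudo-haploid samples drawn at the given allele frequencies.

    ``reference_freqs`` is (n_loci,) for a single source population or
    (n_loci, K); with K columns, samples are assigned to populations
    round-robin, mirroring the reference panel's mixture.  Observed
    genotypes are 2 * Bernoulli(p) in {0, 2}; missing calls are placed
    uniformly at ``missing_rate``.
    """
    return _generate_samples(
        reference_freqs, n_samples, missing_rate, seed, id_prefix, pseudo_haploid=True
    )


def generate_diploid(
    reference_freqs: np.ndarray,
    n_samples: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "TEST",
) -> GenotypePanel:
    """Held-out diploid samples drawn at the given allele frequencies.

    Same population-assignment convention as :func:`generate_ancient_like`,
    but with Binomial(2, p) genotypes — in-distribution test samples for a
    reference panel generated from the same frequencies.
    """
    return _generate_samples(
        reference_freqs, n_samples, missing_rate, seed, id_prefix, pseudo_haploid=False
    )


def _generate_samples(
    freqs: np.ndarray,
    n_samples: int,
    missing_rate: float,
    seed: int,
    id_prefix: str,
    pseudo_haploid: bool,
) -> GenotypePanel:
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate {missing_rate} outside [0, 1)")
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.ndim == 1:
        freqs = freqs[:, None]
    n_loci, k = freqs.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assignment = np.arange(n_samples) % k
    p = freqs[:, assignment]
    if pseudo_haploid:
        geno = (2 * rng.binomial(1, p)).astype(np.int8)
    else:
        geno = rng.binomial(2, p).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING

    mode = PSEUDO_HAPLOID if pseudo_haploid else DIPLOID
    return GenotypePanel(
        genotypes=geno,
        locus_ids=np.array([f"rs{i}" for i in range(n_loci)], dtype=object),
        sample_ids=np.array(
            [f"{id_prefix}{j:04d}" for j in range(n_samples)], dtype=object
        ),
        sample_labels=np.array([f"POP{c}" for c in assignment], dtype=object),
        ploidy_mode=np.full(n_samples, mode, dtype=object),
    )
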