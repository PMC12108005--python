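"""Genotype panel container.

A panel is a loci x samples matrix of reference-allele counts (0, 1, 2) with
9 marking a missing call, plus ordered locus/sample identifiers, optional
population labels, and a per-sample ploidy mode.  Modern samples are diploid;
low-coverage ancient samples are typically *pseudo-haploid*: one allele is
drawn at random per locus, so every call is homozygous (0 or 2) and the
genotype value 1 never occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sentinel for a missing genotype call (EIGENSTRAT convention).
MISSING: int = 9

DIPLOID = "diploid"
PSEUDO_HAPLOID = "pseudo-haploid"

_ALLOWED = frozenset({0, 1, 2, MISSING})


def infer_ploidy(genotypes: np.ndarray) -> np.ndarray:
    """Infer a per-sample ploidy mode from the genotype matrix.

    A sample is called pseudo-haploid iff it has at least one observed
    genotype and none of its observed genotypes equals 1 (heterozygous calls
    are impossible under pseudo-haploid calling).  Samples with no observed
    genotypes default to diploid.
    """
    g = np.asarray(genotypes)
    has_het = (g == 1).any(axis=0)
    has_obs = (g != MISSING).any(axis=0)
    modes = np.where(~has_het & has_obs, PSEUDO_HAPLOID, DIPLOID)
    return modes.astype(object)


@dataclass
class GenotypePanel:
    """Loci x samples genotype matrix with metadata.

    Parameters
    ----------
    genotypes
        Integer matrix, shape ``(n_loci, n_samples)``, entries in
        ``{0, 1, 2, 9}`` where 9 is missing.
    locus_ids, sample_ids
        Ordered identifiers for rows and columns.
    sample_labels
        Optional population/locality label per sample (stored in the
        ind-file group column).
    ploidy_mode
        Per-sample mode, ``"diploid"`` or ``"pseudo-haploid"``; inferred
        from the data when not given.
    snp_meta
        Optional per-locus metadata frame with columns
        ``chrom, genetic_pos, physical_pos, allele1, allele2`` (opaque
        metadata; no coordinate arithmetic is ever performed on it).
    """

    genotypes: np.ndarray
    locus_ids: np.ndarray
    sample_ids: np.ndarray
    sample_labels: np.ndarray | None = None
    ploidy_mode: np.ndarray | None = None
    snp_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D loci x samples matrix")
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.sample_labels is not None:
            self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.ploidy_mode is None:
            self.ploidy_mode = infer_ploidy(self.genotypes)
        else:
            self.ploidy_mode = np.asarray(self.ploidy_mode, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        d, n = self.genotypes.shape
        if len(self.locus_ids) != d:
            raise ValidationError(
                f"{len(self.locus_ids)} locus ids for {d} genotype rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} genotype columns"
            )
        if self.sample_labels is not None and len(self.sample_labels) != n:
            raise ValidationError("sample_labels length mismatch")
        if len(self.ploidy_mode) != n:
            raise ValidationError("ploidy_mode length mismatch")
        bad = ~np.isin(self.genotypes, list(_ALLOWED))
        if bad.any():
            value = int(self.genotypes[bad][0])
            raise ValidationError(f"genotype value {value} outside {{0,1,2,9}}")
        pseudo = np.asarray(self.ploidy_mode) == PSEUDO_HAPLOID
        if pseudo.any() and (self.genotypes[:, pseudo] == 1).any():
            raise ValidationError(
                "pseudo-haploid sample contains a heterozygous call (1)"
            )

    # -- basic accessors ----------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean matrix, True where a genotype call is present."""
        return self.genotypes != MISSING

    def column(self, sample_id: str) -> np.ndarray:
        """Genotype column for one sample id."""
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if idx.size == 0:
            raise KeyError(sample_id)
        return self.genotypes[:, idx[0]]

    def equals(self, other: "GenotypePanel") -> bool:
        """Field-by-field equality (metadata frames compared on shared columns)."""
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.ploidy_mode, other.ploidy_mode)
            and (
                (self.sample_labels is None) == (other.sample_labels is None)
                and (
                    self.sample_labels is None
                    or np.array_equal(self.sample_labels, other.sample_labels)
                )
            )
        )


@dataclass(frozen=True)
class CoverageSummary:
    """Per-sample observed-locus counts and SNP coverage fractions.

    SNP coverage is the proportion of loci with a non-missing call,
    ``n_observed / n_loci``.
    """

    sample_ids: np.ndarray
    n_observed: np.ndarray
    coverage: np.ndarray
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_observed": self.n_observed, "coverage": self.coverage},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def coverage_summary(panel: GenotypePanel) -> CoverageSummary:
    """Count observed loci per sample and the corresponding coverage fraction."""
    m = panel.observed.sum(axis=0).astype(np.int64)
    d = panel.n_loci
    cov = m / d if d else np.zeros_like(m, dtype=float)
    return CoverageSummary(
        sample_ids=panel.sample_ids.copy(),
        n_observed=m,
        coverage=cov,
        n_loci=d,
    )
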