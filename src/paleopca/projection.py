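"""Least-squares projection of (possibly incomplete) samples onto a PC space.

A sample z with observed genotypes z* at M of the model's D retained loci is
normalized with the *reference* panel's per-locus statistics and its scores
on the leading P components are estimated by restricted least squares,

    tau_hat = (V_P*^T V_P*)^-1 V_P*^T x*,

where V_P* are the observed rows of the leading eigenvectors.  For a fully
observed sample the Gram matrix is the identity and the estimate reduces to
the plain orthogonal score V_P^T x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConditioningError, InsufficientDataError
from .panel import MISSING, GenotypePanel
from .pca import PCAModel, normalize

#: Reciprocal-condition-number threshold below which the Gram matrix is
#: treated as numerically singular.
RCOND_MIN = 1e-10


@dataclass(frozen=True)
class ProjectionScores:
    """Estimated PC scores of one sample and the mask they were based on."""

    scores: np.ndarray
    mask: np.ndarray
    sample_id: str | None = None

    @property
    def p(self) -> int:
        return len(self.scores)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def gram_solve(
    v_obs: np.ndarray, rhs: np.ndarray, allow_pinv: bool = False
) -> np.ndarray:
    """Solve (v_obs^T v_obs) y = rhs with an explicit conditioning check."""
    gram = v_obs.T @ v_obs
    return solve_gram(gram, rhs, allow_pinv=allow_pinv)


def solve_gram(
    gram: np.ndarray, rhs: np.ndarray, allow_pinv: bool = False
) -> np.ndarray:
    eigs = np.linalg.eigvalsh(gram)
    if eigs[-1] <= 0 or eigs[0] / eigs[-1] < RCOND_MIN:
        if not allow_pinv:
            raise ConditioningError(
                "observed-rows Gram matrix is numerically singular "
                f"(rcond={0.0 if eigs[-1] <= 0 else eigs[0] / eigs[-1]:.2e}); "
                "pass allow_pinv=True to use a pseudo-inverse"
            )
        return np.linalg.pinv(gram) @ rhs
    return np.linalg.solve(gram, rhs)


def project(
    sample: np.ndarray,
    model: PCAModel,
    p: int = 2,
    allow_pinv: bool = False,
    sample_id: str | None = None,
) -> ProjectionScores:
    """Project one genotype column (aligned to the model's retained loci).

    ``sample`` holds raw genotypes (0/1/2, 9 = missing) over the model's
    retained loci, in model locus order.  Centering and scaling use the
    model's own statistics, never the sample's.
    """
    sample = np.asarray(sample)
    if sample.shape != (model.n_loci,):
        raise IndexError(
            f"sample has {sample.shape} entries; model retains {model.n_loci} loci"
        )
    if not 1 <= p <= model.n_components:
        raise ValueError(f"p={p} outside 1..{model.n_components}")
    mask = sample != MISSING
    m = int(mask.sum())
    if m < p:
        raise InsufficientDataError(f"{m} observed loci < {p} components")
    x = normalize(sample, model.locus_stats)
    v_obs = model.eigenvectors[mask, :p]
    scores = gram_solve(v_obs, v_obs.T @ x[mask], allow_pinv=allow_pinv)
    return ProjectionScores(scores=scores, mask=mask, sample_id=sample_id)


def align_to_model(
    panel: GenotypePanel, model: PCAModel
) -> tuple[np.ndarray, int]:
    """Reindex a panel's genotype matrix onto the model's retained loci.

    Returns the (n_model_loci x n_samples) matrix in model locus order —
    model loci absent from the panel become missing — together with the
    number of panel loci dropped because the model excluded them (or never
    saw them).
    """
    pos = pd.Index(panel.locus_ids).get_indexer(pd.Index(model.locus_ids))
    found = pos >= 0
    out = np.full((model.n_loci, panel.n_samples), MISSING, dtype=np.int8)
    out[found] = panel.genotypes[pos[found]]
    n_dropped = panel.n_loci - int(found.sum())
    return out, n_dropped


def project_panel(
    panel: GenotypePanel,
    model: PCAModel,
    p: int = 2,
    allow_pinv: bool = False,
) -> pd.DataFrame:
    """Project every sample of a panel; returns a per-sample score table.

    Columns: PC1..PCp, n_observed, coverage (relative to the model's
    retained loci).
    """
    aligned, _ = align_to_model(panel, model)
    rows = []
    for j, sid in enumerate(panel.sample_ids):
        ps = project(aligned[:, j], model, p=p, allow_pinv=allow_pinv, sample_id=sid)
        rows.append(
            [*ps.scores, ps.n_observed, ps.n_observed / model.n_loci]
        )
    cols = [f"PC{k + 1}" for k in range(p)] + ["n_observed", "coverage"]
    return pd.DataFrame(rows, columns=cols, index=pd.Index(panel.sample_ids, name="sample_id"))
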