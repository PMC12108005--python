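"""Uncertainty ellipses and PC-map plotting.

A bivariate Gaussian's quantile-q confidence region is the ellipse
{x : (x - mu)^T Sigma^-1 (x - mu) <= c} with c the chi-square(2) quantile
at q; its semi-axes are sqrt(c * lambda_k) along the eigenvectors of Sigma.
Exact chi-square quantiles are used rather than 1-/2-sigma rules so the
stated coverage holds in two dimensions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.stats import chi2

from .errors import ValidationError
from .uncertainty import GaussianEmbedding

DEFAULT_QUANTILES: tuple[float, ...] = (0.5, 0.9, 0.95, 0.99)


@dataclass(frozen=True)
class EllipseSpec:
    """Geometry of one confidence ellipse in the PC1/PC2 plane."""

    level: float
    center: np.ndarray
    semi_axes: np.ndarray  # descending
    angle_rad: float  # orientation of the major axis
    degenerate: bool = False

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for an (n, 2) array of points."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = pts @ np.array([[c, -s], [s, c]])
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (rot / self.semi_axes) ** 2
        return np.nan_to_num(q, nan=np.inf).sum(axis=1) <= 1.0


def ellipse_from_gaussian(g: GaussianEmbedding, quantile: float) -> EllipseSpec:
    """Confidence ellipse of a 2-D Gaussian at the given quantile."""
    if g.p != 2:
        raise ValidationError(f"ellipses are defined for P=2, got P={g.p}")
    if not 0.0 <= quantile < 1.0:
        raise ValueError(f"quantile {quantile} outside [0, 1)")
    c = chi2.ppf(quantile, df=2)
    eigs, vecs = np.linalg.eigh(g.cov)
    eigs = np.clip(eigs, 0.0, None)[::-1]
    vecs = vecs[:, ::-1]
    semi = np.sqrt(c * eigs)
    return EllipseSpec(
        level=quantile,
        center=g.mean.copy(),
        semi_axes=semi,
        angle_rad=float(np.arctan2(vecs[1, 0], vecs[0, 0])),
        degenerate=bool(semi[-1] == 0.0),
    )


def plot_map(
    reference_scores: pd.DataFrame,
    embeddings: Sequence[GaussianEmbedding] = (),
    out_path: str | os.PathLike | None = None,
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
    labels: Sequence[str] | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Reference scatter with uncertainty ellipses for projected samples.

    ``reference_scores`` needs PC1/PC2 columns and, optionally, a ``label``
    column used for coloring.  Each embedding is drawn as its mean plus one
    ellipse per quantile.  The figure is written to ``out_path`` when given
    (format by extension: pdf/svg/png).
    """
    if not {"PC1", "PC2"} <= set(reference_scores.columns):
        raise ValidationError("reference scores need PC1 and PC2 columns")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    if "label" in reference_scores.columns:
        for name, grp in reference_scores.groupby("label"):
            ax.scatter(grp["PC1"], grp["PC2"], s=8, alpha=0.6, label=str(name))
        ax.legend(fontsize=7, markerscale=1.5, loc="best")
    else:
        ax.scatter(
            reference_scores["PC1"],
            reference_scores["PC2"],
            s=8,
            c="0.6",
            alpha=0.6,
        )

    for i, g in enumerate(embeddings):
        ax.plot(*g.mean, marker="x", color="black", markersize=6)
        for q in sorted(quantiles):
            spec = ellipse_from_gaussian(g, q)
            ax.add_patch(
                Ellipse(
                    spec.center,
                    width=2 * spec.semi_axes[0],
                    height=2 * spec.semi_axes[1],
                    angle=np.degrees(spec.angle_rad),
                    fill=False,
                    color="black",
                    alpha=0.5,
                    lw=0.8,
                )
            )
        if labels is not None:
            ax.annotate(str(labels[i]), g.mean, fontsize=8)

    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
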