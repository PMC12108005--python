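import numpy as np
import pytest

import paleopca as pp
from paleopca.pca import LocusStats, PCAModel


@pytest.fixture(scope="session")
def study_spec() -> pp.PanelSpec:
    """Default study conditions: 3 pops x 50 samples, 2,000 loci, F=0.02."""
    return pp.PanelSpec()


@pytest.fixture(scope="session")
def ref_panel(study_spec) -> pp.GenotypePanel:
    return pp.generate_reference(study_spec)


@pytest.fixture(scope="session")
def model(ref_panel) -> PCAModel:
    return pp.fit_pca(ref_panel)


@pytest.fixture(scope="session")
def pop_freqs(study_spec) -> np.ndarray:
    return pp.reference_frequencies(study_spec)


def make_toy_model(
    d: int = 6,
    q: int = 4,
    seed: int = 0,
    eigenvalues: np.ndarray | None = None,
) -> PCAModel:
    """Small PCA model with a random orthonormal basis, for algebra tests."""
    rng = np.random.default_rng(seed)
    v, _ = np.linalg.qr(rng.standard_normal((d, d)))
    v = v[:, :q]
    if eigenvalues is None:
        eigenvalues = np.sort(rng.uniform(0.5, 5.0, size=q))[::-1]
    stats = LocusStats(
        mu=np.ones(d),
        p=np.full(d, 0.5),
        s=np.full(d, 0.5),
        retained_idx=np.arange(d),
        n_total=d,
    )
    return PCAModel(
        eigenvectors=v,
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        locus_stats=stats,
        locus_ids=np.array([f"rs{i}" for i in range(d)], dtype=object),
        n_ref=q + 1,
    )
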