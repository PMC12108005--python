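"""Predict embedding uncertainty for sparse samples and draw the PC map.

For three held-out samples at increasing missingness, predicts the Gaussian
over the true embedding from each sample's missingness mask alone, prints
the covariance trace (total predicted variance), and exports a PC map with
50/90/95/99% uncertainty ellipses to uncertainty_map.pdf.
"""

import numpy as np
import pandas as pd

import paleopca as pp

spec = pp.PanelSpec(seed=42)
panel = pp.generate_reference(spec)
model = pp.fit_pca(panel)
freqs = pp.reference_frequencies(spec)
held = pp.generate_diploid(freqs, 3, seed=11)
aligned, _ = pp.align_to_model(held, model)

embeddings, labels = [], []
for j, rate in enumerate([0.5, 0.9, 0.98]):
    column = pp.downsample(aligned[:, j], rate=rate, seed=j)
    scores = pp.project(column, model, p=2)
    sigma = pp.predict_covariance(scores.mask, model, p=2)
    g = pp.predict_embedding(scores, sigma)
    embeddings.append(g)
    labels.append(f"{int(rate * 100)}% missing")
    print(f"{labels[-1]:>12}: mean {g.mean.round(2)}, "
          f"trace(Sigma) = {np.trace(g.cov):.3f}")

ref = pd.DataFrame({
    "PC1": model.ref_scores[:, 0],
    "PC2": model.ref_scores[:, 1],
    "label": model.ref_labels,
})
pp.plot_map(ref, embeddings, out_path="uncertainty_map.pdf", labels=labels)
print("wrote uncertainty_map.pdf — ellipse area grows with missingness, "
      "quantifying where the sample could truly lie.")
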