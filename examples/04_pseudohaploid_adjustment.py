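"""Variance adjustment for pseudo-haploid (ancient-like) samples.

Pseudo-haploid calling reports a single sampled allele per locus, so
genotypes take only the values 0 or 2 and their per-locus variance roughly
doubles relative to diploid calls (4p(1-p) vs 2p(1-p)).  Without
accounting for this, predicted uncertainty is about half the real spread.
This script estimates the per-locus variance factors, projects them into
component space, and shows the KL improvement of the adjusted prediction.
"""

import numpy as np

import paleopca as pp

spec = pp.PanelSpec(seed=42)
panel = pp.generate_reference(spec)
model = pp.fit_pca(panel)
freqs = pp.reference_frequencies(spec)
ancient = pp.generate_ancient_like(freqs, 20, seed=5)

factors = pp.variance_factors(ancient, panel, model)
print(f"mean per-locus factor f_in  = {factors.f_in.mean():.3f}  (analytic: 2)")
print(f"mean per-component f_out    = {factors.f_out.mean():.3f}")

aligned, _ = pp.align_to_model(ancient, model)
kl_un, kl_ad = [], []
for j in range(5):
    kw = dict(rates=(0.75,), n_reps=1000, seed=100 + j)
    kl_un.append(pp.run_downsampling(aligned[:, j], model, **kw)[0].kl)
    kl_ad.append(
        pp.run_downsampling(aligned[:, j], model, factors=factors, **kw)[0].kl
    )
print(f"mean KL at r=0.75, unadjusted: {np.mean(kl_un):.3f}")
print(f"mean KL at r=0.75, adjusted:   {np.mean(kl_ad):.3f}")
print("The adjusted prediction matches the empirical spread of "
      "pseudo-haploid samples; the unadjusted one underestimates it.")
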