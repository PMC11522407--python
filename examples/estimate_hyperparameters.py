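"""Estimate model hyperparameters from a spot dataset.

The Gamma prior on per-cell site coverage is fitted with mixed-type
log-moment estimators applied to the per-mutation average reads per cell;
the Beta shape comes from the chosen expected number of clones per spot;
the Poisson means are the per-spot cell counts themselves.
"""

import numpy as np

import spotclone as sc
from spotclone.hyperest import estimate_gamma_shape_rate, per_cell_read_samples

data, clones, truth, _ = sc.simulate_dataset(sc.SimulationSetup(seed=7))

x = per_cell_read_samples(data.D, data.n_prior)
print(f"per-mutation average reads per cell: median {np.median(x):.3f}, "
      f"{np.sum(x == 0)} unexpressed site(s) dropped from the fit")

r_hat, p_hat = estimate_gamma_shape_rate(x)
print(f"fitted Gamma prior on per-cell coverage: shape r = {r_hat:.3f}, "
      f"rate p = {p_hat:.3f} (mean {r_hat / p_hat:.3f} reads/cell/site)")
print("note: this fits the coverage pooled over clones, which is the prior "
      "the model needs; it is broader than any single clone's coverage")

hyper = sc.build_hyperparams(data.n_prior, data.D, expected_clones=2.5, K=clones.n_clones)
print(f"Beta shape zeta/K = {float(np.asarray(hyper.zeta)) / clones.n_clones:.2f} "
      f"(expected 2.5 of {clones.n_clones} clones per spot)")
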