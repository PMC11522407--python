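"""Compare clonal composition of adjacent versus distant spot pairs.

In real tumors, spatially adjacent spots share clonal composition more than
distant ones. The statistic: sample pairs of spots (adjacent = both grid
offsets at most 1; distant = both greater than 1), correlate each clone's
proportions across pairs, and compare the two correlation distributions
with a one-sided rank-sum test. On simulated data spots are exchangeable,
so this example demonstrates the *negative control*: no adjacency signal.
"""

import numpy as np

import spotclone as sc

data, clones, truth, _ = sc.simulate_dataset(sc.SimulationSetup(seed=3))
rng = np.random.default_rng(0)

adj, dist = [], []
for _ in range(20):  # 20 resamplings of 80 pairs each
    pa = sc.sample_spot_pairs(data.coords, 80, "adjacent", rng)
    pd_ = sc.sample_spot_pairs(data.coords, 80, "distant", rng)
    adj.extend(sc.pair_clonal_correlation(truth.H_true, pa))
    dist.extend(sc.pair_clonal_correlation(truth.H_true, pd_))

adj = np.array(adj); dist = np.array(dist)
med_a, med_d, p = sc.compare_adjacent_vs_distant(
    adj[~np.isnan(adj)], dist[~np.isnan(dist)]
)
print(f"median per-clone correlation, adjacent pairs: {med_a:+.3f}")
print(f"median per-clone correlation, distant pairs:  {med_d:+.3f}")
print(f"one-sided rank-sum p (adjacent > distant):    {p:.3f}")
print("simulated spots are spatially exchangeable, so the medians are both"
      " near zero and the test is non-significant — as it should be; on"
      " real tumor sections the adjacent distribution shifts upward.")

assignments = np.argmax(truth.H_true, axis=1)
pa = sc.sample_spot_pairs(data.coords, 80, "adjacent", rng)
agree = sc.pair_major_clone_agreement(assignments, pa)
print(f"major-clone agreement within adjacent pairs:  {agree:.2f}")
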