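# Methods

## Model

Each spatial-transcriptomics spot s contains N_s cells drawn from K cancer
clones whose genotypes C (zygosity per mutation, in [0, 1]) and bulk
prevalences F are given. The latent structure is:

* **Presence.** Z_sk ∈ {0, 1} indicates clone k in spot s, with
  Z_sk ~ Bern(Π_sk), Π_sk ~ Beta(ζ_s/K, 1). Under this prior the expected
  number of present clones is Kζ_s/(ζ_s+K), so ζ_s/K = E/(K−E) dials a
  target E (e.g. E = 1, 2.5, 4.5 at K = 5 gives ζ/K = 0.25, 1, 9).
* **Proportions.** H_s,· is Dirichlet with concentration F′_k for present
  clones and pseudo-frequency F0 for absent ones, realized through
  independent Gammas G_sk (shape F′ or F0, rate 1) normalized per row.
  F′ discretizes F into 20 equal bins, rounds up, and scales by l:
  F′_k = l·⌈20 F_k⌉/20, with l = 100. F0 keeps all proportions
  positive; default F0 = 0.01, and discretized shapes are floored at F0
  so the Gamma density stays proper for clones absent from the bulk.
* **Coverage.** Φ_ik ≥ 0 is the expected reads per cell at site i in clone
  k, Φ_ik ~ Gamma(r, p) (shape–rate; the mean is r/p — at the study's
  p = 1 this coincides with any r/p² parameterization).
* **Cell counts.** N_s ~ Pois(Λ_s), truncated to N_s ≥ 1 (an annotated
  cancer spot holds at least one cell). In the fixed-count variant N_s is
  a known constant.
* **Reads.** D_is ~ Pois(N_s Σ_k H_sk Φ_ik);
  A_is ~ Binom(D_is, Σ_k H_sk Φ_ik C_ik / Σ_k H_sk Φ_ik). The Binomial
  success probability is degree-0 homogeneous in Φ; when the expected
  coverage is exactly zero (possible only with D_is = 0) the convention is
  q = 0 so the site contributes nothing.

## Inference

Metropolis-Hastings-within-Gibbs, sweep order Π → Z → Φ → G → (flip,
swap) → N:

* Π_sk | Z is conjugate: Beta(ζ_s/K + Z_sk, 2 − Z_sk).
* Z_sk is binary-Gibbs, proportional to Bern(Z|Π)·Gamma(G | shape_Z, 1),
  computed in log space.
* Φ, G, N have no closed conditional and use random-walk MH with
  zero-truncated normal proposals; the truncation normalizers enter the
  acceptance ratio, which is the standard min{1, f(x′)Q(x|x′)/(f(x)Q(x′|x))}.
  N uses integer-rounded proposals whose exact probability is the
  truncated normal's unit-interval mass; support is restricted to N ≥ 1.
  Updates are vectorized across the conditionally independent axis
  (mutations for a Φ column, spots for a G column and for N) and sweep
  clone columns in fixed order for reproducibility.
* **Mode-switching (Z, G) move.** The single-site updates above cannot
  switch a clone's presence: flipping Z requires G to cross a region
  where the Gamma(F′, 1) prior (F′ ≈ 20–100) has essentially zero
  density, so chains started from a generic state stay in whichever
  presence configuration they first fit (observed as a stable wrong mode
  with ~8× the error of a truth-initialized chain). Each sweep therefore
  also proposes, per (s, k), flipping Z_sk jointly with a fresh G_sk drawn
  from the Gamma prior of the flipped state. The proposed G's prior
  cancels its proposal density, leaving acceptance = Bernoulli odds ×
  the spot's likelihood ratio — an exact MH move on the joint that hops
  directly between the presence basins.
* **Clone-label swap.** A second trap appears at low coverage: the chain
  can settle into a stable, self-consistent *mislabeling* of two similar
  (typically nested parent/child) clones, attributing each one's activity
  pattern to the other's genotype. Once per sweep a uniformly chosen pair
  of clones has its entire latent columns (Z, Π, G — hence H — and Φ)
  proposed for exchange while the genotypes stay put. The Beta and Φ
  priors are exchangeable over clones and the (Z, G) pairing travels
  together, so acceptance is the full likelihood ratio times a G-prior
  ratio when the two discretized prevalences differ. From a mislabeled
  mode the swapped state is the correct one and the move is accepted in a
  single step.
* **Adaptation.** Every b sweeps during burn-in (default b = 100; the
  validation studies use 50) each block's step size is updated as
  σ ← σ(1 + (R_c − R_o)), with R_c the window's acceptance rate and R_o
  the target (0.44). Acceptance above target grows the step, below target
  shrinks it; this is the stable direction of the feedback — the opposite
  sign repels the chain from the target rate, since acceptance decreases
  monotonically in step size. Adaptation is frozen after burn-in so the
  sampled kernel is fixed and the stationary distribution exact.
* **Initialization.** Z = 1 everywhere, Π from its prior, G from its prior
  given Z, N at the cell-count input, and Φ at the per-site per-cell
  coverage estimate mean_s(D_is/n_s), identical across clones. The
  exchangeable Φ start matters: drawing Φ from its heavy-near-zero prior
  seeds order-of-magnitude asymmetries between clones at each site, and
  because Φ is shared across spots these can freeze into a
  self-consistent mislabeling of nested parent/child clones. Starting
  symmetric lets the reads break the ties.
* Defaults: n_iter = 20 000, burn-in = 10 000, thin = 5 — deliberately
  generous. The validation studies use 2600 sweeps with 600 burn-in at
  S = 100 (the coverage battery: 800 sweeps at S = 50), which reproduces
  the study's error levels; seeded runs are bit-reproducible, so the
  reported numbers are exact re-runs.
* **Multi-start selection.** `run_multistart` runs independent chains
  from different seeds and keeps the one with the highest mean
  post-burn-in log joint — a model-internal criterion that discards
  chains stranded in minor modes (at small S a short single chain does so
  in roughly a quarter of runs). The coverage-monotonicity battery uses
  two starts; elsewhere a single chain suffices.
* The coverage battery additionally compares coverage levels with common
  random numbers (the same data seed across levels, so the simulated
  clone structure and spot mixtures are identical and only read depth
  varies): in the prior-dominated configurations the level-to-level error
  gaps are of order 1e-3 and would otherwise drown in truth-sampling
  noise.
* Posterior summaries are elementwise means of kept samples; H rows are
  re-normalized onto the simplex. Major clone = argmax of the posterior
  mean, ties to the lowest clone index.

## Hyperparameter estimation

Λ_s is taken directly from image-derived cell counts. (r, p) are fitted by
mixed-type log-moment estimators on x_i = mean_s D_is/n_s (average reads
per cell at site i): with Q = I·Σx ln x − Σln x·Σx, r̂ = I·Σx/Q and
p̂ = I²/Q. Sites with x_i = 0 (never observed) have no logarithm and are
dropped with a logged count. ζ_s is spot-constant from a user-chosen
expected clones per spot.

Two caveats, verified numerically: x_i estimates the coverage *pooled
over clones* (≈ the average of K per-clone Gammas), whose shape is about
K·r rather than r; and the discreteness floor of x (multiples of 1/(S·n))
plus the dropping of zero sites truncate the lower tail the log-moment
estimator leans on. The fitted (r̂, p̂) therefore describe the pooled
per-cell coverage — the right scale for the prior the model needs — and
should not be read as estimates of a simulation's per-clone r. A
simulate→estimate round trip does not return the generating r.

## Simulator

The generator reproduces the validation study's conditions:

* Genotypes: a random rooted tree on K clones (each non-root node attaches
  uniformly to a lower-indexed node), clone 0 the mutation-free base
  clone; each of M mutations lands on a uniform non-root branch and is
  inherited by the subtree. Trees are resampled until the realized mean
  mutations per clone is within 15% of target. Feasible targets lie in
  [M/K, M(K−1)/K]; the decreased-mutation configuration therefore uses
  M = 20 with target 5.1 (a 30-mutation panel cannot go below 6).
* Configurations: basic (K=5, M=30, 13.6 mutations/clone, E=2.5),
  increased/decreased mutations (15 / 5.1), increased/decreased clones
  (E = 4.5 / 1). Coverage levels map to r ∈ {0.02, 0.07, 0.09, 0.19} at
  p = 1; with Λ = 25 cells/spot these give mean spot coverages of roughly
  15/52/67/142 reads — the same ordering and scale as the reference
  conditions, whose exact Λ is not published, so coverage enters the
  validation as a monotone factor rather than an absolute target.
* Bulk prevalences default to balanced, F_k = 1/K. With skewed random
  prevalences the informative Dirichlet(F′) prior alone predicts the
  dominant clone, and the weak-data conditions become artificially easy —
  incompatible with the near-chance accuracy the study reports there.
  Balanced F makes the prior exchangeable over clones so that accuracy is
  carried by the reads. A flat-Dirichlet option is provided.
* Cell-count noise is additive Poisson (mean 0, 1, or 10) applied to the
  reported counts only; missing-mutation experiments drop a uniform
  fraction of mutation rows consistently from A, D, and C.
* S = 100 spots on a 10×10 unit grid by default; coordinates are array
  indices.

What the simulator does *not* emulate: spatial autocorrelation of clone
mixtures (spots are exchangeable — the adjacency statistics use this as a
negative control), expression-driven variation in site coverage,
copy-number dynamics, or doublet/segmentation artifacts in cell counts.
Passing recovery tests on these data shows correctness of the inference
under the model's own assumptions, not robustness to real-tissue effects
beyond the noise and masking scenarios above.

## Evaluation statistics

MAE = mean over spots and clones of |H_est − H_true| (range [0,
2(K−1)/K]); major-clone accuracy = fraction of spots with matching argmax.
Spot pairs are sampled uniformly without replacement from all qualifying
pairs; adjacency uses absolute offsets (|ΔX| ≤ 1 and |ΔY| ≤ 1; distant:
both > 1) since signed constraints would depend on array orientation.
Per-clone Pearson correlations across pairs are reported per clone and
pooled over clones × resamplings; zero-variance clones are missing, not
zero. Adjacent-vs-distant comparisons use the one-sided two-sample
rank-sum test.

## Expression regression

Y = N′HB with N′ = diag(N). Genes are column-separable, so B is solved per
gene by bounded least squares (B ≥ 0, no intercept) via
`scipy.optimize.lsq_linear`; rank-deficient designs return a flagged,
non-unique solution. Y is regressed as raw counts (optional per-spot
depth normalization is off by default). Gene ranking orders genes by
max_k B_kg, ties lexicographic on the label.

## Numerical choices

* Beta/Gamma/Poisson/Binomial log-kernels via `scipy.special` xlogy/xlog1py
  with data-independent constants dropped inside the sampler and kept in
  the full log-joint (which is validated term-by-term at 1e-10). The
  per-entry read-likelihood kernel is numba-compiled and cached in the
  sweep workspace, updated incrementally on accepted moves.
* Truncated-normal sampling by inverse CDF; proposal normalizers clipped
  at 1e-300 before logs. G draws floored at 1e-12 to avoid exact zeros
  from tiny shapes.
* Running coverage matrices R = ΦHᵀ and T = (Φ∘C)Hᵀ are updated
  incrementally and refreshed every 500 sweeps to cancel drift.
* Chains, simulations, and file outputs are bit-reproducible given seeds.
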