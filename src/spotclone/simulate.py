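"""Synthetic-data generator with known ground truth.

Reproduces the simulation-study conditions used to validate the model:
clone genotypes on a random phylogeny with a mutation-free base clone,
balanced bulk clone frequencies, four coverage levels set by
the Gamma shape of per-cell site coverage (r in {0.02, 0.07, 0.09, 0.19}
at rate p = 1), a controlled expected number of clones per spot, additive
Poisson noise on the reported cell counts, and uniform masking of a
fraction of mutation rows (mutations absent from the ST reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    CloneSet,
    Hyperparams,
    SpotDataset,
    sample_generative,
    zeta_over_K_from_expected_clones,
)

#: Gamma shape of per-cell site coverage at each named coverage level (p = 1).
COVERAGE_LEVELS: dict[str, float] = {
    "very_low": 0.02,
    "low": 0.07,
    "medium": 0.09,
    "high": 0.19,
}

#: Poisson mean of the additive cell-count noise at each named level.
NOISE_LEVELS: dict[str, float] = {"none": 0.0, "small": 1.0, "large": 10.0}

#: The five clone/mutation configurations of the simulation study.
#: (K, M, target mean mutations per clone). The decreased-mutation target
#: is infeasible at M = 30 (the floor is M/K with a star phylogeny), so
#: that configuration uses a smaller mutation panel.
CONFIGURATIONS: dict[str, tuple[int, int, float]] = {
    "basic": (5, 30, 13.6),
    "increased_mutations": (5, 30, 15.0),
    "decreased_mutations": (5, 20, 5.1),
    "increased_clones": (5, 30, 13.6),
    "decreased_clones": (5, 30, 13.6),
}

#: Expected clones per spot for each configuration.
EXPECTED_CLONES: dict[str, float] = {
    "basic": 2.5,
    "increased_mutations": 2.5,
    "decreased_mutations": 2.5,
    "increased_clones": 4.5,
    "decreased_clones": 1.0,
}


@dataclass
class SimulationSetup:
    """One cell of the simulation battery."""

    K: int = 5
    M: int = 30
    avg_mut_per_clone: float = 13.6
    expected_clones_per_spot: float = 2.5
    coverage_level: str = "medium"
    S: int = 100
    grid_shape: tuple[int, int] = (10, 10)
    noise_level: str = "none"
    missing_fraction: float = 0.0
    Lambda: float = 25.0
    seed: int = 0
    binary_genotypes: bool = True
    prevalence: str = "balanced"  # "balanced" (F_k = 1/K) or "dirichlet"

    def __post_init__(self) -> None:
        if self.coverage_level not in COVERAGE_LEVELS:
            raise ValueError(f"unknown coverage level {self.coverage_level!r}")
        if self.noise_level not in NOISE_LEVELS:
            raise ValueError(f"unknown noise level {self.noise_level!r}")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0 < self.expected_clones_per_spot < self.K:
            raise ValueError("expected clones per spot must be in (0, K)")
        if self.prevalence not in ("balanced", "dirichlet"):
            raise ValueError("prevalence must be 'balanced' or 'dirichlet'")
        if self.grid_shape[0] * self.grid_shape[1] < self.S:
            raise ValueError("grid too small for the requested spot count")

    @property
    def r(self) -> float:
        return COVERAGE_LEVELS[self.coverage_level]

    @classmethod
    def from_configuration(
        cls, name: str, coverage_level: str = "medium", **kw
    ) -> "SimulationSetup":
        K, M, avg = CONFIGURATIONS[name]
        return cls(
            K=K,
            M=M,
            avg_mut_per_clone=avg,
            expected_clones_per_spot=EXPECTED_CLONES[name],
            coverage_level=coverage_level,
            **kw,
        )


@dataclass
class GroundTruth:
    """Latent truth behind one simulated dataset."""

    H_true: np.ndarray
    Z_true: np.ndarray
    N_true: np.ndarray
    Phi_true: np.ndarray
    C_true: np.ndarray
    F_true: np.ndarray
    tree_parent: np.ndarray = field(default=None)  # type: ignore[assignment]


def _random_tree(K: int, rng: np.random.Generator) -> np.ndarray:
    """Parent pointers of a random rooted tree on K nodes (root = 0).

    Each non-root node attaches uniformly to any lower-indexed node, which
    spans chains through stars.
    """
    parent = np.full(K, -1, dtype=int)
    for v in range(1, K):
        parent[v] = rng.integers(0, v)
    return parent


def _subtree_members(parent: np.ndarray) -> list[list[int]]:
    """For each node, the list of nodes in its subtree (itself included)."""
    K = parent.size
    members = [[v] for v in range(K)]
    # children have higher indices than parents by construction
    for v in range(K - 1, 0, -1):
        members[parent[v]].extend(members[v])
    return members


def generate_clone_genotypes(
    K: int,
    M: int,
    avg_mut_per_clone: float,
    rng: np.random.Generator,
    tol: float = 0.15,
    max_tries: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary genotype matrix from a random clonal phylogeny.

    Clone 0 is the mutation-free base clone (the tree root). Each mutation
    is placed on a uniformly random non-root branch and inherited by every
    clone in that branch's subtree. Trees and placements are resampled
    until the realized mean mutations per clone (over all K clones) is
    within ``tol`` of ``avg_mut_per_clone``.

    Returns (C, parent) with C of shape M x K and parent the tree's parent
    pointers. Raises if the target is outside the feasible range
    [M/K, M*(sum of a chain's subtree sizes)/K].
    """
    if K < 2 or M < 1:
        raise ValueError("need K >= 2 clones and M >= 1 mutations")
    # mean mutations/clone = (M/K) * mean subtree size over chosen branches;
    # branch subtree sizes range 1 (leaf) .. K-1 (edge below the root)
    lo = M / K
    hi = M * (K - 1) / K
    if not lo * (1 - tol) <= avg_mut_per_clone <= hi * (1 + tol):
        raise ValueError(
            f"target {avg_mut_per_clone} mutations/clone is outside the "
            f"feasible range [{lo:.2f}, {hi:.2f}] for K={K}, M={M}"
        )
    for _ in range(max_tries):
        parent = _random_tree(K, rng)
        members = _subtree_members(parent)
        branch = rng.integers(1, K, size=M)
        C = np.zeros((M, K), dtype=float)
        for i, v in enumerate(branch):
            C[i, members[v]] = 1.0
        realized = C.sum() / K
        if abs(realized - avg_mut_per_clone) <= tol * avg_mut_per_clone:
            return C, parent
    raise RuntimeError(
        f"could not hit {avg_mut_per_clone} mutations/clone within "
        f"{tol:.0%} after {max_tries} tries (feasible range [{lo:.2f}, {hi:.2f}])"
    )


def add_cell_count_noise(
    N_true: np.ndarray, noise_level: str, rng: np.random.Generator
) -> np.ndarray:
    """Additive Poisson noise on reported cell counts (none/small/large)."""
    eps_mean = NOISE_LEVELS[noise_level]
    N_true = np.asarray(N_true)
    if eps_mean == 0.0:
        return N_true.copy()
    return N_true + rng.poisson(eps_mean, size=N_true.shape)


def mask_missing_mutations(
    data: SpotDataset,
    clones: CloneSet,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[SpotDataset, CloneSet]:
    """Drop a uniformly chosen fraction of mutation rows from A, D and C.

    Emulates variants that fall outside the transcribed/captured regions of
    the ST library. Clone columns are untouched.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    M = data.n_mutations
    n_drop = int(np.floor(fraction * M))
    if n_drop >= M:
        raise ValueError("masking would remove every mutation")
    keep = np.sort(rng.choice(M, size=M - n_drop, replace=False))
    new_data = SpotDataset(
        A=data.A[keep],
        D=data.D[keep],
        coords=data.coords,
        n_prior=data.n_prior,
        labels_mutations=(
            [data.labels_mutations[i] for i in keep]
            if data.labels_mutations
            else None
        ),
        labels_spots=data.labels_spots,
    )
    new_clones = CloneSet(
        C=clones.C[keep],
        F=clones.F,
        F0=clones.F0,
        l=clones.l,
        labels_mutations=(
            [clones.labels_mutations[i] for i in keep]
            if clones.labels_mutations
            else None
        ),
        labels_clones=clones.labels_clones,
    )
    return new_data, new_clones


def simulate_dataset(
    setup: SimulationSetup,
) -> tuple[SpotDataset, CloneSet, GroundTruth, Hyperparams]:
    """Generate one dataset with ground truth under the given setup.

    Bulk clone frequencies are balanced (1/K each) by default, or drawn
    from a flat Dirichlet; genotypes come from a random phylogeny; all
    latent and observed variables from the generative model. The reported per-spot cell counts
    (``n_prior``) carry the requested additive noise, while the ground
    truth keeps the exact counts.
    """
    rng = np.random.default_rng(setup.seed)
    C, parent = generate_clone_genotypes(
        setup.K, setup.M, setup.avg_mut_per_clone, rng
    )
    if setup.prevalence == "balanced":
        # balanced clonal architecture: every clone equally prevalent in
        # bulk, so the Dirichlet prior is exchangeable across clones and
        # spot compositions are identified by the reads, not the prior
        F = np.full(setup.K, 1.0 / setup.K)
    else:
        F = rng.dirichlet(np.ones(setup.K))
    clones = CloneSet(C=C, F=F)
    zeta = zeta_over_K_from_expected_clones(
        setup.expected_clones_per_spot, setup.K
    ) * setup.K
    hyper = Hyperparams(zeta=zeta, r=setup.r, p=1.0, Lambda=setup.Lambda)
    rows, cols = setup.grid_shape
    coords = np.indices((rows, cols)).reshape(2, -1).T[: setup.S]
    state, data = sample_generative(clones, hyper, setup.S, rng, coords=coords)
    noisy_counts = add_cell_count_noise(state.N, setup.noise_level, rng)
    data = replace(data, n_prior=np.maximum(noisy_counts, 1))
    truth = GroundTruth(
        H_true=state.H,
        Z_true=state.Z,
        N_true=state.N,
        Phi_true=state.Phi,
        C_true=C,
        F_true=F,
        tree_parent=parent,
    )
    if setup.missing_fraction > 0:
        data, clones = mask_missing_mutations(
            data, clones, setup.missing_fraction, rng
        )
        truth.Phi_true = None  # rows no longer aligned; H/Z/N truth unchanged
    return data, clones, truth, hyper
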