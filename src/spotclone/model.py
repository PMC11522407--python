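"""Generative model for clone mixtures in spatial-transcriptomics spots.

The model explains somatic-variant read counts observed in ST spots as a
mixture of cancer clones. Each spot ``s`` holds ``N_s`` cells drawn from a
subset of ``K`` clones (a Beta-Bernoulli feature allocation ``Z``); the
mixture weights ``H_s,.`` follow a Dirichlet whose concentrations are the
(discretized, scaled) bulk clone frequencies for present clones and a small
pseudo-frequency ``F0`` for absent ones. Per-cell site coverage ``Phi_i,k``
is Gamma distributed; total reads ``D_i,s`` are Poisson with rate
``N_s * sum_k H_sk Phi_ik`` and alternated reads ``A_i,s`` are Binomial with
a success probability given by the zygosity-weighted coverage fraction.

This module holds the data containers, every prior/likelihood log-density,
the deterministic transforms (frequency discretization, Beta-shape
calibration), and forward sampling from the full generative process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy

logger = logging.getLogger(__name__)

DEFAULT_F0 = 0.01
DEFAULT_SCALING = 100.0
_FREQ_BINS = 20


def discretize_prevalence(F: np.ndarray, l: float = DEFAULT_SCALING) -> np.ndarray:
    """Discretize clone prevalences into 20 equal bins and scale by ``l``.

    Each frequency is rounded *up* to the upper bound of its 1/20-wide bin,
    then multiplied by ``l``, giving the Dirichlet/Gamma shape used for
    clones present in a spot. A frequency of exactly 0 maps to 0; callers
    decide whether a zero shape is admissible (the sampler floors shapes at
    the pseudo-frequency).
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0) or np.any(F > 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if l <= 0:
        raise ValueError("scaling factor l must be positive")
    return l * np.ceil(_FREQ_BINS * F) / _FREQ_BINS


def zeta_over_K_from_expected_clones(expected_clones: float, K: int) -> float:
    """Beta shape ratio ``zeta_s / K`` that yields a target expected number
    of clones per spot.

    Under ``Pi_sk ~ Beta(zeta_s/K, 1)`` and ``Z_sk ~ Bern(Pi_sk)`` the
    expected count of present clones is ``K * zeta_s / (zeta_s + K)``;
    inverting gives ``zeta_s/K = E / (K - E)``.
    """
    if not 0 < expected_clones < K:
        raise ValueError(
            f"expected clones per spot must lie in (0, {K}); got {expected_clones}"
        )
    return expected_clones / (K - expected_clones)


def expected_clones_per_spot(zeta_s: float, K: int) -> float:
    """Expected number of clones present in a spot: ``K*zeta_s/(zeta_s+K)``."""
    if zeta_s <= 0 or K < 1:
        raise ValueError("zeta_s must be positive and K >= 1")
    return K * zeta_s / (zeta_s + K)


def alt_read_success_probability(
    H_s: np.ndarray, Phi_i: np.ndarray, C_i: np.ndarray
) -> float:
    """Binomial success probability for alternated reads at one site/spot.

    ``(sum_k H_sk Phi_ik C_ik) / (sum_k H_sk Phi_ik)`` — the fraction of
    expected reads carrying the variant allele, weighted by clone zygosity.
    Degree-0 homogeneous in ``Phi``. When the denominator is exactly zero
    (no expected coverage, only reachable with D=0) the convention is 0.
    """
    num = float(np.dot(H_s, np.asarray(Phi_i) * np.asarray(C_i)))
    den = float(np.dot(H_s, Phi_i))
    if den == 0.0:
        logger.debug("degenerate site: zero expected coverage, success prob := 0")
        return 0.0
    return num / den


@dataclass
class CloneSet:
    """Genotypes and bulk prevalences of the reconstructed clones.

    ``C`` is an M x K zygosity matrix (0 = no mutation, 1 = all alleles
    mutated); ``F`` the K-simplex of bulk clone prevalences. ``F_disc``
    stores the discretized, ``l``-scaled prevalences used as Dirichlet
    concentrations, floored at the pseudo-frequency ``F0`` so that a clone
    absent from the bulk still has a proper (if tiny) Gamma shape.
    """

    C: np.ndarray
    F: np.ndarray
    F0: float = DEFAULT_F0
    l: float = DEFAULT_SCALING
    F_disc: np.ndarray = field(init=False)
    labels_mutations: list[str] | None = None
    labels_clones: list[str] | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.C.ndim != 2:
            raise ValueError("C must be a 2-D (mutations x clones) matrix")
        if self.C.shape[1] != self.F.shape[0]:
            raise ValueError("C and F disagree on the number of clones")
        if np.any(self.C < 0) or np.any(self.C > 1):
            raise ValueError("zygosity entries must lie in [0, 1]")
        if np.any(self.F < 0) or abs(self.F.sum() - 1.0) > 1e-8:
            raise ValueError("F must be non-negative and sum to 1")
        if self.F0 <= 0 or self.l <= 0:
            raise ValueError("F0 and l must be positive")
        self.F_disc = np.maximum(discretize_prevalence(self.F, self.l), self.F0)

    @property
    def n_mutations(self) -> int:
        return self.C.shape[0]

    @property
    def n_clones(self) -> int:
        return self.C.shape[1]


@dataclass
class SpotDataset:
    """Per-spot observed data: read counts, grid coordinates, cell counts.

    ``A``/``D`` are M x S alternated/total read-count matrices, ``coords``
    S x 2 integer array-grid positions, ``n_prior`` the image-derived cell
    count estimate per spot (used as Poisson prior mean, or as fixed N).
    """

    A: np.ndarray
    D: np.ndarray
    coords: np.ndarray
    n_prior: np.ndarray
    labels_mutations: list[str] | None = None
    labels_spots: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        self.D = np.asarray(self.D)
        self.coords = np.asarray(self.coords)
        self.n_prior = np.asarray(self.n_prior)
        if self.A.shape != self.D.shape:
            raise ValueError("A and D must have identical shape")
        if np.any(self.D < 0):
            raise ValueError("total read counts must be non-negative")
        bad = np.argwhere((self.A > self.D) | (self.A < 0))
        if bad.size:
            i, s = bad[0]
            raise ValueError(
                f"alternated reads exceed total reads (or are negative) at "
                f"mutation {i}, spot {s}: A={self.A[i, s]}, D={self.D[i, s]}"
            )
        if self.coords.shape != (self.A.shape[1], 2):
            raise ValueError("coords must be S x 2")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise ValueError("spot coordinates must be unique")
        if np.any(self.n_prior < 1):
            raise ValueError("prior cell counts must be >= 1")

    @property
    def n_mutations(self) -> int:
        return self.A.shape[0]

    @property
    def n_spots(self) -> int:
        return self.A.shape[1]


@dataclass
class Hyperparams:
    """Model hyperparameters.

    zeta : Beta shape numerator per spot (scalar broadcasts); zeta/K tunes
        the expected number of clones per spot.
    r, p : shape and rate of the Gamma prior on per-cell site coverage Phi;
        the prior mean is r/p.
    Lambda : expected cells per spot (Poisson prior mean on N).
    fixed_n : treat the provided cell counts as known constants instead of
        latent variables (the "fixed" model variant).
    """

    zeta: np.ndarray | float
    r: float
    p: float
    Lambda: np.ndarray | float
    fixed_n: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.zeta) <= 0):
            raise ValueError("zeta must be positive")
        if self.r <= 0 or self.p <= 0:
            raise ValueError("r and p must be positive")
        if np.any(np.asarray(self.Lambda) <= 0):
            raise ValueError("Lambda must be positive")

    def zeta_vector(self, S: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.zeta, dtype=float), (S,)).copy()

    def lambda_vector(self, S: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.Lambda, dtype=float), (S,)).copy()


@dataclass
class LatentState:
    """All latent variables of the model at one MCMC iteration."""

    Z: np.ndarray    # S x K binary presence indicators
    Pi: np.ndarray   # S x K Beta-Bernoulli parameters
    G: np.ndarray    # S x K positive Gamma draws
    H: np.ndarray    # S x K proportions, row-normalized G
    Phi: np.ndarray  # M x K per-cell per-site expected coverage
    N: np.ndarray    # S cell counts (integers >= 1)

    def validate(self) -> None:
        if not np.all((self.Z == 0) | (self.Z == 1)):
            raise ValueError("Z must be binary")
        if np.any(self.G <= 0):
            raise ValueError("G must be strictly positive")
        if np.max(np.abs(self.H.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("H rows must sum to 1")
        if np.max(np.abs(self.H - self.G / self.G.sum(axis=1, keepdims=True))) > 1e-10:
            raise ValueError("H must equal row-normalized G")
        if np.any(self.Phi < 0):
            raise ValueError("Phi must be non-negative")
        if np.any(self.N < 1):
            raise ValueError("N must be >= 1")

    def copy(self) -> "LatentState":
        return LatentState(
            self.Z.copy(), self.Pi.copy(), self.G.copy(),
            self.H.copy(), self.Phi.copy(), self.N.copy(),
        )


# ---------------------------------------------------------------------------
# log-density building blocks (kernels keep data-dependent constants because
# they are used for the full joint; the sampler uses its own reduced forms)

def _beta_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        xlogy(a - 1.0, x)
        + xlog1py(b - 1.0, -x)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
    )

def _gamma_logpdf(x: np.ndarray, shape: np.ndarray, rate: float = 1.0) -> np.ndarray:
    return (
        xlogy(shape, rate) + xlogy(shape - 1.0, x) - rate * x - gammaln(shape)
    )

def _poisson_logpmf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return xlogy(k, lam) - lam - gammaln(k + 1.0)

def _binom_logpmf(k: np.ndarray, n: np.ndarray, q: np.ndarray) -> np.ndarray:
    return (
        gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
        + xlogy(k, q) + xlog1py(n - k, -q)
    )


def gamma_shapes_for_G(clones: CloneSet, Z: np.ndarray) -> np.ndarray:
    """S x K Gamma shapes ``F'_k^Z * F0^(1-Z)`` (floored discretized freqs)."""
    return np.where(Z == 1, clones.F_disc[None, :], clones.F0)


def expected_coverage(H: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """M x S matrix of ``sum_k H_sk Phi_ik`` (per-cell expected site reads)."""
    return Phi @ H.T


def success_probabilities(
    H: np.ndarray, Phi: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """M x S matrix of Binomial success probabilities (0 where coverage is 0)."""
    den = Phi @ H.T
    num = (Phi * C) @ H.T
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(q, 0.0, 1.0)


def log_joint_density(
    state: LatentState,
    data: SpotDataset | None,
    clones: CloneSet,
    hyper: Hyperparams,
) -> float:
    """Full log joint density of latents and observations.

    Sums the Beta prior on Pi, Bernoulli on Z, Gamma on G, Gamma on Phi,
    (truncated-at-1) Poisson on N unless ``fixed_n``, and — when ``data``
    is given — the Poisson likelihood of D and Binomial likelihood of A.
    ``data=None`` gives the prior-only value.
    """
    state.validate()
    S, K = state.Z.shape
    zeta = hyper.zeta_vector(S)
    out = 0.0
    out += float(np.sum(_beta_logpdf(state.Pi, (zeta / K)[:, None], 1.0)))
    out += float(np.sum(xlogy(state.Z, state.Pi) + xlog1py(1 - state.Z, -state.Pi)))
    shapes = gamma_shapes_for_G(clones, state.Z)
    out += float(np.sum(_gamma_logpdf(state.G, shapes, 1.0)))
    out += float(np.sum(_gamma_logpdf(state.Phi, hyper.r, hyper.p)))
    if not hyper.fixed_n:
        lam = hyper.lambda_vector(S)
        # Poisson prior truncated to N >= 1
        logtrunc = np.log1p(-np.exp(-lam))
        out += float(np.sum(_poisson_logpmf(state.N, lam) - logtrunc))
    if data is not None and data.n_mutations and data.n_spots:
        rate = state.N[None, :] * expected_coverage(state.H, state.Phi)
        out += float(np.sum(_poisson_logpmf(data.D, rate)))
        q = success_probabilities(state.H, state.Phi, clones.C)
        with np.errstate(invalid="ignore"):
            ll_a = _binom_logpmf(data.A, data.D, q)
        # D == 0 sites contribute zero regardless of q (convention q := 0)
        out += float(np.sum(np.where(data.D > 0, ll_a, 0.0)))
    if not np.isfinite(out):
        raise ValueError("log joint is not finite for the given state")
    return out


def sample_generative(
    clones: CloneSet,
    hyper: Hyperparams,
    S: int,
    rng: np.random.Generator,
    coords: np.ndarray | None = None,
) -> tuple[LatentState, SpotDataset]:
    """Draw one dataset from the full generative process.

    Samples Pi -> Z -> G -> H -> Phi -> N -> D -> A in topological order.
    N is drawn from Poisson(Lambda) truncated to >= 1 (a spot contains at
    least one cell). ``coords`` defaults to a near-square integer grid.
    """
    M, K = clones.C.shape
    zeta = hyper.zeta_vector(S)
    Pi = rng.beta((zeta / K)[:, None] * np.ones((S, K)), 1.0)
    Z = (rng.random((S, K)) < Pi).astype(np.int8)
    shapes = gamma_shapes_for_G(clones, Z)
    G = rng.gamma(shape=shapes, scale=1.0)
    G = np.maximum(G, 1e-300)  # guard against underflow to exactly 0
    H = G / G.sum(axis=1, keepdims=True)
    Phi = rng.gamma(shape=hyper.r, scale=1.0 / hyper.p, size=(M, K))
    lam = hyper.lambda_vector(S)
    N = rng.poisson(lam)
    while np.any(N < 1):  # truncate to >= 1
        idx = N < 1
        N[idx] = rng.poisson(lam[idx])
    rate = N[None, :] * expected_coverage(H, Phi)
    D = rng.poisson(rate)
    q = success_probabilities(H, Phi, clones.C)
    A = rng.binomial(D, q)
    if coords is None:
        side = int(np.ceil(np.sqrt(S)))
        grid = np.indices((side, side)).reshape(2, -1).T[:S]
        coords = grid
    state = LatentState(Z=Z, Pi=Pi, G=G, H=H, Phi=Phi, N=N)
    data = SpotDataset(A=A, D=D, coords=coords, n_prior=np.maximum(N, 1))
    return state, data
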