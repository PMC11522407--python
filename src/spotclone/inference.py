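"""Metropolis-Hastings-within-Gibbs sampler for the clone-mixture model.

Closed-form Gibbs updates exist for the Beta-Bernoulli block (Pi, Z); the
per-cell coverage Phi, the Gamma draws G behind the mixture weights H, and
the cell counts N have no conjugate conditional and are updated with
Metropolis-Hastings steps using zero-truncated normal random-walk
proposals. Proposal step sizes are adapted from acceptance-rate feedback
during burn-in only, so the post-burn-in chain is a fixed-kernel Markov
chain with the correct stationary distribution.

Sweep order: Pi -> Z -> Phi -> G -> N (N skipped in the fixed-N variant).
Each block is vectorized over the independent axis (mutations for a Phi
column, spots for a G column and for N), looping only over clone columns,
which keeps a full sweep at a few dozen numpy calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.special import gammaln, ndtr, ndtri, xlog1py, xlogy

from .model import (
    CloneSet,
    Hyperparams,
    LatentState,
    SpotDataset,
    gamma_shapes_for_G,
    log_joint_density,
)

logger = logging.getLogger(__name__)


@dataclass
class ChainSettings:
    """MCMC run configuration.

    Defaults are deliberately generous (20k sweeps, half burn-in); the
    scaled-down settings used in examples and validation runs are passed
    explicitly. Adaptation of the proposal step sizes happens every
    ``tune_interval`` sweeps during burn-in and is frozen afterward.
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    tune_interval: int = 100
    target_accept: float = 0.44
    sigma_phi: float = 0.5
    sigma_g: float = 0.5
    sigma_n: float = 0.5
    fixed_n: bool = False
    store_h_trace: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1 or self.tune_interval < 1:
            raise ValueError("thin and tune_interval must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target acceptance rate must be in (0, 1)")
        if min(self.sigma_phi, self.sigma_g, self.sigma_n) <= 0:
            raise ValueError("initial proposal SDs must be positive")


@dataclass
class PosteriorSummary:
    """Posterior means and sampler diagnostics."""

    H_mean: np.ndarray
    N_mean: np.ndarray
    Phi_mean: np.ndarray
    Z_mean: np.ndarray
    accept_rates: dict[str, float]
    n_samples: int
    sigmas: dict[str, float]
    mean_log_joint: float = float("nan")
    H_trace: np.ndarray | None = None

    def major_clones(self) -> np.ndarray:
        """Argmax clone per spot; ties resolve to the lowest clone index."""
        return np.argmax(self.H_mean, axis=1)


def adapt_proposal_sigma(sigma: float, target_rate: float, current_rate: float) -> float:
    """Acceptance-rate feedback on a random-walk step size.

    Multiplies sigma by ``1 + (current - target)``: acceptance above target
    means the steps are too timid, so the step grows; below target it
    shrinks. This is the stable feedback direction — the fixed point at the
    target rate attracts, since acceptance decreases with step size.
    """
    delta = current_rate - target_rate
    new = sigma * (1.0 + delta)
    return max(new, 1e-12)


# -- zero-truncated normal proposal helpers ---------------------------------

def _sample_truncnorm(
    mu: np.ndarray, sigma: float, rng: np.random.Generator, lower: float = 0.0
) -> np.ndarray:
    """Vector of draws from Normal(mu, sigma) truncated to (lower, inf)."""
    alpha = ndtr((lower - mu) / sigma)
    u = rng.random(mu.shape)
    x = mu + sigma * ndtri(alpha + u * (1.0 - alpha))
    # inverse-CDF can round to the boundary at extreme alpha
    return np.maximum(x, lower + 1e-12)


def _log_truncnorm_norm(mu: np.ndarray, sigma: float, lower: float = 0.0) -> np.ndarray:
    """log of the truncation normalizer P(X > lower) for X ~ N(mu, sigma)."""
    return np.log(np.maximum(ndtr((mu - lower) / sigma), 1e-300))


def _integer_proposal_logpmf(
    n: np.ndarray, mu: np.ndarray, sigma: float
) -> np.ndarray:
    """Log-probability of integer ``n`` under round(truncnorm(mu, sigma, >0.5)).

    The mass of integer n is the truncated normal's probability of the unit
    interval [n-1/2, n+1/2]; support is n >= 1.
    """
    z_hi = ndtr((n + 0.5 - mu) / sigma)
    z_lo = ndtr((n - 0.5 - mu) / sigma)
    norm = 1.0 - ndtr((0.5 - mu) / sigma)
    return np.log(np.maximum(z_hi - z_lo, 1e-300)) - np.log(np.maximum(norm, 1e-300))


# -- Gibbs blocks ------------------------------------------------------------

def gibbs_update_pi(
    state: LatentState, hyper: Hyperparams, rng: np.random.Generator
) -> None:
    """Conjugate Beta update: Pi_sk ~ Beta(zeta_s/K + Z_sk, 2 - Z_sk)."""
    S, K = state.Z.shape
    a = (hyper.zeta_vector(S) / K)[:, None] + state.Z
    b = 2.0 - state.Z
    state.Pi = rng.beta(a, b)


def gibbs_update_z(
    state: LatentState, clones: CloneSet, rng: np.random.Generator
) -> None:
    """Exact binary update of the clone-presence indicators.

    P(Z_sk = z) is proportional to Bern(z | Pi_sk) * Gamma(G_sk | shape_z, 1)
    where shape_1 is the discretized prevalence and shape_0 the
    pseudo-frequency; both masses are formed in log space.
    """
    logG = np.log(state.G)
    a1 = clones.F_disc[None, :]
    a0 = clones.F0
    log1 = np.log(np.maximum(state.Pi, 1e-300)) + (a1 - 1.0) * logG - gammaln(a1)
    log0 = (
        np.log(np.maximum(1.0 - state.Pi, 1e-300))
        + (a0 - 1.0) * logG
        - gammaln(a0)
    )
    # shared -G and rate terms cancel between the two masses
    m = np.maximum(log1, log0)
    p1 = np.exp(log1 - m)
    p1 = p1 / (p1 + np.exp(log0 - m))
    state.Z = (rng.random(state.Z.shape) < p1).astype(np.int8)


@numba.njit(cache=True, fastmath=False)
def _site_loglik_jit(A, D, R, T, N):  # pragma: no cover - exercised via wrapper
    M, S = R.shape
    out = np.empty((M, S))
    for i in range(M):
        for s in range(S):
            r = R[i, s]
            if r < 1e-300:
                r = 1e-300
            q = T[i, s] / r
            if q > 1.0:
                q = 1.0
            ll = -N[s] * R[i, s]
            d = D[i, s]
            if d > 0:
                a = A[i, s]
                if a > 0:
                    ll += a * np.log(q)
                if d > a:
                    ll += (d - a) * np.log1p(-q)
                ll += d * np.log(r)
            out[i, s] = ll
    return out


def _site_loglik(A, D, R, T, N):
    """Binomial + Poisson log-likelihood kernel, elementwise over M x S.

    Drops terms constant in the latent variables (binomial coefficient,
    log D!, D log N). Safe at R = 0 (only with D = 0, contributing 0).
    """
    return _site_loglik_jit(
        np.asarray(A, dtype=np.float64),
        np.asarray(D, dtype=np.float64),
        np.ascontiguousarray(R),
        np.ascontiguousarray(T),
        np.asarray(N, dtype=np.float64),
    )


class _SweepWorkspace:
    """Running coverage matrices R = Phi H^T, T = (Phi C) H^T and the
    per-entry likelihood kernel LL = _site_loglik(A, D, R, T, N), all
    updated incrementally on accepted moves."""

    def __init__(self, state: LatentState, clones: CloneSet, data: SpotDataset):
        self.C = clones.C
        self.A = np.asarray(data.A, dtype=np.float64)
        self.D = np.asarray(data.D, dtype=np.float64)
        self.D_colsum = self.D.sum(axis=0)
        self.refresh(state)

    def refresh(self, state: LatentState) -> None:
        self.R = state.Phi @ state.H.T
        self.T = (state.Phi * self.C) @ state.H.T
        self.LL = _site_loglik(self.A, self.D, self.R, self.T, state.N)


def mh_update_phi(
    state: LatentState,
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    sigma: float,
    rng: np.random.Generator,
    ws: _SweepWorkspace,
) -> tuple[int, int]:
    """MH update of every Phi entry, one clone column at a time.

    Rows (mutations) are conditionally independent given the rest, so each
    column update proposes an M-vector from the zero-truncated normal and
    accepts per row. Returns (accepted, proposed) counts.
    """
    M, K = state.Phi.shape
    acc = 0
    for k in range(K):
        cur = state.Phi[:, k]
        prop = _sample_truncnorm(cur, sigma, rng)
        d = prop - cur
        Rn = ws.R + d[:, None] * state.H[:, k][None, :]
        Tn = ws.T + (d * clones.C[:, k])[:, None] * state.H[:, k][None, :]
        LLn = _site_loglik(ws.A, ws.D, Rn, Tn, state.N)
        ll_new = LLn.sum(axis=1)
        ll_old = ws.LL.sum(axis=1)
        lp = (hyper.r - 1.0) * (np.log(prop) - np.log(cur)) - hyper.p * d
        corr = _log_truncnorm_norm(cur, sigma) - _log_truncnorm_norm(prop, sigma)
        logratio = ll_new - ll_old + lp + corr
        accept = np.log(rng.random(M)) < logratio
        if np.any(accept):
            state.Phi[accept, k] = prop[accept]
            ws.R[accept] = Rn[accept]
            ws.T[accept] = Tn[accept]
            ws.LL[accept] = LLn[accept]
        acc += int(accept.sum())
    return acc, M * K


def mh_update_g(
    state: LatentState,
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    sigma: float,
    rng: np.random.Generator,
    ws: _SweepWorkspace,
) -> tuple[int, int]:
    """MH update of every G entry (and hence H), one clone column at a time.

    Changing G_sk renormalizes the whole row H_s, so the likelihood of all
    sites in spot s enters the ratio. Spots are independent given the rest;
    acceptance is per spot. Returns (accepted, proposed) counts.
    """
    S, K = state.G.shape
    shapes = gamma_shapes_for_G(clones, state.Z)
    PhiC = state.Phi * clones.C
    acc = 0
    for k in range(K):
        cur = state.G[:, k]
        prop = _sample_truncnorm(cur, sigma, rng)
        rowsum = state.G.sum(axis=1)
        newsum = rowsum - cur + prop
        Hn = state.G / newsum[:, None]
        Hn[:, k] = prop / newsum
        Rn = state.Phi @ Hn.T
        Tn = PhiC @ Hn.T
        LLn = _site_loglik(ws.A, ws.D, Rn, Tn, state.N)
        ll_new = LLn.sum(axis=0)
        ll_old = ws.LL.sum(axis=0)
        a = shapes[:, k]
        lp = (a - 1.0) * (np.log(prop) - np.log(cur)) - (prop - cur)
        corr = _log_truncnorm_norm(cur, sigma) - _log_truncnorm_norm(prop, sigma)
        logratio = ll_new - ll_old + lp + corr
        accept = np.log(rng.random(S)) < logratio
        if np.any(accept):
            state.G[accept, k] = prop[accept]
            state.H[accept] = state.G[accept] / state.G[accept].sum(
                axis=1, keepdims=True
            )
            ws.R[:, accept] = Rn[:, accept]
            ws.T[:, accept] = Tn[:, accept]
        acc += int(accept.sum())
    return acc, S * K


def mh_flip_z(
    state: LatentState,
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    rng: np.random.Generator,
    ws: _SweepWorkspace,
) -> tuple[int, int]:
    """Joint (Z, G) mode-switching move.

    The single-site Gibbs update of Z conditions on the current G, and the
    random-walk update of G conditions on Z, so switching a clone's
    presence requires G to cross a region where the Gamma(F', 1) prior has
    essentially no mass — the chain cannot tunnel between the two modes.
    This move proposes flipping Z_sk together with a fresh G_sk drawn from
    the Gamma prior of the *flipped* state. The prior of the proposed G
    cancels against its proposal density, leaving an acceptance ratio of
    the Bernoulli odds times the spot's likelihood ratio — a valid
    Metropolis-Hastings move on the joint that hops directly between the
    present and absent basins. Returns (accepted, proposed) counts.
    """
    S, K = state.Z.shape
    PhiC = state.Phi * clones.C
    acc = 0
    for k in range(K):
        z_new = 1 - state.Z[:, k]
        a_new = np.where(z_new == 1, clones.F_disc[k], clones.F0)
        prop = np.maximum(rng.gamma(shape=a_new, scale=1.0), 1e-12)
        cur = state.G[:, k]
        newsum = state.G.sum(axis=1) - cur + prop
        Hn = state.G / newsum[:, None]
        Hn[:, k] = prop / newsum
        Rn = state.Phi @ Hn.T
        Tn = PhiC @ Hn.T
        LLn = _site_loglik(ws.A, ws.D, Rn, Tn, state.N)
        ll_new = LLn.sum(axis=0)
        ll_old = ws.LL.sum(axis=0)
        pi_k = np.clip(state.Pi[:, k], 1e-12, 1.0 - 1e-12)
        bern = np.where(
            z_new == 1,
            np.log(pi_k) - np.log1p(-pi_k),
            np.log1p(-pi_k) - np.log(pi_k),
        )
        logratio = ll_new - ll_old + bern
        accept = np.log(rng.random(S)) < logratio
        if np.any(accept):
            state.Z[accept, k] = z_new[accept]
            state.G[accept, k] = prop[accept]
            state.H[accept] = state.G[accept] / state.G[accept].sum(
                axis=1, keepdims=True
            )
            ws.R[:, accept] = Rn[:, accept]
            ws.T[:, accept] = Tn[:, accept]
            ws.LL[:, accept] = LLn[:, accept]
        acc += int(accept.sum())
    return acc, S * K


def mh_swap_clones(
    state: LatentState,
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    rng: np.random.Generator,
    ws: _SweepWorkspace,
) -> bool:
    """Global label-switching move: exchange two clones' latent columns.

    Proposes swapping columns (k1, k2) of Z, Pi, G (hence H) and Phi while
    the genotypes stay put — i.e. re-attributing the two mixture
    components to each other's genotype. When the chain has settled into a
    mislabeled assignment of similar (e.g. nested parent/child) clones,
    the swapped state is the correctly labeled mode and the move jumps
    there in one step, which single-entry updates can only do through an
    astronomically unlikely sequence. The Beta and Phi priors are
    exchangeable over clones and the (Z, G) pairing travels together, so
    the acceptance ratio is the likelihood ratio times the G-prior ratio
    from any difference in the two clones' discretized prevalences.
    Returns whether the proposal was accepted.
    """
    S, K = state.Z.shape
    if K < 2:
        return False
    k1, k2 = rng.choice(K, size=2, replace=False)
    perm = np.arange(K)
    perm[k1], perm[k2] = k2, k1
    Hn = state.H[:, perm]
    Phin = state.Phi[:, perm]
    Rn = Phin @ Hn.T
    Tn = (Phin * clones.C) @ Hn.T
    LLn = _site_loglik(ws.A, ws.D, Rn, Tn, state.N)
    ll_new = LLn.sum()
    ll_old = ws.LL.sum()
    lp = 0.0
    if clones.F_disc[k1] != clones.F_disc[k2]:
        shapes_old = gamma_shapes_for_G(clones, state.Z)
        shapes_new = gamma_shapes_for_G(clones, state.Z[:, perm])
        Gn = state.G[:, perm]
        lp = float(
            np.sum(_g_prior_logpdf(Gn, shapes_new))
            - np.sum(_g_prior_logpdf(state.G, shapes_old))
        )
    if np.log(rng.random()) < ll_new - ll_old + lp:
        state.Z = state.Z[:, perm]
        state.Pi = state.Pi[:, perm]
        state.G = state.G[:, perm]
        state.H = Hn
        state.Phi = Phin
        ws.R = Rn
        ws.T = Tn
        ws.LL = LLn
        return True
    return False


def _g_prior_logpdf(G: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    return (shapes - 1.0) * np.log(G) - G - gammaln(shapes)


def mh_update_n(
    state: LatentState,
    data: SpotDataset,
    hyper: Hyperparams,
    sigma: float,
    rng: np.random.Generator,
    ws: _SweepWorkspace,
) -> tuple[int, int]:
    """MH update of the per-spot cell counts with integer proposals.

    A continuous draw from a normal truncated at 0.5 is rounded to the
    nearest integer (support N >= 1); the MH correction uses the exact
    unit-interval mass of each integer under the truncated proposal.
    Target: Poisson(Lambda_s) prior (truncation constant cancels) times the
    Poisson likelihood of the spot's total reads. No-op when ``fixed_n``.
    """
    if hyper.fixed_n:
        return 0, 0
    S = state.N.shape[0]
    lam = hyper.lambda_vector(S)
    cur = state.N.astype(float)
    y = _sample_truncnorm(cur, sigma, rng, lower=0.5)
    prop = np.round(y)
    Rcol = ws.R.sum(axis=0)
    d = prop - cur
    loglik = -d * Rcol + ws.D_colsum * (np.log(prop) - np.log(cur))
    lp = d * np.log(lam) - (gammaln(prop + 1.0) - gammaln(cur + 1.0))
    corr = _integer_proposal_logpmf(cur, prop, sigma) - _integer_proposal_logpmf(
        prop, cur, sigma
    )
    logratio = loglik + lp + corr
    accept = np.log(rng.random(S)) < logratio
    if np.any(accept):
        # LL holds -N_s R (the D log N term is not part of the kernel)
        ws.LL[:, accept] -= d[accept][None, :] * ws.R[:, accept]
    state.N = np.where(accept, prop, cur).astype(np.int64)
    return int(accept.sum()), S


def initialize_state(
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> LatentState:
    """Feasible start: all clones present, N at its prior, Phi at data scale.

    Phi is initialized at the per-site per-cell coverage estimate
    ``mean_s D_is / n_s``, identical across clones. An exchangeable start
    matters: drawing Phi from its heavy-near-zero Gamma prior seeds
    arbitrary order-of-magnitude asymmetries between clones at each site,
    and because Phi is shared across spots the chain can settle into a
    self-consistent wrong labeling of nested (parent/child) clones.
    Starting symmetric lets the reads, not the draw, break the ties.
    """
    M, K = clones.C.shape
    S = data.n_spots
    zeta = hyper.zeta_vector(S)
    Pi = rng.beta((zeta / K)[:, None] * np.ones((S, K)), 1.0)
    Z = np.ones((S, K), dtype=np.int8)
    G = rng.gamma(shape=gamma_shapes_for_G(clones, Z), scale=1.0)
    G = np.maximum(G, 1e-12)
    H = G / G.sum(axis=1, keepdims=True)
    x = (data.D / np.maximum(data.n_prior, 1)[None, :]).mean(axis=1)
    Phi = np.tile(np.maximum(x, 1e-4)[:, None], (1, K))
    N = np.asarray(data.n_prior, dtype=np.int64).copy()
    return LatentState(Z=Z, Pi=Pi, G=G, H=H, Phi=Phi, N=N)


def run_chain(
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    settings: ChainSettings,
) -> PosteriorSummary:
    """Run the full Gibbs sampler and return posterior summaries.

    Bit-reproducible given ``settings.seed``. Raises on dimension mismatch
    or a non-finite log joint at initialization.
    """
    if data.n_mutations != clones.n_mutations:
        raise ValueError(
            f"data has {data.n_mutations} mutations but clones {clones.n_mutations}"
        )
    if settings.fixed_n != hyper.fixed_n:
        hyper = Hyperparams(
            zeta=hyper.zeta, r=hyper.r, p=hyper.p,
            Lambda=hyper.Lambda, fixed_n=settings.fixed_n,
        )
    rng = np.random.default_rng(settings.seed)
    state = initialize_state(data, clones, hyper, rng)
    lj = log_joint_density(state, data, clones, hyper)
    if not np.isfinite(lj):  # pragma: no cover - log_joint raises first
        raise ValueError("non-finite log joint at initialization")

    n_keep = (settings.n_iter - settings.burn_in) // settings.thin
    if n_keep < 1:
        raise ValueError("no post-burn-in samples: increase n_iter or reduce thin")

    ws = _SweepWorkspace(state, clones, data)
    sig = {"phi": settings.sigma_phi, "g": settings.sigma_g, "n": settings.sigma_n}
    win = {"phi": [0, 0], "g": [0, 0], "n": [0, 0]}
    tot = {"phi": [0, 0], "g": [0, 0], "n": [0, 0]}

    H_sum = np.zeros_like(state.H)
    N_sum = np.zeros_like(state.N, dtype=float)
    Phi_sum = np.zeros_like(state.Phi)
    Z_sum = np.zeros(state.Z.shape, dtype=float)
    H_trace = (
        np.empty((n_keep,) + state.H.shape) if settings.store_h_trace else None
    )
    lj_sum = 0.0
    kept = 0

    for t in range(settings.n_iter):
        gibbs_update_pi(state, hyper, rng)
        gibbs_update_z(state, clones, rng)
        a, n = mh_update_phi(state, data, clones, hyper, sig["phi"], rng, ws)
        win["phi"][0] += a; win["phi"][1] += n
        a, n = mh_update_g(state, data, clones, hyper, sig["g"], rng, ws)
        win["g"][0] += a; win["g"][1] += n
        mh_flip_z(state, data, clones, hyper, rng, ws)
        mh_swap_clones(state, data, clones, hyper, rng, ws)
        a, n = mh_update_n(state, data, hyper, sig["n"], rng, ws)
        win["n"][0] += a; win["n"][1] += n
        if (t + 1) % 500 == 0:
            ws.refresh(state)  # cancel incremental-update drift

        in_burn = t < settings.burn_in
        if in_burn and (t + 1) % settings.tune_interval == 0:
            for blk in ("phi", "g", "n"):
                if win[blk][1]:
                    rate = win[blk][0] / win[blk][1]
                    sig[blk] = adapt_proposal_sigma(
                        sig[blk], settings.target_accept, rate
                    )
                win[blk] = [0, 0]
        if not in_burn:
            for blk in ("phi", "g", "n"):
                tot[blk][0] += win[blk][0]; tot[blk][1] += win[blk][1]
                win[blk] = [0, 0]
            if (t - settings.burn_in) % settings.thin == 0:
                H_sum += state.H
                N_sum += state.N
                Phi_sum += state.Phi
                Z_sum += state.Z
                lj_sum += log_joint_density(state, data, clones, hyper)
                if H_trace is not None:
                    H_trace[kept] = state.H
                kept += 1

    H_mean = H_sum / kept
    H_mean = H_mean / H_mean.sum(axis=1, keepdims=True)
    accept = {
        blk: (tot[blk][0] / tot[blk][1] if tot[blk][1] else float("nan"))
        for blk in ("phi", "g", "n")
    }
    return PosteriorSummary(
        H_mean=H_mean,
        N_mean=N_sum / kept,
        Phi_mean=Phi_sum / kept,
        Z_mean=Z_sum / kept,
        accept_rates=accept,
        n_samples=kept,
        sigmas=dict(sig),
        mean_log_joint=lj_sum / kept,
        H_trace=H_trace,
    )


def run_multistart(
    data: SpotDataset,
    clones: CloneSet,
    hyper: Hyperparams,
    settings: ChainSettings,
    n_chains: int = 2,
) -> PosteriorSummary:
    """Run independent chains from different seeds and keep the best.

    The posterior over presence patterns and clone labels is multimodal
    and a single chain can settle in a minor mode. Chains are compared by
    their mean post-burn-in log joint density — a model-internal
    criterion — and the highest-scoring chain's summary is returned.
    """
    best: PosteriorSummary | None = None
    for c in range(n_chains):
        s = ChainSettings(
            n_iter=settings.n_iter, burn_in=settings.burn_in,
            thin=settings.thin, seed=settings.seed + 7919 * c,
            tune_interval=settings.tune_interval,
            target_accept=settings.target_accept,
            sigma_phi=settings.sigma_phi, sigma_g=settings.sigma_g,
            sigma_n=settings.sigma_n, fixed_n=settings.fixed_n,
            store_h_trace=settings.store_h_trace,
        )
        res = run_chain(data, clones, hyper, s)
        if best is None or res.mean_log_joint > best.mean_log_joint:
            best = res
    return best


def summarize_posterior(samples: list[LatentState]) -> PosteriorSummary:
    """Summarize an explicit list of kept states (used for small studies).

    Elementwise means; H rows re-normalized onto the simplex.
    """
    if not samples:
        raise ValueError("no post-burn-in samples to summarize")
    H_mean = np.mean([s.H for s in samples], axis=0)
    H_mean = H_mean / H_mean.sum(axis=1, keepdims=True)
    return PosteriorSummary(
        H_mean=H_mean,
        N_mean=np.mean([s.N for s in samples], axis=0),
        Phi_mean=np.mean([s.Phi for s in samples], axis=0),
        Z_mean=np.mean([s.Z for s in samples], axis=0),
        accept_rates={},
        n_samples=len(samples),
        sigmas={},
    )
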