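"""Sampler blocks against independent oracles, plus end-to-end behavior.

Each conditional update is checked on a minimal instance against direct
sampling, closed-form posteriors, or enumeration — never against the code
path it exercises.
"""

import numpy as np
import pytest
from scipy import stats

import spotclone as sc
from spotclone.inference import (
    mh_swap_clones,
    ChainSettings,
    _SweepWorkspace,
    adapt_proposal_sigma,
    gibbs_update_pi,
    initialize_state,
    mh_flip_z,
    mh_update_g,
    mh_update_n,
    mh_update_phi,
    run_chain,
    summarize_posterior,
)
from spotclone.model import CloneSet, Hyperparams, SpotDataset


def _empty_dataset(M: int, S: int = 0) -> SpotDataset:
    """Dataset with zero spots: likelihood terms vanish, priors remain."""
    return SpotDataset(
        A=np.zeros((M, S), dtype=int),
        D=np.zeros((M, S), dtype=int),
        coords=np.column_stack([np.arange(S), np.zeros(S, dtype=int)]),
        n_prior=np.ones(S, dtype=int),
    )


def _single_clone_setup(r=2.0, p=1.5, zeta=1.0, lam=9.0):
    clones = CloneSet(C=np.array([[1.0]]), F=np.array([1.0]))
    hyper = Hyperparams(zeta=zeta, r=r, p=p, Lambda=lam)
    return clones, hyper


class TestPiBlock:
    def test_beta_posterior_distribution(self):
        """Draws follow Beta(zeta/K + Z, 2 - Z): KS distance < 0.01 at 1e5."""
        clones = CloneSet(C=np.ones((1, 2)), F=np.array([0.5, 0.5]))
        hyper = Hyperparams(zeta=0.5, r=1.0, p=1.0, Lambda=5.0)
        rng = np.random.default_rng(0)
        state, _ = sc.sample_generative(clones, hyper, 1, rng)
        state.Z = np.array([[1, 0]], dtype=np.int8)
        n = 100_000
        draws = np.empty((n, 2))
        for t in range(n):
            gibbs_update_pi(state, hyper, rng)
            draws[t] = state.Pi[0]
        # zeta/K = 0.25; Z=1 -> Beta(1.25, 1), Z=0 -> Beta(0.25, 2)
        d1 = stats.kstest(draws[:, 0], stats.beta(1.25, 1.0).cdf).statistic
        d0 = stats.kstest(draws[:, 1], stats.beta(0.25, 2.0).cdf).statistic
        assert d1 < 0.01 and d0 < 0.01
        assert draws[:, 0].mean() == pytest.approx(1.25 / 2.25, abs=0.005)


class TestPhiBlock:
    def test_proposals_nonnegative_and_prior_recovery(self):
        """With no data the chain's long-run Phi mean is the prior mean r/p."""
        clones, hyper = _single_clone_setup(r=2.0, p=1.5)
        data = _empty_dataset(1, 0)
        rng = np.random.default_rng(1)
        state = sc.LatentState(
            Z=np.zeros((0, 1), dtype=np.int8), Pi=np.zeros((0, 1)),
            G=np.zeros((0, 1)), H=np.zeros((0, 1)),
            Phi=np.array([[1.0]]), N=np.zeros(0, dtype=np.int64),
        )
        ws = _SweepWorkspace(state, clones, data)
        n = 60_000
        kept = np.empty(n)
        for t in range(n):
            mh_update_phi(state, data, clones, hyper, 1.2, rng, ws)
            assert state.Phi[0, 0] >= 0
            kept[t] = state.Phi[0, 0]
        ess = n / (2 * 10)  # conservative autocorrelation allowance
        se = kept.std(ddof=1) / np.sqrt(ess)
        assert abs(kept.mean() - 2.0 / 1.5) < 3 * se

    def test_stationary_matches_closed_form_posterior(self):
        """On 1 site / 1 clone / 1 spot with H=1 fixed, the Phi conditional
        is Gamma(r + D, p + N) in closed form (the Binomial factor is
        constant); the chain's samples match it (KS < 0.02)."""
        clones, hyper = _single_clone_setup(r=0.5, p=1.0)
        D_val, N_val = 7, 4
        data = SpotDataset(
            A=np.array([[7]]), D=np.array([[D_val]]),
            coords=np.array([[0, 0]]), n_prior=np.array([N_val]),
        )
        rng = np.random.default_rng(2)
        state = sc.LatentState(
            Z=np.ones((1, 1), dtype=np.int8), Pi=np.array([[0.5]]),
            G=np.array([[1.0]]), H=np.array([[1.0]]),
            Phi=np.array([[0.5]]), N=np.array([N_val], dtype=np.int64),
        )
        ws = _SweepWorkspace(state, clones, data)
        n = 80_000
        kept = np.empty(n)
        for t in range(n):
            mh_update_phi(state, data, clones, hyper, 0.8, rng, ws)
            kept[t] = state.Phi[0, 0]
        target = stats.gamma(0.5 + D_val, scale=1.0 / (1.0 + N_val))
        d = stats.kstest(kept[::4], target.cdf).statistic
        assert d < 0.02


class TestGBlock:
    def test_h_rows_remain_on_simplex(self, tiny_clones, tiny_hyper):
        rng = np.random.default_rng(3)
        state, data = sc.sample_generative(tiny_clones, tiny_hyper, 5, rng)
        ws = _SweepWorkspace(state, tiny_clones, data)
        for _ in range(200):
            mh_update_g(state, data, tiny_clones, tiny_hyper, 0.5, rng, ws)
            np.testing.assert_allclose(state.H.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(
                state.H, state.G / state.G.sum(axis=1, keepdims=True), atol=1e-12
            )

    def test_no_data_stationary_matches_gamma_prior(self):
        """1 spot, 2 clones, no data: G entries are independently
        Gamma(shape, 1); MH samples match direct sampling (KS < 0.02)."""
        clones = CloneSet(C=np.ones((1, 2)), F=np.array([0.25, 0.75]))
        hyper = Hyperparams(zeta=2.0, r=1.0, p=1.0, Lambda=5.0)
        data = _empty_dataset(1, 1)
        rng = np.random.default_rng(4)
        state = sc.LatentState(
            Z=np.array([[1, 0]], dtype=np.int8), Pi=np.array([[0.5, 0.5]]),
            G=np.array([[1.0, 0.5]]), H=np.array([[2 / 3, 1 / 3]]),
            Phi=np.array([[0.1, 0.1]]), N=np.array([1], dtype=np.int64),
        )
        ws = _SweepWorkspace(state, clones, data)
        n = 100_000
        kept = np.empty(n)
        for t in range(n):
            mh_update_g(state, data, clones, hyper, 8.0, rng, ws)
            kept[t] = state.G[0, 0]
        # Z=1 for clone 0 -> shape = F'_0 = 25
        target = stats.gamma(clones.F_disc[0], scale=1.0)
        d = stats.kstest(kept[::5], target.cdf).statistic
        assert d < 0.02

    def test_no_data_h_converges_to_dirichlet_mean(self):
        """Long-run H mean equals the Dirichlet mean of the active shapes."""
        clones = CloneSet(C=np.ones((1, 2)), F=np.array([0.4, 0.6]))
        hyper = Hyperparams(zeta=2.0, r=1.0, p=1.0, Lambda=5.0)
        data = _empty_dataset(1, 1)
        rng = np.random.default_rng(5)
        state = sc.LatentState(
            Z=np.array([[1, 1]], dtype=np.int8), Pi=np.array([[0.5, 0.5]]),
            G=np.array([[1.0, 1.0]]), H=np.array([[0.5, 0.5]]),
            Phi=np.array([[0.1, 0.1]]), N=np.array([1], dtype=np.int64),
        )
        ws = _SweepWorkspace(state, clones, data)
        n = 60_000
        kept = np.empty(n)
        for t in range(n):
            mh_update_g(state, data, clones, hyper, 10.0, rng, ws)
            kept[t] = state.H[0, 0]
        shapes = clones.F_disc  # (40, 60) at l=100
        want = shapes[0] / shapes.sum()
        se = kept.std(ddof=1) / np.sqrt(n / 20)
        assert abs(kept.mean() - want) < 3 * se


class TestNBlock:
    def test_fixed_n_is_noop(self, tiny_clones):
        hyper = Hyperparams(zeta=2.0, r=0.09, p=1.0, Lambda=10.0, fixed_n=True)
        rng = np.random.default_rng(6)
        state, data = sc.sample_generative(tiny_clones, hyper, 10, rng)
        ws = _SweepWorkspace(state, tiny_clones, data)
        before = state.N.copy()
        for _ in range(50):
            mh_update_n(state, data, hyper, 0.5, rng, ws)
        np.testing.assert_array_equal(state.N, before)

    def test_no_data_matches_truncated_poisson(self):
        """Without likelihood terms N targets Poisson(Lambda) restricted to
        N >= 1; the chain matches the truncated mean and support."""
        lam = 3.0
        hyper = Hyperparams(zeta=1.0, r=1.0, p=1.0, Lambda=lam)
        data = _empty_dataset(1, 1)
        rng = np.random.default_rng(7)
        state = sc.LatentState(
            Z=np.ones((1, 1), dtype=np.int8), Pi=np.array([[0.5]]),
            G=np.array([[1.0]]), H=np.array([[1.0]]),
            Phi=np.array([[0.0]]), N=np.array([2], dtype=np.int64),
        )  # Phi = 0: the D = 0 likelihood term vanishes, prior only
        ws = _SweepWorkspace(state, sc.CloneSet(
            C=np.ones((1, 1)), F=np.array([1.0])), data)
        n = 60_000
        kept = np.empty(n, dtype=int)
        for t in range(n):
            mh_update_n(state, data, hyper, 2.0, rng, ws)
            kept[t] = state.N[0]
        assert kept.min() >= 1
        want = lam / (1.0 - np.exp(-lam))  # mean of zero-truncated Poisson
        se = kept.std(ddof=1) / np.sqrt(n / 20)
        assert abs(kept.mean() - want) < 3 * se


class TestFlipMove:
    def test_flip_preserves_invariants_and_mixes_z(self, tiny_clones, tiny_hyper):
        rng = np.random.default_rng(8)
        state, data = sc.sample_generative(tiny_clones, tiny_hyper, 20, rng)
        ws = _SweepWorkspace(state, tiny_clones, data)
        flips = 0
        z0 = state.Z.copy()
        for _ in range(300):
            mh_flip_z(state, data, tiny_clones, tiny_hyper, rng, ws)
            np.testing.assert_allclose(state.H.sum(axis=1), 1.0, atol=1e-12)
        flips = np.sum(state.Z != z0)
        assert flips > 0  # the move actually travels between presence modes


class TestSwapMove:
    def test_swap_corrects_a_mislabeled_state(self):
        """Starting from a state whose two clone columns are deliberately
        exchanged relative to the data-generating labels, the global swap
        move restores the correct labeling (higher likelihood) quickly."""
        rng = np.random.default_rng(20)
        C = np.zeros((12, 3))
        C[:6, 1] = 1.0  # clone 1 carries the first six mutations
        C[6:, 2] = 1.0  # clone 2 the rest; clone 0 is the base clone
        clones = CloneSet(C=C, F=np.full(3, 1 / 3))
        hyper = Hyperparams(zeta=3.0, r=0.19, p=1.0, Lambda=25.0)
        state, data = sc.sample_generative(clones, hyper, 40, rng)
        perm = [0, 2, 1]
        bad = sc.LatentState(
            Z=state.Z[:, perm], Pi=state.Pi[:, perm], G=state.G[:, perm],
            H=state.H[:, perm], Phi=state.Phi[:, perm], N=state.N.copy(),
        )
        from spotclone.inference import _site_loglik

        ws = _SweepWorkspace(bad, clones, data)
        before = _site_loglik(data.A, data.D, ws.R, ws.T, bad.N).sum()
        accepted = False
        for _ in range(30):
            accepted |= mh_swap_clones(bad, data, clones, hyper, rng, ws)
        after = _site_loglik(data.A, data.D, ws.R, ws.T, bad.N).sum()
        assert accepted and after > before
        np.testing.assert_allclose(bad.H.sum(axis=1), 1.0, atol=1e-12)
        # columns 1 and 2 are back where the data wants them
        np.testing.assert_array_equal(bad.Z[:, 1], state.Z[:, 1])


class TestAdaptation:
    def test_feedback_direction(self):
        # acceptance below target -> smaller steps; above -> larger
        assert adapt_proposal_sigma(1.0, 0.44, 0.24) == pytest.approx(0.8)
        assert adapt_proposal_sigma(1.0, 0.44, 0.64) == pytest.approx(1.2)
        assert adapt_proposal_sigma(2.0, 0.44, 0.44) == pytest.approx(2.0)

    def test_self_tuning_on_gaussian_target(self):
        """Random-walk MH on a standard normal with feedback tuning lands
        within 0.1 of the target acceptance rate after burn-in."""
        rng = np.random.default_rng(9)
        x, sigma = 0.0, 37.0  # absurd initial step
        target = 0.44
        acc_win, nwin = 0, 0
        for t in range(4000):
            prop = x + sigma * rng.standard_normal()
            if np.log(rng.random()) < -(prop**2 - x**2) / 2:
                x = prop
                acc_win += 1
            nwin += 1
            if (t + 1) % 100 == 0:
                sigma = adapt_proposal_sigma(sigma, target, acc_win / nwin)
                acc_win, nwin = 0, 0
        acc = 0
        for t in range(4000):
            prop = x + sigma * rng.standard_normal()
            if np.log(rng.random()) < -(prop**2 - x**2) / 2:
                x = prop
                acc += 1
        assert abs(acc / 4000 - target) < 0.1


class TestRunChain:
    def test_no_kept_samples_is_an_error(self):
        with pytest.raises(ValueError):
            ChainSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="post-burn-in"):
            s = ChainSettings(n_iter=101, burn_in=100, thin=5)
            clones = CloneSet(C=np.ones((1, 1)), F=np.array([1.0]))
            hyper = Hyperparams(zeta=1.0, r=1.0, p=1.0, Lambda=2.0)
            _, data = sc.sample_generative(
                clones, hyper, 2, np.random.default_rng(0)
            )
            run_chain(data, clones, hyper, s)

    def test_dimension_mismatch_rejected(self, tiny_clones, tiny_hyper):
        data = _empty_dataset(5, 3)
        with pytest.raises(ValueError, match="mutations"):
            run_chain(data, tiny_clones, tiny_hyper, ChainSettings(n_iter=10, burn_in=1, thin=1))

    def test_deterministic_given_seed(self, tiny_clones, tiny_hyper):
        _, data = sc.sample_generative(
            tiny_clones, tiny_hyper, 10, np.random.default_rng(11)
        )
        s = ChainSettings(n_iter=120, burn_in=40, thin=2, seed=5, tune_interval=20)
        r1 = run_chain(data, tiny_clones, tiny_hyper, s)
        r2 = run_chain(data, tiny_clones, tiny_hyper, s)
        np.testing.assert_array_equal(r1.H_mean, r2.H_mean)
        np.testing.assert_array_equal(r1.N_mean, r2.N_mean)
        assert r1.accept_rates == r2.accept_rates

    def test_posterior_rows_on_simplex_and_rates_in_unit_interval(
        self, tiny_clones, tiny_hyper
    ):
        _, data = sc.sample_generative(
            tiny_clones, tiny_hyper, 15, np.random.default_rng(12)
        )
        s = ChainSettings(n_iter=300, burn_in=100, thin=2, seed=1, tune_interval=50)
        res = run_chain(data, tiny_clones, tiny_hyper, s)
        np.testing.assert_allclose(res.H_mean.sum(axis=1), 1.0, atol=1e-12)
        for v in res.accept_rates.values():
            assert 0.0 < v < 1.0
        assert res.n_samples == 100


class TestSummarize:
    def test_constant_chain_and_hand_average(self, tiny_clones, tiny_hyper):
        rng = np.random.default_rng(13)
        states = [
            sc.sample_generative(tiny_clones, tiny_hyper, 2, rng)[0]
            for _ in range(3)
        ]
        summ = summarize_posterior(states)
        want_N = np.mean([s.N for s in states], axis=0)
        np.testing.assert_allclose(summ.N_mean, want_N)
        np.testing.assert_allclose(summ.H_mean.sum(axis=1), 1.0, atol=1e-12)
        const = summarize_posterior([states[0], states[0]])
        np.testing.assert_allclose(const.Phi_mean, states[0].Phi)
        with pytest.raises(ValueError):
            summarize_posterior([])
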