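import numpy as np
import pytest
from scipy import stats as sps

from admixsel import timeseries as ts
from admixsel.popdata import DatedSample, ValidationError
from admixsel.scan import NumericalError
from admixsel.wfsim import selection_update, simulate_time_series


def _no_data(T, K=1):
    return ts._SampleArrays(T=T, K=K, a_by_t={}, q_by_t={}, idx_by_t={}, n_total=0)


def _particles(counts, weights=None):
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    P = counts.shape[0]
    w = np.full(P, 1.0 / P) if weights is None else np.asarray(weights, float)
    return ts.ParticleSet(atoms=counts, weights=w)


class TestPostMating:
    @pytest.mark.parametrize(
        "f,s,expected", [(0.4, 0.0, 0.4), (0.0, 0.5, 0.0), (0.3, 0.1, 0.33 / 1.03)]
    )
    def test_examples(self, f, s, expected):
        assert ts.post_mating_frequency(f, s) == pytest.approx(expected, abs=1e-9)


class TestTransition:
    def test_absorbing_states(self):
        rng = np.random.default_rng(0)
        lost = _particles(np.zeros((5, 2), dtype=int))
        out = ts.transition_particles(lost, np.array([0.1, 0.2]), N=10, rng=rng)
        assert np.all(out.atoms == 0)
        fixed = _particles(np.full((5, 2), 20, dtype=int))
        out = ts.transition_particles(fixed, np.zeros(2), N=10, rng=rng)
        assert np.all(out.atoms == 20)

    def test_one_step_marginal_matches_exact_kernel(self):
        # K=1, 2N=20: compare the empirical transition row against the
        # binomial kernel by chi-square goodness of fit
        rng = np.random.default_rng(1)
        two_n, start, s = 20, 10, 0.1
        reps = 100_000
        src = _particles(np.full(reps, start, dtype=int))
        out = ts.transition_particles(src, np.array([s]), N=10, rng=rng)
        counts = np.bincount(out.atoms[:, 0], minlength=two_n + 1)
        p_exact = sps.binom.pmf(np.arange(two_n + 1), two_n, selection_update(start / two_n, s))
        keep = p_exact * reps >= 5
        f_exp = p_exact[keep] / p_exact[keep].sum() * counts[keep].sum()
        chi2 = sps.chisquare(counts[keep], f_exp)
        assert chi2.pvalue > 1e-3

    def test_weights_untouched(self):
        w = np.array([0.7, 0.2, 0.1])
        p = _particles(np.array([1, 5, 9]), w)
        out = ts.transition_particles(p, np.array([0.0]), N=5, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.weights, w)


class TestWeights:
    def test_no_samples_leaves_weights(self):
        p = _particles(np.array([0, 10, 20]))
        out, c = ts.update_weights(p, np.array([]), np.empty((0, 1)), N=10)
        np.testing.assert_array_equal(out.weights, p.weights)
        assert c == 0.0

    def test_impossible_datum_zeroes_atoms(self):
        # derived allele observed from ancestry 1, but one atom has f=0 there
        p = _particles(np.array([[0, 10], [10, 10]]))
        out, _ = ts.update_weights(
            p, np.array([1]), np.array([[1.0, 0.0]]), N=10
        )
        assert out.weights[0] == 0.0 and out.weights[1] == 1.0

    def test_all_impossible_raises_with_time(self):
        p = _particles(np.array([[0], [0]]))
        with pytest.raises(NumericalError, match="time 7"):
            ts.update_weights(p, np.array([1]), np.array([[1.0]]), N=10, time_label=7)

    def test_marginalized_emission_mixture(self):
        # loadings (0.5, 0.5), atom frequencies (0.8, 0.2), derived allele:
        # emission = 0.5*0.8 + 0.5*0.2 = 0.5 for atom 1 vs 0.5*0.4+0.5*0.6 for atom 2
        p = _particles(np.array([[16, 4], [8, 12]]))
        out, _ = ts.update_weights(p, np.array([1]), np.array([[0.5, 0.5]]), N=10)
        np.testing.assert_allclose(out.weights, [0.5, 0.5])

    def test_conditional_emission_uses_z(self):
        p = _particles(np.array([[16, 4], [8, 12]]))
        out, _ = ts.update_weights(
            p, np.array([1]), np.array([[0.5, 0.5]]), N=10, z=np.array([0])
        )
        np.testing.assert_allclose(out.weights, [0.8 / 1.2, 0.4 / 1.2])


class TestResampling:
    def test_equal_weights_never_resample(self):
        p = _particles(np.arange(10))
        out, parents = ts.resample_if_needed(p, 0.5, np.random.default_rng(0))
        np.testing.assert_array_equal(parents, np.arange(10))
        np.testing.assert_array_equal(out.atoms, p.atoms)

    def test_degenerate_weight_copies_winner(self):
        w = np.zeros(8)
        w[3] = 1.0
        p = _particles(np.arange(8), w)
        out, parents = ts.resample_if_needed(p, 0.5, np.random.default_rng(0))
        assert np.all(out.atoms == 3)
        assert np.all(parents == 3)
        np.testing.assert_allclose(out.weights, 1 / 8)

    def test_systematic_resampling_unbiased(self):
        rng = np.random.default_rng(3)
        atoms = np.arange(10)
        w = rng.dirichlet(np.ones(10))
        p = _particles(atoms, w)
        target = float(np.sum(atoms * w))
        means = [
            float(np.mean(ts.resample_if_needed(p, 1.0, rng)[0].atoms))
            for _ in range(5000)
        ]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - target) < 4 * se


class TestFilterAndTrajectories:
    def test_prior_chain_recovered_without_data(self):
        # no observations, s=0: drawn trajectories must follow the neutral
        # WF chain; compare the t=0 marginal to its exact distribution
        T, N, P = 4, 10, 40_000
        rng = np.random.default_rng(5)
        hist = ts.run_filter(_no_data(T), np.zeros((T, 1)), N, P, rng)
        two_n = 2 * N
        pi = np.full(two_n + 1, 1 / (two_n + 1))
        A = sps.binom.pmf(
            np.arange(two_n + 1)[None, :], two_n, (np.arange(two_n + 1) / two_n)[:, None]
        )
        for _ in range(T):
            pi = pi @ A
        pf = np.bincount(hist.atoms[0][:, 0], weights=hist.weights[0], minlength=two_n + 1)
        assert 0.5 * np.abs(pf - pi).sum() < 0.02

    def test_trajectories_on_grid_and_in_range(self):
        rng = np.random.default_rng(6)
        hist = ts.run_filter(_no_data(5), np.zeros((5, 1)), 10, 500, rng)
        for _ in range(20):
            f = ts.sample_trajectory(hist, rng)
            assert f.shape == (6, 1)
            assert np.all((f >= 0) & (f <= 1))
            np.testing.assert_array_equal(f * 20, np.rint(f * 20))

    def test_filtered_marginals_match_exact_hmm(self):
        # small-scale version of the module's primary oracle
        samples, _ = simulate_time_series(Ne=10, s=0.05, T=3, samples_per_gen=4, f0=0.5, seed=8)
        data = ts._bin_samples(samples)
        s = np.full((3, 1), 0.05)
        hist = ts.run_filter(data, s, 10, 30_000, np.random.default_rng(9))
        two_n = 20
        states = np.arange(two_n + 1) / two_n
        pi = np.full(two_n + 1, 1 / (two_n + 1))

        def emis(t):
            a = data.a_by_t.get(t)
            if a is None:
                return np.ones(two_n + 1)
            c1 = int((a == 1).sum())
            c0 = int((a == 0).sum())
            return states**c1 * (1 - states) ** c0

        pi = pi * emis(3)
        pi /= pi.sum()
        for t in range(2, -1, -1):
            A = sps.binom.pmf(
                np.arange(two_n + 1)[None, :], two_n,
                selection_update(states, 0.05)[:, None],
            )
            pi = pi @ A
            pi = pi * emis(t)
            pi /= pi.sum()
            if t == 0:
                pf = np.bincount(
                    hist.atoms[0][:, 0], weights=hist.weights[0], minlength=two_n + 1
                )
                assert 0.5 * np.abs(pf - pi).sum() < 0.03


class TestLatent:
    def test_forced_by_frequency(self):
        data = ts._SampleArrays(
            T=1, K=2,
            a_by_t={0: np.array([1])},
            q_by_t={0: np.array([[0.5, 0.5]])},
            idx_by_t={0: np.array([0])},
            n_total=1,
        )
        f = np.array([[1.0, 0.0], [0.5, 0.5]])
        z = ts.sample_latent(data, f, np.random.default_rng(0))
        assert z[0] == 0

    def test_forced_by_loadings(self):
        data = ts._SampleArrays(
            T=1, K=2,
            a_by_t={0: np.array([0])},
            q_by_t={0: np.array([[1.0, 0.0]])},
            idx_by_t={0: np.array([0])},
            n_total=1,
        )
        f = np.array([[0.3, 0.9], [0.5, 0.5]])
        for seed in range(5):
            assert ts.sample_latent(data, f, np.random.default_rng(seed))[0] == 0

    def test_posterior_proportion(self):
        n = 100_000
        data = ts._SampleArrays(
            T=1, K=2,
            a_by_t={0: np.ones(n, dtype=int)},
            q_by_t={0: np.tile([0.5, 0.5], (n, 1))},
            idx_by_t={0: np.arange(n)},
            n_total=n,
        )
        f = np.array([[0.8, 0.2], [0.5, 0.5]])
        z = ts.sample_latent(data, f, np.random.default_rng(1))
        # P(z=ancestry 1) = 0.4/0.5 = 0.8
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(np.mean(z == 0) - 0.8) < 3 * se


class TestSelectionSampling:
    def _random_walk_f(self, T, seed=0):
        rng = np.random.default_rng(seed)
        f = 0.5 + np.cumsum(rng.normal(0, 0.01, size=T + 1))
        return np.clip(f, 0.05, 0.95)[:, None]

    def test_large_alpha_forces_constant_surface(self):
        f = self._random_walk_f(30)
        rng = np.random.default_rng(2)
        s = np.zeros((30, 1))
        for _ in range(300):
            surf, _ = ts.sample_selection(s, f, 500, alpha=1e8, beta=1.0, mala_step=0.01, rng=rng)
            s = surf.s
        assert np.ptp(s) < 1e-3

    def test_large_beta_ties_ancestries(self):
        T = 20
        f = np.concatenate([self._random_walk_f(T, 3), self._random_walk_f(T, 4)], axis=1)
        rng = np.random.default_rng(5)
        s = np.zeros((T, 2))
        for _ in range(300):
            surf, _ = ts.sample_selection(s, f, 500, alpha=1.0, beta=1e8, mala_step=0.01, rng=rng)
            s = surf.s
        assert np.max(np.abs(s[:, 0] - s[:, 1])) < 1e-3

    def test_neutral_frequency_implies_zero_selection(self):
        # constant f = 0.5 with a huge population: the likelihood pins s at 0
        T = 25
        f = np.full((T + 1, 1), 0.5)
        rng = np.random.default_rng(6)
        s = np.zeros((T, 1))
        draws = []
        step = 0.01
        for it in range(800):
            surf, acc = ts.sample_selection(s, f, 500_000, alpha=2.0, beta=0.02, mala_step=step, rng=rng)
            s = surf.s
            if it < 200:
                step = float(np.clip(step * np.exp(0.05 * (acc - 0.57)), 1e-5, 1))
            else:
                draws.append(s.mean())
        assert abs(np.mean(draws)) < 0.01

    def test_boundary_frequencies_skipped(self):
        f = np.array([[0.0], [0.0], [1.0]])
        rng = np.random.default_rng(7)
        surf, _ = ts.sample_selection(np.zeros((2, 1)), f, 100, 2.0, 0.02, 0.05, rng)
        assert np.all(np.isfinite(surf.s))


class TestHyperparams:
    def test_constant_surface_reduces_to_prior_shift(self):
        hyper = ts.SmoothingHyperparams(a_alpha=2.0, b_alpha=3.0)
        s = np.full((10, 2), 0.03)
        rng = np.random.default_rng(0)
        draws = np.array([ts.sample_hyperparams(s, hyper, rng)[0] for _ in range(20_000)])
        # alpha ~ Gamma(2 + 10, 3) exactly (zero penalty)
        expected_mean = (hyper.a_alpha + 10 * 2 / 2) / hyper.b_alpha
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - expected_mean) < 4 * se

    def test_single_ancestry_beta_is_prior(self):
        hyper = ts.SmoothingHyperparams(a_beta=1.5, b_beta=2.5)
        s = np.random.default_rng(1).normal(0, 0.1, size=(12, 1))
        rng = np.random.default_rng(2)
        draws = np.array([ts.sample_hyperparams(s, hyper, rng)[1] for _ in range(20_000)])
        ks = sps.kstest(draws, sps.gamma(a=1.5, scale=1 / 2.5).cdf)
        assert ks.pvalue > 0.01

    def test_moment_matches_penalty(self):
        hyper = ts.SmoothingHyperparams()
        rng0 = np.random.default_rng(3)
        s = rng0.normal(0, 0.05, size=(8, 2))
        S = float(np.sum(np.diff(s, axis=0) ** 2))
        rng = np.random.default_rng(4)
        draws = np.array([ts.sample_hyperparams(s, hyper, rng)[0] for _ in range(20_000)])
        expected = (hyper.a_alpha + 8 * 2 / 2) / (hyper.b_alpha + S / 2)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 4 * se


class TestGibbs:
    def test_determinism_bit_identical(self):
        samples, _ = simulate_time_series(Ne=200, s=0.02, T=10, samples_per_gen=5, seed=3)
        cfg = ts.GibbsConfig(N=200, particles=100, iterations=15, burn_in=5,
                             thin=1, seed=42)
        a, _ = ts.run_gibbs(samples, cfg)
        b, _ = ts.run_gibbs(samples, cfg)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.f, b.f)

    def test_bayes_mode_updates_hyperparams(self):
        samples, _ = simulate_time_series(Ne=200, s=0.0, T=10, samples_per_gen=5, seed=4)
        cfg = ts.GibbsConfig(N=200, particles=100, iterations=20, burn_in=5,
                             thin=1, mode="bayes", seed=1)
        draws, summary = ts.run_gibbs(samples, cfg)
        assert draws.alpha.std() > 0  # hyperparameters actually move
        assert {"t", "k", "s_median", "f_median"} <= set(summary.columns)

    def test_validation(self):
        samples, _ = simulate_time_series(Ne=200, s=0.0, T=5, samples_per_gen=2, seed=5)
        with pytest.raises(ValidationError):
            ts.GibbsConfig(iterations=10, burn_in=10)
        one_time = [DatedSample(time=0, allele=0, loadings=np.array([1.0]))] * 3
        with pytest.raises(ValidationError, match="distinct times"):
            ts.run_gibbs(one_time, ts.GibbsConfig(N=100, particles=50, iterations=5, burn_in=1))
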