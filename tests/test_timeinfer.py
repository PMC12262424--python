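"""TMRCA decoding, Wright-Fisher likelihood, chi-squared arithmetic and
divergence-based rate estimation."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from introscan import timeinfer as ti


class TestTMRCAPosterior:
    def test_two_bin_bayes_arithmetic(self):
        """Zero differences over 20 kbp at mu=1e-8 strongly favour the young
        bin: posterior = e^-0.4 / (e^-0.4 + e^-4)."""
        grid = ti.pairwise_tmrca_posterior(
            [0], 20_000, 1e-8, np.array([1000.0, 10_000.0])
        )
        expect = math.exp(-0.4) / (math.exp(-0.4) + math.exp(-4.0))
        assert grid.posterior[0, 0] == pytest.approx(expect, abs=1e-4)

    def test_point_prior_pins_posterior(self):
        bins = np.array([500.0, 5000.0, 50_000.0])
        grid = ti.pairwise_tmrca_posterior(
            [3, 10, 2], 10_000, 1e-8, bins, prior=np.array([0.0, 1.0, 0.0])
        )
        np.testing.assert_allclose(grid.posterior[:, 1], 1.0)

    def test_posteriors_normalise(self):
        rng = np.random.default_rng(1)
        grid = ti.pairwise_tmrca_posterior(
            rng.poisson(5, size=200), 20_000, 1e-8, np.geomspace(100, 1e5, 16)
        )
        np.testing.assert_allclose(grid.posterior.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_win, n_bin = int(rng.integers(2, 10)), int(rng.integers(2, 5))
        bins = np.sort(rng.uniform(100, 50_000, size=n_bin))
        counts = rng.poisson(3, size=n_win)
        prior = rng.dirichlet(np.ones(n_bin))
        rho = 0.2
        L, mu = 10_000, 1e-8
        grid = ti.pairwise_tmrca_posterior(counts, L, mu, bins, prior, switch_prob=rho)
        A = (1 - rho) * np.eye(n_bin) + rho * np.tile(prior, (n_bin, 1))
        post = np.zeros((n_win, n_bin))
        total = 0.0
        for path in itertools.product(range(n_bin), repeat=n_win):
            pr = prior[path[0]] * stats.poisson.pmf(counts[0], 2 * mu * L * bins[path[0]])
            for t in range(1, n_win):
                pr *= A[path[t - 1], path[t]] * stats.poisson.pmf(
                    counts[t], 2 * mu * L * bins[path[t]]
                )
            total += pr
            for t in range(n_win):
                post[t, path[t]] += pr
        np.testing.assert_allclose(grid.posterior, post / total, atol=1e-10)

    def test_recovers_known_window_tmrca(self):
        """Posterior-mean TMRCA tracks the true per-window pair coalescence
        times from an independent coalescent simulation."""
        import msprime

        mu, L = 1.25e-8, 20_000
        ts = msprime.sim_ancestry(
            samples=1, population_size=10_000, sequence_length=2_000_000,
            recombination_rate=1e-8, random_seed=5,
        )
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=6)
        n_win = 100
        true_t = np.zeros(n_win)
        for w in range(n_win):
            a, b = w * L, (w + 1) * L
            acc = tot = 0.0
            for tree in ts.trees():
                ov = min(tree.interval[1], b) - max(tree.interval[0], a)
                if ov > 0:
                    acc += ov * tree.tmrca(0, 1)
                    tot += ov
            true_t[w] = acc / tot
        diffs = np.zeros(n_win, dtype=int)
        for var in mts.variants():
            w = int(var.site.position // L)
            if w < n_win and var.genotypes[0] != var.genotypes[1]:
                diffs[w] += 1
        grid = ti.pairwise_tmrca_posterior(
            diffs, L, mu, np.geomspace(50, 200_000, 24)
        )
        err = np.abs(np.log10(grid.posterior_mean()) - np.log10(true_t))
        assert err.mean() <= 0.35

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ti.pairwise_tmrca_posterior([1], 100, 1e-8, np.array([100.0]))
        with pytest.raises(ValueError):
            ti.pairwise_tmrca_posterior(
                [1], 100, 1e-8, np.array([100.0, 10.0])
            )
        with pytest.raises(ValueError):
            ti.pairwise_tmrca_posterior(
                [1], 100, 1e-8, np.array([10.0, 100.0]), prior=np.zeros(2)
            )


class TestSweepScore:
    @staticmethod
    def uniform_grid(n_bins=10):
        bins = np.linspace(100, 1000, n_bins)
        post = np.full((4, n_bins), 1 / n_bins)
        return ti.TMRCAGrid(
            window_starts=np.arange(4) * 100, window_ends=(np.arange(4) + 1) * 100,
            time_bins=bins, posterior=post, mu=1e-8, L=100,
            prior=np.full(n_bins, 1 / n_bins),
        )

    def test_all_recent_mass_scores_one(self):
        grid = self.uniform_grid()
        grid.posterior = np.zeros_like(grid.posterior)
        grid.posterior[:, 0] = 1.0
        per, agg = ti.sweep_score(grid, recent_threshold=150)
        assert agg == 1.0

    def test_uniform_posterior_proportional_mass(self):
        grid = self.uniform_grid(10)
        # bins are 100,200,...,1000; threshold 400 covers three bins
        per, agg = ti.sweep_score(grid, recent_threshold=400)
        assert agg == pytest.approx(0.3)

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            ti.sweep_score(self.uniform_grid(), recent_threshold=5)


class TestWFLoglik:
    def test_single_observation_matches_quadrature(self):
        """With s=0 and one observation under the uniform initial prior, the
        likelihood is the integral of the binomial over p."""
        obs = ti.TrajectoryObservations(times=[5.0], counts=[3], sizes=[10])
        ll = ti.wf_loglik(obs, 0.0, 10_000, grid_size=5001)
        ref, _ = integrate.quad(lambda p: stats.binom.pmf(3, 10, p), 0, 1)
        assert ll == pytest.approx(math.log(ref), abs=1e-6)

    def test_wrong_sign_selection_penalised(self):
        obs = ti.TrajectoryObservations(
            times=[300.0, 200.0, 100.0, 0.0],
            counts=[45, 30, 15, 5],
            sizes=[50, 50, 50, 50],
        )
        assert ti.wf_loglik(obs, 0.5, 10_000) < ti.wf_loglik(obs, 0.0, 10_000)

    def test_coarse_grid_refused(self):
        obs = ti.TrajectoryObservations(times=[0.0], counts=[1], sizes=[10])
        with pytest.raises(ValueError):
            ti.wf_loglik(obs, 0.0, 10_000, grid_size=50)

    def test_observation_validation(self):
        with pytest.raises(ValueError):
            ti.TrajectoryObservations(times=[0.0, 100.0], counts=[1, 1], sizes=[10, 10])
        with pytest.raises(ValueError):
            ti.TrajectoryObservations(times=[10.0], counts=[11], sizes=[10])


class TestFitSelection:
    def test_logistic_trajectory_recovers_s(self):
        """Dense observations of a deterministic logistic rise at s=0.01."""
        s, p = 0.01, 0.05
        times = np.arange(600, -1, -50, dtype=float)
        traj = {}
        pp = p
        for g in range(600, -1, -1):
            traj[g] = pp
            pp = pp + s * pp * (1 - pp) / (1 + s * pp)
        counts = [int(round(traj[t] * 200)) for t in times]
        obs = ti.TrajectoryObservations(times=times, counts=counts,
                                        sizes=[200] * len(times))
        fit = ti.fit_selection(obs, "single_epoch", N=100_000)
        assert 0.005 <= fit.params["s"] <= 0.02
        assert fit.p_value < 0.05

    def test_two_epoch_nests_single_epoch(self):
        rng = np.random.default_rng(9)
        times = [400.0, 200.0, 100.0, 0.0]
        counts = [2, 5, 30, 45]
        obs = ti.TrajectoryObservations(times=times, counts=counts, sizes=[60] * 4)
        single = ti.fit_selection(obs, "single_epoch", N=10_000)
        double = ti.fit_selection(obs, "two_epoch", N=10_000)
        assert double.loglik_alt >= single.loglik_alt - 1e-6
        assert double.df == 3 and single.df == 1

    def test_alternative_dominates_null(self):
        obs = ti.TrajectoryObservations(times=[100.0, 0.0], counts=[5, 6],
                                        sizes=[20, 20])
        fit = ti.fit_selection(obs, "single_epoch", N=10_000)
        assert fit.loglik_alt >= fit.loglik_null
        assert fit.statistic >= 0


def gammq_reference(a, x, max_iter=600):
    """Regularised upper incomplete gamma via series / continued fraction
    (independent of scipy)."""
    if x < a + 1:
        # lower series, then complement
        term = 1.0 / a
        total = term
        for n in range(1, max_iter):
            term *= x / (a + n)
            total += term
            if abs(term) < abs(total) * 1e-16:
                break
        gln = math.lgamma(a)
        return 1.0 - total * math.exp(-x + a * math.log(x) - gln)
    # Lentz continued fraction for the upper tail
    gln = math.lgamma(a)
    b = x + 1.0 - a
    c = 1e308
    d = 1.0 / b
    h = d
    for i in range(1, max_iter):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < 1e-300:
            d = 1e-300
        c = b + an / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return math.exp(-x + a * math.log(x) - gln) * h


class TestChi2SF:
    @pytest.mark.parametrize(
        "stat,df,expected,tol",
        [
            (6.8468, 1, 0.0088, 2e-4),
            (5.16, 1, 0.023, 2e-4),
            (10.84, 3, 0.0126, 2e-4),
            (18.47, 3, 0.0003, 1e-4),
            (0.0, 1, 1.0, 0),
        ],
    )
    def test_worked_examples(self, stat, df, expected, tol):
        assert ti.chi2_sf(stat, df) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_matches_series_reference(self):
        for df in range(1, 11):
            for stat in np.linspace(0.01, 50, 40):
                ref = gammq_reference(df / 2, stat / 2)
                assert ti.chi2_sf(stat, df) == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ti.chi2_sf(-1.0, 1)
        with pytest.raises(ValueError):
            ti.chi2_sf(1.0, 0)


class TestHORMutationRate:
    def test_closed_form(self):
        est = ti.hor_mutation_rate(
            np.array([0.004]), (500_000, 500_000), (10_000, 10_000), g=25, n_grid=1
        )
        assert est.mean == pytest.approx(5.0e-8)

    def test_zero_divergence_zero_rate(self):
        est = ti.hor_mutation_rate(np.zeros(5), (400_000, 700_000), (5000, 20_000))
        assert est.mean == 0.0

    def test_homogeneity(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(0.001, 0.01, size=20)
        a = ti.hor_mutation_rate(d, (400_000, 700_000), (5000, 20_000))
        b = ti.hor_mutation_rate(2 * d, (400_000, 700_000), (5000, 20_000))
        np.testing.assert_allclose(b.estimates, 2 * a.estimates, rtol=1e-12)

    def test_saturated_windows_flagged(self):
        est = ti.hor_mutation_rate(
            np.array([0.01, 0.8]), (400_000, 700_000), (5000, 20_000)
        )
        assert est.saturated.tolist() == [False, True]
        assert np.isnan(est.estimates[1]).all()

    def test_per_allele_scaling(self):
        est = ti.hor_mutation_rate(
            np.array([0.004]), (500_000, 500_000), (10_000, 10_000), g=25, n_grid=1
        )
        assert est.per_allele(2000) == pytest.approx(1e-4)


class TestPhred:
    def test_qv_to_error_worked_example(self):
        assert ti.phred_convert(44.5, "to_error") == pytest.approx(3.5e-5, rel=0.02)

    def test_error_to_qv_worked_example(self):
        assert ti.phred_convert(3.29e-5, "to_qv") == pytest.approx(44.8, abs=0.05)

    def test_qv_ten(self):
        assert ti.phred_convert(10, "to_error") == pytest.approx(0.1)

    def test_round_trip(self):
        assert ti.phred_convert(
            ti.phred_convert(33.3, "to_error"), "to_qv"
        ) == pytest.approx(33.3)

    def test_zero_error_infinite_qv(self):
        with pytest.warns(UserWarning):
            assert ti.phred_convert(0.0, "to_qv") == np.inf


class TestPairwiseDivergence:
    def test_identical_sequences(self):
        seq = "ACGT" * 500
        out = ti.pairwise_divergence(seq, seq, window=1000)
        assert (out["divergence"] == 0).all()

    def test_known_mismatch_count_with_jc(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(list("ACGT"), size=20_000))
        b = list(a)
        idx = rng.choice(20_000, size=20, replace=False)
        for i in idx:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        raw = ti.pairwise_divergence(a, b, window=20_000)
        assert raw["divergence"].iloc[0] == pytest.approx(0.001)
        jc = ti.pairwise_divergence(a, b, window=20_000, jc_correct=True)
        assert jc["divergence"].iloc[0] == pytest.approx(0.0010007, abs=1e-6)

    def test_gap_columns_excluded(self):
        a = "AAAA----AAAA"
        b = "AAAATTTTAAAC"
        out = ti.pairwise_divergence(a, b, window=12)
        assert out["divergence"].iloc[0] == pytest.approx(1 / 8)

    def test_saturation_flagged(self):
        a = "A" * 1000
        b = "C" * 1000
        out = ti.pairwise_divergence(a, b, window=1000, jc_correct=True)
        assert out["flag"].iloc[0] == "saturated"

    def test_sparse_alignment_flagged_missing(self):
        a = "A" * 10 + "-" * 90
        b = "A" * 100
        out = ti.pairwise_divergence(a, b, window=100)
        assert out["flag"].iloc[0] == "missing"
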