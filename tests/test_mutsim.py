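"""Mutation placement and read simulation."""

import numpy as np
import pytest
from scipy import stats

import vaftree as vt


class TestAssignMutations:
    def test_zero_rate_means_no_mutations(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 20), rng)
        asn = vt.assign_mutations(tree, 0.0, 500, rng)
        assert np.all(asn == -1)

    def test_mutated_fraction_matches_first_order_rate(self, rng):
        """Fraction of mutated sites ~ 1 - exp(-mu L) for small mu L."""
        tree = vt.sample_tree(vt.BDParams(0.0, 2), rng)
        L = tree.total_length
        mu = 0.01 / L
        n_sites = 200000
        asn = vt.assign_mutations(tree, mu, n_sites, rng)
        frac = np.mean(asn >= 0)
        expect = 1.0 - np.exp(-mu * L)
        se = np.sqrt(expect * (1 - expect) / n_sites)
        assert abs(frac - expect) < 4 * se + 1e-4

    def test_per_branch_counts_proportional_to_length(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 64), rng)
        mu = 0.05 / tree.total_length
        n_sites = 300000
        asn = vt.assign_mutations(tree, mu, n_sites, rng)
        hit = asn[asn >= 0]
        counts = np.bincount(hit, minlength=tree.branch_lengths.size)
        expected = tree.branch_lengths / tree.total_length * hit.size
        keep = expected >= 5
        chi = stats.chisquare(counts[keep], expected[keep] * counts[keep].sum() / expected[keep].sum())
        assert chi.pvalue > 0.01

    def test_single_hit_approximation_enforced(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 20), rng)
        with pytest.raises(ValueError, match="single-hit"):
            vt.assign_mutations(tree, 0.2 / tree.total_length, 10, rng)
        with pytest.warns(UserWarning, match="strained"):
            vt.assign_mutations(tree, 0.05 / tree.total_length, 10, rng)


class TestSimulateReads:
    def test_error_free_unmutated_sites_are_clean(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 50), rng)
        asn = np.full(300, -1)
        tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", 40), 0.0, rng)
        assert np.all(tab.mutant_totals == 0)
        assert np.all(tab.r == 40)

    def test_leaf_branch_hypergeometric_mean(self, rng):
        """A leaf-branch mutation (f = 1/n) yields on average r/n mutant reads."""
        n = 1000
        tree = vt.sample_tree(vt.BDParams(0.5, n), rng)
        leaf_idx = int(np.nonzero(tree.branch_leaf_counts == 1)[0][0])
        asn = np.full(20000, leaf_idx)
        r = 500
        tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", r), 0.0, rng)
        assert set(np.unique(tab.mutant_totals)) <= {0, 1}
        mean = tab.mutant_totals.mean()
        se = np.sqrt(r / n / 20000)  # ~Bernoulli(r/n)
        assert abs(mean - r / n) < 4 * se

    def test_depth_cannot_exceed_allele_pool(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 20), rng)
        with pytest.raises(ValueError, match="allele pool"):
            vt.simulate_reads(np.full(5, -1), tree, vt.DepthModel("fixed", 100), 0.0, rng)
        # ploidy 2 doubles the pool
        tab = vt.simulate_reads(
            np.full(5, -1), tree, vt.DepthModel("fixed", 40), 0.0, rng, ploidy=2
        )
        assert tab.n_sites == 5

    def test_read_conservation_with_errors(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.5, 100), rng)
        asn = vt.assign_mutations(tree, 1e-3 / tree.total_length, 2000, rng)
        tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", 80), 0.05, rng)
        assert np.all(tab.m_types.sum(axis=1) <= tab.r)
        assert np.all(tab.m_types >= 0)
        # errors hit every type: with eps = 0.05 and 2000*80 reads all three
        # mutant columns must be populated
        assert np.all(tab.m_types.sum(axis=0) > 0)

    def test_hypergeometric_approaches_binomial_for_large_n(self, rng):
        """With eps=0, ploidy=1 and n >> r the mutant counts at a fixed
        branch follow Binom(r, f) — the likelihood's model assumption."""
        n = 5000
        tree = vt.sample_tree(vt.BDParams(0.0, n), rng)
        counts = tree.branch_leaf_counts
        k = int(np.argmin(np.abs(counts - n // 10)))  # branch with f ~ 0.1
        f = counts[k] / n
        asn = np.full(12000, k)
        r = 50
        tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", r), 0.0, rng)
        m = tab.mutant_totals
        edges = np.arange(r + 2)
        obs = np.histogram(m, bins=edges)[0]
        exp = stats.binom.pmf(np.arange(r + 1), r, f) * m.size
        keep = exp >= 5
        chi = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert chi.pvalue > 0.005

    def test_depth_models(self, rng):
        dm = vt.DepthModel("poisson", 30)
        r = dm.sample(5000, rng)
        assert r.min() >= 1
        assert abs(r.mean() - 30) < 1
        hist = {10: 50, 20: 50}
        dm = vt.DepthModel("empirical", histogram=hist)
        assert dm.mean_depth == 15
        r = dm.sample(2000, rng)
        assert set(np.unique(r)) <= {10, 20}
        with pytest.raises(ValueError):
            vt.DepthModel("gamma")


class TestExpectedObservedMutations:
    def test_zero_mu(self, rng):
        ens = vt.sample_ensemble(vt.BDParams(0.5, 10), 3, rng)
        assert vt.expected_observed_mutations(0.0, ens, 100) == 0.0

    def test_hand_worked_two_leaf_tree(self):
        """n=2 tree, both branches length t, depth 2: mu*2t*(1-1/4)."""
        t = 0.7
        tree = vt.LineageTree([t])
        ens = vt.TreeEnsemble(delta=0.0, trees=[tree])
        mu = 0.013
        got = vt.expected_observed_mutations(mu, ens, 2)
        assert np.isclose(got, 1.5 * mu * t)

    def test_deep_coverage_limit_is_total_length(self, rng):
        ens = vt.sample_ensemble(vt.BDParams(0.5, 40), 5, rng)
        mu = 1e-4
        got = vt.expected_observed_mutations(mu, ens, 1e7)
        meanL = np.mean([t.total_length for t in ens])
        assert np.isclose(got, mu * meanL, rtol=1e-3)


class TestChooseMu:
    def test_round_trip_and_linearity(self, rng):
        ens = vt.sample_ensemble(vt.BDParams(0.5, 50), 5, rng)
        mu0 = 1e-4
        target = vt.expected_observed_mutations(mu0, ens, 100)
        back = vt.choose_mu_for_target(target, ens, 100)
        assert np.isclose(back.mu, mu0)
        double = vt.choose_mu_for_target(2 * target, ens, 100)
        assert np.isclose(double.mu, 2 * mu0)
        per_genome = vt.choose_mu_for_target(target * 1000, ens, 100, n_sites=1000)
        assert np.isclose(per_genome.mu, mu0)

    def test_simulated_counts_hit_target(self, rng):
        """Observed mutated-site counts land within +-3 sqrt(target)."""
        params = vt.BDParams(0.5, 400)
        ref = vt.sample_ensemble(params, 20, rng)
        target, n_sites, depth = 400, 50000, 100
        mu = vt.choose_mu_for_target(target, ref, depth, n_sites=n_sites)
        counts = []
        for _ in range(10):
            tree = vt.sample_tree(params, rng)
            asn = vt.assign_mutations(tree, mu, n_sites, rng)
            tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", depth), 0.0, rng)
            counts.append(int((tab.mutant_totals > 0).sum()))
        assert abs(np.mean(counts) - target) < 3 * np.sqrt(target)


class TestVafSpectrum:
    def test_trivial_cases(self):
        tab = vt.ReadCountTable(r=np.array([10, 10]), m=np.array([0, 0]))
        counts, _ = vt.vaf_spectrum(tab, np.linspace(0.01, 1, 11))
        assert counts.sum() == 0
        tab = vt.ReadCountTable(r=np.array([2]), m=np.array([1]))
        counts, edges = vt.vaf_spectrum(tab, np.linspace(0.0, 1, 11))
        assert counts.sum() == 1
        assert counts[np.searchsorted(edges, 0.5, side="right") - 1] == 1

    def test_bad_bins_rejected(self):
        tab = vt.ReadCountTable(r=np.array([2]), m=np.array([1]))
        with pytest.raises(ValueError):
            vt.vaf_spectrum(tab, np.array([0.5, 0.5]))

    def test_tenfold_mu_scales_spectrum(self, rng):
        """Raising mu rescales the VAF spectrum without changing its shape."""
        tree = vt.sample_tree(vt.BDParams(0.9, 500), rng)
        mu = 5e-4 / tree.total_length
        n_sites = 200000
        tabs = []
        for m in (mu, 10 * mu):
            asn = vt.assign_mutations(tree, m, n_sites, rng)
            tabs.append(
                vt.simulate_reads(asn, tree, vt.DepthModel("fixed", 200), 0.0, rng)
            )
        bins = np.array([0.0, 0.01, 0.05, 0.2, 1.0])
        c1, _ = vt.vaf_spectrum(tabs[0], bins)
        c10, _ = vt.vaf_spectrum(tabs[1], bins)
        ratio = c10.sum() / c1.sum()
        assert 8 < ratio < 12
        for a, b in zip(c1, c10):
            assert abs(b - 10 * a) < 5 * np.sqrt(10 * a + b + 1)
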