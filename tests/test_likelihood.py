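"""Per-site probabilities and tree/ensemble log-likelihoods."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import vaftree as vt
from vaftree.likelihood import SiteClassTable


def direct_site_prob(m, r, mu, summary, eps):
    """Straight-line re-implementation with scipy pmfs (test oracle)."""
    total = 0.0
    L = sum(l for l, _ in summary)
    for l, f in summary:
        p = f * (1 - eps) + (1 - f) * eps
        total += mu * l * stats.binom.pmf(m, r, p)
    total += (1 - mu * L) * stats.binom.pmf(m, r, eps)
    return total


class TestSiteProb2State:
    def test_no_mutation_limit(self):
        s = [(1.0, 0.5), (1.0, 0.5)]
        assert vt.site_prob_2state(0, 5, 0.0, s, 0.0) == pytest.approx(1.0)
        assert vt.site_prob_2state(2, 5, 0.0, s, 0.0) == pytest.approx(0.0)

    def test_hand_worked_two_leaf_tree(self):
        """n=2 tree with unit branches: p(1 of 2) = 2 * mu * Binom(1,2,1/2)."""
        s = [(1.0, 0.5), (1.0, 0.5)]
        assert vt.site_prob_2state(1, 2, 0.1, s, 0.0) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        r=st.integers(1, 20),
        eps=st.floats(0.0, 0.05),
        seed=st.integers(0, 10**6),
    )
    def test_normalization(self, r, eps, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        l = rng.random(k) + 0.01
        f = rng.random(k) * 0.98 + 0.01
        mu = rng.random() * 0.5 / l.sum()
        s = np.column_stack([l, f])
        total = sum(vt.site_prob_2state(m, r, mu, s, eps) for m in range(r + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_oracle(self, rng):
        for _ in range(20):
            k = rng.integers(1, 8)
            l = rng.random(k)
            f = rng.random(k) * 0.98 + 0.01
            mu = rng.random() * 0.3 / l.sum()
            eps = rng.choice([0.0, 1e-4, 0.01])
            r = int(rng.integers(1, 60))
            m = int(rng.integers(0, r + 1))
            s = list(zip(l, f))
            assert vt.site_prob_2state(m, r, mu, s, eps) == pytest.approx(
                direct_site_prob(m, r, mu, s, eps), rel=1e-10, abs=1e-300
            )

    def test_error_free_limit_of_error_model(self, rng):
        """eps -> 0 continuously recovers the error-free expression."""
        s = [(0.8, 0.25), (0.4, 0.5), (0.1, 0.9)]
        for m, r in [(0, 30), (1, 30), (10, 30)]:
            p0 = vt.site_prob_2state(m, r, 0.05, s, 0.0)
            p1 = vt.site_prob_2state(m, r, 0.05, s, 1e-12)
            assert p1 == pytest.approx(p0, rel=1e-6)

    def test_excess_mutation_mass_rejected(self):
        with pytest.raises(ValueError, match="mu\\*L"):
            vt.site_prob_2state(0, 5, 2.0, [(1.0, 0.5)], 0.0)


class TestSiteProb4State:
    def test_no_mutation_no_error(self):
        s = [(1.0, 0.5)]
        assert vt.site_prob_4state(0, 0, 0, 5, 0.0, s, 0.0) == pytest.approx(1.0)

    def test_exhaustive_normalization_small_r(self, rng):
        for _ in range(4):
            k = rng.integers(1, 4)
            l = rng.random(k)
            f = rng.random(k) * 0.9 + 0.05
            mu = rng.random() * 0.5 / l.sum()
            eps = rng.random() * 0.3
            r = int(rng.integers(1, 6))
            s = np.column_stack([l, f])
            total = sum(
                vt.site_prob_4state(m1, m2, m3, r, mu, s, eps)
                for m1, m2, m3 in product(range(r + 1), repeat=3)
                if m1 + m2 + m3 <= r
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_reduces_to_2state_without_errors(self, rng):
        """At eps=0 a single observed mutant type carries 1/3 of the 2-state
        mass (the uniform choice of the true mutant type)."""
        s = [(0.5, 0.4), (0.3, 0.7)]
        for m, r in [(1, 5), (3, 7), (5, 9)]:
            p2 = vt.site_prob_2state(m, r, 0.02, s, 0.0)
            for args in [(m, 0, 0), (0, m, 0), (0, 0, m)]:
                assert 3 * vt.site_prob_4state(*args, r, 0.02, s, 0.0) == pytest.approx(p2)

    def test_rejects_overfull_counts(self):
        with pytest.raises(ValueError):
            vt.site_prob_4state(3, 3, 3, 5, 0.01, [(1.0, 0.5)], 0.0)


class TestTreeLoglik:
    def test_clean_site_gives_zero_loglik(self):
        tree = vt.LineageTree([1.0])
        tab = vt.ReadCountTable(r=np.array([10]), m=np.array([0]))
        assert vt.tree_loglik(tab, 0.0, tree, 0.0) == pytest.approx(0.0)

    def test_aggregation_invariance(self, small_dataset):
        """Compressing identical sites into multiplicity classes changes
        nothing."""
        tab = small_dataset["table"]
        tree = small_dataset["tree"]
        mu = small_dataset["mu"]
        classes = SiteClassTable.from_table(tab, "2state")
        direct = vt.tree_loglik(tab, mu, tree, 0.0)
        via_classes = vt.tree_loglik(classes, mu, tree, 0.0)
        assert direct == pytest.approx(via_classes)
        # duplicating every site doubles the log-likelihood
        tab2 = vt.ReadCountTable(
            r=np.concatenate([tab.r, tab.r]), m=np.concatenate([tab.m, tab.m])
        )
        assert vt.tree_loglik(tab2, mu, tree, 0.0) == pytest.approx(2 * direct)

    def test_time_rescaling_invariance(self, small_dataset):
        """Scaling branch lengths by c and mu by 1/c leaves the likelihood
        unchanged (time units are arbitrary)."""
        tab = small_dataset["table"]
        tree = small_dataset["tree"]
        mu = small_dataset["mu"]
        c = 13.7
        scaled = vt.LineageTree(tree.depths * c)
        for eps in (0.0, 1e-3):
            a = vt.tree_loglik(tab, mu, tree, eps)
            b = vt.tree_loglik(tab, mu / c, scaled, eps)
            assert b == pytest.approx(a, rel=1e-10)

    def test_zero_probability_class_reported(self):
        tree = vt.LineageTree([1.0])
        tab = vt.ReadCountTable(r=np.array([10]), m=np.array([3]))
        with pytest.warns(UserWarning, match="zero probability"):
            ll = vt.tree_loglik(tab, 0.0, tree, 0.0)
        assert ll == -np.inf

    def test_merged_and_unmerged_summaries_agree(self, rng):
        tree = vt.sample_tree(vt.BDParams(0.7, 30), rng)
        lu, fu, _ = vt.branch_summary(tree, merge=False)
        lm, fm, _ = vt.branch_summary(tree, merge=True)
        assert lm.size < lu.size
        for m, r in [(0, 40), (3, 40), (20, 40)]:
            pu = vt.site_prob_2state(m, r, 1e-3, np.column_stack([lu, fu]), 1e-4)
            pm = vt.site_prob_2state(m, r, 1e-3, np.column_stack([lm, fm]), 1e-4)
            assert pu == pytest.approx(pm, rel=1e-12)

    def test_mu_sensitivity_peaks_near_truth(self, rng):
        """For a clonal-ish site the site probability is maximized near the
        mu that generated it (sign-error guard)."""
        tree = vt.sample_tree(vt.BDParams(0.5, 100), rng)
        tab_mu = 1e-3 / tree.total_length
        asn = vt.assign_mutations(tree, tab_mu, 5000, rng)
        tab = vt.simulate_reads(asn, tree, vt.DepthModel("fixed", 50), 0.0, rng)
        tab = tab.to_two_state()
        mus = tab_mu * np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        lls = [vt.tree_loglik(tab, m, tree, 0.0) for m in mus]
        assert np.argmax(lls) in (2, 3, 4)


class TestMeanLoglik:
    def test_single_and_identical_tree_ensembles(self, small_dataset):
        tab = small_dataset["table"]
        tree = small_dataset["tree"]
        mu = small_dataset["mu"]
        single = vt.TreeEnsemble(delta=0.5, trees=[tree])
        ll = vt.tree_loglik(tab, mu, tree, 0.0)
        assert vt.mean_loglik(tab, mu, single, 0.0) == pytest.approx(ll)
        triple = vt.TreeEnsemble(delta=0.5, trees=[tree, tree, tree])
        assert vt.mean_loglik(tab, mu, triple, 0.0) == pytest.approx(ll)

    def test_logavg_diagnostic_bounded_below_by_mean(self, small_dataset, rng):
        """Jensen: log of the averaged likelihood >= mean log-likelihood."""
        from vaftree.likelihood import ensemble_logavg_lik

        tab = small_dataset["table"]
        mu = small_dataset["mu"]
        ens = vt.sample_ensemble(vt.BDParams(0.5, 200), 5, rng)
        mean = vt.mean_loglik(tab, mu, ens, 0.0)
        avg = ensemble_logavg_lik(tab, mu, ens, 0.0)
        assert avg >= mean
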