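import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycoevo.famevol import (
    bd_matrix,
    bd_transition,
    estimate_lambda,
    family_likelihood,
    family_pvalue,
    identify_branches,
    _transition_cache,
    _viterbi_sizes,
)
from mycoevo.seqio import parse_newick
from mycoevo.simulate import simulate_family_counts


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        assert bd_transition(3, 3, 0.0, 0.5) == 1.0
        assert bd_transition(3, 2, 0.0, 0.5) == 0.0

    def test_single_gene_extinction_closed_form(self):
        # P(1 -> 0) = lam*t / (1 + lam*t); at lam*t = 1 this is 1/2
        assert bd_transition(1, 0, 1.0, 1.0) == pytest.approx(0.5)
        for lt in (0.1, 0.3, 0.45):
            assert bd_transition(1, 0, lt, 1.0) == pytest.approx(
                lt / (1 + lt), rel=1e-12
            )

    def test_hand_expanded_case(self):
        # s=2, c=1, alpha=1/4 (lam*t = 1/3): 2 a^3 + 2 a (1-2a) = 0.28125
        assert bd_transition(2, 1, 1 / 3, 1.0) == pytest.approx(0.28125)

    @given(st.integers(1, 6), st.floats(0.01, 1.2), st.floats(0.01, 0.4))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_distribution_sums_to_one(self, s, t, lam):
        # closed-form domain (lam*t <= 0.5); longer branches are covered by
        # the Chapman-Kolmogorov product test below
        total = sum(bd_transition(s, c, t, lam) for c in range(0, 400))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_long_branch_split_consistent_with_product(self):
        # lam*t > 0.5 triggers Chapman-Kolmogorov splitting; the result
        # must match an explicit two-segment product
        lam, t = 0.5, 3.0
        m_full = bd_matrix(t, lam, 120)
        m_half = bd_matrix(t / 2, lam, 120)
        # compare away from the truncation boundary, where both
        # segmentations agree to machine precision
        assert np.allclose(m_full[:21, :21], (m_half @ m_half)[:21, :21],
                           atol=1e-12)

    def test_matches_event_level_simulation(self):
        """Closed form vs Monte-Carlo from the independent event-level
        simulator, across a small (s, t, lam) grid."""
        n = 4000
        for s, t, lam in itertools.product((1, 3), (0.8, 2.0), (0.2, 0.5)):
            tree = parse_newick(f"(A:{t},B:0);")
            tbl, _ = simulate_family_counts(tree, lam, s, n, seed=17)
            for c in (0, s):
                emp = float((tbl["A"] == c).mean())
                exact = bd_transition(s, c, t, lam)
                se = max(np.sqrt(exact * (1 - exact) / n), 1e-4)
                assert abs(emp - exact) <= 3 * se, (s, t, lam, c)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bd_transition(0, 1, 1.0, 0.5)
        with pytest.raises(ValueError):
            bd_transition(1, -1, 1.0, 0.5)
        with pytest.raises(ValueError):
            bd_transition(1, 1, 1.0, -0.5)


class TestFamilyLikelihood:
    def test_single_branch_reduces_to_transition(self):
        tree = parse_newick("(A:1.2,B:0);")
        lam = 0.3
        counts = {"A": 2, "B": 4}
        max_size = 10
        # root fixed at B's count because the B branch has length 0
        prior = np.zeros(max_size + 1)
        prior[4] = 1.0
        ll = family_likelihood(tree, counts, lam, prior, max_size)
        assert np.exp(ll) == pytest.approx(bd_transition(4, 2, 1.2, lam),
                                           rel=1e-9)

    def test_lambda_zero_is_indicator(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        same = {"A": 5, "B": 5, "C": 5}
        diff = {"A": 5, "B": 5, "C": 4}
        prior = np.zeros(11)
        prior[1:] = 0.1
        assert np.exp(family_likelihood(tree, same, 0.0, prior, 10)) == (
            pytest.approx(0.1)
        )
        assert family_likelihood(tree, diff, 0.0, prior, 10) == -np.inf

    def test_pruning_matches_bruteforce_enumeration(self):
        """3-leaf tree: pruning equals the exhaustive sum over all
        ancestral size assignments."""
        tree = parse_newick("((A:0.7,B:0.9):0.5,C:1.1);")
        lam, max_size = 0.4, 8
        counts = {"A": 2, "B": 1, "C": 3}
        prior = np.zeros(max_size + 1)
        prior[1:] = 1.0 / max_size
        ll = family_likelihood(tree, counts, lam, prior, max_size)

        def p(s, c, t):
            if s == 0:
                return float(c == 0)
            return bd_transition(s, c, t, lam, max_size=max_size)

        brute = 0.0
        for root in range(0, max_size + 1):
            for anc in range(0, max_size + 1):
                brute += (
                    prior[root]
                    * p(root, anc, 0.5)
                    * p(anc, counts["A"], 0.7)
                    * p(anc, counts["B"], 0.9)
                    * p(root, counts["C"], 1.1)
                )
        assert np.exp(ll) == pytest.approx(brute, rel=1e-6)


class TestLambdaEstimation:
    def test_recovers_simulated_rate(self):
        tree = parse_newick("((A:180,B:180):10,C:190);")
        tbl, _ = simulate_family_counts(tree, 0.002, 10, 200, seed=1)
        params = estimate_lambda(tbl, tree)
        assert 0.001 <= params.lam <= 0.004
        assert not params.degenerate

    def test_constant_table_returns_zero(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tbl = pd.DataFrame({"A": [3, 5], "B": [3, 5], "C": [3, 5]},
                           index=["f1", "f2"])
        params = estimate_lambda(tbl, tree)
        assert params.lam == 0.0 and params.degenerate

    def test_mle_beats_neighbouring_rates(self):
        tree = parse_newick("((A:50,B:50):20,C:70);")
        tbl, _ = simulate_family_counts(tree, 0.005, 6, 60, seed=2)
        params = estimate_lambda(tbl, tree)
        max_size = params.max_size

        def total_ll(lam):
            mats = _transition_cache(tree, lam, max_size)
            return sum(
                family_likelihood(tree, row, lam, max_size=max_size,
                                  _mats=mats)
                for _, row in tbl.iterrows()
            )

        best = total_ll(params.lam)
        assert best >= total_ll(params.lam * 0.5) - 1e-6
        assert best >= total_ll(params.lam * 2.0) - 1e-6


class TestFamilyPvalue:
    def test_same_seed_reproduces(self):
        tree = parse_newick("((A:50,B:50):20,C:70);")
        fam = pd.Series({"A": 4, "B": 7, "C": 2})
        p1 = family_pvalue(fam, tree, 0.003, m=200, seed=9)
        p2 = family_pvalue(fam, tree, 0.003, m=200, seed=9)
        assert p1 == p2

    def test_add_one_correction_floor(self):
        tree = parse_newick("((A:50,B:50):20,C:70);")
        fam = pd.Series({"A": 1, "B": 40, "C": 1})
        p = family_pvalue(fam, tree, 0.0005, m=50, seed=0, max_size=80)
        assert p >= 1 / 51

    def test_wild_expansion_is_significant(self):
        tree = parse_newick("((A:50,B:50):20,C:70);")
        fam = pd.Series({"A": 30, "B": 3, "C": 3})
        p = family_pvalue(fam, tree, 0.001, m=400, seed=1, max_size=60)
        assert p <= 0.05


class TestBranchIdentification:
    def test_lambda_zero_flags_only_discordant_terminal(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        fam = pd.Series({"A": 5, "B": 5, "C": 4})
        res = identify_branches(fam, tree, 0.0, max_size=10)
        flagged = res.branches.loc[res.branches.significant, "branch"]
        assert list(flagged) == ["b_C"]

    def test_viterbi_matches_bruteforce(self):
        tree = parse_newick("((A:0.7,B:0.9):0.5,C:1.1);")
        lam, max_size = 0.4, 6
        counts = pd.Series({"A": 2, "B": 1, "C": 3})
        mats = _transition_cache(tree, lam, max_size)
        prior = np.zeros(max_size + 1)
        prior[1:] = 1.0 / max_size
        assign = _viterbi_sizes(tree, counts, mats, prior, max_size)

        def p(s, c, t):
            if s == 0:
                return float(c == 0)
            return bd_transition(s, c, t, lam, max_size=max_size)

        best, arg = -1.0, None
        for root in range(1, max_size + 1):
            for anc in range(0, max_size + 1):
                val = (prior[root] * p(root, anc, 0.5)
                       * p(anc, 2, 0.7) * p(anc, 1, 0.9)
                       * p(root, 3, 1.1))
                if val > best:
                    best, arg = val, (root, anc)

        # score the Viterbi assignment the same way and compare optima
        nodes = list(tree.preorder_node_iter())
        root_nd = tree.seed_node
        anc_nd = next(nd for nd in nodes
                      if nd is not root_nd and not nd.is_leaf())
        vit = (assign[id(root_nd)], assign[id(anc_nd)])
        val_vit = (prior[vit[0]] * p(vit[0], vit[1], 0.5)
                   * p(vit[1], 2, 0.7) * p(vit[1], 1, 0.9)
                   * p(vit[0], 3, 1.1))
        assert val_vit == pytest.approx(best, rel=1e-9)
        assert vit == arg

    def test_symmetric_counts_give_symmetric_scores(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fam = pd.Series({"A": 4, "B": 4, "C": 4, "D": 4})
        res = identify_branches(fam, tree, 0.01, max_size=10)
        df = res.branches.set_index("branch")
        assert df.loc["b_A", "exceedance_p"] == pytest.approx(
            df.loc["b_B", "exceedance_p"]
        )
        assert df.loc["b_A", "likelihood_ratio"] == pytest.approx(
            df.loc["b_C", "likelihood_ratio"], rel=1e-3
        )
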