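import numpy as np
import pytest

from mycoevo import codons
from mycoevo.relsel import (
    NucModelSpec,
    RateClassGrid,
    RELFit,
    _CodonPruner,
    fit_rel,
    site_bayes_factor,
)
from mycoevo.simulate import SiteClassSpec, simulate_codon_alignment

from conftest import balanced_tree


class TestNucModelSpec:
    def test_all_exchanges_must_be_mapped(self):
        with pytest.raises(ValueError, match="not mapped"):
            NucModelSpec({"AC": "ref"})

    def test_reference_must_appear(self):
        with pytest.raises(ValueError, match="reference"):
            NucModelSpec({ex: "R_X" for ex in codons.EXCHANGES})

    def test_ct_only_model_has_one_free_parameter(self):
        spec = NucModelSpec.ct_only()
        assert spec.free_params == ["R_CT"]
        rates = spec.rates({"R_CT": 4.0})
        assert rates[codons.EXCHANGES.index("CT")] == 4.0
        assert sum(r == 1.0 for r in rates) == 5

    def test_shared_transversion_model_groups_exchanges(self):
        spec = NucModelSpec.shared_transversions()
        assert spec.free_params == ["R_AC", "R_CG", "R_CT"]
        rates = spec.rates({"R_AC": 2.0, "R_CG": 3.0, "R_CT": 5.0})
        by_ex = dict(zip(codons.EXCHANGES, rates))
        assert by_ex["AC"] == by_ex["AT"] == 2.0
        assert by_ex["CG"] == by_ex["GT"] == 3.0
        assert by_ex["AG"] == 1.0 and by_ex["CT"] == 5.0


class TestCodonGenerator:
    @pytest.fixture
    def q(self):
        pi = np.random.default_rng(0).dirichlet(np.ones(codons.N_CODONS))
        return codons.mg94_rate_matrix(
            np.array([1.0, 2.0, 1.0, 1.0, 3.0, 1.0]), 0.4, 1.1, pi
        ), pi

    def test_rows_sum_to_zero(self, q):
        mat, _ = q
        assert np.abs(mat.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, q):
        mat, pi = q
        flux = pi[:, None] * mat
        assert np.abs(flux - flux.T).max() < 1e-15

    def test_multi_nucleotide_moves_forbidden(self, q):
        mat, _ = q
        for i in (0, 17, 42):
            for j in range(codons.N_CODONS):
                diff = sum(a != b for a, b in zip(codons.SENSE_CODONS[i],
                                                  codons.SENSE_CODONS[j]))
                if diff > 1:
                    assert mat[i, j] == 0.0

    def test_dn_zero_kills_nonsynonymous_rates(self):
        pi = np.full(codons.N_CODONS, 1 / codons.N_CODONS)
        mat = codons.mg94_rate_matrix(np.ones(6), 0.0, 1.0, pi)
        aa = codons.CODON_AA
        for i, j, ns in zip(codons.NEI_FROM, codons.NEI_TO, codons.NEI_NONSYN):
            if ns:
                assert mat[i, j] == 0.0
            assert (aa[i] != aa[j]) == bool(ns)


class TestBayesFactorArithmetic:
    def _fit_with_posteriors(self, prior_pos, post_pos):
        """Two classes (positive, negative) with crafted site likelihoods
        that produce the requested posterior."""
        grid = RateClassGrid([0.5, 2.0], [1.0 - prior_pos, prior_pos],
                             [1.0], [1.0])
        # want posterior on class 2 = post_pos:
        # w2 L2 / (w1 L1 + w2 L2) = post_pos with L1 = 1
        l2 = post_pos * (1 - prior_pos) / ((1 - post_pos) * prior_pos)
        site_ll = np.log(np.array([[1.0], [l2]]))
        return RELFit(grid, NucModelSpec.single_rate(), np.ones(6),
                      np.full(codons.N_CODONS, 1 / codons.N_CODONS), 1.0,
                      0.0, True, 1, site_class_loglik=site_ll)

    def test_bf_from_prior_point_two_posterior_point_nine(self):
        res = site_bayes_factor(self._fit_with_posteriors(0.2, 0.9))
        assert res.bayes_factor_positive[0] == pytest.approx(36.0, rel=1e-9)

    def test_posterior_equal_prior_gives_unit_bf(self):
        res = site_bayes_factor(self._fit_with_posteriors(0.3, 0.3))
        assert res.bayes_factor_positive[0] == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_prior_convention(self):
        grid = RateClassGrid([0.5], [1.0], [1.0], [1.0])  # no positive class
        fit = RELFit(grid, NucModelSpec.single_rate(), np.ones(6),
                     np.full(codons.N_CODONS, 1 / codons.N_CODONS), 1.0,
                     0.0, True, 1, site_class_loglik=np.zeros((1, 3)))
        res = site_bayes_factor(fit)
        assert (res.bayes_factor_positive == 0.0).all()

    def test_printed_rate_ratio_arithmetic(self):
        # reporting arithmetic for a fitted top class
        assert round(0.49 / 0.21, 2) == 2.33


class TestRELFit:
    def test_likelihood_invariant_to_taxon_order(self):
        tree = balanced_tree(6, 0.3)
        aln, _ = simulate_codon_alignment(
            tree, 50, SiteClassSpec([(0.5, 1.0)]), seed=1
        )
        perm = [3, 1, 5, 0, 4, 2]
        aln_p = type(aln)([aln.taxa[i] for i in perm],
                          [aln.rows[i] for i in perm])
        grid = RateClassGrid([0.2, 1.0], [0.6, 0.4], [1.0], [1.0])
        pi = codons.f3x4_frequencies(aln.rows)
        l1 = _CodonPruner(aln, tree).mixture_loglik(grid, np.ones(6), pi, 1.0)
        l2 = _CodonPruner(aln_p, tree).mixture_loglik(grid, np.ones(6), pi, 1.0)
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_refit_with_permuted_taxa_matches(self):
        tree = balanced_tree(5, 0.3)
        aln, _ = simulate_codon_alignment(
            tree, 40, SiteClassSpec([(0.5, 1.0)]), seed=2
        )
        perm = [4, 2, 0, 1, 3]
        aln_p = type(aln)([aln.taxa[i] for i in perm],
                          [aln.rows[i] for i in perm])
        f1 = fit_rel(aln, tree, bins=2, starts=1, seed=0, maxiter=60)
        f2 = fit_rel(aln_p, tree, bins=2, starts=1, seed=0, maxiter=60)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)

    def test_single_class_data_collapses_grid(self):
        """Data simulated at a single omega ~ 1: the fitted grid's
        prior-mean dN over prior-mean dS sits near 1.  (The individual
        class straddling the mean is not identifiable, so the mean ratio
        is the meaningful collapse statistic.)"""
        tree = balanced_tree(10, 0.25)
        aln, _ = simulate_codon_alignment(
            tree, 300, SiteClassSpec([(1.0, 1.0)]), seed=3
        )
        fit = fit_rel(aln, tree, bins=3, starts=1, seed=0)
        mean_dn = float(np.dot(fit.grid.dn_weights, fit.grid.dn_values))
        mean_ds = float(np.dot(fit.grid.ds_weights, fit.grid.ds_values))
        assert 0.8 <= mean_dn / mean_ds <= 1.25
        # dN itself concentrates: the heaviest dN value carries most weight
        assert fit.grid.dn_weights.max() >= 0.6

    def test_site_posteriors_sum_to_one(self):
        tree = balanced_tree(6, 0.3)
        aln, _ = simulate_codon_alignment(
            tree, 60, SiteClassSpec([(0.3, 0.7), (2.0, 0.3)]), seed=4
        )
        fit = fit_rel(aln, tree, bins=2, starts=1, seed=0, maxiter=80)
        res = site_bayes_factor(fit)
        assert np.allclose(res.posterior_by_class.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_taxa_rejected(self):
        tree = balanced_tree(4, 0.2)
        aln, _ = simulate_codon_alignment(
            tree, 20, SiteClassSpec([(1.0, 1.0)]), seed=5
        )
        small = type(aln)(aln.taxa[:2], aln.rows[:2])
        with pytest.raises(ValueError):
            fit_rel(small, tree, starts=1)

    def test_conserved_control_gene_shows_no_positive_sites(self):
        """A short, strongly conserved gene (the actin/tef-style control)
        yields zero strong-positive calls."""
        tree = balanced_tree(10, 0.15)
        aln, _ = simulate_codon_alignment(
            tree, 120, SiteClassSpec([(0.05, 0.8), (0.3, 0.2)]), seed=6
        )
        fit = fit_rel(aln, tree, bins=3, starts=1, seed=0)
        res = site_bayes_factor(fit)
        assert res.classification.count("positive_strong") == 0
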