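import numpy as np
import pytest

from mycoevo import codons
from mycoevo.bgm import (
    BGMConfig,
    EdgePosterior,
    SubstitutionMatrix,
    bgm_edge_posteriors,
    enumerate_edge_posteriors,
    filter_sites,
    global_dnds_fit,
    group_coevolving,
    map_nonsyn_substitutions,
    reconstruct_ancestral,
)
from mycoevo.relsel import NucModelSpec, RateClassGrid, RELFit
from mycoevo.seqio import CodonAlignment, parse_newick
from mycoevo.simulate import CoevolSpec, SiteClassSpec, simulate_codon_alignment

from conftest import balanced_tree


def _uniform_fit(omega: float = 1.0) -> RELFit:
    pi = np.full(codons.N_CODONS, 1 / codons.N_CODONS)
    grid = RateClassGrid([omega], [1.0], [1.0], [1.0])
    return RELFit(grid, NucModelSpec.single_rate(), np.ones(6), pi, 1.0,
                  0.0, True, 1)


class TestAncestralReconstruction:
    def test_invariant_site_reconstructed_everywhere(self):
        tree = balanced_tree(6, 0.2)
        aln = CodonAlignment([f"t{i}" for i in range(6)], ["ATGGCT"] * 6)
        recon = reconstruct_ancestral(aln, tree, _uniform_fit())
        for node_id, post in recon.posteriors.items():
            assert post.argmax(axis=1).tolist() == [
                codons.CODON_INDEX["ATG"], codons.CODON_INDEX["GCT"]
            ]

    def test_posteriors_sum_to_one(self):
        tree = balanced_tree(6, 0.2)
        aln, _ = simulate_codon_alignment(
            tree, 20, SiteClassSpec([(1.0, 1.0)]), seed=1
        )
        recon = reconstruct_ancestral(aln, tree, _uniform_fit())
        for post in recon.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_two_leaf_root_posterior_symmetric(self):
        """Equal branch lengths, states x != y, uniform frequencies: the
        root posterior puts equal mass on the two one-step
        reconstructions."""
        tree = parse_newick("(a:0.4,b:0.4);")
        aln = CodonAlignment(["a", "b"], ["AAA", "AAG"])
        recon = reconstruct_ancestral(aln, tree, _uniform_fit())
        root_post = next(
            p for nid, p in recon.posteriors.items() if nid.startswith("node")
        )
        pa = root_post[0, codons.CODON_INDEX["AAA"]]
        pb = root_post[0, codons.CODON_INDEX["AAG"]]
        # AAA and AAG have slightly different sense-codon neighbourhoods,
        # so symmetry is near-exact rather than exact
        assert pa == pytest.approx(pb, rel=1e-4)
        assert pa + pb > 0.9


class TestSubstitutionMapping:
    def test_invariant_amino_acid_gives_zero_column(self):
        tree = balanced_tree(6, 0.2)
        # CTT/CTC/CTA all encode Leu: nucleotide changes, no aa change
        rows = ["CTT", "CTC", "CTA", "CTT", "CTC", "CTA"]
        aln = CodonAlignment([f"t{i}" for i in range(6)], rows)
        recon = reconstruct_ancestral(aln, tree, _uniform_fit())
        mat = map_nonsyn_substitutions(recon)
        assert mat.binary[:, 0].sum() == 0

    def test_counts_are_column_sums(self):
        rng = np.random.default_rng(0)
        x = (rng.random((10, 4)) < 0.4).astype(int)
        mat = SubstitutionMatrix([f"b{i}" for i in range(10)],
                                 np.arange(1, 5), x, x.astype(float))
        assert (mat.counts == x.sum(axis=0)).all()

    def test_mapping_recovers_true_events(self):
        """Cells where the simulator recorded a non-synonymous event are
        mapped as 1 in >= 90% of cases (and quiet cells stay 0)."""
        tree = balanced_tree(16, 0.15)
        hits = 0
        total = 0
        quiet_wrong = 0
        quiet_total = 0
        for seed in range(3):
            aln, truth = simulate_codon_alignment(
                tree, 60, SiteClassSpec([(0.4, 0.6), (1.0, 0.4)]), seed=seed
            )
            fit = global_dnds_fit(aln, tree, seed=0)
            recon = reconstruct_ancestral(aln, tree, fit)
            mat = map_nonsyn_substitutions(recon)
            rows = [mat.branch_ids.index(b) for b in truth.branch_ids]
            mapped = mat.binary[rows]
            true_cells = truth.nonsyn_counts > 0
            hits += int(mapped[true_cells].sum())
            total += int(true_cells.sum())
            quiet_wrong += int(mapped[~true_cells].sum())
            quiet_total += int((~true_cells).sum())
        assert hits / total >= 0.85
        assert quiet_wrong / quiet_total <= 0.02


class TestFilterSites:
    def _matrix(self, cols):
        x = np.array(cols).T
        return SubstitutionMatrix([f"b{i}" for i in range(x.shape[0])],
                                  np.arange(1, x.shape[1] + 1), x,
                                  x.astype(float))

    def test_threshold_boundary(self):
        mat = self._matrix([
            [1, 1, 0, 0, 0],   # 2 events -> dropped
            [1, 1, 1, 0, 0],   # 3 events -> kept
            [1, 1, 1, 1, 0],   # 4 events -> kept
        ])
        assert filter_sites(mat, 3) == [2, 3]

    def test_empty_retention_raises_downstream(self):
        mat = self._matrix([[1, 0, 0, 0]])
        with pytest.raises(ValueError, match="BGM-eligible"):
            bgm_edge_posteriors(mat, [], BGMConfig())


class TestEdgePosteriors:
    def test_identical_high_count_columns_strongly_associated(self):
        rng = np.random.default_rng(2)
        n = 40
        shared = (rng.random(n) < 0.3).astype(int)
        while shared.sum() < 10:
            shared = (rng.random(n) < 0.35).astype(int)
        cols = [shared, shared.copy()]
        cols += [(rng.random(n) < 0.2).astype(int) for _ in range(3)]
        x = np.array(cols).T
        mat = SubstitutionMatrix([f"b{i}" for i in range(n)],
                                 np.arange(1, 6), x, x.astype(float))
        exact = enumerate_edge_posteriors(mat, [1, 2, 3, 4, 5])
        assert exact.get(1, 2) >= 0.9

    def test_mcmc_matches_enumeration(self):
        """Seeded MCMC within 0.05 of the exact posterior on every edge of
        a 5-node network."""
        rng = np.random.default_rng(3)
        x = (rng.random((40, 5)) < 0.25).astype(int)
        x[:, 1] = x[:, 0] ^ (rng.random(40) < 0.1)
        mat = SubstitutionMatrix([f"b{i}" for i in range(40)],
                                 np.arange(1, 6), x, x.astype(float))
        sites = [1, 2, 3, 4, 5]
        exact = enumerate_edge_posteriors(mat, sites)
        mc = bgm_edge_posteriors(mat, sites,
                                 BGMConfig(chain_length=60000, seed=0))
        for pair, p_exact in exact.probs.items():
            assert mc.probs[pair] == pytest.approx(p_exact, abs=0.05)

    def test_iid_null_rarely_flags_pairs(self):
        """Independent Bernoulli(0.2) columns: few pair posteriors reach
        0.5 under the uniform structure prior."""
        fracs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = (rng.random((40, 10)) < 0.2).astype(int)
            mat = SubstitutionMatrix([f"b{i}" for i in range(40)],
                                     np.arange(1, 11), x, x.astype(float))
            mc = bgm_edge_posteriors(
                mat, list(range(1, 11)),
                BGMConfig(chain_length=30000, seed=seed),
            )
            vals = np.array(list(mc.probs.values()))
            fracs.append((vals >= 0.5).mean())
        assert np.mean(fracs) <= 0.10

    def test_seeded_runs_reproduce(self):
        rng = np.random.default_rng(5)
        x = (rng.random((30, 6)) < 0.3).astype(int)
        mat = SubstitutionMatrix([f"b{i}" for i in range(30)],
                                 np.arange(1, 7), x, x.astype(float))
        cfg = BGMConfig(chain_length=10000, seed=11)
        r1 = bgm_edge_posteriors(mat, list(range(1, 7)), cfg)
        r2 = bgm_edge_posteriors(mat, list(range(1, 7)), cfg)
        assert r1.probs == r2.probs


class TestGrouping:
    def test_hand_union(self):
        ep = EdgePosterior([1, 2, 3, 4, 5], {
            frozenset((1, 2)): 0.9, frozenset((2, 3)): 0.8,
            frozenset((4, 5)): 0.7, frozenset((1, 5)): 0.2,
        })
        groups = group_coevolving(ep, 0.5)
        assert sorted(sorted(g) for g in groups) == [[1, 2, 3], [4, 5]]

    def test_groups_have_at_least_two_sites(self):
        ep = EdgePosterior([1, 2], {frozenset((1, 2)): 0.6})
        groups = group_coevolving(ep, 0.5)
        assert all(len(g) >= 2 for g in groups)


class TestEngineeredPairDetection:
    def test_coupled_pair_found_uncoupled_control_not(self):
        """A mutually coupled pair is detected at posterior >= 0.5 while a
        matched uncoupled control pair stays below (small replicate
        version; the 20-replicate rate lives in the acceptance suite)."""
        tree = balanced_tree(30, 0.15)
        classes = [(0.2, 0.7), (1.0, 0.3)]
        overrides = {10: 1, 20: 1, 40: 1, 50: 1}
        found, ctrl = [], []
        for seed in (1, 2, 3):
            mult = np.ones(60)
            mult[[9, 19, 39, 49]] = 1.3
            aln, _ = simulate_codon_alignment(
                tree, 60,
                SiteClassSpec(classes, rate_multipliers=mult,
                              class_overrides=overrides),
                CoevolSpec([(10, 20), (20, 10)], coupling=30.0), seed=seed,
            )
            fit = global_dnds_fit(aln, tree, seed=0)
            recon = reconstruct_ancestral(aln, tree, fit)
            mat = map_nonsyn_substitutions(recon)
            retained = filter_sites(mat, 3)
            if 10 not in retained or 20 not in retained:
                found.append(0.0)
                continue
            mc = bgm_edge_posteriors(
                mat, retained, BGMConfig(chain_length=40000, seed=seed)
            )
            found.append(mc.get(10, 20))
            ctrl.append(mc.get(40, 50))
        assert np.mean([p >= 0.5 for p in found]) >= 2 / 3
        assert all(c < 0.5 for c in ctrl)
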