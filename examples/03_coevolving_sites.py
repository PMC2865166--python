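"""Detect co-evolving codon pairs by substitution mapping + BGM.

Simulates a mutually coupled codon pair (sites 10 and 20), maps
non-synonymous substitutions onto branches via ancestral reconstruction,
and fits the Bayesian network over sites with >= 3 events.
"""

import numpy as np

from mycoevo import bgm
from mycoevo.seqio import parse_newick
from mycoevo.simulate import CoevolSpec, SiteClassSpec, simulate_codon_alignment


def balanced_tree(n, bl):
    labels = [f"t{i}" for i in range(n)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{bl}"
        m = len(ls) // 2
        return f"({build(ls[:m])},{build(ls[m:])}):{bl}"

    return parse_newick(f"({build(labels[:n//2])},{build(labels[n//2:])});")


tree = balanced_tree(30, 0.15)
mult = np.ones(60)
mult[[9, 19]] = 1.3
aln, truth = simulate_codon_alignment(
    tree, 60,
    SiteClassSpec([(0.2, 0.7), (1.0, 0.3)], rate_multipliers=mult,
                  class_overrides={10: 1, 20: 1}),
    CoevolSpec([(10, 20), (20, 10)], coupling=30.0),
    seed=4,
)

fit = bgm.global_dnds_fit(aln, tree, seed=0)
recon = bgm.reconstruct_ancestral(aln, tree, fit)
matrix = bgm.map_nonsyn_substitutions(recon)
retained = bgm.filter_sites(matrix, min_subs=3)
print(f"sites with >= 3 non-synonymous branch events: {len(retained)}")

edges = bgm.bgm_edge_posteriors(
    matrix, retained, bgm.BGMConfig(chain_length=40000, seed=0)
)
print(f"posterior for the engineered pair (10, 20): "
      f"{edges.get(10, 20):.2f}")
groups = bgm.group_coevolving(edges, threshold=0.5)
print(f"co-evolving groups at posterior >= 0.5: "
      f"{[sorted(g) for g in groups]}")
print("A posterior >= 0.5 for (10, 20) recovers the coupling built into "
      "the simulation: both sites' non-synonymous substitutions "
      "concentrate on the same branches.")
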