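"""Scan codons for positive selection with the REL model.

Simulates a 300-codon alignment on 12 taxa in which 10% of sites evolve
at dN/dS = 5 over a purifying background, fits the 3 x 3 random-effects
rate-class grid and classifies sites by Bayes factor.
"""

import numpy as np

from mycoevo.relsel import fit_rel, site_bayes_factor
from mycoevo.seqio import parse_newick
from mycoevo.simulate import SiteClassSpec, simulate_codon_alignment


def balanced_tree(n, bl):
    labels = [f"t{i}" for i in range(n)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{bl}"
        m = len(ls) // 2
        return f"({build(ls[:m])},{build(ls[m:])}):{bl}"

    return parse_newick(f"({build(labels[:n//2])},{build(labels[n//2:])});")


tree = balanced_tree(12, 0.25)
aln, truth = simulate_codon_alignment(
    tree, 300, SiteClassSpec([(0.1, 0.5), (0.5, 0.4), (5.0, 0.1)]), seed=11
)

fit = fit_rel(aln, tree, bins=3, starts=1, seed=0)
print("fitted dN values ", np.round(fit.grid.dn_values, 2),
      "weights", np.round(fit.grid.dn_weights, 2))
print("fitted dS values ", np.round(fit.grid.ds_values, 2),
      "weights", np.round(fit.grid.ds_weights, 2))

res = site_bayes_factor(fit)
strong = [int(s) for s, c in zip(res.sites, res.classification)
          if c == "positive_strong"]
true_pos = sorted(np.flatnonzero(truth.omegas > 1) + 1)
print(f"strong-positive sites (BF >= 50): {len(strong)}")
print(f"  truly positive among them: "
      f"{len(set(strong) & set(true_pos))}/{len(strong)}")
print("The top dN class near 5 with ~10% weight mirrors the simulated "
      "positive fraction; a Bayes factor >= 50 means the site's "
      "posterior odds of dN > dS are 50x its prior odds.")
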