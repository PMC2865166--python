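"""Locate poorly conserved regions in a protein with RCA.

Simulates a small gene family in which residues 80-100 evolve six times
faster than the rest, estimates per-site rates with the empirical-Bayes
gamma model, smooths the standardized scores with the 7-residue window
and calls peaks at the 0.5-SD intensity threshold.
"""

import numpy as np

from mycoevo.rca import rca_profile
from mycoevo.seqio import parse_newick, translate
from mycoevo.simulate import SiteClassSpec, simulate_codon_alignment
from mycoevo.siterates import eb_site_rates


def balanced_tree(n, bl):
    labels = [f"t{i}" for i in range(n)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{bl}"
        m = len(ls) // 2
        return f"({build(ls[:m])},{build(ls[m:])}):{bl}"

    return parse_newick(f"({build(labels[:n//2])},{build(labels[n//2:])});")


tree = balanced_tree(12, 0.15)
multipliers = np.ones(200)
multipliers[79:100] = 6.0  # the engineered variable region
aln, truth = simulate_codon_alignment(
    tree, 200, SiteClassSpec([(0.5, 1.0)], rate_multipliers=multipliers),
    seed=0,
)

profile = eb_site_rates(translate(aln), tree)
rca = rca_profile(profile, window_n=7, intensity=0.5)

print(f"fitted gamma shape alpha = {profile.alpha:.2f}")
print(f"called {len(rca.peaks)} peak(s):")
for pk in rca.peaks:
    print(f"  {pk.label or '-':>4}  residues {pk.start}-{pk.end}  "
          f"max W = {pk.max_w:.2f}")
print("A peak overlapping residues 80-100 recovers the engineered "
      "fast-evolving block; W is the 7-residue mean of standardized "
      "rates, so W >= 0.5 marks runs about half an SD less conserved "
      "than the protein average.")
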