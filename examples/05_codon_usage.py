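"""Separate genes by codon-usage bias with correspondence analysis.

Builds two sets of synthetic CDS — one preferring GC-ending codons, one
preferring AT-ending codons (the signature that distinguishes a
horizontally transferred gene from its host genome) — and ordinates them
on the first two CA axes, plus a pairwise identity summary.
"""

import numpy as np

from mycoevo.seqio import Alignment, SequenceRecord
from mycoevo.usage import codon_counts, correspondence_analysis, pairwise_identity

rng = np.random.default_rng(0)
gc_codons = ["GCC", "GCG", "AAG", "GGC", "CTG", "TTC"]
at_codons = ["GCA", "GCT", "AAA", "GGT", "CTA", "TTT"]

records = []
for g in range(4):
    records.append(SequenceRecord(f"host{g}",
                                  "".join(rng.choice(gc_codons, 150))))
for g in range(4):
    records.append(SequenceRecord(f"transfer{g}",
                                  "".join(rng.choice(at_codons, 150))))

table = codon_counts(records)
ca = correspondence_analysis(table, k=2)
print("gene positions on CA axes 1-2:")
print(ca.to_frame().round(3).to_string(index=False))
print(f"axis inertias: {np.round(ca.inertias, 3)} "
      f"(of total {ca.total_inertia:.3f})")

rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(3)]
aln = Alignment(["a", "b", "c"], rows)
_, mean, sd = pairwise_identity(aln)
print(f"mean pairwise identity of three random sequences: "
      f"{mean:.1f} +/- {sd:.1f}%")
print("The two usage groups separate cleanly on axis 1: codon-usage "
      "bias alone distinguishes them, independent of protein sequence.")
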