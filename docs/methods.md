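# Methods

`mycoevo` implements a set of comparative molecular-evolution analyses of
the kind applied to fungal gene families whose members evolve under
contrasting selective regimes — for example chitinase genes expressed
during mycoparasitic attack.  This note documents the models, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Sequence and coordinate conventions

All coordinates are 1-based and inclusive.  A codon alignment requires
every row length to be a multiple of three, gaps only as whole `---`
triplets, and no internal stop codon under the universal genetic code; a
shared terminal stop column is silently dropped at translation.  Region
masks address either alignment columns or ungapped positions of a
designated reference row ("reference space", matching the way variable
repeat regions are reported against a reference strain); columns where
the reference is gapped cannot be addressed in reference space.
Ambiguity codes are allowed in input and are treated in every likelihood
as missing data (sum over compatible states).

## Site-rate estimation and reverse conservation analysis (RCA)

Per-column evolutionary rates on amino-acid alignments come from an
empirical-Bayes rate model: a reversible amino-acid process (JTT
exchangeabilities, by default with alignment-wide empirical frequencies)
whose branch lengths are scaled per site by a rate drawn from a
discretized gamma prior with mean 1 (default K = 16 equal-probability
categories, category means).  Column likelihoods use Felsenstein pruning,
vectorized over columns with per-column rescaling against underflow.  The
gamma shape `alpha` and a single overall tree-scale factor are estimated
jointly by bounded quasi-Newton maximization of the marginal likelihood;
the tree-scale frees the prior's unit mean from the units of the input
branch lengths (which may be neutral codon substitutions, amino-acid
replacements, or arbitrary).  The per-column posterior-mean rate is
reported together with its standardized form, the S score (mean 0, sample
SD 1 over scored columns; high = poorly conserved).  Columns with more
than 50% gaps are scored but flagged, and the flag propagates to the RCA
table.  If no tree is supplied one is built by neighbour-joining on
Poisson-corrected distances.

RCA then smooths the standardized scores with a centered sliding-window
mean (window n = 7 by default; edge windows shrink so every position gets
a value — an `edges="nan"` mode leaves partial windows undefined instead)
and calls peaks as maximal runs of positions with window mean at or above
an intensity threshold (default 0.5 SD; the boundary value counts as
significant).  Peaks are labelled with Roman numerals N-terminal to
C-terminal; only peaks spanning at least 3 residues receive labels, which
mirrors how multi-residue variable regions are reported, but the calls
themselves are unaffected.  Normalization precedes windowing.  Two
profiles on a shared coordinate frame are compared by flagging maximal
runs where exactly one profile is at or above the threshold; this is a
stated operationalization of "regions with different W mean score
distribution", not a claim of equivalence with any visual assessment.

## Random-effects-likelihood (REL) selection scan

Codon evolution follows an MG94-style model: substitution `i -> j` is
allowed only between sense codons differing at one nucleotide position,
with rate `rho(exchange) * pi_j * (dS if synonymous else dN)`.  The six
unordered nucleotide exchanges map onto named rate parameters through a
constraint table (one parameter fixed at 1 as reference), so both a
single-rate model and partly pooled reversible models are expressible;
two ready-made constraint maps cover the common cases "only C<->T has its
own rate" and "A<->G reference, pooled {A<->C, A<->T} and {C<->G, G<->T},
free C<->T".  Codon frequencies default to the F3x4 estimator, with
empirical codon frequencies as an option.

dN and dS are random effects: each is a three-point discrete distribution
(values and weights), and the product measure defines nine rate classes
per site.  The fit maximizes the mixture log-likelihood over the grid
values and weights, the free exchange rates, and a single tree-scale
factor; branch lengths are held proportional to the input tree.  This
scale-only treatment of branch lengths is a deliberate design choice: it
keeps the optimization low-dimensional and well conditioned, and on data
simulated with known branch lengths the scale factor absorbs the unit
mismatch exactly.  Identifiability is resolved by sorting values
ascending within each distribution and normalizing so the prior-mean
synonymous rate is 1.  Values are parameterized as cumulative sums of
exponentials (ascending by construction) and weights through a softmax;
optimization is L-BFGS-B with seeded jittered restarts (default 5; the
test and acceptance runs use 1–2 restarts, which on these problem sizes
reach the same optimum).  Class likelihoods reuse one eigendecomposition
of the pi-symmetrized generator per class and pattern-compressed pruning.

Per site, the empirical-Bayes posterior over the nine classes is
proportional to prior weight times class likelihood.  `P+` is the
posterior mass on classes with dN > dS (classes with |dN - dS| below 1e-9
count toward neither side), and the Bayes factor is posterior odds over
prior odds.  Sites are classified strong positive (BF+ >= 50), weak
positive (10 <= BF+ < 50), purifying (BF- >= 50), else neutral.  A prior
mass of exactly 0 or 1 makes the Bayes factor degenerate; the convention
is BF 0/infinity as appropriate.

A caveat established during validation: when the data contain a
nontrivial fraction of exactly-neutral sites, the fitted top dN class can
land marginally above the dS scale and a few high-substitution neutral
sites then reach BF >= 50.  This is inherent to the discretized
random-effects construction, not an implementation artifact; the
specificity experiment below quantifies it.  Relatedly, the individual
class values of the fitted grid are not identifiable when the generating
process is a single class — the MLE may spread dS into classes straddling
the mean while dN collapses — so grid-collapse checks are made on the
prior-mean ratio, which is stable (no detectable bias: omega-hat mean
1.03, SD 0.10 over six 500-codon replicates; 1.02 at 5000 codons).

## Co-evolving codon detection

A single-class ("global dN/dS") fit of the same codon model drives
marginal ancestral reconstruction at every internal node (inside-outside
message passing; ambiguity averaged).  For every branch and site the
method computes the joint parent–child posterior and from it the
probability that parent and child encode different amino acids — the
expected non-synonymous substitution indicator — which is binarized at
0.5 (raw expectations are exported for audit).  Sites with fewer than 3
non-synonymous branch events are discarded.

Over the retained sites a Bayesian network with in-degree at most 2 is
fitted: uniform prior over DAGs, Beta(1,1)–Bernoulli marginal likelihood
per node given its parent configuration.  Edge posteriors are estimated
by Metropolis–Hastings over structures (symmetric edge-toggle proposals
with acyclicity checks), two independent chains, 20% burn-in, with a
warning if the chains disagree by more than 0.1 on any edge.  Structure
MCMC was chosen over order-space sampling because the package's
correctness contract is agreement with exhaustive DAG enumeration under
the uniform-DAG prior (provided as an oracle for up to 7 sites), and
order sampling carries a known order-counting bias against that prior.
The association statistic for a pair is the posterior probability of an
edge in either direction; groups of co-evolving sites are connected
components of the association graph at threshold 0.5.

Under this prior and scoring, fully independent Bernoulli(0.2) columns
(10 sites x 40 branches) yield about 7% of pairs at posterior >= 0.5 —
the uniform structure prior is not sparse — so pair lists at the default
threshold should be read with that base rate in mind.

## Birth–death gene-family analysis

Family size evolves by a linear birth–death process with equal per-copy
birth and death rate `lam` (per gene per time unit; time in million years
for dated species trees).  The transition probability has the classical
closed form in `alpha = lam*t/(1+lam*t)`; it is evaluated by signed
log-space summation, and branches with `lam*t > 0.5` are split into equal
segments combined by the Chapman–Kolmogorov product over a truncated size
space (the alternating sum changes sign regime at alpha = 0.5).  Zero is
absorbing.  Family likelihoods prune over ancestral sizes 0..max_size
(max_size at least twice the largest observed count); the root prior is
uniform over 1..max_size.  All-zero families are excluded from rate
estimation.  `lam` is estimated by bounded 1-D search on the summed
log-likelihood; a table in which every family is constant across species
returns `lam = 0` with a degeneracy flag.

Family p-values are Monte-Carlo: the fraction of simulated null families
(root from the root prior, evolved under `lam`) whose likelihood is at
most the observed one, with an add-one correction.  Branch identification
uses the Viterbi (max-product) ancestral assignment; each branch gets (a)
an exceedance probability — the total probability, given the parent's
Viterbi size, of transitions no more likely than the observed one — and
(b) a likelihood ratio from refitting that branch's rate freely against
the global rate.  Branches are flagged at p <= 0.05 or ratio > 50.  When
a family is impossible under the global rate (for example `lam = 0` with
discordant counts) the Viterbi pass uses a vanishing positive rate so the
most parsimonious assignment is defined, and the likelihood-ratio flag is
restricted to branches whose own Viterbi transition violates the rate.

## Codon usage and identity

Codon-usage tables count the 61 sense codons per gene (terminal stops
tolerated, internal stops rejected).  Correspondence analysis is the
standard SVD of the chi-square standardized residuals of the
relative-frequency matrix; by default counts are first normalized within
genes ("usage frequencies"), making coordinates invariant to gene length;
raw-count and RSCU modes are available.  Axis signs are canonicalized
(largest-magnitude coordinate positive).  Methionine and tryptophan
codons are retained.  Percent nucleotide identity excludes positions
where either sequence of a pair is gapped; the summary is the mean and
sample SD over unordered pairs.

## Phylogenetics

Poisson-corrected distances `d = -ln(1 - p)` support complete or
pairwise deletion of gaps/missing data; a maximum-likelihood pairwise JTT
distance is provided as an alternative metric.  Neighbour-joining breaks
Q-matrix ties toward the lowest index pair (deterministic builds) and
clamps negative branch estimates to zero, transferring the deficit to the
sister branch so the joined pair's path length is preserved.  Bootstrap
support is the percentage of column-resampled replicates containing each
internal bipartition of the point tree.

## The synthetic-data generator

Codon alignments are simulated event-by-event (exact stochastic
simulation per branch) under the same MG94 structure the inference
assumes, with the generator normalized so a neutral site substitutes at
rate 1 at stationarity — branch lengths are then neutral substitutions
per codon.  Sites carry a dN/dS class drawn from a user mixture
(optionally pinned per site), plus an optional overall gamma rate
multiplier.  The root sequence is drawn from the stationary codon
distribution and every realized substitution is recorded, so downstream
detectors can be scored against exact ground truth.

Co-evolving pairs are engineered at the event level: a partner site's
non-synonymous rate is multiplied by the coupling factor from the moment
its driver sustains a non-synonymous substitution on a branch, until the
branch ends.  A pair listed in both orientations is simulated jointly
(two-site Gillespie) so the coupling is mutual — the natural model for
structurally interacting residues, and the regime in which
substitution-mapping detectors have usable power.  One-way coupling is
weaker by construction: the partner's window of elevated rate is only the
remainder of the branch, and amino-acid-level mapping further attenuates
it (multiple hits on a branch can cancel at the protein level).

Family-count tables evolve by event-level linear birth–death simulation
on a dated species tree, recording every internal node size.

What these simulations emulate: alignments of roughly 340–430 codons over
6–13 taxa at high nucleotide identity, with site classes under
purifying/neutral/positive selection, engineered co-evolving pairs, and
smooth regional conservation structure; and family-size vectors on dated
trees.  What they do not emulate: indels and alignment error, intron
misannotation, recombination, codon-usage selection, lineage-specific
rate shifts, and non-equilibrium base composition.  Passing recovery
tests on this generator shows the estimators are correct and powered
under their own assumptions; it does not certify performance on real
alignments where those assumptions fail.

## Study conditions used in tests and the acceptance script

Problem sizes were chosen once as representative desk-scale versions of
the analyses: selection-scan recovery uses 12 taxa x 400 codons with 10%
of sites at omega = 5 over a purifying-dominated background
(omega 0.1/0.5 at 50%/40%), and specificity uses 300-codon null runs
(omega 0.1/0.5/1.0 at 50%/40%/10%, six replicates in the test suite,
three in the acceptance script); co-evolution detection uses 30 taxa x 60
codons with a mutually coupled pair (coupling 30) and matched uncoupled
control sites (20 pipeline replicates in both the test suite and the
script; across 40 independent replicates the detection rate is 0.875); site-rate recovery uses 12 taxa x 400 sites with gamma(0.5)
multipliers; peak detection uses a 21-residue fast block on a 200-residue
background (20 and 10 replicates respectively); birth–death checks use a
three-species dated tree with the 180/10 million-year split structure,
200 families at lam = 0.002, Monte-Carlo kernels at 3000–4000 replicates,
and p-value calibration at 200 x 200 resamplings.

## Known limitations

- The REL fit optimizes a tree-scale factor, not individual branch
  lengths; trees whose relative branch lengths are badly wrong will
  propagate that error into site classification.
- Bayes-factor classification inherits the discretization artifacts noted
  above; borderline "strong" calls adjacent to a neutral background class
  deserve inspection of the fitted grid.
- The BGM's uniform structure prior is permissive; the enumeration oracle
  bounds MCMC error but not the base rate of spurious associations.
- The birth–death model assumes equal birth and death rates and a single
  rate for all branches and families; the branch likelihood-ratio test is
  a one-branch relaxation, not a multi-rate model.
- Correspondence analysis and identity summaries assume in-frame,
  stop-free CDS input; no frame repair is attempted.
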