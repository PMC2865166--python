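"""Detection of co-evolving codon sites.

Pipeline: fit a single-class (global dN/dS) codon model, reconstruct
marginal ancestral codon distributions, map the expected non-synonymous
substitution indicator onto every (branch, site) cell, retain sites with at
least ``min_subs`` non-synonymous branch events, and fit a Bayesian
graphical model (directed network, in-degree <= 2, uniform structure
prior, Beta(1,1)-Bernoulli node scores) over the retained sites.  The
association statistic for a pair is the posterior probability of an edge
in either direction; connected components of pairs at/above a threshold
form co-evolving groups.

Edge posteriors are estimated by Metropolis-Hastings over structures
(edge toggle / reversal moves); an exhaustive enumeration oracle is
provided for small networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import codons
from .relsel import NucModelSpec, RELFit, fit_rel
from .seqio import CodonAlignment

__all__ = [
    "BGMConfig",
    "SubstitutionMatrix",
    "EdgePosterior",
    "AncestralReconstruction",
    "global_dnds_fit",
    "reconstruct_ancestral",
    "map_nonsyn_substitutions",
    "filter_sites",
    "bgm_edge_posteriors",
    "enumerate_edge_posteriors",
    "group_coevolving",
]


@dataclass
class BGMConfig:
    max_parents: int = 2
    min_subs: int = 3
    chain_length: int = 100_000
    burn_in_fraction: float = 0.2
    n_chains: int = 2
    seed: int = 0
    edge_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0 < self.edge_threshold < 1:
            raise ValueError("edge_threshold must be in (0, 1)")


@dataclass
class SubstitutionMatrix:
    """Branch x site non-synonymous substitution indicators."""

    branch_ids: list[str]
    sites: np.ndarray            # 1-based codon positions
    binary: np.ndarray           # (n_branches, n_sites) in {0,1}
    expected: np.ndarray         # posterior expectation before binarization

    @property
    def counts(self) -> np.ndarray:
        """Per-site non-synonymous branch counts (column sums)."""
        return self.binary.sum(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.binary, index=self.branch_ids,
                          columns=[f"site{s}" for s in self.sites])
        df.to_csv(path, sep="\t")


@dataclass
class EdgePosterior:
    """Direction-marginalized association probabilities per site pair."""

    sites: list[int]
    probs: dict[frozenset, float]
    diagnostics: dict = field(default_factory=dict)

    def get(self, a: int, b: int) -> float:
        return self.probs.get(frozenset((a, b)), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(min(p), max(p), v) for p, v in self.probs.items()]
        rows.sort()
        return pd.DataFrame(rows, columns=["site1", "site2", "posterior"])


@dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    node_ids: list[str]
    # per node: (n_sites, 61) marginal posterior over codon states
    posteriors: dict[str, np.ndarray]
    # per branch (child node id): (n_sites,) P(parent aa != child aa)
    branch_nonsyn_prob: dict[str, np.ndarray]
    branch_ids: list[str]


def global_dnds_fit(aln: CodonAlignment, tree: dendropy.Tree,
                    spec: NucModelSpec | None = None, seed: int = 0) -> RELFit:
    """Single-class (global dN/dS) MG94 fit used for reconstruction."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_rel(aln, tree, spec=spec, bins=1, starts=2, seed=seed)


def _node_id(node, k: int) -> str:
    return node.taxon.label if node.taxon else f"node{k}"


_AA_GROUPS = [np.flatnonzero(codons.CODON_AA_ID == g)
              for g in range(codons.CODON_AA_ID.max() + 1)]


def reconstruct_ancestral(
    aln: CodonAlignment, tree: dendropy.Tree, fit: RELFit
) -> AncestralReconstruction:
    """Marginal ancestral codon posteriors at every internal node.

    Ambiguous or gapped leaf codons contribute a flat indicator (averaging
    over compatible states).  Also computes, for every branch, the
    posterior probability that parent and child encode different amino
    acids — the expected non-synonymous substitution indicator.
    """
    dn, ds = fit.grid.class_values()[0]
    q = codons.mg94_rate_matrix(fit.exch_rates, dn, ds, fit.codon_freqs)
    pi = fit.codon_freqs
    b = np.sqrt(pi)
    s = (q * b[:, None]) / b[None, :]
    lam, v = np.linalg.eigh((s + s.T) / 2)
    right, left = v / b[:, None], v * b[:, None]

    def pmat(t: float) -> np.ndarray:
        return np.clip(right @ (np.exp(lam * t * fit.tree_scale)[:, None] * left.T),
                       1e-300, None)

    n_sites = aln.length_codons
    nst = codons.N_CODONS
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    nodes = list(tree.preorder_node_iter())
    ids = {id(nd): _node_id(nd, k) for k, nd in enumerate(nodes)}

    below: dict[int, np.ndarray] = {}
    msg_up: dict[int, np.ndarray] = {}   # message from node to its parent
    pmats: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            st = np.empty(n_sites, dtype=np.int64)
            row = aln.rows[taxon_row[nd.taxon.label]]
            for k in range(n_sites):
                st[k] = codons.CODON_INDEX.get(row[3 * k : 3 * k + 3], -1)
            part = np.zeros((n_sites, nst))
            known = st >= 0
            part[~known, :] = 1.0
            part[known, st[known]] = 1.0
        else:
            part = np.ones((n_sites, nst))
            for child in nd.child_nodes():
                part = part * msg_up[id(child)]
            mx = part.max(axis=1, keepdims=True)
            part = part / np.where(mx > 0, mx, 1.0)
        below[id(nd)] = part
        if nd.parent_node is not None:
            t = nd.edge.length if nd.edge.length is not None else 0.0
            p = pmat(t)
            pmats[id(nd)] = p
            msg_up[id(nd)] = part @ p.T

    above: dict[int, np.ndarray] = {id(tree.seed_node): np.tile(pi, (n_sites, 1))}
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            ctx = above[id(nd)].copy()
            for sib in nd.child_nodes():
                if sib is not child:
                    ctx *= msg_up[id(sib)]
            a = ctx @ pmats[id(child)]
            mx = a.max(axis=1, keepdims=True)
            above[id(child)] = a / np.where(mx > 0, mx, 1.0)

    posteriors: dict[str, np.ndarray] = {}
    for nd in nodes:
        post = above[id(nd)] * below[id(nd)]
        post = post / post.sum(axis=1, keepdims=True)
        posteriors[ids[id(nd)]] = post

    branch_nonsyn: dict[str, np.ndarray] = {}
    branch_ids: list[str] = []
    for nd in nodes:
        if nd.parent_node is None:
            continue
        par = nd.parent_node
        ctx = above[id(par)].copy()
        for sib in par.child_nodes():
            if sib is not nd:
                ctx *= msg_up[id(sib)]
        p = pmats[id(nd)]
        bpart = below[id(nd)]
        full = ((ctx @ p) * bpart).sum(axis=1)
        same = np.zeros(n_sites)
        for g in _AA_GROUPS:
            same += ((ctx[:, g] @ p[np.ix_(g, g)]) * bpart[:, g]).sum(axis=1)
        bid = f"b_{ids[id(nd)]}"
        branch_ids.append(bid)
        with np.errstate(invalid="ignore"):
            branch_nonsyn[bid] = 1.0 - np.clip(same / np.clip(full, 1e-300, None),
                                               0.0, 1.0)
    return AncestralReconstruction(
        tree=tree, node_ids=[ids[id(nd)] for nd in nodes],
        posteriors=posteriors, branch_nonsyn_prob=branch_nonsyn,
        branch_ids=branch_ids,
    )


def map_nonsyn_substitutions(recon: AncestralReconstruction) -> SubstitutionMatrix:
    """Binarize expected non-synonymous indicators at 0.5 per (branch, site)."""
    expected = np.stack([recon.branch_nonsyn_prob[b] for b in recon.branch_ids])
    binary = (expected >= 0.5).astype(np.int64)
    sites = np.arange(1, expected.shape[1] + 1)
    return SubstitutionMatrix(list(recon.branch_ids), sites, binary, expected)


def filter_sites(matrix: SubstitutionMatrix, min_subs: int = 3) -> list[int]:
    """Sites with at least ``min_subs`` non-synonymous branch events."""
    counts = matrix.counts
    return [int(s) for s, c in zip(matrix.sites, counts) if c >= min_subs]


# ---------------------------------------------------------------------------
# Bayesian-network scoring and posterior estimation
# ---------------------------------------------------------------------------

def _node_score(x: np.ndarray, i: int, parents: tuple[int, ...]) -> float:
    """Beta(1,1)-Bernoulli marginal log-likelihood of column i given its
    parent configuration counts."""
    child = x[:, i]
    if parents:
        cfg = np.zeros(x.shape[0], dtype=np.int64)
        for p in parents:
            cfg = cfg * 2 + x[:, p]
        ncfg = 2 ** len(parents)
    else:
        cfg = np.zeros(x.shape[0], dtype=np.int64)
        ncfg = 1
    score = 0.0
    for c in range(ncfg):
        sel = cfg == c
        n = int(sel.sum())
        if n == 0:
            continue
        n1 = int(child[sel].sum())
        n0 = n - n1
        score += gammaln(n1 + 1) + gammaln(n0 + 1) - gammaln(n + 2)
    return float(score)


class _ScoreCache:
    def __init__(self, x: np.ndarray):
        self.x = x
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, i: int, parents: frozenset) -> float:
        key = (i, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = _node_score(self.x, i, key[1])
        return self._cache[key]


def _has_path(parents: list[set[int]], src: int, dst: int) -> bool:
    """True if dst is reachable from src following child->parent? No:
    parents[i] holds the parents of i; an edge p -> i exists for p in
    parents[i].  Path src ~> dst along directed edges."""
    stack = [src]
    seen = {src}
    children = {k: [] for k in range(len(parents))}
    for child, ps in enumerate(parents):
        for p in ps:
            children[p].append(child)
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _mcmc_chain(x: np.ndarray, n_nodes: int, config: BGMConfig,
                rng: np.random.Generator) -> np.ndarray:
    score = _ScoreCache(x)
    parents: list[set[int]] = [set() for _ in range(n_nodes)]
    node_sc = np.array([score(i, frozenset()) for i in range(n_nodes)])
    burn = int(config.chain_length * config.burn_in_fraction)
    acc = np.zeros((n_nodes, n_nodes))
    n_samples = 0
    for step in range(config.chain_length):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        # toggle edge j -> i (symmetric proposal)
        if j in parents[i]:
            new_par = parents[i] - {j}
            ok = True
        else:
            new_par = parents[i] | {j}
            ok = len(new_par) <= config.max_parents and not _has_path(
                parents, i, j
            )
        if ok:
            new_sc = score(i, frozenset(new_par))
            if np.log(rng.random()) < new_sc - node_sc[i]:
                parents[i] = new_par
                node_sc[i] = new_sc
        if step >= burn:
            n_samples += 1
            for a in range(n_nodes):
                for p in parents[a]:
                    acc[min(a, p), max(a, p)] += 1
    return acc / max(n_samples, 1)


def bgm_edge_posteriors(
    matrix: SubstitutionMatrix,
    retained_sites: list[int] | None = None,
    config: BGMConfig | None = None,
) -> EdgePosterior:
    """Posterior edge probabilities by MCMC over network structures.

    ``retained_sites`` defaults to :func:`filter_sites` at the config's
    ``min_subs``.  Runs ``n_chains`` independent chains and warns if any
    edge's estimates disagree by more than 0.1.
    """
    config = config or BGMConfig()
    if retained_sites is None:
        retained_sites = filter_sites(matrix, config.min_subs)
    if len(retained_sites) < 2:
        raise ValueError("no BGM-eligible sites: fewer than 2 sites retained")
    site_idx = {int(s): k for k, s in enumerate(matrix.sites)}
    x = matrix.binary[:, [site_idx[s] for s in retained_sites]]
    n = x.shape[1]
    rng = np.random.default_rng(config.seed)
    chains = [
        _mcmc_chain(x, n, config, np.random.default_rng(rng.integers(2**31)))
        for _ in range(config.n_chains)
    ]
    mean = np.mean(chains, axis=0)
    spread = np.max(np.abs(np.max(chains, axis=0) - np.min(chains, axis=0)))
    diagnostics = {"max_chain_disagreement": float(spread),
                   "n_chains": config.n_chains,
                   "chain_length": config.chain_length}
    if spread > 0.1:
        warnings.warn(
            f"BGM chains disagree by up to {spread:.2f} on some edge; "
            "consider longer chains", stacklevel=2,
        )
    probs = {}
    for a in range(n):
        for b in range(a + 1, n):
            probs[frozenset((retained_sites[a], retained_sites[b]))] = float(
                mean[a, b]
            )
    return EdgePosterior(list(retained_sites), probs, diagnostics)


def enumerate_edge_posteriors(
    matrix: SubstitutionMatrix,
    retained_sites: list[int],
    max_parents: int = 2,
) -> EdgePosterior:
    """Exact edge posteriors by exhaustive enumeration of all DAGs with
    bounded in-degree (feasible for up to ~6 sites)."""
    site_idx = {int(s): k for k, s in enumerate(matrix.sites)}
    x = matrix.binary[:, [site_idx[s] for s in retained_sites]]
    n = x.shape[1]
    if n > 7:
        raise ValueError("enumeration oracle limited to 7 sites")
    score = _ScoreCache(x)
    others = {i: [j for j in range(n) if j != i] for i in range(n)}
    psets: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    for i in range(n):
        entries = []
        for k in range(max_parents + 1):
            for combo in itertools.combinations(others[i], k):
                entries.append((combo, score(i, frozenset(combo))))
        psets[i] = entries

    log_weights: list[float] = []
    edge_logw: dict[tuple[int, int], list[float]] = {
        (a, b): [] for a in range(n) for b in range(a + 1, n)
    }
    for assignment in itertools.product(*(psets[i] for i in range(n))):
        parents = [set(assignment[i][0]) for i in range(n)]
        # acyclicity via Kahn's algorithm
        indeg = [len(p) for p in parents]
        children = {k: [] for k in range(n)}
        for child, ps in enumerate(parents):
            for p in ps:
                children[p].append(child)
        queue = [k for k in range(n) if indeg[k] == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for w in children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != n:
            continue
        lw = sum(a[1] for a in assignment)
        log_weights.append(lw)
        for a in range(n):
            for p in parents[a]:
                edge_logw[(min(a, p), max(a, p))].append(lw)
    total = logsumexp(log_weights)
    probs = {}
    for (a, b), lws in edge_logw.items():
        pr = float(np.exp(logsumexp(lws) - total)) if lws else 0.0
        probs[frozenset((retained_sites[a], retained_sites[b]))] = pr
    return EdgePosterior(list(retained_sites), probs, {"exact": True})


def group_coevolving(edges: EdgePosterior, threshold: float = 0.5) -> list[set[int]]:
    """Connected components of the association graph at ``threshold``."""
    g = nx.Graph()
    for pair, p in edges.probs.items():
        if p >= threshold:
            a, b = tuple(pair)
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]
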