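"""Empirical-Bayes per-site evolutionary rates on amino-acid alignments.

The model is a reversible amino-acid substitution process (JTT by default,
optionally with empirical frequencies) whose branch lengths are scaled per
site by a rate drawn from a discretized gamma prior with mean 1.  The
posterior-mean rate per column and its standardized form (the S score:
high = poorly conserved) feed the reverse conservation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import jtt
from .seqio import Alignment

__all__ = [
    "AAModel",
    "SiteRateProfile",
    "gamma_categories",
    "column_likelihood",
    "eb_site_rates",
]


class AAModel:
    """Reversible amino-acid model with cached eigendecomposition."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.q = q
        self.pi = pi
        b = np.sqrt(pi)
        s = (q * b[:, None]) / b[None, :]
        lam, v = np.linalg.eigh((s + s.T) / 2)
        self._lam = lam
        self._left = v * b[:, None]   # P(t) = right @ (exp(lam t) * left.T)
        self._right = v / b[:, None]

    @classmethod
    def jtt(cls, freqs: np.ndarray | None = None) -> "AAModel":
        return cls(*jtt.rate_matrix(freqs))

    def prob(self, t: float) -> np.ndarray:
        """Transition matrix ``expm(Q t)`` (clipped to be non-negative)."""
        p = self._right @ (np.exp(self._lam * t)[:, None] * self._left.T)
        return np.clip(p, 0.0, None)


@dataclass
class SiteRateProfile:
    """Per-column posterior-mean rates and standardized S scores."""

    columns: np.ndarray          # 1-based alignment columns
    reference_positions: np.ndarray  # 1-based reference positions (-1 = gap in ref)
    rates: np.ndarray            # posterior-mean rate per column
    s_scores: np.ndarray         # standardized rates, mean 0 sd 1
    gap_flags: np.ndarray        # True where > 50% of rows are gaps
    alpha: float                 # fitted gamma shape

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\treference_position\trate\tS\tgap_flag\n")
            for c, rp, r, s, g in zip(self.columns, self.reference_positions,
                                      self.rates, self.s_scores, self.gap_flags):
                fh.write(f"{c}\t{rp}\t{r:.6g}\t{s:.6g}\t{int(g)}\n")


def gamma_categories(alpha: float, k: int) -> np.ndarray:
    """Means of ``k`` equal-probability categories of Gamma(alpha, mean 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    return np.clip(k * (upper - lower), 1e-8, None)


def _encode(aln: Alignment) -> np.ndarray:
    """(n_taxa, n_cols) state ids; -1 for gaps/ambiguity."""
    out = np.full((aln.n_taxa, aln.length), -1, dtype=np.int64)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            out[r, c] = jtt.AA_INDEX.get(ch, -1)
    return out


def _site_log_likelihoods(
    states: np.ndarray,
    taxa: list[str],
    tree: dendropy.Tree,
    model: AAModel,
    rate: float,
) -> np.ndarray:
    """Log-likelihood of every column at a single rate (Felsenstein pruning,
    vectorized over columns, with per-column rescaling)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    taxon_row = {t: i for i, t in enumerate(taxa)}
    ncols = states.shape[1]
    nstate = len(model.pi)
    log_scale = np.zeros(ncols)

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in taxon_row:
                raise ValueError(f"tree leaf {lab!r} missing from alignment")
            st = states[taxon_row[lab]]
            part = np.zeros((ncols, nstate))
            known = st >= 0
            part[~known, :] = 1.0  # gap/ambiguity: sum over all states
            part[known, st[known]] = 1.0
            return part
        nonlocal log_scale
        part = np.ones((ncols, nstate))
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            pmat = model.prob(rate * t)
            part = part * (partial(child) @ pmat.T)
        mx = part.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        log_scale += np.log(mx)
        return part / mx[:, None]

    root_part = partial(tree.seed_node)
    lik = root_part @ model.pi
    return np.log(np.clip(lik, 1e-300, None)) + log_scale


def column_likelihood(
    column: dict[str, str],
    tree: dendropy.Tree,
    rate: float,
    model: AAModel | None = None,
) -> float:
    """Likelihood of a single column (mapping taxon -> residue)."""
    model = model or AAModel.jtt()
    taxa = list(column)
    states = np.array(
        [[jtt.AA_INDEX.get(column[t], -1)] for t in taxa], dtype=np.int64
    )
    return float(np.exp(_site_log_likelihoods(states, taxa, tree, model, rate)[0]))


def eb_site_rates(
    aln: Alignment,
    tree: dendropy.Tree | None = None,
    model: AAModel | None = None,
    k: int = 16,
    alpha: float | None = None,
) -> SiteRateProfile:
    """Empirical-Bayes posterior-mean rate and S score per column.

    The gamma shape is estimated by maximizing the marginal likelihood
    ``sum_i log sum_cat w L_i(r_cat)`` unless ``alpha`` is given.  If no
    tree is supplied one is built internally by neighbour-joining on
    Poisson distances.
    """
    if k < 2:
        raise ValueError("constant rates: need at least 2 rate categories")
    if model is None:
        freqs = _empirical_aa_freqs(aln)
        model = AAModel.jtt(freqs)
    if tree is None:
        from .phylo import nj, poisson_distance

        tree = nj(poisson_distance(aln, deletion="pairwise"))
    tree_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not tree_taxa.issubset(set(aln.taxa)):
        raise ValueError("tree/alignment taxon mismatch")
    states = _encode(aln)

    def marginal(avalue: float, scale: float) -> tuple[float, np.ndarray, np.ndarray]:
        rates = gamma_categories(avalue, k)
        ll = np.stack([
            _site_log_likelihoods(states, aln.taxa, tree, model, r * scale)
            for r in rates
        ])  # (k, ncols)
        mx = ll.max(axis=0)
        lik = np.exp(ll - mx)          # weights are uniform 1/k
        marg = float((np.log(lik.mean(axis=0)) + mx).sum())
        post = lik / lik.sum(axis=0)
        rhat = (rates[:, None] * post).sum(axis=0)
        return marg, rhat, post

    # a free overall branch-scale factor decouples the gamma prior's unit
    # mean from the units of the input branch lengths
    tree_scale = 1.0
    if alpha is None:
        from scipy.optimize import minimize

        def objective(x: np.ndarray) -> float:
            val = marginal(float(np.exp(x[0])), float(np.exp(x[1])))[0]
            return -val if np.isfinite(val) else 1e12

        res = minimize(
            objective, x0=np.array([0.0, 0.0]), method="L-BFGS-B",
            bounds=[(np.log(0.02), np.log(50.0)), (np.log(1e-3), np.log(1e3))],
        )
        alpha = float(np.exp(res.x[0]))
        tree_scale = float(np.exp(res.x[1]))
    _, rhat, _ = marginal(alpha, tree_scale)

    sd = rhat.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("constant rates: S scores undefined")
    s = (rhat - rhat.mean()) / sd
    gap_flags = (states < 0).mean(axis=0) > 0.5
    refpos = np.full(aln.length, -1, dtype=np.int64)
    if aln.reference_taxon is not None:
        for pos, col in aln.reference_to_columns().items():
            refpos[col - 1] = pos
    return SiteRateProfile(
        columns=np.arange(1, aln.length + 1),
        reference_positions=refpos,
        rates=rhat,
        s_scores=s,
        gap_flags=gap_flags,
        alpha=alpha,
    )


def _empirical_aa_freqs(aln: Alignment) -> np.ndarray:
    counts = np.full(20, 0.5)
    for row in aln.rows:
        for ch in row:
            i = jtt.AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()
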