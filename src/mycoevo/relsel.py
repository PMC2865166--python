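"""Random-effects-likelihood (REL) scan for site-level selection.

dN and dS are each fitted as a three-point discrete distribution (values +
weights), whose product measure defines nine dN/dS rate classes.  Codon
evolution within a class follows an MG94-style model built on a constrained
reversible nucleotide model (exchange classes may share named rate
parameters, one fixed to 1 as reference).  After fitting, each site gets an
empirical-Bayes posterior over the nine classes, the posterior probability
that dN > dS, and a Bayes factor; sites are classified as under strong
(BF >= 50) or weak (10 <= BF < 50) positive selection, purifying selection,
or neutral evolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import codons
from .seqio import CodonAlignment

__all__ = [
    "NucModelSpec",
    "RateClassGrid",
    "RELFit",
    "SiteSelectionResult",
    "build_codon_model",
    "fit_rel",
    "site_bayes_factor",
]

_OMEGA_TIE_TOL = 1e-9


@dataclass
class NucModelSpec:
    """Constraint map from the six nucleotide exchanges to rate parameters.

    ``mapping`` assigns each unordered exchange (``AC, AG, AT, CG, CT, GT``)
    a parameter name; every exchange whose name equals ``reference`` has
    rate fixed to 1.
    """

    mapping: dict[str, str]
    reference: str = "ref"

    def __post_init__(self) -> None:
        missing = set(codons.EXCHANGES) - set(self.mapping)
        if missing:
            raise ValueError(f"exchanges not mapped: {sorted(missing)}")
        if self.reference not in self.mapping.values():
            raise ValueError("no exchange maps to the reference parameter")

    @property
    def free_params(self) -> list[str]:
        seen: list[str] = []
        for ex in codons.EXCHANGES:
            name = self.mapping[ex]
            if name != self.reference and name not in seen:
                seen.append(name)
        return seen

    def rates(self, values: dict[str, float]) -> np.ndarray:
        """6-vector of exchange rates given free-parameter values."""
        out = np.empty(6)
        for k, ex in enumerate(codons.EXCHANGES):
            name = self.mapping[ex]
            out[k] = 1.0 if name == self.reference else values[name]
        return out

    @classmethod
    def single_rate(cls) -> "NucModelSpec":
        return cls({ex: "ref" for ex in codons.EXCHANGES})

    @classmethod
    def rev(cls) -> "NucModelSpec":
        """Fully general reversible model, A<->G as reference."""
        return cls({ex: ("ref" if ex == "AG" else f"R_{ex}")
                    for ex in codons.EXCHANGES})

    @classmethod
    def ct_only(cls) -> "NucModelSpec":
        """All exchanges at the reference rate except C<->T (own R_CT)."""
        return cls({ex: ("R_CT" if ex == "CT" else "ref")
                    for ex in codons.EXCHANGES})

    @classmethod
    def shared_transversions(cls) -> "NucModelSpec":
        """A<->G reference; {A<->C, A<->T} share R_AC; {C<->G, G<->T} share
        R_CG; C<->T has its own R_CT."""
        return cls({"AG": "ref", "AC": "R_AC", "AT": "R_AC",
                    "CG": "R_CG", "GT": "R_CG", "CT": "R_CT"})


@dataclass
class RateClassGrid:
    """3 x 3 (generally bins x bins) product grid of dN and dS classes."""

    dn_values: np.ndarray
    dn_weights: np.ndarray
    ds_values: np.ndarray
    ds_weights: np.ndarray

    def __post_init__(self) -> None:
        for arr in ("dn_values", "dn_weights", "ds_values", "ds_weights"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if abs(self.dn_weights.sum() - 1) > 1e-8 or abs(self.ds_weights.sum() - 1) > 1e-8:
            raise ValueError("weights must sum to 1")
        if np.any(self.dn_values < 0) or np.any(self.ds_values < 0):
            raise ValueError("rate values must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.dn_values.size * self.ds_values.size

    def class_weights(self) -> np.ndarray:
        """Flattened prior weights, dN-major (class k = (a, b) -> a*bins+b)."""
        return np.outer(self.dn_weights, self.ds_weights).ravel()

    def class_values(self) -> list[tuple[float, float]]:
        return [(float(dn), float(ds))
                for dn in self.dn_values for ds in self.ds_values]

    def positive_mask(self) -> np.ndarray:
        return np.array([dn > ds + _OMEGA_TIE_TOL for dn, ds in self.class_values()])

    def negative_mask(self) -> np.ndarray:
        return np.array([ds > dn + _OMEGA_TIE_TOL for dn, ds in self.class_values()])


@dataclass
class RELFit:
    grid: RateClassGrid
    spec: NucModelSpec
    exch_rates: np.ndarray
    codon_freqs: np.ndarray
    tree_scale: float
    log_likelihood: float
    converged: bool
    n_starts: int
    message: str = ""
    site_class_loglik: np.ndarray | None = None  # (n_classes, n_sites)

    def summary(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood,
            "tree_scale": self.tree_scale,
            "dn_values": self.grid.dn_values.tolist(),
            "dn_weights": self.grid.dn_weights.tolist(),
            "ds_values": self.grid.ds_values.tolist(),
            "ds_weights": self.grid.ds_weights.tolist(),
            "exchange_rates": dict(zip(codons.EXCHANGES,
                                       self.exch_rates.tolist())),
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


@dataclass
class SiteSelectionResult:
    sites: np.ndarray                # 1-based codon positions
    posterior_positive: np.ndarray
    prior_positive: float
    bayes_factor_positive: np.ndarray
    bayes_factor_negative: np.ndarray
    classification: list[str]
    posterior_by_class: np.ndarray   # (n_sites, n_classes)
    reference_positions: np.ndarray | None = None  # -1 where ref is gapped

    def to_frame(self) -> pd.DataFrame:
        refpos = (self.reference_positions
                  if self.reference_positions is not None
                  else np.full(self.sites.size, -1))
        return pd.DataFrame({
            "site": self.sites,
            "reference_position": refpos,
            "posterior_positive": self.posterior_positive,
            "bf_positive": self.bayes_factor_positive,
            "bf_negative": self.bayes_factor_negative,
            "class": self.classification,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_codon_model(spec_rates, dn: float, ds: float, codon_freqs) -> np.ndarray:
    """61 x 61 MG94 generator for one (dN, dS) class."""
    return codons.mg94_rate_matrix(spec_rates, dn, ds, codon_freqs)


class _CodonPruner:
    """Pattern-compressed pruning engine for one alignment + tree."""

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree):
        tree_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if not tree_taxa == set(aln.taxa):
            raise ValueError("tree/alignment taxon mismatch")
        self.tree = tree
        self.n_sites = aln.length_codons
        states = np.empty((aln.n_taxa, self.n_sites), dtype=np.int64)
        for k in range(1, self.n_sites + 1):
            states[:, k - 1] = codons.encode_column(aln.rows, k)
        pats, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = pats            # (n_taxa, n_pat)
        self.pattern_of_site = inverse
        self.counts = counts.astype(float)
        self.taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self.postorder = list(tree.postorder_node_iter())
        self.edge_lengths = {
            id(nd): (nd.edge.length if nd.edge.length is not None else 0.0)
            for nd in self.postorder
        }

    def pattern_loglik(self, q: np.ndarray, pi: np.ndarray,
                       scale: float) -> np.ndarray:
        """Per-pattern log-likelihood under generator ``q`` with branch
        lengths multiplied by ``scale``."""
        b = np.sqrt(pi)
        s = (q * b[:, None]) / b[None, :]
        lam, v = np.linalg.eigh((s + s.T) / 2)
        right = v / b[:, None]
        left = v * b[:, None]
        npat = self.patterns.shape[1]
        nst = codons.N_CODONS
        log_scale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        for nd in self.postorder:
            if nd.is_leaf():
                st = self.patterns[self.taxon_row[nd.taxon.label]]
                part = np.zeros((npat, nst))
                known = st >= 0
                part[~known, :] = 1.0
                part[known, st[known]] = 1.0
            else:
                part = np.ones((npat, nst))
                for child in nd.child_nodes():
                    t = self.edge_lengths[id(child)] * scale
                    pmat = np.clip(
                        right @ (np.exp(lam * t)[:, None] * left.T), 0.0, None
                    )
                    part = part * (partials.pop(id(child)) @ pmat.T)
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                log_scale += np.log(mx)
                part = part / mx[:, None]
            partials[id(nd)] = part
        root = partials[id(self.postorder[-1])]
        lik = root @ pi
        return np.log(np.clip(lik, 1e-300, None)) + log_scale

    def class_logliks(self, grid: RateClassGrid, exch: np.ndarray,
                      pi: np.ndarray, scale: float) -> np.ndarray:
        """(n_classes, n_sites) site log-likelihood per rate class."""
        out = np.empty((grid.n_classes, self.patterns.shape[1]))
        for k, (dn, ds) in enumerate(grid.class_values()):
            q = codons.mg94_rate_matrix(exch, dn, ds, pi)
            out[k] = self.pattern_loglik(q, pi, scale)
        return out[:, self.pattern_of_site]

    def mixture_loglik(self, grid, exch, pi, scale) -> float:
        ll = self.class_logliks(grid, exch, pi, scale)
        lw = np.log(np.clip(grid.class_weights(), 1e-300, None))
        return float(logsumexp(ll + lw[:, None], axis=0).sum())


def _unpack(theta: np.ndarray, bins: int, n_free: int):
    """theta -> (free exch values, grid, scale); dS is normalized so the
    prior-mean synonymous rate is 1, resolving the rate/branch-length
    scale confound."""
    k = 0
    exch_vals = np.exp(theta[k : k + n_free]); k += n_free
    dn = np.cumsum(np.exp(theta[k : k + bins])); k += bins
    if bins > 1:
        wn = _softmax(theta[k : k + bins - 1]); k += bins - 1
        ds = np.cumsum(np.concatenate([[1.0], np.exp(theta[k : k + bins - 1])]))
        k += bins - 1
        ws = _softmax(theta[k : k + bins - 1]); k += bins - 1
    else:
        wn = np.array([1.0])
        ds = np.array([1.0])
        ws = np.array([1.0])
    scale = float(np.exp(theta[k])); k += 1
    mean_ds = float(np.dot(ws, ds))
    grid = RateClassGrid(dn / mean_ds, wn, ds / mean_ds, ws)
    return exch_vals, grid, scale


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.concatenate([x, [0.0]])
    z = np.exp(z - z.max())
    return z / z.sum()


def fit_rel(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    spec: NucModelSpec | None = None,
    bins: int = 3,
    starts: int = 5,
    seed: int = 0,
    codon_freqs: np.ndarray | str = "f3x4",
    maxiter: int = 200,
) -> RELFit:
    """Fit the REL model by maximum likelihood.

    Branch lengths are held proportional to the input tree with a single
    free tree-scale factor; the dS distribution is normalized to prior mean
    1.  ``starts`` seeded jittered restarts guard against local optima.
    """
    spec = spec or NucModelSpec.single_rate()
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if aln.n_taxa < 10:
        warnings.warn(
            f"only {aln.n_taxa} sequences; at least 10 are recommended for a "
            "reliable REL fit", stacklevel=2,
        )
    if isinstance(codon_freqs, str):
        if codon_freqs == "f3x4":
            pi = codons.f3x4_frequencies(aln.rows)
        elif codon_freqs == "empirical":
            pi = codons.empirical_codon_frequencies(aln.rows)
        else:
            raise ValueError(f"unknown codon frequency mode {codon_freqs!r}")
    else:
        pi = np.asarray(codon_freqs, float)
    pruner = _CodonPruner(aln, tree)
    n_free = len(spec.free_params)
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        try:
            exch_vals, grid, scale = _unpack(theta, bins, n_free)
            exch = spec.rates(dict(zip(spec.free_params, exch_vals)))
            ll = pruner.class_logliks(grid, exch, pi, scale)
            lw = np.log(np.clip(grid.class_weights(), 1e-300, None))
            val = logsumexp(ll + lw[:, None], axis=0).sum()
            if not np.isfinite(val):
                return 1e12
            return -float(val)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    # initial point: dN spread below/around/above the dS scale, even weights
    if bins > 1:
        init = np.concatenate([
            np.zeros(n_free),
            np.log(np.array([0.1, 0.4, 1.0])[:bins]),   # dN increments
            np.zeros(bins - 1),
            np.log(np.full(bins - 1, 1.0)),             # dS increments
            np.zeros(bins - 1),
            [0.0],                                       # log tree scale
        ])
    else:
        init = np.concatenate([np.zeros(n_free), [np.log(0.5)], [0.0]])

    best = None
    for s in range(max(1, starts)):
        x0 = init if s == 0 else init + rng.normal(0, 0.5, size=init.size)
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("REL fit failed to converge in all starts")

    exch_vals, grid, scale = _unpack(best.x, bins, n_free)
    exch = spec.rates(dict(zip(spec.free_params, exch_vals)))
    site_ll = pruner.class_logliks(grid, exch, pi, scale)
    return RELFit(
        grid=grid, spec=spec, exch_rates=exch, codon_freqs=pi,
        tree_scale=scale, log_likelihood=-float(best.fun),
        converged=bool(best.success), n_starts=max(1, starts),
        message=str(best.message), site_class_loglik=site_ll,
    )


def site_bayes_factor(
    fit: RELFit,
    aln: CodonAlignment | None = None,
    tree: dendropy.Tree | None = None,
    bf_strong: float = 50.0,
    bf_weak: float = 10.0,
) -> SiteSelectionResult:
    """Per-site empirical-Bayes selection classification.

    Uses the per-class site likelihoods stored in the fit (recomputing them
    if an alignment and tree are supplied).  The Bayes factor is the
    posterior odds of dN > dS over the prior odds; by convention a prior of
    exactly 0 or 1 yields BF 0/inf and the site is classified from the
    posterior alone.
    """
    if fit.site_class_loglik is None:
        if aln is None or tree is None:
            raise ValueError("fit carries no site likelihoods; pass aln and tree")
        pruner = _CodonPruner(aln, tree)
        site_ll = pruner.class_logliks(fit.grid, fit.exch_rates,
                                       fit.codon_freqs, fit.tree_scale)
    else:
        site_ll = fit.site_class_loglik
    w = fit.grid.class_weights()
    lw = np.log(np.clip(w, 1e-300, None))
    log_post = site_ll + lw[:, None]
    log_post -= logsumexp(log_post, axis=0)
    post = np.exp(log_post)            # (n_classes, n_sites)

    pos_mask = fit.grid.positive_mask()
    neg_mask = fit.grid.negative_mask()
    prior_pos = float(w[pos_mask].sum())
    prior_neg = float(w[neg_mask].sum())
    post_pos = post[pos_mask].sum(axis=0)
    post_neg = post[neg_mask].sum(axis=0)

    def odds_ratio(p_post: np.ndarray, p_prior: float) -> np.ndarray:
        if p_prior <= 0.0:
            return np.where(p_post > 0, np.inf, 0.0)
        if p_prior >= 1.0:
            return np.where(p_post < 1, 0.0, 1.0)
        prior_odds = p_prior / (1.0 - p_prior)
        with np.errstate(divide="ignore"):
            post_odds = p_post / np.clip(1.0 - p_post, 1e-300, None)
        return post_odds / prior_odds

    bf_pos = odds_ratio(post_pos, prior_pos)
    bf_neg = odds_ratio(post_neg, prior_neg)
    classes = []
    for bp, bn in zip(bf_pos, bf_neg):
        if bp >= bf_strong:
            classes.append("positive_strong")
        elif bp >= bf_weak:
            classes.append("positive_weak")
        elif bn >= bf_strong:
            classes.append("purifying")
        else:
            classes.append("neutral")
    n_sites = site_ll.shape[1]
    refpos = None
    if aln is not None and aln.reference_taxon is not None:
        refpos = np.full(n_sites, -1, dtype=np.int64)
        for pos, col in aln.reference_to_codons().items():
            refpos[col - 1] = pos
    return SiteSelectionResult(
        sites=np.arange(1, n_sites + 1),
        posterior_positive=post_pos,
        prior_positive=prior_pos,
        bayes_factor_positive=bf_pos,
        bayes_factor_negative=bf_neg,
        classification=classes,
        posterior_by_class=post.T,
        reference_positions=refpos,
    )
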