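"""Distance-based phylogeny reconstruction with bootstrap support.

Implements Poisson-corrected and JTT maximum-likelihood pairwise distances
on amino-acid alignments, neighbour-joining with deterministic tie-breaking,
and non-parametric bootstrap support for the internal bipartitions of a
point-estimate tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt
from .seqio import Alignment, parse_newick

__all__ = [
    "DistanceMatrix",
    "UndefinedDistanceError",
    "poisson_distance",
    "jtt_distance",
    "nj",
    "bootstrap_support",
]

_MISSING = set("-X?.")


class UndefinedDistanceError(ValueError):
    """A pairwise distance is undefined (saturation or no shared columns)."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("entries must be finite and non-negative")
        self.matrix = m

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.matrix):
                fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _p_distances(aln: Alignment, deletion: str) -> np.ndarray:
    """Proportion of differing residues per pair under a deletion rule."""
    if deletion not in ("complete", "pairwise"):
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    rows = aln.rows
    n = len(rows)
    cols = np.array([[c for c in r] for r in rows])
    missing = np.isin(cols, list(_MISSING))
    if deletion == "complete":
        keep = ~missing.any(axis=0)
        cols = cols[:, keep]
        missing = missing[:, keep]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(missing[i] | missing[j])
            m = int(ok.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns for pair ({aln.taxa[i]}, {aln.taxa[j]})"
                )
            diff = int((cols[i, ok] != cols[j, ok]).sum())
            p[i, j] = p[j, i] = diff / m
    return p


def poisson_distance(aln: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """Poisson-corrected amino-acid distance ``d = -ln(1 - p)``."""
    p = _p_distances(aln, deletion)
    n = len(aln.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if p[i, j] >= 1.0:
                raise UndefinedDistanceError(
                    f"p = 1 for pair ({aln.taxa[i]}, {aln.taxa[j]}); "
                    "Poisson distance undefined"
                )
    d = -np.log1p(-p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.taxa), d)


def jtt_distance(aln: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """Maximum-likelihood pairwise distance under the JTT model."""
    q, pi = jtt.rate_matrix()
    # eigendecomposition of the pi-symmetrized generator for fast P(t)
    b = np.sqrt(pi)
    s = (q * b[:, None]) / b[None, :]
    lam, v = np.linalg.eigh((s + s.T) / 2)
    left = v * b[:, None]
    right = v / b[:, None]

    def prob(t: float) -> np.ndarray:
        return np.clip(right @ (np.exp(lam * t)[:, None] * left.T), 1e-300, None)

    rows = aln.rows
    n = len(rows)
    cols = np.array([[c for c in r] for r in rows])
    missing = ~np.isin(cols, list(jtt.AMINO_ACIDS))
    if deletion == "complete":
        keep = ~missing.any(axis=0)
        cols = cols[:, keep]
        missing = missing[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(missing[i] | missing[j])
            if not ok.any():
                raise UndefinedDistanceError(
                    f"no comparable columns for pair ({aln.taxa[i]}, {aln.taxa[j]})"
                )
            xi = np.array([jtt.AA_INDEX[c] for c in cols[i, ok]])
            xj = np.array([jtt.AA_INDEX[c] for c in cols[j, ok]])

            def nll(t: float) -> float:
                pmat = prob(max(t, 1e-9))
                return -float(np.log(pi[xi] * pmat[xi, xj]).sum())

            res = minimize_scalar(nll, bounds=(1e-6, 20.0), method="bounded")
            d[i, j] = d[j, i] = float(res.x)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.taxa), d)


def nj(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining.

    Ties in the Q-matrix are broken toward the lowest ``(i, j)`` index pair
    so builds are deterministic.  Negative branch-length estimates are
    clamped to zero with the deficit transferred to the sister branch,
    preserving the joined pair's path length.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbour-joining needs at least 3 taxa")
    d = dist.matrix.copy()
    nodes = [f"{t}" for t in dist.taxa]  # newick fragments
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        qm = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(qm, np.inf)
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if best is None or qm[a, b] < best[0] - 1e-15:
                    best = (qm[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        vi = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        nold = d.shape[0]
        new = np.zeros(nold)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        new = np.clip(new, 0.0, None)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[nold, :nold] = new
        d[:nold, nold] = new
        nodes.append(f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})")
        active = [k for k in active if k not in (i, j)] + [nold]

    i, j, k = active
    va = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    newick = f"({nodes[i]}:{va:.10g},{nodes[j]}:{vb:.10g},{nodes[k]}:{vc:.10g});"
    return parse_newick(newick)


def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, canonicalized to the
    side not containing the alphabetically first taxon."""
    anchor = min(all_taxa)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        if anchor in side:
            side = all_taxa - side
        out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    builder: Callable[[Alignment], dendropy.Tree],
    n: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """Column-bootstrap support (percent) for each internal bipartition.

    Returns the point-estimate tree with supports stored as internal node
    labels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    point = builder(aln)
    all_taxa = frozenset(aln.taxa)
    point_bips = {}
    for node in point.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        canon = side if min(all_taxa) not in side else all_taxa - side
        if len(side) >= 2 and len(all_taxa - side) >= 2:
            point_bips[canon] = node
    counts = {bp: 0 for bp in point_bips}
    ncols = aln.length
    for _ in range(n):
        idx = rng.integers(0, ncols, size=ncols)
        rows = ["".join(r[i] for i in idx) for r in aln.rows]
        rep = builder(Alignment(list(aln.taxa), rows))
        rep_bips = _bipartitions(rep, all_taxa)
        for bp in counts:
            if bp in rep_bips:
                counts[bp] += 1
    for bp, node in point_bips.items():
        node.label = f"{100.0 * counts[bp] / n:g}"
    return point
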