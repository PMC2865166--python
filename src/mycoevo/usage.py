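"""Codon-usage composition analyses.

Correspondence analysis (CA) of per-gene codon-usage frequencies — the
standard chi-square-residual SVD — separates genes by compositional bias
(e.g. a horizontally transferred gene retaining donor-like usage), and
pairwise percent nucleotide identity summarizes overall divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import codons
from .seqio import Alignment, SequenceRecord

__all__ = [
    "CAResult",
    "codon_counts",
    "correspondence_analysis",
    "pairwise_identity",
]


@dataclass
class CAResult:
    genes: list[str]
    coordinates: np.ndarray   # (n_genes, k) principal row coordinates
    inertias: np.ndarray      # per retained axis
    total_inertia: float

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{k + 1}": self.coordinates[:, k]
                for k in range(self.coordinates.shape[1])}
        return pd.DataFrame({"gene": self.genes, **cols})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def codon_counts(genes: list[SequenceRecord]) -> pd.DataFrame:
    """Genes x 61 sense-codon count table (stop codons excluded).

    Sequences must be in-frame CDS; a terminal stop is tolerated, internal
    stops are errors.
    """
    rows = {}
    for rec in genes:
        seq = rec.residues.replace("-", "")
        if len(seq) % 3:
            raise ValueError(f"gene {rec.id!r}: length {len(seq)} not a "
                             "multiple of 3")
        counts = np.zeros(codons.N_CODONS, dtype=np.int64)
        n_cod = len(seq) // 3
        for k in range(n_cod):
            cod = seq[3 * k : 3 * k + 3]
            if cod in codons.CODON_INDEX:
                counts[codons.CODON_INDEX[cod]] += 1
            elif cod in {"TAA", "TAG", "TGA"}:
                if k < n_cod - 1:
                    raise ValueError(
                        f"gene {rec.id!r}: internal stop codon at codon {k + 1}"
                    )
            # ambiguous codons are skipped
        rows[rec.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(codons.SENSE_CODONS))


def correspondence_analysis(
    table: pd.DataFrame,
    k: int = 2,
    frequencies: bool = True,
    rscu: bool = False,
) -> CAResult:
    """Correspondence analysis of a genes x codons table.

    With ``frequencies=True`` (default) each gene's counts are first
    normalized to within-gene relative frequencies, so coordinates are
    invariant to gene length.  ``rscu=True`` instead converts counts to
    relative synonymous codon usage before the CA.  Axis signs are
    canonicalized (largest-magnitude coordinate on each axis positive).
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    x = table.to_numpy(dtype=float)
    if rscu:
        x = _rscu(x, list(table.columns))
    elif frequencies:
        row_tot = x.sum(axis=1, keepdims=True)
        if np.any(row_tot == 0):
            raise ValueError("gene with zero codon counts")
        x = x / row_tot
    keep = x.sum(axis=0) > 0
    x = x[:, keep]
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("gene with zero usage after dropping unused codons")

    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, _vt = np.linalg.svd(s, full_matrices=False)
    total_inertia = float((sv**2).sum())
    n_axes = min(k, sv.size)
    coords = (u[:, :n_axes] * sv[:n_axes]) / np.sqrt(r)[:, None]
    for ax in range(n_axes):
        col = coords[:, ax]
        if col[np.abs(col).argmax()] < 0:
            coords[:, ax] = -col
    return CAResult(list(table.index), coords, sv[:n_axes] ** 2, total_inertia)


def _rscu(x: np.ndarray, columns: list[str]) -> np.ndarray:
    """Relative synonymous codon usage per row, grouped by the amino acid
    each column's codon encodes."""
    aa_of = [codons.CODON_AA[codons.CODON_INDEX[c]] for c in columns]
    out = np.zeros_like(x, dtype=float)
    for aa in set(aa_of):
        idx = np.flatnonzero([a == aa for a in aa_of])
        fam = x[:, idx]
        tot = fam.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, idx] = np.where(tot > 0, fam * len(idx) / tot, 0.0)
    return out


def pairwise_identity(aln: Alignment) -> tuple[pd.DataFrame, float, float]:
    """Percent identity per pair, plus mean and sample SD over pairs.

    Positions where either sequence has a gap are excluded from the
    comparison.
    """
    n = aln.n_taxa
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([[c for c in row] for row in aln.rows])
    gap = np.isin(arr, ["-", "?", "."])
    mat = np.full((n, n), 100.0)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable positions for pair ({aln.taxa[i]}, "
                    f"{aln.taxa[j]})"
                )
            ident = 100.0 * (arr[i, ok] == arr[j, ok]).sum() / m
            mat[i, j] = mat[j, i] = ident
            vals.append(ident)
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    df = pd.DataFrame(mat, index=aln.taxa, columns=aln.taxa)
    return df, float(vals.mean()), sd
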