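"""Codon-state machinery for MG94-style models.

Enumerates the 61 sense codons of the universal code, their single-nucleotide
neighbour structure (position, exchange class, synonymous or not) and the
F3x4 codon-frequency estimator.  Exchange classes are the six unordered
nucleotide pairs ``AC, AG, AT, CG, CT, GT``.
"""

from __future__ import annotations

import itertools

import numpy as np

from .seqio import CODON_TABLE, STOP_CODONS

NUCS = "ACGT"
EXCHANGES = ("AC", "AG", "AT", "CG", "CT", "GT")

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
CODON_AA = tuple(CODON_TABLE[c] for c in SENSE_CODONS)

#: integer amino-acid id per sense codon (for fast nonsyn checks)
_AA_IDS = {a: i for i, a in enumerate(sorted(set(CODON_AA)))}
CODON_AA_ID = np.array([_AA_IDS[a] for a in CODON_AA])


def exchange_of(a: str, b: str) -> str:
    return a + b if a < b else b + a


def _build_neighbors():
    """(i, j, exchange_index, is_nonsyn) for all single-nt codon moves."""
    rows = []
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for n in NUCS:
                if n == ci[pos]:
                    continue
                cj = ci[:pos] + n + ci[pos + 1 :]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                ex = EXCHANGES.index(exchange_of(ci[pos], n))
                rows.append((i, j, ex, CODON_AA[i] != CODON_AA[j]))
    arr = np.array(rows, dtype=np.int64)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3].astype(bool)

NEI_FROM, NEI_TO, NEI_EXCH, NEI_NONSYN = _build_neighbors()


def mg94_rate_matrix(
    exch_rates: np.ndarray,
    dn: float,
    ds: float,
    codon_freqs: np.ndarray,
) -> np.ndarray:
    """MG94xREV generator on the 61 sense codons.

    ``rate(i -> j) = rho[exchange] * pi_j * (ds if synonymous else dn)`` for
    single-nucleotide moves, zero otherwise.  The matrix is reversible with
    stationary distribution ``codon_freqs`` and is *not* rescaled here;
    callers control overall scale through ``dn``/``ds`` and branch lengths.
    """
    rho = np.asarray(exch_rates, dtype=float)
    pi = np.asarray(codon_freqs, dtype=float)
    if rho.shape != (6,) or np.any(rho < 0):
        raise ValueError("need 6 non-negative exchange rates")
    if pi.shape != (N_CODONS,) or np.any(pi <= 0):
        raise ValueError(f"need {N_CODONS} positive codon frequencies")
    if dn < 0 or ds < 0:
        raise ValueError("dn and ds must be non-negative")
    pi = pi / pi.sum()
    q = np.zeros((N_CODONS, N_CODONS))
    rates = rho[NEI_EXCH] * pi[NEI_TO] * np.where(NEI_NONSYN, dn, ds)
    q[NEI_FROM, NEI_TO] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def f3x4_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """F3x4 codon-frequency estimator from ungapped in-frame sequences.

    Position-specific nucleotide frequencies are multiplied and renormalized
    over the 61 sense codons.  A pseudo-count guards against absent
    nucleotides in short inputs.
    """
    counts = np.ones((3, 4)) * 0.5  # pseudo-count
    for s in codon_seqs:
        s = s.replace("-", "")
        for k in range(0, len(s) - len(s) % 3, 3):
            for pos in range(3):
                n = s[k + pos]
                if n in NUCS:
                    counts[pos, NUCS.index(n)] += 1
    fr = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [fr[0, NUCS.index(c[0])] * fr[1, NUCS.index(c[1])] * fr[2, NUCS.index(c[2])]
         for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def empirical_codon_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """Observed sense-codon frequencies with a small pseudo-count."""
    counts = np.full(N_CODONS, 0.5)
    for s in codon_seqs:
        s = s.replace("-", "")
        for k in range(0, len(s) - len(s) % 3, 3):
            cod = s[k : k + 3]
            if cod in CODON_INDEX:
                counts[CODON_INDEX[cod]] += 1
    return counts / counts.sum()


def encode_column(aln_rows: list[str], codon_pos: int) -> np.ndarray:
    """Codon-state ids for one codon column; -1 for gap/ambiguous."""
    out = np.empty(len(aln_rows), dtype=np.int64)
    k = 3 * (codon_pos - 1)
    for r, row in enumerate(aln_rows):
        out[r] = CODON_INDEX.get(row[k : k + 3], -1)
    return out
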