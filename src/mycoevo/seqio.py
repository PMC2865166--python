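"""Sequence, alignment and tree I/O plus the core data model.

The central container is :class:`CodonAlignment`: an in-frame alignment of
protein-coding nucleotide sequences in which gaps occur only as whole codon
triplets and no row contains an internal stop codon.  Amino-acid alignments
are plain :class:`Alignment` objects produced by :func:`translate`.

Coordinates are 1-based and inclusive throughout, in either *alignment*
space (column index) or *reference* space (ungapped position in a designated
reference row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "FormatError",
    "SequenceRecord",
    "Alignment",
    "CodonAlignment",
    "RegionMask",
    "read_fasta",
    "write_fasta",
    "translate",
    "mask_regions",
    "read_newick",
    "write_newick",
    "parse_newick",
]

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
CODON_TABLE = dict(standard_dna_table.forward_table)

#: characters tolerated in input residue strings (nucleotide + amino acid
#: alphabets, ambiguity codes, gap and unknown symbols)
_ALLOWED = frozenset("ABCDEFGHIKLMNPQRSTVWXYZUOJ*-?.")


class FormatError(ValueError):
    """Raised for malformed sequence/alignment/tree input."""


@dataclass
class SequenceRecord:
    """A single named sequence (nucleotide or amino acid)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues.upper()) - _ALLOWED
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-alphabet characters: "
                + "".join(sorted(bad))
            )
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An aligned set of equal-length sequences."""

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence[str],
        reference_taxon: str | None = None,
    ):
        taxa = list(taxa)
        rows = [r.upper() for r in rows]
        if len(taxa) != len(rows):
            raise FormatError("taxa and rows differ in number")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise FormatError(f"duplicate taxa: {', '.join(dupes)}")
        if not rows:
            raise FormatError("empty alignment")
        n = len(rows[0])
        if n == 0:
            raise FormatError("zero-length alignment")
        for t, r in zip(taxa, rows):
            if len(r) != n:
                raise FormatError(f"row {t!r} has length {len(r)}, expected {n}")
        if reference_taxon is not None and reference_taxon not in taxa:
            raise FormatError(f"reference taxon {reference_taxon!r} not in alignment")
        self.taxa = taxa
        self.rows = rows
        self.reference_taxon = reference_taxon

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> str:
        """Column ``i`` (1-based)."""
        return "".join(r[i - 1] for r in self.rows)

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(t, r) for t, r in zip(self.taxa, self.rows)]

    def take_columns(self, cols: Iterable[int]) -> "Alignment":
        """New alignment from 1-based columns, order preserved."""
        idx = [c - 1 for c in cols]
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return type(self)(self.taxa, rows, self.reference_taxon)

    def reference_to_columns(self) -> dict[int, int]:
        """Map 1-based ungapped reference positions -> alignment columns."""
        if self.reference_taxon is None:
            raise FormatError("alignment has no reference taxon")
        ref = self.row(self.reference_taxon)
        out: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref, start=1):
            if ch != "-":
                pos += 1
                out[pos] = col
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.n_taxa} taxa x {self.length} cols>"


class CodonAlignment(Alignment):
    """In-frame coding alignment; gaps only as whole '---' triplets."""

    def __init__(self, taxa, rows, reference_taxon=None):
        super().__init__(taxa, rows, reference_taxon)
        if self.length % 3:
            raise FormatError(f"alignment length {self.length} is not a multiple of 3")
        for t, r in zip(self.taxa, self.rows):
            ungapped_i = 0
            n_cod = len(r) // 3
            for k in range(n_cod):
                cod = r[3 * k : 3 * k + 3]
                if "-" in cod and cod != "---":
                    raise FormatError(
                        f"row {t!r}: partial gap codon {cod!r} at codon {k + 1}"
                    )
            ungapped = r.replace("---", "")
            for k in range(0, len(ungapped) - 3, 3):
                if ungapped[k : k + 3] in STOP_CODONS:
                    raise FormatError(
                        f"row {t!r}: internal stop codon at ungapped codon {k // 3 + 1}"
                    )
            del ungapped_i

    @property
    def length_codons(self) -> int:
        return self.length // 3

    def codon(self, taxon: str, i: int) -> str:
        """Codon ``i`` (1-based) of a row."""
        r = self.row(taxon)
        return r[3 * (i - 1) : 3 * i]

    def take_codons(self, codons: Iterable[int]) -> "CodonAlignment":
        cols: list[int] = []
        for c in codons:
            cols.extend((3 * (c - 1) + 1, 3 * (c - 1) + 2, 3 * c))
        return self.take_columns(cols)

    def reference_to_codons(self) -> dict[int, int]:
        """Map 1-based ungapped reference *codon* positions -> codon columns."""
        if self.reference_taxon is None:
            raise FormatError("alignment has no reference taxon")
        ref = self.row(self.reference_taxon)
        out: dict[int, int] = {}
        pos = 0
        for k in range(self.length_codons):
            if ref[3 * k : 3 * k + 3] != "---":
                pos += 1
                out[pos] = k + 1
        return out


@dataclass
class RegionMask:
    """1-based inclusive intervals to remove, in alignment or reference space."""

    intervals: list[tuple[int, int]]
    coordinate_space: str = "reference"

    def __post_init__(self) -> None:
        if self.coordinate_space not in ("alignment", "reference"):
            raise ValueError(f"unknown coordinate space {self.coordinate_space!r}")
        ivs = sorted(tuple(iv) for iv in self.intervals)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"interval start {a} > end {b}")
            if a < 1:
                raise ValueError("intervals are 1-based")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping intervals ({a1},{b1}) and ({a2},{b2})")
        self.intervals = ivs

    @property
    def total_length(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMask":
        """Read a mask table with columns ``space  start  end``."""
        ivs: list[tuple[int, int]] = []
        space = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] in ("space", "coordinate_space"):
                    continue  # header
                sp, a, b = parts[0], int(parts[1]), int(parts[2])
                if space is None:
                    space = sp
                elif sp != space:
                    raise FormatError("mixed coordinate spaces in mask file")
                ivs.append((a, b))
        if space is None:
            raise FormatError(f"empty mask file {path}")
        return cls(ivs, space)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("space\tstart\tend\n")
            for a, b in self.intervals:
                fh.write(f"{self.coordinate_space}\t{a}\t{b}\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path, codon: bool = False,
                   reference_taxon: str | None = None) -> Alignment:
    """Read an aligned FASTA as :class:`Alignment` or :class:`CodonAlignment`."""
    recs = read_fasta(path)
    cls = CodonAlignment if codon else Alignment
    return cls([r.id for r in recs], [r.residues for r in recs], reference_taxon)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(aln.records(), path)


def translate(aln: CodonAlignment) -> Alignment:
    """Translate a codon alignment under the universal code.

    Gap codons become ``-``; a terminal stop codon (shared column) is
    dropped from all rows; internal stops have already been rejected by the
    :class:`CodonAlignment` invariants but are re-checked defensively.
    """
    n = aln.length_codons
    out_rows: list[str] = []
    # drop the final codon column if any row ends with a stop there
    drop_last = any(
        aln.codon(t, n) in STOP_CODONS for t in aln.taxa
    )
    upto = n - 1 if drop_last else n
    if upto == 0:
        raise FormatError("alignment is a single stop codon")
    for t in aln.taxa:
        aas: list[str] = []
        for k in range(1, upto + 1):
            cod = aln.codon(t, k)
            if cod == "---":
                aas.append("-")
            elif cod in STOP_CODONS:
                raise FormatError(f"row {t!r}: internal stop codon at codon {k}")
            elif cod in CODON_TABLE:
                aas.append(CODON_TABLE[cod])
            else:
                aas.append("X")  # ambiguity
        out_rows.append("".join(aas))
    return Alignment(list(aln.taxa), out_rows, aln.reference_taxon)


def _mask_columns(aln: Alignment, mask: RegionMask, unit: str) -> list[int]:
    """Resolve a mask to a sorted list of 1-based columns to remove.

    ``unit`` is 'residue' for plain alignments and 'codon' for codon
    alignments (mask coordinates then address codon positions).
    """
    ncols = aln.length_codons if unit == "codon" else aln.length  # type: ignore[attr-defined]
    if mask.coordinate_space == "alignment":
        cols = set()
        for a, b in mask.intervals:
            if b > ncols:
                raise ValueError(f"interval ({a},{b}) beyond alignment length {ncols}")
            cols.update(range(a, b + 1))
    else:
        if aln.reference_taxon is None:
            raise FormatError("reference-space mask but alignment has no reference taxon")
        ref_map = (
            aln.reference_to_codons() if unit == "codon" else aln.reference_to_columns()  # type: ignore[attr-defined]
        )
        maxref = max(ref_map) if ref_map else 0
        cols = set()
        for a, b in mask.intervals:
            if b > maxref:
                raise ValueError(
                    f"interval ({a},{b}) beyond reference length {maxref}"
                )
            cols.update(ref_map[p] for p in range(a, b + 1))
    return sorted(cols)


def mask_regions(aln: Alignment, mask: RegionMask) -> Alignment:
    """Remove masked columns (codon columns for a :class:`CodonAlignment`)."""
    if isinstance(aln, CodonAlignment):
        drop = set(_mask_columns(aln, mask, "codon"))
        keep = [c for c in range(1, aln.length_codons + 1) if c not in drop]
        if not keep:
            raise ValueError("mask removes every column")
        return aln.take_codons(keep)
    drop = set(_mask_columns(aln, mask, "residue"))
    keep = [c for c in range(1, aln.length + 1) if c not in drop]
    if not keep:
        raise ValueError("mask removes every column")
    return aln.take_columns(keep)


# ---------------------------------------------------------------------------
# Trees.  PhyloTree is a dendropy.Tree; these wrappers pin down the schema
# and the invariant checks used across the package.
# ---------------------------------------------------------------------------

def _check_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf names in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    return tree


def parse_newick(s: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=s, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"newick parse error: {exc}") from exc
    return _check_tree(tree)


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise FormatError(f"newick parse error in {path}: {exc}") from exc
    return _check_tree(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".10g")


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          real_value_format_specifier=".10g").strip()
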