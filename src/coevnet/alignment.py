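"""Protein multiple sequence alignments: parsing, curation, numbering, subsets.

The alignment is the substrate of every downstream computation.  Columns are
curated in the order the analysis requires: length-band filtering of rows,
removal of columns where the reference sequence is gapped (which defines the
residue numbering), and removal of gap-rich columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import AA_INDEX, ALPHABET, GAP, GAP_CODE, UNKNOWN


class AlignmentError(ValueError):
    """Malformed or degenerate alignment input."""


@dataclass
class Alignment:
    """A rectangular protein alignment with optional per-row taxon labels.

    rows are uppercase strings over the 20 amino acids, ``-`` and ``X``;
    ``X`` keeps its identity in the text representation but counts as a gap
    in every frequency computation.
    """

    seq_ids: list[str]
    rows: list[str]
    taxon: list[str] | None = None
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise AlignmentError("seq_ids and rows length mismatch")
        if len(self.seq_ids) != len(set(self.seq_ids)):
            raise AlignmentError("sequence identifiers must be unique")
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        width = len(self.rows[0])
        for sid, row in zip(self.seq_ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"record {sid!r} has length {len(row)}, expected {width}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentError(f"record {sid!r} contains invalid characters {sorted(bad)}")
        if self.taxon is not None and len(self.taxon) != len(self.rows):
            raise AlignmentError("taxon labels must have one label per row")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def encoded(self) -> np.ndarray:
        """(n_seqs, n_cols) uint8 matrix; residues 0..19, gap/X -> GAP_CODE."""
        if self._encoded is None:
            lut = np.full(128, 255, dtype=np.uint8)
            for aa, idx in AA_INDEX.items():
                lut[ord(aa)] = idx
            lut[ord(GAP)] = GAP_CODE
            lut[ord(UNKNOWN)] = GAP_CODE
            buf = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
            self._encoded = lut[buf].reshape(self.n_seqs, self.n_cols)
        return self._encoded

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def gap_fraction(self, j: int | None = None) -> np.ndarray | float:
        """Fraction of gap/X characters per column (or for one column)."""
        frac = (self.encoded == GAP_CODE).mean(axis=0)
        return frac if j is None else float(frac[j])

    def ungapped_fraction(self) -> np.ndarray:
        return 1.0 - self.gap_fraction()

    def take_rows(self, idx: Sequence[int]) -> "Alignment":
        idx = list(idx)
        return Alignment(
            [self.seq_ids[i] for i in idx],
            [self.rows[i] for i in idx],
            [self.taxon[i] for i in idx] if self.taxon is not None else None,
        )

    def take_columns(self, idx: Sequence[int]) -> "Alignment":
        idx = list(idx)
        return Alignment(
            list(self.seq_ids),
            ["".join(row[j] for j in idx) for row in self.rows],
            list(self.taxon) if self.taxon is not None else None,
        )


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between retained alignment columns and reference residue numbers."""

    ref_seq_id: str
    ref_start: int
    col_to_resnum: dict[int, int]
    resnum_to_col: dict[int, int]

    @property
    def positions(self) -> np.ndarray:
        """Residue numbers in column order."""
        return np.array([self.col_to_resnum[c] for c in sorted(self.col_to_resnum)])

    def restrict(self, kept_columns: Sequence[int]) -> "ReferenceMap":
        """Re-index the map after dropping columns (e.g. gap filtering).

        ``kept_columns`` are current column indices; the returned map numbers
        the surviving columns 0..k-1 while keeping their residue numbers.
        """
        c2r = {new: self.col_to_resnum[old] for new, old in enumerate(kept_columns)}
        return ReferenceMap(self.ref_seq_id, self.ref_start, c2r,
                            {r: c for c, r in c2r.items()})


@dataclass(frozen=True)
class ColumnMask:
    """Per-column keep flags with a drop reason for each removed column."""

    keep: np.ndarray
    reason: dict[int, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; ``.`` is normalised to ``-``, case to upper."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 FASTA records, found {len(records)}")
    seq_ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    width = len(rows[0])
    for k, (sid, row) in enumerate(zip(seq_ids, rows), start=1):
        if len(row) != width:
            raise AlignmentError(
                f"{path}: record {k} ({sid!r}) has length {len(row)}, expected {width}"
            )
    return Alignment(seq_ids, rows)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.seq_ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_taxon_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: seq_id <tab> taxon."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"taxon table line not two columns: {line!r}")
        out[parts[0]] = parts[1]
    return out


def attach_taxa(aln: Alignment, table: Mapping[str, str]) -> Alignment:
    missing = [s for s in aln.seq_ids if s not in table]
    if missing:
        raise AlignmentError(f"taxon table missing {len(missing)} ids, e.g. {missing[0]!r}")
    return Alignment(list(aln.seq_ids), list(aln.rows), [table[s] for s in aln.seq_ids])


def residue_length(row: str) -> int:
    """Number of non-gap characters (X counts as a residue for length)."""
    return sum(1 for ch in row if ch != GAP)


def curate_by_length(aln: Alignment, min_len: int = 245, max_len: int = 265) -> Alignment:
    """Keep rows whose ungapped length lies in [min_len, max_len] (inclusive)."""
    idx = [i for i, row in enumerate(aln.rows)
           if min_len <= residue_length(row) <= max_len]
    if not idx:
        raise AlignmentError(
            f"no sequences with length in [{min_len}, {max_len}]"
        )
    return aln.take_rows(idx)


def build_reference_map(
    aln: Alignment, ref_seq_id: str, ref_start: int
) -> tuple[Alignment, ReferenceMap]:
    """Drop columns gapped in the reference row; number the rest from ref_start."""
    try:
        ref_row = aln.rows[aln.seq_ids.index(ref_seq_id)]
    except ValueError:
        raise AlignmentError(f"reference sequence {ref_seq_id!r} not in alignment") from None
    kept = [j for j, ch in enumerate(ref_row) if ch != GAP]
    if not kept:
        raise AlignmentError("reference sequence is entirely gapped")
    c2r = {new: ref_start + new for new in range(len(kept))}
    rmap = ReferenceMap(ref_seq_id, ref_start, c2r, {r: c for c, r in c2r.items()})
    return aln.take_columns(kept), rmap


def filter_gap_columns(
    aln: Alignment, max_gap_frac: float = 0.35, rmap: ReferenceMap | None = None
) -> tuple[Alignment, ColumnMask] | tuple[Alignment, ColumnMask, ReferenceMap]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    When a ReferenceMap is given, a re-indexed map over the surviving columns
    is returned as a third element.
    """
    if not (0 < max_gap_frac < 1):
        raise ValueError("max_gap_frac must be in (0, 1)")
    frac = aln.gap_fraction()
    keep = frac <= max_gap_frac
    reason = {j: "gap-fraction" for j in np.flatnonzero(~keep)}
    mask = ColumnMask(keep, reason)
    kept_idx = list(np.flatnonzero(keep))
    out = aln.take_columns(kept_idx) if kept_idx else aln.take_columns([])
    if not kept_idx:
        raise AlignmentError("all columns exceeded the gap-fraction threshold")
    if rmap is not None:
        return out, mask, rmap.restrict(kept_idx)
    return out, mask


def extract_perturbation_subset(
    aln: Alignment, rmap: ReferenceMap, resnum: int, residue: str
) -> Alignment:
    """Rows carrying ``residue`` at the column mapped to ``resnum``.

    This is the mutation-defined sub-alignment used for perturbation
    analysis: e.g. all sequences with T where the reference has S.
    """
    if resnum not in rmap.resnum_to_col:
        raise AlignmentError(f"residue number {resnum} is not mapped")
    col = rmap.resnum_to_col[resnum]
    residue = residue.upper()
    idx = [i for i, row in enumerate(aln.rows) if row[col] == residue]
    if not idx:
        spectrum: dict[str, int] = {}
        for row in aln.rows:
            spectrum[row[col]] = spectrum.get(row[col], 0) + 1
        raise AlignmentError(
            f"no sequences carry {residue} at position {resnum}; "
            f"observed spectrum: {dict(sorted(spectrum.items()))}"
        )
    return aln.take_rows(idx)


def write_column_map(mask: ColumnMask, rmap: ReferenceMap | None, path: str | Path) -> None:
    """TSV of (column_index, residue_number, kept, reason)."""
    lines = ["column_index\tresidue_number\tkept\treason"]
    kept_seen = 0
    for j, keep in enumerate(mask.keep):
        resnum = ""
        if keep and rmap is not None:
            resnum = str(rmap.col_to_resnum.get(kept_seen, ""))
            kept_seen += 1
        lines.append(f"{j}\t{resnum}\t{int(keep)}\t{mask.reason.get(j, '')}")
    Path(path).write_text("\n".join(lines) + "\n")
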