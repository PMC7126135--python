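"""Alignment I/O, external-aligner invocation, coordinate mapping and truncation.

Alignments are gapped, equal-length rows with 1-based column coordinates,
matching how positions are cited in the conservation results. Alignment
itself is delegated to an external program (MUSCLE by default, any
command template in practice); a passthrough mode accepts a pre-aligned
FASTA instead.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import TextIO

from Bio import SeqIO

from .ingest import EXTENDED_AA, HomologousGroup

GAP = "-"
_ALIGNMENT_ALPHABET = EXTENDED_AA | {GAP}


class RaggedAlignmentError(ValueError):
    """Rows of an alignment have unequal lengths."""


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped rows; columns are 1-based."""

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row ids must be unique")
        width = len(self.rows[0])
        if width == 0:
            raise ValueError("alignment must have at least one column")
        for rid, row in zip(self.row_ids, self.rows):
            if len(row) != width:
                raise RaggedAlignmentError(
                    f"row '{rid}' has length {len(row)}, expected {width}"
                )
            bad = set(row) - _ALIGNMENT_ALPHABET
            if bad:
                raise ValueError(f"row '{rid}' contains invalid symbols {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no row '{row_id}' in alignment") from None

    def column(self, col: int) -> str:
        """Symbols of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(row[col - 1] for row in self.rows)

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def all_gap_rows(self) -> list[str]:
        return [rid for rid, row in zip(self.row_ids, self.rows) if set(row) == {GAP}]


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based, inclusive column range."""

    start_col: int
    end_col: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_col <= self.end_col:
            raise ValueError(f"invalid region {self.start_col}..{self.end_col}")

    def validate_for(self, aln: Alignment) -> None:
        if self.end_col > aln.n_cols:
            raise ValueError(
                f"region {self.start_col}..{self.end_col} exceeds alignment width {aln.n_cols}"
            )


def _canonical(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_msa(source: str | Path | TextIO) -> Alignment:
    """Read an aligned FASTA; '.' gaps are normalized to '-'."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    ids, rows = [], []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        ids.append(rec.id)
        rows.append(_canonical(str(rec.seq)))
    if not rows:
        raise ValueError("empty alignment file")
    return Alignment(tuple(ids), tuple(rows))


def write_msa(aln: Alignment, dest: str | Path | TextIO) -> None:
    """Write aligned FASTA, 60 characters per line."""
    def _dump(fh: TextIO) -> None:
        for rid, row in zip(aln.row_ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _dump(fh)
    else:
        _dump(dest)


DEFAULT_ALIGNER_TEMPLATE = "muscle -in {in} -out {out}"


def run_aligner(
    group: HomologousGroup,
    aligner_command: str = DEFAULT_ALIGNER_TEMPLATE,
    premade_msa: str | Path | None = None,
) -> Alignment:
    """Align a group with an external command, or accept a pre-made alignment.

    ``aligner_command`` is a template with ``{in}`` and optionally
    ``{out}`` placeholders; without ``{out}`` the aligner's stdout is taken
    as the aligned FASTA (the MAFFT convention). With ``premade_msa`` the
    file is read verbatim instead and no aligner is invoked. In either
    case the de-gapped alignment rows must reproduce the group's sequences.
    """
    if premade_msa is not None:
        aln = read_msa(premade_msa)
        _check_degap_roundtrip(group, aln)
        return aln
    if not group.members:
        raise ValueError("cannot align an empty group")

    executable = shlex.split(aligner_command)[0]
    if shutil.which(executable) is None:
        raise FileNotFoundError(
            f"aligner '{executable}' not found on PATH; either install it or supply "
            f"a pre-aligned FASTA via premade_msa (--premade-msa)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "input.fasta"
        outfile = Path(tmp) / "output.fasta"
        with open(infile, "w") as fh:
            for rec in group.members:
                fh.write(f">{rec.accession}\n{rec.sequence}\n")
        cmd = [
            arg.replace("{in}", str(infile)).replace("{out}", str(outfile))
            for arg in shlex.split(aligner_command)
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"aligner exited with status {proc.returncode}: {proc.stderr.strip()}"
            )
        if "{out}" in aligner_command:
            aln = read_msa(outfile)
        else:
            aln = read_msa(StringIO(proc.stdout))
    _check_degap_roundtrip(group, aln)
    return aln


def _check_degap_roundtrip(group: HomologousGroup, aln: Alignment) -> None:
    expected = {rec.accession: rec.sequence for rec in group.members}
    if not group.members:
        return
    for rid, row in zip(aln.row_ids, aln.rows):
        source = expected.get(rid)
        if source is not None and row.replace(GAP, "") != source:
            raise ValueError(
                f"de-gapped alignment row '{rid}' does not reproduce the input sequence"
            )


def map_residue_to_column(aln: Alignment, row_id: str, residue_index: int) -> int:
    """Map a 1-based ungapped residue index of one row to its alignment column."""
    row = aln.row(row_id)
    if residue_index < 1:
        raise IndexError(f"residue index {residue_index} out of range")
    seen = 0
    for col, symbol in enumerate(row, start=1):
        if symbol != GAP:
            seen += 1
            if seen == residue_index:
                return col
    raise IndexError(
        f"residue index {residue_index} exceeds ungapped length {seen} of row '{row_id}'"
    )


def truncate_alignment(aln: Alignment, first_kept_col: int) -> Alignment:
    """Keep columns ``first_kept_col``..n_cols (1-based, inclusive) for all rows.

    Rows that become all-gap are retained; callers can flag them via
    :meth:`Alignment.all_gap_rows`.
    """
    if not 1 <= first_kept_col <= aln.n_cols:
        raise IndexError(f"column {first_kept_col} out of range 1..{aln.n_cols}")
    return Alignment(aln.row_ids, tuple(row[first_kept_col - 1 :] for row in aln.rows))
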