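"""Gap-weighted relative-entropy conservation scoring of alignment columns.

Each column's residue distribution P is compared with background amino-acid
frequencies Q through the Kullback-Leibler divergence in base 2,

    D_KL(P||Q) = sum_a P(a) * log2(P(a) / Q(a))   [bits],

computed over the non-gap symbols of the column (the alphabet is the 20
standard amino acids plus the ambiguity codes B, Z and X). Sparsely
populated columns are penalized by multiplying by the column's non-gap
fraction:

    G_W = D_KL(P||Q) * nongap_fraction.

A column is called conserved when G_W strictly exceeds the score of a
hypothetical gapless all-arginine column, log2(1/Q(R)) — about 4.1354 bits
under UniProt natural-abundance frequencies. Arginine is the yardstick
because protamines are arginine-rich: a column has to be *more* surprising
than pure arginine to stand out. Methionine at the start of a protein
(the initiator Met) is ignored, i.e. treated as a gap in all column
statistics.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TextIO

import pandas as pd

from .ingest import STANDARD_AA
from .msa import GAP, Alignment

DEFAULT_BACKGROUND_RESOURCE = "uniprot_2019_abundance.tsv"


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background amino-acid frequencies Q(a) over the 23-symbol alphabet.

    The ambiguity codes are assigned Q(B)=Q(D)+Q(N), Q(Z)=Q(E)+Q(Q) and
    Q(X)=1; the X upper bound makes any unknown residue contribute a
    non-positive term, conservatively deflating scores.
    """

    q: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.q)
        if missing:
            raise ValueError(f"background table missing residues: {sorted(missing)}")
        nonpos = [a for a, f in self.q.items() if f <= 0]
        if nonpos:
            raise ValueError(f"non-positive background frequency for: {sorted(nonpos)}")
        total = sum(self.q[a] for a in STANDARD_AA)
        if not 0.98 < total <= 1.02:
            raise ValueError(f"standard-aa background frequencies sum to {total:.4f}, not ~1")
        q = dict(self.q)
        q.setdefault("B", q["D"] + q["N"])
        q.setdefault("Z", q["E"] + q["Q"])
        q.setdefault("X", 1.0)
        object.__setattr__(self, "q", q)

    def __getitem__(self, symbol: str) -> float:
        return self.q[symbol]


def load_background(table: str | Path | TextIO) -> BackgroundFrequencies:
    """Load a two-column (symbol, frequency) background table; '#' comments allowed."""
    if isinstance(table, (str, Path)):
        label = Path(table).name
        text = Path(table).read_text()
    else:
        label = getattr(table, "name", "stream")
        text = table.read()
    q: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'symbol frequency', got '{line}'")
        symbol, freq = parts[0].upper(), float(parts[1])
        if symbol in q:
            raise ValueError(f"line {lineno}: duplicate symbol '{symbol}'")
        q[symbol] = freq
    return BackgroundFrequencies(q, source_label=label)


def default_background() -> BackgroundFrequencies:
    """The bundled UniProt natural-abundance table."""
    ref = resources.files("protascan.data") / DEFAULT_BACKGROUND_RESOURCE
    with resources.as_file(ref) as path:
        bg = load_background(path)
    return BackgroundFrequencies(bg.q, source_label="UniProt 2019_05 natural abundance")


@dataclass(frozen=True)
class MaskedAlignment:
    """An alignment plus a set of masked (row_index, column) cells.

    Masked cells are treated as gaps in all column statistics.
    """

    alignment: Alignment
    masked: frozenset[tuple[int, int]] = frozenset()

    def is_masked(self, row_index: int, col: int) -> bool:
        return (row_index, col) in self.masked


def mask_leading_met(aln: Alignment) -> MaskedAlignment:
    """Mask each row's first non-gap symbol if it is the initiator methionine."""
    masked = set()
    for i, row in enumerate(aln.rows):
        for col, symbol in enumerate(row, start=1):
            if symbol != GAP:
                if symbol == "M":
                    masked.add((i, col))
                break
    return MaskedAlignment(aln, frozenset(masked))


@dataclass(frozen=True)
class ColumnProfile:
    """Non-gap symbol counts and frequencies for one alignment column.

    Masked symbols count toward the gap side: ``n_gap`` is gaps plus masked
    cells, and P(a) is normalized over the remaining symbols only.
    """

    column: int
    counts: dict[str, int]
    n_rows: int
    n_gap: int

    @property
    def n_nongap(self) -> int:
        return self.n_rows - self.n_gap

    @property
    def nongap_fraction(self) -> float:
        return self.n_nongap / self.n_rows

    @property
    def p(self) -> dict[str, float]:
        total = self.n_nongap
        if total == 0:
            return {}
        return {a: c / total for a, c in self.counts.items()}

    def majority(self) -> tuple[str | None, float]:
        """The most frequent non-gap symbol and its non-gap purity."""
        if not self.counts:
            return None, float("nan")
        symbol = max(sorted(self.counts), key=lambda a: self.counts[a])
        return symbol, self.counts[symbol] / self.n_nongap


def column_profile(aln: Alignment | MaskedAlignment, col: int) -> ColumnProfile:
    """Profile of 1-based column ``col``; an all-gap column is valid, not an error."""
    if isinstance(aln, Alignment):
        aln = MaskedAlignment(aln)
    base = aln.alignment
    if not 1 <= col <= base.n_cols:
        raise IndexError(f"column {col} out of range 1..{base.n_cols}")
    counts: Counter[str] = Counter()
    for i, row in enumerate(base.rows):
        symbol = row[col - 1]
        if symbol == GAP or aln.is_masked(i, col):
            continue
        counts[symbol] += 1
    n_rows = base.n_rows
    return ColumnProfile(col, dict(counts), n_rows, n_rows - sum(counts.values()))


def relative_entropy(profile: ColumnProfile, bg: BackgroundFrequencies) -> float:
    """D_KL(P||Q) of the column in bits; symbols absent from the column contribute 0."""
    p = profile.p
    if not p:
        raise ValueError(f"column {profile.column} has no non-gap symbols")
    return sum(pa * math.log2(pa / bg[a]) for a, pa in p.items())


def gap_weighted_score(profile: ColumnProfile, bg: BackgroundFrequencies) -> float:
    """Relative entropy scaled by the column's non-gap fraction; 0 for all-gap columns."""
    if profile.n_nongap == 0:
        return 0.0
    return profile.nongap_fraction * relative_entropy(profile, bg)


def conservation_threshold(
    bg: BackgroundFrequencies, reference_residue: str = "R"
) -> float:
    """Score of a gapless column composed entirely of ``reference_residue``.

    For P concentrated on one residue the divergence reduces to
    log2(1/Q(residue)); positions must strictly exceed this to be called
    conserved.
    """
    if reference_residue not in bg.q:
        raise KeyError(f"unknown residue '{reference_residue}'")
    return math.log2(1.0 / bg[reference_residue])


@dataclass(frozen=True)
class ColumnScore:
    column: int
    d_kl: float
    gap_weight: float
    g_w: float
    conserved: bool
    majority_symbol: str | None
    purity: float


@dataclass
class ConservationResult:
    """Per-column conservation scores for one alignment."""

    columns: list[ColumnScore]
    threshold: float
    background_label: str = ""

    def conserved_positions(self) -> list[int]:
        """Conserved columns sorted by descending gap-weighted score."""
        hits = [c for c in self.columns if c.conserved]
        return [c.column for c in sorted(hits, key=lambda c: (-c.g_w, c.column))]

    def __getitem__(self, col: int) -> ColumnScore:
        return self.columns[col - 1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "column": [c.column for c in self.columns],
                "d_kl": [c.d_kl for c in self.columns],
                "gap_weight": [c.gap_weight for c in self.columns],
                "g_w": [c.g_w for c in self.columns],
                "conserved": [c.conserved for c in self.columns],
                "majority_symbol": [c.majority_symbol for c in self.columns],
                "purity": [c.purity for c in self.columns],
            }
        )
        df.attrs["threshold"] = self.threshold
        df.attrs["background_label"] = self.background_label
        return df

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold_bits\t{self.threshold!r}\n")
            fh.write(f"# background\t{self.background_label}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def scan_alignment(
    aln: Alignment | MaskedAlignment,
    bg: BackgroundFrequencies,
    threshold: float | None = None,
    apply_leading_met_mask: bool = True,
) -> ConservationResult:
    """Score every column and call conserved positions.

    A plain :class:`Alignment` gets the initiator-Met mask applied first
    (disable with ``apply_leading_met_mask=False``); a pre-masked
    :class:`MaskedAlignment` is used as given. Conservation uses a strict
    inequality: a column scoring exactly the threshold is not conserved.
    """
    if isinstance(aln, Alignment):
        masked = mask_leading_met(aln) if apply_leading_met_mask else MaskedAlignment(aln)
    else:
        masked = aln
    if threshold is None:
        threshold = conservation_threshold(bg)
    scores = []
    for col in range(1, masked.alignment.n_cols + 1):
        profile = column_profile(masked, col)
        if profile.n_nongap == 0:
            d_kl, g_w = 0.0, 0.0
        else:
            d_kl = relative_entropy(profile, bg)
            g_w = profile.nongap_fraction * d_kl
        majority_symbol, purity = profile.majority()
        scores.append(
            ColumnScore(
                column=col,
                d_kl=d_kl,
                gap_weight=profile.nongap_fraction,
                g_w=g_w,
                conserved=g_w > threshold,
                majority_symbol=majority_symbol,
                purity=purity,
            )
        )
    return ConservationResult(scores, threshold, bg.source_label)
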