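"""Charged-residue (arginine-lysine) density analysis.

Protamines bind the DNA phosphate backbone through their positively charged
residues. The per-sequence statistic is the fraction of residues that are
arginine or lysine (histidine excluded by default: it is mostly
deprotonated at physiological pH), computed over the whole sequence or over
a DNA-binding-region window of an alignment. Groups are summarized by
five-number quartile summaries and compared pairwise with Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import STANDARD_AA
from .msa import GAP, Alignment, RegionSpec

DEFAULT_CHARGED = frozenset({"R", "K"})


@dataclass(frozen=True)
class ResidueSet:
    """The residues counted in the density numerator (default arginine+lysine)."""

    symbols: frozenset[str] = DEFAULT_CHARGED

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("residue set must be non-empty")
        bad = set(self.symbols) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues in residue set: {sorted(bad)}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def residue_frequency(
    sequence: str,
    residues: ResidueSet = ResidueSet(),
    exclude_leading_met: bool = True,
) -> float:
    """Fraction of the sequence's residues in ``residues``.

    The initiator methionine is excluded from both numerator and
    denominator, consistent with the conservation scan's masking.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if exclude_leading_met and seq.startswith("M"):
        seq = seq[1:]
        if not seq:
            raise ValueError("sequence is a bare initiator methionine")
    return sum(1 for s in seq if s in residues) / len(seq)


def region_residue_frequency(
    aln: Alignment,
    row_id: str,
    region: RegionSpec,
    residues: ResidueSet = ResidueSet(),
    exclude_leading_met: bool = True,
) -> float | None:
    """Density over a row's non-gap symbols within an alignment window.

    The denominator is the number of non-gap symbols the row places in
    columns ``start_col..end_col`` (not the window width), so gappy rows
    remain comparable. A row with no non-gap symbol in the window has no
    defined density and ``None`` is returned.
    """
    region.validate_for(aln)
    row = aln.row(row_id)
    first_nongap = next((i for i, s in enumerate(row, start=1) if s != GAP), None)
    symbols = []
    for col in range(region.start_col, region.end_col + 1):
        s = row[col - 1]
        if s == GAP:
            continue
        if exclude_leading_met and s == "M" and col == first_nongap:
            continue
        symbols.append(s)
    if not symbols:
        return None
    return sum(1 for s in symbols if s in residues) / len(symbols)


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


def quartile_summary(freqs: list[float]) -> FiveNumberSummary:
    """Min, quartiles and max with linear interpolation between closest ranks."""
    if len(freqs) == 0:
        raise ValueError("cannot summarize an empty list")
    q = np.percentile(np.asarray(freqs, dtype=float), [0, 25, 50, 75, 100])
    return FiveNumberSummary(*map(float, q))


@dataclass
class GroupComposition:
    """Per-sequence charged-residue densities for one group."""

    group_name: str
    frequencies: dict[str, float]
    summary: FiveNumberSummary
    region: RegionSpec | None = None
    n_missing: int = 0

    def values(self) -> list[float]:
        return list(self.frequencies.values())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.frequencies), "frequency": list(self.frequencies.values())}
        )


def group_composition(
    group_name: str,
    sequences: dict[str, str],
    residues: ResidueSet = ResidueSet(),
) -> GroupComposition:
    """Whole-sequence densities and their quartile summary for a group."""
    freqs = {rid: residue_frequency(seq, residues) for rid, seq in sequences.items()}
    return GroupComposition(group_name, freqs, quartile_summary(list(freqs.values())))


def region_group_composition(
    group_name: str,
    aln: Alignment,
    region: RegionSpec,
    residues: ResidueSet = ResidueSet(),
) -> GroupComposition:
    """DNA-binding-region densities for every row of a group's alignment."""
    freqs: dict[str, float] = {}
    n_missing = 0
    for rid in aln.row_ids:
        f = region_residue_frequency(aln, rid, region, residues)
        if f is None:
            n_missing += 1
        else:
            freqs[rid] = f
    if not freqs:
        raise ValueError(f"{group_name}: no row has residues in the region")
    return GroupComposition(
        group_name, freqs, quartile_summary(list(freqs.values())), region, n_missing
    )


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


def welch_t_test(a: list[float], b: list[float]) -> WelchResult:
    """Two-sided unequal-variance t-test, df by Welch-Satterthwaite.

    Two identical zero-variance samples get p=1 by convention; distinct
    zero-variance samples get p=0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0 and vy == 0:
        df = float(nx + ny - 2)
        if x.mean() == y.mean():
            return WelchResult(0.0, df, 1.0)
        t = float("inf") if x.mean() > y.mean() else float("-inf")
        return WelchResult(t, df, 0.0)
    se2 = vx / nx + vy / ny
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    df = float(se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t, df, p)


def pairwise_welch(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise Welch p-values (diagonal NaN)."""
    names = list(groups)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            p = welch_t_test(groups[gi], groups[gj]).p_value
            mat.loc[gi, gj] = p
            mat.loc[gj, gi] = p
    return mat


def summary_table(compositions: list[GroupComposition]) -> pd.DataFrame:
    """Min/Q1/median/Q3/max table, one row per group."""
    rows = []
    for comp in compositions:
        s = comp.summary
        rows.append(
            {
                "group": comp.group_name,
                "n": len(comp.frequencies),
                "min": s.minimum,
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "max": s.maximum,
            }
        )
    return pd.DataFrame(rows)
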