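"""Synthetic protamine-like families with known ground truth.

Real protamines are short, arginine-rich sequences in which a handful of
alignment columns (cysteine in eutherians, tyrosine in metatherians) are
nearly pure. The generator emulates exactly that statistical structure:
rows are drawn i.i.d. from an arginine-heavy background composition,
selected columns are "planted" to emit a chosen residue with purity pi,
and gaps are inserted i.i.d. per cell at a configurable rate. Because the
conservation score depends only on per-column symbol and gap fractions,
i.i.d. gaps are sufficient; no indel-block or phylogenetic structure is
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import BackgroundFrequencies
from .ingest import HomologousGroup, ProteinRecord, STANDARD_AA
from .msa import GAP, Alignment

# Arginine-rich background mimicking fish protamines (~70% arginine), the
# stress case for the all-arginine threshold: background columns should
# hover near but never above it.
FISH_LIKE_COMPOSITION: dict[str, float] = {
    "R": 0.70,
    "S": 0.06,
    "K": 0.05,
    "G": 0.05,
    "A": 0.04,
    "P": 0.04,
    "V": 0.03,
    "T": 0.02,
    "Y": 0.01,
}


@dataclass(frozen=True)
class PlantedColumn:
    column: int
    residue: str
    purity: float


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Parameters of one synthetic protamine-like family."""

    n_sequences: int = 50
    length: int = 60
    background_composition: dict[str, float] = field(
        default_factory=lambda: dict(FISH_LIKE_COMPOSITION)
    )
    planted_columns: tuple[PlantedColumn, ...] = ()
    gap_rate: float = 0.0
    leading_met: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_sequences < 2:
            problems.append("n_sequences must be >= 2")
        if self.length < 1:
            problems.append("length must be >= 1")
        if not 0 <= self.gap_rate < 1:
            problems.append("gap_rate must be in [0, 1)")
        total = sum(self.background_composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            problems.append(f"background composition sums to {total:.6f}, not 1")
        if set(self.background_composition) - STANDARD_AA:
            problems.append("background composition contains non-standard residues")
        first_plantable = 2 if self.leading_met else 1
        for pc in self.planted_columns:
            if not first_plantable <= pc.column <= self.length:
                problems.append(f"planted column {pc.column} outside {first_plantable}..{self.length}")
            if pc.residue not in STANDARD_AA:
                problems.append(f"planted residue '{pc.residue}' not a standard amino acid")
            if not 0 < pc.purity <= 1:
                problems.append(f"planted purity {pc.purity} outside (0, 1]")
            if pc.purity <= self.background_composition.get(pc.residue, 0.0):
                problems.append(
                    f"planted purity {pc.purity} must exceed the background "
                    f"probability of '{pc.residue}'"
                )
        if len({pc.column for pc in self.planted_columns}) != len(self.planted_columns):
            problems.append("planted columns must be distinct")
        if problems:
            raise ValueError("invalid synthetic family config: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    """Ground-truth labels and realized per-column statistics."""

    planted: dict[int, PlantedColumn]
    realized_purity: dict[int, float]
    realized_gap_fraction: dict[int, float]
    n_cols: int

    def is_planted(self, col: int) -> bool:
        return col in self.planted

    def background_columns(self) -> list[int]:
        return [c for c in range(1, self.n_cols + 1) if c not in self.planted]


def _draw_background(rng: np.random.Generator, composition: dict[str, float], size: int):
    symbols = sorted(composition)
    probs = np.array([composition[s] for s in symbols])
    probs = probs / probs.sum()
    return rng.choice(np.array(symbols), size=size, p=probs)


def generate_family(
    config: SyntheticFamilyConfig,
) -> tuple[HomologousGroup, Alignment, SyntheticTruth]:
    """Generate one gapped family alignment plus its de-gapped sequences.

    A planted column emits its residue with probability pi and a background
    draw otherwise; every cell is independently replaced by a gap at the
    configured rate. With ``leading_met`` the first column is an ungapped
    initiator methionine on every row, as in mammalian protamines
    (MARYR...). Fully deterministic under the config's seed.
    """
    rng = np.random.default_rng(config.seed)
    n, length = config.n_sequences, config.length
    planted = {pc.column: pc for pc in config.planted_columns}

    grid = _draw_background(rng, config.background_composition, (n, length))
    for pc in config.planted_columns:
        emit = rng.random(n) < pc.purity
        col_bg = _draw_background(rng, config.background_composition, n)
        grid[:, pc.column - 1] = np.where(emit, pc.residue, col_bg)
    gaps = rng.random((n, length)) < config.gap_rate
    if config.leading_met:
        grid[:, 0] = "M"
        gaps[:, 0] = False
    # a row of pure gaps cannot be de-gapped to a sequence; keep one residue
    for i in range(n):
        if gaps[i].all():
            keep = int(rng.integers(length))
            gaps[i, keep] = False

    rows = []
    for i in range(n):
        rows.append(
            "".join(GAP if gaps[i, j] else grid[i, j] for j in range(length))
        )
    row_ids = tuple(f"SYN{i + 1:04d}" for i in range(n))
    aln = Alignment(row_ids, tuple(rows))

    members = [
        ProteinRecord(
            accession=rid,
            reviewed=True,
            gene_names=frozenset({"SYNP1"}),
            organism=f"Synthetica specimen {i + 1}",
            lineage=("Synthetica",),
            description="synthetic protamine-like protein",
            sequence=aln.degapped(rid),
        )
        for i, rid in enumerate(row_ids)
    ]
    group = HomologousGroup(
        "synthetic",
        members,
        provenance={"generator": "protascan.synthetic.generate_family", "seed": config.seed},
    )

    realized_purity: dict[int, float] = {}
    realized_gap: dict[int, float] = {}
    for col in range(1, length + 1):
        col_syms = [rows[i][col - 1] for i in range(n)]
        n_gap = sum(1 for s in col_syms if s == GAP)
        realized_gap[col] = n_gap / n
        if col in planted:
            nongap = n - n_gap
            hits = sum(1 for s in col_syms if s == planted[col].residue)
            realized_purity[col] = hits / nongap if nongap else float("nan")
    truth = SyntheticTruth(planted, realized_purity, realized_gap, length)
    return group, aln, truth


def expected_column_distribution(
    planted: PlantedColumn, background_composition: dict[str, float]
) -> dict[str, float]:
    """Expected non-gap symbol distribution of a planted column."""
    dist = {a: (1 - planted.purity) * f for a, f in background_composition.items()}
    dist[planted.residue] = dist.get(planted.residue, 0.0) + planted.purity
    return {a: f for a, f in dist.items() if f > 0}


def expected_planted_score(
    planted: PlantedColumn,
    config: SyntheticFamilyConfig,
    bg: BackgroundFrequencies,
) -> float:
    """Closed-form expected gap-weighted score of a planted column, in bits.

    (1 - gap_rate) * D_KL(expected distribution || Q); the realized score
    fluctuates around this with the sampling noise of n_sequences draws.
    """
    dist = expected_column_distribution(planted, config.background_composition)
    d_kl = sum(p * math.log2(p / bg[a]) for a, p in dist.items())
    return (1 - config.gap_rate) * d_kl


def generate_two_group_composition(
    n_a: int,
    n_b: int,
    rk_a: float,
    rk_b: float,
    length: int = 50,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Two synthetic sequence sets with target arginine+lysine probabilities.

    Each residue is independently charged with the group's R+K probability
    (split 85:15 between R and K, mirroring the arginine dominance of real
    protamines) and otherwise drawn from the non-charged part of the
    fish-like composition. Per-sequence R+K frequencies then concentrate
    binomially around the targets.
    """
    for rk in (rk_a, rk_b):
        if not 0 < rk < 1:
            raise ValueError(f"R+K probability {rk} outside (0, 1)")
    if min(n_a, n_b) < 1 or length < 1:
        raise ValueError("sample sizes and length must be positive")
    rng = np.random.default_rng(seed)
    noncharged = {
        a: f for a, f in FISH_LIKE_COMPOSITION.items() if a not in ("R", "K")
    }
    total = sum(noncharged.values())
    noncharged = {a: f / total for a, f in noncharged.items()}

    def _group(n: int, rk: float) -> list[str]:
        seqs = []
        for _ in range(n):
            charged = rng.random(length) < rk
            is_r = rng.random(length) < 0.85
            fill = _draw_background(rng, noncharged, length)
            seq = np.where(charged, np.where(is_r, "R", "K"), fill)
            seqs.append("".join(seq))
        return seqs

    return _group(n_a, rk_a), _group(n_b, rk_b)


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Per-column ground truth as TSV (label, planted residue/purity, realized stats)."""
    with open(path, "w") as fh:
        fh.write("column\tlabel\tresidue\ttarget_purity\trealized_purity\trealized_gap_fraction\n")
        for col in range(1, truth.n_cols + 1):
            if truth.is_planted(col):
                pc = truth.planted[col]
                fh.write(
                    f"{col}\tplanted\t{pc.residue}\t{pc.purity}\t"
                    f"{truth.realized_purity[col]:.6f}\t{truth.realized_gap_fraction[col]:.6f}\n"
                )
            else:
                fh.write(
                    f"{col}\tbackground\t\t\t\t{truth.realized_gap_fraction[col]:.6f}\n"
                )
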