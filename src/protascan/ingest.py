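"""Parsing of UniProt-style protein records and assembly of homologous groups.

Protamine families are assembled from an already-downloaded UniProt record
set (FASTA with ``sp|ACC|NAME``/``tr|ACC|NAME`` headers, or a tab-separated
export) by lineage/gene-name rules, with per-organism deduplication that
prefers reviewed (Swiss-Prot) entries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_AA = STANDARD_AA | frozenset("BZX")

_UNIPROT_HEADER = re.compile(r"^(?P<db>sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)\s*(?P<rest>.*)$")


class RecordParseError(ValueError):
    """A record could not be parsed from its source."""


@dataclass(frozen=True)
class ProteinRecord:
    """One UniProt-style entry."""

    accession: str
    reviewed: bool
    gene_names: frozenset[str]
    organism: str
    lineage: tuple[str, ...]
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - EXTENDED_AA
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains non-amino-acid symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class GroupRule:
    """Membership rule for one homologous group.

    A record belongs to the group when its lineage contains
    ``required_lineage_taxon``, its gene names intersect
    ``accepted_gene_names`` (skipped when the set is empty), and its
    description contains none of ``description_exclusion_words``
    (case-insensitive substring match).
    """

    group_name: str
    required_lineage_taxon: str
    accepted_gene_names: frozenset[str] = frozenset()
    description_exclusion_words: frozenset[str] = frozenset()
    dedupe_per_organism: bool = True

    def matches(self, record: ProteinRecord) -> bool:
        if self.required_lineage_taxon not in record.lineage:
            return False
        if self.accepted_gene_names and not (record.gene_names & self.accepted_gene_names):
            return False
        desc = record.description.lower()
        return not any(word.lower() in desc for word in self.description_exclusion_words)


# The four groups analysed in the protamine study. Gene-name matching is
# exact and case-sensitive against all synonyms a record lists; the fish
# group is lineage-only with a "like" description exclusion and allows
# several paralogs per species.
EUTHERIAN_P1 = GroupRule("eutherian_p1", "Eutheria", frozenset({"PRM1", "Prm1"}))
EUTHERIAN_P2 = GroupRule("eutherian_p2", "Eutheria", frozenset({"PRM2", "Prm2"}))
METATHERIAN_P1 = GroupRule("metatherian_p1", "Metatheria", frozenset({"PRM1", "Prm1"}))
FISH = GroupRule(
    "fish",
    "Actinopterygii",
    description_exclusion_words=frozenset({"like"}),
    dedupe_per_organism=False,
)
STANDARD_RULES = {
    rule.group_name: rule for rule in (EUTHERIAN_P1, EUTHERIAN_P2, METATHERIAN_P1, FISH)
}


@dataclass
class HomologousGroup:
    name: str
    members: list[ProteinRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def organisms(self) -> list[str]:
        return [m.organism for m in self.members]


def _parse_fasta_record(rec) -> ProteinRecord:
    m = _UNIPROT_HEADER.match(rec.description)
    if m is None:
        raise RecordParseError(f"malformed UniProt FASTA header: '>{rec.description}'")
    rest = m.group("rest")
    organism = ""
    gene_names: set[str] = set()
    os_match = re.search(r"\bOS=(.+?)(?=\s+\w\w?=|$)", rest)
    if os_match:
        organism = os_match.group(1).strip()
    gn_match = re.search(r"\bGN=(\S+)", rest)
    if gn_match:
        gene_names.add(gn_match.group(1))
    description = re.split(r"\s+OS=", rest)[0].strip()
    return ProteinRecord(
        accession=m.group("acc"),
        reviewed=m.group("db") == "sp",
        gene_names=frozenset(gene_names),
        organism=organism or m.group("name"),
        lineage=(),
        description=description,
        sequence=str(rec.seq).upper(),
    )


_REVIEWED_TOKENS = {"reviewed", "yes", "true", "1", "swiss-prot", "swissprot", "sp"}
_UNREVIEWED_TOKENS = {"unreviewed", "no", "false", "0", "trembl", "tr"}

_TAB_COLUMNS = ("accession", "reviewed", "gene_names", "organism", "lineage",
                "protein_name", "sequence")


def _parse_tabular(lines: Iterable[str]) -> list[ProteinRecord]:
    it = iter(lines)
    try:
        header = next(it)
    except StopIteration:
        return []
    cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
    missing = set(_TAB_COLUMNS) - set(cols)
    if missing:
        raise RecordParseError(f"tabular export missing columns: {sorted(missing)}")
    idx = {c: cols.index(c) for c in _TAB_COLUMNS}
    records = []
    for lineno, line in enumerate(it, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(cols):
            raise RecordParseError(f"line {lineno}: expected {len(cols)} fields, got {len(parts)}")
        token = parts[idx["reviewed"]].strip().lower()
        if token in _REVIEWED_TOKENS:
            reviewed = True
        elif token in _UNREVIEWED_TOKENS:
            reviewed = False
        else:
            raise RecordParseError(f"line {lineno}: unrecognized reviewed flag '{token}'")
        gene_names = frozenset(
            g for g in re.split(r"[;\s]+", parts[idx["gene_names"]].strip()) if g
        )
        lineage = tuple(
            t.strip() for t in parts[idx["lineage"]].split(";") if t.strip()
        )
        try:
            records.append(
                ProteinRecord(
                    accession=parts[idx["accession"]].strip(),
                    reviewed=reviewed,
                    gene_names=gene_names,
                    organism=parts[idx["organism"]].strip(),
                    lineage=lineage,
                    description=parts[idx["protein_name"]].strip(),
                    sequence=parts[idx["sequence"]].strip().upper(),
                )
            )
        except ValueError as exc:
            raise RecordParseError(f"line {lineno}: {exc}") from exc
    return records


def parse_uniprot_entries(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Parse protein records from UniProt-header FASTA or a tab-separated export.

    The dialect is sniffed from the first non-blank character: ``>`` means
    FASTA, anything else a tabular export with a header row naming the
    columns accession, reviewed, gene_names, organism, lineage,
    protein_name and sequence. Raises :class:`RecordParseError` on
    malformed input and on duplicate accessions.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    if stripped.startswith(">"):
        records = [_parse_fasta_record(r) for r in SeqIO.parse(StringIO(text), "fasta")]
    else:
        records = _parse_tabular(StringIO(text))
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise RecordParseError(f"duplicate accession: {rec.accession}")
        seen.add(rec.accession)
    return records


def filter_group(records: list[ProteinRecord], rule: GroupRule) -> HomologousGroup:
    """Select the records satisfying ``rule``, preserving input order."""
    members = [r for r in records if rule.matches(r)]
    provenance = {
        "rule": rule.group_name,
        "required_lineage_taxon": rule.required_lineage_taxon,
        "n_input": len(records),
        "n_after_filter": len(members),
    }
    return HomologousGroup(rule.group_name, members, provenance)


def dedupe_per_organism(group: HomologousGroup) -> HomologousGroup:
    """Keep at most one member per organism.

    Reviewed (Swiss-Prot) entries win over unreviewed ones; among equally
    reviewed candidates the lexicographically smallest accession wins. The
    output is sorted by accession so the result does not depend on input
    order.
    """
    best: dict[str, ProteinRecord] = {}
    for rec in group.members:
        incumbent = best.get(rec.organism)
        if incumbent is None:
            best[rec.organism] = rec
            continue
        if (not incumbent.reviewed, incumbent.accession) > (not rec.reviewed, rec.accession):
            best[rec.organism] = rec
    members = sorted(best.values(), key=lambda r: r.accession)
    provenance = dict(group.provenance)
    provenance["n_after_dedupe"] = len(members)
    return HomologousGroup(group.name, members, provenance)


def remove_listed_members(
    group: HomologousGroup, exclusions: set[str], reason: str
) -> HomologousGroup:
    """Drop members whose accession or organism appears in ``exclusions``.

    Exclusions that match no member raise a warning, not an error.
    """
    exclusions = set(exclusions)
    matched: set[str] = set()
    kept = []
    for rec in group.members:
        hit = {rec.accession, rec.organism} & exclusions
        if hit:
            matched |= hit
        else:
            kept.append(rec)
    unmatched = exclusions - matched
    if unmatched:
        warnings.warn(
            f"{group.name}: exclusions matched nothing: {sorted(unmatched)}",
            stacklevel=2,
        )
    provenance = dict(group.provenance)
    provenance["removals"] = {
        "reason": reason,
        "n_removed": len(group.members) - len(kept),
        "unmatched_exclusions": sorted(unmatched),
    }
    return HomologousGroup(group.name, kept, provenance)


def write_group_fasta(group: HomologousGroup, path: str | Path) -> None:
    """Write the group's (ungapped) sequences as FASTA with UniProt-style headers."""
    with open(path, "w") as fh:
        for rec in group.members:
            db = "sp" if rec.reviewed else "tr"
            name = rec.organism.replace(" ", "_") or rec.accession
            fh.write(f">{db}|{rec.accession}|{name} {rec.description}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
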