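"""Sequence, alignment and table I/O plus the core data model.

Protein sequences live in plain (optionally line-wrapped) FASTA, one file per
proteome.  Alignments are plain gapped FASTA with ``-`` as the only gap
character (``.`` is converted on read).  Tabular inputs/outputs are TSV with a
header row.  Domain intervals are 1-based inclusive in ungapped reference
coordinates, matching the UniProt feature convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import ALPHABET, AMBIGUOUS

log = logging.getLogger(__name__)

_CANONICAL = set(ALPHABET)


def sanitize_seq(seq: str, *, map_ambiguous: bool = True) -> str:
    """Upper-case a residue string; map B/Z/U/O/J to X (with a warning) or reject.

    Letters outside the 20 canonical residues, X and the ambiguity codes are
    always rejected.
    """
    s = seq.upper()
    residues = set(s)
    amb = residues & AMBIGUOUS
    if amb:
        if not map_ambiguous:
            raise ValueError(f"ambiguous residues {sorted(amb)} present and mapping disabled")
        log.warning("mapping ambiguous residues %s to X", sorted(amb))
        for a in amb:
            s = s.replace(a, "X")
        residues = set(s)
    bad = residues - _CANONICAL
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession and source proteome tag."""

    id: str
    species: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty protein id")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteomeSet:
    """Species → proteins, plus the nested taxonomic levels under study.

    ``levels`` maps a level name (e.g. genus / wgd / class) to the set of
    member species.  When ``nested_order`` is given the sets must be nested in
    that order (genus ⊆ wgd ⊆ class), mirroring the three evolutionary levels
    centred on the reference species.
    """

    proteomes: dict[str, list[ProteinRecord]]
    levels: dict[str, set[str]] = field(default_factory=dict)

    def validate(self, nested_order: list[str] | None = None) -> None:
        for name, species in self.levels.items():
            missing = species - set(self.proteomes)
            if missing:
                raise ValueError(f"level {name!r} names unknown species {sorted(missing)}")
        if nested_order:
            for inner, outer in zip(nested_order, nested_order[1:]):
                if not self.levels[inner] <= self.levels[outer]:
                    extra = self.levels[inner] - self.levels[outer]
                    raise ValueError(
                        f"levels not nested: {inner!r} has species {sorted(extra)} "
                        f"absent from {outer!r}"
                    )

    def proteome(self, species: str) -> list[ProteinRecord]:
        return self.proteomes[species]


@dataclass
class ProteinSetTable:
    """Reference proteins with their category (KP/PFP/PLP) and optional
    experimentally determined domain boundaries (1-based inclusive)."""

    entries: dict[str, dict]  # accession -> {category, domain_start, domain_end}

    CATEGORIES = ("KP", "PFP", "PLP")

    def __post_init__(self):
        for acc, e in self.entries.items():
            if e["category"] not in self.CATEGORIES:
                raise ValueError(f"{acc}: unknown category {e['category']!r}")
            ds, de = e.get("domain_start"), e.get("domain_end")
            if (ds is None) != (de is None):
                raise ValueError(f"{acc}: domain interval must give both ends")
            if ds is not None and not (1 <= ds <= de):
                raise ValueError(f"{acc}: invalid domain interval {ds}..{de}")

    def category(self, acc: str) -> str:
        return self.entries[acc]["category"]

    def domain(self, acc: str) -> tuple[int, int] | None:
        e = self.entries[acc]
        if e.get("domain_start") is None:
            return None
        return e["domain_start"], e["domain_end"]


@dataclass
class AlignmentBlock:
    """A multiple alignment: ordered (id, gapped sequence) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != ncol:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {ncol}"
                )

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, *, species: str = "", map_ambiguous: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA file into ProteinRecords (order preserved).

    The id is the first whitespace-delimited token of the description line;
    the full description is retained verbatim.  Empty files and duplicate ids
    are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                species=species,
                seq=sanitize_seq(str(rec.seq), map_ambiguous=map_ambiguous),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, *, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_aligned_fasta(path) -> AlignmentBlock:
    """Read a plain gapped FASTA alignment; '.' gaps are converted to '-'.

    All-gap columns are kept as-is (column post-processing is left to the
    caller).  Ragged rows raise with the offending id and lengths.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper().replace(".", "-")))
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return AlignmentBlock(rows=rows)


def write_aligned_fasta(block: AlignmentBlock, path, *, width: int = 60) -> None:
    recs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in block.rows]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def load_level_table(
    path,
    *,
    known_species: set[str] | None = None,
    nested_order: list[str] | None = None,
) -> dict[str, set[str]]:
    """Load the species → level-membership TSV.

    Expected columns: ``species`` plus one 0/1 flag column per level.  Returns
    level name → species set.  Species absent from ``known_species`` are
    reported as a warning; an empty level is an error; nesting is validated
    when ``nested_order`` is given (innermost first).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "species" not in df.columns:
        raise ValueError(f"{path}: missing 'species' column")
    level_cols = [c for c in df.columns if c != "species"]
    if not level_cols:
        raise ValueError(f"{path}: no level columns")
    levels: dict[str, set[str]] = {}
    for col in level_cols:
        members = set(df.loc[df[col].astype(int) == 1, "species"])
        if not members:
            raise ValueError(f"{path}: level {col!r} has no species")
        levels[col] = members
    if known_species is not None:
        unknown = set(df["species"]) - known_species
        if unknown:
            warnings.warn(f"species not in any proteome: {sorted(unknown)}")
    if nested_order:
        for inner, outer in zip(nested_order, nested_order[1:]):
            extra = levels[inner] - levels[outer]
            if extra:
                raise ValueError(
                    f"nesting violation: {sorted(extra)} in {inner!r} but not {outer!r}"
                )
    return levels


def load_protein_sets(path) -> ProteinSetTable:
    """Load the protein-set TSV: accession, category, domain_start, domain_end."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "category": str})
    entries = {}
    for _, row in df.iterrows():
        ds = row.get("domain_start")
        de = row.get("domain_end")
        entries[row["accession"]] = {
            "category": row["category"],
            "domain_start": int(ds) if pd.notna(ds) else None,
            "domain_end": int(de) if pd.notna(de) else None,
        }
    return ProteinSetTable(entries=entries)


def write_protein_sets(table: ProteinSetTable, path) -> None:
    rows = []
    for acc, e in table.entries.items():
        rows.append(
            {
                "accession": acc,
                "category": e["category"],
                "domain_start": e.get("domain_start"),
                "domain_end": e.get("domain_end"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
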