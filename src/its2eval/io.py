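"""Sequence records, taxonomy tables and FASTA/TSV serialization.

All sequences are uppercase DNA over ``A/C/G/T/N``; ``U`` is normalized to
``T`` on read.  Coordinates are 0-based, half-open throughout the package.
Taxonomy is carried as a per-record table mapping sequence id to a
four-level lineage (kingdom-level group, family, genus, species).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

TAXONOMY_COLUMNS = ["id", "group", "family", "genus", "species"]
GROUND_TRUTH_COLUMNS = ["id", "core_start", "core_end", "reject_reason", "contaminant"]


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")
    return s


@dataclass
class SequenceRecord:
    """One DNA sequence with identifier and optional free-text description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def n_count(self) -> int:
        return self.seq.count("N")

    def gc_fraction(self) -> float:
        """G+C over unambiguous (non-N) positions; NaN for all-N sequences."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return (self.seq.count("G") + self.seq.count("C")) / acgt


@dataclass(frozen=True)
class Lineage:
    group: str
    family: str
    genus: str
    species: str


class Taxonomy:
    """A species-level hierarchy: group -> family -> genus -> species.

    Invariants enforced on construction: genus names are unique across the
    dataset and species names are unique within their genus (hence globally,
    since species names embed the genus binomially).
    """

    def __init__(self, lineages: Sequence[Lineage]):
        self.lineages = list(lineages)
        genus_to_family: dict[str, str] = {}
        seen_species: set[tuple[str, str]] = set()
        for lin in self.lineages:
            prev = genus_to_family.get(lin.genus)
            if prev is not None and prev != lin.family:
                raise ValueError(f"genus {lin.genus!r} appears in two families")
            genus_to_family[lin.genus] = lin.family
            key = (lin.genus, lin.species)
            if key in seen_species:
                raise ValueError(f"duplicate species {lin.species!r} in genus {lin.genus!r}")
            seen_species.add(key)

    @property
    def species(self) -> list[str]:
        return [lin.species for lin in self.lineages]

    @property
    def genera(self) -> list[str]:
        return sorted({lin.genus for lin in self.lineages})

    @property
    def families(self) -> list[str]:
        return sorted({lin.family for lin in self.lineages})

    def by_species(self) -> dict[str, Lineage]:
        return {lin.species: lin for lin in self.lineages}

    def __len__(self) -> int:
        return len(self.lineages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return self.lineages == other.lineages


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq),
                                      description=rec.description[len(rec.id):].strip()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    try:
        seqrecs = [SeqRecord(Seq(r.seq), id=r.id, description=r.description)
                   for r in records]
        with open(path, "w") as fh:
            SeqIO.write(seqrecs, fh, "fasta")
    except OSError as exc:
        raise OSError(f"cannot write FASTA to {path}: {exc}") from exc


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns {sorted(missing)}")
    return df[TAXONOMY_COLUMNS]


def write_taxonomy_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TAXONOMY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "reject_reason": str})
    df["reject_reason"] = df["reject_reason"].fillna("")
    df["contaminant"] = df["contaminant"].astype(bool)
    return df[GROUND_TRUTH_COLUMNS]


def write_ground_truth(df: pd.DataFrame, path: str | Path) -> None:
    df[GROUND_TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def taxonomy_lookup(taxonomy_table: pd.DataFrame) -> dict[str, Lineage]:
    """Map record id -> Lineage; raises on duplicate ids."""
    if taxonomy_table["id"].duplicated().any():
        dup = taxonomy_table.loc[taxonomy_table["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in taxonomy table")
    return {
        row.id: Lineage(row.group, row.family, row.genus, row.species)
        for row in taxonomy_table.itertuples()
    }
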