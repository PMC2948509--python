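"""Reference-database curation: exclusion filters, fungal screen, consensus.

Records are excluded, with the first failing rule reported, in the fixed
order: trimmed length below the minimum, more than the allowed number of
ambiguous N bases, an unnamed species epithet (``sp.`` / ``spp.`` /
``aff.`` tokens), and finally membership in a genus left with fewer than
the minimum number of species after the first three rules.  Suspected
fungal contaminants are flagged by two independent routes — a fungal
profile scan (E-value gate) and best-identity similarity search against a
fungal reference pool — and are reported rather than silently removed;
dropping them is an explicit configuration choice.

Per-species reference barcodes are majority-rule consensus sequences over
a center-star multiple alignment (star centered on the longest record);
ties become IUPAC ambiguity codes and majority-gap columns are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import GumbelCalibration, ProfileModel, calibrate, scan_profile
from .distances import AlignmentScoring, make_aligner
from .io import (
    SequenceRecord,
    read_fasta,
    read_taxonomy_table,
    taxonomy_lookup,
    write_fasta,
    write_taxonomy_table,
)

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

REASON_SHORT = "short"
REASON_AMBIGUOUS = "ambiguous"
REASON_UNNAMED = "unnamed"
REASON_MONOTYPIC = "monotypic_genus"
REASON_FUNGAL = "suspect_fungal"


@dataclass(frozen=True)
class CurationConfig:
    """Exclusion thresholds; defaults follow the inclusive boundary reading:
    exactly ``min_length`` nt is kept and exactly ``max_n`` Ns is kept."""

    min_length: int = 100
    max_n: int = 2
    unnamed_tokens: tuple[str, ...] = ("sp.", "spp.", "aff.")
    min_species_per_genus: int = 2
    fungal_max_evalue: float = 1.0
    fungal_min_identity: float = 0.90
    drop_fungal: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_n < 0:
            raise ValueError("max_n must be >= 0")


def apply_filters(
    records: Sequence[SequenceRecord],
    taxonomy_table: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Partition records into (kept, rejected id -> first failing reason).

    Genus occupancy is evaluated on the set surviving the first three
    rules, so the result is independent of input order.
    """
    lookup = taxonomy_lookup(taxonomy_table)
    for rec in records:
        if rec.id not in lookup:
            raise KeyError(f"record {rec.id!r} has no taxonomy row")

    rejected: dict[str, str] = {}
    survivors: list[SequenceRecord] = []
    for rec in records:
        species = lookup[rec.id].species
        if len(rec) < config.min_length:
            rejected[rec.id] = REASON_SHORT
        elif rec.n_count() > config.max_n:
            rejected[rec.id] = REASON_AMBIGUOUS
        elif any(tok.lower() in species.lower() for tok in config.unnamed_tokens):
            rejected[rec.id] = REASON_UNNAMED
        else:
            survivors.append(rec)

    species_per_genus: dict[str, set[str]] = {}
    for rec in survivors:
        lin = lookup[rec.id]
        species_per_genus.setdefault(lin.genus, set()).add(lin.species)

    kept = []
    for rec in survivors:
        lin = lookup[rec.id]
        if len(species_per_genus[lin.genus]) < config.min_species_per_genus:
            rejected[rec.id] = REASON_MONOTYPIC
        else:
            kept.append(rec)
    return kept, rejected


def screen_fungal(
    records: Sequence[SequenceRecord],
    fungal_profile: ProfileModel | None,
    fungal_refs: Sequence[SequenceRecord],
    config: CurationConfig = CurationConfig(),
    scoring: AlignmentScoring = AlignmentScoring(),
    calib_seed: int = 0,
) -> pd.DataFrame:
    """Flag suspected fungal records via the profile and similarity routes.

    Returns one row per record with separate ``suspect_fungal_hmm`` and
    ``suspect_fungal_blast`` flags (the two counts are reported apart, as
    independent lines of evidence).  Identity is coverage-weighted so that
    short chance local alignments cannot saturate it: identical columns of
    the best local alignment divided by the length of the shorter of the
    two sequences.
    """
    if not records:
        return pd.DataFrame(columns=["id", "suspect_fungal_hmm",
                                     "suspect_fungal_blast", "best_identity"])
    if fungal_profile is None and not fungal_refs:
        warnings.warn("empty fungal reference set: fungal screening skipped")
        return pd.DataFrame({
            "id": [r.id for r in records],
            "suspect_fungal_hmm": False,
            "suspect_fungal_blast": False,
            "best_identity": float("nan"),
        })

    hmm_cal: GumbelCalibration | None = None
    if fungal_profile is not None:
        hmm_cal = calibrate(fungal_profile, records[0].seq, seed=calib_seed)
    aligner = make_aligner(scoring, "local")

    rows = []
    for rec in records:
        hmm_flag = False
        if fungal_profile is not None:
            hit = scan_profile(fungal_profile, rec, calibration=hmm_cal)
            hmm_flag = hit.e_value <= config.fungal_max_evalue
        best_identity = float("nan")
        blast_flag = False
        for ref in fungal_refs:
            alignment = aligner.align(rec.seq, ref.seq)[0]
            denom = min(len(rec.seq), len(ref.seq))
            ident = alignment.counts().identities / denom if denom else 0.0
            if not best_identity >= ident:   # NaN-safe maximum
                best_identity = ident
        if fungal_refs:
            blast_flag = best_identity >= config.fungal_min_identity
        rows.append({"id": rec.id, "suspect_fungal_hmm": hmm_flag,
                     "suspect_fungal_blast": blast_flag,
                     "best_identity": best_identity})
    return pd.DataFrame(rows)


def _center_star_msa(
    seqs: Sequence[str],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[str]:
    """Multiple alignment by pairwise merging around the longest sequence."""
    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_idx]
    aligner = make_aligner(scoring, "global")

    residues: list[dict[int, str]] = []     # per row: center position -> residue
    insertions: list[dict[int, str]] = []   # per row: insertion before center pos
    order = []
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        order.append(i)
        alignment = aligner.align(center, s)[0]
        ca, ra = str(alignment[0]), str(alignment[1])
        res: dict[int, str] = {}
        ins: dict[int, str] = {}
        cpos = 0
        for x, y in zip(ca, ra):
            if x == "-":
                if y != "-":
                    ins[cpos] = ins.get(cpos, "") + y
            else:
                res[cpos] = y
                cpos += 1
        residues.append(res)
        insertions.append(ins)

    max_ins = {p: max(len(ins.get(p, "")) for ins in insertions) if insertions else 0
               for p in range(len(center) + 1)}

    rows = [[] for _ in range(len(seqs))]
    row_of = {idx: r + 1 for r, idx in enumerate(order)}  # row 0 is the center
    for p in range(len(center) + 1):
        width = max_ins[p]
        if width:
            rows[0].append("-" * width)
            for r, ins in enumerate(insertions):
                frag = ins.get(p, "")
                rows[r + 1].append(frag.ljust(width, "-"))
        if p < len(center):
            rows[0].append(center[p])
            for r, res in enumerate(residues):
                rows[r + 1].append(res.get(p, "-"))

    merged = ["".join(parts) for parts in rows]
    # restore the input order of rows
    out = [""] * len(seqs)
    out[center_idx] = merged[0]
    for idx in order:
        out[idx] = merged[row_of[idx]]
    return out


def species_consensus(
    records: Sequence[SequenceRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> str:
    """Majority-rule consensus barcode of one species' records.

    Columns that are majority-gap are dropped; residue ties yield the
    IUPAC code of the tied set.  A single record is its own consensus.
    """
    if not records:
        raise ValueError("cannot build a consensus from zero records")
    if len(records) == 1:
        return records[0].seq
    msa = _center_star_msa([r.seq for r in records], scoring)
    nrows = len(msa)
    out = []
    for col in zip(*msa):
        gaps = col.count("-")
        if gaps * 2 > nrows:
            continue
        counts = {b: col.count(b) for b in "ACGT"}
        top = max(counts.values())
        if top == 0:
            out.append("N")     # column of Ns/gaps only
            continue
        tied = frozenset(b for b, c in counts.items() if c == top)
        out.append(IUPAC_CODES[tied])
    return "".join(out)


@dataclass
class ReferenceDatabase:
    """Curated records indexed by taxonomy, plus per-species consensus barcodes."""

    records: list[SequenceRecord]
    taxonomy_table: pd.DataFrame        # rows for retained records only
    consensus: dict[str, str]           # species -> consensus sequence
    provenance: pd.DataFrame            # id, decision, reason

    def __post_init__(self) -> None:
        self._lineages = taxonomy_lookup(self.taxonomy_table)

    def lineage_of(self, record_id: str):
        return self._lineages[record_id]

    @property
    def species(self) -> list[str]:
        return sorted({lin.species for lin in self._lineages.values()})

    @property
    def genera(self) -> list[str]:
        return sorted({lin.genus for lin in self._lineages.values()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return (self.records == other.records
                and self.consensus == other.consensus
                and self.taxonomy_table.reset_index(drop=True).equals(
                    other.taxonomy_table.reset_index(drop=True))
                and self.provenance.reset_index(drop=True).equals(
                    other.provenance.reset_index(drop=True)))

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"records": out / "refdb.fasta",
                 "taxonomy": out / "taxonomy.tsv",
                 "consensus": out / "consensus.fasta",
                 "provenance": out / "provenance.tsv"}
        write_fasta(self.records, paths["records"])
        write_taxonomy_table(self.taxonomy_table, paths["taxonomy"])
        with open(paths["consensus"], "w") as fh:   # may contain IUPAC codes
            for sp in sorted(self.consensus):
                fh.write(f">{sp.replace(' ', '_')}\n{self.consensus[sp]}\n")
        self.provenance.to_csv(paths["provenance"], sep="\t", index=False)
        return paths

    @classmethod
    def load(cls, out_dir: str | Path) -> "ReferenceDatabase":
        out = Path(out_dir)
        records = read_fasta(out / "refdb.fasta")
        taxonomy = read_taxonomy_table(out / "taxonomy.tsv")
        consensus = {}
        with open(out / "consensus.fasta") as fh:
            name = None
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    name = line[1:].replace("_", " ")
                    consensus[name] = ""
                elif name is not None:
                    consensus[name] += line
        provenance = pd.read_csv(out / "provenance.tsv", sep="\t", dtype=str).fillna("")
        return cls(records, taxonomy, consensus, provenance)


def build_reference_db(
    records: Sequence[SequenceRecord],
    taxonomy_table: pd.DataFrame,
    config: CurationConfig = CurationConfig(),
    fungal_profile: ProfileModel | None = None,
    fungal_refs: Sequence[SequenceRecord] = (),
    scoring: AlignmentScoring = AlignmentScoring(),
    calib_seed: int = 0,
) -> ReferenceDatabase:
    """Filters -> fungal screen -> per-species consensus, with full provenance."""
    kept, rejected = apply_filters(records, taxonomy_table, config)

    flags = None
    if fungal_profile is not None or fungal_refs:
        flags = screen_fungal(kept, fungal_profile, fungal_refs, config,
                              scoring, calib_seed)
        if config.drop_fungal and len(flags):
            suspect = set(flags.loc[flags.suspect_fungal_hmm
                                    | flags.suspect_fungal_blast, "id"])
            kept = [r for r in kept if r.id not in suspect]
            for rid in suspect:
                rejected[rid] = REASON_FUNGAL

    if not kept:
        raise ValueError("empty reference database: no records survive curation")

    lookup = taxonomy_lookup(taxonomy_table)
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in kept:
        by_species.setdefault(lookup[rec.id].species, []).append(rec)
    consensus = {sp: species_consensus(recs, scoring)
                 for sp, recs in by_species.items()}

    kept_ids = {r.id for r in kept}
    prov_rows = []
    for rec in records:
        if rec.id in kept_ids:
            prov_rows.append({"id": rec.id, "decision": "kept", "reason": ""})
        else:
            prov_rows.append({"id": rec.id, "decision": "rejected",
                              "reason": rejected[rec.id]})
    if flags is not None and len(flags):
        flag_map = flags.set_index("id")
        for row in prov_rows:
            if row["id"] in flag_map.index and row["decision"] == "kept":
                f = flag_map.loc[row["id"]]
                marks = []
                if f.suspect_fungal_hmm:
                    marks.append("suspect_fungal_hmm")
                if f.suspect_fungal_blast:
                    marks.append("suspect_fungal_blast")
                row["reason"] = ";".join(marks)

    tax = taxonomy_table[taxonomy_table["id"].isin(kept_ids)].reset_index(drop=True)
    provenance = pd.DataFrame(prov_rows, columns=["id", "decision", "reason"])
    return ReferenceDatabase(records=list(kept), taxonomy_table=tax,
                             consensus=consensus, provenance=provenance)
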