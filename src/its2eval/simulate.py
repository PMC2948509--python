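"""Seeded generator of taxonomically structured ITS2-like datasets.

The generator emulates the structure of a multi-family rRNA barcode
collection: per genus, an ancestral ITS2 core is drawn at a target GC
composition and species diverge from it under a Kimura two-parameter
(K2P) substitution process; conserved 5.8S-tail and 28S-head anchor
segments (shared dataset-wide, with small per-record noise) flank each
core.  The within-genus tree is a star phylogeny and ultrametric: species
tips sit at depth ``inter_branch`` and conspecific records coalesce at
depth ``intra_branch``, so the expected pairwise K2P distance is
``2*inter_branch`` between congeneric species and ``2*intra_branch``
within a species — the quantities the divergence module estimates.

Degenerate records (too short, N-rich, unnamed "sp."/"aff." species,
fungal contaminants) can be injected at seeded rates to exercise the
curation filters, with every alteration recorded in the ground truth.

All randomness flows from ``SimulationParams.seed``; identical parameters
yield byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Lineage,
    SequenceRecord,
    Taxonomy,
    read_fasta,
    read_ground_truth,
    read_taxonomy_table,
    write_fasta,
    write_ground_truth,
    write_taxonomy_table,
)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: stream label mixed into the seed for the degenerate-injection RNG, so the
#: injection draw can be replayed independently of sequence simulation
DEGENERATE_STREAM = 17


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Branch lengths are expected substitutions per site.  ``intra_branch``
    is the coalescent depth within a species (half the expected
    conspecific pairwise distance); ``inter_branch`` is the species-tip
    depth within a genus (half the expected congeneric distance).
    """

    seed: int
    n_families: int = 5
    genera_per_family: int = 10
    species_per_genus: int = 2
    seqs_per_species: int = 3
    core_length: int = 360
    flank_5_8S_length: int = 60
    flank_28S_length: int = 60
    intra_branch: float = 0.01
    inter_branch: float = 0.2
    kappa: float = 2.0
    gc_target: float = 0.55
    flank_noise: float = 0.02
    contaminant_rate: float = 0.0
    short_rate: float = 0.0
    n_rate: float = 0.0
    unnamed_rate: float = 0.0
    group_name: str = "simulated"

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "seqs_per_species", "core_length", "flank_5_8S_length",
                     "flank_28S_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("contaminant_rate", "short_rate", "n_rate", "unnamed_rate",
                     "gc_target", "flank_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.intra_branch < 0 or self.inter_branch < 0:
            raise ValueError("branch lengths must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        total = (self.contaminant_rate + self.short_rate + self.n_rate
                 + self.unnamed_rate)
        if total > 1.0 + 1e-12:
            raise ValueError(f"degenerate rates sum to {total} > 1")


def k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K2P (K80) substitution probabilities after branch length ``t``.

    Rates are normalized so ``t`` is the expected number of substitutions
    per site; ``kappa`` is the transition/transversion *rate* ratio
    alpha/beta.  Base order A, C, G, T.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    # transition partners: A<->G, C<->T
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = p_ts
    P[1, 3] = P[3, 1] = p_ts
    return P


def _draw_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _evolve(seq: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve an index-encoded sequence along a branch of length ``t``."""
    if t == 0.0:
        rng.random(len(seq))  # keep the stream position branch-independent
        return seq.copy()
    P = k2p_transition_matrix(t, kappa)
    cum = np.cumsum(P, axis=1)[seq]          # (L, 4)
    u = rng.random(len(seq))
    return (u[:, None] > cum).sum(axis=1).astype(seq.dtype)


def _point_noise(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` by a uniform other base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    shifts = rng.integers(1, 4, size=len(seq))
    out[hit] = (out[hit] + shifts[hit]) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


@dataclass
class SimulatedDataset:
    """Records plus ground truth and the auxiliary inputs downstream stages need."""

    params: SimulationParams
    records: list[SequenceRecord]
    taxonomy: Taxonomy
    taxonomy_table: pd.DataFrame
    ground_truth: pd.DataFrame
    anchor_5_8S: str
    anchor_28S: str
    alignment_5_8S: list[SequenceRecord]
    alignment_28S: list[SequenceRecord]
    fungal_refs: list[SequenceRecord]


def generate_taxonomy(params: SimulationParams) -> Taxonomy:
    """Deterministic group/family/genus/species hierarchy with unique names."""
    lineages = []
    genus_no = 0
    for f in range(params.n_families):
        family = f"Fam{f + 1:02d}"
        for _g in range(params.genera_per_family):
            genus_no += 1
            genus = f"Genus{genus_no:03d}"
            for s in range(params.species_per_genus):
                species = f"{genus} var{s + 1:02d}"
                lineages.append(Lineage(params.group_name, family, genus, species))
    return Taxonomy(lineages)


def simulate_sequences(
    taxonomy: Taxonomy, params: SimulationParams
) -> SimulatedDataset:
    """Simulate flanked ITS2-like records for every species in ``taxonomy``.

    Returns the records together with per-record taxonomy rows, ground-truth
    core intervals (0-based half-open on the raw sequence), the canonical
    anchor segments, small noisy anchor alignments for profile building, and
    a divergent fungal reference pool for contamination screening.
    """
    rng = np.random.default_rng(params.seed)
    anchor58 = _draw_sequence(params.flank_5_8S_length, params.gc_target, rng)
    anchor28 = _draw_sequence(params.flank_28S_length, params.gc_target, rng)

    # anchor alignments: substitution-only noisy copies, already column-aligned
    aln58 = [SequenceRecord(f"aln58_{i + 1}", _to_str(_point_noise(anchor58, params.flank_noise, rng)))
             for i in range(8)]
    aln28 = [SequenceRecord(f"aln28_{i + 1}", _to_str(_point_noise(anchor28, params.flank_noise, rng)))
             for i in range(8)]

    # fungal decoy pool: unrelated high-divergence cores at neutral GC
    fungal_core = _draw_sequence(params.core_length, 0.50, rng)
    fungal_refs = [
        SequenceRecord(f"fungal{i + 1:02d}", _to_str(_point_noise(fungal_core, 0.05, rng)))
        for i in range(6)
    ]

    species_branch = max(params.inter_branch - params.intra_branch, 0.0)

    records: list[SequenceRecord] = []
    tax_rows = []
    gt_rows = []
    by_genus: dict[str, list[Lineage]] = {}
    for lin in taxonomy.lineages:
        by_genus.setdefault(lin.genus, []).append(lin)

    for genus in sorted(by_genus):
        ancestral = _draw_sequence(params.core_length, params.gc_target, rng)
        for lin in by_genus[genus]:
            species_core = _evolve(ancestral, species_branch, params.kappa, rng)
            epithet = lin.species.split()[-1]
            for k in range(params.seqs_per_species):
                core = _evolve(species_core, params.intra_branch, params.kappa, rng)
                f58 = _point_noise(anchor58, params.flank_noise, rng)
                f28 = _point_noise(anchor28, params.flank_noise, rng)
                rid = f"{genus}_{epithet}_r{k + 1}"
                seq = _to_str(f58) + _to_str(core) + _to_str(f28)
                records.append(SequenceRecord(rid, seq))
                tax_rows.append((rid, lin.group, lin.family, lin.genus, lin.species))
                core_start = len(f58)
                gt_rows.append((rid, core_start, core_start + len(core), "", False))

    taxonomy_table = pd.DataFrame(tax_rows, columns=["id", "group", "family",
                                                     "genus", "species"])
    ground_truth = pd.DataFrame(gt_rows, columns=["id", "core_start", "core_end",
                                                  "reject_reason", "contaminant"])
    return SimulatedDataset(
        params=params,
        records=records,
        taxonomy=taxonomy,
        taxonomy_table=taxonomy_table,
        ground_truth=ground_truth,
        anchor_5_8S=_to_str(anchor58),
        anchor_28S=_to_str(anchor28),
        alignment_5_8S=aln58,
        alignment_28S=aln28,
        fungal_refs=fungal_refs,
    )


def draw_degenerate_categories(n: int, params: SimulationParams) -> list[str]:
    """Replay the seeded category draw used by :func:`inject_degenerates`.

    Returns one of ``short / ambiguous / unnamed / contaminant / ""`` per
    record, in record order.
    """
    rng = np.random.default_rng([params.seed, DEGENERATE_STREAM])
    u = rng.random(n)
    edges = np.cumsum([params.short_rate, params.n_rate, params.unnamed_rate,
                       params.contaminant_rate])
    names = ["short", "ambiguous", "unnamed", "contaminant"]
    out = []
    for x in u:
        idx = int(np.searchsorted(edges, x, side="right"))
        out.append(names[idx] if idx < 4 else "")
    return out


def inject_degenerates(dataset: SimulatedDataset,
                       params: SimulationParams | None = None) -> SimulatedDataset:
    """Return a copy of ``dataset`` with seeded degenerate records injected.

    A seeded fraction of records is truncated below 100 nt (core shortened),
    given >=3 ambiguous N bases, relabelled with an unnamed "sp."/"aff."
    species, or replaced by a fungal decoy core.  Each altered record's
    intended-reject reason (or contamination flag) is recorded in the
    returned ground truth; all degenerate draws use an RNG stream separate
    from sequence simulation so they are replayable.
    """
    params = params or dataset.params
    cats = draw_degenerate_categories(len(dataset.records), params)
    rng = np.random.default_rng([params.seed, DEGENERATE_STREAM, 1])

    fungal_pool = [np.array([_BASE_INDEX[b] for b in r.seq]) for r in dataset.fungal_refs]

    records = []
    tax = dataset.taxonomy_table.copy()
    gt = dataset.ground_truth.copy()
    tax = tax.set_index("id", drop=False)
    gt = gt.set_index("id", drop=False)

    for rec, cat in zip(dataset.records, cats):
        row = gt.loc[rec.id]
        start, end = int(row.core_start), int(row.core_end)
        flank5, core, flank3 = rec.seq[:start], rec.seq[start:end], rec.seq[end:]
        if cat == "short":
            new_len = int(rng.integers(40, 100))
            core = core[:new_len]
            gt.loc[rec.id, ["core_end", "reject_reason"]] = start + len(core), "short"
        elif cat == "ambiguous":
            k = int(rng.integers(3, 6))
            pos = rng.choice(len(core), size=min(k, len(core)), replace=False)
            core_list = list(core)
            for p in pos:
                core_list[p] = "N"
            core = "".join(core_list)
            gt.loc[rec.id, "reject_reason"] = "ambiguous"
        elif cat == "unnamed":
            genus = tax.loc[rec.id, "genus"]
            epithet = tax.loc[rec.id, "species"].split()[-1]
            token = "sp." if rng.random() < 0.5 else f"aff. {epithet}"
            tax.loc[rec.id, "species"] = f"{genus} {token}"
            gt.loc[rec.id, "reject_reason"] = "unnamed"
        elif cat == "contaminant":
            decoy = fungal_pool[int(rng.integers(len(fungal_pool)))]
            core = _to_str(_point_noise(decoy, 0.02, rng))
            gt.loc[rec.id, ["core_end", "reject_reason"]] = start + len(core), "contaminant"
            gt.loc[rec.id, "contaminant"] = True
        records.append(SequenceRecord(rec.id, flank5 + core + flank3,
                                      rec.description))

    return replace(
        dataset,
        records=records,
        taxonomy_table=tax.reset_index(drop=True),
        ground_truth=gt.reset_index(drop=True),
    )


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Convenience: taxonomy + sequences + degenerate injection in one call."""
    dataset = simulate_sequences(generate_taxonomy(params), params)
    if (params.short_rate or params.n_rate or params.unnamed_rate
            or params.contaminant_rate):
        dataset = inject_degenerates(dataset, params)
    return dataset


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a dataset to FASTA/TSV files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw_fasta": out / "raw.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "alignment_5_8S": out / "aln_5_8S.fasta",
        "alignment_28S": out / "aln_28S.fasta",
        "fungal_refs": out / "fungal_refs.fasta",
    }
    try:
        write_fasta(dataset.records, paths["raw_fasta"])
        write_taxonomy_table(dataset.taxonomy_table, paths["taxonomy"])
        write_ground_truth(dataset.ground_truth, paths["ground_truth"])
        write_fasta(dataset.alignment_5_8S, paths["alignment_5_8S"])
        write_fasta(dataset.alignment_28S, paths["alignment_28S"])
        write_fasta(dataset.fungal_refs, paths["fungal_refs"])
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return paths


def read_dataset(out_dir: str | Path) -> tuple[list[SequenceRecord], pd.DataFrame, pd.DataFrame]:
    """Read back (records, taxonomy table, ground truth) written by write_dataset."""
    out = Path(out_dir)
    return (
        read_fasta(out / "raw.fasta"),
        read_taxonomy_table(out / "taxonomy.tsv"),
        read_ground_truth(out / "ground_truth.tsv"),
    )
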