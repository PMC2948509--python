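"""Pairwise K2P divergence and the six intra/inter-specific barcode-gap metrics.

Distances are Kimura two-parameter (K2P): over alignment columns where both
residues are unambiguous bases, with transition proportion P and
transversion proportion Q,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairs are aligned globally (Needleman-Wunsch with affine gaps) before
counting; gap and N columns are excluded from P and Q.  Saturated pairs
(a log argument <= 0) are flagged invalid and excluded from all means,
with a logged count, rather than clamped.

Intra-specific variation is summarized by the pooled mean conspecific
distance, theta (per-species mean, averaged unweighted over species) and
the coalescent depth (per-species maximum, averaged over species);
inter-specific divergence by the pooled mean congeneric heterospecific
distance, theta-prime (per-genus mean, averaged unweighted over genera)
and the minimum inter-specific distance (per-species nearest congeneric
heterospecific, averaged over species).  Standard deviations are
population-style (divide by n) over the respective pooled or per-taxon
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io import SequenceRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class AlignmentScoring:
    """Shared DNA scoring for global (divergence) and local (search) alignment."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0      # cost of the first residue of a gap
    gap_extend: float = -1.0    # each further residue


def make_aligner(scoring: AlignmentScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


@dataclass
class AlignedPair:
    """Two gapped sequences of equal length plus their source ids."""

    a: str
    b: str
    id_a: str = "a"
    id_b: str = "b"
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned sequences differ in gapped length")


def align_pair(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignedPair:
    """Optimal global alignment of two sequences under affine-gap scoring.

    A gap of length g costs ``gap_open + (g-1) * gap_extend``.  Among
    co-optimal alignments the first in Bio.Align's deterministic
    enumeration order is taken.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else str(a)
    sb = b.seq if isinstance(b, SequenceRecord) else str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = make_aligner(scoring, "global")
    alignment = aligner.align(sa, sb)[0]
    return AlignedPair(
        a=str(alignment[0]),
        b=str(alignment[1]),
        id_a=a.id if isinstance(a, SequenceRecord) else "a",
        id_b=b.id if isinstance(b, SequenceRecord) else "b",
        score=alignment.score,
    )


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    n_comparable: int
    d: float            # NaN when invalid
    valid: bool


def k2p_from_proportions(P: float, Q: float, n_comparable: int = 0) -> K2PResult:
    """K2P distance from transition/transversion proportions (closed form)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P, Q, n_comparable, float("nan"), False)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P, Q, n_comparable, d, True)


def k2p_distance(pair: AlignedPair) -> K2PResult:
    """K2P distance over comparable columns (both residues in {A,C,G,T})."""
    transitions = transversions = n = 0
    for x, y in zip(pair.a, pair.b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError(f"no comparable columns between {pair.id_a!r} and {pair.id_b!r}")
    return k2p_from_proportions(transitions / n, transversions / n, n)


def p_distance(pair: AlignedPair) -> float:
    """Plain proportion of differing comparable columns (for diagnostics)."""
    diff = n = 0
    for x, y in zip(pair.a, pair.b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("no comparable columns")
    return diff / n


@dataclass
class DistanceMatrix:
    """Symmetric labelled K2P matrix with per-pair validity flags."""

    ids: list[str]
    d: np.ndarray           # (n, n) float, NaN where invalid
    valid: np.ndarray       # (n, n) bool; diagonal True

    @property
    def n_invalid_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int((~self.valid[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def distance_matrix(
    records: Sequence[SequenceRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DistanceMatrix:
    """All-pairs K2P distances (align_pair + k2p_distance per pair)."""
    if len(records) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    n = len(records)
    d = np.zeros((n, n))
    valid = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(align_pair(records[i], records[j], scoring))
            d[i, j] = d[j, i] = res.d
            valid[i, j] = valid[j, i] = res.valid
    return DistanceMatrix(ids=[r.id for r in records], d=d, valid=valid)


@dataclass(frozen=True)
class MetricStat:
    """Mean +/- population SD of one divergence metric, with sample size."""

    mean: float
    sd: float
    n: int

    @staticmethod
    def from_sample(values: Sequence[float]) -> "MetricStat | None":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return None
        return MetricStat(float(arr.mean()), float(arr.std(ddof=0)), int(arr.size))


@dataclass
class _PairSamples:
    """Raw per-pair / per-taxon samples feeding the six metrics."""

    intra_pooled: list[float] = field(default_factory=list)
    species_means: list[float] = field(default_factory=list)
    species_maxima: list[float] = field(default_factory=list)
    inter_pooled: list[float] = field(default_factory=list)
    genus_means: list[float] = field(default_factory=list)
    species_min_inter: list[float] = field(default_factory=list)
    n_invalid: int = 0
    n_species_multi: int = 0    # species with >= 2 records
    n_genera_multi: int = 0     # genera with >= 2 species

    def merge(self, other: "_PairSamples") -> None:
        for name in ("intra_pooled", "species_means", "species_maxima",
                     "inter_pooled", "genus_means", "species_min_inter"):
            getattr(self, name).extend(getattr(other, name))
        self.n_invalid += other.n_invalid
        self.n_species_multi += other.n_species_multi
        self.n_genera_multi += other.n_genera_multi


def _collect_samples(
    matrix: DistanceMatrix,
    species: Sequence[str],
    genus: Sequence[str] | None = None,
) -> _PairSamples:
    n = len(matrix.ids)
    if len(species) != n:
        raise ValueError("species labels must cover all matrix rows")
    if genus is not None and len(genus) != n:
        raise ValueError("genus labels must cover all matrix rows")
    out = _PairSamples()
    out.n_invalid = matrix.n_invalid_pairs

    # conspecific samples
    by_species: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        by_species.setdefault(sp, []).append(i)
    for sp, idx in by_species.items():
        if len(idx) < 2:
            continue
        vals = [matrix.d[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
                if matrix.valid[i, j]]
        if not vals:
            continue
        out.n_species_multi += 1
        out.intra_pooled.extend(vals)
        out.species_means.append(float(np.mean(vals)))
        out.species_maxima.append(float(np.max(vals)))

    # congeneric heterospecific samples
    if genus is None:
        genus = ["_one_genus"] * n
    by_genus: dict[str, list[int]] = {}
    for i, g in enumerate(genus):
        by_genus.setdefault(g, []).append(i)
    for g, idx in by_genus.items():
        if len({species[i] for i in idx}) < 2:
            continue
        pair_vals = []
        per_species_min: dict[str, float] = {}
        for a, i in enumerate(idx):
            for j in idx[a + 1:]:
                if species[i] == species[j] or not matrix.valid[i, j]:
                    continue
                v = matrix.d[i, j]
                pair_vals.append(v)
                for sp in (species[i], species[j]):
                    if sp not in per_species_min or v < per_species_min[sp]:
                        per_species_min[sp] = v
        if not pair_vals:
            continue
        out.n_genera_multi += 1
        out.inter_pooled.extend(pair_vals)
        out.genus_means.append(float(np.mean(pair_vals)))
        out.species_min_inter.extend(per_species_min[sp] for sp in sorted(per_species_min))
    return out


@dataclass
class IntraMetrics:
    all_intra: MetricStat | None
    theta: MetricStat | None
    coalescent_depth: MetricStat | None


@dataclass
class InterMetrics:
    all_inter: MetricStat | None
    theta_prime: MetricStat | None
    min_inter: MetricStat | None


def intra_metrics(matrix: DistanceMatrix, species: Sequence[str]) -> IntraMetrics:
    """Pooled conspecific mean, theta and coalescent depth.

    Species with fewer than 2 records contribute nothing; when no species
    has >= 2 records all three metrics are absent (None).
    """
    s = _collect_samples(matrix, species)
    return IntraMetrics(
        all_intra=MetricStat.from_sample(s.intra_pooled),
        theta=MetricStat.from_sample(s.species_means),
        coalescent_depth=MetricStat.from_sample(s.species_maxima),
    )


def inter_metrics(
    matrix: DistanceMatrix,
    species: Sequence[str],
    genus: Sequence[str],
) -> InterMetrics:
    """Pooled congeneric mean, theta-prime and minimum inter-specific distance.

    theta-prime averages genera unweighted; the pooled mean weights genera
    by pair count.  Genera without >= 2 species contribute nothing.
    """
    s = _collect_samples(matrix, species, genus)
    return InterMetrics(
        all_inter=MetricStat.from_sample(s.inter_pooled),
        theta_prime=MetricStat.from_sample(s.genus_means),
        min_inter=MetricStat.from_sample(s.species_min_inter),
    )


@dataclass
class DivergenceSummary:
    """The six barcode-gap statistics for one taxon set."""

    all_inter: MetricStat | None
    theta_prime: MetricStat | None
    min_inter: MetricStat | None
    all_intra: MetricStat | None
    theta: MetricStat | None
    coalescent_depth: MetricStat | None
    n_records: int
    n_species: int
    n_genera: int
    n_invalid_pairs: int

    _FIELDS = ("all_inter", "theta_prime", "min_inter",
               "all_intra", "theta", "coalescent_depth")

    def to_row(self) -> dict:
        row: dict = {"n_records": self.n_records, "n_species": self.n_species,
                     "n_genera": self.n_genera,
                     "n_invalid_pairs": self.n_invalid_pairs}
        for name in self._FIELDS:
            stat: MetricStat | None = getattr(self, name)
            row[f"{name}_mean"] = stat.mean if stat else pd.NA
            row[f"{name}_sd"] = stat.sd if stat else pd.NA
            row[f"{name}_n"] = stat.n if stat else 0
        return row


def divergence_summary(
    records: Sequence[SequenceRecord],
    taxonomy_table: pd.DataFrame,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DivergenceSummary:
    """Six metrics for one taxon set; distances are computed within genera only.

    Congeneric comparison is the paper-style protocol: conspecific and
    congeneric heterospecific pairs both live inside a genus, so per-genus
    distance matrices suffice and cross-genus alignments are never made.
    """
    tax = taxonomy_table.set_index("id")
    missing = [r.id for r in records if r.id not in tax.index]
    if missing:
        raise KeyError(f"records without taxonomy rows: {missing[:5]}")
    by_genus: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_genus.setdefault(tax.at[rec.id, "genus"], []).append(rec)

    samples = _PairSamples()
    for g in sorted(by_genus):
        recs = by_genus[g]
        if len(recs) < 2:
            continue
        matrix = distance_matrix(recs, scoring)
        species = [tax.at[r.id, "species"] for r in recs]
        samples.merge(_collect_samples(matrix, species, [g] * len(recs)))

    return DivergenceSummary(
        all_inter=MetricStat.from_sample(samples.inter_pooled),
        theta_prime=MetricStat.from_sample(samples.genus_means),
        min_inter=MetricStat.from_sample(samples.species_min_inter),
        all_intra=MetricStat.from_sample(samples.intra_pooled),
        theta=MetricStat.from_sample(samples.species_means),
        coalescent_depth=MetricStat.from_sample(samples.species_maxima),
        n_records=len(records),
        n_species=int(tax.loc[[r.id for r in records], "species"].nunique()),
        n_genera=len(by_genus),
        n_invalid_pairs=samples.n_invalid,
    )


def divergence_table(
    records: Sequence[SequenceRecord],
    taxonomy_table: pd.DataFrame,
    group_by: str = "group",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """One divergence-summary row per taxon set (``group_by`` column value)."""
    if group_by not in ("group", "family", "genus"):
        raise ValueError(f"unknown grouping column {group_by!r}")
    tax = taxonomy_table.set_index("id")
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault(tax.at[rec.id, group_by], []).append(rec)
    rows = []
    for key in sorted(groups):
        summary = divergence_summary(groups[key], taxonomy_table, scoring)
        rows.append({group_by: key, **summary.to_row()})
    return pd.DataFrame(rows)


def composition_summary(
    records: Sequence[SequenceRecord],
    taxonomy_table: pd.DataFrame,
    group_by: str = "group",
) -> pd.DataFrame:
    """Length and GC box-plot statistics per taxon set.

    GC counts G+C over unambiguous positions only; N is excluded from both
    numerator and denominator.
    """
    tax = taxonomy_table.set_index("id")
    rows = []
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault(tax.at[rec.id, group_by], []).append(rec)
    for key in sorted(groups):
        lengths = np.array([len(r) for r in groups[key]], dtype=float)
        gcs = np.array([r.gc_fraction() for r in groups[key]], dtype=float)
        gcs = gcs[~np.isnan(gcs)]
        row = {group_by: key, "n": len(groups[key]),
               "length_mean": lengths.mean(), "length_median": float(np.median(lengths)),
               "length_q25": float(np.percentile(lengths, 25)),
               "length_q75": float(np.percentile(lengths, 75))}
        if gcs.size:
            row.update(gc_mean=gcs.mean(), gc_median=float(np.median(gcs)),
                       gc_q25=float(np.percentile(gcs, 25)),
                       gc_q75=float(np.percentile(gcs, 75)))
        else:
            row.update(gc_mean=pd.NA, gc_median=pd.NA, gc_q25=pd.NA, gc_q75=pd.NA)
        rows.append(row)
    return pd.DataFrame(rows)
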