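"""Top-hit (BLAST1-style) species assignment and success-rate evaluation.

Every query is scored against every reference record by local affine-gap
alignment (Smith-Waterman, same scoring configuration as the divergence
module, so similarity and distance rankings agree).  The top-hit rule: if
all hits tied at rank 1 belong to a single species, the query is assigned
to it and judged correct or incorrect against its true label; if the tied
set spans several species the query is ambiguous at the species level —
but a tie confined to one genus still yields a genus-level assignment.

Evaluation is leave-one-out by default: the query's own record (by id, not
its species) is excluded, so success reflects informative matching rather
than trivial self-hits.  An ``incorrect`` outcome is tracked as a third
category; folding it into ``ambiguous`` reproduces the two-column
correct/ambiguous presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .curate import ReferenceDatabase
from .distances import AlignmentScoring, make_aligner
from .io import Lineage, SequenceRecord, taxonomy_lookup

LEVELS = ("species", "genus")
GROUPINGS = ("group", "family", "genus")


@dataclass(frozen=True)
class SearchHit:
    """One scored reference record; ties share the extremal (competition) rank."""

    subject_id: str
    score: float
    rank: int
    identity: float | None = None   # computed for the rank-1 tier only


def similarity_search(
    query: SequenceRecord,
    db: ReferenceDatabase,
    exclude: frozenset[str] | set[str] = frozenset(),
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[SearchHit]:
    """Rank all non-excluded reference records by local alignment score.

    Ordering is deterministic: score descending, then subject id ascending.
    """
    subjects = [r for r in db.records if r.id not in exclude]
    if not subjects:
        raise ValueError("reference database is empty after exclusion")
    aligner = make_aligner(scoring, "local")
    scored = sorted(((float(aligner.score(query.seq, s.seq)), s.id, s)
                     for s in subjects), key=lambda t: (-t[0], t[1]))
    top_score = scored[0][0]

    hits = []
    rank = 1
    for pos, (score, sid, subj) in enumerate(scored):
        if pos and score < scored[pos - 1][0]:
            rank = pos + 1
        identity = None
        if score == top_score:
            alignment = aligner.align(query.seq, subj.seq)[0]
            c = alignment.counts()
            denom = c.identities + c.mismatches + c.gaps
            identity = c.identities / denom if denom else 0.0
        hits.append(SearchHit(subject_id=sid, score=score, rank=rank,
                              identity=identity))
    return hits


@dataclass
class IdentificationResult:
    """Top-hit assignment for one query, judged at species and genus level."""

    query_id: str
    true_species: str
    true_genus: str
    top_species: tuple[str, ...]        # sorted species of the rank-1 tier
    top_genera: tuple[str, ...]
    assigned_species: str | None        # set iff the tier is one species
    status_species: str                 # correct | ambiguous | incorrect
    status_genus: str
    top_score: float
    species_in_db: bool                 # truth present in the searched set


def blast1_identify(
    query: SequenceRecord,
    truth: Lineage,
    db: ReferenceDatabase,
    leave_one_out: bool = True,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> IdentificationResult:
    """Assign one query by the top-hit rule against ``db``."""
    exclude = frozenset({query.id}) if leave_one_out else frozenset()
    hits = similarity_search(query, db, exclude, scoring)
    tier = [h for h in hits if h.rank == 1]
    tier_species = sorted({db.lineage_of(h.subject_id).species for h in tier})
    tier_genera = sorted({db.lineage_of(h.subject_id).genus for h in tier})

    if len(tier_species) == 1:
        assigned = tier_species[0]
        status_species = "correct" if assigned == truth.species else "incorrect"
    else:
        assigned = None
        status_species = "ambiguous"
    if len(tier_genera) == 1:
        status_genus = "correct" if tier_genera[0] == truth.genus else "incorrect"
    else:
        status_genus = "ambiguous"

    searched_species = {db.lineage_of(r.id).species
                       for r in db.records if r.id not in exclude}
    return IdentificationResult(
        query_id=query.id,
        true_species=truth.species,
        true_genus=truth.genus,
        top_species=tuple(tier_species),
        top_genera=tuple(tier_genera),
        assigned_species=assigned,
        status_species=status_species,
        status_genus=status_genus,
        top_score=tier[0].score,
        species_in_db=truth.species in searched_species,
    )


def identification_table(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    rows = [{
        "query_id": r.query_id,
        "true_species": r.true_species,
        "true_genus": r.true_genus,
        "top_species": ";".join(r.top_species),
        "assigned_species": r.assigned_species or "",
        "status_species": r.status_species,
        "status_genus": r.status_genus,
        "top_score": r.top_score,
        "species_in_db": r.species_in_db,
    } for r in results]
    return pd.DataFrame(rows, columns=["query_id", "true_species", "true_genus",
                                       "top_species", "assigned_species",
                                       "status_species", "status_genus",
                                       "top_score", "species_in_db"])


def evaluate_success(
    queries: Sequence[SequenceRecord],
    query_taxonomy: pd.DataFrame,
    db: ReferenceDatabase,
    group_by: str = "group",
    level: str = "species",
    leave_one_out: bool = True,
    scoring: AlignmentScoring = AlignmentScoring(),
    fold_incorrect_into_ambiguous: bool = False,
    results: Sequence[IdentificationResult] | None = None,
) -> tuple[list[IdentificationResult], pd.DataFrame]:
    """Per-group success percentages at one taxonomic level.

    Returns the per-query results plus one report row per group with >= 1
    query: query count, species count, and percent correct / ambiguous /
    incorrect (summing to 100 within rounding).  Pass precomputed
    ``results`` to re-aggregate without re-searching.
    """
    if group_by not in GROUPINGS:
        raise ValueError(f"unknown grouping key {group_by!r}; use one of {GROUPINGS}")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; use one of {LEVELS}")
    lookup = taxonomy_lookup(query_taxonomy)
    for q in queries:
        if q.id not in lookup:
            raise KeyError(f"query {q.id!r} has no taxonomy row")

    if results is None:
        results = [blast1_identify(q, lookup[q.id], db, leave_one_out, scoring)
                   for q in queries]

    status_of = {r.query_id: (r.status_species if level == "species"
                              else r.status_genus) for r in results}
    groups: dict[str, list[SequenceRecord]] = {}
    for q in queries:
        groups.setdefault(getattr(lookup[q.id], group_by), []).append(q)

    rows = []
    for key in sorted(groups):
        members = groups[key]
        statuses = [status_of[q.id] for q in members]
        n = len(statuses)
        n_corr = statuses.count("correct")
        n_amb = statuses.count("ambiguous")
        n_inc = statuses.count("incorrect")
        if fold_incorrect_into_ambiguous:
            n_amb += n_inc
            n_inc = 0
        rows.append({
            group_by: key,
            "level": level,
            "n_species": len({lookup[q.id].species for q in members}),
            "n_queries": n,
            "pct_correct": 100.0 * n_corr / n,
            "pct_ambiguous": 100.0 * n_amb / n,
            "pct_incorrect": 100.0 * n_inc / n,
        })
    report = pd.DataFrame(rows, columns=[group_by, "level", "n_species",
                                         "n_queries", "pct_correct",
                                         "pct_ambiguous", "pct_incorrect"])
    return list(results), report
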