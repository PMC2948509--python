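from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_taxonomy_table, random_dna
from its2eval import (
    AlignmentScoring,
    ReferenceDatabase,
    SequenceRecord,
    blast1_identify,
    build_reference_db,
    evaluate_success,
    similarity_search,
)
from its2eval.io import Lineage
from oracles import nearest_neighbor_species

SCORING = AlignmentScoring()


def make_db(records, rows):
    """Reference database without curation side effects, for direct tests."""
    tax = make_taxonomy_table(rows)
    return ReferenceDatabase(records=list(records), taxonomy_table=tax,
                             consensus={},
                             provenance=pd.DataFrame(columns=["id", "decision",
                                                              "reason"]))


def random_family(rng, n_genera=2, n_species=3, n_seqs=2, length=90,
                  mut=0.12):
    """Small random dataset with per-genus ancestors and species variants."""
    records, rows = [], []
    for g in range(n_genera):
        ancestor = random_dna(length, rng)
        for s in range(n_species):
            chars = list(ancestor)
            for i in range(length):
                if rng.random() < mut:
                    chars[i] = "ACGT"[int(rng.integers(4))]
            species = "".join(chars)
            for k in range(n_seqs):
                seq = list(species)
                for i in range(length):
                    if rng.random() < 0.01:
                        seq[i] = "ACGT"[int(rng.integers(4))]
                rid = f"g{g}s{s}r{k}"
                records.append(SequenceRecord(rid, "".join(seq)))
                rows.append((rid, "set1", f"F{g}", f"G{g}", f"G{g} sp{s}"))
    return records, rows


class TestSimilaritySearch:
    def test_identical_record_is_uniquely_top_ranked(self):
        rng = np.random.default_rng(0)
        seqs = [random_dna(80, rng) for _ in range(5)]
        records = [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        rows = [(f"r{i}", "set1", "F", "G", f"G sp{i}") for i in range(5)]
        db = make_db(records, rows)
        query = SequenceRecord("q", seqs[2])
        hits = similarity_search(query, db)
        assert hits[0].subject_id == "r2" and hits[0].rank == 1
        assert hits[1].rank > 1
        assert hits[0].identity == pytest.approx(1.0)

    def test_duplicate_subjects_share_rank_one(self):
        rng = np.random.default_rng(1)
        seq = random_dna(80, rng)
        records = [SequenceRecord("a", seq), SequenceRecord("b", seq),
                   SequenceRecord("c", random_dna(80, rng))]
        rows = [("a", "s", "F", "G", "G x"), ("b", "s", "F", "G", "G y"),
                ("c", "s", "F", "G", "G z")]
        hits = similarity_search(SequenceRecord("q", seq), make_db(records, rows))
        assert [h.rank for h in hits[:2]] == [1, 1]
        assert hits[2].rank == 3

    def test_empty_database_after_exclusion_raises(self):
        records = [SequenceRecord("a", "ACGT" * 20)]
        db = make_db(records, [("a", "s", "F", "G", "G x")])
        with pytest.raises(ValueError, match="empty"):
            similarity_search(SequenceRecord("a", "ACGT" * 20), db,
                              exclude={"a"})


class TestBlast1Identify:
    def test_conspecific_nearest_neighbor_is_correct(self):
        rng = np.random.default_rng(2)
        records, rows = random_family(rng)
        db = make_db(records, rows)
        truth = Lineage("set1", "F0", "G0", "G0 sp0")
        res = blast1_identify(records[0], truth, db)
        assert res.status_species == "correct"
        assert res.assigned_species == "G0 sp0"

    def test_shared_sequence_across_species_is_ambiguous(self):
        rng = np.random.default_rng(3)
        seq = random_dna(90, rng)
        records = [SequenceRecord("a", seq), SequenceRecord("b", seq),
                   SequenceRecord("q", seq)]
        rows = [("a", "s", "F", "G", "G x"), ("b", "s", "F", "G", "G y"),
                ("q", "s", "F", "G", "G x")]
        db = make_db(records, rows)
        res = blast1_identify(records[2], Lineage("s", "F", "G", "G x"), db)
        assert res.status_species == "ambiguous"
        assert res.status_genus == "correct"     # tie confined to one genus
        assert res.assigned_species is None

    def test_adversarial_nearest_heterospecific_is_incorrect(self):
        rng = np.random.default_rng(4)
        base = random_dna(90, rng)
        far = list(base)
        for i in range(0, 90, 3):
            far[i] = "ACGT"[("ACGT".index(far[i]) + 1) % 4]
        records = [SequenceRecord("self_far", "".join(far)),    # conspecific, distant
                   SequenceRecord("other_near", base)]          # heterospecific, close
        rows = [("self_far", "s", "F", "G", "G x"),
                ("other_near", "s", "F", "G", "G y")]
        db = make_db(records, rows)
        query = SequenceRecord("q", base)
        res = blast1_identify(query, Lineage("s", "F", "G", "G x"), db,
                              leave_one_out=False)
        assert res.status_species == "incorrect"
        assert res.status_genus == "correct"

    def test_leave_one_out_never_matches_own_id(self):
        rng = np.random.default_rng(5)
        records, rows = random_family(rng)
        db = make_db(records, rows)
        for rec in records[:6]:
            hits = similarity_search(rec, db, exclude={rec.id})
            assert rec.id not in {h.subject_id for h in hits}

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_decisions_match_exhaustive_nearest_neighbor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records, rows = random_family(rng, n_genera=2, n_species=3, n_seqs=2)
        db = make_db(records, rows)
        tax = make_taxonomy_table(rows).set_index("id")
        species_of = tax["species"].to_dict()
        subjects = {r.id: r.seq for r in records}
        for rec in records:
            truth = Lineage(*tax.loc[rec.id])
            res = blast1_identify(rec, truth, db, leave_one_out=True)
            expected = nearest_neighbor_species(
                rec.id, rec.seq, subjects, species_of, SCORING.match,
                SCORING.mismatch, SCORING.gap_open, SCORING.gap_extend)
            assert set(res.top_species) == expected


class TestEvaluateSuccess:
    def test_well_separated_dataset_identifies_everything(self, small_dataset):
        gt = small_dataset.ground_truth.set_index("id")
        cores = [SequenceRecord(r.id, r.seq[gt.at[r.id, "core_start"]:
                                            gt.at[r.id, "core_end"]])
                 for r in small_dataset.records]
        db = build_reference_db(cores, small_dataset.taxonomy_table)
        _, report = evaluate_success(cores, small_dataset.taxonomy_table, db)
        assert report.iloc[0].pct_correct == 100.0

    def test_genus_rate_at_least_species_rate(self, small_dataset):
        gt = small_dataset.ground_truth.set_index("id")
        cores = [SequenceRecord(r.id, r.seq[gt.at[r.id, "core_start"]:
                                            gt.at[r.id, "core_end"]])
                 for r in small_dataset.records]
        db = build_reference_db(cores, small_dataset.taxonomy_table)
        results, rep_sp = evaluate_success(cores, small_dataset.taxonomy_table,
                                           db, level="species")
        _, rep_gen = evaluate_success(cores, small_dataset.taxonomy_table, db,
                                      level="genus", results=results)
        assert rep_gen.iloc[0].pct_correct >= rep_sp.iloc[0].pct_correct

    def test_collapsed_species_force_ambiguity(self):
        """All species in a genus sharing one sequence: species level fully
        ambiguous, genus level fully correct."""
        rng = np.random.default_rng(7)
        records, rows = [], []
        for g in range(3):
            shared = random_dna(100, rng)
            for s in range(2):
                for k in range(2):
                    rid = f"g{g}s{s}r{k}"
                    records.append(SequenceRecord(rid, shared))
                    rows.append((rid, "set1", "F", f"G{g}", f"G{g} sp{s}"))
        tax = make_taxonomy_table(rows)
        db = make_db(records, rows)
        results, rep_sp = evaluate_success(records, tax, db, level="species")
        _, rep_gen = evaluate_success(records, tax, db, level="genus",
                                      results=results)
        assert rep_sp.iloc[0].pct_ambiguous == 100.0
        assert rep_sp.iloc[0].pct_correct == 0.0
        assert rep_gen.iloc[0].pct_correct == 100.0

    def test_single_query_group_reports_100_0(self):
        rng = np.random.default_rng(8)
        records, rows = random_family(rng, n_genera=1, n_species=2, n_seqs=2)
        # move one query into its own family to isolate a one-query group
        rows = [(rid, grp, "Fsolo" if rid == "g0s0r0" else fam, gen, sp)
                for rid, grp, fam, gen, sp in rows]
        tax = make_taxonomy_table(rows)
        db = make_db(records, rows)
        _, report = evaluate_success(records, tax, db, group_by="family")
        solo = report.set_index("family").loc["Fsolo"]
        assert solo.n_queries == 1
        assert solo.pct_correct + solo.pct_ambiguous + solo.pct_incorrect == 100.0

    def test_report_is_independent_of_record_order(self):
        rng = np.random.default_rng(9)
        records, rows = random_family(rng)
        tax = make_taxonomy_table(rows)
        db = make_db(records, rows)
        _, baseline = evaluate_success(records, tax, db)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        db2 = make_db(list(reversed(records)), rows)
        _, again = evaluate_success(shuffled, tax, db2)
        assert baseline.equals(again)

    def test_fold_incorrect_into_ambiguous_preserves_totals(self):
        rng = np.random.default_rng(10)
        records, rows = random_family(rng, mut=0.02)   # some confusions likely
        tax = make_taxonomy_table(rows)
        db = make_db(records, rows)
        _, folded = evaluate_success(records, tax, db,
                                     fold_incorrect_into_ambiguous=True)
        assert (folded.pct_incorrect == 0).all()
        assert np.allclose(folded.pct_correct + folded.pct_ambiguous, 100.0)

    def test_unknown_grouping_key_rejected(self, small_dataset):
        db = make_db(small_dataset.records,
                     list(small_dataset.taxonomy_table.itertuples(index=False)))
        with pytest.raises(ValueError, match="grouping"):
            evaluate_success(small_dataset.records,
                             small_dataset.taxonomy_table, db,
                             group_by="phylum")
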