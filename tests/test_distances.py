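from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import make_taxonomy_table, random_dna
from its2eval import (
    AlignedPair,
    AlignmentScoring,
    DistanceMatrix,
    SequenceRecord,
    align_pair,
    composition_summary,
    distance_matrix,
    divergence_summary,
    inter_metrics,
    intra_metrics,
    k2p_distance,
    k2p_from_proportions,
    p_distance,
)
from oracles import enumerate_global_score

SCORING = AlignmentScoring()


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        pair = align_pair("ACGT", "ACGT")
        assert pair.a == "ACGT" and pair.b == "ACGT"
        assert pair.score == 4.0

    def test_single_deletion_example(self):
        pair = align_pair("ACGT", "AGT")
        assert pair.score == -2.0            # 3 matches + one 1-nt gap opening
        assert pair.a.replace("-", "") == "ACGT"
        assert pair.b.count("-") == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_optimal_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(int(rng.integers(3, 8)), rng)
        b = random_dna(int(rng.integers(3, 8)), rng)
        expected = enumerate_global_score(a, b, SCORING.match, SCORING.mismatch,
                                          SCORING.gap_open, SCORING.gap_extend)
        assert align_pair(a, b).score == pytest.approx(expected)

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = random_dna(50, rng), random_dna(45, rng)
        assert align_pair(a, b).score == align_pair(b, a).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestK2P:
    def test_closed_form_value(self):
        res = k2p_from_proportions(0.10, 0.05)
        assert res.d == pytest.approx(-0.5 * math.log(0.75)
                                      - 0.25 * math.log(0.90), abs=1e-12)

    def test_identical_pair_is_zero(self):
        res = k2p_distance(AlignedPair("ACGTACGT", "ACGTACGT"))
        assert res.P == res.Q == 0.0 and res.d == 0.0 and res.valid

    def test_saturated_pair_flagged_invalid(self):
        res = k2p_from_proportions(0.5, 0.1)
        assert not res.valid and math.isnan(res.d)

    def test_gap_and_n_columns_excluded(self):
        # 4 comparable columns; the gap and N columns do not count
        res = k2p_distance(AlignedPair("ACGT-N", "ACTTAN"))
        assert res.n_comparable == 4
        # by hand: A=A, C=C, G vs T is a transversion, T=T
        assert res.P == 0.0 and res.Q == 0.25

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance(AlignedPair("NNNN", "ACGT"))

    @pytest.mark.parametrize("seed", range(5))
    def test_k2p_never_below_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(200, rng)
        chars = list(a)
        for i in range(len(chars)):
            if rng.random() < 0.15:
                chars[i] = "ACGT"[int(rng.integers(4))]
        pair = AlignedPair(a, "".join(chars))
        res = k2p_distance(pair)
        if res.valid:
            assert res.d >= p_distance(pair) - 1e-12


class TestDistanceMatrix:
    def test_identical_records_give_zero_matrix(self):
        recs = [SequenceRecord(i, "ACGTACGTAC") for i in "abc"]
        m = distance_matrix(recs)
        assert np.allclose(m.d, 0.0)
        assert m.valid.all()

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(4)
        recs = [SequenceRecord(f"r{i}", random_dna(80, rng)) for i in range(4)]
        m = distance_matrix(recs)
        for i in range(4):
            for j in range(i + 1, 4):
                expect = k2p_distance(align_pair(recs[i], recs[j]))
                if expect.valid:
                    assert m.d[i, j] == expect.d
                else:
                    assert not m.valid[i, j]

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        recs = [SequenceRecord(f"r{i}", random_dna(60, rng)) for i in range(3)]
        m = distance_matrix(recs)
        assert np.array_equal(m.d, m.d.T, equal_nan=True)
        assert np.array_equal(m.valid, m.valid.T)
        assert np.allclose(np.diag(m.d), 0.0)


def _matrix_from(values: dict[tuple[int, int], float], n: int) -> DistanceMatrix:
    d = np.zeros((n, n))
    for (i, j), v in values.items():
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d,
                          valid=np.ones((n, n), dtype=bool))


class TestIntraMetrics:
    def test_hand_enumerated_species(self):
        # one species, three records, pairwise distances 0.01/0.02/0.03
        m = _matrix_from({(0, 1): 0.01, (0, 2): 0.02, (1, 2): 0.03}, 3)
        res = intra_metrics(m, ["sp1"] * 3)
        assert res.all_intra.mean == pytest.approx(0.02)
        assert res.theta.mean == pytest.approx(0.02)
        assert res.coalescent_depth.mean == pytest.approx(0.03)
        assert res.theta.n == 1

    def test_identical_conspecific_records_give_zero(self):
        m = _matrix_from({}, 3)
        res = intra_metrics(m, ["sp1"] * 3)
        assert res.all_intra.mean == 0.0
        assert res.coalescent_depth.mean == 0.0

    def test_singleton_species_contribute_nothing(self):
        m = _matrix_from({(0, 1): 0.4}, 3)
        res = intra_metrics(m, ["sp1", "sp2", "sp3"])
        assert res.all_intra is None and res.theta is None

    def test_depth_at_least_theta_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 6
            vals = {(i, j): float(rng.random() * 0.2)
                    for i in range(n) for j in range(i + 1, n)}
            m = _matrix_from(vals, n)
            res = intra_metrics(m, ["a"] * 3 + ["b"] * 3)
            assert res.coalescent_depth.mean >= res.theta.mean


class TestInterMetrics:
    def test_single_pair_genus_collapses_all_three(self):
        m = _matrix_from({(0, 1): 0.1}, 2)
        res = inter_metrics(m, ["sp1", "sp2"], ["G"] * 2)
        assert res.all_inter.mean == pytest.approx(0.1)
        assert res.theta_prime.mean == pytest.approx(0.1)
        assert res.min_inter.mean == pytest.approx(0.1)

    def test_theta_prime_weighs_genera_equally(self):
        # genus A: one heterospecific pair at 0.1
        # genus B: three records of two species -> two pairs at 0.3
        vals = {(0, 1): 0.1, (2, 3): 0.3, (2, 4): 0.3}
        m = _matrix_from(vals, 5)
        species = ["a1", "a2", "b1", "b2", "b2"]
        genus = ["A", "A", "B", "B", "B"]
        res = inter_metrics(m, species, genus)
        assert res.theta_prime.mean == pytest.approx(0.2)       # (0.1+0.3)/2
        assert res.all_inter.mean == pytest.approx((0.1 + 0.3 + 0.3) / 3)

    def test_min_inter_never_exceeds_genus_mean(self):
        rng = np.random.default_rng(9)
        vals = {(i, j): float(rng.random()) for i in range(4)
                for j in range(i + 1, 4)}
        m = _matrix_from(vals, 4)
        res = inter_metrics(m, ["s1", "s2", "s3", "s4"], ["G"] * 4)
        assert res.min_inter.mean <= res.theta_prime.mean + 1e-12

    def test_no_multispecies_genus_reports_absent(self):
        m = _matrix_from({(0, 1): 0.1}, 2)
        res = inter_metrics(m, ["sp1", "sp1"], ["G", "G"])
        assert res.all_inter is None and res.theta_prime is None


class TestDivergenceSummary:
    def test_all_intra_equals_theta_under_equal_pair_counts(self):
        """With one conspecific pair per species the pooled and per-species
        averages coincide."""
        rng = np.random.default_rng(12)
        rows, recs = [], []
        for s in range(3):
            base = random_dna(150, rng)
            for k in range(2):
                rid = f"s{s}_{k}"
                chars = list(base)
                if k:
                    for pos in rng.choice(150, size=3, replace=False):
                        chars[pos] = "ACGT"[int(rng.integers(4))]
                recs.append(SequenceRecord(rid, "".join(chars)))
                rows.append((rid, "g", "f", "GenA" if s < 2 else "GenB",
                             f"sp{s}"))
        tax = make_taxonomy_table(rows)
        summary = divergence_summary(recs, tax)
        assert summary.all_intra.mean == pytest.approx(summary.theta.mean)

    def test_recovers_twice_the_species_branch_on_synthetic_data(self, small_dataset):
        gt = small_dataset.ground_truth.set_index("id")
        cores = [SequenceRecord(r.id, r.seq[gt.at[r.id, "core_start"]:
                                            gt.at[r.id, "core_end"]])
                 for r in small_dataset.records]
        summary = divergence_summary(cores, small_dataset.taxonomy_table)
        assert summary.all_inter.mean > summary.all_intra.mean
        se = summary.all_inter.sd / math.sqrt(summary.all_inter.n)
        assert abs(summary.all_inter.mean - 0.4) < 4 * se

    def test_coalescent_depth_at_least_theta(self, small_dataset):
        gt = small_dataset.ground_truth.set_index("id")
        cores = [SequenceRecord(r.id, r.seq[gt.at[r.id, "core_start"]:
                                            gt.at[r.id, "core_end"]])
                 for r in small_dataset.records]
        summary = divergence_summary(cores, small_dataset.taxonomy_table)
        assert summary.coalescent_depth.mean >= summary.theta.mean


class TestCompositionSummary:
    def test_length_statistics(self):
        rng = np.random.default_rng(1)
        recs = [SequenceRecord("a", random_dna(100, rng)),
                SequenceRecord("b", random_dna(200, rng)),
                SequenceRecord("c", random_dna(300, rng))]
        tax = make_taxonomy_table([(i, "g", "f", "G", f"G {i}") for i in "abc"])
        out = composition_summary(recs, tax).iloc[0]
        assert out.length_mean == 200 and out.length_median == 200

    @pytest.mark.parametrize("seq,gc", [("GGCC", 1.0), ("ATGC", 0.5),
                                        ("ATGCN", 0.5)])
    def test_gc_excludes_ambiguous_positions(self, seq, gc):
        recs = [SequenceRecord("a", seq)]
        tax = make_taxonomy_table([("a", "g", "f", "G", "G a")])
        assert composition_summary(recs, tax).iloc[0].gc_mean == pytest.approx(gc)

    def test_quartiles_are_ordered(self, small_dataset):
        out = composition_summary(small_dataset.records,
                                  small_dataset.taxonomy_table).iloc[0]
        assert out.length_q25 <= out.length_median <= out.length_q75
        assert out.gc_q25 <= out.gc_median <= out.gc_q75
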