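"""Per-locus CV matrices, pairwise length weights, and the combination."""

import numpy as np
import pytest

from cvbarcode.multilocus_distance import (
    DistanceMatrix,
    combine_matrices,
    locus_distance_matrix,
    pair_weights,
    weight_matrices,
)

from _oracles import brute_combined_entry, dense_cv_distance, random_dna
from conftest import make_dataset, random_dataset


class TestLocusDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        ds = make_dataset(
            {"matK": {f"G{i}_sp{i}_01": "ACGTACGTAC" for i in range(4)}}
        )
        dm = locus_distance_matrix(ds, "matK", 3)
        np.testing.assert_array_equal(dm.values, np.zeros((4, 4)))

    def test_orthogonal_sequences_hit_half(self):
        ds = make_dataset({"matK": {"A_a_1": "AAAA", "C_c_1": "CCCC"}})
        dm = locus_distance_matrix(ds, "matK", 2)
        assert dm.values[0, 1] == 0.5

    def test_matches_pairwise_dense_oracle(self, rng):
        ds = random_dataset(rng, 5, {"matK": 60})
        dm = locus_distance_matrix(ds, "matK", 4)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = dense_cv_distance(
                    ds.record(ds.taxa[i], "matK").residues,
                    ds.record(ds.taxa[j], "matK").residues,
                    4,
                )
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_short_sequence_error_names_taxon_and_locus(self):
        ds = make_dataset({"matK": {"A_a_1": "ACG", "C_c_1": "ACGTACGT"}})
        with pytest.raises(ValueError, match="A_a_1.*matK"):
            locus_distance_matrix(ds, "matK", 5)

    def test_background_mode_stays_within_unit_interval(self, rng):
        ds = random_dataset(rng, 4, {"matK": 100})
        dm = locus_distance_matrix(ds, "matK", 4, mode="background")
        assert dm.values.max() <= 1.0
        assert dm.values.min() >= 0.0
        assert np.all(np.diag(dm.values) == 0)


class TestPairWeights:
    def test_equal_lengths_split_evenly(self):
        ds = make_dataset({
            "matK": {"A_a_1": "A" * 100, "B_b_1": "C" * 100},
            "rbcL": {"A_a_1": "G" * 100, "B_b_1": "T" * 100},
        })
        w = pair_weights(ds, ("A_a_1", "B_b_1"))
        assert w.as_dict() == {"matK": 0.5, "rbcL": 0.5}

    def test_length_ratio_drives_weights(self):
        ds = make_dataset({
            "matK": {"A_a_1": "A" * 100, "B_b_1": "C" * 100},
            "rbcL": {"A_a_1": "G" * 300, "B_b_1": "T" * 300},
        })
        w = pair_weights(ds, ("A_a_1", "B_b_1")).as_dict()
        assert w["matK"] == pytest.approx(0.25)
        assert w["rbcL"] == pytest.approx(0.75)

    def test_three_locus_hand_computed_shares(self):
        # pair sums 1600, 1100, 900 -> 1600/3600, 1100/3600, 900/3600
        ds = make_dataset({
            "matK": {"A_a_1": "A" * 800, "B_b_1": "C" * 800},
            "rbcL": {"A_a_1": "G" * 550, "B_b_1": "T" * 550},
            "trnH-psbA": {"A_a_1": "A" * 450, "B_b_1": "C" * 450},
        })
        w = pair_weights(ds, ("A_a_1", "B_b_1")).as_dict()
        assert w["matK"] == pytest.approx(1600 / 3600, abs=1e-12)
        assert w["rbcL"] == pytest.approx(1100 / 3600, abs=1e-12)
        assert w["trnH-psbA"] == pytest.approx(900 / 3600, abs=1e-12)

    def test_weights_sum_to_one(self, rng):
        for _ in range(25):
            lens = {f"loc{g}": int(rng.integers(50, 900)) for g in range(3)}
            ds = random_dataset(rng, 3, lens)
            for j in range(1, 3):
                w = pair_weights(ds, (ds.taxa[0], ds.taxa[j]))
                assert sum(w.weights) == pytest.approx(1.0, abs=1e-12)

    def test_vectorized_weight_matrices_agree_with_pairwise(self, rng):
        ds = random_dataset(rng, 5, {"a": 120, "b": 300, "c": 77})
        W = weight_matrices(ds)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                w = pair_weights(ds, (ds.taxa[i], ds.taxa[j])).as_dict()
                for locus in ds.loci:
                    assert W[locus][i, j] == w[locus]


class TestCombine:
    @staticmethod
    def _matrices(ds, k_map):
        return {
            locus: locus_distance_matrix(ds, locus, k)
            for locus, k in k_map.items()
        }

    def test_identical_inputs_are_a_fixed_point(self, rng):
        ds = random_dataset(rng, 4, {"a": 80, "b": 80})
        dm = locus_distance_matrix(ds, "a", 3)
        twin = DistanceMatrix(ids=dm.ids, values=dm.values, locus="b", K_used=3)
        combined = combine_matrices({"a": dm, "b": twin}, ds)
        np.testing.assert_array_equal(combined.values, dm.values)

    def test_equal_lengths_average_the_matrices(self):
        ds = make_dataset({
            "a": {"A_a_1": "ACGTACGTAC", "B_b_1": "TGCATGCATG"},
            "b": {"A_a_1": "ACGTACGTAC", "B_b_1": "TTTTGGGGCC"},
        })
        m1 = np.array([[0.0, 0.2], [0.2, 0.0]])
        m2 = np.array([[0.0, 0.4], [0.4, 0.0]])
        combined = combine_matrices(
            {
                "a": DistanceMatrix(ids=tuple(ds.sequence_ids), values=m1, locus="a"),
                "b": DistanceMatrix(ids=tuple(ds.sequence_ids), values=m2, locus="b"),
            },
            ds,
        )
        assert combined.values[0, 1] == pytest.approx(0.3, abs=1e-12)

    def test_matches_per_pair_brute_force(self, rng):
        ds = random_dataset(rng, 6, {"a": 200, "b": 401, "c": 97})
        mats = self._matrices(ds, {"a": 4, "b": 5, "c": 3})
        combined = combine_matrices(mats, ds)
        for i in range(6):
            for j in range(i + 1, 6):
                assert combined.values[i, j] == pytest.approx(
                    brute_combined_entry(ds, mats, i, j), abs=1e-12
                )

    def test_convex_combination_bounds(self, rng):
        ds = random_dataset(rng, 6, {"a": 150, "b": 333})
        mats = self._matrices(ds, {"a": 4, "b": 6})
        combined = combine_matrices(mats, ds)
        stack = np.stack([m.values for m in mats.values()])
        off = ~np.eye(6, dtype=bool)
        assert np.all(combined.values[off] >= stack.min(axis=0)[off] - 1e-12)
        assert np.all(combined.values[off] <= stack.max(axis=0)[off] + 1e-12)

    def test_permutation_commutes_with_combination(self, rng):
        ds = random_dataset(rng, 5, {"a": 100, "b": 250})
        mats = self._matrices(ds, {"a": 4, "b": 4})
        combined = combine_matrices(mats, ds)
        order = list(rng.permutation(5))
        idx = np.asarray(order)
        # permute the dataset, recombine, compare to permuting the result
        from cvbarcode.sequence_io import MultiLocusDataset

        ds_perm = MultiLocusDataset(
            loci=ds.loci,
            taxa=[ds.taxa[i] for i in order],
            records=ds.records,
            strict=ds.strict,
        )
        mats_perm = {loc: m.permuted(order) for loc, m in mats.items()}
        combined_perm = combine_matrices(mats_perm, ds_perm)
        np.testing.assert_allclose(
            combined_perm.values, combined.values[np.ix_(idx, idx)], atol=0
        )

    def test_taxon_order_mismatch_rejected(self, rng):
        ds = random_dataset(rng, 4, {"a": 90, "b": 90})
        mats = self._matrices(ds, {"a": 3, "b": 3})
        mats["b"] = mats["b"].permuted([1, 0, 2, 3])
        with pytest.raises(ValueError, match="taxon order"):
            combine_matrices(mats, ds)

    def test_missing_locus_weight_renormalizes_non_strict(self):
        ds = make_dataset(
            {
                "a": {"A_a_1": "ACGTACGTAC", "B_b_1": "TGCATGCATG",
                      "C_c_1": "GGGTTTCCCA"},
                "b": {"A_a_1": "ACGTACGTAC", "B_b_1": "TGCATGCATG"},
            },
            strict=False,
        )
        W = weight_matrices(ds)
        # C_c_1 lacks locus b: its pairs put full weight on locus a
        assert W["a"][0, 2] == 1.0
        assert W["b"][0, 2] == 0.0
        assert W["a"][0, 1] + W["b"][0, 1] == pytest.approx(1.0)
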