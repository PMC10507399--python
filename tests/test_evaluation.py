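"""Concordance metrics, the repeated-subsample protocol, and the tetramer gate."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import cytosweep as cs
from oracles import ari_brute_force, entropy, fm_brute_force, mi_brute_force


def _labels(ids, labels):
    return pd.DataFrame({"cell_id": ids, "label": labels})


class TestAccuracy:
    def test_identical_tables(self):
        t = _labels(list("abcd"), ["T", "T", "B", "NK"])
        assert cs.accuracy(t, t) == 1.0

    def test_three_of_four_matching(self):
        t = _labels(list("abcd"), ["T", "T", "B", "NK"])
        p = _labels(list("abcd"), ["T", "T", "B", "B"])
        assert cs.accuracy(t, p) == 0.75

    def test_disjoint_vocabularies_give_zero(self):
        t = _labels(list("abc"), ["T", "B", "NK"])
        p = _labels(list("abc"), ["x", "y", "z"])
        assert cs.accuracy(t, p) == 0.0

    def test_restricted_to_shared_barcodes(self):
        t = _labels(list("abcd"), ["T"] * 4)
        p = _labels(list("cdef"), ["T", "B", "T", "T"])
        assert cs.accuracy(t, p) == 0.5  # c matches, d does not

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            cs.accuracy(_labels(["a"], ["T"]), _labels(["b"], ["T"]))


class TestPartitionMetrics:
    def test_ari_identical_partitions(self):
        assert cs.adjusted_rand_index(list("aabb"), list("xxyy")) == pytest.approx(1.0)

    def test_ari_crossed_pairs_is_minus_half(self):
        assert cs.adjusted_rand_index(list("aabb"), list("xyxy")) == pytest.approx(-0.5)

    def test_ari_single_prediction_cluster_is_zero(self):
        assert cs.adjusted_rand_index(list("aabb"), list("xxxx")) == pytest.approx(0.0)

    def test_fm_identical_partitions(self):
        assert cs.fowlkes_mallows(list("aabb"), list("xxyy")) == pytest.approx(1.0)

    def test_fm_crossed_pairs_is_zero(self):
        assert cs.fowlkes_mallows(list("aabb"), list("xyxy")) == pytest.approx(0.0)

    def test_fm_pair_enumeration_example(self):
        # truth {a,a,a}, pred {x,x,y}: TP=1, FP=0, FN=2 -> 1/sqrt(3)
        assert cs.fowlkes_mallows(list("aaa"), list("xxy")) == pytest.approx(1 / math.sqrt(3))

    def test_fm_all_singletons_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cs.fowlkes_mallows(list("abcd"), list("abcd"))

    def test_mi_constant_prediction_is_zero(self):
        assert cs.mutual_information(list("aabb"), list("xxxx")) == pytest.approx(0.0)

    def test_mi_identical_even_split_is_ln2(self):
        assert cs.mutual_information(list("aabb"), list("xxyy")) == pytest.approx(math.log(2))

    def test_mi_bounded_by_entropies(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            t = rng.integers(0, 4, size=n).tolist()
            p = rng.integers(0, 5, size=n).tolist()
            mi = cs.mutual_information(t, p)
            assert mi <= min(entropy(t), entropy(p)) + 1e-12
            assert mi >= -1e-12

    def test_oracle_equivalence_on_random_partitions(self, rng):
        """ARI/FM/MI agree with brute-force pair & contingency enumeration."""
        for _ in range(100):
            n = int(rng.integers(6, 40))
            t = rng.integers(0, int(rng.integers(2, 5)), size=n).tolist()
            p = rng.integers(0, int(rng.integers(2, 5)), size=n).tolist()
            assert cs.adjusted_rand_index(t, p) == pytest.approx(
                ari_brute_force(t, p), abs=1e-9
            )
            assert cs.mutual_information(t, p) == pytest.approx(
                mi_brute_force(t, p), abs=1e-9
            )
            try:
                expected_fm = fm_brute_force(t, p)
            except AssertionError:
                continue
            assert cs.fowlkes_mallows(t, p) == pytest.approx(expected_fm, abs=1e-9)

    def test_metrics_invariant_to_pred_relabeling_except_accuracy(self):
        t = _labels(list("abcdef"), ["T", "T", "B", "B", "NK", "NK"])
        p1 = ["T", "T", "B", "NK", "NK", "NK"]
        swap = {"T": "B", "B": "NK", "NK": "T"}
        p2 = [swap[x] for x in p1]
        assert cs.adjusted_rand_index(t["label"], p1) == cs.adjusted_rand_index(t["label"], p2)
        assert cs.fowlkes_mallows(t["label"], p1) == cs.fowlkes_mallows(t["label"], p2)
        assert cs.mutual_information(t["label"], p1) == pytest.approx(
            cs.mutual_information(t["label"], p2)
        )
        assert cs.accuracy(t, _labels(list("abcdef"), p1)) != cs.accuracy(
            t, _labels(list("abcdef"), p2)
        )


class TestConcordanceReport:
    def _truth(self, n=2_000, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(n)]
        labels = rng.choice(["T4", "T8", "B", "Mono", "NK"], size=n,
                            p=[0.3, 0.25, 0.15, 0.2, 0.1])
        return _labels(ids, labels)

    def test_perfect_prediction_gives_unit_means(self):
        truth = self._truth()
        report = cs.concordance_report(truth, truth, n_per_repeat=500, n_repeats=5, seed=3)
        means = report.means
        assert means["accuracy"] == 1.0
        assert means["adjusted_rand_index"] == pytest.approx(1.0)
        assert means["fowlkes_mallows"] == pytest.approx(1.0)
        assert means["mutual_information"] > 0

    def test_fixed_master_seed_reproducible(self):
        truth = self._truth()
        pred = truth.copy()
        pred.loc[:99, "label"] = "B"
        a = cs.concordance_report(truth, pred, n_per_repeat=400, n_repeats=6, seed=9)
        b = cs.concordance_report(truth, pred, n_per_repeat=400, n_repeats=6, seed=9)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)
        assert a.seeds == b.seeds

    def test_oversized_request_capped_with_warning(self):
        truth = self._truth(n=300)
        with pytest.warns(UserWarning, match="capped"):
            report = cs.concordance_report(truth, truth, n_per_repeat=10_000, n_repeats=2, seed=1)
        assert report.n_per_repeat == 300

    def test_planted_ten_percent_confusion(self):
        truth = self._truth(n=12_000, seed=4)
        rng = np.random.default_rng(5)
        pred = truth.copy()
        flip = rng.choice(len(pred), size=1_200, replace=False)
        vocab = ["T4", "T8", "B", "Mono", "NK"]
        for i in flip:
            wrong = [v for v in vocab if v != pred.loc[i, "label"]]
            pred.loc[i, "label"] = wrong[int(rng.integers(len(wrong)))]
        report = cs.concordance_report(truth, pred, n_per_repeat=10_000, n_repeats=10, seed=6)
        sd = math.sqrt(0.9 * 0.1 / 10_000)
        assert abs(report.means["accuracy"] - 0.90) <= 3 * sd


class TestTetramerGate:
    def test_standard_normal_tail_fraction(self):
        rng = np.random.default_rng(100)
        x = rng.standard_normal(10_000)
        frac = cs.tetramer_gate(x).mean()
        p = norm.sf(3)  # ~0.00135
        sd = math.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) <= 3 * sd

    def test_constant_vector_all_negative(self):
        with pytest.warns(UserWarning, match="variance"):
            out = cs.tetramer_gate(np.full(50, 7.0))
        assert not out.any()

    def test_single_outlier_gated_positive(self):
        x = np.array([0.0] * 99 + [1000.0])
        out = cs.tetramer_gate(x)
        # mean = 10, sd(ddof=1) ~ 100 -> threshold ~ 310 < 1000
        assert out[-1]
        assert out.sum() == 1

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cs.tetramer_gate(np.array([1.0]))
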