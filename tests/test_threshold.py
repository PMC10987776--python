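"""Time slicing, classification semantics, metrics, and the F1 sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgtool import (
    ConfusionCounts,
    KGError,
    LabeledPair,
    classify,
    metrics,
    sweep_threshold,
    time_slice_split,
)
from kgtool.threshold import (
    load_labeled_pairs,
    sample_negative_pairs,
    write_labeled_pairs,
)

from oracles import brute_best_threshold, brute_f1


def _pairs(scores, labels, years=None):
    years = years or [2010] * len(scores)
    return [
        LabeledPair(f"a{i}", f"b{i}", s, l, y)
        for i, (s, l, y) in enumerate(zip(scores, labels, years))
    ]


class TestTimeSliceSplit:
    def test_partition_at_cutoff(self):
        pairs = _pairs([1, 2, 3, 4], [1, 1, 0, 0], [2010, 2017, 2018, 2023])
        train, validation = time_slice_split(pairs, 2017)
        assert len(train) == 2 and len(validation) == 2
        assert set(train) | set(validation) == set(pairs)
        assert not set(train) & set(validation)

    def test_empty_validation(self):
        pairs = _pairs([1, 2], [1, 0], [2000, 2001])
        train, validation = time_slice_split(pairs, 2017)
        assert len(train) == 2 and validation == []


class TestClassify:
    def test_basic_counts(self):
        counts = classify(_pairs([600, 400], [True, False]), 502.36)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (1, 1, 0, 0)

    def test_score_equal_to_threshold_is_positive(self):
        counts = classify(_pairs([502.36], [True]), 502.36)
        assert counts.TP == 1 and counts.FN == 0

    def test_all_four_cells(self):
        pairs = _pairs([600, 600, 400, 400], [True, False, True, False])
        counts = classify(pairs, 502.36)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (1, 1, 1, 1)

    @given(
        st.lists(
            st.tuples(st.floats(0, 1000), st.booleans()), min_size=1, max_size=40
        ),
        st.floats(0, 1000),
        st.floats(0, 500),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, items, threshold, bump):
        pairs = _pairs([s for s, _ in items], [l for _, l in items])
        low = classify(pairs, threshold)
        high = classify(pairs, threshold + bump)
        assert high.TP <= low.TP and high.FP <= low.FP
        assert high.TN >= low.TN and high.FN >= low.FN


class TestMetrics:
    def test_balanced_example(self):
        m = metrics(ConfusionCounts(3, 3, 1, 1))
        assert m.accuracy == m.precision == m.recall == m.f1 == 0.75

    def test_perfect(self):
        m = metrics(ConfusionCounts(5, 5, 0, 0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_degenerate_denominators_flagged(self):
        m = metrics(ConfusionCounts(0, 2, 0, 2))
        assert m.accuracy == 0.5
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert set(m.undefined) == {"precision", "f1"}

    def test_empty_counts_error(self):
        with pytest.raises(KGError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_range_and_harmonic_identity(self, tp_tn_fp_fn):
        tp, tn, fp, fn = tp_tn_fp_fn
        if tp + tn + fp + fn == 0:
            return
        m = metrics(ConfusionCounts(tp, tn, fp, fn))
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )


class TestSweepThreshold:
    def test_separable_case(self):
        result = sweep_threshold(
            _pairs([10, 20, 600, 700], [False, False, True, True])
        )
        assert result.threshold == 600
        assert result.best_f1 == 1.0

    def test_all_positive(self):
        result = sweep_threshold(_pairs([5, 9, 2], [True, True, True]))
        assert result.threshold == 2 and result.best_f1 == 1.0

    def test_no_positives_error(self):
        with pytest.raises(KGError):
            sweep_threshold(_pairs([1, 2], [False, False]))

    def test_best_is_max_of_curve(self):
        rng = np.random.default_rng(0)
        pairs = _pairs(
            rng.uniform(0, 100, 50).tolist(), (rng.random(50) < 0.4).tolist()
        )
        result = sweep_threshold(pairs)
        assert result.best_f1 == max(f1 for _, f1 in result.curve)
        assert dict(result.curve)[result.threshold] == result.best_f1

    def test_matches_brute_force_oracle_on_200_random_pairs(self):
        rng = np.random.default_rng(99)
        scores = np.round(rng.uniform(0, 1000, 200), 1).tolist()
        labels = (rng.random(200) < 0.5).tolist()
        result = sweep_threshold(_pairs(scores, labels))
        oracle_t, oracle_f1 = brute_best_threshold(scores, labels)
        assert result.threshold == oracle_t
        assert result.best_f1 == pytest.approx(oracle_f1)
        for t, f1 in result.curve:
            assert f1 == pytest.approx(brute_f1(scores, labels, t))

    def test_tie_broken_toward_smallest_threshold(self):
        # thresholds 10 and 20 both give F1 = 1 when all pairs are positive
        result = sweep_threshold(_pairs([10, 20], [True, True]))
        assert result.threshold == 10


class TestPairUtilities:
    def test_negative_sampling_avoids_shared_traits(self):
        traits = {
            "g1": {"salt"},
            "g2": {"salt"},
            "g3": {"drought"},
            "g4": {"height"},
        }
        rng = np.random.default_rng(1)
        pairs = sample_negative_pairs(traits, 3, rng)
        assert len(pairs) == 3
        for g1, g2 in pairs:
            assert not traits[g1] & traits[g2]
        with pytest.raises(KGError):
            sample_negative_pairs(traits, 100, rng)

    def test_tsv_round_trip(self, tmp_path):
        pairs = _pairs([1.5, 2.0], [True, False], [2001, 2019])
        path = tmp_path / "pairs.tsv"
        write_labeled_pairs(pairs, path)
        assert load_labeled_pairs(path) == pairs
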