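"""Polyphenotype mining, combination tables and comprehensive ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kgtool import (
    KGError,
    combination_counts,
    comprehensive_rank,
    mine_polyphenotype,
    per_trait_rank,
    rank_candidates,
)
from kgtool.polypheno import PolyphenotypeRecord

from oracles import dense_rank_oracle


def _pred_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "trait", "best_score", "supporting_gene", "threshold", "passed"]
    )


class TestMinePolyphenotype:
    def test_two_trait_gene_kept_single_trait_gene_dropped(self):
        df = _pred_frame(
            [
                ["g1", "salt", 900.0, "k1", 500.0, True],
                ["g1", "drought", 800.0, "k2", 500.0, True],
                ["g2", "salt", 700.0, "k1", 500.0, True],
                ["g2", "drought", 300.0, "k2", 500.0, False],
            ]
        )
        records = mine_polyphenotype(df, known_genes={"g1"})
        assert len(records) == 1
        rec = records[0]
        assert rec.gene == "g1" and rec.traits == frozenset({"salt", "drought"})
        assert rec.status == "known"

    def test_failed_traits_never_included(self):
        df = _pred_frame(
            [
                ["g1", "salt", 900.0, "k1", 500.0, True],
                ["g1", "drought", 800.0, "k2", 500.0, True],
                ["g1", "height", 100.0, "k3", 500.0, False],
            ]
        )
        (rec,) = mine_polyphenotype(df)
        assert rec.traits == frozenset({"salt", "drought"})

    def test_planted_multi_trait_gene_recovered(self):
        from kgtool.predict import predict_all
        from kgtool.synth import FixtureConfig, generate
        from kgtool.threshold import sweep_threshold

        bundle = generate(FixtureConfig(seed=5, traits_per_unknown=3))
        thr = sweep_threshold(bundle.labeled_pairs).threshold
        genes = bundle.manifest["genes"]
        candidates = sorted(g for g in genes if genes[g]["role"] == "planted")
        df, _ = predict_all(
            bundle.kg, candidates, bundle.associations, bundle.provider, threshold=thr
        )
        records = mine_polyphenotype(df)
        by_gene = {r.gene: r.traits for r in records}
        for gene in candidates:
            assert by_gene[gene] == frozenset(genes[gene]["traits"])


class TestCombinationCounts:
    def test_grouping(self):
        records = [
            PolyphenotypeRecord("g1", frozenset({"salt", "drought"}),
                                {"salt": 1.0, "drought": 1.0}),
            PolyphenotypeRecord("g2", frozenset({"salt", "drought"}),
                                {"salt": 1.0, "drought": 1.0}),
            PolyphenotypeRecord("g3", frozenset({"salt", "drought", "disease"}),
                                {"salt": 1.0, "drought": 1.0, "disease": 1.0}),
        ]
        table = combination_counts(records)
        assert table.rows[frozenset({"salt", "drought"})] == 2
        assert table.rows[frozenset({"salt", "drought", "disease"})] == 1
        assert table.total == 3  # conservation: each gene in exactly one row

    def test_empty(self):
        table = combination_counts([])
        assert table.rows == {} and len(table.to_frame()) == 0

    def test_frame_ordering(self):
        records = [
            PolyphenotypeRecord("g1", frozenset({"b", "c", "a"}),
                                {"a": 1.0, "b": 1.0, "c": 1.0}),
            PolyphenotypeRecord("g2", frozenset({"b", "a"}), {"a": 1.0, "b": 1.0}),
        ]
        frame = combination_counts(records).to_frame()
        assert list(frame["traits"]) == ["a, b", "a, b, c"]  # size then lexicographic


class TestPerTraitRank:
    def test_dense_definition(self):
        ranks = per_trait_rank({"a": 900, "b": 700, "c": 700, "d": 500}, "dense")
        assert ranks == {"a": 1, "b": 2, "c": 2, "d": 3}

    def test_single_gene(self):
        assert per_trait_rank({"solo": 1.0}) == {"solo": 1}

    def test_ordinal_ties_by_gene_id(self):
        ranks = per_trait_rank({"b": 700, "a": 700}, "ordinal")
        assert ranks == {"a": 1, "b": 2}

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            scores = {f"g{i}": float(rng.integers(0, 6)) for i in range(10)}
            assert per_trait_rank(scores, "dense") == dense_rank_oracle(scores)

    def test_dense_ranks_are_contiguous(self):
        rng = np.random.default_rng(23)
        scores = {f"g{i}": float(rng.integers(0, 4)) for i in range(12)}
        ranks = per_trait_rank(scores, "dense")
        assert sorted(set(ranks.values())) == list(
            range(1, len(set(scores.values())) + 1)
        )


class TestComprehensiveRank:
    @pytest.mark.parametrize(
        "ranks, expected_mean",
        [
            ((8, 5, 4), 17 / 3),  # printed as 5.7
            ((2, 1, 29), 32 / 3),  # printed as 10.7
            ((4, 7, 5, 6, 8), 6.0),
            ((10, 4, 4, 9, 10), 7.4),
        ],
    )
    def test_published_mean_ranks(self, ranks, expected_mean):
        traits = [f"t{i}" for i in range(len(ranks))]
        table = comprehensive_rank({"g": dict(zip(traits, ranks))}, traits)
        assert table.frame["mean_rank"].iloc[0] == pytest.approx(expected_mean)

    def test_mean_between_min_and_max_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        traits = ["a", "b", "c", "d"]
        ranks = {
            f"g{i}": {t: int(rng.integers(1, 30)) for t in traits} for i in range(8)
        }
        table = comprehensive_rank(ranks, traits)
        for row in table.frame.itertuples():
            values = [getattr(row, f"R_{t}") for t in traits]
            assert min(values) <= row.mean_rank <= max(values)
        for perm in itertools.permutations(traits):
            other = comprehensive_rank(ranks, list(perm))
            merged = table.frame.set_index("gene")["mean_rank"]
            assert other.frame.set_index("gene")["mean_rank"].equals(merged)

    def test_dense_shared_comprehensive_rank_and_topk_overflow(self):
        # mirror of the published top-10 pattern: ties at ranks 9 and 10
        means = [1.0, 5.7, 7.0, 9.0, 10.7, 12.0, 13.7, 18.0, 18.3, 18.3, 18.7, 18.7]
        ranks = {
            f"g{i:02d}": {"t": max(1, round(3 * m))} for i, m in enumerate(means)
        }
        table = comprehensive_rank(ranks, ["t"], tie_policy="dense")
        rc = table.frame.set_index("gene")["R_C"]
        assert list(rc) == [1, 2, 3, 4, 5, 6, 7, 8, 9, 9, 10, 10]
        assert len(table.top_k(10)) == 12

    def test_ordinal_policy_gives_exactly_k(self):
        ranks = {f"g{i}": {"t": 5} for i in range(6)}  # all tied
        table = comprehensive_rank(ranks, ["t"], tie_policy="ordinal")
        assert list(table.frame["R_C"]) == [1, 2, 3, 4, 5, 6]
        assert len(table.top_k(3)) == 3

    def test_k_larger_than_cohort(self):
        table = comprehensive_rank({"g": {"t": 1}}, ["t"])
        assert len(table.top_k(100)) == 1

    def test_missing_trait_rank_is_an_error(self):
        with pytest.raises(KGError):
            comprehensive_rank({"g": {"a": 1}}, ["a", "b"])


class TestRankCandidates:
    def test_population_is_genes_predicted_for_all_traits(self):
        df = _pred_frame(
            [
                ["g1", "salt", 900.0, "k", 500.0, True],
                ["g1", "drought", 700.0, "k", 500.0, True],
                ["g2", "salt", 800.0, "k", 500.0, True],
                ["g2", "drought", 900.0, "k", 500.0, True],
                ["g3", "salt", 850.0, "k", 500.0, True],  # no drought: excluded
            ]
        )
        table = rank_candidates(df, ["salt", "drought"], known_genes={"g2"})
        assert list(table.frame["gene"]) == ["g1", "g2"]
        # g1: salt rank 1, drought rank 2 -> 1.5; g2: 2 and 1 -> 1.5
        assert list(table.frame["mean_rank"]) == [1.5, 1.5]
        assert list(table.frame["R_C"]) == [1, 1]
        assert list(table.frame["status"]) == ["unknown", "known"]

    def test_no_common_gene_is_an_error(self):
        df = _pred_frame([["g1", "salt", 900.0, "k", 500.0, True]])
        with pytest.raises(KGError):
            rank_candidates(df, ["salt", "drought"])
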