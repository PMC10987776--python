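"""Polyphenotype mining and comprehensive rank aggregation.

A *polyphenotype gene* is a gene predicted (at the calibrated threshold)
to regulate two or more traits. Mined genes are tabulated by their full
trait combination, and candidates for a target trait set are prioritized
by the mean of their per-trait similarity-score ranks:

    Ssum(g) = (1/n) * sum_i R(g_i)

where R(g_i) is the gene's rank (1 = highest score) for the i-th target
trait. Genes are then ordered by ascending Ssum into a comprehensive
rank R_C. Two tie policies are supported, because published rank tables
use both: ``dense`` lets equal Ssum share an R_C (so a top-10 cut can
return more than 10 genes), ``ordinal`` breaks ties by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import KGError


@dataclass
class PolyphenotypeRecord:
    """A gene with >= 2 predicted traits and its per-trait best scores."""

    gene: str
    traits: frozenset[str]
    per_trait_scores: dict[str, float]
    status: str = "unknown"  # "known" if any trait is literature-verified

    def __post_init__(self) -> None:
        if len(self.traits) < 2:
            raise KGError(f"{self.gene}: a polyphenotype gene needs >= 2 traits")
        if set(self.per_trait_scores) != set(self.traits):
            raise KGError(f"{self.gene}: per_trait_scores keys must equal traits")


@dataclass
class TraitCombinationTable:
    """Gene counts per full trait combination (each gene in exactly one row)."""

    rows: dict[frozenset[str], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ordered = sorted(self.rows.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        return pd.DataFrame(
            [{"traits": ", ".join(sorted(ts)), "n_genes": n} for ts, n in ordered],
            columns=["traits", "n_genes"],
        )

    @property
    def total(self) -> int:
        return sum(self.rows.values())


def mine_polyphenotype(
    predictions: pd.DataFrame,
    known_genes: Iterable[str] = (),
) -> list[PolyphenotypeRecord]:
    """Extract polyphenotype genes from a prediction table.

    Only traits with ``passed`` true count; genes with fewer than two
    passed traits are dropped. ``known_genes`` (genes with any literature
    association) sets the known/unknown status annotation.
    """
    known = set(known_genes)
    records: list[PolyphenotypeRecord] = []
    if not len(predictions):
        return records
    passed = predictions[predictions["passed"]]
    for gene, grp in passed.groupby("gene", sort=True):
        traits = frozenset(grp["trait"])
        if len(traits) < 2:
            continue
        scores = dict(zip(grp["trait"], grp["best_score"]))
        records.append(
            PolyphenotypeRecord(
                gene=str(gene),
                traits=traits,
                per_trait_scores=scores,
                status="known" if gene in known else "unknown",
            )
        )
    return records


def combination_counts(records: list[PolyphenotypeRecord]) -> TraitCombinationTable:
    """Group polyphenotype genes by their full trait set."""
    table = TraitCombinationTable()
    for rec in records:
        table.rows[rec.traits] = table.rows.get(rec.traits, 0) + 1
    return table


def per_trait_rank(
    scores: Mapping[str, float], tie_policy: str = "dense"
) -> dict[str, int]:
    """Rank genes by one trait's score, rank 1 = highest.

    ``dense``: equal scores share a rank and the next distinct score gets
    the next integer. ``ordinal``: ties broken by gene id.
    """
    if not scores:
        raise KGError("cannot rank an empty score map")
    if tie_policy not in {"dense", "ordinal"}:
        raise KGError(f"unknown tie policy {tie_policy!r}")
    s = pd.Series(dict(scores), dtype=float)
    if tie_policy == "dense":
        ranks = s.rank(method="dense", ascending=False).astype(int)
        return dict(ranks.items())
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    return {g: i + 1 for i, g in enumerate(ordered)}


@dataclass
class RankTable:
    """Per-gene target-trait ranks, mean rank Ssum, and comprehensive rank."""

    frame: pd.DataFrame  # columns: gene, R_<trait>..., mean_rank, R_C, status
    traits: tuple[str, ...]
    tie_policy: str

    def top_k(self, k: int) -> pd.DataFrame:
        """All genes with comprehensive rank <= k.

        Under the dense policy tied Ssum values share an R_C, so the cut
        may return more than k genes; under ordinal it is exactly k (or
        the whole cohort if smaller).
        """
        if k < 1:
            raise KGError("k must be >= 1")
        return self.frame[self.frame["R_C"] <= k].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["mean_rank"] = out["mean_rank"].map(lambda v: f"{v:.1f}")
        out.to_csv(path, sep="\t", index=False)


def comprehensive_rank(
    per_trait_ranks: Mapping[str, Mapping[str, int]],
    traits: list[str],
    tie_policy: str = "dense",
    status: Mapping[str, str] | None = None,
) -> RankTable:
    """Aggregate per-trait ranks into Ssum and a comprehensive rank.

    ``per_trait_ranks`` maps gene -> trait -> rank and every gene must
    carry a rank for every target trait. Ssum is kept at full precision;
    1-decimal rounding is presentation-only.
    """
    if not traits:
        raise KGError("need at least one target trait")
    rows = []
    for gene in sorted(per_trait_ranks):
        ranks = per_trait_ranks[gene]
        missing = [t for t in traits if t not in ranks]
        if missing:
            raise KGError(f"gene {gene} lacks ranks for traits {missing}")
        row = {"gene": gene}
        for t in traits:
            if ranks[t] < 1:
                raise KGError(f"gene {gene}: rank for {t} must be >= 1")
            row[f"R_{t}"] = int(ranks[t])
        row["mean_rank"] = sum(ranks[t] for t in traits) / len(traits)
        row["status"] = (status or {}).get(gene, "unknown")
        rows.append(row)
    if not rows:
        raise KGError("no genes to rank")
    df = pd.DataFrame(rows)
    df = df.sort_values(["mean_rank", "gene"]).reset_index(drop=True)
    if tie_policy == "dense":
        df["R_C"] = df["mean_rank"].rank(method="dense").astype(int)
    elif tie_policy == "ordinal":
        df["R_C"] = range(1, len(df) + 1)
    else:
        raise KGError(f"unknown tie policy {tie_policy!r}")
    cols = ["gene"] + [f"R_{t}" for t in traits] + ["mean_rank", "R_C", "status"]
    return RankTable(df[cols], tuple(traits), tie_policy)


def rank_candidates(
    predictions: pd.DataFrame,
    traits: list[str],
    tie_policy: str = "dense",
    known_genes: Iterable[str] = (),
) -> RankTable:
    """Rank the genes predicted for *all* target traits.

    Convenience driver: builds the per-trait score maps from a passed
    prediction table, ranks each trait, and aggregates. The ranked
    population is the set of genes whose predictions pass the threshold
    for every target trait.
    """
    passed = predictions[predictions["passed"]]
    per_trait_scores: dict[str, dict[str, float]] = {}
    for t in traits:
        sub = passed[passed["trait"] == t]
        per_trait_scores[t] = dict(zip(sub["gene"], sub["best_score"]))
    eligible = sorted(set.intersection(*(set(per_trait_scores[t]) for t in traits)))
    if not eligible:
        raise KGError(f"no gene is predicted for all of {traits}")
    ranks_by_trait = {
        t: per_trait_rank(
            {g: per_trait_scores[t][g] for g in eligible}, tie_policy
        )
        for t in traits
    }
    per_gene = {
        g: {t: ranks_by_trait[t][g] for t in traits} for g in eligible
    }
    known = set(known_genes)
    status = {g: ("known" if g in known else "unknown") for g in eligible}
    return comprehensive_rank(per_gene, traits, tie_policy, status)
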