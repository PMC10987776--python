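"""Trait link prediction at a calibrated threshold.

An unannotated gene is scored against every known trait-regulating gene;
for each trait the best (maximum) score over that trait's known genes is
kept, and the trait is predicted when the best score reaches the
threshold. A known gene documented for several traits supports each of
them; a gene that is known for one trait can still be a prediction
candidate for the others (its own documented associations are excluded
from support so it never vouches for itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SelfPairError, UnknownEntityError, UnscorablePairError
from .kg import GeneTraitAssociation, KnowledgeGraph
from .protein import SimilarityProvider
from .similarity import ScoringConfig, gene_similarity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitPrediction:
    """One (gene, trait) link candidate with its best supporting evidence."""

    gene: str
    trait: str
    best_score: float
    supporting_gene: str
    threshold: float

    @property
    def passed(self) -> bool:
        return self.best_score >= self.threshold


@dataclass
class PredictionBatchReport:
    """Per-gene failures collected while running a batch without aborting it."""

    skipped: dict[str, str] = field(default_factory=dict)


def predict_traits(
    kg: KnowledgeGraph,
    gene: str,
    known_associations: list[GeneTraitAssociation],
    provider: SimilarityProvider,
    config: ScoringConfig | None = None,
    threshold: float = 0.0,
) -> list[TraitPrediction]:
    """Predict traits for one gene.

    Returns one :class:`TraitPrediction` per trait that has at least one
    scorable known gene, sorted by best score descending; only entries
    with ``passed`` are predicted links. Unscorable pairs are skipped,
    never counted as failures to pass.
    """
    config = config or ScoringConfig()
    if gene not in kg:
        raise UnknownEntityError(gene)
    best: dict[str, tuple[float, str]] = {}
    score_cache: dict[str, float] = {}
    for a in sorted(known_associations, key=lambda a: (a.trait, a.gene_id)):
        if a.gene_id == gene or a.gene_id not in kg:
            continue  # a gene never supports its own predictions
        if a.gene_id in score_cache:
            s = score_cache[a.gene_id]
        else:
            try:
                s = gene_similarity(kg, gene, a.gene_id, provider, config).S
            except (UnscorablePairError, SelfPairError):
                score_cache[a.gene_id] = float("nan")
                continue
            score_cache[a.gene_id] = s
        if s != s:  # cached unscorable
            continue
        if a.trait not in best or s > best[a.trait][0]:
            best[a.trait] = (s, a.gene_id)
    if not best:
        logger.warning("gene %s: no scorable known genes", gene)
    preds = [
        TraitPrediction(gene, trait, s, supporting, threshold)
        for trait, (s, supporting) in best.items()
    ]
    preds.sort(key=lambda p: (-p.best_score, p.trait))
    return preds


def predict_all(
    kg: KnowledgeGraph,
    unknown_genes: list[str],
    known_associations: list[GeneTraitAssociation],
    provider: SimilarityProvider,
    config: ScoringConfig | None = None,
    threshold: float = 0.0,
) -> tuple[pd.DataFrame, PredictionBatchReport]:
    """Batch driver over a gene list; failures are collected, not fatal.

    The table has columns gene, trait, best_score, supporting_gene,
    threshold, passed, ordered by (gene, best_score descending).
    """
    rows = []
    report = PredictionBatchReport()
    for gene in sorted(set(unknown_genes)):
        try:
            preds = predict_traits(
                kg, gene, known_associations, provider, config, threshold
            )
        except Exception as exc:  # noqa: BLE001 - batch survives per-gene failures
            report.skipped[gene] = f"{type(exc).__name__}: {exc}"
            continue
        for p in preds:
            rows.append(
                {
                    "gene": p.gene,
                    "trait": p.trait,
                    "best_score": p.best_score,
                    "supporting_gene": p.supporting_gene,
                    "threshold": p.threshold,
                    "passed": p.passed,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene", "trait", "best_score", "supporting_gene", "threshold", "passed"],
    )
    if len(df):
        df = df.sort_values(
            ["gene", "best_score", "trait"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df, report


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
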