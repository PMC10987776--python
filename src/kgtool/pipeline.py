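"""End-to-end pipeline: build → score → sweep → predict → mine → rank → venn.

Stages communicate only through files, so every CLI subcommand stays
independently usable; the pipeline simply sequences them from one YAML
configuration and writes a machine-readable run report. With a fixed
seed and unchanged inputs the run is idempotent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .deg import load_deg_table, overlap_report
from .errors import KGError
from .kg import KnowledgeGraph, load_associations, load_triples
from .polypheno import combination_counts, mine_polyphenotype, rank_candidates
from .predict import predict_all, write_predictions
from .protein import AlignmentProvider, SimilarityProvider, TableProvider
from .similarity import ScoringConfig, gene_similarity
from .threshold import (
    LabeledPair,
    classify,
    load_labeled_pairs,
    metrics,
    sample_negative_pairs,
    sweep_threshold,
    time_slice_split,
    write_labeled_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and settings for one pipeline run."""

    triples: Path
    associations: Path
    out_dir: Path
    protein_table: Path | None = None
    protein_fasta: Path | None = None
    labeled_pairs: Path | None = None
    deg_tables: dict[str, Path] = field(default_factory=dict)
    candidate_genes: Path | None = None  # text file, one gene id per line
    cutoff_year: int = 2017
    threshold: float | None = None  # when set, the sweep is skipped
    target_traits: list[str] = field(default_factory=list)
    tie_policy: str = "dense"
    top_k: int = 10
    strict_load: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.triples = Path(self.triples)
        self.associations = Path(self.associations)
        self.out_dir = Path(self.out_dir)
        for name in ("protein_table", "protein_fasta", "labeled_pairs", "candidate_genes"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        self.deg_tables = {k: Path(v) for k, v in self.deg_tables.items()}
        if self.protein_table is None and self.protein_fasta is None:
            raise KGError("config needs protein_table or protein_fasta")
        if self.threshold is not None and self.threshold < 0:
            raise KGError("threshold override must be >= 0")
        for p in [self.triples, self.associations, self.protein_table,
                  self.protein_fasta, self.labeled_pairs, self.candidate_genes,
                  *self.deg_tables.values()]:
            if p is not None and not Path(p).is_file():
                raise KGError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def _p(v):
            return (base / v) if v is not None and not Path(v).is_absolute() else v

        return cls(
            triples=_p(raw["triples"]),
            associations=_p(raw["associations"]),
            out_dir=_p(raw.get("out_dir", "kgtool_out")),
            protein_table=_p(raw.get("protein_table")),
            protein_fasta=_p(raw.get("protein_fasta")),
            labeled_pairs=_p(raw.get("labeled_pairs")),
            deg_tables={k: _p(v) for k, v in (raw.get("deg_tables") or {}).items()},
            candidate_genes=_p(raw.get("candidate_genes")),
            cutoff_year=int(raw.get("cutoff_year", 2017)),
            threshold=raw.get("threshold"),
            target_traits=list(raw.get("target_traits") or []),
            tie_policy=raw.get("tie_policy", "dense"),
            top_k=int(raw.get("top_k", 10)),
            strict_load=bool(raw.get("strict_load", True)),
            seed=int(raw.get("seed", 0)),
        )


def _build_provider(config: PipelineConfig) -> SimilarityProvider:
    if config.protein_table is not None:
        return TableProvider.from_tsv(config.protein_table)
    return AlignmentProvider.from_fasta(config.protein_fasta)


def build_labeled_pairs_from_associations(
    kg: KnowledgeGraph,
    associations,
    provider: SimilarityProvider,
    scoring: ScoringConfig,
    seed: int,
) -> list[LabeledPair]:
    """Construct the gene–gene training pairs from association records.

    Positives are pairs of known genes documented for a common trait
    (year = the later of the two discoveries); negatives are an equal
    number of known-gene pairs sharing no trait, sampled with the given
    seed. Unscorable pairs are skipped.
    """
    traits_by_gene: dict[str, set[str]] = {}
    year_by: dict[tuple[str, str], int] = {}
    for a in associations:
        if a.gene_id not in kg:
            continue
        traits_by_gene.setdefault(a.gene_id, set()).add(a.trait)
        key = (a.gene_id, a.trait)
        year_by[key] = min(year_by.get(key, a.year), a.year)
    order = sorted(traits_by_gene)
    positives = [
        (g1, g2)
        for i, g1 in enumerate(order)
        for g2 in order[i + 1 :]
        if traits_by_gene[g1] & traits_by_gene[g2]
    ]
    rng = np.random.default_rng(seed)
    n_neg = min(
        len(positives),
        sum(
            1
            for i, g1 in enumerate(order)
            for g2 in order[i + 1 :]
            if not traits_by_gene[g1] & traits_by_gene[g2]
        ),
    )
    negatives = sample_negative_pairs(traits_by_gene, n_neg, rng) if n_neg else []
    pairs: list[LabeledPair] = []
    for g1, g2 in positives:
        shared = traits_by_gene[g1] & traits_by_gene[g2]
        year = max(year_by[(g, t)] for g in (g1, g2) for t in shared)
        try:
            s = gene_similarity(kg, g1, g2, provider, scoring).S
        except KGError:
            continue
        pairs.append(LabeledPair(g1, g2, s, True, year))
    for g1, g2 in negatives:
        year = max(
            min(year_by[(g, t)] for t in traits_by_gene[g]) for g in (g1, g2)
        )
        try:
            s = gene_similarity(kg, g1, g2, provider, scoring).S
        except KGError:
            continue
        pairs.append(LabeledPair(g1, g2, s, False, year))
    return pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing intermediates and a JSON run report.

    A stage failure aborts the run with the failing stage named; outputs
    of completed stages are retained. Missing DEG tables or target traits
    simply skip the corresponding stage with a notice in the report.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "seed": config.seed}
    scoring = ScoringConfig()
    stage = "build"
    try:
        kg, load_report = load_triples(config.triples, strict=config.strict_load)
        associations = load_associations(config.associations)
        provider = _build_provider(config)
        report["graph"] = {
            "n_entities": len(kg),
            "n_triples": kg.n_triples,
            "n_skipped_lines": load_report.n_skipped,
        }
        report["stages"].append(stage)

        stage = "pairs"
        if config.labeled_pairs is not None:
            pairs = load_labeled_pairs(config.labeled_pairs)
        else:
            pairs = build_labeled_pairs_from_associations(
                kg, associations, provider, scoring, config.seed
            )
        write_labeled_pairs(pairs, out / "labeled_pairs.tsv")
        report["n_pairs"] = len(pairs)
        report["stages"].append(stage)

        stage = "sweep"
        train, validation = time_slice_split(pairs, config.cutoff_year)
        report["split"] = {"n_train": len(train), "n_validation": len(validation)}
        if config.threshold is not None:
            threshold = float(config.threshold)
            report["threshold"] = {"value": threshold, "source": "override"}
        else:
            sweep = sweep_threshold(train)
            sweep.write_curve(out / "sweep_curve.tsv")
            threshold = sweep.threshold
            report["threshold"] = {
                "value": threshold,
                "source": "sweep",
                "train_f1": sweep.best_f1,
            }
        if validation and any(p.label for p in validation):
            m = metrics(classify(validation, threshold))
            report["validation_metrics"] = {
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            }
        else:
            report["validation_metrics"] = None
        report["stages"].append(stage)

        stage = "predict"
        known_gene_ids = {a.gene_id for a in associations}
        if config.candidate_genes is not None:
            candidates = [
                line.strip()
                for line in config.candidate_genes.read_text().splitlines()
                if line.strip()
            ]
        else:
            candidates = [
                e.id for e in kg.entities("gene") if e.id not in known_gene_ids
            ]
        predictions, batch_report = predict_all(
            kg, candidates, associations, provider, scoring, threshold
        )
        write_predictions(predictions, out / "predictions.tsv")
        report["n_candidates"] = len(candidates)
        report["n_predicted_links"] = int(predictions["passed"].sum()) if len(predictions) else 0
        report["skipped_genes"] = batch_report.skipped
        report["stages"].append(stage)

        stage = "mine"
        records = mine_polyphenotype(predictions, known_gene_ids)
        combos = combination_counts(records)
        combos.to_frame().to_csv(out / "combinations.tsv", sep="\t", index=False)
        report["n_polyphenotype"] = len(records)
        report["n_trait_combinations"] = len(combos.rows)
        report["stages"].append(stage)

        stage = "rank"
        if config.target_traits:
            try:
                table = rank_candidates(
                    predictions, config.target_traits, config.tie_policy, known_gene_ids
                )
                table.to_tsv(out / "rank.tsv")
                top = table.top_k(config.top_k)
                report["top_k"] = top.to_dict(orient="records")
            except KGError as exc:
                report["top_k"] = None
                report["rank_notice"] = str(exc)
        else:
            report["top_k"] = None
            report["rank_notice"] = "no target traits configured"
        report["stages"].append(stage)

        stage = "venn"
        if config.deg_tables and records:
            deg_sets = [
                load_deg_table(path, phenotype)
                for phenotype, path in sorted(config.deg_tables.items())
            ]
            rep = overlap_report({r.gene for r in records}, deg_sets)
            rep.to_json(out / "overlap.json")
            report["overlap"] = rep.to_json()
        else:
            report["overlap"] = None
            report["venn_notice"] = (
                "no DEG tables configured" if not config.deg_tables
                else "no polyphenotype genes to verify"
            )
        report["stages"].append(stage)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
        )
        raise

    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
    )
    return report
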