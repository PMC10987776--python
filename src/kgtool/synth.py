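"""Synthetic knowledge-graph fixtures with planted gene–trait signal.

The generator emulates the statistical structure the similarity score
exploits: genes regulating a common trait share a multi-category
annotation neighborhood (GO terms, pathways, localizations, families)
and encode similar proteins, while unrelated decoy genes share little
and encode dissimilar proteins.

For each trait a *signature* set of annotation entities spanning at
least three categories is created; the trait's known genes and the
planted (to-be-discovered) unknown genes all attach to the full
signature, so any two of them have a large, category-diverse coincident
set. Decoys attach to a few signature entities from a single category
plus private background annotations. Protein similarities are emitted
as a table by default (signal pairs high, decoy pairs low), or as
mutated sequences to exercise the alignment provider.

Every file in the bundle loads through the strict-mode loaders, and the
ground-truth manifest records exactly which genes carry which traits, so
end-to-end recovery is checkable. A fixed seed yields byte-identical
bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import KGError
from .kg import (
    Entity,
    GeneTraitAssociation,
    KnowledgeGraph,
    Triple,
    write_associations,
)
from .protein import ProteinSequence, TableProvider
from .similarity import ScoringConfig, gene_similarity
from .threshold import LabeledPair, sample_negative_pairs, write_labeled_pairs

#: Agronomic trait labels, recycled with numeric suffixes if more are asked for.
TRAIT_POOL = [
    "salt_resistance",
    "drought_resistance",
    "disease_resistance",
    "plant_height_reduce",
    "grain_weight_increase",
    "insect_resistance",
]

#: Categories used for signature annotations, cycled so the coincident set
#: spans several molecular levels (gene- and protein-attached alike).
SIGNATURE_CATEGORIES = [
    "molecular_function",
    "biological_process",
    "signal_pathway",
    "cellular_component",
    "subcellular_localization",
    "protein_family",
    "metabolic_pathway",
]

_GENE_ATTACHED = {
    "molecular_function": "performs",
    "biological_process": "involves_in_biological_process",
    "cellular_component": "located_in_cellular_component",
    "metabolic_pathway": "involves_in_metabolic_pathway",
    "enzyme": "encodes_enzyme_type",
}
_PROTEIN_ATTACHED = {
    "signal_pathway": "involves_in_signal_pathway",
    "subcellular_localization": "located_in_subcellular_localization",
    "protein_domain": "has_protein_domain",
    "protein_family": "belongs_to_protein_family",
}

_SPECIES_CYCLE = ["rice", "arabidopsis", "maize", "wheat"]
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic bundle.

    The defaults describe a small, clearly separated cohort: three traits
    with four literature-known genes each, six plantable unknown genes,
    twelve decoys, trait signatures of nine shared annotation entities
    spanning several categories versus at most one shared entity for
    decoys, and protein similarities of ~80 for trait-sharing pairs
    versus ~15 for unrelated ones (0–100 percent-identity scale).
    """

    n_traits: int = 3
    known_genes_per_trait: int = 4
    n_unknown_true: int = 6
    n_decoys: int = 12
    traits_per_unknown: int = 1
    shared_annotations_signal: int = 9
    shared_annotations_noise: int = 1
    n_background_annotations: int = 2
    protein_sim_signal: float = 80.0
    protein_sim_noise: float = 15.0
    protein_sim_sd: float = 3.0
    year_range: tuple[int, int] = (1990, 2023)
    cutoff_year: int = 2017
    emit_sequences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_traits,
            self.known_genes_per_trait,
        ) < 1 or min(self.n_unknown_true, self.n_decoys) < 0:
            raise KGError("counts must be positive (traits, knowns) or >= 0")
        if not 1 <= self.traits_per_unknown <= self.n_traits:
            raise KGError("traits_per_unknown must be in [1, n_traits]")
        if self.shared_annotations_noise > self.shared_annotations_signal:
            raise KGError(
                "decoy shared-annotation count exceeds the signature pool: "
                f"{self.shared_annotations_noise} > {self.shared_annotations_signal}"
            )
        if self.year_range[0] >= self.year_range[1] or not (
            self.year_range[0] <= self.cutoff_year < self.year_range[1]
        ):
            raise KGError("need year_range[0] <= cutoff_year < year_range[1]")


@dataclass
class FixtureBundle:
    """Everything one generated study provides, in memory and on disk."""

    kg: KnowledgeGraph
    associations: list[GeneTraitAssociation]
    provider: TableProvider
    labeled_pairs: list[LabeledPair]
    manifest: dict
    sequences: list[ProteinSequence] = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)


def _trait_labels(n: int) -> list[str]:
    out = []
    for i in range(n):
        if i < len(TRAIT_POOL):
            out.append(TRAIT_POOL[i])
        else:
            out.append(f"trait_{i + 1}")
    return out


def _protein_id(gene: str) -> str:
    return f"P_{gene}"


class _GraphBuilder:
    def __init__(self) -> None:
        self.kg = KnowledgeGraph()
        self.lines: list[str] = []

    def add(self, head: Entity, relation: str, tail: Entity, source: str = "synthetic"):
        if self.kg.add_triple(Triple(head, relation, tail, source)):
            self.lines.append(
                f"{head.id}\t{head.category}\t{relation}\t{tail.id}\t{tail.category}\t{source}"
            )

    def attach_annotation(self, gene: str, species: str, ann_id: str, category: str):
        """Attach an annotation entity to the gene or its protein, as the
        schema dictates for that category."""
        if category in _GENE_ATTACHED:
            self.add(
                Entity(gene, "gene", species),
                _GENE_ATTACHED[category],
                Entity(ann_id, category),
            )
        elif category in _PROTEIN_ATTACHED:
            self.add(
                Entity(_protein_id(gene), "protein", species),
                _PROTEIN_ATTACHED[category],
                Entity(ann_id, category),
            )
        else:
            raise KGError(f"category {category!r} is not an annotation category")


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for pos in positions:
        chars[pos] = _AA[int(rng.integers(len(_AA)))]
    return "".join(chars)


def generate(config: FixtureConfig, out_dir: str | Path | None = None) -> FixtureBundle:
    """Generate one fixture bundle; write it under *out_dir* if given.

    Files written: ``triples.tsv``, ``associations.csv``,
    ``protein_sim.tsv``, ``labeled_pairs.tsv``, ``manifest.json`` and,
    when sequences are requested, ``proteins.fasta``. All of them
    round-trip through the package loaders in strict mode.
    """
    rng = np.random.default_rng(config.seed)
    traits = _trait_labels(config.n_traits)
    builder = _GraphBuilder()

    # trait signature annotation pools, grouped by category
    signatures: dict[str, list[tuple[str, str]]] = {}  # trait -> [(ann_id, category)]
    for i, trait in enumerate(traits):
        sig = []
        for j in range(config.shared_annotations_signal):
            cat = SIGNATURE_CATEGORIES[j % len(SIGNATURE_CATEGORIES)]
            sig.append((f"{cat}_sig{i}_{j}", cat))
        signatures[trait] = sig

    # gene roster with ground-truth trait sets
    genes: dict[str, dict] = {}  # gene -> {"traits": [..], "role": .., "species": ..}
    sp = 0

    def _register(gene: str, role: str, gene_traits: list[str]) -> None:
        nonlocal sp
        genes[gene] = {
            "traits": gene_traits,
            "role": role,
            "species": _SPECIES_CYCLE[sp % len(_SPECIES_CYCLE)],
            "protein": _protein_id(gene),
        }
        sp += 1

    for i, trait in enumerate(traits):
        for j in range(config.known_genes_per_trait):
            _register(f"G_T{i}_K{j}", "known", [trait])
    for j in range(config.n_unknown_true):
        ts = [
            traits[(j + m) % config.n_traits] for m in range(config.traits_per_unknown)
        ]
        _register(f"G_U{j}", "planted", ts)
    for j in range(config.n_decoys):
        _register(f"G_D{j}", "decoy", [])

    # wire up the graph: protein, trait signatures / decoy noise, background
    for gene in sorted(genes):
        info = genes[gene]
        species = info["species"]
        gene_ent = Entity(gene, "gene", species)
        prot_ent = Entity(info["protein"], "protein", species)
        builder.add(prot_ent, "corresponding_to", gene_ent)
        for trait in info["traits"]:
            for ann_id, cat in signatures[trait]:
                builder.attach_annotation(gene, species, ann_id, cat)
        if info["role"] == "decoy" and config.shared_annotations_noise > 0:
            trait = traits[int(rng.integers(config.n_traits))]
            by_cat: dict[str, list[str]] = {}
            for ann_id, cat in signatures[trait]:
                by_cat.setdefault(cat, []).append(ann_id)
            cat = sorted(by_cat)[int(rng.integers(len(by_cat)))]
            pool = by_cat[cat]
            take = min(config.shared_annotations_noise, len(pool))
            picked = rng.choice(len(pool), size=take, replace=False)
            for idx in sorted(picked):
                builder.attach_annotation(gene, species, pool[idx], cat)
        stable = sum(ord(ch) for ch in gene)  # not hash(): must survive PYTHONHASHSEED
        for m in range(config.n_background_annotations):
            cat = SIGNATURE_CATEGORIES[(stable + m) % len(SIGNATURE_CATEGORIES)]
            builder.attach_annotation(gene, species, f"bg_{gene}_{m}", cat)

    # known-gene association records; 80% of years fall before the cutoff
    associations: list[GeneTraitAssociation] = []
    known_records = [
        (gene, trait)
        for gene in sorted(genes)
        if genes[gene]["role"] == "known"
        for trait in genes[gene]["traits"]
    ]
    lo, hi = config.year_range
    for idx, (gene, trait) in enumerate(known_records):
        if idx % 5 < 4:
            year = int(rng.integers(lo, config.cutoff_year + 1))
        else:
            year = int(rng.integers(config.cutoff_year + 1, hi + 1))
        associations.append(GeneTraitAssociation(gene, trait, year, "synthetic"))

    # protein similarity: signal for trait-sharing pairs, noise otherwise
    provider = TableProvider()
    order = sorted(genes)
    sequences: list[ProteinSequence] = []
    if config.emit_sequences:
        base_by_trait = {
            t: "".join(_AA[int(rng.integers(len(_AA)))] for _ in range(60))
            for t in traits
        }
        for gene in order:
            info = genes[gene]
            if info["traits"]:
                seq = _mutate(base_by_trait[info["traits"][0]], 6, rng)
            else:
                seq = "".join(_AA[int(rng.integers(len(_AA)))] for _ in range(60))
            sequences.append(ProteinSequence(info["protein"], seq))
    for i, g1 in enumerate(order):
        provider.add(genes[g1]["protein"], genes[g1]["protein"], 100.0)
        for g2 in order[i + 1 :]:
            shared = set(genes[g1]["traits"]) & set(genes[g2]["traits"])
            mean = config.protein_sim_signal if shared else config.protein_sim_noise
            score = float(
                np.clip(rng.normal(mean, config.protein_sim_sd), 0.0, 100.0)
            )
            provider.add(genes[g1]["protein"], genes[g2]["protein"], score)

    # labeled gene-gene pairs over the known genes
    year_by_gene_trait = {(a.gene_id, a.trait): a.year for a in associations}
    traits_by_gene = {
        g: set(genes[g]["traits"]) for g in order if genes[g]["role"] == "known"
    }
    scoring = ScoringConfig()
    pairs: list[LabeledPair] = []
    known_order = sorted(traits_by_gene)
    positives = [
        (g1, g2)
        for i, g1 in enumerate(known_order)
        for g2 in known_order[i + 1 :]
        if traits_by_gene[g1] & traits_by_gene[g2]
    ]
    negatives = sample_negative_pairs(traits_by_gene, len(positives), rng)
    for g1, g2 in positives:
        shared = traits_by_gene[g1] & traits_by_gene[g2]
        year = max(
            year_by_gene_trait[(g, t)] for g in (g1, g2) for t in shared
        )
        s = gene_similarity(builder.kg, g1, g2, provider, scoring).S
        pairs.append(LabeledPair(g1, g2, s, True, year))
    for g1, g2 in negatives:
        year = max(
            min(year_by_gene_trait[(g, t)] for t in traits_by_gene[g])
            for g in (g1, g2)
        )
        s = gene_similarity(builder.kg, g1, g2, provider, scoring).S
        pairs.append(LabeledPair(g1, g2, s, False, year))

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "traits": traits,
        "genes": {g: dict(genes[g]) for g in order},
        "planted_links": sorted(
            [g, t]
            for g in order
            if genes[g]["role"] == "planted"
            for t in genes[g]["traits"]
        ),
        "n_entities": len(builder.kg),
        "n_triples": builder.kg.n_triples,
    }

    bundle = FixtureBundle(
        kg=builder.kg,
        associations=associations,
        provider=provider,
        labeled_pairs=pairs,
        manifest=manifest,
        sequences=sequences,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        triples_path = out / "triples.tsv"
        triples_path.write_text(
            "# head_id\thead_category\trelation\ttail_id\ttail_category\tsource\n"
            + "\n".join(sorted(builder.lines))
            + "\n",
            encoding="utf-8",
        )
        write_associations(associations, out / "associations.csv")
        provider.to_tsv(out / "protein_sim.tsv")
        write_labeled_pairs(pairs, out / "labeled_pairs.tsv")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
        )
        bundle.paths = {
            "triples": triples_path,
            "associations": out / "associations.csv",
            "protein_sim": out / "protein_sim.tsv",
            "labeled_pairs": out / "labeled_pairs.tsv",
            "manifest": out / "manifest.json",
        }
        if sequences:
            fasta = out / "proteins.fasta"
            fasta.write_text(
                "".join(f">{s.id}\n{s.residues}\n" for s in sequences),
                encoding="utf-8",
            )
            bundle.paths["fasta"] = fasta
    return bundle


def generate_deg_tables(
    manifest: dict,
    out_dir: str | Path,
    overlap_fraction: float = 0.66,
    n_decoy_rows: int = 5,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one DEG TSV per trait phenotype from a fixture manifest.

    Each gene carrying the trait appears with |log2FC| >= 1 with
    probability *overlap_fraction* and below 1 otherwise; a few decoy
    genes are included below threshold. Returns phenotype -> path.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise KGError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = manifest["genes"]
    decoys = sorted(g for g in genes if genes[g]["role"] == "decoy")
    written: dict[str, Path] = {}
    for trait in manifest["traits"]:
        carriers = sorted(g for g in genes if trait in genes[g]["traits"])
        rows = []
        for gene in carriers:
            if rng.random() < overlap_fraction:
                lfc = float(rng.uniform(1.0, 5.0)) * (1 if rng.random() < 0.5 else -1)
            else:
                lfc = float(rng.uniform(0.0, 0.99)) * (1 if rng.random() < 0.5 else -1)
            rows.append((gene, lfc))
        for gene in decoys[:n_decoy_rows]:
            rows.append((gene, float(rng.uniform(0.0, 0.99))))
        path = out / f"deg_{trait}.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("gene_id\tlog_fc\n")
            for gene, lfc in rows:
                fh.write(f"{gene}\t{lfc:.4f}\n")
        written[trait] = path
    return written


def rice_worked_example() -> tuple[KnowledgeGraph, TableProvider, list[GeneTraitAssociation]]:
    """A didactic miniature reproducing the published rice example.

    The gene LOC_Os05g12260 (protein Q6I5C3, documented for drought
    resistance in 2014) and the unannotated gene LOC_Os02g15640 (protein
    Q6EN42) share twelve annotation entities across four categories —
    four molecular functions, three biological processes, three cellular
    components and two signal pathways — and their proteins score 79.191,
    so S = 12 x 4 x 79.191 = 3801.17 (2 dp).
    """
    builder = _GraphBuilder()
    known, unknown = "LOC_Os05g12260", "LOC_Os02g15640"
    p_known, p_unknown = "Q6I5C3", "Q6EN42"
    for gene, prot in ((known, p_known), (unknown, p_unknown)):
        builder.add(
            Entity(prot, "protein", "rice"),
            "corresponding_to",
            Entity(gene, "gene", "rice"),
        )
    gene_level = (
        [(f"GO:mf{i}", "molecular_function") for i in range(4)]
        + [(f"GO:bp{i}", "biological_process") for i in range(3)]
        + [(f"GO:cc{i}", "cellular_component") for i in range(3)]
    )
    for gene in (known, unknown):
        for ann_id, cat in gene_level:
            builder.attach_annotation(gene, "rice", ann_id, cat)
    for prot in (p_known, p_unknown):
        for i in range(2):
            builder.add(
                Entity(prot, "protein", "rice"),
                "involves_in_signal_pathway",
                Entity(f"pathway{i}", "signal_pathway"),
            )
    builder.add(
        Entity(p_known, "protein", "rice"),
        "associates_with",
        Entity("drought_resistance", "trait"),
    )
    provider = TableProvider({(p_known, p_unknown): 79.191})
    associations = [
        GeneTraitAssociation(known, "drought_resistance", 2014, "PMID:literature")
    ]
    return builder.kg, provider, associations
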