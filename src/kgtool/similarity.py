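"""Gene–gene similarity score S(g1, g2) = C(k) · D(k) · S(p1, p2).

For two gene nodes the score multiplies three signals:

* ``C(k)`` — the number of *coincident entities*: the size of the
  intersection k of the two genes' scoring neighborhoods. This measures
  how much annotation context (GO terms, pathways, localizations,
  families, ...) the genes share.
* ``D(k)`` — the number of distinct entity categories represented in k,
  i.e. across how many molecular levels the overlap spreads.
* ``S(p1, p2)`` — the similarity of the proteins the genes encode
  (sequence conservation), from a :class:`~kgtool.protein.SimilarityProvider`.

A gene's *scoring neighborhood* is its 1-hop neighbor set, optionally
(default on) unioned with the 1-hop neighbors of each protein linked to
it by ``corresponding_to`` — shared pathway or localization annotations
hang off the protein node, not the gene node, in this schema. Trait
nodes are excluded by default so the label being predicted never leaks
into the score.

All counts are over entities: parallel relations to the same neighbor
count once, and the score is exactly symmetric in (g1, g2).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import schema
from .errors import (
    NotAGeneError,
    SelfPairError,
    UnknownPairError,
    UnscorablePairError,
)
from .kg import Entity, GeneTraitAssociation, KnowledgeGraph
from .protein import SimilarityProvider


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs for neighborhood construction and protein-pair choice.

    excluded_categories
        Entity categories removed from scoring neighborhoods. Default
        ``{"trait"}``: scoring against the very trait to be predicted
        would leak labels.
    include_protein_hop
        Whether a gene's neighborhood also includes the 1-hop neighbors
        of its corresponding protein(s). Default on; switch off for a
        strict 1-hop neighborhood.
    protein_pair_policy
        How to pick (p1, p2) when genes map to several proteins:
        ``"max"`` takes the pair with the highest provider score,
        ``"first"`` the lexicographically first resolvable pair.
    """

    excluded_categories: frozenset[str] = frozenset({"trait"})
    include_protein_hop: bool = True
    protein_pair_policy: str = "max"

    def __post_init__(self) -> None:
        unknown = set(self.excluded_categories) - schema.ENTITY_CATEGORIES
        if unknown:
            raise ValueError(f"unknown excluded categories: {sorted(unknown)}")
        if self.protein_pair_policy not in {"max", "first"}:
            raise ValueError(f"bad protein_pair_policy {self.protein_pair_policy!r}")


@dataclass(frozen=True)
class GeneSimilarityResult:
    """The (C, D, Sp, S) decomposition of one gene-pair score."""

    g1: str
    g2: str
    C: int
    D: int
    Sp: float
    S: float
    p1: str
    p2: str
    coincident: frozenset[str] = frozenset()
    traits: tuple[str, ...] = ()

    def tagged(self, traits: tuple[str, ...]) -> "GeneSimilarityResult":
        return GeneSimilarityResult(
            self.g1, self.g2, self.C, self.D, self.Sp, self.S,
            self.p1, self.p2, self.coincident, traits,
        )


def corresponding_proteins(kg: KnowledgeGraph, gene_id: str) -> list[str]:
    """Protein ids linked to a gene by ``corresponding_to`` (either
    direction), sorted for determinism."""
    if kg.category(gene_id) != "gene":
        raise NotAGeneError(gene_id)
    out = set()
    for nb in kg.neighbors(gene_id):
        if nb.category != "protein":
            continue
        g = kg._g
        if g.has_edge(nb.id, gene_id, key="corresponding_to") or g.has_edge(
            gene_id, nb.id, key="corresponding_to"
        ):
            out.add(nb.id)
    return sorted(out)


def scoring_neighborhood(
    kg: KnowledgeGraph, gene_id: str, config: ScoringConfig | None = None
) -> set[Entity]:
    """N(g): the entity set the similarity score counts over."""
    config = config or ScoringConfig()
    if kg.category(gene_id) != "gene":
        raise NotAGeneError(gene_id)
    hood = set(kg.neighbors(gene_id))
    if config.include_protein_hop:
        for pid in corresponding_proteins(kg, gene_id):
            hood |= kg.neighbors(pid)
    hood = {e for e in hood if e.category not in config.excluded_categories}
    hood.discard(kg.entity(gene_id))
    return hood


def coincident_set(
    kg: KnowledgeGraph, g1: str, g2: str, config: ScoringConfig | None = None
) -> set[Entity]:
    """k = N(g1) ∩ N(g2)."""
    config = config or ScoringConfig()
    return scoring_neighborhood(kg, g1, config) & scoring_neighborhood(kg, g2, config)


def _select_protein_pair(
    kg: KnowledgeGraph,
    g1: str,
    g2: str,
    provider: SimilarityProvider,
    policy: str,
) -> tuple[str, str, float]:
    ps1 = corresponding_proteins(kg, g1)
    ps2 = corresponding_proteins(kg, g2)
    if not ps1 or not ps2:
        raise UnscorablePairError(
            f"no corresponding protein for {g1 if not ps1 else g2!r}"
        )
    best: tuple[str, str, float] | None = None
    for p1 in ps1:
        for p2 in ps2:
            try:
                sp = provider.score(p1, p2)
            except UnknownPairError:
                continue
            if policy == "first":
                return p1, p2, sp
            if best is None or sp > best[2]:
                best = (p1, p2, sp)
    if best is None:
        raise UnscorablePairError(
            f"no protein pair for ({g1}, {g2}) is known to the similarity provider"
        )
    return best


def gene_similarity(
    kg: KnowledgeGraph,
    g1: str,
    g2: str,
    provider: SimilarityProvider,
    config: ScoringConfig | None = None,
) -> GeneSimilarityResult:
    """Score one gene pair: S = C(k) · D(k) · S(p1, p2).

    Raises :class:`SelfPairError` for g1 == g2 and
    :class:`UnscorablePairError` when no protein pair can be resolved —
    an unscorable pair is a flagged skip, never a zero.
    """
    config = config or ScoringConfig()
    if g1 == g2:
        raise SelfPairError(g1)
    for g in (g1, g2):
        if kg.category(g) != "gene":
            raise NotAGeneError(g)
    k = coincident_set(kg, g1, g2, config)
    C = len(k)
    D = len({e.category for e in k})
    p1, p2, sp = _select_protein_pair(kg, g1, g2, provider, config.protein_pair_policy)
    # canonical orientation so the result is symmetric in (g1, g2)
    if g1 > g2:
        g1, g2, p1, p2 = g2, g1, p2, p1
    return GeneSimilarityResult(
        g1, g2, C, D, sp, C * D * sp, p1, p2, frozenset(e.id for e in k)
    )


def similarity_to_known(
    kg: KnowledgeGraph,
    unknown_gene: str,
    known_associations: list[GeneTraitAssociation],
    provider: SimilarityProvider,
    config: ScoringConfig | None = None,
) -> list[GeneSimilarityResult]:
    """Score *unknown_gene* against every known trait-regulating gene.

    Returns one result per distinct known gene, tagged with all traits
    that gene is documented for, ordered by known gene id. Self-pairs
    and unscorable pairs are skipped.
    """
    config = config or ScoringConfig()
    traits_by_gene: dict[str, list[str]] = {}
    for a in known_associations:
        traits_by_gene.setdefault(a.gene_id, [])
        if a.trait not in traits_by_gene[a.gene_id]:
            traits_by_gene[a.gene_id].append(a.trait)
    out: list[GeneSimilarityResult] = []
    for known_gene in sorted(traits_by_gene):
        if known_gene == unknown_gene or known_gene not in kg:
            continue
        try:
            res = gene_similarity(kg, unknown_gene, known_gene, provider, config)
        except UnscorablePairError:
            continue
        out.append(res.tagged(tuple(sorted(traits_by_gene[known_gene]))))
    return out
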