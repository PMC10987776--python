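"""Controlled vocabularies of the trait-regulating-gene knowledge graph.

The graph schema is a fixed ontology: 13 entity categories (trait, gene,
protein and ten annotation categories) connected by 14 relation types,
each relation joining exactly one (head category, tail category) pair.
Because every neighborhood query in the scorer is undirected, schema
validation accepts a triple whose endpoint categories match the legal
pair in either orientation.
"""

from __future__ import annotations

from .errors import SchemaError

#: The 13 entity categories (closed set).
ENTITY_CATEGORIES: frozenset[str] = frozenset(
    {
        "trait",
        "gene",
        "protein",
        "gene_symbol",
        "signal_pathway",
        "subcellular_localization",
        "protein_domain",
        "protein_family",
        "cellular_component",
        "molecular_function",
        "biological_process",
        "metabolic_pathway",
        "enzyme",
    }
)

#: The 14 relation types with their legal (head category, tail category)
#: pair, as written in the schema table.
RELATION_PAIRS: dict[str, tuple[str, str]] = {
    "associates_with": ("protein", "trait"),
    "homologous_to": ("protein", "protein"),
    "interacts_with": ("protein", "protein"),
    "corresponding_to": ("protein", "gene"),
    "identify_with": ("protein", "gene_symbol"),
    "involves_in_signal_pathway": ("protein", "signal_pathway"),
    "located_in_subcellular_localization": ("protein", "subcellular_localization"),
    "has_protein_domain": ("protein", "protein_domain"),
    "belongs_to_protein_family": ("protein", "protein_family"),
    "located_in_cellular_component": ("gene", "cellular_component"),
    "performs": ("gene", "molecular_function"),
    "involves_in_biological_process": ("gene", "biological_process"),
    "involves_in_metabolic_pathway": ("gene", "metabolic_pathway"),
    "encodes_enzyme_type": ("gene", "enzyme"),
}

RELATION_TYPES: frozenset[str] = frozenset(RELATION_PAIRS)

#: Optional species annotation values (never used by the scorer).
SPECIES = frozenset({"arabidopsis", "rice", "maize", "wheat", "none"})

#: Annotation categories whose edges hang off the *gene* node.
GENE_ANNOTATION_RELATIONS = {
    "cellular_component": "located_in_cellular_component",
    "molecular_function": "performs",
    "biological_process": "involves_in_biological_process",
    "metabolic_pathway": "involves_in_metabolic_pathway",
    "enzyme": "encodes_enzyme_type",
}

#: Annotation categories whose edges hang off the *protein* node.
PROTEIN_ANNOTATION_RELATIONS = {
    "signal_pathway": "involves_in_signal_pathway",
    "subcellular_localization": "located_in_subcellular_localization",
    "protein_domain": "has_protein_domain",
    "protein_family": "belongs_to_protein_family",
}


def validate_category(name: str) -> str:
    if name not in ENTITY_CATEGORIES:
        raise SchemaError(f"unknown entity category: {name!r}")
    return name


def validate_relation(name: str) -> str:
    if name not in RELATION_TYPES:
        raise SchemaError(f"unknown relation type: {name!r}")
    return name


def validate_triple_categories(head_cat: str, relation: str, tail_cat: str) -> None:
    """Check that *relation* legally joins the two categories.

    The legal pair is accepted in either orientation because adjacency is
    undirected throughout; an illegal pair raises :class:`SchemaError`.
    """
    validate_relation(relation)
    legal = RELATION_PAIRS[relation]
    if (head_cat, tail_cat) != legal and (tail_cat, head_cat) != legal:
        raise SchemaError(
            f"relation {relation!r} may only connect {legal[0]!r} to "
            f"{legal[1]!r}, got ({head_cat!r}, {tail_cat!r})"
        )
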