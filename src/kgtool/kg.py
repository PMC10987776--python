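"""Typed knowledge graph of genes, proteins, traits and annotations.

The graph is a set of typed triples (head entity, relation, tail entity)
over the 13-category / 14-relation schema in :mod:`kgtool.schema`. Edges
are stored with the direction they were written in, but every neighbor
query is undirected: an entity reached through an incoming edge is a
neighbor all the same. Duplicate triples collapse to one — the gene
similarity score counts entities, never parallel edges.

File formats
------------
* Triple file: UTF-8 TSV with six columns
  ``head_id  head_category  relation  tail_id  tail_category  source``;
  lines starting with ``#`` are comments.
* Association file: CSV with header ``gene_id,trait,year,evidence``.
* Bulk export: one node CSV per category (``id:ID,category:LABEL,species``)
  and one relationship CSV per relation (``:START_ID,:END_ID,:TYPE,source``),
  following the bulk-import convention of property-graph databases.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import schema
from .errors import KGError, SchemaError, UnknownEntityError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Entity:
    """A graph node: an opaque id with one of the 13 categories."""

    id: str
    category: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise KGError("entity id must be non-empty")
        schema.validate_category(self.category)


@dataclass(frozen=True)
class Triple:
    """A directed, typed edge between two entities."""

    head: Entity
    relation: str
    tail: Entity
    source: str = ""

    def __post_init__(self) -> None:
        schema.validate_triple_categories(
            self.head.category, self.relation, self.tail.category
        )
        if self.head.id == self.tail.id:
            raise SchemaError(f"self-loop on {self.head.id!r} via {self.relation!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head.id, self.relation, self.tail.id)


@dataclass
class GeneTraitAssociation:
    """A literature-documented (gene, trait) link with its publication year."""

    gene_id: str
    trait: str
    year: int
    evidence: str = ""

    def __post_init__(self) -> None:
        self.year = int(self.year)
        if not 1900 <= self.year <= 2100:
            raise KGError(f"implausible publication year {self.year}")


@dataclass
class LoadReport:
    """Per-file accounting of skipped lines in permissive loading."""

    n_lines: int = 0
    n_loaded: int = 0
    n_duplicates: int = 0
    n_skipped: int = 0
    errors: list[str] = field(default_factory=list)


class KnowledgeGraph:
    """In-memory triple store with undirected neighbor queries.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are
    relation names, so at most one edge exists per (head, relation, tail).
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction ------------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        existing = self._g.nodes.get(entity.id)
        if existing is not None:
            if existing["category"] != entity.category:
                raise SchemaError(
                    f"entity {entity.id!r} declared with conflicting categories "
                    f"{existing['category']!r} and {entity.category!r}"
                )
            if entity.species and not existing.get("species"):
                self._g.nodes[entity.id]["species"] = entity.species
        else:
            self._g.add_node(
                entity.id, category=entity.category, species=entity.species
            )
        return entity

    def add_triple(self, triple: Triple) -> bool:
        """Insert a triple; return ``False`` if it was already present."""
        self.add_entity(triple.head)
        self.add_entity(triple.tail)
        h, r, t = triple.key
        if self._g.has_edge(h, t, key=r):
            return False
        self._g.add_edge(h, t, key=r, source=triple.source)
        return True

    # -- queries -----------------------------------------------------------

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_triples(self) -> int:
        return self._g.number_of_edges()

    def entity(self, entity_id: str) -> Entity:
        try:
            data = self._g.nodes[entity_id]
        except KeyError:
            raise UnknownEntityError(entity_id) from None
        return Entity(entity_id, data["category"], data.get("species"))

    def category(self, entity_id: str) -> str:
        return self.entity(entity_id).category

    def entities(self, category: str | None = None) -> list[Entity]:
        out = [self.entity(n) for n in self._g.nodes]
        if category is not None:
            out = [e for e in out if e.category == category]
        return sorted(out, key=lambda e: e.id)

    def triples(self) -> list[Triple]:
        return sorted(
            (
                Triple(self.entity(u), r, self.entity(v), d.get("source", ""))
                for u, v, r, d in self._g.edges(keys=True, data=True)
            ),
            key=lambda t: t.key,
        )

    def neighbors(self, entity_id: str) -> set[Entity]:
        """All entities adjacent to *entity_id* through any edge, in either
        direction. Never contains the entity itself."""
        if entity_id not in self._g:
            raise UnknownEntityError(entity_id)
        ids = set(self._g.successors(entity_id)) | set(
            self._g.predecessors(entity_id)
        )
        ids.discard(entity_id)
        return {self.entity(n) for n in ids}

    def neighbor_ids(self, entity_id: str) -> set[str]:
        return {e.id for e in self.neighbors(entity_id)}

    # -- summary -----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Per (head category, relation, tail category) statistics.

        Columns mirror the schema statistics table: distinct head count,
        triple count, distinct tail count. Attributes ``n_nodes`` and
        ``n_triples`` carry the global totals.
        """
        rows: dict[tuple[str, str, str], dict[str, set | int]] = {}
        for u, v, r in self._g.edges(keys=True):
            key = (self.category(u), r, self.category(v))
            rec = rows.setdefault(key, {"heads": set(), "tails": set(), "triples": 0})
            rec["heads"].add(u)
            rec["tails"].add(v)
            rec["triples"] += 1
        df = pd.DataFrame(
            [
                {
                    "head_category": h,
                    "relation": r,
                    "tail_category": t,
                    "n_head": len(rec["heads"]),
                    "n_triples": rec["triples"],
                    "n_tail": len(rec["tails"]),
                }
                for (h, r, t), rec in sorted(rows.items())
            ],
            columns=[
                "head_category",
                "relation",
                "tail_category",
                "n_head",
                "n_triples",
                "n_tail",
            ],
        )
        df.attrs["n_nodes"] = self._g.number_of_nodes()
        df.attrs["n_triples"] = self._g.number_of_edges()
        return df

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "entities": [
                {"id": e.id, "category": e.category, "species": e.species}
                for e in self.entities()
            ],
            "triples": [
                {
                    "head": t.head.id,
                    "relation": t.relation,
                    "tail": t.tail.id,
                    "source": t.source,
                }
                for t in self.triples()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "KnowledgeGraph":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        kg = cls()
        for e in payload["entities"]:
            kg.add_entity(Entity(e["id"], e["category"], e.get("species")))
        for t in payload["triples"]:
            kg.add_triple(
                Triple(
                    kg.entity(t["head"]),
                    t["relation"],
                    kg.entity(t["tail"]),
                    t.get("source", ""),
                )
            )
        return kg

    def export_bulk_csv(self, out_dir: str | Path) -> list[Path]:
        """Write per-category node CSVs and per-relation relationship CSVs.

        The layout follows the bulk CSV import convention of property-graph
        databases (``id:ID``/``:LABEL`` node headers, ``:START_ID`` /
        ``:END_ID`` / ``:TYPE`` relationship headers). Files round-trip
        through :func:`load_bulk_csv`.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        by_cat: dict[str, list[Entity]] = {}
        for e in self.entities():
            by_cat.setdefault(e.category, []).append(e)
        for cat in sorted(schema.ENTITY_CATEGORIES):
            path = out / f"nodes_{cat}.csv"
            with path.open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["id:ID", "category:LABEL", "species"])
                for e in by_cat.get(cat, []):
                    w.writerow([e.id, e.category, e.species or ""])
            written.append(path)
        by_rel: dict[str, list[Triple]] = {}
        for t in self.triples():
            by_rel.setdefault(t.relation, []).append(t)
        for rel in sorted(schema.RELATION_TYPES):
            path = out / f"rels_{rel}.csv"
            with path.open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow([":START_ID", ":END_ID", ":TYPE", "source"])
                for t in by_rel.get(rel, []):
                    w.writerow([t.head.id, t.tail.id, t.relation, t.source])
            written.append(path)
        return written


# ---------------------------------------------------------------------------
# loaders


def _parse_triple_line(line: str) -> Triple:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 6:
        raise SchemaError(f"expected 6 tab-separated columns, got {len(cols)}")
    head_id, head_cat, relation, tail_id, tail_cat, source = cols
    head = Entity(head_id, schema.validate_category(head_cat))
    tail = Entity(tail_id, schema.validate_category(tail_cat))
    return Triple(head, relation, tail, source)


def load_triples(
    path: str | Path,
    strict: bool = True,
    kg: KnowledgeGraph | None = None,
) -> tuple[KnowledgeGraph, LoadReport]:
    """Load a 6-column TSV triple file into a knowledge graph.

    Duplicate triples collapse to one (loading the same file twice is a
    no-op). In strict mode any schema violation aborts the load; otherwise
    violating lines are skipped and counted in the returned report.
    Self-loops are always dropped with a warning — no relation in the
    schema is reflexive, and a protein declared homologous to itself
    carries no information.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(p)
    kg = kg if kg is not None else KnowledgeGraph()
    report = LoadReport()
    with p.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            report.n_lines += 1
            try:
                triple = _parse_triple_line(line)
            except SchemaError as exc:
                if "self-loop" in str(exc):
                    logger.warning("line %d: %s (dropped)", lineno, exc)
                    report.n_skipped += 1
                    report.errors.append(f"line {lineno}: {exc}")
                    continue
                if strict:
                    raise SchemaError(f"line {lineno}: {exc}") from exc
                report.n_skipped += 1
                report.errors.append(f"line {lineno}: {exc}")
                continue
            try:
                added = kg.add_triple(triple)
            except SchemaError as exc:
                if strict:
                    raise SchemaError(f"line {lineno}: {exc}") from exc
                report.n_skipped += 1
                report.errors.append(f"line {lineno}: {exc}")
                continue
            if added:
                report.n_loaded += 1
            else:
                report.n_duplicates += 1
    return kg, report


def load_bulk_csv(directory: str | Path) -> KnowledgeGraph:
    """Rebuild a graph from an :meth:`KnowledgeGraph.export_bulk_csv` dump."""
    d = Path(directory)
    kg = KnowledgeGraph()
    for path in sorted(d.glob("nodes_*.csv")):
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                kg.add_entity(
                    Entity(row["id:ID"], row["category:LABEL"], row["species"] or None)
                )
    for path in sorted(d.glob("rels_*.csv")):
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                kg.add_triple(
                    Triple(
                        kg.entity(row[":START_ID"]),
                        row[":TYPE"],
                        kg.entity(row[":END_ID"]),
                        row["source"],
                    )
                )
    return kg


def load_associations(path: str | Path) -> list[GeneTraitAssociation]:
    """Read gene–trait association records from CSV.

    Requires header ``gene_id,trait,year,evidence``; record order is
    preserved and years are coerced to integers (a non-integer year is an
    error).
    """
    p = Path(path)
    with p.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"gene_id", "trait", "year", "evidence"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise KGError(
                f"{p}: association CSV must have columns {sorted(required)}"
            )
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                year = int(row["year"])
            except ValueError as exc:
                raise KGError(f"{p} line {i}: unparsable year {row['year']!r}") from exc
            out.append(
                GeneTraitAssociation(row["gene_id"], row["trait"], year, row["evidence"])
            )
    return out


def write_associations(
    associations: list[GeneTraitAssociation], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["gene_id", "trait", "year", "evidence"])
        for a in associations:
            w.writerow([a.gene_id, a.trait, a.year, a.evidence])
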