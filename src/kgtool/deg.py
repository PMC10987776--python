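"""Validation of mined polyphenotype genes against transcriptome DEG sets.

Differentially expressed gene (DEG) lists — genes passing
|log2 fold change| >= 1 between a stress treatment and its control —
serve as independent evidence. Each polyphenotype gene is assigned to
exactly one Venn region: the exact subset of DEG sets containing it, or
none. The *verified fraction* is the share of polyphenotype genes found
in at least one DEG set.

No id mapping is performed between the gene lists: comparisons are
within one species and nomenclature, and fuzzy matching would fabricate
overlaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import KGError


@dataclass
class DEGSet:
    """A named set of differentially expressed genes for one phenotype."""

    phenotype: str
    genes: frozenset[str]
    species: str = ""
    provenance: str = ""


def load_deg_table(
    path: str | Path,
    phenotype: str,
    species: str = "",
    lfc_threshold: float = 1.0,
) -> DEGSet:
    """Read a DEG TSV (columns ``gene_id``, ``log_fc``; extras ignored)
    and keep genes with |log_fc| >= *lfc_threshold* (inclusive).

    The fold changes are expected already log-transformed (base 2 by
    convention); duplicates collapse.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log_fc"} - set(df.columns)
    if missing:
        raise KGError(f"{path}: DEG table missing columns {sorted(missing)}")
    try:
        lfc = pd.to_numeric(df["log_fc"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise KGError(f"{path}: non-numeric log_fc values") from exc
    kept = df.loc[lfc.abs() >= lfc_threshold, "gene_id"].astype(str)
    return DEGSet(
        phenotype=phenotype,
        genes=frozenset(kept),
        species=species,
        provenance=str(path),
    )


@dataclass
class OverlapReport:
    """Venn-region accounting of polyphenotype genes against DEG sets."""

    total_poly: int
    region_counts: dict[frozenset[str], int]
    in_none: int
    phenotypes: tuple[str, ...] = ()
    region_genes: dict[frozenset[str], frozenset[str]] = field(default_factory=dict)

    @property
    def n_verified(self) -> int:
        return self.total_poly - self.in_none

    @property
    def verified_fraction(self) -> float:
        return self.n_verified / self.total_poly

    @property
    def verified_percent(self) -> int:
        """The fraction rounded to whole percent, for display."""
        return round(100 * self.verified_fraction)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "total_poly": self.total_poly,
            "phenotypes": list(self.phenotypes),
            "regions": [
                {"phenotypes": sorted(region), "count": n}
                for region, n in sorted(
                    self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                )
            ],
            "in_none": self.in_none,
            "n_verified": self.n_verified,
            "verified_fraction": self.verified_fraction,
            "verified_percent": self.verified_percent,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return payload


def overlap_report(poly_genes: Iterable[str], deg_sets: list[DEGSet]) -> OverlapReport:
    """Assign each polyphenotype gene to its exact DEG-set region.

    Region counts partition the polyphenotype set: ``in_none`` plus the
    region counts always sum to the total. The verified fraction is
    exact; rounding happens only at display.
    """
    poly = set(poly_genes)
    if not poly:
        raise KGError("no polyphenotype genes given; verified fraction is undefined")
    if not deg_sets:
        raise KGError("need at least one DEG set")
    phenotypes = tuple(d.phenotype for d in deg_sets)
    if len(set(phenotypes)) != len(phenotypes):
        raise KGError(f"duplicate phenotype labels in DEG sets: {phenotypes}")
    region_counts: dict[frozenset[str], int] = {}
    region_genes: dict[frozenset[str], set[str]] = {}
    in_none = 0
    for gene in poly:
        region = frozenset(d.phenotype for d in deg_sets if gene in d.genes)
        if not region:
            in_none += 1
            continue
        region_counts[region] = region_counts.get(region, 0) + 1
        region_genes.setdefault(region, set()).add(gene)
    return OverlapReport(
        total_poly=len(poly),
        region_counts=region_counts,
        in_none=in_none,
        phenotypes=phenotypes,
        region_genes={r: frozenset(g) for r, g in region_genes.items()},
    )


def plot_venn(report: OverlapReport, path: str | Path) -> None:
    """Draw a simple 2- or 3-set Venn diagram of the overlap report.

    Circles are drawn directly with matplotlib patches; region counts are
    printed at canonical positions. Only 2 or 3 phenotypes are supported.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    names = list(report.phenotypes)
    k = len(names)
    if k not in (2, 3):
        raise KGError("Venn figure supports exactly 2 or 3 DEG sets")
    centers2 = [(-0.5, 0.0), (0.5, 0.0)]
    centers3 = [(-0.5, -0.29), (0.5, -0.29), (0.0, 0.58)]
    centers = centers2 if k == 2 else centers3
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = ["tab:orange", "tab:blue", "tab:red"]
    for (x, y), name, color in zip(centers, names, colors):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3, color=color))
        ax.annotate(name, (x, y + 1.05), ha="center")

    def count(region: frozenset[str]) -> int:
        return report.region_counts.get(region, 0)

    if k == 2:
        a, b = names
        ax.text(-1.0, 0, str(count(frozenset({a}))), ha="center")
        ax.text(1.0, 0, str(count(frozenset({b}))), ha="center")
        ax.text(0.0, 0, str(count(frozenset({a, b}))), ha="center")
    else:
        a, b, c = names
        ax.text(-1.0, -0.5, str(count(frozenset({a}))), ha="center")
        ax.text(1.0, -0.5, str(count(frozenset({b}))), ha="center")
        ax.text(0.0, 1.0, str(count(frozenset({c}))), ha="center")
        ax.text(0.0, -0.5, str(count(frozenset({a, b}))), ha="center")
        ax.text(-0.6, 0.35, str(count(frozenset({a, c}))), ha="center")
        ax.text(0.6, 0.35, str(count(frozenset({b, c}))), ha="center")
        ax.text(0.0, 0.1, str(count(frozenset({a, b, c}))), ha="center")
    ax.text(
        0,
        -1.6,
        f"outside: {report.in_none}   verified: {report.verified_percent}%",
        ha="center",
    )
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.0, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=100)
    plt.close(fig)
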