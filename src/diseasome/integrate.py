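"""Merge the three association sources into one harmonized table.

Deduplication is at the (disease_id, gene_symbol) pair level: identical
pairs reported by several sources collapse to one row whose provenance set
is the union, so no evidence is lost while redundant entries disappear.
Orphanet disorders cross-referenced to an OMIM identifier adopt that OMIM
id as their canonical disease id, which is what makes the cross-source
overlap measurable at all.

Diseases are then labeled by source membership:

* ``OD``  — orphan disease: evidence only from Orphanet;
* ``CD``  — complex disease: evidence only from OMIM/DisGeNet;
* ``BOTH`` — evidence from Orphanet and at least one other source; these
  diseases participate in both the OD and the CD gene networks.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .ingest import Association, Source

logger = logging.getLogger("diseasome")

__all__ = [
    "Category",
    "AssociationRow",
    "AssociationTable",
    "OverlapReport",
    "VENN_REGIONS",
    "merge_sources",
    "label_categories",
    "overlap_report",
    "write_table",
    "read_table",
    "write_overlap_report",
]

from enum import Enum


class Category(str, Enum):
    """Disease class by source membership."""

    OD = "OD"
    CD = "CD"
    BOTH = "BOTH"

    def __str__(self) -> str:
        return self.value


#: name precedence when sources disagree (first wins)
_NAME_PRECEDENCE = (Source.ORPHANET, Source.OMIM, Source.DISGENET)


@dataclass(frozen=True)
class AssociationRow:
    """One unique (disease, gene) pair with provenance and category."""

    disease_id: str
    disease_name: str
    gene_symbol: str
    sources: frozenset[Source]
    category: Category | None = None


@dataclass
class AssociationTable:
    """Deduplicated union of the three sources."""

    rows: list[AssociationRow] = field(default_factory=list)

    def __iter__(self) -> Iterator[AssociationRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def disease_genes(self) -> dict[str, set[str]]:
        """disease_id -> set of associated gene symbols."""
        out: dict[str, set[str]] = {}
        for row in self.rows:
            out.setdefault(row.disease_id, set()).add(row.gene_symbol)
        return out

    def disease_categories(self) -> dict[str, Category]:
        return {r.disease_id: r.category for r in self.rows if r.category is not None}

    def disease_names(self) -> dict[str, str]:
        return {r.disease_id: r.disease_name for r in self.rows}


def merge_sources(
    orphanet: Iterable[Association],
    omim: Iterable[Association],
    disgenet: Iterable[Association],
    orphanet_xref: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Collapse per-source association rows into unique (disease, gene) pairs.

    ``orphanet_xref`` maps ORPHA ids to OMIM ids (as collected by the
    Orphanet reader); a cross-referenced disorder is re-keyed to its OMIM id
    so that the same disease reported by several databases collapses onto a
    single identity.  Disease names follow source precedence
    Orphanet > OMIM > DisGeNet; under equal precedence the first-seen name
    wins and conflicts are logged.  The result is independent of input row
    order up to row ordering (rows come out sorted).
    """
    orphanet_xref = dict(orphanet_xref or {})

    pair_sources: dict[tuple[str, str], set[Source]] = {}
    # disease_id -> (precedence rank, name); lower rank wins
    names: dict[str, tuple[int, str]] = {}

    def canonical(row: Association) -> str:
        if row.source is Source.ORPHANET:
            return orphanet_xref.get(row.disease_id, row.disease_id)
        return row.disease_id

    for source_rows in (orphanet, omim, disgenet):
        for row in source_rows:
            did = canonical(row)
            pair_sources.setdefault((did, row.gene_symbol), set()).add(row.source)
            rank = _NAME_PRECEDENCE.index(row.source)
            held = names.get(did)
            if held is None or rank < held[0]:
                names[did] = (rank, row.disease_name)
            elif rank == held[0] and row.disease_name != held[1]:
                logger.warning(
                    "conflicting names for %s: keeping %r, ignoring %r",
                    did, held[1], row.disease_name,
                )

    rows = [
        AssociationRow(did, names[did][1], gene, frozenset(srcs))
        for (did, gene), srcs in pair_sources.items()
    ]
    rows.sort(key=lambda r: (r.disease_id, r.gene_symbol))
    return AssociationTable(rows)


def label_categories(table: AssociationTable) -> AssociationTable:
    """Assign OD/CD/BOTH per disease from the union of its row provenances."""
    by_disease: dict[str, set[Source]] = {}
    for row in table:
        by_disease.setdefault(row.disease_id, set()).update(row.sources)

    def categorize(sources: set[Source]) -> Category:
        has_orpha = Source.ORPHANET in sources
        has_other = bool(sources - {Source.ORPHANET})
        if has_orpha and has_other:
            return Category.BOTH
        return Category.OD if has_orpha else Category.CD

    cats = {did: categorize(srcs) for did, srcs in by_disease.items()}
    return AssociationTable(
        [replace(r, category=cats[r.disease_id]) for r in table]
    )


# the 7 exclusive regions of the 3-source Venn diagram
VENN_REGIONS = (
    "orphanet_only",
    "omim_only",
    "disgenet_only",
    "orphanet_omim",
    "orphanet_disgenet",
    "omim_disgenet",
    "orphanet_omim_disgenet",
)


@dataclass
class OverlapReport:
    """Cross-source disease overlap and OD/CD gene overlap."""

    venn: dict[str, int]
    n_od_genes: int
    n_cd_genes: int
    n_shared_genes: int

    def total_diseases(self) -> int:
        return sum(self.venn.values())


def overlap_report(table: AssociationTable) -> OverlapReport:
    """Compute the Venn region counts and the OD/CD gene-set overlap.

    Disease Venn regions are computed on canonical disease identities: a
    disease belongs to a source when at least one of its rows carries that
    source.  Gene-level counts: a gene is an OD (resp. CD) gene when it is
    associated with at least one disease of category OD/BOTH (resp.
    CD/BOTH).
    """
    by_disease: dict[str, set[Source]] = {}
    for row in table:
        by_disease.setdefault(row.disease_id, set()).update(row.sources)

    venn = Counter({region: 0 for region in VENN_REGIONS})
    for sources in by_disease.values():
        key = [
            name
            for name, src in (
                ("orphanet", Source.ORPHANET),
                ("omim", Source.OMIM),
                ("disgenet", Source.DISGENET),
            )
            if src in sources
        ]
        region = "_".join(key) + ("_only" if len(key) == 1 else "")
        venn[region] += 1

    cats = label_categories(table).disease_categories() if any(
        r.category is None for r in table
    ) else table.disease_categories()
    od_genes: set[str] = set()
    cd_genes: set[str] = set()
    for row in table:
        cat = cats[row.disease_id]
        if cat in (Category.OD, Category.BOTH):
            od_genes.add(row.gene_symbol)
        if cat in (Category.CD, Category.BOTH):
            cd_genes.add(row.gene_symbol)

    return OverlapReport(
        venn=dict(venn),
        n_od_genes=len(od_genes),
        n_cd_genes=len(cd_genes),
        n_shared_genes=len(od_genes & cd_genes),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_HEADER = "disease_id\tdisease_name\tgene_symbol\tsources\tcategory"


def write_table(table: AssociationTable, path: str | Path) -> None:
    """Write the integrated table as TSV (sources semicolon-joined, sorted)."""
    with open(path, "w", newline="") as fh:
        fh.write(_HEADER + "\n")
        for row in table:
            sources = ";".join(sorted(s.value for s in row.sources))
            category = row.category.value if row.category else ""
            fh.write(
                f"{row.disease_id}\t{row.disease_name}\t{row.gene_symbol}"
                f"\t{sources}\t{category}\n"
            )


def read_table(path: str | Path) -> AssociationTable:
    rows: list[AssociationRow] = []
    with open(path, newline="") as fh:
        header = fh.readline()
        if header.strip() != _HEADER.strip():
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            did, name, gene, sources, category = line.rstrip("\n").split("\t")
            rows.append(
                AssociationRow(
                    did,
                    name,
                    gene,
                    frozenset(Source(s) for s in sources.split(";") if s),
                    Category(category) if category else None,
                )
            )
    return AssociationTable(rows)


def write_overlap_report(report: OverlapReport, tsv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    with open(tsv_path, "w", newline="") as fh:
        fh.write("quantity\tcount\n")
        for region in VENN_REGIONS:
            fh.write(f"venn_{region}\t{report.venn[region]}\n")
        fh.write(f"od_genes\t{report.n_od_genes}\n")
        fh.write(f"cd_genes\t{report.n_cd_genes}\n")
        fh.write(f"shared_genes\t{report.n_shared_genes}\n")
    if json_path is not None:
        payload = {
            "venn": {r: report.venn[r] for r in VENN_REGIONS},
            "od_genes": report.n_od_genes,
            "cd_genes": report.n_cd_genes,
            "shared_genes": report.n_shared_genes,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
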