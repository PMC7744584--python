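"""Readers for the three gene-disease association source dialects.

Gene-disease evidence is harvested from three kinds of resources: an
Orphanet-style XML listing rare disorders with their associated genes, an
OMIM genemap-style TSV carrying phenotype mapping keys, and a DisGeNet-style
TSV keyed by UMLS concept identifiers (CUIs).  Each reader flattens its
dialect into uniform :class:`Association` rows — one row per (disease, gene)
evidence pair — without deduplicating across sources; merging is the job of
:mod:`diseasome.integrate`.

Two auxiliary tables support harmonization: a UMLS CUI → OMIM identifier map
(DisGeNet diseases are re-keyed to OMIM; CUIs resolving to more than one OMIM
identifier are discarded as ambiguous) and an HGNC alias → official-symbol
table (all gene mentions are normalized onto official symbols so the same
gene never appears under two names).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

from lxml import etree

logger = logging.getLogger("diseasome")

__all__ = [
    "Source",
    "Association",
    "ParseResult",
    "UmlsMap",
    "AliasTable",
    "read_orphanet_xml",
    "read_omim_genemap",
    "read_disgenet_tsv",
    "load_umls_map",
    "load_alias_table",
    "normalize_symbols",
    "write_orphanet_xml",
    "write_omim_genemap",
    "write_disgenet_tsv",
]

DISEASE_ID_RE = re.compile(r"^(OMIM|ORPHA):[0-9]+$")
CUI_RE = re.compile(r"^C[0-9]+$")


class Source(str, Enum):
    """Provenance of one association row."""

    ORPHANET = "ORPHANET"
    OMIM = "OMIM"
    DISGENET = "DISGENET"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class Association:
    """One (source, disease, gene) evidence row — the pipeline's atom.

    ``disease_id`` is namespaced (``OMIM:114480`` or ``ORPHA:558``).
    ``gene_symbol`` holds the HGNC official symbol once
    :func:`normalize_symbols` has run; ``raw_gene_symbol`` keeps the symbol
    as printed in the source file.  ``mapped`` records whether the alias
    table resolved the raw symbol.
    """

    source: Source
    disease_id: str
    disease_name: str
    gene_symbol: str
    raw_gene_symbol: str
    mapped: bool = False

    def __post_init__(self) -> None:
        if not DISEASE_ID_RE.match(self.disease_id):
            raise ValueError(f"malformed disease_id: {self.disease_id!r}")
        if not self.gene_symbol:
            raise ValueError("empty gene_symbol")
        if not self.mapped and self.gene_symbol != self.raw_gene_symbol:
            raise ValueError("unmapped row must keep its raw symbol")


@dataclass
class ParseResult:
    """Associations from one source file plus record-level bookkeeping.

    Behaves like a list of :class:`Association` (iteration, ``len``,
    indexing) so callers that only want the rows can treat it as one.
    Counters account for every input record: emitted + skipped + gene-less
    (+ discarded for DisGeNet) covers the file.
    """

    associations: list[Association] = field(default_factory=list)
    skipped: int = 0
    gene_less: int = 0
    ambiguous_cui: int = 0
    unmapped_cui: int = 0
    errors: list[str] = field(default_factory=list)
    # Orphanet disorders cross-referenced to an OMIM identifier
    # ("ORPHA:558" -> "OMIM:154700"); used by integrate.merge_sources to
    # assign the canonical disease id.
    omim_xref: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Association]:
        return iter(self.associations)

    def __len__(self) -> int:
        return len(self.associations)

    def __getitem__(self, i):
        return self.associations[i]


#: UMLS CUI -> set of namespaced OMIM ids ("OMIM:114480").
UmlsMap = Mapping[str, frozenset[str]]

#: case-folded alias -> official HGNC symbol (officials map to themselves).
AliasTable = Mapping[str, str]


# ---------------------------------------------------------------------------
# Orphanet XML dialect
# ---------------------------------------------------------------------------

def read_orphanet_xml(path: str | Path) -> ParseResult:
    """Parse an Orphanet-style disorder/gene XML file.

    The dialect is ``<DisorderList><Disorder id="558" omim="154700">
    <Name>…</Name><GeneList><Gene symbol="FBN1"/>…</GeneList></Disorder>…``;
    unknown sibling elements are ignored.  One association is emitted per
    (disorder, gene) element pair, in order of appearance; duplicated gene
    elements are passed through verbatim (dedup happens at the merge stage).
    Disorders with no gene elements are counted as gene-less.  A malformed
    file raises ``lxml.etree.XMLSyntaxError`` (which names the line);
    disorders missing an id or name are skipped and reported.
    """
    tree = etree.parse(str(path))
    result = ParseResult()
    for disorder in tree.getroot().iter("Disorder"):
        orpha = disorder.get("id")
        name_el = disorder.find("Name")
        name = name_el.text if name_el is not None else None
        if not orpha or not name:
            result.skipped += 1
            result.errors.append(
                f"Disorder at line {disorder.sourceline}: missing id or name"
            )
            continue
        disease_id = f"ORPHA:{orpha}"
        omim = disorder.get("omim")
        if omim:
            result.omim_xref[disease_id] = f"OMIM:{omim}"
        genes = [g.get("symbol") for g in disorder.iter("Gene")]
        genes = [g for g in genes if g]
        if not genes:
            result.gene_less += 1
            logger.debug("gene-less disorder %s (%s)", disease_id, name)
            continue
        for symbol in genes:
            result.associations.append(
                Association(Source.ORPHANET, disease_id, name, symbol, symbol)
            )
    return result


def write_orphanet_xml(
    rows: list[Association],
    path: str | Path,
    omim_xref: Mapping[str, str] | None = None,
) -> None:
    """Serialize associations back to the Orphanet XML dialect.

    Rows are grouped by disease in first-appearance order; gene order within
    a disease is preserved, so a read → write → read round trip reproduces
    the association list exactly.
    """
    omim_xref = omim_xref or {}
    root = etree.Element("DisorderList")
    disorder_els: dict[str, etree._Element] = {}
    for row in rows:
        el = disorder_els.get(row.disease_id)
        if el is None:
            el = etree.SubElement(root, "Disorder", id=row.disease_id.split(":")[1])
            xref = omim_xref.get(row.disease_id)
            if xref:
                el.set("omim", xref.split(":")[1])
            etree.SubElement(el, "Name").text = row.disease_name
            etree.SubElement(el, "GeneList")
            disorder_els[row.disease_id] = el
        etree.SubElement(el.find("GeneList"), "Gene", symbol=row.raw_gene_symbol)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# OMIM genemap dialect
# ---------------------------------------------------------------------------

_MAPPING_KEY_RE = re.compile(r"^\(?([0-9]+)\)?$")


def read_omim_genemap(path: str | Path) -> ParseResult:
    """Parse an OMIM genemap-style TSV.

    Columns: ``omim_id  phenotype_name  mapping_key  gene_symbols`` with a
    ``#``-prefixed header and comma-separated gene symbols.  Only phenotype
    mapping key 3 is retained — the molecular basis of the phenotype is
    known, i.e. mutations have been found in the gene — so each surviving
    row yields one association per listed gene.  Both ``3`` and the
    parenthesized OMIM spelling ``(3)`` are accepted; rows with any other
    key are dropped, and a non-integer key is a record-level error.
    """
    result = ParseResult()
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                result.skipped += 1
                result.errors.append(f"line {lineno}: expected 4 columns")
                continue
            omim_id, name, key_field, gene_field = fields[:4]
            m = _MAPPING_KEY_RE.match(key_field.strip())
            if not m:
                result.skipped += 1
                result.errors.append(f"line {lineno}: non-integer mapping key {key_field!r}")
                continue
            if int(m.group(1)) != 3:
                result.skipped += 1
                continue
            genes = [g.strip() for g in gene_field.split(",") if g.strip()]
            if not genes:
                result.gene_less += 1
                continue
            for symbol in genes:
                result.associations.append(
                    Association(Source.OMIM, f"OMIM:{omim_id.strip()}", name, symbol, symbol)
                )
    return result


def write_omim_genemap(rows: list[Association], path: str | Path) -> None:
    """Serialize associations to the genemap dialect (all rows keyed ``(3)``)."""
    grouped: dict[str, tuple[str, list[str]]] = {}
    for row in rows:
        name, genes = grouped.setdefault(row.disease_id, (row.disease_name, []))
        genes.append(row.raw_gene_symbol)
    with open(path, "w", newline="") as fh:
        fh.write("# omim_id\tphenotype_name\tmapping_key\tgene_symbols\n")
        for disease_id, (name, genes) in grouped.items():
            omim_id = disease_id.split(":")[1]
            fh.write(f"{omim_id}\t{name}\t(3)\t{', '.join(genes)}\n")


# ---------------------------------------------------------------------------
# DisGeNet dialect + UMLS mapping
# ---------------------------------------------------------------------------

def load_umls_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Load the 2-column ``umls_cui  omim_id`` TSV (repeated CUIs = one-to-many)."""
    entries: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cui, omim_id = line.split("\t")[:2]
            entries.setdefault(cui.strip(), set()).add(f"OMIM:{omim_id.strip()}")
    return {cui: frozenset(ids) for cui, ids in entries.items()}


def read_disgenet_tsv(path: str | Path, umap: UmlsMap) -> ParseResult:
    """Parse a DisGeNet-style TSV (``umls_cui  disease_name  gene_symbol``).

    Disease identity is re-keyed from the UMLS CUI to an OMIM identifier via
    ``umap``.  A CUI resolving to exactly one OMIM id yields an association
    under that id; a CUI resolving to two or more OMIM ids is ambiguous and
    the row is discarded (counted); a CUI absent from the map is counted
    separately as unmapped.  Malformed CUIs are record-level errors.
    """
    result = ParseResult()
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                result.skipped += 1
                result.errors.append(f"line {lineno}: expected 3 columns")
                continue
            cui, name, symbol = (f.strip() for f in fields[:3])
            if not CUI_RE.match(cui):
                result.skipped += 1
                result.errors.append(f"line {lineno}: malformed CUI {cui!r}")
                continue
            omim_ids = umap.get(cui)
            if omim_ids is None:
                result.unmapped_cui += 1
                continue
            if len(omim_ids) > 1:
                result.ambiguous_cui += 1
                continue
            if not symbol:
                result.gene_less += 1
                continue
            (disease_id,) = omim_ids
            result.associations.append(
                Association(Source.DISGENET, disease_id, name, symbol, symbol)
            )
    return result


def write_disgenet_tsv(
    rows: list[Association], path: str | Path, cui_by_disease: Mapping[str, str]
) -> None:
    """Serialize associations to the DisGeNet dialect using the given CUIs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(
                [cui_by_disease[row.disease_id], row.disease_name, row.raw_gene_symbol]
            )


# ---------------------------------------------------------------------------
# HGNC symbol normalization
# ---------------------------------------------------------------------------

def load_alias_table(path: str | Path) -> dict[str, str]:
    """Load the 2-column ``alias  official`` TSV, case-folding aliases.

    Every official symbol is also entered as its own (case-folded) alias, so
    a file listing only true aliases still resolves official spellings.
    """
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            alias, official = (f.strip() for f in line.split("\t")[:2])
            table[alias.casefold()] = official
            table.setdefault(official.casefold(), official)
    return table


def normalize_symbols(
    rows: list[Association], aliases: AliasTable
) -> list[Association]:
    """Replace raw gene symbols with HGNC official symbols where resolvable.

    Matching is case-insensitive on the raw symbol; the emitted symbol keeps
    the alias table's casing.  Unresolvable symbols are kept verbatim with
    ``mapped=False`` (they are retained, not dropped); the unmapped fraction
    is logged.  Row count is unchanged and the function is idempotent.
    """
    out: list[Association] = []
    unmapped = 0
    for row in rows:
        official = aliases.get(row.raw_gene_symbol.casefold())
        if official is not None:
            out.append(replace(row, gene_symbol=official, mapped=True))
        else:
            unmapped += 1
            out.append(replace(row, gene_symbol=row.raw_gene_symbol, mapped=False))
    if rows:
        logger.info(
            "normalize_symbols: %d/%d rows unmapped (%.1f%%)",
            unmapped, len(rows), 100 * unmapped / len(rows),
        )
    return out
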