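"""Curation of GWAS-catalog-style association exports into gene lists.

The NHGRI-EBI GWAS catalog export is a wide tab-separated table; the few
columns that matter here are the trait description, the association
p-value, and the two gene annotation fields ("mapped" genes, assigned from
genomic position, and "reported" genes, taken from the source publication).
A curated list is built by keyword-filtering traits, keeping genome-wide
significant associations (p <= 5e-8 by default), splitting the gene fields
on the catalog's separators, dropping non-protein-coding annotation classes
(MIR/LINC/LOC followed by a digit), and deduplicating across studies.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .genesets import GeneSet, normalize_symbol

__all__ = [
    "AssociationRecord",
    "CatalogFilter",
    "DEFAULT_DIALECT",
    "GENOME_WIDE_P",
    "parse_catalog",
    "filter_records",
    "extract_gene_symbols",
    "exclude_noncoding",
    "build_gene_list",
]

logger = logging.getLogger(__name__)

#: Conventional genome-wide significance threshold.
GENOME_WIDE_P = 5e-8

#: Column-name mapping matching the NHGRI-EBI download dialect.
DEFAULT_DIALECT: Mapping[str, str] = {
    "study_id": "STUDY ACCESSION",
    "trait": "DISEASE/TRAIT",
    "p_value": "P-VALUE",
    "mapped_gene_field": "MAPPED_GENE",
    "reported_gene_field": "REPORTED GENE(S)",
}

# Catalog gene-field separators: comma, semicolon, and the " - " used for
# intergenic signals reported with both flanking genes ("TERT - CLPTM1L").
_GENE_SPLIT_RE = re.compile(r"\s*[;,]\s*|\s+-\s+")

# Non-protein-coding classes are removed by prefix + digit; the digit
# anchor keeps protein-coding symbols such as MIRO1 or LINGO1.
_NONCODING_RE = re.compile(r"^(MIR|LINC|LOC)\d")

#: Sentinel the catalog uses for "no reported gene".
_NO_REPORTED = "NR"


@dataclass(frozen=True)
class AssociationRecord:
    """One association row: trait, p-value, and raw gene annotation fields."""

    study_id: str
    trait: str
    p_value: float
    mapped_gene_field: str = ""
    reported_gene_field: str = ""

    def __post_init__(self) -> None:
        if not self.trait.strip():
            raise ValueError("trait must be non-empty")
        if self.p_value < 0:
            raise ValueError("p_value must be non-negative")


@dataclass(frozen=True)
class CatalogFilter:
    """Trait-keyword and significance filter for association records.

    ``include_keywords`` are case-insensitive substrings, any of which must
    match the trait (an empty list matches everything); ``exclude_keywords``
    are substrings none of which may match.  The p threshold is inclusive.
    """

    p_threshold: float = GENOME_WIDE_P
    include_keywords: Sequence[str] = field(default_factory=tuple)
    exclude_keywords: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p_threshold <= 0:
            raise ValueError("p_threshold must be positive")
        object.__setattr__(
            self, "include_keywords", tuple(k.lower() for k in self.include_keywords)
        )
        object.__setattr__(
            self, "exclude_keywords", tuple(k.lower() for k in self.exclude_keywords)
        )

    def matches(self, record: AssociationRecord) -> bool:
        if record.p_value > self.p_threshold:
            return False
        trait = record.trait.lower()
        if self.include_keywords and not any(k in trait for k in self.include_keywords):
            return False
        return not any(k in trait for k in self.exclude_keywords)


def parse_catalog(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> list[AssociationRecord]:
    """Parse a tab-separated catalog export into association records.

    Rows with unparseable p-values or empty traits are logged and skipped;
    a missing file or missing mapped column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    records: list[AssociationRecord] = []
    n_skipped = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for key, column in dialect.items():
            if key in ("study_id",) and column not in header:
                continue  # study accession is optional bookkeeping
            if column not in header:
                raise ValueError(f"catalog {path} is missing required column {column!r}")
        for i, row in enumerate(reader, start=2):
            try:
                record = AssociationRecord(
                    study_id=(row.get(dialect.get("study_id", "")) or "").strip(),
                    trait=(row[dialect["trait"]] or "").strip(),
                    p_value=float(row[dialect["p_value"]]),
                    mapped_gene_field=(row.get(dialect["mapped_gene_field"]) or "").strip(),
                    reported_gene_field=(row.get(dialect["reported_gene_field"]) or "").strip(),
                )
            except (TypeError, ValueError) as exc:
                n_skipped += 1
                logger.warning("skipping malformed row %d of %s: %s", i, path.name, exc)
                continue
            records.append(record)
    logger.info("parsed %d records from %s (%d rows skipped)", len(records), path, n_skipped)
    return records


def filter_records(
    records: Iterable[AssociationRecord], f: CatalogFilter
) -> list[AssociationRecord]:
    """Keep records passing the significance threshold and keyword rules."""
    records = list(records)
    kept = [r for r in records if f.matches(r)]
    logger.info("filter kept %d of %d records", len(kept), len(records))
    return kept


def extract_gene_symbols(
    record: AssociationRecord, use_mapped: bool = True, use_reported: bool = True
) -> set[str]:
    """Split the chosen gene field(s) into normalized symbols.

    Splits on commas, semicolons and the intergenic " - " separator, drops
    empty tokens and the literal "NR" sentinel.
    """
    if not (use_mapped or use_reported):
        raise ValueError("at least one of use_mapped/use_reported must be set")
    fields = []
    if use_mapped:
        fields.append(record.mapped_gene_field)
    if use_reported:
        fields.append(record.reported_gene_field)
    symbols: set[str] = set()
    for raw in fields:
        for token in _GENE_SPLIT_RE.split(raw):
            sym = normalize_symbol(token)
            if sym and sym != _NO_REPORTED:
                symbols.add(sym)
    return symbols


def exclude_noncoding(symbols: Iterable[str]) -> set[str]:
    """Drop MIR/LINC/LOC-class symbols (prefix followed by a digit)."""
    symbols = set(symbols)
    kept = {s for s in symbols if not _NONCODING_RE.match(s)}
    removed = len(symbols) - len(kept)
    if removed:
        logger.info("excluded %d non-coding/uncertain symbols", removed)
    return kept


def build_gene_list(
    records: Iterable[AssociationRecord],
    f: CatalogFilter,
    name: str,
    use_mapped: bool = True,
    use_reported: bool = True,
) -> GeneSet:
    """Filter, extract, clean and deduplicate into a curated gene list."""
    symbols: set[str] = set()
    for record in filter_records(records, f):
        symbols |= extract_gene_symbols(
            record, use_mapped=use_mapped, use_reported=use_reported
        )
    members = exclude_noncoding(symbols)
    if not members:
        logger.warning("gene list %r is empty after filtering", name)
    logger.info("gene list %r has %d unique members", name, len(members))
    return GeneSet(name=name, members=frozenset(members))
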