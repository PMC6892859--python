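"""Cross-trait overlap analysis: disease lists vs reference gene sets.

Orchestrates the enrichment report: for one disease gene list and a panel
of reference sets (e.g. cancer-associated genes, tumor suppressors,
oncogenes, housekeeping genes as a control) on a fixed genome background,
compute each overlap's 2x2 table, fold enrichment, CI and Fisher p, and
serialize the results as TSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .enrichment import (
    DEFAULT_GENOME_SIZE,
    EnrichmentResult,
    enrichment_result,
    make_table,
)
from .genesets import GeneSet

__all__ = [
    "ComparisonSpec",
    "NamedEnrichment",
    "overlap_members",
    "union_reference",
    "overlap_percentage",
    "run_comparisons",
    "results_to_records",
    "write_report",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "disease",
    "reference",
    "n1",
    "z",
    "n2",
    "G",
    "a",
    "b",
    "c",
    "d",
    "cell_expression",
    "fold",
    "ci_low",
    "ci_high",
    "p_fisher",
    "haldane_applied",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One disease list compared against a panel of reference sets."""

    disease_list: GeneSet
    reference_sets: Sequence[GeneSet]
    genome_size: int = DEFAULT_GENOME_SIZE

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if len(self.disease_list) > self.genome_size:
            raise ValueError("disease list larger than the genome background")
        for ref in self.reference_sets:
            if len(ref) > self.genome_size:
                raise ValueError(
                    f"reference set {ref.name!r} larger than the genome background"
                )


@dataclass(frozen=True)
class NamedEnrichment:
    """An EnrichmentResult labelled with its disease/reference pair."""

    disease: str
    reference: str
    result: EnrichmentResult


def overlap_members(a: GeneSet, b: GeneSet, name: Optional[str] = None) -> GeneSet:
    """Members common to both sets (set intersection)."""
    return a.intersection(b, name=name)


def union_reference(sets: Iterable[GeneSet], name: str) -> GeneSet:
    """Deduplicated union of reference sets (e.g. TSG + OG)."""
    members: frozenset[str] = frozenset()
    for s in sets:
        members |= s.members
    return GeneSet(name=name, members=members)


def overlap_percentage(a: GeneSet, b: GeneSet) -> float:
    """Percentage of A's members also found in B: 100 * |A&B| / |A|."""
    if len(a) == 0:
        raise ValueError("overlap percentage undefined for an empty gene set")
    return 100.0 * len(a.members & b.members) / len(a)


def _cell_expression(n1: int, z: int, n2: int, G: int) -> str:
    """Audit string in the report's conventional cell notation."""
    return f"{n1}/({z}-{n1})({n2}-{n1})/({G}-{z}-{n2 - n1})"


def run_comparisons(spec: ComparisonSpec) -> list[NamedEnrichment]:
    """Compute one enrichment result per reference set.

    Counts (n1, z, n2) are always recomputed from the actual gene-set
    members rather than trusted from configuration; G stays fixed at the
    configured genome size regardless of list contents.
    """
    disease = spec.disease_list
    z = len(disease)
    out: list[NamedEnrichment] = []
    for ref in spec.reference_sets:
        n1 = len(disease.members & ref.members)
        n2 = len(ref)
        if z + n2 - n1 > spec.genome_size:
            logger.warning(
                "lists %r and %r jointly exceed the genome background "
                "(z + n2 - n1 = %d > G = %d)",
                disease.name,
                ref.name,
                z + n2 - n1,
                spec.genome_size,
            )
        table = make_table(n1=n1, z=z, n2=n2, G=spec.genome_size)
        out.append(
            NamedEnrichment(
                disease=disease.name, reference=ref.name, result=enrichment_result(table)
            )
        )
    return out


def results_to_records(results: Iterable[NamedEnrichment]) -> list[dict]:
    """Flatten named enrichment results into report-row dictionaries."""
    rows = []
    for item in results:
        r = item.result
        t = r.table
        rows.append(
            {
                "disease": item.disease,
                "reference": item.reference,
                "n1": t.n1,
                "z": t.z,
                "n2": t.n2,
                "G": t.G,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "cell_expression": _cell_expression(t.n1, t.z, t.n2, t.G),
                "fold": round(r.fold, 3),
                "ci_low": round(r.ci_low, 3),
                "ci_high": round(r.ci_high, 3),
                "p_fisher": float(f"{r.p_fisher:.3g}"),
                "haldane_applied": r.haldane_applied,
            }
        )
    return rows


def write_report(
    results: Sequence[NamedEnrichment],
    out_prefix: str | Path,
    provenance: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write the enrichment report as TSV plus a JSON mirror."""
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = results_to_records(results)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    payload = {"provenance": provenance or {}, "results": rows}
    json_path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return tsv_path, json_path
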