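"""Generic pathway over-representation analysis (ORA) against GMT gene sets.

Each pathway of size ``m`` is tested for over-representation in a query
list of size ``q`` on a fixed background of ``B`` genes via the 2x2 table
(k, q-k, m-k, B-q-m+k), where ``k`` is the query/pathway overlap.  Fold
enrichment and the Fisher exact p reuse the overlap-enrichment core, and
Benjamini-Hochberg FDR is applied across all tested pathways.  The
background defaults to the protein-coding genome count; published ORA
tools ship their own annotation-version-specific backgrounds, so results
are comparable but not bit-identical to any particular tool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .enrichment import (
    DEFAULT_GENOME_SIZE,
    bh_fdr,
    fisher_two_sided,
    fold_enrichment,
    make_table,
)
from .genesets import GeneSet, normalize_symbol

__all__ = ["Pathway", "PathwayResult", "read_gmt", "write_gmt", "run_ora", "write_ora_report"]

logger = logging.getLogger(__name__)

#: Pathways smaller than this are excluded before testing (and before FDR).
DEFAULT_MIN_PATHWAY_SIZE = 5


@dataclass(frozen=True)
class Pathway:
    """A named gene set from a pathway database (GMT line)."""

    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PathwayResult:
    """Per-pathway ORA outcome: overlap, fold, raw p and BH-FDR."""

    pathway: Pathway
    k: int
    m: int
    q: int
    background: int
    fold: float
    p_raw: float
    fdr: float

    def __post_init__(self) -> None:
        if self.k > min(self.m, self.q):
            raise ValueError("overlap cannot exceed either set size")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError("p_raw must be in (0, 1]")
        if self.fdr < self.p_raw - 1e-12:
            raise ValueError("fdr cannot be below the raw p-value")


def read_gmt(path: str | Path) -> list[Pathway]:
    """Read pathways from a GMT file (name, description, members per line).

    Lines with fewer than three tab-separated fields are logged and
    skipped; member symbols are normalized and deduplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pathways: list[Pathway] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("skipping short GMT line %d of %s", lineno, path.name)
                continue
            pid, description = fields[0].strip(), fields[1].strip()
            members = {s for s in (normalize_symbol(x) for x in fields[2:]) if s}
            if not members:
                logger.warning("skipping empty pathway on GMT line %d", lineno)
                continue
            pathways.append(Pathway(id=pid, name=description or pid, members=frozenset(members)))
    logger.info("read %d pathways from %s", len(pathways), path)
    return pathways


def write_gmt(pathways: Iterable[Pathway], path: str | Path) -> None:
    """Write pathways in GMT format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for p in pathways:
            fh.write("\t".join([p.id, p.name, *sorted(p.members)]) + "\n")


def run_ora(
    query: GeneSet,
    pathways: Sequence[Pathway],
    background: int = DEFAULT_GENOME_SIZE,
    min_pathway_size: int = DEFAULT_MIN_PATHWAY_SIZE,
) -> list[PathwayResult]:
    """Over-representation of the query in each pathway, sorted by FDR.

    Builds the 2x2 (k, q-k, m-k, B-q-m+k) per pathway, computes fold and
    the Fisher p, then adjusts across all tested pathways with
    Benjamini-Hochberg.
    """
    q = len(query)
    if background < q:
        raise ValueError("background must be at least the query size")
    tested = []
    for p in pathways:
        m = len(p)
        if m > background:
            raise ValueError(f"pathway {p.id!r} larger than the background")
        if m < min_pathway_size:
            logger.info("skipping pathway %s (size %d < %d)", p.id, m, min_pathway_size)
            continue
        if background < q + m - len(query.members & p.members):
            raise ValueError(
                f"background too small for query and pathway {p.id!r} combined"
            )
        tested.append(p)
    tables = [
        make_table(n1=len(query.members & p.members), z=q, n2=len(p), G=background)
        for p in tested
    ]
    raw_p = [fisher_two_sided(t) for t in tables]
    fdr = bh_fdr(raw_p)
    results = [
        PathwayResult(
            pathway=p,
            k=t.n1,
            m=t.n2,
            q=q,
            background=background,
            fold=fold_enrichment(t),
            p_raw=pr,
            fdr=f,
        )
        for p, t, pr, f in zip(tested, tables, raw_p, fdr)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_raw, r.pathway.id))
    return results


def write_ora_report(
    results: Sequence[PathwayResult],
    out_prefix: str | Path,
    provenance: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Serialize ORA results as TSV plus a JSON mirror.

    The report footer records the background size used, since ORA folds
    and p-values are only comparable at a stated background.
    """
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "pathway_id": r.pathway.id,
            "pathway_name": r.pathway.name,
            "pathway_size": r.m,
            "overlap": r.k,
            "query_size": r.q,
            "background": r.background,
            "fold": round(r.fold, 3),
            "p_raw": float(f"{r.p_raw:.3g}"),
            "fdr": float(f"{r.fdr:.3g}"),
        }
        for r in results
    ]
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    background = results[0].background if results else None
    payload = {
        "provenance": provenance or {},
        "background": background,
        "results": rows,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return tsv_path, json_path
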