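"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one of the pipeline's real inputs — gene lists
with a planted fold enrichment, catalog association exports exercising
every curation rule, pathway collections, and country tables with a
planted linear temperature effect — and returns a machine-readable truth
record alongside the data, so recovery can be asserted exactly.

Gene symbols are synthetic tokens (``G000001`` ...) plus deliberately
planted special-prefix tokens; no real gene nomenclature is used, so tests
cannot accidentally depend on it.  A single integer seed drives one named
pseudo-random stream per generator: the same seed always yields
byte-identical output files.

Default design parameters mirror the study conditions the pipeline is
meant for: a protein-coding genome of 20,479 symbols, disease lists of a
few hundred genes, reference sets of ~1,000-4,000, and 87 populations for
the climate table.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .climate import CountryRecord
from .enrichment import DEFAULT_GENOME_SIZE
from .genesets import GeneSet
from .ora import Pathway

__all__ = [
    "OverlapDesign",
    "ClimateDesign",
    "gen_universe_lists",
    "gen_catalog_file",
    "gen_climate_data",
    "gen_pathways",
    "write_catalog_tsv",
    "write_country_csv",
    "write_truth",
]

# Fixed per-generator stream tags so generators never share a stream.
_STREAM = {"overlap": 101, "catalog": 202, "climate": 303, "pathways": 404}


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[kind], int(seed)])


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# planted-overlap gene lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapDesign:
    """Design for a disease/reference list pair with planted fold enrichment.

    ``target_fold`` is the fold enrichment the pair is built to have in
    expectation: each disease member falls inside the reference with
    probability ``target_fold * n2 / G``, so E[overlap] = F * z * n2 / G.
    """

    G: int = DEFAULT_GENOME_SIZE
    z: int = 590
    n2: int = 1375
    target_fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.G, self.z, self.n2) <= 0:
            raise ValueError("G, z, n2 must be positive")
        if self.target_fold < 0:
            raise ValueError("target_fold must be non-negative")
        expected = self.target_fold * self.z * self.n2 / self.G
        if expected > min(self.z, self.n2):
            raise ValueError("infeasible design: expected overlap exceeds min(z, n2)")
        if self.target_fold * self.n2 / self.G > 1.0:
            raise ValueError("infeasible design: per-member overlap rate exceeds 1")


def gen_universe_lists(d: OverlapDesign) -> tuple[GeneSet, GeneSet, GeneSet, dict]:
    """Generate (universe, disease, reference) lists plus a truth record.

    The reference set is a uniform draw of ``n2`` symbols from the
    universe; the disease list draws its overlap count from
    Binomial(z, F * n2 / G) and fills the rest from outside the reference,
    which realizes the designed expected overlap.
    """
    rng = _rng("overlap", d.seed)
    universe_symbols = np.array(_symbols(d.G))
    ref_idx = rng.choice(d.G, size=d.n2, replace=False)
    ref_mask = np.zeros(d.G, dtype=bool)
    ref_mask[ref_idx] = True

    p_in = d.target_fold * d.n2 / d.G
    lo = max(0, d.z - (d.G - d.n2))
    k = int(np.clip(rng.binomial(d.z, p_in), lo, min(d.z, d.n2)))
    inside = rng.choice(ref_idx, size=k, replace=False) if k else np.array([], dtype=int)
    outside_pool = np.flatnonzero(~ref_mask)
    outside = rng.choice(outside_pool, size=d.z - k, replace=False)
    disease_idx = np.concatenate([inside, outside])

    universe = GeneSet("universe", frozenset(universe_symbols), universe_size=d.G)
    reference = GeneSet("reference", frozenset(universe_symbols[ref_idx]), universe_size=d.G)
    disease = GeneSet("disease", frozenset(universe_symbols[disease_idx]), universe_size=d.G)
    truth = {
        "G": d.G,
        "z": d.z,
        "n2": d.n2,
        "target_fold": d.target_fold,
        "expected_n1": d.target_fold * d.z * d.n2 / d.G,
        "realized_n1": k,
        "seed": d.seed,
    }
    assert len(disease.members & reference.members) == k
    return universe, disease, reference, truth


# ---------------------------------------------------------------------------
# catalog association exports
# ---------------------------------------------------------------------------

CATALOG_HEADER = [
    "STUDY ACCESSION",
    "DISEASE/TRAIT",
    "P-VALUE",
    "MAPPED_GENE",
    "REPORTED GENE(S)",
]


def gen_catalog_file(
    path: str | Path,
    n: int = 50,
    seed: int = 0,
    n_fail_p: int = 10,
    n_excluded_trait: int = 0,
    n_noncoding: int = 0,
    n_duplicate: int = 0,
    n_intergenic: int = 0,
    include_trait: str = "cancer",
    excluded_trait: str = "cervical cancer",
    p_threshold: float = 5e-8,
) -> tuple[Path, dict]:
    """Write a synthetic catalog TSV with known pass/fail bookkeeping.

    Of the ``n`` rows, ``n_fail_p`` carry p-values above the threshold,
    ``n_excluded_trait`` carry the excluded trait keyword, ``n_noncoding``
    map only to MIR/LINC/LOC-class symbols, ``n_duplicate`` repeat a gene
    already planted in a passing row, and ``n_intergenic`` report an
    intergenic two-gene mapped field.  All remaining rows map to one fresh
    unique gene each.  The truth record lists the exact gene set the
    curation pipeline should recover.
    """
    specials = n_fail_p + n_excluded_trait + n_noncoding + n_duplicate + n_intergenic
    if specials > n:
        raise ValueError("special row counts exceed total row count")
    n_plain = n - specials
    if n_duplicate > 0 and n_plain + n_intergenic == 0:
        raise ValueError("duplicate rows need at least one passing gene to repeat")
    rng = _rng("catalog", seed)

    fresh = iter(_symbols(10 * n + 20))
    noncoding_pool = ["MIR", "LINC", "LOC"]
    rows: list[dict] = []
    expected: list[str] = []

    def passing_p() -> str:
        return f"{float(rng.uniform(0.1, 1.0)) * p_threshold:.2e}"

    for i in range(n_plain):
        gene = next(fresh)
        expected.append(gene)
        rows.append({"trait": include_trait, "p": passing_p(), "mapped": gene, "reported": "NR"})
    for i in range(n_intergenic):
        g1, g2 = next(fresh), next(fresh)
        expected.extend([g1, g2])
        rows.append(
            {"trait": include_trait, "p": passing_p(), "mapped": f"{g1} - {g2}", "reported": ""}
        )
    for i in range(n_duplicate):
        gene = expected[int(rng.integers(len(expected)))]
        rows.append({"trait": include_trait, "p": passing_p(), "mapped": gene, "reported": gene})
    for i in range(n_noncoding):
        prefix = noncoding_pool[i % len(noncoding_pool)]
        rows.append(
            {
                "trait": include_trait,
                "p": passing_p(),
                "mapped": f"{prefix}{int(rng.integers(100, 99999))}",
                "reported": "NR",
            }
        )
    for i in range(n_excluded_trait):
        rows.append(
            {"trait": excluded_trait, "p": passing_p(), "mapped": next(fresh), "reported": "NR"}
        )
    for i in range(n_fail_p):
        p = float(rng.uniform(2.0, 100.0)) * p_threshold
        rows.append({"trait": include_trait, "p": f"{p:.2e}", "mapped": next(fresh), "reported": "NR"})

    order = rng.permutation(len(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_HEADER)
        for j, idx in enumerate(order):
            r = rows[idx]
            writer.writerow([f"GCST{j:06d}", r["trait"], r["p"], r["mapped"], r["reported"]])
    truth = {
        "n_records": n,
        "n_fail_p": n_fail_p,
        "n_excluded_trait": n_excluded_trait,
        "n_noncoding": n_noncoding,
        "n_duplicate": n_duplicate,
        "n_intergenic": n_intergenic,
        "expected_genes": sorted(set(expected)),
        "seed": seed,
    }
    return path, truth


# ---------------------------------------------------------------------------
# country climate tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateDesign:
    """Design for a country table with a planted linear temperature effect.

    Defaults emulate an 87-population table of age-standardized rates per
    100,000 regressed on national extreme low temperatures spanning -70 to
    +10 degC.  ``sigma`` defaults to the noise level at which a slope of
    -0.3 per degC yields a population R^2 of about 0.135 for temperatures
    uniform on that range (sigma^2 = beta1^2 var(x) (1 - R^2)/R^2).
    """

    n: int = 87
    beta0: float = 50.0
    beta1: float = -0.3
    sigma: float = 17.54
    temp_range: tuple[float, float] = (-70.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.temp_range[0] >= self.temp_range[1]:
            raise ValueError("temp_range must be an increasing interval")


def gen_climate_data(d: ClimateDesign) -> tuple[list[CountryRecord], dict]:
    """Generate country records with outcome = beta0 + beta1*temp + noise.

    Temperatures are uniform on the design range; Gaussian noise is added
    and the outcome floored at zero (rates cannot be negative).
    """
    rng = _rng("climate", d.seed)
    temps = rng.uniform(d.temp_range[0], d.temp_range[1], size=d.n)
    noise = rng.normal(0.0, d.sigma, size=d.n)
    outcomes = np.maximum(d.beta0 + d.beta1 * temps + noise, 0.0)
    records = [
        CountryRecord(
            population=f"POP{i:03d}",
            extreme_low_temp=float(t),
            outcome=float(y),
        )
        for i, (t, y) in enumerate(zip(temps, outcomes), start=1)
    ]
    truth = {
        "n": d.n,
        "beta0": d.beta0,
        "beta1": d.beta1,
        "sigma": d.sigma,
        "temp_range": list(d.temp_range),
        "n_floored": int(np.sum(d.beta0 + d.beta1 * temps + noise < 0)),
        "seed": d.seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# pathway collections
# ---------------------------------------------------------------------------


def gen_pathways(
    n_pathways: int = 10,
    seed: int = 7,
    universe_size: int = DEFAULT_GENOME_SIZE,
    size_range: tuple[int, int] = (20, 300),
    enriched_in: Optional[GeneSet] = None,
    enriched_overlap: int = 0,
) -> tuple[list[Pathway], dict]:
    """Generate synthetic pathways, optionally planting one enriched in a query.

    If ``enriched_in`` is given, the first pathway is built to share exactly
    ``enriched_overlap`` members with that gene set; the rest are uniform
    draws from the universe.
    """
    if not (0 < size_range[0] <= size_range[1] <= universe_size):
        raise ValueError("invalid size_range")
    rng = _rng("pathways", seed)
    universe = np.array(_symbols(universe_size))
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_pathways)
    pathways: list[Pathway] = []
    for i, m in enumerate(sizes):
        if i == 0 and enriched_in is not None:
            if enriched_overlap > min(m, len(enriched_in)):
                raise ValueError("enriched_overlap exceeds pathway or query size")
            query_members = np.array(sorted(enriched_in.members))
            inside = rng.choice(query_members, size=enriched_overlap, replace=False)
            pool = np.array(sorted(set(universe) - set(query_members)))
            outside = rng.choice(pool, size=int(m) - enriched_overlap, replace=False)
            members = frozenset(inside) | frozenset(outside)
        else:
            members = frozenset(universe[rng.choice(universe_size, size=int(m), replace=False)])
        pathways.append(Pathway(id=f"P{i:05d}", name=f"synthetic pathway {i}", members=members))
    truth = {
        "n_pathways": n_pathways,
        "sizes": [int(s) for s in sizes],
        "enriched_overlap": enriched_overlap if enriched_in is not None else None,
        "seed": seed,
    }
    return pathways, truth


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def write_catalog_tsv(rows: Sequence[Sequence[str]], path: str | Path) -> Path:
    """Write raw catalog rows (already ordered) under the standard header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_HEADER)
        writer.writerows(rows)
    return path


def write_country_csv(records: Sequence[CountryRecord], path: str | Path) -> Path:
    """Write country records in the CSV dialect ``read_country_table`` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["population", "extreme_low_temp_c", "outcome", "stratum", "flags"])
        for r in records:
            writer.writerow(
                [
                    r.population,
                    f"{r.extreme_low_temp:.6f}",
                    f"{r.outcome:.6f}",
                    r.stratum or "",
                    ";".join(sorted(r.flags)),
                ]
            )
    return path


def write_truth(truth: dict, path: str | Path) -> Path:
    """Write a generator truth record as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
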