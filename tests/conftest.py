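"""Shared fixtures: the published enrichment table and small file fixtures."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@dataclass(frozen=True)
class Table1Row:
    """One published enrichment row: counts plus printed statistics.

    ``p_ulp`` is one unit in the last printed digit of the p-value, so
    agreement "at printed precision" means |p - p_printed| <= p_ulp / 2.
    """

    disease: str
    reference: str
    n1: int
    z: int
    n2: int
    fold: float
    ci_low: float
    ci_high: float
    p_printed: float
    p_ulp: float


# Published cross-trait enrichment table: four mental-disorder GWAS gene
# lists against cancer-associated genes (CAG), tumor suppressors (TSG),
# oncogenes (OG), their union, and housekeeping genes (HG) as a control,
# on a 20,479-gene background.
TABLE1 = [
    Table1Row("suicide", "CAG", 65, 590, 1375, 1.641, 1.297, 2.075, 7.83e-5, 1e-7),
    Table1Row("suicide", "TSG", 66, 590, 1037, 2.209, 1.747, 2.794, 1.46e-9, 1e-11),
    Table1Row("suicide", "OG", 66, 590, 724, 3.164, 2.493, 4.016, 9.84e-17, 1e-19),
    Table1Row("suicide", "TSG+OG", 122, 590, 1660, 2.551, 2.164, 3.008, 2.82e-22, 1e-24),
    Table1Row("suicide", "HG", 53, 590, 3800, 0.484, 0.374, 0.627, 7.75e-11, 1e-13),
    Table1Row("depression", "CAG", 20, 225, 1375, 1.324, 0.869, 2.018, 0.181, 1e-3),
    Table1Row("depression", "TSG", 17, 225, 1037, 1.492, 0.941, 2.366, 0.092, 1e-3),
    Table1Row("depression", "OG", 4, 225, 724, 0.503, 0.190, 1.332, 0.200, 1e-3),
    Table1Row("depression", "TSG+OG", 20, 225, 1660, 1.097, 0.720, 1.670, 0.623, 1e-3),
    Table1Row("depression", "HG", 45, 225, 3800, 1.078, 0.829, 1.402, 0.547, 1e-3),
    Table1Row("anxiety", "CAG", 3, 31, 1375, 1.441, 0.491, 4.230, 0.462, 1e-3),
    Table1Row("anxiety", "TSG", 3, 31, 1037, 1.911, 0.651, 5.611, 0.206, 1e-3),
    Table1Row("anxiety", "OG", 0, 31, 724, 0.442, 0.028, 6.916, 0.627, 1e-3),
    Table1Row("anxiety", "TSG+OG", 3, 31, 1660, 1.194, 0.407, 3.503, 0.737, 1e-3),
    Table1Row("anxiety", "HG", 7, 31, 3800, 1.217, 0.634, 2.337, 0.496, 1e-3),
    Table1Row("schizophrenia", "CAG", 4, 36, 1375, 1.655, 0.656, 4.175, 0.302, 1e-3),
    Table1Row("schizophrenia", "TSG", 2, 36, 1037, 1.097, 0.285, 4.224, 0.704, 1e-3),
    Table1Row("schizophrenia", "OG", 0, 36, 724, 0.382, 0.024, 5.999, 0.639, 1e-3),
    Table1Row("schizophrenia", "TSG+OG", 2, 36, 1660, 0.685, 0.178, 2.638, 0.766, 1e-3),
    Table1Row("schizophrenia", "HG", 11, 36, 3800, 1.647, 1.005, 2.697, 0.083, 1e-3),
]

GENOME_SIZE = 20479


@pytest.fixture(scope="session")
def table1_rows() -> list[Table1Row]:
    return TABLE1


@pytest.fixture()
def catalog_tsv(tmp_path):
    """A tiny well-formed catalog export with the standard header."""
    path = tmp_path / "catalog.tsv"
    lines = [
        "STUDY ACCESSION\tDISEASE/TRAIT\tP-VALUE\tMAPPED_GENE\tREPORTED GENE(S)",
        "GCST000001\tBreast cancer\t2e-09\tFGFR2\tFGFR2",
        "GCST000002\tLung cancer\t5e-08\tTERT - CLPTM1L\tNR",
        "GCST000003\tProstate cancer\t1e-10\tCDKN2A, CDKN2B\tCDKN2A; CDKN2B",
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
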