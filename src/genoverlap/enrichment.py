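"""Statistical core for 2x2 gene-set overlap enrichment.

The central quantity is the fold enrichment of an overlap: a disease gene
list of size ``z`` and a reference gene set of size ``n2`` drawn from a
genome background of ``G`` protein-coding genes share ``n1`` members.  The
fold enrichment is the observed overlap proportion within the disease list
divided by the reference set's genome-wide proportion,

    fold = (n1 / z) / (n2 / G)  =  n1 * G / (z * n2),

i.e. observed over expected overlap.  A log-normal (Katz-style) confidence
interval accompanies it, and significance comes from the two-sided Fisher
exact test on the 2x2 table

    a = n1          b = z - n1
    c = n2 - n1     d = G - z - (n2 - n1)

whose four cells partition the genome.  When the overlap is empty (or any
cell is zero) the ratio is undefined; a Haldane-Anscombe-style continuity
correction of 0.5 is applied to the overlap cell ``a`` and its row
complement ``b`` for the fold and CI.  The reference proportion ``n2 / G``
is left uncorrected: that convention, rather than correcting all four
cells, is the one that reproduces published zero-overlap fold values.  The
Fisher p-value is always computed on the uncorrected integer table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_GENOME_SIZE",
    "ContingencyTable",
    "EnrichmentResult",
    "make_table",
    "apply_haldane",
    "fold_enrichment",
    "katz_ci",
    "fisher_two_sided",
    "bh_fdr",
    "enrichment_result",
]

#: Number of human protein-coding genes used as the default universe.
DEFAULT_GENOME_SIZE = 20479

# z-quantile for a 95% two-sided interval.
_Z975 = 1.959964

# Relative tolerance of the two-sided Fisher point-probability rule,
# matching mainstream implementations.
_FISHER_RELTOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """The overlap 2x2: counts (n1, z, n2, G) with derived cells a,b,c,d."""

    n1: int
    z: int
    n2: int
    G: int = DEFAULT_GENOME_SIZE

    @property
    def a(self) -> int:
        return self.n1

    @property
    def b(self) -> int:
        return self.z - self.n1

    @property
    def c(self) -> int:
        return self.n2 - self.n1

    @property
    def d(self) -> int:
        return self.G - self.z - (self.n2 - self.n1)

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def __post_init__(self) -> None:
        for field_name in ("n1", "z", "n2", "G"):
            v = getattr(self, field_name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{field_name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{field_name} must be non-negative, got {v}")
        if self.G <= 0:
            raise ValueError("G must be positive")
        for cell_name in ("a", "b", "c", "d"):
            if getattr(self, cell_name) < 0:
                raise ValueError(
                    f"negative derived cell {cell_name} = {getattr(self, cell_name)} "
                    f"for (n1={self.n1}, z={self.z}, n2={self.n2}, G={self.G})"
                )
        assert self.a + self.b + self.c + self.d == self.G


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment comparison: fold, 95% CI, Fisher p, and its table."""

    table: ContingencyTable
    fold: float
    ci_low: float
    ci_high: float
    p_fisher: float
    haldane_applied: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.fold <= self.ci_high):
            raise ValueError("CI must bracket the fold estimate")
        if not (0.0 < self.p_fisher <= 1.0):
            raise ValueError("p_fisher must be in (0, 1]")


def make_table(n1: int, z: int, n2: int, G: int = DEFAULT_GENOME_SIZE) -> ContingencyTable:
    """Build and validate the overlap 2x2 from the four counts."""
    return ContingencyTable(n1=n1, z=z, n2=n2, G=G)


def apply_haldane(t: ContingencyTable) -> tuple[tuple[float, float, float, float], bool]:
    """Continuity-correct a table containing a zero cell.

    Returns ``((a', b', c', d'), applied)``: if any cell of ``t`` is zero,
    0.5 is added to all four cells; otherwise the cells pass through
    unchanged.  Only the ratio/CI computations consume the corrected cells;
    the exact test never does.
    """
    cells = t.cells
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells), True
    return tuple(float(x) for x in cells), False


def fold_enrichment(t: ContingencyTable) -> float:
    """Observed/expected overlap proportion ratio.

    Equals ``n1 * G / (z * n2)`` exactly when no cell is zero.  With a zero
    cell, the corrected overlap proportion ``a' / (a' + b')`` is divided by
    the *uncorrected* reference proportion ``n2 / G``.
    """
    (a, b, _c, _d), _ = apply_haldane(t)
    if t.n2 == 0 or t.z == 0:
        raise ValueError("fold enrichment undefined for empty disease list or reference set")
    return (a / (a + b)) / (t.n2 / t.G)


def katz_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float]:
    """Log-normal (Katz-style) confidence interval for the fold enrichment.

    SE on the log scale is ``sqrt(1/a' - 1/z + 1/n2 - 1/G)`` with the
    continuity-corrected overlap cell ``a'`` and the raw margins, matching
    the ratio's observed/expected construction.  The interval is
    ``fold * exp(+-z_{alpha/2} * SE)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    (a, _b, _c, _d), _ = apply_haldane(t)
    fold = fold_enrichment(t)
    se = math.sqrt(1.0 / a - 1.0 / t.z + 1.0 / t.n2 - 1.0 / t.G)
    from scipy.stats import norm

    zq = _Z975 if alpha == 0.05 else float(norm.ppf(1.0 - alpha / 2.0))
    return fold * math.exp(-zq * se), fold * math.exp(zq * se)


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(A = a) for the hypergeometric cell distribution with fixed margins."""
    n = row1 + row2
    lg = math.lgamma
    return (
        lg(row1 + 1) - lg(a + 1) - lg(row1 - a + 1)
        + lg(row2 + 1) - lg(col1 - a + 1) - lg(row2 - (col1 - a) + 1)
        - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1))
    )


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed one (up to
    a 1 + 1e-7 relative tolerance).  Computed in log space via
    log-factorials so it stays stable at genome-scale cell counts.
    """
    a, b, c, d = t.cells
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    log_obs = _log_hypergeom_pmf(a, row1, row2, col1)
    cutoff = log_obs + math.log(_FISHER_RELTOL)
    logs = [
        lp
        for k in range(lo, hi + 1)
        if (lp := _log_hypergeom_pmf(k, row1, row2, col1)) <= cutoff
    ]
    m = max(logs)
    p = math.exp(m) * sum(math.exp(lp - m) for lp in logs)
    return min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrichment_result(
    t: ContingencyTable, alpha: float = 0.05, p_value: Optional[float] = None
) -> EnrichmentResult:
    """Compose fold, CI and Fisher p for one table into an EnrichmentResult."""
    _, applied = apply_haldane(t)
    low, high = katz_ci(t, alpha=alpha)
    return EnrichmentResult(
        table=t,
        fold=fold_enrichment(t),
        ci_low=low,
        ci_high=high,
        p_fisher=fisher_two_sided(t) if p_value is None else p_value,
        haldane_applied=applied,
    )
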