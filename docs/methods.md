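# Methods

## Overlap enrichment model

All enrichment statistics treat gene lists as simple random draws from a
fixed universe of G protein-coding genes (default 20,479). For a disease
list of size z and a reference set of size n2 with overlap n1, the 2×2
table is a = n1, b = z − n1, c = n2 − n1, d = G − z − (n2 − n1); the four
cells partition the genome, which the constructor enforces (any negative
derived cell is fatal and names the cell).

**Fold enrichment** is the ratio of the observed overlap proportion in
the disease list to the reference set's genome-wide share:
fold = (n1/z)/(n2/G) = n1·G/(z·n2). This is an observed/expected count
ratio, not the textbook risk ratio a/(a+b) ÷ c/(c+d); the two differ
whenever the overlap is an appreciable fraction of the reference set, and
the observed/expected form is the convention this package standardizes on
for both the list-vs-list and the pathway stage.

**Zero cells.** When any cell is zero the ratio or its log-variance is
undefined. The package adds 0.5 to the overlap cell and its row
complement (a′ = a + 0.5, a′ + b′ = z + 1) and leaves the reference
proportion n2/G uncorrected. Correcting the denominator proportion as
well is a defensible alternative; the asymmetric convention was chosen
because it reproduces published zero-overlap fold values exactly at
3-decimal rounding, and the difference (third decimal place) is far below
the statistical uncertainty of a zero-overlap estimate. The correction is
flagged in every result (`haldane_applied`) and never touches the exact
test.

**Confidence interval.** A Katz-style log-normal interval
fold·exp(±z_{α/2}·SE) with SE = sqrt(1/a′ − 1/z + 1/n2 − 1/G), i.e. the
delta-method variance of log[(a/z)/(n2/G)] with n2/G treated as the
fixed-margin expected proportion. α defaults to 0.05 with
z_{0.025} = 1.959964.

**Fisher exact test.** Two-sided by the point-probability rule: the sum
of hypergeometric probabilities of all tables with the observed margins
whose point probability is at most the observed one times (1 + 1e−7);
the tolerance factor guards against ties lost to floating-point rounding
and matches mainstream implementations. Probabilities are computed in log
space via `lgamma`, so the test is stable at genome-scale counts. The
test suite checks it against two independent routes: exhaustive
enumeration in exact rational arithmetic, and `scipy.stats.fisher_exact`.

**FDR.** Benjamini–Hochberg step-up, delegated to
`statsmodels.stats.multitest.multipletests`, with hand-executed step-up
values frozen in the tests as the oracle. Inputs outside [0, 1] are
fatal.

## Catalog curation

Association exports are filtered with an inclusive genome-wide threshold
(p ≤ 5 × 10⁻⁸ by default — inclusive so that boundary associations are
kept), case-insensitive substring trait keywords (include list empty =
match all; any exclude match drops the record). Gene fields are split on
commas, semicolons and the " - " intergenic separator, so an intergenic
signal contributes both flanking genes; the literal "NR" sentinel and
empty tokens are dropped; symbols are trimmed and uppercased.
Non-protein-coding classes are removed by the prefix+digit patterns
MIR\d, LINC\d, LOC\d — the digit anchor prevents dropping protein-coding
symbols such as MIRO1 or LINGO1, at the risk of diverging from any manual
curation that treated edge symbols differently. Lists are deduplicated at
the gene level only; studies are never deduplicated. Counts at every
filter step are logged.

## Pathway over-representation

Each pathway of size m is tested against the query (size q) on background
B via the 2×2 (k, q−k, m−k, B−q−m+k), reusing the fold and Fisher
machinery above, then BH-adjusted across the tested pathways. Pathways
smaller than `min_pathway_size` (default 5 — below that a single shared
gene dominates the statistic) are skipped before FDR. B defaults to the
20,479-gene universe and is configurable; published ORA tools embed
annotation-version-specific backgrounds (≈20,600 by back-calculation for
some), so their printed folds and FDRs are approximated, not reproduced,
and every report records the background used.

## Climate regression

Univariate OLS (via statsmodels) of an age-standardized rate per 100,000
on the signed national extreme low temperature in °C. The predictor is
deliberately left signed — colder = more negative — and reports carry an
explicit plain-language direction line instead of re-signing x, avoiding
silent sign conventions: a *negative* slope means higher rates in colder
countries. Adjusted R² uses the single-predictor formula with
denominator n − 2; the slope p-value is the two-sided t-test with n − 2
df. Records excluded by flag (e.g. an outlying population) or restricted
to a stratum (sex, disorder) are handled by the scenario mechanism, which
re-fits and reports side by side; fits need ≥ 3 points and fail on
zero-variance temperature. No leverage or robust diagnostics are
computed — the with/without-flag scenarios are the supported sensitivity
analysis.

## Synthetic data designs

* **Overlap lists** (`OverlapDesign`, defaults G = 20479, z = 590,
  n2 = 1375): the reference set is a uniform draw; the disease list draws
  its overlap count from Binomial(z, F·n2/G) and fills the remainder from
  outside the reference, so E[n1] = F·z·n2/G exactly. Defaults mirror the
  cardinalities of the motivating analysis. The generator treats genes as
  independent draws — it does not emulate linkage-based locus clustering
  or per-study correlation of real GWAS hits, and neither does the Fisher
  model being tested, so passing tests validate the statistics under
  their own independence assumption, not that assumption itself.
* **Catalog files**: planted numbers of sub-threshold rows,
  excluded-trait rows, MIR/LINC/LOC rows, duplicate genes and intergenic
  fields, with the exact expected final gene list in the truth record.
* **Country tables** (`ClimateDesign`, defaults n = 87 populations,
  β₀ = 50 per 100,000, β₁ = −0.3 per °C, temperatures uniform on
  [−70, 10] °C): outcome = β₀ + β₁·temp + N(0, σ²), floored at zero. The
  default σ = 17.54 comes from the closed form
  σ² = β₁²·var(x)·(1 − R²)/R² at a target population R² of 0.135, the
  scale of reported country-level cold–incidence associations; β₀ is set
  high enough that the zero floor is almost never hit, keeping the
  planted model linear. Real country data have spatially correlated
  residuals and measurement error, which the generator does not emulate.
* **Pathways**: uniform draws with configurable sizes, optionally one
  pathway planted to share an exact overlap with a query.

Every generator is driven by one integer seed through a named,
generator-specific stream; the same seed yields byte-identical files
(hashed in tests). Symbols are synthetic tokens (G000001…), never real
gene names.

## Numerical and reporting choices

Reports round folds and CI bounds to 3 decimals and print p-values to 3
significant figures; underlying objects keep full precision. Fisher
p-values are capped at 1. Empty curated lists are a warning, not an
error; an empty reference set is an error at fold computation (the ratio
is undefined). Monte Carlo suite sizes (200 seeds for fold recovery, 500
for slope recovery, 2000 for type-I calibration) keep the whole test
suite under a minute on one CPU while leaving binomial noise on the
checked rates well inside the asserted tolerances.

## Known limitations

* The gene-level independence assumption above: enrichment p-values are
  anti-conservative when disease lists contain many genes from single
  loci.
* The asymmetric zero-cell correction is a reverse-engineered convention;
  other software applies the 0.5 correction to all four cells and will
  differ in the third decimal on zero-overlap rows.
* ORA results depend on the background and annotation version; only the
  generic contract is implemented.
* The ecological regression is population-level: it supports no
  individual-level inference, and no spatial autocorrelation correction
  is applied.
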