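# genoverlap

Cross-trait gene-list overlap enrichment, generic pathway
over-representation, and ecological regression of disease rates on extreme
low temperature — the statistical toolkit for asking whether a
GWAS-derived disease gene list (for example, genes associated with suicide
attempt) shares more genes with a reference set (cancer-associated genes,
tumor suppressors, oncogenes, or housekeeping genes as a control) than the
genome background predicts, and whether a condition's country-level
incidence tracks how cold a country gets.

It is written for biostatisticians and genetic epidemiologists who want
these comparisons as reproducible, scriptable pipeline stages instead of
spreadsheet operations.

## The statistics

For a disease list of size *z* and a reference set of size *n₂* drawn from
a genome of *G* protein-coding genes (default *G* = 20,479) sharing *n₁*
genes, the package builds the 2×2 table

|            | in disease list | not in list        |
|------------|-----------------|--------------------|
| overlap    | a = n₁          | c = n₂ − n₁        |
| rest       | b = z − n₁      | d = G − z − (n₂−n₁)|

and reports

* **fold enrichment** — observed over expected overlap,
  `fold = (n₁/z) / (n₂/G)`; when a cell is zero, a Haldane–Anscombe-style
  0.5 correction is applied to the overlap cell and its row complement
  while the reference proportion n₂/G stays uncorrected;
* a **95% log-normal CI**, `fold · exp(±1.96·SE)` with
  `SE = √(1/a′ − 1/z + 1/n₂ − 1/G)`;
* the **two-sided Fisher exact p** (point-probability rule, computed in
  log space on the uncorrected integer table);
* **Benjamini–Hochberg FDR** across pathways in the over-representation
  stage.

The climate stage fits univariate OLS `rate = β₀ + β₁·temperature`, with
the two-sided t-test on β₁ (n − 2 df) and the single-predictor adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2).

## Worked example

```python
from genoverlap import make_table, enrichment_result

r = enrichment_result(make_table(n1=65, z=590, n2=1375, G=20479))
print(f"fold = {r.fold:.3f}  95% CI ({r.ci_low:.3f}, {r.ci_high:.3f})  p = {r.p_fisher:.3g}")
```

prints

```
fold = 1.641  95% CI (1.297, 2.075)  p = 7.83e-05
```

— a disease list of 590 genes shares 65 genes with a 1,375-gene reference
set, 1.64× more overlap than the 590·1375/20479 ≈ 39.6 genes expected by
chance, and a chance overlap this extreme has probability 7.8 × 10⁻⁵.

The same stages run from the shell. Generating a synthetic 87-country
table with the default planted temperature effect and regressing on it:

```sh
$ genoverlap synth --config cfg.yaml --out data --seed 11   # synth: {kind: climate}
$ genoverlap climate --config climate.yaml --out reg
all: n=87 slope=-0.3005/degC adjR2=0.109 p=0.00107
```

The negative slope means higher rates in colder countries; with the
default design (β₁ = −0.3, σ calibrated for a population R² ≈ 0.135) this
seed realizes an adjusted R² of 0.109. Subcommands: `build-lists`
(catalog curation), `enrich` (overlap report), `ora` (pathway
over-representation), `climate`, `synth`; see `genoverlap --help`.

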