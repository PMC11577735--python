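# constru

Conditional prognostic biomarker discovery for tumor expression cohorts.

Immune activity scores — here the cytolytic activity score **CYTscore**,
the mean log2 expression of *GZMA* and *PRF1* — predict survival in some
tumors and not others. `constru` implements a gene-stratified scanning
algorithm (CONSTRU: Computing Prognostic Marker Dependencies by Successive
Testing of Gene-Stratified Subgroups) that asks, for **every gene** in an
expression matrix: does the prognostic power of the score depend on that
gene's expression level?  It was developed for high-grade serous ovarian
cancer (HGSC) cohorts but applies to any gene × sample log2 expression
matrix with right-censored overall survival.

## The method

For each gene, tumors are split into expression tertiles (T1 = lowest
third).  Within each tertile a multivariable Cox proportional-hazards
model is fitted:

```
h(t | x) = h0(t) · exp(β·CYTscore + β_age·age + β_stage·stage + β_deb·debulking)
```

and the score term's hazard ratio (HR) and Wald p-value are recorded.
Genes are then ranked by the **parity score**

```
parity = (−log10 P / HR)[T1] − (−log10 P / HR)[T3]
```

which contrasts the score's significance and effect size between the
gene's lower and upper tertiles.  Genes correlated with the score itself
(|Pearson r| > 0.15) are excluded, percentile ranks are assigned over the
survivors, and **UpperT** / **LowerT** candidates are genes ranked within
an extreme percentile cutoff (default 4%) in *every* training cohort.
The stratification signature **STRATsig** is the mean log2 expression of
the UpperT genes minus that of the LowerT genes; its population tertiles
define patient subgroups in which the score's prognostic power differs
sharply.

The package covers the full workflow: cohort I/O and validation,
follow-up capping at 8 years, multi-probe collapsing, a fast Efron/Newton
Cox fitter, the genome-wide scan, parity ranking and candidate selection,
signature scoring (including the shipped 13-gene UpperT, 27-gene LowerT,
2-gene CYTscore and 8-gene APM lists), tertile-conditional and
subgroup survival evaluation, an FDR-controlled per-gene screen, and a
synthetic-cohort generator that makes every stage testable without
external data.

## Worked example

```python
import constru as cs

spec = cs.SimulationSpec(
    n_samples=300, n_genes=100, seed=7,
    planted=[cs.PlantedGene(gene_index=5, active_tertile="T3", beta_score=-1.0)],
)
cohort = cs.cap_cohort(cs.simulate_cohort(spec), horizon_years=8.0)
score = cs.score_signature(cohort.expr, cs.builtin_signature("CYTscore")).scores.to_numpy()

gene = cohort.expr.data.loc[cs.planted_gene_names(spec)[0]].to_numpy()
labels = cs.tertile_split(gene).labels
clin = cohort.clinical.data
for tert in ("T1", "T3"):
    m = labels == tert
    row = cs.fit_cox(clin.os_time[m], clin.os_event[m],
                     [cs.Term("CYTscore", score[m])])["CYTscore"]
    print(f"{tert}: HR {row['hr']:.2f} (95% CI {row['ci95_low']:.2f}-{row['ci95_high']:.2f}), p {row['p']:.2g}")
```

prints

```
T1: HR 1.12 (95% CI 0.84-1.50), p 0.43
T3: HR 0.34 (95% CI 0.25-0.48), p 1.5e-10
```

— the cytolytic score is unrelated to survival in the conditioning gene's
lower tertile (HR ≈ 1) but strongly protective in its upper tertile
(HR 0.34: each unit of score roughly thirds the hazard), which is exactly
the kind of hidden conditional structure the scan is built to find.  The
`examples/` directory walks through each capability: cohort simulation,
the scan and parity ranking, two-cohort candidate selection with held-out
evaluation, and signature scoring with the FDR screen.

A thin CLI mirrors the workflow for shell use:

```bash
constru simulate --n-samples 300 --n-genes 200 --seed 1 --pair --out sim/
constru scan --expr sim/sim1_expression.tsv --clinical sim/sim1_clinical.tsv --out scan_a/
constru select scan_a/cohort_constru.tsv scan_b/cohort_constru.tsv --cutoff 4 --out genes/
constru evaluate --expr test_expr.tsv --clinical test_clin.tsv --stratifier STRATsig --out report/
```

Every command writes a provenance record (config hash, seed, version) and
is byte-identical on rerun.

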