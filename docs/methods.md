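# Methods

## The model

`constru` searches for *conditional* prognostic structure: genes whose
expression level switches the association between a continuous score and
overall survival on or off.  The primitive is a tertile-conditional Cox
analysis.  For gene *g* with expression vector *x_g*, samples are ranked
ascending (ties broken by original sample position, so the assignment is
deterministic) and the sample at 0-based rank *r* of *n* is placed in
tertile ⌊3r/n⌋ ∈ {T1, T2, T3}; group sizes therefore differ by at most
one for every *n* ≥ 6.  Within each tertile the model

h(t | x) = h₀(t) · exp(β·score + β_age·age + Σ β_stage·1[stage level] + Σ β_deb·1[debulking level])

is fitted and the score term's hazard ratio and two-sided Wald p-value
recorded.  The default score is CYTscore, the mean log2 expression of
GZMA and PRF1.

Gene ranking uses the parity score
(−log10 P / HR)[T1] − (−log10 P / HR)[T3], computed only when both the T1
and T3 fits converged; p-values are clamped at 1e-300 before the log.
Percentile ranks are 0-based ascending average ranks scaled to [0, 100],
computed over the unfiltered estimable records; the rank convention
(average for ties, 100·r/(n−1) scaling) is an implementation choice fixed
for determinism.  Genes with |Pearson r(gene, score)| > 0.15 are excluded
before ranking: their tertiles compress the score's distribution by
construction, making any conditional contrast uninterpretable.  The
whole-cohort interaction model (score + gene + score×gene, interaction
term centered) is fitted and reported for every gene for comparison, but
never participates in selection.

Candidate selection intersects rankings across ≥ 2 training cohorts:
UpperT genes sit at percentile ≤ c in every cohort, LowerT genes at
≥ 100 − c, with c = 4 by default (2 and 6 supported for sensitivity).
Signatures are scored as the mean log2 expression of their genes;
STRATsig is the UpperT mean minus the LowerT mean, so it is invariant to
any uniform shift of the matrix.  The APM signature instead sums per-gene
z-scores (population SD, computed within the scoring cohort, so the
cohort mean is exactly 0; whether a fixed external reference should be
used instead is left open by its source — within-cohort is implemented).
Signature genes absent from a matrix are omitted and reported; scoring
fails if less than half of a signature is present, unless overridden.

## Cox fitting

The fitter maximizes the Efron partial likelihood (the standard treatment
of tied event times in the field's reference survival software) by
Newton-Raphson with step-halving on likelihood decrease, tolerance 1e-7
on the coefficient change, at most 100 iterations, on internally
standardized covariates.  Standard errors come from the inverse observed
information; confidence intervals are exp(β ± 1.96·se).  Categorical
covariates expand to indicators against declared reference levels (stage:
low, debulking: optimal) with NA carried as an explicit third level.
Monotone likelihood (quasi-separation) is detected as a standardized
coefficient beyond 50 or a standardized standard error beyond 50; such
fits are flagged non-converged and their inferential fields are NaN.

The implementation is vectorized (risk-set sums via reverse cumulative
sums, tie groups precomputed per dataset) because the genome-wide scan
performs four fits per gene — three tertile models and the interaction
model — i.e. ~8,000 fits per 2,000-gene cohort; the validation suite
executes on the order of 10⁵ fits.  Correctness is checked three
independent ways in the tests: a brute-force grid-search maximization of
the Efron likelihood, lifelines (Efron), and scikit-survival (Breslow, on
tie-free data where the two likelihoods coincide).

Inside the scan, nuisance indicator columns whose minority level has
fewer than 3 samples within the current subset are dropped before
fitting: a one-sample level is quasi-separated, and whether Newton
iteration stalls on it depends on row ordering.  Only the score term's
inference must be sound for a tertile record to count as estimable; a
flagged record is kept in the output with a reason code but excluded from
parity ranking, preventing ±∞ parity artifacts.

Logrank tests (unweighted, k groups, chi-square with k−1 df) and
Kaplan-Meier estimation delegate to lifelines; two-sample location
comparisons run Shapiro-Wilk on both samples at α = 0.05 and use the
t-test only if both pass, otherwise the Mann-Whitney rank-sum test.
Benjamini-Hochberg adjustment (statsmodels) is applied only in the
per-gene survival screen, not in the scan itself.

## Cohort handling

Expression is assumed log2 scale; a loader offset flag applies
log2(x + c) for raw inputs.  Missing expression cells are rejected by
default (silent imputation can move tertile boundaries); an explicit
per-gene row-mean imputation mode exists.  Multi-probe genes are
collapsed by arithmetic mean per sample.  Alignment restricts to the
shared samples in expression order and drops — with a logged report —
samples missing survival annotation, and samples with exactly zero
follow-up time (their handling is otherwise undefined).  Follow-up is
administratively censored at 8 years: times beyond the horizon become
censored observations at the horizon; events at exactly 8 years are
retained (the boundary is read as inclusive).  Age with partial
missingness is mean-imputed within cohort; a fully missing covariate is
dropped from every model with a warning.

## The synthetic cohort generator

The generator emulates the statistical structure the scan assumes, at
HGSC-like scale: n = 600 tumors and 2,000 genes by default, gene-wise
normal log2 expression (means ~N(7, 1.5), SD 1), two score genes drawn
bivariate normal with correlation 0.7, age ~N(60, 10), stage high in 92%
and suboptimal debulking in 40% of tumors (matching the descriptive
ranges of published HGSC cohorts loosely, not exactly), with 10% / 5% /
5% missingness in age / stage / debulking.  Survival is Weibull
proportional hazards, shape 1.2 and scale 8.6 years — chosen so that
roughly 55% of tumors experience an event within the 8-year horizon —
with uniform dropout over (0, 25] years and end-of-study censoring at 15
years.

The conditional effect is planted per gene: a sample inside the planted
gene's active tertile (computed from the simulated expression by the same
split rule the scan uses, so discovery is exactly the inverse of
generation) receives an additional log-hazard β_score · (score − mean
score).  The score is centered inside this term deliberately: Cox fits
are invariant to the centering, so the within-tertile association is
β_score either way, but without centering the indicator would also scale
the active tertile's baseline hazard by exp(β·mean) ≈ e⁻⁷ and leave it
with essentially no events.  Default covariate effects are β_age = 0.1
per SD and β_debulking = 0.7 (HR ≈ 2, the magnitude reported for
suboptimal debulking).

Planted genes sharing an active tertile can form a co-expressed module
(single latent factor, within-module correlation ρ_m), and the T3-active
and T1-active modules' factors can be correlated with each other (ρ_x).
This mirrors how real stratification signatures behave: their genes are
coordinated expression programs, positively correlated within the UpperT
and LowerT groups and negatively correlated between them.  The
anti-correlation matters for a *difference* signature: without it, the
low tertile of UpperT − LowerT admits samples in which both modules are
high — samples whose UpperT module is active — and the conditional
contrast between signature tertiles blurs.

What the generator does **not** emulate: probe-level microarray
structure, batch effects, gene-gene correlation outside planted modules,
non-proportional hazards, and informative censoring.  Passing tests
therefore demonstrate that the pipeline recovers the conditional
structure it defines, under an idealized expression model — not that it
would do so at the same rates on real cohorts, where effects are weaker
and diffuse across correlated genes.

## Validation designs and problem sizes

The heavy end-to-end checks run at n = 600 and 2,000 genes, the working
size throughout:

* **Null calibration** — five all-null cohorts; the fraction of genes
  with T3 score-p < 0.05 is pooled across the batch.  Pooling is
  essential: within one cohort every gene's tertile model shares the same
  survival data, so per-gene p-values are strongly correlated, and a
  cohort carrying a chance marginal score-survival association (expected
  in ~5% of null cohorts) lifts all its fractions coherently.  The
  per-cohort fraction is therefore far more variable than a binomial
  count would suggest.
* **Recovery** — ten independent cohort pairs with one T3-active planted
  gene (β = −1): the planted gene's parity percentile and its recovery by
  4th-percentile cross-cohort selection.  The candidate sets also contain
  ~n_genes·(0.04)² ≈ 3 chance genes per side, the unavoidable cost of
  intersecting two 4th-percentile tails.
* **End-to-end signature behavior** — ten runs with the two-module design
  (5 + 5 planted genes, ρ_m = 0.9, ρ_x = −0.6, per-gene β = −0.1 so a
  fully active sample carries a total log-hazard near −1): candidates are
  selected from a cohort pair, UpperT/LowerT/STRATsig signatures built
  from them, and the score's Cox p within STRATsig tertiles measured on a
  third cohort.  The module structure is what makes this chain
  statistically meaningful: with a single planted gene the candidate sets
  are dominated by the chance genes, the built signature is only weakly
  correlated with the true conditioning axis, and the strong planted
  effect leaks into the signature's low tertile.

The per-gene screen's null check uses 1,000-gene cohorts; the Cox-vs-grid
oracle uses n = 30 single-covariate datasets with a β grid of step 1e-4.

## Known limitations

* The parity score divides −log10 P by HR exactly as defined; alternative
  ranking functions can be plugged in where the scan computes it, but
  none are shipped.
* Tertiles are the only quantile scheme; per-gene optimal cutpoints are
  out of scope.
* No FDR control is applied across the scan itself — selection relies on
  cross-cohort reproducibility instead, and chance genes enter the
  candidate sets at the rate given above.
* The Cox fitter covers right-censored, time-fixed covariates only: no
  stratified baselines, frailty, competing risks, or proportionality
  diagnostics.
* Subgroup evaluations inherit whole-cohort tertile assignments by
  design (the single most consequential analysis choice: tertiles are
  population descriptors, never recomputed inside subsets); users wanting
  subset-specific tertiles must relabel explicitly.
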