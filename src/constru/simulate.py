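"""Synthetic HGSC-like cohorts with tertile-conditional score effects.

The generator emulates the data model the scan assumes: a log2-scale
expression matrix of a few thousand genes over a few hundred tumors, a
two-gene cytolytic score (correlated effector genes named GZMA and PRF1),
clinical covariates with realistic missingness, and right-censored
overall survival whose score effect is switched on only inside chosen
expression tertiles of designated "planted" conditioning genes.  Because
the planted tertile is computed from the simulated expression by the same
split rule the scan uses, discovery is exactly the inverse problem of
generation.

Survival follows a Weibull proportional-hazards model: baseline shape
1.2, scale chosen so roughly 55% of tumors experience an event within
8 years, with uniform dropout and administrative end-of-study censoring
layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, Cohort, ExpressionMatrix
from .core import tertile_split

SCORE_GENES = ("GZMA", "PRF1")


class SimulationError(ValueError):
    pass


@dataclass
class PlantedGene:
    """A conditioning gene: score log-hazard ``beta_score`` is active only
    for samples inside ``active_tertile`` of the gene's expression."""

    gene_index: int
    active_tertile: str = "T3"
    beta_score: float = -1.0

    def __post_init__(self) -> None:
        if self.active_tertile not in ("T1", "T3"):
            raise SimulationError("active_tertile must be 'T1' or 'T3'")


@dataclass
class SimulationSpec:
    """Generative parameters; defaults emulate an HGSC expression cohort."""

    n_samples: int = 600
    n_genes: int = 2000
    seed: int = 0
    planted: list[PlantedGene] = field(default_factory=list)
    beta_age: float = 0.1          # log-hazard per SD of age
    beta_debulking: float = 0.7    # log-hazard for suboptimal debulking (~HR 2)
    weibull_shape: float = 1.2
    weibull_scale: float = 8.6     # years; ~55% events by year 8 at baseline
    admin_horizon: float = 15.0    # end-of-study censoring, years
    dropout_max: float = 25.0      # uniform dropout over (0, dropout_max]
    age_missing: float = 0.10
    stage_missing: float = 0.05
    debulking_missing: float = 0.05
    score_gene_correlation: float = 0.7
    planted_correlation: float = 0.0  # within-module correlation of planted genes sharing an active tertile
    planted_module_correlation: float = 0.0  # correlation between the T3-module and T1-module latent factors
    expression_sd: float = 1.0
    frac_stage_high: float = 0.92
    frac_suboptimal: float = 0.4

    def validate(self) -> None:
        if self.n_samples < 60:
            raise SimulationError("n_samples must be >= 60")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if not -1 < self.score_gene_correlation < 1:
            raise SimulationError("|score_gene_correlation| must be < 1")
        if not 0 <= self.planted_correlation < 1:
            raise SimulationError("planted_correlation must be in [0, 1)")
        if not -1 < self.planted_module_correlation < 1:
            raise SimulationError("|planted_module_correlation| must be < 1")
        if self.admin_horizon <= 0 or self.dropout_max <= 0:
            raise SimulationError("censoring horizons must be positive")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise SimulationError("Weibull parameters must be positive")
        idx = [p.gene_index for p in self.planted]
        if len(idx) != len(set(idx)):
            raise SimulationError("planted gene indices must be distinct")
        for p in self.planted:
            if not 0 <= p.gene_index < self.n_genes:
                raise SimulationError(f"planted gene index {p.gene_index} out of range")
        for frac in (self.age_missing, self.stage_missing, self.debulking_missing):
            if not 0 <= frac < 1:
                raise SimulationError("missingness fractions must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def planted_gene_names(spec: SimulationSpec) -> list[str]:
    return [gene_name(p.gene_index) for p in spec.planted]


def simulate_cohort(spec: SimulationSpec, name: str = "sim", seed: int | None = None) -> Cohort:
    """Draw one cohort from the generative model; reproducible from the seed.

    Expression is gene-wise normal on the log2 scale (gene means drawn
    from N(7, 1.5), common noise SD from the spec); the two score genes
    are drawn bivariate-normal with the specified correlation and the
    cytolytic score is their per-sample mean.  The per-sample log hazard is

        eta = sum_planted beta_score * (score - mean(score)) * 1[sample in active tertile]
              + beta_age * (age - 60)/10 + beta_debulking * 1[suboptimal]

    and event times follow the Weibull baseline accelerated by exp(eta).
    The score is centered inside the planted term so that switching the
    effect on does not also rescale the active tertile's baseline event
    rate (Cox fits are invariant to the centering; the within-tertile
    association is beta_score either way).
    Observed time is the minimum of the event time, a uniform dropout
    time, and the administrative horizon.  Covariate values are masked to
    NA at the spec's fractions after the hazard is computed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, g = spec.n_samples, spec.n_genes

    gene_means = rng.normal(7.0, 1.5, size=g)
    expr = rng.normal(gene_means[:, None], spec.expression_sd, size=(g, n))
    gene_ids = [gene_name(i) for i in range(g)]

    # planted genes sharing an active tertile may form a co-expressed module
    # (one latent factor per tertile group), emulating the coordinated
    # expression programs real conditioning genes belong to
    if spec.planted_correlation > 0:
        rho_m = spec.planted_correlation
        rho_x = spec.planted_module_correlation
        f3 = rng.standard_normal(n)
        f1 = rho_x * f3 + np.sqrt(1 - rho_x**2) * rng.standard_normal(n)
        factors = {"T3": f3, "T1": f1}
        for tert_group in ("T1", "T3"):
            members = [p.gene_index for p in spec.planted if p.active_tertile == tert_group]
            if len(members) < 2:
                continue
            for gi in members:
                eps = rng.standard_normal(n)
                latent = np.sqrt(rho_m) * factors[tert_group] + np.sqrt(1 - rho_m) * eps
                expr[gi] = gene_means[gi] + spec.expression_sd * latent

    rho = spec.score_gene_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    gzma = 7.0 + spec.expression_sd * z1
    prf1 = 7.0 + spec.expression_sd * z2
    score = (gzma + prf1) / 2.0

    age = rng.normal(60.0, 10.0, size=n)
    suboptimal = rng.random(n) < spec.frac_suboptimal
    stage_high = rng.random(n) < spec.frac_stage_high

    eta = spec.beta_age * (age - 60.0) / 10.0 + spec.beta_debulking * suboptimal
    score_c = score - score.mean()
    for p in spec.planted:
        tert = tertile_split(expr[p.gene_index])
        eta = eta + p.beta_score * score_c * tert.mask(p.active_tertile)

    u = rng.random(n)
    t_event = spec.weibull_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / spec.weibull_shape)
    t_drop = rng.uniform(0.0, spec.dropout_max, size=n)
    t_cens = np.minimum(t_drop, spec.admin_horizon)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    os_time = np.maximum(os_time, 1e-6)  # guard against zero follow-up

    mask_age = rng.random(n) < spec.age_missing
    mask_stage = rng.random(n) < spec.stage_missing
    mask_deb = rng.random(n) < spec.debulking_missing

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    expr_df = pd.DataFrame(
        np.vstack([expr, gzma[None, :], prf1[None, :]]),
        index=pd.Index(gene_ids + list(SCORE_GENES), name="feature_id"),
        columns=sample_ids,
    )
    clin = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": np.where(mask_age, np.nan, age),
            "stage": np.where(mask_stage, None,
                              np.where(stage_high, "high", "low")).astype(object),
            "debulking": np.where(mask_deb, None,
                                  np.where(suboptimal, "suboptimal", "optimal")).astype(object),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return Cohort(ExpressionMatrix(expr_df, feature_kind="gene"), ClinicalTable(clin), name=name)


def simulate_cohort_pair(spec: SimulationSpec, seed_a: int, seed_b: int) -> tuple[Cohort, Cohort]:
    """Two independent cohorts from one spec, sharing the gene universe.

    Emulates a two-cohort training design where candidate genes must rank
    extreme in both cohorts.
    """
    if seed_a == seed_b:
        raise SimulationError("seed_a and seed_b must differ")
    a = simulate_cohort(spec, name=f"sim{seed_a}", seed=seed_a)
    b = simulate_cohort(spec, name=f"sim{seed_b}", seed=seed_b)
    return a, b
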