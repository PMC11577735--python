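"""Tertile-conditional survival evaluation and per-gene screening.

Answers the question the stratification signature exists for: within
which tertile of a stratifier (a gene, STRATsig, a pathway score) does a
prognostic score (CYTscore) associate with overall survival?  Score
tertiles (Lo/Mid/Hi) and stratifier tertiles are always computed on the
FULL cohort and carried into tertile subsets and clinical subgroups,
never recomputed inside them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import Cohort
from .core import TERTILE_NAMES, ConstruError, _covariate_design, _score_fit, tertile_split
from .survival import KMEstimate, SurvivalError, km_estimate, logrank_test
from .signatures import assign_score_tertiles

logger = logging.getLogger(__name__)

STRATIFIER_SCORE_GUARD_R = 0.5


@dataclass
class TertileReport:
    """Statistics for one stratifier tertile."""

    tertile: str
    n: int
    n_events: int
    estimable: bool
    logrank_chi2: float = np.nan
    logrank_p: float = np.nan
    cox_score_hr: float = np.nan
    cox_score_p: float = np.nan
    km: KMEstimate | None = None
    reason: str = ""


@dataclass
class TertileSurvivalReport:
    stratifier_name: str
    score_name: str
    tertiles: dict[str, TertileReport] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in TERTILE_NAMES:
            r = self.tertiles[t]
            rows.append({
                "tertile": t, "n": r.n, "n_events": r.n_events, "estimable": r.estimable,
                "logrank_chi2": r.logrank_chi2, "logrank_p": r.logrank_p,
                "cox_score_hr": r.cox_score_hr, "cox_score_p": r.cox_score_p,
                "reason": r.reason,
            })
        return pd.DataFrame(rows)


@dataclass
class SubgroupReport:
    name: str
    n: int
    report: TertileSurvivalReport | None
    skipped: bool = False
    reason: str = ""


def _tertile_report(tertile, times, events, score, score_groups, Z, znames, with_km) -> TertileReport:
    n = len(times)
    n_ev = int(events.sum())
    rep = TertileReport(tertile=tertile, n=n, n_events=n_ev, estimable=False)
    if n_ev < 2:
        rep.reason = "fewer than 2 events"
        return rep
    fit = _score_fit(times, events, score, Z, znames)
    if not fit["converged"]:
        rep.reason = "score Cox fit non-estimable"
        return rep
    rep.cox_score_hr, rep.cox_score_p = fit["hr"], fit["p"]
    groups_present = pd.unique(score_groups)
    if len(groups_present) >= 2:
        try:
            rep.logrank_chi2, rep.logrank_p = logrank_test(times, events, score_groups)
        except SurvivalError:
            pass
    if with_km:
        rep.km = km_estimate(times, events, score_groups if len(groups_present) >= 2 else None)
    rep.estimable = True
    return rep


def evaluate_tertiles(
    cohort: Cohort,
    stratifier_scores,
    score,
    covariates: tuple[str, ...] = ("age", "stage", "debulking"),
    stratifier_name: str = "stratifier",
    score_name: str = "CYTscore",
    with_km: bool = True,
    stratifier_tertiles=None,
    score_tertiles=None,
) -> TertileSurvivalReport:
    """Score-survival statistics within each stratifier tertile.

    Within each tertile of ``stratifier_scores`` (computed on the full
    cohort): a logrank test across the score's Lo/Mid/Hi population groups
    restricted to that tertile, and a covariate-adjusted Cox fit of the
    continuous score.  A stratifier strongly correlated with the score
    (|Pearson r| > 0.5) is rejected: its tertiles would compress the
    score's distribution and the comparison would be circular.

    Pre-computed tertile labels may be supplied (``stratifier_tertiles``,
    ``score_tertiles``) so subgroup analyses can inherit full-cohort
    assignments.
    """
    strat = np.asarray(stratifier_scores, dtype=float)
    sc = np.asarray(score, dtype=float)
    if len(strat) != cohort.n_samples or len(sc) != cohort.n_samples:
        raise ConstruError("stratifier/score length does not match cohort")
    r = stats.pearsonr(strat, sc).statistic if np.ptp(strat) > 0 and np.ptp(sc) > 0 else 0.0
    if abs(r) > STRATIFIER_SCORE_GUARD_R:
        raise ConstruError(
            f"stratifier correlated with score (|r| = {abs(r):.2f} > {STRATIFIER_SCORE_GUARD_R})")

    strat_labels = (stratifier_tertiles if stratifier_tertiles is not None
                    else tertile_split(strat).labels)
    score_groups = (score_tertiles if score_tertiles is not None
                    else assign_score_tertiles(sc, "LoMidHi").labels)
    strat_labels = np.asarray(strat_labels)
    score_groups = np.asarray(score_groups)

    clin = cohort.clinical.data
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    Z, znames = _covariate_design(cohort, covariates)

    report = TertileSurvivalReport(stratifier_name=stratifier_name, score_name=score_name)
    for t in TERTILE_NAMES:
        m = strat_labels == t
        report.tertiles[t] = _tertile_report(t, times[m], events[m], sc[m],
                                             score_groups[m], Z[m], znames, with_km)
    return report


def evaluate_subgroups(
    cohort: Cohort,
    stratifier_scores,
    score,
    subgroup_specs: dict,
    covariates: tuple[str, ...] = ("age", "stage", "debulking"),
    stratifier_name: str = "stratifier",
    score_name: str = "CYTscore",
    with_km: bool = False,
) -> list[SubgroupReport]:
    """Tertile-conditional evaluation inside clinical subgroups.

    ``subgroup_specs`` maps a subgroup name either to a callable taking the
    clinical DataFrame and returning a boolean mask, or to a
    (column, value) pair selecting rows equal to the value.  Stratifier and
    score tertiles are computed once on the full cohort and inherited by
    every subgroup; empty or unresolvable subgroups are skipped with a
    warning.
    """
    strat = np.asarray(stratifier_scores, dtype=float)
    sc = np.asarray(score, dtype=float)
    strat_labels = tertile_split(strat).labels
    score_groups = assign_score_tertiles(sc, "LoMidHi").labels
    clin = cohort.clinical.data

    out: list[SubgroupReport] = []
    for name, spec in subgroup_specs.items():
        try:
            if callable(spec):
                mask = np.asarray(spec(clin), dtype=bool)
            else:
                col, value = spec
                if col not in clin.columns:
                    raise KeyError(col)
                mask = (clin[col] == value).to_numpy()
        except KeyError as exc:
            logger.warning("subgroup %r references missing covariate %s; skipped", name, exc)
            out.append(SubgroupReport(name, 0, None, skipped=True, reason=f"missing covariate {exc}"))
            continue
        if not mask.any():
            logger.warning("subgroup %r is empty; skipped", name)
            out.append(SubgroupReport(name, 0, None, skipped=True, reason="empty subgroup"))
            continue
        ids = [s for s, keep in zip(cohort.sample_ids, mask) if keep]
        sub = Cohort(cohort.expr.subset_samples(ids), cohort.clinical.subset(ids),
                     name=f"{cohort.name}:{name}")
        rep = evaluate_tertiles(sub, strat[mask], sc[mask], covariates=covariates,
                                stratifier_name=stratifier_name, score_name=score_name,
                                with_km=with_km,
                                stratifier_tertiles=strat_labels[mask],
                                score_tertiles=score_groups[mask])
        out.append(SubgroupReport(name, int(mask.sum()), rep))
    return out


def gene_survival_screen(
    cohort: Cohort,
    sample_mask=None,
    hr_threshold: float = 0.80,
    fdr_alpha: float = 0.01,
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-gene Cox screen with Benjamini-Hochberg FDR control.

    Within the selected samples (typically one stratifier tertile), each
    gene's expression enters a Cox model as a continuous term (optionally
    covariate-adjusted); p-values are BH-adjusted across all estimable
    genes and genes with HR < ``hr_threshold`` and adjusted p <
    ``fdr_alpha`` are flagged as positively associated with survival.
    """
    if sample_mask is None:
        sample_mask = np.ones(cohort.n_samples, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    ids = [s for s, keep in zip(cohort.sample_ids, sample_mask) if keep]
    sub = Cohort(cohort.expr.subset_samples(ids), cohort.clinical.subset(ids),
                 name=cohort.name)
    clin = sub.clinical.data
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    Z, znames = _covariate_design(sub, covariates) if covariates else (np.empty((len(ids), 0)), [])

    rows, dropped = [], 0
    mat = sub.expr.data
    for g, x in zip(mat.index, mat.to_numpy(dtype=float)):
        fit = _score_fit(times, events, x, Z, znames)
        if fit["converged"]:
            rows.append({"gene": g, "hr": fit["hr"], "p": fit["p"]})
        else:
            dropped += 1
    if dropped:
        logger.info("gene screen: %d non-estimable genes dropped", dropped)
    if not rows:
        return pd.DataFrame(columns=["gene", "hr", "p", "p_adj", "flagged"])
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["flagged"] = (df["hr"] < hr_threshold) & (df["p_adj"] < fdr_alpha)
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)
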