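"""The CONSTRU scan: tertile-conditional prognostic-score statistics per gene.

For every gene in a cohort, samples are split into expression tertiles
(T1 = lowest third).  Within each tertile a multivariable Cox model of a
continuous prognostic score (typically the cytolytic activity score,
CYTscore) adjusted for age, FIGO stage and debulking status is fitted,
and the score term's hazard ratio and Wald p-value recorded.  Genes are
then ranked by the parity score

    (-log10 P / HR)[T1] - (-log10 P / HR)[T3]

which contrasts the score's significance and effect size between the
gene's lower and upper tertiles: large positive values mark genes whose
LOW expression conditions a favorable score-survival association
("LowerT" genes), large negative values mark genes whose HIGH expression
does ("UpperT" genes).  Genes intrinsically correlated with the score
(|Pearson r| > 0.15) are excluded before percentile ranking, since their
tertiles compress the score's distribution by construction.  Candidate
signature genes are those ranked within an extreme percentile cutoff in
every training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .survival import P_FLOOR, _fit_raw, wald_p

logger = logging.getLogger(__name__)

TERTILE_NAMES = ("T1", "T2", "T3")
DEFAULT_CORR_THRESHOLD = 0.15
DEFAULT_CUTOFF_PERCENTILE = 4.0


class ConstruError(ValueError):
    pass


@dataclass
class TertileLabels:
    """Per-sample tertile assignment plus the two boundary values."""

    labels: np.ndarray  # dtype '<U2', values in {"T1","T2","T3"}
    boundaries: tuple[float, float]

    def mask(self, tertile: str) -> np.ndarray:
        return self.labels == tertile

    def sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {str(lab): int(c) for lab, c in zip(labels, counts)}


def tertile_split(values) -> TertileLabels:
    """Split samples into expression tertiles, lowest third first.

    Samples are sorted ascending by value, ties broken by original index
    (stable sort), and the sample at 0-based sorted rank r of n receives
    tertile floor(3r/n).  Group sizes therefore differ by at most one and
    the assignment is deterministic for any input, including all-tied.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 6:
        raise ConstruError(f"tertile split requires at least 6 samples, got {n}")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    idx = (3 * ranks) // n
    labels = np.array(TERTILE_NAMES)[idx]
    sorted_v = v[order]
    b1 = float(sorted_v[np.searchsorted((3 * np.arange(n)) // n, 1)])
    b2 = float(sorted_v[np.searchsorted((3 * np.arange(n)) // n, 2)])
    return TertileLabels(labels=labels, boundaries=(b1, b2))


def parity_score(p_t1: float, hr_t1: float, p_t3: float, hr_t3: float) -> float:
    """Parity score (-log10 P / HR)[T1] - (-log10 P / HR)[T3].

    p-values are clamped at 1e-300 before the log; non-positive p or HR is
    an error (inputs must come from converged fits).
    """
    for nm, val in (("p_t1", p_t1), ("p_t3", p_t3)):
        if not (0 < val <= 1):
            raise ConstruError(f"{nm} must be in (0, 1], got {val}")
    for nm, val in (("hr_t1", hr_t1), ("hr_t3", hr_t3)):
        if val <= 0:
            raise ConstruError(f"{nm} must be positive, got {val}")
    t1 = -np.log10(max(p_t1, P_FLOOR)) / hr_t1
    t3 = -np.log10(max(p_t3, P_FLOOR)) / hr_t3
    return float(t1 - t3)


def percentile_rank(values) -> np.ndarray:
    """Map values to percentile ranks in [0, 100].

    Ascending 0-based ranks (average rank for ties) scaled by
    100/(n-1), so the minimum maps to 0 and the maximum to 100.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ConstruError("percentile ranking requires at least 2 values")
    if np.isnan(v).any():
        raise ConstruError("percentile ranking input contains missing values")
    ranks = stats.rankdata(v, method="average") - 1.0
    return 100.0 * ranks / (len(v) - 1)


@dataclass
class ConstruRecord:
    gene: str
    tertile_stats: dict = field(default_factory=dict)  # "T1"/"T2"/"T3" -> dict(hr,p,n,n_events,converged)
    interaction_hr: float = np.nan
    interaction_p: float = np.nan
    cyt_correlation: float = np.nan
    parity: float = np.nan
    parity_percentile: float = np.nan
    filtered_reason: str = ""

    @property
    def filtered(self) -> bool:
        return bool(self.filtered_reason)

    @property
    def estimable(self) -> bool:
        t = self.tertile_stats
        return bool(t) and t["T1"]["converged"] and t["T3"]["converged"]


@dataclass
class ConstruTable:
    """One scan's output: a record per gene plus the scan's provenance fields."""

    cohort_name: str
    score_name: str
    covariates: list[str]
    records: list[ConstruRecord]

    def record(self, gene: str) -> ConstruRecord:
        for r in self.records:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"gene": r.gene}
            for t in TERTILE_NAMES:
                s = r.tertile_stats.get(t, {})
                row[f"{t.lower()}_hr"] = s.get("hr", np.nan)
                row[f"{t.lower()}_p"] = s.get("p", np.nan)
                row[f"{t.lower()}_n"] = s.get("n", np.nan)
                row[f"{t.lower()}_events"] = s.get("n_events", np.nan)
            row["interaction_hr"] = r.interaction_hr
            row["interaction_p"] = r.interaction_p
            row["cyt_r"] = r.cyt_correlation
            row["parity"] = r.parity
            row["parity_percentile"] = r.parity_percentile
            row["filtered_reason"] = r.filtered_reason
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def ranked_genes(self) -> pd.Series:
        """Parity percentile for every unfiltered, estimable gene."""
        pairs = [(r.gene, r.parity_percentile) for r in self.records
                 if not r.filtered and not np.isnan(r.parity_percentile)]
        return pd.Series(dict(pairs), name="parity_percentile")


def _rank_records(records: list[ConstruRecord]) -> None:
    """(Re)compute parity percentiles over unfiltered records with a parity score."""
    eligible = [r for r in records if not r.filtered and not np.isnan(r.parity)]
    for r in records:
        r.parity_percentile = np.nan
    if len(eligible) >= 2:
        pct = percentile_rank([r.parity for r in eligible])
        for r, q in zip(eligible, pct):
            r.parity_percentile = float(q)


def _covariate_design(cohort: Cohort, covariates) -> tuple[np.ndarray, list[str]]:
    """Adjustment-covariate block for the scan's Cox models.

    Age enters continuous (partial missingness mean-imputed within cohort;
    fully missing -> dropped with a warning).  Stage and debulking enter as
    indicators against their reference levels (low, optimal) with NA as an
    explicit third level.  All-constant columns are dropped, since a
    cohort, or a tertile of one, may lack a level entirely.
    """
    clin = cohort.clinical.data
    cols, names = [], []
    for cov in covariates:
        if cov not in clin.columns:
            logger.warning("cohort %s: covariate %r absent, dropped from scan models", cohort.name, cov)
            continue
        if cov == "age":
            age = clin["age"].to_numpy(dtype=float)
            if np.isnan(age).all():
                logger.warning("cohort %s: age entirely missing, dropped from scan models", cohort.name)
                continue
            if np.isnan(age).any():
                age = np.where(np.isnan(age), np.nanmean(age), age)
            cols.append(age)
            names.append("age")
        else:
            ref = {"stage": "low", "debulking": "optimal"}.get(cov)
            vals = clin[cov].astype(object).where(clin[cov].notna(), "NA").astype(str).to_numpy()
            for lev in pd.unique(vals):
                if lev == ref:
                    continue
                cols.append((vals == lev).astype(float))
                names.append(f"{cov}[{lev}]")
    if not cols:
        return np.empty((cohort.n_samples, 0)), []
    X = np.column_stack(cols)
    keep = X.max(axis=0) != X.min(axis=0)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.info("cohort %s: constant covariate columns dropped: %s", cohort.name, dropped)
    return X[:, keep], [n for n, k in zip(names, keep) if k]


MIN_LEVEL_COUNT = 3  # smallest indicator level still fit inside a subset


def _usable_columns(Z: np.ndarray) -> np.ndarray:
    """Mask of nuisance-covariate columns estimable within a subset.

    Constant columns are unusable; 0/1 indicator columns whose minority
    level has fewer than MIN_LEVEL_COUNT samples are dropped too, since
    near-empty levels are quasi-separated and make the fit's convergence
    depend on row order.
    """
    keep = np.ones(Z.shape[1], dtype=bool)
    n = Z.shape[0]
    for j in range(Z.shape[1]):
        col = Z[:, j]
        if np.ptp(col) == 0:
            keep[j] = False
            continue
        if ((col == 0) | (col == 1)).all():
            ones = int(col.sum())
            if min(ones, n - ones) < MIN_LEVEL_COUNT:
                keep[j] = False
    return keep


def _score_fit(times, events, score, Z, names=None, presorted=False):
    """Cox fit of [score | covariates]; returns the score term's stats dict.

    Covariate columns constant within the subset are dropped (a tertile may
    lack a categorical level entirely); a constant score is non-estimable.
    """
    out = {"hr": np.nan, "p": np.nan, "n": len(times), "n_events": int(np.sum(events)),
           "converged": False}
    if out["n_events"] < 2 or np.ptp(score) == 0:
        return out
    if Z.shape[1]:
        keep = _usable_columns(Z)
        X = np.column_stack([score, Z[:, keep]])
    else:
        X = np.asarray(score, dtype=float)[:, None]
    try:
        beta, se, _, conv = _fit_raw(times, events, X, presorted=presorted)
    except np.linalg.LinAlgError:
        return out
    # only the score term's inference must be sound; a quasi-separated
    # nuisance indicator (e.g. a one-sample NA level inside a tertile)
    # does not void the record
    if conv and np.isfinite(se[0]) and se[0] * X[:, 0].std() <= 50:
        out["hr"] = float(np.exp(beta[0]))
        out["p"] = float(wald_p(beta[:1], se[:1])[0])
        out["converged"] = True
    return out


def constru_scan(
    cohort: Cohort,
    score,
    score_name: str = "CYTscore",
    covariates: tuple[str, ...] = ("age", "stage", "debulking"),
    genes=None,
) -> ConstruTable:
    """Run the tertile-conditional Cox scan over every gene of a cohort.

    For each gene: split samples into expression tertiles; within each
    tertile fit Cox(score + covariates) and record the score term's HR and
    Wald p; on the whole cohort fit Cox(score + gene + score*gene) and
    record the interaction term; record Pearson r(gene, score).  Genes with
    constant expression are flagged and carry no statistics.  Parity scores
    are computed where the T1 and T3 fits both converged, and percentile
    ranks assigned over those records.

    ``score`` is a per-sample vector aligned with the cohort; ``genes``
    optionally restricts the scan to a subset of feature IDs.
    """
    score = np.asarray(score, dtype=float)
    if len(score) != cohort.n_samples:
        raise ConstruError("score length does not match cohort")
    if not np.isfinite(score).all():
        raise ConstruError("score must be finite for all samples")

    clin = cohort.clinical.data
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    Z, znames = _covariate_design(cohort, covariates)

    expr = cohort.expr.data
    gene_ids = list(expr.index) if genes is None else [g for g in genes if g in expr.index]
    mat = expr.to_numpy(dtype=float)
    index_of = {}
    for i, g in enumerate(expr.index):
        index_of.setdefault(g, i)

    # sort the cohort by time once; subsets of time-sorted arrays stay sorted,
    # so the per-gene fits skip their own argsort
    order = np.argsort(times, kind="stable")
    times_s, events_s = times[order], events[order]
    score_s, Z_s = score[order], Z[order]
    score_sc = score_s - score_s.mean()

    # Pearson r(gene, score) for all genes in one pass
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((mat_c**2).sum(axis=1))
    s_c = score - score.mean()
    s_norm = np.sqrt((s_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_all = (mat_c @ s_c) / (norms * s_norm)

    records: list[ConstruRecord] = []
    for g in gene_ids:
        gi = index_of[g]
        x = mat[gi]
        rec = ConstruRecord(gene=g)
        if np.ptp(x) == 0:
            rec.filtered_reason = "constant"
            records.append(rec)
            continue
        rec.cyt_correlation = float(corr_all[gi])

        tert = tertile_split(x)
        for t in TERTILE_NAMES:
            m = tert.mask(t)[order]
            rec.tertile_stats[t] = _score_fit(times_s[m], events_s[m], score_s[m],
                                              Z_s[m], znames, presorted=True)
        # whole-cohort interaction model: score + gene + score x gene (centered product)
        x_s = x[order]
        inter = np.column_stack([score_s, x_s, score_sc * (x_s - x_s.mean())])
        try:
            beta, se, _, conv = _fit_raw(times_s, events_s, inter, presorted=True)
            if conv and np.isfinite(se[2]):
                rec.interaction_hr = float(np.exp(beta[2]))
                rec.interaction_p = float(wald_p(beta[2:], se[2:])[0])
        except np.linalg.LinAlgError:
            pass

        if rec.estimable:
            s = rec.tertile_stats
            rec.parity = parity_score(s["T1"]["p"], s["T1"]["hr"], s["T3"]["p"], s["T3"]["hr"])
        else:
            rec.filtered_reason = rec.filtered_reason or "non-estimable"
        records.append(rec)

    _rank_records(records)
    return ConstruTable(cohort_name=cohort.name, score_name=score_name,
                        covariates=list(znames), records=records)


def correlation_filter(table: ConstruTable, threshold: float = DEFAULT_CORR_THRESHOLD) -> ConstruTable:
    """Flag genes intrinsically correlated with the score and re-rank survivors.

    Records with |Pearson r| > threshold are marked "score-correlated";
    parity percentiles are recomputed over the remaining unfiltered,
    estimable records.  Returns a new table; the input is not modified.
    """
    if not (0 < threshold < 1):
        raise ConstruError(f"correlation threshold must be in (0, 1), got {threshold}")
    new_records = []
    for r in table.records:
        r2 = ConstruRecord(gene=r.gene, tertile_stats=dict(r.tertile_stats),
                           interaction_hr=r.interaction_hr, interaction_p=r.interaction_p,
                           cyt_correlation=r.cyt_correlation, parity=r.parity,
                           filtered_reason=r.filtered_reason)
        if not r2.filtered and abs(r2.cyt_correlation) > threshold:
            r2.filtered_reason = "score-correlated"
        new_records.append(r2)
    _rank_records(new_records)
    return ConstruTable(table.cohort_name, table.score_name, list(table.covariates), new_records)


@dataclass
class CandidateSets:
    """UpperT/LowerT candidate genes shared across training cohorts."""

    upperT_genes: set[str]
    lowerT_genes: set[str]
    cutoff_percentile: float
    source_cohorts: list[str]

    def write(self, upper_path, lower_path) -> None:
        for path, genes in ((upper_path, self.upperT_genes), (lower_path, self.lowerT_genes)):
            with open(path, "w") as fh:
                for g in sorted(genes):
                    fh.write(g + "\n")


def select_candidates(tables: list[ConstruTable],
                      cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE) -> CandidateSets:
    """Select UpperT/LowerT genes extreme in EVERY cohort's parity ranking.

    UpperT genes (high expression conditions the score-survival
    association) sit at parity percentile <= cutoff in every table; LowerT
    genes at percentile >= 100 - cutoff in every table.  The sets are
    disjoint by construction for any cutoff < 50.
    """
    if len(tables) < 2:
        raise ConstruError("candidate selection requires at least 2 cohort tables")
    if not (0 < cutoff_percentile < 50):
        raise ConstruError(f"cutoff percentile must be in (0, 50), got {cutoff_percentile}")
    ranked = [t.ranked_genes() for t in tables]
    universe = set(ranked[0].index)
    for r in ranked[1:]:
        universe &= set(r.index)
    if not universe:
        raise ConstruError("no genes shared by all cohort tables after filtering")
    upper = {g for g in universe if all(r[g] <= cutoff_percentile for r in ranked)}
    lower = {g for g in universe if all(r[g] >= 100 - cutoff_percentile for r in ranked)}
    both = upper & lower
    upper -= both
    lower -= both
    return CandidateSets(upperT_genes=upper, lowerT_genes=lower,
                         cutoff_percentile=cutoff_percentile,
                         source_cohorts=[t.cohort_name for t in tables])
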