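"""Survival-analysis primitives: Cox PH fitting, logrank, Kaplan-Meier.

The Cox fitter is a vectorized Newton-Raphson maximizer of the Efron
partial likelihood, written for the genome-wide scan's workload of tens of
thousands of small fits (n of a few hundred, a handful of covariates)
where per-fit overhead dominates.  Inference is Wald per term:
p = 2*Phi(-|beta/se|), 95% CI = exp(beta +/- 1.96*se).  Logrank and
Kaplan-Meier estimation delegate to lifelines; two-sample distribution
comparison follows the Shapiro-Wilk-gated t-test / Mann-Whitney rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

Z95 = 1.959963984540054  # Phi^{-1}(0.975)
P_FLOOR = 1e-300  # clamp before any -log10 downstream


class SurvivalError(ValueError):
    pass


@dataclass
class Term:
    """One model term: continuous values, or categorical with a reference level."""

    name: str
    values: np.ndarray | pd.Series | list
    kind: str = "continuous"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SurvivalError(f"term {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class CoxResult:
    """Per-term Wald inference from one proportional-hazards fit.

    ``summary`` is a DataFrame indexed by expanded term name with columns
    coef, hr, ci95_low, ci95_high, se, p.  Non-converged fits carry NaN in
    every inferential column.
    """

    summary: pd.DataFrame
    n_samples: int
    n_events: int
    converged: bool
    log_partial_likelihood: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.summary.loc[term]

    def to_json_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "terms": {
                name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for name, row in self.summary.iterrows()
            },
        }


@dataclass
class KMEstimate:
    """Product-limit survival estimates, optionally per group."""

    groups: dict = field(default_factory=dict)  # label -> DataFrame(time, survival, at_risk)

    @property
    def grouped(self) -> bool:
        return len(self.groups) > 1

    def survival_at(self, t: float, group=None) -> float:
        tbl = self.groups[group if group is not None else next(iter(self.groups))]
        mask = tbl["time"] <= t
        return float(tbl.loc[mask, "survival"].iloc[-1]) if mask.any() else 1.0


# ---------------------------------------------------------------------------
# Efron partial likelihood core
# ---------------------------------------------------------------------------

def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _tie_groups(T, E):
    """Event indices and tied-event group structure; fixed across Newton steps.

    Returns (ev, starts, d, risk_idx): positions of events in the
    time-sorted arrays, the start offset of each tied group within ev, the
    group death counts, and the index in T where each group's risk set
    {j : T_j >= t} begins.
    """
    ev = np.flatnonzero(E == 1)
    Te = T[ev]
    changed = np.empty(len(ev), dtype=bool)
    changed[0] = True
    np.not_equal(Te[1:], Te[:-1], out=changed[1:])
    starts = np.flatnonzero(changed)
    d = np.diff(np.append(starts, len(ev)))
    risk_idx = np.searchsorted(T, Te[starts], side="left")
    return ev, starts, d, risk_idx


def _efron_ll_grad_hess(beta, X, groups):
    """Log partial likelihood, gradient, and negative Hessian (information).

    Expects rows in ascending time order with ``groups`` from
    :func:`_tie_groups`.  Tied events use Efron's within-tie averaging of
    the death set.  The value is invariant to a constant shift of the
    linear predictor, so eta is centered at its max for overflow safety.
    """
    n, p = X.shape
    ev, starts, d, risk_idx = groups
    # divergent trial steps can underflow risk sums to zero; the resulting
    # non-finite likelihood is caught by the caller's step-halving loop
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        eta = X @ beta
        eta = eta - eta.max()
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = wx[:, :, None] * X[:, None, :]  # n x p x p

        cw = _rev_cumsum(w)
        cwx = _rev_cumsum(wx)
        cwxx = _rev_cumsum(wxx)

        phiR = cw[risk_idx]
        S1R = cwx[risk_idx]
        S2R = cwxx[risk_idx]
        phiD = np.add.reduceat(w[ev], starts)
        S1D = np.add.reduceat(wx[ev], starts)
        S2D = np.add.reduceat(wxx[ev], starts)

        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0)
        hess = np.zeros((p, p))
        for l in range(int(d.max())):
            m = d > l
            frac = (l / d[m])[:, None]
            r = phiR[m] - frac[:, 0] * phiD[m]
            a = S1R[m] - frac * S1D[m]
            M = S2R[m] - frac[:, :, None] * S2D[m]
            ll -= float(np.log(r).sum())
            grad -= (a / r[:, None]).sum(axis=0)
            hess += (M / r[:, None, None]).sum(axis=0)
            hess -= np.einsum("ij,ik,i->jk", a, a, 1.0 / r**2)
    return ll, grad, hess


def _newton_cox(T, E, X, tol=1e-7, max_iter=100, presorted=False):
    """Maximize the Efron partial likelihood; returns (beta, se, ll, converged)."""
    n, p = X.shape
    if not presorted:
        order = np.argsort(T, kind="stable")
        T, E, X = T[order], E[order], X[order]
    groups = _tie_groups(T, E)
    beta = np.zeros(p)
    ll, grad, info = _efron_ll_grad_hess(beta, X, groups)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), ll, False
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _efron_ll_grad_hess(cand, X, groups)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return beta, np.full(p, np.nan), ll, False
        delta = float(np.abs(cand - beta).max())
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if delta < tol:
            converged = True
            break
    # monotone likelihood: coefficients drifting without bound, or the
    # information flattening out (huge standard errors on the standardized
    # scale the caller passes in)
    if converged and np.abs(beta).max() > 50:
        converged = False
    if not converged:
        return beta, np.full(p, np.nan), ll, False
    try:
        with np.errstate(invalid="ignore"):
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return beta, np.full(p, np.nan), ll, False
    if not np.all(np.isfinite(se)):
        return beta, np.full(p, np.nan), ll, False
    return beta, se, ll, True


def _fit_raw(T, E, X, tol=1e-7, max_iter=100, presorted=False):
    """Standardize, fit, back-transform; returns (beta, se, ll, converged).

    Lean array-level path used by the genome-wide scan; the caller is
    responsible for input validation (no constant columns, >= 2 events).
    """
    mu, sd = X.mean(axis=0), X.std(axis=0)
    beta_s, se_s, ll, converged = _newton_cox(T, E, (X - mu) / sd, tol=tol,
                                              max_iter=max_iter, presorted=presorted)
    return beta_s / sd, se_s / sd, ll, converged


def wald_p(beta, se) -> np.ndarray:
    """Two-sided normal Wald p-value, clamped to [1e-300, 1]."""
    return np.clip(2 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se))), P_FLOOR, 1.0)


def fit_cox_matrix(times, events, X, names=None, tol=1e-7, max_iter=100) -> CoxResult:
    """Fit a Cox PH model from a pre-built design matrix (no expansion).

    This is the hot path used by the genome-wide scan.  ``X`` is n x p and
    must contain no constant column (error naming the column).  At least 2
    events are required.
    """
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(T) != n or len(E) != n:
        raise SurvivalError("times, events and design matrix differ in length")
    if p == 0:
        raise SurvivalError("at least one model term required")
    if E.sum() < 2:
        raise SurvivalError("fewer than 2 events")
    ptps = X.max(axis=0) - X.min(axis=0)
    if (ptps == 0).any():
        const = names[int(np.argmax(ptps == 0))]
        raise SurvivalError(f"covariate {const!r} is constant across samples")
    # standardized internally for numerical conditioning, back-transformed after
    beta, se, ll, converged = _fit_raw(T, E, X, tol=tol, max_iter=max_iter)
    # monotone likelihood in any term (quasi-separation): the information
    # flattens and the standardized standard error blows up
    if converged and (se * X.std(axis=0)).max() > 50:
        converged = False
        beta = se = np.full(p, np.nan)
    if converged:
        pvals = wald_p(beta, se)
        with np.errstate(over="ignore"):
            hr, ci_lo, ci_hi = np.exp(beta), np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)
        summary = pd.DataFrame(
            {
                "coef": beta,
                "hr": hr,
                "ci95_low": ci_lo,
                "ci95_high": ci_hi,
                "se": se,
                "p": pvals,
            },
            index=pd.Index(names, name="term"),
        )
    else:
        summary = pd.DataFrame(
            np.full((p, 6), np.nan),
            columns=["coef", "hr", "ci95_low", "ci95_high", "se", "p"],
            index=pd.Index(names, name="term"),
        )
    return CoxResult(summary, n_samples=n, n_events=int(E.sum()), converged=bool(converged),
                     log_partial_likelihood=float(ll))


def expand_terms(terms: list[Term], n: int) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix, expanding categoricals to indicator contrasts."""
    cols, names = [], []
    for t in terms:
        v = np.asarray(pd.Series(t.values).to_numpy())
        if len(v) != n:
            raise SurvivalError(f"term {t.name!r} has length {len(v)}, expected {n}")
        if t.kind == "continuous":
            v = v.astype(float)
            if np.isnan(v).any():
                raise SurvivalError(f"term {t.name!r} contains missing values")
            cols.append(v)
            names.append(t.name)
        else:
            levels = pd.unique(pd.Series(v).astype(str))
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise SurvivalError(f"term {t.name!r}: reference level {ref!r} absent from data")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((pd.Series(v).astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{t.name}[{lev}]")
    if not cols:
        raise SurvivalError("no model columns after expansion")
    return np.column_stack(cols), names


def fit_cox(times, events, terms: list[Term], tol=1e-7, max_iter=100) -> CoxResult:
    """Fit a multivariable Cox PH model from a term specification.

    Continuous terms enter as-is; categorical terms are expanded to
    indicators against their declared reference level.  Ties use Efron's
    method; inference is the Wald test per coefficient.
    """
    T = np.asarray(times, dtype=float)
    X, names = expand_terms(terms, len(T))
    return fit_cox_matrix(T, events, X, names=names, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Logrank, Kaplan-Meier, distribution comparison
# ---------------------------------------------------------------------------

def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Unweighted k-group logrank test; returns (chi_square, p_value)."""
    g = pd.Series(group_labels).astype(str).to_numpy()
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise SurvivalError("logrank test requires at least 2 non-empty groups")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events, int))
    return float(res.test_statistic), float(max(res.p_value, P_FLOOR))


def km_estimate(times, events, group_labels=None) -> KMEstimate:
    """Kaplan-Meier product-limit estimate, overall or per group."""
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    if len(T) == 0:
        raise SurvivalError("empty input")
    if group_labels is None:
        groups = {"all": np.ones(len(T), dtype=bool)}
    else:
        g = pd.Series(group_labels).astype(str).to_numpy()
        groups = {lab: g == lab for lab in pd.unique(g)}
    out = {}
    for lab, mask in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(T[mask], E[mask])
        tbl = kmf.event_table
        surv = kmf.survival_function_
        out[lab] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return KMEstimate(groups=out)


def compare_distributions(x, y, alpha: float = 0.05) -> tuple[str, float, float]:
    """Two-sample location comparison with a normality-gated test choice.

    Shapiro-Wilk is run on each sample at the given alpha; if both pass, a
    two-sided two-sample t-test is used, otherwise the two-sided
    Mann-Whitney rank-sum test.  Returns (test_name, statistic, p_value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise SurvivalError("each sample must have length >= 3")
    normal = True
    for v in (x, y):
        if np.ptp(v) == 0:  # Shapiro undefined for constant input; clearly non-normal branch
            normal = False
            continue
        if stats.shapiro(v).pvalue < alpha:
            normal = False
    if normal:
        res = stats.ttest_ind(x, y)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "Mann-Whitney", float(res.statistic), float(res.pvalue)
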