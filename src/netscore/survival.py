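"""Self-contained survival-analysis engine.

Cox proportional hazards (Newton-Raphson on the Breslow partial
likelihood), the Kaplan-Meier product-limit estimator, the K-sample
log-rank test, Harrell's concordance index, and median dichotomization.

All routines take survival data as a pandas DataFrame with columns
``time`` (positive, months) and ``event`` (1 = event, 0 = censored),
indexed by sample id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxResult",
    "KMCurve",
    "ConcordanceResult",
    "cox_fit",
    "cox_loglik",
    "kaplan_meier",
    "logrank_test",
    "concordance_index",
    "dichotomize_by_median",
]


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximization fails."""


@dataclass
class CoxResult:
    """Fitted Cox proportional-hazards model.

    Per covariate: log-hazard coefficient, hazard ratio ``exp(beta)``,
    Wald 95% CI on the hazard-ratio scale, Wald z and p. ``loglik`` is
    the log partial likelihood at the optimum (Breslow ties).
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    converged: bool

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def _validate_survival(survival: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=float)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValueError("event indicator must be 0 or 1")
    return time, event


def _breslow_quantities(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray):
    """Log partial likelihood, gradient and Hessian under Breslow ties.

    Samples are processed sorted by decreasing time so that risk sets are
    running sums; tied times share one risk-set boundary.
    """
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta_shift = eta - eta.max()  # overflow guard; shift cancels in all ratios
    theta = np.exp(eta_shift)

    S0 = np.cumsum(theta)
    S1 = np.cumsum(theta[:, None] * Xs, axis=0)
    S2 = np.cumsum(theta[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    # risk set of sample i = all j with t_j >= t_i: with descending sort this
    # is the prefix ending at the LAST index whose time equals t_i
    last = np.searchsorted(-ts, -ts, side="right") - 1

    ev = es == 1.0
    idx = last[ev]
    s0 = S0[idx]
    loglik = float(np.sum(eta_shift[ev] - np.log(s0)))
    xbar = S1[idx] / s0[:, None]
    grad = np.sum(Xs[ev] - xbar, axis=0)
    hess = -np.sum(S2[idx] / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :], axis=0)
    return loglik, grad, hess


def cox_loglik(X: np.ndarray, survival: pd.DataFrame, beta: np.ndarray) -> float:
    """Breslow log partial likelihood at an arbitrary coefficient vector."""
    time, event = _validate_survival(survival)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    ll, _, _ = _breslow_quantities(X, time, event, np.asarray(beta, dtype=float))
    return ll


def cox_fit(
    design: pd.DataFrame | np.ndarray,
    survival: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Parameters
    ----------
    design
        Samples x covariates. A DataFrame supplies covariate names;
        categorical columns are expanded to reference-coded indicators
        with the most frequent level as reference.
    survival
        DataFrame with ``time`` and ``event`` columns aligned to the
        design rows.

    Raises
    ------
    ValueError
        On constant covariates, missing values, or zero events.
    ConvergenceError
        On monotone likelihood (coefficients diverging, e.g. perfect
        separation) or failure to converge within ``max_iter``.
    """
    if isinstance(design, pd.DataFrame):
        design = _expand_categoricals(design)
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]

    time, event = _validate_survival(survival)
    if X.shape[0] != len(time):
        raise ValueError("design and survival have different numbers of samples")
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant covariate(s): {bad}")

    p = X.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _breslow_quantities(X, time, event, beta)
    ll_prev = ll_null
    converged = False
    for it in range(1, max_iter + 1):
        ll, grad, hess = _breslow_quantities(X, time, event, beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        # step-halving keeps the likelihood monotone
        new_beta = beta - step
        ll_new, _, _ = _breslow_quantities(X, time, event, new_beta)
        halvings = 0
        while ll_new < ll and halvings < 10:
            step *= 0.5
            new_beta = beta - step
            ll_new, _, _ = _breslow_quantities(X, time, event, new_beta)
            halvings += 1
        beta = new_beta
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation?)"
            )
        if abs(ll_new - ll_prev) < tol and np.max(np.abs(grad)) < np.sqrt(tol):
            converged = True
            ll_prev = ll_new
            break
        ll_prev = ll_new
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    # monotone likelihood: a coefficient spanning > ~10 log-hazard units
    # across one SD of its covariate means the optimum ran to infinity
    if np.any(np.abs(beta) * sd > 10.0):
        bad = [names[i] for i in np.flatnonzero(np.abs(beta) * sd > 10.0)]
        raise ConvergenceError(
            f"monotone likelihood (perfect separation?) in covariate(s) {bad}"
        )

    ll_final, _, hess = _breslow_quantities(X, time, event, beta)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxResult(
        names=names,
        coef=beta,
        se=se,
        loglik=ll_final,
        loglik_null=ll_null,
        n=len(time),
        n_events=n_events,
        n_iter=it,
        converged=converged,
    )


def _expand_categoricals(design: pd.DataFrame) -> pd.DataFrame:
    """Reference-code non-numeric columns; reference = most frequent level."""
    out = {}
    for col in design.columns:
        s = design[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            counts = s.value_counts()
            ref = counts.index[0]
            for level in counts.index[1:]:
                out[f"{col}[{level}]"] = (s == level).astype(float)
    return pd.DataFrame(out, index=design.index)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray  # events at each time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.n_events}
        )


def kaplan_meier(survival: pd.DataFrame) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    time, event = _validate_survival(survival)
    if len(time) == 0:
        raise ValueError("empty survival table")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1.0])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for tt in ev_times:
        n_i = int(np.sum(t >= tt))
        d_i = int(np.sum((t == tt) & (e == 1.0)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        times=ev_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        censor_times=np.sort(t[e == 0.0]),
    )


def logrank_test(groups: np.ndarray | pd.Series, survival: pd.DataFrame):
    """K-sample log-rank test.

    Sums observed-minus-expected events per group over distinct event
    times, with the hypergeometric covariance; the statistic is the
    quadratic form over K-1 groups, chi-square with K-1 df.

    Returns
    -------
    (chi2, df, p)
    """
    time, event = _validate_survival(survival)
    groups = np.asarray(groups)
    if len(groups) != len(time):
        raise ValueError("group labels and survival table differ in length")
    labels, g = np.unique(groups, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least 2 non-empty groups")

    ev_times = np.unique(time[event == 1.0])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for tt in ev_times:
        at_risk = time >= tt
        n_t = int(at_risk.sum())
        d_t = int(((time == tt) & (event == 1.0)).sum())
        if n_t <= 1:
            continue
        n_k = np.bincount(g[at_risk], minlength=K).astype(float)
        d_k = np.bincount(g[(time == tt) & (event == 1.0)], minlength=K).astype(float)
        O += d_k
        E += d_t * n_k / n_t
        frac = n_k / n_t
        mult = d_t * (n_t - d_t) / (n_t - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(diff, 0):
        chi2 = 0.0
    else:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    df = K - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class ConcordanceResult:
    c_index: float
    se: float
    n_pairs: int


def _c_from_arrays(score, time, event) -> tuple[float, int]:
    # comparable pair: the strictly smaller time had the event;
    # tied event times are not comparable
    ti = time[:, None]
    tj = time[None, :]
    comparable = (ti < tj) & (event[:, None] == 1.0)
    si = score[:, None]
    sj = score[None, :]
    conc = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return float(conc[comparable].sum() / n_pairs), n_pairs


def concordance_index(
    score: np.ndarray | pd.Series,
    survival: pd.DataFrame,
    *,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ConcordanceResult:
    """Harrell's C: fraction of comparable pairs where the higher score
    fails first. Tied scores count 0.5. SE by seeded bootstrap over samples.
    """
    time, event = _validate_survival(survival)
    score = np.asarray(score, dtype=float)
    if len(score) != len(time):
        raise ValueError("score and survival table differ in length")
    c, n_pairs = _c_from_arrays(score, time, event)

    se = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(time)
        cs = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                cb, _ = _c_from_arrays(score[idx], time[idx], event[idx])
            except ValueError:
                continue
            cs.append(cb)
        if len(cs) > 1:
            se = float(np.std(cs, ddof=1))
    return ConcordanceResult(c_index=c, se=se, n_pairs=n_pairs)


def dichotomize_by_median(score: pd.Series | np.ndarray) -> pd.Series:
    """Split scores at the within-cohort median: > median -> "high",
    <= median -> "low". Degenerate (all-equal) scores are an error."""
    s = pd.Series(score) if not isinstance(score, pd.Series) else score
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    if s.nunique() == 1:
        raise ValueError("all scores identical: degenerate median split")
    med = float(s.median())
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="risk_group")
    if (labels == "high").sum() == 0:
        warnings.warn("median split produced an empty high-risk group")
    return labels
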