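"""Core survival estimators: Kaplan-Meier, log-rank, Cox PH, baseline tests.

These are the building blocks the whole failure-timing pipeline reuses. The
Cox model is fit by damped Newton iteration on the partial likelihood (Efron
tie handling by default, Breslow optional) so that the log-rank statistic,
the score test and the scan machinery all share one set of conventions:
right-censored times, censored observations remaining at risk at their own
time, and events preceding censorings at tied times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) right-continuous, S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly ascending")


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-D sequences")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator.

    Subjects censored at t remain in the risk set for the event at t
    (events before censorings at ties).
    """
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float), minlength=uniq.size)
    removed = np.bincount(inv, minlength=uniq.size)
    n_risk = t.size - np.concatenate([[0], np.cumsum(removed)[:-1]])
    has_event = d > 0
    ev_t, ev_d, ev_n = uniq[has_event], d[has_event], n_risk[has_event]
    surv = np.cumprod(1.0 - ev_d / ev_n)
    return KMCurve(event_times=ev_t, survival=surv,
                   at_risk=ev_n.astype(int), n_events=ev_d.astype(int))


def survival_at(curve: KMCurve, t) -> np.ndarray | float:
    """Right-continuous step-function lookup; S(t) = 1 before the first event."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.event_times, t_arr, side="right")
    s = np.concatenate([[1.0], curve.survival])[idx]
    return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s


def nelson_aalen(times, events):
    """Cumulative-hazard step function: (event_times, H) with H = sum d_i/n_i."""
    curve = km_estimate(times, events)
    increments = curve.n_events / curve.at_risk
    return curve.event_times, np.cumsum(increments)


# ---------------------------------------------------------------------------
# log-rank


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(*groups) -> LogRankResult:
    """K-sample log-rank test with hypergeometric variance at ties.

    ``groups``: two or more (times, events) pairs. With zero events in
    total the statistic is 0 and p = 1 by convention.
    """
    if len(groups) == 1:  # allow a single sequence of pairs
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    parsed = [_check_times_events(t, e) for t, e in groups]
    k = len(parsed)
    times = np.concatenate([t for t, _ in parsed])
    events = np.concatenate([e for _, e in parsed])
    labels = np.concatenate([np.full(t.size, g) for g, (t, _) in enumerate(parsed)])

    if events.sum() == 0:
        return LogRankResult(0.0, k - 1, 1.0, np.zeros(k), np.zeros(k))

    order = np.argsort(times, kind="stable")
    times, events, labels = times[order], events[order], labels[order]
    uniq, inv = np.unique(times, return_inverse=True)
    m = uniq.size
    # per unique time: deaths and removals per group
    d_g = np.zeros((m, k))
    r_g = np.zeros((m, k))
    np.add.at(d_g, (inv, labels), events.astype(float))
    np.add.at(r_g, (inv, labels), 1.0)
    n_g = r_g[::-1].cumsum(axis=0)[::-1]  # at risk per group at each time
    n_tot = n_g.sum(axis=1)
    d_tot = d_g.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d_tot[:, None] * n_g / n_tot[:, None]
        frac = n_g / n_tot[:, None]
        mult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
        # covariance of the group event counts at each time
        cov_t = mult[:, None, None] * (
            np.einsum("ti,ij->tij", frac, np.eye(k))
            - np.einsum("ti,tj->tij", frac, frac)
        )
    observed = d_g.sum(axis=0)
    exp_tot = np.nan_to_num(expected).sum(axis=0)
    U = observed - exp_tot
    V = cov_t.sum(axis=0)
    Vr = V[:-1, :-1]
    try:
        chi2 = float(U[:-1] @ np.linalg.solve(Vr, U[:-1]))
    except np.linalg.LinAlgError:
        chi2 = float(U[:-1] @ np.linalg.pinv(Vr) @ U[:-1])
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p, observed, exp_tot)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Result container mirroring a multivariable hazard-ratio table."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_value: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties_method: str
    converged: bool
    n_iter: int
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_value,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _cox_loglik_derivs(beta, X, times, events, ties):
    """Negative log partial likelihood, gradient and Hessian.

    Subjects sorted by descending time; tied event times handled by the
    Efron or Breslow approximation.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # running risk-set sums (descending time order assumed)
    S0 = np.cumsum(w)
    S1 = np.cumsum(wx, axis=0)
    S2 = np.cumsum(wxx, axis=0)

    # tie groups of equal time (descending order): risk set for an event is
    # everything up to and including the last member of its own group
    uniq, first = np.unique(-times, return_index=True)
    last = np.append(first[1:], n) - 1
    group = np.searchsorted(first, np.arange(n), side="right") - 1
    d_per_group = np.bincount(group, weights=events.astype(float),
                              minlength=uniq.size)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    # vectorised path: groups with a single event (Efron == Breslow there)
    single = d_per_group[group] == 1
    ev1 = events & single
    if ev1.any():
        idx = last[group[ev1]]
        s0 = S0[idx]
        s1 = S1[idx]
        loglik += float(eta[ev1].sum() - np.log(s0).sum())
        ratio = s1 / s0[:, None]
        grad += X[ev1].sum(axis=0) - ratio.sum(axis=0)
        hess += np.einsum("ijk,i->jk", S2[idx], 1.0 / s0)
        hess -= np.einsum("ij,ik->jk", ratio, ratio)

    # general path: tied event times
    for g in np.nonzero(d_per_group >= 2)[0]:
        tie = slice(first[g], last[g] + 1)
        ev = events[tie]
        d = int(d_per_group[g])
        Xd = X[tie][ev]
        wd = w[tie][ev]
        s0, s1, s2 = S0[last[g]], S1[last[g]], S2[last[g]]
        loglik += eta[tie][ev].sum()
        if ties == "breslow":
            loglik -= d * np.log(s0)
            grad += Xd.sum(axis=0) - d * s1 / s0
            hess += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            wd_sum = wd.sum()
            wdx_sum = (wd[:, None] * Xd).sum(axis=0)
            wdxx_sum = np.einsum("i,ij,ik->jk", wd, Xd, Xd)
            for r in range(d):
                f = r / d
                s0r = s0 - f * wd_sum
                s1r = s1 - f * wdx_sum
                s2r = s2 - f * wdxx_sum
                loglik -= np.log(s0r)
                grad += -s1r / s0r
                hess += s2r / s0r - np.outer(s1r, s1r) / s0r**2
            grad += Xd.sum(axis=0)
    return -loglik, -grad, hess


class CoxPHModel(BaseEstimator):
    """Cox proportional-hazards regression via damped Newton iteration.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie-handling approximation for the partial likelihood.
    alpha : float
        Two-sided level for the Wald confidence intervals (default 0.05,
        i.e. 95% CIs).
    tol : float
        Convergence tolerance on the gradient max-norm.

    Fitted attributes (trailing underscore): ``coef_``, ``se_``,
    ``hazard_ratios_``, ``p_values_``, ``conf_int_``, ``loglik_``,
    ``converged_``, ``nll_path_`` (damped Newton guarantees this path is
    non-increasing), and ``result_`` (a :class:`CoxFit`).
    """

    def __init__(self, ties: str = "efron", alpha: float = 0.05,
                 max_iter: int = 100, tol: float = 1e-8):
        self.ties = ties
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, durations, events):
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            names = [f"x{i}" for i in range(Xv.shape[1])]
        t, e = _check_times_events(durations, events)
        if Xv.shape[0] != t.size:
            raise ValueError("X and durations disagree in length")
        if e.sum() == 0:
            raise ValueError("Cox model requires at least one event")
        if np.any(np.ptp(Xv, axis=0) == 0):
            warnings.warn("constant covariate column in Cox fit", stacklevel=2)

        order = np.argsort(-t, kind="stable")
        Xs, ts, es = Xv[order], t[order], e[order]

        p = Xs.shape[1]
        beta = np.zeros(p)
        nll, grad, hess = _cox_loglik_derivs(beta, Xs, ts, es, self.ties)
        path = [nll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # step-halving: never accept an increase of the negative loglik
            scale = 1.0
            for _ in range(30):
                cand = beta - scale * step
                nll_new, grad_new, hess_new = _cox_loglik_derivs(
                    cand, Xs, ts, es, self.ties)
                if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                    break
                scale /= 2.0
            else:
                break
            beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
            path.append(nll)
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("Cox fit did not converge (possible separation); "
                          "inspect result_.converged", stacklevel=2)

        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        z = stats.norm.ppf(1 - self.alpha / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals = 2 * stats.norm.sf(np.abs(beta / np.where(se > 0, se, np.nan)))
        pvals = np.where(np.isnan(pvals), 1.0, pvals)

        self.feature_names_ = names
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        self.hazard_ratios_ = np.exp(beta)
        with np.errstate(over="ignore"):  # separated fits: CI bound -> inf
            self.conf_int_ = np.column_stack([np.exp(beta - z * se),
                                              np.exp(beta + z * se)])
        self.p_values_ = pvals
        self.loglik_ = -nll
        self.converged_ = converged
        self.nll_path_ = np.asarray(path)
        self.result_ = CoxFit(
            names=names, coef=beta, se=se, hazard_ratio=np.exp(beta),
            ci_lower=self.conf_int_[:, 0], ci_upper=self.conf_int_[:, 1],
            p_value=pvals, loglik=-nll, n=t.size, n_events=int(e.sum()),
            ties_method=self.ties, converged=converged, n_iter=it,
        )
        return self

    def predict_partial_hazard(self, X):
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return np.exp(Xv @ self.coef_)

    def score_test(self, X, durations, events) -> tuple[float, float]:
        """Score (log-rank-type) test at beta = 0."""
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        t, e = _check_times_events(durations, events)
        order = np.argsort(-t, kind="stable")
        _, grad, hess = _cox_loglik_derivs(
            np.zeros(Xv.shape[1]), Xv[order], t[order], e[order], self.ties)
        U = -grad
        chi2 = float(U @ np.linalg.solve(hess, U))
        return chi2, float(stats.chi2.sf(chi2, Xv.shape[1]))


def cox_fit(X, durations, events, ties: str = "efron") -> CoxFit:
    """Functional wrapper over :class:`CoxPHModel`."""
    return CoxPHModel(ties=ties).fit(X, durations, events).result_


class BackwardEliminatedCox(BaseEstimator):
    """Univariable screening followed by backward elimination.

    Candidates are first screened by univariable Wald P < ``screen_alpha``
    (0.10); the survivors enter one multivariable model from which the
    largest-P covariate is removed until every retained covariate has
    Wald P < ``stay_alpha`` (0.05). ``elimination_trace_`` records every
    removal (screening and elimination) with the P value at removal.
    """

    def __init__(self, screen_alpha: float = 0.10, stay_alpha: float = 0.05,
                 ties: str = "efron"):
        self.screen_alpha = screen_alpha
        self.stay_alpha = stay_alpha
        self.ties = ties

    def fit(self, X: pd.DataFrame, durations, events):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in X.columns]
        if X.shape[1] == 0:
            raise ValueError("candidate covariate set is empty")
        trace: list[tuple[str, float]] = []
        survivors: list[str] = []
        for col in X.columns:
            uni = cox_fit(X[[col]], durations, events, ties=self.ties)
            if uni.p_value[0] < self.screen_alpha:
                survivors.append(col)
            else:
                trace.append((str(col), float(uni.p_value[0])))

        fit = None
        while survivors:
            fit = cox_fit(X[survivors], durations, events, ties=self.ties)
            worst = int(np.argmax(fit.p_value))
            if fit.p_value[worst] < self.stay_alpha:
                break
            trace.append((survivors[worst], float(fit.p_value[worst])))
            survivors.pop(worst)
            fit = None

        self.retained_ = list(survivors)
        self.elimination_trace_ = trace
        if survivors:
            self.result_ = fit if fit is not None else cox_fit(
                X[survivors], durations, events, ties=self.ties)
            self.result_.elimination_trace = trace
        else:
            self.result_ = CoxFit(
                names=[], coef=np.array([]), se=np.array([]),
                hazard_ratio=np.array([]), ci_lower=np.array([]),
                ci_upper=np.array([]), p_value=np.array([]), loglik=np.nan,
                n=len(np.asarray(durations)), n_events=int(np.sum(events)),
                ties_method=self.ties, converged=True, n_iter=0,
                elimination_trace=trace)
        return self


def backward_eliminate(X, durations, events, screen_alpha: float = 0.10,
                       stay_alpha: float = 0.05, ties: str = "efron") -> CoxFit:
    est = BackwardEliminatedCox(screen_alpha=screen_alpha,
                                stay_alpha=stay_alpha, ties=ties)
    return est.fit(X, durations, events).result_


# ---------------------------------------------------------------------------
# baseline-table contingency tests


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p_value: float
    method: str


def contingency_test(table) -> ContingencyResult:
    """Chi-square test of independence; Fisher's exact for sparse 2x2 tables.

    Switches to Fisher's exact test when the table is 2x2 and any expected
    count falls below 5. Zero row/column margins are rejected.
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.number):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    expected = stats.contingency.expected_freq(tab)
    if tab.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(tab)
        return ContingencyResult(float(odds), float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return ContingencyResult(float(chi2), float(p), "chi-square")


# ---------------------------------------------------------------------------
# endpoint derivation


ENDPOINT_COLUMNS = [
    "patient_id",
    "os_time", "os_event",
    "ffs_time", "ffs_event",
    "lrffs_time", "lrffs_event",
    "dffs_time", "dffs_event",
    "pf_lrf_time", "pf_lrf_event",
    "pf_df_time", "pf_df_event",
]


def derive_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Derive OS / FFS / LRFFS / DFFS / post-failure OS per patient.

    All clocks start at treatment initiation. Deaths without the relevant
    failure censor LRFFS/DFFS at death or last contact (no competing-risk
    estimator — a known optimistic bias, matching conventional KM/Cox use).
    Post-failure OS (``pf_*``) is OS time minus the failure time and is NaN
    for patients without that failure; for patients with both failure types
    each post-failure clock starts at its own failure.
    """
    required = ["t_locoregional", "locoregional_event", "t_distant",
                "distant_event", "t_death_or_lastcontact", "death"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns: {missing}")
    bad: list[str] = []
    ids = records["patient_id"].astype(str) if "patient_id" in records else \
        pd.Series([str(i) for i in records.index], index=records.index)
    tl = pd.to_numeric(records["t_locoregional"], errors="coerce")
    td = pd.to_numeric(records["t_distant"], errors="coerce")
    to = pd.to_numeric(records["t_death_or_lastcontact"], errors="coerce")
    for name, col in (("t_locoregional", tl), ("t_distant", td),
                      ("t_death_or_lastcontact", to)):
        mask = col.isna() | (col < 0)
        bad.extend(f"{ids[i]}: invalid {name}" for i in records.index[mask])
    el = records["locoregional_event"].astype(bool)
    ed = records["distant_event"].astype(bool)
    dead = records["death"].astype(bool)
    for flag, tcol, name in ((el, tl, "locoregional"), (ed, td, "distant")):
        mask = flag & (tcol > to + 1e-9)
        bad.extend(f"{ids[i]}: {name} failure after last contact"
                   for i in records.index[mask])
    if bad:
        raise ValueError("invalid patient records: " + "; ".join(bad[:20]))

    out = pd.DataFrame(index=records.index)
    out["patient_id"] = ids
    out["os_time"], out["os_event"] = to, dead.astype(int)
    out["lrffs_time"], out["lrffs_event"] = tl, el.astype(int)
    out["dffs_time"], out["dffs_event"] = td, ed.astype(int)
    ffs_time = np.minimum(np.minimum(tl, td), to)
    ffs_event = el | ed | dead
    out["ffs_time"], out["ffs_event"] = ffs_time, ffs_event.astype(int)
    out["pf_lrf_time"] = np.where(el, to - tl, np.nan)
    out["pf_lrf_event"] = np.where(el, dead.astype(int), np.nan)
    out["pf_df_time"] = np.where(ed, to - td, np.nan)
    out["pf_df_event"] = np.where(ed, dead.astype(int), np.nan)
    return out[ENDPOINT_COLUMNS]
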