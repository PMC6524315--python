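"""Survival estimators for the risk-group validation.

Kaplan-Meier curves (with delayed entry at the 6-month inclusion threshold)
are delegated to lifelines.  The Cox proportional-hazards machinery is
implemented here directly because the validation needs a combination no
single installed library exposes: Breslow tie handling, left truncation,
the Breslow baseline survival at the reference covariate pattern, and a
cluster-robust (nephrology-unit) sandwich covariance.

Event times stay on the enrolment clock; delayed entry is handled by
truncating risk sets at the entry time, never by shifting the time origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import FollowUp

__all__ = [
    "ENTRY_TIME",
    "SurvivalCurve",
    "CoxFit",
    "ConvergenceError",
    "km_curve",
    "km_risk_at",
    "fit_cox",
    "predict_node_survival",
    "information_criteria",
]

#: Default delayed-entry time (years): the cohorts' minimum follow-up.
ENTRY_TIME = 0.5


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (or likelihood is monotone)."""


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function with at-risk bookkeeping.

    ``survival[i]`` is the value on ``[times[i], times[i+1])``; before
    ``times[0]`` (and at the entry time) survival is 1.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray | None = None
    n_events: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    entry_time: float = ENTRY_TIME
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.size and (
            self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12
        ):
            raise ValueError("survival must lie in [0, 1]")

    def _step_index(self, t: float) -> int:
        return int(np.searchsorted(self.times, t, side="right")) - 1

    def survival_at(self, t: float) -> float:
        """S(t): value of the last step at or before ``t`` (1 before any)."""
        i = self._step_index(t)
        return 1.0 if i < 0 else float(self.survival[i])

    def risk_at(self, t: float) -> float:
        if t < self.entry_time:
            raise ValueError(f"t={t} precedes the entry time {self.entry_time}")
        return 1.0 - self.survival_at(t)

    def ci_at(self, t: float) -> tuple[float, float]:
        if self.ci_lower is None or self.ci_upper is None:
            raise ValueError("curve carries no confidence band")
        i = self._step_index(t)
        if i < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[i]), float(self.ci_upper[i])

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "survival": self.survival}
        for name, arr in (
            ("n_at_risk", self.n_at_risk),
            ("n_events", self.n_events),
            ("ci_lower", self.ci_lower),
            ("ci_upper", self.ci_upper),
        ):
            if arr is not None:
                data[name] = arr
        return pd.DataFrame(data)

    def to_json(self) -> str:
        return self.to_frame().to_json(orient="records")


def km_curve(
    followups: Iterable[FollowUp],
    event_of_interest: str,
    entry_time: float = ENTRY_TIME,
    label: str = "",
) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve for one cause.

    Any other terminal event is censored at its time (the competing outcome is
    handled by censoring, as in the cause-specific analyses; the cumulative-
    incidence machinery is the corrective companion).  Risk sets start at
    ``entry_time``.  Confidence band: Greenwood variance on the log(-log S)
    scale (exponential Greenwood), lifelines' default.
    """
    fus = list(followups)
    durations = np.array([f.time for f in fus])
    events = np.array([f.event == event_of_interest for f in fus], dtype=int)
    if durations.size == 0 or not np.any(durations > entry_time):
        raise ValueError("no subjects at risk after the entry time")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations,
        events,
        entry=np.full(durations.size, entry_time),
        label=label or event_of_interest,
    )
    table = kmf.event_table
    times = np.asarray(table.index, dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    return SurvivalCurve(
        times=times,
        survival=surv,
        n_at_risk=table["at_risk"].to_numpy(),
        n_events=table["observed"].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        entry_time=entry_time,
        label=label or event_of_interest,
    )


def km_risk_at(curve: SurvivalCurve, t: float) -> float:
    """Cumulative failure probability 1 - S(t) read off the step curve."""
    return curve.risk_at(t)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, covariances, baseline survival, fit indices."""

    coefficients: pd.Series  # log-hazard scale
    model_covariance: pd.DataFrame
    robust_covariance: pd.DataFrame
    baseline_survival: SurvivalCurve
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    entry_time: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("HR")

    @property
    def df(self) -> int:
        return len(self.coefficients)

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.robust_covariance)), index=self.coefficients.index
        )

    @property
    def model_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.model_covariance)), index=self.coefficients.index
        )

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df

    @property
    def bic(self) -> float:
        # events-based sample size, the survival-analysis convention
        return -2.0 * self.loglik + np.log(self.n_events) * self.df

    def confint(self, robust: bool = True, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.robust_se if robust else self.model_se
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "hr_lower": np.exp(self.coefficients - z * se),
                "hr_upper": np.exp(self.coefficients + z * se),
            }
        )

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.robust_se
        z = self.coefficients / se
        out = pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "robust_se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )
        return out.join(self.confint())

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.to_dict(),
                "hazard_ratios": self.hazard_ratios.to_dict(),
                "robust_se": self.robust_se.to_dict(),
                "loglik": self.loglik,
                "n": self.n,
                "n_events": self.n_events,
                "aic": self.aic,
                "bic": self.bic,
                "ties": self.ties,
            }
        )


def _risk_tail_sums(t_sorted, e_sorted, vals_t, vals_e, u):
    """Sum of vals over the risk set R(u) = {j: e_j < u <= t_j} for each u.

    ``vals_t``/``vals_e`` are the per-subject values ordered by time and by
    entry respectively; suffix sums give each tail in O(log n).
    """
    suf_t = np.concatenate([np.cumsum(vals_t[::-1], axis=0)[::-1], np.zeros((1,) + vals_t.shape[1:])])
    suf_e = np.concatenate([np.cumsum(vals_e[::-1], axis=0)[::-1], np.zeros((1,) + vals_e.shape[1:])])
    it = np.searchsorted(t_sorted, u, side="left")
    ie = np.searchsorted(e_sorted, u, side="left")
    return suf_t[it] - suf_e[ie]


class _CoxData:
    """Pre-sorted design for partial-likelihood evaluation."""

    def __init__(self, time, event, X, entry):
        self.time = np.asarray(time, float)
        self.event = np.asarray(event, bool)
        self.X = np.asarray(X, float)
        self.entry = np.asarray(entry, float)
        self.n, self.p = self.X.shape
        self.ot = np.argsort(self.time, kind="stable")
        self.oe = np.argsort(self.entry, kind="stable")
        self.t_sorted = self.time[self.ot]
        self.e_sorted = self.entry[self.oe]
        ev_times = self.time[self.event]
        self.u, self.tie_first = np.unique(ev_times, return_index=True)
        # per unique event time: count and sum of covariates over tied events
        self.d = np.zeros(self.u.size)
        self.sx = np.zeros((self.u.size, self.p))
        idx = np.searchsorted(self.u, self.time[self.event])
        np.add.at(self.d, idx, 1.0)
        np.add.at(self.sx, idx, self.X[self.event])
        # covariate sums of tied events are needed for Efron adjustments
        self.tie_rows = [np.flatnonzero(self.event & (self.time == uk)) for uk in self.u]

    def risk_sums(self, r):
        """S0 (m,), S1 (m,p), S2 (m,p,p) over risk sets at each event time."""
        X = self.X
        rX = r[:, None] * X
        rXX = rX[:, :, None] * X[:, None, :]
        S0 = _risk_tail_sums(self.t_sorted, self.e_sorted, r[self.ot, None], r[self.oe, None], self.u)[:, 0]
        S1 = _risk_tail_sums(self.t_sorted, self.e_sorted, rX[self.ot], rX[self.oe], self.u)
        S2 = _risk_tail_sums(self.t_sorted, self.e_sorted, rXX[self.ot], rXX[self.oe], self.u)
        return S0, S1, S2


def _breslow_quantities(data: _CoxData, beta):
    r = np.exp(np.clip(data.X @ beta, -500, 500))
    S0, S1, S2 = data.risk_sums(r)
    if np.any(S0 <= 0):
        raise ConvergenceError("empty risk set at an event time")
    m = S1 / S0[:, None]
    ll = float(np.sum(data.sx @ beta) - np.sum(data.d * np.log(S0)))
    score = np.sum(data.sx - data.d[:, None] * m, axis=0)
    info = np.einsum(
        "k,kij->ij", data.d, S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :]
    )
    return ll, score, info, r, S0, S1, m


def _efron_quantities(data: _CoxData, beta):
    r = np.exp(np.clip(data.X @ beta, -500, 500))
    S0, S1, S2 = data.risk_sums(r)
    ll = float(np.sum(data.sx @ beta))
    score = data.sx.sum(axis=0)
    info = np.zeros((data.p, data.p))
    for k in range(data.u.size):
        rows = data.tie_rows[k]
        dk = rows.size
        r_t = r[rows]
        s0t, s1t = r_t.sum(), (r_t[:, None] * data.X[rows]).sum(axis=0)
        s2t = np.einsum("i,ij,ik->jk", r_t, data.X[rows], data.X[rows])
        frac = np.arange(dk) / dk
        a0 = S0[k] - frac * s0t
        a1 = S1[k][None, :] - frac[:, None] * s1t[None, :]
        a2 = S2[k][None, :, :] - frac[:, None, None] * s2t[None, :, :]
        ll -= float(np.sum(np.log(a0)))
        mk = a1 / a0[:, None]
        score -= mk.sum(axis=0)
        info += np.sum(
            a2 / a0[:, None, None] - mk[:, :, None] * mk[:, None, :], axis=0
        )
    return ll, score, info, r, S0, S1, S1 / S0[:, None]


def _score_residuals(data: _CoxData, r, S0, m):
    """Per-subject score residuals (Breslow form) for the sandwich meat."""
    a = data.d / S0  # (m,)
    b = a[:, None] * m  # (m,p)
    A = np.concatenate([[0.0], np.cumsum(a)])
    B = np.vstack([np.zeros(data.p), np.cumsum(b, axis=0)])
    # prefix over event times u_k <= t
    i_t = np.searchsorted(data.u, data.time, side="right")
    i_e = np.searchsorted(data.u, data.entry, side="right")
    dA = A[i_t] - A[i_e]
    dB = B[i_t] - B[i_e]
    U = -r[:, None] * (data.X * dA[:, None] - dB)
    ev = data.event
    k_idx = np.searchsorted(data.u, data.time[ev])
    U[ev] += data.X[ev] - m[k_idx]
    return U


def fit_cox(
    data: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    cluster_col: str | None = None,
    entry_time: float = ENTRY_TIME,
    entry_col: str | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    ``event_col`` must be 0/1 for the event of interest (competing outcomes
    pre-coded as censorings).  Left truncation: every subject enters the risk
    sets at ``entry_time`` (or a per-subject ``entry_col``).  ``ties`` is
    ``"breslow"`` (default, matching the software the original analysis used)
    or ``"efron"``.

    Returns both the model-based (inverse information) covariance and the
    cluster sandwich covariance; with ``cluster_col=None`` every subject is
    its own cluster, giving the ordinary robust (score-residual) covariance.

    Raises :class:`ConvergenceError` on monotone likelihood (complete
    separation) or singular designs instead of silently "converging".
    """
    covariates = list(covariates)
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy()
    if event.dtype == object or str(event.dtype).startswith("str"):
        raise ValueError("event_col must be 0/1 for the cause of interest")
    event = event.astype(bool)
    X = data[covariates].to_numpy(float) if covariates else np.empty((len(data), 0))
    entry = (
        data[entry_col].to_numpy(float)
        if entry_col is not None
        else np.full(len(data), entry_time)
    )
    if not np.any(event & (time > entry.min())):
        raise ValueError("no events after the entry time")
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise ConvergenceError("singular design: covariates not full rank")

    cd = _CoxData(time, event, X, entry)
    quantities = _breslow_quantities if ties == "breslow" else _efron_quantities
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    beta = np.zeros(cd.p)
    ll, score, info, r, S0, S1, m = quantities(cd, beta)
    ll_null = ll
    for _ in range(max_iter):
        if cd.p == 0:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta + step
        # step-halving on overshoot
        for _ in range(30):
            ll_new, score_new, info_new, r, S0, S1, m = quantities(cd, new_beta)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if np.any(np.abs(new_beta) > 25):
            raise ConvergenceError(
                "monotone partial likelihood: complete separation suspected"
            )
        converged = abs(ll_new - ll) < tol * (abs(ll) + 1.0)
        beta, ll, score, info = new_beta, ll_new, score_new, info_new
        if converged:
            break
    else:
        if cd.p:
            raise ConvergenceError(f"no convergence in {max_iter} iterations")
    if cd.p and np.any(np.abs(beta) > 15):
        raise ConvergenceError(
            "monotone partial likelihood: complete separation suspected"
        )

    if cd.p:
        model_cov = np.linalg.inv(info)
        # sandwich: cluster-summed score residuals (Breslow-form residuals;
        # under Efron ties they are evaluated at the Efron optimum)
        U = _score_residuals(cd, r, S0, m)
        if cluster_col is not None:
            groups = pd.factorize(data[cluster_col])[0]
            Ug = np.zeros((groups.max() + 1, cd.p))
            np.add.at(Ug, groups, U)
        else:
            Ug = U
        meat = Ug.T @ Ug
        robust_cov = model_cov @ meat @ model_cov
    else:
        model_cov = np.zeros((0, 0))
        robust_cov = np.zeros((0, 0))

    # Breslow baseline cumulative hazard at the reference pattern (x = 0)
    if ties == "breslow":
        h0 = cd.d / S0
    else:
        h0 = np.array(
            [
                np.sum(
                    1.0
                    / (
                        S0[k]
                        - (np.arange(rows.size) / rows.size) * r[rows].sum()
                    )
                )
                for k, rows in enumerate(cd.tie_rows)
            ]
        )
    base_times = np.concatenate([[entry.min()], cd.u])
    base_surv = np.exp(-np.concatenate([[0.0], np.cumsum(h0)]))
    baseline = SurvivalCurve(
        times=base_times,
        survival=base_surv,
        entry_time=float(entry.min()),
        label="baseline",
    )
    idx = pd.Index(covariates)
    return CoxFit(
        coefficients=pd.Series(beta, index=idx, name="coef"),
        model_covariance=pd.DataFrame(model_cov, index=idx, columns=idx),
        robust_covariance=pd.DataFrame(robust_cov, index=idx, columns=idx),
        baseline_survival=baseline,
        loglik=ll,
        loglik_null=ll_null,
        n=len(data),
        n_events=int(event.sum()),
        ties=ties,
        entry_time=float(entry.min()),
    )


def predict_node_survival(fit: CoxFit, node_coefficient: float | str) -> SurvivalCurve:
    """Survival curve implied for a node: S(t) = S0(t) ** exp(beta_node).

    ``node_coefficient`` is either the log-hazard value itself (0 for the
    reference node) or the name of a fitted coefficient.
    """
    beta = (
        float(fit.coefficients[node_coefficient])
        if isinstance(node_coefficient, str)
        else float(node_coefficient)
    )
    base = fit.baseline_survival
    return SurvivalCurve(
        times=base.times.copy(),
        survival=base.survival ** np.exp(beta),
        entry_time=base.entry_time,
        label=f"predicted(beta={beta:.4g})",
    )


def information_criteria(fit: CoxFit) -> tuple[float, float]:
    """(AIC, BIC) of a fitted model; BIC uses the number of events as n."""
    return fit.aic, fit.bic
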