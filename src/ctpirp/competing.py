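"""Competing-risks estimation: cumulative incidence and Fine-Gray regression.

RRT inception, death and (optionally) loss to follow-up compete: whichever
happens first precludes the others.  Cause-specific Kaplan-Meier curves that
censor the competing outcome overstate absolute risk; the Aalen-Johansen
cumulative incidence function (CIF) and the Fine-Gray subdistribution-hazard
model are the corrective companions used here.

Both estimators are implemented in-package (no installed Python library
provides Fine-Gray; the Aalen-Johansen increments are computed directly so
that the conservation identity  sum_k CIF_k(t) + S(t) = 1  holds to machine
precision at every event time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import FollowUp
from .survival import ENTRY_TIME, ConvergenceError, SurvivalCurve

__all__ = [
    "CIFCurve",
    "CompetingRisksResult",
    "FineGrayFit",
    "aalen_johansen_cif",
    "fit_fine_gray",
]


@dataclass
class CIFCurve:
    """Non-decreasing cumulative incidence step function for one cause."""

    times: np.ndarray
    incidence: np.ndarray
    cause: str
    entry_time: float = ENTRY_TIME

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.incidence = np.asarray(self.incidence, float)
        if np.any(np.diff(self.incidence) < -1e-12):
            raise ValueError("CIF must be non-decreasing")
        if self.incidence.size and (
            self.incidence.min() < -1e-12 or self.incidence.max() > 1 + 1e-12
        ):
            raise ValueError("CIF must lie in [0, 1]")

    def incidence_at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return 0.0 if i < 0 else float(self.incidence[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "cause": self.cause, "cif": self.incidence}
        )


@dataclass
class CompetingRisksResult:
    """Aalen-Johansen estimate: one CIF per cause plus event-free survival."""

    cifs: dict[str, CIFCurve]
    event_free: SurvivalCurve

    def conservation_error(self) -> float:
        """max_t |sum_k CIF_k(t) + S(t) - 1| over the event grid (0 in exact arithmetic)."""
        total = sum(c.incidence for c in self.cifs.values())
        return float(np.max(np.abs(total + self.event_free.survival - 1.0), initial=0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.cifs.values()], ignore_index=True)


def aalen_johansen_cif(
    followups: Iterable[FollowUp],
    causes: Sequence[str] = ("rrt", "death"),
    entry_time: float = ENTRY_TIME,
) -> CompetingRisksResult:
    """Aalen-Johansen cumulative incidence per cause with delayed entry.

    CIF_k(t) = sum over event times u <= t of S(u-) * d_k(u) / n(u), where
    S(u-) is the left limit of the all-cause Kaplan-Meier curve and n(u) the
    number at risk.  Outcomes not listed in ``causes`` are censorings.
    """
    fus = list(followups)
    if not fus:
        raise ValueError("no follow-up records")
    known = {"rrt", "death", "lost", "admin_censor"}
    for c in causes:
        if c not in known:
            raise ValueError(f"unknown cause label: {c!r}")
    time = np.array([f.time for f in fus])
    cause_idx = {c: i for i, c in enumerate(causes)}
    status = np.array([cause_idx.get(f.event, -1) for f in fus])
    entry = np.full(time.size, entry_time)

    u = np.unique(time[status >= 0])
    n_at = np.array([np.sum((entry < t) & (time >= t)) for t in u])
    d = np.zeros((u.size, len(causes)))
    for k, t in enumerate(u):
        at_t = time == t
        for c, j in cause_idx.items():
            d[k, j] = np.sum(at_t & (status == j))
    d_all = d.sum(axis=1)
    s_prev = np.concatenate([[1.0], np.cumprod(1.0 - d_all / n_at)])
    incr = s_prev[:-1, None] * d / n_at[:, None]
    cifs = {
        c: CIFCurve(times=u, incidence=np.cumsum(incr[:, j]), cause=c, entry_time=entry_time)
        for c, j in cause_idx.items()
    }
    event_free = SurvivalCurve(
        times=u, survival=s_prev[1:], entry_time=entry_time, label="event-free"
    )
    return CompetingRisksResult(cifs=cifs, event_free=event_free)


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution-hazard regression
# ---------------------------------------------------------------------------


def _km_left_limits(time, event, entry, query):
    """Exact product-limit estimate evaluated as left limits G(q-)."""
    u = np.unique(time[event])
    surv = np.ones(u.size)
    s = 1.0
    for k, t in enumerate(u):
        n = np.sum((entry < t) & (time >= t))
        dk = np.sum((time == t) & event)
        s *= 1.0 - dk / n
        surv[k] = s
    idx = np.searchsorted(u, query, side="left") - 1  # last event time < q
    out = np.ones(np.size(query))
    np.putmask(out, idx >= 0, surv[np.clip(idx, 0, None)])
    return out


@dataclass
class FineGrayFit:
    """Fitted Fine-Gray model on the subdistribution-hazard scale."""

    coefficients: pd.Series
    model_covariance: pd.DataFrame
    robust_covariance: pd.DataFrame
    censoring_curve: SurvivalCurve  # KM of the censoring distribution (weights)
    baseline_cif: CIFCurve  # predicted CIF at covariates 0
    loglik: float
    n: int
    n_events: int
    cause: str

    @property
    def shr(self) -> pd.Series:
        """Subdistribution hazard ratios exp(coef)."""
        return np.exp(self.coefficients).rename("SHR")

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.robust_covariance)), index=self.coefficients.index
        )

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = self.robust_se
        return pd.DataFrame(
            {
                "shr_lower": np.exp(self.coefficients - z * se),
                "shr_upper": np.exp(self.coefficients + z * se),
            }
        )

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        se = self.robust_se
        z = self.coefficients / se
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "SHR": self.shr,
                "robust_se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        ).join(self.confint())

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.to_dict(),
                "shr": self.shr.to_dict(),
                "robust_se": self.robust_se.to_dict(),
                "loglik": self.loglik,
                "n": self.n,
                "n_events": self.n_events,
                "cause": self.cause,
            }
        )


def fine_gray_weights(
    time: np.ndarray,
    status: np.ndarray,
    entry: np.ndarray,
    event_times: np.ndarray,
    weight_floor: float = 1e-6,
):
    """IPCW risk-set weight matrix W[k, i] at each cause-of-interest time.

    ``status``: 1 = cause of interest, 2 = competing cause, 0 = censored.
    A subject failing from a competing cause at s stays in every later risk
    set with weight G(u-)/G(s-), where G is the Kaplan-Meier estimate of the
    censoring distribution; censored subjects and cause-of-interest failures
    leave as usual.  Weights below ``weight_floor`` are clipped to zero.
    """
    cens = status == 0
    G_at_u = _km_left_limits(time, cens, entry, event_times)
    G_at_T = _km_left_limits(time, cens, entry, time)
    natural = (entry[None, :] < event_times[:, None]) & (
        time[None, :] >= event_times[:, None]
    )
    W = natural.astype(float)
    extended = (status == 2)[None, :] & (time[None, :] < event_times[:, None])
    ratio = G_at_u[:, None] / np.maximum(G_at_T[None, :], weight_floor)
    W[extended] = np.clip(ratio, 0.0, 1.0)[extended]
    W[W < weight_floor] = 0.0
    return W, G_at_u


def fit_fine_gray(
    data: pd.DataFrame,
    covariates: Sequence[str],
    cause_of_interest: str = "rrt",
    competing_causes: Sequence[str] = ("death",),
    duration_col: str = "time",
    event_col: str = "event",
    cluster_col: str | None = None,
    entry_time: float = ENTRY_TIME,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> FineGrayFit:
    """Fine-Gray regression for one cause against its competitors.

    Maximizes the IPCW-weighted partial likelihood in which subjects failing
    from ``competing_causes`` remain in later risk sets with censoring-
    distribution weights.  Any outcome in neither set is treated as censoring
    (both for risk-set removal and for the weight model).  Covariance is the
    cluster sandwich of :mod:`ctpirp.survival`; it does not include the
    (small, variance-reducing) contribution of estimating the weights, and is
    therefore mildly conservative.

    With no competing events present the weights are identically one and the
    fit reduces exactly to the cause-specific Cox model.
    """
    covariates = list(covariates)
    time = data[duration_col].to_numpy(float)
    raw = data[event_col].to_numpy()
    status = np.zeros(time.size, dtype=int)
    status[np.isin(raw, [cause_of_interest])] = 1
    status[np.isin(raw, list(competing_causes))] = 2
    if not np.any(status == 1):
        raise ValueError(f"no events of cause {cause_of_interest!r}")
    X = data[covariates].to_numpy(float)
    n, p = X.shape
    entry = np.full(n, entry_time)

    u, tie_inv = np.unique(time[status == 1], return_inverse=True)
    d = np.bincount(tie_inv, minlength=u.size).astype(float)
    sx = np.zeros((u.size, p))
    np.add.at(sx, tie_inv, X[status == 1])
    W, G_at_u = fine_gray_weights(time, status, entry, u)

    def quantities(beta):
        r = np.exp(np.clip(X @ beta, -500, 500))
        Wr = W * r[None, :]
        S0 = Wr.sum(axis=1)
        if np.any(S0 <= 0):
            raise ConvergenceError("empty weighted risk set at an event time")
        S1 = Wr @ X
        m = S1 / S0[:, None]
        ll = float(np.sum(sx @ beta) - np.sum(d * np.log(S0)))
        score = np.sum(sx - d[:, None] * m, axis=0)
        S2 = np.einsum("ki,ij,il->kjl", Wr, X, X)
        info = np.einsum(
            "k,kij->ij", d, S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :]
        )
        return ll, score, info, r, S0, m

    beta = np.zeros(p)
    ll, score, info, r, S0, m = quantities(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        new_beta = beta + step
        for _ in range(30):
            ll_new, score_new, info_new, r, S0, m = quantities(new_beta)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if np.any(np.abs(new_beta) > 25):
            raise ConvergenceError(
                "monotone weighted partial likelihood: separation suspected"
            )
        converged = abs(ll_new - ll) < tol * (abs(ll) + 1.0)
        beta, ll, score, info = new_beta, ll_new, score_new, info_new
        if converged:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    if np.any(np.abs(beta) > 15):
        raise ConvergenceError(
            "monotone weighted partial likelihood: separation suspected"
        )

    model_cov = np.linalg.inv(info)
    # sandwich meat from per-subject score residuals of the weighted likelihood
    c = d / S0
    P = W.T @ c
    Q = W.T @ (c[:, None] * m)
    U = -r[:, None] * (X * P[:, None] - Q)
    ev = status == 1
    U[ev] += X[ev] - m[tie_inv]
    if cluster_col is not None:
        groups = pd.factorize(data[cluster_col])[0]
        Ug = np.zeros((groups.max() + 1, p))
        np.add.at(Ug, groups, U)
    else:
        Ug = U
    robust_cov = model_cov @ (Ug.T @ Ug) @ model_cov

    h0 = d / S0
    baseline_cif = CIFCurve(
        times=u,
        incidence=1.0 - np.exp(-np.cumsum(h0)),
        cause=cause_of_interest,
        entry_time=entry_time,
    )
    cens_curve = SurvivalCurve(
        times=u, survival=G_at_u, entry_time=entry_time, label="censoring KM (G(t-))"
    )
    idx = pd.Index(covariates)
    return FineGrayFit(
        coefficients=pd.Series(beta, index=idx, name="coef"),
        model_covariance=pd.DataFrame(model_cov, index=idx, columns=idx),
        robust_covariance=pd.DataFrame(robust_cov, index=idx, columns=idx),
        censoring_curve=cens_curve,
        baseline_cif=baseline_cif,
        loglik=ll,
        n=n,
        n_events=int(ev.sum()),
        cause=cause_of_interest,
    )
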