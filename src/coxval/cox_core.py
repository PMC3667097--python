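"""Cox partial-likelihood machinery and nonparametric survival estimators.

Everything downstream — calibration slope, misspecification test, baseline
smoothing, risk-group hazard ratios — rests on a small set of primitives:

* :func:`fit_cox` maximises the Cox partial likelihood by Newton iteration
  with step-halving, supports an *offset* (a linear term with coefficient
  fixed at 1, used to hold a published PI fixed), handles the
  zero-covariate case (offset only, for likelihood-ratio tests), and ties
  by Efron's method (default) or Breslow's.
* :func:`kaplan_meier` — product-limit survival with Greenwood standard
  errors.
* :func:`baseline_cumhaz` — Breslow cumulative hazard with the PI as a
  fixed offset, i.e. the baseline at PI = 0 (the derivation mean when the
  PI is centered).
* :func:`logrank_test` — k-group logrank; implemented because analysts use
  it, but carrying a deprecation notice: a significant logrank between
  risk groups tests a silly null hypothesis and does not quantify
  discrimination.

Numerical notes.  The linear predictor is shifted by its maximum before
exponentiation so risk-set sums cannot overflow.  Convergence is declared
when the relative change in partial log-likelihood falls below 1e-9;
monotone likelihood (separation) surfaces as a ConvergenceError with a
diagnostic rather than silently huge coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ConvergenceError, DataError
from .model_spec import SurvivalSample

__all__ = [
    "CoxFit",
    "StepCurve",
    "LogrankResult",
    "fit_cox",
    "kaplan_meier",
    "baseline_cumhaz",
    "baseline_survival",
    "logrank_test",
    "schoenfeld_residuals",
    "LOGRANK_CAVEAT",
]

LOGRANK_CAVEAT = (
    "Logrank/Cox tests between risk groups are not recommended: the P-value "
    "quantifies evidence against the null hypothesis that the risk groups "
    "have identical survival, not the model's discrimination."
)


@dataclass
class StepCurve:
    """Right-continuous step function over time.

    ``flavor`` is ``"survival"`` (values in [0,1], non-increasing) or
    ``"cumhaz"`` (values >= 0, non-decreasing).  Before the first step the
    curve is 1 (survival) or 0 (cumulative hazard).
    """

    times: np.ndarray
    values: np.ndarray
    flavor: str = "survival"
    se: Optional[np.ndarray] = None
    at_risk: Optional[np.ndarray] = None
    n_events: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.flavor not in ("survival", "cumhaz"):
            raise ConfigurationError(f"unknown StepCurve flavor {self.flavor!r}")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("StepCurve times must be strictly increasing")
        if self.times.shape != self.values.shape:
            raise ConfigurationError("times and values must have equal length")
        if self.values.size:
            d = np.diff(self.values)
            if self.flavor == "survival":
                if self.values[0] > 1 + 1e-12 or np.any(d > 1e-12) or np.any(self.values < -1e-12):
                    raise ConfigurationError("survival curve must be non-increasing in [0,1]")
            else:
                if np.any(self.values < -1e-12) or np.any(d < -1e-12):
                    raise ConfigurationError("cumulative hazard must be non-negative, non-decreasing")
        for name in ("se", "at_risk", "n_events"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def baseline_value(self) -> float:
        return 1.0 if self.flavor == "survival" else 0.0

    def evaluate(self, t) -> np.ndarray:
        """Step-function value at time(s) t (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.full(t.shape, self.baseline_value)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.baseline_value)
        return out

    def se_at(self, t) -> np.ndarray:
        if self.se is None:
            raise ConfigurationError("this curve carries no standard errors")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.se[np.clip(idx, 0, None)], 0.0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "value": self.values}
        if self.se is not None:
            cols["se"] = self.se
        if self.at_risk is not None:
            cols["at_risk"] = self.at_risk
        if self.n_events is not None:
            cols["events"] = self.n_events
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, flavor: str = "survival") -> "StepCurve":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            values=df["value"].to_numpy(),
            flavor=flavor,
            se=df["se"].to_numpy() if "se" in df else None,
            at_risk=df["at_risk"].to_numpy() if "at_risk" in df else None,
            n_events=df["events"].to_numpy() if "events" in df else None,
        )


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    log_likelihood_null: float  # at beta = 0 (offset, if any, included)
    n_subjects: int
    n_events: int
    offset_used: bool
    ties_method: str
    covariate_names: tuple[str, ...] = ()
    n_iter: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance)) if self.covariance.size else np.array([])

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = np.divide(self.coefficients, se, out=np.zeros_like(se), where=se > 0)
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "hr": np.exp(self.coefficients),
            },
            index=list(self.covariate_names),
        )


# --------------------------------------------------------------------------
# internal machinery


class _PartialLikelihood:
    """Sorted/grouped data plus Efron/Breslow evaluation of ll, score, info."""

    def __init__(self, time, event, X, offset, ties):
        order = np.argsort(-time, kind="stable")  # descending time
        self.t = time[order]
        self.d = event[order].astype(bool)
        self.X = X[order]
        self.off = offset[order]
        self.n, self.p = self.X.shape
        self.ties = ties
        # contiguous tie groups in the descending-sorted data
        boundary = np.flatnonzero(np.diff(self.t) != 0)
        starts = np.concatenate(([0], boundary + 1))
        ends = np.concatenate((boundary, [self.n - 1]))
        self.group_start, self.group_end = starts, ends
        # map each subject to the last index of its tie group (risk-set end)
        group_id = np.zeros(self.n, dtype=int)
        group_id[starts] = 1
        group_id = np.cumsum(group_id) - 1
        self.riskset_end = ends[group_id]
        self.group_id = group_id
        self.event_idx = np.flatnonzero(self.d)
        # tie groups containing >= 2 deaths (need Efron correction)
        deaths_per_group = np.zeros(len(starts), dtype=int)
        np.add.at(deaths_per_group, group_id[self.d], 1)
        self.multi_death_groups = np.flatnonzero(deaths_per_group >= 2)

    def evaluate(self, beta, want_derivs=True):
        eta = self.X @ beta + self.off if self.p else self.off.copy()
        emax = eta.max()
        w = np.exp(eta - emax)
        cw = np.cumsum(w)
        ev = self.event_idx
        re = self.riskset_end[ev]
        S0 = cw[re]
        ll = float(np.sum(eta[ev] - emax) - np.sum(np.log(S0)))
        U = H = None
        if want_derivs and self.p:
            wX = w[:, None] * self.X
            cwX = np.cumsum(wX, axis=0)
            wXX = wX[:, :, None] * self.X[:, None, :]
            cwXX = np.cumsum(wXX, axis=0)
            S1 = cwX[re]  # (ne, p)
            S2 = cwXX[re]  # (ne, p, p)
            m = S1 / S0[:, None]
            U = (self.X[ev] - m).sum(axis=0)
            H = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", m, m)
        elif want_derivs:
            U = np.zeros(0)
            H = np.zeros((0, 0))

        if self.ties == "efron" and self.multi_death_groups.size:
            ll, U, H = self._efron_correct(ll, U, H, w, cw, eta, emax, want_derivs)
        return ll, U, H

    def _efron_correct(self, ll, U, H, w, cw, eta, emax, want_derivs):
        """Replace Breslow contributions of multi-death tie groups by Efron's."""
        p = self.p
        for g in self.multi_death_groups:
            s, e = self.group_start[g], self.group_end[g]
            members = np.arange(s, e + 1)
            dead = members[self.d[s:e + 1]]
            dd = len(dead)
            S0 = cw[e]
            D0 = w[dead].sum()
            # remove the Breslow terms for these deaths
            ll += dd * np.log(S0)
            frac = np.arange(dd) / dd
            phi = S0 - frac * D0
            ll -= np.sum(np.log(phi))
            if want_derivs and p:
                wX = w[:, None] * self.X
                # risk-set sums at this group (recompute locally, groups are few)
                S1 = wX[: e + 1].sum(axis=0)
                S2 = (wX[: e + 1, :, None] * self.X[: e + 1, None, :]).sum(axis=0)
                D1 = wX[dead].sum(axis=0)
                D2 = (wX[dead, :, None] * self.X[dead, None, :]).sum(axis=0)
                m_b = S1 / S0
                U += dd * m_b
                H -= dd * (S2 / S0 - np.outer(m_b, m_b))
                for l in range(dd):
                    num1 = S1 - frac[l] * D1
                    num2 = S2 - frac[l] * D2
                    m_l = num1 / phi[l]
                    U -= m_l
                    H += num2 / phi[l] - np.outer(m_l, m_l)
        return ll, U, H


def _design(sample: SurvivalSample, covariate_names, offset_name):
    data = sample.data
    for c in list(covariate_names) + ([offset_name] if offset_name else []):
        if c not in data.columns:
            raise ConfigurationError(f"column {c!r} not found in the dataset")
    X = data[list(covariate_names)].to_numpy(dtype=float) if covariate_names else \
        np.empty((len(data), 0))
    if X.size and not np.isfinite(X).all():
        raise DataError("covariates contain missing or non-finite values")
    offset = (
        data[offset_name].to_numpy(dtype=float)
        if offset_name
        else np.zeros(len(data))
    )
    if not np.isfinite(offset).all():
        raise DataError("offset column contains missing or non-finite values")
    return X, offset


def fit_cox(
    sample: SurvivalSample,
    covariate_names: Sequence[str] = (),
    offset_name: Optional[str] = None,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximise the Cox partial likelihood.

    ``offset_name`` names a column entering the linear predictor with
    coefficient fixed at 1 (an exact linear term, not a penalised
    approximation).  With no covariates at all the function just evaluates
    the offset-only partial log-likelihood, which is what likelihood-ratio
    tests against an offset model need.
    """
    if ties not in ("efron", "breslow"):
        raise ConfigurationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    covariate_names = list(covariate_names)
    time, event = sample.time, sample.event
    if event.sum() < 1:
        raise DataError("cannot fit a Cox model: the sample contains no events")
    X, offset = _design(sample, covariate_names, offset_name)
    n, p = X.shape
    if p:
        sds = X.std(axis=0)
        degenerate = [covariate_names[j] for j in np.flatnonzero(sds == 0)]
        if degenerate:
            raise DataError(f"constant covariate column(s): {degenerate}")

    pl = _PartialLikelihood(time, event, X, offset, ties)
    beta = np.zeros(p)
    ll, U, H = pl.evaluate(beta)
    ll_null = ll

    n_iter = 0
    if p:
        for n_iter in range(1, max_iter + 1):
            try:
                delta = np.linalg.solve(H, U)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(
                    "singular information matrix (collinear covariates or "
                    f"separation) for {covariate_names}"
                ) from e
            step = 1.0
            for _ in range(40):  # step-halving on overshoot
                cand = beta + step * delta
                ll_new, U_new, H_new = pl.evaluate(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            else:
                raise ConvergenceError("step-halving failed to improve the likelihood")
            converged = abs(ll_new - ll) < tol * (abs(ll) + tol)
            beta, ll, U, H = cand, ll_new, U_new, H_new
            if converged:
                break
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} Newton iterations "
                f"(|beta| = {np.abs(beta).max():.3g}); possible monotone "
                "likelihood (separation)"
            )
        if np.abs(beta).max() > 20:
            raise ConvergenceError(
                f"coefficient diverged (max |beta| = {np.abs(beta).max():.3g}); "
                "monotone likelihood (separation) in the data"
            )
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError("singular information at the optimum") from e
    else:
        cov = np.zeros((0, 0))

    return CoxFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        n_subjects=n,
        n_events=int(event.sum()),
        offset_used=offset_name is not None,
        ties_method=ties,
        covariate_names=tuple(covariate_names),
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# nonparametric estimators


def _risk_table(time, event):
    """Unique event times with death counts and numbers at risk.

    Subjects censored at an event time are still at risk at that time
    (censoring-at-event-time convention: deaths precede censorings).
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ut = np.unique(t[e == 1])
    n_at_risk = len(t) - np.searchsorted(t, ut, side="left")
    deaths = np.array([int(e[t == u].sum()) for u in ut])
    return ut, deaths, n_at_risk


def kaplan_meier(sample: SurvivalSample) -> StepCurve:
    """Product-limit survival estimate with Greenwood standard errors."""
    if len(sample) < 1:
        raise DataError("empty sample")
    ut, d, n = _risk_table(sample.time, sample.event)
    if ut.size == 0:
        return StepCurve(times=np.array([]), values=np.array([]), flavor="survival")
    s = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(np.where(n > d, d / (n * (n - d)), np.nan))
    se = s * np.sqrt(greenwood)
    return StepCurve(
        times=ut, values=s, flavor="survival", se=se, at_risk=n, n_events=d
    )


def baseline_cumhaz(sample: SurvivalSample, pi_name: str = "_pi") -> StepCurve:
    """Breslow baseline cumulative hazard with the PI as fixed offset.

    Fits nothing: the model ln h(t) = ln h0(t) + PI is imposed with the
    published PI, and H0 accumulates d_k / sum_{riskset} exp(PI_j) at each
    event time.  With all PI = 0 this is the Nelson-Aalen estimator.  The
    curve is the baseline at PI = 0, i.e. at the derivation mean when the
    PI was centered there.
    """
    if sample.n_events < 1:
        raise DataError("no events: cannot estimate a baseline hazard")
    X, off = _design(sample, [], pi_name)
    time, event = sample.time, sample.event
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], np.exp(off[order] - off.max())
    ut = np.unique(t[e == 1])
    # sum of weights over subjects still at risk at each event time
    rev_cumw = np.cumsum(w[::-1])[::-1]
    first_at_risk = np.searchsorted(t, ut, side="left")
    S0 = rev_cumw[first_at_risk] * np.exp(off.max())
    d = np.array([int(e[t == u].sum()) for u in ut])
    n_at_risk = len(t) - first_at_risk
    increments = d / S0
    return StepCurve(
        times=ut,
        values=np.cumsum(increments),
        flavor="cumhaz",
        at_risk=n_at_risk,
        n_events=d,
    )


def baseline_survival(
    sample: SurvivalSample, pi_name: str = "_pi", method: str = "exp"
) -> StepCurve:
    """Baseline survival S0(t).

    ``method="exp"`` returns exp(-H0) from the Breslow cumulative hazard
    (consistent with the smoothed-baseline machinery); ``"product-limit"``
    gives the Kaplan-Meier-like alternative prod(1 - d_k / S0risk_k).
    """
    H = baseline_cumhaz(sample, pi_name)
    if method == "exp":
        vals = np.exp(-H.values)
    elif method == "product-limit":
        inc = np.diff(np.concatenate(([0.0], H.values)))
        vals = np.cumprod(np.clip(1.0 - inc, 0.0, 1.0))
    else:
        raise ConfigurationError(f"unknown baseline survival method {method!r}")
    return StepCurve(
        times=H.times, values=vals, flavor="survival",
        at_risk=H.at_risk, n_events=H.n_events,
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    caveat: str = LOGRANK_CAVEAT


def logrank_test(sample: SurvivalSample, group_name: str = "_group") -> LogrankResult:
    """k-group logrank chi-squared test (deprecated as a validation method).

    Always reported together with the caveat that between-group P-values do
    not measure discrimination.
    """
    if group_name not in sample.data.columns:
        raise ConfigurationError(f"column {group_name!r} not found")
    codes, levels = pd.factorize(sample.data[group_name], sort=True)
    k = len(levels)
    if k < 2:
        raise ConfigurationError("logrank test needs at least two non-empty groups")
    warnings.warn(LOGRANK_CAVEAT, UserWarning, stacklevel=2)
    time, event = sample.time, sample.event
    ut = np.unique(time[event == 1])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for u in ut:
        at_risk = time >= u
        n = at_risk.sum()
        dying = (time == u) & (event == 1)
        d = dying.sum()
        ng = np.bincount(codes[at_risk], minlength=k).astype(float)
        og = np.bincount(codes[dying], minlength=k).astype(float)
        eg = d * ng / n
        OmE += og - eg
        if n > 1:
            mult = d * (n - d) / (n - 1)
            V += mult * (np.diag(ng / n) - np.outer(ng / n, ng / n))
    try:
        stat = float(OmE[:-1] @ np.linalg.solve(V[:-1, :-1], OmE[:-1]))
    except np.linalg.LinAlgError as e:
        raise DataError("singular logrank covariance (a group has no events?)") from e
    df = k - 1
    return LogrankResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def schoenfeld_residuals(
    sample: SurvivalSample,
    covariate_names: Sequence[str],
    beta: np.ndarray,
    offset_name: Optional[str] = None,
):
    """Schoenfeld residuals x_i - xbar(t_i) at each event, Breslow weighting.

    Returns (event_times, residual matrix of shape (n_events, p)).
    """
    X, off = _design(sample, list(covariate_names), offset_name)
    time, event = sample.time, sample.event
    pl = _PartialLikelihood(time, event, X, np.asarray(off), "breslow")
    eta = pl.X @ np.asarray(beta, dtype=float) + pl.off
    w = np.exp(eta - eta.max())
    cw = np.cumsum(w)
    cwX = np.cumsum(w[:, None] * pl.X, axis=0)
    ev = pl.event_idx
    re = pl.riskset_end[ev]
    m = cwX[re] / cw[re][:, None]
    resid = pl.X[ev] - m
    t_ev = pl.t[ev]
    order = np.argsort(t_ev, kind="stable")
    return t_ev[order], resid[order]
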