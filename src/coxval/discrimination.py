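"""Discrimination measures for a prognostic index under right censoring.

Implements Harrell's c-index, Goenen & Heller's concordance probability K,
the Royston-Sauerbrei D statistic, and the explained-variation measures
R2_D and R2_PM.  c, D and R2_D depend on the PI only through its ranks;
K depends on the PI differences themselves but not on the outcome at all,
which is what makes it evaluable (and asymptotically unbiased) in a
validation dataset; R2_PM is a monotone transform of the PI spread.

Two constants recur: sigma^2 = pi^2/6 ~ 1.645, the residual variance on the
log relative-hazard scale implied by a proportional-hazards model, and
kappa = sqrt(8/pi) ~ 1.596, the scaling that relates D to the standard
deviation of a Normally distributed PI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cox_core import fit_cox
from .exceptions import DataError
from .model_spec import PI_COL, SurvivalSample

__all__ = [
    "SIGMA2_PH",
    "KAPPA",
    "EstimateSE",
    "DiscriminationReport",
    "harrell_c",
    "gonen_heller_k",
    "d_statistic",
    "r2_d",
    "r2_pm",
    "discrimination_report",
]

#: pi^2 / 6: the "residual variance" of a PH model on the log-hazard scale.
SIGMA2_PH = np.pi ** 2 / 6
#: sqrt(8/pi): rankit scaling factor in the D statistic.
KAPPA = np.sqrt(8 / np.pi)


@dataclass(frozen=True)
class EstimateSE:
    estimate: float
    se: float

    def __iter__(self):
        yield self.estimate
        yield self.se


def _pair_matrices(time, event, pi):
    """Concordance scores and evaluability weights for all ordered pairs.

    A pair is evaluable when the member with the shorter follow-up had the
    event; pairs tied on time are evaluable only if exactly one member is
    an event (the event member counts as having the shorter time).  Ties in
    the PI score 1/2.
    """
    dt = time[:, None] - time[None, :]  # t_i - t_j
    dp = pi[:, None] - pi[None, :]
    e_i = event[:, None].astype(bool)
    e_j = event[None, :].astype(bool)
    # i has the strictly shorter time and had the event
    usable = (dt < 0) & e_i
    # tied times: exactly one event; the event member is 'first'
    tied = (dt == 0) & e_i & ~e_j
    usable = usable | tied
    np.fill_diagonal(usable, False)
    # shorter time with event and higher PI -> concordant
    score = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return usable, score


def harrell_c(sample: SurvivalSample, pi_name: str = PI_COL) -> EstimateSE:
    """Harrell's c: proportion of evaluable pairs ordered concordantly.

    SE by the asymptotic U-statistic (projection) variance of the ratio of
    the concordance-score and evaluability U-statistics.
    """
    pi = sample.data[pi_name].to_numpy(dtype=float) if pi_name != PI_COL else sample.pi
    time, event = sample.time, sample.event
    if event.sum() < 1:
        raise DataError("no events: no evaluable pairs for the c-index")
    usable, score = _pair_matrices(time, event, pi)
    W = usable.astype(float)
    n_pairs = W.sum()
    if n_pairs == 0:
        raise DataError("no evaluable pairs under the censoring pattern")
    c = float((W * score).sum() / n_pairs)
    # symmetrise ordered-pair kernels, then project onto subjects
    n = len(time)
    S = W * score
    a_i = S.sum(axis=1) + S.sum(axis=0)  # per-subject concordance mass
    b_i = W.sum(axis=1) + W.sum(axis=0)  # per-subject evaluability mass
    g_i = (a_i - c * b_i) / (n - 1)
    u_w = b_i.sum() / (n * (n - 1))
    var_c = 4.0 * np.var(g_i, ddof=1) / n / u_w ** 2
    return EstimateSE(c, float(np.sqrt(var_c)))


def gonen_heller_k(
    pi_values,
    se_method: str = "analytic",
    n_boot: int = 200,
    seed: int = 0,
) -> EstimateSE:
    """Goenen & Heller's concordance probability estimate K.

    K is a double sum over subject pairs of logistic functions of PI
    differences: under proportional hazards the probability that the
    higher-PI member of a pair fails first is expit(|PI_i - PI_j|), and K
    averages that over all pairs.  The outcome is never used, so K is free
    of the censoring-induced optimism that affects the c-index.  Tied PIs
    contribute 1/2 (the logistic function of zero), so a constant PI gives
    exactly 0.5.

    The analytic SE is the U-statistic projection variance, which treats
    the published coefficients as fixed — exactly the external-validation
    situation; a subject-resampling bootstrap is selectable.
    """
    pi = np.asarray(pi_values, dtype=float)
    n = len(pi)
    if n < 2:
        raise DataError("K needs at least two subjects")
    if np.ptp(pi) == 0:
        warnings.warn("all PI values are equal: K degenerates to 0.5", UserWarning)
        return EstimateSE(0.5, 0.0)
    kernel = expit(np.abs(pi[:, None] - pi[None, :]))
    np.fill_diagonal(kernel, 0.0)
    K = float(kernel.sum() / (n * (n - 1)))
    if se_method == "analytic":
        kbar_i = kernel.sum(axis=1) / (n - 1)
        var_k = 4.0 * np.var(kbar_i, ddof=1) / n
        se = float(np.sqrt(var_k))
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            kb = expit(np.abs(pi[idx][:, None] - pi[idx][None, :]))
            np.fill_diagonal(kb, 0.0)
            reps[b] = kb.sum() / (n * (n - 1))
        se = float(reps.std(ddof=1))
    else:
        raise DataError(f"unknown se_method {se_method!r}")
    return EstimateSE(K, se)


def _blom_rankits(pi: np.ndarray) -> np.ndarray:
    """Blom-approximation rankits, averaged within PI ties."""
    n = len(pi)
    order = np.argsort(pi, kind="stable")
    positions = np.arange(1, n + 1)
    blom = stats.norm.ppf((positions - 0.375) / (n + 0.25))
    z = np.empty(n)
    z[order] = blom
    # average rankits over tied PI values
    df = pd.DataFrame({"pi": pi, "z": z})
    z = df.groupby("pi")["z"].transform("mean").to_numpy()
    return z


def d_statistic(sample: SurvivalSample, pi_name: str = PI_COL) -> EstimateSE:
    """Royston-Sauerbrei D: prognostic separation on the log-hazard scale.

    Order the PI, form the rankits (expected standard-Normal order
    statistics, Blom's approximation), divide by kappa = sqrt(8/pi), and
    take the Cox regression coefficient on the scaled rankits.  D is the
    log hazard ratio between the prognostic halves of an idealised
    Normally distributed PI.
    """
    pi = sample.data[pi_name].to_numpy(dtype=float) if pi_name != PI_COL else sample.pi
    if sample.event.sum() < 1:
        raise DataError("no events: cannot compute D")
    if np.ptp(pi) == 0:
        warnings.warn("constant PI: D = 0", UserWarning)
        return EstimateSE(0.0, np.nan)
    work = sample.copy()
    work.data["_rankit"] = _blom_rankits(pi) / KAPPA
    fit = fit_cox(work, ["_rankit"])
    return EstimateSE(float(fit.coefficients[0]), float(fit.se[0]))


def r2_d(D: float) -> float:
    """Explained variation R2_D = (D^2/kappa^2) / (sigma^2 + D^2/kappa^2)."""
    if not np.isfinite(D):
        raise DataError("D must be finite")
    u = D ** 2 / KAPPA ** 2
    return float(u / (SIGMA2_PH + u))


def r2_pm(pi_sd: float) -> float:
    """R2_PM = s^2 / (sigma^2 + s^2), with s the PI standard deviation."""
    if not (pi_sd >= 0):
        raise DataError("pi_sd must be non-negative")
    s2 = pi_sd ** 2
    return float(s2 / (SIGMA2_PH + s2))


def _r2_d_se(D: float, se_D: float) -> float:
    # delta method through R2_D(D)
    u = D ** 2 / KAPPA ** 2
    dR_dD = (2 * D / KAPPA ** 2) * SIGMA2_PH / (SIGMA2_PH + u) ** 2
    return float(abs(dR_dD) * se_D)


@dataclass
class DiscriminationReport:
    harrell_c: EstimateSE
    gonen_heller_k: EstimateSE
    d_statistic: EstimateSE
    r2_d: float
    r2_d_se: float
    r2_pm: float
    pi_sd: float
    n_subjects: int
    n_events: int
    sigma2: float = SIGMA2_PH
    kappa: float = KAPPA

    def __post_init__(self) -> None:
        # internal consistency of the explained-variation chain
        assert abs(self.r2_d - r2_d(self.d_statistic.estimate)) < 1e-12

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Harrell c-index", self.harrell_c.estimate, self.harrell_c.se),
            ("Gonen & Heller K", self.gonen_heller_k.estimate, self.gonen_heller_k.se),
            ("D statistic", self.d_statistic.estimate, self.d_statistic.se),
            ("Explained variation (R2_D)", self.r2_d, self.r2_d_se),
            ("Explained variation (R2_PM)", self.r2_pm, np.nan),
            ("PI spread (SD)", self.pi_sd, np.nan),
        ]
        return pd.DataFrame(rows, columns=["measure", "estimate", "se"])


def discrimination_report(
    sample: SurvivalSample, pi_name: str = PI_COL
) -> DiscriminationReport:
    """All discrimination measures for one dataset, Table-4 shaped."""
    pi = sample.data[pi_name].to_numpy(dtype=float) if pi_name != PI_COL else sample.pi
    c = harrell_c(sample, pi_name)
    K = gonen_heller_k(pi)
    D = d_statistic(sample, pi_name)
    sd = float(np.std(pi, ddof=1))
    return DiscriminationReport(
        harrell_c=c,
        gonen_heller_k=K,
        d_statistic=D,
        r2_d=r2_d(D.estimate),
        r2_d_se=_r2_d_se(D.estimate, D.se),
        r2_pm=r2_pm(sd),
        pi_sd=sd,
        n_subjects=len(sample),
        n_events=sample.n_events,
    )
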