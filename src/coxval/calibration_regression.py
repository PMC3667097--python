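"""Calibration slope, misspecification test, proportional-hazards check.

Method 1: re-estimate the regression coefficient on the published PI in
the validation data (the "calibration slope").  By construction the slope
is exactly 1 in the derivation data; < 1 in new data signals attenuated
(poorer) discrimination, > 1 better.  The likelihood-ratio test of slope
= 1 compares the free fit with the model holding the PI as an offset; its
P-value may be anti-conservative since derivation-side uncertainty in the
coefficients is ignored.

Method 2: with the PI held as an offset, regress on the model's own
(transformed) covariates: ln h(t) = ln h0(t) + x'beta* + PI.  The beta*
are the differences between validation-data and derivation-data
coefficients (the latter treated as fixed numbers), and a joint test of
beta* = 0 checks fit while protecting the type-1 error relative to
covariate-by-covariate testing.

The proportional-hazards check uses the Grambsch-Therneau scaled-Schoenfeld
correlation test.  A breach of PH need not invalidate the model's
discrimination, but calls for scrutiny of calibration over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cox_core import fit_cox, kaplan_meier, schoenfeld_residuals
from .exceptions import ConfigurationError, DataError
from .model_spec import PI_COL, SurvivalSample

__all__ = [
    "SlopeResult",
    "MisspecificationResult",
    "PHCheckResult",
    "calibration_slope",
    "misspecification_test",
    "ph_check",
    "SLOPE_CAVEAT",
    "PH_CAVEAT",
]

SLOPE_CAVEAT = (
    "The P-value for slope = 1 may be anti-conservative: it does not allow "
    "for uncertainty in the published coefficients that make up the PI."
)
PH_CAVEAT = (
    "A breach of proportional hazards does not necessarily invalidate the "
    "model's discrimination, but the calibration over time should be "
    "scrutinised."
)


@dataclass(frozen=True)
class SlopeResult:
    slope: float
    se: float
    lr_statistic: float  # LR test of slope = 1
    p_value: float
    n_subjects: int
    n_events: int
    caveat: str = SLOPE_CAVEAT

    @property
    def interpretation(self) -> str:
        if self.slope < 1:
            return "slope < 1: discrimination poorer than in the derivation data"
        if self.slope > 1:
            return "slope > 1: discrimination better than in the derivation data"
        return "slope = 1: discrimination preserved"


def calibration_slope(sample: SurvivalSample, pi_name: str = PI_COL) -> SlopeResult:
    """Cox regression on the PI alone; LR test that the slope is 1."""
    pi = sample.data[pi_name] if pi_name in sample.data.columns else None
    if pi is None:
        raise ConfigurationError(f"column {pi_name!r} not found; compute the PI first")
    if np.ptp(pi.to_numpy(dtype=float)) == 0:
        raise DataError("PI is constant: the calibration slope is undefined")
    free = fit_cox(sample, [pi_name])
    constrained = fit_cox(sample, [], offset_name=pi_name)
    lr = max(0.0, 2.0 * (free.log_likelihood - constrained.log_likelihood))
    return SlopeResult(
        slope=float(free.coefficients[0]),
        se=float(free.se[0]),
        lr_statistic=float(lr),
        p_value=float(stats.chi2.sf(lr, 1)),
        n_subjects=free.n_subjects,
        n_events=free.n_events,
    )


@dataclass(frozen=True)
class MisspecificationResult:
    beta_star: pd.Series
    covariance: np.ndarray
    lr_statistic: float
    wald_statistic: float
    joint_statistic: float  # the one selected by `test`
    df: int
    p_value: float
    test: str
    per_covariate: pd.DataFrame  # secondary: per-covariate z and p

    def __post_init__(self):
        assert self.df == len(self.beta_star)


def misspecification_test(
    sample: SurvivalSample,
    covariate_names: Sequence[str],
    pi_name: str = PI_COL,
    test: str = "lr",
) -> MisspecificationResult:
    """Joint test of beta* = 0 in the PI-offset model.

    ``covariate_names`` must be the model's own transformed covariate
    columns.  Both the likelihood-ratio statistic (offset model vs offset +
    covariates; the default) and the Wald statistic are computed.
    Derivation-side coefficient uncertainty is ignored by design.
    """
    if test not in ("lr", "wald"):
        raise ConfigurationError(f"test must be 'lr' or 'wald', got {test!r}")
    covariate_names = list(covariate_names)
    if not covariate_names:
        raise ConfigurationError("misspecification test needs at least one covariate")
    X = sample.data[covariate_names].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < len(covariate_names) + 1:
        _, R = np.linalg.qr(X - X.mean(axis=0))
        diag = np.abs(np.diag(R))
        offending = [covariate_names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise DataError(
            f"collinear covariates: singular information involving {offending or covariate_names}"
        )
    alt = fit_cox(sample, covariate_names, offset_name=pi_name)
    null = fit_cox(sample, [], offset_name=pi_name)
    lr = max(0.0, 2.0 * (alt.log_likelihood - null.log_likelihood))
    beta = alt.coefficients
    wald = float(beta @ np.linalg.solve(alt.covariance, beta))
    df = len(covariate_names)
    joint = lr if test == "lr" else wald
    z = beta / alt.se
    per_cov = pd.DataFrame(
        {
            "beta_star": beta,
            "se": alt.se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=covariate_names,
    )
    return MisspecificationResult(
        beta_star=pd.Series(beta, index=covariate_names),
        covariance=alt.covariance,
        lr_statistic=float(lr),
        wald_statistic=wald,
        joint_statistic=float(joint),
        df=df,
        p_value=float(stats.chi2.sf(joint, df)),
        test=test,
        per_covariate=per_cov,
    )


@dataclass(frozen=True)
class PHCheckResult:
    per_covariate: pd.DataFrame  # chi2, df, p per covariate
    global_statistic: float
    df: int
    p_value: float
    transform: str
    caveat: str = PH_CAVEAT


def _time_transform(sample: SurvivalSample, event_times: np.ndarray, kind: str):
    if kind == "identity":
        return event_times.astype(float)
    if kind == "rank":
        return stats.rankdata(event_times, method="average")
    if kind == "km":
        km = kaplan_meier(sample)
        return 1.0 - km.evaluate(event_times)
    raise ConfigurationError(f"unknown time transform {kind!r}")


def ph_check(
    sample: SurvivalSample,
    covariate_names: Optional[Sequence[str]] = None,
    transform: str = "km",
    ties: str = "efron",
) -> PHCheckResult:
    """Grambsch-Therneau test of proportional hazards.

    Fits a Cox model on ``covariate_names`` (default: the PI alone, slope
    re-estimated), computes Schoenfeld residuals at event times, and tests
    the correlation of each residual with a transform of time (default:
    the Kaplan-Meier transform 1 - S_KM(t), common practice).  The global
    statistic is chi-squared on p degrees of freedom.
    """
    if covariate_names is None:
        covariate_names = [PI_COL]
    covariate_names = list(covariate_names)
    if sample.n_events < 3:
        raise DataError("proportional-hazards check needs at least 3 events")
    fit = fit_cox(sample, covariate_names, ties=ties)
    t_ev, resid = schoenfeld_residuals(sample, covariate_names, fit.coefficients)
    d, p = resid.shape
    g = _time_transform(sample, t_ev, transform)
    gc = g - g.mean()
    ssg = float(gc @ gc)
    u = gc @ resid  # (p,)
    # GT approximation: per-event residual covariance ~ information / d
    Ibar = np.linalg.inv(fit.covariance) / d
    V = ssg * Ibar
    global_stat = float(u @ np.linalg.solve(V, u))
    per_stat = u ** 2 / (ssg * np.diag(Ibar))
    per_cov = pd.DataFrame(
        {
            "chi2": per_stat,
            "df": 1,
            "p": stats.chi2.sf(per_stat, 1),
        },
        index=covariate_names,
    )
    return PHCheckResult(
        per_covariate=per_cov,
        global_statistic=global_stat,
        df=p,
        p_value=float(stats.chi2.sf(global_stat, p)),
        transform=transform,
    )
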