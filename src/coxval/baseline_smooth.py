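"""Transportable smooth baseline: FP2 approximation of ln H0(t).

The baseline survival function S0(t) is the L3 information a publication
must carry before calibration can be checked in new data, yet it is almost
never reported because the Cox model does not estimate it parametrically.
The remedy implemented here: estimate the baseline cumulative hazard H0(t)
in the derivation data (Breslow, PI as offset), then approximate ln H0(t)
by a second-degree fractional polynomial (FP2) in time by ordinary least
squares over the observed event times.  An FP2 with powers (p1, p2) from
the set {-2, -1, -0.5, 0, 0.5, 1, 2, 3} is

    ln H0(t) ~ g0 + g1 * t^p1 + g2 * t^p2,

with the conventions t^0 = ln t and, for repeated powers (p, p), the second
basis function t^p * ln t.  The best pair is chosen by exhaustive search
over all 36 pairs (smallest residual sum of squares).  Three numbers and a
power pair then transport the whole baseline: S0(t) = exp(-exp(ln H0(t))).

Pointwise uncertainty comes from bootstrap resampling of the derivation
subjects: per replicate, a Cox model is fitted to the PI, the baseline
cumulative hazard is predicted, the best FP2 is refitted, and the band is
mean +/- 1.96 SD across replicates on the log cumulative-hazard scale,
back-transformed.

Evaluation outside the fitted time range is refused by default: the point
of truncating validation follow-up is precisely to avoid extrapolating the
baseline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cox_core import StepCurve, baseline_cumhaz, fit_cox
from .exceptions import ConfigurationError, ConvergenceError, DataError
from .model_spec import PI_COL, SurvivalSample

__all__ = [
    "FP_POWERS",
    "fp2_basis",
    "FP2BaselineFit",
    "BaselineLookup",
    "BootstrapBand",
    "fit_fp2_log_cumhaz",
    "bootstrap_band",
    "evaluate_s0",
]

#: The standard fractional-polynomial power set.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_term(t: np.ndarray, power: float) -> np.ndarray:
    return np.log(t) if power == 0 else t ** power


def fp2_basis(t, powers: Sequence[float]) -> np.ndarray:
    """The two FP2 basis columns at time(s) t > 0.

    Repeated powers (p, p) give t^p and t^p * ln t; power 0 means ln t.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise DataError("FP basis is defined for strictly positive times only")
    p1, p2 = powers
    b1 = _fp_term(t, p1)
    b2 = b1 * np.log(t) if p1 == p2 else _fp_term(t, p2)
    return np.column_stack([b1, b2])


@dataclass
class FP2BaselineFit:
    """Fitted FP2 approximation to ln H0(t) — the transportable L3 object."""

    powers: tuple[float, float]
    coefficients: tuple[float, float, float]  # (g0, g1, g2)
    r_squared: float
    time_range: tuple[float, float]
    time_unit: str = "years"
    rss: float = np.nan
    monotone: bool = True

    def __post_init__(self) -> None:
        self.powers = tuple(float(p) for p in self.powers)
        self.coefficients = tuple(float(c) for c in self.coefficients)
        self.time_range = tuple(float(t) for t in self.time_range)
        for p in self.powers:
            if p not in FP_POWERS:
                raise ConfigurationError(f"power {p} outside the FP power set {FP_POWERS}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ConfigurationError("r_squared must lie in [0, 1]")

    def _check_range(self, times: np.ndarray, allow_extrapolation: bool) -> None:
        lo, hi = self.time_range
        tol = 1e-9 * max(1.0, hi)
        if not allow_extrapolation and (
            times.min() < lo - tol or times.max() > hi + tol
        ):
            raise ConfigurationError(
                f"time(s) outside the fitted range [{lo:g}, {hi:g}] "
                f"{self.time_unit}; truncate follow-up rather than "
                "extrapolating the baseline (or pass allow_extrapolation=True)"
            )

    def evaluate_log_cumhaz(self, times, allow_extrapolation: bool = False) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times <= 0):
            raise DataError("baseline evaluation needs strictly positive times")
        self._check_range(times, allow_extrapolation)
        g0, g1, g2 = self.coefficients
        B = fp2_basis(times, self.powers)
        return g0 + B @ np.array([g1, g2])

    def evaluate_s0(self, times, allow_extrapolation: bool = False) -> np.ndarray:
        return np.exp(-np.exp(self.evaluate_log_cumhaz(times, allow_extrapolation)))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline": {
                "form": "fp2_log_cumhaz",
                "powers": list(self.powers),
                "coefficients": list(self.coefficients),
                "r_squared": float(self.r_squared),
                "time_range": list(self.time_range),
                "time_unit": self.time_unit,
            }
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FP2BaselineFit":
        if "baseline" in d:
            d = d["baseline"]
        return cls(
            powers=tuple(d["powers"]),
            coefficients=tuple(d["coefficients"]),
            r_squared=float(d.get("r_squared", 1.0)),
            time_range=tuple(d["time_range"]),
            time_unit=d.get("time_unit", "years"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "FP2BaselineFit":
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
        return cls.from_dict(yaml.safe_load(text))

    def to_lookup_table(self, times) -> pd.DataFrame:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return pd.DataFrame({"time": times, "s0": self.evaluate_s0(times)})


@dataclass
class BaselineLookup:
    """Baseline published as a (time, S0) look-up table.

    Duck-typed like :class:`FP2BaselineFit` (evaluate_log_cumhaz /
    evaluate_s0 / time_range) so the calibration machinery accepts either.
    Interpolation is linear on the ln H0 scale, which preserves positivity
    and monotonicity of the cumulative hazard.
    """

    times: np.ndarray
    s0: np.ndarray
    time_unit: str = "years"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("lookup times must be strictly increasing")
        if np.any((self.s0 <= 0) | (self.s0 >= 1)) or np.any(np.diff(self.s0) > 0):
            raise ConfigurationError("lookup S0 must be non-increasing within (0, 1)")

    @property
    def time_range(self) -> tuple[float, float]:
        return (float(self.times[0]), float(self.times[-1]))

    def evaluate_log_cumhaz(self, times, allow_extrapolation: bool = False) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.time_range
        if not allow_extrapolation and (times.min() < lo or times.max() > hi):
            raise ConfigurationError(
                f"time(s) outside the look-up range [{lo:g}, {hi:g}]; truncate "
                "follow-up rather than extrapolating"
            )
        lnH = np.log(-np.log(self.s0))
        return np.interp(times, self.times, lnH)

    def evaluate_s0(self, times, allow_extrapolation: bool = False) -> np.ndarray:
        return np.exp(-np.exp(self.evaluate_log_cumhaz(times, allow_extrapolation)))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "s0": self.s0}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, time_unit: str = "years") -> "BaselineLookup":
        df = pd.read_csv(path)
        return cls(times=df["time"].to_numpy(), s0=df["s0"].to_numpy(), time_unit=time_unit)


def fit_fp2_log_cumhaz(
    baseline: StepCurve, time_unit: str = "years"
) -> FP2BaselineFit:
    """Exhaustive-search FP2 OLS fit to ln H0 at the observed event times.

    Unweighted ordinary least squares over every power pair; the pair with
    the smallest residual sum of squares wins.  A monotonicity warning is
    attached if the fitted curve decreases anywhere over the fitted range.
    """
    if baseline.flavor != "cumhaz":
        raise ConfigurationError("fit_fp2_log_cumhaz expects a cumulative-hazard curve")
    keep = (baseline.values > 0) & (baseline.times > 0)
    t = baseline.times[keep]
    y = np.log(baseline.values[keep])
    if len(t) < 8:
        raise DataError(
            f"need at least 8 event times with positive H0 to fit an FP2; got {len(t)}"
        )
    best = None
    tss = float(((y - y.mean()) ** 2).sum())
    for p1, p2 in itertools.combinations_with_replacement(FP_POWERS, 2):
        B = np.column_stack([np.ones_like(t), fp2_basis(t, (p1, p2))])
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        rss = float(((y - B @ coef) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, (p1, p2), coef)
    rss, powers, coef = best
    r2 = 1.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    fit = FP2BaselineFit(
        powers=powers,
        coefficients=tuple(coef),
        r_squared=min(r2, 1.0),
        time_range=(float(t.min()), float(t.max())),
        time_unit=time_unit,
        rss=rss,
    )
    grid = np.linspace(fit.time_range[0], fit.time_range[1], 200)
    lnH = fit.evaluate_log_cumhaz(grid)
    if np.any(np.diff(lnH) < -1e-10):
        fit.monotone = False
        warnings.warn(
            "fitted FP2 baseline is not monotone over the fitted time range",
            UserWarning,
        )
    return fit


@dataclass
class BootstrapBand:
    """Pointwise 95% bootstrap band for the baseline cumulative hazard."""

    times: np.ndarray
    lower: np.ndarray  # cumulative-hazard scale
    upper: np.ndarray
    log_mean: np.ndarray
    log_sd: np.ndarray
    n_boot: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        for name in ("times", "lower", "upper", "log_mean", "log_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lower > self.upper):
            raise ConfigurationError("band lower bound exceeds upper bound")

    def to_survival(self) -> pd.DataFrame:
        """The band on the survival scale (bounds swap under exp(-H))."""
        return pd.DataFrame(
            {
                "time": self.times,
                "lower": np.exp(-self.upper),
                "upper": np.exp(-self.lower),
            }
        )

    def contains_log_cumhaz(self, lnH: np.ndarray) -> np.ndarray:
        H = np.exp(np.asarray(lnH, dtype=float))
        return (H >= self.lower) & (H <= self.upper)


def bootstrap_band(
    sample: SurvivalSample,
    n_boot: int = 100,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    pi_name: str = PI_COL,
) -> BootstrapBand:
    """Bootstrap the FP2 baseline fit on resampled derivation subjects.

    Per replicate: resample subjects with replacement, fit a Cox model to
    the PI, predict the baseline cumulative hazard, fit the best FP2, and
    evaluate ln H0 on the grid.  The band is mean +/- 1.96 SD on the log
    cumulative-hazard scale, back-transformed.  Replicates without events
    (or on which the fit degenerates) are redrawn and counted.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be at least 2")
    if pi_name not in sample.data.columns:
        raise ConfigurationError(f"column {pi_name!r} not found; compute the PI first")
    rng = np.random.default_rng(seed)
    n = len(sample)
    if grid is None:
        ev_times = sample.time[sample.event == 1]
        grid = np.linspace(ev_times.min(), ev_times.max(), 100)
    grid = np.asarray(grid, dtype=float)
    draws = np.empty((n_boot, len(grid)))
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        boot = SurvivalSample(
            sample.data.iloc[idx].reset_index(drop=True),
            sample.time_col,
            sample.event_col,
        )
        try:
            if boot.n_events == 0:
                raise DataError("no events in bootstrap replicate")
            if np.ptp(boot.data[pi_name].to_numpy()) == 0:
                raise DataError("degenerate PI in bootstrap replicate")
            fit = fit_cox(boot, [pi_name])
            scaled = boot.copy()
            scaled.data["_boot_lp"] = float(fit.coefficients[0]) * boot.data[pi_name]
            H = baseline_cumhaz(scaled, "_boot_lp")
            with warnings.catch_warnings():
                # non-monotone FP2 tails in small resamples are expected
                warnings.simplefilter("ignore", UserWarning)
                fp = fit_fp2_log_cumhaz(H)
            draws[b] = fp.evaluate_log_cumhaz(grid, allow_extrapolation=True)
        except (DataError, ConvergenceError, np.linalg.LinAlgError) as exc:
            redrawn += 1
            if redrawn > 10 * n_boot:
                raise DataError(
                    f"bootstrap failed: too many degenerate replicates ({exc})"
                )
            continue
        b += 1
    log_mean = draws.mean(axis=0)
    log_sd = draws.std(axis=0, ddof=1)
    lower = np.exp(log_mean - 1.96 * log_sd)
    upper = np.exp(log_mean + 1.96 * log_sd)
    return BootstrapBand(
        times=grid,
        lower=lower,
        upper=upper,
        log_mean=log_mean,
        log_sd=log_sd,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=redrawn,
    )


def evaluate_s0(fit, times, allow_extrapolation: bool = False) -> np.ndarray:
    """Baseline survival S0(t) = exp(-exp(ln H0(t))) from a fitted baseline."""
    return fit.evaluate_s0(times, allow_extrapolation=allow_extrapolation)
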