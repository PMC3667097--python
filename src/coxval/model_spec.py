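"""Published Cox model (L1 information), prognostic index, risk groups.

A published Cox prognostic model is, for validation purposes, its set of
regression coefficients together with a precise statement of how each
covariate was coded and transformed.  This module represents that bundle,
evaluates the prognostic index (PI) — the linear predictor, i.e. the log
relative hazard versus a subject with PI = 0 — on any compatible dataset,
and forms risk groups by cutting the PI at centiles chosen to minimise the
information lost by grouping (Cox's minimal-information-loss centiles;
16th/50th/84th for four groups).

No coefficient is ever re-estimated here: the guiding principle of external
validation is to apply the model in the validation data exactly as it was
applied in the derivation data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError

__all__ = [
    "CovariateTransform",
    "ModelTerm",
    "PublishedModel",
    "SurvivalSample",
    "RiskGrouping",
    "compute_pi",
    "cox_cutpoints",
    "assign_groups",
    "truncate_followup",
    "COX_CENTILES",
    "PI_COL",
    "GROUP_COL",
]

#: Column names used to store the computed PI and risk-group label.
PI_COL = "_pi"
GROUP_COL = "_group"

_KINDS = ("identity", "power", "power_times_log", "indicator")

#: Cox's minimal-information-loss centiles for grouping a (roughly Normal)
#: continuous score into k groups.  For k = 4 the cutpoints are the 16th,
#: 50th and 84th centiles, i.e. approximately mean and mean +/- 1 SD on a
#: standard Normal scale.
COX_CENTILES = {
    2: (50.0,),
    3: (27.0, 73.0),
    4: (16.0, 50.0, 84.0),
    5: (11.0, 35.0, 65.0, 89.0),
}

_FOUR_GROUP_LABELS = ("Good", "Fairly good", "Fairly poor", "Poor")


@dataclass(frozen=True)
class CovariateTransform:
    """How a raw covariate is turned into a model term.

    ``kind`` is one of ``identity``, ``power`` (x^power), ``power_times_log``
    (x^power * ln x) or ``indicator`` (1 if the value equals ``level``).
    ``scale`` is a positive divisor applied to the raw value *before* the
    transformation; published fractional-polynomial models frequently rescale
    covariates this way, and the scaling must be stated explicitly because
    the transformed coefficients are meaningless without it.
    """

    source_name: str
    kind: str = "identity"
    power: Optional[float] = None
    scale: float = 1.0
    level: Optional[object] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown transform kind {self.kind!r}; expected one of {_KINDS}"
            )
        if not (self.scale > 0):
            raise ConfigurationError(
                f"transform for {self.source_name!r}: scale must be > 0, got {self.scale}"
            )
        if self.kind in ("power", "power_times_log") and self.power is None:
            raise ConfigurationError(
                f"transform for {self.source_name!r}: kind {self.kind!r} requires a power"
            )
        if self.kind == "indicator" and self.level is None:
            raise ConfigurationError(
                f"transform for {self.source_name!r}: indicator requires a level"
            )

    @property
    def column_label(self) -> str:
        if self.kind == "identity":
            base = self.source_name
        elif self.kind == "power":
            base = f"{self.source_name}^{self.power:g}"
        elif self.kind == "power_times_log":
            base = f"{self.source_name}^{self.power:g}*ln({self.source_name})"
        else:
            base = f"{self.source_name}=={self.level}"
        if self.scale != 1.0:
            base = f"{base}[/{self.scale:g}]"
        return base

    def evaluate(self, values: pd.Series) -> np.ndarray:
        """Evaluate the transform on one covariate column.

        Raises :class:`DataError` for missing values or for non-positive
        post-scaling values under a power/log transform (no silent
        imputation or clipping).
        """
        if self.kind == "indicator":
            if values.isna().any():
                bad = [int(i) for i in np.flatnonzero(values.isna().to_numpy())[:5]]
                raise DataError(
                    f"missing value for covariate {self.source_name!r} at row(s) {bad}"
                )
            return (values == self.level).to_numpy(dtype=float)

        x = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = [int(i) for i in np.flatnonzero(np.isnan(x))[:5]]
            raise DataError(
                f"missing or non-numeric value for covariate {self.source_name!r} "
                f"at row(s) {bad}"
            )
        x = x / self.scale
        if self.kind == "identity":
            return x
        if np.any(x <= 0):
            bad = [int(i) for i in np.flatnonzero(x <= 0)[:5]]
            raise DataError(
                f"covariate {self.source_name!r}: non-positive value after scaling "
                f"under a power/log transform at row(s) {bad}"
            )
        if self.kind == "power":
            return x ** self.power
        return (x ** self.power) * np.log(x)

    def to_dict(self) -> dict:
        d = {"name": self.source_name, "kind": self.kind}
        if self.power is not None:
            d["power"] = float(self.power)
        if self.scale != 1.0:
            d["scale"] = float(self.scale)
        if self.level is not None:
            d["level"] = self.level
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateTransform":
        return cls(
            source_name=d["name"],
            kind=d.get("kind", "identity"),
            power=d.get("power"),
            scale=float(d.get("scale", 1.0)),
            level=d.get("level"),
        )


@dataclass(frozen=True)
class ModelTerm:
    transform: CovariateTransform
    coefficient: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient):
            raise ConfigurationError(
                f"non-finite coefficient for {self.transform.source_name!r}"
            )


@dataclass(frozen=True)
class PublishedModel:
    """L1 information: transforms, coefficients, and the centering constant.

    ``centering_constant`` is the mean of the (uncentered) linear predictor
    in the derivation data; it is subtracted so that PI = 0 corresponds to
    average derivation risk.  0 is permitted when the model was reported
    uncentered.
    """

    terms: tuple[ModelTerm, ...]
    centering_constant: float = 0.0
    time_unit: str = "years"
    max_followup: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ConfigurationError("a published model needs at least one term")
        object.__setattr__(self, "terms", tuple(self.terms))
        if not np.isfinite(self.centering_constant):
            raise ConfigurationError("centering_constant must be finite")

    @property
    def covariate_names(self) -> list[str]:
        return [t.transform.source_name for t in self.terms]

    def transformed_columns(self, data: pd.DataFrame) -> pd.DataFrame:
        """Evaluate each term's transform; columns named by the term labels."""
        cols = {}
        for i, term in enumerate(self.terms):
            name = term.transform.source_name
            if name not in data.columns:
                raise ConfigurationError(
                    f"model covariate {name!r} is missing from the dataset "
                    f"(available: {list(data.columns)})"
                )
            label = term.transform.column_label
            if label in cols:  # two terms on the same transform label
                label = f"{label}#{i}"
            cols[label] = term.transform.evaluate(data[name])
        return pd.DataFrame(cols, index=data.index)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor (the PI) per subject."""
        Z = self.transformed_columns(data).to_numpy()
        beta = np.array([t.coefficient for t in self.terms])
        return Z @ beta - self.centering_constant

    # -- structured-text round trip -------------------------------------
    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            d = t.transform.to_dict()
            d["coefficient"] = float(t.coefficient)
            if t.se is not None:
                d["se"] = float(t.se)
            terms.append(d)
        out = {
            "time_unit": self.time_unit,
            "centering_constant": float(self.centering_constant),
            "terms": terms,
        }
        if self.max_followup is not None:
            out["max_followup"] = float(self.max_followup)
        return {"model": out}

    @classmethod
    def from_dict(cls, d: dict) -> "PublishedModel":
        if "model" in d:
            d = d["model"]
        try:
            terms = tuple(
                ModelTerm(
                    transform=CovariateTransform.from_dict(td),
                    coefficient=float(td["coefficient"]),
                    se=(float(td["se"]) if "se" in td else None),
                )
                for td in d["terms"]
            )
        except KeyError as e:
            raise ConfigurationError(f"model spec is missing key {e}") from e
        return cls(
            terms=terms,
            centering_constant=float(d.get("centering_constant", 0.0)),
            time_unit=d.get("time_unit", "years"),
            max_followup=(
                float(d["max_followup"]) if d.get("max_followup") is not None else None
            ),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PublishedModel":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class SurvivalSample:
    """One row per subject: follow-up time, event indicator, covariates.

    The computed PI and risk-group label live in the columns ``_pi`` and
    ``_group`` of ``data`` once :func:`compute_pi` / :func:`assign_groups`
    have run.
    """

    data: pd.DataFrame
    time_col: str = "time"
    event_col: str = "event"

    def __post_init__(self) -> None:
        for col in (self.time_col, self.event_col):
            if col not in self.data.columns:
                raise ConfigurationError(f"column {col!r} not found in the dataset")
        t = self.time
        e = self.data[self.event_col].to_numpy()
        if np.isnan(t).any() or (t < 0).any():
            raise DataError("follow-up times must be non-negative and non-missing")
        if not np.isin(e, (0, 1)).all():
            bad = sorted(set(e) - {0, 1})
            raise DataError(
                f"event indicator must be coded 0/1; found value(s) {bad} "
                "(use an explicit event remapping)"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data[self.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data[self.event_col].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def has_pi(self) -> bool:
        return PI_COL in self.data.columns

    @property
    def pi(self) -> np.ndarray:
        if not self.has_pi:
            raise ConfigurationError(
                "PI has not been computed on this sample; call compute_pi first"
            )
        return self.data[PI_COL].to_numpy(dtype=float)

    @property
    def has_group(self) -> bool:
        return GROUP_COL in self.data.columns

    @property
    def group(self) -> pd.Series:
        if not self.has_group:
            raise ConfigurationError(
                "risk groups have not been assigned; call assign_groups first"
            )
        return self.data[GROUP_COL]

    def copy(self) -> "SurvivalSample":
        return SurvivalSample(self.data.copy(), self.time_col, self.event_col)

    def with_pi(self, pi: np.ndarray) -> "SurvivalSample":
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (len(self),):
            raise ConfigurationError("pi must have one value per subject")
        if not np.isfinite(pi).all():
            raise DataError("pi values must all be finite")
        out = self.copy()
        out.data[PI_COL] = pi
        return out


@dataclass(frozen=True)
class RiskGrouping:
    """Strictly increasing PI cutpoints and the ordered group labels."""

    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        object.__setattr__(self, "labels", tuple(self.labels))
        if np.any(np.diff(cp) <= 0):
            raise ConfigurationError("cutpoints must be strictly increasing")
        if len(self.labels) != len(cp) + 1:
            raise ConfigurationError(
                f"{len(cp)} cutpoints need {len(cp) + 1} labels, got {len(self.labels)}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def assign(self, pi: np.ndarray) -> np.ndarray:
        """Group index per subject.

        Intervals are closed on the left and open on the right, the lowest
        interval unbounded below: a PI exactly at a cutpoint goes to the
        higher-risk group.
        """
        return np.searchsorted(np.asarray(self.cutpoints), np.asarray(pi), side="right")

    def to_dict(self) -> dict:
        return {
            "risk_groups": {
                "cutpoints": [float(c) for c in self.cutpoints],
                "labels": list(self.labels),
                "source": self.source,
            }
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskGrouping":
        if "risk_groups" in d:
            d = d["risk_groups"]
        return cls(
            cutpoints=tuple(d["cutpoints"]),
            labels=tuple(d["labels"]),
            source=d.get("source", "unspecified"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RiskGrouping":
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
        return cls.from_dict(yaml.safe_load(text))


def compute_pi(model: PublishedModel, sample: SurvivalSample) -> SurvivalSample:
    """Evaluate the published PI on a sample; no refitting occurs.

    PI_i = sum_k beta_k * transform_k(x_ik) - centering_constant.
    """
    return sample.with_pi(model.linear_predictor(sample.data))


def cox_cutpoints(
    pi_values: Sequence[float],
    n_groups: int = 4,
    centiles: Optional[Sequence[float]] = None,
    source: str = "derivation centiles",
) -> RiskGrouping:
    """Risk-group cutpoints at Cox's minimal-information-loss centiles.

    For four groups these are the 16th, 50th and 84th empirical centiles
    (mean and mean +/- 1 SD on a standard Normal scale).  Percentiles use
    linear interpolation of the empirical distribution (numpy's default,
    type-7).
    """
    pi = np.asarray(pi_values, dtype=float)
    if centiles is None:
        if n_groups not in COX_CENTILES:
            raise ConfigurationError(
                f"n_groups={n_groups} not in the built-in centile table "
                f"{sorted(COX_CENTILES)}; pass explicit centiles"
            )
        centiles = COX_CENTILES[n_groups]
    centiles = tuple(float(c) for c in centiles)
    if len(centiles) != n_groups - 1 or np.any(np.diff(centiles) <= 0) or \
            min(centiles) <= 0 or max(centiles) >= 100:
        raise ConfigurationError(
            f"need {n_groups - 1} strictly increasing centiles in (0, 100)"
        )
    if len(np.unique(pi)) <= n_groups:
        raise DataError(
            "PI distribution is degenerate: fewer distinct values than groups"
        )
    cuts = np.percentile(pi, centiles, method="linear")
    if np.any(np.diff(cuts) <= 0):
        raise DataError(
            "empirical centiles are not strictly increasing; the PI "
            "distribution is too discrete for this grouping"
        )
    if n_groups == 4:
        labels = _FOUR_GROUP_LABELS
    else:
        labels = tuple(f"Group {i + 1}" for i in range(n_groups))
    return RiskGrouping(cutpoints=tuple(cuts), labels=labels, source=source)


def assign_groups(sample: SurvivalSample, grouping: RiskGrouping) -> SurvivalSample:
    """Label each subject with the risk group its PI falls in."""
    idx = grouping.assign(sample.pi)  # raises if PI absent
    out = sample.copy()
    out.data[GROUP_COL] = pd.Categorical.from_codes(
        idx, categories=list(grouping.labels), ordered=True
    )
    return out


def truncate_followup(sample: SurvivalSample, horizon: float) -> SurvivalSample:
    """Administratively censor follow-up beyond ``horizon``.

    Subjects with time > horizon get time = horizon and event = 0; times
    exactly at the horizon are kept unchanged.  Used to keep the validation
    follow-up within the derivation follow-up so the baseline survival
    function is never extrapolated.
    """
    if not (horizon > 0):
        raise ConfigurationError("truncation horizon must be positive")
    out = sample.copy()
    over = out.data[sample.time_col] > horizon
    out.data.loc[over, sample.time_col] = horizon
    out.data.loc[over, sample.event_col] = 0
    return out
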