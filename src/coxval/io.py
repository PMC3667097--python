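"""Readers for validation datasets (delimited text and Stata tables)."""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .exceptions import ConfigurationError, DataError
from .model_spec import SurvivalSample

__all__ = ["load_sample_csv", "load_sample_stata", "make_sample"]


def make_sample(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    event_map: Optional[Mapping] = None,
    time_divisor: Optional[float] = None,
) -> SurvivalSample:
    """Build a SurvivalSample, optionally remapping event codes.

    ``event_map`` maps raw values onto 0/1 explicitly (e.g. {2: 1, 1: 0});
    no silent recoding is performed.  ``time_divisor`` converts the time
    unit (e.g. 12 to go from months to years) — the model's time unit and
    the data's must agree.
    """
    df = df.copy()
    if event_map is not None:
        mapped = df[event_col].map(dict(event_map))
        if mapped.isna().any():
            unmapped = sorted(set(df[event_col][mapped.isna()]))
            raise DataError(f"event values {unmapped} not covered by the event map")
        df[event_col] = mapped
    if time_divisor is not None:
        if not time_divisor > 0:
            raise ConfigurationError("time divisor must be positive")
        df[time_col] = df[time_col] / time_divisor
    return SurvivalSample(df, time_col, event_col)


def load_sample_csv(path, time_col: str = "time", event_col: str = "event",
                    event_map=None, time_divisor=None, **read_kwargs) -> SurvivalSample:
    """Read a delimited-text dataset (header required, one row per subject)."""
    return make_sample(pd.read_csv(path, **read_kwargs), time_col, event_col,
                       event_map, time_divisor)


def load_sample_stata(path, time_col: str, event_col: str,
                      event_map=None, time_divisor=None) -> SurvivalSample:
    """Read a Stata .dta table (e.g. the published breast-cancer examples)."""
    return make_sample(pd.read_stata(path), time_col, event_col,
                       event_map, time_divisor)
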