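"""Stratified soil summaries and percent change against the control.

Soil variables tracked through the chronosequence: pH, soil organic matter
(SOM, g/kg), alkali-hydrolyzable nitrogen (AN, mg/kg) and total phosphorus
(TP, g/kg), each sampled in three depth layers at three canopy positions.
"X % higher than the control" is computed as 100 * (T - C) / C, so
"250.08 % higher" means a 3.5008-fold ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DegenerateInputError, SchemaError
from .io import SoilSample, soil_to_frame

logger = logging.getLogger(__name__)

__all__ = ["SoilSummary", "stratified_summary", "percent_change_vs_control",
           "soil_summary_table"]

SOIL_VARIABLES = ("pH", "SOM", "AN", "TP")

# dimension name -> column in the flattened soil frame
_DIMS = {"restoration_years": "restoration_years",
         "depth_layer": "depth_layer",
         "position": "position"}


@dataclass(frozen=True)
class SoilSummary:
    """Mean/sd of one variable within one group; collapsed dims read "all"."""

    restoration_years: int | str
    depth_layer: str
    position: str
    variable: str
    mean: float
    sd: float
    n: int


def stratified_summary(samples: Iterable[SoilSample],
                       by: Sequence[str] = ("restoration_years",
                                            "depth_layer", "position"),
                       variables: Sequence[str] = SOIL_VARIABLES
                       ) -> list[SoilSummary]:
    """Group samples by the requested dimensions and summarise each variable.

    ``by`` lists any subset of {restoration_years, depth_layer, position};
    dimensions left out are collapsed and reported as ``"all"``. Mean is
    arithmetic; sd is the sample (n-1) standard deviation, 0 when n = 1.
    """
    for dim in by:
        if dim not in _DIMS:
            raise SchemaError(f"unknown grouping dimension {dim!r}")
    for var in variables:
        if var not in SOIL_VARIABLES:
            raise SchemaError(f"unknown soil variable {var!r}")
    df = soil_to_frame(samples)
    if df.empty:
        raise DegenerateInputError("no soil samples")
    keys = [_DIMS[d] for d in by]
    grouped = df.groupby(keys, sort=True) if keys else [((), df)]
    out: list[SoilSummary] = []
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        labels = dict(zip(keys, key))
        for var in variables:
            vals = sub[var]
            n = int(vals.count())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            out.append(SoilSummary(
                restoration_years=labels.get("restoration_years", "all"),
                depth_layer=labels.get("depth_layer", "all"),
                position=labels.get("position", "all"),
                variable=var,
                mean=float(vals.mean()),
                sd=sd,
                n=n,
            ))
    return out


def percent_change_vs_control(treatment_mean: float,
                              control_mean: float) -> float:
    """Percent change of a treatment mean relative to the control mean.

    100 * (T - C) / C; positive when the treatment exceeds the control.
    """
    if control_mean <= 0:
        raise DegenerateInputError(
            f"control mean must be > 0, got {control_mean}")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def soil_summary_table(samples: Iterable[SoilSample],
                       by: Sequence[str] = ("restoration_years",
                                            "depth_layer", "position"),
                       control_years: int = 0) -> pd.DataFrame:
    """Summary table with percent change vs the year-``control_years`` group.

    The control for each (depth_layer, position, variable) cell is the mean
    of the matching group at the control age; rows whose control is absent
    or non-positive carry NA in ``pct_change_vs_control``.
    """
    summaries = stratified_summary(samples, by=by)
    rows = [s.__dict__ for s in summaries]
    df = pd.DataFrame(rows)
    control = {
        (s.depth_layer, s.position, s.variable): s.mean
        for s in summaries
        if s.restoration_years == control_years
    }

    def pct(row):
        c = control.get((row["depth_layer"], row["position"],
                         row["variable"]))
        if c is None or c <= 0:
            return float("nan")
        return percent_change_vs_control(row["mean"], c)

    if "restoration_years" in by:
        df["pct_change_vs_control"] = df.apply(pct, axis=1)
    else:
        df["pct_change_vs_control"] = float("nan")
    return df
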