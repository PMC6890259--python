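"""Continuous forcing functions built from sampled arterial time courses.

The model treats the arterial side as exogenous: measured arterial
concentrations of insulin, glucose, triglyceride, glycerol and NEFA are
interpolated and supplied as dependent inputs to the flux terms.
Piecewise-linear interpolation with constant extrapolation outside the
sampled range is a documented convention of this package (with only seven
samples, splines overshoot and can go negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .io import ARTERIAL_ANALYTES

__all__ = ["ForcingSet", "build_forcing", "basal_value"]


@dataclass
class ForcingSet:
    """Piecewise-linear arterial forcings plus the basal insulin level.

    Attributes
    ----------
    nodes : dict
        Per analyte, ``(times, values)`` arrays defining the interpolant.
    basal_insulin : float
        I_B, mean of the fasting insulin samples (uU/ml).
    """

    nodes: dict[str, tuple[np.ndarray, np.ndarray]]
    basal_insulin: float
    fasting: dict[str, float] = field(default_factory=dict)

    def __call__(self, analyte: str, t):
        """Evaluate one arterial forcing at time(s) ``t``.

        Exact at sample nodes; constant extrapolation outside the sampled
        interval.
        """
        xp, fp = self.nodes[analyte]
        return np.interp(t, xp, fp)

    def insulin(self, t):
        return self("insulin", t)

    def as_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return self.nodes


def basal_value(times: np.ndarray, values: np.ndarray) -> float:
    """Basal (fasting) reference level: mean of the samples at t <= 0.

    A single fasting sample is returned as-is.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = times <= 0.0
    if not mask.any():
        raise InsufficientDataError("no fasting sample (t <= 0) available")
    return float(values[mask].mean())


def build_forcing(arterial: pd.DataFrame, min_points: int = 4) -> ForcingSet:
    """Build a :class:`ForcingSet` from the arterial slice of a study table.

    Parameters
    ----------
    arterial : DataFrame
        Long-format table with columns ``time``, ``metabolite``, ``value``
        (one subject, or a cohort mean), site already restricted to
        arterial samples.
    min_points : int
        Minimum number of distinct sample times per analyte.
    """
    nodes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fasting: dict[str, float] = {}
    for analyte in ARTERIAL_ANALYTES:
        sub = arterial[arterial["metabolite"] == analyte]
        if sub.empty:
            raise InsufficientDataError(f"no arterial samples for {analyte!r}")
        grp = sub.groupby("time")["value"].mean().sort_index()
        times = grp.index.to_numpy(dtype=float)
        values = grp.to_numpy(dtype=float)
        if len(times) < min_points:
            raise InsufficientDataError(
                f"{analyte!r} has {len(times)} sample times; need >= {min_points}"
            )
        if np.any(values < 0):
            raise InsufficientDataError(f"negative arterial concentration for {analyte!r}")
        nodes[analyte] = (times, values)
        fasting[analyte] = basal_value(times, values)
    i_b = fasting["insulin"]
    if not i_b > 0:
        raise InsufficientDataError(f"basal insulin must be positive, got {i_b}")
    return ForcingSet(nodes=nodes, basal_insulin=i_b, fasting=fasting)
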