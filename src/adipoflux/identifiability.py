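"""Profile-likelihood identifiability analysis and local sensitivities.

A parameter is profiled by fixing it on a grid around its optimum and
re-estimating all remaining parameters at each grid value (warm-started
from the neighbouring grid point).  The resulting cost profile is
classified against the chi-square threshold for one degree of freedom at
95% (delta = 3.84): crossing on both sides within the grid means the
parameter is identifiable, crossing on one side only means it has a
practical upper or lower bound, and a flat profile means it is
practically non-identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PARAM_NAMES, FLUX_SERIES
from .estimation import FitResult, fit_local
from .exceptions import AdipofluxError
from .forcing import ForcingSet
from .model import ModelParameters, simulate
from .observables import FluxDataset

__all__ = [
    "ProfileGrid",
    "ProfileResult",
    "profile_likelihood",
    "classify_identifiability",
    "local_sensitivities",
    "PROFILE_THRESHOLD",
]

#: chi-square quantile, 1 dof, 95%
PROFILE_THRESHOLD = 3.84

CLASSES = ("identifiable", "bounded_above", "bounded_below", "non_identifiable")


@dataclass
class ProfileGrid:
    """Grid specification: log-spaced, ``span_decades`` each side of the
    optimum with ``n_per_side`` points (coarse default keeps a full
    14-parameter scan tractable)."""

    n_per_side: int = 5
    span_decades: float = 2.0


@dataclass
class ProfileResult:
    parameter: str
    values: np.ndarray          # grid (ascending), optimum included
    costs: np.ndarray           # re-optimized cost at each grid value
    optimum_value: float
    optimum_cost: float
    classification: str
    flags: list[str] = field(default_factory=list)


def _grid_sides(opt_value: float, bounds: tuple[float, float],
                grid: ProfileGrid):
    lo_b, hi_b = bounds
    v = max(opt_value, 1e-12 * max(hi_b, 1.0))
    factor = 10.0 ** grid.span_decades
    upper_end = min(v * factor, hi_b)
    lower_end = max(v / factor, lo_b if lo_b > 0 else v / factor)
    up = np.geomspace(v, upper_end, grid.n_per_side + 1)[1:]
    down = np.geomspace(v, lower_end, grid.n_per_side + 1)[1:]
    return down, up


def profile_likelihood(
    fit: FitResult,
    param: str,
    dataset: FluxDataset,
    forcing: ForcingSet,
    grid: ProfileGrid | None = None,
    series: tuple[str, ...] | None = None,
) -> ProfileResult:
    """Profile one parameter around the fitted optimum.

    Walks outward from the optimum on each side, fixing ``param`` and
    re-fitting the remaining parameters locally from the previous grid
    point's optimum.  A refit failure at a grid point is flagged and the
    profile continues from the last good optimum.
    """
    if param not in PARAM_NAMES:
        raise AdipofluxError(f"unknown parameter {param!r}")
    grid = grid or ProfileGrid()
    # profile refits resolve the cost against a threshold of 3.84, so they
    # need far less precision than the final fit: forward differences,
    # looser solver/optimizer tolerances and an iteration cap keep the
    # full 14-parameter scan tractable
    import copy
    config = copy.deepcopy(fit.config)
    config.optimizer.local_jac = "2-point"
    config.optimizer.local_ftol = 1e-6
    config.optimizer.local_xtol = 1e-8
    config.optimizer.local_gtol = 1e-8
    config.optimizer.local_max_nfev = 40 * (len(PARAM_NAMES) + 1)
    config.solver.rtol = 1e-6
    config.solver.atol = 1e-8
    opt_params = fit.model_parameters()
    opt_value = fit.params[param]
    down, up = _grid_sides(opt_value, config.bounds[param], grid)

    flags: list[str] = []

    def walk(values):
        costs = []
        start = opt_params
        for v in values:
            try:
                sub = fit_local(start, dataset, forcing, config,
                                series=series, fixed={param: float(v)})
                costs.append(sub.cost)
                start = sub.model_parameters()
            except AdipofluxError as exc:  # pragma: no cover - solver edge
                flags.append(f"refit failed at {param}={v:.4g}: {exc}")
                costs.append(np.nan)
        return np.asarray(costs)

    cost_down = walk(down)
    cost_up = walk(up)

    values = np.concatenate([down[::-1], [opt_value], up])
    costs = np.concatenate([cost_down[::-1], [fit.cost], cost_up])

    threshold = fit.cost + PROFILE_THRESHOLD
    crosses_low = np.nanmax(cost_down) >= threshold if cost_down.size else False
    crosses_high = np.nanmax(cost_up) >= threshold if cost_up.size else False
    # hitting a hard parameter bound that keeps the profile below the
    # threshold counts as not crossing on that side
    if crosses_low and crosses_high:
        classification = "identifiable"
    elif crosses_high:
        classification = "bounded_above"
    elif crosses_low:
        classification = "bounded_below"
    else:
        classification = "non_identifiable"

    prof_min = np.nanmin(costs)
    if prof_min < fit.cost - 1e-3 * max(fit.cost, 1.0):
        flags.append(
            f"profile found a lower cost ({prof_min:.6g} < {fit.cost:.6g}); "
            "the fit may not be at the global optimum"
        )

    return ProfileResult(
        parameter=param, values=values, costs=costs,
        optimum_value=opt_value, optimum_cost=fit.cost,
        classification=classification, flags=flags,
    )


def classify_identifiability(profiles: list[ProfileResult]):
    """Summary counts per identifiability class plus a per-parameter map."""
    per_param = {p.parameter: p.classification for p in profiles}
    counts = {c: 0 for c in CLASSES}
    for c in per_param.values():
        counts[c] += 1
    counts["bounded"] = counts["bounded_above"] + counts["bounded_below"]
    return counts, per_param


def local_sensitivities(
    p: ModelParameters,
    forcing: ForcingSet,
    t_grid,
    rel_step: float = 1e-4,
    solver=None,
):
    """Central-difference sensitivities d flux_j(t_i) / d log p_k.

    Differences are taken on log-parameters (the parameters span several
    orders of magnitude); a parameter at zero gets a one-sided difference
    on an absolute step and is flagged.

    Returns ``(sens, flags)`` with ``sens[series][param]`` an array over
    ``t_grid``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    flags: list[str] = []
    base = simulate(p, forcing, t_grid=t_grid, solver=solver)
    sens: dict[str, dict[str, np.ndarray]] = {s: {} for s in FLUX_SERIES}
    for name in PARAM_NAMES:
        v = getattr(p, name)
        if v > 0:
            hi = p.replace(**{name: v * np.exp(rel_step)})
            lo = p.replace(**{name: v * np.exp(-rel_step)})
            f_hi = simulate(hi, forcing, t_grid=t_grid, solver=solver).fluxes
            f_lo = simulate(lo, forcing, t_grid=t_grid, solver=solver).fluxes
            for s in FLUX_SERIES:
                sens[s][name] = (np.asarray(f_hi[s]) - np.asarray(f_lo[s])) / (2 * rel_step)
        else:
            flags.append(f"{name} at zero: one-sided absolute difference")
            step = rel_step
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_hi = simulate(p.replace(**{name: step}), forcing,
                                t_grid=t_grid, solver=solver).fluxes
            for s in FLUX_SERIES:
                sens[s][name] = (np.asarray(f_hi[s]) - np.asarray(base.fluxes[s])) / step
    return sens, flags
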