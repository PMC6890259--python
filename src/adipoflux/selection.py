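"""AICc-based selection among candidate flux-term variants.

Each measured flux series can be described by competing rate laws (a
divide-and-conquer decomposition: every variant is fit to one series in
isolation, with arterial curves as forcings).  Variants of differing
complexity are ranked with the small-sample-corrected Akaike Information
Criterion computed from the sigma-weighted residual sum of squares.

Built-in variants
-----------------
TG (LPL lipolysis of circulating TG):
  * ``lpl_linear_delayed``    k * [TG_art] * I_delay(tau)      (k = 2)
  * ``lpl_linear_undelayed``  k * [TG_art] * [I_art]           (k = 1)
  * ``lpl_mm_delayed``        Vmax [TG_art]/(Km+[TG_art]) * I_delay  (k = 3)
Spill-over fraction:
  * ``spill_insulin_only``    d/100 * I_B/[I_art]              (k = 1)
  * ``spill_basal_insulin``   (s0 + d * I_B/[I_art]) / 100     (k = 2)
  * ``spill_constant``        s0 / 100                         (k = 1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .exceptions import AdipofluxError, ParameterError
from .forcing import ForcingSet
from .observables import FluxDataset

__all__ = ["TermVariant", "aicc", "select_term", "builtin_variants"]


def aicc(rss: float, n_obs: int, k_params: int) -> float:
    """Small-sample-corrected Akaike Information Criterion.

    n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1), with RSS the weighted
    residual sum of squares (the fitting cost).
    """
    if n_obs - k_params - 1 <= 0:
        raise ParameterError(
            f"AICc undefined for n={n_obs}, k={k_params} (n - k - 1 <= 0)"
        )
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n_obs * math.log(rss / n_obs) + 2 * k_params \
        + 2 * k_params * (k_params + 1) / (n_obs - k_params - 1)


def _delayed_insulin(forcing: ForcingSet, tau: float, times: np.ndarray) -> np.ndarray:
    """Three-compartment delay chain output driven by the arterial insulin
    interpolant, started at basal insulin."""
    t_i, v_i = forcing.nodes["insulin"]
    i_b = forcing.basal_insulin
    inv = 1.0 / tau

    def rhs(t, y):
        i_art = np.interp(t, t_i, v_i)
        return ((i_art - y[0]) * inv, (y[0] - y[1]) * inv, (y[1] - y[2]) * inv)

    t0, t1 = float(times[0]), float(times[-1])
    sol = solve_ivp(rhs, (t0, t1), [i_b] * 3, method="LSODA",
                    rtol=1e-8, atol=1e-10, dense_output=True)
    if not sol.success:  # pragma: no cover
        raise AdipofluxError(f"delay-chain integration failed: {sol.message}")
    return sol.sol(times)[2]


@dataclass
class TermVariant:
    """A candidate rate expression for one flux series.

    ``predict(theta, forcing, times)`` returns the series prediction in
    the measured convention; ``theta`` has length ``len(param_names)``.
    """

    name: str
    series: str
    param_names: tuple[str, ...]
    predict: Callable[[np.ndarray, ForcingSet, np.ndarray], np.ndarray]
    bounds: tuple[tuple[float, float], ...]
    init: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


def _v_lpl_delayed(theta, forcing, times):
    k_ad, tau = theta
    if tau <= 0:
        return np.full_like(times, 1e6, dtype=float)
    i_d = _delayed_insulin(forcing, tau, times)
    return k_ad * forcing("tg", times) * i_d


def _v_lpl_undelayed(theta, forcing, times):
    (k_ad,) = theta
    return k_ad * forcing("tg", times) * forcing("insulin", times)


def _v_lpl_mm_delayed(theta, forcing, times):
    vmax, km, tau = theta
    if tau <= 0 or km < 0:
        return np.full_like(times, 1e6, dtype=float)
    i_d = _delayed_insulin(forcing, tau, times)
    tg = forcing("tg", times)
    return vmax * tg / (km + tg) * i_d


def _v_spill_insulin(theta, forcing, times):
    (d,) = theta
    f = (d / 100.0) * forcing.basal_insulin / forcing("insulin", times)
    return np.clip(f, 0.0, 1.0)


def _v_spill_basal_insulin(theta, forcing, times):
    s0, d = theta
    f = (s0 + d * forcing.basal_insulin / forcing("insulin", times)) / 100.0
    return np.clip(f, 0.0, 1.0)


def _v_spill_constant(theta, forcing, times):
    (s0,) = theta
    return np.full_like(np.asarray(times, dtype=float), s0 / 100.0).clip(0.0, 1.0)


def builtin_variants(series: str) -> list[TermVariant]:
    if series == "tg":
        return [
            TermVariant("lpl_linear_delayed", "tg", ("k_ad", "tau_lpl"),
                        _v_lpl_delayed, ((0.0, 1.0), (1.0, 600.0)), (0.01, 120.0)),
            TermVariant("lpl_linear_undelayed", "tg", ("k_ad",),
                        _v_lpl_undelayed, ((0.0, 1.0),), (0.01,)),
            TermVariant("lpl_mm_delayed", "tg", ("vmax", "km", "tau_lpl"),
                        _v_lpl_mm_delayed,
                        ((0.0, 10.0), (1e-3, 50.0), (1.0, 600.0)),
                        (0.02, 2.0, 120.0)),
        ]
    if series == "spill":
        return [
            TermVariant("spill_insulin_only", "spill", ("d_spill",),
                        _v_spill_insulin, ((0.0, 100.0),), (25.0,)),
            TermVariant("spill_basal_insulin", "spill", ("s_basal", "d_spill"),
                        _v_spill_basal_insulin,
                        ((0.0, 100.0), (0.0, 100.0)), (10.0, 15.0)),
            TermVariant("spill_constant", "spill", ("s_constant",),
                        _v_spill_constant, ((0.0, 100.0),), (25.0,)),
        ]
    raise AdipofluxError(f"no built-in variants for series {series!r}")


def _fit_variant(variant: TermVariant, dataset: FluxDataset,
                 forcing: ForcingSet, seed: int, n_starts: int = 20):
    """Multi-start weighted least squares of one variant against one series."""
    s = variant.series
    mask = dataset.mask[s]
    times = dataset.times[mask]
    mu = dataset.mu[s][mask]
    sigma = dataset.sigma[s][mask]
    lo = np.array([b[0] for b in variant.bounds])
    hi = np.array([b[1] for b in variant.bounds])

    def resid(theta):
        pred = variant.predict(theta, forcing, times)
        r = (pred - mu) / sigma
        return np.where(np.isfinite(r), r, 1e6)

    rng = np.random.default_rng(seed)
    starts = [np.asarray(variant.init, dtype=float)]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise AdipofluxError(f"variant {variant.name} could not be fitted")
    return best


def select_term(
    variants: list[TermVariant],
    dataset: FluxDataset,
    forcing: ForcingSet,
    seed: int = 0,
    n_obs: int | None = None,
) -> pd.DataFrame:
    """Fit each variant to its flux series and rank by AICc (ascending).

    ``n_obs`` defaults to the number of included points of the series
    (the canonical seven when all are usable).  Ties are broken by a
    stable sort on the variant name.  Variants whose fit fails are
    excluded and flagged in the ``failed`` column of the output.
    """
    if len(variants) < 2:
        raise AdipofluxError("need at least 2 variants to select among")
    rows = []
    for i, v in enumerate(variants):
        n = n_obs if n_obs is not None else int(dataset.mask[v.series].sum())
        try:
            rss, theta = _fit_variant(v, dataset, forcing, seed=seed + i)
            score = aicc(rss, n, v.k)
            rows.append({"variant": v.name, "series": v.series, "k": v.k,
                         "n_obs": n, "rss": rss, "aicc": score,
                         "params": dict(zip(v.param_names, map(float, theta))),
                         "failed": False})
        except AdipofluxError as exc:
            rows.append({"variant": v.name, "series": v.series, "k": v.k,
                         "n_obs": n, "rss": np.nan, "aicc": np.inf,
                         "params": {}, "failed": True, "flag": str(exc)})
    df = pd.DataFrame(rows).sort_values(
        ["aicc", "variant"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
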