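"""Synthetic arteriovenous meal-challenge cohorts.

The generator emulates the sampling design of a 16-subject mixed-meal
arteriovenous study: seven sampling times (-30, 0, 60, 120, 180, 240,
300 min), a fasting plateau followed by postprandial excursions, adipose
tissue blood flow, and a meal tracer labelling dietary TG.  Every other
module of the package is testable against it without any download.

Arterial curve family: a fasting plateau plus a log-normal-shaped
postprandial bump per analyte (amplitude, peak time, log-width); NEFA is
plateau minus an insulin-driven dip plus a late rebound.  Between-subject
variability is log-normal on the shape parameters; measurement noise is
additive Gaussian per flux series with an SD proportional to the series'
dynamic range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CANONICAL_TIMES
from .exceptions import AdipofluxError
from .forcing import ForcingSet, build_forcing
from .model import ModelParameters, SimulationResult, simulate
from .observables import FluxDataset, tracer_spill_fraction

__all__ = [
    "ShapeParams",
    "CohortSpec",
    "generate_arterial_profiles",
    "generate_cohort_fluxes",
    "generate_tracer_series",
    "cohort_mean_forcing",
]


@dataclass
class ShapeParams:
    """Fasting level plus a log-normal postprandial bump."""

    fasting: float
    amplitude: float
    peak_time: float
    width: float  # log-scale width

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.fasting + _bump(t, self.amplitude, self.peak_time, self.width)


def _bump(t, amplitude, peak_time, width):
    """Log-normal-shaped excursion, zero at and before t = 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = np.log(t[pos] / peak_time)
    out[pos] = amplitude * np.exp(-(x * x) / (2.0 * width * width))
    return out


def _default_shapes() -> dict[str, ShapeParams]:
    # fasting levels and excursions typical of an overweight cohort after
    # a high-fat mixed meal: insulin/glucose peak 60-120 min, TG peaks
    # late (180-240 min), glycerol varies modestly
    return {
        "insulin": ShapeParams(8.0, 50.0, 75.0, 0.50),   # uU/ml
        "glucose": ShapeParams(5.2, 2.5, 60.0, 0.45),    # mmol/l
        "tg": ShapeParams(1.2, 0.9, 210.0, 0.45),        # mmol/l
        # glycerol roughly doubles after a mixed meal; the excursion must be
        # large enough that the net glycerol flux transiently turns into an
        # uptake, as observed arteriovenously
        "glycerol": ShapeParams(0.08, 0.08, 120.0, 0.60),  # mmol/l
    }


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults are the emulated study design: 16 subjects, the canonical
    7-point grid, the baseline ground-truth parameters, flux noise SD of
    15% of each series' dynamic range, and constant ATBF.
    """

    seed: int
    n_subjects: int = 16
    times: tuple[float, ...] = CANONICAL_TIMES
    true_params: ModelParameters = field(default_factory=ModelParameters.baseline)
    shapes: dict[str, ShapeParams] = field(default_factory=_default_shapes)
    # NEFA: plateau - dip + late rebound
    nefa_fasting: float = 0.55
    nefa_dip: tuple[float, float, float] = (0.35, 90.0, 0.50)      # (A, Tp, w)
    nefa_rebound: tuple[float, float, float] = (0.25, 280.0, 0.35)
    nefa_floor: float = 0.05
    shape_cv: float = 0.20        # lognormal CV on levels/amplitudes
    peak_time_cv: float = 0.10    # lognormal CV on peak times
    noise_frac: float = 0.15      # flux noise SD as fraction of dynamic range
    noise_prop_floor: float = 0.02  # proportional noise floor
    spill_late_inflation: float = 2.5  # spill noise factor after 180 min
    tracer_peak: float = 150.0    # meal-appearance envelope peak (min)
    tracer_width: float = 0.60
    atbf: float = 3.0             # ml/(100 ml tissue . min)
    max_retries: int = 5

    def __post_init__(self) -> None:
        if self.shape_cv < 0 or self.noise_frac < 0:
            raise AdipofluxError("CVs and noise fractions must be >= 0")
        for s in self.shapes.values():
            if s.fasting <= 0:
                raise AdipofluxError("fasting levels must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size else 1.0
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _subject_arterial(spec: CohortSpec, rng: np.random.Generator):
    """One subject's arterial concentration curves at the sampling times."""
    t = np.asarray(spec.times, dtype=float)
    curves: dict[str, np.ndarray] = {}
    for analyte, shape in spec.shapes.items():
        fasting = shape.fasting * _lognormal_factor(rng, spec.shape_cv)
        amp = shape.amplitude * _lognormal_factor(rng, spec.shape_cv)
        peak = shape.peak_time * _lognormal_factor(rng, spec.peak_time_cv)
        curves[analyte] = fasting + _bump(t, amp, peak, shape.width)
    # NEFA: dip under insulin then late rebound above fasting
    f0 = spec.nefa_fasting * _lognormal_factor(rng, spec.shape_cv)
    a_d, t_d, w_d = spec.nefa_dip
    a_r, t_r, w_r = spec.nefa_rebound
    dip = _bump(t, a_d * _lognormal_factor(rng, spec.shape_cv),
                t_d * _lognormal_factor(rng, spec.peak_time_cv), w_d)
    reb = _bump(t, a_r * _lognormal_factor(rng, spec.shape_cv),
                t_r * _lognormal_factor(rng, spec.peak_time_cv), w_r)
    curves["nefa"] = np.maximum(f0 - dip + reb, spec.nefa_floor)
    return curves


def _forcing_from_curves(times, curves) -> ForcingSet:
    rows = []
    for analyte, vals in curves.items():
        for t, v in zip(times, vals):
            rows.append({"subject_id": "s", "time": t, "site": "arterial",
                         "metabolite": analyte, "value": v})
    return build_forcing(pd.DataFrame(rows))


def generate_arterial_profiles(spec: CohortSpec) -> list[ForcingSet]:
    """Per-subject arterial forcings, reproducible from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_subjects):
        curves = _subject_arterial(spec, rng)
        out.append(_forcing_from_curves(spec.times, curves))
    return out


def generate_tracer_series(
    spec: CohortSpec,
    sim: SimulationResult,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
):
    """Labelled TG-hydrolysis and NEFA-efflux series for one subject.

    The meal tracer labels dietary TG with a log-normal appearance
    envelope; labelled NEFA efflux is the model spill fraction times the
    labelled hydrolysis, with noise on the recovered fraction that is
    inflated after 180 min (emulating label recycling).  With zero noise,
    ``tracer_spill_fraction`` inverts the construction exactly.
    """
    t = np.asarray(spec.times, dtype=float)
    fluxes = sim.eval_at(t)
    envelope = _bump(t, 1.0, spec.tracer_peak, spec.tracer_width)
    hyd = envelope * np.asarray(fluxes["tg"], dtype=float)
    frac = np.asarray(fluxes["spill"], dtype=float)
    if noise_sd > 0:
        sd = np.where(t > 180.0, spec.spill_late_inflation * noise_sd, noise_sd)
        frac = np.clip(frac + rng.normal(0.0, sd), 0.0, 1.0)
    rel = frac * hyd
    return hyd, rel


def _nominal_sigma(mu_mat: np.ndarray, noise_frac: float) -> float:
    """Fitting weight for a zero-dispersion series (documented convention:
    the would-be noise scale of the series, never zero)."""
    finite = mu_mat[np.isfinite(mu_mat)]
    if finite.size == 0:
        return 1.0
    rng_ = float(finite.max() - finite.min())
    return max(noise_frac * rng_, 1e-3 * float(np.abs(finite).max()), 1e-6)


def generate_cohort_fluxes(spec: CohortSpec):
    """Generate a full synthetic cohort.

    Returns ``(study_table, flux_dataset, true_params)``.  Per subject,
    the model is simulated at the true parameters under that subject's
    arterial forcing; the five flux series are evaluated at the sampling
    times, Gaussian noise is added, and venous concentrations are
    back-computed as ``venous = arterial - flux/atbf`` so that the A-V
    calculation reproduces the noisy flux exactly.  Cross-subject means
    and standard deviations form the :class:`FluxDataset`; when the
    dispersion is degenerate (single subject or zero noise/variability) a
    nominal positive weight replaces sigma.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    n, m = spec.n_subjects, len(t)

    flux_mats = {s: np.full((n, m), np.nan) for s in
                 ("tg", "glucose", "glycerol", "nefa", "spill")}
    rows: list[dict] = []

    # noiseless noise scales are set from a reference subject at the
    # cohort-mean shapes so the noise level is a property of the design,
    # not of any one draw
    ref_curves = {a: s.curve(t) for a, s in spec.shapes.items()}
    f0 = spec.nefa_fasting
    ref_curves["nefa"] = np.maximum(
        f0 - _bump(t, *spec.nefa_dip) + _bump(t, *spec.nefa_rebound),
        spec.nefa_floor,
    )
    ref_sim = simulate(spec.true_params, _forcing_from_curves(t, ref_curves), t_grid=t)
    noise_sd = {}
    for s in ("tg", "glucose", "glycerol", "nefa", "spill"):
        vals = np.asarray(ref_sim.fluxes[s], dtype=float)
        noise_sd[s] = spec.noise_frac * float(vals.max() - vals.min())

    for si in range(spec.n_subjects):
        for attempt in range(spec.max_retries):
            curves = _subject_arterial(spec, rng)
            try:
                forcing = _forcing_from_curves(t, curves)
                sim = simulate(spec.true_params, forcing, t_grid=t)
                break
            except AdipofluxError:  # pragma: no cover - resample pathological draw
                continue
        else:  # pragma: no cover
            raise AdipofluxError(f"subject {si}: no valid draw in {spec.max_retries} tries")

        subj = f"S{si + 1:02d}"
        fluxes = {k: np.asarray(v, dtype=float) for k, v in sim.eval_at(t).items()}
        for s in ("tg", "glucose", "glycerol", "nefa"):
            noisy = fluxes[s].copy()
            if spec.noise_frac > 0:
                sd = np.maximum(noise_sd[s], spec.noise_prop_floor * np.abs(noisy))
                noisy += rng.normal(0.0, sd)
            flux_mats[s][si] = noisy

        hyd, rel = generate_tracer_series(
            spec, sim, rng,
            noise_sd=noise_sd["spill"] if spec.noise_frac > 0 else 0.0,
        )
        flux_mats["spill"][si] = tracer_spill_fraction(hyd, rel)

        met_map = {"tg": "tg", "glucose": "glucose",
                   "glycerol": "glycerol", "nefa": "nefa"}
        for ti, tt in enumerate(t):
            for analyte, art in curves.items():
                rows.append({"subject_id": subj, "time": tt, "site": "arterial",
                             "metabolite": analyte, "value": art[ti],
                             "atbf": spec.atbf})
            for s, met in met_map.items():
                art = curves[met][ti]
                ven = max(art - flux_mats[s][si, ti] / spec.atbf, 0.0)
                rows.append({"subject_id": subj, "time": tt, "site": "venous",
                             "metabolite": met, "value": ven,
                             "atbf": spec.atbf})
            rows.append({"subject_id": subj, "time": tt, "site": "arterial",
                         "metabolite": "tg_tracer", "value": max(hyd[ti], 0.0),
                         "atbf": spec.atbf})
            rows.append({"subject_id": subj, "time": tt, "site": "arterial",
                         "metabolite": "nefa_tracer", "value": max(rel[ti], 0.0),
                         "atbf": spec.atbf})

    table = pd.DataFrame(rows)

    mu, sigma = {}, {}
    degenerate = spec.n_subjects < 2 or (
        spec.noise_frac == 0 and spec.shape_cv == 0 and spec.peak_time_cv == 0
    )
    import warnings
    for s, mat in flux_mats.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu[s] = np.nanmean(mat, axis=0)
            sd = (np.nanstd(mat, axis=0, ddof=1)
                  if spec.n_subjects > 1 else np.zeros(m))
        if degenerate or not np.any(sd > 0):
            sd = np.full(m, _nominal_sigma(mat, max(spec.noise_frac, 0.15)))
        else:
            # guard isolated zero-dispersion points
            sd = np.where(sd > 0, sd, _nominal_sigma(mat, max(spec.noise_frac, 0.15)))
        sd = np.where(np.isfinite(mu[s]), sd, np.nan)
        sigma[s] = sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = FluxDataset.from_series(t, mu, sigma, n_subjects=spec.n_subjects)
    return table, dataset, spec.true_params


def cohort_mean_forcing(table: pd.DataFrame) -> ForcingSet:
    """Cohort-mean arterial forcing (the fitting input) from a study table."""
    arterial = table[(table["site"] == "arterial")
                     & table["metabolite"].isin(
                         ["insulin", "glucose", "tg", "glycerol", "nefa"])]
    return build_forcing(arterial)
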