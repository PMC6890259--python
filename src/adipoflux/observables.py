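"""Quantities derived directly from measurements.

Arteriovenous fluxes, tracer-based fractional spill-over, the HOMA-IR and
ADIPO-IR insulin-resistance indices, trapezoidal AUC summaries, and the
assembly of a cohort :class:`FluxDataset` (the fitting target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CANONICAL_TIMES, FLUX_SERIES, PMOL_PER_UU_ML
from .exceptions import InsufficientDataError, SchemaError

__all__ = [
    "FluxDataset",
    "av_flux",
    "tracer_spill_fraction",
    "homa_ir",
    "adipo_ir",
    "auc",
    "build_flux_dataset",
]

#: HOMA-IR cut-off band for flagging whole-body insulin resistance
HOMA_IR_CUTOFF_BAND = (1.85, 2.01)


@dataclass
class FluxDataset:
    """Cohort mean +/- dispersion of each measured flux series.

    ``mu[series]`` and ``sigma[series]`` are aligned with ``times``.
    ``sigma`` is the cross-subject standard deviation used as the fitting
    weight; SEM (= sigma/sqrt(n)) appears only in plots.  Points with
    non-finite or zero sigma are excluded from the cost via ``mask``.
    """

    times: np.ndarray
    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]     # True where the point enters the cost
    n_subjects: int

    def n_points(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))

    @classmethod
    def from_series(cls, times, mu, sigma, n_subjects=1) -> "FluxDataset":
        times = np.asarray(times, dtype=float)
        mu = {k: np.asarray(v, dtype=float) for k, v in mu.items()}
        sigma = {k: np.asarray(v, dtype=float) for k, v in sigma.items()}
        mask = {}
        for k in mu:
            s = sigma[k]
            ok = np.isfinite(mu[k]) & np.isfinite(s) & (s > 0)
            if not ok.all():
                warnings.warn(
                    f"{k}: {int((~ok).sum())} point(s) with zero/undefined "
                    "dispersion excluded from the cost"
                )
            mask[k] = ok
        return cls(times=times, mu=mu, sigma=sigma, mask=mask,
                   n_subjects=n_subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for series in self.mu:
            for i, t in enumerate(self.times):
                rows.append({
                    "series": series, "time": t,
                    "mu": self.mu[series][i], "sigma": self.sigma[series][i],
                    "included": bool(self.mask[series][i]),
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_subjects: int = 1) -> "FluxDataset":
        times = np.array(sorted(df["time"].unique()), dtype=float)
        mu, sigma = {}, {}
        for series, sub in df.groupby("series"):
            sub = sub.set_index("time").reindex(times)
            mu[series] = sub["mu"].to_numpy(dtype=float)
            sigma[series] = sub["sigma"].to_numpy(dtype=float)
        return cls.from_series(times, mu, sigma, n_subjects=n_subjects)


def av_flux(arterial, venous, atbf):
    """Arteriovenous flux: (arterial - venous) x ATBF.

    Positive = net uptake by the tissue, negative = net release.
    Concentrations in mmol/l and ATBF in ml/(100 ml tissue . min) give the
    flux in umol/(100 ml tissue . min).
    """
    return (np.asarray(arterial, dtype=float) - np.asarray(venous, dtype=float)) * np.asarray(atbf, dtype=float)


def tracer_spill_fraction(labelled_tg_hydrolysis, labelled_nefa_release):
    """Fractional spill-over from labelled fluxes: 1 - fractional extraction.

    Computed as labelled NEFA efflux over labelled TG-fatty-acid
    hydrolysis (per fatty-acid equivalent), clamped to [0, 1].  Returns
    NaN where hydrolysis is zero (undefined; such points are excluded
    from fitting).
    """
    hyd = np.asarray(labelled_tg_hydrolysis, dtype=float)
    rel = np.asarray(labelled_nefa_release, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(hyd > 0, rel / np.where(hyd > 0, hyd, 1.0), np.nan)
    return np.clip(frac, 0.0, 1.0)


def homa_ir(fasting_glucose: float, fasting_insulin: float) -> float:
    """Whole-body insulin-resistance index.

    fasting glucose (mmol/l) x fasting insulin (uU/ml) / 22.4.
    """
    return fasting_glucose * fasting_insulin / 22.4


def adipo_ir(fasting_nefa: float, fasting_insulin_uU_ml: float) -> float:
    """Adipose-specific insulin-resistance surrogate.

    fasting NEFA (mmol/l) x fasting insulin (pmol/l).  The insulin
    argument uses the internal uU/ml unit and is converted (x 6.0) here.
    """
    return fasting_nefa * fasting_insulin_uU_ml * PMOL_PER_UU_ML


def auc(times, values) -> float:
    """Trapezoidal total area under the curve over the given times."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("auc needs at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise SchemaError("auc requires strictly increasing times")
    return float(np.trapezoid(values, times))


def build_flux_dataset(cohort: pd.DataFrame) -> FluxDataset:
    """Per-subject A-V fluxes and tracer spill-over -> cohort FluxDataset.

    Expects a validated long study table with arterial and venous rows for
    tg, glucose, glycerol, nefa (plus optional tg_tracer / nefa_tracer
    rows) and an ``atbf`` column on the venous rows (or any rows; the per
    (subject, time) mean is used).  Cross-subject means and standard
    deviations at each canonical time become mu and sigma.
    """
    subjects = cohort["subject_id"].unique()
    if len(subjects) < 2:
        raise InsufficientDataError("need >= 2 subjects for a dispersion estimate")
    times = np.array(CANONICAL_TIMES, dtype=float)

    atbf = (
        cohort.dropna(subset=["atbf"])
        .groupby(["subject_id", "time"])["atbf"].mean()
        if "atbf" in cohort.columns else None
    )
    if atbf is None:
        raise SchemaError("cohort table lacks the atbf column")

    wide = cohort.pivot_table(
        index=["subject_id", "time"], columns=["site", "metabolite"],
        values="value", aggfunc="first",
    )

    per_subject: dict[str, np.ndarray] = {
        s: np.full((len(subjects), len(times)), np.nan) for s in FLUX_SERIES
    }
    met_of = {"tg": "tg", "glucose": "glucose", "glycerol": "glycerol", "nefa": "nefa"}
    for si, subj in enumerate(subjects):
        for ti, t in enumerate(times):
            key = (subj, t)
            if key not in wide.index:
                continue
            row = wide.loc[key]
            bf = atbf.get(key, np.nan)
            for series, met in met_of.items():
                a = row.get(("arterial", met), np.nan)
                v = row.get(("venous", met), np.nan)
                if np.isfinite(a) and np.isfinite(v) and np.isfinite(bf):
                    per_subject[series][si, ti] = av_flux(a, v, bf)
            # tracer-based spill-over (arterial labelled fluxes, already
            # quantified as fluxes in the tracer rows)
            hyd = row.get(("arterial", "tg_tracer"), np.nan)
            rel = row.get(("arterial", "nefa_tracer"), np.nan)
            if np.isfinite(hyd) and np.isfinite(rel) and hyd > 0:
                per_subject["spill"][si, ti] = tracer_spill_fraction(hyd, rel)

    mu, sigma = {}, {}
    for series, mat in per_subject.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu[series] = np.nanmean(mat, axis=0)
            sigma[series] = np.nanstd(mat, axis=0, ddof=1)
        n_missing = int(np.all(np.isnan(mat), axis=0).sum())
        if n_missing:
            warnings.warn(f"{series}: {n_missing} time point(s) missing; dropped")
    return FluxDataset.from_series(times, mu, sigma, n_subjects=len(subjects))
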