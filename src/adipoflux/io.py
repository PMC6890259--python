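"""Reading, validation and writing of all tabular artifacts.

The on-disk dialect is deliberately narrow: UTF-8 CSV with an explicit
header and decimal points.  The long-format study table schema is a
convention of this package (the measurement protocol does not prescribe a
file layout):

    subject_id, time, site, metabolite, value[, atbf][, unit]

with ``site`` in {arterial, venous}, ``metabolite`` in
{insulin, glucose, tg, glycerol, nefa, tg_tracer, nefa_tracer},
``time`` in minutes and ``atbf`` in ml/(100 ml tissue . min).

Insulin may be supplied in pmol/l by tagging the row ``unit=pmol/l``; it
is converted to uU/ml (divide by 6.0) on read, the only place unit
conversion happens.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import CANONICAL_TIMES, PMOL_PER_UU_ML, PARAM_NAMES
from .exceptions import SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import FitResult

METABOLITES = ("insulin", "glucose", "tg", "glycerol", "nefa", "tg_tracer", "nefa_tracer")
ARTERIAL_ANALYTES = ("insulin", "glucose", "tg", "glycerol", "nefa")
SITES = ("arterial", "venous")
REQUIRED_COLUMNS = ("subject_id", "time", "site", "metabolite", "value")


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format study table; returns a normalized copy.

    Raises
    ------
    SchemaError
        On a missing column, unknown site/metabolite, off-grid time,
        negative concentration or ATBF, or duplicate
        (subject, time, site, metabolite) key.  The message names the
        offending row.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    out = df.copy()
    out["time"] = out["time"].astype(float)
    out["value"] = out["value"].astype(float)

    bad_site = ~out["site"].isin(SITES)
    if bad_site.any():
        i = out.index[bad_site][0]
        raise SchemaError(f"row {i}: unknown site {out.loc[i, 'site']!r}")
    bad_met = ~out["metabolite"].isin(METABOLITES)
    if bad_met.any():
        i = out.index[bad_met][0]
        raise SchemaError(f"row {i}: unknown metabolite {out.loc[i, 'metabolite']!r}")
    off_grid = ~out["time"].isin(CANONICAL_TIMES)
    if off_grid.any():
        i = out.index[off_grid][0]
        raise SchemaError(
            f"row {i}: time {out.loc[i, 'time']} not on the canonical grid "
            f"{CANONICAL_TIMES}"
        )

    # unit normalization (insulin pmol/l -> uU/ml), then drop the tag
    if "unit" in out.columns:
        unit = out["unit"].fillna("")
        pmol = (out["metabolite"] == "insulin") & (unit == "pmol/l")
        out.loc[pmol, "value"] = out.loc[pmol, "value"] / PMOL_PER_UU_ML
        known = unit.isin(("", "pmol/l", "uU/ml", "mmol/l"))
        if not known.all():
            i = out.index[~known][0]
            raise SchemaError(f"row {i}: unknown unit tag {unit[i]!r}")
        out = out.drop(columns=["unit"])

    neg = out["value"] < 0
    if neg.any():
        i = out.index[neg][0]
        raise SchemaError(f"row {i}: negative concentration {out.loc[i, 'value']}")
    if "atbf" in out.columns:
        atbf = out["atbf"].astype(float)
        if (atbf.dropna() < 0).any():
            i = out.index[atbf < 0][0]
            raise SchemaError(f"row {i}: negative atbf {atbf[i]}")
        out["atbf"] = atbf

    key = ["subject_id", "time", "site", "metabolite"]
    dup = out.duplicated(subset=key)
    if dup.any():
        i = out.index[dup][0]
        raise SchemaError(
            f"row {i}: duplicate key {tuple(out.loc[i, key])}"
        )
    return out


def read_study_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a study-table CSV (see module docstring)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    return validate_study_table(pd.read_csv(path))


def write_study_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_study_table(df).to_csv(path, index=False)


def write_results(fit: "FitResult", path: str | Path) -> None:
    """Write a fit as a parameter table plus a JSON provenance sidecar.

    ``<path>.csv`` holds one row per parameter with the estimate and its
    95% confidence interval formatted ``"(lo, hi)"``; ``<path>.json``
    holds the seed, bounds, solver/optimizer settings, cost and config
    hash so any run can be reproduced exactly.
    """
    path = Path(path)
    rows = []
    for name in PARAM_NAMES:
        est = fit.params[name]
        lo, hi = fit.ci95[name]
        rows.append(
            {
                "parameter": name,
                "estimate": repr(float(est)),
                "ci95": f"({_fmt(lo)}, {_fmt(hi)})",
            }
        )
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)

    sidecar = {
        "seed": fit.seed,
        "cost": fit.cost,
        "cost_breakdown": fit.cost_breakdown,
        "params": {k: float(v) for k, v in fit.params.items()},
        "ci95": {k: [float(a), float(b)] for k, (a, b) in fit.ci95.items()},
        "bounds": {k: list(v) for k, v in fit.config.bounds.items()},
        "solver": fit.config.solver.__dict__,
        "optimizer": fit.config.optimizer.__dict__,
        "config_hash": fit.config.config_hash(),
        "n_local_restarts": fit.n_local_restarts,
        "converged": fit.converged,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_results(path: str | Path) -> "FitResult":
    """Read a fit written by :func:`write_results` back into a FitResult."""
    from .config import RunConfig, SolverSettings, OptimizerSettings
    from .estimation import FitResult

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    config = RunConfig(
        seed=sidecar["seed"],
        bounds={k: tuple(v) for k, v in sidecar["bounds"].items()},
        solver=SolverSettings(**sidecar["solver"]),
        optimizer=OptimizerSettings(**sidecar["optimizer"]),
    )
    return FitResult(
        params=dict(sidecar["params"]),
        cost=sidecar["cost"],
        cost_breakdown=dict(sidecar["cost_breakdown"]),
        ci95={k: tuple(v) for k, v in sidecar["ci95"].items()},
        jacobian=None,
        seed=sidecar["seed"],
        n_local_restarts=sidecar["n_local_restarts"],
        converged=sidecar["converged"],
        config=config,
    )


def _fmt(x: float) -> str:
    if not np.isfinite(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.6g}"
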