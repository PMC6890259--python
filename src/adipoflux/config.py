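"""Run configuration: parameter metadata, bounds, sign convention, solver
and optimiser settings.

Internal unit convention
------------------------
time            min
insulin         uU/ml          (1 uU/ml = 6.0 pmol/l, converted at I/O only)
glucose, TG,
glycerol, NEFA  mmol/l
ATBF            ml/(100 ml tissue . min)
fluxes          umol/(100 ml tissue . min) = (mmol/l difference) x ATBF

Sign convention ("av_uptake_positive"): a measured flux is
(arterial - venous) x ATBF, so net uptake by the tissue is positive and
net release is negative.  Model flux expressions are mapped onto this
convention by ``SIGN_TABLE``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

# Estimable parameters, in canonical vector order.
PARAM_NAMES: tuple[str, ...] = (
    "k_ad",       # LPL lipolysis rate constant (per uU/ml per min on mmol/l TG)
    "tau_lpl",    # LPL insulin delay (min)
    "tau_at",     # adipose-compartment insulin delay (min)
    "d_spill",    # spill-over constant (percent scale, dimensionless)
    "glut1",      # insulin-independent glucose uptake rate (per min scale)
    "glut4",      # insulin-dependent glucose uptake rate (per uU/ml per min scale)
    "p_gly",      # glycerol plasma<->adipose exchange rate (per min)
    "b_atl",      # basal adipose-triglyceride lipolysis (umol/100 ml/min)
    "atl_max",    # maximal insulin-suppressible ATL lipolysis (umol/100 ml/min)
    "k_atl",      # ATL insulin half-inhibition constant (uU/ml)
    "p_nefa",     # NEFA plasma<->adipose exchange rate (per min)
    "k_reester",  # re-esterification rate constant (per uU/ml per (mmol/l) per min)
    "frac_use",   # fraction of glucose uptake routed to G-3-P, in [0, 1]
    "tau_g3p",    # G-3-P production delay (min)
)

#: parameters that are fractions, additionally bounded above by one
FRACTION_PARAMS: frozenset[str] = frozenset({"frac_use"})

# Mapping from "release-positive" model rate expressions onto the measured
# (arterial - venous) x ATBF convention: uptake positive, release negative.
SIGN_TABLE: dict[str, int] = {
    "tg": +1,        # TG hydrolysis removes TG from plasma -> uptake, positive
    "spill": +1,     # a fraction in [0, 1]; no sign
    "glucose": +1,   # glucose uptake positive
    "glycerol": -1,  # fasting glycerol release is negative
    "nefa": -1,      # fasting NEFA release is negative
}

FLUX_SERIES: tuple[str, ...] = ("tg", "spill", "glucose", "glycerol", "nefa")

#: canonical meal-challenge sampling grid (min); meal at t = 0
CANONICAL_TIMES: tuple[float, ...] = (-30.0, 0.0, 60.0, 120.0, 180.0, 240.0, 300.0)

#: insulin unit conversion, applied only at the I/O boundary
PMOL_PER_UU_ML: float = 6.0


@dataclass
class SolverSettings:
    """ODE solver settings for :func:`adipoflux.model.simulate`."""

    method: str = "LSODA"   # adaptive, stiff-capable
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 30.0


@dataclass
class OptimizerSettings:
    """Global (controlled random search) + local least-squares settings."""

    n_init: int = 250           # random initial parameter sets seeding CRS
    population: int | None = None  # default max(10*dim, n_init)
    max_fevals: int = 4_000
    stall_evals: int = 1_000    # stop after this many evals without
    stall_rtol: float = 1e-8    # relative cost improvement above stall_rtol
    local_jac: str = "3-point"  # central differences; forward differences
    #                             stall on the ODE integration error floor
    local_xtol: float = 1e-12
    local_ftol: float = 1e-12
    local_gtol: float = 1e-12
    local_max_nfev: int | None = None
    n_polish: int = 3           # best CRS points refined locally
    # divide-and-conquer refinement: per-series stage fits with
    # pre-screened multistarts, then a joint polish
    stage_rounds: int = 2
    stage_draws: int = 30       # uniform + log-uniform draws per stage
    stage_polish: int = 4       # best-screened draws refined per stage


@dataclass
class RunConfig:
    """Everything a fitting run needs besides the data."""

    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: default_bounds())
    sign_convention: str = "av_uptake_positive"
    cost_weights: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in FLUX_SERIES}
    )
    solver: SolverSettings = field(default_factory=SolverSettings)
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo < 0:
                raise ValueError(f"lower bound of {name} must be >= 0, got {lo}")
            if name in FRACTION_PARAMS and hi > 1.0:
                raise ValueError(f"{name} is a fraction; upper bound must be <= 1")
            if hi <= lo:
                raise ValueError(f"empty bound box for {name}: ({lo}, {hi})")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash embedded in every output artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_truth() -> dict[str, float]:
    """Baseline parameter values used as the synthetic-data ground truth.

    ``k_ad``, ``tau_lpl``, ``tau_at``, ``p_gly`` and ``p_nefa`` are the
    published baseline estimates for this model class; the remaining nine
    are placeholders chosen to give physiologically plausible fasting and
    postprandial flux magnitudes (see docs/methods.md), not literature
    values.
    """
    return {
        "k_ad": 0.0096,
        "tau_lpl": 156.92,
        "tau_at": 21.19,
        "d_spill": 30.0,
        "glut1": 0.02,
        "glut4": 0.004,
        "p_gly": 0.249,
        "b_atl": 0.05,
        "atl_max": 0.35,
        "k_atl": 10.0,
        "p_nefa": 0.0444,
        "k_reester": 0.001,
        "frac_use": 0.4,
        "tau_g3p": 30.0,
    }


def default_bounds(scale: float = 10.0) -> dict[str, tuple[float, float]]:
    """Search box: [0, scale x baseline] per parameter, fractions capped at 1.

    All parameters are bounded below by zero; fraction-valued parameters
    are additionally bounded above by one.
    """
    truth = default_truth()
    bounds: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        hi = scale * truth[name] if truth[name] > 0 else 1e3
        if name in FRACTION_PARAMS:
            hi = 1.0
        bounds[name] = (0.0, hi)
    return bounds
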