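"""Two-compartment kinetic model of postprandial adipose tissue metabolism.

The model describes metabolite exchange between blood plasma and a lumped
interstitial adipose compartment during a mixed-meal challenge.  Arterial
concentrations (insulin, glucose, TG, glycerol, NEFA) act as exogenous
forcings; the state comprises two three-compartment insulin delay chains
(LPL and adipose), adipose glycerol and NEFA, a G-6-P pool, a delayed
G-3-P production signal, and the adipose G-3-P concentration.

Processes
---------
* LPL lipolysis of circulating TG: rate ``k_ad * [TG_art] * [I_LPL]``,
  insulin-stimulated through the slow delay chain; releases 1 glycerol and
  3 NEFA per TG hydrolysed.
* Spill-over: a fraction ``f = d_spill/100 * I_B/[I_art]`` (clamped to
  [0, 1]) of LPL-derived NEFA escapes into plasma; the rest enters the
  adipose compartment.  Fatty-acid mass balance at the LPL node holds
  exactly: spill + adipose influx = 3 x hydrolysis.
* Glucose uptake: ``glut1*[G_art] + glut4*[G_art]*[I_AT]``; a fraction
  ``frac_use`` is routed through G-6-P to G-3-P production (two trioses
  per glucose) with a two-compartment delay ``tau_g3p``.
* ATL lipolysis of stored TG: ``b_atl + atl_max/(1 + I_AT/k_atl)``,
  insulin-inhibited, releasing glycerol and NEFA inside the adipose
  compartment.
* Concentration-gradient diffusion of glycerol and NEFA between plasma
  (augmented by the LPL release) and the adipose compartment.
* Re-esterification: TG resynthesis at rate
  ``k_reester*[I_AT]*[NEFA_AT]*[G3P_AT]`` consuming 3 NEFA and 1 G-3-P.

Measured fluxes follow the arteriovenous convention (uptake positive,
release negative); see ``config.SIGN_TABLE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .config import PARAM_NAMES, FRACTION_PARAMS, SolverSettings, default_truth
from .exceptions import (
    DegenerateDelayError,
    InitializationError,
    IntegrationError,
    ParameterError,
)
from .forcing import ForcingSet

__all__ = [
    "ModelParameters",
    "SimulationResult",
    "delay_chain_rhs",
    "delay_chain_step_response",
    "tg_flux",
    "spill_fraction",
    "glucose_flux",
    "atl_rate",
    "initial_state",
    "simulate",
    "STATE_NAMES",
]

STATE_NAMES: tuple[str, ...] = (
    "I1_LPL", "I2_LPL", "I_LPL",
    "I1_AT", "I2_AT", "I_AT",
    "GLY_AT", "NEFA_AT",
    "G6P", "G3P_pro", "G3P_AT",
)

RATE_NAMES: tuple[str, ...] = (
    "lpl_hydrolysis",      # TG hydrolysed by LPL (umol TG/100 ml/min)
    "spill_fraction",      # f, dimensionless
    "nefa_spill",          # 3 f lpl, NEFA into plasma
    "nefa_lpl_influx",     # 3 (1-f) lpl, NEFA into adipose
    "gly_lpl_release",     # lpl, glycerol into plasma (1:1)
    "atl_lipolysis",       # TG-equivalent ATL rate
    "glucose_uptake",      # glut1+glut4 uptake magnitude
    "gly_diffusion",       # plasma->adipose glycerol diffusion (positive into tissue)
    "nefa_diffusion",      # plasma->adipose NEFA diffusion (positive into tissue)
    "reesterification",    # TG synthesis rate (consumes 3 NEFA, 1 G3P)
    "g3p_production",      # delayed G-3-P production signal
    "gly_sink",            # optional first-order adipose glycerol sink
)


@dataclass
class ModelParameters:
    """The 14 estimable constants of the refined model.

    Basal insulin I_B is a property of the forcing, not a parameter.
    ``k_sink`` enables the optional first-order adipose glycerol sink
    (disabled by default) and the ``*_no_delay`` flags bypass the insulin
    delay chains (used for undelayed term variants); none of these three
    count among the 14 estimable parameters.
    """

    k_ad: float = 0.0096
    tau_lpl: float = 156.92
    tau_at: float = 21.19
    d_spill: float = 30.0
    glut1: float = 0.02
    glut4: float = 0.004
    p_gly: float = 0.249
    b_atl: float = 0.05
    atl_max: float = 0.35
    k_atl: float = 10.0
    p_nefa: float = 0.0444
    k_reester: float = 0.001
    frac_use: float = 0.4
    tau_g3p: float = 30.0
    k_sink: float = 0.0
    lpl_no_delay: bool = False
    at_no_delay: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        for name in FRACTION_PARAMS:
            if getattr(self, name) > 1.0:
                raise ParameterError(f"{name} is a fraction; got {getattr(self, name)}")
        if self.tau_lpl == 0 and not self.lpl_no_delay:
            raise DegenerateDelayError("tau_lpl = 0; set lpl_no_delay instead")
        if self.tau_at == 0 and not self.at_no_delay:
            raise DegenerateDelayError("tau_at = 0; set at_no_delay instead")
        if self.tau_g3p == 0:
            raise ParameterError("tau_g3p must be > 0")
        if self.atl_max > 0 and self.k_atl == 0:
            raise ParameterError("k_atl = 0 with atl_max > 0")

    @classmethod
    def baseline(cls) -> "ModelParameters":
        return cls(**default_truth())

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec, **extra) -> "ModelParameters":
        vals = {n: float(v) for n, v in zip(PARAM_NAMES, vec, strict=True)}
        vals.update(extra)
        return cls(**vals)

    def replace(self, **changes) -> "ModelParameters":
        d = asdict(self)
        d.update(changes)
        return ModelParameters(**d)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


# ---------------------------------------------------------------------------
# elementary flux terms
# ---------------------------------------------------------------------------

def delay_chain_rhs(chain, i_art: float, tau: float):
    """RHS of the three-compartment insulin delay chain.

    d[I1]/dt = (I_art - I1)/tau, d[I2]/dt = (I1 - I2)/tau,
    d[I_delay]/dt = (I2 - I_delay)/tau.
    """
    if tau <= 0:
        raise DegenerateDelayError("delay chain requires tau > 0; use the bypass flag")
    i1, i2, i3 = chain
    return ((i_art - i1) / tau, (i1 - i2) / tau, (i2 - i3) / tau)


def delay_chain_step_response(t, i0: float, tau: float):
    """Closed-form chain output for a step of height ``i0`` from rest.

    I_delay(t) = i0 * (1 - exp(-t/tau) * (1 + t/tau + t^2/(2 tau^2))),
    the Erlang(3) cumulative response of the linear cascade.
    """
    x = np.asarray(t, dtype=float) / tau
    return i0 * (1.0 - np.exp(-x) * (1.0 + x + 0.5 * x * x))


def tg_flux(k_ad: float, tg_art, i_lpl):
    """LPL hydrolysis of circulating TG, ``k_ad * [TG_art] * [I_LPL]``.

    Positive in the measured convention (TG removal from plasma = uptake).
    """
    return k_ad * tg_art * i_lpl


def spill_fraction(d_spill: float, i_b: float, i_art):
    """Fraction of LPL-derived NEFA spilling into plasma.

    f = (1/100) * d_spill * I_B / [I_art], clamped to [0, 1]: inversely
    proportional to arterial insulin, so spill-over rises late in the
    postprandial period as insulin falls.
    """
    i_art = np.asarray(i_art, dtype=float)
    if np.any(i_art <= 0):
        raise ParameterError("spill_fraction undefined at I_art <= 0")
    f = (d_spill / 100.0) * i_b / i_art
    return np.clip(f, 0.0, 1.0)


def glucose_flux(glut1: float, glut4: float, g_art, i_at):
    """Adipose glucose uptake magnitude, insulin-independent + dependent.

    ``glut1*[G_art] + glut4*[G_art]*[I_AT]``; positive = uptake in the
    measured convention.
    """
    return glut1 * g_art + glut4 * g_art * i_at


def atl_rate(b_atl: float, atl_max: float, k_atl: float, i_at):
    """Lipolysis of adipose-stored TG: basal plus saturable insulin-inhibited.

    ``b_atl + atl_max / (1 + I_AT/k_atl)``, strictly decreasing in I_AT.
    """
    if atl_max > 0 and k_atl <= 0:
        raise ParameterError("k_atl must be > 0 when atl_max > 0")
    if atl_max == 0:
        return b_atl + np.zeros_like(np.asarray(i_at, dtype=float))
    return b_atl + atl_max / (1.0 + np.asarray(i_at, dtype=float) / k_atl)


# ---------------------------------------------------------------------------
# RHS and constituent rates
# ---------------------------------------------------------------------------

def _rates(p: ModelParameters, y, i_art, g_art, tg_art, gly_art, nefa_art, i_b):
    """All constituent reaction rates at one instant (or vectorized)."""
    i_lpl = i_art if p.lpl_no_delay else y[2]
    i_at = i_art if p.at_no_delay else y[5]
    gly_at, nefa_at = y[6], y[7]
    g3p_pro, g3p_at = y[9], y[10]

    lpl = p.k_ad * tg_art * i_lpl
    f = np.clip((p.d_spill / 100.0) * i_b / i_art, 0.0, 1.0)
    atl = atl_rate(p.b_atl, p.atl_max, p.k_atl, i_at)
    uptake = glucose_flux(p.glut1, p.glut4, g_art, i_at)
    gly_diff = p.p_gly * ((gly_art + lpl) - gly_at)
    nefa_pl = nefa_art + 3.0 * f * lpl
    nefa_diff = p.p_nefa * (nefa_pl - nefa_at)
    reester = p.k_reester * i_at * nefa_at * g3p_at
    sink = p.k_sink * gly_at
    return {
        "lpl_hydrolysis": lpl,
        "spill_fraction": f,
        "nefa_spill": 3.0 * f * lpl,
        "nefa_lpl_influx": 3.0 * (1.0 - f) * lpl,
        "gly_lpl_release": lpl,
        "atl_lipolysis": atl,
        "glucose_uptake": uptake,
        "gly_diffusion": gly_diff,
        "nefa_diffusion": nefa_diff,
        "reesterification": reester,
        "g3p_production": g3p_pro,
        "gly_sink": sink,
    }


def _measured_fluxes(rates: dict) -> dict:
    """Map constituent rates onto the measured A-V convention.

    tg: hydrolysis (uptake, +).  glucose: uptake (+).
    glycerol: diffusion into tissue minus LPL release into plasma.
    nefa: diffusion into tissue minus spill into plasma.
    spill: the fraction itself.
    """
    return {
        "tg": rates["lpl_hydrolysis"],
        "spill": rates["spill_fraction"],
        "glucose": rates["glucose_uptake"],
        "glycerol": rates["gly_diffusion"] - rates["gly_lpl_release"],
        "nefa": rates["nefa_diffusion"] - rates["nefa_spill"],
    }


try:  # optional JIT of the RHS; the pure-Python path is the reference
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_RHS_CORE = None


def _get_jit_core():
    """Compile (once) the numba RHS core; None when numba is unavailable."""
    global _RHS_CORE
    if _numba is None:
        return None
    if _RHS_CORE is None:
        @_numba.njit(cache=False, fastmath=False)
        def core(t, y, pv, ft, fv, i_b):
            i_art = np.interp(t, ft, fv[0])
            g_art = np.interp(t, ft, fv[1])
            tg_art = np.interp(t, ft, fv[2])
            gly_art = np.interp(t, ft, fv[3])
            nefa_art = np.interp(t, ft, fv[4])
            (k_ad, inv_tl, inv_ta, d_spill, glut1, glut4, p_gly, b_atl,
             atl_max, k_atl, p_nefa, k_re, frac_use, inv_tg3p, k_sink,
             lpl_byp, at_byp) = (
                pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7],
                pv[8], pv[9], pv[10], pv[11], pv[12], pv[13], pv[14],
                pv[15], pv[16])
            i1l, i2l, i3l = y[0], y[1], y[2]
            i1a, i2a, i3a = y[3], y[4], y[5]
            gly_at, nefa_at = y[6], y[7]
            g6p, g3p_pro, g3p_at = y[8], y[9], y[10]
            i_lpl = i_art if lpl_byp > 0.5 else i3l
            i_at = i_art if at_byp > 0.5 else i3a
            lpl = k_ad * tg_art * i_lpl
            f = (d_spill / 100.0) * i_b / i_art
            if f > 1.0:
                f = 1.0
            elif f < 0.0:
                f = 0.0
            if atl_max > 0.0:
                atl = b_atl + atl_max / (1.0 + i_at / k_atl)
            else:
                atl = b_atl
            uptake = glut1 * g_art + glut4 * g_art * i_at
            gly_diff = p_gly * ((gly_art + lpl) - gly_at)
            nefa_pl = nefa_art + 3.0 * f * lpl
            nefa_diff = p_nefa * (nefa_pl - nefa_at)
            reester = k_re * i_at * nefa_at * g3p_at
            out = np.empty(11)
            out[0] = (i_art - i1l) * inv_tl
            out[1] = (i1l - i2l) * inv_tl
            out[2] = (i2l - i3l) * inv_tl
            out[3] = (i_art - i1a) * inv_ta
            out[4] = (i1a - i2a) * inv_ta
            out[5] = (i2a - i3a) * inv_ta
            out[6] = gly_diff + atl - k_sink * gly_at
            out[7] = 3.0 * (1.0 - f) * lpl + nefa_diff + 3.0 * atl - 3.0 * reester
            out[8] = (2.0 * frac_use * uptake - g6p) * inv_tg3p
            out[9] = (g6p - g3p_pro) * inv_tg3p
            out[10] = g3p_pro - reester
            return out

        _RHS_CORE = core
    return _RHS_CORE


def _make_rhs_jit(p: ModelParameters, forcing: ForcingSet):
    """JIT-compiled RHS; requires all five forcings to share one time grid."""
    core = _get_jit_core()
    if core is None:
        return None
    grids = [forcing.nodes[a][0] for a in
             ("insulin", "glucose", "tg", "glycerol", "nefa")]
    if not all(len(g) == len(grids[0]) and np.array_equal(g, grids[0])
               for g in grids[1:]):
        return None
    ft = np.ascontiguousarray(grids[0], dtype=float)
    fv = np.ascontiguousarray(
        np.vstack([forcing.nodes[a][1] for a in
                   ("insulin", "glucose", "tg", "glycerol", "nefa")]),
        dtype=float)
    pv = np.array([
        p.k_ad,
        0.0 if p.lpl_no_delay else 1.0 / p.tau_lpl,
        0.0 if p.at_no_delay else 1.0 / p.tau_at,
        p.d_spill, p.glut1, p.glut4, p.p_gly, p.b_atl, p.atl_max,
        max(p.k_atl, 1e-300), p.p_nefa, p.k_reester, p.frac_use,
        1.0 / p.tau_g3p, p.k_sink,
        1.0 if p.lpl_no_delay else 0.0,
        1.0 if p.at_no_delay else 0.0,
    ])
    i_b = float(forcing.basal_insulin)

    def rhs(t, y):
        return core(t, y, pv, ft, fv, i_b)

    return rhs


def _make_rhs(p: ModelParameters, forcing: ForcingSet):
    t_i, v_i = forcing.nodes["insulin"]
    t_g, v_g = forcing.nodes["glucose"]
    t_tg, v_tg = forcing.nodes["tg"]
    t_gl, v_gl = forcing.nodes["glycerol"]
    t_nf, v_nf = forcing.nodes["nefa"]
    i_b = forcing.basal_insulin
    inv_tau_lpl = 0.0 if p.lpl_no_delay else 1.0 / p.tau_lpl
    inv_tau_at = 0.0 if p.at_no_delay else 1.0 / p.tau_at
    inv_tau_g3p = 1.0 / p.tau_g3p
    k_ad, d_spill = p.k_ad, p.d_spill
    glut1, glut4 = p.glut1, p.glut4
    p_gly, p_nefa = p.p_gly, p.p_nefa
    b_atl, atl_max, k_atl = p.b_atl, p.atl_max, p.k_atl
    k_re, frac_use, k_sink = p.k_reester, p.frac_use, p.k_sink
    lpl_bypass, at_bypass = p.lpl_no_delay, p.at_no_delay

    def rhs(t, y):
        i_art = np.interp(t, t_i, v_i)
        g_art = np.interp(t, t_g, v_g)
        tg_art = np.interp(t, t_tg, v_tg)
        gly_art = np.interp(t, t_gl, v_gl)
        nefa_art = np.interp(t, t_nf, v_nf)

        i1l, i2l, i3l, i1a, i2a, i3a, gly_at, nefa_at, g6p, g3p_pro, g3p_at = y
        i_lpl = i_art if lpl_bypass else i3l
        i_at = i_art if at_bypass else i3a

        lpl = k_ad * tg_art * i_lpl
        f = (d_spill / 100.0) * i_b / i_art
        if f > 1.0:
            f = 1.0
        elif f < 0.0:
            f = 0.0
        if atl_max > 0.0:
            atl = b_atl + atl_max / (1.0 + i_at / k_atl)
        else:
            atl = b_atl
        uptake = glut1 * g_art + glut4 * g_art * i_at
        gly_diff = p_gly * ((gly_art + lpl) - gly_at)
        nefa_pl = nefa_art + 3.0 * f * lpl
        nefa_diff = p_nefa * (nefa_pl - nefa_at)
        reester = k_re * i_at * nefa_at * g3p_at

        return (
            (i_art - i1l) * inv_tau_lpl,
            (i1l - i2l) * inv_tau_lpl,
            (i2l - i3l) * inv_tau_lpl,
            (i_art - i1a) * inv_tau_at,
            (i1a - i2a) * inv_tau_at,
            (i2a - i3a) * inv_tau_at,
            gly_diff + atl - k_sink * gly_at,
            3.0 * (1.0 - f) * lpl + nefa_diff + 3.0 * atl - 3.0 * reester,
            (2.0 * frac_use * uptake - g6p) * inv_tau_g3p,
            (g6p - g3p_pro) * inv_tau_g3p,
            g3p_pro - reester,
        )

    return rhs


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def initial_state(p: ModelParameters, forcing: ForcingSet) -> np.ndarray:
    """Fasting fixed point of the RHS with forcings frozen at fasting values.

    Delay chains start at basal insulin I_B; GLY_AT, NEFA_AT, G6P,
    G3P_pro and G3P_AT are solved algebraically from the steady-state
    conditions.  Raises :class:`InitializationError` when no non-negative
    fixed point exists (e.g. positive G-3-P production with zero
    re-esterification capacity).
    """
    i_b = forcing.basal_insulin
    fast = forcing.fasting
    g_f, tg_f = fast["glucose"], fast["tg"]
    gly_f, nefa_f = fast["glycerol"], fast["nefa"]

    lpl_f = float(tg_flux(p.k_ad, tg_f, i_b))
    f_b = float(spill_fraction(p.d_spill, i_b, i_b))
    atl_f = float(atl_rate(p.b_atl, p.atl_max, p.k_atl, i_b))
    uptake_f = float(glucose_flux(p.glut1, p.glut4, g_f, i_b))
    g6p = 2.0 * p.frac_use * uptake_f
    g3p_pro = g6p

    # dGLY_AT/dt = 0: p_gly*((gly_f + lpl) - GLY) + atl - k_sink*GLY = 0
    denom = p.p_gly + p.k_sink
    if denom > 0:
        gly_at = (p.p_gly * (gly_f + lpl_f) + atl_f) / denom
    elif atl_f == 0.0:
        gly_at = gly_f
    else:
        raise InitializationError(
            "fasting ATL glycerol release with no glycerol export route "
            "(p_gly = k_sink = 0)"
        )

    # dNEFA_AT/dt = 0 and dG3P_AT/dt = 0 combined (re-esterification rate
    # equals G-3-P production at steady state):
    nefa_pl_f = nefa_f + 3.0 * f_b * lpl_f
    excess = 3.0 * ((1.0 - f_b) * lpl_f + atl_f - g3p_pro)
    if p.p_nefa > 0:
        nefa_at = nefa_pl_f + excess / p.p_nefa
    elif abs(excess) < 1e-12:
        nefa_at = nefa_f
    else:
        raise InitializationError("fasting NEFA imbalance with p_nefa = 0")
    if nefa_at < 0:
        raise InitializationError(
            f"no non-negative fasting NEFA_AT (got {nefa_at:.4g}); fasting "
            "re-esterification demand exceeds lipolytic supply",
            violation=-nefa_at,
        )

    denom_g3p = p.k_reester * i_b * nefa_at
    if g3p_pro == 0.0:
        g3p_at = 0.0
    elif denom_g3p > 0:
        g3p_at = g3p_pro / denom_g3p
    else:
        raise InitializationError(
            "positive G-3-P production with zero re-esterification capacity "
            "(k_reester * I_B * NEFA_AT = 0)"
        )

    y0 = np.array(
        [i_b, i_b, i_b, i_b, i_b, i_b, gly_at, nefa_at, g6p, g3p_pro, g3p_at]
    )
    if not np.all(np.isfinite(y0)):
        raise InitializationError(f"non-finite initial state {y0}")
    return y0


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Dense model trajectory with flux and constituent-rate time courses."""

    params: ModelParameters
    forcing: ForcingSet
    t: np.ndarray                       # evaluation grid (min)
    states: dict[str, np.ndarray]       # per STATE_NAMES
    fluxes: dict[str, np.ndarray]       # measured-convention series
    rates: dict[str, np.ndarray]        # per RATE_NAMES
    sol: object = field(default=None, repr=False)   # dense OdeSolution

    def eval_at(self, times) -> dict[str, np.ndarray]:
        """Measured-convention flux series on an arbitrary time grid."""
        times = np.asarray(times, dtype=float)
        y = self.sol(times)
        fc = self.forcing
        rates = _rates(
            self.params, y,
            fc("insulin", times), fc("glucose", times), fc("tg", times),
            fc("glycerol", times), fc("nefa", times), fc.basal_insulin,
        )
        return _measured_fluxes(rates)


def simulate(
    p: ModelParameters,
    forcing: ForcingSet,
    t_grid=None,
    solver: SolverSettings | None = None,
) -> SimulationResult:
    """Integrate the model over a meal challenge.

    Starts at t = -30 min from the fasting fixed point; the meal at t = 0
    is implicit in the forcing data (no discrete event).  Adaptive,
    stiff-capable integration with dense output.
    """
    solver = solver or SolverSettings()
    if t_grid is None:
        t_grid = np.arange(-30.0, 300.0 + 1.0, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])

    y0 = initial_state(p, forcing)
    rhs = _make_rhs_jit(p, forcing) or _make_rhs(p, forcing)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        dense_output=True,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else t0
        raise IntegrationError(f"solver failed: {sol.message}", last_time=last)

    y = sol.sol(t_grid)
    fc = forcing
    rates = _rates(
        p, y,
        fc("insulin", t_grid), fc("glucose", t_grid), fc("tg", t_grid),
        fc("glycerol", t_grid), fc("nefa", t_grid), fc.basal_insulin,
    )
    fluxes = _measured_fluxes(rates)
    states = {name: y[i] for i, name in enumerate(STATE_NAMES)}
    return SimulationResult(
        params=p, forcing=forcing, t=t_grid,
        states=states, fluxes=fluxes, rates=rates, sol=sol.sol,
    )
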