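"""CO2-response model forms for net leaf photosynthesis.

Four model families describe the net photosynthetic rate P_n
(μmol CO2 m⁻² s⁻¹) as a function of CO2 mole fraction C
(μmol mol⁻¹, either intercellular C_i or ambient C_a):

* a biochemical (Farquhar-type) model taking the minimum of the
  Rubisco-, RuBP-regeneration- and triose-phosphate-utilization-limited
  carboxylation rates,
* the rectangular hyperbola,
* the Michaelis–Menten form (algebraically identical to the rectangular
  hyperbola under K = P_nmax/α),
* a modified rectangular hyperbola that allows the curve to bend over
  and decline at high CO2.

Each empirical form carries an additive respiration intercept R_p, so
the model value at C = 0 is exactly −R_p; when the curve was measured
at 21 % O2 that intercept estimates total light respiration R_L, and at
2 % O2 (photorespiration suppressed) it estimates day respiration R_d.

All evaluators are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "FvCBParams",
    "RectHyperbolaParams",
    "MichaelisMentenParams",
    "ModRectHyperbolaParams",
    "eval_rect_hyperbola",
    "eval_michaelis_menten",
    "eval_mod_rect_hyperbola",
    "eval_fvcb",
    "derived_quantities",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class FvCBParams:
    """Parameters of the biochemical (Farquhar-type) model.

    Free parameters are ``vcmax``, ``j``, ``tpu`` and ``rd``; the kinetic
    constants ``kc``, ``ko``, ``o`` and ``gamma_star`` are held fixed
    (they are not identifiable from a single 12-point curve).

    Units: vcmax, j, tpu, rd in μmol m⁻² s⁻¹; kc, gamma_star in
    μmol mol⁻¹; ko and o in mmol mol⁻¹.
    """

    vcmax: float
    j: float
    tpu: float
    rd: float = 0.0
    kc: float = 270.0
    ko: float = 165.0
    o: float = 210.0
    gamma_star: float = 37.0

    def __post_init__(self) -> None:
        for name in ("vcmax", "j", "tpu", "kc", "ko", "o", "gamma_star"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.rd >= 0, "rd must be non-negative")
        _require(self.gamma_star < self.kc, "gamma_star must be below kc")


@dataclass(frozen=True)
class RectHyperbolaParams:
    """Rectangular-hyperbola parameters: initial slope ``alpha``,
    asymptote ``pnmax`` (μmol m⁻² s⁻¹) and respiration intercept ``rp``."""

    alpha: float
    pnmax: float
    rp: float = 0.0

    def __post_init__(self) -> None:
        _require(self.alpha > 0, "alpha must be strictly positive")
        _require(self.pnmax > 0, "pnmax must be strictly positive")
        _require(self.rp >= 0, "rp must be non-negative")


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Michaelis–Menten parameters: ``pnmax``, half-saturation ``k``
    (μmol mol⁻¹) and respiration intercept ``rp``."""

    pnmax: float
    k: float
    rp: float = 0.0

    def __post_init__(self) -> None:
        _require(self.pnmax > 0, "pnmax must be strictly positive")
        _require(self.k > 0, "k must be strictly positive")
        _require(self.rp >= 0, "rp must be non-negative")


@dataclass(frozen=True)
class ModRectHyperbolaParams:
    """Modified rectangular hyperbola: P_n = a·(1 − b·C)/(1 + c·C)·C − R_p.

    ``a`` is the initial slope; ``b`` and ``c`` (mol μmol⁻¹) shape the
    high-CO2 decline. With b = c = 0 the form degenerates to a line.
    """

    a: float
    b: float
    c: float
    rp: float = 0.0

    def __post_init__(self) -> None:
        _require(self.a > 0, "a must be strictly positive")
        _require(self.b >= 0, "b must be non-negative")
        _require(self.c >= 0, "c must be non-negative")
        _require(self.rp >= 0, "rp must be non-negative")


def _check_conc(conc):
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("CO2 concentration must be non-negative")
    return conc


def eval_rect_hyperbola(params: RectHyperbolaParams, conc):
    """Net rate α·P_nmax·C/(α·C + P_nmax) − R_p.

    Tends to ``pnmax − rp`` as C → ∞ and equals ``−rp`` at C = 0.
    """
    c = _check_conc(conc)
    out = params.alpha * params.pnmax * c / (params.alpha * c + params.pnmax) - params.rp
    return out if out.ndim else float(out)


def eval_michaelis_menten(params: MichaelisMentenParams, conc):
    """Net rate P_nmax·C/(C + K) − R_p.

    Identical to :func:`eval_rect_hyperbola` when K = P_nmax/α.
    """
    c = _check_conc(conc)
    out = params.pnmax * c / (c + params.k) - params.rp
    return out if out.ndim else float(out)


def eval_mod_rect_hyperbola(params: ModRectHyperbolaParams, conc):
    """Net rate a·(1 − b·C)/(1 + c·C)·C − R_p."""
    c = _check_conc(conc)
    denom = 1.0 + params.c * c
    if np.any(denom <= 0):
        raise ValueError("1 + c*C must stay positive over the evaluated range")
    out = params.a * (1.0 - params.b * c) / denom * c - params.rp
    return out if out.ndim else float(out)


def fvcb_limiting_rates(params: FvCBParams, ci):
    """The three potential carboxylation rates (w_c, w_j, w_p).

    w_c = V_cmax·C_i/(C_i + K_c(1 + O/K_o))  (Rubisco-limited)
    w_j = J·C_i/(4·C_i + 8·γ*)               (RuBP-regeneration-limited)
    w_p = 3·TPU                              (export-limited, flat)
    """
    c = np.asarray(ci, dtype=float)
    wc = params.vcmax * c / (c + params.kc * (1.0 + params.o / params.ko))
    wj = params.j * c / (4.0 * c + 8.0 * params.gamma_star)
    wp = np.full_like(c, 3.0 * params.tpu)
    return wc, wj, wp


def eval_fvcb(params: FvCBParams, ci):
    """Net rate min(w_c, w_j, w_p)·(1 − γ*/C_i) − R_d.

    The factor (1 − γ*/C_i) discounts gross carboxylation by
    photorespiratory CO2 release; at C_i = γ* the gross term vanishes
    and the model returns −R_d. Requires C_i > 0.
    """
    c = np.asarray(ci, dtype=float)
    if np.any(c <= 0):
        raise ValueError("eval_fvcb requires ci > 0")
    wc, wj, wp = fvcb_limiting_rates(params, c)
    gross = np.minimum(np.minimum(wc, wj), wp) * (1.0 - params.gamma_star / c)
    out = gross - params.rd
    return out if out.ndim else float(out)


_EVALUATORS = {
    RectHyperbolaParams: eval_rect_hyperbola,
    MichaelisMentenParams: eval_michaelis_menten,
    ModRectHyperbolaParams: eval_mod_rect_hyperbola,
    FvCBParams: eval_fvcb,
}


def evaluate(params, conc):
    """Dispatch to the evaluator matching the parameter type."""
    return _EVALUATORS[type(params)](params, conc)


@dataclass
class DerivedQuantities:
    intercept_at_zero: Optional[float]
    co2_compensation_point: Optional[float]
    pn_max_realized: float


def derived_quantities(params, c_max: float = 1200.0, n_grid: int = 2001) -> DerivedQuantities:
    """Model intercept, CO2 compensation point and realized maximum on [0, c_max].

    The intercept at C = 0 equals −R_p for the empirical forms (the
    quantity reported as fitted light/day respiration); it is undefined
    for the biochemical form, whose compensation factor diverges at 0.
    The compensation point is the first sign change of the model on
    (0, c_max], refined with Brent's method; the realized maximum comes
    from a dense grid scan with local bounded refinement — no
    closed-form expressions are used.
    """
    is_fvcb = isinstance(params, FvCBParams)
    f = _EVALUATORS[type(params)]
    lo = 1e-6 if is_fvcb else 0.0
    grid = np.linspace(lo, c_max, n_grid)
    vals = np.asarray(f(params, grid))

    intercept = None if is_fvcb else float(f(params, 0.0))

    comp: Optional[float] = None
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if vals[0] == 0.0:
        comp = float(grid[0])
    elif crossings.size:
        i = int(crossings[0])
        if vals[i + 1] == 0.0:
            comp = float(grid[i + 1])
        else:
            comp = float(optimize.brentq(lambda x: float(f(params, x)), grid[i], grid[i + 1]))
    elif not is_fvcb and params.rp == 0:
        comp = 0.0

    i_best = int(np.argmax(vals))
    a = grid[max(i_best - 1, 0)]
    b = grid[min(i_best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda x: -float(f(params, x)), bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    pn_max = max(float(-res.fun), float(vals[i_best]))
    return DerivedQuantities(intercept, comp, pn_max)
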