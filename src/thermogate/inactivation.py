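"""Empirical irreversible temperature-dependent inactivation overlay.

During slow heating ramps a fraction of channels is lost irreversibly;
this is modelled as an exponential survival factor applied pointwise on
top of an equilibrium P_o-T curve:

    Po_inact(t, T) = Po(T) * f(t, T),     f(t, T) = exp(-k(T) * t)

with an Eyring-like rate  k(T) = k0 * exp(-(dH_act - T*dS_act)/(R*T))
whose pre-factor carries the protective effect of external Na⁺ through
the equilibrium fraction of Na⁺-bound states, k0 = A * (1 - F_Na)^2.
Ramp time is obtained from temperature through an empirical sigmoid
time-transform matched to experimental temperature-vs-time records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import R_KCAL
from .gating import AllostericModel, fraction_na_bound
from .thermo import PoTRelation

__all__ = [
    "InactivationParams",
    "inactivation_rate",
    "ramp_time_from_temperature",
    "apply_inactivation",
]

# Empirical ramp time-transform coefficients (ramp-clock units).
_RAMP_SLOPE = -0.83258
_RAMP_OFFSET = 3.3181


@dataclass(frozen=True)
class InactivationParams:
    """Parameters of the inactivation overlay.

    A: dimensionless pre-factor constant (canonical 200); dH_act:
    activation enthalpy, kcal/mol (canonical 45); dS_act: activation
    entropy, kcal/(mol K) (canonical 0.133); Tmax: maximal ramp
    temperature, K (canonical 333).
    """

    A: float = 200.0
    dH_act: float = 45.0
    dS_act: float = 0.133
    Tmax: float = 333.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.Tmax <= 0:
            raise ValueError("Tmax must be positive")


def inactivation_rate(p: InactivationParams, T, F_Na=0.0):
    """Inactivation rate k = A*(1-F_Na)^2 * exp(-(dH_act - T*dS_act)/(R*T)).

    Non-negative; increasing in T for positive activation enthalpy;
    fully suppressed at F_Na = 1 (complete Na⁺ occupancy).
    """
    T = np.asarray(T, dtype=float)
    F_Na = np.asarray(F_Na, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    if np.any((F_Na < 0) | (F_Na > 1)):
        raise ValueError("F_Na must lie in [0, 1]")
    k0 = p.A * (1.0 - F_Na) ** 2
    k = k0 * np.exp(-(p.dH_act - T * p.dS_act) / (R_KCAL * T))
    return k if k.ndim else float(k)


def ramp_time_from_temperature(p: InactivationParams, T):
    """Ramp-clock time at which a heating ramp reaches temperature T.

    t(T) = -0.83258 * ln(Tmax/(T - 0.1) - 1) + 3.3181, the inverse of a
    sigmoidal temperature-vs-time record that saturates at Tmax; strictly
    increasing in T on its admissible domain
    0.1 + Tmax/(1 + e^x) < T < Tmax + 0.1 (practically T < Tmax).
    """
    T = np.asarray(T, dtype=float)
    arg = p.Tmax / (T - 0.1) - 1.0
    if np.any(T <= 0.1) or np.any(arg <= 0):
        raise ValueError(
            f"temperature outside the transform domain "
            f"(0.1 K < T < {p.Tmax + 0.1} K required)")
    t = _RAMP_SLOPE * np.log(arg) + _RAMP_OFFSET
    return t if t.ndim else float(t)


def apply_inactivation(pot: PoTRelation, p: InactivationParams,
                       model: AllostericModel, na: float,
                       caps: float = 0.0,
                       mode: Literal["pointwise", "cumulative"] = "pointwise",
                       time_scale: float = 1.0) -> PoTRelation:
    """Overlay inactivation on an equilibrium P_o-T relation.

    At every grid point the Na⁺-bound fraction F_Na is evaluated from the
    gating model, the ramp time from the sigmoid transform, and the
    survival factor f = exp(-k(T)*t) applied.  The default ``pointwise``
    mode multiplies by the instantaneous-rate survival exactly as the
    empirical recipe prescribes; ``cumulative`` instead uses the
    cumulative hazard exp(-integral k dt) along the ramp (a non-canonical
    variant).  ``time_scale`` scales all ramp times; a fast ramp
    (time_scale -> 0) leaves the equilibrium curve untouched.

    The temperature grid must be monotone increasing (heating ramp).
    """
    T = pot.T
    if T.size > 1 and np.any(np.diff(T) <= 0):
        raise ValueError("P_o-T grid must be monotone increasing in T")
    fna = np.array([fraction_na_bound(model, t, na, caps) for t in T])
    k = inactivation_rate(p, T, fna)
    t = ramp_time_from_temperature(p, T) * time_scale
    if mode == "pointwise":
        hazard = k * t
    elif mode == "cumulative":
        hazard = cumulative_trapezoid(k, t, initial=0.0) if T.size > 1 \
            else np.zeros_like(T)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    f = np.exp(-np.maximum(hazard, 0.0))
    return replace(
        pot, Po=pot.Po * f,
        provenance=list(pot.provenance) + [{
            "step": "inactivation", "mode": mode, "A": p.A,
            "dH_act": p.dH_act, "dS_act": p.dS_act, "Tmax": p.Tmax,
            "na_M": na, "time_scale": time_scale}],
    )
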