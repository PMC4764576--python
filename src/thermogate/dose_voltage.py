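"""Hill dose-response fitting, voltage dependence of Na⁺ affinity, and
theoretical GHK current-voltage relations.

External Na⁺ is an inhibitor in this system, so the Hill equation is
written with ``Imax`` as the zero-ligand (maximal) response and ``Imin``
the response at saturating Na⁺:

    I([X]) = Imin + (Imax - Imin) / (1 + ([X]/K12)^s)

The half-inhibition constant's voltage dependence follows
``K12(V) = K12(0) * exp(-z_delta*V/(kB*T))`` and is extracted by
log-linear regression.  Theoretical I-V curves combine a Boltzmann
open-probability factor with the Goldman-Hodgkin-Katz constant-field
flux for a bi-ionic condition (internal cation X1, external cation X2
with permeability ratio f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy import stats

from .constants import FARADAY, KB_OVER_E, R_J
from .thermo import FitResult

__all__ = [
    "DoseResponse",
    "HillParams",
    "GhkParams",
    "K12Voltage",
    "hill_eval",
    "hill_fit",
    "fit_k12_voltage",
    "ghk_iv",
]


@dataclass
class DoseResponse:
    """Normalised responses at a set of ligand concentrations (molar)."""

    conc: np.ndarray
    response: np.ndarray
    sem: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc and response must have the same length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters for an inhibitory ligand.

    Imax is the response at zero ligand, Imin at saturating ligand,
    K12 the half-inhibition concentration (M), s the Hill coefficient.
    """

    Imin: float
    Imax: float
    K12: float
    s: float

    def __post_init__(self) -> None:
        if self.K12 <= 0:
            raise ValueError("K12 must be positive")
        if self.s <= 0:
            raise ValueError("Hill coefficient s must be positive")


def hill_eval(p: HillParams, conc):
    """Evaluate the inhibitory Hill equation at concentrations (M).

    conc = 0 returns Imax (zero-ligand, maximal response); conc -> inf
    tends to Imin; conc = K12 gives the midpoint (Imin + Imax)/2.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    out = p.Imin + (p.Imax - p.Imin) / (1.0 + (conc / p.K12) ** p.s)
    return out if out.ndim else float(out)


def _hill_func(conc, Imin, Imax, K12, s):
    return Imin + (Imax - Imin) / (1.0 + (conc / K12) ** s)


def hill_fit(dr: DoseResponse,
             bounds: dict | None = None,
             fix: dict | None = None) -> FitResult:
    """Nonlinear least-squares fit of the Hill equation to a dose-response.

    Parameters are bounded (K12 and s strictly positive); ``fix`` pins
    selected parameters (e.g. ``{"Imin": 0.0, "Imax": 1.0}``).  Returns
    the fitted :class:`HillParams` in ``params["hill"]`` along with
    scalar parameter values and standard errors.
    """
    if np.unique(dr.conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    model = Model(_hill_func, independent_vars=["conc"])
    pos = dr.conc[dr.conc > 0]
    k0 = np.median(pos) if pos.size else 1e-3
    params = model.make_params(
        Imin=dict(value=float(dr.response.min()), min=-10, max=10),
        Imax=dict(value=float(dr.response.max()), min=-10, max=10),
        K12=dict(value=float(k0), min=1e-12, max=1e3),
        s=dict(value=1.0, min=1e-3, max=20.0),
    )
    if bounds:
        for name, (lo, hi) in bounds.items():
            params[name].set(min=lo, max=hi)
    if fix:
        for name, value in fix.items():
            params[name].set(value=value, vary=False)
    result = model.fit(dr.response, params, conc=dr.conc)
    if not result.success:
        raise RuntimeError(f"Hill fit did not converge: {result.message}")
    vals = {k: float(v) for k, v in result.best_values.items()}
    stderr = {k: (float(p.stderr) if p.stderr is not None else float("nan"))
              for k, p in result.params.items()}
    hill = HillParams(Imin=vals["Imin"], Imax=vals["Imax"],
                      K12=vals["K12"], s=vals["s"])
    return FitResult(params={**vals, "hill": hill}, stderr=stderr,
                     residuals=np.asarray(result.residual),
                     method="lmfit least_squares (Hill)")


@dataclass(frozen=True)
class K12Voltage:
    """Exponential voltage dependence of the half-inhibition constant."""

    K12_0: float      # affinity at 0 mV, M
    z_delta: float    # effective charge, e0

    def __post_init__(self) -> None:
        if self.K12_0 <= 0:
            raise ValueError("K12_0 must be positive")

    def __call__(self, V_mV, T: float = 295.15):
        vt = KB_OVER_E * T * 1e3   # thermal voltage in mV
        return self.K12_0 * np.exp(-self.z_delta * np.asarray(V_mV) / vt)


def fit_k12_voltage(k12_by_V, T: float = 295.15) -> K12Voltage:
    """Fit K12(V) = K12(0)*exp(-z_delta*V/(kB*T)) by log-linear regression.

    ``k12_by_V`` is a sequence of (voltage mV, K12 M) pairs, at least 3.
    """
    arr = np.asarray(k12_by_V, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (V, K12) pairs")
    V, k12 = arr[:, 0], arr[:, 1]
    if np.any(k12 <= 0):
        raise ValueError("K12 values must be positive")
    res = stats.linregress(V, np.log(k12))
    vt = KB_OVER_E * T * 1e3   # mV
    return K12Voltage(K12_0=float(np.exp(res.intercept)),
                      z_delta=float(-res.slope * vt))


@dataclass(frozen=True)
class GhkParams:
    """Parameters of the Boltzmann-gated GHK current-voltage relation.

    N: channel count; Po_min/Po_max: open probability at V << 0 / V >> 0;
    z: gating charge (e0); V12: half-activation voltage (mV); P_X1:
    permeability of the internal cation (m/s); z_X1/z_X2: charges of the
    internal/external cations; X1_in/X2_out: their molar concentrations;
    f: permeability ratio P_X2/P_X1.
    """

    N: float
    Po_min: float
    Po_max: float
    z: float
    V12: float
    P_X1: float
    z_X1: int = 1
    z_X2: int = 1
    X1_in: float = 0.130
    X2_out: float = 0.130
    f: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.Po_min <= self.Po_max <= 1.0):
            raise ValueError("require 0 <= Po_min <= Po_max <= 1")
        if self.P_X1 <= 0:
            raise ValueError("P_X1 must be positive")
        if self.f < 0:
            raise ValueError("f must be non-negative")


def _flux_factor(a):
    """a / (1 - exp(-a)), series-expanded near a = 0, overflow-safe."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    out = np.empty_like(a)
    small = np.abs(a) < 1e-4
    out[small] = 1.0 + a[small] / 2.0 + a[small] ** 2 / 12.0
    big_neg = a < -500.0
    out[big_neg] = 0.0
    rest = ~(small | big_neg)
    out[rest] = a[rest] / (1.0 - np.exp(-a[rest]))
    return out


def ghk_iv(p: GhkParams, V_grid_mV, T: float = 295.15):
    """Theoretical I-V relation: Boltzmann P_o factor times GHK flux.

    I(V) = N * [Po_min + (Po_max - Po_min)/(1 + exp(-zF(V - V12)/RT))]
           * [P_X1 z1 F [X1]_i s(z1 u) - f P_X1 z2 F [X2]_o s(-z2 u)],

    with u = F*V/(R*T) and s(a) = a/(1 - exp(-a)); the permeability
    ratio f scales only the inward (external-cation) term.  The removable
    singularity at V = 0 is patched with a second-order series, making
    the curve continuous across 0.  Voltage in mV, concentrations molar
    (converted to mol/m^3 internally); the current is in arbitrary
    per-channel flux units set by P_X1.
    """
    scalar = np.isscalar(V_grid_mV) or np.ndim(V_grid_mV) == 0
    V = np.atleast_1d(np.asarray(V_grid_mV, dtype=float)) * 1e-3   # volts
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage grid must be finite")
    u = FARADAY * V / (R_J * T)
    po = p.Po_min + (p.Po_max - p.Po_min) / (
        1.0 + np.exp(-p.z * FARADAY * (V - p.V12 * 1e-3) / (R_J * T)))
    c1 = p.X1_in * 1e3    # mol/m^3
    c2 = p.X2_out * 1e3
    out_term = p.P_X1 * p.z_X1 * FARADAY * c1 * _flux_factor(p.z_X1 * u)
    in_term = p.f * p.P_X1 * p.z_X2 * FARADAY * c2 * _flux_factor(-p.z_X2 * u)
    I = p.N * po * (out_term - in_term)
    return float(I[0]) if scalar else I
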