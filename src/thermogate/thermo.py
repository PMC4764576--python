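"""Conversion of macroscopic current–temperature data into P_o–T relations.

The macroscopic current through a population of channels factors as
``I(T) = N * i(T) * P_o(T)`` plus leak.  The single-channel conduction
term ``i(T)`` follows an Arrhenius law with an activation enthalpy of
about 9 kcal/mol; dividing it out of an I-T relation leaves a quantity
proportional to the open probability, which is then placed on an absolute
scale using the relative current magnitudes at a reference temperature
and a known reference P_o.

Apparent enthalpies are extracted from the steepest portions of I-T (or
P_o-T) relations with the exponential

    I(T) = exp(-(dH_app - T*dS_app) / (R*T))

fit as a straight line on ln I vs 1/T (slope -> -dH_app/R, intercept ->
dS_app/R); the dH_app/dS_app pair is degenerate with an overall amplitude
on normalised data, so dH_app is the reported quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import R_KCAL, celsius_to_kelvin

__all__ = [
    "ITRelation",
    "PoTRelation",
    "ConductionModel",
    "FitResult",
    "fit_exponential_enthalpy",
    "open_channel_current",
    "it_to_pot",
    "average_relations",
    "scale_pot",
    "q10_from_enthalpy",
]

#: Default reference temperature for normalisation/scaling: 22 °C.
DEFAULT_T_REF: float = celsius_to_kelvin(22.0)


@dataclass
class FitResult:
    """Estimated parameters with uncertainties and residuals."""

    params: dict
    stderr: dict
    residuals: np.ndarray
    method: str


def _as_1d(name, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return x


@dataclass
class ITRelation:
    """Current vs temperature samples for one cell/condition.

    T in kelvin (strictly inside (250, 350)), I in pA (or normalised),
    voltage the holding/test potential in mV.
    """

    T: np.ndarray
    I: np.ndarray
    voltage: float = 90.0
    condition: str = ""
    normalization: dict | None = None

    def __post_init__(self) -> None:
        self.T = _as_1d("T", self.T)
        self.I = _as_1d("I", self.I)
        if self.T.shape != self.I.shape:
            raise ValueError("T and I must have the same length")
        if np.any((self.T <= 250.0) | (self.T >= 350.0)):
            raise ValueError("temperatures must lie strictly within (250, 350) K")

    def normalized_at(self, T_ref: float = DEFAULT_T_REF,
                      tol_K: float = 1.0) -> "ITRelation":
        """Normalise currents to the sample nearest T_ref (within tol_K)."""
        idx = int(np.argmin(np.abs(self.T - T_ref)))
        if abs(self.T[idx] - T_ref) > tol_K:
            raise ValueError(
                f"no sample within {tol_K} K of reference {T_ref} K")
        ref = self.I[idx]
        if ref == 0:
            raise ValueError("reference current is zero")
        return ITRelation(self.T.copy(), self.I / ref, self.voltage,
                          self.condition,
                          {"T_ref": float(self.T[idx]), "I_ref": float(ref)})


@dataclass
class PoTRelation:
    """Open probability vs temperature, with scaling provenance."""

    T: np.ndarray
    Po: np.ndarray
    sem: np.ndarray | None = None
    T_sem: np.ndarray | None = None
    condition: str = ""
    scale_ref: dict | None = None
    provenance: list = field(default_factory=list)
    dHapp_fits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = _as_1d("T", self.T)
        self.Po = _as_1d("Po", self.Po)
        if self.T.shape != self.Po.shape:
            raise ValueError("T and Po must have the same length")


@dataclass(frozen=True)
class ConductionModel:
    """Arrhenius model of open-channel conduction: i(T) = i0*exp(-dH/(R*T)).

    ``dH_conduction`` is the activation enthalpy in kcal/mol (canonical
    value 9.0); ``i0`` the pre-exponential amplitude in pA.
    """

    i0: float = 1.0
    dH_conduction: float = 9.0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")

    @classmethod
    def from_room_current(cls, i_room: float, dH: float = 9.0,
                          T_ref: float = DEFAULT_T_REF) -> "ConductionModel":
        """Build a model with a given single-channel current at T_ref."""
        i0 = i_room / np.exp(-dH / (R_KCAL * T_ref))
        return cls(i0=i0, dH_conduction=dH)


def open_channel_current(cm: ConductionModel, T):
    """Single-channel current i(T) = i0 * exp(-dH/(R*T)), pA.

    Strictly increasing in T for a positive activation enthalpy.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = cm.i0 * np.exp(-cm.dH_conduction / (R_KCAL * T))
    return out if out.ndim else float(out)


def fit_exponential_enthalpy(rel: ITRelation | PoTRelation,
                             T_range: tuple[float, float] | None = None
                             ) -> FitResult:
    """Fit I(T) = exp(-(dH_app - T*dS_app)/(R*T)) over a temperature range.

    Performed as ordinary least squares on ln I vs 1/T; returns dH_app
    (kcal/mol) and dS_app (kcal/(mol K)) with standard errors.
    """
    T = rel.T
    y = rel.I if isinstance(rel, ITRelation) else rel.Po
    if T_range is not None:
        mask = (T >= T_range[0]) & (T <= T_range[1])
        T, y = T[mask], y[mask]
    if T.size < 4:
        raise ValueError("need at least 4 samples in the fitted range")
    if np.any(y <= 0):
        raise ValueError("non-positive currents in the fitted range")
    x = 1.0 / T
    lny = np.log(y)
    res = stats.linregress(x, lny)
    dH = -res.slope * R_KCAL
    dS = res.intercept * R_KCAL
    resid = lny - (res.intercept + res.slope * x)
    return FitResult(
        params={"dHapp": dH, "dSapp": dS},
        stderr={"dHapp": res.stderr * R_KCAL,
                "dSapp": res.intercept_stderr * R_KCAL},
        residuals=resid,
        method="ols ln(I) vs 1/T",
    )


def it_to_pot(rel: ITRelation, cm: ConductionModel) -> PoTRelation:
    """Divide the conduction temperature dependence out of an I-T relation.

    Returns the unscaled relation Po_unscaled(T) = I(T)/i(T): if the
    currents were generated as ``N * i(T) * P_o(T)`` the output is
    proportional to P_o(T).
    """
    i = open_channel_current(cm, rel.T)
    if np.any(i == 0):
        raise ZeroDivisionError("conduction current is zero")
    return PoTRelation(
        T=rel.T.copy(), Po=rel.I / i, condition=rel.condition,
        provenance=[{"step": "conduction_correction",
                     "dH_conduction": cm.dH_conduction, "i0": cm.i0}],
    )


def average_relations(rels: Sequence[ITRelation] | Sequence[PoTRelation],
                      T_bin: float = 1.0):
    """Average several relations on a fixed-width temperature grid.

    Samples from all relations are pooled into bins of width ``T_bin``;
    per bin the mean and SEM of both the temperature and the value are
    reported, and bins with fewer than two samples are dropped (a
    programmatic replacement for manually matching similar temperatures
    across cells).
    """
    if len(rels) < 2:
        raise ValueError("need at least 2 relations to average")
    if T_bin <= 0:
        raise ValueError("T_bin must be positive")
    is_pot = isinstance(rels[0], PoTRelation)
    T_all = np.concatenate([r.T for r in rels])
    y_all = np.concatenate([(r.Po if is_pot else r.I) for r in rels])
    lo = np.floor(T_all.min() / T_bin) * T_bin
    edges = np.arange(lo, T_all.max() + T_bin, T_bin)
    idx = np.digitize(T_all, edges)
    T_m, T_s, y_m, y_s = [], [], [], []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() < 2:
            continue
        n = sel.sum()
        T_m.append(T_all[sel].mean())
        T_s.append(T_all[sel].std(ddof=1) / np.sqrt(n))
        y_m.append(y_all[sel].mean())
        y_s.append(y_all[sel].std(ddof=1) / np.sqrt(n))
    if not T_m:
        raise ValueError("no temperature bin holds samples from >=2 points "
                         "(disjoint ranges?)")
    order = np.argsort(T_m)
    T_m, y_m = np.asarray(T_m)[order], np.asarray(y_m)[order]
    T_s, y_s = np.asarray(T_s)[order], np.asarray(y_s)[order]
    if is_pot:
        return PoTRelation(T=T_m, Po=y_m, sem=y_s, T_sem=T_s,
                           condition=rels[0].condition,
                           provenance=[{"step": "average",
                                        "n_relations": len(rels),
                                        "T_bin": T_bin}])
    return ITRelation(T=T_m, I=y_m, voltage=rels[0].voltage,
                      condition=rels[0].condition)


def scale_pot(rel: PoTRelation, current_ratio_at_ref: float,
              reference_Po: float, T_ref: float = DEFAULT_T_REF,
              tol_K: float = 1.0) -> PoTRelation:
    """Place an unscaled P_o-T relation on an absolute P_o scale.

    The curve is multiplied so that its value at the reference
    temperature equals ``reference_Po * current_ratio_at_ref``, where the
    ratio is the macroscopic current of this condition relative to the
    reference condition at T_ref (e.g. 2/9 for the zero-Na current
    against the saturating-capsaicin current, whose reference P_o is
    ~0.9).  Chained scalings through intermediate references compose
    multiplicatively; every step is recorded in ``provenance``.
    """
    if not (0.0 < reference_Po <= 1.0):
        raise ValueError("reference_Po must lie in (0, 1]")
    if current_ratio_at_ref <= 0:
        raise ValueError("current_ratio_at_ref must be positive")
    idx = int(np.argmin(np.abs(rel.T - T_ref)))
    if abs(rel.T[idx] - T_ref) > tol_K:
        raise ValueError(f"no sample within {tol_K} K of reference {T_ref} K")
    target = reference_Po * current_ratio_at_ref
    factor = target / rel.Po[idx]
    Po = rel.Po * factor
    over = Po > 1.0 + 1e-9
    if np.any(over):
        bad = rel.T[over]
        raise ValueError(
            f"scaling pushes P_o above 1 at T = {bad.min():.2f}..."
            f"{bad.max():.2f} K")
    step = {"step": "scale", "T_ref": float(rel.T[idx]),
            "current_ratio": current_ratio_at_ref,
            "reference_Po": reference_Po, "factor": float(factor)}
    return PoTRelation(
        T=rel.T.copy(), Po=Po,
        sem=None if rel.sem is None else rel.sem * factor,
        T_sem=rel.T_sem, condition=rel.condition,
        scale_ref={"reference_Po": reference_Po,
                   "reference_T": float(rel.T[idx])},
        provenance=list(rel.provenance) + [step],
        dHapp_fits=list(rel.dHapp_fits),
    )


def q10_from_enthalpy(dHapp: float) -> float:
    """Approximate Q10 from an apparent enthalpy: Q10 ≈ exp(dH_app/20)."""
    return float(np.exp(dHapp / 20.0))
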