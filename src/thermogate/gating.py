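"""Allosteric state models of temperature-, Na⁺- and capsaicin-dependent gating.

The central object is a coupled-equilibrium (MWC-style) scheme for a
thermoTRP channel: a temperature-insensitive pore opening equilibrium
(constant ``L``), a two-step temperature-driven sensor activation
(van 't Hoff constants ``J1`` and ``J2`` applied sequentially), binding of
external Na⁺ (association constant ``K1'`` with a Hill-style cooperativity
exponent), and an optional capsaicin binding step.  Coupling between
equilibria is expressed through dimensionless multiplicative allosteric
factors: the first and second sensor steps increase the opening constant
by ``D`` and ``D*E``; Na⁺ binding scales ``J1`` by ``G``, ``J2`` by ``H``
and ``L`` by ``F``.

The open probability is computed from the partition function over all
states; :func:`enumerate_states` provides the explicit state-by-state
statistical weights used as the brute-force oracle for the vectorised
partition-function implementation.

Two reduced alternative schemes are provided: a model in which Na⁺ binding
re-routes opening through its own temperature-dependent transition
(:func:`open_probability_model_ii`) and a single-sensor-step model
(:func:`open_probability_model_iii`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .constants import R_KCAL

__all__ = [
    "ThermoTransition",
    "AllostericModel",
    "ModelII",
    "ModelIII",
    "StateWeight",
    "equilibrium_constant",
    "enumerate_states",
    "open_probability",
    "fraction_na_bound",
    "open_probability_model_ii",
    "open_probability_model_iii",
]


@dataclass(frozen=True)
class ThermoTransition:
    """A two-state equilibrium parameterised thermodynamically.

    Parameters
    ----------
    dH0 : float
        Standard enthalpy change, kcal/mol.  For ``dCp != 0`` this is the
        enthalpy at the reference temperature ``T0`` (the heat-capacity
        form printed in the literature corresponds to ``dH0 = 0`` at
        ``T0``).
    dS0 : float
        Standard entropy change, kcal/(mol K); at ``T0`` when ``dCp != 0``.
    dCp : float, optional
        Heat-capacity change, kcal/(mol K).  Default 0 (plain van 't Hoff).
    T0 : float, optional
        Reference temperature (K); required when ``dCp != 0``.
    """

    dH0: float
    dS0: float
    dCp: float = 0.0
    T0: float | None = None

    def __post_init__(self) -> None:
        if self.dCp != 0.0 and (self.T0 is None or self.T0 <= 0):
            raise ValueError("T0 > 0 is required when dCp != 0")

    def __call__(self, T):
        return equilibrium_constant(self, T)

    def midpoint(self) -> float:
        """Temperature (K) at which the equilibrium constant equals 1.

        Only defined for the van 't Hoff form with dH0 and dS0 of the
        same sign.
        """
        if self.dCp != 0.0:
            raise ValueError("midpoint() is defined for the dCp = 0 form only")
        if self.dS0 == 0:
            raise ValueError("midpoint undefined for dS0 = 0")
        return self.dH0 / self.dS0


def equilibrium_constant(tr: ThermoTransition, T):
    """Equilibrium constant J(T) of a thermodynamic transition.

    With ``dCp = 0`` this is the van 't Hoff expression
    ``exp(-(dH0 - T*dS0) / (R*T))``.  With ``dCp != 0`` the enthalpy and
    entropy acquire their standard linear/logarithmic temperature
    dependence about ``T0``:

    ``ln J = -(dH0 + dCp*(T - T0))/(R*T) + (dS0 + dCp*ln(T/T0))/R``

    which for ``dH0 = 0`` reduces to
    ``exp(dS0/R - dCp/R * (1 - T0/T + ln(T0/T)))``.

    Parameters
    ----------
    tr : ThermoTransition
    T : float or ndarray
        Temperature in kelvin, > 0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    if tr.dCp == 0.0:
        lnJ = -(tr.dH0 - T * tr.dS0) / (R_KCAL * T)
    else:
        dH = tr.dH0 + tr.dCp * (T - tr.T0)
        dS = tr.dS0 + tr.dCp * np.log(T / tr.T0)
        lnJ = -dH / (R_KCAL * T) + dS / R_KCAL
    out = np.exp(lnJ)
    return out if out.ndim else float(out)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class AllostericModel:
    """Parameter set for the full two-sensor-step allosteric scheme.

    All equilibrium constants and allosteric factors are dimensionless
    except the association constants ``K1_prime`` (per molar Na⁺) and
    ``K2_prime`` (per molar capsaicin).  Binding terms enter the weights
    as ``(K' * [ligand]) ** coop_exponent``.

    Capsaicin coupling factors are named for the equilibrium they act on
    (``c_L`` opening, ``c_J1``/``c_J2`` sensor steps, ``c_Na`` Na⁺
    binding); all default to 1 (neutral).
    """

    L: float
    J1: ThermoTransition
    J2: ThermoTransition
    D: float = 1.0
    E: float = 1.0
    K1_prime: float = 1.0
    F: float = 1.0
    G: float = 1.0
    H: float = 1.0
    K2_prime: float | None = None
    c_L: float = 1.0
    c_J1: float = 1.0
    c_J2: float = 1.0
    c_Na: float = 1.0
    coop_exponent: float = 1.5

    def __post_init__(self) -> None:
        for name in ("L", "D", "E", "K1_prime", "F", "G", "H",
                     "c_L", "c_J1", "c_J2", "c_Na", "coop_exponent"):
            _positive(name, getattr(self, name))
        if self.K2_prime is not None:
            _positive("K2_prime", self.K2_prime)

    @property
    def n_states(self) -> int:
        return 24 if self.K2_prime is not None else 12


@dataclass(frozen=True)
class StateWeight:
    """Statistical weight of one conformational/liganded state.

    The reference state (closed pore, resting sensor, unliganded) has
    weight 1; all other weights are relative to it.
    """

    sensor_step: int
    pore: Literal["closed", "open"]
    na_bound: bool
    caps_bound: bool
    weight: float


def _binding_term(K_prime: float, conc: float, coop: float) -> float:
    # (K' * [X]) ** coop; exactly zero at zero ligand for any coop > 0
    x = K_prime * conc
    return 0.0 if x == 0.0 else x**coop


def _iter_states(model: AllostericModel,
                 caps_present: bool) -> Iterator[tuple[int, bool, bool, bool]]:
    caps_options = (False, True) if caps_present else (False,)
    for sensor in (0, 1, 2):
        for is_open in (False, True):
            for na_b in (False, True):
                for caps_b in caps_options:
                    yield sensor, is_open, na_b, caps_b


def enumerate_states(model: AllostericModel, T: float, na: float,
                     caps: float = 0.0) -> list[StateWeight]:
    """Explicitly enumerate every state of the scheme with its weight.

    This is the scalar, loop-based construction of the partition function
    used as the internal consistency oracle for :func:`open_probability`.

    Weight construction: sensor step 1 contributes ``J1(T)``, step 2
    ``J1(T)*J2(T)`` (sequential arrangement); an open pore contributes
    ``L``, multiplied by ``D`` once the sensor has left the resting state
    and additionally by ``E`` when fully activated.  A Na⁺-bound state
    carries ``(K1'*[Na])**coop`` and the coupling factors ``G`` (sensor
    step >= 1), ``H`` (step 2) and ``F`` (open pore).  Capsaicin binding
    is handled analogously with its own constant and couplings.
    """
    if na < 0 or caps < 0:
        raise ValueError("ligand concentrations must be non-negative")
    caps_present = model.K2_prime is not None
    if caps > 0 and not caps_present:
        raise ValueError("caps > 0 requires a model with K2_prime set")
    J1 = float(equilibrium_constant(model.J1, T))
    J2 = float(equilibrium_constant(model.J2, T))
    K1 = _binding_term(model.K1_prime, na, model.coop_exponent)
    K2 = (_binding_term(model.K2_prime, caps, model.coop_exponent)
          if caps_present else 0.0)

    states: list[StateWeight] = []
    for sensor, is_open, na_b, caps_b in _iter_states(model, caps_present):
        w = 1.0
        if sensor >= 1:
            w *= J1
        if sensor == 2:
            w *= J2
        if is_open:
            w *= model.L
            if sensor >= 1:
                w *= model.D
            if sensor == 2:
                w *= model.E
        if na_b:
            w *= K1
            if sensor >= 1:
                w *= model.G
            if sensor == 2:
                w *= model.H
            if is_open:
                w *= model.F
        if caps_b:
            w *= K2
            if sensor >= 1:
                w *= model.c_J1
            if sensor == 2:
                w *= model.c_J2
            if is_open:
                w *= model.c_L
            if na_b:
                w *= model.c_Na
        states.append(StateWeight(sensor, "open" if is_open else "closed",
                                  na_b, caps_b, w))
    return states


def _weight_arrays(model: AllostericModel, T, na: float, caps: float):
    """Vectorised total/open/Na-bound weight sums over a temperature array."""
    if na < 0 or caps < 0:
        raise ValueError("ligand concentrations must be non-negative")
    caps_present = model.K2_prime is not None
    if caps > 0 and not caps_present:
        raise ValueError("caps > 0 requires a model with K2_prime set")
    T = np.asarray(T, dtype=float)
    J1 = np.asarray(equilibrium_constant(model.J1, T))
    J2 = np.asarray(equilibrium_constant(model.J2, T))
    K1 = _binding_term(model.K1_prime, na, model.coop_exponent)
    K2 = (_binding_term(model.K2_prime, caps, model.coop_exponent)
          if caps_present else 0.0)

    total = np.zeros_like(J1)
    open_w = np.zeros_like(J1)
    na_w = np.zeros_like(J1)
    sensor_w = (np.ones_like(J1), J1, J1 * J2)
    for sensor, is_open, na_b, caps_b in _iter_states(model, caps_present):
        w = sensor_w[sensor].copy()
        if is_open:
            w *= model.L
            if sensor >= 1:
                w *= model.D
            if sensor == 2:
                w *= model.E
        if na_b:
            w *= K1 * (model.G if sensor >= 1 else 1.0) \
                 * (model.H if sensor == 2 else 1.0) \
                 * (model.F if is_open else 1.0)
        if caps_b:
            w *= K2 * (model.c_J1 if sensor >= 1 else 1.0) \
                 * (model.c_J2 if sensor == 2 else 1.0) \
                 * (model.c_L if is_open else 1.0) \
                 * (model.c_Na if na_b else 1.0)
        total += w
        if is_open:
            open_w += w
        if na_b:
            na_w += w
    return total, open_w, na_w


def open_probability(model: AllostericModel, T, na: float = 0.0,
                     caps: float = 0.0):
    """Equilibrium open probability P_o(T, [Na], [caps]).

    ``P_o = sum(open-state weights) / sum(all weights)``; always in
    [0, 1].  Accepts scalar or array temperature (kelvin).
    """
    total, open_w, _ = _weight_arrays(model, T, na, caps)
    po = open_w / total
    return po if po.ndim else float(po)


def fraction_na_bound(model: AllostericModel, T, na: float = 0.0,
                      caps: float = 0.0):
    """Equilibrium occupancy of Na⁺-bound states, F_Na(T, [Na], [caps])."""
    total, _, na_w = _weight_arrays(model, T, na, caps)
    f = na_w / total
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Alternative schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelII:
    """Scheme in which Na⁺ binding re-routes opening through J3.

    Eight states in two rows.  Na⁺-free row: resting closed state (1),
    sensor-activated closed state (J1), open state (J1*L) and a second
    temperature-driven open state (J1*L*J2).  Na⁺-bound row (binding term
    ``(K1'*[Na])**coop``): the first transition is scaled by ``G`` and
    opening proceeds through its own temperature-dependent constant
    ``J3`` instead of ``L``.
    """

    L: float
    J1: ThermoTransition
    J2: ThermoTransition
    J3: ThermoTransition
    G: float = 1.0
    K1_prime: float = 1.0
    coop_exponent: float = 1.5

    def __post_init__(self) -> None:
        for name in ("L", "G", "K1_prime", "coop_exponent"):
            _positive(name, getattr(self, name))


def open_probability_model_ii(params: ModelII, T, na: float = 0.0):
    """Open probability of the 8-state Na⁺-rerouted opening scheme."""
    if na < 0:
        raise ValueError("ligand concentrations must be non-negative")
    T = np.asarray(T, dtype=float)
    J1 = np.asarray(equilibrium_constant(params.J1, T))
    J2 = np.asarray(equilibrium_constant(params.J2, T))
    J3 = np.asarray(equilibrium_constant(params.J3, T))
    K1 = _binding_term(params.K1_prime, na, params.coop_exponent)
    L, G = params.L, params.G

    c_free = 1.0 + J1
    o_free = J1 * L * (1.0 + J2)
    c_na = K1 * (1.0 + G * J1)
    o_na = K1 * G * J1 * J3 * (1.0 + J2)
    po = (o_free + o_na) / (c_free + o_free + c_na + o_na)
    return po if po.ndim else float(po)


@dataclass(frozen=True)
class ModelIII:
    """Single-sensor-step variant of the full scheme.

    Equivalent to the main model with the second sensor transition
    removed: sensor in {resting, active}, opening coupled through ``D``,
    Na⁺ binding coupled through ``F`` (opening) and ``G`` (sensor).
    """

    L: float
    J1: ThermoTransition
    D: float = 1.0
    K1_prime: float = 1.0
    F: float = 1.0
    G: float = 1.0
    coop_exponent: float = 1.5

    def __post_init__(self) -> None:
        for name in ("L", "D", "K1_prime", "F", "G", "coop_exponent"):
            _positive(name, getattr(self, name))


def open_probability_model_iii(params: ModelIII, T, na: float = 0.0):
    """Open probability of the 8-state single-sensor scheme."""
    if na < 0:
        raise ValueError("ligand concentrations must be non-negative")
    T = np.asarray(T, dtype=float)
    J1 = np.asarray(equilibrium_constant(params.J1, T))
    K1 = _binding_term(params.K1_prime, na, params.coop_exponent)
    L, D, F, G = params.L, params.D, params.F, params.G

    total = np.zeros_like(J1)
    open_w = np.zeros_like(J1)
    for sensor in (0, 1):
        for is_open in (False, True):
            for na_b in (False, True):
                w = J1 if sensor else np.ones_like(J1)
                if is_open:
                    w = w * L * (D if sensor else 1.0)
                if na_b:
                    w = w * K1 * (G if sensor else 1.0) * (F if is_open else 1.0)
                total = total + w
                if is_open:
                    open_w = open_w + w
    po = open_w / total
    return po if po.ndim else float(po)
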