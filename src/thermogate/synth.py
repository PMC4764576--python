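"""Seeded synthetic-data generator for every input the pipeline consumes.

Emulates the statistical structure the analysis assumes: macroscopic
ramp currents I = N*i(T)*P_o(T,[Na],[caps]) + leak + noise with
Arrhenius open-channel conduction; multi-sweep binomial/Markov channel
fluctuations for noise analysis; Hill-shaped dose-response curves; and
single-channel amplitude tables with Gaussian scatter.  Every generator
draws from a fresh ``numpy.random.default_rng(cfg.seed)``, so identical
configurations produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .dose_voltage import DoseResponse, HillParams, hill_eval
from .gating import AllostericModel, ThermoTransition, open_probability
from .inactivation import InactivationParams, inactivation_rate, \
    ramp_time_from_temperature
from .noise import SweepEnsemble
from .thermo import ConductionModel, ITRelation, open_channel_current
from .gating import fraction_na_bound

__all__ = [
    "SimConfig",
    "default_model",
    "gen_it_ramp",
    "gen_noise_ensemble",
    "gen_dose_response",
    "gen_single_channel_amplitudes",
]


def default_model(**overrides) -> AllostericModel:
    """Illustrative two-sensor-step model parameter set (non-canonical).

    Chosen to reproduce the qualitative P_o-T phenomenology: a rise at
    low temperature, an intermediate plateau whose level falls as [Na⁺]
    rises, and a steep second rise near 40 °C.  The published fits'
    numerical parameter values are not reproduced in print, so these are
    the package's own defaults, not the study's.
    """
    params = dict(
        L=0.005,
        J1=ThermoTransition(dH0=30.0, dS0=30.0 / 278.0),
        J2=ThermoTransition(dH0=80.0, dS0=80.0 / 318.0),
        D=50.0,
        E=1000.0,
        K1_prime=1.0 / 0.007,
        F=0.12,
        G=0.01,
        H=1.0,
    )
    params.update(overrides)
    return AllostericModel(**params)


@dataclass(frozen=True)
class SimConfig:
    """Configuration shared by the generators.

    n_channels: population size; i_room: single-channel current at 22 °C
    (pA); conduction_dH: Arrhenius enthalpy of conduction (kcal/mol);
    leak: constant leak current (pA); noise_sd: Gaussian measurement
    noise (pA); ramp: (T_start_K, T_end_K, n_points).
    """

    seed: int = 0
    n_channels: int = 400
    i_room: float = 2.0
    conduction_dH: float = 9.0
    model: AllostericModel = field(default_factory=default_model)
    leak: float = 0.0
    noise_sd: float = 0.0
    ramp: tuple[float, float, int] = (279.15, 318.15, 80)
    ramp_shape: str = "linear"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def conduction(self) -> ConductionModel:
        return ConductionModel.from_room_current(self.i_room,
                                                 self.conduction_dH)


def _ramp_grid(cfg: SimConfig) -> np.ndarray:
    T0, T1, n = cfg.ramp
    if cfg.ramp_shape == "linear":
        return np.linspace(T0, T1, n)
    if cfg.ramp_shape == "sigmoid":
        # equally spaced in ramp-clock time under the empirical transform
        p = InactivationParams(Tmax=max(T1 + 5.0, 333.0))
        t = np.linspace(ramp_time_from_temperature(p, T0),
                        ramp_time_from_temperature(p, T1), n)
        # invert t(T) numerically (monotone)
        Ts = np.linspace(T0, T1, 4000)
        return np.interp(t, ramp_time_from_temperature(p, Ts), Ts)
    raise ValueError(f"unknown ramp shape {cfg.ramp_shape!r}")


def gen_it_ramp(cfg: SimConfig, na: float, caps: float = 0.0,
                inactivation: InactivationParams | None = None,
                voltage: float = 90.0) -> ITRelation:
    """Macroscopic current during a heating ramp.

    I(T) = n_channels * i(T) * P_o(T, na, caps) [* survival] + leak
    + Gaussian noise.  With ``inactivation`` given, the pointwise
    survival factor exp(-k(T) t(T)) of the empirical overlay is applied.
    """
    rng = np.random.default_rng(cfg.seed)
    T = _ramp_grid(cfg)
    po = np.asarray(open_probability(cfg.model, T, na, caps))
    if inactivation is not None:
        fna = np.array([fraction_na_bound(cfg.model, t, na, caps) for t in T])
        k = inactivation_rate(inactivation, T, fna)
        t = ramp_time_from_temperature(inactivation, T)
        po = po * np.exp(-np.maximum(k * t, 0.0))
    i = open_channel_current(cfg.conduction, T)
    I = cfg.n_channels * i * po + cfg.leak
    if cfg.noise_sd > 0:
        I = I + rng.normal(0.0, cfg.noise_sd, size=I.shape)
    label = f"na={na:g}M caps={caps:g}M"
    return ITRelation(T=T, I=I, voltage=voltage, condition=label)


def gen_noise_ensemble(cfg: SimConfig, Po: float, n_sweeps: int = 50,
                       n_samples: int = 400,
                       correlation_time: float = 0.0,
                       sample_interval: float = 1e-3,
                       rundown: float = 0.0,
                       baseline_sd: float = 0.0,
                       temperature: float = celsius_to_kelvin(24.0)
                       ) -> SweepEnsemble:
    """Stochastic sweep ensemble from a population of two-state channels.

    Each of ``n_channels`` channels is open with stationary probability
    ``Po``.  With ``correlation_time`` = 0 the open count is an
    independent binomial draw per sample; otherwise each channel follows
    a two-state Markov chain with exponential autocorrelation of that
    time constant (seconds).  ``rundown`` applies a linear multiplicative
    amplitude decline across sweeps (e.g. 0.2 = 20% loss by the last
    sweep).  Baseline Gaussian noise of SD ``baseline_sd`` pA is added.
    """
    if not (0.0 <= Po <= 1.0):
        raise ValueError("Po must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_channels
    i_unit = open_channel_current(cfg.conduction, temperature)
    if correlation_time <= 0.0:
        n_open = rng.binomial(N, Po, size=(n_sweeps, n_samples))
    else:
        dt = sample_interval
        relax = 1.0 - np.exp(-dt / correlation_time)
        n_open = np.empty((n_sweeps, n_samples), dtype=np.int64)
        for j in range(n_sweeps):
            state = rng.random(N) < Po
            n_open[j, 0] = state.sum()
            for k in range(1, n_samples):
                flip = rng.random(N) < relax
                state = np.where(flip, rng.random(N) < Po, state)
                n_open[j, k] = state.sum()
    sweeps = i_unit * n_open.astype(float)
    if rundown != 0.0 and n_sweeps > 1:
        factors = 1.0 - rundown * np.arange(n_sweeps) / (n_sweeps - 1)
        sweeps = sweeps * factors[:, None]
    if baseline_sd > 0.0:
        sweeps = sweeps + rng.normal(0.0, baseline_sd, size=sweeps.shape)
    win = (int(0.05 * n_samples), n_samples - int(0.05 * n_samples))
    return SweepEnsemble(sweeps=sweeps, sample_interval=sample_interval,
                         steady_state_window=win,
                         condition=f"Po={Po:g}")


def gen_dose_response(cfg: SimConfig, hill: HillParams, conc_grid,
                      noise_sd: float = 0.0) -> DoseResponse:
    """Hill-shaped dose-response samples with optional Gaussian noise."""
    rng = np.random.default_rng(cfg.seed)
    conc = np.asarray(conc_grid, dtype=float)
    resp = np.asarray(hill_eval(hill, conc), dtype=float)
    if noise_sd > 0.0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return DoseResponse(conc=conc, response=resp)


def gen_single_channel_amplitudes(cfg: SimConfig, T_grid,
                                  scatter_sd: float = 0.0) -> pd.DataFrame:
    """Single-channel current amplitudes i(T) with Gaussian scatter.

    Returns a DataFrame with columns ``T_K`` and ``i_pA``.
    """
    rng = np.random.default_rng(cfg.seed)
    T = np.asarray(T_grid, dtype=float)
    if np.any((T <= 250.0) | (T >= 350.0)):
        raise ValueError("T_grid must lie within (250, 350) K")
    i = np.asarray(open_channel_current(cfg.conduction, T), dtype=float)
    if scatter_sd > 0.0:
        i = i + rng.normal(0.0, scatter_sd * i, size=i.shape)
    return pd.DataFrame({"T_K": T, "i_pA": i})
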