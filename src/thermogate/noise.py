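"""Hybrid non-stationary/stationary noise analysis of current sweep ensembles.

The variance of the current across repeated sweeps at a fixed voltage is
computed from successive differences of sweeps,

    y_j = (x_j - x_{j+1}) / 2,        j = 1..N-1
    sigma2_I = 2/(N-2) * sum_j (y_j - ybar)^2,

which cancels slow common drift (rundown) to first order, unlike the
naive ensemble variance.  The variance-mean relation of a homogeneous
population of N identical channels with unitary current i is the
parabola

    sigma2 = I_mean * i - I_mean^2 / N,

whose fit yields i and N; the absolute open probability then follows
from the steady-state mean current as P_o = I_mean,ss / (i * N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SweepEnsemble",
    "NoiseFit",
    "successive_difference_variance",
    "naive_ensemble_variance",
    "correct_leak_baseline",
    "fit_variance_mean",
    "open_prob_from_noise",
]


@dataclass
class SweepEnsemble:
    """Equal-length current sweeps recorded at a fixed voltage.

    sweeps: array (n_sweeps, n_samples) in pA; sample_interval in s;
    steady_state_window an index interval (start, stop) marking the
    steady-state portion; condition a free-form label.
    """

    sweeps: np.ndarray
    sample_interval: float = 1e-4
    steady_state_window: tuple[int, int] | None = None
    condition: str = ""
    voltage: float = 90.0

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D array (n_sweeps, n_samples)")
        if self.sweeps.shape[0] < 3:
            raise ValueError("need at least 3 sweeps")
        if self.steady_state_window is not None:
            a, b = self.steady_state_window
            if not (0 <= a < b <= self.sweeps.shape[1]):
                raise ValueError("steady_state_window outside the trace")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


@dataclass
class NoiseFit:
    """Result of a variance-mean fit: unitary current, channel count."""

    i_hat: float
    N_hat: float
    Po_hat: float | None = None
    constrained: bool = False
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.i_hat <= 0 or self.N_hat <= 0:
            raise ValueError("i_hat and N_hat must be positive")


def successive_difference_variance(ens: SweepEnsemble
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point variance from successive sweep differences, and mean.

    Returns ``(sigma2, I_mean)``, each of length n_samples.  Requires at
    least 3 sweeps (the estimator divides by N - 2).
    """
    x = ens.sweeps
    N = x.shape[0]
    if N < 3:
        raise ValueError("need at least 3 sweeps")
    y = 0.5 * (x[:-1] - x[1:])            # (N-1, n_samples)
    ybar = y.mean(axis=0)
    sigma2 = 2.0 / (N - 2) * ((y - ybar) ** 2).sum(axis=0)
    imean = x.mean(axis=0)
    return sigma2, imean


def naive_ensemble_variance(ens: SweepEnsemble
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Plain across-sweep sample variance (drift-sensitive comparator)."""
    x = ens.sweeps
    return x.var(axis=0, ddof=1), x.mean(axis=0)


def correct_leak_baseline(sigma2, imean, baseline_sigma2, baseline_imean,
                          trim_frac: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract baseline variance and mean; trim capacitive edges.

    ``baseline_*`` may be scalars (steady-state statistics of the
    baseline segment) or arrays matching the traces.  The first and last
    ``trim_frac`` of the samples are dropped, where capacitive transients
    contaminate the records.  A warning is issued when more than 10% of
    the corrected variances are negative.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    imean = np.asarray(imean, dtype=float)
    s = sigma2 - np.asarray(baseline_sigma2, dtype=float)
    m = imean - np.asarray(baseline_imean, dtype=float)
    if trim_frac > 0:
        k = int(np.floor(trim_frac * s.shape[-1]))
        if k > 0:
            s, m = s[..., k:-k], m[..., k:-k]
    if s.size and (s < 0).mean() > 0.10:
        warnings.warn("more than 10% of corrected variances are negative; "
                      "check the baseline segment", stacklevel=2)
    return s, m


def fit_variance_mean(sigma2, imean, i_fixed: float | None = None
                      ) -> NoiseFit:
    """Least-squares fit of sigma2 = I*i - I^2/N to (variance, mean) pairs.

    The model is linear in (i, 1/N), so the fit is an exact linear least
    squares (unweighted).  With ``i_fixed`` given, only N is fitted
    ("constrained" mode, used when the unitary current is known from
    single-channel recordings).  Points from several conditions may be
    pooled before calling, which fits shared i and N.
    """
    sigma2 = np.asarray(sigma2, dtype=float).ravel()
    I = np.asarray(imean, dtype=float).ravel()
    if sigma2.shape != I.shape:
        raise ValueError("sigma2 and imean must have the same length")
    if I.size < 10:
        raise ValueError("need at least 10 (sigma2, I) pairs")
    Iabs = np.abs(I[I != 0])
    if Iabs.size == 0 or Iabs.max() / Iabs.min() < 1.2:
        raise ValueError("I_mean range too narrow to separate i and N "
                         "(max/min < 1.2)")
    if i_fixed is None:
        A = np.column_stack([I, -I**2])
        coef, *_ = np.linalg.lstsq(A, sigma2, rcond=None)
        i_hat, invN = coef
        if i_hat <= 0 or invN <= 0:
            raise ValueError("variance-mean fit produced non-positive i or N")
        resid = sigma2 - A @ coef
        return NoiseFit(i_hat=float(i_hat), N_hat=float(1.0 / invN),
                        constrained=False, residuals=resid)
    # constrained: sigma2 - I*i_fixed = -(I^2) * (1/N)
    rhs = sigma2 - I * i_fixed
    invN = -(I**2 @ rhs) / (I**2 @ I**2)
    if invN <= 0:
        raise ValueError("constrained variance-mean fit produced "
                         "non-positive N")
    resid = rhs + I**2 * invN
    return NoiseFit(i_hat=float(i_fixed), N_hat=float(1.0 / invN),
                    constrained=True, residuals=resid)


def open_prob_from_noise(fit: NoiseFit, Imean_ss: float) -> float:
    """Absolute open probability P_o = I_mean,ss / (i * N).

    Values above 1 (possible through estimation noise) are reported
    clipped to 1 with a warning.
    """
    if Imean_ss < 0:
        raise ValueError("Imean_ss must be non-negative")
    denom = fit.i_hat * fit.N_hat
    if denom == 0:
        raise ZeroDivisionError("i * N is zero")
    po = Imean_ss / denom
    if po > 1.0:
        warnings.warn(f"P_o estimate {po:.3f} exceeds 1; clipping",
                      stacklevel=2)
        po = 1.0
    return float(po)
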