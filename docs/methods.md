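# Methods

This note documents the models, estimators and numerical choices in
`thermogate`, their assumptions, and what the synthetic-data tests do
and do not demonstrate about real recordings.

## Equilibrium gating model

The main scheme (`thermogate.gating`) couples four equilibria: pore
opening (constant *L*, temperature-insensitive), a sequential two-step
temperature sensor (*J₁*, *J₂*), external Na⁺ binding (*K₁′*, per molar)
and optionally capsaicin binding (*K₂′*).  Statistical weights are
built relative to the reference state (closed, sensor resting,
unliganded): sensor step 1 contributes J₁(T), step 2 contributes
J₁·J₂ (sequential arrangement — a parallel-sensor variant is not
provided); an open pore contributes L, times D once the sensor has left
rest and times D·E when fully active; a Na⁺-bound state carries
(K₁′·[Na])^1.5 and the factors G (sensor ≥ 1), H (sensor = 2) and F
(open).  Coupling factors multiply the weight of the conformation the
corresponding transition points to, so the same factor appears on both
paths around each thermodynamic cycle (detailed balance is automatic).
P_o and the Na⁺-bound fraction F_Na are weight ratios against the full
partition function; a brute-force state enumeration is kept as an
internal oracle and checked to 1e−12 against the vectorised evaluation.

Assumptions inherited from the scheme: opening itself carries no
enthalpy; voltage-dependent transitions are excluded (all analyses are
at a fixed test potential); cooperativity of binding is an empirical
Hill-type exponent (default 1.5, configurable), not a subunit-resolved
tetramer expansion.

### Temperature dependence of sensor steps

With ΔCp = 0, J(T) = exp(−(ΔH° − TΔS°)/RT), so ln J is affine in 1/T.
With ΔCp ≠ 0 the general form
ln J = −(ΔH°(T₀) + ΔCp(T−T₀))/RT + (ΔS°(T₀) + ΔCp·ln(T/T₀))/R is used;
the published heat-capacity expression is the special case ΔH°(T₀) = 0.
An exact van 't Hoff equivalent of a ΔCp ≠ 0 parameterisation does not
exist (the ΔCp form contains a ln T term that is not affine in 1/T);
what holds, and what the tests assert, is that for steep sensor
transitions with moderate ΔCp (≈ −0.5 kcal mol⁻¹ K⁻¹) refitting ΔH°/ΔS°
to the ΔCp-generated P_o–T family leaves residuals below experimental
resolution (< 0.02 in P_o) inside the 280–315 K window, with the
residual shrinking linearly as ΔCp → 0 and vanishing exactly at
ΔCp = 0.  Perfect (1e−6-level) indistinguishability over a 35 K window
is achievable only in the ΔCp → 0 limit; the irreducible mismatch is
≈ 1.2e−3·|ΔCp|/R in ln J.

### Alternative schemes

The Na⁺-rerouted-opening scheme (8 states) lets Na⁺-bound channels open
through their own temperature-dependent constant J₃ instead of L; the
figure source does not state whether the open-open step J₂ also occurs
in the Na⁺-bound row, and this implementation includes it so the two
rows are structurally parallel.  The single-sensor scheme is the main
model with the second step's weight removed, which the tests exploit as
a cross-model oracle.

## I–T → P_o–T analysis

Open-channel conduction is Arrhenius, i(T) = i₀·exp(−ΔH^≠/RT) with
ΔH^≠ = 9 kcal/mol by default.  Apparent enthalpies are fit as ordinary
least squares of ln I on 1/T: the ΔH/ΔS pair of the exponential is
degenerate with an overall amplitude on normalised data, so ΔH_app
(−slope·R) is the reported quantity.  Averaging across cells replaces
manual temperature-matching with fixed-width binning (default 1 K; bins
with fewer than two pooled samples are dropped, SEM reported on both
axes).  Absolute scaling multiplies an unscaled relation so its value
at the reference temperature equals reference_P_o × current-ratio; the
reference temperature defaults to 22 °C (24 °C accepted via config),
the anchor sample is the nearest grid point within 1 K, chained
scalings compose multiplicatively, and each step is recorded in a
provenance list.  Scaling that pushes any P_o above 1 is an error that
names the offending temperatures.  Leak subtraction is off by default
(constant-leak correction available), reflecting conditions where the
leak is negligible relative to the signal.

## Noise analysis

Variance is estimated from successive differences of sweeps,
y_j = (x_j − x_{j+1})/2 and σ²_I = 2/(N−2)·Σ(y_j − ȳ)², which cancels
slow common rundown to first order; the naive ensemble variance is kept
as a comparator and fails by an order of magnitude under a drift that
barely biases the successive-difference estimate.  The variance–mean
relation σ² = I·i − I²/N is linear in (i, 1/N) and solved by exact
linear least squares, unweighted (the weighting of time points is not
specified in the source procedure; unweighted is the package's choice).
A constrained mode fixes i from external single-channel estimates.  A
single stationary condition yields a degenerate point cloud (I range
max/min < 1.2 is rejected as non-identifiable), so absolute P_o
estimation pools a low-P_o and a high-P_o condition into one fit with
shared i and N, then applies P_o = I_ss/(i·N).  Low-pass filtering of
the records reduces the apparent unitary current — the direction of the
known systematic underestimate — which the tests reproduce with a
moving-average filter; the magnitude depends on the filter and is not
asserted.  Edge trimming of 5% per side removes capacitive transients.

## Dose–response, affinity–voltage and GHK curves

Na⁺ is an inhibitor: the Hill equation is parameterised with Imax as the
zero-ligand response, I([X]) = Imin + (Imax−Imin)/(1+([X]/K₁/₂)^s),
fit by bounded nonlinear least squares (lmfit).  K₁/₂(V) =
K₁/₂(0)·exp(−zδV/k_BT) is fit by log-linear regression.  Theoretical
I–V curves multiply a Boltzmann open-probability factor by the
constant-field (GHK) flux for a bi-ionic condition, with the
permeability ratio f applied to the inward (external-cation) summand
only, as printed in the source figure; the removable singularity at
V = 0 is patched by a second-order series for |FV/RT| < 1e−4, and the
flux factor is clamped for very negative arguments to avoid overflow.
Voltages are mV at interfaces, volts internally.

## Inactivation overlay

Irreversible heat-driven channel loss during slow ramps is modelled as a
pointwise survival factor f(t,T) = exp(−k(T)·t) on top of the
equilibrium curve, with k(T) = A·(1−F_Na)²·exp(−(ΔH^≠−TΔS^≠)/RT)
(defaults A = 200, ΔH^≠ = 45 kcal/mol, ΔS^≠ = 0.133 kcal mol⁻¹ K⁻¹) and
ramp time from the empirical sigmoid transform
t = −0.83258·ln(T_max/(T−0.1) − 1) + 3.3181, T_max = 333 K.  The
transform's flattened printed form is typographically ambiguous; the
parse adopted is the one for which T → T_max as t → ∞.  Time units are
the ramp-clock units implicit in the transform; only relative times
matter.  Ramp-clock times are negative at low temperature, so the
survival exponent is clamped at zero — the overlay never exceeds the
equilibrium curve.  The default is the pointwise product exactly as the
empirical recipe prescribes; a cumulative-hazard variant
exp(−∫k dt) is provided as an explicitly non-canonical option.  Scaling
all times by ε → 0 recovers the equilibrium curve (the fast-jump
limit).

## Synthetic-data generator

The generator (`thermogate.synth`) emulates: macroscopic ramp currents
I = N·i(T)·P_o + leak + Gaussian noise (default N = 400 channels,
i = 2 pA at 22 °C, ramp 279–318 K); sweep ensembles of two-state
channels (independent binomial per sample, or Markov with an
exponential correlation time; optional linear rundown across sweeps;
noise protocols at 24 °C, 50 sweeps, matching the bench protocol
scale); Hill dose–response tables over Na⁺/NMDG⁺ mixtures totalling
130 mM; and single-channel amplitude tables with fractional Gaussian
scatter.  Every generator call creates a fresh
`numpy.random.default_rng(seed)`, so identical configurations give
byte-identical CSVs.  The default model parameters are an illustrative
set (the published fit values are not reproduced in print): L = 0.005,
J₁ = (30 kcal/mol, midpoint 278 K), J₂ = (80 kcal/mol, midpoint 318 K),
D = 50, E = 1000, K₁′ = 1/7 mM⁻¹, F = 0.12, G = 0.01, H = 1, chosen
once so the family reproduces the qualitative phenomenology: a
low-temperature rise, an intermediate plateau whose level (P_o ≈ 0.2 at
22 °C in 0 Na⁺) falls as [Na⁺] rises, and a steep rise near 40–45 °C.

What passing tests show: the estimators are correct and well-behaved on
data satisfying their own assumptions (homogeneous channels, Gaussian
instrument noise, exact Arrhenius conduction, stationary two-state
gating).  What they do not show: robustness to heterogeneous channel
populations, series-resistance and filtering artefacts, temperature
measurement error, or real rundown kinetics beyond the linear
multiplicative model.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by design: 1000 random
draws for the enumeration oracle, 10 seeds × (2 × 50 sweeps × 400
samples) for the noise recovery, 200 seeded datasets for the Hill
recovery study, 80-point ramps for pipeline checks.  The full suite
runs in a few seconds on one CPU.  All stochastic steps take their seed
from the configuration, and pipeline artifacts embed the seed and a
hash of the validated configuration, so any run is bit-reproducible.
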