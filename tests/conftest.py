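import numpy as np
import pytest

from thermogate import AllostericModel, ThermoTransition, default_model


@pytest.fixture
def model_i():
    """Illustrative two-sensor-step model with Na coupling."""
    return default_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_model(rng, with_caps: bool = False) -> AllostericModel:
    """Log-uniform random parameter draw for oracle-equivalence checks."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    kwargs = dict(
        L=lu(1e-4, 10),
        J1=ThermoTransition(dH0=rng.uniform(-50, 80),
                            dS0=rng.uniform(-0.1, 0.3)),
        J2=ThermoTransition(dH0=rng.uniform(-50, 80),
                            dS0=rng.uniform(-0.1, 0.3)),
        D=lu(1e-2, 1e3), E=lu(1e-2, 1e3),
        K1_prime=lu(1e-1, 1e3),
        F=lu(1e-3, 1e2), G=lu(1e-3, 1e2), H=lu(1e-3, 1e2),
        coop_exponent=float(rng.uniform(0.5, 2.5)),
    )
    if with_caps:
        kwargs.update(K2_prime=lu(1e2, 1e8),
                      c_L=lu(1e-2, 1e4), c_J1=lu(1e-2, 1e2),
                      c_J2=lu(1e-2, 1e2), c_Na=lu(1e-2, 1e2))
    return AllostericModel(**kwargs)
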