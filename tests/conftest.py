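import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import predfr as pf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRUE_A = 4.05  # attack rate, per day
TRUE_H = 0.218  # handling time, days


@pytest.fixture(scope="session")
def table1_dataset():
    """No-choice dataset generated at the reference treatment means."""
    return pf.simulate_nochoice_dataset(pf.NoChoiceGeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fr_dataset():
    """Binomial-mode functional-response dataset at the reference estimates."""
    return pf.simulate_fr_dataset(
        pf.FrGeneratorConfig(a=TRUE_A, h=TRUE_H, T=1.0, reps=10, seed=13)
    )


@pytest.fixture(scope="session")
def nochoice_frame(table1_dataset):
    return pd.DataFrame(
        {
            "factor_A": [t.predator_species for t in table1_dataset],
            "factor_B": [t.stages[0] for t in table1_dataset],
            "response": [t.consumed[t.stages[0]] for t in table1_dataset],
        }
    )


def newton_rogers(N0, a, h, T):
    """Independent root-finding oracle for the implicit Rogers equation.

    Brackets the physical root in [0, min(N0, T/h)] and polishes it with
    safeguarded Brent iteration plus a few Newton steps; no Lambert W.
    """
    import math

    from scipy.optimize import brentq

    if N0 == 0 or a == 0:
        return 0.0

    def f(ne):
        return ne - N0 * (1.0 - math.exp(a * (h * ne - T)))

    upper = min(N0, T / h) if h > 0 else N0
    ne = brentq(f, 0.0, upper, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    for _ in range(3):  # Newton polish near the root
        e = math.exp(a * (h * ne - T))
        ne -= (ne - N0 * (1.0 - e)) / (1.0 + N0 * e * a * h)
    return ne
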