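import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lovedyn as ld
from lovedyn import defaults

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p_eq_n():
    return ld.scenario("P_eq_N")


@pytest.fixture(scope="session")
def default_settings():
    return ld.RunSettings()


@pytest.fixture
def canonical(request):
    """LoveParams with canonical b, c, d and a given a."""
    return defaults.canonical_params


def strobe_run(a: float, scenario_name: str = "P_eq_N",
               settings_: ld.RunSettings | None = None) -> ld.PoincareSection:
    """Integrate + strobe one canonical configuration."""
    s = settings_ or ld.RunSettings()
    traj = ld.integrate(defaults.canonical_params(a), ld.scenario(scenario_name), s)
    return ld.strobe(traj)


@pytest.fixture(scope="session")
def quick_settings():
    """Shorter windows for tests that only need coarse dynamics."""
    return ld.RunSettings(transient_periods=300, record_periods=100)


def n_distinct(points: np.ndarray, tol: float = 1e-6) -> int:
    return len(np.unique(np.round(points / tol).astype(np.int64), axis=0))


def tangent_is_generic(matrix: np.ndarray,
                       tangent=(1.0, 0.0), min_coeff: float = 1e-2) -> bool:
    """True if the tangent has a resolvable component along the dominant
    eigenvector (the Benettin method requires a generic start; an exactly
    eigen-aligned tangent converges to a sub-dominant exponent)."""
    w, V = np.linalg.eig(matrix)
    try:
        coeff = np.linalg.solve(V, np.asarray(tangent, dtype=complex))
    except np.linalg.LinAlgError:
        return False
    return abs(coeff[np.argmax(w.real)]) > min_coeff
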