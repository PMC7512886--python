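"""Frozen default parameters and thresholds (version 1).

These pin down the canonical study conditions — the fixed romantic-style
coefficients, the five reference values of ``a`` spanning the
period-doubling route to chaos, and every numerical threshold used by
the diagnostics — in one place, so that the ``regime-suite`` command and
the test suite run against a single versioned set of conventions.
"""

from .model import LoveParams, State  # noqa: F401  (re-exported for config use)

DEFAULTS_VERSION = 1

#: Fixed coefficients: Juliet responds positively to Romeo and to herself,
#: Romeo is discouraged by Juliet's affection.
CANONICAL_B = -2.0
CANONICAL_C = 1.0
CANONICAL_D = 1.0

#: Reference values of Romeo's self-feeling coefficient, spanning
#: period-1, period-2, period-4, single-scroll chaotic (Rössler-type) and
#: double-scroll chaotic regimes under the P_eq_N scenario.
REGIME_A_VALUES = (-5.41, -3.451, -3.406, -3.201, -2.561)

#: Integration defaults: 2000 steps per forcing period at omega = 1.
DT = 1e-3
TRANSIENT_PERIODS = 500
RECORD_PERIODS = 200
INITIAL_STATE = (0.1, 0.1)

#: Initial-condition panel for robustness checks of regime labels.
INITIAL_STATE_PANEL = ((0.1, 0.1), (1.0, 0.0), (-0.5, 0.5))

#: Diagnostics thresholds.
REL_TOL = 1e-3
LYAPUNOV_PERIODS = 2000
CHAOS_THRESHOLD = 0.01


def canonical_params(a: float) -> LoveParams:
    """Love parameters with the canonical b, c, d and the given ``a``."""
    return LoveParams(a=a, b=CANONICAL_B, c=CANONICAL_C, d=CANONICAL_D)
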