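"""Core definitions of the forced Romeo–Juliet love model.

The state is the pair (R, J) of signed love/hate levels.  The coupled
system is

    dR/dt = a*R + b*J*(1 - |J|) + y(t)
    dJ/dt = c*R*(1 - |R|) + d*J + f(t)

where ``a, b`` encode Romeo's romantic style (response to his own and to
Juliet's feelings) and ``c, d`` Juliet's.  The external environment —
advice from a third party — is a sine wave ``y(t) = A*sin(omega*pi*t) + B``
applied, in the standard setup, to Romeo's equation only (``f = 0``).
``A + B`` is the positive magnitude of the advice and ``-A + B`` the
negative magnitude; their relative size defines the three canonical
scenarios ``P_eq_N`` (B = 0), ``P_gt_N`` (B > 0) and ``P_lt_N`` (B < 0).

Note on frequency: ``omega`` multiplies ``pi*t`` inside the sine, so the
forcing period is ``2/omega`` — **not** ``2*pi/omega``.  With the default
``omega = 1`` the period is exactly 2 time units.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForcingTarget",
    "LoveParams",
    "ForcingSpec",
    "State",
    "FixedPointReport",
    "forcing_value",
    "vector_field",
    "jacobian",
    "classify_fixed_point",
    "saddle_boundary_a",
    "scenario",
    "SCENARIO_NAMES",
]


class ForcingTarget(str, enum.Enum):
    """Which equation receives the additive forcing."""

    ROMEO = "romeo"
    JULIET = "juliet"
    BOTH = "both"

    @property
    def on_romeo(self) -> bool:
        return self in (ForcingTarget.ROMEO, ForcingTarget.BOTH)

    @property
    def on_juliet(self) -> bool:
        return self in (ForcingTarget.JULIET, ForcingTarget.BOTH)


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class LoveParams:
    """Romantic-style coefficients.

    a : Romeo's response to his own feelings
    b : Romeo's response to Juliet's feelings
    c : Juliet's response to Romeo's feelings
    d : Juliet's response to her own feelings
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _require_finite(a=self.a, b=self.b, c=self.c, d=self.d)

    @property
    def saddle_condition(self) -> bool:
        """True iff a*d < b*c, i.e. the origin of the linearized model is a saddle."""
        return self.a * self.d < self.b * self.c

    def matrix(self) -> np.ndarray:
        """Coefficient matrix [[a, b], [c, d]] of the linearized model at the origin."""
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ForcingSpec:
    """Sinusoidal environment y(t) = A*sin(omega*pi*t) + B.

    ``A >= 0`` is the advice amplitude, ``B`` its offset and ``omega > 0``
    the frequency parameter (instantaneous angular frequency omega*pi, so
    the period is ``2/omega``).
    """

    A: float
    B: float
    omega: float = 1.0
    target: ForcingTarget = ForcingTarget.ROMEO

    def __post_init__(self) -> None:
        _require_finite(A=self.A, B=self.B, omega=self.omega)
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not isinstance(self.target, ForcingTarget):
            object.__setattr__(self, "target", ForcingTarget(self.target))

    def period(self) -> float:
        """Forcing period 2/omega (sin(omega*pi*(t + 2/omega)) = sin(omega*pi*t))."""
        return 2.0 / self.omega

    def positive_magnitude(self) -> float:
        """Peak positive advice, A + B."""
        return self.A + self.B

    def negative_magnitude(self) -> float:
        """Peak negative advice, -A + B."""
        return -self.A + self.B


@dataclass(frozen=True)
class State:
    """Instantaneous love/hate levels of Romeo and Juliet (negative = hate)."""

    R: float
    J: float

    def __post_init__(self) -> None:
        _require_finite(R=self.R, J=self.J)


def forcing_value(t, f: ForcingSpec):
    """Evaluate y(t) = A*sin(omega*pi*t) + B at scalar or array ``t``."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time t must be finite")
    out = f.A * np.sin(f.omega * np.pi * t) + f.B
    return float(out) if out.ndim == 0 else out


def vector_field(t: float, s: State, p: LoveParams,
                 f: ForcingSpec) -> tuple[float, float]:
    """Right-hand side (dR/dt, dJ/dt) of the forced model at time ``t``."""
    y = forcing_value(t, f)
    dR = p.a * s.R + p.b * s.J * (1.0 - abs(s.J))
    dJ = p.c * s.R * (1.0 - abs(s.R)) + p.d * s.J
    if f.target.on_romeo:
        dR += y
    if f.target.on_juliet:
        dJ += y
    return dR, dJ


def jacobian(s: State, p: LoveParams) -> np.ndarray:
    """State Jacobian [[a, b(1-2|J|)], [c(1-2|R|), d]].

    d/dx x(1-|x|) = 1-2|x| is a genuine two-sided derivative everywhere
    (the one-sided limits agree at x=0; only the second derivative has a
    kink), so the same formula is used on the axes.  The additive forcing
    has no state dependence and does not appear.
    """
    return np.array(
        [
            [p.a, p.b * (1.0 - 2.0 * abs(s.J))],
            [p.c * (1.0 - 2.0 * abs(s.R)), p.d],
        ],
        dtype=float,
    )


@dataclass(frozen=True)
class FixedPointReport:
    """Linear classification of the origin of the unforced model.

    ``saddle_label`` is the classical dichotomy used for this model:
    ``saddle`` iff a*d < b*c (negative determinant), the regime in which
    sustained love/hate dynamics and chaos occur.  ``spectral_label`` is
    the full eigenvalue classification, which the dichotomy alone does
    not determine (a*d > b*c gives asymptotic stability only when the
    trace a + d is also negative).
    """

    determinant: float
    trace: float
    eigenvalues: tuple[complex, complex]
    saddle_label: str  # "saddle" | "non_saddle"
    spectral_label: str  # saddle|stable_node|stable_spiral|unstable_node|unstable_spiral|center|degenerate


def classify_fixed_point(p: LoveParams) -> FixedPointReport:
    """Classify the fixed point (R, J) = (0, 0) of the linearized model."""
    det = p.a * p.d - p.b * p.c
    tr = p.a + p.d
    disc = tr * tr - 4.0 * det
    if disc >= 0:
        sq = math.sqrt(disc)
        eigs = ((tr + sq) / 2.0 + 0.0j, (tr - sq) / 2.0 + 0.0j)
    else:
        sq = math.sqrt(-disc)
        eigs = (complex(tr / 2.0, sq / 2.0), complex(tr / 2.0, -sq / 2.0))

    if det < 0:
        spectral = "saddle"
    elif det == 0:
        spectral = "degenerate"
    elif tr == 0:
        spectral = "center"
    elif tr < 0:
        spectral = "stable_spiral" if disc < 0 else "stable_node"
    else:
        spectral = "unstable_spiral" if disc < 0 else "unstable_node"

    return FixedPointReport(
        determinant=det,
        trace=tr,
        eigenvalues=eigs,
        saddle_label="saddle" if det < 0 else "non_saddle",
        spectral_label=spectral,
    )


def saddle_boundary_a(b: float, c: float, d: float) -> float:
    """The value of ``a`` at which a*d = b*c, i.e. the saddle boundary.

    With the canonical b=-2, c=1, d=1 this is exactly -2: the saddle
    condition a*d < b*c reduces to a < -2.
    """
    if d == 0:
        raise ValueError("saddle boundary in a is undefined for d = 0")
    return b * c / d


#: The three canonical advice scenarios: equal, predominantly positive and
#: predominantly negative advice.  All force Romeo's equation only.
_SCENARIOS = {
    "P_eq_N": ForcingSpec(A=5.0, B=0.0, omega=1.0, target=ForcingTarget.ROMEO),
    "P_gt_N": ForcingSpec(A=6.0, B=1.0, omega=1.0, target=ForcingTarget.ROMEO),
    "P_lt_N": ForcingSpec(A=6.0, B=-1.0, omega=1.0, target=ForcingTarget.ROMEO),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario(name: str) -> ForcingSpec:
    """Return a canonical forcing preset by name (P_eq_N, P_gt_N, P_lt_N)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        ) from None
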