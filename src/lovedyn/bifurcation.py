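"""Parameter sweeps over Romeo's self-feeling coefficient ``a``.

As ``a`` increases from strongly negative values towards the saddle
boundary, the forced model undergoes a period-doubling cascade
(1 → 2 → 4 → ... → chaos).  The sweep integrates at each grid value,
strobes the recorded window, detects the period and estimates the
maximal Lyapunov exponent; with continuation enabled the final state at
one grid value seeds the next, which shortens transients and follows a
branch through the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .diagnostics import detect_period
from .integrate import (DivergenceError, PoincareSection, RunSettings,
                        State, integrate, strobe)
from .lyapunov import max_lyapunov
from .model import ForcingSpec, LoveParams

__all__ = ["BifurcationScan", "DoublingEvent", "sweep", "doubling_points",
           "default_a_grid"]


def default_a_grid(n: int = 400) -> np.ndarray:
    """Uniform grid on [-6.0, -2.01]: inside the saddle region a < -2,
    fine enough to resolve the period-doubling cascade."""
    return np.linspace(-6.0, -2.01, n)


@dataclass(frozen=True)
class BifurcationScan:
    """Results of a sweep over ``a`` for one forcing scenario.

    ``sections[i]`` / ``lyapunovs[i]`` / ``periods[i]`` correspond to
    ``a_values[i]``; a divergent grid point is recorded as ``None`` /
    NaN / ``None`` rather than aborting the sweep.
    """

    a_values: np.ndarray
    sections: list  # list[PoincareSection | None]
    lyapunovs: np.ndarray
    periods: list  # list[int | None]
    scenario: ForcingSpec
    settings: RunSettings
    continuation: bool

    def __post_init__(self) -> None:
        n = len(self.a_values)
        if not (len(self.sections) == len(self.lyapunovs) == len(self.periods) == n):
            raise ValueError("a_values, sections, lyapunovs, periods must align")

    def to_csv(self, path) -> None:
        """Long format ``a,k,R,J,lambda`` — one row per strobe point."""
        rows = []
        for a, sec, lam in zip(self.a_values, self.sections, self.lyapunovs):
            if sec is None:
                continue
            for k, (R, J) in enumerate(sec.points):
                rows.append((a, k, R, J, lam))
        data = np.array(rows, dtype=float)
        np.savetxt(path, data, fmt=["%.17g", "%d", "%.17g", "%.17g", "%.17g"],
                   delimiter=",", header="a,k,R,J,lambda", comments="")


def sweep(a_grid, scenario: ForcingSpec, s: RunSettings,
          continuation: bool = True, base: LoveParams | None = None,
          lyap_periods: int = 400, rel_tol: float = 1e-3) -> BifurcationScan:
    """Sweep ``a`` in ascending order over ``a_grid``.

    ``base`` supplies the fixed coefficients b, c, d (default -2, 1, 1).
    At each grid value the model is integrated, strobed and period-
    detected, and the maximal Lyapunov exponent is estimated over
    ``lyap_periods`` forcing periods.  With ``continuation=True`` the
    final recorded state at one value initializes the next.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid.ndim != 1 or len(a_grid) == 0:
        raise ValueError("a_grid must be a nonempty 1-D array")
    if np.any(np.diff(a_grid) <= 0) and len(a_grid) > 1:
        raise ValueError("a_grid must be sorted ascending")
    if base is None:
        base = LoveParams(a=a_grid[0], b=-2.0, c=1.0, d=1.0)

    sections: list[PoincareSection | None] = []
    periods: list[int | None] = []
    lams = np.full(len(a_grid), np.nan)
    current = s
    for i, a in enumerate(a_grid):
        p = replace(base, a=float(a))
        try:
            traj = integrate(p, scenario, current)
            sec = strobe(traj)
            lam = max_lyapunov(p, scenario, current, n_periods=lyap_periods)
        except DivergenceError:
            sections.append(None)
            periods.append(None)
            continue
        sections.append(sec)
        periods.append(detect_period(sec, rel_tol=rel_tol))
        lams[i] = lam.value
        if continuation:
            current = replace(current,
                              initial_state=State(float(traj.R[-1]), float(traj.J[-1])))
    return BifurcationScan(a_values=a_grid, sections=sections, lyapunovs=lams,
                           periods=periods, scenario=scenario, settings=s,
                           continuation=continuation)


@dataclass(frozen=True)
class DoublingEvent:
    """A change of detected period between consecutive grid values.

    ``period_after`` is ``None`` when the orbit enters an aperiodic
    (chaotic or unresolved) regime inside the interval.
    """

    a_lo: float
    a_hi: float
    period_before: int
    period_after: int | None


def doubling_points(scan: BifurcationScan) -> list[DoublingEvent]:
    """Locate period-doubling (n → 2n) and periodic → aperiodic intervals.

    Scans consecutive grid pairs; divergent (missing) points are skipped.
    Returns an empty list if the detected period never changes.
    """
    events = []
    prev_a = prev_p = None
    have_prev = False
    for a, sec, p in zip(scan.a_values, scan.sections, scan.periods):
        if sec is None:
            continue  # divergent point: no verdict either way
        if have_prev and prev_p is not None:
            if p is not None and p == 2 * prev_p:
                events.append(DoublingEvent(float(prev_a), float(a), prev_p, p))
            elif p is None:
                events.append(DoublingEvent(float(prev_a), float(a), prev_p, None))
        prev_a, prev_p, have_prev = a, p, True
    return events
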