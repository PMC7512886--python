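"""Fixed-step RK4 integration and stroboscopic sampling.

A fixed step is used (rather than an adaptive solver) so that the forcing
period is an exact integer number of steps: the stroboscopic Poincaré
section is then read off the stored trajectory without interpolation, and
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model import ForcingSpec, LoveParams, State

__all__ = [
    "RunSettings",
    "Trajectory",
    "PoincareSection",
    "DivergenceError",
    "integrate",
    "strobe",
]

#: Above this |R| or |J| the run is declared divergent.  The model is
#: bounded in every regime of interest, so an excursion this large is a
#: parameter or configuration error and should fail loudly.
DEFAULT_OVERFLOW_GUARD = 1e6


class DivergenceError(RuntimeError):
    """Raised when a trajectory exceeds the overflow guard."""

    def __init__(self, step: int, time: float, guard: float):
        self.step = step
        self.time = time
        self.guard = guard
        super().__init__(
            f"trajectory exceeded |R| or |J| > {guard:g} at step {step} (t = {time:g})"
        )


@dataclass(frozen=True)
class RunSettings:
    """Integration settings.

    dt                : step size; the forcing period must be an integer
                        multiple of it (default 0.001 → 2000 steps per
                        period at omega = 1)
    t0                : start time (forcing phase reference)
    transient_periods : forcing periods discarded before recording;
                        period-doubling transients near bifurcation
                        points settle slowly, hence the long default
    record_periods    : forcing periods recorded
    initial_state     : starting (R, J)
    """

    dt: float = 1e-3
    t0: float = 0.0
    transient_periods: int = 500
    record_periods: int = 200
    initial_state: State = field(default_factory=lambda: State(0.1, 0.1))
    overflow_guard: float = DEFAULT_OVERFLOW_GUARD

    def __post_init__(self) -> None:
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if self.transient_periods < 0:
            raise ValueError("transient_periods must be >= 0")
        if self.record_periods <= 0:
            raise ValueError("record_periods must be > 0")
        if self.transient_periods + self.record_periods < 1:
            raise ValueError("transient_periods + record_periods must be >= 1")

    def steps_per_period(self, forcing: ForcingSpec) -> int:
        """Number of dt steps in one forcing period; errors if not integral."""
        ratio = forcing.period() / self.dt
        spp = round(ratio)
        if spp < 1 or abs(ratio - spp) > 1e-9 * ratio:
            raise ValueError(
                f"forcing period {forcing.period()!r} must be an integer "
                f"multiple of dt = {self.dt!r} (got ratio {ratio!r})"
            )
        return spp


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled (R, J) time series over the recording window."""

    times: np.ndarray
    R: np.ndarray
    J: np.ndarray
    settings: RunSettings | None = None
    params: LoveParams | None = None
    forcing: ForcingSpec | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.R) != n or len(self.J) != n:
            raise ValueError("times, R, J must have equal length")
        if n >= 2:
            steps = np.diff(self.times)
            # atol absorbs float quantization of t = t0 + k*dt at large t
            atol = 64 * np.finfo(float).eps * max(1.0, float(np.abs(self.times).max()))
            if np.any(steps <= 0) or not np.allclose(
                steps, steps[0], rtol=1e-9, atol=atol
            ):
                raise ValueError("times must be strictly increasing with constant spacing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path) -> None:
        """Write ``t,R,J`` rows at full float precision (round-trips exactly)."""
        data = np.column_stack([self.times, self.R, self.J])
        np.savetxt(path, data, fmt="%.17g", delimiter=",", header="t,R,J", comments="")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times=data[:, 0], R=data[:, 1], J=data[:, 2])


@dataclass(frozen=True)
class PoincareSection:
    """Stroboscopic section: (R, J) sampled once per forcing period.

    A period-n orbit of the forced system produces exactly n distinct
    points; a chaotic orbit scatters over a fractal set.
    """

    points: np.ndarray  # shape (k, 2)
    period: float
    phase: float
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a non-empty (k, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("section points must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def R(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def J(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path) -> None:
        """Write ``k,t,R,J`` rows at full float precision."""
        k = np.arange(len(self.points))
        t = self.times if self.times is not None else np.full(len(k), np.nan)
        data = np.column_stack([k, t, self.points])
        np.savetxt(path, data, fmt=["%d", "%.17g", "%.17g", "%.17g"],
                   delimiter=",", header="k,t,R,J", comments="")


def integrate(p: LoveParams, f: ForcingSpec, s: RunSettings) -> Trajectory:
    """Integrate the forced model with classical RK4 at fixed step ``s.dt``.

    The first ``transient_periods`` forcing periods are discarded; the
    returned trajectory covers the following ``record_periods`` periods
    (``record_periods * steps_per_period + 1`` samples, endpoints
    included).  Identical inputs give bit-identical output.

    Raises :class:`DivergenceError` if |R| or |J| exceeds the overflow
    guard at any step, including during the transient.
    """
    spp = s.steps_per_period(f)
    n_skip = s.transient_periods * spp
    n_rec = s.record_periods * spp
    out, status = _kernels.rk4_path(
        p.a, p.b, p.c, p.d, f.A, f.B, f.omega,
        f.target.on_romeo, f.target.on_juliet,
        s.initial_state.R, s.initial_state.J,
        s.t0, s.dt, n_skip, n_rec, s.overflow_guard,
    )
    if status >= 0:
        raise DivergenceError(step=status, time=s.t0 + status * s.dt,
                              guard=s.overflow_guard)
    times = s.t0 + (n_skip + np.arange(n_rec + 1)) * s.dt
    return Trajectory(times=times, R=out[:, 0].copy(), J=out[:, 1].copy(),
                      settings=s, params=p, forcing=f)


def strobe(traj: Trajectory, phase: float = 0.0) -> PoincareSection:
    """Sample the trajectory once per forcing period at the given phase.

    Returns the ``record_periods`` points at times
    ``t_record_start + phase + k*T``, k = 0 .. record_periods - 1, where
    T is the forcing period.  ``phase`` must lie in [0, T) and be an
    integer multiple of dt.
    """
    if traj.settings is None or traj.forcing is None:
        raise ValueError("strobe requires a trajectory with settings and forcing metadata")
    s, f = traj.settings, traj.forcing
    spp = s.steps_per_period(f)
    T = f.period()
    if not (0.0 <= phase < T):
        raise ValueError(f"phase must lie in [0, {T}), got {phase}")
    ratio = phase / s.dt
    off = round(ratio)
    if abs(ratio - off) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(f"phase {phase!r} must be an integer multiple of dt {s.dt!r}")
    if s.record_periods < 1 or len(traj) < spp + 1:
        raise ValueError("recording window must cover at least one full forcing period")
    idx = off + spp * np.arange(s.record_periods)
    pts = np.column_stack([traj.R[idx], traj.J[idx]])
    return PoincareSection(points=pts, period=T, phase=phase, times=traj.times[idx])


def continue_from(s: RunSettings, traj: Trajectory) -> RunSettings:
    """Settings that restart from the final state (and time phase) of ``traj``.

    The new t0 keeps the forcing phase consistent: the final sample of a
    recorded window always lies at a whole number of periods past t0, so
    restarting at t0 preserves the strobe phase.
    """
    return replace(s, initial_state=State(float(traj.R[-1]), float(traj.J[-1])))
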