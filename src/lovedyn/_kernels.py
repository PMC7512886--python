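"""Numba-compiled fixed-step RK4 kernels.

The state is kept as scalars (R, J) rather than arrays: the system is
two-dimensional and the scalar form lets numba generate tight loops.
Time is reconstructed as ``t0 + i*dt`` at every step instead of being
accumulated, so long runs do not drift.

Kernels return a ``status`` integer: ``-1`` on success, otherwise the
index of the step at which the overflow guard tripped.  Raising
exceptions is left to the Python wrappers.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(t, R, J, a, b, c, d, A, B, omega, on_R, on_J):
    """Vector field dR/dt = aR + bJ(1-|J|) [+y], dJ/dt = cR(1-|R|) + dJ [+y]."""
    y = A * np.sin(omega * np.pi * t) + B
    dR = a * R + b * J * (1.0 - abs(J))
    dJ = c * R * (1.0 - abs(R)) + d * J
    if on_R:
        dR += y
    if on_J:
        dJ += y
    return dR, dJ


@njit(cache=True)
def rk4_path(a, b, c, d, A, B, omega, on_R, on_J,
             R0, J0, t0, dt, n_skip, n_rec, guard):
    """Integrate, discarding the first ``n_skip`` steps.

    Returns an ``(n_rec + 1, 2)`` array of recorded (R, J) samples — the
    state at steps ``n_skip .. n_skip + n_rec`` inclusive — and a status.
    """
    R = R0
    J = J0
    out = np.empty((n_rec + 1, 2))
    total = n_skip + n_rec
    for i in range(total + 1):
        if not (abs(R) <= guard and abs(J) <= guard):
            return out, i
        if i >= n_skip:
            out[i - n_skip, 0] = R
            out[i - n_skip, 1] = J
        if i == total:
            break
        t = t0 + i * dt
        h = dt
        k1R, k1J = _rhs(t, R, J, a, b, c, d, A, B, omega, on_R, on_J)
        k2R, k2J = _rhs(t + 0.5 * h, R + 0.5 * h * k1R, J + 0.5 * h * k1J,
                        a, b, c, d, A, B, omega, on_R, on_J)
        k3R, k3J = _rhs(t + 0.5 * h, R + 0.5 * h * k2R, J + 0.5 * h * k2J,
                        a, b, c, d, A, B, omega, on_R, on_J)
        k4R, k4J = _rhs(t + h, R + h * k3R, J + h * k3J,
                        a, b, c, d, A, B, omega, on_R, on_J)
        R = R + h / 6.0 * (k1R + 2.0 * k2R + 2.0 * k3R + k4R)
        J = J + h / 6.0 * (k1J + 2.0 * k2J + 2.0 * k3J + k4J)
    return out, -1


@njit(cache=True)
def _rhs_var(t, R, J, vR, vJ, a, b, c, d, A, B, omega, on_R, on_J):
    """Base field plus variational (tangent) field.

    The Jacobian is [[a, b(1-2|J|)], [c(1-2|R|), d]]; the additive forcing
    does not enter the tangent dynamics.  d/dx x(1-|x|) = 1-2|x| holds as
    a two-sided derivative everywhere including x=0.
    """
    y = A * np.sin(omega * np.pi * t) + B
    dR = a * R + b * J * (1.0 - abs(J))
    dJ = c * R * (1.0 - abs(R)) + d * J
    if on_R:
        dR += y
    if on_J:
        dJ += y
    dvR = a * vR + b * (1.0 - 2.0 * abs(J)) * vJ
    dvJ = c * (1.0 - 2.0 * abs(R)) * vR + d * vJ
    return dR, dJ, dvR, dvJ


@njit(cache=True)
def rk4_tangent(a, b, c, d, A, B, omega, on_R, on_J,
                R0, J0, v0R, v0J, t0, dt, renorm_steps,
                n_skip_renorms, n_renorms, guard):
    """Benettin co-integration of state and unit tangent vector.

    The combined 4-dimensional system (base + variational) is advanced
    with the same RK4 stepping; the tangent is renormalized every
    ``renorm_steps`` steps.  Log stretch factors from the first
    ``n_skip_renorms`` renormalizations are discarded; the remaining
    ``n_renorms`` are returned.
    """
    R = R0
    J = J0
    nv0 = np.sqrt(v0R * v0R + v0J * v0J)
    vR = v0R / nv0
    vJ = v0J / nv0
    logs = np.empty(n_renorms)
    step = 0
    for m in range(n_skip_renorms + n_renorms):
        for _ in range(renorm_steps):
            if not (abs(R) <= guard and abs(J) <= guard):
                return logs, step
            t = t0 + step * dt
            h = dt
            k1R, k1J, k1u, k1v = _rhs_var(t, R, J, vR, vJ,
                                          a, b, c, d, A, B, omega, on_R, on_J)
            k2R, k2J, k2u, k2v = _rhs_var(t + 0.5 * h, R + 0.5 * h * k1R,
                                          J + 0.5 * h * k1J, vR + 0.5 * h * k1u,
                                          vJ + 0.5 * h * k1v,
                                          a, b, c, d, A, B, omega, on_R, on_J)
            k3R, k3J, k3u, k3v = _rhs_var(t + 0.5 * h, R + 0.5 * h * k2R,
                                          J + 0.5 * h * k2J, vR + 0.5 * h * k2u,
                                          vJ + 0.5 * h * k2v,
                                          a, b, c, d, A, B, omega, on_R, on_J)
            k4R, k4J, k4u, k4v = _rhs_var(t + h, R + h * k3R, J + h * k3J,
                                          vR + h * k3u, vJ + h * k3v,
                                          a, b, c, d, A, B, omega, on_R, on_J)
            R = R + h / 6.0 * (k1R + 2.0 * k2R + 2.0 * k3R + k4R)
            J = J + h / 6.0 * (k1J + 2.0 * k2J + 2.0 * k3J + k4J)
            vR = vR + h / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
            vJ = vJ + h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            step += 1
        nv = np.sqrt(vR * vR + vJ * vJ)
        if m >= n_skip_renorms:
            logs[m - n_skip_renorms] = np.log(nv)
        vR /= nv
        vJ /= nv
    return logs, -1
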