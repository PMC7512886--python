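import numpy as np
import pytest

import lovedyn as ld
from lovedyn import defaults
from lovedyn.integrate import continue_from

from conftest import n_distinct, strobe_run


def test_unforced_origin_stays_zero():
    p = ld.LoveParams(a=-3.0, b=-2.0, c=1.0, d=1.0)
    f = ld.ForcingSpec(A=0.0, B=0.0)
    s = ld.RunSettings(transient_periods=0, record_periods=3,
                       initial_state=ld.State(0.0, 0.0))
    traj = ld.integrate(p, f, s)
    assert np.all(traj.R == 0.0) and np.all(traj.J == 0.0)


def test_stable_spiral_decays_to_origin():
    """det > 0 and trace < 0: the unforced origin is locally attracting;
    200 time units bring a small perturbation within 1e-6 of it.  The
    stability is local only — the nonlinear terms create a coexisting
    stable fixed point whose basin captures larger perturbations."""
    p = ld.LoveParams(a=-1.5, b=-2.0, c=1.0, d=1.0)
    f = ld.ForcingSpec(A=0.0, B=0.0)
    for ic in [(0.02, 0.02), (0.1, -0.1)]:
        s = ld.RunSettings(transient_periods=0, record_periods=100,
                           initial_state=ld.State(*ic))
        traj = ld.integrate(p, f, s)
        assert abs(traj.R[-1]) < 1e-6 and abs(traj.J[-1]) < 1e-6
    # (0.1, 0.1) lies in the basin of the coexisting equilibrium
    s = ld.RunSettings(transient_periods=0, record_periods=100,
                       initial_state=ld.State(0.1, 0.1))
    traj = ld.integrate(p, f, s)
    assert np.hypot(traj.R[-1], traj.J[-1]) > 1.0


def test_integration_is_bit_deterministic(p_eq_n):
    p = defaults.canonical_params(-2.561)
    s = ld.RunSettings(transient_periods=50, record_periods=20)
    t1 = ld.integrate(p, p_eq_n, s)
    t2 = ld.integrate(p, p_eq_n, s)
    assert np.array_equal(t1.R, t2.R) and np.array_equal(t1.J, t2.J)


def test_divergence_raises_with_step():
    p = ld.LoveParams(a=5.0, b=0.0, c=0.0, d=5.0)
    f = ld.ForcingSpec(A=5.0, B=0.0)
    s = ld.RunSettings(transient_periods=0, record_periods=10,
                       initial_state=ld.State(1.0, 1.0))
    with pytest.raises(ld.DivergenceError, match="step"):
        ld.integrate(p, f, s)


def test_settings_validation():
    with pytest.raises(ValueError):
        ld.RunSettings(dt=-0.1)
    with pytest.raises(ValueError):
        ld.RunSettings(transient_periods=-1)
    with pytest.raises(ValueError):
        ld.RunSettings(record_periods=0)
    s = ld.RunSettings(dt=0.3)
    with pytest.raises(ValueError, match="integer multiple"):
        s.steps_per_period(ld.ForcingSpec(A=1.0, B=0.0, omega=1.0))


def test_trajectory_window_and_spacing(p_eq_n):
    s = ld.RunSettings(transient_periods=2, record_periods=3)
    traj = ld.integrate(defaults.canonical_params(-5.41), p_eq_n, s)
    spp = s.steps_per_period(p_eq_n)
    assert len(traj) == 3 * spp + 1
    assert traj.times[0] == pytest.approx(2 * p_eq_n.period())
    np.testing.assert_allclose(np.diff(traj.times), s.dt, rtol=1e-9)


def test_strobe_count_equals_record_periods(p_eq_n, quick_settings):
    sec = strobe_run(-5.41, settings_=quick_settings)
    assert len(sec) == quick_settings.record_periods


def test_period1_orbit_has_single_strobe_point(quick_settings):
    sec = strobe_run(-5.41, settings_=quick_settings)
    assert n_distinct(sec.points, tol=1e-6) == 1


def test_period1_trajectory_repeats_with_forcing_period(p_eq_n, quick_settings):
    traj = ld.integrate(defaults.canonical_params(-5.41), p_eq_n, quick_settings)
    spp = quick_settings.steps_per_period(p_eq_n)
    assert traj.R.std() > 0.1  # non-constant oscillation
    np.testing.assert_allclose(traj.R[spp:], traj.R[:-spp], atol=1e-7)


def test_strobe_phase_validation(p_eq_n, quick_settings):
    traj = ld.integrate(defaults.canonical_params(-5.41), p_eq_n, quick_settings)
    with pytest.raises(ValueError):
        ld.strobe(traj, phase=2.0)  # = period, out of range
    with pytest.raises(ValueError):
        ld.strobe(traj, phase=0.00037)  # not a multiple of dt
    sec = ld.strobe(traj, phase=0.5)
    assert len(sec) == quick_settings.record_periods


def test_strobe_requires_metadata():
    traj = ld.Trajectory(times=np.arange(5) * 0.1, R=np.zeros(5), J=np.zeros(5))
    with pytest.raises(ValueError, match="metadata"):
        ld.strobe(traj)


def test_rk4_order_by_step_halving(p_eq_n):
    """Richardson estimate of the convergence order on a one-period window."""
    p = ld.LoveParams(a=-3.0, b=-2.0, c=1.0, d=1.0)
    finals = []
    for dt in (0.01, 0.005, 0.0025):
        s = ld.RunSettings(dt=dt, transient_periods=0, record_periods=1,
                           initial_state=ld.State(0.3, 0.2))
        traj = ld.integrate(p, p_eq_n, s)
        finals.append(np.array([traj.R[-1], traj.J[-1]]))
    e1 = np.linalg.norm(finals[0] - finals[1])
    e2 = np.linalg.norm(finals[1] - finals[2])
    order = np.log2(e1 / e2)
    assert order >= 3.5


def test_odd_symmetry_of_pure_sine_forcing(p_eq_n):
    """With B=0, (R,J) -> (-R,-J) plus a half-period shift maps solutions
    to solutions; broken when B != 0."""
    p = ld.LoveParams(a=-3.0, b=-2.0, c=1.0, d=1.0)
    kw = dict(transient_periods=0, record_periods=5)
    t1 = ld.integrate(p, p_eq_n, ld.RunSettings(initial_state=ld.State(0.4, -0.3), **kw))
    t2 = ld.integrate(p, p_eq_n, ld.RunSettings(t0=1.0, initial_state=ld.State(-0.4, 0.3), **kw))
    assert np.max(np.abs(t1.R + t2.R)) < 1e-9
    assert np.max(np.abs(t1.J + t2.J)) < 1e-9

    f_off = ld.ForcingSpec(A=5.0, B=1.0)
    t3 = ld.integrate(p, f_off, ld.RunSettings(initial_state=ld.State(0.4, -0.3), **kw))
    t4 = ld.integrate(p, f_off, ld.RunSettings(t0=1.0, initial_state=ld.State(-0.4, 0.3), **kw))
    assert np.max(np.abs(t3.R + t4.R)) > 1e-3


def test_strobed_symmetry_between_phases(quick_settings, p_eq_n):
    """For the pure-sine scenario the phase-0 strobe set maps onto the
    negated phase-1 strobe set (as a set) on a symmetric attractor."""
    traj = ld.integrate(defaults.canonical_params(-2.561), p_eq_n,
                        ld.RunSettings(record_periods=400))
    s0 = ld.strobe(traj, phase=0.0).points
    s1 = -ld.strobe(traj, phase=1.0).points
    from scipy.spatial.distance import cdist, pdist
    d = cdist(s0, s1)
    hausdorff = max(d.min(axis=0).max(), d.min(axis=1).max())
    assert hausdorff / pdist(s0).max() < 0.3


def test_trajectory_csv_round_trip(tmp_path, p_eq_n):
    s = ld.RunSettings(transient_periods=1, record_periods=2)
    traj = ld.integrate(defaults.canonical_params(-2.561), p_eq_n, s)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    back = ld.Trajectory.from_csv(path)
    np.testing.assert_array_equal(back.times, traj.times)
    np.testing.assert_array_equal(back.R, traj.R)
    np.testing.assert_array_equal(back.J, traj.J)


def test_section_csv_has_strobe_times(tmp_path, quick_settings):
    sec = strobe_run(-5.41, settings_=quick_settings)
    path = tmp_path / "sec.csv"
    sec.to_csv(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert data.shape == (len(sec), 4)
    np.testing.assert_array_equal(data[:, 0], np.arange(len(sec)))
    np.testing.assert_array_equal(data[:, 2:], sec.points)


def test_continue_from_preserves_phase(p_eq_n):
    p = defaults.canonical_params(-5.41)
    s = ld.RunSettings(transient_periods=100, record_periods=50)
    traj = ld.integrate(p, p_eq_n, s)
    s2 = continue_from(ld.RunSettings(transient_periods=0, record_periods=50), traj)
    traj2 = ld.integrate(p, p_eq_n, s2)
    # restarting from the end of a whole number of periods keeps the strobe
    # landing on the same attractor point
    sec1 = ld.strobe(traj).points[-1]
    sec2 = ld.strobe(traj2).points[-1]
    np.testing.assert_allclose(sec1, sec2, atol=1e-6)
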