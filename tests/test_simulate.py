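"""Integration, limit-cycle measurement, arrest detection, size control."""

import math

import numpy as np
import pytest

from mitoclock import (
    IntegrationError,
    LineageTrace,
    ModelDefinition,
    ParameterSet,
    detect_arrest,
    find_limit_cycle,
    get_model,
    integrate,
    interdivision_stats,
    simulate_size_control,
    validate_state,
)
from mitoclock.simulate import DivisionRecord


def _toy(names, rhs):
    return ModelDefinition(id="toy", state_names=names, rhs=rhs)


# --------------------------------------------------------------------------
# integrate
# --------------------------------------------------------------------------

def test_zero_synthesis_gives_zero_trajectory(m1, p1):
    p = p1.replace(ksy_cycb=0.0)
    traj = integrate(m1, p, np.zeros(3), (0, 500))
    assert np.abs(traj.states).max() < 1e-12


def test_tolerance_halving_converges(m2, p2):
    x0 = np.zeros(5)
    a = integrate(m2, p2, x0, (0, 300), rtol=1e-8, atol=1e-10)
    b = integrate(m2, p2, x0, (0, 300), rtol=5e-9, atol=5e-11)
    rel = np.abs(a.states[-1] - b.states[-1]) / np.maximum(
        np.abs(b.states[-1]), 1e-3)
    assert rel.max() < 1e-6


def test_integration_failure_is_diagnosed():
    # finite-time blow-up: step size collapses near t = pi/4
    blowup = _toy(("MPF",), lambda y, p: np.array([1.0 + y[0] ** 2]))
    with pytest.raises(IntegrationError) as err:
        integrate(blowup, ParameterSet(), [1.0], (0, 10), method="RK45")
    assert err.value.t == pytest.approx(np.pi / 4, abs=0.01)
    assert err.value.state is not None


def test_trajectory_invariants_hold(m4, p4):
    traj = integrate(m4, p4, np.zeros(6), (0, 800))
    for row in traj.states[::20]:
        # the APCPC20 <= APCP ordering is an initial-state constraint only:
        # mitotic exit dephosphorylates APC faster than Cdc20 unbinds
        validate_state(m4, row, p4, tol=1e-7, check_binding=False)
    # closure consistency: free B55 and the sequestered complex sum to total
    total = traj.derived["B55_free"] + traj.derived["ENSAPB55"]
    np.testing.assert_allclose(total, p4.B55_tot, rtol=1e-9)


def test_cross_integrator_agreement(m2, p2):
    x0 = np.zeros(5)
    a = integrate(m2, p2, x0, (0, 1200), method="LSODA")
    b = integrate(m2, p2, x0, (0, 1200), method="Radau")
    w = a.times > 400
    for traj in (a, b):
        assert traj["MPF"][w].max() > 0.3    # oscillatory in both
    assert abs(a["MPF"][w].max() - b["MPF"][w].max()) < 1e-4
    assert abs(a["MPF"][w].min() - b["MPF"][w].min()) < 1e-4


# --------------------------------------------------------------------------
# find_limit_cycle
# --------------------------------------------------------------------------

def test_harmonic_oscillator_period_recovered():
    omega = 0.5
    osc = _toy(("MPF", "v"),
               lambda y, p: np.array([y[1], -omega**2 * y[0]]))
    lc = find_limit_cycle(osc, ParameterSet(), [1.0, 0.0], max_time=400.0)
    assert lc.oscillatory
    assert lc.period == pytest.approx(2 * math.pi / omega, rel=1e-3)


def test_negative_feedback_oscillator_period(m1, p1):
    lc = find_limit_cycle(m1, p1, np.zeros(3))
    assert lc.oscillatory and lc.converged
    assert lc.period == pytest.approx(46.0, abs=2.0)
    assert lc.maxima["MPF"] > lc.minima["MPF"]
    # orbit endpoints coincide (peak to peak over one period)
    np.testing.assert_allclose(lc.orbit.states[0], lc.orbit.states[-1],
                               rtol=0, atol=1e-4)


def test_steady_system_reports_no_cycle(m4, p4):
    # G2-arrest parameters: no oscillation from the arrested state
    p = p4.replace(Cdc25_tot=0.4)
    res = detect_arrest(m4, p, np.zeros(6), horizon=2500)
    lc = find_limit_cycle(m4, p, res.terminal_state, max_time=1500)
    assert not lc.oscillatory
    assert lc.period is None


def test_cycle_independent_of_initial_condition(m3, p3):
    lc1 = find_limit_cycle(m3, p3, np.zeros(5))
    lc2 = find_limit_cycle(m3, p3, [0.5, 0.3, 2.0, 0.2, 0.1])
    assert lc1.converged and lc2.converged
    assert lc1.period == pytest.approx(lc2.period, rel=5e-3)
    for k in ("MPF", "APCP"):
        assert lc1.maxima[k] == pytest.approx(lc2.maxima[k], rel=5e-3)


def test_futile_cycling_lower_with_tyrosine_switch(m3, m4, p4):
    """With the Wee1/Cdc25 switch, kinase and phosphatase are strictly
    out-of-phase: the time-average of MPF*B55 drops well below that of the
    switch-free model at the shared parameter set."""
    def avg_product(lc):
        orb = lc.orbit
        return float(np.trapezoid(orb["MPF"] * orb["B55_free"], orb.times)
                     / (orb.times[-1] - orb.times[0]))
    lc3 = find_limit_cycle(m3, p4, np.zeros(5))
    lc4 = find_limit_cycle(m4, p4, np.zeros(6))
    assert lc3.oscillatory and lc4.oscillatory
    assert avg_product(lc4) < avg_product(lc3)


# --------------------------------------------------------------------------
# detect_arrest
# --------------------------------------------------------------------------

def test_detect_arrest_classifies_oscillation(m4, p4):
    res = detect_arrest(m4, p4, np.zeros(6), horizon=2000)
    assert res.classification == "oscillation"
    assert res.cycle is not None and res.cycle.converged


def test_detect_arrest_classifies_steady_state(m4, p4):
    res = detect_arrest(m4, p4.replace(Cdc25_tot=0.4), np.zeros(6),
                        horizon=2500)
    assert res.classification == "steady-state"
    assert res.max_rhs < 1e-8 and res.drift < 1e-6


# --------------------------------------------------------------------------
# size control
# --------------------------------------------------------------------------

#: the approach to the asymptotic division cycle is geometric with a factor
#: of ~0.3 per cycle, so five discarded cycles leave transients < 1e-3
_DISCARD = 5


@pytest.fixture(scope="module")
def lineage(m4, p4):
    trace, traj = simulate_size_control(get_model("model4"), p4, mu=0.005,
                                        v0=1.0, n_cycles=12)
    return trace, traj


def test_division_halves_size_exactly(lineage):
    trace, traj = lineage
    for prev, nxt in zip(trace.records, trace.records[1:]):
        assert nxt.v_birth == prev.v_division / 2.0
    assert len(traj.division_times) == len(trace)
    assert np.all(np.diff(trace.division_times) > 0)


def test_interdivision_time_is_mass_doubling_time(lineage):
    trace, _ = lineage
    st = interdivision_stats(trace, discard=_DISCARD)
    assert st.mean_cycle_min == pytest.approx(math.log(2) / 0.005, rel=0.03)
    assert st.cv_cycle < 0.01


def test_growth_law_scaling(m4, p4):
    # doubling the growth rate halves the interdivision time (ln2 / mu)
    trace, _ = simulate_size_control(m4, p4, mu=0.01, v0=1.0, n_cycles=12)
    st = interdivision_stats(trace, discard=_DISCARD)
    assert st.mean_cycle_min == pytest.approx(math.log(2) / 0.01, rel=0.03)


def test_size_homeostasis_from_extreme_birth_sizes(m4, p4, lineage):
    ref = interdivision_stats(lineage[0], discard=_DISCARD).mean_division_size
    for v0 in (0.3, 2.0):
        trace, _ = simulate_size_control(m4, p4, mu=0.005, v0=v0,
                                         n_cycles=10)
        st = interdivision_stats(trace, discard=_DISCARD)
        assert st.mean_division_size == pytest.approx(ref, rel=0.02)


def test_size_control_argument_validation(m4, p4):
    with pytest.raises(ValueError, match="mu"):
        simulate_size_control(m4, p4, mu=0.0)
    with pytest.raises(ValueError, match="exit_threshold"):
        simulate_size_control(m4, p4, entry_threshold=0.2, exit_threshold=0.5)


# --------------------------------------------------------------------------
# interdivision_stats on hand-built traces
# --------------------------------------------------------------------------

def _trace(durations):
    t, records = 0.0, []
    records.append(DivisionRecord(0.0, 0.5, 1.0, float("nan"), 1.5))
    for d in durations:
        t += d
        records.append(DivisionRecord(t, 0.5, 1.0, d, 1.5))
    return LineageTrace(records=records, mu=0.005)


def test_stats_identical_cycles_have_zero_cv():
    st = interdivision_stats(_trace([140.0] * 6))
    assert st.cv_cycle == 0.0
    assert st.mean_cycle_min == 140.0


def test_stats_alternating_cycles_mean():
    st = interdivision_stats(_trace([100.0, 180.0] * 3))
    assert st.mean_cycle_min == pytest.approx(140.0)
    assert st.n_cycles == 4


def test_stats_require_enough_cycles():
    with pytest.raises(ValueError, match="completed cycles"):
        interdivision_stats(_trace([140.0] * 4))
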