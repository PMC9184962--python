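"""Continuation, fold/Hopf detection, pseudo-nullclines and SNIC tests.

Bifurcation detection is checked on analytic normal forms (exact locations
known) before being trusted on the cell-cycle models.
"""

import numpy as np
import pytest

from mitoclock import (
    ModelDefinition,
    ParameterSet,
    classify_snic,
    continue_branch,
    find_steady_states,
    jacobian,
    model_jacobian,
    parameter_rhs,
    pseudo_nullcline,
)


# --------------------------------------------------------------------------
# jacobian
# --------------------------------------------------------------------------

def test_jacobian_exact_on_linear_system():
    A = np.array([[1.0, -2.0, 0.5], [0.0, -3.0, 1.0], [2.0, 0.1, -0.7]])
    J = jacobian(lambda y: A @ y, np.array([0.3, -1.2, 2.0]))
    np.testing.assert_allclose(J, A, rtol=1e-9, atol=1e-12)


def test_jacobian_step_halving_consistency(m1, p1):
    y = np.array([0.3, 0.4, 0.2])
    J1 = jacobian(lambda x: m1.rhs(x, p1), y, rel_step=1e-6)
    J2 = jacobian(lambda x: m1.rhs(x, p1), y, rel_step=5e-7)
    assert np.abs(J1 - J2).max() / np.abs(J2).max() < 1e-6


def test_oscillator_steady_state_is_unstable_focus(m1, p1):
    states = find_steady_states(m1, p1, n_starts=40)
    assert len(states) == 1
    (ss,) = states
    eigs = ss.eigenvalues
    cplx = eigs[np.abs(eigs.imag) > 1e-9]
    assert cplx.size == 2 and np.all(cplx.real > 0)   # oscillation encircles it
    J = model_jacobian(m1, p1, ss.state)
    np.testing.assert_allclose(np.sort(np.linalg.eigvals(J).real),
                               np.sort(eigs.real), rtol=1e-6)


# --------------------------------------------------------------------------
# find_steady_states
# --------------------------------------------------------------------------

def test_linear_fixed_point_recovered_exactly():
    A = np.array([[-1.0, 0.3], [0.2, -2.0]])
    target = np.array([0.4, 0.7])
    toy = ModelDefinition(id="lin", state_names=("MPF", "y"),
                          rhs=lambda y, p: A @ (y - target))
    states = find_steady_states(toy, ParameterSet(), n_starts=30)
    assert len(states) == 1
    np.testing.assert_allclose(states[0].state, target, atol=1e-10)
    assert states[0].stability == "stable node"


def test_model2_has_unique_unstable_state(m2, p2):
    states = find_steady_states(m2, p2, n_starts=120, seed=4)
    phys = [s for s in states
            if s.state[4] <= s.state[3] + 1e-6]      # APCPC20 <= APCP
    assert len(phys) == 1
    assert not phys[0].stable                         # cycle encloses it


def test_g2_arrest_coexisting_states(m4, p4):
    # lowered Cdc25 creates a node + saddle pair on the high-cyclin branch
    p = p4.replace(Cdc25_tot=0.4)
    states = find_steady_states(m4, p4.replace(Cdc25_tot=0.4),
                                n_starts=150, seed=5)
    phys = [s for s in states if s.state[1] <= s.state[0] + 1e-6
            and s.state[5] <= s.state[4] + 1e-6]
    assert len(phys) >= 2
    stable_low = [s for s in phys
                  if s.stable and s.state[1] < 0.2 and s.state[0] > 1.5]
    assert stable_low, "expected a stable high-CycBT / low-MPF (G2) node"
    assert any(s.stability == "saddle" for s in phys)


# --------------------------------------------------------------------------
# continuation on normal forms
# --------------------------------------------------------------------------

def _fold_nf(y, p):
    return np.array([p - y[0] ** 2])


def test_saddle_node_normal_form_fold_location():
    br = continue_branch(_fold_nf, np.array([1.0]), 1.0, (-0.5, 1.0),
                        ds0=0.01, ds_max=0.05)
    assert len(br.folds) == 1
    assert abs(br.folds[0].param) < 1e-6
    assert abs(br.folds[0].state[0]) < 1e-3
    # stability flips exactly at the fold: x>0 stable, x<0 unstable
    for pt in br.points:
        if abs(pt.state[0]) > 1e-2:
            want = "stable node" if pt.state[0] > 0 else "unstable node"
            assert pt.stability == want


def _hopf_nf(y, p):
    x, v = y
    r2 = x * x + v * v
    return np.array([p * x - v - x * r2, x + p * v - v * r2])


def test_hopf_normal_form_location():
    br = continue_branch(_hopf_nf, np.zeros(2), -0.5, (-0.5, 0.5),
                        ds0=0.01, ds_max=0.05)
    assert len(br.hopfs) == 1
    assert abs(br.hopfs[0].param) < 1e-6
    assert not br.folds


def _cubic_nf(y, p):
    # x' = 1 + p*x - x^3: fold at p = 3/2^(2/3), no oscillation anywhere
    return np.array([1.0 + p * y[0] - y[0] ** 3])


def test_cubic_fold_location_and_plain_fold_classification():
    p_fold = 3.0 / 2.0 ** (2.0 / 3.0)
    br = continue_branch(_cubic_nf, np.array([-1.53]), 3.0, (0.5, 3.0),
                        ds0=0.01, ds_max=0.05)
    assert br.folds
    assert br.folds[0].param == pytest.approx(p_fold, abs=1e-6)
    res = classify_snic(_cubic_nf, br.folds[0].param, -1, [-0.8],
                        mpf_index=0, far_param=3.0, max_time=400.0)
    assert res.kind == "fold"


def _snic_nf(y, p):
    # rotation theta' = p - sin(theta) on an attracting unit circle:
    # saddle-node of on-circle fixed points at p = 1 births a limit cycle
    # with period 2*pi/sqrt(p^2-1) -> infinity (the SNIC signature)
    x, v = y
    r2 = x * x + v * v
    return np.array([x * (1 - r2) - v * (p - v), v * (1 - r2) + x * (p - v)])


def test_snic_normal_form_classification():
    br = continue_branch(_snic_nf, np.array([np.sqrt(1 - 0.25), 0.5]), 0.5,
                        (0.0, 1.0), ds0=0.01, ds_max=0.05)
    assert br.folds
    assert br.folds[0].param == pytest.approx(1.0, abs=1e-6)
    res = classify_snic(_snic_nf, 1.0, +1, [1.0, 0.0], mpf_index=0,
                        far_param=3.0, max_time=1500.0)
    assert res.kind == "SNIC"
    assert res.divergence_ratio > 5
    assert np.all(np.diff(res.probe_periods) > 0)    # diverging toward fold


# --------------------------------------------------------------------------
# pseudo-nullclines
# --------------------------------------------------------------------------

def test_pseudo_nullcline_equals_true_nullcline_in_two_variables():
    # x' = a - x(1 + y^2): clamping y gives the closed form x = a/(1+y^2)
    a = 0.8
    toy = ModelDefinition(
        id="toy2", state_names=("MPF", "Y"),
        rhs=lambda s, p: np.array([a - s[0] * (1 + s[1] ** 2),
                                   s[0] - s[1]]))
    nc = pseudo_nullcline(toy, ParameterSet(), clamp="Y",
                          clamp_range=(0.0, 3.0), n_steps=100)
    np.testing.assert_allclose(nc.response_values,
                               a / (1 + nc.clamp_values ** 2), atol=1e-6)
    assert nc.shape == "monotone" and not nc.folds


def test_cycle_envelope_straddles_oscillation_onset(m4, p4):
    """Below the size threshold the clamped-V system sits at a low-MPF
    steady state; above it a large-amplitude cycle whose MPF extrema
    bracket the coexisting (unstable) steady-state branch."""
    from mitoclock import cycle_envelope, find_steady_states

    fun = parameter_rhs(m4, p4, "Cdc25_tot")
    env = cycle_envelope(fun, [0.45, 1.1], np.zeros(6), mpf_index=1,
                         param_name="V")
    assert not env.oscillatory[0]
    assert env.mpf_max[0] < 0.3                  # parked at the arrested state
    assert env.oscillatory[1] and env.period[1] > 0
    assert env.mpf_max[1] > env.mpf_min[1]
    # the oscillation encloses the unstable steady state at the same V
    states = find_steady_states(m4, p4.replace(Cdc25_tot=1.1),
                                n_starts=60, seed=2)
    inside = [s for s in states
              if env.mpf_min[1] < s.state[1] < env.mpf_max[1]]
    assert inside and all(not s.stable for s in inside)


def test_model2_nullcline_is_monotone(m2, p2):
    # without B55 -> Gwl feedback the APC/C response to MPF has no folds
    nc = pseudo_nullcline(m2, p2, clamp="MPF", clamp_range=(0.02, 1.2),
                          response="APCPC20", n_steps=150)
    assert nc.complete
    assert nc.shape == "monotone"
    assert not nc.folds


def test_model3_nullcline_is_bistable(m3, p3):
    # B55 dephosphorylates Gwl: the APC/C response becomes S-shaped
    nc = pseudo_nullcline(m3, p3, clamp="MPF", clamp_range=(0.02, 1.2),
                          response="APCPC20", n_steps=200)
    assert nc.shape == "S"
    assert len(nc.folds) == 2
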