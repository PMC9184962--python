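"""Numerical integration, limit-cycle measurement, arrest detection and the
size-controlled hybrid cell cycle.

All integrations use a stiff-capable adaptive method (LSODA by default) with
tight tolerances (rtol 1e-8, atol 1e-10): models 3 and 4 are relaxation
oscillators with abrupt mitotic jumps, and the tQSSA closure makes the ENSA
equation stiff when the Michaelis constant is small.

The oscillation observable throughout is MPF activity: periods are measured
as the mean spacing of successive MPF maxima after transient removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .models import ModelDefinition, ParameterSet

__all__ = [
    "Trajectory",
    "LimitCycle",
    "ArrestResult",
    "DivisionRecord",
    "LineageTrace",
    "IntegrationError",
    "integrate",
    "find_limit_cycle",
    "detect_arrest",
    "simulate_size_control",
    "interdivision_stats",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Integration failed (e.g. step-size collapse); carries time and state."""

    def __init__(self, message: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time grid plus state matrix from one integration.

    ``states`` has one row per time point, columns ordered as
    ``state_names``.  ``derived`` holds closure time series (B55_free, f,
    Wee1 and Cdc25 activities) where the model defines them.
    ``division_times`` is non-empty only for size-control runs.
    """

    model_id: str
    state_names: tuple[str, ...]
    times: np.ndarray
    states: np.ndarray
    derived: dict[str, np.ndarray] = field(default_factory=dict)
    division_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.state_names:
            return self.states[:, self.state_names.index(name)]
        return self.derived[name]

    def frame(self) -> pd.DataFrame:
        """Tidy table: one row per time point (time in min, conc. in a.u.)."""
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "time_min", self.times)
        for k, v in self.derived.items():
            df[k] = v
        return df


@dataclass
class LimitCycle:
    """Summary of a periodic orbit (or the finding that there is none)."""

    oscillatory: bool
    period: float | None = None          # min
    period_cv: float | None = None       # coefficient of variation of spacings
    converged: bool = False
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    maxima: dict[str, float] = field(default_factory=dict)
    minima: dict[str, float] = field(default_factory=dict)
    orbit: Trajectory | None = None      # one sampled period

    @property
    def amplitude(self) -> dict[str, float]:
        return {k: self.maxima[k] - self.minima[k] for k in self.maxima}


@dataclass
class ArrestResult:
    """Outcome of long-time classification: arrested or still cycling."""

    classification: str                  # 'steady-state' | 'oscillation' | 'inconclusive'
    terminal_state: np.ndarray
    terminal_time: float
    max_rhs: float
    drift: float
    cycle: LimitCycle | None = None


@dataclass
class DivisionRecord:
    time: float                 # min, at division
    v_birth: float              # size at the start of this cycle
    v_division: float           # size at division (daughter = v_division / 2)
    cycle_duration: float       # min; nan for the first (partial) cycle
    mpf_peak: float             # max MPF during the cycle


@dataclass
class LineageTrace:
    """Sequence of division events from the size-control simulator."""

    records: list[DivisionRecord]
    mu: float

    def __len__(self) -> int:
        return len(self.records)

    @property
    def division_times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def v_at_division(self) -> np.ndarray:
        return np.array([r.v_division for r in self.records])

    @property
    def v_at_birth(self) -> np.ndarray:
        return np.array([r.v_birth for r in self.records])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


@dataclass
class InterdivisionStats:
    n_cycles: int
    mean_cycle_min: float
    cv_cycle: float
    mean_birth_size: float
    mean_division_size: float


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

def _solve(fun, t_span, x0, rtol, atol, method, dense=True, events=None,
           max_step=np.inf):
    sol = solve_ivp(fun, t_span, x0, method=method, rtol=rtol, atol=atol,
                    dense_output=dense, events=events, max_step=max_step)
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t_span[0]
        y_last = sol.y[:, -1] if sol.t.size else np.asarray(x0)
        raise IntegrationError(
            f"integration failed at t = {t_last:.6g} min "
            f"(state {np.array2string(y_last, precision=6)}): {sol.message}",
            t=t_last, state=y_last)
    return sol


def integrate(model: ModelDefinition, params: ParameterSet, x0, t_span,
              t_eval=None, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, method: str = "LSODA") -> Trajectory:
    """Integrate ``model`` over ``t_span`` and return a :class:`Trajectory`.

    ``t_eval`` defaults to 2000 uniformly spaced output points (the solver
    steps adaptively regardless; output is from dense interpolation).
    Deterministic: identical inputs give identical output.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (len(model.state_names),):
        raise ValueError(f"x0 must have length {len(model.state_names)} "
                         f"for {model.id}")
    if not np.all(np.isfinite(t_span)):
        raise ValueError("t_span must be finite")
    sol = _solve(lambda t, y: model.rhs(y, params), t_span, x0, rtol, atol,
                 method)
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 2000)
    t_eval = np.asarray(t_eval, dtype=float)
    states = sol.sol(t_eval).T
    return Trajectory(model_id=model.id, state_names=model.state_names,
                      times=t_eval, states=states,
                      derived=_derived_series(model, params, t_eval, states))


def _derived_series(model, params, times, states) -> dict[str, np.ndarray]:
    if model.closures is None:
        return {}
    keys = model.derived(states[0], params).keys()
    out = {k: np.empty(len(times)) for k in keys}
    for i, row in enumerate(states):
        d = model.derived(row, params)
        for k in keys:
            out[k][i] = d[k]
    return out


# --------------------------------------------------------------------------
# Limit-cycle measurement
# --------------------------------------------------------------------------

def _refine_peak(f, t_lo, t_hi):
    """Maximise the scalar signal f on [t_lo, t_hi] (dense-output bracket)."""
    res = minimize_scalar(lambda t: -f(t), bounds=(t_lo, t_hi),
                          method="bounded",
                          options={"xatol": 1e-10 * max(1.0, t_hi)})
    return float(res.x)


def _measure_cycle(f_dense, t0, t1, obs_index, osc_tol):
    """Refined maxima of observable ``obs_index`` on window [t0, t1].

    Returns (peak_times, amplitude_ok).  f_dense(t) -> state vector.
    """
    grid = np.linspace(t0, t1, 20000)
    ys = f_dense(grid)
    m = ys[obs_index]
    lo, hi = m.min(), m.max()
    if hi - lo < osc_tol:
        return np.empty(0), False
    thr = lo + 0.5 * (hi - lo)
    idx = np.where((m[1:-1] > m[:-2]) & (m[1:-1] >= m[2:]) & (m[1:-1] > thr))[0] + 1
    peaks = [_refine_peak(lambda t: float(f_dense(t)[obs_index]),
                          grid[i - 1], grid[i + 1]) for i in idx
             if 0 < i < len(grid) - 1]
    return np.array(peaks), True


def find_limit_cycle(model: ModelDefinition, params: ParameterSet, x0,
                     transient: float | None = None, max_time: float = 4000.0,
                     observable: str = "MPF", min_peaks: int = 5,
                     cv_tol: float = 1e-3, osc_tol: float = 1e-4,
                     rtol: float = DEFAULT_RTOL,
                     atol: float = DEFAULT_ATOL) -> LimitCycle:
    """Locate and characterise a stable limit cycle by forward integration.

    The trajectory is integrated to ``max_time``; an initial transient
    (default: the larger of 500 min and three rough periods) is discarded;
    the period is the mean spacing of at least ``min_peaks`` successive
    maxima of the observable (MPF by default), each refined on the dense
    solution.  The cycle is flagged converged when the coefficient of
    variation of the spacings is below ``cv_tol``.  A non-oscillatory
    outcome (amplitude below ``osc_tol``) is reported, not raised.
    """
    fun = lambda t, y: model.rhs(y, params)
    sol = _solve(fun, (0.0, max_time), np.asarray(x0, float), rtol, atol,
                 "LSODA")
    obs = model.index(observable)

    t0 = min(500.0, 0.25 * max_time)
    peaks, osc = _measure_cycle(sol.sol, t0, max_time, obs, osc_tol)
    if osc and len(peaks) >= 3:
        rough = float(np.median(np.diff(peaks)))
        t0 = max(500.0, 3.0 * rough) if transient is None else transient
        t0 = min(t0, max_time - (min_peaks + 1) * rough)
        peaks, osc = _measure_cycle(sol.sol, t0, max_time, obs, osc_tol)
    elif transient is not None:
        peaks, osc = _measure_cycle(sol.sol, transient, max_time, obs,
                                    osc_tol)
    if not osc or len(peaks) < min_peaks:
        return LimitCycle(oscillatory=False, peak_times=peaks)

    spacings = np.diff(peaks)
    period = float(spacings.mean())
    cv = float(spacings.std() / period)

    # one sampled orbit over the final full period
    t_orbit = np.linspace(peaks[-2], peaks[-1], 600)
    states = sol.sol(t_orbit).T
    orbit = Trajectory(model.id, model.state_names, t_orbit, states,
                       derived=_derived_series(model, params, t_orbit, states))
    # extrema over the last few periods (robust to sampling phase)
    t_ext = np.linspace(peaks[0], peaks[-1], 20000)
    ys = sol.sol(t_ext)
    maxima = {n: float(ys[i].max()) for i, n in enumerate(model.state_names)}
    minima = {n: float(ys[i].min()) for i, n in enumerate(model.state_names)}
    return LimitCycle(oscillatory=True, period=period, period_cv=cv,
                      converged=cv < cv_tol, peak_times=peaks,
                      maxima=maxima, minima=minima, orbit=orbit)


# --------------------------------------------------------------------------
# Arrest detection
# --------------------------------------------------------------------------

def detect_arrest(model: ModelDefinition, params: ParameterSet, x0,
                  horizon: float = 3000.0, rhs_tol: float = 1e-8,
                  drift_tol: float = 1e-6, rtol: float = DEFAULT_RTOL,
                  atol: float = DEFAULT_ATOL) -> ArrestResult:
    """Classify the long-time behaviour as arrested steady state or cycling.

    A steady state is declared when, over the trailing 10% of the horizon,
    the largest right-hand-side component stays below ``rhs_tol`` and the
    state drifts by less than ``drift_tol``.  Otherwise the trajectory is
    handed to :func:`find_limit_cycle`; if that also fails to converge the
    result is flagged inconclusive.
    """
    fun = lambda t, y: model.rhs(y, params)
    x0 = np.asarray(x0, dtype=float)
    sol = _solve(fun, (0.0, horizon), x0, rtol, atol, "LSODA")
    t_win = np.linspace(0.9 * horizon, horizon, 200)
    ys = sol.sol(t_win)
    max_rhs = max(float(np.abs(model.rhs(ys[:, i], params)).max())
                  for i in range(0, len(t_win), 10))
    drift = float((ys.max(axis=1) - ys.min(axis=1)).max())
    terminal = ys[:, -1]
    if max_rhs < rhs_tol and drift < drift_tol:
        return ArrestResult("steady-state", terminal, horizon, max_rhs, drift)
    cyc = find_limit_cycle(model, params, x0, max_time=max(horizon, 3000.0))
    if cyc.oscillatory and cyc.converged:
        return ArrestResult("oscillation", terminal, horizon, max_rhs, drift,
                            cycle=cyc)
    return ArrestResult("inconclusive", terminal, horizon, max_rhs, drift,
                        cycle=cyc if cyc.oscillatory else None)


# --------------------------------------------------------------------------
# Size-controlled division cycle
# --------------------------------------------------------------------------

class SizeControlError(RuntimeError):
    """No division occurred in the allotted time; carries the last state."""

    def __init__(self, message, t, state):
        super().__init__(f"{message} (t = {t:.4g} min, state = "
                         f"{np.array2string(np.asarray(state), precision=5)})")
        self.t = t
        self.state = state


def simulate_size_control(model: ModelDefinition, params: ParameterSet,
                          mu: float = 0.005, v0: float = 1.0,
                          entry_threshold: float = 0.5,
                          exit_threshold: float = 0.2,
                          n_cycles: int = 12, x0=None,
                          max_time: float | None = None,
                          rtol: float = DEFAULT_RTOL,
                          atol: float = DEFAULT_ATOL,
                          sample_per_min: float = 2.0,
                          ) -> tuple[LineageTrace, Trajectory]:
    """Hybrid simulation of growth-coupled mitotic cycles.

    Cell size V grows exponentially (dV/dt = mu*V) and feeds back on the
    division machinery through [Cdc25_tot] = V(t): bigger cells make more of
    the activating phosphatase.  A division fires on the downward crossing
    of MPF through ``exit_threshold``, armed only after MPF has exceeded
    ``entry_threshold`` (mitotic entry) since the last division; at division
    V -> V/2 instantaneously while all protein concentrations (intensive
    quantities) stay continuous.  Crossings are located by the integrator's
    event root-finding (well below 1e-8 min).

    Returns the lineage of division records and the full trajectory with V
    appended as the last state column.
    """
    if mu <= 0:
        raise ValueError("growth rate mu must be positive")
    if not exit_threshold < entry_threshold:
        raise ValueError("exit_threshold must lie below entry_threshold")
    if max_time is None:
        max_time = (n_cycles + 4) * 2.0 * math.log(2.0) / mu

    names = model.state_names + ("V",)
    i_mpf = model.index("MPF")

    def fun(t, y):
        p = params.replace(Cdc25_tot=y[-1])
        return np.append(model.rhs(y[:-1], p), mu * y[-1])

    def ev_entry(t, y):
        return y[i_mpf] - entry_threshold
    ev_entry.direction = 1.0
    ev_entry.terminal = True

    def ev_exit(t, y):
        return y[i_mpf] - exit_threshold
    ev_exit.direction = -1.0
    ev_exit.terminal = True

    if x0 is None:
        x0 = np.zeros(len(model.state_names))
    y = np.append(np.asarray(x0, float), v0)
    t = 0.0
    records: list[DivisionRecord] = []
    ts_all, ys_all, div_times = [], [], []
    t_birth, v_birth = 0.0, v0

    def _run_until(event, y, t, phase):
        sol = _solve(fun, (t, max_time), y, rtol, atol, "LSODA",
                     events=[event])
        n = max(2, int((sol.t[-1] - t) * sample_per_min))
        tt = np.linspace(t, sol.t[-1], n)
        seg = sol.sol(tt)
        ts_all.append(tt)
        ys_all.append(seg)
        if not sol.t_events[0].size:
            raise SizeControlError(
                f"no {phase} event before max_time = {max_time:.4g} min",
                sol.t[-1], sol.y[:, -1])
        te = float(sol.t_events[0][0])
        return te, sol.y_events[0][0].copy(), float(seg[i_mpf].max())

    for _ in range(n_cycles):
        t, y, _ = _run_until(ev_entry, y, t, "mitotic-entry")
        t, y, peak = _run_until(ev_exit, y, t, "mitotic-exit")
        v_div = float(y[-1])
        records.append(DivisionRecord(
            time=t, v_birth=v_birth, v_division=v_div,
            cycle_duration=t - t_birth if records else float("nan"),
            mpf_peak=peak))
        div_times.append(t)
        y = y.copy()
        y[-1] = v_div / 2.0
        t_birth, v_birth = t, y[-1]

    times = np.concatenate(ts_all)
    states = np.concatenate(ys_all, axis=1).T
    traj = Trajectory(model_id=model.id + "_size", state_names=names,
                      times=times, states=states,
                      division_times=np.array(div_times))
    return LineageTrace(records=records, mu=mu), traj


def interdivision_stats(trace: LineageTrace,
                        discard: int = 2) -> InterdivisionStats:
    """Cycle-time and size statistics over the lineage, transients removed.

    The first ``discard`` completed cycles are dropped; at least three must
    remain.  Cycle durations are the intervals between successive divisions.
    """
    durations = np.array([r.cycle_duration for r in trace.records])
    durations = durations[np.isfinite(durations)]
    if len(durations) - discard < 3:
        raise ValueError(
            f"need >= {discard + 3} completed cycles, have {len(durations)}")
    keep = slice(discard, None)
    d = durations[keep]
    vb = trace.v_at_birth[1:][keep]     # births that start a completed cycle
    vd = trace.v_at_division[1:][keep]
    return InterdivisionStats(
        n_cycles=len(d),
        mean_cycle_min=float(d.mean()),
        cv_cycle=float(d.std() / d.mean()),
        mean_birth_size=float(vb.mean()),
        mean_division_size=float(vd.mean()),
    )
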