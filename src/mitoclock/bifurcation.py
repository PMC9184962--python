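"""Steady-state branches, stability, pseudo-nullclines and bifurcations.

The continuation machinery is native: pseudo-arclength continuation with a
secant predictor and damped-Newton corrector, adequate for the dimension
(<= 7) of the cell-cycle models.  Jacobians are central finite differences.
Folds are detected by a sign change of the parameter component of the branch
tangent and refined by bisection; Hopf points by a complex-conjugate
eigenvalue pair crossing the imaginary axis.

A *pseudo-nullcline* is the steady-state branch of a reduced system in which
one variable's ODE has been removed and that variable is treated as the
continuation parameter — the projection used throughout the phase-plane
figures of this package.

A fold is classified as a SNIC (saddle-node on an invariant circle) by the
period-divergence signature: stable oscillations exist just beyond the fold
on the side where the steady state vanishes, and their period grows
monotonically and without apparent bound as the parameter approaches the
fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import ModelDefinition, ParameterSet
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, _measure_cycle, _solve

__all__ = [
    "SteadyState",
    "Branch",
    "BranchPoint",
    "NullclineCurve",
    "CycleEnvelope",
    "SnicResult",
    "jacobian",
    "find_steady_states",
    "continue_branch",
    "pseudo_nullcline",
    "classify_snic",
    "cycle_envelope",
    "parameter_rhs",
    "clamped_rhs",
]


# --------------------------------------------------------------------------
# Jacobian and stability
# --------------------------------------------------------------------------

def jacobian(fun: Callable[[np.ndarray], np.ndarray], y: np.ndarray,
             rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``y``.

    Step per component: ``rel_step * max(|y_i|, 1)``.  A symmetric-step
    consistency check (halving the step) guards against an unluckily scaled
    step; the half-step estimate is returned.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(fun(y))):
        raise ValueError("jacobian requested at a state where the model "
                         "right-hand side is not finite")

    def fd(h_scale):
        n = len(y)
        m = len(fun(y))
        J = np.empty((m, n))
        for i in range(n):
            h = h_scale * max(abs(y[i]), 1.0)
            e = np.zeros(n)
            e[i] = h
            J[:, i] = (fun(y + e) - fun(y - e)) / (2.0 * h)
        return J

    J1 = fd(rel_step)
    J2 = fd(0.5 * rel_step)
    scale = max(np.abs(J2).max(), 1e-30)
    if np.abs(J1 - J2).max() > 1e-3 * scale:
        # the coarse step saw curvature; trust the finer one
        J2 = fd(0.25 * rel_step)
    return J2


def model_jacobian(model: ModelDefinition, params: ParameterSet,
                   state) -> np.ndarray:
    """Jacobian of a model right-hand side with respect to the state."""
    return jacobian(lambda y: model.rhs(y, params), np.asarray(state, float))


def _stability(eigs: np.ndarray, tol: float = 0.0) -> str:
    re = eigs.real
    if np.all(re < -tol):
        return "stable focus" if np.any(np.abs(eigs.imag) > 1e-12) else "stable node"
    if np.all(re > tol):
        return "unstable focus" if np.any(np.abs(eigs.imag) > 1e-12) else "unstable node"
    return "saddle"


@dataclass
class SteadyState:
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    residual: float

    @property
    def stable(self) -> bool:
        return self.stability.startswith("stable")


# --------------------------------------------------------------------------
# Damped Newton and steady-state search
# --------------------------------------------------------------------------

def _eval(fun, y):
    """Evaluate fun, mapping domain failures to an infinite residual."""
    try:
        f = np.asarray(fun(y), dtype=float)
    except (FloatingPointError, ValueError, OverflowError):
        return None
    return f if np.all(np.isfinite(f)) else None


def _newton(fun, y0, tol=1e-12, max_iter=60):
    """Damped Newton with simple backtracking; returns (y, ok)."""
    y = np.asarray(y0, dtype=float).copy()
    f = _eval(fun, y)
    if f is None:
        return y, False
    for _ in range(max_iter):
        nf = np.linalg.norm(f)
        if nf < tol:
            return y, True
        try:
            J = jacobian(fun, y)
            step = np.linalg.solve(J, -f)
        except (np.linalg.LinAlgError, ValueError):
            return y, False
        lam = 1.0
        for _ in range(25):
            y_new = y + lam * step
            f_new = _eval(fun, y_new)
            if f_new is not None and np.linalg.norm(f_new) < nf:
                break
            lam *= 0.5
        else:
            return y, False
        y, f = y_new, f_new
    return y, np.linalg.norm(f) < tol


def _default_box(model: ModelDefinition, params: ParameterSet) -> np.ndarray:
    """Upper bounds of the admissible state box from conservation totals."""
    hi = []
    totals = dict(model.conservation)
    bt_cap = (params.ksy_cycb / params.kde1_cycb
              if params.ksy_cycb and params.kde1_cycb else 2.0)
    for name in model.state_names:
        if name in totals:
            hi.append(getattr(params, totals[name]))
        else:   # MPF, CycBT, KinP fallback
            hi.append(bt_cap)
    return np.asarray(hi, dtype=float)


def find_steady_states(model: ModelDefinition, params: ParameterSet,
                       search_grid: np.ndarray | None = None,
                       n_starts: int = 64, seed: int = 0,
                       residual_tol: float = 1e-10,
                       merge_tol: float = 1e-6) -> list[SteadyState]:
    """Root-search for steady states from many starting points.

    Starting points default to a seeded uniform sample of ``n_starts``
    (>= 27) points spanning the admissible state box (bounded by the
    conservation totals and the cyclin-synthesis ceiling ksy/kde1).  Each
    start runs damped Newton; converged roots with residual below
    ``residual_tol`` are merged at distance ``merge_tol`` and classified by
    the eigenvalues of the Jacobian.  An empty list is a legal outcome.
    """
    fun = lambda y: model.rhs(y, params)
    if search_grid is None:
        if n_starts < 27:
            raise ValueError("need at least 27 starting points")
        rng = np.random.default_rng(seed)
        hi = _default_box(model, params)
        search_grid = rng.uniform(0.0, 1.0, (n_starts, len(hi))) * hi
    found: list[SteadyState] = []
    for y0 in np.atleast_2d(search_grid):
        y, ok = _newton(fun, y0)
        if not ok or np.any(y < -1e-9):
            continue
        res = float(np.linalg.norm(fun(y)))
        if res > residual_tol:
            continue
        if any(np.linalg.norm(y - s.state) < merge_tol for s in found):
            continue
        eigs = np.linalg.eigvals(jacobian(fun, y))
        found.append(SteadyState(state=y, eigenvalues=eigs,
                                 stability=_stability(eigs), residual=res))
    found.sort(key=lambda s: tuple(s.state))
    return found


# --------------------------------------------------------------------------
# Pseudo-arclength continuation
# --------------------------------------------------------------------------

@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    kind: str = "regular"       # 'regular' | 'fold' | 'hopf'


@dataclass
class Branch:
    """Continuation curve of steady states against one parameter."""

    param_name: str
    points: list[BranchPoint]
    folds: list[BranchPoint] = field(default_factory=list)
    hopfs: list[BranchPoint] = field(default_factory=list)
    truncated: bool = False
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([p.param for p in self.points])

    def states(self) -> np.ndarray:
        return np.array([p.state for p in self.points])

    def frame(self, state_names: Sequence[str] | None = None) -> pd.DataFrame:
        cols = (list(state_names) if state_names is not None
                else [f"x{i}" for i in range(len(self.points[0].state))])
        rows = []
        for p in self.points:
            rows.append({self.param_name: p.param,
                         **dict(zip(cols, p.state)),
                         "stability": p.stability, "point_type": p.kind})
        for p in self.folds:
            rows.append({self.param_name: p.param,
                         **dict(zip(cols, p.state)),
                         "stability": p.stability, "point_type": "fold"})
        for p in self.hopfs:
            rows.append({self.param_name: p.param,
                         **dict(zip(cols, p.state)),
                         "stability": p.stability, "point_type": "hopf"})
        df = pd.DataFrame(rows).sort_values(self.param_name)
        return df.reset_index(drop=True)


def parameter_rhs(model: ModelDefinition, params: ParameterSet,
                  name: str) -> Callable[[np.ndarray, float], np.ndarray]:
    """rhs as a function of (state, value-of-one-free-parameter)."""
    return lambda y, v: model.rhs(y, params.replace(**{name: v}))


def clamped_rhs(model: ModelDefinition, params: ParameterSet,
                clamp: str) -> tuple[Callable[[np.ndarray, float], np.ndarray],
                                     list[str]]:
    """Reduced rhs with one state variable clamped as a parameter.

    Removes the clamped variable's ODE; the remaining equations see the
    clamped value.  Returns (fun(y_reduced, clamp_value), reduced names).
    """
    idx = model.index(clamp)
    keep = [i for i in range(len(model.state_names)) if i != idx]
    names = [model.state_names[i] for i in keep]

    def fun(y_red, c):
        full = np.empty(len(model.state_names))
        full[keep] = y_red
        full[idx] = c
        return model.rhs(full, params)[keep]

    return fun, names


def _tangent(fun, y, p, z_prev=None, eps=1e-6):
    """Unit tangent (dy, dp) of the branch f(y, p) = 0."""
    Jy = jacobian(lambda yy: fun(yy, p), y)
    hp = eps * max(abs(p), 1.0)
    Jp = (fun(y, p + hp) - fun(y, p - hp)) / (2.0 * hp)
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = Jy
    A[:n, n] = Jp
    A[n] = z_prev if z_prev is not None else np.eye(n + 1)[n]
    b = np.zeros(n + 1)
    b[n] = 1.0
    try:
        z = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        z = np.linalg.lstsq(A, b, rcond=None)[0]
    return z / np.linalg.norm(z), Jy


def _correct(fun, y_pred, p_pred, z, y_ref, p_ref, ds, tol=1e-11, max_iter=12):
    """Newton corrector on [f(y,p); z . ((y,p)-(y_ref,p_ref)) - ds]."""
    n = len(y_pred)
    y, p = y_pred.copy(), p_pred
    for it in range(max_iter):
        f = fun(y, p)
        g = z[:n] @ (y - y_ref) + z[n] * (p - p_ref) - ds
        r = np.append(f, g)
        if np.linalg.norm(r) < tol:
            return y, p, True, it
        Jy = jacobian(lambda yy: fun(yy, p), y)
        hp = 1e-6 * max(abs(p), 1.0)
        Jp = (fun(y, p + hp) - fun(y, p - hp)) / (2.0 * hp)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = Jy
        A[:n, n] = Jp
        A[n, :n] = z[:n]
        A[n, n] = z[n]
        try:
            d = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            return y, p, False, it
        y = y + d[:n]
        p = p + d[n]
    return y, p, False, max_iter


def continue_branch(fun: Callable[[np.ndarray, float], np.ndarray],
                    y0: np.ndarray, p0: float,
                    p_range: tuple[float, float],
                    param_name: str = "param",
                    ds0: float = 1e-3, ds_max: float = 0.02,
                    ds_min: float = 1e-9, max_points: int = 4000,
                    bif_tol: float = 1e-6,
                    state_box: np.ndarray | None = None) -> Branch:
    """Pseudo-arclength continuation of the steady-state branch f(y, p) = 0.

    Starts from a converged root near (y0, p0) and walks toward the far end
    of ``p_range``, around folds if necessary.  Folds are flagged where the
    parameter component of the unit tangent changes sign and refined by
    bisection in arclength to ``bif_tol`` in the parameter; Hopf points
    where the leading complex pair's real part changes sign, refined the
    same way.  If the branch leaves the admissible state box the result is
    truncated and flagged.
    """
    y0 = np.asarray(y0, dtype=float)
    y, ok = _newton(lambda yy: fun(yy, p0), y0)
    if not ok:
        raise ValueError("no steady state found at the start of the range")
    p = p0
    lo, hi = min(p_range), max(p_range)
    direction = 1.0 if (hi - p0) >= (p0 - lo) else -1.0

    z, Jy = _tangent(fun, y, p)
    if z[-1] * direction < 0:
        z = -z
    eigs = np.linalg.eigvals(Jy)
    points = [BranchPoint(p, y.copy(), eigs, _stability(eigs))]
    branch = Branch(param_name=param_name, points=points)

    def pair_re(e):
        """Real part of the complex pair closest to the imaginary axis."""
        cplx = e[np.abs(e.imag) > 1e-9]
        if cplx.size == 0:
            return None
        return float(cplx.real[np.argmin(np.abs(cplx.real))])

    ds = ds0
    while len(points) < max_points:
        prev = points[-1]
        y_pred = prev.state + ds * z[:-1]
        p_pred = prev.param + ds * z[-1]
        y_new, p_new, ok, iters = _correct(fun, y_pred, p_pred, z,
                                           prev.state, prev.param, ds)
        if not ok:
            ds *= 0.4
            if ds < ds_min:
                branch.truncated = True
                branch.message = "corrector failed at minimal step"
                break
            continue
        z_new, Jy = _tangent(fun, y_new, p_new, z_prev=z)
        if z_new @ np.append(y_new - prev.state, p_new - prev.param) < 0:
            z_new = -z_new
        eigs_new = np.linalg.eigvals(Jy)
        pt = BranchPoint(p_new, y_new, eigs_new, _stability(eigs_new))

        # fold: parameter tangent component changes sign
        if z[-1] * z_new[-1] < 0:
            fold = _refine_fold(fun, prev, z, ds, bif_tol)
            if fold is not None:
                fold.kind = "fold"
                branch.folds.append(fold)
        # Hopf: leading complex pair crosses the imaginary axis
        r0, r1 = pair_re(points[-1].eigenvalues), pair_re(eigs_new)
        if r0 is not None and r1 is not None and r0 * r1 < 0:
            hopf = _refine_hopf(fun, prev, z, ds, bif_tol, pair_re)
            if hopf is not None:
                hopf.kind = "hopf"
                branch.hopfs.append(hopf)

        points.append(pt)
        z = z_new
        ds = min(ds * (1.4 if iters <= 3 else 1.0), ds_max)

        if not (lo - 1e-9 <= p_new <= hi + 1e-9):
            break
        if state_box is not None and (np.any(y_new < -1e-6)
                                      or np.any(y_new > state_box + 1e-6)):
            branch.truncated = True
            branch.message = "branch left the admissible state box"
            break
    else:
        branch.truncated = True
        branch.message = "max_points reached"
    return branch


def _step_from(fun, pt, z, ds):
    """One corrected arclength step of size ds from branch point pt."""
    y_pred = pt.state + ds * z[:-1]
    p_pred = pt.param + ds * z[-1]
    y, p, ok, _ = _correct(fun, y_pred, p_pred, z, pt.state, pt.param, ds)
    if not ok:
        return None
    z_new, Jy = _tangent(fun, y, p, z_prev=z)
    if z_new @ np.append(y - pt.state, p - pt.param) < 0:
        z_new = -z_new
    return y, p, z_new, Jy


def _refine_fold(fun, pt, z, ds, tol):
    """Bisection in arclength on the tangent's parameter component."""
    a, b = 0.0, ds
    za = z[-1]
    state, param, eigs = pt.state, pt.param, pt.eigenvalues
    for _ in range(80):
        mid = 0.5 * (a + b)
        step = _step_from(fun, pt, z, mid)
        if step is None:
            b = mid
            continue
        y, p, z_new, Jy = step
        if z_new[-1] * za > 0:
            a = mid
        else:
            b = mid
        state, param, eigs = y, p, np.linalg.eigvals(Jy)
        if abs(b - a) < tol:
            break
    return BranchPoint(param, state, eigs, _stability(eigs))


def _refine_hopf(fun, pt, z, ds, tol, pair_re):
    """Bisection in arclength on the leading complex pair's real part."""
    a, b = 0.0, ds
    ra = pair_re(pt.eigenvalues)
    state, param, eigs = pt.state, pt.param, pt.eigenvalues
    for _ in range(80):
        mid = 0.5 * (a + b)
        step = _step_from(fun, pt, z, mid)
        if step is None:
            b = mid
            continue
        y, p, _, Jy = step
        e = np.linalg.eigvals(Jy)
        r = pair_re(e)
        if r is None or ra is None or r * ra > 0:
            a = mid
        else:
            b = mid
        state, param, eigs = y, p, e
        if abs(b - a) < tol:
            break
    return BranchPoint(param, state, eigs, _stability(eigs))


# --------------------------------------------------------------------------
# Pseudo-nullclines
# --------------------------------------------------------------------------

@dataclass
class NullclineCurve:
    """Steady-state branch of a one-variable-clamped reduced system."""

    clamp_name: str
    response_name: str
    clamp_values: np.ndarray
    response_values: np.ndarray
    states: np.ndarray                  # reduced-system states, row per point
    state_names: tuple[str, ...]
    folds: list[tuple[float, float]]    # (clamp value, response value)
    shape: str                          # 'monotone' | 'S' | 'Z' | 'complex'
    complete: bool = True
    message: str = ""

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, self.clamp_name, self.clamp_values)
        return df


def _classify_shape(n_folds: int, increasing: bool) -> str:
    if n_folds == 0:
        return "monotone"
    if n_folds == 2:
        return "S" if increasing else "Z"
    return "complex"


def pseudo_nullcline(model: ModelDefinition, params: ParameterSet,
                     clamp: str, clamp_range: tuple[float, float],
                     n_steps: int = 400, response: str | None = None,
                     x0=None, **cont_kw) -> NullclineCurve:
    """Continue the steady states of the reduced system over the clamped
    variable, i.e. the pseudo-nullcline of the *response* variable.

    The clamped variable's ODE is removed and its value is the continuation
    parameter.  The branch starts from the steady state reached by the
    reduced dynamics at the low end of ``clamp_range``.  With two folds the
    curve is classified 'S' (response increasing with the clamp) or 'Z'
    (decreasing); note an S-shaped branch appears N-shaped when the plot
    puts the response on the abscissa.
    """
    fun, names = clamped_rhs(model, params, clamp)
    if response is None:
        response = "MPF" if "MPF" in names else names[0]
    r_idx = names.index(response)
    c0, c1 = clamp_range
    if x0 is None:
        # settle the reduced dynamics at the low end to find the first root
        sol = _solve(lambda t, y: fun(y, c0), (0.0, 4000.0),
                     np.zeros(len(names)), DEFAULT_RTOL, DEFAULT_ATOL,
                     "LSODA", dense=False)
        x0 = sol.y[:, -1]
    span = abs(c1 - c0)
    cont_kw.setdefault("ds0", span / (4 * n_steps))
    cont_kw.setdefault("ds_max", span / n_steps)
    branch = continue_branch(fun, np.asarray(x0, float), c0, (c0, c1),
                             param_name=clamp, **cont_kw)
    cv = branch.params
    st = branch.states()
    rv = st[:, r_idx]
    folds = [(f.param, f.state[r_idx]) for f in branch.folds]
    increasing = rv[-1] >= rv[0]
    reached = cv.max() >= max(c0, c1) - 1e-6
    return NullclineCurve(
        clamp_name=clamp, response_name=response, clamp_values=cv,
        response_values=rv, states=st, state_names=tuple(names),
        folds=folds, shape=_classify_shape(len(folds), increasing),
        complete=reached and not branch.truncated,
        message=branch.message)


# --------------------------------------------------------------------------
# Limit-cycle envelope and SNIC classification
# --------------------------------------------------------------------------

@dataclass
class CycleEnvelope:
    """Per parameter value: oscillation flag, MPF extrema and period."""

    param_name: str
    values: np.ndarray
    oscillatory: np.ndarray
    mpf_max: np.ndarray
    mpf_min: np.ndarray
    period: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.param_name: self.values,
                             "oscillatory": self.oscillatory,
                             "MPF_max": self.mpf_max,
                             "MPF_min": self.mpf_min,
                             "period_min": self.period})


def _probe_cycle(fun, x0, mpf_index, max_time=4000.0, transient=None,
                 min_peaks=4, osc_tol=1e-3):
    """(period, mpf_min, mpf_max) of the attractor of y' = fun(y, .)."""
    sol = _solve(lambda t, y: fun(y), (0.0, max_time), np.asarray(x0, float),
                 DEFAULT_RTOL, DEFAULT_ATOL, "LSODA")
    t0 = 0.25 * max_time if transient is None else transient
    peaks, osc = _measure_cycle(sol.sol, t0, max_time, mpf_index, osc_tol)
    tt = np.linspace(t0, max_time, 8000)
    m = sol.sol(tt)[mpf_index]
    if not osc or len(peaks) < min_peaks:
        return None, float(m[-1]), float(m[-1])
    return float(np.diff(peaks).mean()), float(m.min()), float(m.max())


def cycle_envelope(fun: Callable[[np.ndarray, float], np.ndarray],
                   values: Sequence[float], x0, mpf_index: int,
                   param_name: str = "param", max_time: float = 4000.0,
                   ) -> CycleEnvelope:
    """Brute-force oscillation envelope: integrate at each parameter value,
    measure the MPF extrema and period of the attractor (if periodic)."""
    values = np.asarray(values, dtype=float)
    osc = np.zeros(len(values), dtype=bool)
    mmax = np.full(len(values), np.nan)
    mmin = np.full(len(values), np.nan)
    per = np.full(len(values), np.nan)
    for i, v in enumerate(values):
        p_, lo_, hi_ = _probe_cycle(lambda y: fun(y, v), x0, mpf_index,
                                    max_time=max_time)
        osc[i] = p_ is not None
        mmin[i], mmax[i] = lo_, hi_
        per[i] = p_ if p_ is not None else np.nan
    return CycleEnvelope(param_name, values, osc, mmax, mmin, per)


@dataclass
class SnicResult:
    kind: str                   # 'SNIC' | 'fold' | 'inconclusive'
    fold_param: float
    probe_params: np.ndarray
    probe_periods: np.ndarray
    far_period: float | None
    divergence_ratio: float | None


def classify_snic(fun: Callable[[np.ndarray, float], np.ndarray],
                  fold_param: float, side: int, x0, mpf_index: int,
                  far_param: float, rel_offsets=(0.25, 0.08, 0.025, 0.008),
                  period_factor: float = 5.0,
                  max_time: float = 8000.0) -> SnicResult:
    """Decide whether a fold is a saddle-node on an invariant circle.

    Probes the attractor at parameter values approaching the fold from the
    side (``side`` = +1 or -1) on which the steady state has vanished.  The
    fold is a SNIC when stable oscillations exist at every probe, their
    period increases monotonically toward the fold, and the period closest
    to the fold exceeds ``period_factor`` times the far-field period.  A
    fold with no nearby oscillation is 'fold'; a failed probe is
    'inconclusive'.
    """
    scale = abs(far_param - fold_param)
    probes = np.array([fold_param + side * r * scale for r in rel_offsets])
    far_period, _, _ = _probe_cycle(lambda y: fun(y, far_param), x0,
                                    mpf_index, max_time=max_time)
    periods = []
    for v in probes:
        p_, _, _ = _probe_cycle(lambda y: fun(y, v), x0, mpf_index,
                                max_time=max_time)
        periods.append(p_ if p_ is not None else np.nan)
    periods = np.array(periods, dtype=float)
    if far_period is None or np.isnan(periods).all():
        return SnicResult("fold", fold_param, probes, periods, far_period, None)
    if np.isnan(periods).any():
        return SnicResult("inconclusive", fold_param, probes, periods,
                          far_period, None)
    ratio = float(periods[-1] / far_period)
    monotone = bool(np.all(np.diff(periods) > 0))
    kind = "SNIC" if (monotone and ratio > period_factor) else "fold"
    return SnicResult(kind, fold_param, probes, periods, far_period, ratio)
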